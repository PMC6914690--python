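"""A fully planted cross-species scenario for demonstrations and validation.

One call builds every pipeline input with known ground truth: an RI panel
with a trait controlled by one causal marker, a mouse annotation with a gene
sitting on that marker, human homologs (one-to-many included), an LD panel
with block structure inside each human gene, GWAS summary statistics whose
only true signal sits in the homolog of the causal-locus mouse gene, an
expression matrix with a coexpression module sharing a cis-eQTL at the causal
marker, and a disease catalog enriched for the module.  Running the pipeline
on these inputs should recover the planted homolog as the unique
Bonferroni-significant candidate and the module's catalog enrichment.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .pipeline import PipelineConfig, derive_seed
from .simdata import (
    CisEffect,
    LDBlock,
    ModuleSpec,
    _block_haplotypes,
    simulate_expression,
    simulate_gwas_summary,
    simulate_ri_genotypes,
    simulate_trait,
    uniform_marker_map,
)
from .types import (
    ExpressionMatrix,
    GeneAnnotation,
    GWASSummary,
    HomologyMap,
    LDReference,
    QTLSpec,
    StrainGenotypes,
)

__all__ = ["ScenarioConfig", "PlantedScenario", "build_scenario", "write_scenario"]


@dataclass
class ScenarioConfig:
    """Sizes and effect settings for the planted scenario.

    Defaults give an 80-strain panel mapped at 2 cM density (the typical
    power regime for a two-founder RI family), a causal marker explaining
    half the strain-mean variance, LD blocks of 8 SNPs at rho 0.6 inside
    each human gene, and a noncentrality of 6 at the planted GWAS SNP.
    """

    n_strains: int = 80
    chrom_length_cM: float = 60.0
    spacing_cM: float = 2.0
    h2: float = 0.5
    effect: float = 1.0
    snps_per_gene: int = 8
    ld_rho: float = 0.6
    n_ld_individuals: int = 300
    gwas_lambda: float = 6.0
    n_module_genes: int = 12
    n_background_genes: int = 60
    module_loading: float = 1.0
    module_noise_sd: float = 0.5
    cis_effect: float = 0.8


@dataclass
class PlantedScenario:
    """All pipeline inputs plus the planted ground truth."""

    genotypes: StrainGenotypes
    traits: pd.DataFrame
    gwas: GWASSummary
    ld_panel: LDReference
    mouse_genes: GeneAnnotation
    human_genes_Mb: GeneAnnotation
    human_genes_bp: GeneAnnotation
    homology: HomologyMap
    expression: "pd.DataFrame | None"
    catalog: pd.DataFrame
    causal_marker: str
    target_mouse_gene: str
    target_human_gene: str
    seed_gene: str
    module_members: list = field(default_factory=list)


# Mouse gene layout: (gene_id, symbol, chrom, start_Mb, end_Mb).  One gene
# (MG05) straddles the causal marker at 30 Mb on chromosome 2.
_MOUSE_GENES = [
    ("MG01", "GeneA", "2", 9.9, 10.1),
    ("MG02", "GeneB", "2", 19.9, 20.1),
    ("MG03", "GeneC", "2", 26.9, 27.1),
    ("MG05", "GeneE", "2", 29.9, 30.1),
    ("MG06", "GeneF", "2", 33.9, 34.1),
    ("MG07", "GeneG", "2", 44.9, 45.1),
    ("MG08", "GeneH", "19", 9.9, 10.1),
    ("MG09", "GeneI", "19", 24.9, 25.1),
    ("MG10", "GeneJ", "19", 39.9, 40.1),
    ("MG11", "GeneK", "19", 54.9, 55.1),
]

# MG03 has two human homologs (a paralog split); MG11 has none.
_HOMOLOGY = [
    ("MG01", "HG01"), ("MG02", "HG02"), ("MG03", "HG03"), ("MG03", "HG03B"),
    ("MG05", "HG05"), ("MG06", "HG06"), ("MG07", "HG07"), ("MG08", "HG08"),
    ("MG09", "HG09"), ("MG10", "HG10"),
]


def build_scenario(seed: int, cfg: ScenarioConfig | None = None) -> PlantedScenario:
    """Simulate every input with the planted signal chain wired together."""
    cfg = cfg or ScenarioConfig()
    marker_map = uniform_marker_map(
        n_chrom=2,
        chrom_length_cM=cfg.chrom_length_cM,
        spacing_cM=cfg.spacing_cM,
        Mb_per_cM=1.0,
    )
    # rename chromosomes 1/2 -> 2/19 to mirror a two-chromosome mouse scan
    marker_map.table["chrom"] = marker_map.table["chrom"].map({"1": "2", "2": "19"})
    geno = simulate_ri_genotypes(
        cfg.n_strains, marker_map, seed=derive_seed(seed, "genotypes")
    )
    dist = np.abs(marker_map.table["pos_cM"].to_numpy() - cfg.chrom_length_cM / 2)
    dist[marker_map.table["chrom"].to_numpy() != "2"] = np.inf
    causal_idx = int(np.argmin(dist))
    causal_marker = str(marker_map.table.at[causal_idx, "marker_id"])
    trait = simulate_trait(
        geno,
        QTLSpec(marker_id=causal_marker, a=cfg.effect, h2=cfg.h2),
        seed=derive_seed(seed, "trait"),
    )
    traits = trait.to_frame(name="ppi_trait")

    mouse = GeneAnnotation(
        pd.DataFrame(
            _MOUSE_GENES, columns=["gene_id", "symbol", "chrom", "start", "end"]
        ),
        species="mouse",
        units="Mb",
    )
    homology = HomologyMap(
        pd.DataFrame(_HOMOLOGY, columns=["mouse_gene_id", "human_gene_id"])
    )
    human_ids = sorted(set(h for _, h in _HOMOLOGY))
    # human genes tiled on chromosome 10, 20 kb bodies spaced 50 kb apart
    h_rows = []
    for i, hid in enumerate(human_ids):
        start = 1_000_000 + i * 50_000
        h_rows.append(
            {
                "gene_id": hid,
                "symbol": hid,
                "chrom": "10",
                "start": start,
                "end": start + 20_000,
            }
        )
    human_bp = GeneAnnotation(pd.DataFrame(h_rows), species="human", units="bp")
    h_mb = human_bp.table.copy()
    h_mb[["start", "end"]] = h_mb[["start", "end"]] / 1e6
    human_mb = GeneAnnotation(h_mb, species="human", units="Mb")
    homology.validate_against(mouse, human_bp)

    # LD panel: one AR(1) block per human gene, SNPs spread inside the body
    rng = np.random.default_rng(derive_seed(seed, "ld_panel"))
    blocks = [
        LDBlock(n_snps=cfg.snps_per_gene, rho=cfg.ld_rho) for _ in human_ids
    ]
    haps = np.concatenate(
        [_block_haplotypes(rng, 2 * cfg.n_ld_individuals, b) for b in blocks], axis=1
    )
    dosages = haps[: cfg.n_ld_individuals] + haps[cfg.n_ld_individuals :]
    snp_ids, snp_pos = [], []
    for i, hid in enumerate(human_ids):
        g = human_bp.table.iloc[i]
        pos = np.linspace(g["start"] + 500, g["end"] - 500, cfg.snps_per_gene)
        for j in range(cfg.snps_per_gene):
            snp_ids.append(f"rs_{hid}_{j + 1}")
            snp_pos.append(int(pos[j]))
    panel = LDReference(
        snp_ids=np.array(snp_ids),
        chrom=np.full(len(snp_ids), "10"),
        pos_bp=np.array(snp_pos),
        dosages=dosages.astype(np.int64),
    )

    target_mouse = "MG05"
    target_human = sorted(
        homology.pairs.loc[homology.pairs["mouse_gene_id"] == target_mouse,
                           "human_gene_id"]
    )[0]
    planted_snp = f"rs_{target_human}_{cfg.snps_per_gene // 2}"
    gwas = simulate_gwas_summary(
        panel,
        human_bp,
        causal_spec={planted_snp: cfg.gwas_lambda},
        seed=derive_seed(seed, "gwas"),
    )

    # expression: a coexpression module sharing a cis-eQTL at the causal marker
    module_members = [f"EX_M{i + 1:02d}" for i in range(cfg.n_module_genes)]
    seed_gene = module_members[0]
    background = [f"EX_B{i + 1:03d}" for i in range(cfg.n_background_genes)]
    expr = simulate_expression(
        geno,
        [
            ModuleSpec(
                members=module_members,
                loading=cfg.module_loading,
                noise_sd=cfg.module_noise_sd,
                cis_effects=[
                    CisEffect(
                        gene_id=seed_gene,
                        marker_id=causal_marker,
                        effect=cfg.cis_effect,
                    )
                ],
            )
        ],
        seed=derive_seed(seed, "expression"),
        extra_genes=background,
    )

    # disease catalog: half the module plus a slice of the background,
    # with some multi-gene rows as association catalogs have
    disease = module_members[: cfg.n_module_genes // 2] + background[:10]
    cat_rows = []
    for i in range(0, len(disease), 2):
        cat_rows.append(
            {
                "association_id": f"ASSOC{i // 2 + 1:03d}",
                "mapped_genes": ", ".join(disease[i : i + 2]),
            }
        )
    catalog = pd.DataFrame(cat_rows)

    return PlantedScenario(
        genotypes=geno,
        traits=traits,
        gwas=gwas,
        ld_panel=panel,
        mouse_genes=mouse,
        human_genes_Mb=human_mb,
        human_genes_bp=human_bp,
        homology=homology,
        expression=expr.values,
        catalog=catalog,
        causal_marker=causal_marker,
        target_mouse_gene=target_mouse,
        target_human_gene=target_human,
        seed_gene=seed_gene,
        module_members=module_members,
    )


def write_scenario(
    scn: PlantedScenario,
    directory: str | Path,
    seed: int = 1,
    n_perm_qtl: int = 5000,
    n_perm_enrich: int = 10_000,
) -> Path:
    """Write every input table plus a ready-to-run YAML pipeline config.

    Returns the config path; ``xqtl run-all -c <config>`` (or
    :func:`xqtl.pipeline.run_all`) consumes it directly.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _io.write_genotypes(scn.genotypes, d / "genotypes.tsv")
    _io.write_traits(scn.traits, d / "traits.tsv")
    _io.write_gwas_summary(scn.gwas, d / "gwas.tsv")
    _io.write_ld_panel(scn.ld_panel, d / "ld_panel.tsv")
    _io.write_annotation(scn.mouse_genes, d / "mouse_genes.tsv")
    _io.write_annotation(scn.human_genes_bp, d / "human_genes_bp.tsv")
    _io.write_homology(scn.homology, d / "homology.tsv")
    if scn.expression is not None:
        _io.write_expression(ExpressionMatrix(scn.expression), d / "expression.tsv")
    _io.write_catalog(scn.catalog, d / "catalog.tsv")
    cfg = {
        "genotypes": "genotypes.tsv",
        "traits": "traits.tsv",
        "gwas": "gwas.tsv",
        "ld_panel": "ld_panel.tsv",
        "mouse_genes": "mouse_genes.tsv",
        "human_genes_bp": "human_genes_bp.tsv",
        "homology": "homology.tsv",
        "expression": "expression.tsv" if scn.expression is not None else None,
        "catalog": "catalog.tsv",
        "coexpr_seed_gene": scn.seed_gene,
        "out_dir": "out",
        "seed": seed,
        "n_perm_qtl": n_perm_qtl,
        "n_perm_enrich": n_perm_enrich,
    }
    cfg_path = d / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return cfg_path
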