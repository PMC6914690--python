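"""End-to-end orchestration: configuration, stage seeding, and run_all.

The pipeline chains the five analysis stages in the order the science
dictates — QTL scan with permutation threshold, LOD-drop support intervals,
interval-to-gene intersection, homolog mapping, gene-based GWAS (GATES),
Bonferroni selection, coexpression screening, and disease-gene enrichment —
writing each stage's table before the next begins.  A single master seed
determines every stage's randomness: stage seeds are derived by hashing the
stage name with the master seed, so adding a stage never perturbs another's
random stream.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpr as _coexpr
from . import enrich as _enrich
from . import gates as _gates
from . import integrate as _integrate
from . import io as _io
from . import qtl as _qtl
from .types import GeneAnnotation, QTLInterval

__all__ = ["PipelineConfig", "RunReport", "derive_seed", "load_config", "run_all"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed: SHA-256 of 'master:stage', reduced below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Input paths and stage parameters for a full run.

    Paths are resolved relative to the config file's directory when loaded
    from YAML.  Defaults mirror the study's stated constants: 5,000 QTL
    permutations at alpha 0.05, a 1.5-LOD support interval, coexpression
    thresholds r >= 0.5 / p <= 0.05, and 100,000 enrichment permutations.
    """

    genotypes: str
    traits: str
    gwas: str
    ld_panel: str
    mouse_genes: str  # Mb-unit annotation
    human_genes_bp: str  # bp-unit annotation for SNP assignment
    homology: str
    expression: str | None = None
    catalog: str | None = None
    coexpr_seed_gene: str | None = None
    out_dir: str = "xqtl_out"
    seed: int = 1
    n_perm_qtl: int = 5000
    alpha: float = 0.05
    drop_lod: float = 1.5
    r_thresh: float = 0.5
    p_thresh: float = 0.05
    n_perm_enrich: int = 100_000
    window_kb: float = 0.0
    cis_window_Mb: float = 5.0
    ld_transform: str = "polynomial"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 0.5):
            raise ValueError("alpha must be in (0, 0.5]")
        if self.n_perm_qtl < 100:
            raise ValueError("n_perm_qtl must be >= 100")
        if self.drop_lod <= 0:
            raise ValueError("drop_lod must be positive")


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "seed" not in raw:
        raise ValueError(f"{path}: config must state a seed")
    base = path.parent
    cfg = PipelineConfig(**raw)
    for name in (
        "genotypes", "traits", "gwas", "ld_panel", "mouse_genes",
        "human_genes_bp", "homology", "expression", "catalog",
    ):
        val = getattr(cfg, name)
        if val is not None and not Path(val).is_absolute():
            setattr(cfg, name, str(base / val))
    if not Path(cfg.out_dir).is_absolute():
        cfg.out_dir = str(base / cfg.out_dir)
    return cfg


@dataclass
class RunReport:
    """Audit trail of a run: parameters, per-stage row counts, file digests."""

    parameters: dict
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)

    def log(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, **info})

    def checksum(self, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.checksums[Path(path).name] = digest

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "parameters": self.parameters,
                    "stages": self.stages,
                    "warnings": self.warnings,
                    "checksums": self.checksums,
                },
                fh,
                indent=2,
                default=str,
            )


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_all(cfg: PipelineConfig) -> RunReport:
    """Execute the full cross-species pipeline and write stage outputs.

    Any stage failure propagates tagged with the stage name, after the report
    collected so far is written to ``run_report.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(parameters=asdict(cfg))
    try:
        _run_stages(cfg, out, report)
    except Exception as e:
        report.warnings.append(f"aborted: {type(e).__name__}: {e}")
        report.write(out / "run_report.json")
        raise RuntimeError(f"pipeline stage failed: {e}") from e
    report.write(out / "run_report.json")
    return report


def _run_stages(cfg: PipelineConfig, out: Path, report: RunReport) -> None:
    geno = _io.read_genotypes(cfg.genotypes)
    traits = _io.read_traits(cfg.traits)
    gwas = _io.read_gwas_summary(cfg.gwas)
    panel = _io.read_ld_panel(cfg.ld_panel)
    mouse_genes = _io.read_annotation(cfg.mouse_genes)
    human_genes_bp = _io.read_annotation(cfg.human_genes_bp)
    homology = _io.read_homology(cfg.homology)
    report.log(
        "load",
        n_strains=geno.n_strains,
        n_markers=geno.markers.n_markers,
        n_traits=traits.shape[1],
        n_snps=len(gwas.table),
        n_mouse_genes=len(mouse_genes.table),
        n_human_genes=len(human_genes_bp.table),
    )

    # --- QTL scans, thresholds, intervals -------------------------------
    intervals: list[tuple[str, QTLInterval]] = []
    for trait_id in traits.columns:
        trait = traits[trait_id].dropna()
        scan = _qtl.marker_regression_scan(trait, geno, trait_id=trait_id)
        thr = _qtl.permutation_threshold(
            trait,
            geno,
            n_perm=cfg.n_perm_qtl,
            alpha=cfg.alpha,
            seed=derive_seed(cfg.seed, f"qtl_perm:{trait_id}"),
        )
        scan_path = out / f"scan_{trait_id}.tsv"
        _fmt(scan.table, scan_path)
        report.checksum(scan_path)
        with open(out / f"threshold_{trait_id}.json", "w") as fh:
            json.dump(
                {
                    "trait": trait_id,
                    "alpha": thr.alpha,
                    "n_perm": thr.n_perm,
                    "threshold_LRS": thr.threshold_lrs,
                },
                fh,
                indent=2,
            )
        peak = scan.peak()
        significant = bool(peak["LRS"] >= thr.threshold_lrs)
        report.log(
            "qtl",
            trait=trait_id,
            peak_marker=peak["marker"],
            peak_LRS=float(peak["LRS"]),
            threshold_LRS=thr.threshold_lrs,
            significant=significant,
        )
        if significant:
            chrom_scan = scan.table[scan.table["chrom"] == peak["chrom"]]
            chrom_peak = chrom_scan.loc[chrom_scan["LRS"].idxmax(), "marker"]
            iv = _qtl.support_interval(scan, chrom_peak, drop_lod=cfg.drop_lod)
            intervals.append((trait_id, iv))

    # --- interval genes and homologs -------------------------------------
    candidates = []
    for trait_id, iv in intervals:
        mg = _integrate.genes_in_interval(mouse_genes, iv)
        report.log(
            "interval",
            trait=trait_id,
            chrom=iv.chrom,
            start_Mb=iv.start_Mb,
            end_Mb=iv.end_Mb,
            n_mouse_genes=len(mg),
        )
        for m in mg:
            for h in _integrate.map_homologs([m], homology):
                candidates.append(
                    {"trait_id": trait_id, "mouse_gene": m, "human_gene": h}
                )
    candidates = pd.DataFrame(
        candidates, columns=["trait_id", "mouse_gene", "human_gene"]
    ).drop_duplicates(ignore_index=True)

    # --- gene-based GWAS and Bonferroni selection -------------------------
    genebased = _gates.gene_based_scan(
        gwas,
        panel,
        human_genes_bp,
        window_kb=cfg.window_kb,
        transform=cfg.ld_transform,
    )
    _fmt(genebased, out / "genebased.tsv")
    report.checksum(out / "genebased.tsv")
    report.log("gates", n_genes_tested=len(genebased))

    if len(candidates):
        table = _integrate.bonferroni_select(candidates, genebased, alpha=cfg.alpha)
        pos = human_genes_bp.table.set_index("gene_id")
        table["human_position"] = table["human_gene"].map(
            lambda g: f"{pos.at[g, 'chrom']}:{pos.at[g, 'start']}-{pos.at[g, 'end']}"
            if g in pos.index
            else ""
        )
    else:
        report.warnings.append("no significant QTL: candidate table is empty")
        table = candidates.assign(
            p_gates=pd.Series(dtype=float),
            n_homologs_tested=pd.Series(dtype=int),
            bonferroni_threshold=pd.Series(dtype=float),
            nominal=pd.Series(dtype=bool),
            corrected=pd.Series(dtype=bool),
            human_position=pd.Series(dtype=str),
        )
    _fmt(table, out / "candidates.tsv")
    report.checksum(out / "candidates.tsv")
    report.log(
        "integrate",
        n_candidates=len(table),
        n_corrected=int(table["corrected"].sum()) if len(table) else 0,
    )

    # --- coexpression and enrichment (optional inputs) --------------------
    if cfg.expression and cfg.coexpr_seed_gene:
        expr = _io.read_expression(cfg.expression)
        corr = _coexpr.correlate_seed(expr, cfg.coexpr_seed_gene)
        cset = _coexpr.screen(
            corr, r_thresh=cfg.r_thresh, p_thresh=cfg.p_thresh,
            seed_id=cfg.coexpr_seed_gene,
        )
        coexpr_table = corr.loc[cset.members].reset_index()
        _fmt(coexpr_table, out / "coexpr.tsv")
        report.checksum(out / "coexpr.tsv")
        report.log("coexpr", seed_gene=cfg.coexpr_seed_gene, n_members=len(cset.members))
        if cfg.catalog:
            catalog = _io.read_catalog(cfg.catalog)
            disease = _io.catalog_genes(catalog)
            background = expr.values.index.tolist()
            res = _enrich.enrichment_test(
                cset.members,
                disease,
                background,
                n_perm=cfg.n_perm_enrich,
                seed=derive_seed(cfg.seed, "enrich"),
            )
            enr = pd.DataFrame(
                [
                    {
                        "seed_gene": cfg.coexpr_seed_gene,
                        "empirical_p": res.render_empirical(),
                        "smoothed_p": res.smoothed_p,
                        "hypergeom_p": res.hypergeom_p,
                        "overlap": res.observed_overlap,
                        "n_coexpressed": res.set_size,
                        "n_disease_in_background": res.disease_in_background,
                        "background": res.background_size,
                        "n_perm": res.n_perm,
                    }
                ]
            )
            _fmt(enr, out / "enrichment.tsv")
            report.checksum(out / "enrichment.tsv")
            report.log(
                "enrich",
                overlap=res.observed_overlap,
                smoothed_p=res.smoothed_p,
                hypergeom_p=res.hypergeom_p,
            )
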