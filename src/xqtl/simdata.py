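"""Synthetic data generators for every pipeline input.

The generators reproduce the statistical structure the analysis assumes —
recombinant-inbred genotype mosaics with map expansion, strain-mean traits
with a planted QTL at a stated heritability, LD-blocked GWAS z-scores,
expression matrices with latent coexpression modules and cis-eQTL, and
annotation/homology tables with one-to-many homologs — so the whole pipeline
is testable without any external download.  All randomness flows through
:class:`numpy.random.Generator` seeded explicitly; same seed and configuration
give identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    ALLELE_CODE,
    ExpressionMatrix,
    GeneAnnotation,
    GWASSummary,
    HomologyMap,
    LDReference,
    MarkerMap,
    QTLSpec,
    StrainGenotypes,
)

__all__ = [
    "haldane_recomb_fraction",
    "ri_expansion",
    "uniform_marker_map",
    "simulate_ri_genotypes",
    "simulate_trait",
    "LDBlock",
    "simulate_ld_panel",
    "simulate_gwas_summary",
    "ModuleSpec",
    "CisEffect",
    "simulate_expression",
    "AnnotationConfig",
    "simulate_annotation_homology",
]


def haldane_recomb_fraction(d_morgans: np.ndarray | float) -> np.ndarray | float:
    """Map distance (Morgans) -> recombination fraction, no interference.

    r = (1 - exp(-2d)) / 2.
    """
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_morgans, float)))


def ri_expansion(r: np.ndarray | float, mating: str = "sib") -> np.ndarray | float:
    """Expand a per-meiosis recombination fraction for a recombinant-inbred panel.

    Repeated inbreeding accumulates recombinations, so adjacent markers in the
    finished lines recombine more often than in a single meiosis.  For panels
    fixed by sib-mating (the usual two-founder mouse design) the expansion is
    R = 4r / (1 + 6r); for selfing it is R = 2r / (1 + 2r).
    """
    r = np.asarray(r, float)
    if mating == "sib":
        return 4.0 * r / (1.0 + 6.0 * r)
    if mating == "selfing":
        return 2.0 * r / (1.0 + 2.0 * r)
    raise ValueError(f"unknown mating system {mating!r}")


def uniform_marker_map(
    n_chrom: int = 2,
    chrom_length_cM: float = 80.0,
    spacing_cM: float = 2.0,
    Mb_per_cM: float = 2.0,
) -> MarkerMap:
    """Evenly spaced marker map (default one marker per 2 cM) on named
    chromosomes 1..n, with physical positions at a fixed Mb/cM ratio."""
    rows = []
    n_per = int(np.floor(chrom_length_cM / spacing_cM)) + 1
    for c in range(1, n_chrom + 1):
        for i in range(n_per):
            cm = i * spacing_cM
            rows.append(
                {
                    "marker_id": f"m{c}_{i:03d}",
                    "chrom": str(c),
                    "pos_cM": cm,
                    "pos_Mb": cm * Mb_per_cM,
                }
            )
    return MarkerMap(pd.DataFrame(rows))


def simulate_ri_genotypes(
    n_strains: int,
    marker_map: MarkerMap,
    seed: int,
    mating: str = "sib",
    strain_prefix: str = "BXD",
) -> StrainGenotypes:
    """Draw fully inbred two-founder strains as first-order Markov mosaics.

    Each strain and chromosome starts from a fair coin on the founder allele;
    successive markers switch founder with probability R obtained by the
    Haldane map function followed by the RI expansion for the chosen mating
    system.  All calls are homozygous (coded B/D).
    """
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    tbl = marker_map.table
    rng = np.random.default_rng(seed)
    n_markers = marker_map.n_markers
    calls = np.empty((n_strains, n_markers), dtype="<U1")
    col = 0
    for chrom, sub in tbl.groupby("chrom", sort=False):
        cm = sub["pos_cM"].to_numpy(float)
        d = np.diff(cm) / 100.0  # Morgans
        R = np.asarray(ri_expansion(haldane_recomb_fraction(d), mating), float)
        m = len(cm)
        # state 0 = B allele, 1 = D allele
        state = rng.integers(0, 2, size=n_strains)
        block = np.empty((n_strains, m), dtype=np.int64)
        block[:, 0] = state
        if m > 1:
            flips = rng.random((n_strains, m - 1)) < R[None, :]
            block[:, 1:] = flips
            np.cumsum(block, axis=1, out=block)
            block &= 1  # parity of initial state + flips
        calls[:, col : col + m] = np.where(block == 1, "D", "B")
        col += m
    strains = [f"{strain_prefix}{i + 1:03d}" for i in range(n_strains)]
    return StrainGenotypes(strains=strains, markers=marker_map, calls=calls)


def simulate_trait(
    genotypes: StrainGenotypes,
    qtl_spec: QTLSpec,
    seed: int,
    noise_sd: float = 1.0,
) -> pd.Series:
    """Strain-mean trait y = a*g + e with the causal marker explaining h2.

    The environmental variance is set from the realized genotype variance so
    that a^2 Var(g) / (a^2 Var(g) + sigma_e^2) = h2.  With h2 = 0 the trait is
    pure Gaussian noise at ``noise_sd`` (the genetic term is dropped).
    """
    rng = np.random.default_rng(seed)
    ids = genotypes.markers.marker_ids
    idx = np.flatnonzero(ids == qtl_spec.marker_id)
    if idx.size == 0:
        raise KeyError(f"causal marker {qtl_spec.marker_id!r} not in map")
    g = genotypes.additive[:, idx[0]]
    n = genotypes.n_strains
    if qtl_spec.h2 == 0.0 or qtl_spec.a == 0.0:
        y = rng.normal(0.0, noise_sd, size=n)
    else:
        var_g = g.var()
        if var_g == 0.0:
            raise ValueError("causal marker is monomorphic in this panel")
        genetic_var = qtl_spec.a**2 * var_g
        sigma_e = np.sqrt(genetic_var * (1.0 - qtl_spec.h2) / qtl_spec.h2)
        y = qtl_spec.a * g + rng.normal(0.0, sigma_e, size=n)
    return pd.Series(y, index=genotypes.strains, name="trait")


@dataclass(frozen=True)
class LDBlock:
    """One LD block: SNP count and adjacent-SNP haplotype correlation rho."""

    n_snps: int
    rho: float
    maf: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")


def _block_haplotypes(rng: np.random.Generator, n_hap: int, block: LDBlock) -> np.ndarray:
    """AR(1) binary haplotypes: copy the previous allele w.p. rho, else redraw.

    This copy-or-refresh chain has exactly corr(a_i, a_{i+1}) = rho and
    corr(a_i, a_{i+k}) = rho^k for alleles sharing the block's frequency.
    """
    h = np.empty((n_hap, block.n_snps), dtype=np.int8)
    h[:, 0] = rng.random(n_hap) < block.maf
    for j in range(1, block.n_snps):
        copy = rng.random(n_hap) < block.rho
        fresh = rng.random(n_hap) < block.maf
        h[:, j] = np.where(copy, h[:, j - 1], fresh)
    return h


def simulate_ld_panel(
    n_ind: int,
    block_spec: list[LDBlock],
    seed: int,
    chrom: str = "10",
    start_bp: int = 1_000_000,
    spacing_bp: int = 5_000,
) -> LDReference:
    """Diploid LD reference panel with block-structured haplotype correlation.

    Haplotypes are drawn independently per block with AR(1) correlation rho
    inside the block and independence between blocks; dosages are sums of two
    independent haplotypes.  SNPs are laid out left to right at a fixed bp
    spacing on a single chromosome.
    """
    rng = np.random.default_rng(seed)
    hap_blocks = [_block_haplotypes(rng, 2 * n_ind, b) for b in block_spec]
    haps = np.concatenate(hap_blocks, axis=1)
    dosages = haps[:n_ind] + haps[n_ind:]
    n_snps = dosages.shape[1]
    pos = start_bp + spacing_bp * np.arange(n_snps)
    return LDReference(
        snp_ids=np.array([f"rs{i + 1:06d}" for i in range(n_snps)]),
        chrom=np.full(n_snps, chrom),
        pos_bp=pos,
        dosages=dosages.astype(np.int64),
    )


def ld_correlation_matrix(panel: LDReference, ridge: float = 1e-6) -> np.ndarray:
    """Dosage Pearson correlation with monomorphic rows zeroed off-diagonal,
    plus a small diagonal ridge for numerical stability near perfect LD."""
    X = panel.dosages.astype(float)
    sd = X.std(axis=0)
    mono = sd == 0
    Xc = X - X.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Xs = np.where(mono[None, :], 0.0, Xc / np.where(mono, 1.0, sd)[None, :])
    R = (Xs.T @ Xs) / X.shape[0]
    R[mono, :] = 0.0
    R[:, mono] = 0.0
    np.fill_diagonal(R, 1.0)
    return R + ridge * np.eye(R.shape[0])


def simulate_gwas_summary(
    ld_panel: LDReference,
    annotation: GeneAnnotation | None,
    causal_spec: dict[str, float],
    seed: int,
    ridge: float = 1e-6,
) -> GWASSummary:
    """Summary statistics consistent with the panel's LD.

    The z-vector is multivariate normal with mean R @ lambda and covariance R,
    where R is the (ridge-regularized) panel LD correlation and lambda the
    per-SNP noncentrality from ``causal_spec`` (zero elsewhere); two-sided
    p = 2 Phi(-|z|).  Under the global null the p-values are marginally
    Uniform(0, 1).  ``annotation`` is accepted for symmetry with real inputs
    (causal SNPs are usually chosen inside genes) but not otherwise used.
    """
    rng = np.random.default_rng(seed)
    unknown = set(causal_spec) - set(ld_panel.snp_ids.tolist())
    if unknown:
        raise KeyError(f"causal SNPs absent from panel: {sorted(unknown)}")
    R = ld_correlation_matrix(ld_panel, ridge=ridge)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as e:  # pragma: no cover - ridge should prevent
        raise ValueError("LD matrix not positive definite after regularization") from e
    lam = np.zeros(len(ld_panel.snp_ids))
    snp_index = {s: i for i, s in enumerate(ld_panel.snp_ids.tolist())}
    for snp, val in causal_spec.items():
        lam[snp_index[snp]] = val
    z = R @ lam + L @ rng.standard_normal(len(lam))
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {
            "SNP": ld_panel.snp_ids,
            "CHR": ld_panel.chrom,
            "BP": ld_panel.pos_bp,
            "A1": "A",
            "A2": "G",
            "P": p,
        }
    )
    return GWASSummary(table)


@dataclass(frozen=True)
class CisEffect:
    """Planted cis-eQTL: genotype at ``marker_id`` shifts ``gene_id``'s level."""

    gene_id: str
    marker_id: str
    effect: float


@dataclass
class ModuleSpec:
    """One latent coexpression module plus optional planted cis-eQTL."""

    members: list
    loading: float = 1.0
    noise_sd: float = 1.0
    cis_effects: list = field(default_factory=list)


def simulate_expression(
    genotypes: StrainGenotypes,
    module_spec: list[ModuleSpec],
    seed: int,
    extra_genes: list | None = None,
    extra_noise_sd: float = 1.0,
) -> ExpressionMatrix:
    """Expression with latent-factor modules and optional genetic control.

    Module members follow loading * latent + sum(cis effects) + noise with one
    shared standard-normal latent factor per module and per strain; genes in
    ``extra_genes`` are independent noise.  Two members with loading L and
    noise sd s have expected correlation L^2 / (L^2 + s^2).
    """
    rng = np.random.default_rng(seed)
    n = genotypes.n_strains
    marker_index = {m: i for i, m in enumerate(genotypes.markers.marker_ids.tolist())}
    G = genotypes.additive
    rows: dict[str, np.ndarray] = {}
    for spec in module_spec:
        latent = rng.standard_normal(n)
        cis_by_gene: dict[str, np.ndarray] = {}
        for ce in spec.cis_effects:
            if ce.gene_id not in spec.members:
                raise KeyError(f"cis effect targets unknown module gene {ce.gene_id!r}")
            if ce.marker_id not in marker_index:
                raise KeyError(f"cis effect references unknown marker {ce.marker_id!r}")
            g = G[:, marker_index[ce.marker_id]]
            cis_by_gene[ce.gene_id] = cis_by_gene.get(ce.gene_id, 0.0) + ce.effect * g
        for gene in spec.members:
            if gene in rows:
                raise ValueError(f"gene {gene!r} appears in two modules")
            rows[gene] = (
                spec.loading * latent
                + cis_by_gene.get(gene, 0.0)
                + rng.normal(0.0, spec.noise_sd, size=n)
            )
    for gene in extra_genes or []:
        if gene in rows:
            raise ValueError(f"gene {gene!r} both module member and background")
        rows[gene] = rng.normal(0.0, extra_noise_sd, size=n)
    values = pd.DataFrame.from_dict(rows, orient="index", columns=genotypes.strains)
    return ExpressionMatrix(values)


@dataclass
class AnnotationConfig:
    """Layout for paired mouse/human annotations and their homology."""

    n_mouse_genes: int = 20
    mouse_chrom_length_Mb: float = 100.0
    mouse_chroms: tuple = ("2", "19")
    human_chrom: str = "10"
    human_chrom_length_Mb: float = 130.0
    gene_length_Mb: float = 0.1
    frac_zero_homologs: float = 0.1
    frac_two_homologs: float = 0.1


def simulate_annotation_homology(
    config: AnnotationConfig, seed: int
) -> tuple[GeneAnnotation, GeneAnnotation, HomologyMap]:
    """Non-overlapping mouse genes, their human homologs, and the pairing.

    Mouse genes are spread evenly over the configured chromosomes; each gets
    0, 1 or 2 human homologs at the configured fractions (two homologs model
    paralog splits, as when one rodent gene answers to two human copies).
    Human genes are laid out on a single chromosome.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    per_chrom = int(np.ceil(cfg.n_mouse_genes / len(cfg.mouse_chroms)))
    slot = cfg.mouse_chrom_length_Mb / per_chrom
    if slot <= cfg.gene_length_Mb:
        raise ValueError("more mouse genes than fit on the chromosomes")
    mouse_rows = []
    i = 0
    for chrom in cfg.mouse_chroms:
        for j in range(per_chrom):
            if i >= cfg.n_mouse_genes:
                break
            start = j * slot + 0.25 * slot
            mouse_rows.append(
                {
                    "gene_id": f"MGENE{i + 1:04d}",
                    "symbol": f"Gene{i + 1}",
                    "chrom": chrom,
                    "start": round(start, 4),
                    "end": round(start + cfg.gene_length_Mb, 4),
                }
            )
            i += 1
    mouse = GeneAnnotation(pd.DataFrame(mouse_rows), species="mouse", units="Mb")

    u = rng.random(cfg.n_mouse_genes)
    n_hom = np.where(
        u < cfg.frac_zero_homologs,
        0,
        np.where(u < cfg.frac_zero_homologs + cfg.frac_two_homologs, 2, 1),
    )
    human_rows = []
    pair_rows = []
    k = 0
    total_human = int(n_hom.sum())
    h_slot = cfg.human_chrom_length_Mb / max(total_human, 1)
    if total_human and h_slot <= cfg.gene_length_Mb:
        raise ValueError("more human genes than fit on the chromosome")
    for i, row in enumerate(mouse_rows):
        for copy in range(n_hom[i]):
            hid = f"HGENE{k + 1:04d}"
            start = k * h_slot + 0.25 * h_slot
            human_rows.append(
                {
                    "gene_id": hid,
                    "symbol": row["symbol"].upper() + ("B" if copy else ""),
                    "chrom": cfg.human_chrom,
                    "start": round(start, 4),
                    "end": round(start + cfg.gene_length_Mb, 4),
                }
            )
            pair_rows.append(
                {"mouse_gene_id": row["gene_id"], "human_gene_id": hid}
            )
            k += 1
    human = GeneAnnotation(
        pd.DataFrame(human_rows, columns=["gene_id", "symbol", "chrom", "start", "end"]),
        species="human",
        units="Mb",
    )
    homology = HomologyMap(
        pd.DataFrame(pair_rows, columns=["mouse_gene_id", "human_gene_id"])
    )
    if len(homology.pairs):
        homology.validate_against(mouse, human)
    return mouse, human, homology
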