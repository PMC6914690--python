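"""Core containers shared across the pipeline.

Everything tabular is held as a :class:`pandas.DataFrame` with a documented
column contract; thin dataclasses add the invariants that a bare frame cannot
express (map monotonicity, homozygous calls, unit tags).  Physical positions
are 1-based bp internally; megabases appear only in gene tables that mirror
published coordinate lists, and every annotation carries an explicit ``units``
tag so the two scales can never be mixed silently.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "StrainGenotypes",
    "QTLSpec",
    "LDReference",
    "GWASSummary",
    "GeneAnnotation",
    "HomologyMap",
    "ExpressionMatrix",
    "QTLScan",
    "PermutationThreshold",
    "QTLInterval",
    "GeneSNPSet",
    "GeneBasedResult",
    "CoexpressionSet",
    "Eigengene",
    "EnrichmentResult",
]

#: Additive genotype coding: C57BL/6J ("B") allele -> -1, DBA/2J ("D") -> +1,
#: so a positive additive effect means the D allele increases the trait.
ALLELE_CODE = {"B": -1.0, "D": 1.0}


@dataclass
class MarkerMap:
    """Genetic + physical marker map.

    ``table`` columns: marker_id, chrom, pos_cM, pos_Mb.  Within each
    chromosome both positions must be non-decreasing and marker ids unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker_id", "chrom", "pos_cM", "pos_Mb"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"marker map missing columns: {sorted(missing)}")
        if self.table["marker_id"].duplicated().any():
            dups = self.table.loc[self.table["marker_id"].duplicated(), "marker_id"]
            raise ValueError(f"duplicate marker ids: {sorted(set(dups))}")
        for chrom, sub in self.table.groupby("chrom", sort=False):
            for col in ("pos_cM", "pos_Mb"):
                if np.any(np.diff(sub[col].to_numpy(float)) < 0):
                    raise ValueError(
                        f"non-monotone {col} on chromosome {chrom}"
                    )
        self.table = self.table.reset_index(drop=True)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))


@dataclass
class StrainGenotypes:
    """Fully inbred panel genotypes: strains x markers calls in {B, D}."""

    strains: list
    markers: MarkerMap
    calls: np.ndarray  # shape (n_strains, n_markers), dtype <U1

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U1")
        if self.calls.shape != (len(self.strains), self.markers.n_markers):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.strains)} strains x {self.markers.n_markers} markers"
            )
        bad = set(np.unique(self.calls)) - {"B", "D"}
        if bad:
            raise ValueError(f"non-homozygous or unknown calls: {sorted(bad)}")

    @property
    def additive(self) -> np.ndarray:
        """Additive coding (B -> -1, D -> +1), shape (n_strains, n_markers)."""
        return np.where(self.calls == "D", 1.0, -1.0)

    @property
    def n_strains(self) -> int:
        return len(self.strains)


@dataclass(frozen=True)
class QTLSpec:
    """Ground truth for a planted QTL: causal marker, additive effect, h2."""

    marker_id: str
    a: float
    h2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError(f"h2 must be in [0, 1), got {self.h2}")


@dataclass
class LDReference:
    """Reference genotype panel used to estimate LD: individuals x SNPs dosages."""

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray  # 1-based
    dosages: np.ndarray  # (n_individuals, n_snps) in {0, 1, 2}

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.snp_ids):
            raise ValueError("dosage matrix shape inconsistent with SNP ids")
        vals = set(np.unique(self.dosages).tolist())
        if not vals <= {0, 1, 2}:
            raise ValueError(f"dosages must be in {{0,1,2}}, got {sorted(vals)}")

    @property
    def monomorphic(self) -> np.ndarray:
        """Boolean mask of SNPs with zero dosage variance in the panel."""
        return self.dosages.std(axis=0) == 0

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]


@dataclass
class GWASSummary:
    """SNP association summary table: SNP, CHR, BP, A1, A2, P (daner-like)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"SNP", "CHR", "BP", "A1", "A2", "P"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"GWAS summary missing columns: {sorted(missing)}")
        p = self.table["P"].to_numpy(float)
        bad = np.flatnonzero(~((p > 0) & (p <= 1)))
        if bad.size:
            raise ValueError(
                f"p-values outside (0, 1] at rows {bad[:5].tolist()} "
                f"(values {p[bad[:5]].tolist()})"
            )
        self.table = self.table.reset_index(drop=True)


@dataclass
class GeneAnnotation:
    """Gene coordinate table for one species.

    Columns: gene_id, symbol, chrom, start, end (+ optional strand); ``units``
    declares whether start/end are Mb (gene tables) or bp (SNP-scale work).
    """

    table: pd.DataFrame
    species: str
    units: str = "Mb"

    def __post_init__(self) -> None:
        if self.units not in ("Mb", "bp"):
            raise ValueError(f"units must be 'Mb' or 'bp', got {self.units!r}")
        required = {"gene_id", "symbol", "chrom", "start", "end"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if (self.table["start"] > self.table["end"]).any():
            raise ValueError("gene with start > end")
        if self.table["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids within a species annotation")
        self.table = self.table.reset_index(drop=True)


@dataclass
class HomologyMap:
    """Mouse-human homolog pairs; one-to-many allowed in both directions."""

    pairs: pd.DataFrame  # columns mouse_gene_id, human_gene_id

    def __post_init__(self) -> None:
        required = {"mouse_gene_id", "human_gene_id"}
        missing = required - set(self.pairs.columns)
        if missing:
            raise ValueError(f"homology map missing columns: {sorted(missing)}")
        self.pairs = self.pairs.drop_duplicates().reset_index(drop=True)

    def validate_against(self, mouse: GeneAnnotation, human: GeneAnnotation) -> None:
        unknown_m = set(self.pairs["mouse_gene_id"]) - set(mouse.table["gene_id"])
        unknown_h = set(self.pairs["human_gene_id"]) - set(human.table["gene_id"])
        if unknown_m or unknown_h:
            raise ValueError(
                f"homology references unknown genes: mouse={sorted(unknown_m)}, "
                f"human={sorted(unknown_h)}"
            )


@dataclass
class ExpressionMatrix:
    """Probes/genes x strains expression values (log2-scale arbitrary units)."""

    values: pd.DataFrame  # index: probe_or_gene ids, columns: strain ids

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate probe/gene row ids")
        arr = self.values.to_numpy(float)
        if np.isinf(arr).any():
            raise ValueError("non-finite expression values")

    @property
    def strains(self) -> list:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# Result containers


@dataclass
class QTLScan:
    """Per-marker single-QTL scan: LRS, LOD and signed additive effect."""

    table: pd.DataFrame  # marker, chrom, pos_cM, pos_Mb, LRS, LOD, additive_effect, flag
    trait_id: str
    n_strains: int

    def peak(self) -> pd.Series:
        """Row of the genome-wide maximum LRS (first on ties)."""
        return self.table.loc[self.table["LRS"].idxmax()]


@dataclass
class PermutationThreshold:
    """Empirical genome-wide significance threshold from trait permutations."""

    alpha: float
    n_perm: int
    threshold_lrs: float
    max_lrs: np.ndarray  # per-permutation genome-wide max LRS
    seed: int | None = None


@dataclass
class QTLInterval:
    """LOD-drop support interval around a scan peak, in Mb."""

    chrom: str
    start_Mb: float
    end_Mb: float
    peak_marker: str
    peak_lrs: float
    drop_lod: float

    def __post_init__(self) -> None:
        if self.start_Mb > self.end_Mb:
            raise ValueError("interval start after end")


@dataclass
class GeneSNPSet:
    """SNPs assigned to one gene for gene-based association testing."""

    gene_id: str
    snp_ids: np.ndarray
    pos_bp: np.ndarray
    p_values: np.ndarray
    window_kb: float

    def __post_init__(self) -> None:
        if len(self.snp_ids) == 0:
            raise ValueError(f"gene {self.gene_id}: empty SNP set")


@dataclass(frozen=True)
class GeneBasedResult:
    """Gene-level association: SNP count M, effective test count Me, p-value."""

    gene_id: str
    m: int
    me: float
    p_gene: float


@dataclass
class CoexpressionSet:
    """Genes passing the seed-correlation screen, with the thresholds used."""

    seed_id: str
    table: pd.DataFrame  # gene, r, p, n for every tested gene
    members: list  # gene ids with |r| >= r_thresh and p <= p_thresh
    r_thresh: float
    p_thresh: float


@dataclass
class Eigengene:
    """First principal component of standardized probes, one score per strain."""

    scores: pd.Series  # indexed by strain
    variance_explained: float
    probe_ids: list
    sign_convention: str = "positive-mean-probe-correlation"


@dataclass
class EnrichmentResult:
    """Overlap of a gene set with a disease catalog against a permutation null."""

    background_size: int
    disease_in_background: int
    set_size: int
    observed_overlap: int
    n_perm: int
    exceed_count: int  # permutations with overlap strictly greater than observed
    ge_count: int  # permutations with overlap >= observed
    empirical_p: float  # exceed_count / n_perm
    smoothed_p: float  # (ge_count + 1) / (n_perm + 1)
    hypergeom_p: float
    seed: int

    def render_empirical(self) -> str:
        """Text form of the strict empirical p; a zero prints as a floor."""
        if self.empirical_p == 0.0:
            return f"< {1.0 / self.n_perm:g}"
        return f"{self.empirical_p:g}"
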