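"""Single-marker QTL scans on strain means with permutation thresholds.

The model at each marker is ordinary least squares of the strain-mean trait
on the additive founder code (B = -1, D = +1), giving the likelihood-ratio
statistic LRS = n * ln(RSS0 / RSS1) against the intercept-only model and the
additive effect a = half the D-minus-B difference in allele-group means (a
positive effect means the D allele raises the trait).  Genome-wide
significance comes from shuffling trait values across strains and taking the
(1 - alpha) quantile of the per-shuffle maximum LRS; support intervals use
the classic LOD-drop rule.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    GeneAnnotation,
    MarkerMap,
    PermutationThreshold,
    QTLInterval,
    QTLScan,
    StrainGenotypes,
)

__all__ = [
    "LRS_CAP",
    "lrs_to_lod",
    "marker_regression_scan",
    "permutation_threshold",
    "scan_max_lrs",
    "support_interval",
    "classify_eqtl",
]

#: Sentinel for a perfect fit (RSS1 = 0); kept finite so scans serialize.
LRS_CAP = 9999.0


def lrs_to_lod(lrs: float | np.ndarray) -> float | np.ndarray:
    """LOD = LRS / (2 ln 10)."""
    arr = np.asarray(lrs, float)
    if np.any(arr < 0):
        raise ValueError("LRS must be non-negative")
    out = arr / (2.0 * np.log(10.0))
    return float(out) if np.isscalar(lrs) else out


def _align(trait: pd.Series, genotypes: StrainGenotypes) -> tuple[np.ndarray, np.ndarray]:
    """Intersect trait and genotypes on strain id; returns (y, G)."""
    common = [s for s in genotypes.strains if s in trait.index]
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 strains with both trait and genotype, got {len(common)}"
        )
    y = trait.loc[common].to_numpy(float)
    if np.isnan(y).any():
        keep = ~np.isnan(y)
        common = [s for s, k in zip(common, keep) if k]
        if len(common) < 3:
            raise ValueError("fewer than 3 strains after dropping missing trait values")
        y = y[keep]
    rows = [genotypes.strains.index(s) for s in common]
    G = genotypes.additive[rows, :]
    return y, G


def _lrs_components(y: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker (LRS, additive effect, perfect-fit mask) for one trait.

    Uses LRS = -n ln(1 - r^2), equivalent to n ln(RSS0/RSS1) for simple OLS.
    Monomorphic markers get LRS = 0 and effect 0.
    """
    n = len(y)
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    Gc = G - G.mean(axis=0)
    ss_g = np.einsum("ij,ij->j", Gc, Gc)
    mono = ss_g == 0
    cov = yc @ Gc
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(mono, 0.0, cov / np.where(mono, 1.0, ss_g))
        if ss_y == 0.0:
            r2 = np.zeros(G.shape[1])
        else:
            r2 = np.where(mono, 0.0, cov**2 / (np.where(mono, 1.0, ss_g) * ss_y))
    r2 = np.clip(r2, 0.0, 1.0)
    perfect = (r2 >= 1.0 - 1e-12) & ~mono & (ss_y > 0)
    with np.errstate(divide="ignore"):
        lrs = np.where(perfect, LRS_CAP, -n * np.log1p(-np.minimum(r2, 1.0 - 1e-300)))
    lrs = np.where(mono, 0.0, lrs)
    return lrs, slope, perfect


def marker_regression_scan(
    trait: pd.Series, genotypes: StrainGenotypes, trait_id: str = "trait"
) -> QTLScan:
    """Genome-wide single-marker regression scan of one strain-mean trait.

    Returns per-marker LRS, LOD and the signed additive effect; monomorphic
    markers are flagged and scored 0, and a perfect fit is capped at the
    :data:`LRS_CAP` sentinel and flagged.
    """
    y, G = _align(trait, genotypes)
    lrs, slope, perfect = _lrs_components(y, G)
    mono = G.std(axis=0) == 0
    flag = np.where(mono, "monomorphic", np.where(perfect, "perfect_fit", ""))
    table = genotypes.markers.table.copy()
    table = table.rename(columns={"marker_id": "marker"})
    table["LRS"] = lrs
    table["LOD"] = lrs_to_lod(lrs)
    table["additive_effect"] = slope
    table["flag"] = flag
    return QTLScan(table=table, trait_id=trait_id, n_strains=len(y))


def scan_max_lrs(traits: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Genome-wide max LRS for many traits at once.

    ``traits`` is (n_traits, n_strains) and ``G`` (n_strains, n_markers);
    each row is scanned against all markers via the correlation identity
    LRS = -n ln(1 - r^2).  Markers with zero variance are ignored.  Used for
    permutation nulls and calibration studies, where flags are irrelevant.
    """
    n = G.shape[0]
    Yc = traits - traits.mean(axis=1, keepdims=True)
    ss_y = np.einsum("ij,ij->i", Yc, Yc)
    Gc = G - G.mean(axis=0)
    ss_g = np.einsum("ij,ij->j", Gc, Gc)
    keep = ss_g > 0
    Gn = Gc[:, keep] / np.sqrt(ss_g[keep])[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        Yn = Yc / np.sqrt(ss_y)[:, None]
    Yn = np.nan_to_num(Yn)
    r2 = np.clip((Yn @ Gn) ** 2, 0.0, 1.0 - 1e-300)
    return (-n * np.log1p(-r2)).max(axis=1)


def permutation_threshold(
    trait: pd.Series,
    genotypes: StrainGenotypes,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PermutationThreshold:
    """Empirical genome-wide LRS threshold from trait permutations.

    Trait values are shuffled across strains (genotypes fixed, which breaks
    the trait-genotype pairing while preserving marker LD), the genome-wide
    maximum LRS recorded per shuffle, and the threshold taken as the
    (1 - alpha) empirical quantile with linear (type-7) interpolation.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not 0.0 < alpha <= 0.5:
        raise ValueError("alpha must be in (0, 0.5]")
    y, G = _align(trait, genotypes)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
    max_lrs = scan_max_lrs(perms, G)
    threshold = float(np.quantile(max_lrs, 1.0 - alpha))
    return PermutationThreshold(
        alpha=alpha, n_perm=n_perm, threshold_lrs=threshold, max_lrs=max_lrs, seed=seed
    )


def support_interval(
    scan: QTLScan, peak_marker: str, drop_lod: float = 1.5
) -> QTLInterval:
    """LOD-drop support interval around a chromosome's peak marker.

    The interval runs outward from the peak to the first flanking markers
    whose LOD falls below peak LOD - ``drop_lod``; endpoints are those
    markers' Mb positions, clipped to the chromosome ends when no marker
    drops low enough.
    """
    t = scan.table
    row = t.index[t["marker"] == peak_marker]
    if len(row) == 0:
        raise KeyError(f"marker {peak_marker!r} not in scan")
    i = int(row[0])
    chrom = t.at[i, "chrom"]
    sub = t[t["chrom"] == chrom].reset_index()
    j = int(sub.index[sub["marker"] == peak_marker][0])
    lod = sub["LOD"].to_numpy(float)
    if lod[j] < lod.max():
        raise ValueError(
            f"marker {peak_marker!r} is not the chromosome-wide LOD maximum"
        )
    cut = lod[j] - drop_lod
    left = 0
    for k in range(j - 1, -1, -1):
        if lod[k] < cut:
            left = k
            break
    right = len(sub) - 1
    for k in range(j + 1, len(sub)):
        if lod[k] < cut:
            right = k
            break
    return QTLInterval(
        chrom=str(chrom),
        start_Mb=float(sub.at[left, "pos_Mb"]),
        end_Mb=float(sub.at[right, "pos_Mb"]),
        peak_marker=peak_marker,
        peak_lrs=float(sub.at[j, "LRS"]),
        drop_lod=drop_lod,
    )


def classify_eqtl(
    peak_chrom: str,
    peak_pos_Mb: float,
    gene: pd.Series,
    cis_window_Mb: float = 5.0,
) -> str:
    """Classify an expression QTL peak as ``cis`` or ``trans``.

    A peak is cis iff it lies on the gene's chromosome within
    ``cis_window_Mb`` of the gene body (distance 0 inside the body; the
    boundary distance == window counts as cis).  ``gene`` is a row of a
    Mb-unit :class:`~xqtl.types.GeneAnnotation` table.
    """
    if str(peak_chrom) != str(gene["chrom"]):
        return "trans"
    if gene["start"] <= peak_pos_Mb <= gene["end"]:
        return "cis"
    dist = min(abs(peak_pos_Mb - gene["start"]), abs(peak_pos_Mb - gene["end"]))
    return "cis" if dist <= cis_window_Mb else "trans"
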