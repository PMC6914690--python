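"""Seed-gene coexpression screening and eigengene summaries.

A seed transcript is correlated against every other row of an expression
matrix (Pearson or Spearman, pairwise-complete strains); genes passing
|r| >= r_thresh and p <= p_thresh form the coexpression set.  When a gene is
represented by several probes, the probes are standardized and collapsed to
their first principal component (an eigengene) whose per-strain scores can be
mapped like any other trait.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import CoexpressionSet, Eigengene, ExpressionMatrix

__all__ = ["correlate_seed", "screen", "eigengene"]


def _corr_p_two_sided(r: float, n: int, method: str) -> float:
    """Two-sided p for a sample correlation via the t transform.

    The same t approximation is applied to Spearman's rho (adequate for the
    n >= 10 panels used here; exact small-n Spearman tails are not needed).
    """
    if n < 4 or abs(r) >= 1.0:
        return 0.0 if abs(r) >= 1.0 else 1.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlate_seed(
    expr: ExpressionMatrix, seed_id: str, method: str = "pearson"
) -> pd.DataFrame:
    """Correlate every row with the seed row over pairwise-complete strains.

    Returns a frame indexed by gene with columns r, p, n; the seed itself is
    included (r = 1) so callers can drop or keep it explicitly.  Rows with
    zero variance on the shared strains are excluded and flagged in the
    ``excluded`` attribute of the result (``df.attrs['excluded']``).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be pearson or spearman, got {method!r}")
    V = expr.values
    if seed_id not in V.index:
        raise KeyError(f"seed {seed_id!r} not in expression matrix")
    seed = V.loc[seed_id].to_numpy(float)
    rows = []
    excluded = []
    for gene, vals in V.iterrows():
        x = vals.to_numpy(float)
        ok = ~(np.isnan(x) | np.isnan(seed))
        n = int(ok.sum())
        if n < 4:
            excluded.append(gene)
            continue
        xs, ss = x[ok], seed[ok]
        if method == "spearman":
            xs = stats.rankdata(xs)
            ss = stats.rankdata(ss)
        if xs.std() == 0 or ss.std() == 0:
            excluded.append(gene)
            continue
        r = float(np.corrcoef(xs, ss)[0, 1])
        rows.append({"gene": gene, "r": r, "p": _corr_p_two_sided(r, n, method), "n": n})
    out = pd.DataFrame(rows, columns=["gene", "r", "p", "n"]).set_index("gene")
    out.attrs["excluded"] = excluded
    out.attrs["method"] = method
    out.attrs["seed_id"] = seed_id
    return out


def screen(
    correlations: pd.DataFrame,
    r_thresh: float = 0.5,
    p_thresh: float = 0.05,
    seed_id: str | None = None,
) -> CoexpressionSet:
    """Select genes with |r| >= r_thresh and p <= p_thresh (both inclusive).

    The seed gene is excluded from membership.  Members are ordered by |r|
    descending, ties broken by gene id, so output order is deterministic.
    """
    if not (0.0 < r_thresh <= 1.0) or not (0.0 < p_thresh <= 1.0):
        raise ValueError("thresholds must be in (0, 1]")
    seed_id = seed_id or correlations.attrs.get("seed_id", "")
    c = correlations.drop(index=seed_id, errors="ignore")
    passed = c[(c["r"].abs() >= r_thresh) & (c["p"] <= p_thresh)].copy()
    passed["_abs"] = passed["r"].abs()
    passed = (
        passed.rename_axis("gene")
        .sort_values(["_abs", "gene"], ascending=[False, True], kind="mergesort")
        .drop(columns="_abs")
    )
    return CoexpressionSet(
        seed_id=seed_id,
        table=correlations,
        members=passed.index.tolist(),
        r_thresh=r_thresh,
        p_thresh=p_thresh,
    )


def eigengene(expr: ExpressionMatrix, probe_ids: list[str]) -> Eigengene:
    """First principal component of standardized probes, one score per strain.

    Probes are centered and scaled to unit variance; missing strain values
    are mean-imputed (i.e. set to 0 after standardization) inside the PCA
    only.  Zero-variance probes are dropped; the PC1 sign is fixed so the
    eigengene correlates non-negatively with the mean standardized probe.
    Scores are unit-normalized PC1 loadings over strains and have mean 0.
    """
    V = expr.values
    missing = [p for p in probe_ids if p not in V.index]
    if missing:
        raise KeyError(f"probes not in expression matrix: {missing}")
    X = V.loc[probe_ids].to_numpy(float)  # probes x strains
    if X.shape[1] < 3:
        raise ValueError("eigengene needs >= 3 strains")
    kept = []
    Z = []
    for pid, row in zip(probe_ids, X):
        ok = ~np.isnan(row)
        mu, sd = row[ok].mean(), row[ok].std()
        if sd == 0 or ok.sum() < 2:
            continue
        z = np.where(ok, (row - mu) / sd, 0.0)
        kept.append(pid)
        Z.append(z)
    if not kept:
        raise ValueError("all probes have zero variance; no eigengene")
    Z = np.asarray(Z)  # k x n, rows standardized
    # PC1 of the strains in probe space: right singular vector of Z
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    scores = vt[0]
    mean_probe = Z.mean(axis=0)
    if scores @ mean_probe < 0:
        scores = -scores
    scores = scores - scores.mean()
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    return Eigengene(
        scores=pd.Series(scores, index=V.columns, name="eigengene"),
        variance_explained=var_explained,
        probe_ids=kept,
    )
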