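"""Permutation test for disease-gene enrichment of a coexpression set.

The observed statistic is the overlap k between the coexpression set and the
disease catalog, both restricted to the expression background of N genes
containing K catalog genes.  The null redraws the coexpression set: each
permutation samples n genes uniformly without replacement from the background
and records its catalog overlap.  Two p-values are reported: the strict
empirical estimate #{overlap > k}/n_perm, and a smoothed estimate
(#{overlap >= k} + 1)/(n_perm + 1) that can never be exactly zero.  Because
the null is exactly hypergeometric, the analytic upper tail
P(X >= k), X ~ Hypergeometric(N, K, n), is computed alongside as a check.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .types import EnrichmentResult

__all__ = [
    "observed_overlap",
    "hypergeometric_pvalue",
    "permutation_enrichment",
    "enrichment_test",
]

#: Permutations are generated in fixed-size chunks, each from a counter-based
#: Philox stream keyed by (seed, chunk index); results are therefore
#: reproducible and independent of chunk execution order.
CHUNK = 1024


def observed_overlap(
    coexpr_set: set | list,
    disease_set: set | list,
    background: set | list,
) -> int:
    """k = |coexpr & disease & background|; the coexpression set must already
    live inside the background (anything else is a contract violation)."""
    coexpr = set(coexpr_set)
    bg = set(background)
    outside = coexpr - bg
    if outside:
        raise ValueError(
            f"coexpression genes outside the background: {sorted(outside)[:5]}"
        )
    return len(coexpr & set(disease_set) & bg)


def hypergeometric_pvalue(k_obs: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k_obs) for X ~ Hypergeometric(N, K, n), log-space."""
    if not (0 <= k_obs <= min(n, K)) or K > N or n > N:
        raise ValueError(
            f"impossible configuration: k={k_obs}, K={K}, n={n}, N={N}"
        )
    if k_obs == 0:
        return 1.0
    return float(stats.hypergeom.sf(k_obs - 1, N, K, n))


def permutation_enrichment(
    background: list,
    disease_set: set | list,
    n: int,
    k_obs: int,
    n_perm: int = 100_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Monte-Carlo null for the set-overlap statistic.

    Each permutation draws ``n`` genes without replacement from the
    ``background`` and counts how many fall in ``disease_set`` (intersected
    with the background first).  Reports both the strict and the smoothed
    empirical p together with the exact hypergeometric tail.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    N = len(background)
    if n > N:
        raise ValueError(f"set size n={n} exceeds background N={N}")
    disease = set(disease_set) & set(background)
    K = len(disease)
    indicator = np.fromiter(
        (g in disease for g in background), count=N, dtype=np.float64
    )
    exceed = 0
    ge = 0
    done = 0
    chunk_idx = 0
    while done < n_perm:
        size = min(CHUNK, n_perm - done)
        rng = np.random.Generator(np.random.Philox(key=(seed, chunk_idx)))
        # n smallest of N uniform keys = uniform draw of n without replacement
        keys = rng.random((size, N))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        overlaps = indicator[idx].sum(axis=1)
        exceed += int((overlaps > k_obs).sum())
        ge += int((overlaps >= k_obs).sum())
        done += size
        chunk_idx += 1
    return EnrichmentResult(
        background_size=N,
        disease_in_background=K,
        set_size=n,
        observed_overlap=k_obs,
        n_perm=n_perm,
        exceed_count=exceed,
        ge_count=ge,
        empirical_p=exceed / n_perm,
        smoothed_p=(ge + 1) / (n_perm + 1),
        hypergeom_p=hypergeometric_pvalue(k_obs, K, n, N),
        seed=seed,
    )


def enrichment_test(
    coexpr_set: list,
    disease_set: set | list,
    background: list,
    n_perm: int = 100_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Observed overlap plus its permutation and analytic p-values."""
    k = observed_overlap(coexpr_set, disease_set, background)
    return permutation_enrichment(
        background=background,
        disease_set=disease_set,
        n=len(set(coexpr_set)),
        k_obs=k,
        n_perm=n_perm,
        seed=seed,
    )
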