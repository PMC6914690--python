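"""Cross-species integration: QTL intervals -> mouse genes -> human homologs
-> Bonferroni selection over the homolog set.

The multiple-testing burden is the number of distinct human homologs that
were actually testable in the gene-based GWAS across all analyzed intervals
jointly; each homolog's gene-level p is then flagged nominally significant
(p <= alpha) and Bonferroni significant (p <= alpha / N).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .types import GeneAnnotation, HomologyMap, QTLInterval

__all__ = ["genes_in_interval", "map_homologs", "bonferroni_select"]


def genes_in_interval(
    annotation: GeneAnnotation, interval: QTLInterval
) -> list[str]:
    """Mouse genes overlapping a QTL interval (closed intervals, any overlap).

    A gene merely abutting an endpoint counts.  The annotation must be in Mb
    units; a magnitude check guards against accidentally passing bp values.
    """
    if annotation.units != "Mb":
        raise ValueError("interval intersection expects an Mb-unit annotation")
    t = annotation.table
    if len(t) and t["start"].max() > 5e3:
        raise ValueError(
            "annotation positions look like bp, not Mb; check the units tag"
        )
    sub = t[t["chrom"].astype(str) == str(interval.chrom)]
    hit = sub[(sub["end"] >= interval.start_Mb) & (sub["start"] <= interval.end_Mb)]
    return hit["gene_id"].tolist()


def map_homologs(mouse_genes: list[str], homology: HomologyMap) -> list[str]:
    """Distinct human homologs of the given mouse genes, sorted by id.

    One-to-many pairs contribute every homolog; homologs shared by several
    mouse genes are counted once.  Mouse genes without any homolog simply do
    not contribute.
    """
    pairs = homology.pairs
    hit = pairs[pairs["mouse_gene_id"].isin(mouse_genes)]
    return sorted(set(hit["human_gene_id"]))


def bonferroni_select(
    candidates: pd.DataFrame,
    gene_based_results: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag candidate homologs at nominal and Bonferroni-corrected levels.

    ``candidates`` carries one row per (trait, mouse gene, human homolog);
    ``gene_based_results`` the gene-level GWAS table with columns
    ``gene``/``p_gates``.  N counts distinct homologs with a gene-based p
    across all traits jointly; homologs absent from the GWAS results are kept
    as untested rows and excluded from N.  Flags use the <= rule so a p
    exactly at the threshold passes.
    """
    required = {"trait_id", "mouse_gene", "human_gene"}
    missing = required - set(candidates.columns)
    if missing:
        raise ValueError(f"candidates missing columns: {sorted(missing)}")
    pmap = dict(
        zip(gene_based_results["gene"], gene_based_results["p_gates"].astype(float))
    )
    out = candidates.copy()
    out["p_gates"] = out["human_gene"].map(pmap)
    tested = set(out.loc[out["p_gates"].notna(), "human_gene"])
    n_tested = len(tested)
    if n_tested == 0:
        raise ValueError("no candidate homolog has a gene-based p-value")
    threshold = alpha / n_tested
    out["n_homologs_tested"] = n_tested
    out["bonferroni_threshold"] = threshold
    p = out["p_gates"]
    out["nominal"] = (p <= alpha).fillna(False)
    out["corrected"] = (p <= threshold).fillna(False)
    return out.reset_index(drop=True)
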