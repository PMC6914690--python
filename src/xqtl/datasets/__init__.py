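"""Bundled worked-example tables.

The PPI QTL example carries the published coordinates of the mouse genes in
the two genome-wide significant prepulse-inhibition QTL (chromosome 2 for
trait 18755, chromosome 19 for trait 11428), their human homologs on
chromosome 10, and the homology pairing (one mouse gene, Asah2, maps to two
human genes).  Intersecting the intervals with the mouse annotation and
mapping through the homology yields 4, 8 and 12 distinct human homologs for
trait 18755, trait 11428, and both jointly.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from ..io import read_annotation, read_homology
from ..types import GeneAnnotation, HomologyMap, QTLInterval

__all__ = ["load_ppi_qtl_example"]


def _path(name: str):
    return resources.files(__package__).joinpath(name)


def load_ppi_qtl_example() -> tuple[
    GeneAnnotation, GeneAnnotation, HomologyMap, dict[str, QTLInterval]
]:
    """Load the PPI QTL worked example.

    Returns (mouse annotation, human annotation, homology map, intervals by
    trait id); annotations are in Mb.
    """
    with resources.as_file(_path("ppi_mouse_genes.tsv")) as p:
        mouse = read_annotation(p)
    with resources.as_file(_path("ppi_human_genes.tsv")) as p:
        human = read_annotation(p)
    with resources.as_file(_path("ppi_homology.tsv")) as p:
        homology = read_homology(p)
    with resources.as_file(_path("ppi_qtl_intervals.tsv")) as p:
        iv = pd.read_csv(p, sep="\t", comment="#", dtype={"trait_id": str, "chrom": str})
    intervals = {
        row["trait_id"]: QTLInterval(
            chrom=row["chrom"],
            start_Mb=float(row["start_Mb"]),
            end_Mb=float(row["end_Mb"]),
            peak_marker=row["peak_marker"],
            peak_lrs=float(row["peak_LRS"]),
            drop_lod=1.5,
        )
        for _, row in iv.iterrows()
    }
    return mouse, human, homology, intervals
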