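"""Readers and writers for the pipeline's tab-separated table dialects.

All files are TSV with a header row; lines starting with ``#`` are comments,
except the ``# key=value`` tags some writers emit (units, species), which the
corresponding readers parse.  Every reader validates its contract and names
the offending file line on failure; write(read(f)) round-trips semantically.

Dialects
--------
genotypes      marker_id, chrom, pos_cM, pos_Mb, then one B/D column per strain
traits         strain, then one numeric column per trait id
GWAS summary   SNP, CHR, BP, A1, A2, P (daner-like)
dosage panel   individual_id, then one column per SNP; two reserved leading
               rows ``_chrom`` and ``_pos_bp`` carry the SNP map
annotation     gene_id, symbol, chrom, start, end [, strand]; tagged with
               ``# species=...`` and ``# units=Mb|bp``
homology       mouse_gene_id, human_gene_id
expression     probe_id, then one numeric column per strain
catalog        association_id, mapped_genes (comma/semicolon separated)
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    GeneAnnotation,
    GWASSummary,
    HomologyMap,
    LDReference,
    MarkerMap,
    StrainGenotypes,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_traits",
    "write_traits",
    "read_gwas_summary",
    "write_gwas_summary",
    "read_ld_panel",
    "write_ld_panel",
    "read_annotation",
    "write_annotation",
    "read_homology",
    "write_homology",
    "read_expression",
    "write_expression",
    "read_catalog",
    "write_catalog",
    "catalog_genes",
]


def _read_tagged_tsv(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """TSV with '#' comments; '# key=value' comments are returned as tags."""
    tags: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body and " " not in body.split("=", 1)[0]:
                k, v = body.split("=", 1)
                tags[k.strip()] = v.strip()
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "CHR": str})
    return df, tags


def _require(df: pd.DataFrame, cols: set, path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")


# -- genotypes --------------------------------------------------------------


def read_genotypes(path: str | Path) -> StrainGenotypes:
    df, _ = _read_tagged_tsv(path)
    _require(df, {"marker_id", "chrom", "pos_cM", "pos_Mb"}, path)
    strain_cols = [c for c in df.columns if c not in ("marker_id", "chrom", "pos_cM", "pos_Mb")]
    if not strain_cols:
        raise ValueError(f"{path}: no strain columns")
    calls = df[strain_cols].to_numpy(dtype="<U1").T  # strains x markers
    bad = np.argwhere(~np.isin(calls, ["B", "D"]))
    if bad.size:
        s, m = bad[0]
        raise ValueError(
            f"{path}: line {m + 2}: invalid call {calls[s, m]!r} for strain "
            f"{strain_cols[s]!r} (expected B or D)"
        )
    markers = MarkerMap(df[["marker_id", "chrom", "pos_cM", "pos_Mb"]].copy())
    return StrainGenotypes(strains=strain_cols, markers=markers, calls=calls)


def write_genotypes(geno: StrainGenotypes, path: str | Path) -> None:
    df = geno.markers.table.copy()
    for i, s in enumerate(geno.strains):
        df[s] = geno.calls[i]
    df.to_csv(path, sep="\t", index=False)


# -- traits ------------------------------------------------------------------


def read_traits(path: str | Path) -> pd.DataFrame:
    """Strain-mean trait table indexed by strain, one column per trait."""
    df, _ = _read_tagged_tsv(path)
    _require(df, {"strain"}, path)
    df = df.set_index("strain")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no trait columns")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric value for strain {bad[0]!r} in {col!r}")
        df[col] = vals
    return df


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.rename_axis("strain").to_csv(path, sep="\t")


# -- GWAS summary ------------------------------------------------------------


def read_gwas_summary(path: str | Path) -> GWASSummary:
    df, _ = _read_tagged_tsv(path)
    _require(df, {"SNP", "CHR", "BP", "A1", "A2", "P"}, path)
    p = pd.to_numeric(df["P"], errors="coerce")
    bad = np.flatnonzero(~((p > 0) & (p <= 1)))
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"{path}: line {i + 2}: p-value {df['P'].iloc[i]!r} outside (0, 1]"
        )
    df["P"] = p
    return GWASSummary(df)


def write_gwas_summary(gwas: GWASSummary, path: str | Path) -> None:
    gwas.table.to_csv(path, sep="\t", index=False)


# -- LD dosage panel ---------------------------------------------------------


def read_ld_panel(path: str | Path) -> LDReference:
    df, _ = _read_tagged_tsv(path)
    _require(df, {"individual_id"}, path)
    df = df.set_index("individual_id")
    for row in ("_chrom", "_pos_bp"):
        if row not in df.index:
            raise ValueError(f"{path}: missing reserved SNP-map row {row!r}")
    chrom = df.loc["_chrom"].astype(str).to_numpy()
    pos = df.loc["_pos_bp"].astype(float).astype(np.int64).to_numpy()
    dose = df.drop(index=["_chrom", "_pos_bp"]).astype(float)
    vals = dose.to_numpy()
    if not np.isin(vals, [0.0, 1.0, 2.0]).all():
        bad = np.argwhere(~np.isin(vals, [0.0, 1.0, 2.0]))[0]
        raise ValueError(
            f"{path}: invalid dosage {vals[tuple(bad)]!r} for individual "
            f"{dose.index[bad[0]]!r}"
        )
    return LDReference(
        snp_ids=np.asarray(df.columns),
        chrom=chrom,
        pos_bp=pos,
        dosages=vals.astype(np.int64),
    )


def write_ld_panel(panel: LDReference, path: str | Path) -> None:
    df = pd.DataFrame(
        panel.dosages,
        index=[f"I{i + 1:05d}" for i in range(panel.n_individuals)],
        columns=panel.snp_ids,
    )
    head = pd.DataFrame(
        [panel.chrom, panel.pos_bp], index=["_chrom", "_pos_bp"], columns=panel.snp_ids
    )
    pd.concat([head, df]).rename_axis("individual_id").to_csv(path, sep="\t")


# -- annotation / homology ---------------------------------------------------


def read_annotation(path: str | Path) -> GeneAnnotation:
    df, tags = _read_tagged_tsv(path)
    _require(df, {"gene_id", "symbol", "chrom", "start", "end"}, path)
    return GeneAnnotation(
        df, species=tags.get("species", "unknown"), units=tags.get("units", "Mb")
    )


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# species={ann.species}\n# units={ann.units}\n")
        ann.table.to_csv(fh, sep="\t", index=False)


def read_homology(path: str | Path) -> HomologyMap:
    df, _ = _read_tagged_tsv(path)
    _require(df, {"mouse_gene_id", "human_gene_id"}, path)
    return HomologyMap(df)


def write_homology(hom: HomologyMap, path: str | Path) -> None:
    hom.pairs.to_csv(path, sep="\t", index=False)


# -- expression --------------------------------------------------------------


def read_expression(path: str | Path) -> ExpressionMatrix:
    df, _ = _read_tagged_tsv(path)
    _require(df, {"probe_id"}, path)
    return ExpressionMatrix(df.set_index("probe_id").astype(float))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.rename_axis("probe_id").to_csv(path, sep="\t")


# -- disease catalog ---------------------------------------------------------


def read_catalog(path: str | Path) -> pd.DataFrame:
    df, _ = _read_tagged_tsv(path)
    _require(df, {"association_id", "mapped_genes"}, path)
    return df


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def catalog_genes(catalog: pd.DataFrame) -> set:
    """Expand multi-gene catalog rows to the distinct set of mapped genes.

    Rows may map a hit to several genes (comma or semicolon separated, as
    association catalogs do when a signal spans an LD block); empty mappings
    are dropped.
    """
    genes: set = set()
    for cell in catalog["mapped_genes"].fillna(""):
        for g in str(cell).replace(";", ",").split(","):
            g = g.strip()
            if g:
                genes.add(g)
    return genes
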