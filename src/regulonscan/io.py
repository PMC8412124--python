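"""Readers and writers for the tab-separated formats the pipeline touches.

All files are UTF-8 TSV.  Gene-set collections use the Broad GMT dialect
(``set_id<TAB>description<TAB>gene...``).  Differential-expression tables
need ``gene_id``, ``log2fc`` and ``padj`` columns (renameable through
``column_map``); any column named ``mean_<label>`` is read as a per-group
mean expression.  Expression matrices are written samples-in-rows with a
separate sample metadata table (``sample_id``, ``group``, ``age``).
"""

from __future__ import annotations

import csv
import math
import os
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    DEGene,
    DETable,
    EnrichmentRow,
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    OrthologMap,
)

__all__ = [
    "read_de_table",
    "write_de_table",
    "read_gmt",
    "write_gmt",
    "read_ortholog_map",
    "write_ortholog_map",
    "write_enrichment_table",
    "read_enrichment_table",
    "read_expression",
    "write_expression",
]

_MANDATORY_DE_COLUMNS = ("gene_id", "log2fc", "padj")


def read_de_table(
    path: str | os.PathLike,
    species: str,
    column_map: Mapping[str, str] | None = None,
) -> DETable:
    """Read a per-gene differential-expression TSV into a :class:`DETable`.

    ``column_map`` maps canonical names (``gene_id``, ``log2fc``, ``padj``)
    to the file's column headers.  Rows with an empty/NA adjusted p-value
    are kept with ``tested=False`` (they drop out of the expressed
    universe, mirroring DE tools' independent filtering).
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)
    missing = [c for c in _MANDATORY_DE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    mean_cols = [c for c in df.columns if c.startswith("mean_")]

    genes: list[DEGene] = []
    for row in df.itertuples(index=False):
        padj = getattr(row, "padj")
        padj = None if pd.isna(padj) else float(padj)
        log2fc = getattr(row, "log2fc")
        log2fc = math.nan if pd.isna(log2fc) else float(log2fc)
        means = {}
        for c in mean_cols:
            v = getattr(row, c)
            if not pd.isna(v):
                means[c[len("mean_"):]] = float(v)
        genes.append(
            DEGene(
                gene_id=str(getattr(row, "gene_id")),
                log2fc=log2fc,
                padj=padj,
                group_means=means,
                tested=padj is not None,
            )
        )
    return DETable(species=species, genes=genes)


def write_de_table(table: DETable, path: str | os.PathLike) -> None:
    """Write a :class:`DETable` in the dialect :func:`read_de_table` expects."""
    labels: list[str] = []
    for g in table.genes:
        for lbl in g.group_means:
            if lbl not in labels:
                labels.append(lbl)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "log2fc", "padj"] + [f"mean_{l}" for l in labels])
        for g in table.genes:
            row = [
                g.gene_id,
                format(g.log2fc, ".6g"),
                "" if g.padj is None else format(g.padj, ".6g"),
            ]
            row += [
                format(g.group_means[l], ".6g") if l in g.group_means else ""
                for l in labels
            ]
            w.writerow(row)


def read_gmt(path: str | os.PathLike, kind: str) -> GeneSetCollection:
    """Read a Broad-dialect GMT file; duplicate genes within a set collapse."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT lines need >= 3 tab-separated "
                    f"fields (set_id, description, genes...), got {len(fields)}"
                )
            set_id, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if set_id in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set id {set_id!r}")
            sets[set_id] = (desc, genes)
    return GeneSetCollection(sets=sets, kind=kind)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for set_id, (name, genes) in collection.sets.items():
            fh.write("\t".join([set_id, name] + sorted(genes)) + "\n")


def read_ortholog_map(
    path: str | os.PathLike,
    from_species: str,
    to_species: str,
    header: bool = False,
) -> OrthologMap:
    """Read a two-column source/destination symbol TSV (BioMart-style export).

    A blank destination field means the source gene has no homolog and
    contributes no pair.  Duplicate rows collapse (set semantics).
    """
    pairs: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) > 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            src = fields[0].strip()
            dst = fields[1].strip() if len(fields) == 2 else ""
            if not src:
                raise FormatError(f"{path}: line {lineno}: empty source symbol")
            if dst:
                pairs.add((src, dst))
    return OrthologMap(from_species=from_species, to_species=to_species,
                       pairs=frozenset(pairs))


def write_ortholog_map(omap: OrthologMap, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for a, b in sorted(omap.pairs):
            fh.write(f"{a}\t{b}\n")


_ENRICHMENT_COLUMNS = ["tf_id", "K_expressed", "k_up", "n_up", "N_universe",
                       "p", "enriched"]


def write_enrichment_table(
    rows: Sequence[EnrichmentRow],
    path: str | os.PathLike,
    allow_empty: bool = False,
) -> None:
    """Write enrichment rows as TSV; p in scientific notation, 3 sig digits."""
    if not rows and not allow_empty:
        raise ValueError("refusing to write an empty enrichment table "
                         "(pass allow_empty=True to override)")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_ENRICHMENT_COLUMNS)
        for r in rows:
            w.writerow([r.tf_id, r.K_expressed, r.k_up, r.n_up, r.N_universe,
                        format(r.p, ".2e"), str(r.enriched).lower()])


def read_enrichment_table(path: str | os.PathLike) -> list[EnrichmentRow]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _ENRICHMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return [
        EnrichmentRow(
            tf_id=str(r.tf_id),
            K_expressed=int(r.K_expressed),
            k_up=int(r.k_up),
            n_up=int(r.n_up),
            N_universe=int(r.N_universe),
            p=float(r.p),
            enriched=bool(r.enriched),
        )
        for r in df.itertuples(index=False)
    ]


def read_expression(
    values_path: str | os.PathLike,
    metadata_path: str | os.PathLike,
) -> ExpressionMatrix:
    """Read a samples-in-rows expression TSV plus its sample metadata TSV."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    if set(values.index) != set(meta.index):
        raise FormatError("expression and metadata sample ids differ")
    meta = meta.loc[values.index]
    return ExpressionMatrix(values=values, metadata=meta)


def write_expression(
    expr: ExpressionMatrix,
    values_path: str | os.PathLike,
    metadata_path: str | os.PathLike,
) -> None:
    expr.values.to_csv(values_path, sep="\t", index_label="sample_id",
                       float_format="%.6g")
    expr.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id",
                         float_format="%.6g")
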