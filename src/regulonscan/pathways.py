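"""Pathway/GO over-representation and its intersection with TF regulons.

The upregulated gene list is tested against each set of a collection with
the same hypergeometric upper tail used for regulons, restricted to the
expressed-gene universe, with Benjamini-Hochberg correction across all
tested sets.  The regulon overlay then asks, for the top-ranked pathways,
how many of each pathway's upregulated members are targets of each TF —
a dominant regulator leaves multiple targets in every top pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .enrichment import bh_adjust, hypergeom_upper_tail
from .model import (
    DomainError,
    GeneSetCollection,
    PathwayRow,
    RegulonDB,
    TailConvention,
    as_normset,
)

__all__ = ["OverlayResult", "ora", "tf_pathway_counts"]


def ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    convention: TailConvention = TailConvention.GE,
) -> tuple[list[PathwayRow], list[str]]:
    """Over-representation of ``query`` in each set of ``collection``.

    Query genes outside the universe are dropped with a warning; each set
    is likewise restricted to the universe before testing.  Rows come back
    sorted ascending by (padj, p, set_id).
    """
    uni = as_normset(universe)
    if not uni:
        raise DomainError("empty universe")
    q = as_normset(query)
    warnings: list[str] = []
    outside = q - uni
    if outside:
        warnings.append(
            f"{len(outside)} query gene(s) outside the universe dropped: "
            f"{sorted(outside)[:10]}"
        )
        q &= uni
    N, n = len(uni), len(q)
    rows: list[PathwayRow] = []
    for set_id, (name, genes) in collection.sets.items():
        in_universe = genes & uni
        K = len(in_universe)
        k = len(in_universe & q)
        p = hypergeom_upper_tail(N, K, n, k, convention) if K else 1.0
        rows.append(PathwayRow(set_id=set_id, name=name, K_expressed=K,
                               k_up=k, p=p, padj=1.0))
    adjusted = bh_adjust([r.p for r in rows])
    for row, padj in zip(rows, adjusted):
        row.padj = padj
    rows.sort(key=lambda r: (r.padj, r.p, r.set_id))
    return rows, warnings


@dataclass
class OverlayResult:
    """Top pathways annotated with per-TF target counts."""

    rows: list[PathwayRow]
    #: per TF: number of top pathways with more than one of its targets
    multiple_target_pathways: dict[str, int]
    warnings: list[str] = field(default_factory=list)


def tf_pathway_counts(
    rows: Sequence[PathwayRow],
    db: RegulonDB,
    collection: GeneSetCollection,
    up: Iterable[str],
    top_n: int = 20,
) -> OverlayResult:
    """Fill TF-target counts for the ``top_n`` pathways (rows must be sorted).

    For each top pathway and TF:  count = |regulon ∩ pathway ∩ upregulated|;
    the per-TF summary is the number of top pathways where that count
    exceeds one.
    """
    warnings: list[str] = []
    if top_n > len(rows):
        warnings.append(f"top_n={top_n} clamped to {len(rows)} available rows")
        top_n = len(rows)
    up_set = as_normset(up)
    top = list(rows[:top_n])
    summary = {tf: 0 for tf in db.regulons}
    for row in top:
        _, pathway_genes = collection.sets[row.set_id]
        counts: dict[str, int] = {}
        for tf_id, regulon in db.regulons.items():
            c = len(regulon.targets & pathway_genes & up_set)
            counts[tf_id] = c
            if c > 1:
                summary[tf_id] += 1
        row.tf_target_counts = counts
    return OverlayResult(rows=top, multiple_target_pathways=summary,
                         warnings=warnings)
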