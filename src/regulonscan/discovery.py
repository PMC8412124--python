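"""Candidate transcription-factor selection.

A candidate TF is an upregulated gene that is (a) annotated as a
DNA-binding transcription factor (the GO:0003700-style universe supplied
as a gene-set collection) and (b) present in the regulon database, so its
target set can actually be tested.  Factors of prior biological interest
can be forced into the candidate list even when not differentially
expressed; forced symbols missing from the regulon database are reported,
never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .model import CandidateTF, DETable, DomainError, GeneSetCollection, RegulonDB, norm

__all__ = ["CandidateSelection", "select_candidate_tfs"]


@dataclass
class CandidateSelection:
    """Candidate list plus non-fatal warnings (e.g. unmapped forced TFs)."""

    candidates: list[CandidateTF]
    warnings: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)


def select_candidate_tfs(
    de: DETable,
    tf_universe: GeneSetCollection,
    db: RegulonDB,
    forced: Sequence[str] = (),
    alpha: float = 0.05,
    direction: str = "up",
) -> CandidateSelection:
    """Intersect significant DE genes with the TF universe and regulon DB.

    Returns candidates ordered by descending mean expression (ties broken
    by symbol), followed by forced factors.  Output is invariant to the DE
    table's row order, and shrinking the TF universe can only shrink the
    list.
    """
    if tf_universe.kind != "TF-universe":
        raise DomainError(
            f"tf_universe must have kind 'TF-universe', got {tf_universe.kind!r}"
        )
    sig = de.upregulated(alpha, direction)
    tf_symbols = tf_universe.members()

    selected: list[CandidateTF] = []
    for key in sig & tf_symbols:
        if key not in db:
            continue
        gene = de.get(key)
        assert gene is not None
        selected.append(
            CandidateTF(
                tf_id=gene.gene_id,
                log2fc=gene.log2fc,
                padj=gene.padj,
                in_regulon_db=True,
                forced=False,
                mean_expression=gene.mean_expression,
            )
        )
    selected.sort(
        key=lambda c: (
            -(c.mean_expression if not math.isnan(c.mean_expression) else -math.inf),
            norm(c.tf_id),
        )
    )

    warnings: list[str] = []
    seen = {norm(c.tf_id) for c in selected}
    for symbol in forced:
        if norm(symbol) in seen:
            continue  # already selected on its own merit
        if norm(symbol) not in db:
            warnings.append(f"forced TF {symbol!r} absent from the regulon database")
            continue
        gene = de.get(symbol)
        selected.append(
            CandidateTF(
                tf_id=symbol,
                log2fc=gene.log2fc if gene else math.nan,
                padj=gene.padj if gene else None,
                in_regulon_db=True,
                forced=True,
                mean_expression=gene.mean_expression if gene else math.nan,
            )
        )
        seen.add(norm(symbol))
    return CandidateSelection(candidates=selected, warnings=warnings)
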