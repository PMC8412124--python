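"""Cross-species regulon transfer through an ortholog map.

A regulon built in one species (e.g. from human ChIP catalogues) is
carried into another by replacing each target with all of its homologs
(one-to-many expansions are retained in full; many-to-one collapses by
set semantics).  Targets without a homolog are dropped and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    OrthologMap,
    Regulon,
    RegulonDB,
    SpeciesMismatchError,
    TransferReport,
)

__all__ = ["DBTransferResult", "transfer_regulon", "transfer_db"]


def transfer_regulon(
    regulon: Regulon, omap: OrthologMap
) -> tuple[Regulon | None, TransferReport]:
    """Map one regulon across species.

    Returns the destination regulon (``None`` when no target has a
    homolog) and a :class:`TransferReport`.  The destination set is the
    deduplicated union of all homologs, so it is independent of target
    iteration order.
    """
    if regulon.species != omap.from_species:
        raise SpeciesMismatchError(
            f"regulon is {regulon.species!r}, map maps from {omap.from_species!r}"
        )
    dest: set[str] = set()
    dropped: set[str] = set()
    for target in regulon.targets:
        homologs = omap.homologs(target)
        if homologs:
            dest |= homologs
        else:
            dropped.add(target)
    report = TransferReport(
        source_count=len(regulon.targets),
        mapped_count=len(regulon.targets) - len(dropped),
        expanded_count=len(dest),
        dropped=frozenset(dropped),
    )
    if not dest:
        return None, report
    # the TF's own identity crosses species through the same map when present
    tf_homologs = omap.homologs(regulon.tf_id)
    tf_id = min(tf_homologs) if tf_homologs else regulon.tf_id
    return Regulon(tf_id=tf_id, targets=frozenset(dest), species=omap.to_species), report


@dataclass
class DBTransferResult:
    """A transferred regulon database plus per-TF reports and warnings."""

    db: RegulonDB
    reports: dict[str, TransferReport]
    warnings: list[str] = field(default_factory=list)


def transfer_db(db: RegulonDB, omap: OrthologMap) -> DBTransferResult:
    """Transfer every regulon; TFs mapping to nothing are excluded with a warning."""
    regulons: dict[str, Regulon] = {}
    reports: dict[str, TransferReport] = {}
    warnings: list[str] = []
    for tf_id, regulon in db.regulons.items():
        transferred, report = transfer_regulon(regulon, omap)
        reports[tf_id] = report
        if transferred is None:
            warnings.append(
                f"regulon {tf_id!r} has no targets with homologs in "
                f"{omap.to_species!r}; excluded"
            )
            continue
        regulons[transferred.tf_id] = transferred
    return DBTransferResult(
        db=RegulonDB(regulons=regulons, species=omap.to_species),
        reports=reports,
        warnings=warnings,
    )
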