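"""Domain types for regulon over-representation analysis.

The pipeline revolves around a handful of small containers: per-gene
differential-expression records (:class:`DEGene`, :class:`DETable`),
TF target sets (:class:`Regulon`, :class:`RegulonDB`), generic gene-set
collections, cross-species homology pairs, a sample-by-gene expression
matrix, and the per-TF enrichment result row.

Gene symbols are matched case-insensitively throughout (human symbols are
conventionally upper-case, zebrafish lower-case); the :func:`norm` helper
is the single normalisation point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "DomainError",
    "SpeciesMismatchError",
    "norm",
    "DEGene",
    "DETable",
    "Regulon",
    "RegulonDB",
    "GeneSetCollection",
    "OrthologMap",
    "ExpressionMatrix",
    "TailConvention",
    "EnrichmentRow",
    "CandidateTF",
    "TransferReport",
    "CorrelationRow",
    "PathwayRow",
    "CalibrationResult",
]


class FormatError(ValueError):
    """A file does not conform to its expected tabular dialect."""


class DomainError(ValueError):
    """A value violates a mathematical precondition (named in the message)."""


class SpeciesMismatchError(ValueError):
    """Two objects tagged with different species were combined."""


def norm(symbol: str) -> str:
    """Case-insensitive gene-symbol key."""
    return symbol.casefold()


@dataclass
class DEGene:
    """One gene's differential-expression record.

    ``padj`` is ``None`` for genes the DE tool did not assign an adjusted
    p-value (e.g. removed by independent filtering); such genes carry
    ``tested=False`` and are excluded from the expressed-gene universe.
    """

    gene_id: str
    log2fc: float
    padj: float | None = None
    group_means: Mapping[str, float] = field(default_factory=dict)
    tested: bool = True

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise DomainError("gene_id must be nonempty")
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise DomainError(f"padj must lie in [0, 1], got {self.padj}")
        for label, v in self.group_means.items():
            if v < 0:
                raise DomainError(f"group mean {label!r} must be >= 0, got {v}")
        if self.padj is None:
            self.tested = False

    @property
    def mean_expression(self) -> float:
        if not self.group_means:
            return math.nan
        return float(np.mean(list(self.group_means.values())))


@dataclass
class DETable:
    """A species-tagged differential-expression table, unique by gene id."""

    species: str
    genes: list[DEGene]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        dups: list[str] = []
        for g in self.genes:
            key = norm(g.gene_id)
            if key in seen:
                dups.append(g.gene_id)
            seen[key] = g.gene_id
        if dups:
            raise FormatError(f"duplicate gene ids: {sorted(set(dups))}")
        self._by_key = {norm(g.gene_id): g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def get(self, symbol: str) -> DEGene | None:
        return self._by_key.get(norm(symbol))

    @property
    def expressed(self) -> set[str]:
        """Normalised ids of all genes with a DE test result."""
        return {norm(g.gene_id) for g in self.genes if g.tested}

    def upregulated(self, alpha: float = 0.05, direction: str = "up") -> set[str]:
        """Normalised ids of significant genes in the requested direction.

        ``direction`` is one of ``up`` (log2FC > 0), ``down`` (< 0) or
        ``both``.  Monotone in ``alpha``.
        """
        if not (0.0 < alpha < 1.0):
            raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
        if direction not in ("up", "down", "both"):
            raise DomainError(f"direction must be up/down/both, got {direction!r}")
        out = set()
        for g in self.genes:
            if not g.tested or g.padj is None or g.padj >= alpha:
                continue
            if direction == "up" and g.log2fc <= 0:
                continue
            if direction == "down" and g.log2fc >= 0:
                continue
            out.add(norm(g.gene_id))
        return out


@dataclass
class Regulon:
    """A transcription factor and its inferred target-gene set."""

    tf_id: str
    targets: frozenset[str]
    species: str

    def __post_init__(self) -> None:
        if not self.targets:
            raise DomainError(f"regulon {self.tf_id!r} has no targets")
        self.targets = frozenset(norm(t) for t in self.targets)


@dataclass
class RegulonDB:
    """TF id -> Regulon map, all tagged with one species."""

    regulons: dict[str, Regulon]
    species: str

    def __post_init__(self) -> None:
        for tf, reg in self.regulons.items():
            if reg.species != self.species:
                raise SpeciesMismatchError(
                    f"regulon {tf!r} is {reg.species!r}, database is {self.species!r}"
                )
        self._by_key = {norm(tf): reg for tf, reg in self.regulons.items()}

    def __contains__(self, tf_id: str) -> bool:
        return norm(tf_id) in self._by_key

    def __len__(self) -> int:
        return len(self.regulons)

    def get(self, tf_id: str) -> Regulon | None:
        return self._by_key.get(norm(tf_id))


#: allowed collection kinds
COLLECTION_KINDS = ("pathway", "GO-CC", "GO-BP", "GO-MF", "TF-universe")


@dataclass
class GeneSetCollection:
    """Named gene sets of one kind (pathways, a GO slice, or a TF universe)."""

    sets: dict[str, tuple[str, frozenset[str]]]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in COLLECTION_KINDS:
            raise DomainError(f"unknown collection kind {self.kind!r}")
        normed = {}
        for set_id, (name, genes) in self.sets.items():
            if not genes:
                raise DomainError(f"gene set {set_id!r} is empty")
            normed[set_id] = (name, frozenset(norm(g) for g in genes))
        self.sets = normed

    def __len__(self) -> int:
        return len(self.sets)

    def members(self) -> set[str]:
        """Union of all member genes (normalised)."""
        out: set[str] = set()
        for _, genes in self.sets.values():
            out |= genes
        return out


@dataclass
class OrthologMap:
    """One-to-many/many-to-one gene-symbol homology pairs between species."""

    from_species: str
    to_species: str
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if not a or not b:
                raise DomainError("ortholog pair symbols must be nonempty")
        self.pairs = frozenset((norm(a), b) for a, b in self.pairs)
        fwd: dict[str, set[str]] = {}
        for a, b in self.pairs:
            fwd.setdefault(a, set()).add(b)
        self._fwd = fwd

    def __len__(self) -> int:
        return len(self.pairs)

    def homologs(self, symbol: str) -> set[str]:
        """Destination symbols for ``symbol`` (empty set if none)."""
        return set(self._fwd.get(norm(symbol), ()))

    def reversed(self) -> "OrthologMap":
        return OrthologMap(
            from_species=self.to_species,
            to_species=self.from_species,
            pairs=frozenset((b, a) for a, b in self.pairs),
        )


@dataclass
class ExpressionMatrix:
    """Sample-by-gene FPKM matrix with per-sample metadata.

    ``values`` is indexed by sample id with genes as columns; ``metadata``
    shares the sample index and may carry ``group`` (case/control) and
    ``age`` (years) columns.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise FormatError("sample ids must be unique")
        if not self.values.index.equals(self.metadata.index):
            raise FormatError("expression and metadata sample ids differ")
        if (self.values.to_numpy() < 0).any():
            raise DomainError("expression values must be >= 0")
        self._gene_key = {norm(c): c for c in self.values.columns}

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    def has_gene(self, symbol: str) -> bool:
        return norm(symbol) in self._gene_key

    def gene_values(self, symbol: str) -> np.ndarray:
        col = self._gene_key.get(norm(symbol))
        if col is None:
            raise KeyError(f"gene {symbol!r} absent from expression matrix")
        return self.values[col].to_numpy(dtype=float)


class TailConvention(str, Enum):
    """Upper-tail convention for the hypergeometric test.

    ``GE`` is P(X >= k), the standard over-representation definition;
    ``GT`` is the strict tail P(X > k).
    """

    GE = "ge"
    GT = "gt"


@dataclass
class EnrichmentRow:
    """One TF's over-representation result (a Table-1-shaped record)."""

    tf_id: str
    K_expressed: int
    k_up: int
    n_up: int
    N_universe: int
    p: float
    enriched: bool

    def __post_init__(self) -> None:
        if not (0 <= self.k_up <= min(self.K_expressed, self.n_up)):
            raise DomainError(
                f"need 0 <= k_up <= min(K_expressed, n_up); got k={self.k_up}, "
                f"K={self.K_expressed}, n={self.n_up}"
            )
        if self.K_expressed > self.N_universe:
            raise DomainError("K_expressed exceeds N_universe")
        if self.n_up > self.N_universe:
            raise DomainError("n_up exceeds N_universe")
        if not (0.0 <= self.p <= 1.0):
            raise DomainError(f"p must lie in [0, 1], got {self.p}")


@dataclass
class CandidateTF:
    """A TF selected for regulon enrichment.

    ``forced=True`` marks factors carried into the analysis on prior
    biological grounds although not differentially expressed themselves.
    """

    tf_id: str
    log2fc: float
    padj: float | None
    in_regulon_db: bool
    forced: bool
    mean_expression: float = math.nan


@dataclass
class TransferReport:
    """Bookkeeping for one regulon's ortholog transfer."""

    source_count: int
    mapped_count: int
    expanded_count: int
    dropped: frozenset[str]

    def __post_init__(self) -> None:
        if self.mapped_count + len(self.dropped) != self.source_count:
            raise DomainError("mapped_count + |dropped| must equal source_count")


@dataclass
class CorrelationRow:
    """Spearman correlation of a gene with another gene or a covariate."""

    gene_a: str
    gene_b: str
    rho: float
    p: float
    n: int
    method: str  # "exact-permutation" | "t-approximation"

    def __post_init__(self) -> None:
        if abs(self.rho) > 1 + 1e-12:
            raise DomainError(f"|rho| must be <= 1, got {self.rho}")
        if not (0.0 < self.p <= 1.0):
            raise DomainError(f"p must lie in (0, 1], got {self.p}")
        if self.n < 3:
            raise DomainError("need n >= 3 paired samples")


@dataclass
class PathwayRow:
    """One gene set's over-representation result plus TF-target counts."""

    set_id: str
    name: str
    K_expressed: int
    k_up: int
    p: float
    padj: float
    tf_target_counts: dict[str, int] = field(default_factory=dict)

    def multiple_flag(self, tf_id: str) -> bool:
        return self.tf_target_counts.get(tf_id, 0) > 1


@dataclass
class CalibrationResult:
    """Universe sizes consistent with an anchor enrichment row.

    ``windows`` maps each scanned tail convention to the inclusive
    ``(lo, hi)`` intervals of universe sizes N reproducing the anchor's
    printed p-value at its printed precision.  ``n_chosen`` is the midpoint
    of the widest window of the best-fitting convention, or ``None`` when no
    N fits.  ``uninformative`` flags anchors (k=0, p=1) consistent with the
    whole range.
    """

    windows: dict[TailConvention, list[tuple[int, int]]]
    n_chosen: int | None
    convention: TailConvention | None
    uninformative: bool = False

    @property
    def has_solution(self) -> bool:
        return self.n_chosen is not None


def as_normset(symbols: Iterable[str]) -> set[str]:
    """Normalise an iterable of symbols into a comparison set."""
    return {norm(s) for s in symbols}
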