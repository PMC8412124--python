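"""Exact hypergeometric over-representation of TF targets among DE genes.

The central statistic is the hypergeometric upper tail: drawing ``n``
upregulated genes from a universe of ``N`` expressed genes of which ``K``
are targets of a TF, the enrichment p-value is

    P(X >= k) = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

(the ``GE`` convention; ``GT`` starts the sum at k+1).  The sum is
evaluated in log-space (log-gamma terms combined with log-sum-exp) so that
tail probabilities down to ~1e-23 keep full relative precision — naive
1 - CDF subtraction would lose them entirely.

Published enrichment tables often print (K, k, p) per TF but not the
universe size N.  :func:`calibrate_universe` inverts one anchor row: it
scans a range of plausible N and returns every value whose recomputed
p-value rounds to the anchor's printed figure at its printed precision,
for each candidate tail convention.
"""

from __future__ import annotations

import math
import re
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .model import (
    CandidateTF,
    CalibrationResult,
    DETable,
    DomainError,
    EnrichmentRow,
    Regulon,
    RegulonDB,
    SpeciesMismatchError,
    TailConvention,
)

__all__ = [
    "hypergeom_upper_tail",
    "log_hypergeom_upper_tail",
    "regulon_overlap",
    "enrich_tfs",
    "calibrate_universe",
    "bh_adjust",
    "matches_printed",
]


def _check_counts(N: int, K: int, n: int, k: int) -> None:
    if not 0 <= k:
        raise DomainError(f"violated 0 <= k: k={k}")
    if k > min(K, n):
        raise DomainError(f"violated k <= min(K, n): k={k}, K={K}, n={n}")
    if K > N:
        raise DomainError(f"violated K <= N: K={K}, N={N}")
    if n > N:
        raise DomainError(f"violated n <= N: n={n}, N={N}")
    if K < 0 or n < 0 or N < 0:
        raise DomainError("counts must be nonnegative")


def _log_pmf_terms(N: int, K: int, n: int, i: np.ndarray) -> np.ndarray:
    """log P(X = i) for hypergeometric(N, K, n) at integer array ``i``.

    Entries with zero probability (n - i > N - K) come back as -inf.
    """
    i = np.asarray(i, dtype=np.int64)
    valid = (i >= 0) & (i <= K) & (n - i >= 0) & (n - i <= N - K)
    out = np.full(i.shape, -np.inf, dtype=float)
    iv = i[valid]
    out[valid] = (
        gammaln(K + 1) - gammaln(iv + 1) - gammaln(K - iv + 1)
        + gammaln(N - K + 1) - gammaln(n - iv + 1) - gammaln(N - K - (n - iv) + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return out


def log_hypergeom_upper_tail(
    N: int, K: int, n: int, k: int,
    convention: TailConvention = TailConvention.GE,
) -> float:
    """Natural log of the upper-tail probability (-inf for an empty tail)."""
    _check_counts(N, K, n, k)
    lo = k if convention is TailConvention.GE else k + 1
    hi = min(K, n)
    if lo > hi:
        return -math.inf
    if lo <= 0:
        return 0.0  # the sum spans the whole support: exactly 1
    terms = _log_pmf_terms(N, K, n, np.arange(lo, hi + 1))
    return float(min(logsumexp(terms), 0.0))


def hypergeom_upper_tail(
    N: int, K: int, n: int, k: int,
    convention: TailConvention = TailConvention.GE,
) -> float:
    """Upper-tail hypergeometric probability.

    Under ``GE`` the result lies in (0, 1]; under ``GT`` the empty sum at
    k = min(K, n) returns exactly 0 — the only case a zero is produced.
    """
    lp = log_hypergeom_upper_tail(N, K, n, k, convention)
    return 0.0 if lp == -math.inf else min(1.0, math.exp(lp))


def regulon_overlap(
    regulon: Regulon, de: DETable, alpha: float = 0.05, direction: str = "up"
) -> tuple[int, int]:
    """Count a regulon's targets among expressed and significant DE genes.

    Returns ``(K_expressed, k_up)``; symbol matching is case-insensitive.
    """
    if regulon.species != de.species:
        raise SpeciesMismatchError(
            f"regulon is {regulon.species!r}, DE table is {de.species!r}"
        )
    expressed = de.expressed
    up = de.upregulated(alpha, direction)
    return len(regulon.targets & expressed), len(regulon.targets & up)


def enrich_tfs(
    candidates: Sequence[CandidateTF],
    db: RegulonDB,
    de: DETable,
    alpha: float = 0.05,
    convention: TailConvention = TailConvention.GE,
    direction: str = "up",
    enriched_threshold: float = 0.05,
) -> list[EnrichmentRow]:
    """One hypergeometric enrichment row per candidate TF, sorted by p.

    The universe is the expressed-gene set of ``de``; a candidate without
    a regulon in ``db`` is an upstream contract violation and raises.
    """
    expressed = de.expressed
    up = de.upregulated(alpha, direction)
    N, n = len(expressed), len(up)
    rows: list[EnrichmentRow] = []
    for cand in candidates:
        reg = db.get(cand.tf_id)
        if reg is None:
            raise KeyError(f"candidate TF {cand.tf_id!r} has no regulon in the database")
        K, k = regulon_overlap(reg, de, alpha, direction)
        p = hypergeom_upper_tail(N, K, n, k, convention)
        rows.append(
            EnrichmentRow(
                tf_id=cand.tf_id,
                K_expressed=K,
                k_up=k,
                n_up=n,
                N_universe=N,
                p=p,
                enriched=p < enriched_threshold,
            )
        )
    rows.sort(key=lambda r: (r.p, r.tf_id))
    return rows


_SCI_RE = re.compile(r"^\s*([0-9]*\.?[0-9]+)\s*[eE]\s*([+-]?[0-9]+)\s*$")


def matches_printed(value: float, printed: str) -> bool:
    """Does ``value`` round to the printed p-value at its printed precision?

    ``"2.10E-07"`` is compared at 3 significant digits, ``"0.0009"`` at 4
    decimal places, ``"0.56"`` at 2 — the precision is read off the
    literal itself.
    """
    printed = printed.strip().replace("−", "-").replace("‐", "-")
    m = _SCI_RE.match(printed)
    if m:
        mantissa = m.group(1)
        decimals = len(mantissa.split(".")[1]) if "." in mantissa else 0
        if value <= 0:
            return False
        return format(value, f".{decimals}e") == format(float(printed), f".{decimals}e")
    if "." in printed:
        decimals = len(printed.split(".")[1])
    else:
        decimals = 0
    return abs(round(value, decimals) - float(printed)) < 10.0 ** -(decimals + 6)


def _tail_over_range(
    Ns: np.ndarray, K: int, n: int, k: int, convention: TailConvention,
    chunk: int = 2048,
) -> np.ndarray:
    """Vectorised upper tail over an array of universe sizes."""
    lo = k if convention is TailConvention.GE else k + 1
    hi = min(K, n)
    out = np.ones(len(Ns), dtype=float)
    if lo > hi:
        return np.zeros(len(Ns), dtype=float)
    if lo <= 0:
        return out
    i = np.arange(lo, hi + 1, dtype=np.int64)
    const = gammaln(K + 1) - gammaln(i + 1) - gammaln(K - i + 1) - gammaln(n - i + 1)
    for start in range(0, len(Ns), chunk):
        Nb = Ns[start:start + chunk, None].astype(np.int64)
        rest = Nb - K - (n - i)[None, :]
        valid = rest >= 0
        with np.errstate(invalid="ignore"):
            t = (
                const[None, :]
                + gammaln(np.maximum(Nb - K, 0) + 1)
                - gammaln(np.maximum(rest, 0) + 1)
                - (gammaln(Nb + 1) - gammaln(n + 1) - gammaln(Nb - n + 1))
            )
        terms = np.where(valid, t, -np.inf)
        out[start:start + chunk] = np.exp(logsumexp(terms, axis=1))
    return np.minimum(out, 1.0)


def _intervals(values: np.ndarray) -> list[tuple[int, int]]:
    """Collapse a sorted integer array into inclusive (lo, hi) runs."""
    if len(values) == 0:
        return []
    runs = []
    lo = prev = int(values[0])
    for v in values[1:]:
        v = int(v)
        if v == prev + 1:
            prev = v
        else:
            runs.append((lo, prev))
            lo = prev = v
    runs.append((lo, prev))
    return runs


def calibrate_universe(
    K: int,
    k: int,
    n: int,
    printed_p: str,
    n_range: tuple[int, int] = (8000, 40000),
    conventions: Iterable[TailConvention] = (TailConvention.GE, TailConvention.GT),
) -> CalibrationResult:
    """Recover universe sizes N consistent with an anchor enrichment row.

    Scans integer N over ``n_range`` (inclusive) and keeps those where the
    recomputed upper tail rounds to ``printed_p`` at its printed precision.
    ``n_chosen`` is the midpoint of the widest run of consistent N under
    the best-fitting convention (the one with the most consistent sizes;
    ties favour GE).  An empty scan yields an explicit no-solution result.
    """
    lo_N = max(n_range[0], K, n)
    Ns = np.arange(lo_N, n_range[1] + 1, dtype=np.int64)
    windows: dict[TailConvention, list[tuple[int, int]]] = {}
    counts: dict[TailConvention, int] = {}
    for conv in conventions:
        if len(Ns) == 0:
            windows[conv] = []
            counts[conv] = 0
            continue
        ps = _tail_over_range(Ns, K, n, k, conv)
        ok = np.array([matches_printed(p, printed_p) for p in ps])
        windows[conv] = _intervals(Ns[ok])
        counts[conv] = int(ok.sum())

    uninformative = (
        k == 0
        and any(counts.values())
        and all(
            counts[c] == len(Ns) for c in windows if counts[c] > 0
        )
    )
    best: TailConvention | None = None
    for conv in conventions:  # iteration order = preference order
        if counts[conv] and (best is None or counts[conv] > counts[best]):
            best = conv
    if best is None:
        return CalibrationResult(windows=windows, n_chosen=None, convention=None)
    widest = max(windows[best], key=lambda w: w[1] - w[0])
    n_chosen = (widest[0] + widest[1]) // 2
    return CalibrationResult(
        windows=windows,
        n_chosen=n_chosen,
        convention=best,
        uninformative=uninformative,
    )


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out.tolist()
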