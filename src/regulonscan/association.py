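"""Spearman rank correlation with an exact permutation null for small n.

Cohort sizes in post-mortem/resection brain studies are tiny (here ~10-12
samples per group), so the large-sample t-approximation for Spearman's
rho is questionable.  For n <= 10 samples without ties this module
enumerates the full n! permutation null of the rank statistic

    rho = 1 - 6 * S / (n (n^2 - 1)),   S = sum_i (r_i - q_i)^2

and reports the exact two-sided p-value P(|rho_perm| >= |rho|).  With
ties, or above n = 10 (12! is no longer interactive), it falls back to
the t-approximation  t = rho * sqrt((n-2) / (1 - rho^2))  on n-2 degrees
of freedom.
"""

from __future__ import annotations

import itertools
import math
import warnings as _warnings
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .model import CorrelationRow, DomainError, ExpressionMatrix, norm

__all__ = [
    "spearman_rho",
    "spearman_p",
    "correlate_pair",
    "correlate_tf_targets",
    "correlate_covariate",
    "EXACT_N_MAX",
]

#: largest n for which the full n! permutation null is enumerated
EXACT_N_MAX = 10


def _as_vector(x: Sequence[float]) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise DomainError("inputs must be 1-D vectors")
    return v


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rho: Pearson correlation of midranks."""
    xv, yv = _as_vector(x), _as_vector(y)
    if len(xv) != len(yv):
        raise DomainError(f"length mismatch: {len(xv)} vs {len(yv)}")
    if len(xv) < 3:
        raise DomainError("need n >= 3 paired observations")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DomainError("correlation undefined for a constant vector")
    rx = stats.rankdata(xv)  # average (mid-) ranks for ties
    ry = stats.rankdata(yv)
    return float(np.corrcoef(rx, ry)[0, 1])


@lru_cache(maxsize=None)
def _exact_abs_rho_distribution(n: int) -> tuple[np.ndarray, np.ndarray]:
    """(|rho| values, permutation counts) over all n! rank permutations.

    Without ties the statistic depends only on S = sum of squared rank
    differences, whose permutation distribution is tabulated once per n
    and cached.
    """
    base = np.arange(n, dtype=np.int64)
    nperm = math.factorial(n)
    flat = np.fromiter(
        itertools.chain.from_iterable(itertools.permutations(range(n))),
        dtype=np.int8,
        count=nperm * n,
    ).reshape(nperm, n)
    S = ((flat.astype(np.int32) - base) ** 2).sum(axis=1)
    counts = np.bincount(S)
    s_values = np.nonzero(counts)[0]
    rho = 1.0 - 6.0 * s_values / (n * (n * n - 1))
    return np.abs(rho), counts[s_values].astype(np.int64)


def spearman_p(
    rho: float,
    n: int,
    mode: str = "exact",
    mc_samples: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided p-value for an observed Spearman rho at sample size n.

    ``mode='exact'`` enumerates all n! rank permutations (n <= 10), or
    Monte-Carlo samples the null when ``mc_samples`` is given; the exact
    null assumes no ties.  ``mode='approx'`` uses the t-approximation.
    """
    if n < 3:
        raise DomainError("need n >= 3")
    if abs(rho) > 1 + 1e-12:
        raise DomainError(f"|rho| must be <= 1, got {rho}")
    rho = float(np.clip(rho, -1.0, 1.0))
    if mode == "approx":
        if abs(rho) >= 1.0:
            return float(2.0 * stats.t.sf(np.inf, df=n - 2))  # 0.0-adjacent
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        return float(2.0 * stats.t.sf(abs(t), df=n - 2))
    if mode != "exact":
        raise DomainError(f"mode must be 'exact' or 'approx', got {mode!r}")
    if n > EXACT_N_MAX:
        if mc_samples is None:
            raise DomainError(
                f"exact enumeration is limited to n <= {EXACT_N_MAX}; "
                "supply mc_samples for a Monte-Carlo null or use mode='approx'"
            )
        rng = np.random.default_rng() if rng is None else rng
        base = np.arange(n, dtype=float)
        hits = 0
        for _ in range(mc_samples):
            perm = rng.permutation(n)
            s = ((perm - base) ** 2).sum()
            r = 1.0 - 6.0 * s / (n * (n * n - 1))
            if abs(r) >= abs(rho) - 1e-12:
                hits += 1
        return max(hits, 1) / mc_samples
    abs_rho, counts = _exact_abs_rho_distribution(n)
    mask = abs_rho >= abs(rho) - 1e-12
    return float(counts[mask].sum() / counts.sum())


def correlate_pair(
    x: Sequence[float],
    y: Sequence[float],
    warn_sink: list[str] | None = None,
) -> tuple[float, float, str]:
    """rho, two-sided p, and the method actually used.

    Exact enumeration for n <= 10 tie-free vectors; otherwise the
    t-approximation (with a warning when ties forced the fallback).
    """
    xv, yv = _as_vector(x), _as_vector(y)
    rho = spearman_rho(xv, yv)
    n = len(xv)
    has_ties = len(np.unique(xv)) < n or len(np.unique(yv)) < n
    if n <= EXACT_N_MAX and not has_ties:
        return rho, spearman_p(rho, n, mode="exact"), "exact-permutation"
    if n <= EXACT_N_MAX and has_ties:
        msg = "ties present: exact permutation null disabled, using t-approximation"
        if warn_sink is not None:
            warn_sink.append(msg)
        else:
            _warnings.warn(msg, stacklevel=2)
    return rho, spearman_p(rho, n, mode="approx"), "t-approximation"


def correlate_tf_targets(
    expr: ExpressionMatrix,
    tf: str,
    targets: Iterable[str],
    rho_min: float = 0.70,
    p_max: float = 0.05,
) -> tuple[list[CorrelationRow], int, list[str]]:
    """Correlate a TF's expression with each of its targets across samples.

    Returns one row per present target, the count passing the one-sided
    confirmation filter (rho > rho_min and p < p_max), and warnings for
    targets absent from the matrix.  The TF itself must be present.
    """
    if not expr.has_gene(tf):
        raise KeyError(f"TF {tf!r} absent from expression matrix")
    x = expr.gene_values(tf)
    rows: list[CorrelationRow] = []
    warnings_list: list[str] = []
    passing = 0
    for target in sorted(set(norm(t) for t in targets)):
        if norm(target) == norm(tf):
            continue
        if not expr.has_gene(target):
            warnings_list.append(f"target {target!r} absent from expression matrix; skipped")
            continue
        y = expr.gene_values(target)
        rho, p, method = correlate_pair(x, y, warn_sink=warnings_list)
        rows.append(
            CorrelationRow(gene_a=tf, gene_b=target, rho=rho, p=p,
                           n=len(x), method=method)
        )
        if rho > rho_min and p < p_max:
            passing += 1
    return rows, passing, warnings_list


def correlate_covariate(
    expr: ExpressionMatrix,
    gene: str,
    covariate: str = "age",
    group: str | None = None,
) -> CorrelationRow:
    """Correlate one gene's expression with a sample covariate within a group."""
    meta = expr.metadata
    if group is not None:
        if "group" not in meta.columns:
            raise DomainError("metadata has no 'group' column")
        mask = (meta["group"] == group).to_numpy()
    else:
        mask = np.ones(len(meta), dtype=bool)
    if covariate not in meta.columns:
        raise DomainError(f"covariate {covariate!r} absent from sample metadata")
    cov = meta[covariate].to_numpy(dtype=float)[mask]
    if np.isnan(cov).any():
        bad = [s for s, v in zip(np.asarray(expr.samples)[mask], cov) if np.isnan(v)]
        raise DomainError(f"covariate {covariate!r} missing for samples {bad}")
    if mask.sum() < 3:
        raise DomainError(f"need n >= 3 samples in group {group!r}, got {int(mask.sum())}")
    x = expr.gene_values(gene)[mask]
    rho, p, method = correlate_pair(x, cov)
    return CorrelationRow(
        gene_a=gene,
        gene_b=covariate if group is None else f"{covariate}[{group}]",
        rho=rho, p=p, n=int(mask.sum()), method=method,
    )
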