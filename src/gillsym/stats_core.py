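"""Generic statistics used across the pipeline.

Implements, from the standard closed forms, the small set of tests the
analysis needs: Pearson and Spearman correlation with two-sided p-values,
Benjamini-Hochberg and Holm multiple-testing corrections, the tie-corrected
Kruskal-Wallis omnibus test, and Dunn's post hoc pairwise z-tests with a
compact letter display.  Only distribution functions (Student t, chi-square,
standard normal) are delegated to scipy.

Conventions
-----------
* Correlation p-values are two-sided, from the t-distribution with n-2 df;
  Spearman uses the same t-approximation on rank correlations (mid-ranks for
  ties), the default behaviour of the common reference implementations.
* Holm returns adjusted p-values (step-down, monotonicity enforced,
  clipped to 1); BH returns step-up q-values.
* Dunn z-statistics use the tie-corrected pooled variance of mean-rank
  differences and two-sided normal p-values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sps

from .errors import DataError, StatPreconditionError

__all__ = [
    "CorrelationResult",
    "PairwiseComparison",
    "GroupComparisonResult",
    "pearson",
    "spearman",
    "bh_fdr",
    "holm",
    "kruskal_wallis",
    "dunn_posthoc",
]


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    p_value: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.coefficient <= 1.0 + 1e-12:
            raise DataError(f"correlation coefficient out of range: {self.coefficient}")


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_holm: float


@dataclass
class GroupComparisonResult:
    """Kruskal-Wallis omnibus result, optionally with Dunn post hoc output."""

    H: float
    p_value: float
    groups: list[tuple[str, int]]
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    letters: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def _as_float_arrays(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1:
        raise DataError("correlation inputs must be 1-dimensional")
    if len(xa) != len(ya):
        raise DataError(f"length mismatch: {len(xa)} vs {len(ya)}")
    if len(xa) < 3:
        raise DataError("need n >= 3 for a correlation p-value")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DataError("correlation undefined for a constant vector")
    return xa, ya


def _corr_p(r: float, n: int) -> float:
    """Two-sided p from the t-distribution with n-2 df."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * _sps.t.sf(abs(t), df=n - 2))


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided t-test p-value."""
    xa, ya = _as_float_arrays(x, y)
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    r = float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    return CorrelationResult(r, _corr_p(r, len(xa)), len(xa), "pearson")


def _midranks(a: np.ndarray) -> np.ndarray:
    order = np.argsort(a, kind="mergesort")
    ranks = np.empty(len(a), dtype=float)
    sa = a[order]
    i = 0
    while i < len(a):
        j = i
        while j + 1 < len(a) and sa[j + 1] == sa[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation (mid-ranks for ties, t-approximation p)."""
    xa, ya = _as_float_arrays(x, y)
    rho_res = pearson(_midranks(xa), _midranks(ya))
    return CorrelationResult(rho_res.coefficient, rho_res.p_value, len(xa), "spearman")


# ---------------------------------------------------------------------------
# multiple-testing corrections
# ---------------------------------------------------------------------------

def _check_pvec(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    return p


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = _check_pvec(p_values)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def holm(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, order-preserving."""
    p = _check_pvec(p_values)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    stepped = p[order] * (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn's test
# ---------------------------------------------------------------------------

def _prep_groups(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]
                 ) -> dict[str, np.ndarray]:
    if isinstance(groups, Mapping):
        named = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    else:
        named = {f"group{i + 1}": np.asarray(v, dtype=float) for i, v in enumerate(groups)}
    if len(named) < 2:
        raise DataError("need at least 2 groups")
    for label, arr in named.items():
        if arr.size == 0:
            raise DataError(f"group {label!r} is empty")
    return named


def _rank_setup(named: dict[str, np.ndarray]):
    labels = list(named)
    pooled = np.concatenate([named[g] for g in labels])
    ranks = _midranks(pooled)
    n = len(pooled)
    split, start = {}, 0
    for g in labels:
        k = len(named[g])
        split[g] = ranks[start : start + k]
        start += k
    # tie term: sum over tied groups of (t^3 - t)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    return labels, split, n, tie_sum


def kruskal_wallis(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]
                   ) -> GroupComparisonResult:
    """Tie-corrected Kruskal-Wallis H test.

    Degenerate input where every pooled value is identical yields H = 0 and
    p = 1 rather than an error, so fully tied synthetic data pass through.
    """
    named = _prep_groups(groups)
    labels, split, n, tie_sum = _rank_setup(named)
    h = 12.0 / (n * (n + 1)) * sum(
        split[g].sum() ** 2 / len(split[g]) for g in labels
    ) - 3.0 * (n + 1)
    correction = 1.0 - tie_sum / (n**3 - n) if n > 1 else 1.0
    if correction <= 0:  # all values identical
        h, p = 0.0, 1.0
    else:
        h = h / correction
        h = max(h, 0.0)
        p = float(_sps.chi2.sf(h, df=len(labels) - 1))
    return GroupComparisonResult(H=float(h), p_value=p,
                                 groups=[(g, len(named[g])) for g in labels])


def _compact_letters(labels: Sequence[str], significant: set[frozenset[str]],
                     mean_rank: Mapping[str, float]) -> dict[str, str]:
    """Insert-absorb compact letter display.

    Start from one letter covering all groups; split on every significantly
    different pair; absorb redundant subsets.  Groups sharing a letter are
    pairwise not significantly different, and every non-different pair shares
    at least one letter.
    """
    letter_sets: list[set[str]] = [set(labels)]
    for pair in significant:
        a, b = tuple(pair)
        new_sets: list[set[str]] = []
        for ls in letter_sets:
            if a in ls and b in ls:
                new_sets.extend([ls - {a}, ls - {b}])
            else:
                new_sets.append(ls)
        # absorb: drop sets contained in another
        new_sets = [s for s in new_sets if s and not any(
            s < t for t in new_sets)]
        deduped: list[set[str]] = []
        for s in new_sets:
            if s not in deduped:
                deduped.append(s)
        letter_sets = deduped
    letter_sets.sort(key=lambda s: min(mean_rank[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {g: "" for g in labels}
    for i, ls in enumerate(letter_sets):
        ch = alphabet[i % len(alphabet)]
        for g in ls:
            out[g] += ch
    return out


def dunn_posthoc(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
                 alpha: float = 0.05, force: bool = False) -> GroupComparisonResult:
    """Dunn's post hoc pairwise comparisons with Holm correction.

    Runs the Kruskal-Wallis omnibus first; unless ``force`` is set, a
    non-significant omnibus raises :class:`StatPreconditionError`.  Pairwise
    z statistics use mean-rank differences over the tie-corrected pooled
    variance; p-values are two-sided normal, Holm-adjusted across all
    g(g-1)/2 pairs.  ``letters`` carries the compact letter display: groups
    sharing a letter are not significantly different at ``alpha``.
    """
    named = _prep_groups(groups)
    omnibus = kruskal_wallis(named)
    if omnibus.p_value > alpha and not force:
        raise StatPreconditionError(
            f"Kruskal-Wallis not significant (p={omnibus.p_value:.4g} > {alpha}); "
            "pass force=True to run Dunn's test anyway"
        )
    labels, split, n, tie_sum = _rank_setup(named)
    mean_rank = {g: float(split[g].mean()) for g in labels}
    base_var = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1)) if n > 1 else 0.0
    pairs = list(itertools.combinations(labels, 2))
    zs, praw = [], []
    for a, b in pairs:
        se = math.sqrt(base_var * (1.0 / len(split[a]) + 1.0 / len(split[b])))
        z = 0.0 if se == 0 else (mean_rank[a] - mean_rank[b]) / se
        zs.append(z)
        praw.append(1.0 if se == 0 else float(2.0 * _sps.norm.sf(abs(z))))
    padj = holm(praw)
    pairwise = [
        PairwiseComparison(a, b, z=zs[i], p_raw=praw[i], p_holm=float(padj[i]))
        for i, (a, b) in enumerate(pairs)
    ]
    significant = {
        frozenset((c.group_a, c.group_b)) for c in pairwise if c.p_holm <= alpha
    }
    letters = _compact_letters(labels, significant, mean_rank)
    return GroupComparisonResult(H=omnibus.H, p_value=omnibus.p_value,
                                 groups=omnibus.groups, pairwise=pairwise,
                                 letters=letters)
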