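"""Richness-preserving null models for symbiont co-occurrence.

The null hypothesis throughout: each host specimen acquires its observed
number of symbiont species k_i as a uniformly random k_i-subset of the
S-species candidate pool, independently across specimens.  Host-level
richness is preserved; species identities carry no signal.  Against this
null the module provides

* :func:`pair_inclusion_prob` -- the exact probability C(S-2, k-2)/C(S, k)
  = k(k-1)/(S(S-1)) that a *specific* pair of species is included in one
  host of richness k (zero for k < 2);
* :func:`pair_absence_test` -- the exact Poisson-binomial test for pairs of
  species never observed together: P(no co-occurrence anywhere) =
  prod_i (1 - p_i) over specimens;
* :func:`guarantee_prob` -- the probability that *every* host community
  contains at least one of m designated species (used for the nitrogen-fixer
  guarantee), prod_i [1 - C(S-m, k_i)/C(S, k_i)];
* :func:`mc_randomize` -- Monte Carlo tabulation of null frequencies for
  whole community patterns, with empirical 95% envelopes, two-sided
  pseudocount p-values and BH/Holm corrections;
* :func:`exact_combination_null` -- the closed-form binomial null for one
  fixed combination, the independent check on the Monte Carlo machinery;
* :func:`cooccurrence_report` -- the per-host-group and combined report.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sps

from .errors import DataError
from .io_model import COMBINED, PresenceMatrix
from .stats_core import bh_fdr, holm

__all__ = [
    "NullTestConfig",
    "CombinationTestResult",
    "PairAbsenceResult",
    "GuaranteeResult",
    "CooccurrenceReport",
    "pair_inclusion_prob",
    "pair_absence_test",
    "guarantee_prob",
    "exact_combination_null",
    "mc_randomize",
    "cooccurrence_report",
]

_UNIVERSES = ("sizes_present", "all_nonempty", "observed_only")


@dataclass
class NullTestConfig:
    """Knobs of the Monte Carlo randomization test.

    replicates
        Number of random community redraws (10 000 in the reference
        analysis).
    envelope_level
        Central coverage of the null envelope (0.95 -> the 2.5% and 97.5%
        empirical order statistics).
    pseudocount_correction
        Use (count+1)/(reps+1) tail estimates so a Monte Carlo p-value is
        never exactly zero.
    combination_universe
        Which combinations form the tested (and multiplicity-corrected)
        family: every pool subset whose size occurs among the specimens
        (``sizes_present``, default), every non-empty subset
        (``all_nonempty``), or only the observed patterns
        (``observed_only``).
    """

    replicates: int = 10_000
    seed: int | None = None
    envelope_level: float = 0.95
    pseudocount_correction: bool = True
    combination_universe: str = "sizes_present"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise DataError("replicates must be >= 1")
        if not 0.0 < self.envelope_level < 1.0:
            raise DataError("envelope_level must lie in (0, 1)")
        if self.combination_universe not in _UNIVERSES:
            raise DataError(
                f"combination_universe must be one of {_UNIVERSES}")


@dataclass(frozen=True)
class CombinationTestResult:
    """Observed vs null frequency of one exact community pattern."""

    pattern: frozenset[str]
    observed: int
    null_mean: float
    env_low: int
    env_high: int
    p_two: float
    q_bh: float
    p_holm: float

    @property
    def size(self) -> int:
        return len(self.pattern)

    def label(self) -> str:
        return "+".join(sorted(self.pattern))


@dataclass(frozen=True)
class PairAbsenceResult:
    """Exact Poisson-binomial result for one never-co-occurring pair."""

    pair: frozenset[str]
    p_exact: float
    q_bh: float
    p_holm: float


@dataclass(frozen=True)
class GuaranteeResult:
    """P(every host draws >= 1 designated species) under the null."""

    designated_set: frozenset[str]
    probability: float
    n_specimens: int
    pool_size: int


@dataclass
class CooccurrenceReport:
    """Bundle of all null-model outputs for one dataset."""

    per_group: dict[str, list[CombinationTestResult]]
    pair_absence: list[PairAbsenceResult]
    guarantee: GuaranteeResult | None
    config: NullTestConfig


# ---------------------------------------------------------------------------
# exact probabilities
# ---------------------------------------------------------------------------

def pair_inclusion_prob(k: int, S: int) -> float:
    """P(a specific species pair is drawn by a host of richness k).

    Under a uniform k-subset of an S-species pool this is
    C(S-2, k-2) / C(S, k) = k(k-1) / (S(S-1)) for k >= 2, and 0 for k < 2.
    """
    if S < 2:
        raise DataError("pool size S must be >= 2")
    if k < 0 or k > S:
        raise DataError(f"richness k={k} out of range for S={S}")
    if k < 2:
        return 0.0
    return math.comb(S - 2, k - 2) / math.comb(S, k)


def _subset_inclusion_prob(k: int, S: int, m: int) -> float:
    """P(a uniform k-subset of S avoids all m designated species)."""
    if k > S - m:
        return 0.0
    return math.comb(S - m, k) / math.comb(S, k)


def guarantee_prob(richness: Sequence[int], S: int, m: int,
                   designated: Iterable[str] | None = None) -> GuaranteeResult:
    """Probability every host community includes >= 1 designated species.

    ``richness`` are the observed per-host k_i (preserved by the null); ``m``
    of the ``S`` pool species are designated (e.g. the nitrogen fixers).
    Independence across hosts gives
    prod_i [1 - C(S-m, k_i)/C(S, k_i)], with C(S-m, k)=0 whenever k > S-m.
    An empty richness vector is vacuously guaranteed (probability 1).
    """
    if not 0 <= m <= S:
        raise DataError(f"designated count m={m} out of range for S={S}")
    ks = [int(k) for k in richness]
    prob = 1.0
    for k in ks:
        if not 0 <= k <= S:
            raise DataError(f"richness value {k} out of range for S={S}")
        # a host drawing k species misses all m designated ones w.p. C(S-m,k)/C(S,k);
        # k = 0 always misses (probability 0 of including one) when m > 0
        prob *= 1.0 - _subset_inclusion_prob(k, S, m)
    designated_set = frozenset(designated) if designated is not None else frozenset()
    return GuaranteeResult(designated_set=designated_set, probability=float(prob),
                           n_specimens=len(ks), pool_size=S)


def pair_absence_test(
    pm: PresenceMatrix,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[PairAbsenceResult]:
    """Exact Poisson-binomial test for species pairs never seen together.

    For each candidate pair the number of hosts containing both species is a
    Poisson-binomial sum over hosts with success probabilities
    p_i = pair_inclusion_prob(k_i, S); the exact p-value for total absence
    is P(sum = 0) = prod_i (1 - p_i).  BH and Holm corrections are applied
    across the tested pairs as the family.

    ``pairs`` defaults to every unordered pool pair with zero observed
    co-occurrences.  Supplying a pair that *is* observed together raises
    :class:`DataError` (the absence test is undefined for it).
    """
    S = pm.pool_size
    ks = pm.richness().to_numpy()
    if pairs is None:
        pairs = [
            (a, b)
            for a, b in itertools.combinations(pm.pool, 2)
            if pm.cooccurrence_count(a, b) == 0
        ]
    else:
        pairs = [tuple(p) for p in pairs]
        for a, b in pairs:
            if pm.cooccurrence_count(a, b) > 0:
                raise DataError(
                    f"pair ({a}, {b}) is observed together; absence test undefined")
    p_exact = [
        float(np.prod([1.0 - pair_inclusion_prob(int(k), S) for k in ks]))
        for _ in pairs
    ]
    q = bh_fdr(p_exact)
    ph = holm(p_exact)
    return [
        PairAbsenceResult(pair=frozenset(pairs[i]), p_exact=p_exact[i],
                          q_bh=float(q[i]), p_holm=float(ph[i]))
        for i in range(len(pairs))
    ]


def exact_combination_null(n_k: int, S: int, k: int, observed: int
                           ) -> tuple[float, float]:
    """Closed-form null for the frequency of one fixed k-combination.

    Among the n_k hosts of richness k, each independently realises the fixed
    combination with probability 1/C(S, k), so the null count is
    Binomial(n_k, 1/C(S, k)).  Returns (expected count, exact two-sided p)
    with p = min(1, 2 * min(P(X >= obs), P(X <= obs))).
    """
    if n_k < 0:
        raise DataError("n_k must be >= 0")
    if not 0 < k <= S:
        raise DataError(f"combination size k={k} out of range for S={S}")
    if observed > n_k:
        raise DataError(f"observed={observed} exceeds the {n_k} hosts of richness {k}")
    prob = 1.0 / math.comb(S, k)
    expected = n_k * prob
    if n_k == 0:
        return 0.0, 1.0
    upper = float(_sps.binom.sf(observed - 1, n_k, prob))  # P(X >= obs)
    lower = float(_sps.binom.cdf(observed, n_k, prob))     # P(X <= obs)
    p_two = min(1.0, 2.0 * min(upper, lower))
    return expected, p_two


# ---------------------------------------------------------------------------
# Monte Carlo randomization
# ---------------------------------------------------------------------------

def _masks_to_set(mask: int, pool: Sequence[str]) -> frozenset[str]:
    return frozenset(pool[i] for i in range(len(pool)) if mask >> i & 1)


def _universe_masks(config: NullTestConfig, pool: Sequence[str],
                    observed_masks: Counter[int], sizes: set[int]) -> list[int]:
    S = len(pool)
    if config.combination_universe == "observed_only":
        return sorted(observed_masks)
    if config.combination_universe == "all_nonempty":
        wanted = set(range(1, S + 1))
    else:  # sizes_present
        wanted = {s for s in sizes if s > 0}
    masks = []
    for k in sorted(wanted):
        for combo in itertools.combinations(range(S), k):
            masks.append(sum(1 << i for i in combo))
    return masks


def _draw_null_masks(ks: np.ndarray, S: int, reps: int,
                     rng: np.random.Generator) -> np.ndarray:
    """(n_specimens, reps) bitmask array of uniform richness-preserving draws."""
    out = np.zeros((len(ks), reps), dtype=np.int64)
    r = rng.random((len(ks), reps, S))
    for i, k in enumerate(ks):
        if k == 0:
            continue
        idx = np.argpartition(r[i], k - 1, axis=1)[:, :k]  # k smallest -> uniform subset
        out[i] = np.bitwise_or.reduce(np.left_shift(np.int64(1), idx), axis=1)
    return out


def mc_randomize(pm: PresenceMatrix, config: NullTestConfig | None = None,
                 group: str | None = None) -> list[CombinationTestResult]:
    """Richness-preserving Monte Carlo test of community-pattern frequencies.

    Every replicate redraws each specimen's community as a uniform
    k_i-subset of the S-species pool.  For every combination in the
    configured universe the null frequency distribution is tabulated; the
    result carries the null mean, the empirical envelope (order statistics
    at the configured level, no interpolation, hence achievable counts), a
    two-sided Monte Carlo p-value, and BH / Holm corrections computed over
    the universe as the family.  Identical seed implies identical output.
    """
    config = config or NullTestConfig()
    sub = pm.subset(group) if group not in (None, COMBINED) else pm
    pool = sub.pool
    S = len(pool)
    ks = sub.richness().to_numpy()
    if (ks > S).any():
        raise DataError("specimen richness exceeds pool size")
    reps = config.replicates

    observed_masks: Counter[int] = Counter()
    col_idx = {t: i for i, t in enumerate(pool)}
    for spec in sub.specimens:
        members = sub.members(spec)
        if members:
            observed_masks[sum(1 << col_idx[t] for t in members)] += 1

    universe = _universe_masks(config, pool, observed_masks, set(ks.tolist()))
    rng = np.random.default_rng(config.seed)
    null_masks = _draw_null_masks(ks, S, reps, rng)

    q_lo = (1.0 - config.envelope_level) / 2.0
    lo_idx = int(math.floor(q_lo * (reps - 1)))
    hi_idx = int(math.ceil((1.0 - q_lo) * (reps - 1)))

    results: list[dict] = []
    for mask in universe:
        counts = (null_masks == mask).sum(axis=0)
        obs = observed_masks.get(mask, 0)
        ge = int((counts >= obs).sum())
        le = int((counts <= obs).sum())
        if config.pseudocount_correction:
            p_two = min(1.0, 2.0 * min(ge + 1, le + 1) / (reps + 1))
        else:
            p_two = min(1.0, 2.0 * min(ge, le) / reps) if reps else 1.0
            p_two = max(p_two, 0.0)
        counts_sorted = np.sort(counts)
        results.append(dict(
            mask=mask, observed=obs, null_mean=float(counts.mean()),
            env_low=int(counts_sorted[lo_idx]), env_high=int(counts_sorted[hi_idx]),
            p_two=p_two,
        ))

    pvec = [r["p_two"] for r in results]
    qv, hv = bh_fdr(pvec), holm(pvec)
    out = [
        CombinationTestResult(
            pattern=_masks_to_set(r["mask"], pool), observed=r["observed"],
            null_mean=r["null_mean"], env_low=r["env_low"], env_high=r["env_high"],
            p_two=r["p_two"], q_bh=float(qv[i]), p_holm=float(hv[i]),
        )
        for i, r in enumerate(results)
    ]
    out.sort(key=lambda c: (-c.observed, c.size, tuple(sorted(c.pattern))))
    return out


def cooccurrence_report(
    pm: PresenceMatrix,
    config: NullTestConfig | None = None,
    groups: Sequence[str] | None = None,
    fixers: Iterable[str] | None = None,
) -> CooccurrenceReport:
    """Full co-occurrence analysis: per-group + combined MC tests, the exact
    pair-absence tests, and (when ``fixers`` is given) the guarantee
    probability that every specimen carries at least one designated species.

    ``groups`` defaults to the distinct host_group labels of ``pm``; they
    must partition the specimens.  Group randomizations use seeds derived
    deterministically from ``config.seed`` so the whole report is
    reproducible from one seed.
    """
    config = config or NullTestConfig()
    if groups is None:
        if pm.host_group is not None:
            groups = sorted(pd_unique(pm.host_group.loc[pm.present.index]))
        else:
            groups = []
    per_group: dict[str, list[CombinationTestResult]] = {}
    base_seed = config.seed
    for i, label in enumerate(list(groups) + [COMBINED]):
        sub_seed = None if base_seed is None else int((base_seed + 7919 * i) % 2**31)
        sub_cfg = NullTestConfig(
            replicates=config.replicates, seed=sub_seed,
            envelope_level=config.envelope_level,
            pseudocount_correction=config.pseudocount_correction,
            combination_universe=config.combination_universe,
        )
        per_group[label] = mc_randomize(pm, sub_cfg, group=label)
    pairs = pair_absence_test(pm)
    guarantee = None
    if fixers is not None:
        fixer_set = frozenset(fixers)
        unknown = fixer_set - set(pm.pool)
        if unknown:
            raise DataError(f"designated taxa not in pool: {sorted(unknown)}")
        res = guarantee_prob(pm.richness().tolist(), pm.pool_size, len(fixer_set))
        guarantee = GuaranteeResult(designated_set=fixer_set,
                                    probability=res.probability,
                                    n_specimens=res.n_specimens,
                                    pool_size=res.pool_size)
    return CooccurrenceReport(per_group=per_group, pair_absence=pairs,
                              guarantee=guarantee, config=config)


def pd_unique(series) -> list[str]:
    return [str(v) for v in dict.fromkeys(series.tolist())]
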