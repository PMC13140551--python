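"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gillsym.io_model import AbundanceTable, PresenceMatrix


def make_pm(rows, pool, groups=None, threshold=0.0) -> PresenceMatrix:
    """Presence matrix from a list of member sets (one per specimen)."""
    pool = list(pool)
    idx = [f"s{i + 1}" for i in range(len(rows))]
    present = pd.DataFrame(
        [[t in r for t in pool] for r in rows], index=idx, columns=pool)
    hg = None
    if groups is not None:
        hg = pd.Series(list(groups), index=idx, name="host_group")
    return PresenceMatrix(present, threshold_percent=threshold, host_group=hg)


def make_counts(rows, pool, groups=None) -> AbundanceTable:
    """Abundance table from per-specimen {taxon: count} dicts."""
    pool = list(pool)
    idx = [f"s{i + 1}" for i in range(len(rows))]
    df = pd.DataFrame(
        [[float(r.get(t, 0)) for t in pool] for r in rows], index=idx, columns=pool)
    hg = None
    if groups is not None:
        hg = pd.Series(list(groups), index=idx, name="host_group")
    return AbundanceTable(df, unit="read_count", host_group=hg)


@pytest.fixture
def pm_factory():
    return make_pm


@pytest.fixture
def counts_factory():
    return make_counts


# ---------------------------------------------------------------------------
# brute-force oracles over all richness-preserving assignments
# ---------------------------------------------------------------------------

def enumerate_assignments(richness, S):
    """Yield every richness-preserving assignment of species (0..S-1) subsets."""
    per_specimen = [
        list(itertools.combinations(range(S), k)) for k in richness
    ]
    yield from itertools.product(*per_specimen)


def brute_force_pair_absence(richness, S, pair=(0, 1)) -> float:
    """Exact P(pair never co-occurs) by full enumeration of assignments."""
    a, b = pair
    total = 0
    absent = 0
    for assignment in enumerate_assignments(richness, S):
        total += 1
        if not any(a in comm and b in comm for comm in assignment):
            absent += 1
    return absent / total


def brute_force_guarantee(richness, S, m) -> float:
    """Exact P(every specimen draws >= 1 of the first m species)."""
    designated = set(range(m))
    total = 0
    ok = 0
    for assignment in enumerate_assignments(richness, S):
        total += 1
        if all(designated & set(comm) for comm in assignment):
            ok += 1
    return ok / total
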