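"""Core data model for specimen-by-symbiont abundance data.

The analysis pipeline starts from a table of per-specimen symbiont read
counts (one row per host specimen, one column per symbiont taxon).  This
module provides the containers and the elementary derivations every
downstream stage consumes:

* :class:`AbundanceTable` -- counts or percent relative abundances;
* :func:`relative_abundance` -- counts -> percent, row-normalised to 100;
* :class:`PresenceMatrix` -- boolean occupancy over a declared taxon pool,
  obtained by thresholding percent abundances;
* :func:`richness_vector`, :func:`enumerate_patterns`, :func:`prevalence`,
  :func:`mean_abundance` -- the occupancy summaries (per-specimen richness
  k_i, distinct community patterns, per-taxon prevalence and zero-inclusive
  mean abundance).

Tables are stored as pandas DataFrames (specimens on the index, taxa on the
columns); specimen-to-host-species assignments travel alongside as a
``host_group`` Series.  All readers consume plain TSV.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

#: Pseudo-group label meaning "all specimens, ignoring host species".
COMBINED = "combined"

_VALID_UNITS = ("read_count", "percent")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecimenRecord:
    """One host specimen: an opaque id plus its host-species stratum."""

    specimen_id: str
    host_group: str | None = None
    metadata: str | None = None


@dataclass
class AbundanceTable:
    """Specimens x taxa abundance values, in read counts or percent.

    Parameters
    ----------
    values
        DataFrame with specimen ids on the index and taxon ids on the
        columns.  Non-negative; if ``unit == "percent"`` every row must sum
        to 100 (within 1e-6).
    unit
        ``"read_count"`` or ``"percent"``.
    host_group
        Optional Series mapping specimen id -> host-group label.
    """

    values: pd.DataFrame
    unit: str
    host_group: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- contract ----------------------------------------------------------
    def validate(self) -> None:
        if self.unit not in _VALID_UNITS:
            raise DataError(f"unknown unit {self.unit!r}; expected one of {_VALID_UNITS}")
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = sorted(idx[idx.duplicated()].unique())
            raise DataError(f"duplicate specimen id(s): {dups}")
        if cols.duplicated().any():
            dups = sorted(cols[cols.duplicated()].unique())
            raise DataError(f"duplicate taxon id(s): {dups}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise DataError("abundance values must be numeric")
        if arr.size and np.isnan(arr.astype(float)).any():
            i, j = np.argwhere(np.isnan(arr.astype(float)))[0]
            raise DataError(f"missing value at specimen {idx[i]!r}, taxon {cols[j]!r}")
        if arr.size and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise DataError(
                f"negative value at specimen {idx[i]!r}, taxon {cols[j]!r}: {arr[i, j]}"
            )
        if self.unit == "percent" and len(self.values):
            sums = arr.sum(axis=1)
            bad = np.abs(sums - 100.0) > 1e-6
            # all-zero rows are tolerated (aposymbiotic specimen placeholder)
            bad &= sums != 0
            if bad.any():
                i = int(np.argmax(bad))
                raise DataError(
                    f"percent row for specimen {idx[i]!r} sums to {sums[i]}, not 100"
                )
        if self.host_group is not None:
            missing = idx.difference(self.host_group.index)
            if len(missing):
                raise DataError(f"host_group missing for specimen(s): {sorted(missing)}")

    # -- conveniences ------------------------------------------------------
    @property
    def specimens(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.values.columns)

    def specimen_records(self) -> list[SpecimenRecord]:
        hg = self.host_group
        return [
            SpecimenRecord(s, None if hg is None else str(hg.loc[s]))
            for s in self.specimens
        ]

    def group_index(self, group: str | None) -> pd.Index:
        """Specimen ids belonging to ``group`` (``None``/"combined" = all)."""
        if group is None or group == COMBINED:
            return self.values.index
        if self.host_group is None:
            raise DataError("no host_group metadata attached; cannot select a group")
        sel = self.host_group.loc[self.values.index] == group
        if not sel.any():
            raise DataError(f"unknown or empty host group {group!r}")
        return self.values.index[sel.to_numpy()]


@dataclass
class PresenceMatrix:
    """Boolean specimen x taxon occupancy over a declared taxon pool.

    ``present`` has one column per pool member (taxa never detected keep an
    all-False column); ``pool_size`` S is the number of candidate taxa the
    null models randomise over.
    """

    present: pd.DataFrame
    threshold_percent: float
    host_group: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.present.columns.duplicated().any():
            raise DataError("duplicate taxon id in pool")
        if self.present.index.duplicated().any():
            raise DataError("duplicate specimen id in presence matrix")
        self.present = self.present.astype(bool)

    @property
    def pool(self) -> list[str]:
        return list(self.present.columns)

    @property
    def pool_size(self) -> int:
        return self.present.shape[1]

    @property
    def specimens(self) -> list[str]:
        return list(self.present.index)

    def richness(self) -> pd.Series:
        """Per-specimen richness k_i (row sums)."""
        return self.present.sum(axis=1).astype(int)

    def members(self, specimen: str) -> frozenset[str]:
        row = self.present.loc[specimen]
        return frozenset(row.index[row.to_numpy()])

    def group_index(self, group: str | None) -> pd.Index:
        if group is None or group == COMBINED:
            return self.present.index
        if self.host_group is None:
            raise DataError("no host_group metadata attached; cannot select a group")
        sel = self.host_group.loc[self.present.index] == group
        if not sel.any():
            raise DataError(f"unknown or empty host group {group!r}")
        return self.present.index[sel.to_numpy()]

    def subset(self, group: str | None) -> "PresenceMatrix":
        """Presence matrix restricted to one host group (pool unchanged)."""
        idx = self.group_index(group)
        hg = None if self.host_group is None else self.host_group.loc[idx]
        return PresenceMatrix(self.present.loc[idx], self.threshold_percent, hg)

    def cooccurrence_count(self, a: str, b: str) -> int:
        """Number of specimens in which taxa ``a`` and ``b`` are both present."""
        for t in (a, b):
            if t not in self.present.columns:
                raise DataError(f"taxon {t!r} not in pool")
        return int((self.present[a] & self.present[b]).sum())


@dataclass(frozen=True)
class CommunityPattern:
    """One distinct symbiont combination and how many specimens exhibit it."""

    members: frozenset[str]
    count: int
    group: str = COMBINED

    @property
    def size(self) -> int:
        return len(self.members)

    def label(self) -> str:
        return "+".join(sorted(self.members))


@dataclass
class RichnessSummary:
    """Per-specimen richness values for one group, with mean and sample sd."""

    group: str
    values: list[int] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values else math.nan

    @property
    def sd(self) -> float:
        # sample (n-1) estimator
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else math.nan


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DataError(f"cannot parse {path}: {exc}") from exc
    return df


def read_abundance_table(
    path: str | Path,
    unit: str,
    metadata_path: str | Path | None = None,
) -> AbundanceTable:
    """Read a specimen x taxon abundance TSV.

    The file has a header row ``specimen_id<TAB><taxon>...`` and one row per
    specimen.  Cells must be non-negative numbers; a non-numeric or negative
    cell raises :class:`DataError` naming the offending row and column.  When
    ``metadata_path`` is given it must be a two-column TSV
    ``specimen_id<TAB>host_group``.
    """
    raw = _read_tsv(path)
    df = pd.DataFrame(index=raw.index.astype(str))
    for col in raw.columns:
        series = pd.to_numeric(raw[col], errors="coerce")
        bad = series.isna() & raw[col].notna()
        if bad.any():
            spec = raw.index[bad.to_numpy()][0]
            raise DataError(
                f"non-numeric cell at specimen {spec!r}, taxon {col!r}: "
                f"{raw.loc[spec, col]!r}"
            )
        if series.isna().any():
            spec = raw.index[series.isna().to_numpy()][0]
            raise DataError(f"empty cell at specimen {spec!r}, taxon {col!r}")
        df[str(col)] = series.to_numpy()
    host_group = read_metadata(metadata_path) if metadata_path is not None else None
    return AbundanceTable(df, unit=unit, host_group=host_group)


def read_metadata(path: str | Path) -> pd.Series:
    """Read a ``specimen_id<TAB>host_group`` TSV into a Series."""
    df = _read_tsv(path)
    if df.shape[1] < 1:
        raise DataError(f"metadata file {path} needs a host_group column")
    series = df.iloc[:, 0].astype(str)
    series.index = series.index.astype(str)
    series.name = "host_group"
    if series.index.duplicated().any():
        raise DataError("duplicate specimen id in metadata")
    return series


def write_abundance_table(table: AbundanceTable, path: str | Path,
                          header_comment: str | None = None) -> None:
    """Write an abundance TSV; percent values use 4 decimal places."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(f"# unit={table.unit}\n")
        if table.unit == "percent":
            out = table.values.round(4)
            float_format = "%.4f"
        else:
            out = table.values.astype(int) if _all_integral(table.values) else table.values
            float_format = None
        out.to_csv(fh, sep="\t", index_label="specimen_id", float_format=float_format)


def _all_integral(df: pd.DataFrame) -> bool:
    arr = df.to_numpy()
    return bool(arr.size == 0 or np.allclose(arr, np.round(arr)))


def write_presence_matrix(pm: PresenceMatrix, path: str | Path,
                          header_comment: str | None = None) -> None:
    """Write the 0/1 occupancy TSV with threshold and pool size recorded."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(f"# threshold_percent={pm.threshold_percent} S={pm.pool_size}\n")
        pm.present.astype(int).to_csv(fh, sep="\t", index_label="specimen_id")


def read_presence_matrix(path: str | Path,
                         metadata_path: str | Path | None = None) -> PresenceMatrix:
    """Read a 0/1 occupancy TSV written by :func:`write_presence_matrix`."""
    threshold = 0.0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "threshold_percent=" in line:
                threshold = float(line.split("threshold_percent=")[1].split()[0])
    df = _read_tsv(path)
    df = df.astype(float).astype(int).astype(bool)
    df.index = df.index.astype(str)
    hg = read_metadata(metadata_path) if metadata_path is not None else None
    return PresenceMatrix(df, threshold_percent=threshold, host_group=hg)


# ---------------------------------------------------------------------------
# derivations
# ---------------------------------------------------------------------------

def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Convert read counts to percent relative abundance per specimen.

    Each cell becomes ``100 * count / row_total``; every specimen row of the
    result sums to 100 within 1e-9.  A specimen with zero total reads cannot
    be normalised and raises :class:`DataError` listing the specimen(s).
    """
    if table.unit != "read_count":
        raise DataError(f"relative_abundance expects read counts, got unit={table.unit!r}")
    totals = table.values.sum(axis=1)
    zeros = totals[totals == 0]
    if len(zeros):
        raise DataError(
            "cannot normalise specimen(s) with zero total reads: "
            + ", ".join(map(str, zeros.index))
        )
    pct = table.values.div(totals, axis=0) * 100.0
    return AbundanceTable(pct, unit="percent", host_group=table.host_group)


def derive_presence(
    table: AbundanceTable,
    threshold_percent: float = 0.0,
    pool: Sequence[str] | None = None,
) -> PresenceMatrix:
    """Threshold a percent-abundance table into a presence/absence matrix.

    A taxon is scored present in a specimen when its relative abundance is
    strictly greater than ``threshold_percent``.  The taxon ``pool`` declares
    the S candidates the null models randomise over; it defaults to the
    table's taxa and must cover them.
    """
    if table.unit != "percent":
        raise DataError("derive_presence expects a percent table; run relative_abundance first")
    if threshold_percent < 0:
        raise DataError("threshold_percent must be >= 0")
    pool = list(pool) if pool is not None else list(table.taxa)
    missing = set(table.taxa) - set(pool)
    if missing:
        raise DataError(f"pool is missing taxa present in the table: {sorted(missing)}")
    present = pd.DataFrame(False, index=table.values.index, columns=pool)
    for t in table.taxa:
        present[t] = table.values[t] > threshold_percent
    empty = present.index[~present.any(axis=1)]
    for spec in empty:
        logger.info("specimen %s has no taxon above %.4g%%: flagged aposymbiotic",
                    spec, threshold_percent)
    return PresenceMatrix(present, threshold_percent=threshold_percent,
                          host_group=table.host_group)


def richness_vector(pm: PresenceMatrix, group: str | None = None) -> RichnessSummary:
    """Per-specimen richness values k_i for one host group.

    Mean is reported as NaN for an empty group and the sample (n-1) standard
    deviation as NaN when fewer than two specimens are available.
    """
    idx = pm.group_index(group)
    values = pm.present.loc[idx].sum(axis=1).astype(int).tolist()
    return RichnessSummary(group=group or COMBINED, values=values)


def enumerate_patterns(pm: PresenceMatrix, group: str | None = None) -> list[CommunityPattern]:
    """Distinct non-empty community patterns, most frequent first.

    Ties in frequency are broken lexicographically on the sorted member
    tuple so output order is deterministic.  Counts over all returned
    patterns sum to the number of specimens with at least one taxon.
    """
    idx = pm.group_index(group)
    counter: Counter[frozenset[str]] = Counter()
    for spec in idx:
        m = pm.members(spec)
        if m:
            counter[m] += 1
    patterns = [
        CommunityPattern(members=m, count=c, group=group or COMBINED)
        for m, c in counter.items()
    ]
    patterns.sort(key=lambda p: (-p.count, tuple(sorted(p.members))))
    return patterns


def prevalence(pm: PresenceMatrix, taxon: str, group: str | None = None) -> float:
    """Fraction of the group's specimens in which ``taxon`` is present."""
    if taxon not in pm.present.columns:
        raise DataError(f"taxon {taxon!r} not in pool")
    idx = pm.group_index(group)
    if len(idx) == 0:
        raise DataError(f"empty group {group!r}")
    return float(pm.present.loc[idx, taxon].mean())


def mean_abundance(table: AbundanceTable, taxon: str, group: str | None = None) -> float:
    """Zero-inclusive mean percent abundance of ``taxon`` over a group.

    Specimens in which the taxon is absent contribute zeros, matching how
    prevalence-abundance correlations are computed downstream.
    """
    if table.unit != "percent":
        raise DataError("mean_abundance expects a percent table")
    if taxon not in table.values.columns:
        if taxon in getattr(table, "_pool", ()):  # pragma: no cover - defensive
            return 0.0
        raise DataError(f"taxon {taxon!r} not in table")
    idx = table.group_index(group)
    if len(idx) == 0:
        raise DataError(f"empty group {group!r}")
    return float(table.values.loc[idx, taxon].mean())
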