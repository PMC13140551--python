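"""Species delimitation of genome bins from pairwise gANI/AF comparisons.

Genome bins recovered from different specimens are grouped into bacterial
species using genome-wide average nucleotide identity (gANI) and alignment
fraction (AF): an edge joins two genomes when gANI > 95% and AF > 0.60 (the
common species-delimitation cutoffs), and species are the connected
components of the resulting graph.  Missing pairs are treated as
below-threshold, mirroring how distant genome pairs are simply not reported
by fragment-mapping ANI tools.  Within each species the best bin is kept by
CheckM-style quality (completeness - 5 x contamination, ties by lower
strain heterogeneity, then id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import DataError

logger = logging.getLogger(__name__)

_SYMMETRIZE = ("mean", "min", "max")


@dataclass(frozen=True)
class AniRecord:
    """One directed FastANI-style comparison (query vs reference)."""

    query: str
    reference: str
    gani: float
    fragments_mapped: int
    fragments_total: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.gani <= 100.0:
            raise DataError(f"gANI out of range: {self.gani}")
        if self.fragments_total <= 0 or self.fragments_mapped < 0:
            raise DataError("fragment counts must be positive / non-negative")
        if self.fragments_mapped > self.fragments_total:
            raise DataError("fragments_mapped exceeds fragments_total")

    @property
    def af(self) -> float:
        return self.fragments_mapped / self.fragments_total


@dataclass(frozen=True)
class GenomeQuality:
    """CheckM-style quality for one genome bin (percent units)."""

    genome: str
    completeness: float
    contamination: float
    heterogeneity: float = 0.0

    def __post_init__(self) -> None:
        for name in ("completeness", "contamination", "heterogeneity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise DataError(f"{name} out of range for {self.genome}: {v}")

    @property
    def score(self) -> float:
        """MIMAG-style dereplication score: completeness - 5 x contamination."""
        return self.completeness - 5.0 * self.contamination


@dataclass
class SpeciesCluster:
    """One delimited species: member genomes plus the retained representative."""

    label: str
    members: frozenset[str]
    representative: str | None = None
    min_within_gani: float | None = None
    min_within_af: float | None = None


def read_fastani(path: str | Path) -> list[AniRecord]:
    """Parse the 5-column FastANI output dialect.

    Columns: query, reference, ANI (percent), fragments mapped, fragments
    total.  Self-comparisons are dropped (with a log note); a row with the
    wrong column count raises :class:`DataError` naming the line.
    """
    records: list[AniRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) != 5:
                raise DataError(
                    f"{path}:{lineno}: expected 5 tab-separated columns, got {len(cells)}")
            q, r, ani, fm, ft = cells
            if q == r:
                logger.info("dropping self-comparison for %s at line %d", q, lineno)
                continue
            try:
                records.append(AniRecord(q, r, float(ani), int(fm), int(ft)))
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
    return records


def _symmetrized_edges(records: Sequence[AniRecord], symmetrize: str
                       ) -> dict[frozenset[str], tuple[float, float]]:
    if symmetrize not in _SYMMETRIZE:
        raise DataError(f"symmetrize must be one of {_SYMMETRIZE}")
    directed: dict[frozenset[str], list[tuple[float, float]]] = {}
    for rec in records:
        if rec.query == rec.reference:
            continue
        directed.setdefault(frozenset((rec.query, rec.reference)), []).append(
            (rec.gani, rec.af))
    agg = {"mean": lambda v: sum(v) / len(v), "min": min, "max": max}[symmetrize]
    return {
        pair: (agg([g for g, _ in vals]), agg([a for _, a in vals]))
        for pair, vals in directed.items()
    }


def delimit_species(
    records: Sequence[AniRecord],
    genomes: Iterable[str] | None = None,
    gani_min: float = 95.0,
    af_min: float = 0.60,
    symmetrize: str = "mean",
) -> list[SpeciesCluster]:
    """Cluster genomes into species by thresholded gANI/AF connectivity.

    Reciprocal comparisons are symmetrized (arithmetic mean by default; a
    single available direction is used as-is).  An undirected edge joins a
    pair when symmetrized gANI > ``gani_min`` and AF > ``af_min``; species
    are connected components (single-linkage semantics).  ``genomes`` may
    list ids beyond those appearing in ``records`` so that unreferenced
    genomes form singleton clusters.  Cluster labels are ``species_<n>``
    numbered by sorted minimum member id, so output is deterministic.
    """
    g = nx.Graph()
    for rec in records:
        g.add_node(rec.query)
        g.add_node(rec.reference)
    if genomes is not None:
        g.add_nodes_from(genomes)
    edges = _symmetrized_edges(records, symmetrize)
    for pair, (gani, af) in edges.items():
        if gani > gani_min and af > af_min:
            a, b = tuple(pair)
            g.add_edge(a, b, gani=gani, af=af)
    components = sorted((sorted(c) for c in nx.connected_components(g)),
                        key=lambda c: c[0])
    clusters: list[SpeciesCluster] = []
    for i, comp in enumerate(components, start=1):
        within = [edges[p] for p in edges
                  if set(p) <= set(comp) and p in edges]
        clusters.append(SpeciesCluster(
            label=f"species_{i}",
            members=frozenset(comp),
            min_within_gani=min((g_ for g_, _ in within), default=None),
            min_within_af=min((a_ for _, a_ in within), default=None),
        ))
    return clusters


def select_representative(cluster: SpeciesCluster,
                          qualities: Mapping[str, GenomeQuality]) -> str:
    """Pick the best-quality member bin of one species cluster.

    Ranking: highest completeness - 5 x contamination, ties broken by lower
    strain heterogeneity, then lexicographic genome id.
    """
    missing = [m for m in cluster.members if m not in qualities]
    if missing:
        raise DataError(f"missing quality record(s) for: {sorted(missing)}")
    best = min(
        sorted(cluster.members),
        key=lambda m: (-qualities[m].score, qualities[m].heterogeneity, m),
    )
    return best


def dereplicate(
    records: Sequence[AniRecord],
    qualities: Mapping[str, GenomeQuality],
    genomes: Iterable[str] | None = None,
    gani_min: float = 95.0,
    af_min: float = 0.60,
    symmetrize: str = "mean",
) -> list[SpeciesCluster]:
    """Delimit species and attach the best-quality representative to each."""
    if genomes is None:
        genomes = list(qualities)
    clusters = delimit_species(records, genomes=genomes, gani_min=gani_min,
                               af_min=af_min, symmetrize=symmetrize)
    for c in clusters:
        c.representative = select_representative(c, qualities)
    return clusters


def read_checkm(path: str | Path) -> dict[str, GenomeQuality]:
    """Read a CheckM-style quality TSV: genome, completeness, contamination,
    heterogeneity (percent units)."""
    out: dict[str, GenomeQuality] = {}
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                continue
            if len(cells) < 3:
                raise DataError(f"quality row needs >= 3 columns: {line!r}")
            het = float(cells[3]) if len(cells) > 3 else 0.0
            q = GenomeQuality(cells[0], float(cells[1]), float(cells[2]), het)
            if q.genome in out:
                raise DataError(f"duplicate genome id {q.genome!r} in quality table")
            out[q.genome] = q
    return out


def write_clusters(clusters: Sequence[SpeciesCluster], path: str | Path,
                   header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("genome\tspecies_label\trepresentative_flag\n")
        for c in clusters:
            for m in sorted(c.members):
                flag = int(m == c.representative)
                fh.write(f"{m}\t{c.label}\t{flag}\n")
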