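"""Synthetic specimen-symbiont datasets with the study's statistical structure.

The generator emulates the sampling design the analysis assumes: two host
species sampled from one co-culture (14 "Lp" + 22 "Tb" specimens by
default), a pool of 7 candidate symbiont species of which 3 are nitrogen
fixers, per-specimen richness k drawn from a per-group distribution over
1..5, a uniformly random k-subset of the pool (optionally with particular
combinations enriched by multiplicative weights), symmetric-Dirichlet
relative abundances within each host, and multinomial read counts at a
log-normally dispersed sequencing depth.  Gene catalogs are planted to
mirror the functional structure: fixers carry the full 17 nif classes (one
random fixer loses nifJ, never an essential class), non-fixers carry none or
nifJ only, and CAZyme catalogs share a planted core (with a tagged
lignocellulose-active subset) plus taxon-private subfamilies.

Everything is reproducible from a single integer seed, and the generating
truth is returned alongside the emitted tables so tests can check recovery.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dereplication import AniRecord, GenomeQuality
from .errors import DataError
from .gene_content import (
    ACCESSORY_NIF,
    ALL_NIF,
    DEFAULT_LIGNOCELLULOSE_TAGS,
    CazymeCatalog,
    NifCatalog,
)
from .io_model import AbundanceTable

DEFAULT_POOL = ("sp1", "sp2", "sp3", "sp4", "sp5", "sp6", "sp7")
DEFAULT_FIXERS = ("sp1", "sp2", "sp4")

# per-group richness distributions over k = 1..5, chosen to match the
# reference cohort's group means and spreads (Lp: 2.2 +/- 0.7, max 3;
# Tb: 2.7 +/- 1.0, max 5)
DEFAULT_RICHNESS = {
    "Lp": (0.15, 0.50, 0.35, 0.0, 0.0),
    "Tb": (0.10, 0.35, 0.35, 0.15, 0.05),
}


@dataclass
class CatalogSpec:
    """Planted structure of the synthetic gene catalogs."""

    n_core_cazymes: int = 58
    n_core_lignocellulose: int = 23
    n_private_cazymes: int = 20
    private_lignocellulose_fraction: float = 0.5
    nifj_knockout: bool = True      # one random fixer loses nifJ
    nonfixer_nifj_taxa: int = 1     # this many non-fixers carry nifJ alone


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort."""

    S: int = 7
    pool: tuple[str, ...] = DEFAULT_POOL
    fixers: tuple[str, ...] = DEFAULT_FIXERS
    host_groups: tuple[tuple[str, int], ...] = (("Lp", 14), ("Tb", 22))
    richness_distribution: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_RICHNESS))
    enrichment: Mapping[frozenset, float] = field(default_factory=dict)
    require_fixer: bool = False
    abundance_concentration: float = 1.0
    read_depth: float = 1e6
    read_depth_sigma: float = 0.3
    catalog_spec: CatalogSpec = field(default_factory=CatalogSpec)
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.pool) != self.S:
            raise DataError(f"pool has {len(self.pool)} taxa but S={self.S}")
        if len(set(self.pool)) != self.S:
            raise DataError("duplicate taxon in pool")
        if not set(self.fixers) <= set(self.pool):
            raise DataError("fixers must be a subset of the pool")
        self.enrichment = {frozenset(c): float(w) for c, w in self.enrichment.items()}
        for c, w in self.enrichment.items():
            if w <= 0:
                raise DataError(f"enrichment weight for {sorted(c)} must be > 0")
            if not c <= set(self.pool):
                raise DataError(f"enriched combination {sorted(c)} not within pool")
        for g, probs in self.richness_distribution.items():
            p = np.asarray(probs, dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise DataError(f"richness probabilities for group {g!r} must be "
                                "non-negative and sum to 1")
            if len(p) > self.S:
                raise DataError(f"richness support for group {g!r} exceeds pool size")
        for g, _ in self.host_groups:
            if g not in self.richness_distribution:
                raise DataError(f"no richness distribution for host group {g!r}")
        if self.require_fixer and not self.fixers:
            raise DataError("require_fixer needs a non-empty fixer set")


@dataclass
class SyntheticTruth:
    """The generating state behind one simulated dataset."""

    communities: dict[str, frozenset[str]]
    abundances: dict[str, dict[str, float]]
    enrichment: dict[frozenset, float]
    core_cazymes: frozenset[str]
    core_lignocellulose: frozenset[str]
    fixers: frozenset[str]
    rejection_draws: int = 0
    rejection_accepted: int = 0

    @property
    def acceptance_rate(self) -> float:
        if self.rejection_draws == 0:
            return 1.0
        return self.rejection_accepted / self.rejection_draws

    def to_json(self, path: str | Path) -> None:
        payload = {
            "communities": {s: sorted(m) for s, m in self.communities.items()},
            "abundances": self.abundances,
            "enrichment": {"+".join(sorted(c)): w for c, w in self.enrichment.items()},
            "core_cazymes": sorted(self.core_cazymes),
            "core_lignocellulose": sorted(self.core_lignocellulose),
            "fixers": sorted(self.fixers),
            "rejection_draws": self.rejection_draws,
            "rejection_accepted": self.rejection_accepted,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SimulatedDataset:
    counts: AbundanceTable
    metadata: pd.Series
    nif_catalog: NifCatalog
    cazyme_catalog: CazymeCatalog
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# community simulation
# ---------------------------------------------------------------------------

def _combo_tables(config: SimulationConfig) -> dict[int, tuple[list[frozenset[str]], np.ndarray]]:
    """Per-richness enumeration of candidate combinations with draw weights."""
    tables = {}
    max_k = max(len(p) for p in
                (np.asarray(v) for v in config.richness_distribution.values()))
    for k in range(1, max_k + 1):
        combos = [frozenset(c) for c in itertools.combinations(config.pool, k)]
        weights = np.array([config.enrichment.get(c, 1.0) for c in combos])
        tables[k] = (combos, weights / weights.sum())
    return tables


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Draw one synthetic cohort: counts, metadata, catalogs, and truth.

    Per specimen: richness k from the group's distribution; a k-subset with
    probability proportional to its enrichment weight (uniform under the
    empty default); under ``require_fixer``, rejection sampling until the
    subset meets the fixer set (the richness marginal is untouched; the
    acceptance rate is recorded on the truth object); symmetric Dirichlet
    relative abundances over members; log-normal total depth; multinomial
    read counts.  Identical config and seed give identical output.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    tables = _combo_tables(config)
    fixer_set = frozenset(config.fixers)

    specimens: list[str] = []
    groups: list[str] = []
    communities: dict[str, frozenset[str]] = {}
    true_abund: dict[str, dict[str, float]] = {}
    rows: list[dict[str, int]] = []
    n_draws = 0
    n_accepted = 0
    for glabel, n in config.host_groups:
        probs = np.asarray(config.richness_distribution[glabel], dtype=float)
        ks = rng.choice(np.arange(1, len(probs) + 1), size=n, p=probs)
        for j, k in enumerate(ks):
            spec = f"{glabel}_{j + 1:02d}"
            combos, weights = tables[int(k)]
            while True:
                n_draws += 1
                comm = combos[int(rng.choice(len(combos), p=weights))]
                if not config.require_fixer or comm & fixer_set:
                    n_accepted += 1
                    break
            members = sorted(comm)
            props = rng.dirichlet([config.abundance_concentration] * len(members))
            depth = max(len(members), int(round(rng.lognormal(
                mean=math.log(config.read_depth), sigma=config.read_depth_sigma))))
            reads = rng.multinomial(depth, props)
            row = dict.fromkeys(config.pool, 0)
            for t, r in zip(members, reads):
                row[t] = int(r)
            rows.append(row)
            specimens.append(spec)
            groups.append(glabel)
            communities[spec] = comm
            true_abund[spec] = {t: float(p) for t, p in zip(members, props)}

    counts = pd.DataFrame(rows, index=pd.Index(specimens, name="specimen_id"),
                          columns=list(config.pool))
    metadata = pd.Series(groups, index=counts.index, name="host_group")
    nif_cat, caz_cat, core, core_ligno = _plant_catalogs(config, rng)
    truth = SyntheticTruth(
        communities=communities, abundances=true_abund,
        enrichment=dict(config.enrichment), core_cazymes=core,
        core_lignocellulose=core_ligno, fixers=fixer_set,
        rejection_draws=n_draws, rejection_accepted=n_accepted,
    )
    table = AbundanceTable(counts, unit="read_count", host_group=metadata)
    return SimulatedDataset(counts=table, metadata=metadata, nif_catalog=nif_cat,
                            cazyme_catalog=caz_cat, truth=truth)


_LIGNO_TAG_CYCLE = tuple(sorted(DEFAULT_LIGNOCELLULOSE_TAGS))
_NON_LIGNO_TAGS = ("chitin", "starch", "glycogen", "peptidoglycan", "trehalose")


def _plant_catalogs(config: SimulationConfig, rng: np.random.Generator
                    ) -> tuple[NifCatalog, CazymeCatalog, frozenset[str], frozenset[str]]:
    spec = config.catalog_spec
    if spec.n_core_lignocellulose > spec.n_core_cazymes:
        raise DataError("planted lignocellulose core cannot exceed the core size")
    fixer_set = frozenset(config.fixers)

    # --- nif classes -------------------------------------------------------
    nif: dict[str, frozenset[str]] = {}
    fixers_sorted = sorted(fixer_set)
    knockout_taxon = None
    if spec.nifj_knockout and fixers_sorted:
        knockout_taxon = fixers_sorted[int(rng.integers(len(fixers_sorted)))]
    for t in config.pool:
        if t in fixer_set:
            classes = set(ALL_NIF)
            if t == knockout_taxon:
                classes.discard("nifJ")
            nif[t] = frozenset(classes)
        else:
            nif[t] = frozenset()
    non_fixers = [t for t in config.pool if t not in fixer_set]
    if spec.nonfixer_nifj_taxa and non_fixers:
        chosen = rng.choice(len(non_fixers),
                            size=min(spec.nonfixer_nifj_taxa, len(non_fixers)),
                            replace=False)
        for idx in np.atleast_1d(chosen):
            nif[non_fixers[int(idx)]] = frozenset({"nifJ"})

    # --- CAZyme subfamilies ------------------------------------------------
    core = [f"CORE{i + 1:03d}" for i in range(spec.n_core_cazymes)]
    core_ligno = core[: spec.n_core_lignocellulose]
    substrates: dict[str, frozenset[str]] = {}
    for i, sf in enumerate(core):
        if sf in core_ligno:
            substrates[sf] = frozenset({_LIGNO_TAG_CYCLE[i % len(_LIGNO_TAG_CYCLE)]})
        else:
            substrates[sf] = frozenset({_NON_LIGNO_TAGS[i % len(_NON_LIGNO_TAGS)]})
    caz: dict[str, frozenset[str]] = {}
    for t in config.pool:
        private = [f"PRIV_{t}_{i + 1:03d}" for i in range(spec.n_private_cazymes)]
        n_ligno_priv = int(round(spec.private_lignocellulose_fraction * len(private)))
        for i, sf in enumerate(private):
            if i < n_ligno_priv:
                substrates[sf] = frozenset(
                    {_LIGNO_TAG_CYCLE[int(rng.integers(len(_LIGNO_TAG_CYCLE)))]})
            else:
                substrates[sf] = frozenset(
                    {_NON_LIGNO_TAGS[int(rng.integers(len(_NON_LIGNO_TAGS)))]})
        caz[t] = frozenset(core) | frozenset(private)
    return (NifCatalog(nif),
            CazymeCatalog(caz, substrates),
            frozenset(core), frozenset(core_ligno))


# ---------------------------------------------------------------------------
# ANI simulation
# ---------------------------------------------------------------------------

@dataclass
class AniSimConfig:
    within_gani: tuple[float, float] = (97.0, 100.0)
    within_af: tuple[float, float] = (0.85, 1.0)
    emit_between: bool = False
    between_gani: tuple[float, float] = (75.0, 80.0)
    between_af: tuple[float, float] = (0.2, 0.5)
    fragments_total: int = 100
    seed: int | None = None


def simulate_ani(
    partition: Sequence[Sequence[str]],
    config: AniSimConfig | None = None,
) -> tuple[list[AniRecord], dict[str, GenomeQuality]]:
    """Emit FastANI-style records and quality rows for a planted partition.

    Within-cluster pairs get reciprocal records with gANI ~ U(97, 100) and
    AF ~ U(0.85, 1.0); between-cluster pairs are omitted by default
    (fragment-mapping ANI tools do not report distant pairs) or, when
    ``emit_between`` is set, emitted around gANI 75-80.  Quality values are
    drawn in MIMAG high-quality ranges so representative selection has
    non-trivial choices to make.
    """
    config = config or AniSimConfig()
    if not partition or any(len(c) == 0 for c in partition):
        raise DataError("partition must be a non-empty list of non-empty clusters")
    flat = [g for c in partition for g in c]
    if len(set(flat)) != len(flat):
        raise DataError("genome ids must be unique across clusters")
    rng = np.random.default_rng(config.seed)
    records: list[AniRecord] = []

    def emit(a: str, b: str, grange: tuple[float, float], arange: tuple[float, float]):
        for q, r in ((a, b), (b, a)):
            gani = float(rng.uniform(*grange))
            af = float(rng.uniform(*arange))
            records.append(AniRecord(q, r, gani,
                                     int(round(af * config.fragments_total)),
                                     config.fragments_total))

    for cluster in partition:
        for a, b in itertools.combinations(sorted(cluster), 2):
            emit(a, b, config.within_gani, config.within_af)
    if config.emit_between:
        for ca, cb in itertools.combinations(range(len(partition)), 2):
            for a in partition[ca]:
                for b in partition[cb]:
                    emit(a, b, config.between_gani, config.between_af)

    qualities = {
        g: GenomeQuality(
            genome=g,
            completeness=float(rng.uniform(90.0, 100.0)),
            contamination=float(rng.uniform(0.0, 0.5)),
            heterogeneity=float(rng.uniform(0.0, 5.0)),
        )
        for g in flat
    }
    return records, qualities


# ---------------------------------------------------------------------------
# TSV emission
# ---------------------------------------------------------------------------

def write_dataset(ds: SimulatedDataset, outdir: str | Path,
                  header_comment: str | None = None) -> dict[str, Path]:
    """Write the simulated tables in the exact dialects the readers consume."""
    from .gene_content import write_catalog
    from .io_model import write_abundance_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "catalog": outdir / "catalog.tsv",
        "truth": outdir / "truth.json",
    }
    write_abundance_table(ds.counts, paths["counts"], header_comment)
    with open(paths["metadata"], "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("specimen_id\thost_group\n")
        for spec, grp in ds.metadata.items():
            fh.write(f"{spec}\t{grp}\n")
    write_catalog(ds.nif_catalog, ds.cazyme_catalog, paths["catalog"], header_comment)
    ds.truth.to_json(paths["truth"])
    return paths
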