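"""Nitrogen-fixation prediction and core gene-set constraint analysis.

Two functional gene inventories drive the biology here:

*nif* gene classes.  Diazotrophy is predicted from the presence of the six
essential core classes (nifH, nifD, nifK, nifE, nifN, nifB); the regulatory
(nifA, nifL) and accessory (nifM/S/T/U/V/W/Q/Z/J) classes complete the 17
recognised classes but do not, individually, predict the capability --
nifJ in particular occurs in non-diazotrophs.

CAZyme subfamilies.  Carbohydrate-active enzyme modules, classified at the
subfamily level with predicted substrate tags.  "Lignocellulose-active"
subfamilies target the structural polymers of wood (cellulose,
hemicelluloses, lignin) or their degradation oligomers.

The constraint logic rests on one ecological premise: every symbiont
community observed in a living host must supply every symbiont-dependent
function, so it is *sufficient*.  The inclusion-minimal observed communities
(the antichain) are the binding constraints, and the intersection of their
union gene sets is an upper bound on the core gene set hosts require.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError
from .io_model import PresenceMatrix
from .stats_core import GroupComparisonResult, dunn_posthoc, kruskal_wallis

logger = logging.getLogger(__name__)

# the 17 recognised nif gene classes, tiered
ESSENTIAL_NIF = frozenset({"nifH", "nifD", "nifK", "nifE", "nifN", "nifB"})
REGULATORY_NIF = frozenset({"nifA", "nifL"})
ACCESSORY_NIF = frozenset(
    {"nifM", "nifS", "nifT", "nifU", "nifV", "nifW", "nifQ", "nifZ", "nifJ"})
ALL_NIF = ESSENTIAL_NIF | REGULATORY_NIF | ACCESSORY_NIF
assert len(ALL_NIF) == 17

#: substrate vocabulary counted as lignocellulose-active: the structural
#: polymers of wood, plus the oligomers released by their deconstruction
DEFAULT_LIGNOCELLULOSE_TAGS = frozenset({
    "cellulose", "xylan", "mannan", "beta-glucan", "xyloglucan",
    "arabinan", "galactan", "lignin",
    "cellooligosaccharide", "xylooligosaccharide", "mannooligosaccharide",
    "mixed-linkage-oligosaccharide", "arabinooligosaccharide",
    "galactooligosaccharide", "hemicellulose",
})


@dataclass
class NifCatalog:
    """Per-taxon sets of nif gene-class labels."""

    classes: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for taxon, labels in self.classes.items():
            labels = frozenset(labels)
            unknown = labels - ALL_NIF
            if unknown:
                logger.warning("taxon %s carries unrecognised nif label(s): %s",
                               taxon, sorted(unknown))
            clean[taxon] = labels
        self.classes = clean

    def __getitem__(self, taxon: str) -> frozenset[str]:
        if taxon not in self.classes:
            raise DataError(f"taxon {taxon!r} not in nif catalog")
        return self.classes[taxon]

    def taxa(self) -> list[str]:
        return sorted(self.classes)


@dataclass
class CazymeCatalog:
    """Per-taxon CAZyme subfamily sets plus subfamily -> substrate tags."""

    subfamilies: dict[str, frozenset[str]] = field(default_factory=dict)
    substrates: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.subfamilies = {t: frozenset(s) for t, s in self.subfamilies.items()}
        self.substrates = {sf: frozenset(tags) for sf, tags in self.substrates.items()}
        seen = set().union(*self.subfamilies.values()) if self.subfamilies else set()
        orphans = set(self.substrates) - seen
        if orphans:
            logger.warning("substrate map has %d orphan subfamilies (no taxon carries them)",
                           len(orphans))

    def __getitem__(self, taxon: str) -> frozenset[str]:
        if taxon not in self.subfamilies:
            raise DataError(f"taxon {taxon!r} not in CAZyme catalog")
        return self.subfamilies[taxon]

    def taxa(self) -> list[str]:
        return sorted(self.subfamilies)


@dataclass
class FixerPrediction:
    taxon: str
    is_fixer: bool
    missing_essential: frozenset[str]


@dataclass
class CoreSetResult:
    """Core gene-set constraint derived from sufficient communities."""

    sufficient_communities: list[frozenset[str]]
    core: frozenset[str]
    lignocellulose_core: frozenset[str] | None = None


# ---------------------------------------------------------------------------
# catalog I/O
# ---------------------------------------------------------------------------

_COORD_SUFFIX = re.compile(r"\(\d+-\d+\)$")


def parse_dbcan_overview(path_or_lines, min_tools: int = 2) -> frozenset[str]:
    """Extract high-confidence subfamily tokens from a dbCAN overview table.

    Expects the overview TSV dialect: a header then one row per gene with a
    ``#ofTools`` column counting how many annotation methods (HMMER, DIAMOND,
    Hotpep/dbCAN_sub) agree.  Rows supported by fewer than ``min_tools``
    methods are dropped; subfamily tokens like ``GH5_2(123-456)`` are kept
    with coordinate suffixes stripped.  Malformed rows are skipped with a
    warning; a file with no usable rows is an error.
    """
    if isinstance(path_or_lines, (str, Path)):
        with open(path_or_lines) as fh:
            lines = fh.read().splitlines()
    else:
        lines = list(path_or_lines)
    lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise DataError("empty dbCAN overview input")
    header = lines[0].rstrip("\n").split("\t")
    try:
        tools_col = next(i for i, h in enumerate(header) if "#oftools" in h.lower().replace(" ", ""))
    except StopIteration:
        raise DataError("dbCAN overview header lacks a #ofTools column") from None
    subfams: set[str] = set()
    n_ok = 0
    for ln in lines[1:]:
        cells = ln.rstrip("\n").split("\t")
        if len(cells) != len(header):
            logger.warning("skipping malformed dbCAN row: %r", ln[:80])
            continue
        try:
            n_tools = int(cells[tools_col])
        except ValueError:
            logger.warning("skipping dbCAN row with non-integer #ofTools: %r", ln[:80])
            continue
        n_ok += 1
        if n_tools < min_tools:
            continue
        for i, cell in enumerate(cells):
            if i in (0, tools_col) or cell in ("-", ""):
                continue
            for token in re.split(r"[+,]", cell):
                token = _COORD_SUFFIX.sub("", token.strip())
                if re.fullmatch(r"(GH|GT|PL|CE|AA|CBM)\d+(_\d+)?", token):
                    subfams.add(token)
    if n_ok == 0:
        raise DataError("no parseable rows in dbCAN overview input")
    return frozenset(subfams)


def read_catalog(path: str | Path) -> tuple[NifCatalog, CazymeCatalog]:
    """Read the unified catalog TSV.

    Columns: ``taxon_id  element_type  element_id  substrate_tags`` where
    element_type is ``nif_class`` or ``cazyme_subfamily`` and substrate_tags
    is a comma-separated list (empty or ``-`` for none).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    need = {"taxon_id", "element_type", "element_id"}
    if not need <= set(df.columns):
        raise DataError(f"catalog TSV must have columns {sorted(need)}")
    nif: dict[str, set[str]] = {}
    caz: dict[str, set[str]] = {}
    subs: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        taxon, etype, eid = row.taxon_id, row.element_type, row.element_id
        if etype == "nif_class":
            nif.setdefault(taxon, set()).add(eid)
        elif etype == "cazyme_subfamily":
            caz.setdefault(taxon, set()).add(eid)
            tags = getattr(row, "substrate_tags", "")
            if tags and tags != "-":
                subs.setdefault(eid, set()).update(
                    t.strip() for t in tags.split(",") if t.strip())
        else:
            raise DataError(f"unknown element_type {etype!r} for taxon {taxon!r}")
    return (NifCatalog({t: frozenset(s) for t, s in nif.items()}),
            CazymeCatalog({t: frozenset(s) for t, s in caz.items()},
                          {sf: frozenset(s) for sf, s in subs.items()}))


def write_catalog(nif: NifCatalog, caz: CazymeCatalog, path: str | Path,
                  header_comment: str | None = None) -> None:
    rows = []
    for taxon in nif.taxa():
        for cls in sorted(nif.classes[taxon]):
            rows.append((taxon, "nif_class", cls, "-"))
    for taxon in caz.taxa():
        for sf in sorted(caz.subfamilies[taxon]):
            tags = ",".join(sorted(caz.substrates.get(sf, ()))) or "-"
            rows.append((taxon, "cazyme_subfamily", sf, tags))
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("taxon_id\telement_type\telement_id\tsubstrate_tags\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")


# ---------------------------------------------------------------------------
# nitrogen fixation
# ---------------------------------------------------------------------------

def predict_fixer(nif_set: Iterable[str], taxon: str = "") -> FixerPrediction:
    """Predict diazotrophy: true iff all six essential core classes present.

    Accessory and regulatory classes never affect the call; in particular a
    genome carrying only nifJ is a predicted non-fixer.
    """
    s = frozenset(nif_set)
    missing = ESSENTIAL_NIF - s
    return FixerPrediction(taxon=taxon, is_fixer=not missing,
                           missing_essential=missing)


def predict_fixers(catalog: NifCatalog) -> dict[str, FixerPrediction]:
    return {t: predict_fixer(catalog.classes[t], t) for t in catalog.taxa()}


def shared_nif_core(catalog: NifCatalog, taxa: Sequence[str]) -> frozenset[str]:
    """Intersection of nif gene-class sets over the given taxa."""
    if not taxa:
        raise DataError("shared_nif_core needs at least one taxon")
    core = catalog[taxa[0]]
    for t in taxa[1:]:
        core = core & catalog[t]
    return core


# ---------------------------------------------------------------------------
# core gene-set constraints
# ---------------------------------------------------------------------------

def sufficient_communities(pm: PresenceMatrix) -> list[frozenset[str]]:
    """Inclusion-minimal observed communities (the binding constraints).

    Every non-empty observed community is sufficient (it supported a living
    host); a community is dropped when a strict subset of it was also
    observed, because the subset already binds the intersection.  The result
    is an antichain, sorted by size then lexicographically.
    """
    observed = {pm.members(s) for s in pm.specimens if pm.members(s)}
    if not observed:
        raise DataError("no specimen has any taxon present")
    minimal = [
        c for c in observed
        if not any(o < c for o in observed)
    ]
    minimal.sort(key=lambda c: (len(c), tuple(sorted(c))))
    return minimal


def core_gene_set(
    catalog: CazymeCatalog | NifCatalog | Mapping[str, frozenset[str]],
    communities: Sequence[Iterable[str]],
    substrate_tags: Iterable[str] | None = None,
) -> CoreSetResult:
    """Intersect community union gene sets to bound the core gene set.

    Each community's gene set is the union over its member taxa; the core is
    the intersection over all communities.  When the catalog carries
    substrate annotations, ``lignocellulose_core`` holds the subset of the
    core passing :func:`lignocellulose_filter`.
    """
    if not communities:
        raise DataError("need at least one sufficient community")
    genesets = _genesets_of(catalog)
    comms = [frozenset(c) for c in communities]
    union_sets = []
    for c in comms:
        unknown = c - set(genesets)
        if unknown:
            raise DataError(f"community member(s) missing from catalog: {sorted(unknown)}")
        u: frozenset[str] = frozenset()
        for t in c:
            u = u | genesets[t]
        union_sets.append(u)
    core = union_sets[0]
    for u in union_sets[1:]:
        core = core & u
    if not core:
        logger.warning("core gene set is empty across %d communities "
                       "(biologically implausible for a shared function)", len(comms))
    ligno = None
    if isinstance(catalog, CazymeCatalog):
        ligno = lignocellulose_filter(catalog, core, substrate_tags)
    return CoreSetResult(sufficient_communities=comms, core=core,
                         lignocellulose_core=ligno)


def _genesets_of(catalog) -> Mapping[str, frozenset[str]]:
    if isinstance(catalog, CazymeCatalog):
        return catalog.subfamilies
    if isinstance(catalog, NifCatalog):
        return catalog.classes
    return catalog


def lignocellulose_filter(
    catalog: CazymeCatalog,
    subfamilies: Iterable[str],
    substrate_tags: Iterable[str] | None = None,
) -> frozenset[str]:
    """Subfamilies whose substrate tags intersect the lignocellulose vocabulary.

    Subfamilies without a substrate mapping are treated as non-matching (and
    counted in a log line) rather than raising, since substrate prediction
    coverage is never complete.
    """
    tags = frozenset(substrate_tags) if substrate_tags is not None \
        else DEFAULT_LIGNOCELLULOSE_TAGS
    subfamilies = list(subfamilies)
    unmapped = [sf for sf in subfamilies if sf not in catalog.substrates]
    if unmapped:
        logger.info("%d/%d subfamilies lack substrate tags and are treated as "
                    "non-lignocellulose", len(unmapped), len(subfamilies))
    return frozenset(
        sf for sf in subfamilies
        if catalog.substrates.get(sf, frozenset()) & tags
    )


# ---------------------------------------------------------------------------
# diversity vs richness
# ---------------------------------------------------------------------------

@dataclass
class DiversityResult:
    """Per-specimen lignocellulose-active subfamily diversity, grouped by k."""

    per_specimen: pd.Series                 # specimen -> diversity
    by_richness: dict[int, list[int]]       # k -> diversity values
    comparison: GroupComparisonResult | None
    mode: str


def diversity_by_richness(
    pm: PresenceMatrix,
    catalog: CazymeCatalog,
    mode: str = "per_metagenome_union",
    substrate_tags: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> DiversityResult:
    """Lignocellulose-active CAZyme diversity as a function of richness k.

    Default mode ``per_metagenome_union``: a specimen's diversity is the
    number of distinct lignocellulose-active subfamilies in the union of its
    members' subfamily sets.  Mode ``per_mag`` instead contributes one value
    per (specimen, member) pair -- the member's own lignocellulose-active
    subfamily count -- grouped by the specimen's richness.  Groups (keyed by
    k) are compared with Kruskal-Wallis; when the omnibus is significant at
    ``alpha``, Dunn's test with Holm correction is run and attached.
    """
    if mode not in ("per_metagenome_union", "per_mag"):
        raise DataError(f"unknown diversity mode {mode!r}")
    values: dict[str, int] = {}
    by_richness: dict[int, list[int]] = {}
    for spec in pm.specimens:
        members = pm.members(spec)
        if not members:
            continue
        missing = members - set(catalog.subfamilies)
        if missing:
            raise DataError(f"no CAZyme catalog entry for taxon {sorted(missing)[0]!r} "
                            f"(specimen {spec!r})")
        k = len(members)
        if mode == "per_metagenome_union":
            union: frozenset[str] = frozenset()
            for t in members:
                union = union | catalog[t]
            d = len(lignocellulose_filter(catalog, union, substrate_tags))
            values[spec] = d
            by_richness.setdefault(k, []).append(d)
        else:
            per_mag = [
                len(lignocellulose_filter(catalog, catalog[t], substrate_tags))
                for t in sorted(members)
            ]
            values[spec] = int(round(sum(per_mag) / len(per_mag)))
            by_richness.setdefault(k, []).extend(per_mag)
    comparison = None
    if len(by_richness) >= 2:
        named = {f"k={k}": v for k, v in sorted(by_richness.items())}
        omnibus = kruskal_wallis(named)
        if omnibus.p_value <= alpha:
            comparison = dunn_posthoc(named, alpha=alpha)
        else:
            comparison = omnibus
    return DiversityResult(per_specimen=pd.Series(values, dtype=int),
                           by_richness=by_richness, comparison=comparison,
                           mode=mode)
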