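"""The five-level fuzzy similarity classifier for herbarium comparison units.

A binary same-name/different-name comparison is useless for pre-Linnaean
collections: every collector spelled and compounded names his own way.  The
comparison therefore assigns each query unit (a specimen, or a distinct
taxon) one of five ordinal similarity levels against a target collection:

=====  =====================  ==========================================
level  label                  condition (vs the best target specimen)
=====  =====================  ==========================================
100    exact similarity       same species, exactly the same name(s)
75     large similarity       same species, largely the same name(s)
50     partial similarity     same species, partly the same name(s)
25     vague / coincidental   name shared but wrong species (D1); species
                              shared but names only roughly similar or
                              different (D2); name and species present but
                              on *different* target specimens (D3)
0      no similarity          neither species nor name present (E)
=====  =====================  ==========================================

"largely" vs "partly" is decided by the proportion of the query's names
that find a counterpart on the candidate specimen (``theta_largely``,
default 2/3).  When the target holds duplicates, only the most similar
counterpart counts; ties break deterministically on higher name coverage,
then lower target specimen number, so results never depend on row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io import Collection, Specimen, LEVELS
from .normalize import (
    Lexicons,
    MatchParams,
    NameMatchGrade,
    OriginalName,
    default_lexicons,
    match_names,
    normalize_binomial,
    normalize_name,
    stems_roughly_similar,
)

__all__ = [
    "Thresholds",
    "NameSetSimilarity",
    "SpecimenComparison",
    "SimilarityProfile",
    "name_set_similarity",
    "classify_pair",
    "classify_unit",
    "compare_collections",
    "NameCache",
]

BRANCH_LEVEL = {"A": 100, "B": 75, "C": 50, "D1": 25, "D2": 25, "D3": 25, "E": 0}


@dataclass(frozen=True)
class Thresholds:
    """Pipeline tunables, echoed into every report for provenance.

    theta_largely: minimum fraction of the query unit's names that must be
    matched (with at least one exact/variant-strength match) for the
    "largely the same names" category; 2/3 reproduces the published
    four-name worked example at the large-similarity level.  "partly" is
    any non-zero shared proportion below that.
    """

    theta_largely: float = 2.0 / 3.0
    match: MatchParams = field(default_factory=MatchParams)
    undetermined_policy: str = "non_match"  # or "exclude"

    def echo(self) -> dict:
        return {
            "theta_largely": self.theta_largely,
            "variant_max_edits": self.match.variant_max_edits,
            "suffixes": list(self.match.suffixes),
            "min_stem_len": self.match.min_stem_len,
            "roughly_max_stem_edits": self.match.roughly_max_stem_edits,
            "undetermined_policy": self.undetermined_policy,
        }


DEFAULT_THRESHOLDS = Thresholds()


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NameSetSimilarity:
    """Outcome of matching two specimens' name sets one-to-one.

    Coverages are fractions of each side's names matched at the given
    strength; ``category`` is the ordinal label feeding the level rules:
    exact > largely > partly > roughly > different.
    """

    query_coverage: float
    exact_coverage: float
    candidate_coverage: float
    category: str
    pairs: tuple[tuple[int, int, str], ...] = ()  # (query idx, cand idx, grade)
    reason: str = ""


@dataclass(frozen=True)
class SpecimenComparison:
    """One query unit's verdict against one target collection."""

    unit_id: str
    best_counterpart: int | None
    species_match: bool
    name_similarity: NameSetSimilarity
    level: int
    branch: str
    target_id: str = ""

    def __post_init__(self):
        assert self.level == BRANCH_LEVEL[self.branch], \
            f"level {self.level} inconsistent with branch {self.branch}"


@dataclass(frozen=True)
class SimilarityProfile:
    """Counts of query units per similarity level for one collection pair."""

    query_id: str
    target_id: str
    counts: Mapping[int, int]
    n_units: int
    config_echo: Mapping = field(default_factory=dict)

    def __post_init__(self):
        assert sum(self.counts.values()) == self.n_units, \
            "level counts must sum to the number of comparison units"

    def as_dict(self) -> dict[int, int]:
        return {level: int(self.counts.get(level, 0)) for level in LEVELS}


# ---------------------------------------------------------------------------
# Normalized-name cache
# ---------------------------------------------------------------------------


class NameCache:
    """Memoizes raw-string -> OriginalName across a whole comparison run."""

    def __init__(self, lexicons: Lexicons | None = None):
        self.lexicons = lexicons or default_lexicons()
        self._names: dict[str, OriginalName] = {}
        self._binomials: dict[str, str] = {}

    def name(self, raw: str) -> OriginalName:
        got = self._names.get(raw)
        if got is None:
            got = self._names[raw] = normalize_name(raw, self.lexicons)
        return got

    def names(self, specimen: Specimen) -> tuple[OriginalName, ...]:
        return tuple(self.name(raw) for raw in specimen.original_names)

    def binomial(self, determination: str) -> str:
        got = self._binomials.get(determination)
        if got is None:
            got = self._binomials[determination] = normalize_binomial(determination)
        return got


# ---------------------------------------------------------------------------
# Name-set similarity
# ---------------------------------------------------------------------------


def name_set_similarity(query: Sequence[OriginalName],
                        candidate: Sequence[OriginalName],
                        thresholds: Thresholds = DEFAULT_THRESHOLDS,
                        ) -> NameSetSimilarity:
    """Match two name sets one-to-one and categorize the shared proportion.

    Matching is greedy on descending grade (exact=3 > variant=2 > partial=1)
    with index order breaking ties, which makes the outcome independent of
    input permutation up to relabeling.  Marker-only names (e.g. a bare
    "alius") are excluded from both sides before computing coverages.
    """
    q_eff = [(i, n) for i, n in enumerate(query) if not n.marker_only]
    c_eff = [(j, n) for j, n in enumerate(candidate) if not n.marker_only]
    if not q_eff or not c_eff:
        return NameSetSimilarity(0.0, 0.0, 0.0, "different",
                                 reason="marker-only name set")

    params = thresholds.match
    grades: list[tuple[int, int, int, NameMatchGrade]] = []
    for qi, (i, qn) in enumerate(q_eff):
        for cj, (j, cn) in enumerate(c_eff):
            g = match_names(qn, cn, params)
            if g.grade != "none":
                grades.append((g.value, qi, cj, g))
    # highest grade first; stable index order for determinism
    grades.sort(key=lambda t: (-t[0], t[1], t[2]))

    used_q: set[int] = set()
    used_c: set[int] = set()
    pairs: list[tuple[int, int, str]] = []
    for value, qi, cj, g in grades:
        if qi in used_q or cj in used_c:
            continue
        used_q.add(qi)
        used_c.add(cj)
        pairs.append((q_eff[qi][0], c_eff[cj][0], g.grade))

    nq, nc = len(q_eff), len(c_eff)
    matched = len(pairs)
    strong = sum(1 for _, _, g in pairs if g in ("exact", "variant"))
    query_coverage = matched / nq
    exact_coverage = strong / nq
    candidate_coverage = matched / nc

    if matched == nq and matched == nc and strong == matched:
        category = "exact"
    elif query_coverage >= thresholds.theta_largely and strong >= 1:
        category = "largely"
    elif matched > 0:
        category = "partly"
    else:
        category = "different"
        # weak residual signal: principal stems nearly agree somewhere
        for _, qn in q_eff:
            for _, cn in c_eff:
                if qn.principal and cn.principal and \
                        stems_roughly_similar(qn.principal, cn.principal, params):
                    category = "roughly"
                    break
            if category == "roughly":
                break

    return NameSetSimilarity(
        query_coverage=query_coverage,
        exact_coverage=exact_coverage,
        candidate_coverage=candidate_coverage,
        category=category,
        pairs=tuple(pairs),
    )


# ---------------------------------------------------------------------------
# Pair- and unit-level classification
# ---------------------------------------------------------------------------


def classify_pair(query: Specimen, candidate: Specimen,
                  thresholds: Thresholds = DEFAULT_THRESHOLDS,
                  cache: NameCache | None = None,
                  ) -> tuple[int, str, NameSetSimilarity]:
    """Level and rationale branch for one query/candidate specimen pair.

    Species equality is string equality of normalized binomials; a missing
    determination on either side counts as a species non-match under the
    default policy.
    """
    cache = cache or NameCache()
    q_bin = cache.binomial(query.determination)
    c_bin = cache.binomial(candidate.determination)
    species_match = bool(q_bin) and q_bin == c_bin

    sim = name_set_similarity(cache.names(query), cache.names(candidate),
                              thresholds)
    if species_match and sim.category == "exact":
        return 100, "A", sim
    if species_match and sim.category == "largely":
        return 75, "B", sim
    if species_match and sim.category == "partly":
        return 50, "C", sim
    if not species_match and sim.category in ("exact", "largely", "partly"):
        return 25, "D1", sim
    if species_match:  # roughly or different names
        return 25, "D2", sim
    return 0, "E", sim


def _unit_specimens(unit) -> list[Specimen]:
    return list(unit) if isinstance(unit, (list, tuple)) else [unit]


def classify_unit(query_unit, target: Collection,
                  thresholds: Thresholds = DEFAULT_THRESHOLDS,
                  cache: NameCache | None = None,
                  unit_id: str | None = None) -> SpecimenComparison:
    """Best-counterpart verdict for one query unit against a full collection.

    Every target specimen is scored with :func:`classify_pair`; only the
    most similar counterpart counts (the duplicate rule).  Ties break on
    higher query-name coverage, then lower target specimen number.  If the
    best is below 50 but the target holds the query's name (at >= partly
    strength) and the query's species on *different* specimens, the unit is
    re-branched to the cross-assignment case (25, D3).
    """
    if len(target) == 0:
        raise ValueError("empty target collection")
    cache = cache or NameCache()
    specimens = _unit_specimens(query_unit)
    uid = unit_id if unit_id is not None else \
        f"{specimens[0].collection_id}:{specimens[0].specimen_no}"

    best: tuple[int, float, int] | None = None  # (level, coverage, spec_no) key
    best_rec: tuple[int, str, NameSetSimilarity, Specimen] | None = None
    name_holders: set[int] = set()     # target specimens sharing a name
    species_holders: set[int] = set()  # target specimens sharing the species

    for q in specimens:
        q_bin = cache.binomial(q.determination)
        for cand in target:
            level, branch, sim = classify_pair(q, cand, thresholds, cache)
            if sim.category in ("exact", "largely", "partly"):
                name_holders.add(cand.specimen_no)
            if q_bin and cache.binomial(cand.determination) == q_bin:
                species_holders.add(cand.specimen_no)
            key = (level, sim.query_coverage, -cand.specimen_no)
            if best is None or key > best:
                best = key
                best_rec = (level, branch, sim, cand)

    level, branch, sim, cand = best_rec
    best_counterpart: int | None = cand.specimen_no

    # cross-assignment: the query's name and species are both in the target
    # but carried by *different* specimens (if one specimen carried both,
    # the pair rules would already have scored >= 50)
    if level < 50 and name_holders and species_holders \
            and len(name_holders | species_holders) >= 2:
        level, branch = 25, "D3"
        best_counterpart = None
    if branch == "E":
        best_counterpart = None

    species_match = branch in ("A", "B", "C", "D2")
    return SpecimenComparison(
        unit_id=uid,
        best_counterpart=best_counterpart,
        species_match=species_match,
        name_similarity=sim,
        level=level,
        branch=branch,
        target_id=target.id,
    )


# ---------------------------------------------------------------------------
# Collection-level comparison
# ---------------------------------------------------------------------------


def build_units(query: Collection, unit_mode: str, cache: NameCache,
                ) -> list[tuple[str, list[Specimen]]]:
    """Form comparison units: one per specimen, or one per distinct taxon.

    In taxon mode specimens sharing a normalized determination form one
    unit; undetermined specimens each stay their own unit.
    """
    if unit_mode == "specimen":
        return [(f"{query.id}:{sp.specimen_no}", [sp]) for sp in query]
    if unit_mode != "taxon":
        raise ValueError(f"unknown unit_mode {unit_mode!r}")
    groups: dict[str, list[Specimen]] = {}
    order: list[str] = []
    for sp in query:
        key = cache.binomial(sp.determination)
        if not key:
            key = f"{query.id}:undet:{sp.specimen_no}"
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(sp)
    return [(key, groups[key]) for key in order]


def compare_collections(query: Collection,
                        targets: Collection | Sequence[Collection],
                        thresholds: Thresholds = DEFAULT_THRESHOLDS,
                        unit_mode: str | None = None,
                        lexicons: Lexicons | None = None,
                        cache: NameCache | None = None,
                        ) -> tuple[SimilarityProfile, list[SpecimenComparison]]:
    """Profile one query collection against one or two target collections.

    With two targets ("combined" mode, e.g. a herbarium plus an earlier
    index of the same maker) each unit receives the better of its
    per-target verdicts, so no unit's level can drop when a second target
    is added.  Returns the level profile and the per-unit assignments.
    """
    target_list = [targets] if isinstance(targets, Collection) else list(targets)
    if not target_list:
        raise ValueError("at least one target collection required")
    for t in target_list:
        if len(t) == 0:
            raise ValueError(f"empty target collection {t.id!r}")
    mode = unit_mode or query.unit_mode or "taxon"
    cache = cache or NameCache(lexicons)

    units = build_units(query, mode, cache)
    if mode == "taxon" and all(
            not cache.binomial(sp.determination) for sp in query):
        raise ValueError("taxon unit mode requires at least one determination")

    assignments: list[SpecimenComparison] = []
    for uid, members in units:
        best = None
        for t in target_list:  # ties keep the earlier target
            c = classify_unit(members, t, thresholds, cache, unit_id=uid)
            key = (c.level, c.name_similarity.query_coverage)
            if best is None or key > best[0]:
                best = (key, c)
        assignments.append(best[1])

    counts = {level: 0 for level in LEVELS}
    for a in assignments:
        counts[a.level] += 1
    target_id = "+".join(t.id for t in target_list)
    profile = SimilarityProfile(
        query_id=query.id,
        target_id=target_id,
        counts=counts,
        n_units=len(assignments),
        config_echo={
            "unit_mode": mode,
            "combined": len(target_list) > 1,
            "targets": [t.id for t in target_list],
            **thresholds.echo(),
        },
    )
    return profile, assignments
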