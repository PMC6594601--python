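"""Synthetic paired collections with known ground-truth similarity.

Emulates the statistical structure of two 16th-century herbaria that may or
may not share plant material: a shared species pool in which every species
carries a small lexicon of period names; a "common origin" probability
``rho_common_origin`` that a target specimen of a shared species copies the
query's name choices verbatim (two books built from the same material and
name list); independent re-draws from the species lexicon otherwise (merely
contemporary naming); plus orthographic mutation, extra appended names,
target-side duplicates and cross-assignment confusions (names swapped
between two target specimens).

Ground truth is assigned *generatively* — from which copy/confusion event
fired and plain string-identity set logic on the realized name lists —
never by running the classifier, so classifier validation is not circular.

Generated principal name tokens are kept well separated (edit distance >= 2
and distinct declension stems, globally) so that at zero noise the fuzzy
matcher sees exactly the string-identity structure the truth encodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Collection, Specimen
from .normalize import MatchParams, default_lexicons, strip_declension
from .similarity import Thresholds, compare_collections

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SpeciesPool",
    "generate_lexicon",
    "generate_pair",
    "write_pair",
    "classifier_agreement",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    All probabilities in [0, 1]; sizes positive; ``n_query <= n_species``
    (query species are distinct so specimen and taxon units coincide).
    ``p_shared_species`` controls whether a query species occurs in the
    target at all; ``rho_common_origin`` controls, *given* a shared species,
    whether the target copies the query's name choices.
    """

    n_species: int = 60
    names_per_species: tuple[int, int] = (1, 3)
    n_query: int = 40
    n_target: int = 80
    rho_common_origin: float = 0.7
    p_shared_species: float = 0.85
    p_mutation: float = 0.0
    p_extra_name: float = 0.0
    p_cross_assign: float = 0.0
    p_duplicate: float = 0.1
    seed: int = 0
    theta_largely: float = 2.0 / 3.0
    query_id: str = "query"
    target_id: str = "target"

    def __post_init__(self):
        lo, hi = self.names_per_species
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid names_per_species range {self.names_per_species}")
        for name in ("n_species", "n_query", "n_target"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_query > self.n_species:
            raise ValueError("n_query cannot exceed n_species")
        for name in ("rho_common_origin", "p_shared_species", "p_mutation",
                     "p_extra_name", "p_cross_assign", "p_duplicate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Intended level and branch per query unit (specimen-mode unit ids)."""

    records: dict[str, tuple[int, str]]

    def level(self, unit_id: str) -> int:
        return self.records[unit_id][0]

    def as_frame(self) -> pd.DataFrame:
        rows = [{"unit_id": uid, "level": lvl, "branch": br}
                for uid, (lvl, br) in self.records.items()]
        return pd.DataFrame(rows, columns=["unit_id", "level", "branch"])


@dataclass(frozen=True)
class SpeciesPool:
    """Species with determinations and per-species period-name lexicons."""

    determinations: tuple[str, ...]
    name_lists: tuple[tuple[str, ...], ...]

    def __len__(self) -> int:
        return len(self.determinations)


# ---------------------------------------------------------------------------
# Latin-like word grammar
# ---------------------------------------------------------------------------

# v/j/y excluded so generated tokens are already in unified orthography;
# mutation reintroduces the interchangeable glyphs deliberately.
_ONSETS = ["b", "c", "d", "f", "g", "l", "m", "n", "p", "r", "s", "t",
           "br", "cr", "tr", "pl", "st", "th", "ph"]
_VOWELS = ["a", "e", "i", "o", "u"]
_CODAS = ["", "", "", "n", "r", "s", "x"]
_ENDINGS = ["a", "um", "us", "is", "on", "ia", "ium", "o", "e"]


def _word(rng: np.random.Generator) -> str:
    n_syll = int(rng.integers(2, 4))
    parts = []
    for _ in range(n_syll):
        parts.append(_ONSETS[rng.integers(len(_ONSETS))])
        parts.append(_VOWELS[rng.integers(len(_VOWELS))])
        parts.append(_CODAS[rng.integers(len(_CODAS))])
    parts.append(_ENDINGS[rng.integers(len(_ENDINGS))])
    return "".join(parts)


def _edit(a: str, b: str) -> int:
    import edlib
    return a != b and edlib.align(a, b)["editDistance"] or 0


class _TokenRegistry:
    """Hands out principal tokens pairwise separated in spelling and stem."""

    def __init__(self, params: MatchParams | None = None):
        self.params = params or MatchParams()
        self.tokens: list[str] = []
        self.stems: list[str] = []
        lex = default_lexicons()
        self.forbidden = set(lex.markers) | set(lex.conjunctions)

    def draw(self, rng: np.random.Generator, max_tries: int = 2000) -> str:
        for _ in range(max_tries):
            w = _word(rng)
            if w in self.forbidden or " " in w:
                continue
            stem = strip_declension(w, self.params)
            ok = all(
                _edit(w, t) > self.params.variant_max_edits
                and stem != s
                and _edit(stem, s) > self.params.roughly_max_stem_edits
                for t, s in zip(self.tokens, self.stems)
            )
            if ok:
                self.tokens.append(w)
                self.stems.append(stem)
                return w
        raise RuntimeError("token space exhausted; lower n_species or "
                           "names_per_species")


# ---------------------------------------------------------------------------
# Lexicon / pool generation
# ---------------------------------------------------------------------------


def generate_lexicon(config: SyntheticConfig,
                     seed: int | None = None) -> SpeciesPool:
    """Reproducible species pool with 1..k Latin-like names per species.

    Every name's principal token is globally unique and well separated, so
    names of different species never fuzzy-match; a name is one or two
    tokens (principal plus optional qualifier epithet).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    registry = _TokenRegistry()
    lo, hi = config.names_per_species
    dets, name_lists = [], []
    for _ in range(config.n_species):
        genus = registry.draw(rng).capitalize()
        epithet = _word(rng)
        dets.append(f"{genus} {epithet}")
        k = int(rng.integers(lo, hi + 1))
        names = []
        for _ in range(k):
            principal = registry.draw(rng).capitalize()
            if rng.random() < 0.4:
                names.append(f"{principal} {_word(rng)}")
            else:
                names.append(principal)
        name_lists.append(tuple(names))
    return SpeciesPool(tuple(dets), tuple(name_lists))


# ---------------------------------------------------------------------------
# Orthographic mutation
# ---------------------------------------------------------------------------

_RECOVERABLE = [("u", "v"), ("i", "j"), ("i", "y"), ("ae", "æ")]
_ALPHABET = "abcdefghilmnoprstu"


def _mutate_token(token: str, rng: np.random.Generator) -> str:
    """One orthographic edit: a unification-set glyph swap when applicable,
    else (or with equal chance) a random letter substitution."""
    ops = [(pat, repl) for pat, repl in _RECOVERABLE if pat in token]
    ops.append(("@sub", ""))
    pat, repl = ops[rng.integers(len(ops))]
    if pat == "@sub":
        pos = int(rng.integers(len(token)))
        letter = _ALPHABET[rng.integers(len(_ALPHABET))]
        return token[:pos] + letter + token[pos + 1:]
    occurrences = [i for i in range(len(token)) if token.startswith(pat, i)]
    pos = occurrences[rng.integers(len(occurrences))]
    return token[:pos] + repl + token[pos + len(pat):]


def _mutate_name(name: str, p: float, rng: np.random.Generator) -> str:
    if p <= 0:
        return name
    out = []
    for tok in name.split(" "):
        if rng.random() < p:
            tok = _mutate_token(tok, rng)
        out.append(tok)
    return " ".join(out)


# ---------------------------------------------------------------------------
# Constructive truth (string-identity set logic, not the classifier)
# ---------------------------------------------------------------------------


def _identity_level(query_names: Sequence[str], target_name_lists,
                    theta: float) -> tuple[int, str]:
    """Best level over a species' target specimens by exact string identity."""
    best = (25, "D2")
    qs = set(query_names)
    for t_names in target_name_lists:
        ts = set(t_names)
        inter = qs & ts
        if qs == ts:
            cand = (100, "A")
        elif inter and len(inter) / len(qs) >= theta:
            cand = (75, "B")
        elif inter:
            cand = (50, "C")
        else:
            cand = (25, "D2")
        if cand[0] > best[0]:
            best = cand
    return best


# ---------------------------------------------------------------------------
# Pair generation
# ---------------------------------------------------------------------------


def _subset(rng: np.random.Generator, items: Sequence[str],
            k: int | None = None) -> list[str]:
    if k is None:
        k = int(rng.integers(1, len(items) + 1))
    idx = sorted(rng.choice(len(items), size=k, replace=False).tolist())
    return [items[i] for i in idx]


def generate_pair(config: SyntheticConfig, seed: int | None = None,
                  pool: SpeciesPool | None = None,
                  ) -> tuple[Collection, Collection, GroundTruth]:
    """Generate a (query, target, truth) triple under ``config``.

    Identical config and seed give byte-identical collections.  With all
    noise probabilities zero the classifier recovers the truth exactly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if pool is None:
        pool = generate_lexicon(config, seed=int(rng.integers(2 ** 31)))

    species_idx = rng.permutation(len(pool))
    query_species = sorted(species_idx[: config.n_query].tolist())
    decoy_species = species_idx[config.n_query:].tolist()

    # --- query side (clean names; orthographic noise applied at assembly) --
    q_names_by_species: dict[int, list[str]] = {}
    for s in query_species:
        q_names_by_species[s] = _subset(rng, pool.name_lists[s])

    # --- target side ------------------------------------------------------
    shared = [s for s in query_species
              if rng.random() < config.p_shared_species][: config.n_target]
    if not shared and not decoy_species:
        # a target must hold at least one specimen; with no decoy species
        # available the only source is a shared query species
        shared = [query_species[int(rng.integers(len(query_species)))]]
    target_entries: list[dict] = []  # species, names, copied flag
    copied_entry_of: dict[int, int] = {}
    extra_specimens_of: dict[int, list[int]] = {}

    for s in shared:
        lexicon = pool.name_lists[s]
        copied = rng.random() < config.rho_common_origin
        names = list(q_names_by_species[s]) if copied else _subset(rng, lexicon)
        pure_copy = copied
        if rng.random() < config.p_extra_name:
            unused = [n for n in lexicon if n not in names]
            if unused:
                names.append(unused[int(rng.integers(len(unused)))])
                pure_copy = False
        entry = {"species": s, "names": names, "pure_copy": pure_copy}
        copied_entry_of[s] = len(target_entries)
        target_entries.append(entry)
        if rng.random() < config.p_duplicate:
            dup = {"species": s, "names": _subset(rng, lexicon),
                   "pure_copy": False}
            extra_specimens_of.setdefault(s, []).append(len(target_entries))
            target_entries.append(dup)

    rng.shuffle(decoy_species)
    for s in decoy_species:
        if len(target_entries) >= config.n_target:
            break
        target_entries.append({"species": s,
                               "names": _subset(rng, pool.name_lists[s]),
                               "pure_copy": False})

    # --- cross-assignment confusions --------------------------------------
    # swap name lists between two pure-copy, non-duplicated target specimens
    # of different species: the query keeps finding its names, but on the
    # wrong plant, while its plant sits there under the other set of names.
    cross_assigned: set[int] = set()
    if config.p_cross_assign > 0:
        eligible = [s for s in shared
                    if target_entries[copied_entry_of[s]]["pure_copy"]
                    and s not in extra_specimens_of]
        rng.shuffle(eligible)
        for a, b in zip(eligible[0::2], eligible[1::2]):
            if rng.random() < config.p_cross_assign:
                ia, ib = copied_entry_of[a], copied_entry_of[b]
                target_entries[ia]["names"], target_entries[ib]["names"] = \
                    target_entries[ib]["names"], target_entries[ia]["names"]
                cross_assigned.update((a, b))

    # --- constructive ground truth ----------------------------------------
    shared_set = set(shared)
    truth: dict[str, tuple[int, str]] = {}
    for no, s in enumerate(query_species, start=1):
        uid = f"{config.query_id}:{no}"
        if s in cross_assigned:
            truth[uid] = (25, "D3")
        elif s in shared_set:
            lists = [target_entries[copied_entry_of[s]]["names"]]
            lists += [target_entries[i]["names"]
                      for i in extra_specimens_of.get(s, [])]
            truth[uid] = _identity_level(q_names_by_species[s], lists,
                                         config.theta_largely)
        else:
            truth[uid] = (0, "E")

    # --- orthographic noise and assembly -----------------------------------
    # Noise is applied independently on both sides: each historical scribe
    # misspelled on his own, so a copied name can drift on both copies and
    # land beyond the variant budget — that is what makes it unrecoverable.
    query_specimens = []
    for no, s in enumerate(query_species, start=1):
        names = tuple(_mutate_name(n, config.p_mutation, rng)
                      for n in q_names_by_species[s])
        query_specimens.append(Specimen(
            collection_id=config.query_id, specimen_no=no,
            original_names=names,
            determination=pool.determinations[s]))

    order = rng.permutation(len(target_entries))
    target_specimens = []
    for no, i in enumerate(order.tolist(), start=1):
        e = target_entries[i]
        names = tuple(_mutate_name(n, config.p_mutation, rng)
                      for n in e["names"])
        target_specimens.append(Specimen(
            collection_id=config.target_id, specimen_no=no,
            original_names=names,
            determination=pool.determinations[e["species"]]))

    query = Collection(id=config.query_id, specimens=query_specimens,
                       unit_mode="specimen")
    target = Collection(id=config.target_id, specimens=target_specimens,
                        unit_mode="specimen")
    return query, target, GroundTruth(truth)


# ---------------------------------------------------------------------------
# Evaluation helpers
# ---------------------------------------------------------------------------


def classifier_agreement(query: Collection, target: Collection,
                         truth: GroundTruth,
                         thresholds: Thresholds | None = None) -> dict:
    """Run the classifier and score it against the generative truth.

    Returns level agreement (fraction of units whose assigned level equals
    the intended one), branch agreement, and the mean assigned level.
    """
    thresholds = thresholds or Thresholds()
    profile, assignments = compare_collections(
        query, target, thresholds=thresholds, unit_mode="specimen")
    n = len(assignments)
    level_hits = sum(1 for a in assignments
                     if a.level == truth.level(a.unit_id))
    branch_hits = sum(1 for a in assignments
                      if (a.level, a.branch) == truth.records[a.unit_id])
    return {
        "n_units": n,
        "level_agreement": level_hits / n,
        "branch_agreement": branch_hits / n,
        "mean_assigned_level": sum(a.level for a in assignments) / n,
        "mean_truth_level": sum(lvl for lvl, _ in truth.records.values()) / n,
        "profile": profile,
    }


def write_pair(query: Collection, target: Collection, truth: GroundTruth,
               out_dir: str | Path) -> dict[str, Path]:
    """Write the pair as standard specimen CSVs plus a ground-truth CSV."""
    from .io import write_collection

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "query": out_dir / f"{query.id}.csv",
        "target": out_dir / f"{target.id}.csv",
        "truth": out_dir / "ground_truth.csv",
    }
    write_collection(query, paths["query"])
    write_collection(target, paths["target"])
    truth.as_frame().to_csv(paths["truth"], index=False)
    return paths
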