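"""Normalization and fuzzy matching of early-modern (pre-Linnaean) plant names.

Sixteenth-century herbarium labels carry polynomial Latin phrase names with
no standardized spelling: ``u``/``v`` and ``i``/``j`` are interchangeable
glyphs, ``y`` freely replaces ``i``, and ligatures ``æ``/``œ`` alternate with
``ae``/``oe``.  On top of the orthography, labels mix in usage qualifiers
("vulgo" = commonly, "quibusdam" = by some), conjunctions linking alternative
names ("seu", "sive", "vel"), and author citations.  This module turns a raw
label into a comparable token sequence plus structured metadata, and grades
the similarity of two such names on the ordinal scale
``exact > variant > partial > none``.

Matching rules
--------------
* *exact* — identical normalized token sequences.
* *variant* — same token count, every aligned token within the orthographic
  variant distance (Levenshtein <= 1 after normalization), at least one
  token not identical.  "Aron" ~ "Arum" is a variant pair.
* *partial* — the principal (first non-marker) tokens agree at exact,
  variant, or declension-stem strength, but the names as wholes do not.
  "Erisimi" ~ "Erysimum" is a stem pair: after y→i unification the two
  differ only by the declension endings -i / -um.
* *none* — principal tokens unrelated.

Greek-script names are never matched against Latin-script names: writing
names in Greek characters was itself a distinguishing habit of particular
collectors, so a cross-script match would be spurious.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Mapping

import edlib

__all__ = [
    "Lexicons",
    "OriginalName",
    "NameMatchGrade",
    "MatchParams",
    "normalize_name",
    "classify_name",
    "match_names",
    "normalize_binomial",
    "GRADE_ORDER",
]

# ---------------------------------------------------------------------------
# Lexicons
# ---------------------------------------------------------------------------


def _read_terms(text: str) -> list[str]:
    out = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line.lower())
    return out


def _read_authors(text: str) -> dict[str, str]:
    """Parse ``Label: form1, form2`` lines into {normalized form -> label}."""
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line or ":" not in line:
            continue
        label, forms = line.split(":", 1)
        for form in forms.split(","):
            form = _unify_orthography(form.strip().lower())
            if form:
                mapping[form] = label.strip()
    return mapping


@dataclass(frozen=True)
class Lexicons:
    """Editable term lists driving marker/conjunction/author/vernacular logic.

    All terms are stored in normalized orthography so lookups happen after
    unification.  Files are one term per line, UTF-8, ``#`` comments.
    """

    markers: tuple[str, ...]
    conjunctions: tuple[str, ...]
    authors: Mapping[str, str]  # normalized surface form -> canonical label
    vernacular_markers: tuple[str, ...]
    italian_tokens: frozenset[str]

    @classmethod
    def default(cls) -> "Lexicons":
        pkg = resources.files("herblink.lexicons")
        return cls.from_texts(
            markers=(pkg / "markers.txt").read_text("utf-8"),
            conjunctions=(pkg / "conjunctions.txt").read_text("utf-8"),
            authors=(pkg / "authors.txt").read_text("utf-8"),
            vernacular_markers=(pkg / "vernacular_markers.txt").read_text("utf-8"),
            italian_tokens=(pkg / "italian_tokens.txt").read_text("utf-8"),
        )

    @classmethod
    def from_texts(cls, markers: str, conjunctions: str, authors: str,
                   vernacular_markers: str, italian_tokens: str) -> "Lexicons":
        return cls(
            markers=tuple(_unify_orthography(t) for t in _read_terms(markers)),
            conjunctions=tuple(_unify_orthography(t) for t in _read_terms(conjunctions)),
            authors=_read_authors(authors),
            vernacular_markers=tuple(_unify_orthography(t) for t in _read_terms(vernacular_markers)),
            italian_tokens=frozenset(_unify_orthography(t) for t in _read_terms(italian_tokens)),
        )

    @classmethod
    def from_dir(cls, path: str | Path) -> "Lexicons":
        path = Path(path)
        return cls.from_texts(
            markers=(path / "markers.txt").read_text("utf-8"),
            conjunctions=(path / "conjunctions.txt").read_text("utf-8"),
            authors=(path / "authors.txt").read_text("utf-8"),
            vernacular_markers=(path / "vernacular_markers.txt").read_text("utf-8"),
            italian_tokens=(path / "italian_tokens.txt").read_text("utf-8"),
        )


_DEFAULT_LEXICONS: Lexicons | None = None


def default_lexicons() -> Lexicons:
    global _DEFAULT_LEXICONS
    if _DEFAULT_LEXICONS is None:
        _DEFAULT_LEXICONS = Lexicons.default()
    return _DEFAULT_LEXICONS


# ---------------------------------------------------------------------------
# Orthographic unification
# ---------------------------------------------------------------------------

_LIGATURES = {"æ": "ae", "œ": "oe", "ﬀ": "ff", "ﬁ": "fi"}

# v -> u, j -> i, y -> i: collapses the interchangeable early-modern glyph
# pairs onto one representative each.
_GLYPHS = str.maketrans({"v": "u", "j": "i", "y": "i"})

_GREEK_RE = re.compile(r"[Ͱ-Ͽἀ-῿]")
_PUNCT_RE = re.compile(r"[^\w\sͰ-Ͽἀ-῿]", re.UNICODE)
_WS_RE = re.compile(r"\s+")


def _strip_diacritics(text: str) -> str:
    # NFKD + drop combining marks; Greek letters keep their base forms.
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def _unify_orthography(text: str, ch_to_c: bool = False) -> str:
    """Lowercase and collapse interchangeable period spellings."""
    text = text.lower()
    for lig, repl in _LIGATURES.items():
        text = text.replace(lig, repl)
    # second case-fold: some codepoints only reach a cased base form after
    # NFKD decomposition
    text = _strip_diacritics(text).lower()
    text = text.translate(_GLYPHS)
    if ch_to_c:
        text = text.replace("ch", "c")
    text = _PUNCT_RE.sub(" ", text)
    return _WS_RE.sub(" ", text).strip()


def contains_greek(text: str) -> bool:
    return bool(_GREEK_RE.search(text))


# ---------------------------------------------------------------------------
# OriginalName
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OriginalName:
    """A single period name, raw plus normalized and annotated.

    ``tokens`` is the comparable sequence: lowercased, orthography-unified,
    markers and conjunctions removed.  A name consisting solely of marker
    words has empty ``tokens`` and ``marker_only`` set.
    """

    raw: str
    tokens: tuple[str, ...]
    markers: frozenset[str] = frozenset()
    has_conjunction: bool = False
    language: str = "latin"  # latin | vernacular | greek_script | mixed
    citations: frozenset[str] = frozenset()
    marker_only: bool = False

    @property
    def principal(self) -> str | None:
        """First non-marker token — the load-bearing word of a phrase name."""
        return self.tokens[0] if self.tokens else None

    @property
    def normalized(self) -> str:
        return " ".join(self.tokens)


def normalize_name(raw: str, lexicons: Lexicons | None = None,
                   ch_to_c: bool = False) -> OriginalName:
    """Normalize one raw period name into an :class:`OriginalName`.

    Raises ``ValueError`` on blank input.  Greek-script names get
    ``language="greek_script"`` and are kept untransliterated (their tokens
    are the unified Greek words); mixed-script names get ``language="mixed"``.
    Normalization is idempotent: feeding ``name.normalized`` back through
    yields the same tokens.
    """
    if raw is None or not str(raw).strip():
        raise ValueError("blank name")
    raw = str(raw)
    lex = lexicons or default_lexicons()

    unified = _unify_orthography(raw, ch_to_c=ch_to_c)
    greek = contains_greek(unified)
    latin_part = _GREEK_RE.sub(" ", unified)
    has_latin = bool(latin_part.strip())

    markers: set[str] = set()
    # multi-word marker phrases first, longest first, so "ab aliquibus" wins
    # over the bare "aliquibus"
    working = f" {unified} "
    for phrase in sorted(lex.markers, key=len, reverse=True):
        needle = f" {phrase} "
        if needle in working:
            markers.add(phrase)
            working = working.replace(needle, " ")
    tokens_all = working.split()

    has_conjunction = any(t in lex.conjunctions for t in tokens_all)
    tokens = tuple(t for t in tokens_all if t not in lex.conjunctions)

    citations = frozenset(lex.authors[t] for t in tokens if t in lex.authors)

    vernacular = bool(markers & set(lex.vernacular_markers)) or any(
        t in lex.italian_tokens for t in tokens
    )
    if greek and has_latin:
        language = "mixed"
    elif greek:
        language = "greek_script"
    elif vernacular:
        language = "vernacular"
    else:
        language = "latin"

    return OriginalName(
        raw=raw,
        tokens=tokens,
        markers=frozenset(markers),
        has_conjunction=has_conjunction,
        language=language,
        citations=citations,
        marker_only=not tokens,
    )


def classify_name(name: OriginalName, lexicons: Lexicons | None = None) -> dict:
    """Style record for one normalized name (used by collection profiling)."""
    return {
        "language": name.language,
        "has_conjunction": name.has_conjunction,
        "has_marker": bool(name.markers),
        "citations": set(name.citations),
    }


# ---------------------------------------------------------------------------
# Name-vs-name grading
# ---------------------------------------------------------------------------

GRADE_ORDER = {"exact": 3, "variant": 2, "partial": 1, "none": 0}

# Declension endings treated as equivalent when comparing stems; a fixed
# suffix table keeps the behaviour deterministic and auditable, unlike a
# full Latin morphological analyzer.
DECLENSION_SUFFIXES = ("um", "us", "ae", "on", "a", "i")


@dataclass(frozen=True)
class MatchParams:
    """Tunables for the orthographic-variant layer.

    variant_max_edits: Levenshtein budget for a token pair to count as a
    spelling variant (default 1 — "Aron"/"Arum" yes, "Robertina"/"Albertina"
    no).  min_stem_len guards against stripping a suffix off very short
    tokens.  roughly_max_stem_edits controls the weak "roughly similar"
    signal used only to distinguish the 25%-level sub-cases.
    """

    variant_max_edits: int = 1
    suffixes: tuple[str, ...] = DECLENSION_SUFFIXES
    min_stem_len: int = 2  # "Aron"/"Arum" must reach their shared stem "ar-"
    roughly_max_stem_edits: int = 1


DEFAULT_PARAMS = MatchParams()


@dataclass(frozen=True)
class NameMatchGrade:
    grade: str  # exact | variant | partial | none
    evidence: tuple[tuple[str, str, str], ...] = ()  # (query tok, cand tok, strength)
    reason: str = ""

    @property
    def value(self) -> int:
        return GRADE_ORDER[self.grade]


@lru_cache(maxsize=1 << 18)
def _edit_distance(a: str, b: str) -> int:
    if a == b:
        return 0
    return edlib.align(a, b)["editDistance"]


def strip_declension(token: str, params: MatchParams = DEFAULT_PARAMS) -> str:
    for suf in sorted(params.suffixes, key=len, reverse=True):
        if token.endswith(suf) and len(token) - len(suf) >= params.min_stem_len:
            return token[: -len(suf)]
    return token


def token_strength(a: str, b: str, params: MatchParams = DEFAULT_PARAMS) -> str:
    """Grade one token pair: exact | variant | stem | none."""
    if a == b:
        return "exact"
    if _edit_distance(a, b) <= params.variant_max_edits:
        return "variant"
    if strip_declension(a, params) == strip_declension(b, params):
        return "stem"
    return "none"


def stems_roughly_similar(a: str, b: str, params: MatchParams = DEFAULT_PARAMS) -> bool:
    """Weak signal: stems within a small edit distance but not equivalent."""
    sa, sb = strip_declension(a, params), strip_declension(b, params)
    return 0 < _edit_distance(sa, sb) <= params.roughly_max_stem_edits


def match_names(a: OriginalName, b: OriginalName,
                params: MatchParams = DEFAULT_PARAMS) -> NameMatchGrade:
    """Grade two normalized names; symmetric in its arguments.

    Marker-only names never match (grade ``none``), and Greek-script names
    only ever match other Greek-script names.
    """
    if a.marker_only or b.marker_only:
        return NameMatchGrade("none", reason="marker-only name")
    if (a.language == "greek_script") != (b.language == "greek_script"):
        return NameMatchGrade("none", reason="cross-script")

    if a.tokens == b.tokens:
        ev = tuple((t, t, "exact") for t in a.tokens)
        return NameMatchGrade("exact", evidence=ev)

    if len(a.tokens) == len(b.tokens):
        strengths = [token_strength(x, y, params) for x, y in zip(a.tokens, b.tokens)]
        if all(s in ("exact", "variant") for s in strengths):
            ev = tuple((x, y, s) for (x, y), s in zip(zip(a.tokens, b.tokens), strengths))
            return NameMatchGrade("variant", evidence=ev)

    pa, pb = a.principal, b.principal
    ps = token_strength(pa, pb, params)
    if ps in ("exact", "variant", "stem"):
        return NameMatchGrade("partial", evidence=((pa, pb, ps),))
    return NameMatchGrade("none")


# ---------------------------------------------------------------------------
# Determinations
# ---------------------------------------------------------------------------

_BINOMIAL_CLEAN_RE = re.compile(r"[^a-z\s\-]")


def normalize_binomial(determination: str | None) -> str:
    """Canonical ``genus epithet`` form for species-equality tests.

    Lowercases, strips authorship and infraspecific trailers, keeps the
    first two epithets.  Empty / missing determinations normalize to "".
    """
    if determination is None:
        return ""
    text = str(determination).strip().lower()
    if not text or text in ("nan", "none", "indet", "indet."):
        return ""
    text = text.replace("×", " ").replace(" x ", " ")
    text = _BINOMIAL_CLEAN_RE.sub(" ", text)
    parts = [p for p in text.split() if p not in ("x", "cf", "aff")]
    return " ".join(parts[:2])
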