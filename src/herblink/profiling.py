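"""Naming-style statistics that distinguish collections.

Beyond which plants a collector pressed, *how* he named them is a
fingerprint: single Latin names vs long vernacular phrases, conjunctions
linking alternative names ("seu", "sive", "vel", "et", "over"), generic
qualifiers ("alius", "aliquibus"), Greek-script names, and which classical
authors he cites.  These rates are descriptive — they support qualitative
attribution arguments rather than the ordinal similarity levels.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .io import Collection
from .normalize import Lexicons, default_lexicons, normalize_name

__all__ = ["LexicalProfile", "lexical_profile", "profiles_frame"]


@dataclass(frozen=True)
class LexicalProfile:
    """Per-collection naming-style summary; all rates are specimen fractions."""

    collection_id: str
    n_specimens: int
    mean_names_per_specimen: float
    conjunction_rate: float
    vernacular_rate: float
    greek_script_rate: float
    marker_rate: float
    citation_counts: Mapping[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "collection_id": self.collection_id,
            "n_specimens": self.n_specimens,
            "mean_names_per_specimen": self.mean_names_per_specimen,
            "conjunction_rate": self.conjunction_rate,
            "vernacular_rate": self.vernacular_rate,
            "greek_script_rate": self.greek_script_rate,
            "marker_rate": self.marker_rate,
            "citation_counts": dict(self.citation_counts),
        }


def lexical_profile(collection: Collection,
                    lexicons: Lexicons | None = None) -> LexicalProfile:
    """Aggregate per-name style flags to specimen-level rates.

    A specimen counts toward a rate if *any* of its names carries the
    feature (collections differ in preference, not in per-name tallies).
    Citation counts tally every author mention across all names.
    """
    if len(collection) == 0:
        raise ValueError(f"empty collection {collection.id!r}")
    lex = lexicons or default_lexicons()

    n = len(collection)
    total_names = 0
    conj = vern = greek = marker = 0
    citations: Counter[str] = Counter()
    for sp in collection:
        names = [normalize_name(raw, lex) for raw in sp.original_names]
        total_names += len(names)
        if any(nm.has_conjunction for nm in names):
            conj += 1
        if any(nm.language == "vernacular" for nm in names):
            vern += 1
        if any(nm.language in ("greek_script", "mixed") for nm in names):
            greek += 1
        if any(nm.markers for nm in names):
            marker += 1
        for nm in names:
            citations.update(nm.citations)

    return LexicalProfile(
        collection_id=collection.id,
        n_specimens=n,
        mean_names_per_specimen=total_names / n,
        conjunction_rate=conj / n,
        vernacular_rate=vern / n,
        greek_script_rate=greek / n,
        marker_rate=marker / n,
        citation_counts=dict(citations),
    )


def profiles_frame(profiles: list[LexicalProfile]) -> pd.DataFrame:
    """One row per collection, citation counts flattened to a string."""
    rows = []
    for p in profiles:
        row = p.as_dict()
        row["citation_counts"] = "; ".join(
            f"{k}:{v}" for k, v in sorted(p.citation_counts.items()))
        rows.append(row)
    return pd.DataFrame(rows)
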