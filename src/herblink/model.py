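"""Model/Results surface for collection comparison.

:class:`CollectionSimilarity` is built from a query collection and one or
two target collections; :meth:`~CollectionSimilarity.fit` runs the
five-level classification and returns a :class:`SimilarityResults` holding
the level profile, the per-unit assignments, a text ``summary()`` and
plotting/saving helpers — the shape familiar from statistical modelling
packages, adapted to a record-linkage estimator whose "parameters" are the
per-unit similarity levels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .io import Collection, ColumnMapping, LEVELS, read_collection, \
    write_comparison_report
from .normalize import Lexicons
from .similarity import SimilarityProfile, SpecimenComparison, Thresholds, \
    compare_collections

__all__ = ["CollectionSimilarity", "SimilarityResults"]

_LEVEL_LABELS = {100: "exact", 75: "large", 50: "partial",
                 25: "vague/coincidental", 0: "none"}


class CollectionSimilarity:
    """Five-level botanical similarity of a query collection vs target(s).

    Parameters
    ----------
    query : Collection
        The collection whose units are classified.
    targets : Collection or sequence of Collection
        One target, or two for combined mode (each unit keeps its better
        verdict; useful when a maker left both a herbarium and an earlier
        name index).
    thresholds : Thresholds, optional
        Matching tunables; defaults reproduce the documented worked
        examples.
    unit_mode : {"taxon", "specimen"}, optional
        Defaults to the query collection's own ``unit_mode``.
    """

    def __init__(self, query: Collection,
                 targets: Collection | Sequence[Collection],
                 thresholds: Thresholds | None = None,
                 unit_mode: str | None = None,
                 lexicons: Lexicons | None = None):
        self.query = query
        self.targets = [targets] if isinstance(targets, Collection) \
            else list(targets)
        self.thresholds = thresholds or Thresholds()
        self.unit_mode = unit_mode
        self.lexicons = lexicons

    @classmethod
    def from_files(cls, query_path, target_paths,
                   mapping: ColumnMapping | dict | str | None = None,
                   thresholds: Thresholds | None = None,
                   unit_mode: str | None = None) -> "CollectionSimilarity":
        """Build directly from specimen-table files (CSV/TSV/XLSX)."""
        if isinstance(target_paths, (str, Path)):
            target_paths = [target_paths]
        query = read_collection(query_path, mapping=mapping)
        targets = [read_collection(p, mapping=mapping) for p in target_paths]
        return cls(query, targets, thresholds=thresholds, unit_mode=unit_mode)

    def fit(self) -> "SimilarityResults":
        profile, assignments = compare_collections(
            self.query, self.targets, thresholds=self.thresholds,
            unit_mode=self.unit_mode, lexicons=self.lexicons)
        return SimilarityResults(self, profile, assignments)


class SimilarityResults:
    """Fitted comparison: level profile plus per-unit assignments."""

    def __init__(self, model: CollectionSimilarity,
                 profile: SimilarityProfile,
                 assignments: list[SpecimenComparison]):
        self.model = model
        self.profile = profile
        self.assignments = assignments

    @property
    def counts(self) -> dict[int, int]:
        return self.profile.as_dict()

    @property
    def n_units(self) -> int:
        return self.profile.n_units

    def frame(self) -> pd.DataFrame:
        """Per-unit assignments as a DataFrame."""
        return pd.DataFrame([{
            "unit_id": a.unit_id,
            "best_counterpart": a.best_counterpart,
            "level": a.level,
            "branch": a.branch,
            "species_match": a.species_match,
            "category": a.name_similarity.category,
            "query_coverage": a.name_similarity.query_coverage,
            "target_id": a.target_id,
        } for a in self.assignments])

    def summary(self) -> str:
        """Readable per-level table with percentages."""
        p = self.profile
        lines = [
            "Botanical similarity profile",
            "=" * 46,
            f"query:   {p.query_id}",
            f"targets: {', '.join(p.config_echo.get('targets', [p.target_id]))}"
            + ("  (combined)" if p.config_echo.get("combined") else ""),
            f"units:   {p.n_units} ({p.config_echo.get('unit_mode')})",
            "-" * 46,
            f"{'level':>6}  {'label':<20} {'count':>6} {'share':>8}",
        ]
        for level in LEVELS:
            c = p.counts.get(level, 0)
            lines.append(f"{level:>5}%  {_LEVEL_LABELS[level]:<20} {c:>6} "
                         f"{100.0 * c / p.n_units:>7.1f}%")
        lines.append("-" * 46)
        lines.append(f"{'total':>6}  {'':<20} {p.n_units:>6} {'100.0%':>8}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar chart of the level profile (counts per similarity level)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.2))
        levels = list(LEVELS)
        counts = [self.profile.counts.get(lv, 0) for lv in levels]
        ax.bar([f"{lv}%" for lv in levels], counts, color="#4a7c59")
        ax.set_xlabel("similarity level")
        ax.set_ylabel("query units")
        ax.set_title(f"{self.profile.query_id} vs {self.profile.target_id}")
        return ax

    def save(self, out_dir) -> dict:
        """Write the per-unit CSV and JSON summary report."""
        return write_comparison_report(self.profile, self.assignments, out_dir)

    def __repr__(self) -> str:
        return (f"<SimilarityResults {self.profile.query_id} vs "
                f"{self.profile.target_id}: {self.counts}>")
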