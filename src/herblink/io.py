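"""Reading and writing specimen tables and comparison outputs.

A specimen table is one row per herbarium sheet: a specimen number, the
original (period) name field — possibly several names separated by ";" —
the current determination, and optional volume/folio.  Column layouts vary
between digitized collections, so reading is driven by a
:class:`ColumnMapping` (inline or loaded from YAML/JSON) rather than fixed
headers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

__all__ = [
    "Specimen",
    "Collection",
    "ColumnMapping",
    "MappingError",
    "ValidationError",
    "read_collection",
    "write_comparison_report",
    "read_assignments",
    "tally_levels",
    "LEVELS",
]

LEVELS = (100, 75, 50, 25, 0)


class MappingError(ValueError):
    """A mapped column is missing from the file."""


class ValidationError(ValueError):
    """The file violates a specimen-table invariant."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Specimen:
    """One herbarium sheet entry: original name(s) plus determination.

    original_names holds the raw name strings as printed (>= 1, each
    non-blank); determination is the modern binomial, empty string when the
    sheet is undetermined.
    """

    collection_id: str
    specimen_no: int
    original_names: tuple[str, ...]
    determination: str = ""
    volume: str | None = None
    folio: str | None = None

    def __post_init__(self):
        if not self.original_names:
            raise ValidationError(
                f"specimen {self.specimen_no}: empty original-name list")
        for name in self.original_names:
            if not str(name).strip():
                raise ValidationError(
                    f"specimen {self.specimen_no}: blank original name")
        if self.specimen_no <= 0:
            raise ValidationError(
                f"specimen number must be positive, got {self.specimen_no}")


@dataclass
class Collection:
    """An ordered set of specimens under one collection id."""

    id: str
    specimens: list[Specimen] = field(default_factory=list)
    unit_mode: str = "taxon"  # how comparison units are formed

    def __post_init__(self):
        seen: dict[int, int] = {}
        dupes = []
        for sp in self.specimens:
            if sp.collection_id != self.id:
                raise ValidationError(
                    f"specimen {sp.specimen_no} has collection_id "
                    f"{sp.collection_id!r}, expected {self.id!r}")
            if sp.specimen_no in seen:
                dupes.append(sp.specimen_no)
            seen[sp.specimen_no] = 1
        if dupes:
            raise ValidationError(
                f"duplicate specimen numbers in {self.id!r}: {sorted(set(dupes))}")

    def __len__(self) -> int:
        return len(self.specimens)

    def __iter__(self):
        return iter(self.specimens)


# ---------------------------------------------------------------------------
# Column mapping
# ---------------------------------------------------------------------------


@dataclass
class ColumnMapping:
    """Names the columns of a specimen table and how to split the name field.

    ``separator`` splits compound original-name fields (";" as commonly
    printed); ``secondary_separator`` optionally enables a second split
    character (some indices separate with ","), applied after the first.
    ``sheet`` selects an XLSX worksheet by name or index.
    """

    specimen_no: str = "specimen_no"
    original_names: str = "original_names"
    determination: str = "determination"
    volume: str | None = None
    folio: str | None = None
    separator: str = ";"
    secondary_separator: str | None = None
    sheet: str | int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "ColumnMapping":
        path = Path(path)
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) if path.suffix.lower() in (".yml", ".yaml") \
                else json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise MappingError(f"unknown mapping keys: {sorted(unknown)}")
        return cls(**data)

    def split_names(self, raw: str) -> list[str]:
        parts = [raw]
        seps = [self.separator]
        if self.secondary_separator:
            seps.append(self.secondary_separator)
        for sep in seps:
            parts = [piece for chunk in parts for piece in chunk.split(sep)]
        return [p.strip() for p in parts if p.strip()]


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    return {".csv": "csv", ".tsv": "tsv", ".tab": "tsv",
            ".xlsx": "xlsx", ".xlsm": "xlsx"}.get(suffix, "csv")


def _load_frame(path: Path, fmt: str, mapping: ColumnMapping) -> pd.DataFrame:
    if fmt == "csv":
        return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                           encoding="utf-8")
    if fmt == "xlsx":
        frame = pd.read_excel(path, sheet_name=mapping.sheet, dtype=str)
        return frame.fillna("")
    raise ValueError(f"unsupported format {fmt!r}")


def read_collection(path: str | Path, format: str | None = None,
                    mapping: ColumnMapping | dict | str | Path | None = None,
                    collection_id: str | None = None,
                    unit_mode: str = "taxon") -> Collection:
    """Read one specimen table into a :class:`Collection`.

    Rows are preserved in file order, one specimen per row; the original-name
    field is split on the mapping's separator(s) and each part trimmed.
    Raises :class:`MappingError` when a mapped column is absent and
    :class:`ValidationError` on duplicate specimen numbers or empty name
    fields (with the offending row).
    """
    path = Path(path)
    if isinstance(mapping, (str, Path)):
        mapping = ColumnMapping.from_file(mapping)
    elif isinstance(mapping, dict):
        mapping = ColumnMapping(**mapping)
    elif mapping is None:
        mapping = ColumnMapping()
    fmt = format or _infer_format(path)
    frame = _load_frame(path, fmt, mapping)

    required = {"specimen number": mapping.specimen_no,
                "original names": mapping.original_names,
                "determination": mapping.determination}
    for role, col in required.items():
        if col not in frame.columns:
            raise MappingError(
                f"mapped {role} column {col!r} not found in {path.name} "
                f"(columns: {list(frame.columns)})")

    cid = collection_id or path.stem
    specimens: list[Specimen] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        rec = dict(zip(frame.columns, row))
        raw_names = str(rec[mapping.original_names])
        names = mapping.split_names(raw_names)
        if not names:
            raise ValidationError(
                f"{path.name} row {idx}: empty original-name field")
        try:
            no = int(float(rec[mapping.specimen_no]))
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path.name} row {idx}: bad specimen number "
                f"{rec[mapping.specimen_no]!r}") from None
        specimens.append(Specimen(
            collection_id=cid,
            specimen_no=no,
            original_names=tuple(names),
            determination=str(rec[mapping.determination]).strip(),
            volume=str(rec[mapping.volume]).strip() if mapping.volume else None,
            folio=str(rec[mapping.folio]).strip() if mapping.folio else None,
        ))
    return Collection(id=cid, specimens=specimens, unit_mode=unit_mode)


# ---------------------------------------------------------------------------
# Comparison reports
# ---------------------------------------------------------------------------

ASSIGNMENT_COLUMNS = ["unit_id", "best_counterpart", "level", "branch",
                      "query_coverage", "species_match"]


def write_comparison_report(profile, assignments: Sequence, out_dir: str | Path,
                            ) -> dict[str, Path]:
    """Write a per-unit CSV and a JSON summary for one collection comparison.

    ``profile`` is a SimilarityProfile and ``assignments`` the per-unit
    SpecimenComparison records produced together with it; their totals must
    agree.  Returns the paths written.
    """
    total = sum(profile.counts.values())
    if total != len(assignments) or profile.n_units != len(assignments):
        raise ValidationError(
            f"profile counts sum to {total} (n_units={profile.n_units}) but "
            f"{len(assignments)} assignments given")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = [{
        "unit_id": a.unit_id,
        "best_counterpart": "" if a.best_counterpart is None else a.best_counterpart,
        "level": a.level,
        "branch": a.branch,
        "query_coverage": round(a.name_similarity.query_coverage, 6),
        "species_match": a.species_match,
    } for a in assignments]
    per_unit = out_dir / f"{profile.query_id}_vs_{profile.target_id}_units.csv"
    pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS).to_csv(per_unit, index=False)

    summary = {
        "query_id": profile.query_id,
        "target_id": profile.target_id,
        "n_units": profile.n_units,
        "counts": {str(level): profile.counts.get(level, 0) for level in LEVELS},
        "config": profile.config_echo,
    }
    summary_path = out_dir / f"{profile.query_id}_vs_{profile.target_id}_summary.json"
    with open(summary_path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, ensure_ascii=False)
    return {"per_unit": per_unit, "summary": summary_path}


def write_collection(collection: Collection, path: str | Path,
                     separator: str = "; ") -> Path:
    """Write a collection as a standard specimen CSV (names joined by ";")."""
    path = Path(path)
    rows = [{
        "specimen_no": sp.specimen_no,
        "original_names": separator.join(sp.original_names),
        "determination": sp.determination,
        "volume": sp.volume or "",
        "folio": sp.folio or "",
    } for sp in collection]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_assignments(path: str | Path, level_column: str = "level",
                     unit_column: str | None = None) -> pd.DataFrame:
    """Load a per-unit assignment table (CSV/TSV/XLSX).

    Works both for tables this package wrote and for externally curated
    per-unit similarity tables, as long as one column carries the assigned
    level.  The level column is coerced to integers in {0,25,50,75,100}.
    """
    path = Path(path)
    fmt = _infer_format(path)
    if fmt == "xlsx":
        frame = pd.read_excel(path).fillna("")
    else:
        frame = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",",
                            keep_default_na=False, encoding="utf-8")
    if level_column not in frame.columns:
        raise MappingError(f"level column {level_column!r} not in {path.name}")
    levels = pd.to_numeric(frame[level_column], errors="raise").astype(int)
    bad = sorted(set(levels) - set(LEVELS))
    if bad:
        raise ValidationError(f"invalid similarity levels in {path.name}: {bad}")
    frame = frame.copy()
    frame[level_column] = levels
    return frame


def tally_levels(assignments: pd.DataFrame, level_column: str = "level",
                 ) -> dict[int, int]:
    """Count units per similarity level; every level key is present."""
    counts = assignments[level_column].value_counts().to_dict()
    return {level: int(counts.get(level, 0)) for level in LEVELS}
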