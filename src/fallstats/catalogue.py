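"""Catalogue of published fall/ADL movement repositories and selection rules.

The module carries a machine-readable transcription of the metadata of the 25
publicly released inertial-sensor repositories used to benchmark wearable
fall-detection systems (sensor placements, sampling rates, accelerometer
ranges, sample counts, subject demographics), together with the filters used
to pick comparable subsets of them and the taxonomy that groups raw activity
labels into five generic movement classes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .errors import CatalogueError, UnknownActivityError

__all__ = [
    "ActivityClass",
    "DatasetRecord",
    "SelectionCriteria",
    "BODY_POSITIONS",
    "SENSOR_KINDS",
    "WAIST_SELECTION",
    "WRIST_SELECTION",
    "load_catalogue",
    "select_datasets",
    "load_label_map",
    "classify_activity",
]

#: Recognized body positions for sensing points.  "hip" is kept distinct from
#: "waist": at least one repository placed its sensor on the hip and was not
#: pooled with the waist-mounted ones in comparative analyses.
BODY_POSITIONS = frozenset(
    {"waist", "wrist", "chest", "thigh", "ankle", "head", "neck", "hip"}
)

SENSOR_KINDS = frozenset({"accelerometer", "gyroscope", "magnetometer", "orientation"})


class ActivityClass(enum.Enum):
    """Generic movement classes by required physical effort / outcome."""

    BASIC = "basic"
    STANDARD = "standard"
    SPORTING = "sporting"
    NEAR_FALL = "near_fall"
    FALL = "fall"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def is_fall(self) -> bool:
        return self is ActivityClass.FALL


@dataclass(frozen=True)
class DatasetRecord:
    """One catalogue row: a published movement repository.

    Ranged metadata (sampling rate jitter, demographic ranges) is stored as a
    nominal value plus optional spread / (min, max) bounds; filters only use
    the nominal values.  ``release_group`` ties together repositories that
    were published as a single release and whose sample counts are pooled
    when a minimum-sample filter is applied.
    """

    name: str
    year: int
    positions: frozenset
    sensors: frozenset
    sampling_rate_hz: float | None = None
    sampling_rate_spread_hz: float | None = None
    accel_range_g: float | None = None
    n_samples_total: int | None = None
    n_adl: int | None = None
    n_fall: int | None = None
    n_subjects: int | None = None
    age_range: tuple | None = None
    weight_range: tuple | None = None
    height_range: tuple | None = None
    release_group: str | None = None
    notes: str = ""

    def validate(self) -> None:
        if not self.name:
            raise CatalogueError("dataset record with empty name")
        unknown = set(self.positions) - BODY_POSITIONS
        if unknown:
            raise CatalogueError(f"{self.name}: unknown positions {sorted(unknown)}")
        unknown = set(self.sensors) - SENSOR_KINDS
        if unknown:
            raise CatalogueError(f"{self.name}: unknown sensors {sorted(unknown)}")
        if self.accel_range_g is not None and not self.accel_range_g > 0:
            raise CatalogueError(f"{self.name}: accel_range_g must be > 0")
        if self.sampling_rate_hz is not None and not self.sampling_rate_hz > 0:
            raise CatalogueError(f"{self.name}: sampling_rate_hz must be > 0")
        counts = (self.n_samples_total, self.n_adl, self.n_fall)
        if all(c is not None for c in counts) and counts[0] != counts[1] + counts[2]:
            raise CatalogueError(
                f"{self.name}: n_samples_total != n_adl + n_fall "
                f"({counts[0]} != {counts[1]} + {counts[2]})"
            )


@dataclass(frozen=True)
class SelectionCriteria:
    """Filters used to pick comparable repositories.

    ``excluded_names`` covers purpose-based exclusions that no numeric rule
    expresses (e.g. a repository aimed at fall-risk scoring rather than fall
    detection).
    """

    required_position: str | None = None
    min_samples: int = 0
    min_accel_range_g: float = 0.0
    excluded_names: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.min_samples < 0:
            raise CatalogueError("min_samples must be >= 0")
        if self.min_accel_range_g < 0:
            raise CatalogueError("min_accel_range_g must be >= 0")
        object.__setattr__(self, "excluded_names", frozenset(self.excluded_names))


#: Waist analysis preset: waist placement, at least 300 recorded movements,
#: and an accelerometer range able to represent the 4-5 g impact peaks of
#: falls (a +/-2 g sensor cannot; we require at least +/-4.5 g).  One
#: fall-risk-oriented repository with only 5 falls is excluded by name.
WAIST_SELECTION = SelectionCriteria(
    required_position="waist",
    min_samples=300,
    min_accel_range_g=4.5,
    excluded_names=frozenset({"SMotion"}),
)

#: Wrist analysis preset: same floors applied to wrist-mounted recordings.
WRIST_SELECTION = SelectionCriteria(
    required_position="wrist",
    min_samples=300,
    min_accel_range_g=4.5,
)


def _split(cell: str) -> frozenset:
    if not cell or (isinstance(cell, float) and math.isnan(cell)):
        return frozenset()
    return frozenset(p.strip() for p in str(cell).split(";") if p.strip())


def _num(cell, kind=float):
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    if isinstance(cell, str) and not cell.strip():
        return None
    return kind(float(cell))


def _range(lo, hi) -> tuple | None:
    lo, hi = _num(lo), _num(hi)
    if lo is None and hi is None:
        return None
    return (lo, hi)


_REQUIRED_COLUMNS = ("name", "year", "positions")


def load_catalogue(path: str | Path | None = None) -> list[DatasetRecord]:
    """Load and validate a catalogue CSV; default is the bundled 25-row table."""
    if path is None:
        with resources.as_file(
            resources.files("fallstats.data") / "catalogue.csv"
        ) as p:
            return load_catalogue(p)
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _REQUIRED_COLUMNS:
        if col not in table.columns:
            raise CatalogueError(f"catalogue missing required column {col!r}")
    records = []
    for i, row in table.iterrows():
        rowname = row.get("name") or f"row {i + 1}"
        for col in _REQUIRED_COLUMNS:
            if not str(row[col]).strip():
                raise CatalogueError(f"{rowname}: missing required field {col!r}")
        try:
            rec = DatasetRecord(
                name=row["name"].strip(),
                year=int(row["year"]),
                positions=_split(row["positions"]),
                sensors=_split(row.get("sensors", "")),
                sampling_rate_hz=_num(row.get("sampling_rate_hz")),
                sampling_rate_spread_hz=_num(row.get("sampling_rate_spread_hz")),
                accel_range_g=_num(row.get("accel_range_g")),
                n_samples_total=_num(row.get("n_samples_total"), int),
                n_adl=_num(row.get("n_adl"), int),
                n_fall=_num(row.get("n_fall"), int),
                n_subjects=_num(row.get("n_subjects"), int),
                age_range=_range(row.get("age_min"), row.get("age_max")),
                weight_range=_range(row.get("weight_min"), row.get("weight_max")),
                height_range=_range(row.get("height_min"), row.get("height_max")),
                release_group=(row.get("release_group") or "").strip() or None,
                notes=(row.get("notes") or "").strip(),
            )
        except (ValueError, TypeError) as exc:
            raise CatalogueError(f"{rowname}: unparseable field ({exc})") from exc
        rec.validate()
        records.append(rec)
    return records


def _effective_samples(record: DatasetRecord, group_totals: dict) -> int:
    """Sample count used by the min-samples floor; pooled over a joint release."""
    if record.release_group is not None:
        return group_totals.get(record.release_group, 0)
    return record.n_samples_total or 0


def select_datasets(
    records: list[DatasetRecord], criteria: SelectionCriteria
) -> list[DatasetRecord]:
    """Filter catalogue records by position, sample floor, and sensor range.

    Records with an unknown accelerometer range fail any positive range floor;
    order of the input is preserved.  The operation is idempotent and
    monotone in the numeric floors.
    """
    group_totals: dict = {}
    for r in records:
        if r.release_group is not None:
            group_totals[r.release_group] = (
                group_totals.get(r.release_group, 0) + (r.n_samples_total or 0)
            )
    kept = []
    for r in records:
        if r.name in criteria.excluded_names:
            continue
        if (
            criteria.required_position is not None
            and criteria.required_position not in r.positions
        ):
            continue
        if _effective_samples(r, group_totals) < criteria.min_samples:
            continue
        if criteria.min_accel_range_g > 0 and (
            r.accel_range_g is None or r.accel_range_g < criteria.min_accel_range_g
        ):
            continue
        kept.append(r)
    return kept


def normalize_label(label: str) -> str:
    """Canonical form used for label-map lookup."""
    return " ".join(str(label).strip().lower().replace("-", " ").replace("_", " ").split())


def load_label_map(path: str | Path | None = None) -> dict:
    """Load a label map (class -> raw labels) into {normalized label: class}."""
    if path is None:
        with resources.as_file(
            resources.files("fallstats.data") / "activity_labels.yaml"
        ) as p:
            return load_label_map(p)
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    mapping: dict = {}
    for class_name, labels in raw.items():
        cls = ActivityClass(class_name)
        for label in labels:
            key = normalize_label(label)
            if key in mapping and mapping[key] is not cls:
                raise CatalogueError(
                    f"label {key!r} mapped to both {mapping[key]} and {cls}"
                )
            mapping[key] = cls
    return mapping


_DEFAULT_LABEL_MAP: dict | None = None


def _default_label_map() -> dict:
    global _DEFAULT_LABEL_MAP
    if _DEFAULT_LABEL_MAP is None:
        _DEFAULT_LABEL_MAP = load_label_map()
    return _DEFAULT_LABEL_MAP


def classify_activity(label: str, label_map: dict | None = None) -> ActivityClass:
    """Resolve a raw activity label to its movement class.

    Fall subtypes are open-ended: any normalized label starting with "fall"
    maps to the fall class.  Unmapped labels raise; they are never silently
    dropped.
    """
    if label_map is None:
        label_map = _default_label_map()
    key = normalize_label(label)
    if key in label_map:
        return label_map[key]
    if key.startswith("fall"):
        return ActivityClass.FALL
    raise UnknownActivityError(f"unknown activity label {label!r}")
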