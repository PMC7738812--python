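"""Reading, validating and writing triaxial accelerometer traces.

Canonical unit is g (standard gravity, 9.80665 m/s^2).  Trace files are plain
CSV with header ``t_s,ax_g,ay_g,az_g``; a manifest CSV carries one metadata
row per trace.  Timestamps are informational only: the sampling rate from the
metadata is authoritative, since several source repositories report nominal
rates with jitter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TraceParseError, TraceValidationError

logger = logging.getLogger(__name__)

STANDARD_GRAVITY = 9.80665  # m/s^2 per g

#: Slack allowed on |component| <= range_g, for quantization round-off.
RANGE_TOLERANCE_G = 1e-6

_AXES = ("x", "y", "z")

__all__ = [
    "AccelTrace",
    "VerticalAxisEstimate",
    "STANDARD_GRAVITY",
    "read_trace",
    "write_trace",
    "read_manifest",
    "write_manifest",
    "infer_vertical_axis",
]


@dataclass
class AccelTrace:
    """One labelled recording: three acceleration component series in g."""

    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float
    dataset: str = ""
    subject: str = ""
    position: str = ""
    activity_label: str = ""
    trace_id: str = ""
    range_g: float | None = None
    vertical_axis_override: str | None = None

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        self.validate()

    @property
    def n(self) -> int:
        return self.ax.shape[0]

    @property
    def components(self) -> np.ndarray:
        """(n, 3) array of the acceleration components in g."""
        return np.column_stack([self.ax, self.ay, self.az])

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    def validate(self) -> None:
        if not (self.ax.ndim == self.ay.ndim == self.az.ndim == 1):
            raise TraceValidationError("component series must be one-dimensional")
        if not (self.ax.shape == self.ay.shape == self.az.shape):
            raise TraceValidationError("component series must have equal length")
        if self.ax.shape[0] < 1:
            raise TraceValidationError("empty trace")
        if not self.fs > 0:
            raise TraceValidationError(f"sampling rate must be > 0, got {self.fs}")
        for name, arr in zip(_AXES, (self.ax, self.ay, self.az)):
            if not np.all(np.isfinite(arr)):
                raise TraceValidationError(f"non-finite values in a_{name}")
        if self.range_g is not None:
            peak = max(abs(self.ax).max(), abs(self.ay).max(), abs(self.az).max())
            if peak > self.range_g + RANGE_TOLERANCE_G:
                raise TraceValidationError(
                    f"|component| {peak:.6g} g exceeds sensor range "
                    f"+/-{self.range_g:g} g"
                )


@dataclass(frozen=True)
class VerticalAxisEstimate:
    """Which component axis carries gravity, by largest |mean| projection."""

    axis: str
    mean_abs_projection: float


def infer_vertical_axis(trace: AccelTrace) -> VerticalAxisEstimate:
    """Pick the gravity-dominant axis from the full-trace component means.

    The full trace (not the analysis window) is used because the orientation
    before any event defines the standing reference.  A metadata override
    takes precedence.  Ties within 1e-9 are broken in x, y, z order with a
    logged warning.
    """
    if trace.vertical_axis_override is not None:
        axis = trace.vertical_axis_override
        if axis not in _AXES:
            raise TraceValidationError(f"vertical_axis_override must be one of {_AXES}")
        proj = abs(float(np.mean(getattr(trace, "a" + axis))))
        return VerticalAxisEstimate(axis=axis, mean_abs_projection=proj)
    means = [abs(float(np.mean(a))) for a in (trace.ax, trace.ay, trace.az)]
    best = max(means)
    winners = [ax for ax, m in zip(_AXES, means) if best - m <= 1e-9]
    if len(winners) > 1:
        logger.warning(
            "vertical-axis tie between %s (|mean| projections %s); using %s",
            winners, [f"{m:.3g}" for m in means], winners[0],
        )
    axis = winners[0]
    return VerticalAxisEstimate(axis=axis, mean_abs_projection=means[_AXES.index(axis)])


def read_trace(
    path: str | Path,
    fs: float,
    unit: str = "g",
    *,
    dataset: str = "",
    subject: str = "",
    position: str = "",
    activity_label: str = "",
    trace_id: str = "",
    range_g: float | None = None,
    vertical_axis_override: str | None = None,
) -> AccelTrace:
    """Read one trace CSV (columns ``t_s,ax_g,ay_g,az_g``) into g units."""
    path = Path(path)
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise TraceParseError(f"{path}: cannot parse ({exc})") from exc
    missing = {"ax_g", "ay_g", "az_g"} - set(table.columns)
    if missing:
        raise TraceParseError(f"{path}: missing columns {sorted(missing)}")
    if len(table) == 0:
        raise TraceParseError(f"{path}: empty trace")
    comps = {}
    for col in ("ax_g", "ay_g", "az_g"):
        values = pd.to_numeric(table[col], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(np.isnan(values) & ~table[col].isna().to_numpy())
        if bad.size:
            raise TraceParseError(
                f"{path}: non-numeric value in column {col} at data row {bad[0] + 1}"
            )
        if np.isnan(values).any():
            row = int(np.flatnonzero(np.isnan(values))[0]) + 1
            raise TraceParseError(f"{path}: missing value in column {col} at row {row}")
        comps[col] = values
    scale = {"g": 1.0, "m/s^2": 1.0 / STANDARD_GRAVITY, "m/s2": 1.0 / STANDARD_GRAVITY}
    if unit not in scale:
        raise TraceParseError(f"unknown unit {unit!r}; expected 'g' or 'm/s^2'")
    s = scale[unit]
    return AccelTrace(
        ax=comps["ax_g"] * s,
        ay=comps["ay_g"] * s,
        az=comps["az_g"] * s,
        fs=fs,
        dataset=dataset,
        subject=subject,
        position=position,
        activity_label=activity_label,
        trace_id=trace_id or path.stem,
        range_g=range_g,
        vertical_axis_override=vertical_axis_override,
    )


def write_trace(trace: AccelTrace, path: str | Path) -> Path:
    """Write a trace deterministically with full round-trip float precision."""
    trace.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = trace.t
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("t_s,ax_g,ay_g,az_g\n")
        for i in range(trace.n):
            fh.write(
                f"{t[i]:.9g},{trace.ax[i]:.17g},{trace.ay[i]:.17g},{trace.az[i]:.17g}\n"
            )
    return path


_MANIFEST_COLUMNS = [
    "trace_id",
    "path",
    "dataset",
    "subject",
    "position",
    "activity_label",
    "fs_hz",
    "range_g",
    "unit",
    "vertical_axis_override",
]


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(rows, columns=_MANIFEST_COLUMNS)
    table.to_csv(path, index=False, lineterminator="\n")
    return path


def read_manifest(path: str | Path) -> list[AccelTrace]:
    """Load every trace listed in a manifest CSV (paths relative to it)."""
    path = Path(path)
    table = pd.read_csv(path, dtype={"vertical_axis_override": str})
    missing = set(_MANIFEST_COLUMNS[:7]) - set(table.columns)
    if missing:
        raise TraceParseError(f"{path}: manifest missing columns {sorted(missing)}")
    traces = []
    for _, row in table.iterrows():
        override = row.get("vertical_axis_override")
        if isinstance(override, float) and np.isnan(override):
            override = None
        range_g = row.get("range_g")
        if isinstance(range_g, float) and np.isnan(range_g):
            range_g = None
        traces.append(
            read_trace(
                path.parent / row["path"],
                fs=float(row["fs_hz"]),
                unit=str(row.get("unit", "g")),
                dataset=str(row["dataset"]),
                subject=str(row["subject"]),
                position=str(row["position"]),
                activity_label=str(row["activity_label"]),
                trace_id=str(row["trace_id"]),
                range_g=range_g,
                vertical_axis_override=override or None,
            )
        )
    return traces
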