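"""Synthetic labelled accelerometer traces with fall phase structure.

The generator emulates what a body-worn triaxial accelerometer records, in g,
for the five generic movement classes:

* basic      - gravity along the vertical axis plus sensor noise, with an
               optional slow smooth reorientation;
* standard   - adds a periodic gait oscillation of moderate amplitude;
* sporting   - faster, larger gait oscillation;
* fall       - pre-fall gait, a free-fall decay of the acceleration module
               toward ``freefall_depth_g``, a sharp half-sine impact peak
               reaching ``impact_peak_g``, a damped post-impact oscillation,
               and rest with the gravity direction rotated by
               ``post_rotation_rad`` (the body ends up lying down);
* near fall  - a dip and recovery with no impact above 2 g and no final
               orientation change.

The module magnitude (SMV) envelope is constructed first and distributed to
the components through a time-varying orientation, because falls are
characterized by SMV valleys and peaks rather than per-axis templates.  All
components are clipped to the simulated sensor range.  Given identical
parameters and seed the output is bit-for-bit reproducible; scenario builders
derive one child seed per trace from the dataset seed with a documented
counter scheme.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .catalogue import ActivityClass
from .errors import ConfigError
from .trace_io import AccelTrace, write_manifest, write_trace

__all__ = [
    "ActivityParams",
    "SyntheticDatasetConfig",
    "default_params",
    "generate_trace",
    "generate_dataset",
    "generate_scenario",
    "null_scenario",
    "heterogeneous_scenario",
    "load_scenario_config",
]

_CLASS_ORDER = [
    ActivityClass.BASIC,
    ActivityClass.STANDARD,
    ActivityClass.SPORTING,
    ActivityClass.NEAR_FALL,
    ActivityClass.FALL,
]

#: Raw labels cycled over when generating traces of a class, so downstream
#: label classification is exercised on realistic subtype names.
_CLASS_LABELS = {
    ActivityClass.BASIC: ["standing", "sitting down", "lying down"],
    ActivityClass.STANDARD: ["walking", "climbing stairs", "picking"],
    ActivityClass.SPORTING: ["jogging", "jumping"],
    ActivityClass.NEAR_FALL: ["stumble", "trip"],
    ActivityClass.FALL: ["fall forward", "fall backwards", "fall lateral"],
}


@dataclass(frozen=True)
class ActivityParams:
    """Generator parameters for one movement class.

    Amplitudes are in g, durations in seconds, the gait frequency in Hz.
    ``freefall_depth_g`` is the SMV target of the pre-impact valley,
    ``impact_peak_g`` the exact SMV value of the impact peak sample.
    """

    activity_class: ActivityClass
    duration_s: float = 8.0
    gait_freq_hz: float = 0.0
    gait_amp_g: float = 0.0
    noise_sd_g: float = 0.03
    freefall_depth_g: float = 0.3
    freefall_dur_s: float = 0.3
    impact_peak_g: float = 5.5
    impact_dur_s: float = 0.1
    post_rotation_rad: float = 0.0
    recovery_dur_s: float = 0.4
    recovery: bool = False

    def validate(self) -> None:
        if not 0 <= self.freefall_depth_g < 1:
            raise ConfigError("freefall_depth_g must be in [0, 1)")
        if self.activity_class is ActivityClass.FALL and not self.impact_peak_g > 1:
            raise ConfigError("impact_peak_g must be > 1 g for falls")
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be > 0")
        if self.noise_sd_g < 0:
            raise ConfigError("noise_sd_g must be >= 0")
        if self.activity_class is ActivityClass.FALL:
            needed = 0.4 * self.duration_s + self.freefall_dur_s + self.impact_dur_s + 0.5
            if needed > self.duration_s:
                raise ConfigError(
                    "duration_s too short for the fall phase structure"
                )


_DEFAULTS = {
    ActivityClass.BASIC: dict(noise_sd_g=0.03),
    ActivityClass.STANDARD: dict(gait_freq_hz=1.8, gait_amp_g=0.25, noise_sd_g=0.05),
    ActivityClass.SPORTING: dict(gait_freq_hz=2.8, gait_amp_g=0.6, noise_sd_g=0.08),
    ActivityClass.NEAR_FALL: dict(
        gait_freq_hz=1.8, gait_amp_g=0.25, noise_sd_g=0.05,
        freefall_depth_g=0.4, freefall_dur_s=0.3, recovery=True,
    ),
    ActivityClass.FALL: dict(
        gait_freq_hz=1.8, gait_amp_g=0.25, noise_sd_g=0.05,
        freefall_depth_g=0.3, freefall_dur_s=0.3,
        impact_peak_g=5.5, impact_dur_s=0.1,
        post_rotation_rad=math.pi / 2,
    ),
}


def default_params(activity_class: ActivityClass) -> ActivityParams:
    """Default generator parameters for one movement class."""
    return ActivityParams(activity_class=activity_class, **_DEFAULTS[activity_class])


def _tilt_direction(theta: np.ndarray) -> np.ndarray:
    """Unit gravity direction tilted by theta from the z axis, in the x-z plane."""
    return np.stack([np.sin(theta), np.zeros_like(theta), np.cos(theta)], axis=1)


def generate_trace(
    params: ActivityParams,
    fs: float,
    range_g: float = 16.0,
    seed=0,
    *,
    dataset: str = "synthetic",
    subject: str = "s00",
    position: str = "waist",
    activity_label: str | None = None,
    trace_id: str = "",
) -> AccelTrace:
    """Generate one trace; identical (params, fs, seed) give identical output."""
    params.validate()
    if not fs > 0:
        raise ConfigError("fs must be > 0")
    if not range_g > 0:
        raise ConfigError("range_g must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(params.duration_s * fs))
    if n < 2:
        raise ConfigError("duration_s * fs must give at least 2 samples")
    t = np.arange(n) / fs
    cls = params.activity_class

    env = np.ones(n)
    theta = np.zeros(n)
    gait_mask = np.zeros(n, dtype=bool)
    phase = rng.uniform(0.0, 2.0 * np.pi)

    if cls in (ActivityClass.BASIC, ActivityClass.STANDARD, ActivityClass.SPORTING):
        gait_mask[:] = cls is not ActivityClass.BASIC
        theta = np.linspace(0.0, params.post_rotation_rad, n)
    else:
        i0 = int(round(0.4 * params.duration_s * fs))
        i1 = i0 + max(1, int(round(params.freefall_dur_s * fs)))
        if cls is ActivityClass.FALL:
            i2 = i1 + max(2, int(round(params.impact_dur_s * fs)))
            i3 = min(n, i2 + max(1, int(round(0.4 * fs))))
            if i3 > n:
                raise ConfigError("fall phases do not fit in duration_s")
            gait_mask[:i0] = True
            env[i0:i1] = np.linspace(1.0, params.freefall_depth_g, i1 - i0,
                                     endpoint=False)
            # half-sine impact; the mid sample is pinned to the exact peak
            j = np.arange(i2 - i1 + 1)
            seg = params.freefall_depth_g + (
                params.impact_peak_g - params.freefall_depth_g
            ) * np.sin(np.pi * j / (i2 - i1))
            stop = min(i2 + 1, n)
            env[i1:stop] = seg[: stop - i1]
            p = (i1 + i2) // 2
            env[p] = params.impact_peak_g
            # damped post-impact oscillation around 1 g
            osc = t[i2 + 1 : i3] - t[i2]
            env[i2 + 1 : i3] = 1.0 + 0.3 * (params.impact_peak_g - 1.0) * np.exp(
                -8.0 * osc
            ) * np.cos(2.0 * np.pi * 6.0 * osc)
            env[i3:] = 1.0
            ramp = np.clip((np.arange(n) - i1) / max(i3 - i1, 1), 0.0, 1.0)
            theta = params.post_rotation_rad * ramp
        else:  # near fall: dip plus recovery, no rotation, no impact >= 2 g
            rec = max(2, int(round(params.recovery_dur_s * fs)))
            i2 = min(n, i1 + rec)
            gait_mask[:i0] = True
            gait_mask[i2:] = True
            env[i0:i1] = np.linspace(1.0, params.freefall_depth_g, i1 - i0,
                                     endpoint=False)
            # recover with a mild overshoot bump (max 1.4 g, well under 2 g)
            j = np.arange(i2 - i1)
            half = np.sin(np.pi * j / max(i2 - i1, 1))
            env[i1:i2] = (
                params.freefall_depth_g
                + (1.0 - params.freefall_depth_g) * (j / max(i2 - i1 - 1, 1))
                + 0.4 * half
            )
            env[i2:] = 1.0

    if params.gait_amp_g > 0 and params.gait_freq_hz > 0:
        gait = params.gait_amp_g * np.sin(2 * np.pi * params.gait_freq_hz * t + phase)
        env = env + np.where(gait_mask, gait, 0.0)

    comp = env[:, None] * _tilt_direction(theta)

    if params.gait_amp_g > 0 and params.gait_freq_hz > 0:
        sway = 0.3 * params.gait_amp_g * np.sin(
            2 * np.pi * 2 * params.gait_freq_hz * t + 1.7 * phase
        )
        comp[:, 1] += np.where(gait_mask, sway, 0.0)

    if params.noise_sd_g > 0:
        comp = comp + rng.normal(0.0, params.noise_sd_g, comp.shape)

    np.clip(comp, -range_g, range_g, out=comp)

    if activity_label is None:
        activity_label = _CLASS_LABELS[cls][0]
    return AccelTrace(
        ax=comp[:, 0], ay=comp[:, 1], az=comp[:, 2],
        fs=fs, dataset=dataset, subject=subject, position=position,
        activity_label=activity_label, trace_id=trace_id or f"{dataset}-trace",
        range_g=range_g,
    )


@dataclass
class SyntheticDatasetConfig:
    """One synthetic "repository": per-class counts, parameters, and knobs.

    ``amplitude_multiplier`` scales gait amplitudes and fall impact peaks;
    ``noise_multiplier`` scales the sensor noise.  Fall impact peaks are
    drawn per trace from ``impact_peak_range_g`` (then scaled), reflecting
    the spread of impact violence across recorded falls.
    """

    name: str
    n_traces: dict
    fs: float = 50.0
    range_g: float = 16.0
    params: dict = field(default_factory=dict)
    amplitude_multiplier: float = 1.0
    noise_multiplier: float = 1.0
    impact_peak_range_g: tuple = (3.0, 8.0)
    position: str = "waist"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ConfigError(f"{self.name}: fs must be > 0")
        if not (self.amplitude_multiplier > 0 and self.noise_multiplier > 0):
            raise ConfigError(f"{self.name}: multipliers must be > 0")
        lo, hi = self.impact_peak_range_g
        if not (1 < lo <= hi):
            raise ConfigError(f"{self.name}: impact_peak_range_g must satisfy 1 < lo <= hi")
        self.n_traces = {
            (ActivityClass(k) if not isinstance(k, ActivityClass) else k): int(v)
            for k, v in self.n_traces.items()
        }

    def class_params(self, cls: ActivityClass) -> ActivityParams:
        return self.params.get(cls, default_params(cls))


def _trace_seed(dataset_seed: int, class_index: int, trace_index: int):
    """Documented counter scheme: one child seed per (class, trace) slot."""
    return np.random.SeedSequence([int(dataset_seed), class_index, trace_index])


def generate_dataset(config: SyntheticDatasetConfig) -> list:
    """All traces of one synthetic dataset, fully determined by its config."""
    traces = []
    for ci, cls in enumerate(_CLASS_ORDER):
        count = config.n_traces.get(cls, 0)
        labels = _CLASS_LABELS[cls]
        for j in range(count):
            ss = _trace_seed(config.seed, ci, j)
            jitter_ss, noise_ss = ss.spawn(2)
            jrng = np.random.default_rng(jitter_ss)
            p = config.class_params(cls)
            amp = config.amplitude_multiplier
            updates = {"noise_sd_g": p.noise_sd_g * config.noise_multiplier}
            if p.gait_amp_g > 0:
                updates["gait_amp_g"] = (
                    p.gait_amp_g * amp * jrng.uniform(0.85, 1.15)
                )
                updates["gait_freq_hz"] = p.gait_freq_hz * jrng.uniform(0.9, 1.1)
            if cls is ActivityClass.FALL:
                lo, hi = config.impact_peak_range_g
                updates["impact_peak_g"] = jrng.uniform(lo, hi) * amp
            traces.append(
                generate_trace(
                    replace(p, **updates),
                    fs=config.fs,
                    range_g=config.range_g,
                    seed=noise_ss,
                    dataset=config.name,
                    subject=f"s{j % 10:02d}",
                    position=config.position,
                    activity_label=labels[j % len(labels)],
                    trace_id=f"{config.name}-{cls.value}-{j:03d}",
                )
            )
    return traces


def generate_scenario(configs, out_dir: str | Path | None = None):
    """Generate every dataset of a scenario; optionally write traces + manifest.

    Returns ``(traces, manifest_rows)``.  When ``out_dir`` is given, the trace
    CSVs, a ``manifest.csv``, and a ``scenario.json`` recording every dataset
    seed are written there; two runs with the same configs are byte-identical.
    """
    names = [c.name for c in configs]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate dataset names in scenario: {names}")
    traces, rows = [], []
    for config in configs:
        for trace in generate_dataset(config):
            traces.append(trace)
            rows.append(
                {
                    "trace_id": trace.trace_id,
                    "path": f"{config.name}/{trace.trace_id}.csv",
                    "dataset": trace.dataset,
                    "subject": trace.subject,
                    "position": trace.position,
                    "activity_label": trace.activity_label,
                    "fs_hz": trace.fs,
                    "range_g": trace.range_g,
                    "unit": "g",
                    "vertical_axis_override": "",
                }
            )
    if out_dir is not None:
        out_dir = Path(out_dir)
        for trace, row in zip(traces, rows):
            write_trace(trace, out_dir / row["path"])
        write_manifest(rows, out_dir / "manifest.csv")
        meta = [
            {
                "name": c.name, "seed": c.seed, "fs": c.fs, "range_g": c.range_g,
                "amplitude_multiplier": c.amplitude_multiplier,
                "noise_multiplier": c.noise_multiplier,
                "impact_peak_range_g": list(c.impact_peak_range_g),
                "position": c.position,
                "n_traces": {k.value: v for k, v in c.n_traces.items()},
            }
            for c in configs
        ]
        with open(out_dir / "scenario.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return traces, rows


_DEFAULT_N_PER_CLASS = {
    ActivityClass.BASIC: 10,
    ActivityClass.STANDARD: 10,
    ActivityClass.SPORTING: 6,
    ActivityClass.NEAR_FALL: 6,
    ActivityClass.FALL: 20,
}


def _dataset_seed(root_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([int(root_seed), index]).generate_state(1)[0])


def null_scenario(
    seed: int,
    n_datasets: int = 5,
    n_per_class: dict | None = None,
    fs: float = 50.0,
    range_g: float = 16.0,
) -> list:
    """Homogeneous scenario: identical parameters, different seeds.

    Between-dataset differences are pure sampling noise, so downstream ANOVA
    rejections estimate the type-I error.
    """
    n_per_class = dict(n_per_class or _DEFAULT_N_PER_CLASS)
    return [
        SyntheticDatasetConfig(
            name=f"NULL{i + 1}",
            n_traces=n_per_class,
            fs=fs,
            range_g=range_g,
            seed=_dataset_seed(seed, i),
        )
        for i in range(n_datasets)
    ]


def heterogeneous_scenario(
    seed: int,
    n_per_class: dict | None = None,
) -> list:
    """Five datasets with technological/testbed-style parameter shifts.

    Dataset HET4 has amplitude_multiplier = 2 (its gait amplitudes and fall
    impact peaks are doubled), the others differ in sampling rate and noise
    level; this emulates detectable heterogeneity between repositories.
    """
    n_per_class = dict(n_per_class or _DEFAULT_N_PER_CLASS)
    knobs = [
        dict(fs=50.0, amplitude_multiplier=1.0, noise_multiplier=1.0),
        dict(fs=100.0, amplitude_multiplier=1.0, noise_multiplier=1.5),
        dict(fs=25.0, amplitude_multiplier=1.0, noise_multiplier=0.8),
        dict(fs=50.0, amplitude_multiplier=2.0, noise_multiplier=1.0),
        dict(fs=33.0, amplitude_multiplier=1.0, noise_multiplier=1.2),
    ]
    return [
        SyntheticDatasetConfig(
            name=f"HET{i + 1}",
            n_traces=n_per_class,
            range_g=16.0,
            seed=_dataset_seed(seed, i),
            **kn,
        )
        for i, kn in enumerate(knobs)
    ]


def load_scenario_config(path: str | Path) -> list:
    """Load a scenario from YAML: a ``datasets`` list of config mappings."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "datasets" not in raw:
        raise ConfigError(f"{path}: scenario file needs a 'datasets' list")
    configs = []
    for entry in raw["datasets"]:
        entry = dict(entry)
        if "impact_peak_range_g" in entry:
            entry["impact_peak_range_g"] = tuple(entry["impact_peak_range_g"])
        configs.append(SyntheticDatasetConfig(**entry))
    return configs
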