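"""The twelve mobility statistics computed on the analysis window.

All statistics are evaluated on the N_W samples of the located observation
interval, with the acceleration in g.  Conventions that matter:

* Population normalizers (1/N_W) are used for the standard deviation, the
  skewness, and the autocorrelation coefficients.
* The consecutive-sample statistics (mean absolute SMV difference, mean
  rotation angle) use the N_W - 1 sample pairs fully inside the window while
  keeping the 1/N_W prefactor.
* The energy is the per-axis sum of squared DFT coefficients divided by N_W
  (a plain unnormalized transform, no taper, no padding); by Parseval's
  identity this equals the sum of squared window samples, which tests use as
  an independent oracle.
* For a constant window (sigma_SMV = 0), the skewness and the mean
  autocorrelation are undefined and reported as NaN; downstream group
  statistics exclude them with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dataclass_fields

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import TraceTooShortError
from .trace_io import AccelTrace, infer_vertical_axis
from .windowing import AnalysisWindow, DEFAULT_WINDOW_S, locate_analysis_window

logger = logging.getLogger(__name__)

#: Fixed feature order used in every table and report.
FEATURE_NAMES = [
    "mu_smv",
    "sigma_smv",
    "mu_smv_diff",
    "mu_theta",
    "mu_ap",
    "a_wdiff_max",
    "smv_max",
    "smv_min",
    "gamma_smv",
    "sma",
    "energy",
    "mu_r",
]

_AXES = ("x", "y", "z")

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "compute_smv",
    "extract_features",
    "extract_feature_table",
    "MobilityFeatureExtractor",
]


@dataclass(frozen=True)
class FeatureVector:
    """The twelve window statistics of one trace.

    Units: g for the amplitude-like statistics, radians for ``mu_theta``,
    g^2 for ``energy``; ``gamma_smv`` and ``mu_r`` are dimensionless.
    NaN marks a feature that is undefined for the window (constant SMV).
    """

    mu_smv: float        # mean signal magnitude vector
    sigma_smv: float     # population SD of the SMV
    mu_smv_diff: float   # mean |SMV[i+1] - SMV[i]|
    mu_theta: float      # mean rotation angle between consecutive samples
    mu_ap: float         # mean magnitude of the horizontal component pair
    a_wdiff_max: float   # combined per-axis max-min variation of the window
    smv_max: float       # impact peak
    smv_min: float       # free-fall valley
    gamma_smv: float     # skewness of the SMV (population normalizer)
    sma: float           # signal magnitude area
    energy: float        # spectral energy summed over the three axes
    mu_r: float          # mean of the normalized autocorrelation of the SMV

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def compute_smv(trace: AccelTrace, window: AnalysisWindow) -> np.ndarray:
    """Signal Magnitude Vector sqrt(ax^2 + ay^2 + az^2) over the window."""
    sl = window.slice
    if window.stop > trace.n:
        raise IndexError(
            f"window [{window.k_o}, {window.stop}) outside trace of {trace.n} samples"
        )
    return np.sqrt(
        trace.ax[sl] ** 2 + trace.ay[sl] ** 2 + trace.az[sl] ** 2
    )


def _mean_rotation_angle(comp: np.ndarray, n_w: int) -> float:
    """Mean angle between consecutive acceleration vectors, 1/N_W prefactor.

    Zero-magnitude vectors contribute angle 0; the arccos argument is clamped
    to [-1, 1] against round-off.
    """
    a, b = comp[:-1], comp[1:]
    dots = np.einsum("ij,ij->i", a, b)
    norms = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    angles = np.zeros(len(dots))
    ok = norms > 0
    angles[ok] = np.arccos(np.clip(dots[ok] / norms[ok], -1.0, 1.0))
    return float(angles.sum() / n_w)


def _spectral_energy(comp: np.ndarray, n_w: int) -> float:
    """Sum over axes of (1/N_W) * sum_i |DFT(axis)[i]|^2."""
    total = 0.0
    for k in range(3):
        spectrum = np.fft.fft(comp[:, k])
        total += float(np.sum(np.abs(spectrum) ** 2))
    return total / n_w


def _mean_autocorrelation(smv: np.ndarray, mu: float, sigma: float) -> float:
    """Mean over lags 0..N_W-1 of the biased normalized autocorrelation."""
    n_w = smv.shape[0]
    c = smv - mu
    # full linear autocorrelation; lags 0..N_W-1 are the tail half
    r = np.correlate(c, c, mode="full")[n_w - 1 :]
    r /= sigma * sigma * n_w
    return float(r.sum() / n_w)


def extract_features(
    trace: AccelTrace,
    window: AnalysisWindow | None = None,
    *,
    t_w: float = DEFAULT_WINDOW_S,
    vertical_axis: str | None = None,
) -> FeatureVector:
    """Compute the twelve statistics on the trace's analysis window.

    If ``window`` is not given it is located first with duration ``t_w``.
    ``vertical_axis`` identifies the gravity-dominant component; the other
    two form the horizontal pair entering ``mu_ap``.  When omitted it is
    inferred from the full-trace component means (metadata override wins).
    """
    if window is None:
        window = locate_analysis_window(trace, t_w=t_w)
    if vertical_axis is None:
        vertical_axis = infer_vertical_axis(trace).axis
    if vertical_axis not in _AXES:
        raise ValueError(f"vertical_axis must be one of {_AXES}")

    sl = window.slice
    comp = trace.components[sl]
    n_w = window.n_w
    smv = compute_smv(trace, window)

    mu_smv = float(smv.mean())
    sigma_smv = float(np.sqrt(np.mean((smv - mu_smv) ** 2)))
    mu_smv_diff = float(np.abs(np.diff(smv)).sum() / n_w)
    mu_theta = _mean_rotation_angle(comp, n_w)

    horizontal = [k for k, ax in enumerate(_AXES) if ax != vertical_axis]
    mu_ap = float(
        np.sqrt(comp[:, horizontal[0]] ** 2 + comp[:, horizontal[1]] ** 2).mean()
    )

    smv_max = float(smv.max())
    smv_min = float(smv.min())
    sma = float(np.abs(comp).sum() / n_w)
    energy = _spectral_energy(comp, n_w)

    if sigma_smv > 0:
        gamma_smv = float(np.mean((smv - mu_smv) ** 3) / sigma_smv**3)
        mu_r = _mean_autocorrelation(smv, mu_smv, sigma_smv)
    else:
        gamma_smv = float("nan")
        mu_r = float("nan")

    return FeatureVector(
        mu_smv=mu_smv,
        sigma_smv=sigma_smv,
        mu_smv_diff=mu_smv_diff,
        mu_theta=mu_theta,
        mu_ap=mu_ap,
        a_wdiff_max=window.a_wdiff_max,
        smv_max=smv_max,
        smv_min=smv_min,
        gamma_smv=gamma_smv,
        sma=sma,
        energy=energy,
        mu_r=mu_r,
    )


def extract_feature_table(
    traces,
    t_w: float = DEFAULT_WINDOW_S,
    label_map: dict | None = None,
) -> pd.DataFrame:
    """One row per trace: identifiers, window location, then the 12 features.

    Traces shorter than the window are skipped with a logged warning;
    undefined feature values (NaN) are counted in the log.
    """
    from .catalogue import classify_activity  # deferred: avoid import cycle

    rows = []
    skipped = 0
    for trace in traces:
        try:
            window = locate_analysis_window(trace, t_w=t_w)
        except TraceTooShortError as exc:
            skipped += 1
            logger.warning("skipping trace %s: %s", trace.trace_id, exc)
            continue
        fv = extract_features(trace, window)
        row = {
            "trace_id": trace.trace_id,
            "dataset": trace.dataset,
            "subject": trace.subject,
            "position": trace.position,
            "activity_label": trace.activity_label,
            "activity_class": str(classify_activity(trace.activity_label, label_map)),
            "k_o": window.k_o,
            "n_w": window.n_w,
        }
        row.update(fv.as_dict())
        rows.append(row)
    table = pd.DataFrame(rows)
    if skipped:
        logger.warning("%d trace(s) shorter than the %g s window were skipped",
                       skipped, t_w)
    if len(table):
        undefined = table[FEATURE_NAMES].isna().sum()
        undefined = undefined[undefined > 0]
        if len(undefined):
            logger.info("undefined feature values excluded downstream: %s",
                        undefined.to_dict())
    return table


class MobilityFeatureExtractor(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer from traces to the 12-feature table.

    ``transform`` accepts an iterable of :class:`AccelTrace` and returns a
    DataFrame with identifier columns, the window location, and one column
    per statistic.  The transformer is stateless; ``fit`` only validates the
    parameters, so it composes with sklearn pipelines and parameter search.

    Parameters
    ----------
    window_duration_s : float, default 0.5
        Duration of the sliding observation window in seconds.
    label_map : dict or None
        Mapping from normalized activity labels to movement classes; the
        bundled map is used when None.
    """

    def __init__(self, window_duration_s: float = DEFAULT_WINDOW_S,
                 label_map: dict | None = None):
        self.window_duration_s = window_duration_s
        self.label_map = label_map

    def fit(self, X, y=None):
        if not self.window_duration_s > 0:
            raise ValueError("window_duration_s must be > 0")
        self.n_features_out_ = len(FEATURE_NAMES)
        self.feature_names_ = list(FEATURE_NAMES)
        return self

    def transform(self, X) -> pd.DataFrame:
        return extract_feature_table(
            X, t_w=self.window_duration_s, label_map=self.label_map
        )

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
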