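"""The measurement chain from oscilloscope waveform to lineal-energy spectrum.

Steps, mirroring the experimental signal processing:

1. a critical noise threshold from pre-irradiation baseline traces
   (:func:`determine_threshold`);
2. pulse peak extraction above threshold (:func:`extract_peaks`);
3. a linear calibration ``y = a·P + b`` fitted at the entrance depth by
   matching empirical peak-amplitude quantiles against the reference spectrum
   (:func:`fit_calibration`);
4. per-event conversion to lineal energy (:func:`convert_to_lineal`);
5. histogramming into the standard 0.5 keV/µm bins over 0–20 keV/µm
   (:func:`bin_spectrum`);
6. Monte Carlo propagation of the calibration-coefficient uncertainties to
   ȳD (:func:`propagate_calibration_uncertainty`).

Calibration uncertainties u_a and u_b are estimated by a bootstrap over the
events feeding the quantile fit: the Q–Q residuals of a correctly specified
linear model are near zero and would not reflect quantile sampling noise, so
resampling the events is the honest route to standard errors.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from ._rng import as_generator
from .containers import UNIT_KEV_UM, UNIT_MV, EventList, Trace
from .microdosimetry import ydbar as _ydbar

#: standard histogram: 0.5 keV/µm bins from 0 to 20 keV/µm
DEFAULT_BIN_WIDTH = 0.5
DEFAULT_Y_RANGE = (0.0, 20.0)
#: quantile levels of the Q–Q calibration fit (deciles 5%..95%)
DEFAULT_QUANTILES = np.arange(0.05, 0.951, 0.10)


@dataclass
class CalibrationModel:
    """The linear conversion y = a·P + b with 1σ coefficient uncertainties."""

    a: float  # keV/µm per mV
    b: float  # keV/µm
    u_a: float = 0.0
    u_b: float = 0.0
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("calibration slope a must be positive")
        if self.u_a < 0 or self.u_b < 0:
            raise ValueError("uncertainties must be non-negative")

    def to_json(self, path):
        payload = {"a": self.a, "b": self.b, "u_a": self.u_a, "u_b": self.u_b,
                   "method": "quantile-quantile least squares",
                   "quantiles": list(np.asarray(
                       self.fit_diagnostics.get("quantiles", DEFAULT_QUANTILES), dtype=float))}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(a=d["a"], b=d["b"], u_a=d.get("u_a", 0.0), u_b=d.get("u_b", 0.0))


@dataclass
class LinealEnergySpectrum:
    """Binned f(y): uniform 0.5 keV/µm bins over 0–20 keV/µm, half-open
    [low, high), with events at or above the top edge tracked as overflow
    (raw overflow values retained by default so ȳD can use them exactly)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    overflow_count: int = 0
    underflow_count: int = 0
    overflow_values: np.ndarray | None = None

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.bin_edges.size != self.counts.size + 1:
            raise ValueError("bin_edges must have one more entry than counts")
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("bins must be uniform")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_events(self) -> int:
        return int(self.counts.sum()) + int(self.overflow_count)

    def to_csv(self, path):
        import pandas as pd

        df = pd.DataFrame({
            "bin_low_keV_um": self.bin_edges[:-1],
            "bin_high_keV_um": self.bin_edges[1:],
            "count": self.counts,
        })
        over = pd.DataFrame({"bin_low_keV_um": [self.bin_edges[-1]],
                             "bin_high_keV_um": [np.inf],
                             "count": [self.overflow_count]})
        pd.concat([df, over], ignore_index=True).to_csv(path, index=False)


def determine_threshold(baseline, k: float = 5.0) -> float:
    """Critical noise threshold from a pre-irradiation baseline trace:
    mean + k·SD of the baseline samples (default k = 5)."""
    samples = baseline.samples if isinstance(baseline, Trace) else np.asarray(baseline, dtype=float)
    if samples.size == 0:
        raise ValueError("baseline must be non-empty")
    return float(samples.mean() + k * samples.std())


def extract_peaks(trace: Trace, threshold: float, min_separation: int = 1,
                  full_scale: float | None = None, baseline: float = 0.0) -> EventList:
    """Local maxima strictly above ``threshold``, at least ``min_separation``
    samples apart (the taller peak wins within a window).  Peaks at or above
    ``full_scale`` are recorded but counted as saturated.  ``baseline`` is
    subtracted from the reported amplitudes."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if full_scale is None:
        full_scale = float(trace.metadata.get("full_scale", 500.0))
    x = trace.samples
    idx, _ = find_peaks(x, height=np.nextafter(threshold, np.inf),
                        distance=max(1, int(min_separation)))
    amplitudes = x[idx]
    saturated = int(np.sum(amplitudes >= full_scale))
    amplitudes = np.clip(amplitudes - baseline, 0.0, None)
    return EventList(amplitudes, UNIT_MV, saturated_count=saturated,
                     metadata={"threshold_mV": float(threshold),
                               "min_separation": int(min_separation),
                               "full_scale_mV": full_scale, **trace.metadata})


def fit_quantile_line(peak_quantiles, reference_quantiles) -> tuple[float, float]:
    """Ordinary least squares through paired quantiles; returns (a, b).

    This is the deterministic core of the calibration: with noiseless matched
    quantiles it recovers the affine map exactly.
    """
    qp = np.asarray(peak_quantiles, dtype=float)
    qy = np.asarray(reference_quantiles, dtype=float)
    if qp.size != qy.size or qp.size < 2:
        raise ValueError("need at least two paired quantiles")
    if np.ptp(qp) == 0:
        raise ValueError("degenerate peaks: zero spread in quantiles")
    a, b = np.polyfit(qp, qy, 1)
    return float(a), float(b)


def fit_calibration(peaks: EventList, reference, quantiles=None,
                    n_boot: int = 200, seed=0) -> CalibrationModel:
    """Fit y = a·P + b by quantile–quantile least squares at the calibration
    depth: empirical deciles of the peak amplitudes regressed on the same
    quantiles of the reference spectrum.  u_a, u_b are bootstrap standard
    errors over the event sample (``n_boot`` resamples)."""
    q = np.asarray(quantiles if quantiles is not None else DEFAULT_QUANTILES, dtype=float)
    v = np.asarray(peaks.values, dtype=float)
    if v.size < 2 or np.ptp(v) == 0:
        raise ValueError("degenerate peak list: need >= 2 events with non-zero spread")
    if v.size < 100:
        warnings.warn("fewer than 100 events: calibration will be noisy")
    qy = np.asarray(reference.ppf(q), dtype=float)
    qp = np.quantile(v, q)
    a, b = fit_quantile_line(qp, qy)
    if a <= 0:
        raise ValueError("calibration fit produced a non-positive slope")

    rng = as_generator(seed)
    slopes = np.empty(n_boot)
    intercepts = np.empty(n_boot)
    for i in range(n_boot):
        resample = rng.choice(v, size=v.size, replace=True)
        try:
            slopes[i], intercepts[i] = fit_quantile_line(np.quantile(resample, q), qy)
        except ValueError:
            slopes[i], intercepts[i] = a, b
    u_a = float(slopes.std(ddof=1)) if n_boot > 1 else 0.0
    u_b = float(intercepts.std(ddof=1)) if n_boot > 1 else 0.0

    residuals = qy - (a * qp + b)
    return CalibrationModel(
        a=a, b=b, u_a=u_a, u_b=u_b,
        fit_diagnostics={"quantiles": q, "rms_residual": float(np.sqrt(np.mean(residuals**2))),
                         "n_events": int(v.size), "n_boot": int(n_boot)})


def convert_to_lineal(peaks: EventList, calib: CalibrationModel) -> EventList:
    """Apply y = a·P + b per event; non-positive results are dropped and
    counted (they are sub-threshold artifacts of the affine map)."""
    if peaks.unit != UNIT_MV:
        raise ValueError(f"expected peak amplitudes in mV, got {peaks.unit!r}")
    y = calib.a * peaks.values + calib.b
    keep = y > 0
    dropped = int(np.sum(~keep))
    return EventList(y[keep], UNIT_KEV_UM,
                     saturated_count=peaks.saturated_count,
                     dropped_count=peaks.dropped_count + dropped,
                     metadata={**peaks.metadata, "calibration": (calib.a, calib.b)})


def bin_spectrum(events: EventList, bin_width: float = DEFAULT_BIN_WIDTH,
                 y_range: tuple[float, float] = DEFAULT_Y_RANGE,
                 keep_overflow_values: bool = True) -> LinealEnergySpectrum:
    """Histogram lineal energies into half-open uniform bins; events at or
    beyond the top edge go to overflow.  Count conservation holds:
    Σcounts + overflow = number of input events."""
    if events.unit != UNIT_KEV_UM:
        raise ValueError(f"expected lineal energies in keV/um, got {events.unit!r}")
    lo, hi = y_range
    if hi <= lo or bin_width <= 0:
        raise ValueError("invalid binning window")
    n_bins = int(round((hi - lo) / bin_width))
    if not np.isclose(n_bins * bin_width, hi - lo):
        raise ValueError("bin_width must divide the range evenly")
    edges = lo + bin_width * np.arange(n_bins + 1)
    v = events.values
    over = v >= hi
    counts, _ = np.histogram(v[~over], bins=edges)
    return LinealEnergySpectrum(
        bin_edges=edges, counts=counts, overflow_count=int(over.sum()),
        overflow_values=np.sort(v[over]) if keep_overflow_values else None)


def propagate_calibration_uncertainty(calib: CalibrationModel, peaks: EventList,
                                      n_mc: int = 1000, seed=None) -> float:
    """Relative 1σ of ȳD induced by the calibration-coefficient uncertainties.

    Monte Carlo: draw (a, b) from independent normals centred on the fitted
    coefficients with SDs (u_a, u_b), recompute ȳD of the converted events for
    each draw, and report SD/mean over draws.
    """
    if n_mc < 100:
        raise ValueError("n_mc must be at least 100")
    if calib.u_a == 0 and calib.u_b == 0:
        return 0.0
    rng = as_generator(seed)
    a_draws = rng.normal(calib.a, calib.u_a, size=n_mc)
    b_draws = rng.normal(calib.b, calib.u_b, size=n_mc)
    v = np.asarray(peaks.values, dtype=float)
    out = np.empty(n_mc)
    for i in range(n_mc):
        y = a_draws[i] * v + b_draws[i]
        y = y[y > 0]
        out[i] = _ydbar(y)
    return float(out.std(ddof=1) / out.mean())
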