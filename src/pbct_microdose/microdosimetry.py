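"""Microdosimetric statistics.

The radiation-quality metric throughout is the dose-averaged lineal energy

    ȳD = Σ y²·f(y) / Σ y·f(y),

computed either directly on an event list (default, most accurate) or on a
binned spectrum using bin centers (parity with the histogram description of
the measurement).  Also provides the frequency-mean ȳF = Σ y·f(y)/Σ f(y), the
dose-weighted distribution d(y), repeat aggregation, and the two-tailed
unpaired (Welch by default) t-test used for the boron comparisons.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class MicrodoseSummary:
    ydbar: float  # keV/µm
    yfbar: float  # keV/µm
    n_events: int
    source: str = ""


@dataclass
class ComparisonResult:
    """Two-sample comparison of per-repeat ȳD values (or summary triples)."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    equal_var: bool = False


def _values_and_weights(data):
    """Normalize input to (y values, weights); weights None means unit weights."""
    if hasattr(data, "bin_centers") and hasattr(data, "counts"):
        y = np.asarray(data.bin_centers, dtype=float)
        w = np.asarray(data.counts, dtype=float)
        overflow = getattr(data, "overflow_count", 0)
        if overflow:
            raw = getattr(data, "overflow_values", None)
            if raw is not None and len(raw) == overflow:
                y = np.concatenate([y, np.asarray(raw, dtype=float)])
                w = np.concatenate([w, np.ones(overflow)])
            else:
                top = float(data.bin_edges[-1])
                warnings.warn(
                    f"{overflow} overflow events without recorded values; "
                    f"contributing at the top bin edge ({top} keV/um)")
                y = np.concatenate([y, [top]])
                w = np.concatenate([w, [float(overflow)]])
        return y, w
    if hasattr(data, "values") and hasattr(data, "unit"):
        return np.asarray(data.values, dtype=float), None
    return np.asarray(data, dtype=float), None


def ydbar(data) -> float:
    """Dose-averaged lineal energy Σy²f/Σyf (keV/µm)."""
    y, w = _values_and_weights(data)
    if y.size == 0:
        raise ValueError("ydbar of empty input is undefined")
    if w is None:
        w = np.ones_like(y)
    num = float(np.sum(w * y * y))
    den = float(np.sum(w * y))
    if den <= 0:
        raise ValueError("ydbar requires at least one positive lineal energy")
    return num / den


def yfbar(data) -> float:
    """Frequency-mean lineal energy Σyf/Σf (keV/µm)."""
    y, w = _values_and_weights(data)
    if y.size == 0:
        raise ValueError("yfbar of empty input is undefined")
    if w is None:
        w = np.ones_like(y)
    total = float(np.sum(w))
    if total <= 0:
        raise ValueError("yfbar requires non-empty input")
    return float(np.sum(w * y)) / total


def summarize(data, source: str = "") -> MicrodoseSummary:
    y, w = _values_and_weights(data)
    n = int(y.size if w is None else np.sum(w))
    return MicrodoseSummary(ydbar=ydbar(data), yfbar=yfbar(data), n_events=n, source=source)


def dose_distribution(spectrum) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin dose fractions d_i = y_i·f_i / Σ y_j·f_j (sums to 1).

    Returns ``(y, d)``.  With overflow present, one extra entry is appended
    (raw-value dose mass if recorded, else the top bin edge).
    """
    y, w = _values_and_weights(spectrum)
    if y.size == 0 or (w is not None and np.sum(w) == 0):
        raise ValueError("dose_distribution of empty spectrum is undefined")
    if w is None:
        w = np.ones_like(y)
    mass = w * y
    total = float(mass.sum())
    if total <= 0:
        raise ValueError("dose_distribution requires positive lineal energies")
    return y, mass / total


def aggregate_repeats(repeats) -> tuple[float, float]:
    """Sample mean and sample SD (n−1 denominator) of per-repeat ȳD values.

    Accepts floats or :class:`MicrodoseSummary` objects.  A single repeat has
    undefined SD: NaN is returned with a warning.
    """
    vals = np.asarray(
        [r.ydbar if isinstance(r, MicrodoseSummary) else float(r) for r in repeats],
        dtype=float)
    if vals.size == 0:
        raise ValueError("aggregate_repeats requires at least one repeat")
    mean = float(vals.mean())
    if vals.size < 2:
        warnings.warn("single repeat: standard deviation undefined")
        return mean, float("nan")
    return mean, float(vals.std(ddof=1))


def _group_stats(group):
    """(mean, sd, n) from raw values or a (mean, sd, n) triple."""
    if isinstance(group, tuple) and len(group) == 3 and np.isscalar(group[0]):
        mean, sd, n = group
        return float(mean), float(sd), int(n)
    vals = np.asarray(group, dtype=float)
    if vals.size < 2:
        raise ValueError("each group needs n >= 2 (or a (mean, sd, n) triple)")
    return float(vals.mean()), float(vals.std(ddof=1)), int(vals.size)


def compare_conditions(a, b, equal_var: bool = False) -> ComparisonResult:
    """Two-tailed unpaired t-test between condition a and condition b.

    Welch's test (Welch–Satterthwaite degrees of freedom) by default, as the
    per-condition spreads differ markedly between boron-on and boron-off;
    ``equal_var=True`` gives the pooled Student variant.  Accepts raw repeat
    values or ``(mean, sd, n)`` summary triples so that printed summary rows
    can be compared without raw data.  Zero variance in both groups with equal
    means yields t = 0, p = 1 by convention.
    """
    mean_a, sd_a, n_a = _group_stats(a)
    mean_b, sd_b, n_b = _group_stats(b)
    if n_a < 2 or n_b < 2:
        raise ValueError("compare_conditions requires n >= 2 per group")
    va, vb = sd_a**2, sd_b**2
    if va == 0 and vb == 0:
        if mean_a == mean_b:
            t, df, p = 0.0, float(n_a + n_b - 2), 1.0
        else:
            t = math.inf if mean_a > mean_b else -math.inf
            df, p = float(n_a + n_b - 2), 0.0
    else:
        if equal_var:
            sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
            se = math.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
            df = float(n_a + n_b - 2)
        else:
            se = math.sqrt(va / n_a + vb / n_b)
            df = (va / n_a + vb / n_b) ** 2 / (
                (va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1))
        t = (mean_a - mean_b) / se
        p = float(2.0 * sps.t.sf(abs(t), df))
    return ComparisonResult(mean_a=mean_a, sd_a=sd_a, n_a=n_a,
                            mean_b=mean_b, sd_b=sd_b, n_b=n_b,
                            t_statistic=float(t), degrees_of_freedom=float(df),
                            p_value=float(p), equal_var=equal_var)
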