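"""Parameterized reference for the proton beam component.

The measurement chain calibrates against a simulated reference of the proton
lineal-energy field.  That reference is represented here in two layers:

* :func:`reference_ydbar` — the dose-averaged lineal energy ȳD as a function
  of water-equivalent depth, an analytic plateau-plus-skewed-peak curve
  anchored at the entrance (≈2 keV/µm) and Bragg-peak (≈8 keV/µm) values, or
  a tabulated (depth, ȳD) profile supplied by the user;
* :func:`reference_spectrum` — a continuous single-event spectrum f(y) at a
  depth, from a positive-support family (lognormal or gamma) whose parameters
  are solved in closed form so that its dose-averaged lineal energy equals the
  profile value exactly.

Fluence accounting for the irradiation settings (monitor units, cyclotron
current, transmission, protons/cm² at target) is carried by
:class:`BeamConfig` and summarised by :func:`fluence_summary`.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import as_generator


@dataclass
class BeamConfig:
    """Monoenergetic beam delivery settings (one row of the irradiation table)."""

    nominal_energy: float  # MeV
    mu: float = 500_000.0  # monitor units per measurement
    cyclotron_current: float = 0.0  # nA
    transmission_efficiency: float = 0.0  # fraction
    target_fluence: float = 0.0  # protons/cm2
    entrance_depth: float = 0.0  # cm water-equivalent
    bragg_peak_depth: float = 0.0  # cm water-equivalent

    def __post_init__(self):
        if self.mu <= 0 or self.target_fluence < 0:
            raise ValueError("mu must be positive and fluence non-negative")
        if self.bragg_peak_depth <= self.entrance_depth:
            raise ValueError("bragg_peak_depth must exceed entrance_depth")


#: delivery settings for the two beams studied (70 and 190 MeV spot beams)
_STANDARD_BEAMS = {
    70: dict(nominal_energy=70.0, mu=500_000.0, cyclotron_current=400.0,
             transmission_efficiency=0.075, target_fluence=1.5e8,
             entrance_depth=2.0, bragg_peak_depth=3.8),
    190: dict(nominal_energy=190.0, mu=500_000.0, cyclotron_current=23.0,
              transmission_efficiency=0.75, target_fluence=5.0e8,
              entrance_depth=5.0, bragg_peak_depth=22.5),
}


def standard_beam(energy: int | float) -> BeamConfig:
    """The 70 or 190 MeV configuration with its published delivery settings."""
    key = int(round(float(energy)))
    if key not in _STANDARD_BEAMS:
        raise ValueError(f"no standard beam at {energy} MeV; construct BeamConfig explicitly")
    return BeamConfig(**_STANDARD_BEAMS[key])


@dataclass
class DepthProfile:
    """ȳD versus depth: analytic plateau + skewed Gaussian peak, or tabulated.

    The analytic form is exactly ``y_entrance`` at the entrance depth, rises
    monotonically to ``y_peak`` at ``peak_depth`` with a Gaussian shoulder of
    scale ``rise_width``, then falls off distally with the (much narrower)
    ``distal_falloff_width``.  Tabulated (depth, ȳD) pairs override the
    analytic form with monotone piecewise-linear interpolation.
    """

    peak_depth: float  # cm water-equivalent
    y_entrance: float = 2.0  # keV/µm
    y_peak: float = 8.0  # keV/µm
    entrance_depth: float = 0.0  # cm
    rise_width: float | None = None  # cm; default 0.12 * (peak - entrance)
    distal_falloff_width: float | None = None  # cm; default max(0.05, 0.02 * peak)
    distal_floor: float = 0.3  # keV/µm floor beyond the distal edge
    table: tuple | None = None  # (depths cm, ydbar keV/µm), strictly increasing depths

    def __post_init__(self):
        if not self.y_peak > self.y_entrance > 0:
            raise ValueError("require y_peak > y_entrance > 0")
        if self.peak_depth <= self.entrance_depth:
            raise ValueError("peak_depth must exceed entrance_depth")
        if self.rise_width is None:
            self.rise_width = max(0.3, 0.12 * (self.peak_depth - self.entrance_depth))
        if self.distal_falloff_width is None:
            self.distal_falloff_width = max(0.05, 0.02 * self.peak_depth)
        if self.rise_width <= 0 or self.distal_falloff_width <= 0:
            raise ValueError("widths must be positive")
        if self.table is not None:
            d = np.asarray(self.table[0], dtype=float)
            y = np.asarray(self.table[1], dtype=float)
            if d.size < 2 or np.any(np.diff(d) <= 0):
                raise ValueError("tabulated depths must be strictly increasing")
            if np.any(y <= 0):
                raise ValueError("tabulated ydbar values must be positive")
            self.table = (d, y)

    @classmethod
    def for_beam(cls, beam: BeamConfig, **kwargs) -> "DepthProfile":
        return cls(peak_depth=beam.bragg_peak_depth,
                   entrance_depth=beam.entrance_depth, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DepthProfile":
        """Tabulated profile from CSV columns ``depth_cm, ydbar_keV_um``."""
        df = pd.read_csv(path)
        d = df["depth_cm"].to_numpy(dtype=float)
        y = df["ydbar_keV_um"].to_numpy(dtype=float)
        kwargs.setdefault("peak_depth", float(d[np.argmax(y)]))
        kwargs.setdefault("y_peak", float(y.max()) + 1e-9)
        return cls(table=(d, y), **kwargs)


def reference_ydbar(depth, profile: DepthProfile):
    """Reference ȳD (keV/µm) at water-equivalent ``depth`` (cm)."""
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be non-negative")
    if profile.table is not None:
        td, ty = profile.table
        if np.any(d < td[0]) or np.any(d > td[-1]):
            raise ValueError("depth outside tabulated profile domain")
        out = np.interp(d, td, ty)
    else:
        p = profile
        s = np.exp(-((d - p.peak_depth) ** 2) / (2 * p.rise_width**2))
        s0 = math.exp(-((p.entrance_depth - p.peak_depth) ** 2) / (2 * p.rise_width**2))
        rise = p.y_entrance + (p.y_peak - p.y_entrance) * np.clip((s - s0) / (1 - s0), 0.0, 1.0)
        distal = np.maximum(
            p.y_peak * np.exp(-((d - p.peak_depth) ** 2) / (2 * p.distal_falloff_width**2)),
            p.distal_floor)
        out = np.where(d <= p.peak_depth, rise, distal)
    if np.isscalar(depth) or np.ndim(depth) == 0:
        return float(out)
    return out


@dataclass
class SpectrumShapeParams:
    """Family and relative spread (coefficient of variation) of the per-depth
    single-event spectrum model."""

    family: str = "lognormal"
    relative_spread: float = 0.5

    def __post_init__(self):
        if self.family not in ("lognormal", "gamma"):
            raise ValueError(f"unknown spectrum family {self.family!r}")
        if self.relative_spread <= 0:
            raise ValueError("relative_spread must be positive")


class ReferenceSpectrum:
    """A continuous f(y) model with a prescribed dose-averaged lineal energy.

    Parameters are solved from closed-form moments:

    * lognormal(µ, σ): σ² = ln(1 + CV²) and ȳD = E[y²]/E[y] = exp(µ + 3σ²/2),
      so µ = ln(target) − 3σ²/2;
    * gamma(k, θ): k = 1/CV² and ȳD = (k + 1)θ, so θ = target/(k + 1).
    """

    def __init__(self, target_ydbar: float, shape: SpectrumShapeParams | None = None):
        if target_ydbar <= 0:
            raise ValueError("target ydbar must be positive")
        shape = shape if shape is not None else SpectrumShapeParams()
        cv = shape.relative_spread
        if shape.family == "lognormal":
            sigma2 = math.log1p(cv * cv)
            mu = math.log(target_ydbar) - 1.5 * sigma2
            self._dist = stats.lognorm(s=math.sqrt(sigma2), scale=math.exp(mu))
            m1 = math.exp(mu + 0.5 * sigma2)
        else:
            k = 1.0 / (cv * cv)
            theta = target_ydbar / (k + 1.0)
            self._dist = stats.gamma(a=k, scale=theta)
            m1 = k * theta
        self.shape = shape
        self._m1 = m1
        self._m2 = target_ydbar * m1  # since ydbar = m2/m1
        self._target = target_ydbar

    @property
    def ydbar(self) -> float:
        return self._target

    @property
    def yfbar(self) -> float:
        return self._m1

    def moments(self) -> tuple[float, float]:
        """First and second raw moments (E[y], E[y²])."""
        return self._m1, self._m2

    def sample(self, n: int, seed=None) -> np.ndarray:
        if n < 0:
            raise ValueError("n must be non-negative")
        rng = as_generator(seed)
        return self._dist.rvs(size=n, random_state=rng)

    def pdf(self, y):
        return self._dist.pdf(y)

    def cdf(self, y):
        return self._dist.cdf(y)

    def ppf(self, q):
        return self._dist.ppf(q)


def reference_spectrum(depth, profile: DepthProfile,
                       shape: SpectrumShapeParams | None = None) -> ReferenceSpectrum:
    """The per-depth continuous spectrum whose ȳD equals the profile value."""
    return ReferenceSpectrum(reference_ydbar(depth, profile), shape)


def fluence_summary(configs) -> dict:
    """Tabulate configured target fluences and all pairwise ratios.

    Returns ``{"fluences": DataFrame, "ratios": DataFrame}`` with ratios
    ``fluence_a / fluence_b`` for every ordered pair of distinct beams.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("fluence_summary requires at least one BeamConfig")
    fl = pd.DataFrame({
        "energy_MeV": [c.nominal_energy for c in configs],
        "mu": [c.mu for c in configs],
        "cyclotron_current_nA": [c.cyclotron_current for c in configs],
        "fluence_per_cm2": [c.target_fluence for c in configs],
    })
    rows = []
    for a, b in itertools.permutations(configs, 2):
        rows.append({"energy_a_MeV": a.nominal_energy, "energy_b_MeV": b.nominal_energy,
                     "fluence_ratio": a.target_fluence / b.target_fluence})
    ratios = pd.DataFrame(rows, columns=["energy_a_MeV", "energy_b_MeV", "fluence_ratio"])
    return {"fluences": fl, "ratios": ratios}
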