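"""Seeded generator of synthetic detector data.

Three fidelity levels, all reproducible from a single seed:

* ground-truth lineal-energy event lists (:func:`generate_event_stream`) —
  a mixture of proton events from the per-depth reference spectrum and,
  when boron is present, alpha events sampled from the breakup spectrum,
  filtered through the gap and converted to lineal energy;
* oscilloscope peak-amplitude lists (:func:`generate_peak_list`) — the
  ground-truth y values pushed through the inverse of the generator's true
  calibration, clipped at the scope's full scale;
* raw voltage traces (:func:`generate_trace`) — Gaussian baseline noise plus
  exponential-decay pulses at Poisson arrival times.

Repeat-to-repeat variability is modelled as a multiplicative lognormal jitter
on the spectral scale (:func:`generate_study_dataset`), which naturally makes
the across-repeat SD of ȳD proportional to the mean — and therefore larger
for the boron-on conditions whose spectra extend to high y, matching the
qualitative pattern of the measured repeat statistics.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import as_generator
from .alpha_physics import (PMMA_ALPHA_RANGES, AlphaSpectrumModel, DetectorModel,
                            GapGeometry, RangeTable, alpha_event_lineal_energy,
                            interpolate_range, invert_range, transmission_fraction)
from .beam_model import BeamConfig, DepthProfile, SpectrumShapeParams, reference_spectrum
from .containers import UNIT_KEV_UM, UNIT_MV, EventList, Trace
from .signal_pipeline import CalibrationModel

#: generator-side ground-truth calibration; a·500 mV + b ≈ 35 keV/µm keeps the
#: whole 0–20 keV/µm analysis window inside the scope's dynamic range.
DEFAULT_TRUE_CALIBRATION = dict(a=0.07, b=0.1)

#: empirical alpha lineal-energy bounds (keV/µm): the high-y tail region of
#: the measured boron-on spectra within the 0–20 binning window.
DEFAULT_ALPHA_Y_BOUNDS = (8.0, 20.0)


def default_true_calibration() -> CalibrationModel:
    return CalibrationModel(**DEFAULT_TRUE_CALIBRATION)


@dataclass
class ConditionSpec:
    """One experimental condition: (beam, depth, boron flag) plus everything
    needed to generate synthetic data for it."""

    beam: BeamConfig
    depth: float  # cm water-equivalent
    boron: bool = False
    alpha_model: AlphaSpectrumModel = field(default_factory=AlphaSpectrumModel)
    gap: GapGeometry = field(default_factory=lambda: GapGeometry(40.0))
    true_calibration: CalibrationModel = field(default_factory=default_true_calibration)
    n_events: int = 20_000
    n_repeats: int = 10
    repeat_jitter_cv: float = 0.0
    seed: int = 0
    profile: DepthProfile | None = None  # defaults to DepthProfile.for_beam(beam)
    shape: SpectrumShapeParams = field(default_factory=SpectrumShapeParams)
    detector: DetectorModel = field(default_factory=DetectorModel)
    range_table: RangeTable = field(default_factory=lambda: PMMA_ALPHA_RANGES)
    alpha_mode: str = "empirical"
    alpha_params: dict = field(default_factory=lambda: {
        "y_lo": DEFAULT_ALPHA_Y_BOUNDS[0], "y_hi": DEFAULT_ALPHA_Y_BOUNDS[1]})
    label: str = ""

    def __post_init__(self):
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")
        if self.repeat_jitter_cv < 0:
            raise ValueError("repeat_jitter_cv must be non-negative")
        if self.profile is None:
            self.profile = DepthProfile.for_beam(self.beam)
        if not self.label:
            region = "bp" if abs(self.depth - self.beam.bragg_peak_depth) < \
                abs(self.depth - self.beam.entrance_depth) else "entrance"
            tag = "boron" if self.boron else "water"
            self.label = f"{self.beam.nominal_energy:.0f}MeV_{region}_{tag}"


def effective_alpha_fraction(cond: ConditionSpec) -> float:
    """Probability that an event in the stream is alpha-induced:
    admixture weight × gap transmission when boron is present, else 0."""
    if not cond.boron or cond.alpha_model.weight == 0:
        return 0.0
    return cond.alpha_model.weight * transmission_fraction(
        cond.alpha_model, cond.gap, cond.range_table)


def _sample_surviving_alphas(cond: ConditionSpec, n: int, rng) -> np.ndarray:
    """Residual energies at the SV of n alphas that traverse the gap
    (rejection sampling of the emission spectrum through the barrier)."""
    from .alpha_physics import sample_alpha_energies

    g = cond.gap.effective_thickness(cond.range_table)
    out = []
    remaining = n
    frac = max(transmission_fraction(cond.alpha_model, cond.gap, cond.range_table), 1e-6)
    while remaining > 0:
        batch = int(remaining / frac * 1.5) + 16
        e = sample_alpha_energies(cond.alpha_model, batch, rng)
        res_range = interpolate_range(e, cond.range_table) - g
        alive = res_range > 0
        if np.any(alive):
            e_sv = invert_range(res_range[alive], cond.range_table)
            out.append(np.atleast_1d(e_sv)[:remaining])
            remaining -= min(int(alive.sum()), remaining)
    return np.concatenate(out) if out else np.empty(0)


def generate_event_stream(cond: ConditionSpec, rng=None) -> EventList:
    """Ground-truth lineal-energy events (keV/µm) for one acquisition."""
    rng = as_generator(rng if rng is not None else cond.seed)
    spectrum = reference_spectrum(cond.depth, cond.profile, cond.shape)
    w = effective_alpha_fraction(cond)
    n_alpha = int(rng.binomial(cond.n_events, w)) if w > 0 else 0
    y_proton = spectrum.sample(cond.n_events - n_alpha, rng)
    if n_alpha:
        e_sv = _sample_surviving_alphas(cond, n_alpha, rng)
        alpha = alpha_event_lineal_energy(
            e_sv, cond.detector, mode=cond.alpha_mode,
            params={**cond.alpha_params, "table": cond.range_table}, seed=rng)
        y = np.concatenate([y_proton, alpha.y])
    else:
        y = y_proton
    rng.shuffle(y)
    return EventList(y, UNIT_KEV_UM, metadata={
        "label": cond.label, "energy_MeV": cond.beam.nominal_energy,
        "depth_cm": cond.depth, "boron": cond.boron, "n_alpha": n_alpha,
        "alpha_fraction": w})


def ground_truth_ydbar(cond: ConditionSpec) -> float:
    """Closed-form ȳD of the generator mixture: (Σ wᵢ m2ᵢ)/(Σ wᵢ m1ᵢ) over the
    proton and (empirical-mode) alpha components."""
    spectrum = reference_spectrum(cond.depth, cond.profile, cond.shape)
    m1p, m2p = spectrum.moments()
    w = effective_alpha_fraction(cond)
    if w == 0:
        return spectrum.ydbar
    if cond.alpha_mode != "empirical":
        raise NotImplementedError("closed-form ground truth requires the empirical alpha mode")
    lo = float(cond.alpha_params.get("y_lo", DEFAULT_ALPHA_Y_BOUNDS[0]))
    hi = float(cond.alpha_params.get("y_hi", DEFAULT_ALPHA_Y_BOUNDS[1]))
    m1a = 0.5 * (lo + hi)
    m2a = (hi**3 - lo**3) / (3.0 * (hi - lo))
    return ((1 - w) * m2p + w * m2a) / ((1 - w) * m1p + w * m1a)


def generate_peak_list(cond: ConditionSpec, rng=None, events: EventList | None = None) -> EventList:
    """Oscilloscope peak amplitudes (mV): the ground-truth lineal energies
    pushed through the inverse true calibration P = (y − b)/a, clipped at the
    scope full scale with the clipped events counted as saturated."""
    if events is None:
        events = generate_event_stream(cond, rng)
    c = cond.true_calibration
    p = (events.values - c.b) / c.a
    p = np.clip(p, 0.0, None)
    full_scale = cond.detector.oscilloscope_full_scale
    saturated = int(np.sum(p >= full_scale))
    p = np.minimum(p, full_scale)
    return EventList(p, UNIT_MV, saturated_count=saturated,
                     metadata={**events.metadata, "full_scale": full_scale,
                               "true_calibration": (c.a, c.b)})


def generate_trace(cond: ConditionSpec, duration: int, pulse_rate: float = 1e-3,
                   baseline_mean: float = 2.0, baseline_sd: float = 0.5,
                   decay_tau: float = 20.0, rng=None) -> Trace:
    """Raw waveform: Gaussian baseline plus single-exponential-decay pulses at
    Poisson arrival times.  Each pulse's peak amplitude inverts the true
    calibration; amplitudes beyond full scale are clipped and counted.  Only
    the peak matters downstream, so the pulse shape is deliberately simple."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if pulse_rate < 0:
        raise ValueError("pulse_rate must be non-negative")
    rng = as_generator(rng if rng is not None else cond.seed)
    if pulse_rate * decay_tau > 0.05:
        warnings.warn("pulse rate implies substantial pulse overlap; "
                      "pile-up is not modelled")
    samples = rng.normal(baseline_mean, baseline_sd, size=int(duration))
    n_pulses = int(rng.poisson(pulse_rate * duration))
    full_scale = cond.detector.oscilloscope_full_scale
    true_y = np.empty(0)
    saturated = 0
    if n_pulses:
        stream = generate_event_stream(replace(cond, n_events=n_pulses), rng)
        true_y = stream.values
        c = cond.true_calibration
        amps = np.clip((true_y - c.b) / c.a, 0.0, None)
        saturated = int(np.sum(amps >= full_scale))
        amps = np.minimum(amps, full_scale)
        t0 = np.sort(rng.integers(0, duration, size=n_pulses))
        span = int(min(10 * decay_tau, duration))
        kernel = np.exp(-np.arange(span) / decay_tau)
        for start, amp in zip(t0, amps):
            stop = min(start + span, duration)
            samples[start:stop] += amp * kernel[: stop - start]
    samples = np.clip(samples, -full_scale, full_scale)
    return Trace(samples, sample_interval=cond.detector.sample_interval,
                 metadata={"label": cond.label, "full_scale": full_scale,
                           "baseline_mean": baseline_mean, "baseline_sd": baseline_sd,
                           "true_calibration": (cond.true_calibration.a, cond.true_calibration.b),
                           "n_pulses": n_pulses, "saturated_count": saturated,
                           "true_y": true_y})


def _jitter_scale(cv: float, rng) -> float:
    """One multiplicative lognormal scale factor with mean 1 and the given CV."""
    if cv == 0:
        return 1.0
    sigma2 = math.log1p(cv * cv)
    return float(rng.lognormal(-0.5 * sigma2, math.sqrt(sigma2)))


def generate_study_dataset(conditions, level: str = "lineal") -> dict[str, list[EventList]]:
    """For each condition, ``n_repeats`` independent acquisitions.

    Per-repeat seeds are derived deterministically from the condition seed via
    ``SeedSequence.spawn``; per-repeat multiplicative jitter (lognormal with
    CV ``repeat_jitter_cv``) is applied to the spectral scale before the
    detector stage.  ``level`` selects the fidelity: ``"lineal"`` ground-truth
    lineal energies or ``"peaks"`` scope amplitudes.
    """
    if level not in ("lineal", "peaks"):
        raise ValueError("level must be 'lineal' or 'peaks'")
    out: dict[str, list[EventList]] = {}
    for cond in conditions:
        children = np.random.SeedSequence(cond.seed).spawn(cond.n_repeats)
        repeats = []
        for i, child in enumerate(children):
            rng = np.random.default_rng(child)
            stream = generate_event_stream(cond, rng)
            scale = _jitter_scale(cond.repeat_jitter_cv, rng)
            if scale != 1.0:
                stream.values = stream.values * scale
                stream.metadata["jitter_scale"] = scale
            stream.metadata["repeat"] = i
            if level == "peaks":
                stream = generate_peak_list(cond, rng, events=stream)
            repeats.append(stream)
        out[cond.label] = repeats
    return out


def write_study_dataset(dataset: dict[str, list[EventList]], output_dir,
                        conditions=None) -> "Path":
    """Write each repeat as an event CSV plus a ``manifest.json`` listing the
    per-repeat files, seeds, and condition metadata.  Returns the manifest
    path."""
    import json
    from pathlib import Path

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {c.label: c.seed for c in conditions} if conditions else {}
    manifest = {}
    for label, repeats in dataset.items():
        entries = []
        for i, ev in enumerate(repeats):
            path = out / f"{label}_rep{i:02d}.csv"
            ev.to_csv(path)
            entries.append({"path": path.name, "repeat": i, "unit": ev.unit,
                            "n_events": len(ev)})
        manifest[label] = {"seed": seeds.get(label), "repeats": entries}
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest_path
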