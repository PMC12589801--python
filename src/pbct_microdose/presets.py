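"""Published study conditions as ready-made generator presets.

``TABLE2_YDBAR`` carries the per-condition ȳD means and standard deviations
over ten repeats for both beam energies, at entrance and Bragg-peak depths,
with and without boron.  :func:`table2_conditions` turns one beam's four rows
into :class:`~pbct_microdose.synthetic_data.ConditionSpec` objects:

* the proton depth profile is anchored at the without-boron means;
* the boron-on Bragg-peak alpha admixture weight is solved in closed form
  (:func:`solve_alpha_admixture`) so the generator's ground-truth ȳD equals
  the with-boron mean — the per-proton reaction yield at 100 ppm boron is not
  published, so the admixture is calibrated to the measured shift;
* the repeat jitter CV is SD/mean of each row, so across-repeat spreads match
  the published statistics;
* boron at the entrance depth contributes no alphas (their ranges are far
  below the barrier at entrance energies), mirroring the measured null.
"""
from __future__ import annotations

from .alpha_physics import AlphaSpectrumModel, GapGeometry, transmission_fraction
from .beam_model import DepthProfile, standard_beam
from .synthetic_data import DEFAULT_ALPHA_Y_BOUNDS, ConditionSpec

#: measured ȳD summary (keV/µm): (energy MeV, region, boron) -> (mean, sd)
TABLE2_YDBAR = {
    (70, "entrance", False): (2.14, 0.56),
    (70, "entrance", True): (2.08, 0.64),
    (70, "bp", False): (8.02, 0.81),
    (70, "bp", True): (8.88, 0.84),
    (190, "entrance", False): (2.13, 0.35),
    (190, "entrance", True): (2.11, 0.66),
    (190, "bp", False): (7.88, 0.75),
    (190, "bp", True): (10.41, 1.35),
}


def uniform_alpha_moments(bounds=DEFAULT_ALPHA_Y_BOUNDS) -> tuple[float, float]:
    """First and second raw moments of the empirical uniform alpha-y model."""
    lo, hi = bounds
    return 0.5 * (lo + hi), (hi**3 - lo**3) / (3.0 * (hi - lo))


def solve_alpha_admixture(target_ydbar: float, proton_spectrum,
                          alpha_bounds=DEFAULT_ALPHA_Y_BOUNDS) -> float:
    """Effective alpha event fraction w such that the two-component mixture
    has dose-averaged lineal energy ``target_ydbar``.

    Solving (1−w)m2p + w·m2a = T·[(1−w)m1p + w·m1a] for w, where (m1p, m2p)
    are the proton-spectrum moments and (m1a, m2a) the alpha-component
    moments.
    """
    m1p, m2p = proton_spectrum.moments()
    m1a, m2a = uniform_alpha_moments(alpha_bounds)
    t = target_ydbar
    num = t * m1p - m2p
    den = (m2a - m2p) - t * (m1a - m1p)
    if den == 0:
        raise ValueError("degenerate mixture: alpha and proton components coincide")
    w = num / den
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"target ydbar {t} not reachable with these components (w={w:.3f})")
    return float(w)


def table2_profile(energy: int) -> DepthProfile:
    """Depth profile anchored at the published without-boron means."""
    beam = standard_beam(energy)
    y_ent, _ = TABLE2_YDBAR[(energy, "entrance", False)]
    y_bp, _ = TABLE2_YDBAR[(energy, "bp", False)]
    return DepthProfile(peak_depth=beam.bragg_peak_depth, entrance_depth=beam.entrance_depth,
                        y_entrance=y_ent, y_peak=y_bp)


def table2_conditions(energy: int = 190, n_events: int = 20_000, n_repeats: int = 10,
                      gap: GapGeometry | None = None, base_seed: int = 0) -> list[ConditionSpec]:
    """The four measured conditions (entrance/BP × boron off/on) for one beam."""
    beam = standard_beam(energy)
    profile = table2_profile(energy)
    gap = gap if gap is not None else GapGeometry(40.0)
    from .beam_model import ReferenceSpectrum, SpectrumShapeParams

    shape = SpectrumShapeParams()
    bp_target, _ = TABLE2_YDBAR[(energy, "bp", True)]
    proton_bp = ReferenceSpectrum(TABLE2_YDBAR[(energy, "bp", False)][0], shape)
    w_eff = solve_alpha_admixture(bp_target, proton_bp)
    alpha_on = AlphaSpectrumModel(kind="uniform")
    trans = transmission_fraction(alpha_on, gap)
    if trans <= 0:
        raise ValueError("gap blocks all alphas; with-boron target unreachable")
    weight = w_eff / trans
    if weight > 1.0:
        raise ValueError("required admixture weight exceeds 1; widen alpha bounds or gap")

    conditions = []
    for i, (region, boron) in enumerate(
            [("entrance", False), ("entrance", True), ("bp", False), ("bp", True)]):
        depth = beam.entrance_depth if region == "entrance" else beam.bragg_peak_depth
        mean, sd = TABLE2_YDBAR[(energy, region, boron)]
        # entrance boron-on: alphas produced upstream cannot cross the barrier
        model = AlphaSpectrumModel(kind="uniform", weight=weight) \
            if (boron and region == "bp") else AlphaSpectrumModel(kind="uniform", weight=0.0)
        conditions.append(ConditionSpec(
            beam=beam, depth=depth, boron=boron, alpha_model=model, gap=gap,
            n_events=n_events, n_repeats=n_repeats, repeat_jitter_cv=sd / mean,
            seed=base_seed + i, profile=profile, shape=shape,
            label=f"{energy}MeV_{region}_{'boron' if boron else 'water'}"))
    return conditions
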