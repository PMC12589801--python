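# Methods

This note documents the models behind `pbct_microdose`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate, and
the numerical choices that matter.

## Physical setting

A monoenergetic proton pencil beam (70 or 190 MeV) irradiates an SOI
single-sensitive-volume microdosimeter (10 µm thick sensitive layer,
2,500 µm² area, mean chord length taken equal to the thickness at normal
incidence). A small well in front of the detector can hold water or a
boron-carrier solution (BPA at 100 ppm boron); the well and the sensitive
volume are separated by a thin barrier — a 30–50 µm gap plus an LDPE window —
through which only sufficiently energetic alphas from p + ¹¹B → 3α can pass.
Signals are oscilloscope voltage pulses (500 mV full scale); each event's
peak amplitude P maps to lineal energy through the linear calibration
y = a·P + b, fitted once per beam energy at the entrance depth and then
applied to all depths of that energy.

## Alpha energetics

**Range–energy interpolation.** Only four anchors are available (33, 45, 58,
73 µm in PMMA at 5, 6, 7, 8 MeV). Inside the anchors the interpolant is
piecewise linear; outside, a power law R = c·E^k fitted to the two nearest
anchors (k ≈ 1.70 on the low side, ≈ 1.72 on the high side), which matches
the physically expected range–energy behaviour of few-MeV alphas and keeps
the map strictly monotone, hence exactly invertible. Interpolation and
inversion round-trip to better than 1e-9 relative.

**Material equivalence.** Layer thicknesses are converted between materials
by conserving mass thickness, t' = t·ρ_from/ρ_to — the same argument used to
express the 40 µm LDPE (0.92 g/cm³) window as ≈31 µm PMMA (1.18 g/cm³) or
≈37 µm water equivalent. Barriers given as gap + window layers are first
expressed in the range table's material before any threshold computation.

**Alpha emission spectrum.** The three-body breakup spectrum is not published
beyond "broad, bounded by Q = 8.68 MeV". The default is uniform on
(0, 8.68] MeV (the most conservative broad envelope); a three-body
phase-space option dN/dE ∝ √E·√(E_max − E) (a Beta(1.5, 1.5) shape) and a
user-tabulated spectrum are also available. The published above-threshold
fractions of "about 33% and 22%" for 30 vs 50 µm gaps are **not** reproduced
by any of these options under the printed range anchors: the uniform model
gives 0.455/0.264 and the three-body model 0.443/0.212. The distribution for
which those figures hold was not specified, so no attempt is made to force
agreement; the model outputs are simply recorded here.

**Alpha lineal energy.** Two modes convert an alpha arriving at the sensitive
volume into y. The default *empirical* mode draws y uniformly from
[8, 20] keV/µm — the high-y tail region where the measured boron-on spectra
show their excess within the 0–20 keV/µm analysis window. This deliberately
sidesteps the unresolved question of how partial-energy alphas, saturation,
and detector response shape the measured tail. The *physics* mode slows the
alpha through the 10 µm silicon layer using the range table scaled from PMMA
to silicon by density ratio (1.18/2.33): crossers deposit E_in − E_out over
the mean chord length, stoppers their full energy over their residual range.

## Beam reference model

The per-depth reference used for calibration is a documented stand-in for a
Monte Carlo transport result that is not published. Its two constrained
anchors are the entrance plateau (≈2 keV/µm) and Bragg-peak maximum
(≈8 keV/µm). The analytic curve is a plateau plus a Gaussian shoulder of
scale 0.12·(peak − entrance) cm that is exactly y_entrance at the entrance
depth and rises monotonically to y_peak at the peak, followed by a narrow
Gaussian distal fall-off (0.02·peak_depth cm, floored at 0.3 keV/µm since y
beyond the practical range is ill-constrained). A tabulated (depth, ȳD)
profile loaded from CSV overrides the analytic form and is first-class.

The continuous per-depth spectrum f(y) is a lognormal (default) or gamma
distribution — positive support and a heavy right tail, resembling measured
single-event spectra — with coefficient of variation 0.5 (keeps entrance
spectra comfortably inside the 0–20 keV/µm window). Parameters are solved in
closed form so the distribution's E[y²]/E[y] equals the profile's ȳD exactly:
for the lognormal, σ² = ln(1 + CV²) and µ = ln(ȳD) − 3σ²/2; for the gamma,
k = 1/CV² and θ = ȳD/(k + 1).

## Synthetic data generator

An event stream for a condition (beam, depth, boron flag) is a two-component
mixture: with probability 1 − w a proton event from the reference spectrum at
that depth; with probability w an alpha event, where
w = admixture_weight × gap_transmission when boron is present and 0
otherwise. Alpha energies are rejection-sampled through the barrier and
converted to y. The mixture's ground-truth ȳD has the closed form
(Σ wᵢ m2ᵢ)/(Σ wᵢ m1ᵢ) over component moments, which the analysis pipeline is
tested to recover.

The admixture weight is a free parameter — the per-proton reaction yield at
100 ppm boron is not published. The `table2_conditions` preset solves the
effective alpha fraction in closed form so the generator's ground truth
equals the published with-boron Bragg-peak mean (for 190 MeV: w_eff ≈ 0.204,
i.e. weight ≈ 0.57 behind a 40 µm PMMA gap); this calibration to the measured
shift is deliberate and visible, not hidden tuning.

Repeat-to-repeat variability is a multiplicative lognormal jitter on the
spectral scale (mean 1, CV configurable). Because ȳD is degree-1 homogeneous
in the scale, the across-repeat SD of ȳD is ≈ CV·ȳD, so presets set the CV to
the published SD/mean per condition (e.g. 0.75/7.88 for 190 MeV Bragg-peak
water). This also reproduces the qualitative observation that boron-on
conditions — with spectra extending to high y — show larger absolute spreads.
Depth scans default to CV = 0.08, which keeps all per-depth SDs below the
0.9 keV/µm ceiling observed in the measurements. Boron at the entrance depth
contributes no alphas (their ranges are far below the barrier), mirroring the
measured entrance null; the carrier-only (EDV) condition is identical to
water and has no separate generator branch.

Raw traces are Gaussian baseline noise (default mean 2 mV, SD 0.5 mV) plus
single-exponential-decay pulses (instant rise, τ = 20 samples) at Poisson
arrival times, with amplitudes inverting the generator's true calibration
(default a = 0.07 keV/µm/mV, b = 0.1 keV/µm, chosen so the full 0–20 keV/µm
window maps inside the 500 mV scope range) and clipping at full scale
counted. Pile-up is not modelled (the small-area detector was chosen
precisely to minimise it); a warning is emitted when the pulse rate implies
substantial overlap. Peak extraction must use a minimum separation at least
as long as the pulse tail's threshold-crossing time (~150 samples at the
defaults), otherwise noise maxima riding on the tails register as events.

**What passing tests do and do not show.** The generator emulates spectral
shapes, mixture proportions, repeat variability, and the affine
signal-to-lineal-energy map — so green tests demonstrate that the estimation
chain is unbiased and correctly propagates uncertainty *under these models*.
They do not validate detector charge-collection physics, pulse pile-up, gain
drift, beam contamination, or the true alpha yield, none of which are in the
model.

## Measurement chain

**Threshold.** Baseline mean + k·SD with k = 5 (well above a Gaussian noise
floor; configurable).

**Calibration.** "Matching the measured and simulated spectra by
least-squares" is implemented as quantile–quantile regression: empirical
deciles (5%…95%) of the peak amplitudes against the same quantiles of the
reference distribution, fitted by ordinary least squares. Q–Q regression is
scale-equivariant, robust to binning, and reduces to a regression of paired
order statistics. Uncertainties u_a, u_b are bootstrap standard errors over
the event sample (200 resamples): the Q–Q residuals of a correctly specified
linear model are near zero and carry no information about quantile sampling
noise, so a residual-based standard error would be misleadingly small. At the
default calibration sample size (1,500 events) the relative slope uncertainty
u_a/a falls in the 2–4% range reported for the measured fits; uncertainty
propagation with mid-range coefficients (u_a/a = 3%, u_b = 0.15 keV/µm)
yields ≈3% relative 1σ on ȳD at a Bragg-peak-like spectrum. Full-pipeline
recovery runs (the acceptance script's estimator-recovery target) use 50,000
calibration events so that calibration-transfer error is small against the 2%
recovery budget.

**Conversion and binning.** y = a·P + b per event; non-positive results are
dropped with a logged count rather than clamped (they are sub-threshold
artifacts of the affine map). Spectra use half-open 0.5 keV/µm bins over
0–20 keV/µm (40 bins); events at or above 20 keV/µm are tracked as overflow
with their raw values retained by default, so ȳD on a binned spectrum can
still weight the tail exactly. If raw overflow values are discarded, overflow
contributes at the top edge with a warning. ȳD defaults to unbinned event
lists (more accurate); the binned mode uses bin midpoints and converges to
the unbinned value as the width shrinks.

**Statistics.** Repeats aggregate as sample mean and SD (n − 1). Comparisons
use the two-tailed unpaired Welch t-test with Welch–Satterthwaite degrees of
freedom — the published spreads differ nearly twofold between boron-on and
boron-off, making the unequal-variance form the defensible default; the
pooled Student variant is available by flag. A summary-statistic entry point
accepts (mean, SD, n) triples so published rows can be tested without raw
data. No multiple-testing correction is applied across the four condition
pairs, matching the apparent practice of the original analysis. Degenerate
zero-variance equal-mean comparisons return p = 1 by convention.

## Problem sizes and determinism

Default study runs use 20,000 events per acquisition, 10 repeats per
condition, and 1,500 calibration events; the acceptance script uses 120,000
events for the estimator-recovery target, 2,000 Monte Carlo draws for
uncertainty propagation, and 200 master seeds for the significance target.
These sizes give Monte Carlo errors comfortably below the tolerances being
tested while keeping any run to seconds. Every stochastic entry point accepts
a seed or `numpy.random.Generator`; per-repeat and per-condition seeds derive
from a master seed via `SeedSequence.spawn`, so whole studies are bit-for-bit
reproducible and repeats are statistically independent.

## Known limitations

* The depth profile and spectral families are stand-ins constrained only at
  two anchors; no claim of parity with the unpublished transport-derived
  reference curves is made.
* The empirical alpha-y mode is phenomenological; the physics mode ignores
  energy-loss straggling and angular spread, and scales ranges to silicon by
  density alone.
* The alpha admixture weight is calibrated to the published ȳD shift, not
  derived from reaction cross-sections; absolute yields are out of scope.
* Pile-up, gain drift, and multi-channel-analyzer emulation are excluded.
* The ¹⁰B(n,α)⁷Li neutron-capture channel is excluded (its ~1.5 MeV alphas
  cannot cross the barrier, and the measured effect is attributed to ¹¹B).
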