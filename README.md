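# pbct-microdose

Microdosimetric lineal-energy analysis for **proton boron capture therapy
(PBCT)** with a silicon-on-insulator (SOI) microdosimeter.

PBCT aims to boost the biological effectiveness of proton therapy through the
p + ¹¹B → 3α reaction (Q = 8.68 MeV): the short-range alpha particles deposit
densely ionizing energy locally even when the macroscopic dose barely changes.
The observable is the **dose-averaged lineal energy**

    ȳD = Σ y²·f(y) / Σ y·f(y)

where y is the lineal energy (energy imparted by a single event divided by the
track/mean-chord length of a micron-scale sensitive volume, keV/µm) and f(y)
its event-frequency spectrum. A measurable boron-induced increase in ȳD at the
Bragg peak — with no change at the entrance depth — is the signature this
package is built to analyse.

The package is for medical physicists and detector researchers who want a
tested, reproducible stand-in for the full measurement chain: no raw
oscilloscope data are publicly available, so a seeded synthetic generator
emulates the detector signals and the published summary statistics drive the
analysis end to end.

## What it does

* **`alpha_physics`** — alpha range–energy interpolation (33/45/58/73 µm in
  PMMA at 5/6/7/8 MeV, power-law extrapolation outside), mass-thickness
  material equivalence (40 µm LDPE ≈ 31 µm PMMA ≈ 37 µm water), alpha-spectrum
  sampling bounded by the 8.68 MeV Q-value, gap transmission fractions,
  residual energies, and alpha → lineal-energy conversion.
* **`beam_model`** — ȳD-versus-depth reference profiles for 70 and 190 MeV
  beams (entrance ≈ 2 keV/µm, Bragg peak ≈ 8 keV/µm), per-depth continuous
  f(y) models with closed-form moment matching, and fluence accounting.
* **`synthetic_data`** — seeded generation of raw voltage traces, peak
  amplitude lists, and lineal-energy event lists for any (energy, depth,
  boron) condition, with repeat-level variability.
* **`signal_pipeline`** — noise thresholding (baseline mean + 5σ), peak
  extraction, the linear calibration y = a·P + b fitted at the entrance depth
  by quantile–quantile least squares, 0.5 keV/µm binning over 0–20 keV/µm, and
  Monte Carlo propagation of calibration uncertainties to ȳD.
* **`microdosimetry`** — ȳD, ȳF, dose distributions d(y), repeat aggregation,
  and the two-tailed unpaired Welch t-test.
* **`study_runner`** — the depth scans and the four-condition boron study
  (entrance/Bragg peak × boron on/off) end to end, with deterministic reports.

## Worked example

Run the four-condition boron study for the 190 MeV beam on synthetic data:

```python
import pbct_microdose as pm

cfg = pm.StudyConfig(beams=[pm.standard_beam(190)], master_seed=1, n_events=20000)
res = pm.run_boron_study(cfg)
print(res.condition_table.to_string(index=False))
print(res.comparison_table.to_string(index=False))
```

which prints

```
 energy_MeV depth_label  depth_cm  boron  ydbar_mean_keV_um  ydbar_sd_keV_um  n_repeats
      190.0    Entrance       5.0  False           2.181008         0.432337         10
      190.0    Entrance       5.0   True           2.152646         0.717279         10
      190.0  Bragg Peak      22.5  False           7.832892         0.483516         10
      190.0  Bragg Peak      22.5   True          10.855954         1.380079         10
 energy_MeV  depth_cm         t        df  p_value
      190.0       5.0 -0.107089 14.776948 0.916159
      190.0      22.5  6.537355 11.176663 0.000039
```

Each row is the mean and SD of ȳD over ten simulated repeats. At the Bragg
peak the boron admixture raises ȳD from ≈7.8 to ≈10.9 keV/µm and the Welch
test is highly significant (p ≈ 4·10⁻⁵); at the entrance depth boron changes
nothing (p ≈ 0.92) because the alphas cannot cross the 30–50 µm barrier there.

The same study is available from the shell:

```bash
pbct-microdose study --energy 190 --seed 1 --outdir out/ --plots
pbct-microdose depth-scan --energy 190 --seed 1 --out scan.csv
```

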