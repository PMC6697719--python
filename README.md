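# chargevar

Charge-variant analytics for monoclonal-antibody cell culture: quantify
acidic/main/basic variant distributions from pH-gradient cation-exchange
(CEX) chromatograms of crude supernatant, and fit the second-order
glycation kinetics that links acidic-variant accumulation to glucose
exposure during a CHO fed-batch process.

## Who this is for

Process-development scientists monitoring mAb charge heterogeneity as an
in-process quality attribute. Post-translational modifications shift the
antibody's net surface charge: glycation and deamidation produce *acidic*
variants (lower pI), incomplete C-terminal lysine clipping produces *basic*
variants (K1/K2), and the fully clipped species is the *main* variant (K0).
A linear pH gradient on a weak cation exchanger elutes these in order of
net charge directly from supernatant, so the distribution can be followed
daily through a fed-batch run.

## The model

Retention times drift between buffer batches, so every retention time is
normalized by the main variant's: `t_normalized = t_i / t_main`. Peak
areas are integrated within `t_normalized` 0.76–1.23 (the *total peak
area*), and class areas are reported as percentages of it.

Acidic variants form extracellularly by glycation of **newly built** IgG,
first order in each of new IgG and glucose, with two constraints: only a
fraction of freshly produced antibody is susceptible, and an antibody not
converted shortly after synthesis never converts. Integrating the rate law
gives

    acidic(t) = k · D(t),      D(t) = ∫ [ΔmAb] · [glucose] dτ

where `[ΔmAb]` is the dilution-corrected newly built IgG concentration
(piecewise-constant per sampling interval), glucose is interpolated
linearly between daily samples, and `k` is a temperature-dependent
reaction constant in (g_acidic·L)/(g_IgG·g_glucose·day). Pooling runs by
their process temperature and regressing acidic concentration on `D(t)`
through the origin yields one `k` per temperature — 0.09, 0.04 and 0.03
at 37, 34 and 31 °C for the study conditions the synthetic generator
reproduces.

Because no raw instrument data are public, the package ships a first-class
synthetic-data module that emulates the study design (3 temperatures ×
3 glucose feeds × 2 replicates, daily sampling, pulse feeding days 3–13,
temperature shift at day 4) and renders each sample as a Gaussian-peak CEX
trace with baseline drift, detector noise and shared retention jitter.
Every analysis stage is validated by round-tripping against this
generator.

## Worked example

Run the full synthetic study and fit the per-temperature reaction
constants (default: noisy 3×3×2 study, chromatogram quantification per
sample):

```
$ chargevar run-all --seed 1 --out demo --force
 temperature        k  r_squared  n_points  residual_sd  intercept_diagnostic flags
        37.0 0.090423   0.999863        79     0.006496             -0.001341
        34.0 0.039997   0.998831        60     0.004441             -0.000699
        31.0 0.031515   0.927148        60     0.013339             -0.001020
report: demo/report.json
```

The `k` column recovers the generating constants (0.09/0.04/0.03) within
the measurement noise; `intercept_diagnostic` is the intercept of the
*unconstrained* fit and should sit near zero if the through-origin model
is adequate. The output directory contains per-sample charge
distributions, per-run rate series, the k-by-temperature table, and a
`report.json` embedding the effective config and its hash.

Quantifying a single trace from the library:

```python
import chargevar as cv

chrom = cv.synthesize_chromatogram(cv.standard_record(), cv.ChromatogramParams(seed=7))
dist = cv.quantify_distribution(chrom)
# acidic 16.37 %, main 59.16 %, basic 24.47 %, total area 20.03 mAU·min
```

which recovers the reference-standard composition (16.2/59.2/24.5 %)
within the trace noise.

## Layout

- `chargevar.simulate` — fed-batch simulator and CEX trace generator
- `chargevar.chromatography` — baseline, peak detection, retention
  normalization, window integration, classification, calibration
- `chargevar.process` — dilution correction, growth/consumption rates
- `chargevar.kinetics` — D(t), through-origin k fits by temperature
- `chargevar.pipeline` / `chargevar.cli` — orchestration, config, CLI

See `docs/methods.md` for the modeling assumptions, parameter defaults
and known limitations.
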