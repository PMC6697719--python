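# Methods

This note documents the models implemented in `chargevar`, the defaults
of the synthetic-data generator, the numerical choices made where the
design was open, and what the passing tests do and do not demonstrate
about real data.

## Charge-variant quantification

A chromatogram is a uniformly sampled UV trace (mAU vs minutes) from a
weak-CEX separation with a linear pH gradient (0.07 pH/min from pH 7).
Quantification proceeds in five steps:

1. **Baseline.** A straight line is least-squares fitted through the
   leading and trailing 10 % of samples — regions the method keeps free
   of product peaks — and subtracted. This absorbs the 0.2–0.4 mAU
   drift direct-injection supernatants show. No polynomial or rolling
   baseline is attempted: the drift is linear in the generator and, at
   these magnitudes, indistinguishable from linear in practice.
2. **Peak detection.** Local maxima above a height threshold with a
   minimum prominence (`scipy.signal.find_peaks`). Defaults derive from
   a robust noise estimate (1.4826·MAD of first differences / √2):
   height 5×, prominence 3×, with a 1e-6 mAU absolute floor so ideal
   noiseless traces do not degenerate to zero thresholds. Peak
   boundaries are valley-to-valley: the deepest point between adjacent
   apexes, or toward the trace ends for the outermost peaks. Areas are
   trapezoidal on the sampled grid; no peak-shape fitting or
   deconvolution (the assay integrates, it does not deconvolve).
3. **Main-peak identification.** By default the most abundant peak
   (largest area, ties to the earlier apex). This fails for heavily
   stressed samples in which acidic species outgrow K0, so the
   quantifier optionally accepts the normalized peak pattern of the
   reference standard: each detected peak is tried as the normalization
   anchor and the candidate whose induced pattern best matches the
   reference (area-weighted distance to nearest reference position)
   wins. The pattern comparison is invariant to the shared buffer-batch
   retention shift, which is what makes it robust where raw retention
   windows are not. The pipeline uses the pattern anchor; the plain
   abundance rule remains the default for standalone calls.
4. **Normalization and windowing.** Every apex time is divided by the
   main peak's apex time; only peaks with normalized apex in
   [0.76, 1.23] count toward the total peak area.
5. **Classification.** Peaks eluting before the main peak's own left
   boundary (normalized) are acidic, after its right boundary basic.
   Splitting at the main peak's extent rather than exactly at 1.0 keeps
   shoulders of K0 out of the acidic/basic classes. Class percentages
   are class areas over total area × 100 and sum to 100 by
   construction.

Replicate consistency is summarized per class as mean, sample SD
(n−1) and CV % = SD/mean × 100. The area-vs-mass calibration is an
ordinary least-squares fit (statsmodels) of total area on known IgG
mass; titer estimation inverts it.

## Process metrics

Feeding and sampling change the culture volume daily, so measured
concentrations confound biology and dilution. For each interval the
feed-dilution ratio r = V_afterSample / (V_afterSample + V_feed) is
known from the records; the cumulative product R re-expresses any
concentration on the common inoculation-volume basis. Species formed in
different intervals then add coherently: a concentration c formed in
interval i contributes c/R_{i+1} regardless of later feeds. The
kinetics below uses common-basis quantities for exactly this reason;
the interval's own-basis increment is also carried for mass balances
(increment × interval volume sums to total produced mass).

Per interval between consecutive daily samples:

- µ = ln(VCC₂ / (VCC₁·r)) / Δt (dilution-corrected);
- q_gluc = (post-feed glucose − next sampled glucose) / (log-mean VCC ·
  Δt). The log-mean viable-cell integral is exact for exponential
  growth within the interval. VCC stays on the cells/mL basis, so
  q_gluc carries the mixed unit g·L⁻¹·(cells·mL⁻¹)⁻¹·day⁻¹, declared in
  the output metadata.
- ΔmAb = common-basis titer increment, clipped at zero with a logged
  warning when measurement noise drives it negative.

## Glycation kinetics

The driving integral is accumulated on the sampling grid:

    D(t_i) = Σ_{j<i} ΔmAb_j · (g_j + g_{j+1})/2 · Δt_j

i.e. newly built IgG held piecewise-constant per interval and glucose
linearly interpolated between samples — the exact integral of that
piecewise model, so refining the grid between samples cannot change it
(verified against a dense Riemann oracle). Acidic concentration is the
common-basis acidic titer (or acidic % × common-basis total titer when
wired through chromatogram quantification).

The regression of acidic concentration on D is forced through the
origin because the integrated rate law has no intercept; the intercept
of the unconstrained fit is reported as a diagnostic only. Runs are
grouped by their post-shift temperature and pooled across feeds and
replicates within a group.

**Rebaselining at the temperature shift.** For shifted runs the
reaction constant changes at day 4, so the acidic stock built during
the shared 37 °C batch phase does not belong to the post-shift group's
line. The series therefore restarts at the shift day: D and acidic are
measured relative to their day-4 values. This is the exact piecewise
inversion of the rate law and is on by default; without it the 34 °C
and 31 °C slopes inherit a 6 % and 22 % upward bias from the batch
phase. A switch to simply exclude pre-shift samples is also available
but does not remove that bias on its own.

## The synthetic study

The generator reproduces the study conditions end to end: 300 mL
shake-flask start, 2.5×10⁵ cells/mL inoculation, 11 mL daily samples,
pulse feeding days 3–13 with a total of 33 vol% (planned on nominal
volumes as f/(1−f) × start volume, delivered in 11 equal pulses),
feeds carrying +10/+20/+30 g/L extra glucose, temperature held at 37 °C
or shifted to 34/31 °C at day 4, termination at 70 % viability or
day 14.

Per daily interval, in order: sample removal (concentration-neutral),
feed pulse with dilution of all species and cells, exponential growth,
IgG production, glucose consumption bounded at zero (exhaustion sets a
warning flag), acidic conversion of the interval's newly built IgG,
fixed basic fraction of new IgG.

- **Growth**: µ_eff = µ_max(T)·(1 − VCC/VCC_max(T)). The ceiling is
  temperature-dependent (1.4×10⁷ / 8×10⁶ / 5×10⁶ cells/mL at
  37/34/31 °C): a temperature shift arrests proliferation, which is
  both the qualitative observation and the mechanism that differentiates
  glucose consumption between temperatures under a shared q_gluc.
  Because µ_eff is time-varying, the generator records the per-interval
  value it applied (`run.mu_applied`) as ground truth for recovery
  tests. Viability follows a nutrient-independent logistic decline
  (midpoint day 15.5, width 1.2 d) used for termination only.
- **Production**: q_p pg/cell/day × log-mean VCC (15/12/8 at
  37/34/31 °C), giving harvest titers of roughly 0.2–1.1 g/L.
- **Glucose**: one q_gluc = 1.1×10⁻⁷ g·L⁻¹·(cells·mL⁻¹)⁻¹·day⁻¹ shared
  by all temperatures and feeds; feed glucose = 8 g/L base + the feed's
  supplement; 4 g/L at inoculation. These three numbers were set
  together so that, across the whole grid, glucose spans ~1.5–15.5 g/L,
  the 37 °C + Feed 1 culture never exhausts glucose, and the 37 °C +
  Feed 3 culture stays in the linear regime of the conversion rule
  (below). Under a feed-independent q_gluc the terminal glucose spread
  between Feed 1 and Feed 3 is structurally ~9 g/L, so this is the only
  window satisfying all three constraints.
- **Acidic conversion**: the fraction of an interval's new IgG converted
  is min(k(T)·ḡ, cap), with ḡ the trapezoid of the *sampled* (pre-feed)
  glucose at the interval endpoints and cap = min(susceptible fraction,
  1 − basic fraction). Defining the reaction on the daily sampling grid
  makes the generative law exactly the discretization the analysis
  inverts, which is what permits machine-precision parameter recovery;
  it is a modeling choice, not a claim about sub-daily chemistry. The
  susceptibility window — the unspecified "certain time period" within
  which a new antibody can still be converted — is taken to be one
  sampling interval (one day).
- **Susceptible pool**: susceptible fraction 0.95. In the default study
  k·ḡ peaks at 0.90 (37 °C + Feed 3), so the cap never binds and
  acidic(t) = k·D(t) holds exactly; at higher glucose loads (feeds
  ≥ +60 g/L) the cap binds and the acidic/K0 ratio saturates, which
  reproduces the observed flattening of that ratio above ~7 g/L
  qualitatively.
- **Basic variants**: a fixed temperature-dependent fraction of new IgG
  (0.04/0.05/0.09 at 37/34/31 °C) — an intracellular mechanism,
  independent of glucose, constant within a run.
- **Passive reporters**: lactate (batch-phase rise proportional to
  consumption, then 30 %/day consumption) and osmolality (linear in
  glucose, 220 + 8.3·g mOsm/kg, spanning ~233–345) are carried but
  never used by any fit.
- **Measurement noise** (off for noiseless runs): one shared
  multiplicative factor per record for the three titers (5 % CV), so
  variant titers never exceed the total; independent 3 % factors for
  glucose and VCC. All randomness flows from one `numpy` generator
  seeded per run; study seeds derive from a master seed via
  `SeedSequence`, so a master seed regenerates the identical study.

Chromatograms are sums of Gaussians (σ = 0.2 min) at fixed normalized
positions (acidic 0.80/0.87/0.93, K0 at 1.0, basic 1.07/1.14, anchored
at t_main = (pI − start pH)/gradient slope ≈ 22.9 min), all inside the
integration window and valley-separated by construction (validated: a
4σ minimum gap). Total area is linear in injected IgG mass
(0.2 mAU·min/µg; 100 µL injection), partitioned by the record's class
proportions and fixed within-class splits. One jitter factor per trace
scales all centers (σ = 1.5 %); baseline drift is linear (0.3 mAU
default, drawn U(0.2, 0.4) for replicate-consistency studies) and
detector noise i.i.d. Gaussian (0.05 mAU).

## What the tests show — and do not

Round-trip tests demonstrate that each analysis stage exactly inverts
the generator's structure: rate recovery to machine precision, k
recovery to 1e-6 noiseless and within ~1.5 % under default noise, and
composition recovery within 0.2 percentage points from noiseless
traces. They do not demonstrate robustness to phenomena the generator
omits: co-eluting host-cell proteins, non-Gaussian or tailing peaks,
nonlinear baseline excursions, per-peak (rather than shared) retention
shifts, sub-daily glucose dynamics between samples, or assay-to-assay
variability beyond detector noise — the replicate CVs of synthetic
standards (<1 %) are accordingly much tighter than the single-digit
CVs real injections show.

## Numerical choices and degenerate inputs

- Integration is trapezoidal everywhere; daily sampling does not
  support finer schemes.
- Through-origin slope k = ΣDa/ΣD², with R² computed about zero for
  the constrained model; a negative slope is clipped to zero and
  flagged. All-zero D with nonzero acidic is flagged as a model
  violation rather than fitted.
- Ties in main-peak abundance go to the earlier apex; in the pattern
  score, to the larger peak.
- Zero-titer records render as flagged baseline-only traces; traces
  with no detectable product raise a "no product detected" error, which
  the pipeline converts to a per-sample skip with a warning (early
  low-titer days).
- Negative corrected IgG increments (noise) are clipped to zero and
  counted in the rate series' metadata.
- Fed-batch runs carry a warning list (glucose exhaustion, early
  harvest); warnings are aggregated into the pipeline report.

## Known limitations

- The acidic conversion law is defined on the sampling grid; a
  continuous-time generator with sub-daily mixing would make recovery
  approximate rather than exact (at daily sampling the difference is
  far below measurement noise).
- The fraction-of-new-IgG interpretation bounds k·ḡ by the susceptible
  fraction; with the 37 °C constant this caps the usable glucose range
  at ~10.5 g/L. Conditions beyond it are simulated faithfully (the cap
  binds) but are outside the linear model the regression assumes.
- Basic-variant kinetics, Arrhenius temperature dependence of k, and
  assignment of individual acidic peaks to specific modifications are
  out of scope.
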