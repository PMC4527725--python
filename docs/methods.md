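# Methods

This note documents the models, formulae, parameter choices and known
limitations behind `shockhrv`. Units are ms for intervals, ms² for powers,
Hz for frequencies, and conventional clinical units for hemodynamics.

## Synthetic generators (`shockhrv.synth`)

Everything downstream is validated against signals with known ground truth,
so the generators are part of the method, not just test scaffolding.

**RR-interval series.** Beat `k` closes an interval
`NN_k = mean_rr + Σ_b A_b·sin(2π f_b t_k + φ_b) + ε_k`, with one sinusoid per
band (defaults: VLF 0.01 Hz, LF 0.05 Hz, HF 0.4 Hz), seeded random phases and
white noise `ε_k ~ N(0, noise_sd²)`. Beat times accumulate from the interval
sequence, so the sampling is intrinsically uneven, as in real tachograms. A
sinusoid of amplitude `A` ms contributes `A²/2` ms² of band power — the core
oracle for the spectral pipeline. Parameters are validated so intervals stay
positive (`ΣA + 4·noise_sd < mean_rr`).

**Ectopy injection** replaces a binomial selection of intervals
(`rate` per interval) with alternating short/long values `(1∓magnitude)·NN`,
mimicking premature beats with compensatory pauses, and records ground-truth
`ectopic` labels per interval.

**ECG** renders a Gaussian bump (default width 60 ms ≈ 6σ, amplitude 1) at
each beat time at ≥250 Hz plus white baseline noise, and stores the true beat
times for validating the detector.

**Cohort.** A tidy long table (animal, group, time point, variable, value)
for 13 survivors and 7 non-survivors over the 10 protocol time points
(Baseline, Hemorrhage 5/10/15 min, Shock 30/60 min, R0–R180); non-survivors
have no post-resuscitation data by construction. Cell values are drawn from
per-(variable, group, time point) normal distributions; variables that are
physically positive (pressures, flows, lactate, spectral powers — not base
excess) use a normal truncated at 0. The default cell means/SDs encode a
plausible shock-and-resuscitation time course with survivor/non-survivor
separation appearing during hemorrhage and shock and absent at baseline.
The generator reproduces marginal cell distributions only: it does not model
within-animal autocorrelation across time points, so repeated-measures
analyses on generated cohorts see exchangeable errors.

## Preprocessing (`shockhrv.preprocessing`)

**R-peak detection** follows the classic adaptive-threshold scheme: band-pass
5–30 Hz (3rd-order Butterworth, zero-phase `sosfiltfilt`), squared gradient,
150 ms moving-window integration, peak candidates ≥200 ms apart, and an
adaptive threshold `NPKI + 0.25·(SPKI − NPKI)` with signal/noise peak levels
initialized from a 2 s lead-in. Accepted candidates are refined to the argmax
of the 21 ms Hann-smoothed absolute signal within ±50 ms; the smoothing uses
reflect padding so beats at the record edge are not biased, and the record is
zero-padded 0.3 s so edge beats are detectable at all. The 21 ms kernel
(~⅓ of the QRS width) measured best on noisy synthetic ECG (max timing error
2 ms at 10% noise, vs 6 ms for a 9 ms kernel).

**Ectopy screening** flags interval `i` when
`|NN_i − median(5 nearest neighbours)| / median > 0.20`. If more than 5% of
intervals are flagged the window is rejected (`SegmentRejectedError` carrying
the report) rather than silently over-edited. Repairs are cubic-spline
interpolation over the non-flagged onsets (labelled `edited`) or deletion.

**Windows** are half-open `[offset, offset + 300 s)` slices re-referenced to
the window start, refusing windows that the recording does not cover.

## HRV metrics (`shockhrv.hrv`)

**Time domain**: variance, SDNN (sample statistics, `ddof=1`) and RMSSD over
the window's NN intervals; series containing unrepaired `ectopic` labels are
refused.

**Bands** use the pig-specific scheme VLF [0, 0.02), LF [0.02, 0.09),
HF [0.09, 2.0) Hz — HF extends to 2 Hz because pig respiratory rates far
exceed human ones. Derived quantities: `pct = 100·band/(VLF+LF+HF)`,
`nu = 100·band/(LF+HF)`, and LF/HF (reported as undefined, not infinite,
when HF is 0).

**Welch pathway**: the uneven tachogram is interpolated with a spline over
beat-onset times and resampled at 10 Hz, linearly detrended, then Welch PSD
(Hann, 150 s segments, 50% overlap, density scaling). The spline order is 5
(quintic) by default: at a ~1.25 Hz beat rate a 0.4 Hz oscillation has ~3
samples per cycle, and cubic interpolation attenuates its recovered power by
~10% (exactly at the acceptance tolerance), while quintic reduces the bias to
~2%. Band powers are trapezoid integrals with interpolated band-edge values;
the DC bin is excluded.

**Lomb-Scargle pathway** works on the uneven samples directly: polynomial
detrend, frequency grid with spacing `1/(4T)` capped at the mean-beat-rate
Nyquist `n/(2T)`. Without the cap, aliases of HF oscillations (mirrored about
the beat rate) land inside the wide pig HF band and inflate it several-fold.
Scaling `PSD = 2P·T/n` makes band integrals comparable to Welch (agreement
within ~10% on band-limited inputs). When the cap truncates the HF band the
band is clipped to the available range; only failure to cover the LF band is
an error.

## Derived hemodynamics (`shockhrv.hemo`)

Conventional formulae, pinned explicitly: porcine BSA `0.09·BW^(2/3)` m²;
CI = CO/BSA; SVI = 1000·CI/HR; SVRI = 79.92·(MAP−CVP)/CI and
PVRI = 79.92·(mPAP−PAWP)/CI (79.92 dyn·s·cm⁻⁵ per mmHg·min/L);
O₂ content = 1.34·Hb·SaO₂ + 0.0031·PaO₂ (and venous analogue);
DO₂I = 10·CI·CaO₂; VO₂I = 10·CI·(CaO₂−CvO₂) (reverse Fick);
O₂ER = VO₂I/DO₂I; CO₂ gap = PvCO₂ − PaCO₂. Saturations given as percent are
auto-detected (>1.5) and converted with a warning. PPV is
`100·(PPmax−PPmin)/((PPmax+PPmin)/2)` per respiratory cycle, averaged over
cycles; cycles with fewer than 3 beats are skipped with a warning.

## Statistics (`shockhrv.stats`)

**Routing.** Each sample is routed parametric/nonparametric by a one-sample
Kolmogorov–Smirnov test against a normal with the sample's own mean and SD;
parametric iff p ≥ 0.05. Using estimated parameters without a small-sample
correction makes the test conservative, i.e. biased toward the parametric
branch — a deliberate reproduction of common practice, not a recommendation.
Constant samples route nonparametric with a warning.

**Within-group time courses**: complete-case repeated-measures ANOVA
(parametric, via `statsmodels.AnovaRM`) or the Friedman test, with
vs-baseline paired t or Wilcoxon signed-rank post-hoc contrasts,
Holm-adjusted. Data with zero within-animal variation short-circuit to
(F = 0, p = 1).

**Between groups** at one time point: unpaired t (pooled variance) when both
groups route parametric, else two-sided Mann–Whitney U. Contrasts impossible
for structural reasons (no non-survivor data after Shock60) return an explicit
skipped-with-reason record instead of being dropped.

**Mortality model**: multivariable logistic regression of non-survival on
z-standardized predictors. The default fit is Firth's bias-reduced likelihood
(modified-score IRLS with the Jeffreys penalty), which stays finite under the
complete separation that is routine at n = 20. Predictor p-values under the
Firth fit are penalized likelihood-ratio tests profiled the standard way (the
constrained fit keeps the full-design penalty): measured on null data at
n = 20, the Firth Wald test selects at ~0.6% (severely conservative) while
the penalized LRT selects at ~4.6%, near the nominal 5%. Selection is
Holm-adjusted across predictors; an empty selection is a valid outcome.
An unpenalized ML path (`penalized=False`, Wald p-values) is available.
AUC is the in-sample rank statistic — descriptive, not cross-validated.

**No adjustment across variables.** Only post-hoc contrasts inside one
omnibus test are multiplicity-adjusted; marginal p-values across the many
variables of a cohort run are reported as-is, mirroring common practice in
this literature.

## Limitations

- The cohort generator draws cells independently; it cannot exhibit real
  within-animal correlation, regression to the mean, or dropout dynamics.
- The ECG model is a single Gaussian bump per beat — no P/T waves, baseline
  wander, or electrode artifacts; detector performance on real ECG will be
  worse than the synthetic figures.
- The KS routing rule and the absence of across-variable multiplicity control
  mirror common practice in this literature; neither is presented as best
  practice.
- Lomb-Scargle HF power is computed on the clipped band when the mean beat
  rate limits the usable frequency range; compare like with like when mixing
  estimators across windows with different heart rates.
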