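# Methods

## The model family

Pulmonary oxygen uptake after a step change in work rate is described by exponential
components gated by a Heaviside step H (right-continuous, H(0) = 1).  For the
off-transient (recovery; t = 0 at exercise cessation):

```
VO2(t) = EEVO2 − H(t − TDp)·Ap·(1 − e^−(t−TDp)/τp) − H(t − TDsc)·Asc·(1 − e^−(t−TDsc)/τsc)
```

and for the on-transient (t = 0 at exercise onset) the same components are added to
the pre-exercise baseline `VO2base` with rising sign.  Four nested forms per
direction are supported: mono-exponential with `TDp` fixed at 0 (3 free parameters),
mono-exponential with free `TDp` (4), bi-exponential with `TDp = 0` and free slow
component (6), and bi-exponential with both delays free (7).  Amplitudes (`Ap`,
`Asc`) and levels are in mL·kg⁻¹·min⁻¹; delays and time constants in seconds.
Physiological invariants: `Ap > 0`, `τp > 0`, `TDp ≥ 0`; when a slow component is
present `Asc ≥ 0`, `τsc > 0`, `TDsc ≥ TDp`.  The on-transient baseline is a free
parameter by default and can be fixed to a measured pre-exercise mean through
`ModelSpec.extra_fixed`.

Assumptions: the series starts at the transition; the cardiodynamic (phase I)
response is not modelled separately — at recovery it is absorbed into the primary
component, which is the conventional treatment when no phase-I window is excised.

## Fitting

`fit` minimises the sum of squared residuals with `scipy.optimize.least_squares`
(TRF, finite-difference Jacobian, `x_scale="jac"`), unconstrained by default with
optional box bounds.  The objective is piecewise-smooth in the delay parameters
(kinks where a delay crosses a grid point), so a deterministic multistart is used:
the data-driven initial point (levels from 30-s end means, amplitude from the
observed range, τ from the time-to-63%-of-range crossing, TDp = 10 s, TDsc = 90 s,
Asc = 0.1·Ap) plus 4 perturbed restarts drawn from a generator seeded by the caller;
the lowest-RSS converged solution wins, and restarts stop early once the cost is
below 1e-16 (an exact fit cannot be improved).  The fit is bit-reproducible given
(data, init, seed).

Goodness of fit is summarised by the standard error of regression,
`SER = sqrt(RSS/(n − p))`.  "Exact recovery" in the tests means SER ≤ 1e-6
mL·kg⁻¹·min⁻¹ with every free parameter within 1e-4 relative error — the practical
reading of a perfect fit under floating point.

## Model comparison and selection

Nested fits on the same grid are compared with the extra-sum-of-squares F-test,
`F = ((RSS₁−RSS₂)/(p₂−p₁)) / (RSS₂/(n−p₂))`, upper-tail p from the F distribution.
Conventions: equal RSS → F = 0, p = 1; a perfect complex fit against an imperfect
simple one → F = ∞, p = 0.

`select_best` fits all four forms and chooses by SER with a parsimony rule, subject
to two safeguards that matter because the fits are unconstrained:

1. **Interpretability screen.**  A converged fit competes only if its estimates are
   physiologically interpretable: amplitudes positive, time constants at least one
   grid step (a faster exponential is indistinguishable from a step at the sampling
   rate), delays inside the record with `TDsc ≥ TDp`, and a slow component whose
   realised amplitude within the record, `Asc·(1 − e^−(span−TDsc)/τsc)`, exceeds
   twice the residual SER — below that the component is not distinguishable from the
   noise it is fitted to.  Screened-out fits are reported (model, SER, reason), not
   silently dropped.  If every fit is screened out, selection falls back to the raw
   converged fits with a note.
2. **Multiplicity-controlled parsimony.**  Starting from the lowest-SER competing
   fit, a nested simpler model replaces the candidate unless at least one nested
   complex alternative improves on it significantly; the comparisons of a simpler
   model against its complex alternatives form one family and are Hochberg-corrected
   at the selection α (default 0.05).  Without this correction the three complex
   forms each get an independent ~5% chance of beating the generating mono model on
   noise alone, which simulation puts at ~18% combined; with it, mono-generated data
   is assigned the mono form in ~92 of 100 seeded runs.  Exact ties (both SER below
   1e-7) always resolve to the simpler form.

The delay parameters are not identified under the simpler null (the classical
boundary/unidentified-nuisance problem), so the nominal F distribution is
anti-conservative for these comparisons; the screen plus the multiplicity correction
are the package's pragmatic answer, and both are recorded in the selection notes.

## Residual bootstrap

Uncertainty for a single transition comes from a residual bootstrap
(`residual_bootstrap`): resample the base fit's residuals with replacement, add them
to the fitted curve, refit the same model warm-started at the base estimates, and
summarise per-parameter SD, CV and equal-tailed percentile CIs (numpy linear
interpolation between order statistics).  Residual rather than case resampling
preserves the time grid, which carries all the kinetic information; the method and
seed are recorded in the output.  Replicates that fail to refit are dropped and
counted; a result with more than 20% failures is flagged unreliable.  Default 1000
replicates; 200 are used in the coverage tests (100 outer repetitions keep the suite
inside a few minutes on one CPU while still resolving the 90–99% coverage band).

## Breath preprocessing

Raw breath values are never modified: exclusion is flag-only with a reason code, so
every decision is auditable, and `interpolate_1s` simply ignores flagged breaths
when interpolating linearly onto the integer-second grid (no extrapolation beyond
the observed span).  `ensemble_average` takes the pointwise mean of time-aligned
transitions over their common span; `smooth` offers centered moving-average (width
in seconds), rolling-median and n-breath-average filters with truncated windows at
the edges (no invented data at the transition boundary).  `vo2peak_last30` is the
mean of the final 30 s of the exercise phase.

**Errant-breath screen** (`exclude_errant`, default `window=5`, `k=4.5`).  A breath
with zero VO2 is flagged outright (no gas exchange measured — an artifact by
definition).  Every other breath is compared with a robust local trend: a Theil–Sen
line through its `2·(window−1)` nearest kept neighbours (windows shift one-sided at
the record edges), with the deviation studentized by the least-squares prediction
leverage so interior and edge breaths share a single ~N(0, σ²) null scale.  The
threshold is `k` times a series-level robust SD of all deviations (Qn estimator,
chosen over the MAD for its ~2× better efficiency at the 50–100-breath records this
screen sees).  Flagging iterates to a fixed point — removing a flagged breath changes
its neighbours' references — and a reinstatement step then re-examines flagged
breaths (least deviant first) and clears any that only looked deviant because an
errant neighbour contaminated their window.  A second call with the same settings
reproduces the flags exactly.

Why these choices: a plain rolling mean/SD over a 5-breath window estimates scale
with 3 degrees of freedom, whose t-tails force either a several-percent
false-positive rate or no power at all, at any k; a single series-level robust scale
fixes the degrees of freedom, the robust line fixes the slope bias a median
reference suffers on a fast transient (worst at the record edges, where recovery is
steepest), and k = 4.5 sits between the expected extreme clean deviation over a few
hundred breaths (~3.5 robust SDs) and the smallest deviation one would call errant
(≥8 SDs for a 10σ displacement).  The classic rule is retained as
`method="mean_sd"` for comparison.  Residual simulation error: displacements that
clip at zero VO2 are caught by the zero rule, but an errant breath whose realised
deviation happens to fall in the ~4.5–5.5 SD band is indistinguishable from an
extreme noise breath; at 5% errant rate this leaves roughly one mistaken breath per
~250 simulated transitions.

## Synthetic data

`generate_uniform` evaluates a chosen model exactly on a uniform grid (default 1 Hz,
180 s) and adds i.i.d. Gaussian noise; `noise_sd=0` reproduces the curve to machine
precision, which is what makes the exact-recovery validation executable.
`generate_breaths` draws breath intervals from a truncated normal (mean 3.0 s,
SD 0.75 s, floor at a quarter of the mean — a realistic adult breathing rhythm
during/after exercise), evaluates the model at breath times, adds the same Gaussian
noise, and displaces a configurable fraction of breaths by `errant_magnitude ×
noise_sd` with random sign (values clip at zero, as a gas analyser would report).
The default noise SD of 2 mL·kg⁻¹·min⁻¹ is typical breath-by-breath variability for
exercising adults; both defaults are recorded in every `GeneratorConfig` and its
truth sidecar.

What the generator does **not** emulate: stroke-synchronised breathing, heteroskedastic
noise (real breath noise grows somewhat with ventilation), serial correlation between
breaths, and drift in the baseline.  Passing tests therefore demonstrate correctness
of the estimation machinery under the stated noise model, not robustness to every
artefact of real aquatic gas-exchange data.

Truth presets carry group-mean magnitudes for the four swimming intensity domains
(e.g. severe recovery: EEVO2 51.0, A 40.3, τ 37.0; severe onset: peak 51.4, A 40.3,
τ 10.3, TD 19.6 — baseline = peak − amplitude), so simulated cohorts have realistic
scales.  On-transient presets include a delay, hence `preset_spec("on", ...)`
substitutes the mono-with-TD form when the no-TD form is requested.

## Symmetry statistics

Within each intensity domain, on/off parameter pairs are compared with Student's
paired t-test; the effect size is paired Cohen's d standardised by the SD of the
differences (the standardiser is stated in the output, since pooled-SD variants
differ by roughly √2 at these correlations), with a noncentral-t confidence interval
(normal approximation as fallback at extreme t).  The three consecutive-domain
contrasts per parameter and phase form one Hochberg step-up family (backed by
`statsmodels.multipletests("simes-hochberg")`).  Pearson correlation and the OLS
line come from `scipy.stats.linregress`.  Degenerate pairings (zero difference SD,
e.g. identical inputs) produce d = 0 with NaN p and a warning rather than an error,
so a whole table never dies on one degenerate row.

## Numerical choices and degenerate inputs

- Exponential arguments are clipped to [−700, 100] inside the optimiser loop so
  absurd excursions (negative τ during a restart) stay finite rather than overflow.
- A constant series fitted with a mono model returns the plateau with Ap → 0; the
  initialiser guards degenerate ranges with Ap = 0, τ = 30 s.
- Fits warn (not fail) when the record is shorter than 4× the initial τ guess.
- `percentile_ci` rejects empty pools and levels outside (0, 1); zero-width pools
  give zero-width intervals.
- The errant screen's threshold has an absolute floor of 1e-8·(1 + max |VO2|) so
  float-level jitter on near-exact data cannot cascade into flags.

## Known limitations

- The F-test calibration issue for gate parameters is mitigated, not solved; with
  very low noise and long records the bi-exponential forms can still occasionally
  win on mono-generated data.
- Bootstrap CIs are percentile intervals; no BCa or wild-bootstrap variants.
- The reader handles delimited text with comma/semicolon/tab dialects and decimal
  commas; proprietary binary cart exports are out of scope.
- Problem sizes in the test suite (180–300 s records, 100-repetition simulations,
  200-replicate bootstraps) were chosen to resolve the tested properties while
  keeping the whole suite around a minute of CPU; all are parameters, not limits.
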