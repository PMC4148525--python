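# Methods

This note documents the models implemented in `valuechoice`, the defaults
and their rationale, what the synthetic generator emulates, and the design
choices made where the design was genuinely open.

## Choice model and estimation

Options are gambles (magnitude *r* ∈ (0, 1], probability *p*).  Subjective
magnitude is a power utility `r_S = r^α`; subjective probability uses the
one-parameter weighting function `p_S = p^γ / (p^γ + (1−p)^γ)^(1/γ)`, which
passes through 0, 1 and is the identity at γ = 1.  Subjective expected value
is the product `sEV = r_S · p_S`; α = γ = 1 reduces sEV to the objective
(Pascalian) EV exactly.

Choices follow a two-option softmax.  Two parameterizations are
implemented because the field uses both and they imply opposite readings of
τ:

- `temperature_divide` (default): P(left) ∝ exp(sEV/τ).  Larger τ = noisier
  behaviour ("temperature").
- `inverse_temperature_multiply`: P(left) ∝ exp(sEV·τ).  Larger τ = more
  deterministic behaviour.

The default follows the temperature reading (τ increasing with behavioural
stochasticity); both forms share all downstream code, and all likelihood
arithmetic is done through the log-sigmoid of the scaled sEV difference, so
it is stable for arbitrarily extreme `sEV/τ`.

Estimation is a full grid Bayes: log-likelihood evaluated on a 3-D grid,
log-spaced per axis (150 points per axis by default, 60 in the validation
studies to keep runtimes short), uniform prior over grid cells,
normalization by log-sum-exp.  Default bounds α ∈ [0.05, 5], γ ∈ [0.2, 5],
τ ∈ [0.01, 100] span all behavioural regimes of interest; they are
configurable.  Point estimates are the means of the marginal posteriors on
the linear parameter scale.  Fits are per timing condition by default
(condition contrasts of α, γ, τ are the analysis of interest); a joint fit
over all trials is available.  Missed-response trials are excluded from the
likelihood.

**Identifiability.** A parameter-recovery study (`validation.recovery_study`)
quantifies what 210 binary choices support.  With true α ~ U[0.6, 1.2],
γ ~ U[0.5, 1.2] and τ log-uniform on [0.05, 0.2] (the range where simulated
accuracy spans the 70–90% band typical of human performance on this task),
per-subject posterior-mean errors have sd ≈ 0.25–0.35 for α and γ —
comparable to or larger than the between-subject spread of the true values
— and the errors in α̂ and γ̂ are strongly correlated (a likelihood ridge:
both parameters modulate choice sharpness).  Rank correlations between true
and estimated α/γ therefore land around 0.3–0.7 depending on the seed, and
this is an information limit, not an implementation artifact: a maximum-
likelihood oracle that *knows* τ reaches only ≈ 0.82 under the same
conditions.  τ itself is recovered essentially unbiased (mean log-error
within one grid step).  Consequence for real data: single-subject point
estimates of α and γ at 70–210 trials are noisy and should only be
interpreted at the group level.

## Synthetic task generator

The generator emulates the study design: three timing conditions in
alternating 10-trial blocks, 70 trials per condition; magnitudes uniform on
[0.1, 1.0]; probabilities on a whole-percent grid in [10%, 90%]; a
configurable fraction of "no brainer" trials on which one option strictly
dominates on both attributes; outcome delay and inter-trial interval
jittered uniformly on [3.5, 6] s; stimulus onsets laid out with a
per-condition nominal response allowance (1 / 1.5 / 4 s) plus a 1-s outcome
display and 1-s block precues.

**Low chosen/unchosen correlation.** The analysis requires the values of
the chosen and unchosen options to be nearly uncorrelated across trials
(the study design targets r ≈ 0.18).  Drawing the four attributes
independently cannot achieve this: the max and min of two i.i.d. option
values are correlated ≈ 0.45 by order statistics.  The generator therefore
draws the two options' *EVs* near-independently (higher and lower value
from overlapping uniform ranges) and solves the attributes from the EV
pair, with the anti-dominance orientation (which attribute favours the
higher-EV option) randomized so probability does not systematically track
value.  30% of trials are "hard" (EV ratio 1.05–1.3) within a narrow value
band, supplying the difficult choices that identify τ without adding
chosen/unchosen covariance.  A rejection loop over whole candidate
schedules (cap 10,000) guards the bound |r| ≤ 0.2, assessed against a
greedy argmax-EV chooser as a proxy for the actual (choice-dependent)
correlation.

**Reaction times** are log-normal per condition, with location parameters
calibrated (by solving the truncated-log-normal median equation) so that
condition medians are 0.793 / 1.180 / 3.366 s.  The short condition is
truncated at its 1-s response window; the long condition is the 3-s forced
viewing plus a latency truncated at 1 s.  Missed responses occur with a
configurable probability in the deadline conditions (default 0).

**Agents.** `simulate_agent` is the forward choice model (softmax over
sEVs).  `simulate_weighted_agent` is a logistic chooser with explicit
attribute weights, used to plant known decision policies (probability-only
behaviour; probability weight growing with standardized RT; an optional
perceptual-speed advantage for the bar-rendered attribute, gated by the
display mode and off by default).

## BOLD forward model

Per-trial neural amplitude = intercept + w_c·z(chosen) + w_u·z(unchosen),
with values z-scored within condition — the same standardization the
epoched GLMs use, so planted weights are recovered on the analysis scale.
Coding regimes: `sum_coder` (w_c = w_u = w), `diff_coder` (w_c = −w_u = w),
`null`; a regime may be specified per condition.  The event is a single
0.1-s impulse at stimulus onset (the sustained display is deliberately
simplified: the epoched analysis regresses trial-level scalars, not
convolved boxcars), convolved with the canonical HRF on a 0.1-s grid,
sampled at the TR (3 s default) and summed with stationary AR(1) Gaussian
noise (φ = 0.3, sd = 1.0 by default — an SNR at which the default group
analyses at n = 28 detect the planted regimes with high reliability while
single subjects remain visibly noisy).

What the generator does *not* emulate: scanner drift, motion and
physiological artifacts, spatial structure (everything is ROI-level),
hemodynamic nonlinearity and response overlap saturation, and HRF
variability across subjects and regions.  Tests passing on this generator
show the analysis chain is correct and sensitive under its assumptions, not
that real preprocessing is handled — preprocessing is upstream and out of
scope.

## Epoched ROI analysis

Epochs are [0, 16) s from stimulus onset at 0.3-s resolution (54 points),
extracted by evaluating one cubic spline fitted through the whole series —
so samples coinciding with acquisition times are reproduced exactly.
Trials whose window overruns the series are dropped and counted.  No
baseline subtraction: the per-timepoint intercept absorbs mean signal.

The trial-level GLM is OLS across trials at each timepoint.  Parametric
columns are z-scored within subject × condition (population sd), making
amplitudes comparable across ROIs and conditions; constant columns (e.g.,
outcome value when every trial rewarded) are dropped with a warning; rank
deficiency fails loudly, naming columns.  The two regressor sets
({difference, sum} vs {chosen, unchosen}) are exact reparameterizations of
each other when built from identical columns: β_sum = (β_chosen+β_unchosen)/2
and β_diff = (β_chosen−β_unchosen)/2, an identity the tests verify to 1e-8.

The HRF is a double gamma: difference of two gamma densities with modes
exactly at the peak (6 s) and undershoot (16 s) delays, undershoot ratio
1/6, normalized by its analytic peak value (grid-independent).  The
functional family and the amplitude-only fit are package choices — the
amplitude is the least-squares scalar projection ⟨e, h⟩/⟨h, h⟩ of the
effect timecourse onto the kernel, with an optional ±3-s lag grid selected
by minimal residual (off by default).

Group statistics: one-sample t per regressor × ROI × condition (directional
one-tailed where a signed hypothesis is stated — value-sum positive under
time pressure, unchosen-value negative without it — two-tailed otherwise;
every p is labelled with its tail); paired between-condition contrasts; and
a two-way within-subject ANOVA (area × condition) using the standard
repeated-measures decomposition in which each effect is tested against its
own subject-interaction error term — df (1, n−1) for area and (2, 2(n−1))
for condition and interaction with two areas and three conditions.  The
implementation is by explicit sums of squares and is cross-checked against
an independent repeated-measures ANOVA implementation in the test suite.

## Brain–behaviour model

Per condition, choice accuracy (% higher-EV choices) is regressed on the
chosen- and unchosen-value amplitudes of two ROIs simultaneously (four
regressors + intercept, amplitudes z-scored across subjects).  Contrasts:
the chosen-value effect of each region and their direct difference, with
one-tailed p-values in the stated direction reported alongside two-tailed.
A zero-variance response is reported as degenerate rather than failing.

## Validation studies

- **Posterior exactness:** the vectorized log-domain grid posterior matches
  a plain-arithmetic triple-loop enumeration to ~1e-15 relative on every
  cell.
- **Noiseless end-to-end:** with zero noise, a sparse schedule (trials
  spaced beyond the 32-s kernel support) sampled at the epoch resolution
  with grid-aligned onsets, the epoch → GLM → HRF-amplitude chain returns
  the planted weights to machine precision.  Sparseness and alignment are
  what make the identity exact: at TR = 3 s the spline resampling of the
  kernel and response overlap between neighbouring trials each introduce
  small, quantifiable attenuation.
- **Double dissociation:** 20 cohorts of 28 subjects with planted regimes
  (region A: sum coder under time pressure, diff coder otherwise; region B:
  diff coder under time pressure, silent otherwise) — the group
  unchosen-value tests match the planted sign/absence in every cell, and
  the brain–behaviour region contrast flips sign between short and
  middle/long, in ≥ 90% of cohorts at default SNR.
- **Choice regression:** probability-only agents yield positive RP and null
  RM group effects; a planted RT-growing probability weight yields a
  positive RP × RT interaction, with the expected sign in ≥ 90% of cohorts.

Study sizes (50 recovery subjects, 20 cohorts, 60³ grids) are chosen so the
full validation battery completes in a few minutes on one CPU.

## Conventions and open choices

- Choice regression codes: dependent variable = chose left; RP/RM are
  left-minus-right differences; pC = previous choice side (+1 left);
  pO = +1 if the previously chosen side was rewarded (block starts coded
  0); an alternative "winstay" coding (pO points at the previously rewarded
  side) is available behind a flag.  RT is standardized within subject ×
  condition before forming interactions.  Logistic link, no regularization
  by default; separation and non-convergence are flagged in a diagnostic
  column, with an optional small ridge fallback.
- Events tables follow the BIDS events convention (onset/duration first,
  seconds, tab-separated, `n/a` for missing); ROI series are one column per
  ROI with the TR in a `# tr_s=` header comment.  All writes use
  round-trippable float formatting.
- Time origin is run start; onsets are absolute; no slice-timing handling
  (out of scope with preprocessing).
- The equal-objective-EV accuracy metric excludes equal-EV trials from both
  numerator and denominator.
- Whether the original analyses standardized the epoch-GLM regressors, the
  HRF family used for amplitude fitting, and the exact previous-trial
  codings are not derivable from the task description; the choices above
  are declared conventions, each behind an explicit parameter.

## Known limitations

- Single-subject α/γ estimates at ≤ 210 trials are noisy (see
  Identifiability) — group-level contrasts are the supported inference.
- The epoched GLM treats trials as independent; overlap between
  neighbouring trials' hemodynamic responses acts as correlated noise at
  realistic spacing.
- No hierarchical (mixed-effects) models: per-subject fits then group
  tests.
- Gains-only prospect theory: no loss aversion or reference-point
  machinery.
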