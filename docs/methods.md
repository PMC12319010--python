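# Methods

## Response model

The tuning curve is a wrapped (double) Gaussian over direction:

    R(θ) = C + R_p e^{−angdiff(θ−θ_pref)²/2σ²} + α R_p e^{−angdiff(θ−θ_null)²/2σ²}

`angdiff` is the shortest angular distance on the 360° circle, so the
curve is 360°-periodic; `θ_null = θ_pref + 180°`. The null amplitude
is parameterized as a fraction `α ∈ [0, 1]` of the preferred amplitude
rather than as an independent `R_n`: this guarantees `R_n ≤ R_p` at
every grid combination, which a Bayesian scan — unlike a least-squares
fit, where the larger lobe can be relabelled afterwards — needs built
into the parameterization. Angles are degrees throughout; radians
appear only inside trigonometric calls. The library takes angles as
given and is agnostic about compass vs. Cartesian conventions.

Derived quantities use the *full* model responses, offset included:
`R_pref = R(θ_pref)`, `R_null = R(θ_null)`, and the two orthogonal
responses `R(θ_pref ± 90°)`. The selectivity indices are
`OI = (R_pref + R_null − R_orth+ − R_orth−)/(R_pref + R_null)` and
`DI = (R_pref − R_null)/R_pref`. Note the consequences: a flat cell
with positive offset has `OI = 0`, an offset bounds `OI` and `DI`
below 1, and the Gaussian leak into the orthogonal angles bounds `OI`
below `1 − 2e^{−4.5} ≈ 0.978` at `σ = 30°` even with zero offset.

A von Mises curve `A·exp(k[cos(2(θ−φ)) − 1])` (period 180°,
orientation-only) is included as a deliberate model-mismatch probe for
the simulator. The literal "cos2(θ−φ)" is read as `cos(2(θ−φ))`, the
reading under which the function is an orientation-tuning model.

## Noise law

Trial-to-trial response SD grows with the mean approximately as a
power law; a constant floor keeps the noise positive at zero mean:

    σ_noise(m) = C_n + K·m^S

Constants are fitted by nonlinear least squares on pooled
(per-stimulus mean, per-stimulus SD) pairs across *all* cells of a
recording — per-cell fits are deliberately unsupported, since a single
cell's handful of pairs cannot constrain three constants. Residuals
are minimized in linear space (the floor `C_n` breaks log-linearity; a
`loss="log"` option exists); the classical log-log regression supplies
the starting point. Sample SDs use the n−1 denominator. Pairs with
nonpositive mean (possible for dF/F) are excluded from the log-log
initialization but kept in the nonlinear fit. For `m < 0` the law
returns the floor `C_n`: a fractional power of a negative number is
undefined and the floor is the natural continuation of the `m = 0`
case. `K < 0` (seen for cell classes whose noise is nearly
mean-independent) is accepted, but the law is validated to stay
positive over the response range wherever it is evaluated, and raises
otherwise.

A caveat documented by the test suite: with few trials per pair the
individual constants are weakly identified (the floor trades off
against the power term) even when the fitted *curve* is accurate; the
round-trip recovery test therefore uses many trials per pair.

## Likelihood and grid posterior

Observed data are per-angle mean responses `r_i` over `T` trials. The
likelihood of one angle is a normal density centred on the model
response `r̂_i`, with SD `σ_noise(r̂_i)/√T` — the noise is evaluated at
the *model* response, not the observed one, and the `√T` follows the
central-limit scaling of a mean of `T` trials. Angles are independent,
so log likelihoods add. Trial-averaged input with a stated `T` is
accepted in place of trial-level data (the likelihood needs nothing
more).

The posterior is evaluated at every combination of finite value sets
for (C, R_p, α, θ_pref, σ) under a uniform prior and normalized to sum
to one; the evidence is never computed explicitly. All accumulation is
in log space with max-subtraction before exponentiation, so a cell
whose best likelihood is `e^{−10⁵}` still normalizes exactly.
Production grids (linearly spaced between the stated bounds): for
spike rates, C ∈ [0.1, 10] ×60, R_p ∈ [0.1, 20] ×60, α ∈ [0, 1] ×15,
θ ∈ {0°, 5°, …, 355°} (72), σ ∈ [1, 60]° ×60 — 233,280,000
combinations; for calcium dF/F, C ∈ [−MX, MX] ×60,
R_p ∈ [0.001, 3·MX] ×60 and α ×21 — 326,592,000 — where MX is the
cell's maximum absolute per-angle mean response, derived at load time
and recorded in the output.

Summaries are extracted while the joint is in memory and are the only
persisted artifacts: normalized 1-D marginals per parameter; the grid
MLE (argmax over all combinations; exact ties are broken by first
occurrence in C-order over the fixed axis order C, R_p, α, θ, σ
ascending, and flagged); 20-bin histograms of OI and DI on [0, 1]
(left-closed bins, last bin closed; values outside [0, 1], possible
with negative offsets, are clamped into the end bins with a warning);
a histogram of the derived `R(θ_pref) = C + R_p + αR_p e^{−180²/2σ²}`;
and optional 2-D joint marginals for requested parameter pairs.
Because OI, DI and `R(θ_pref)` do not depend on `θ_pref`, they are
computed on the θ-marginalized joint. The marginal of the amplitude
*parameter* `R_p` and the histogram of the derived *response*
`R(θ_pref)` are both provided; they answer different questions and
differ by the offset.

A `GridEvaluator` caches model predictions and noise SDs per
(grid, angles, T) design, so repeated posteriors across simulation
replicates cost a few array passes; when the cache would exceed
~120M elements the evaluator streams over blocks of the C axis
instead. Writing the raw joint to disk is refused by design (order
10 GB per production-grid cell); it is cheap to recompute from the
stored grid definition.

## Simulator

A scenario is a parameter set, an angle list, a trial count, a noise
mode and a seed; sampling adds i.i.d. Gaussian noise per trial.
Noise modes: `fractional` (SD = level × |R(θ)|; the standard "50%
noise" condition is level 0.5 — mean-proportional, matching the noise
law's premise), `noise_model` (SD = σ_noise(R(θ)); use for exact
generative/likelihood match, e.g. calibration studies), and `constant`
(fixed SD, e.g. 2 spikes/s for the von Mises sweep). Samples are not
truncated at zero unless requested, since additive Gaussian noise
legitimately produces negative baseline-subtracted responses.

The scenario library fixes the study conditions: a strongly tuned cell
(C=1, R_p=10, α=0.5, θ=90°, σ=30°) and a weakly tuned one (C=1,
R_p=1, α=0) at 36 evenly spaced directions, T=5, 50% noise; a
temporal-frequency triplet at 16 directions (R_p=7, α=1/7 /
R_p=5, α=1 / R_p=0); an angle-count sweep {4, 8, 16, 32, 36} at
(C=2.5, R_p=7.5, α=0.5); OI and DI sweeps whose amplitudes are solved
numerically so the model index hits targets {0, 0.25, 0.5, 0.75, 1}
(endpoint targets of exactly 1 are unattainable with a positive
offset; the solver sets C=0 there and attains ≈0.98/≈1, and the OI
sweep keeps α=0.5 so that high-OI cells have an identifiable direction
preference); and von Mises curves with A ∈ {0, 2.5, 5, 7.5, 10},
k=2 (half-width comparable to a σ=30° lobe), φ=90°, constant 2 sp/s
noise. Identical seeds give bit-identical datasets.

What the simulator does *not* emulate: spike-count discreteness and
point-process timing, calcium-indicator dynamics and saturation,
adaptation or serial dependence across trials, and correlated noise
across angles. Passing recovery and calibration tests therefore shows
the estimator is correct *under its own noise assumptions*; on real
data the noise law should always be checked on a log-log plot first.

## Performance metrics

Relative error of a marginal against a known truth `x_t` is
`ESE/ESE_u`, where `ESE = Σ_j L̂(x_j)(x_j − x_t)²` and `ESE_u` is the
mean squared error of a *uniform density* on the parameter range
(`(1/(b−a))∫(x−x_t)²dx`; `period²/12` for circular parameters). The
density normalization makes an exactly uniform posterior score 1 —
the natural "no information gained" reference — up to an `O(h²)`
discretization residue (≈4×10⁻⁴ for the 5° θ axis), which is why the
tests assert ≈1 rather than equality. Point mass at the truth scores
0; a confidently wrong posterior can exceed 1. θ_pref errors are
circular with period 360° (180° would be appropriate when only
orientation is defined; callers choose).

Coverage asks whether `x_t` lies between the (50−p/2)% and (50+p/2)%
posterior quantiles, interpolated on the discrete grid via the
midpoint CDF. Circular parameters are first re-centred on the
posterior circular mean so the interval never straddles the wrap.
Calibration (empirical ≈ nominal) is expected when the generative
noise matches the likelihood's and the grid resolves the posterior;
the calibration study uses a 1° θ axis because at 2° the discreteness
of the few-degree-wide posterior makes intervals measurably
conservative.

One-way fixed-effects ANOVA across stimulus angles supplies the
standard responsiveness screen; `run_recovery` chains
simulate → posterior → metrics over seeded replicates into a tidy
table.

## Bootstrap / least-squares comparator

The comparator fits the double Gaussian (independent `R_p`, `R_n`
amplitudes) to per-angle means by bounded nonlinear least squares
(unweighted, as classically practised), then resamples trials with
replacement within each stimulus and refits, building an empirical
parameter distribution. Constraints follow standard practice: the
width floor defaults to half the dataset's angular step (22.5° for
45° steps), amplitudes are bounded by a multiple of the data range,
and `R_p ≥ R_n` is restored post hoc by swapping lobes (θ shifted
180°). Multi-start (4 deterministic starts: θ at the argmax response
and its opposite, σ at the floor and twice the floor; optional seeded
jittered extras) mitigates but does not remove local-minimum
sensitivity — estimates piling up exactly on the σ floor for weakly
tuned cells are the comparator's characteristic failure, and the
comparison utilities expose it (`at_sigma_floor` per fit, a 180°-flip
flag when the two methods' preferred angles are opposite). Failed
fits are recorded, not dropped; more than 50% failures raises.

## Desk-scale grids and problem sizes

The simulation studies and tests run on reduced grids so a full study
fits in minutes on one CPU core. The reduced spiking grid
(C 0.5:0.5:10, R_p 2.5:2.5:20, α {0,.25,.5,.75,1}, θ 0:10°:350,
σ 5:5:60; 345,600 combinations) was designed in a pilot so that each
axis step is at least about twice the posterior width attainable under
the standard recovery conditions (36 angles, T=5, 50% noise) — the
amplitude posterior (SD ≈0.9, heavy-tailed along its ridge with σ) is
the binding constraint — and so the axes contain the library
scenarios' parameter values. Recovery experiments use 100 replicates,
calibration 500, the histogram-mode study 20; the bootstrap comparison
uses 8-angle designs, 50 resamples per cell, and a grid whose
amplitude axis reaches 0.1 (like the production grid) because an
amplitude floor of 2.5 would force a spurious lobe onto flat cells and
reproduce in the grid MLE the very overfit-width pathology the
comparison is about.

## Known limitations

- Exhaustive enumeration scales multiplicatively; the production grids
  are minutes-per-cell on one CPU core (the evaluator streams to bound
  memory). No MCMC/variational shortcut is provided — exact grid
  evaluation is the method.
- The uniform prior is the only one exercised; `GridEvaluator` returns
  log likelihoods, so a nonuniform prior can be added by the caller,
  but none is built in.
- Answer resolution equals grid resolution; marginal modes and MLEs
  inherit the step size.
- Gaussian likelihood on trial means: inappropriate for very low
  counts (T = 1–2 with near-zero rates), where the normal
  approximation to the mean is poor.
- The circular-variance summary is provided for completeness;
  vector-method selectivity screening, not parameter estimation, is
  its job.
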