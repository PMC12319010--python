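# tuningbayes

Grid Bayesian parameter estimation for neuronal orientation and
direction tuning curves.

Neurons in visual cortex (and head-direction systems, and many other
circuits) respond selectively to the angle of a stimulus. The standard
descriptive model is a double Gaussian on the circle,

    R(θ) = C + R_p · exp(−angdiff(θ − θ_pref)² / 2σ²)
             + R_n · exp(−angdiff(θ − θ_null)² / 2σ²),

with offset `C`, preferred- and null-direction amplitudes `R_p ≥ R_n`
(parameterized as `R_n = α·R_p`, `0 ≤ α ≤ 1`), preferred direction
`θ_pref` (with `θ_null = θ_pref + 180°`) and width `σ`. Least-squares
fits of this model are unreliable exactly when one often needs them —
weakly tuned cells — and give no account of parameter uncertainty.

`tuningbayes` instead evaluates the likelihood of the observed
per-angle mean responses at *every* combination of a discrete
five-parameter grid, under a uniform prior, and normalizes the result
into a full joint posterior. Trial-to-trial variability enters through
a mean-dependent noise law `σ_noise(m) = C_n + K·m^S` (fitted from
pooled per-stimulus means and SDs across all cells of a recording),
shrunk by `√T` for averaging over `T` trials. The joint is reduced, in
memory, to compact summaries: per-parameter marginals, the grid MLE,
posterior histograms of the orientation index
`OI = (R_pref + R_null − R_orth+ − R_orth−)/(R_pref + R_null)` and
direction index `DI = (R_pref − R_null)/R_pref`, and of the derived
preferred response `R(θ_pref)` — kilobytes per cell instead of the
gigabytes the raw joint would occupy.

The package also provides a seeded simulator for all the standard
validation conditions (graded selectivity, temporal-frequency series,
angle-count sweeps, von Mises model-mismatch probes), estimator
quality metrics (relative error against an uninformed uniform
posterior, central credible-interval coverage), and the classical
comparator: a trial-resampling bootstrap around a constrained
least-squares fit, with its documented width-floor pathology.

## Worked example

```python
import numpy as np
from tuningbayes import (GridSpec, NoiseModel, compute_posterior,
                         sample_responses, scenario_library)

# strongly direction-tuned cell: C=1, Rp=10, Rn=5, pref 90deg, width 30deg,
# sampled at 36 directions, 5 trials each, 50% multiplicative noise
scenario = scenario_library("well_tuned")
data = sample_responses(scenario, seed=1)

noise = NoiseModel(Cn=0.1, K=0.5, S=1.0)     # sigma(m) ~ 0.5 m
summary = compute_posterior(data, GridSpec.reduced_spiking(), noise)

print(summary.mle)
print("theta marginal mode:",
      summary.grid.theta_pref[np.argmax(summary.marginals["theta_pref"])])
print("OI histogram peak bin:", 0.05 * np.argmax(summary.oi_hist))
```

prints

```
TuningParams(C=1.0, Rp=10.0, alpha=0.5, theta_pref=90.0, sigma=30.0)
theta marginal mode: 90.0
OI histogram peak bin: 0.8500000000000001
```

i.e. the most likely grid combination coincides with the generating
parameters, the direction-preference marginal peaks at 90°, and the
posterior mass of the orientation index falls in the bin containing
its true value of 0.86. For a weakly tuned cell the same call returns
broad marginals instead — the uncertainty is the point.

The same pipeline is scriptable from the shell:

```sh
tuningbayes simulate --scenario well_tuned --seed 7 --out data.csv
tuningbayes fit-noise --in data.csv --out noise.json
tuningbayes estimate --in data.csv --noise noise.json --grid reduced --out summary.json
tuningbayes bootstrap --in data.csv --n-boot 200 --out boot.csv
```

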