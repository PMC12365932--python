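# distractor-learn

Computational modeling of **statistically learned distractor suppression**
in visual search.

In the additional-singleton paradigm, observers search a six-item array for a
shape singleton while, on half of the trials, one non-target item is a salient
color singleton (the distractor). When the distractor appears at one
*high-probability* (HP) location on 66.67% of distractor-present trials,
observers learn to suppress that location: reaction times are faster when the
distractor appears there than at the five *low-probability* (LP) locations.
This package asks *how* that learning proceeds, by fitting and comparing
trial-level computational models of RT, and provides everything needed to do
so without any observed data: paradigm-exact trial-sequence generation,
synthetic RT simulation, hierarchical model fitting and comparison, and
model/parameter-recovery experiments.

## The models

RTs on distractor-present trials (seconds) follow a trial-level Gaussian GLM

```
rt_i = β₀ + β_g · z(e^{-b_g (i-1)}) + β_s · z(s_i) + β_p · prev_absent_i + ε_i,
ε_i ~ N(0, σ²),   σ̂ = √(RSS/n)
```

where `e^{-b_g (i-1)}` is a global exponential practice decay over
distractor-present trials, `prev_absent` codes whether the previous trial had
a distractor, and `s_i` is a model-specific suppression regressor driven by
per-location learning states:

| model | suppression regressor `s_i` | state update |
|---|---|---|
| 1 | graded, `1 − e^{−b_d c_l}` | counts `c_l` of distractors at location `l` |
| 2 | graded, delta rule | `p_l ← p_l + α (Dist_l − p_l)`, start 0.16667 |
| 3 | categorical, `1{distractor at argmax c_l}` (ties included) | counts as model 1 |
| 4–6 | as 1–3 | states reset at each block start |
| 7 | none (priming only: adds a distractor-repetition dummy) | — |
| 8–9 | as 1/4 | without the global decay regressor |

States update on every distractor-present trial; the regressor for trial *i*
uses state through trial *i − 1*. Continuous regressors are z-scored per
subject over the included trials (first trial of each block, inaccurate
trials, and RTs < 200 ms are excluded).

Fitting is hierarchical random-effects inference: per-subject MAP estimates
under Gaussian raw-space priors (rates log-transformed, learning rates
logit-transformed, prior N(0, 6.25)), Laplace model evidence, and iterated
responsibility-weighted updates of group means, variances, and a Dirichlet
over model frequencies. Model comparison reports exceedance probabilities,
the Bayesian omnibus risk (bor), and the protected exceedance probability
`pxp = xp·(1 − bor) + bor/K`.

## Worked example

```python
import numpy as np
import distractor_learn as dl
from distractor_learn.reference import exp1_categorical_group_spec

# 17 subjects simulated from the categorical model (model 3) with the
# published group parameters, on fresh 480-trial constant-probability designs
spec = exp1_categorical_group_spec(17)
data = dl.simulate_group(spec, dl.ExperimentDesign.exp1(), noise=50.0,
                         rng=np.random.default_rng(7))

fit = dl.fit_hierarchical([1, 2, 3, 7], data.subjects,
                          rng=np.random.default_rng(7))
for m, p in zip(fit.comparison.model_ids, fit.comparison.pxp):
    print(f"model {m}: pxp = {p:.3f}")
print(f"bor = {fit.comparison.bor:.4f}")
print("model 3 group means:",
      dict(zip(fit.groups[3].parameter_names,
               np.round(fit.groups[3].group_mean, 4))))
```

prints (exact values vary with the seed):

```
model 1: pxp = 0.005
model 2: pxp = 0.001
model 3: pxp = 0.993
model 7: pxp = 0.001
bor = 0.0033
model 3 group means: {'b_global': -4.2735, 'beta_intercept': 0.875,
 'beta_global_decay': 0.091, 'beta_categorical': -0.0451,
 'beta_prev_absent': -0.0062}
```

The comparison decisively selects the generating categorical model, and the
recovered group coefficients track the simulation inputs: a negative
categorical coefficient (≈ −0.045 s here, i.e. ~45 ms faster when the
distractor occupies the most-suppressed location), an intercept near 0.875 s,
and a log-scale decay rate (`exp(−4.27) ≈ 0.014` per present trial).

The same stages are scriptable from a shell:

```sh
distractor-learn design    --out trials.csv --seed 1
distractor-learn simulate  --model 3 --groupspec g3.json --noise 50 --seed 1 --out sim.csv
distractor-learn fit       --trials sim.csv --models 1,2,3,7 --out fit.json --seed 1
distractor-learn recover   --config recovery.json --out confusion.csv --seed 1
distractor-learn summarize --trials sim.csv --out summaries/
distractor-learn pipeline  --config pipeline.json --out results/ --seed 1
```

## Layout

- `src/distractor_learn/design.py` — paradigm-exact trial sequences and validation
- `src/distractor_learn/models.py` — the nine models, design matrices, GLM likelihood
- `src/distractor_learn/inference.py` — MAP + Laplace fits, hierarchical comparison
- `src/distractor_learn/simulate.py` — group parameter draws and RT simulation
- `src/distractor_learn/recovery.py` — model-recovery experiments
- `src/distractor_learn/behavior.py` — descriptive condition summaries
- `src/distractor_learn/cli.py` — command-line interface
- `docs/methods.md` — modeling assumptions, defaults, and limitations
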