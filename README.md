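# rlddm — RL-DDM analysis of probabilistic selection task data

`rlddm` is a tested, reusable pipeline for studying **stereotype-based
associative learning** with a reinforcement-learning drift-diffusion model
(RL-DDM). It is aimed at behavioural and decision-neuroscience researchers
who run probabilistic selection tasks (PSTs) and want to fit trial-level
choice *and* response-time data jointly, compare hierarchical model
variants, and test directional hypotheses on the posterior.

The package covers the whole workflow:

* **Task simulation** — the standard PST: three same-sex face pairs
  (AB/CD/EF) whose positively reinforced member earns "Correct" feedback
  with probability 0.80/0.70/0.60; blocks of 120 trials that terminate once
  per-pair choice accuracy reaches 0.60/0.55/0.50, up to four blocks
  (480 trials). Sessions carry a between-subject Learning Context factor
  (stereotypic vs. counter-stereotypic) and a within-subject
  Goodness-of-Stereotype-Fit factor (high vs. low fit of the reinforced
  face), assigned by counterbalance group.
* **The RL-DDM.** Each pair holds expected values `q_target`, `q_other`
  (initialized 0.5). After each choice the chosen face's value follows the
  delta rule

  ```
  q  <-  q + η (feedback − q)
  ```

  and the trial's decision is a two-boundary Wiener diffusion with drift

  ```
  v = v_scaling (q_target − q_other)
  ```

  boundary separation `a`, unbiased start (`z = a/2`), and non-decision
  time `t0`. Responses are *response-coded*: the upper boundary is the
  positively reinforced face. The likelihood is the Wiener first-passage
  density, evaluated with both the small-time and large-time series
  expansions and an adaptive switch between them.
* **Hierarchical Bayesian inference** — group means/SDs per condition cell
  partially pool subject-level parameters; sampling runs on log-odds (η),
  log (`a`, `t0`) and natural (`v_scaling`) scales via an adaptive
  Metropolis-within-Gibbs kernel (numba-accelerated likelihood).
* **Model comparison** — the three candidate specifications (learning-context
  model, goodness-of-fit model, integrative model) ranked by DIC, with the
  Gelman–Rubin statistic for convergence.
* **Posterior predictive checks** — simulated cohorts from joint posterior
  draws, compared with the observed per-pair accuracies and RT deciles.
* **Directional posterior tests** — `p_Bayes`, the posterior mass contrary
  to a stated direction, and the complementary posterior odds
  `BF10 = (1 − p_Bayes)/p_Bayes`, plus the prediction-error contrast that
  compares the learning-rate advantage of *surprising* targets across
  learning contexts.

A synthetic-cohort generator (`rlddm.cohort`) emulates the full
2 × 2 design with documented group-level truths, so every stage is testable
with known ground truth and no external data.

## Worked example

```python
import numpy as np
from rlddm import (preset_expt1, generate_cohort, build_model, ModelSpec,
                   prediction_error_contrast)
from rlddm.inference import fit_model

truth = preset_expt1(n_subjects_per_context=12, seed=1)
log, truth_table = generate_cohort(truth)

model = build_model(ModelSpec.integrative(), log)
fit = fit_model(model, n_samples=1500, n_burn=500, n_chains=1, seed=1)
print(f"integrative model: DIC = {fit.dic:.1f} (p_D = {fit.p_d:.1f})")

for ctx in ("stereotypic", "counter-stereotypic"):
    for fl in ("high", "low"):
        d = fit.posterior.natural(f"mu_eta[{ctx}:{fl}]")
        lo, hi = np.quantile(d, [0.025, 0.975])
        print(f"eta {ctx:>20s}/{fl:<4s}: {d.mean():.3f} [{lo:.3f}, {hi:.3f}]")

contrast = prediction_error_contrast(fit.posterior)
print(contrast.test.display())
```

Output:

```
integrative model: DIC = 7764.3 (p_D = 96.8)
eta          stereotypic/high: 0.109 [0.074, 0.159]
eta          stereotypic/low : 0.145 [0.088, 0.216]
eta  counter-stereotypic/high: 0.251 [0.217, 0.304]
eta  counter-stereotypic/low : 0.125 [0.094, 0.152]
p_Bayes[counter-stereotypic surprise advantage > stereotypic surprise advantage] = 0.023, BF10 = 42
```

Reading this: the group-level learning rates are highest for *unexpected*
targets (high-fit faces in the counter-stereotypic context, low-fit faces in
the stereotypic one), and the posterior credible intervals recover the
generating truths (0.10/0.18/0.25/0.12). The directional test says only
2.3% of the posterior mass is contrary to the hypothesis that the surprise
advantage is larger in the counter-stereotypic context — complementary
posterior odds of 42.

The same pipeline is available from the shell:

```bash
rlddm simulate --preset expt1 --n 12 --seed 1 --out sim/
rlddm fit      --log sim/trials.csv --model integrative \
               --samples 1500 --burn 500 --seed 1 --out fit/
rlddm report   --log sim/trials.csv --posterior fit/posterior.csv --out report/
```

## Layout

```
src/rlddm/
  task.py        PST designs, block criterion, trial-log CSV I/O
  wfpt.py        Wiener first-passage density, absorption prob., sampler
  rl.py          delta rule, drift construction, session simulation/likelihood
  cohort.py      synthetic 2x2 cohorts with documented group truths
  inference.py   model specs, hierarchical MCMC, Gelman-Rubin, DIC
  comparison.py  candidate fitting/ranking, posterior predictive checks
  analysis.py    p_Bayes, evidence ratios, prediction-error contrast, reports
  cli.py         `rlddm` command-line interface
docs/methods.md  modelling and numerical details
```
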