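# Methods

## The task model

A probabilistic selection task (PST) session presents fixed face pairs.
Each pair has a *target* (the positively reinforced face) that earns
"Correct" feedback with probability 0.80 (AB), 0.70 (CD) or 0.60 (EF);
choosing the other face earns positive feedback with the complementary
probability. Trials run in blocks of 120 in which each pair appears
equally often in random order. After each block, per-pair accuracy (the
proportion of target choices *in that block*) is compared with the pair's
criterion — 0.60, 0.55, 0.50, inclusive at equality — and the session
stops when every pair passes, or after four blocks (480 trials).

Two design decisions were genuinely open:

* **Blocks vs. cumulative criterion.** The criterion is evaluated on the
  just-completed block only. A block is the natural unit at which accuracy
  is "reached", and a cumulative rule would let early noise mask late
  learning; either reading is defensible, this one is implemented and
  documented.
* **Three or six pairs per session.** By default a session contains six
  pairs (three female, three male, ids suffixed `-F`/`-M`). The
  within-subject goodness-of-fit factor requires both fit levels among the
  targets of a single subject, which the six-pair layout guarantees under
  every counterbalance; `n_pair_sets=1` gives the three-pair variant.

The counterbalance group fixes which fit level is reinforced per face sex
(group 1: high-fit female and low-fit male targets; group 2 mirrored), so
the fit-of-target mapping flips bijectively between groups.

Feedback is drawn i.i.d. Bernoulli per trial by default ("80% likely to be
correct" describes a rate, not a schedule); an exact-proportion shuffled
schedule per block is available behind `feedback_schedule="exact"` for
users who want deterministic reinforcement ratios.

## The RL-DDM

Each pair carries expected values `q_target`, `q_other`, initialized at
0.5 (the uninformative midpoint of binary feedback). Only the chosen
face's value is updated, by the instrumental delta rule
`q <- q + eta (feedback - q)` with learning rate `eta` in (0, 1); unchosen
values neither update nor decay. The trial's drift rate is
`v = v_scaling (q_target - q_other)`, signed toward the upper boundary,
which is response-coded as the positively reinforced face. The decision
process is a two-boundary Wiener diffusion with boundary separation `a`,
relative start fixed at 0.5 (no bias is modelled), non-decision time `t0`
and diffusion coefficient fixed at 1 (the identifiability scaling of the
hierarchical-DDM toolbox lineage; neither convention is a fitted claim
about the data).

Parameters live on condition cells (learning context x goodness-of-fit of
the trial's target). One learning rate serves both feedback signs, since a
single `eta` per cell is what the analysis estimates and reports.

## Wiener first-passage likelihood

The defective first-passage density at the lower boundary in normalized
time `u = (t - t0)/a^2` has two classical series forms; the evaluator
computes the number of terms each needs for absolute tolerance 1e-7
(standard truncation bounds) and uses whichever needs fewer. That makes
the density accurate and continuous across the internal switch (verified
against long-sum references to 1e-6 relative). The upper-boundary density
reflects the process (`v -> -v`, `w -> 1 - w`); `t <= t0` returns zero
density (log -inf), never an exception, so samplers treat impossible RTs
as rejections. The absorption probability uses the exact formula
`expm1(-2 v z)/expm1(-2 v a)` with guarded strong-drift limits.

The first-passage sampler is Euler discretization (default step 1 ms) with
Brownian-bridge absorption inside each step and midpoint crossing times,
which removes the leading O(sqrt(dt)) bias of a naive scheme; measured
Kolmogorov–Smirnov distances against the integrated density are 0.003–0.007
at n = 1e5 with dt = 0.5 ms across drift/boundary settings spanning the
fitted range.

## Synthetic cohorts

`GroupTruth` states group-level means and between-subject SDs on the
sampling scales (log-odds for `eta`, log for `a` and `t0`, natural for
`v_scaling`); subjects draw normal deviates there and transform back, which
keeps every parameter in its legal domain. Subjects alternate contexts and
counterbalance groups; each plays one simulated session.

The presets (`preset_expt1`, `preset_expt2`) encode *synthetic* truths:
the direction of the cell differences follows the surprise-driven learning
account (unexpected targets learn fastest, with the larger advantage in
the counter-stereotypic context), but the magnitudes — e.g. group-mean
learning rates 0.10/0.18/0.25/0.12 and SD 0.3 on the log-odds scale — are
generator choices made once for testability and are not estimates of any
dataset. `preset_context_only` ties each subject's two fit cells to a
single draw; this matters, because with independent per-cell draws the
generated data are genuinely integrative at the subject level and model
comparison correctly refuses to prefer the context-only specification.

What the generator does **not** emulate: RT outliers and lapses, attention
failures, left/right position effects, sequential dependencies beyond the
delta rule, or the RT marginals of any real dataset. Passing tests
therefore demonstrate internal consistency of the pipeline (simulation →
fitting → comparison → testing), not realism of the generative
assumptions for empirical data.

## Hierarchical inference

For each freed parameter family and cell: group mean `mu` ~ normal(0, 2)
on the sampling scale (`v_scaling`: normal(1, 2)), group SD ~
half-normal(1), subject values ~ normal(mu, sigma). `t0` is subject-level
and factor-free in every specification. These priors are weakly
informative and are this package's declaration — the originating analysis
toolbox has its own unpublished defaults.

The kernel is adaptive Metropolis-within-Gibbs:

* subject-level values update by Gaussian random walk, proposed for all
  subjects simultaneously and accepted independently (subjects are
  conditionally independent given the group level);
* group means update by conjugate Gibbs draws;
* group SDs update by random walk on log sigma (with the Jacobian term);
* proposal scales adapt toward 0.44 acceptance in windows of 25 sweeps
  during burn-in only, with a diminishing adaptation rate, so the retained
  chain is a fixed Markov kernel.

Initialization is data-light: mid-range values plus jitter, with each
subject's `t0` capped at 0.95 x their fastest response so no chain starts
at zero likelihood. Chains whose post-burn acceptance collapses below 2%
on any subject node are flagged in the result, never dropped. Default
settings mirror the estimation protocol (10,000 samples, 5,000 burn, one
chain); convergence checks use 3 chains of 5,000/500 and the classic
(split-free) Gelman–Rubin statistic, with the zero-variance guard R = 1
and fits flagged above 1.01.

DIC uses the posterior-mean plug-in on sampling scales:
`p_D = mean(D) - D(theta_bar)`, `DIC = mean(D) + p_D`, with non-finite
deviance draws excluded (error above 1%).

## Posterior predictive checks

One joint posterior draw per simulated dataset (default 50), matched
subject count and session structure; statistics are per-pair choice
accuracy — computed by the same code path as the task's block criterion —
and pooled RT deciles, a stable summary at small cohort sizes. Coverage
is "observed inside the central 95% of simulated values", a sharper,
machine-checkable stand-in for a visual fit review.

## Directional tests and contrasts

`p_Bayes` is the posterior mass contrary to the stated direction over
paired draws, with ties counted against the direction (conservative).
The reported evidence ratio is the complementary posterior odds
`(1 - p)/p`, displayed as the nearest integer (half up) when >= 1, and as
the bound "> 1000" when `p < 0.001`; the raw value is always retained in
JSON. Whether these odds constitute a formal Bayes factor is a matter of
interpretation; the package documents and implements exactly this formula.

The prediction-error contrast works on the natural (0, 1) learning-rate
scale, where learning rates are discussed: per draw,
`delta_stereotypic = eta(low) - eta(high)` within the stereotypic context,
`delta_counter = eta(high) - eta(low)` within the counter-stereotypic
context, and the difference `delta_counter - delta_stereotypic` is tested
directionally. It requires all four context-by-fit cells, i.e. an
integrative-model posterior.

## Problem sizes used by the test suite

The end-to-end recovery, model-recovery and PPC checks run on cohorts of
12 subjects per context with full session lengths, MCMC at 1,500
samples/500 burn, and three seeded replicates — sizes chosen after
calibrating that the sampler's recovery behaviour is already stable there
(group-mean 95% CrI coverage 12–13 of 13 nodes per seed; subject-level
learning-rate rank correlations 0.77–0.90). Larger cohorts and the
default 10,000/5,000 protocol sharpen intervals but do not change any
qualitative outcome.

## Known limitations

* No inter-trial variability parameters (sv, sz, st0) — deliberately out
  of scope, matching the fitted model.
* Metropolis-within-Gibbs mixes more slowly than gradient-based samplers;
  the defaults compensate with draw count, and the diagnostics (R-hat,
  stuck-node flags) are the contract.
* The DIC plug-in at posterior means can misbehave for strongly
  multimodal posteriors; none were observed in the fitted models.
* Single-chain default matches the estimation protocol but cannot compute
  R-hat; use `n_chains=3` for convergence runs.
* The generator's realism is bounded by the model's own assumptions (see
  above); conclusions about empirical data require fitting empirical data.
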