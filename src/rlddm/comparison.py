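"""Candidate-model comparison by DIC and posterior predictive checks.

``fit_candidates`` fits the learning-context, goodness-of-fit and
integrative specifications to one trial log and ranks them by DIC
(lower = better trade-off of likelihood and effective parameters).
``posterior_predictive_check`` simulates whole cohorts from joint
posterior draws — one draw per simulated dataset, so parameter
uncertainty propagates — and compares per-pair choice accuracy and RT
deciles against the observed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import FitResult, MCMCConfig, ModelSpec, build_model, fit_model
from .rl import simulate_session
from .task import TaskDesign, TrialLog, default_design, target_fit_for
from .wfpt import DiffusionParams  # noqa: F401  (re-exported convenience)

__all__ = ["ComparisonTable", "PPCResult", "fit_candidates", "posterior_predictive_check"]

RT_DECILES = np.arange(0.1, 1.0, 0.1)


@dataclass
class ComparisonTable:
    """Ranked DIC table over the three candidate models."""

    rows: pd.DataFrame  # name, dic, p_d, rhat_max, converged, rank
    fits: dict[str, FitResult] = field(default_factory=dict)

    def best(self) -> str:
        return self.rows.loc[self.rows["rank"] == 1, "name"].iloc[0]

    def to_json(self) -> list[dict]:
        return self.rows.to_dict(orient="records")


def fit_candidates(
    trial_log: TrialLog,
    mcmc_config: MCMCConfig | None = None,
    priors: dict | None = None,
) -> ComparisonTable:
    """Fit all three candidate specs and rank them by DIC.

    Candidates that fail convergence checks are annotated in the table
    (``converged`` column) but still ranked.
    """
    cfg = mcmc_config or MCMCConfig()
    fits: dict[str, FitResult] = {}
    rows = []
    for maker in (ModelSpec.context_only, ModelSpec.fit_only, ModelSpec.integrative):
        spec = maker()
        model = build_model(spec, trial_log, priors)
        fit = fit_model(
            model,
            n_samples=cfg.n_samples,
            n_burn=cfg.n_burn,
            n_chains=cfg.n_chains,
            seed=cfg.seed,
        )
        fits[spec.name] = fit
        rows.append(
            {
                "name": spec.name,
                "dic": fit.dic,
                "p_d": fit.p_d,
                "rhat_max": max(fit.rhat.values()) if fit.rhat else np.nan,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows).sort_values("dic", ignore_index=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return ComparisonTable(rows=table, fits=fits)


@dataclass
class PPCResult:
    """Observed vs. simulated summary statistics per pair.

    ``frame`` has one row per (pair, statistic) with the observed value,
    the central 95% band over simulated datasets, and a coverage flag.
    """

    frame: pd.DataFrame
    n_datasets: int
    simulations: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    @property
    def coverage(self) -> float:
        return float(self.frame["covered"].mean())


def _pair_statistics(records: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Per-pair choice accuracy and pooled RT deciles.

    Accuracy is the proportion of target (response == 1) choices — the
    same quantity the task's block criterion evaluates.
    """
    out: dict[tuple[str, str], float] = {}
    for pair, grp in records.groupby("pair", sort=True):
        out[(pair, "accuracy")] = float(grp["response"].mean())
        qs = np.quantile(grp["rt"].to_numpy(), RT_DECILES)
        for d, q in zip(RT_DECILES, qs):
            out[(pair, f"rt_q{int(round(d * 100))}")] = float(q)
    return out


def _design_for_subject(trials: pd.DataFrame, design_template: dict | None) -> TaskDesign:
    """Rebuild a subject's session design from their logged trials."""
    template = dict(design_template or {})
    context = trials["context"].iloc[0]
    pairs = set(trials["pair"])
    n_pair_sets = 2 if any(p.endswith(("-F", "-M")) for p in pairs) else 1
    # counterbalance group follows from the fit level of any female target
    female_pair = next((p for p in sorted(pairs) if not p.endswith("-M")), None)
    fit = trials.loc[trials["pair"] == female_pair, "fit_of_target"].iloc[0]
    sex = "female"
    if n_pair_sets == 1 and female_pair is None:
        sex = "male"
    cb = 1 if target_fit_for(sex, 1) == fit else 2
    return default_design(
        learning_context=context,
        counterbalance_group=cb,
        n_pair_sets=n_pair_sets,
        **template,
    )


def posterior_predictive_check(
    fit_result: FitResult,
    trial_log: TrialLog,
    n_datasets: int = 50,
    rng: np.random.Generator | None = None,
    design_template: dict | None = None,
) -> PPCResult:
    """Simulate ``n_datasets`` cohorts from the fitted posterior.

    Each simulated dataset uses one joint posterior draw (a random
    (chain, draw) index), matched subject count and session structure.
    A statistic is *covered* when the observed value falls inside the
    central 95% of its simulated distribution.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    rng = np.random.default_rng(0) if rng is None else rng
    post = fit_result.posterior
    spec = fit_result.model_spec
    records = trial_log.records

    subjects = list(pd.unique(records["subj_idx"]))
    designs = {}
    contexts = {}
    for subj in subjects:
        trials = records[records["subj_idx"] == subj]
        designs[subj] = _design_for_subject(trials, design_template)
        contexts[subj] = trials["context"].iloc[0]

    observed = _pair_statistics(records)
    sims: dict[tuple[str, str], list[float]] = {k: [] for k in observed}

    n_total = post.n_chains * post.n_draws
    for _ in range(n_datasets):
        flat_idx = int(rng.integers(n_total))
        values = {node: arr.reshape(-1)[flat_idx] for node, arr in post.nodes.items()}
        frames = []
        for subj in subjects:
            ctx = contexts[subj]
            params = _subject_parameter_set(spec, values, subj, ctx)
            frames.append(
                simulate_session(params, designs[subj], rng, subj_idx=subj).records
            )
        sim_stats = _pair_statistics(pd.concat(frames, ignore_index=True))
        for k in sims:
            sims[k].append(sim_stats.get(k, np.nan))

    rows = []
    sim_arrays = {}
    for (pair, stat), obs in observed.items():
        arr = np.asarray(sims[(pair, stat)], dtype=float)
        sim_arrays[(pair, stat)] = arr
        lo, hi = np.nanquantile(arr, [0.025, 0.975])
        rows.append(
            {
                "pair": pair,
                "stat": stat,
                "observed": obs,
                "sim_mean": float(np.nanmean(arr)),
                "sim_lo": float(lo),
                "sim_hi": float(hi),
                "covered": bool(lo <= obs <= hi),
            }
        )
    frame = pd.DataFrame(rows)
    return PPCResult(frame=frame, n_datasets=n_datasets, simulations=sim_arrays)


def _subject_parameter_set(spec: ModelSpec, values: dict, subj, context: str):
    from .inference import _to_natural
    from .rl import ParameterSet
    from .task import FITS

    eta, vs, a = {}, {}, {}
    for fit in FITS:
        label = spec.cell_label(context, fit)
        cell = (context, fit)
        eta[cell] = float(_to_natural("eta", values[f"eta[{subj},{label}]"]))
        vs[cell] = float(values[f"v_scaling[{subj},{label}]"])
        a[cell] = float(_to_natural("a", values[f"a[{subj},{label}]"]))
    t0 = float(_to_natural("t0", values[f"t0[{subj}]"]))
    return ParameterSet(eta=eta, v_scaling=vs, a=a, t0=t0)
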