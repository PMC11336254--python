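"""Hierarchical Bayesian estimation of RL-DDM parameters.

Three candidate model specifications let the learning rate (eta), drift
scaling (v_scaling) and boundary separation (a) vary by Learning Context
only, by Goodness-of-Fit only, or by their 2 x 2 crossing; non-decision
time t0 is always subject-level and factor-free.  Group means and SDs per
freed cell partially pool the subject-level parameters.

Sampling runs on unconstrained scales — log-odds for eta, log for a and
t0, natural for v_scaling — with weakly informative priors: normal(0, 2)
group means (normal(1, 2) for v_scaling), half-normal(1) group SDs.  The
kernel is an adaptive Metropolis-within-Gibbs: random-walk updates of
subject-level values (all subjects in parallel, accepted independently —
subjects are conditionally independent given the group level), conjugate
Gibbs draws for group means, random-walk updates of log group SDs, with
proposal scales tuned toward 0.44 acceptance during burn-in only.

Diagnostics follow common hierarchical-MCMC practice: the multi-chain
Gelman–Rubin potential scale reduction statistic and the Deviance
Information Criterion with the posterior-mean plug-in.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .rl import ParameterSet, _wfpt_logpdf
from .task import CONTEXTS, FITS, TrialLog

__all__ = [
    "ModelSpec",
    "PosteriorSamples",
    "FitResult",
    "build_model",
    "run_mcmc",
    "fit_model",
    "gelman_rubin",
    "compute_dic",
    "MCMCConfig",
]

FAMILIES = ("eta", "v_scaling", "a")  # factor-dependent parameter families

MODEL_NAMES = {
    "context_only": "learning-context model",
    "fit_only": "goodness-of-fit model",
    "context_by_fit": "integrative model",
}


@dataclass(frozen=True)
class ModelSpec:
    """Which experimental factors free the RL-DDM parameters.

    All of eta, v_scaling and a share the same factor dependence within a
    spec; t0 never varies by factor.  Exactly three named specs exist.
    """

    dependence: str  # "context_only" | "fit_only" | "context_by_fit"

    def __post_init__(self) -> None:
        if self.dependence not in MODEL_NAMES:
            raise ValueError(f"dependence must be one of {sorted(MODEL_NAMES)}")

    @property
    def name(self) -> str:
        return MODEL_NAMES[self.dependence]

    @classmethod
    def context_only(cls) -> "ModelSpec":
        return cls("context_only")

    @classmethod
    def fit_only(cls) -> "ModelSpec":
        return cls("fit_only")

    @classmethod
    def integrative(cls) -> "ModelSpec":
        return cls("context_by_fit")

    @classmethod
    def by_name(cls, key: str) -> "ModelSpec":
        aliases = {
            "context": "context_only", "context_only": "context_only",
            "fit": "fit_only", "fit_only": "fit_only",
            "integrative": "context_by_fit", "context_by_fit": "context_by_fit",
        }
        if key not in aliases:
            raise ValueError(f"unknown model {key!r}")
        return cls(aliases[key])

    def cells(self) -> list[str]:
        """Global cell labels for the freed parameter families."""
        if self.dependence == "context_only":
            return list(CONTEXTS)
        if self.dependence == "fit_only":
            return list(FITS)
        return [f"{c}:{f}" for c in CONTEXTS for f in FITS]

    def cell_label(self, context: str, fit: str) -> str:
        if self.dependence == "context_only":
            return context
        if self.dependence == "fit_only":
            return fit
        return f"{context}:{fit}"

    def subject_cells(self, context: str) -> list[str]:
        """Cells a subject in ``context`` can occupy, ordered by FITS."""
        if self.dependence == "context_only":
            return [context]
        if self.dependence == "fit_only":
            return list(FITS)
        return [f"{context}:{f}" for f in FITS]


# --- transforms between sampling and natural scales ----------------------

def _to_natural(fam: str, x):
    if fam == "eta":
        return 1.0 / (1.0 + np.exp(-x))
    if fam in ("a", "t0"):
        return np.exp(x)
    return x


def _to_sampling(fam: str, x):
    if fam == "eta":
        return np.log(x / (1.0 - x))
    if fam in ("a", "t0"):
        return np.log(x)
    return x


DEFAULT_PRIORS = {
    "mu_mean": {"eta": 0.0, "v_scaling": 1.0, "a": 0.0, "t0": -1.0},
    "mu_sd": {"eta": 2.0, "v_scaling": 2.0, "a": 2.0, "t0": 2.0},
    "sigma_scale": {"eta": 1.0, "v_scaling": 1.0, "a": 1.0, "t0": 1.0},
}


@njit(cache=True)
def _cohort_loglik_kernel(ptr, pair_idx, cell_idx, response, feedback, rt,
                          n_pairs, eta, vs, a, t0, q_init):
    """Per-subject session log-likelihoods for the whole cohort."""
    S = ptr.shape[0] - 1
    out = np.empty(S)
    for s in range(S):
        q = np.full((n_pairs[s], 2), q_init)
        ll = 0.0
        bad = False
        for i in range(ptr[s], ptr[s + 1]):
            if rt[i] <= t0[s]:
                bad = True
                break
            p = pair_idx[i]
            c = cell_idx[i]
            v = vs[s, c] * (q[p, 0] - q[p, 1])
            ll += _wfpt_logpdf(rt[i], response[i], v, a[s, c], 0.5, t0[s])
            j = 0 if response[i] == 1 else 1
            q[p, j] += eta[s, c] * (feedback[i] - q[p, j])
        out[s] = -np.inf if bad else ll
    return out


class RLDDMModel:
    """Prepared model graph: data arrays, cell maps, priors, likelihood."""

    def __init__(self, spec: ModelSpec, trial_log: TrialLog, priors: dict):
        self.spec = spec
        self.priors = priors
        records = trial_log.records
        self.subjects = list(pd.unique(records["subj_idx"]))
        S = len(self.subjects)
        self.cells = spec.cells()
        cell_index = {c: i for i, c in enumerate(self.cells)}

        self.subject_context = {}
        ptr = [0]
        pair_idx, cell_idx, response, feedback, rt = [], [], [], [], []
        self.n_pairs = np.empty(S, dtype=np.int64)
        self.min_rt = np.empty(S)
        # local cells per subject (shared by all freed families)
        self.K = 1 if spec.dependence == "context_only" else 2
        self.cell_map = np.empty((S, self.K), dtype=np.int64)
        self.subject_pairs: list[list[str]] = []

        for s, subj in enumerate(self.subjects):
            trials = records[records["subj_idx"] == subj].sort_values("trial")
            ctx = trials["context"].iloc[0]
            self.subject_context[subj] = ctx
            locs = spec.subject_cells(ctx)
            self.cell_map[s] = [cell_index[c] for c in locs]
            loc_index = {c: i for i, c in enumerate(locs)}
            pairs = list(pd.unique(trials["pair"]))
            self.subject_pairs.append(pairs)
            pmap = {p: i for i, p in enumerate(pairs)}
            self.n_pairs[s] = len(pairs)
            self.min_rt[s] = trials["rt"].min()
            pair_idx.append(trials["pair"].map(pmap).to_numpy(np.int64))
            trial_cells = [
                loc_index[spec.cell_label(ctx, f)] for f in trials["fit_of_target"]
            ]
            cell_idx.append(np.asarray(trial_cells, dtype=np.int64))
            response.append(trials["response"].to_numpy(np.int64))
            feedback.append(trials["feedback"].to_numpy(np.int64))
            rt.append(trials["rt"].to_numpy(np.float64))
            ptr.append(ptr[-1] + len(trials))

            counts = np.bincount(cell_idx[-1], minlength=self.K)
            for k in range(self.K):
                if counts[k] < 2:
                    warnings.warn(
                        f"subject {subj!r} has {counts[k]} trial(s) in cell "
                        f"{locs[k]!r}; retained — partial pooling absorbs it",
                        stacklevel=3,
                    )

        self.ptr = np.asarray(ptr, dtype=np.int64)
        self.pair_idx = np.concatenate(pair_idx)
        self.cell_idx = np.concatenate(cell_idx)
        self.response = np.concatenate(response)
        self.feedback = np.concatenate(feedback)
        self.rt = np.concatenate(rt)
        self.n_trials = int(self.ptr[-1])

        # every global cell must be populated somewhere in the cohort
        present = np.zeros(len(self.cells), dtype=bool)
        for s in range(S):
            present[self.cell_map[s]] = True
        if not present.all():
            empty = [c for c, ok in zip(self.cells, present) if not ok]
            raise ValueError(
                f"model spec {spec.name!r} has cohort-wide empty cells {empty}; "
                "the factor cannot be freed on this log"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def loglik_subjects(self, theta_nat: dict[str, np.ndarray]) -> np.ndarray:
        """Per-subject log-likelihood; theta_nat holds natural-scale arrays
        eta/v_scaling/a of shape (S, K) and t0 of shape (S,)."""
        return _cohort_loglik_kernel(
            self.ptr, self.pair_idx, self.cell_idx, self.response, self.feedback,
            self.rt, self.n_pairs, theta_nat["eta"], theta_nat["v_scaling"],
            theta_nat["a"], theta_nat["t0"], 0.5,
        )

    def node_names(self) -> list[str]:
        names = []
        for fam in FAMILIES:
            for c in self.cells:
                names += [f"mu_{fam}[{c}]", f"sigma_{fam}[{c}]"]
        names += ["mu_t0", "sigma_t0"]
        for s, subj in enumerate(self.subjects):
            ctx = self.subject_context[subj]
            for fam in FAMILIES:
                for c in self.spec.subject_cells(ctx):
                    names.append(f"{fam}[{subj},{c}]")
            names.append(f"t0[{subj}]")
        return names

    def theta_natural_from_values(self, values: dict[str, float]) -> dict[str, np.ndarray]:
        """Assemble natural-scale parameter arrays from a node-value map."""
        S, K = self.n_subjects, self.K
        out = {fam: np.empty((S, K)) for fam in FAMILIES}
        out["t0"] = np.empty(S)
        for s, subj in enumerate(self.subjects):
            ctx = self.subject_context[subj]
            for fam in FAMILIES:
                for k, c in enumerate(self.spec.subject_cells(ctx)):
                    out[fam][s, k] = _to_natural(fam, values[f"{fam}[{subj},{c}]"])
            out["t0"][s] = _to_natural("t0", values[f"t0[{subj}]"])
        return out

    def loglik_at(self, values: dict[str, float]) -> float:
        """Total data log-likelihood at sampling-scale node values."""
        return float(np.sum(self.loglik_subjects(self.theta_natural_from_values(values))))

    def parameter_set(self, values: dict[str, float], subj) -> ParameterSet:
        """Natural-scale ParameterSet for one subject (both fit cells)."""
        ctx = self.subject_context[subj]
        eta, vs, a = {}, {}, {}
        for fit in FITS:
            label = self.spec.cell_label(ctx, fit)
            cell = (ctx, fit)
            eta[cell] = float(_to_natural("eta", values[f"eta[{subj},{label}]"]))
            vs[cell] = float(values[f"v_scaling[{subj},{label}]"])
            a[cell] = float(_to_natural("a", values[f"a[{subj},{label}]"]))
        t0 = float(_to_natural("t0", values[f"t0[{subj}]"]))
        return ParameterSet(eta=eta, v_scaling=vs, a=a, t0=t0)


def build_model(
    model_spec: ModelSpec, trial_log: TrialLog, priors: dict | None = None
) -> RLDDMModel:
    """Prepare the hierarchical model graph for a validated trial log.

    The likelihood is the session log-likelihood of :mod:`rlddm.rl` with
    response coding "upper boundary = positively reinforced face".
    """
    merged = {k: dict(v) for k, v in DEFAULT_PRIORS.items()}
    for key, sub in (priors or {}).items():
        merged.setdefault(key, {}).update(sub)
    return RLDDMModel(model_spec, trial_log, merged)


@dataclass
class PosteriorSamples:
    """MCMC draws per node, shape (chains, draws), on sampling scales."""

    nodes: dict[str, np.ndarray]
    deviance: np.ndarray  # (chains, draws) of -2 * data log-likelihood
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.nodes.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.nodes.values())).shape[1]

    def get(self, node: str) -> np.ndarray:
        return self.nodes[node]

    def stacked(self, node: str) -> np.ndarray:
        """All chains concatenated into one draw vector."""
        return self.nodes[node].reshape(-1)

    @staticmethod
    def _family_of(node: str) -> str:
        base = node.split("[")[0]
        for prefix in ("mu_", "sigma_"):
            if base.startswith(prefix):
                base = base[len(prefix):]
        return base

    def natural(self, node: str) -> np.ndarray:
        """Natural-scale view of a location node's stacked draws.

        Group means map through the family transform (giving the group
        median on the natural scale); SD nodes are returned unchanged.
        """
        draws = self.stacked(node)
        if node.split("[")[0].startswith("sigma_"):
            return draws
        return _to_natural(self._family_of(node), draws)

    def mean_values(self) -> dict[str, float]:
        """Posterior means on sampling scales (the DIC plug-in point)."""
        return {k: float(v.mean()) for k, v in self.nodes.items()}

    def to_frame(self) -> pd.DataFrame:
        """Long-format (chain, draw, node, value) table."""
        rows = []
        for node, arr in self.nodes.items():
            for ch in range(arr.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": ch,
                            "draw": np.arange(arr.shape[1]),
                            "node": node,
                            "value": arr[ch],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


@dataclass
class FitResult:
    """A fitted candidate: posterior draws, DIC, convergence diagnostics."""

    posterior: PosteriorSamples
    dic: float
    p_d: float
    rhat: dict[str, float] | None
    model_spec: ModelSpec
    flags: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        if self.rhat is None:
            return not self.flags.get("stuck_nodes")
        return max(self.rhat.values()) <= 1.01 and not self.flags.get("stuck_nodes")

    def summary(self) -> dict:
        out = {
            "model": self.model_spec.name,
            "dic": self.dic,
            "p_d": self.p_d,
            "flags": self.flags,
        }
        if self.rhat is not None:
            out["rhat_max"] = max(self.rhat.values())
        return out

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; defaults follow the study's estimation protocol
    (10,000 samples, 5,000 burn, single chain).  Convergence checks use
    3 chains of 5,000 samples and 500 burn."""

    n_samples: int = 10_000
    n_burn: int = 5_000
    n_chains: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_samples > self.n_burn >= 0:
            raise ValueError("need n_samples > n_burn >= 0")


_INIT_STEP = {"eta": 0.4, "v_scaling": 0.5, "a": 0.15, "t0": 0.05}


def _run_chain(model: RLDDMModel, n_samples: int, n_burn: int, rng: np.random.Generator):
    S, K, C = model.n_subjects, model.K, len(model.cells)
    spec_fams = list(FAMILIES)
    pri = model.priors

    # ---- initialization -------------------------------------------------
    theta = {
        "eta": np.full((S, K), _to_sampling("eta", 0.2)),
        "v_scaling": np.full((S, K), 2.0),
        "a": np.full((S, K), np.log(1.5)),
        # t0 capped below each subject's fastest response to avoid -inf
        "t0": np.log(np.minimum(0.35, 0.95 * model.min_rt)),
    }
    for fam in spec_fams + ["t0"]:
        theta[fam] = theta[fam] + 0.01 * rng.standard_normal(theta[fam].shape)
    theta["t0"] = theta["t0"].reshape(S, 1)
    mu = {fam: np.zeros(C) for fam in spec_fams}
    sigma = {fam: np.full(C, 0.5) for fam in spec_fams}
    for fam in spec_fams:
        for c in range(C):
            mask = model.cell_map == c
            mu[fam][c] = theta[fam][mask].mean()
    mu["t0"] = np.array([theta["t0"].mean()])
    sigma["t0"] = np.array([0.3])

    steps = {fam: np.full((S, K), _INIT_STEP[fam]) for fam in spec_fams}
    steps["t0"] = np.full((S, 1), _INIT_STEP["t0"])
    sig_steps = {fam: np.full(C, 0.3) for fam in spec_fams}
    sig_steps["t0"] = np.full(1, 0.3)
    acc = {fam: np.zeros_like(steps[fam]) for fam in steps}
    sig_acc = {fam: np.zeros_like(sig_steps[fam]) for fam in sig_steps}

    def natural():
        return {
            "eta": _to_natural("eta", theta["eta"]),
            "v_scaling": theta["v_scaling"].copy(),
            "a": _to_natural("a", theta["a"]),
            "t0": _to_natural("t0", theta["t0"][:, 0]),
        }

    nat = natural()
    ll_cur = model.loglik_subjects(nat)
    if not np.all(np.isfinite(ll_cur)):
        raise RuntimeError("non-finite log-likelihood at initialization")

    fam_cells = {fam: (model.cell_map if fam != "t0" else np.zeros((S, 1), np.int64))
                 for fam in list(spec_fams) + ["t0"]}

    n_keep = n_samples - n_burn
    draws = {fam: np.empty((n_keep,) + theta[fam].shape) for fam in theta}
    mu_draws = {fam: np.empty((n_keep, mu[fam].shape[0])) for fam in mu}
    sig_draws = {fam: np.empty((n_keep, sigma[fam].shape[0])) for fam in sigma}
    dev = np.empty(n_keep)

    ADAPT_WINDOW = 25
    post_burn_acc = {fam: np.zeros_like(steps[fam]) for fam in steps}

    for it in range(n_samples):
        adapting = it < n_burn
        # ---- subject-level random-walk updates --------------------------
        for fam in list(spec_fams) + ["t0"]:
            Kf = theta[fam].shape[1]
            for k in range(Kf):
                cur = theta[fam][:, k].copy()
                prop = cur + steps[fam][:, k] * rng.standard_normal(S)
                theta[fam][:, k] = prop
                nat_prop = natural()
                ll_prop = model.loglik_subjects(nat_prop)
                cells_k = fam_cells[fam][:, k]
                mu_k = mu[fam][cells_k]
                sig_k = sigma[fam][cells_k]
                dprior = (cur - mu_k) ** 2 / (2 * sig_k**2) - (prop - mu_k) ** 2 / (2 * sig_k**2)
                logr = ll_prop - ll_cur + dprior
                accept = np.log(rng.random(S)) < logr
                theta[fam][:, k] = np.where(accept, prop, cur)
                ll_cur = np.where(accept, ll_prop, ll_cur)
                acc[fam][:, k] += accept
                if not adapting:
                    post_burn_acc[fam][:, k] += accept
        # ---- group means: conjugate Gibbs --------------------------------
        for fam in list(spec_fams) + ["t0"]:
            m0 = pri["mu_mean"][fam]
            s0 = pri["mu_sd"][fam]
            for c in range(mu[fam].shape[0]):
                mask = fam_cells[fam] == c
                x = theta[fam][mask]
                n = x.size
                prec = 1.0 / s0**2 + n / sigma[fam][c] ** 2
                mean = (m0 / s0**2 + x.sum() / sigma[fam][c] ** 2) / prec
                mu[fam][c] = mean + rng.standard_normal() / np.sqrt(prec)
        # ---- group SDs: random walk on log sigma -------------------------
        for fam in list(spec_fams) + ["t0"]:
            hs = pri["sigma_scale"][fam]
            for c in range(sigma[fam].shape[0]):
                mask = fam_cells[fam] == c
                x = theta[fam][mask]
                n = x.size
                cur_s = sigma[fam][c]
                prop_s = cur_s * np.exp(sig_steps[fam][c] * rng.standard_normal())
                ssq = np.sum((x - mu[fam][c]) ** 2)

                def logp(s):
                    # normal likelihood of subject values + half-normal prior
                    # + log-Jacobian of the log transform
                    return -n * np.log(s) - ssq / (2 * s**2) - s**2 / (2 * hs**2) + np.log(s)

                if np.log(rng.random()) < logp(prop_s) - logp(cur_s):
                    sigma[fam][c] = prop_s
                    sig_acc[fam][c] += 1
        # ---- adaptation during burn-in -----------------------------------
        if adapting and (it + 1) % ADAPT_WINDOW == 0:
            gamma = min(0.5, 5.0 / np.sqrt(it + 1.0))
            for fam in steps:
                rate = acc[fam] / ADAPT_WINDOW
                steps[fam] *= np.exp(gamma * (rate - 0.44))
                acc[fam][:] = 0.0
                srate = sig_acc[fam] / ADAPT_WINDOW
                sig_steps[fam] *= np.exp(gamma * (srate - 0.44))
                sig_acc[fam][:] = 0.0
        if not adapting:
            j = it - n_burn
            for fam in theta:
                draws[fam][j] = theta[fam]
            for fam in mu:
                mu_draws[fam][j] = mu[fam]
                sig_draws[fam][j] = sigma[fam]
            dev[j] = -2.0 * ll_cur.sum()

    post_rate = {fam: post_burn_acc[fam] / max(n_keep, 1) for fam in post_burn_acc}
    return draws, mu_draws, sig_draws, dev, post_rate


def run_mcmc(
    model: RLDDMModel,
    n_samples: int = 10_000,
    n_burn: int = 5_000,
    n_chains: int = 1,
    seed: int = 0,
) -> PosteriorSamples:
    """Sample the hierarchical posterior; (n_samples - n_burn) retained
    draws per chain per node.  Identical seeds yield identical draws.

    Chains whose post-burn subject-level acceptance collapses (< 2%) are
    flagged in ``meta['stuck_nodes']``, never silently dropped.
    """
    cfg = MCMCConfig(n_samples=n_samples, n_burn=n_burn, n_chains=n_chains, seed=seed)
    S = model.n_subjects
    n_keep = n_samples - n_burn
    child_seeds = np.random.SeedSequence(seed).spawn(n_chains)

    node_arrays: dict[str, np.ndarray] = {}
    deviance = np.empty((n_chains, n_keep))
    stuck: list[str] = []

    for ch in range(n_chains):
        rng = np.random.default_rng(child_seeds[ch])
        draws, mu_draws, sig_draws, dev, post_rate = _run_chain(
            model, n_samples, n_burn, rng
        )
        deviance[ch] = dev

        def put(name, vec):
            node_arrays.setdefault(name, np.empty((n_chains, n_keep)))[ch] = vec

        for fam in FAMILIES:
            for ci, c in enumerate(model.cells):
                put(f"mu_{fam}[{c}]", mu_draws[fam][:, ci])
                put(f"sigma_{fam}[{c}]", sig_draws[fam][:, ci])
        put("mu_t0", mu_draws["t0"][:, 0])
        put("sigma_t0", sig_draws["t0"][:, 0])
        for s, subj in enumerate(model.subjects):
            ctx = model.subject_context[subj]
            for fam in FAMILIES:
                for k, c in enumerate(model.spec.subject_cells(ctx)):
                    put(f"{fam}[{subj},{c}]", draws[fam][:, s, k])
            put(f"t0[{subj}]", draws["t0"][:, s, 0])

        for fam, rate in post_rate.items():
            idx = np.argwhere(rate < 0.02)
            for s, k in idx:
                stuck.append(f"chain {ch}: {fam}[{model.subjects[s]}] local cell {k}")

    meta = {
        "n_samples": n_samples,
        "n_burn": n_burn,
        "n_chains": n_chains,
        "thin": 1,
        "seed": seed,
        "model": model.spec.name,
        "stuck_nodes": stuck,
    }
    return PosteriorSamples(nodes=node_arrays, deviance=deviance, meta=meta)


def gelman_rubin(posterior: PosteriorSamples) -> dict[str, float]:
    """Multi-chain Gelman–Rubin potential scale reduction per node.

    Classic (split-free) form: R = sqrt(((n-1)/n W + (1+1/m) B/n) / W).
    Zero-variance nodes (chains stuck at one constant) return 1 by
    convention.  Requires at least two chains.
    """
    if posterior.n_chains < 2:
        raise ValueError(
            "Gelman-Rubin needs >= 2 chains; rerun the sampler with the "
            "convergence configuration (3 chains of 5,000 samples, 500 burn)"
        )
    out = {}
    for node, arr in posterior.nodes.items():
        m, n = arr.shape
        W = arr.var(axis=1, ddof=1).mean()
        B_over_n = arr.mean(axis=1).var(ddof=1)
        if W == 0.0 and B_over_n == 0.0:
            out[node] = 1.0
            continue
        if W == 0.0:
            out[node] = np.inf
            continue
        vhat = (n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n
        out[node] = float(np.sqrt(vhat / W))
    return out


def compute_dic(posterior: PosteriorSamples, loglik_fn) -> tuple[float, float]:
    """Deviance Information Criterion with posterior-mean plug-in.

    p_d = mean(D) - D(theta_bar) on sampling scales; DIC = mean(D) + p_d.
    ``loglik_fn`` maps a {node: value} dict to the total data
    log-likelihood (e.g. ``model.loglik_at``).  Non-finite deviance draws
    are excluded (over 1% non-finite is an error).
    """
    dev = posterior.deviance.reshape(-1)
    finite = np.isfinite(dev)
    n_bad = int((~finite).sum())
    if n_bad > 0.01 * dev.size:
        raise ValueError(f"{n_bad}/{dev.size} non-finite deviance draws")
    mean_dev = float(dev[finite].mean())
    plug_in_dev = -2.0 * float(loglik_fn(posterior.mean_values()))
    p_d = mean_dev - plug_in_dev
    return mean_dev + p_d, p_d


def fit_model(
    model: RLDDMModel,
    n_samples: int = 10_000,
    n_burn: int = 5_000,
    n_chains: int = 1,
    seed: int = 0,
) -> FitResult:
    """Run the sampler and package posterior, DIC and diagnostics."""
    posterior = run_mcmc(model, n_samples, n_burn, n_chains, seed)
    dic, p_d = compute_dic(posterior, model.loglik_at)
    rhat = gelman_rubin(posterior) if n_chains >= 2 else None
    flags = {}
    if posterior.meta["stuck_nodes"]:
        flags["stuck_nodes"] = posterior.meta["stuck_nodes"]
    if rhat is not None and max(rhat.values()) > 1.01:
        flags["rhat_exceeds_1.01"] = True
    return FitResult(
        posterior=posterior, dic=dic, p_d=p_d, rhat=rhat,
        model_spec=model.spec, flags=flags,
    )
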