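"""Reinforcement-learning layer of the RL-DDM.

Each face pair carries two expected values (target and non-target face),
initialized at 0.5 and updated after every choice by the instrumental
delta rule ``q <- q + eta * (feedback - q)`` — only the chosen face's
value moves.  The trial's drift rate is the scaled value difference
``v = v_scaling * (q_target - q_other)``, signed toward the upper
(positively reinforced) boundary, so early trials with undifferentiated
values produce slow, near-random choices and learning speeds both
accuracy and response times.

Provides forward simulation of full PST sessions (blockwise accuracy
termination included) and the session log-likelihood that the Bayesian
machinery uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .task import FITS, LOG_COLUMNS, TaskDesign, TrialLog, check_block_criterion
from .wfpt import _sample_fpt_kernel, _wfpt_logpdf

__all__ = [
    "ParameterSet",
    "QState",
    "update_q",
    "trial_drift",
    "simulate_session",
    "session_loglik",
    "session_loglik_detail",
]

Cell = tuple[str, str]  # (learning_context, goodness_of_fit)


@dataclass(frozen=True)
class ParameterSet:
    """Subject-level RL-DDM parameters per (context, fit) condition cell.

    ``eta``, ``v_scaling`` and ``a`` map condition cells to values;
    ``t0`` is shared across cells.  A model that constrains a parameter
    across a factor simply repeats the value over the collapsed cells.
    """

    eta: dict[Cell, float]
    v_scaling: dict[Cell, float]
    a: dict[Cell, float]
    t0: float

    def __post_init__(self) -> None:
        for cell, e in self.eta.items():
            if not 0.0 < e < 1.0:
                raise ValueError(f"eta{cell} = {e} outside (0, 1)")
        for cell, a in self.a.items():
            if a <= 0.0:
                raise ValueError(f"a{cell} = {a} must be > 0")
        if self.t0 < 0.0:
            raise ValueError("t0 must be >= 0")
        if not (set(self.eta) == set(self.v_scaling) == set(self.a)):
            raise ValueError("eta, v_scaling and a must cover the same cells")

    def cells(self) -> list[Cell]:
        return sorted(self.eta)


class QState:
    """Pair-local expected values: one (q_target, q_other) row per pair."""

    def __init__(self, n_pairs: int, q_init: float = 0.5):
        self.q = np.full((n_pairs, 2), q_init, dtype=float)

    def copy(self) -> "QState":
        new = QState(self.q.shape[0])
        new.q = self.q.copy()
        return new


def update_q(q: float, feedback: int, eta: float) -> float:
    """Delta-rule update of the chosen option's expected value."""
    if not 0.0 < eta < 1.0:
        raise ValueError("eta must lie in (0, 1)")
    if feedback not in (0, 1):
        raise ValueError("feedback must be 0 or 1")
    return q + eta * (feedback - q)


def trial_drift(qstate: QState, pair: int, v_scaling: float) -> float:
    """Drift toward the upper boundary: scaled target/other value gap."""
    return v_scaling * (qstate.q[pair, 0] - qstate.q[pair, 1])


@njit(cache=True)
def _simulate_block_kernel(
    rng, seq, q, p_rew, cell_of_pair, eta_c, vs_c, a_c, t0, dt, force, sched
):
    n = seq.shape[0]
    response = np.empty(n, dtype=np.int64)
    rt = np.empty(n, dtype=np.float64)
    feedback = np.empty(n, dtype=np.int64)
    for i in range(n):
        p = seq[i]
        c = cell_of_pair[p]
        v = vs_c[c] * (q[p, 0] - q[p, 1])
        b, t = _sample_fpt_kernel(rng, 1, v, a_c[c], 0.5, t0, dt)
        resp = b[0] if force < 0 else force
        response[i] = resp
        rt[i] = t[0]
        if sched[i] < 0:
            target_correct = rng.random() < p_rew[p]
        else:
            target_correct = sched[i] == 1
        fb = 1 if (target_correct == (resp == 1)) else 0
        feedback[i] = fb
        j = 0 if resp == 1 else 1
        q[p, j] += eta_c[c] * (fb - q[p, j])
    return response, rt, feedback


@njit(cache=True)
def _session_loglik_kernel(pair_idx, cell_idx, response, feedback, rt, n_pairs,
                           eta_c, vs_c, a_c, t0, q_init):
    """Replay the Q trajectory from the logged feedback and sum trial logpdfs."""
    q = np.full((n_pairs, 2), q_init)
    ll = 0.0
    n_bad = 0
    for i in range(pair_idx.shape[0]):
        p = pair_idx[i]
        c = cell_idx[i]
        if rt[i] <= t0:
            n_bad += 1
            continue
        v = vs_c[c] * (q[p, 0] - q[p, 1])
        ll += _wfpt_logpdf(rt[i], response[i], v, a_c[c], 0.5, t0)
        j = 0 if response[i] == 1 else 1
        q[p, j] += eta_c[c] * (feedback[i] - q[p, j])
    if n_bad > 0:
        return -np.inf, n_bad
    return ll, 0


def _param_arrays(params: ParameterSet, design: TaskDesign):
    """Flatten a ParameterSet for the subject's context into cell arrays.

    Local cells are ordered by FITS = (high, low); every pair maps to the
    local cell of its target's fit level.
    """
    ctx = design.learning_context
    cells = [(ctx, fit) for fit in FITS]
    for cell in cells:
        if cell not in params.eta:
            raise KeyError(f"ParameterSet lacks cell {cell}")
    eta_c = np.array([params.eta[c] for c in cells])
    vs_c = np.array([params.v_scaling[c] for c in cells])
    a_c = np.array([params.a[c] for c in cells])
    cell_of_pair = np.array([FITS.index(p.target_fit) for p in design.pairs], dtype=np.int64)
    return eta_c, vs_c, a_c, cell_of_pair


def simulate_session(
    params: ParameterSet,
    design: TaskDesign,
    rng: np.random.Generator,
    subj_idx=0,
    force_response: int | None = None,
    feedback_schedule: str = "bernoulli",
    dt: float = 1e-3,
) -> TrialLog:
    """Simulate one subject's PST session under the RL-DDM.

    Per trial the drift follows the current expected values, (choice, RT)
    are drawn from the diffusion's first-passage law, feedback is Bernoulli
    in the pair's reward probability (or an exact-proportion shuffled
    schedule with ``feedback_schedule="exact"``), and the chosen face's
    value is updated.  Blocks end via the accuracy criterion; the session
    is capped at ``design.trial_ceiling`` trials.

    ``force_response`` overrides the diffusion's choice (testing hook for
    agents that always pick one face).
    """
    if feedback_schedule not in ("bernoulli", "exact"):
        raise ValueError("feedback_schedule must be 'bernoulli' or 'exact'")
    eta_c, vs_c, a_c, cell_of_pair = _param_arrays(params, design)
    p_rew = np.array([p.p_reward_target for p in design.pairs])
    n_pairs = design.n_pairs
    reps = design.block_length // n_pairs
    q = np.full((n_pairs, 2), 0.5)
    force = -1 if force_response is None else int(force_response)

    frames = []
    trial_no = 1
    for block in range(1, design.max_blocks + 1):
        seq = np.repeat(np.arange(n_pairs), reps)
        rng.shuffle(seq)
        if feedback_schedule == "exact":
            sched = np.empty(design.block_length, dtype=np.int8)
            plans = []
            for p in design.pairs:
                n_corr = int(round(p.p_reward_target * reps))
                plan = np.concatenate(
                    [np.ones(n_corr, dtype=np.int8), np.zeros(reps - n_corr, dtype=np.int8)]
                )
                rng.shuffle(plan)
                plans.append(plan)
            counters = np.zeros(n_pairs, dtype=int)
            for i, pidx in enumerate(seq):
                sched[i] = plans[pidx][counters[pidx]]
                counters[pidx] += 1
        else:
            sched = np.full(design.block_length, -1, dtype=np.int8)

        response, rt, feedback = _simulate_block_kernel(
            rng, seq, q, p_rew, cell_of_pair, eta_c, vs_c, a_c, params.t0, dt, force, sched
        )
        frame = pd.DataFrame(
            {
                "subj_idx": subj_idx,
                "trial": np.arange(trial_no, trial_no + design.block_length),
                "block": block,
                "pair": [design.pairs[i].pair_id for i in seq],
                "response": response,
                "rt": rt,
                "feedback": feedback,
                "context": design.learning_context,
                "fit_of_target": [design.pairs[i].target_fit for i in seq],
            }
        )
        frames.append(frame)
        trial_no += design.block_length
        decision, _ = check_block_criterion(frame, design)
        if decision == "stop":
            break

    records = pd.concat(frames, ignore_index=True)[LOG_COLUMNS]
    return TrialLog(records=records, metadata={"design": design, "subj_idx": subj_idx})


def _trial_arrays(trials: pd.DataFrame, design: TaskDesign):
    pair_lookup = {pid: i for i, pid in enumerate(design.pair_ids)}
    pair_idx = trials["pair"].map(pair_lookup).to_numpy(dtype=np.int64)
    if np.any(pd.isna(trials["pair"].map(pair_lookup))):
        raise KeyError("trial log contains pairs absent from the design")
    fit_lookup = {pid: FITS.index(design.pair(pid).target_fit) for pid in design.pair_ids}
    cell_idx = trials["pair"].map(fit_lookup).to_numpy(dtype=np.int64)
    return (
        pair_idx,
        cell_idx,
        trials["response"].to_numpy(dtype=np.int64),
        trials["feedback"].to_numpy(dtype=np.int64),
        trials["rt"].to_numpy(dtype=np.float64),
    )


def session_loglik_detail(
    trials: pd.DataFrame, params: ParameterSet, design: TaskDesign, q_init: float = 0.5
) -> tuple[float, int]:
    """Session log-likelihood plus the count of invalid (rt <= t0) trials.

    Any invalid trial makes the value ``-inf`` (a rejection for samplers),
    with the count as the diagnostic; no exception is raised.
    """
    trials = trials.sort_values("trial")
    eta_c, vs_c, a_c, _ = _param_arrays(params, design)
    arrays = _trial_arrays(trials, design)
    ll, n_bad = _session_loglik_kernel(
        *arrays, design.n_pairs, eta_c, vs_c, a_c, params.t0, q_init
    )
    return float(ll), int(n_bad)


def session_loglik(
    trials: pd.DataFrame, params: ParameterSet, design: TaskDesign, q_init: float = 0.5
) -> float:
    """Log-likelihood of one subject's chronologically ordered session.

    Sums the Wiener FPT log-density over trials, with the drift of each
    trial rebuilt by replaying the delta rule on the logged feedback
    sequence.  Deterministic: replaying the same log twice is bit-identical.
    """
    return session_loglik_detail(trials, params, design, q_init)[0]
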