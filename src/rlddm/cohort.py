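"""Synthetic cohorts emulating the 2 x 2 stereotype-learning study design.

Generates trial-level data for a cohort with a between-subject Learning
Context factor (stereotypic vs. counter-stereotypic) and a within-subject
Goodness-of-Stereotype-Fit factor (high vs. low fit of each pair's
positively reinforced face).  Subject-level RL-DDM parameters are drawn
from group-level normal distributions on sampling-compatible scales
(log-odds for the learning rate, log for boundary separation and
non-decision time, natural for the drift scaling) and each subject plays
one full PST session through :func:`rlddm.rl.simulate_session`.

The named presets encode *synthetic* group truths: the direction of the
cell differences follows the surprise-driven learning account (unexpected
targets learned faster), but the magnitudes are generator choices made for
testability, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rl import Cell, ParameterSet, simulate_session
from .task import CONTEXTS, FITS, LOG_COLUMNS, TrialLog, default_design

__all__ = [
    "GroupTruth",
    "generate_cohort",
    "preset_expt1",
    "preset_expt2",
    "preset_context_only",
]

ALL_CELLS: tuple[Cell, ...] = tuple((c, f) for c in CONTEXTS for f in FITS)


def logit(p):
    return np.log(p / (1.0 - p))


def expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class GroupTruth:
    """Group-level generative truth on sampling scales.

    Each entry maps a (context, fit) cell to ``(mean, sd)`` of the
    between-subject normal distribution on that parameter's sampling scale:
    log-odds for ``eta``, natural for ``v_scaling``, log for ``a`` and
    ``t0`` (``t0`` has a single cell-free entry).
    """

    eta: dict[Cell, tuple[float, float]]
    v_scaling: dict[Cell, tuple[float, float]]
    a: dict[Cell, tuple[float, float]]
    t0: tuple[float, float]
    n_subjects_per_context: int = 40
    seed: int = 0
    name: str = "custom"
    #: generative factor structure; "context_only" ties each subject's two
    #: fit cells to a single draw (the parameter truly ignores fit)
    dependence: str = "context_by_fit"

    def __post_init__(self) -> None:
        if self.dependence not in ("context_only", "fit_only", "context_by_fit"):
            raise ValueError("dependence must be context_only|fit_only|context_by_fit")
        for fam in ("eta", "v_scaling", "a"):
            for cell, (_, sd) in getattr(self, fam).items():
                if sd < 0:
                    raise ValueError(f"{fam}{cell} SD must be >= 0")
                if cell not in ALL_CELLS:
                    raise ValueError(f"unknown cell {cell}")
            if self.dependence == "context_only":
                for ctx in CONTEXTS:
                    if getattr(self, fam)[(ctx, "high")] != getattr(self, fam)[(ctx, "low")]:
                        raise ValueError(
                            f"context_only truth requires equal {fam} cells within context"
                        )
        if self.t0[1] < 0:
            raise ValueError("t0 SD must be >= 0")
        if self.n_subjects_per_context < 1:
            raise ValueError("need at least one subject per context")

    def natural_means(self) -> dict[str, dict | float]:
        """Group means mapped back to the natural parameter scales."""
        return {
            "eta": {c: float(expit(m)) for c, (m, _) in self.eta.items()},
            "v_scaling": {c: float(m) for c, (m, _) in self.v_scaling.items()},
            "a": {c: float(np.exp(m)) for c, (m, _) in self.a.items()},
            "t0": float(np.exp(self.t0[0])),
        }


def _truth_from_natural(eta, vs, a, t0, sds, n, seed, name) -> GroupTruth:
    return GroupTruth(
        eta={c: (float(logit(v)), sds["eta"]) for c, v in eta.items()},
        v_scaling={c: (float(v), sds["v_scaling"]) for c, v in vs.items()},
        a={c: (float(np.log(v)), sds["a"]) for c, v in a.items()},
        t0=(float(np.log(t0)), sds["t0"]),
        n_subjects_per_context=n,
        seed=seed,
        name=name,
    )


#: between-subject SDs on sampling scales, shared by both presets
_PRESET_SDS = {"eta": 0.30, "v_scaling": 0.50, "a": 0.15, "t0": 0.10}


def preset_expt1(n_subjects_per_context: int = 40, seed: int = 20240001) -> GroupTruth:
    """Occupational-stereotype cohort truth (synthetic magnitudes).

    Learning rates are highest for unexpected targets — high-fit faces in
    the counter-stereotypic context, low-fit faces in the stereotypic one —
    with the unexpectedness gap larger in the counter-stereotypic context.
    Drift scaling favors expected targets in both contexts and boundary
    separation is larger in the counter-stereotypic context.
    """
    ctx_s, ctx_c = CONTEXTS
    return _truth_from_natural(
        eta={(ctx_s, "high"): 0.10, (ctx_s, "low"): 0.18,
             (ctx_c, "high"): 0.25, (ctx_c, "low"): 0.12},
        vs={(ctx_s, "high"): 4.0, (ctx_s, "low"): 3.0,
            (ctx_c, "high"): 3.0, (ctx_c, "low"): 4.0},
        a={(ctx_s, "high"): 1.6, (ctx_s, "low"): 1.6,
           (ctx_c, "high"): 2.0, (ctx_c, "low"): 2.0},
        t0=0.35,
        sds=_PRESET_SDS,
        n=n_subjects_per_context,
        seed=seed,
        name="expt1",
    )


def preset_expt2(n_subjects_per_context: int = 40, seed: int = 20240002) -> GroupTruth:
    """Trait-stereotype cohort truth (synthetic magnitudes).

    Same learning-rate pattern as :func:`preset_expt1`; drift scaling and
    boundary separation are instead larger in the stereotypic context.
    """
    ctx_s, ctx_c = CONTEXTS
    return _truth_from_natural(
        eta={(ctx_s, "high"): 0.10, (ctx_s, "low"): 0.18,
             (ctx_c, "high"): 0.24, (ctx_c, "low"): 0.13},
        vs={(ctx_s, "high"): 4.0, (ctx_s, "low"): 4.0,
            (ctx_c, "high"): 3.0, (ctx_c, "low"): 3.0},
        a={(ctx_s, "high"): 2.0, (ctx_s, "low"): 2.0,
           (ctx_c, "high"): 1.7, (ctx_c, "low"): 1.7},
        t0=0.35,
        sds=_PRESET_SDS,
        n=n_subjects_per_context,
        seed=seed,
        name="expt2",
    )


def preset_context_only(n_subjects_per_context: int = 40, seed: int = 20240003) -> GroupTruth:
    """Truth in which only the learning context matters (model-recovery aid).

    Within each context the high- and low-fit cells are identical and tied
    at the subject level, so the goodness-of-fit factor is genuinely inert.
    """
    ctx_s, ctx_c = CONTEXTS
    truth = _truth_from_natural(
        eta={(ctx_s, "high"): 0.12, (ctx_s, "low"): 0.12,
             (ctx_c, "high"): 0.20, (ctx_c, "low"): 0.20},
        vs={(ctx_s, "high"): 4.0, (ctx_s, "low"): 4.0,
            (ctx_c, "high"): 3.0, (ctx_c, "low"): 3.0},
        a={(ctx_s, "high"): 1.6, (ctx_s, "low"): 1.6,
           (ctx_c, "high"): 2.0, (ctx_c, "low"): 2.0},
        t0=0.35,
        sds=_PRESET_SDS,
        n=n_subjects_per_context,
        seed=seed,
        name="context-only",
    )
    return GroupTruth(
        eta=truth.eta, v_scaling=truth.v_scaling, a=truth.a, t0=truth.t0,
        n_subjects_per_context=truth.n_subjects_per_context, seed=truth.seed,
        name=truth.name, dependence="context_only",
    )


def draw_subject_parameters(
    truth: GroupTruth, context: str, rng: np.random.Generator
) -> ParameterSet:
    """One subject's natural-scale parameters from the group distributions.

    Under a ``context_only`` truth both fit cells share a single draw per
    family, so the subject's parameters genuinely ignore goodness-of-fit.
    """
    cells = [(context, fit) for fit in FITS]

    def draw(dist: dict) -> dict:
        if truth.dependence == "context_only":
            x = rng.normal(*dist[cells[0]])
            return {c: float(x) for c in cells}
        return {c: float(rng.normal(*dist[c])) for c in cells}

    eta = {c: float(expit(x)) for c, x in draw(truth.eta).items()}
    vs = draw(truth.v_scaling)
    a = {c: float(np.exp(x)) for c, x in draw(truth.a).items()}
    t0 = float(np.exp(rng.normal(*truth.t0)))
    return ParameterSet(eta=eta, v_scaling=vs, a=a, t0=t0)


def generate_cohort(
    truth: GroupTruth,
    design_template: dict | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[TrialLog, pd.DataFrame]:
    """Simulate a full cohort and return (trial log, ground-truth table).

    Subjects alternate between the two learning contexts and between the
    two counterbalance groups within context.  ``design_template`` passes
    keyword overrides to :func:`rlddm.task.default_design`.  The truth
    table lists every subject's natural-scale parameters, one row per
    condition cell.
    """
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    template = dict(design_template or {})
    n = truth.n_subjects_per_context

    frames, truth_rows = [], []
    for subj in range(2 * n):
        context = CONTEXTS[subj % 2]
        cb_group = 1 + (subj // 2) % 2
        design = default_design(
            learning_context=context, counterbalance_group=cb_group, **template
        )
        params = draw_subject_parameters(truth, context, rng)
        log = simulate_session(params, design, rng, subj_idx=subj)
        frames.append(log.records)
        for fit in FITS:
            cell = (context, fit)
            truth_rows.append(
                {
                    "subj_idx": subj,
                    "context": context,
                    "fit": fit,
                    "counterbalance_group": cb_group,
                    "eta": params.eta[cell],
                    "v_scaling": params.v_scaling[cell],
                    "a": params.a[cell],
                    "t0": params.t0,
                }
            )

    records = pd.concat(frames, ignore_index=True)[LOG_COLUMNS]
    log = TrialLog(
        records=records,
        metadata={"truth": truth.name, "seed": truth.seed, "design_template": template},
    )
    return log, pd.DataFrame(truth_rows)
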