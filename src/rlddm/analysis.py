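"""Directional posterior tests, prediction-error contrasts and reports.

The evidence summary for a directional hypothesis "A > B" is the
posterior probability of the *contrary* event, p_Bayes = P(A - B <= 0),
computed over paired posterior draws (ties count against the stated
direction, the conservative convention).  The complementary posterior
odds (1 - p_Bayes) / p_Bayes are reported as the evidence ratio BF10,
rounded to the nearest integer (half up) for display when >= 1; p_Bayes
below 0.001 is displayed as "BF10 > 1000".

The prediction-error contrast compares the learning-rate advantage of
*unexpected* targets between learning contexts: within the stereotypic
context low-fit targets are the surprising ones, within the
counter-stereotypic context high-fit targets are, and the per-draw
difference of those two advantages is tested directionally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import FitResult, PosteriorSamples
from .task import CONTEXTS

__all__ = [
    "DirectionalTest",
    "ContrastResult",
    "p_bayes",
    "bf_from_pbayes",
    "format_bf",
    "prediction_error_contrast",
    "report",
]


@dataclass(frozen=True)
class DirectionalTest:
    """Directional posterior comparison of two parameter cells."""

    cell_a: str
    cell_b: str
    direction: str  # "A>B" or "A<B"
    p_bayes: float
    bf10: float

    def display(self) -> str:
        rel = ">" if self.direction == "A>B" else "<"
        return (
            f"p_Bayes[{self.cell_a} {rel} {self.cell_b}] = {self.p_bayes:.3g}, "
            f"BF10 {format_bf(self.p_bayes)}"
        )


def p_bayes(draws_a: np.ndarray, draws_b: np.ndarray, direction: str = "A>B") -> float:
    """Posterior probability contrary to the stated direction.

    For "A > B": the proportion of paired draws with (a - b) <= 0 — ties
    count as contrary evidence.  Small values mean strong support for the
    direction.  Draw vectors must be paired (same chain/draw order).
    """
    a = np.asarray(draws_a, dtype=float)
    b = np.asarray(draws_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired draws required: {a.shape} vs {b.shape}")
    d = a - b
    if direction == "A>B":
        return float(np.mean(d <= 0))
    if direction == "A<B":
        return float(np.mean(d >= 0))
    raise ValueError("direction must be 'A>B' or 'A<B'")


def bf_from_pbayes(p: float) -> float:
    """Complementary posterior odds (1 - p) / p for a directional test.

    ``p = 0`` maps to ``inf`` (reported as a '>' bound, never a number);
    ``p = 1`` maps to 0.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p_bayes must lie in [0, 1]")
    if p == 0.0:
        return math.inf
    return (1.0 - p) / p


def bf_rounded(p: float) -> float:
    """Display rounding: nearest integer (half up) when the odds are >= 1."""
    bf = bf_from_pbayes(p)
    if math.isinf(bf):
        return bf
    if bf >= 1.0:
        return float(math.floor(bf + 0.5))
    return round(bf, 2)


def format_bf(p: float, strong_cut: float = 0.001) -> str:
    """Report-style string; p below ``strong_cut`` prints as '> 1000'."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p_bayes must lie in [0, 1]")
    if p < strong_cut:
        return f"> {1.0 / strong_cut:.0f}"
    bf = bf_rounded(p)
    return f"= {bf:.0f}" if bf >= 1 else f"= {bf:.2f}"


def _directional(cell_a, cell_b, draws_a, draws_b, direction) -> DirectionalTest:
    p = p_bayes(draws_a, draws_b, direction)
    return DirectionalTest(
        cell_a=cell_a, cell_b=cell_b, direction=direction,
        p_bayes=p, bf10=bf_from_pbayes(p),
    )


@dataclass
class ContrastResult:
    """Per-draw surprise advantages and their between-context difference.

    ``delta_stereotypic``  = eta(low fit) - eta(high fit) in the
    stereotypic context; ``delta_counter`` = eta(high) - eta(low) in the
    counter-stereotypic context; ``difference`` = counter - stereotypic.
    All on the natural (0, 1) learning-rate scale.
    """

    delta_stereotypic: np.ndarray
    delta_counter: np.ndarray
    difference: np.ndarray
    test: DirectionalTest


def prediction_error_contrast(posterior: PosteriorSamples) -> ContrastResult:
    """Compare surprise-driven learning-rate advantages across contexts.

    Requires a posterior from the integrative model (all four
    context-by-fit learning-rate cells); tests the direction
    "counter-stereotypic advantage > stereotypic advantage".
    """
    ctx_s, ctx_c = CONTEXTS
    needed = {
        (ctx, fit): f"mu_eta[{ctx}:{fit}]"
        for ctx in CONTEXTS
        for fit in ("high", "low")
    }
    missing = [n for n in needed.values() if n not in posterior.nodes]
    if missing:
        raise ValueError(
            f"posterior lacks learning-rate cells {missing}; the contrast "
            "needs a fit of the integrative model (context_by_fit spec)"
        )
    eta = {cell: posterior.natural(node) for cell, node in needed.items()}
    d_stereo = eta[(ctx_s, "low")] - eta[(ctx_s, "high")]
    d_counter = eta[(ctx_c, "high")] - eta[(ctx_c, "low")]
    diff = d_counter - d_stereo
    test = _directional(
        "counter-stereotypic surprise advantage",
        "stereotypic surprise advantage",
        d_counter, d_stereo, "A>B",
    )
    return ContrastResult(
        delta_stereotypic=d_stereo, delta_counter=d_counter,
        difference=diff, test=test,
    )


def _posterior_summary(fit: FitResult) -> list[dict]:
    rows = []
    for node in sorted(fit.posterior.nodes):
        if not node.startswith(("mu_", "sigma_")):
            continue
        nat = fit.posterior.natural(node)
        lo, hi = np.quantile(nat, [0.025, 0.975])
        rows.append(
            {
                "node": node,
                "mean": float(np.mean(nat)),
                "cri_2.5": float(lo),
                "cri_97.5": float(hi),
            }
        )
    return rows


def report(
    fit_results: dict[str, FitResult],
    tests: list[DirectionalTest],
    contrasts: list[ContrastResult],
    out_dir,
) -> dict:
    """Write a deterministic report bundle (JSON + text + CSV tables).

    Tables cover group-level posterior means with 95% credible intervals
    (natural scales), every directional test with p_Bayes and the rounded
    evidence ratio, and the DIC comparison across fitted models.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    payload = {
        "models": {
            name: {
                "dic": fit.dic,
                "p_d": fit.p_d,
                "rhat_max": max(fit.rhat.values()) if fit.rhat else None,
                "converged": fit.converged,
                "posterior_summary": _posterior_summary(fit),
            }
            for name, fit in sorted(fit_results.items())
        },
        "directional_tests": [
            {
                "cells": [t.cell_a, t.cell_b],
                "direction": t.direction,
                "p_bayes": t.p_bayes,
                "bf10_raw": None if math.isinf(t.bf10) else t.bf10,
                "bf10_display": format_bf(t.p_bayes),
            }
            for t in tests
        ],
        "prediction_error_contrasts": [
            {
                "delta_stereotypic_mean": float(np.mean(c.delta_stereotypic)),
                "delta_counter_mean": float(np.mean(c.delta_counter)),
                "difference_mean": float(np.mean(c.difference)),
                "p_bayes": c.test.p_bayes,
                "bf10_display": format_bf(c.test.p_bayes),
            }
            for c in contrasts
        ],
    }
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)

    lines = ["RL-DDM analysis report", "=" * 60]
    for name, fit in sorted(fit_results.items()):
        lines.append(f"\nModel: {name}  DIC = {fit.dic:.1f}  p_D = {fit.p_d:.1f}")
        lines.append(f"{'node':<42}{'mean':>8}{'2.5%':>8}{'97.5%':>8}")
        for row in _posterior_summary(fit):
            lines.append(
                f"{row['node']:<42}{row['mean']:>8.3f}"
                f"{row['cri_2.5']:>8.3f}{row['cri_97.5']:>8.3f}"
            )
        pd.DataFrame(_posterior_summary(fit)).to_csv(
            out / f"posterior_{name.replace(' ', '_')}.csv", index=False
        )
    if tests:
        lines.append("\nDirectional tests")
        for t in tests:
            lines.append("  " + t.display())
    for c in contrasts:
        lines.append(
            f"\nPrediction-error contrast: difference mean = "
            f"{np.mean(c.difference):+.4f}; {c.test.display()}"
        )
    (out / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return payload
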