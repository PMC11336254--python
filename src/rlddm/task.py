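"""Probabilistic selection task (PST) structure and trial-log I/O.

The PST presents fixed pairs of faces; one member of each pair (the
*target*) is positively reinforced with a pair-specific probability
(0.80 / 0.70 / 0.60 for the three standard pairs).  Learning proceeds in
blocks of 120 trials and terminates once every pair's within-block choice
accuracy reaches its criterion (0.60 / 0.55 / 0.50), up to four blocks
(480 trials).

Each trial's target is a stereotype-related face whose
goodness-of-stereotype-fit (high/low femininity or masculinity) is set by
the counterbalance group, and each subject learns in either a stereotypic
or counter-stereotypic context.  Trials are response-coded: ``response = 1``
means the positively reinforced face was chosen, which maps onto the upper
boundary of the diffusion model downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StimulusPair",
    "TaskDesign",
    "TrialLog",
    "default_design",
    "check_block_criterion",
    "read_trial_log",
    "write_trial_log",
    "read_design_config",
    "write_design_config",
    "TrialLogError",
]

CONTEXTS = ("stereotypic", "counter-stereotypic")
FITS = ("high", "low")
SEXES = ("female", "male")

#: reward probability of the target and accuracy criterion per base pair
BASE_PAIRS = (("AB", 0.80, 0.60), ("CD", 0.70, 0.55), ("EF", 0.60, 0.50))

#: exact column order of the trial-log CSV
LOG_COLUMNS = [
    "subj_idx", "trial", "block", "pair", "response", "rt",
    "feedback", "context", "fit_of_target",
]


class TrialLogError(ValueError):
    """A trial log violated the task-structure invariants."""


@dataclass(frozen=True)
class StimulusPair:
    """One PST face pair with its reinforcement schedule.

    p_reward_target : probability that choosing the target (positively
        reinforced face) yields "Correct" feedback.
    criterion : minimum within-block choice accuracy required for this pair.
    target_fit : goodness-of-stereotype-fit (high/low) of the target face.
    """

    pair_id: str
    p_reward_target: float
    criterion: float
    face_sex: str
    target_fit: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_reward_target <= 1.0:
            raise ValueError("p_reward_target must lie in [0, 1]")
        if not 0.0 <= self.criterion <= 1.0:
            raise ValueError("criterion must lie in [0, 1]")
        if self.face_sex not in SEXES:
            raise ValueError(f"face_sex must be one of {SEXES}")
        if self.target_fit not in FITS:
            raise ValueError(f"target_fit must be one of {FITS}")


@dataclass(frozen=True)
class TaskDesign:
    """PST session layout: pairs, block structure and condition labels."""

    pairs: tuple[StimulusPair, ...]
    block_length: int = 120
    max_blocks: int = 4
    learning_context: str = "stereotypic"
    counterbalance_group: int = 1

    def __post_init__(self) -> None:
        if self.learning_context not in CONTEXTS:
            raise ValueError(f"learning_context must be one of {CONTEXTS}")
        if self.counterbalance_group not in (1, 2):
            raise ValueError("counterbalance_group must be 1 or 2")
        if self.block_length % len(self.pairs) != 0:
            raise ValueError(
                f"block_length {self.block_length} not divisible by "
                f"{len(self.pairs)} pairs: pairs must appear equally often"
            )
        ids = [p.pair_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate pair ids in design")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def trial_ceiling(self) -> int:
        return self.max_blocks * self.block_length

    @property
    def pair_ids(self) -> tuple[str, ...]:
        return tuple(p.pair_id for p in self.pairs)

    def pair(self, pair_id: str) -> StimulusPair:
        for p in self.pairs:
            if p.pair_id == pair_id:
                return p
        raise KeyError(pair_id)


@dataclass
class TrialLog:
    """Trial records for one or more subjects plus generator metadata.

    ``records`` is a DataFrame with :data:`LOG_COLUMNS`; trial indices are
    1-based and strictly increasing within subject.
    """

    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def subjects(self) -> list:
        return list(pd.unique(self.records["subj_idx"]))

    def subject(self, subj_idx) -> pd.DataFrame:
        return self.records[self.records["subj_idx"] == subj_idx]

    def validate(self, design: TaskDesign | None = None) -> None:
        validate_records(self.records, design)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrialLog):
            return NotImplemented
        a = self.records.reset_index(drop=True)
        b = other.records.reset_index(drop=True)
        return a.equals(b)


def target_fit_for(face_sex: str, counterbalance_group: int) -> str:
    """Fit level of the positively reinforced face for a face sex.

    Group 1 rewards high-fit female and low-fit male targets; group 2 is
    the mirror image, so the mapping is a bijective flip between groups.
    """
    if counterbalance_group == 1:
        return "high" if face_sex == "female" else "low"
    if counterbalance_group == 2:
        return "low" if face_sex == "female" else "high"
    raise ValueError("counterbalance_group must be 1 or 2")


def default_design(
    learning_context: str = "stereotypic",
    counterbalance_group: int = 1,
    n_pair_sets: int = 2,
    block_length: int = 120,
    max_blocks: int = 4,
    single_set_sex: str = "female",
) -> TaskDesign:
    """Standard PST design: 80/70/60% pairs with 60/55/50% criteria.

    ``n_pair_sets = 1`` gives three pairs of one face sex
    (``single_set_sex``); ``n_pair_sets = 2`` gives three female plus three
    male pairs (ids suffixed ``-F`` / ``-M``), so both goodness-of-fit
    levels appear among the targets within every session.
    """
    if learning_context not in CONTEXTS:
        raise ValueError(f"learning_context must be one of {CONTEXTS}")
    if counterbalance_group not in (1, 2):
        raise ValueError("counterbalance_group must be 1 or 2")
    if n_pair_sets not in (1, 2):
        raise ValueError("n_pair_sets must be 1 or 2")
    if n_pair_sets == 1 and single_set_sex not in SEXES:
        raise ValueError(f"single_set_sex must be one of {SEXES}")

    sexes = (single_set_sex,) if n_pair_sets == 1 else SEXES
    pairs = []
    for sex in sexes:
        suffix = "" if n_pair_sets == 1 else ("-F" if sex == "female" else "-M")
        for pid, p, crit in BASE_PAIRS:
            pairs.append(
                StimulusPair(
                    pair_id=pid + suffix,
                    p_reward_target=p,
                    criterion=crit,
                    face_sex=sex,
                    target_fit=target_fit_for(sex, counterbalance_group),
                )
            )
    return TaskDesign(
        pairs=tuple(pairs),
        block_length=block_length,
        max_blocks=max_blocks,
        learning_context=learning_context,
        counterbalance_group=counterbalance_group,
    )


def check_block_criterion(
    block_records: pd.DataFrame, design: TaskDesign
) -> tuple[str, dict[str, float]]:
    """Accuracy-criterion decision for one completed block of one subject.

    Accuracy per pair is the proportion of target choices (``response == 1``)
    among that pair's trials in this block; the session stops iff every
    pair's accuracy meets its criterion (thresholds inclusive).  Returns
    ``("stop" | "continue", {pair_id: accuracy})``.
    """
    if len(block_records) != design.block_length:
        raise TrialLogError(
            f"block has {len(block_records)} trials, expected {design.block_length}"
        )
    accuracies: dict[str, float] = {}
    stop = True
    for pair in design.pairs:
        sub = block_records[block_records["pair"] == pair.pair_id]
        if len(sub) == 0:
            raise TrialLogError(f"pair {pair.pair_id!r} absent from block")
        acc = float(np.mean(sub["response"].to_numpy()))
        accuracies[pair.pair_id] = acc
        if acc < pair.criterion:
            stop = False
    return ("stop" if stop else "continue"), accuracies


def validate_records(records: pd.DataFrame, design: TaskDesign | None = None) -> None:
    """Raise :class:`TrialLogError` listing every offending row."""
    missing = [c for c in LOG_COLUMNS if c not in records.columns]
    if missing:
        raise TrialLogError(f"missing columns: {missing}")
    problems: list[str] = []

    bad_rt = records.index[records["rt"] <= 0].tolist()
    if bad_rt:
        problems.append(f"non-positive rt in rows {bad_rt}")
    for col in ("response", "feedback"):
        bad = records.index[~records[col].isin([0, 1])].tolist()
        if bad:
            problems.append(f"{col} not in {{0,1}} in rows {bad}")
    bad_ctx = records.index[~records["context"].isin(CONTEXTS)].tolist()
    if bad_ctx:
        problems.append(f"unknown context in rows {bad_ctx}")
    bad_fit = records.index[~records["fit_of_target"].isin(FITS)].tolist()
    if bad_fit:
        problems.append(f"unknown fit_of_target in rows {bad_fit}")
    if design is not None:
        bad_pair = records.index[~records["pair"].isin(design.pair_ids)].tolist()
        if bad_pair:
            problems.append(f"unknown pair id in rows {bad_pair}")
    for subj, grp in records.groupby("subj_idx", sort=False):
        tr = grp["trial"].to_numpy()
        if len(tr) and (tr[0] != 1 or np.any(np.diff(tr) <= 0)):
            problems.append(f"subject {subj!r}: trial index not strictly increasing from 1")
    if problems:
        raise TrialLogError("; ".join(problems))


_DTYPES = {
    "trial": int, "block": int, "response": int, "feedback": int, "rt": float,
    "pair": str, "context": str, "fit_of_target": str,
}


def write_trial_log(log: TrialLog, path) -> None:
    """Write a trial log as comma-separated UTF-8 text (exact header)."""
    log.records.to_csv(path, index=False, columns=LOG_COLUMNS)


def read_trial_log(path, design: TaskDesign | None = None) -> TrialLog:
    """Read and validate a trial-log CSV; round-trips :func:`write_trial_log`."""
    records = pd.read_csv(path, dtype=_DTYPES)
    validate_records(records, design)
    return TrialLog(records=records[LOG_COLUMNS])


def write_design_config(design: TaskDesign, path, seed: int | None = None) -> None:
    """Persist a design as a YAML key-value file."""
    payload = {
        "learning_context": design.learning_context,
        "counterbalance_group": design.counterbalance_group,
        "block_length": design.block_length,
        "max_blocks": design.max_blocks,
        "pairs": [
            {
                "pair_id": p.pair_id,
                "p_reward_target": p.p_reward_target,
                "criterion": p.criterion,
                "face_sex": p.face_sex,
                "target_fit": p.target_fit,
            }
            for p in design.pairs
        ],
    }
    if seed is not None:
        payload["seed"] = seed
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_design_config(path) -> TaskDesign:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    pairs = tuple(StimulusPair(**p) for p in payload["pairs"])
    return TaskDesign(
        pairs=pairs,
        block_length=payload["block_length"],
        max_blocks=payload["max_blocks"],
        learning_context=payload["learning_context"],
        counterbalance_group=payload["counterbalance_group"],
    )
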