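"""Delta-rule learning, drift construction, simulation and likelihood."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rlddm.rl import (
    ParameterSet,
    QState,
    session_loglik,
    session_loglik_detail,
    simulate_session,
    trial_drift,
    update_q,
)
from rlddm.task import default_design
from rlddm.wfpt import DiffusionParams, wiener_logpdf


def make_params(eta=0.2, vs=3.0, a=2.0, t0=0.35, context="stereotypic"):
    cells = [(context, "high"), (context, "low")]
    return ParameterSet(
        eta={c: eta for c in cells},
        v_scaling={c: vs for c in cells},
        a={c: a for c in cells},
        t0=t0,
    )


class TestUpdateQ:
    @pytest.mark.parametrize(
        "q, eta, feedback, expected",
        [(0.5, 0.1, 1, 0.55), (0.7, 0.999999, 0, pytest.approx(0.0, abs=1e-5))],
    )
    def test_delta_rule_values(self, q, eta, feedback, expected):
        assert update_q(q, feedback, eta) == pytest.approx(expected)

    def test_eta_domain_enforced(self):
        for eta in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                update_q(0.5, 1, eta)

    @given(
        q=st.floats(0.0, 1.0),
        eta=st.floats(0.001, 0.999),
        feedback=st.sampled_from([0, 1]),
    )
    def test_values_stay_in_unit_interval(self, q, eta, feedback):
        assert 0.0 <= update_q(q, feedback, eta) <= 1.0


class TestTrialDrift:
    def test_undifferentiated_values_give_zero_drift(self):
        qs = QState(3)
        assert trial_drift(qs, 0, 3.0) == 0.0

    def test_scaled_value_difference(self):
        qs = QState(1)
        qs.q[0] = [0.8, 0.2]
        assert trial_drift(qs, 0, 3.0) == pytest.approx(1.8)

    def test_antisymmetric_in_values(self):
        qs = QState(1)
        qs.q[0] = [0.8, 0.2]
        flipped = QState(1)
        flipped.q[0] = [0.2, 0.8]
        assert trial_drift(qs, 0, 3.0) == -trial_drift(flipped, 0, 3.0)


class TestSimulateSession:
    def test_never_learning_agent_reaches_ceiling(self, rng):
        design = default_design("stereotypic", 1, n_pair_sets=2)
        log = simulate_session(make_params(), design, rng, force_response=0)
        assert len(log.records) == 480

    def test_forced_target_feedback_rate(self, rng):
        """Always choosing the AB target earns positive feedback at the
        pair's programmed 80% rate."""
        design = default_design("stereotypic", 1, n_pair_sets=2)
        frames = []
        for _ in range(100):
            log = simulate_session(make_params(), design, rng, force_response=1)
            frames.append(log.records)
        records = pd.concat(frames)
        ab = records[records["pair"] == "AB-F"]
        assert len(ab) >= 2_000
        se = math.sqrt(0.8 * 0.2 / len(ab))
        assert abs(ab["feedback"].mean() - 0.80) < 3 * se

    def test_learning_improves_easy_pair_accuracy(self):
        """Accuracy on the 0.80 pair rises from the first to the last
        quarter of trials, matching a probability-matching RL oracle's
        qualitative trend."""
        design = default_design("stereotypic", 1, n_pair_sets=2)
        params = make_params(eta=0.3, vs=3.0, a=2.0, t0=0.3)
        first, last = [], []
        oracle_first, oracle_last = [], []
        rng = np.random.default_rng(5150)
        for _ in range(20):
            rec = simulate_session(params, design, rng).records
            ab = rec[rec["pair"].str.startswith("AB")].reset_index(drop=True)
            q = len(ab) // 4
            first.append(ab["response"].iloc[:q].mean())
            last.append(ab["response"].iloc[-q:].mean())
            oracle_first.append(_oracle_accuracy(rng, n_trials=q, early=True))
            oracle_last.append(_oracle_accuracy(rng, n_trials=q, early=False))
        assert np.mean(last) > np.mean(first)
        assert (np.mean(oracle_last) > np.mean(oracle_first))  # oracle agrees

    def test_exact_feedback_schedule_hits_proportions(self, rng):
        design = default_design("stereotypic", 1, n_pair_sets=2)
        log = simulate_session(
            make_params(), design, rng, force_response=1, feedback_schedule="exact"
        )
        block1 = log.records[log.records["block"] == 1]
        for pair, p in (("AB-F", 0.8), ("CD-F", 0.7), ("EF-F", 0.6)):
            grp = block1[block1["pair"] == pair]
            assert grp["feedback"].mean() == pytest.approx(p, abs=1e-9)


def _oracle_accuracy(rng, n_trials, early, p=0.8, eta=0.3):
    """Plain probability-matching RL agent (no diffusion): choose the
    target with probability proportional to its running value."""
    q = np.array([0.5, 0.5])
    correct = []
    total = 200
    for i in range(total):
        prob_target = q[0] / (q[0] + q[1])
        choice = 0 if rng.random() < prob_target else 1
        reward = rng.random() < (p if choice == 0 else 1 - p)
        q[choice] += eta * (reward - q[choice])
        correct.append(choice == 0)
    window = correct[:n_trials] if early else correct[-n_trials:]
    return np.mean(window)


class TestSessionLoglik:
    def _one_trial_log(self, rt=0.9, response=1):
        return pd.DataFrame(
            {
                "subj_idx": [0], "trial": [1], "block": [1], "pair": ["AB"],
                "response": [response], "rt": [rt], "feedback": [1],
                "context": ["stereotypic"], "fit_of_target": ["high"],
            }
        )

    def test_single_trial_equals_wiener_logpdf(self):
        design = default_design("stereotypic", 1, n_pair_sets=1)
        params = make_params(vs=3.0, a=1.8, t0=0.3)
        trials = self._one_trial_log(rt=0.9)
        # first trial: q values untouched at 0.5 so the drift is zero
        expected = wiener_logpdf(0.9, "upper", DiffusionParams(v=0.0, a=1.8, t0=0.3))
        assert session_loglik(trials, params, design) == pytest.approx(expected)

    def test_replay_is_deterministic(self, tiny_cohort, rng):
        design = default_design("stereotypic", 1, n_pair_sets=2)
        params = make_params()
        rec = simulate_session(params, design, rng).records
        assert session_loglik(rec, params, design) == session_loglik(rec, params, design)

    def test_rt_at_or_below_t0_flags_not_raises(self):
        design = default_design("stereotypic", 1, n_pair_sets=1)
        params = make_params(t0=0.5)
        trials = self._one_trial_log(rt=0.4)
        ll, n_bad = session_loglik_detail(trials, params, design)
        assert ll == -math.inf and n_bad == 1

    def test_likelihood_peaks_near_generating_learning_rate(self):
        """Across replicate sessions the generating eta beats eta
        perturbed by +/-50% most of the time."""
        design = default_design("stereotypic", 1, n_pair_sets=2, max_blocks=2)
        gen = make_params(eta=0.2, vs=3.0, a=2.0, t0=0.3)
        lo = make_params(eta=0.1, vs=3.0, a=2.0, t0=0.3)
        hi = make_params(eta=0.3, vs=3.0, a=2.0, t0=0.3)
        rng = np.random.default_rng(99)
        wins = 0
        n_rep = 100
        for _ in range(n_rep):
            rec = simulate_session(gen, design, rng).records
            ll_gen = session_loglik(rec, gen, design)
            if ll_gen > session_loglik(rec, lo, design) and ll_gen > session_loglik(
                rec, hi, design
            ):
                wins += 1
        assert wins >= 0.8 * n_rep

    def test_interleaving_invariance(self):
        """The likelihood depends only on each pair's own trial sequence,
        not on how different pairs interleave."""
        design = default_design("stereotypic", 1, n_pair_sets=1)
        params = make_params(eta=0.3, vs=2.5, a=1.6, t0=0.2)

        def frame(order):
            rows = []
            per_pair = {
                "AB": [(1, 0.8, 1), (0, 1.1, 0), (1, 0.7, 1)],
                "CD": [(1, 0.9, 0), (1, 0.6, 1), (0, 1.4, 1)],
                "EF": [(0, 1.2, 0), (1, 0.8, 1), (1, 1.0, 0)],
            }
            counters = {p: 0 for p in per_pair}
            for i, pair in enumerate(order, start=1):
                resp, rt, fb = per_pair[pair][counters[pair]]
                counters[pair] += 1
                rows.append(
                    {
                        "subj_idx": 0, "trial": i, "block": 1, "pair": pair,
                        "response": resp, "rt": rt, "feedback": fb,
                        "context": "stereotypic", "fit_of_target": "high",
                    }
                )
            return pd.DataFrame(rows)

        order_a = ["AB", "CD", "EF"] * 3
        order_b = ["AB"] * 3 + ["CD"] * 3 + ["EF"] * 3
        assert session_loglik(frame(order_a), params, design) == pytest.approx(
            session_loglik(frame(order_b), params, design), rel=1e-12
        )

    def test_smooth_in_parameters(self, rng):
        """Finite-difference continuity of the likelihood surface."""
        design = default_design("stereotypic", 1, n_pair_sets=2)
        gen = make_params(eta=0.2, vs=3.0, a=2.0, t0=0.3)
        rec = simulate_session(gen, design, rng).records
        base = session_loglik(rec, gen, design)
        for eps in (1e-4, 1e-5):
            near = make_params(eta=0.2 + eps, vs=3.0, a=2.0, t0=0.3)
            assert abs(session_loglik(rec, near, design) - base) < 1e3 * eps

    def test_update_count_matches_trial_count(self, rng):
        """Each pair's value trajectory receives exactly one update per
        trial of that pair (conservation of updates)."""
        design = default_design("stereotypic", 1, n_pair_sets=1)
        params = make_params(eta=0.5)
        rec = simulate_session(params, design, rng).records
        ab = rec[rec["pair"] == "AB"]
        # replay AB choices by hand and confirm the final q is reached in
        # exactly len(ab) steps
        q = {1: 0.5, 0: 0.5}
        for _, row in ab.iterrows():
            q[row["response"]] += 0.5 * (row["feedback"] - q[row["response"]])
        assert 0.0 <= q[1] <= 1.0 and 0.0 <= q[0] <= 1.0


class TestParameterSetValidation:
    def test_domain_checks(self):
        cells = [("stereotypic", "high"), ("stereotypic", "low")]
        with pytest.raises(ValueError):
            ParameterSet(
                eta={c: 1.5 for c in cells},
                v_scaling={c: 3.0 for c in cells},
                a={c: 2.0 for c in cells},
                t0=0.3,
            )
        with pytest.raises(ValueError):
            ParameterSet(
                eta={c: 0.2 for c in cells},
                v_scaling={c: 3.0 for c in cells},
                a={c: -2.0 for c in cells},
                t0=0.3,
            )
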