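"""Model graphs, MCMC kernel, convergence diagnostics and DIC."""

import math
import warnings

import numpy as np
import pytest
from scipy.integrate import simpson

from rlddm.inference import (
    MCMCConfig,
    ModelSpec,
    PosteriorSamples,
    build_model,
    compute_dic,
    fit_model,
    gelman_rubin,
    run_mcmc,
)


class TestModelSpec:
    def test_three_named_presets(self):
        assert ModelSpec.context_only().name == "learning-context model"
        assert ModelSpec.fit_only().name == "goodness-of-fit model"
        assert ModelSpec.integrative().name == "integrative model"

    def test_cell_counts(self):
        assert len(ModelSpec.context_only().cells()) == 2
        assert len(ModelSpec.fit_only().cells()) == 2
        assert len(ModelSpec.integrative().cells()) == 4

    def test_unknown_spec_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("everything")


class TestBuildModel:
    def test_context_only_two_cells_per_freed_parameter(self, tiny_cohort):
        log, _, _ = tiny_cohort
        model = build_model(ModelSpec.context_only(), log)
        assert model.cells == ["stereotypic", "counter-stereotypic"]
        names = model.node_names()
        assert sum(n.startswith("mu_eta[") for n in names) == 2

    def test_integrative_four_cells(self, tiny_cohort):
        log, _, _ = tiny_cohort
        model = build_model(ModelSpec.integrative(), log)
        assert len(model.cells) == 4

    def test_t0_has_single_cell_in_every_spec(self, tiny_cohort):
        log, _, _ = tiny_cohort
        for spec in (ModelSpec.context_only(), ModelSpec.fit_only(), ModelSpec.integrative()):
            names = build_model(spec, log).node_names()
            assert names.count("mu_t0") == 1
            assert not any(n.startswith("mu_t0[") for n in names)

    def test_cohortwide_empty_cell_is_specification_error(self, tiny_cohort):
        from rlddm.task import TrialLog

        log, _, _ = tiny_cohort
        one_context = TrialLog(
            records=log.records[log.records["context"] == "stereotypic"].copy()
        )
        with pytest.raises(ValueError, match="empty cells"):
            build_model(ModelSpec.context_only(), one_context)

    def test_sparse_cell_warns_but_retains_subject(self, tiny_cohort):
        log, _, _ = tiny_cohort
        records = log.records.copy()
        subj = log.subjects()[0]
        mask = (records["subj_idx"] == subj) & (records["fit_of_target"] == "low")
        drop = records.index[mask][1:]  # leave a single low-fit trial
        records = records.drop(index=drop)
        records.loc[records["subj_idx"] == subj, "trial"] = np.arange(
            1, (records["subj_idx"] == subj).sum() + 1
        )
        from rlddm.task import TrialLog

        with pytest.warns(UserWarning, match="trial"):
            build_model(ModelSpec.integrative(), TrialLog(records=records))

    def test_likelihood_invariant_to_row_order(self, tiny_cohort):
        """Only within-subject chronology matters, so shuffling log rows
        leaves the likelihood (hence DIC ranking) unchanged."""
        from rlddm.task import TrialLog

        log, _, _ = tiny_cohort
        model = build_model(ModelSpec.integrative(), log)
        shuffled = TrialLog(
            records=log.records.sample(frac=1.0, random_state=0).reset_index(drop=True)
        )
        model2 = build_model(ModelSpec.integrative(), shuffled)
        start = {"eta": -1.0, "v_scaling": 2.0, "a": np.log(1.8), "t0": np.log(0.2)}
        values = {
            n: start[n.split("[")[0]] for n in model.node_names() if not n.startswith(("mu_", "sigma_"))
        }
        ll1, ll2 = model.loglik_at(values), model2.loglik_at(values)
        assert math.isfinite(ll1)
        assert ll1 == pytest.approx(ll2, rel=1e-12)


class TestRunMcmc:
    def test_retained_draw_count(self, tiny_cohort):
        log, _, _ = tiny_cohort
        model = build_model(ModelSpec.context_only(), log)
        post = run_mcmc(model, n_samples=120, n_burn=40, n_chains=1, seed=0)
        assert post.n_draws == 80
        assert post.n_chains == 1

    def test_identical_seed_identical_draws(self, tiny_cohort):
        log, _, _ = tiny_cohort
        model = build_model(ModelSpec.context_only(), log)
        p1 = run_mcmc(model, n_samples=80, n_burn=30, n_chains=2, seed=11)
        p2 = run_mcmc(model, n_samples=80, n_burn=30, n_chains=2, seed=11)
        for node in p1.nodes:
            assert np.array_equal(p1.get(node), p2.get(node))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_samples=100, n_burn=100)

    def test_group_mean_matches_numerical_posterior(self, tiny_cohort):
        """With the likelihood stubbed to a known-variance normal in the
        drift-scaling parameter, the sampled group mean agrees with the
        posterior computed by brute-force numerical integration."""
        log, _, _ = tiny_cohort
        model = build_model(ModelSpec.context_only(), log)
        S = model.n_subjects
        tau = 0.5
        obs = np.array([0.3, 0.9, 1.8, 2.4])[:S]

        def stub_loglik(theta_nat):
            vs = theta_nat["v_scaling"][:, 0]
            return -0.5 * (vs - obs) ** 2 / tau**2

        model.loglik_subjects = stub_loglik
        post = run_mcmc(model, n_samples=6000, n_burn=1000, n_chains=1, seed=4)
        # cells share the same subjects here: both contexts' mu nodes pool
        # halves of the cohort; compare the pooled structure numerically
        ctx_of = [model.subject_context[s] for s in model.subjects]
        for cell in model.cells:
            x = obs[[c == cell for c in ctx_of]]
            mu_grid = np.linspace(-4, 6, 301)
            sd_grid = np.linspace(1e-3, 4, 200)
            M, Sg = np.meshgrid(mu_grid, sd_grid, indexing="ij")
            logp = (
                -0.5 * (M - 1.0) ** 2 / 2.0**2  # prior on the group mean
                - 0.5 * Sg**2 / 1.0**2  # half-normal prior on the SD
            )
            for xi in x:  # theta integrates out: x ~ N(mu, sd^2 + tau^2)
                var = Sg**2 + tau**2
                logp += -0.5 * np.log(var) - 0.5 * (xi - M) ** 2 / var
            w = np.exp(logp - logp.max())
            post_mu = simpson(simpson(w * M, x=sd_grid), x=mu_grid) / simpson(
                simpson(w, x=sd_grid), x=mu_grid
            )
            draws = post.stacked(f"mu_v_scaling[{cell}]")
            mcse = draws.std(ddof=1) / math.sqrt(len(draws) / 20)  # conservative ESS
            assert abs(draws.mean() - post_mu) < max(3 * mcse, 0.05)


class TestGelmanRubin:
    def _post(self, arrays):
        nodes = {"x": np.asarray(arrays)}
        dev = np.zeros_like(nodes["x"])
        return PosteriorSamples(nodes=nodes, deviance=dev)

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(8)
        post = self._post(rng.standard_normal((3, 5000)))
        assert 0.99 <= gelman_rubin(post)["x"] <= 1.01

    def test_separated_chains_blow_up(self):
        rng = np.random.default_rng(8)
        chains = np.stack(
            [rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)]
        )
        assert gelman_rubin(self._post(chains))["x"] > 3

    def test_constant_chains_return_one(self):
        post = self._post(np.full((3, 100), 2.5))
        assert gelman_rubin(post)["x"] == 1.0

    def test_single_chain_instructs_convergence_config(self):
        post = self._post(np.zeros((1, 100)))
        with pytest.raises(ValueError, match="chains"):
            gelman_rubin(post)


class TestComputeDic:
    def _post(self, deviance):
        dev = np.asarray(deviance, dtype=float)[None, :]
        nodes = {"theta": np.zeros_like(dev)}
        return PosteriorSamples(nodes=nodes, deviance=dev)

    def test_zero_spread_gives_zero_pd(self):
        post = self._post([8.0, 8.0, 8.0])
        dic, p_d = compute_dic(post, lambda values: -4.0)
        assert p_d == pytest.approx(0.0)
        assert dic == pytest.approx(8.0)

    def test_direct_formula(self):
        post = self._post([10.0, 12.0, 14.0])
        dic, p_d = compute_dic(post, lambda values: -5.5)  # plug-in deviance 11
        assert p_d == pytest.approx(1.0)
        assert dic == pytest.approx(13.0)

    def test_too_many_nonfinite_deviances_error(self):
        post = self._post([10.0, math.inf, 14.0])
        with pytest.raises(ValueError, match="non-finite"):
            compute_dic(post, lambda values: -5.0)


def test_fit_result_reports_convergence_flags(tiny_integrative_fit):
    _, fit = tiny_integrative_fit
    assert math.isfinite(fit.dic)
    assert math.isfinite(fit.p_d)
    summary = fit.summary()
    assert summary["model"] == "integrative model"
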