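"""Likelihood, priors, MCMC machinery, AIS and fit metrics."""

import math

import numpy as np
import pandas as pd
import pytest

import compclass as cc
from compclass.bda import (
    AISSettings,
    ALL_VARIANTS,
    ParamSpace,
    ais_log_evidence,
    bayes_factor,
    fit_metrics,
    joint_log_likelihood,
    log_prior,
    run_mcmc,
    split_rhat,
)

from _oracle import oracle_binomial_loglik


def tiny_design(n_sets=2, seed=0):
    return cc.make_item_design(n_sets, seed=seed)


@pytest.fixture(scope="module")
def tiny_data():
    design = tiny_design()
    theta = cc.default_theta(design)
    return design, theta, cc.simulate_dataset(design, theta, 40, 40, seed=7)


class TestJointLogLikelihood:
    def test_empty_dataset_is_zero(self):
        assert joint_log_likelihood(
            cc.default_theta(tiny_design()), cc.BehavioralDataset.empty()
        ) == 0.0

    def test_single_cell_closed_form(self):
        design = tiny_design(1)
        items = design.items
        # symmetric configuration: sub prior equals the superordinate unit
        # normal and a flat class prior, so p_model = 0.5 for every cell
        theta = cc.ParameterVector(
            1.5, 5.0, np.zeros(3), np.ones(3), cc.ClassPriorParams("flat")
        )
        data = cc.BehavioralDataset(
            items,
            pd.DataFrame(
                [{"item_id": items[0].item_id, "polarity": "positive",
                  "n_sub": 5, "n_total": 10}]
            ),
            pd.DataFrame(columns=["item_id", "polarity", "explicit_class", "n_yes", "n_total"]),
        )
        ll = joint_log_likelihood(theta, data, "flat")
        assert ll == pytest.approx(math.log(math.comb(10, 5)) + 10 * math.log(0.5), abs=1e-9)
        assert ll == pytest.approx(-1.402, abs=5e-4)

    def test_matches_straight_line_oracle(self, tiny_data):
        design, theta, data = tiny_data
        engine = cc.ForwardEngine(design.items)
        probs = engine.predict(
            theta.alpha1, theta.alpha2, theta.sub_mean, theta.sub_sd, theta.class_params
        )
        idx = data.item_index()
        rows = []
        for _, r in data.cc_counts.iterrows():
            p = probs.p_cc[idx[r["item_id"]], 0 if r["polarity"] == "positive" else 1]
            rows.append((r["n_sub"], r["n_total"], p))
        for _, r in data.endorse_counts.iterrows():
            p = probs.p_endorse[idx[r["item_id"]], 0 if r["polarity"] == "positive" else 1]
            rows.append((r["n_yes"], r["n_total"], p))
        assert joint_log_likelihood(theta, data) == pytest.approx(
            oracle_binomial_loglik(rows), abs=1e-9
        )

    def test_unknown_variant_rejected(self, tiny_data):
        _, theta, data = tiny_data
        with pytest.raises(ValueError):
            joint_log_likelihood(theta, data, "maximal")


class TestLogPrior:
    def test_alpha_outside_support(self):
        design = tiny_design()
        theta = cc.default_theta(design, alpha1=25.0)
        assert log_prior(theta) == -np.inf

    def test_sub_mean_density_ratio(self):
        design = tiny_design()
        a = cc.default_theta(design)
        m = a.sub_mean.copy()
        m[0] = 0.0
        b = cc.ParameterVector(a.alpha1, a.alpha2, m, a.sub_sd, a.class_params)
        m2 = m.copy()
        m2[0] = 1.0
        c = cc.ParameterVector(a.alpha1, a.alpha2, m2, a.sub_sd, a.class_params)
        # Normal(0, 2) log-density ratio between mean 1 and mean 0 is -1/8
        assert log_prior(c) - log_prior(b) == pytest.approx(-1 / 8, abs=1e-12)

    def test_finite_at_prior_modes(self):
        space = ParamSpace("basic_freq", 6)
        x = space.pack(cc.default_theta(tiny_design()))
        assert np.isfinite(space.log_prior(x))


class TestMCMC:
    def test_prior_recovery_with_empty_counts(self):
        """With no data the chain must sample the prior: alpha1 ~ U(0, 20)."""
        design = tiny_design(1)
        data = cc.BehavioralDataset.empty(design.items)
        chains = run_mcmc(data, "basic_freq", n_chains=2, n_iter=6000, seed=4)
        xs = np.concatenate([ch.samples for ch in chains])
        names = chains[0].names
        a1 = xs[:, names.index("alpha1")]
        # U(0,20): mean 10, sd 5.77; allow generous Monte-Carlo slack for
        # the autocorrelated random-walk draws
        assert abs(a1.mean() - 10.0) < 2.0
        sd_cols = xs[:, [i for i, n in enumerate(names) if n.startswith("sub_sd")]]
        assert abs(sd_cols.mean() - (2.0 + 0.01) / 2) < 0.2

    def test_fixed_seed_is_bit_identical(self, tiny_data):
        _, _, data = tiny_data
        a = run_mcmc(data, "basic", n_chains=2, n_iter=400, seed=9)
        b = run_mcmc(data, "basic", n_chains=2, n_iter=400, seed=9)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.samples, cb.samples)
            np.testing.assert_array_equal(ca.log_posteriors, cb.log_posteriors)

    def test_different_seeds_differ(self, tiny_data):
        _, _, data = tiny_data
        a = run_mcmc(data, "basic", n_chains=1, n_iter=400, seed=9)
        b = run_mcmc(data, "basic", n_chains=1, n_iter=400, seed=10)
        assert not np.array_equal(a[0].samples, b[0].samples)

    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_all_variants_run(self, tiny_data, variant):
        _, _, data = tiny_data
        chains = run_mcmc(data, variant, n_chains=2, n_iter=300, seed=1)
        assert len(chains) == 2
        assert np.all(np.isfinite(chains[0].log_posteriors))

    def test_rhat_near_one_for_iid_noise(self):
        rng = np.random.default_rng(0)
        chains = [
            cc.Chain(rng.standard_normal((500, 2)), np.zeros(500), 0, 0, ["a", "b"])
            for _ in range(3)
        ]
        assert np.all(split_rhat(chains) < 1.05)


class TestPosteriorPredict:
    def test_degenerate_single_sample_has_zero_width(self, tiny_data):
        design, theta, data = tiny_data
        space = ParamSpace("basic_freq", data.n_categories)
        x = space.pack(theta)
        ch = cc.Chain(x[None, :], np.array([0.0]), 0, 0, list(space.names))
        pred = cc.posterior_predict([ch], data)
        assert np.allclose(pred["ci_low"], pred["ci_high"])
        assert np.allclose(pred["predicted_map"], pred["predicted_mean"])

    def test_prediction_rows_cover_all_cells(self, tiny_data):
        _, theta, data = tiny_data
        space = ParamSpace("basic_freq", data.n_categories)
        ch = cc.Chain(space.pack(theta)[None, :], np.array([0.0]), 0, 0, [])
        pred = cc.posterior_predict([ch], data)
        assert len(pred) == len(data.cc_counts) + len(data.endorse_counts)


class TestFitMetrics:
    def test_perfect_prediction(self):
        r2, mse = fit_metrics([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert (r2, mse) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_constant_prediction_convention(self):
        obs = np.array([0.2, 0.4, 0.9])
        r2, mse = fit_metrics(np.full(3, obs.mean()), obs)
        assert r2 == 0.0
        assert mse == pytest.approx(np.var(obs))

    def test_two_point_closed_form(self):
        r2, mse = fit_metrics([0.2, 0.8], [0.3, 0.7])
        assert mse == pytest.approx(0.01)
        assert r2 == pytest.approx(1.0)

    def test_zero_observed_variance_is_an_error(self):
        with pytest.raises(ValueError):
            fit_metrics([0.2, 0.8], [0.5, 0.5])


class TestMarginalLikelihood:
    def test_beta_binomial_toy_closed_form(self):
        """AIS through the generic machinery on Beta(1,1)-Binomial(10, 5):
        evidence is exactly 1/11."""
        n, k = 10, 5
        coef = math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)

        def loglik(p):
            return coef + k * math.log(p) + (n - k) * math.log(1 - p)

        def sample_prior(rng):
            return rng.uniform()

        def transition(p, ll, beta, rng):
            prop = p + 0.2 * rng.standard_normal()
            if 0 < prop < 1:
                ll_prop = loglik(prop)
                if math.log(rng.uniform()) < beta * (ll_prop - ll):
                    return prop, ll_prop
            return p, ll

        rng = np.random.default_rng(3)
        lml, se, _ = ais_log_evidence(
            sample_prior, loglik, transition, AISSettings(30, 300, 2), rng
        )
        assert lml == pytest.approx(math.log(1 / 11), abs=0.05)

    def test_full_machinery_on_single_item(self):
        """The BDA-level AIS agrees with brute-force numerical integration
        on a one-category, cc-only dataset under the flat variant."""
        design = cc.make_item_design(1, seed=3)
        items = design.items[:1]
        data = cc.BehavioralDataset(
            items,
            pd.DataFrame([
                {"item_id": items[0].item_id, "polarity": "positive", "n_sub": 13, "n_total": 20},
            ]),
            pd.DataFrame(columns=["item_id", "polarity", "explicit_class", "n_yes", "n_total"]),
        )
        lml, se = cc.log_marginal_likelihood(
            data, "flat", AISSettings(25, 200, 2), seed=5
        )
        # independent quadrature over the four free parameters via prior
        # Monte Carlo with a large sample
        space = ParamSpace("flat", 1)
        rng = np.random.default_rng(11)
        lls = []
        for _ in range(4000):
            th = space.unpack(space.sample_prior(rng))
            lls.append(joint_log_likelihood(th, data, "flat"))
        from scipy.special import logsumexp

        ref = logsumexp(lls) - math.log(len(lls))
        assert lml == pytest.approx(ref, abs=0.25)
        assert se < 0.2


def test_bayes_factor_is_difference():
    assert bayes_factor(-100.0, -110.0) == 10.0
    assert bayes_factor(-3.2, -3.2) == 0.0
    with pytest.raises(ValueError):
        bayes_factor(-np.inf, 0.0)


def test_compare_models_emits_all_five_variants(tiny_data):
    """The comparison table has one row per pragmatic variant plus the
    rival literal listener, with a zero log-BF for the reference."""
    _, _, data = tiny_data
    table = cc.compare_models(
        data,
        n_chains=2,
        n_iter=300,
        seed=3,
        ais_settings=AISSettings(n_temperatures=8, n_samples=30, n_transitions=1),
    )
    assert len(table) == 5
    assert set(table["variant"]) == {"flat", "basic", "freq", "basic_freq", "literal"}
    ref = table.set_index("variant").loc["basic_freq", "log_bf_vs_full"]
    assert ref == 0.0
    assert np.all(np.isfinite(table["log_marginal"]))


class TestModelResultsAPI:
    def test_fit_summary_and_text_summary(self, tiny_data):
        _, _, data = tiny_data
        model = cc.ComparisonClassModel(data, variant="basic")
        res = model.fit(n_chains=2, n_iter=1500, seed=2)
        fs = res.fit_summary()
        assert fs.mse_cc >= 0 and fs.r2_cc <= 1
        text = res.summary()
        assert "basic" in text and "alpha2" in text
        tab = res.posterior_summaries()
        assert set(tab.columns) == {"parameter", "mean", "ci_low", "ci_high"}
        assert (tab["ci_low"] <= tab["ci_high"]).all()
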