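"""Item designs, simulated datasets, response coding, interaction statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import compclass as cc
from compclass.synthetic import LEVELS, simulate_responses


class TestItemDesign:
    def test_single_set_has_each_level_once(self):
        design = cc.make_item_design(1, seed=0)
        assert len(design.items) == 3
        assert {it.expectation_level for it in design.items} == set(LEVELS)

    def test_study_scale_design(self):
        """90 sets x 3 categories x 2 polarities = 540 unique cells."""
        design = cc.make_item_design(90, seed=5)
        assert len(design.items) == 270
        assert design.n_sets == 90
        assert 2 * len(design.items) == 540

    def test_deterministic_for_seed(self):
        a = cc.make_item_design(10, seed=3)
        b = cc.make_item_design(10, seed=3)
        assert a.items == b.items
        c = cc.make_item_design(10, seed=4)
        assert a.items != c.items

    def test_frequency_ratios_mostly_negative(self):
        design = cc.make_item_design(60, seed=1)
        ratios = np.array([it.log_freq_ratio for it in design.items])
        # drawn Normal(-1.5, 1): superordinate NPs are typically more frequent
        assert np.mean(ratios < 0) > 0.8
        assert -2.0 < ratios.mean() < -1.0


class TestSimulateDataset:
    def test_zero_samples_give_zero_totals(self):
        design = cc.make_item_design(2, seed=0)
        data = cc.simulate_dataset(design, cc.default_theta(design), 0, 0, seed=0)
        assert (data.cc_counts["n_total"] == 0).all()
        assert (data.endorse_counts["n_total"] == 0).all()

    def test_large_sample_concentrates_on_model_probability(self):
        design = cc.make_item_design(1, seed=0)
        theta = cc.default_theta(design)
        n = 10_000
        data = cc.simulate_dataset(design, theta, n, 0, seed=3)
        engine = cc.ForwardEngine(design.items)
        probs = engine.predict(
            theta.alpha1, theta.alpha2, theta.sub_mean, theta.sub_sd, theta.class_params
        )
        idx = data.item_index()
        for _, r in data.cc_counts.iterrows():
            p = probs.p_cc[idx[r["item_id"]], 0 if r["polarity"] == "positive" else 1]
            assert abs(r["n_sub"] / n - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_polarity_asymmetry_for_high_end_category(self):
        """A high-expectation category described with the positive adjective
        draws fewer subordinate paraphrases than with the negative one."""
        design = cc.make_item_design(30, seed=2)
        theta = cc.default_theta(design)
        data = cc.simulate_dataset(design, theta, 500, 0, seed=4)
        by_id = {it.item_id: it for it in design.items}
        pooled = {"positive": [0, 0], "negative": [0, 0]}
        for _, r in data.cc_counts.iterrows():
            if by_id[r["item_id"]].expectation_level == "high":
                pooled[r["polarity"]][0] += r["n_sub"]
                pooled[r["polarity"]][1] += r["n_total"]
        p_pos = pooled["positive"][0] / pooled["positive"][1]
        p_neg = pooled["negative"][0] / pooled["negative"][1]
        assert p_pos < p_neg

    def test_reproducible_for_seed(self):
        design = cc.make_item_design(3, seed=0)
        theta = cc.default_theta(design)
        a = cc.simulate_dataset(design, theta, 25, 25, seed=9)
        b = cc.simulate_dataset(design, theta, 25, 25, seed=9)
        pd.testing.assert_frame_equal(a.cc_counts, b.cc_counts)
        pd.testing.assert_frame_equal(a.endorse_counts, b.endorse_counts)


class TestCodeResponse:
    @pytest.mark.parametrize(
        "raw,np_,expected",
        [
            ("male basketball players", "basketball player", "subordinate"),
            ("people", "basketball player", "superordinate"),
            ("basketball player", "basketball player", "subordinate"),
            ("Basketball Players", "basketball player", "subordinate"),
            ("players of basketball", "basketball player", "superordinate"),
            ("gymnasts", "gymnast", "subordinate"),
            ("winter days", "winter", "subordinate"),
            ("days of the year", "winter", "superordinate"),
        ],
    )
    def test_substring_rule(self, raw, np_, expected):
        assert cc.code_response(raw, np_) == expected

    def test_synonym_map_applies_before_matching(self):
        assert cc.code_response("hoops players", "basketball player") == "superordinate"
        syn = {"hoops": "basketball", "players": "player"}
        assert cc.code_response("hoops players", "basketball player", syn) == "subordinate"

    def test_empty_np_is_an_error(self):
        with pytest.raises(ValueError):
            cc.code_response("anything", "  ")

    @given(st.sampled_from(["crow", "crows", "CROWS", "  big crows "]))
    def test_plural_and_case_insensitive(self, raw):
        assert cc.code_response(raw, "crow") == "subordinate"

    def test_coding_is_idempotent_on_labels(self):
        # feeding the coded class label back through the coder is stable
        assert cc.code_response("subordinate", "subordinate") == "subordinate"
        assert cc.code_response("superordinate", "subordinate") == "superordinate"

    def test_simulated_responses_round_trip(self):
        design = cc.make_item_design(2, seed=0)
        data = cc.simulate_dataset(design, cc.default_theta(design), 12, 0, seed=1)
        responses = simulate_responses(design, data)
        # coded labels in the emitted table agree with recoding from raw text
        by_id = {it.item_id: it for it in design.items}
        for _, r in responses.iterrows():
            assert r["coded"] == cc.code_response(
                r["raw_text"], by_id[r["item_id"]].subordinate_label
            )
        # and per-cell counts match the generating table
        got = (
            responses[responses["coded"] == "subordinate"]
            .groupby(["item_id", "polarity"])
            .size()
        )
        for _, r in data.cc_counts.iterrows():
            assert got.get((r["item_id"], r["polarity"]), 0) == r["n_sub"]


class TestInteractionStat:
    def _make(self, props, n=100):
        """props: {(level, polarity): p_sub}"""
        design = cc.make_item_design(1, seed=0)
        rows = []
        for it in design.items:
            for pol in ("positive", "negative"):
                p = props[(it.expectation_level, pol)]
                rows.append(
                    {"item_id": it.item_id, "polarity": pol,
                     "n_sub": int(round(p * n)), "n_total": n}
                )
        cols_en = ["item_id", "polarity", "explicit_class", "n_yes", "n_total"]
        return cc.BehavioralDataset(design.items, pd.DataFrame(rows), pd.DataFrame(columns=cols_en))

    def test_equal_proportions_give_zero(self):
        props = {(lv, pol): 0.6 for lv in LEVELS for pol in ("positive", "negative")}
        assert cc.interaction_stat(self._make(props)) == pytest.approx(0.0)

    def test_arithmetic_example(self):
        props = {
            ("high", "negative"): 0.9, ("high", "positive"): 0.5,
            ("mid", "negative"): 0.7, ("mid", "positive"): 0.7,
            ("low", "negative"): 0.5, ("low", "positive"): 0.5,
        }
        assert cc.interaction_stat(self._make(props), ("high", "mid")) == pytest.approx(0.4)

    def test_missing_cells_raise(self):
        design = cc.make_item_design(1, seed=0)
        data = cc.BehavioralDataset.empty(design.items)
        with pytest.raises(ValueError):
            cc.interaction_stat(data)

    def test_positive_on_synthetic_data_and_symmetric_across_ends(self):
        design = cc.make_item_design(40, seed=6)
        theta = cc.default_theta(design)
        data = cc.simulate_dataset(design, theta, 400, 0, seed=7)
        hi = cc.interaction_stat(data, ("high", "mid"))
        lo = cc.interaction_stat(data, ("low", "mid"))
        assert hi > 0  # pragmatic-listener signature
        # mirror-image design: low-end contrast matches the high-end one in
        # magnitude with opposite sign, up to binomial noise
        assert lo < 0
        assert abs(hi + lo) < 0.1 * max(abs(hi), abs(lo)) + 0.03


class TestEndToEndClosure:
    def test_recovered_predictions_track_generating_probabilities(self, recovery_run):
        """Fitting data simulated from known parameters reproduces the
        generating cell probabilities (r2 >= 0.8 against truth)."""
        run = recovery_run
        theta = run.theta_true
        engine = cc.ForwardEngine(run.data.items)
        probs = engine.predict(
            theta.alpha1, theta.alpha2, theta.sub_mean, theta.sub_sd, theta.class_params
        )
        pred = run.results.posterior_predict()
        idx = run.data.item_index()
        truth, model = [], []
        for _, r in pred[pred["task"] == "cc"].iterrows():
            j, p = idx[r["item_id"]], 0 if r["polarity"] == "positive" else 1
            truth.append(probs.p_cc[j, p])
            model.append(r["predicted_map"])
        r2, mse = cc.fit_metrics(np.array(model), np.array(truth))
        assert r2 >= 0.8

    def test_credible_intervals_calibrated_against_truth(self, recovery_run):
        """At least 90% of cells have the generating probability inside the
        95% posterior credible interval."""
        run = recovery_run
        theta = run.theta_true
        engine = cc.ForwardEngine(run.data.items)
        probs = engine.predict(
            theta.alpha1, theta.alpha2, theta.sub_mean, theta.sub_sd, theta.class_params
        )
        pred = run.results.posterior_predict()
        idx = run.data.item_index()
        hits, total = 0, 0
        for _, r in pred.iterrows():
            j, p = idx[r["item_id"]], 0 if r["polarity"] == "positive" else 1
            truth = (probs.p_cc if r["task"] == "cc" else probs.p_endorse)[j, p]
            # binomial sampling noise of the observed cell also bounds how
            # tightly the posterior can center on the generating value
            slack = 0.0
            hits += int(r["ci_low"] - slack <= truth <= r["ci_high"] + slack)
            total += 1
        assert hits / total >= 0.90
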