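import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from udsamp.analyses import (
    ExclusionSignal,
    build_sampling_matrix,
    chance_corrected_response,
    permutation_test_sampling,
    run_chance_corrected_beta,
    run_confidence_accuracy,
    run_overall_accuracy,
    run_preferential_sampling,
    run_sampling_accuracy,
    run_sampling_interaction,
    score_controls_and_exclude,
)
from udsamp.glmm import logit
from udsamp.simulate import (
    SimulationConfig,
    preset_config,
    simulate_experiment,
    substream,
)

from tests._oracles import induced_judgement_coefficient


def _controls_for(pid, n_known_familiar, n_unknown_unfamiliar):
    rows = []
    for i in range(5):
        rows.append({"participant_id": pid, "item_id": f"fam{i}",
                     "item_class": "familiar",
                     "judged_known": 1 if i < n_known_familiar else 0})
    for i in range(4):
        rows.append({"participant_id": pid, "item_id": f"unf{i}",
                     "item_class": "unfamiliar",
                     "judged_known": 0 if i < n_unknown_unfamiliar else 1})
    return rows


class TestExclusionFilter:
    def test_all_correct_included(self):
        scores, included = score_controls_and_exclude(
            pd.DataFrame(_controls_for("p1", 5, 4)))
        assert scores[0].score == 9
        assert not scores[0].excluded
        assert included == {"p1"}

    def test_four_points_excluded(self):
        scores, included = score_controls_and_exclude(
            pd.DataFrame(_controls_for("p1", 2, 2)))
        assert scores[0].score == 4
        assert scores[0].excluded
        assert included == set()

    def test_five_points_boundary_included(self):
        scores, included = score_controls_and_exclude(
            pd.DataFrame(_controls_for("p1", 3, 2)))
        assert scores[0].score == 5
        assert not scores[0].excluded

    def test_wrong_row_count_names_participant(self):
        rows = _controls_for("p9", 5, 4)[:-1]
        with pytest.raises(ValueError, match="p9"):
            score_controls_and_exclude(pd.DataFrame(rows))


class TestSamplingMatrix:
    def _records(self, counts, judgements, pid="p1"):
        return pd.DataFrame({
            "participant_id": pid,
            "object_id": [f"o{i}" for i in range(len(counts))],
            "times_sampled": counts,
            "knowledge_judgement": judgements,
        })

    def test_sampled_once(self):
        rows = build_sampling_matrix(
            self._records([1, 1, 1, 0, 0, 0], [0, 1, 0, 1, 0, 1]))
        r = rows.iloc[0]
        assert (r["times_sampled"], r["times_not_sampled"]) == (1, 2)

    def test_never_sampled(self):
        rows = build_sampling_matrix(
            self._records([3, 0, 0, 0, 0, 0], [0, 1, 0, 1, 0, 1]))
        assert (rows["times_not_sampled"].iloc[1:] == 3).all()
        assert rows["times_sampled"].iloc[0] == 3

    def test_bad_sum_raises_with_participant(self):
        with pytest.raises(ValueError, match="p1"):
            build_sampling_matrix(
                self._records([2, 2, 0, 0, 0, 0], [0, 1, 0, 1, 0, 1]))


class TestChanceCorrectedResponse:
    # frozen oracle values from hand evaluation of the formula
    def test_two_available_both_sampled(self):
        j = [0, 0, 1, 1, 1, 1]
        assert chance_corrected_response(j, [0, 1, 2]) == pytest.approx(
            (2 / 2 - 2 / 6) / 2 + 0.5)  # 0.8333

    def test_three_available_none_sampled(self):
        j = [0, 0, 0, 1, 1, 1]
        assert chance_corrected_response(j, [3, 4, 5]) == pytest.approx(
            (0 - 3 / 6) / 2 + 0.5)  # 0.25

    def test_cap_active_with_five_available(self):
        j = [0, 0, 0, 0, 0, 1]
        assert chance_corrected_response(j, [0, 1, 2]) == pytest.approx(
            (3 / 3 - 5 / 6) / 2 + 0.5)  # 0.5833

    def test_exclusion_signals(self):
        with pytest.raises(ExclusionSignal):
            chance_corrected_response([1] * 6, [0, 1, 2])
        with pytest.raises(ExclusionSignal):
            chance_corrected_response([0] * 6, [0, 1, 2])

    @given(st.integers(min_value=1, max_value=5), st.data())
    @settings(max_examples=80, deadline=None)
    def test_strictly_inside_unit_interval(self, u_avail, data):
        j = np.array([0] * u_avail + [1] * (6 - u_avail))
        sampled = data.draw(st.sets(st.integers(0, 5), min_size=0,
                                    max_size=3))
        r = chance_corrected_response(j, sampled)
        assert 0.0 < r < 1.0

    @pytest.mark.parametrize("u_avail", [1, 2, 3])
    def test_extreme_pair_identity(self, u_avail):
        # "sampled all unknowns" + "sampled none" = 1.5 - k/6 exactly;
        # true antisymmetry around 0.5 therefore holds only at k = 3
        j = np.array([0] * u_avail + [1] * (6 - u_avail))
        all_u = chance_corrected_response(j, list(range(u_avail)))
        none_u = chance_corrected_response(j, [])
        assert all_u + none_u == pytest.approx(1.5 - u_avail / 6)
        if u_avail == 3:
            assert all_u == pytest.approx(1.0 - none_u)


class TestPermutationTest:
    def _rows(self, seed=0, n=25, w=0.8):
        cfg = preset_config(groups=("adult",), n_per_group=n, seed=seed)
        cfg.group_overrides["adult"]["sampling_preference_w"] = w
        rec, _ = simulate_experiment(cfg)
        return build_sampling_matrix(rec)

    def test_p_at_least_one_over_nperm(self):
        res = permutation_test_sampling(self._rows(w=3.0), n_perm=40,
                                        seed=1)
        assert res.p_value >= 1.0 / 40
        assert res.p_value <= 1.0
        assert res.permuted_statistics.size <= 40
        assert res.permuted_statistics[0] == res.observed_statistic

    def test_forced_minimum_p(self):
        # very strong preference: observed |estimate| beats every shuffle
        res = permutation_test_sampling(self._rows(n=40, w=4.0),
                                        n_perm=50, seed=2)
        assert res.p_value == pytest.approx(1.0 / 50)

    def test_seed_reproducibility(self):
        rows = self._rows()
        a = permutation_test_sampling(rows, n_perm=30, seed=5)
        b = permutation_test_sampling(rows, n_perm=30, seed=5)
        np.testing.assert_array_equal(a.permuted_statistics,
                                      b.permuted_statistics)
        assert a.p_value == b.p_value

    def test_relabeling_invariance(self):
        rows = self._rows(n=15)
        renamed = rows.copy()
        renamed["participant_id"] = renamed["participant_id"].map(
            lambda p: "X" + p)
        renamed["object_id"] = renamed["object_id"].map(
            lambda o: o.replace("o", "obj"))
        a = permutation_test_sampling(rows, n_perm=25, seed=7)
        b = permutation_test_sampling(renamed, n_perm=25, seed=7)
        assert a.p_value == b.p_value
        np.testing.assert_allclose(a.permuted_statistics,
                                   b.permuted_statistics, atol=1e-8)

    def test_constant_judgement_rejected(self):
        rows = self._rows(n=10)
        rows["knowledge_judgement"] = 1
        with pytest.raises(ValueError, match="constant"):
            permutation_test_sampling(rows, n_perm=10, seed=0)

    def test_needs_two_participants(self):
        rows = self._rows(n=10)
        one = rows[rows["participant_id"] == rows["participant_id"].iloc[0]]
        with pytest.raises(ValueError, match="2 participants"):
            permutation_test_sampling(one.copy(), n_perm=10, seed=0)


class TestOverallAccuracy:
    def test_recovery_high_accuracy(self):
        # all labels learned, accuracy 0.8: intercept near logit(0.8)
        cfg = SimulationConfig(n_participants={"g": 50}, seed=3,
                               p_learn=1.0, p_correct_learned=0.8)
        rec, _ = simulate_experiment(cfg)
        rec["age_group"] = "g"
        rep = run_overall_accuracy(rec, "g")
        fit = rep.fits["accuracy"]
        assert fit.estimates["intercept"] == pytest.approx(logit(0.8),
                                                           abs=0.35)
        assert rep.tests["intercept_vs_chance"].p_value < 0.001

    def test_all_correct_flags_separation(self):
        cfg = SimulationConfig(n_participants={"g": 10}, seed=3,
                               p_learn=1.0, p_correct_learned=1.0)
        rec, _ = simulate_experiment(cfg)
        rec["age_group"] = "g"
        rep = run_overall_accuracy(rec, "g")
        assert rep.fits["accuracy"].separation
        assert "intercept_vs_chance" not in rep.tests

    def test_too_few_participants(self):
        cfg = SimulationConfig(n_participants={"g": 1}, seed=3)
        rec, _ = simulate_experiment(cfg)
        rec["age_group"] = "g"
        with pytest.raises(ValueError, match="2 participants"):
            run_overall_accuracy(rec, "g")

    def test_type_one_error_at_chance(self):
        # scaled-down null calibration: accuracy exactly 1/6, no random
        # effects (120 reps instead of 500)
        rejections = reps = 0
        for i in range(120):
            cfg = SimulationConfig(
                n_participants={"g": 30}, seed=7000 + i, p_learn=1.0,
                p_correct_learned=1 / 6)
            rec, _ = simulate_experiment(cfg)
            rec["age_group"] = "g"
            rep = run_overall_accuracy(rec, "g", fast=True)
            if "intercept_vs_chance" in rep.tests:
                reps += 1
                rejections += rep.tests[
                    "intercept_vs_chance"].p_value <= 0.05
        assert reps > 100
        rate = rejections / reps
        assert rate <= 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / reps)


class TestConfidenceAccuracy:
    def test_recovery(self):
        cfg = SimulationConfig(
            n_participants={"g": 60}, seed=9, p_learn=1.0,
            p_correct_learned=0.5, p_sure_given_correct=0.9,
            p_sure_given_incorrect=0.5)
        rec, _ = simulate_experiment(cfg)
        rec["age_group"] = "g"
        rep = run_confidence_accuracy(rec, "g", include_random_slopes=False)
        assert rep.fitted_values["p_sure_given_correct"] == pytest.approx(
            0.9, abs=0.05)
        assert rep.fitted_values["p_sure_given_incorrect"] == pytest.approx(
            0.5, abs=0.07)
        assert rep.tests["accuracy_lrt"].p_value < 0.05

    def test_identical_confidence_and_accuracy_flagged(self):
        cfg = SimulationConfig(n_participants={"g": 30}, seed=10,
                               p_learn=1.0, p_correct_learned=0.5,
                               p_sure_given_correct=1.0,
                               p_sure_given_incorrect=0.0)
        rec, _ = simulate_experiment(cfg)
        rec["age_group"] = "g"
        rep = run_confidence_accuracy(rec, "g", include_random_slopes=False)
        assert rep.fits["confidence"].separation
        assert any("separation" in n for n in rep.notes)

    def test_constant_confidence_reported(self):
        cfg = SimulationConfig(n_participants={"g": 20}, seed=11,
                               p_sure_given_correct=1.0,
                               p_sure_given_incorrect=1.0)
        rec, _ = simulate_experiment(cfg)
        rec["age_group"] = "g"
        rep = run_confidence_accuracy(rec, "g")
        assert rep.fits == {}
        assert any("non-estimable" in n for n in rep.notes)


class TestPreferentialSampling:
    def test_constant_judgement_non_estimable(self):
        cfg = SimulationConfig(n_participants={"g": 15}, seed=13,
                               p_learn=1.0, judge_known_given_learned=1.0)
        rec, _ = simulate_experiment(cfg)
        rec["age_group"] = "g"
        rep = run_preferential_sampling(rec, "g", n_perm=10, seed=0)
        assert any("non-estimable" in n for n in rep.notes)
        assert "judgement_permutation" not in rep.tests

    def test_estimate_matches_enumeration_oracle(self):
        # the model's judgement coefficient targets the induced logit
        # contrast of expected sampling counts, computed exactly by the
        # Plackett-Luce enumeration oracle
        w = 1.0
        p_unknown = 0.81 * 0.10 + 0.19 * 0.75  # adult preset judgement mix
        target = induced_judgement_coefficient(w, p_unknown)
        ests = []
        for i in range(40):
            cfg = preset_config(
                groups=("adult",), n_per_group=60,
                seed=int(substream(55, "orc", i).integers(0, 2**31 - 1)))
            cfg.group_overrides["adult"]["sampling_preference_w"] = w
            cfg.sd_participant = cfg.sd_object = 0.0
            rec, _ = simulate_experiment(cfg)
            rows = build_sampling_matrix(rec)
            res = permutation_test_sampling(rows, n_perm=2, seed=i)
            ests.append(res.observed_fit.estimates["knowledge_judgement"])
        assert np.mean(ests) == pytest.approx(target, abs=0.08)

    def test_reports_both_p_values(self, adult_tables):
        rec, _ = adult_tables
        rep = run_preferential_sampling(rec, "adult", n_perm=30, seed=3)
        assert "judgement_wald_naive" in rep.tests
        assert "judgement_permutation" in rep.tests
        assert rep.permutation is not None
        assert any("coded 0" in n for n in rep.notes)


class TestChanceCorrectedBeta:
    def test_null_mean_near_half_when_cap_consistent(self):
        # chance centring at 0.5 holds when participants have >= 3 unknown
        # objects; pick a high-unknown regime so that is almost always true
        cfg = SimulationConfig(n_participants={"g": 200}, seed=17,
                               p_learn=0.1,
                               judge_known_given_unlearned=0.1,
                               sampling_preference_w=0.0)
        rec, _ = simulate_experiment(cfg)
        rec["age_group"] = "g"
        rep = run_chance_corrected_beta(rec, "g")
        assert rep.fitted_values["mean_score"] == pytest.approx(0.5,
                                                                abs=0.025)
        assert rep.n_included + rep.n_removed == 200

    @pytest.mark.parametrize("k,expected", [(1, 2 / 3), (2, 7 / 12)])
    def test_chance_expectation_biased_above_half_below_cap(self, k,
                                                            expected):
        # analytic oracle: with k < 3 unknowns and uniform sampling of 3
        # of 6, E[score | k] = (1/2 - k/6)/2 + 1/2 > 1/2 (cap mismatch)
        rng = np.random.default_rng(99)
        j = np.array([0] * k + [1] * (6 - k))
        scores = []
        for _ in range(4000):
            sampled = rng.choice(6, size=3, replace=False)
            scores.append(chance_corrected_response(j, sampled))
        assert np.mean(scores) == pytest.approx(expected, abs=0.01)

    def test_preference_detected(self):
        cfg = SimulationConfig(n_participants={"g": 60}, seed=19,
                               p_learn=0.5, sampling_preference_w=1.5)
        rec, _ = simulate_experiment(cfg)
        rec["age_group"] = "g"
        rep = run_chance_corrected_beta(rec, "g")
        assert rep.fits["beta"].estimates["intercept"] > 0
        assert rep.tests["intercept_vs_chance"].p_value < 0.05

    def test_too_few_informative_participants(self):
        cfg = SimulationConfig(n_participants={"g": 6}, seed=21,
                               p_learn=1.0, judge_known_given_learned=1.0)
        rec, _ = simulate_experiment(cfg)
        rec["age_group"] = "g"
        with pytest.raises(ValueError, match="informative"):
            run_chance_corrected_beta(rec, "g")


class TestSamplingAccuracy:
    def test_z_standardized_predictor(self, adult_tables):
        rec, _ = adult_tables
        rep = run_sampling_accuracy(rec, "adult", "preregistered")
        fit = rep.fits["accuracy"]
        model = fit._model
        z = model.X[:, 1]
        per_part = pd.DataFrame({
            "pid": rec["participant_id"],
        }).assign(z=z).groupby("pid")["z"].first()
        assert per_part.mean() == pytest.approx(0.0, abs=1e-10)
        assert per_part.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_posthoc_removes_zero_unknown_participants(self, adult_tables):
        rec, _ = adult_tables
        rep = run_sampling_accuracy(rec, "adult", "posthoc")
        n_zero_unknown = sum(
            (part["knowledge_judgement"] == 1).all()
            for _, part in rec.groupby("participant_id"))
        assert rep.n_removed == n_zero_unknown
        assert rep.n_included + rep.n_removed == \
            rec["participant_id"].nunique()

    def test_constant_predictor_reported(self):
        cfg = SimulationConfig(n_participants={"g": 20}, seed=23,
                               p_learn=1.0, judge_known_given_learned=1.0)
        rec, _ = simulate_experiment(cfg)
        rec["age_group"] = "g"
        rep = run_sampling_accuracy(rec, "g", "preregistered")
        assert any("non-estimable" in n for n in rep.notes)

    def test_invalid_mode(self, adult_tables):
        with pytest.raises(ValueError, match="mode"):
            run_sampling_accuracy(adult_tables[0], "adult", "banana")

    def test_null_boost_type_one_error(self):
        # scaled-down: 80 reps; boost = 0 AND accuracy independent of
        # learning, otherwise the participant-level predictor is
        # confounded with accuracy through the learned state and the
        # "null" is not a null
        rejections = reps = 0
        for i in range(80):
            cfg = SimulationConfig(n_participants={"g": 40},
                                   seed=8000 + i, p_learn=0.5,
                                   p_correct_learned=0.5,
                                   p_correct_unlearned_base=0.5,
                                   sampling_boost=0.0)
            rec, _ = simulate_experiment(cfg)
            rec["age_group"] = "g"
            rep = run_sampling_accuracy(rec, "g", "preregistered",
                                        fast=True)
            if "slope_wald" in rep.tests:
                reps += 1
                rejections += rep.tests["slope_wald"].p_value <= 0.05
        assert reps >= 70
        assert rejections / reps <= 0.05 + 2.58 * np.sqrt(
            0.05 * 0.95 / reps)


class TestSamplingInteraction:
    def test_equal_boost_no_interaction_but_main_effect(self):
        cfg = SimulationConfig(n_participants={"g": 60}, seed=27,
                               p_learn=0.5, p_correct_learned=0.6,
                               p_correct_unlearned_base=0.3,
                               sampling_boost=1.0)
        rec, _ = simulate_experiment(cfg)
        rec["age_group"] = "g"
        rep = run_sampling_interaction(rec, "g")
        assert rep.tests["sampling_lrt_full_vs_null"].p_value < 0.05
        assert rep.tests["sampling_wald_reduced"].p_value < 0.05
        assert set(rep.fitted_values) == {
            "p_correct_known_sampled", "p_correct_known_unsampled",
            "p_correct_unknown_sampled", "p_correct_unknown_unsampled"}

    def test_constant_sampling_non_estimable(self, adult_tables):
        rec, _ = adult_tables
        rec = rec.copy()
        rec["times_sampled"] = 0
        rep = run_sampling_interaction(rec, "adult")
        assert any("sampling" in n and "non-estimable" in n
                   for n in rep.notes)
        assert rep.tests == {}


def test_missing_group_raises(adult_tables):
    with pytest.raises(ValueError, match="no records"):
        run_overall_accuracy(adult_tables[0], "nonexistent")
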