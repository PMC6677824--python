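"""Tests for the statistical analysis pipeline."""

import numpy as np
import pandas as pd
import pytest

import episeek as ek
from conftest import make_agents


def tiny_trials(rows):
    """Build a minimal trial table from (pid, block, trial, tid, correct, req)."""
    recs = []
    for pid, block, trial, tid, correct, req in rows:
        valence = ("success" if correct else "failure") if req else "none"
        recs.append((pid, block, trial, tid, 0.01 * (tid + 1), "left",
                     "left" if correct else "right", correct, req, valence,
                     3 if req else 2))
    return pd.DataFrame(recs, columns=ek.TRIAL_COLUMNS)


class TestAggregation:
    def test_hand_counted_example(self):
        trials = tiny_trials([(1, 1, i + 1, 0, c, r) for i, (c, r) in
                              enumerate([(1, 1), (1, 1), (1, 0), (0, 0)])])
        out = ek.aggregate_by_trajectory(trials)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["mu"] == pytest.approx(0.75)
        assert row["request_prop"] == pytest.approx(0.5)
        assert row["infogain"] == pytest.approx(0.811278, abs=1e-5)
        assert row["n_trials"] == 4

    def test_all_correct_zero_infogain(self):
        trials = tiny_trials([(1, 1, i + 1, 0, 1, 0) for i in range(5)])
        out = ek.aggregate_by_trajectory(trials)
        assert out.iloc[0]["mu"] == 1.0
        assert out.iloc[0]["infogain"] == 0.0

    def test_full_session_shape_and_count_conservation(self,
                                                       episodic_cohort,
                                                       episodic_aggregates):
        out = episodic_aggregates
        assert (out.groupby("participant_id").size() == 10).all()
        assert (out["n_trials"] == 80).all()
        totals = out.groupby("participant_id")["n_trials"].sum()
        per_trials = episodic_cohort.groupby("participant_id").size()
        assert (totals == per_trials).all()

    def test_empty_input(self):
        with pytest.raises(ValueError):
            ek.aggregate_by_trajectory(pd.DataFrame(columns=ek.TRIAL_COLUMNS))


class TestFeedbackDerivedAccuracy:
    def test_counts_successes_among_requests(self):
        trials = tiny_trials([
            (1, 1, 1, 0, 1, 1), (1, 1, 2, 0, 0, 1), (1, 1, 3, 0, 1, 1),
            (1, 1, 4, 0, 1, 0),
        ])
        out = ek.feedback_derived_accuracy(trials)
        assert out.iloc[0]["feedback_mu"] == pytest.approx(2 / 3)

    def test_no_requests_is_missing(self):
        trials = tiny_trials([(1, 1, 1, 0, 1, 0), (1, 1, 2, 0, 0, 0)])
        out = ek.feedback_derived_accuracy(trials)
        assert np.isnan(out.iloc[0]["feedback_mu"])

    def test_full_sampling_equals_mu(self, standard_schedule):
        agent = ek.AgentSpec(participant_id=1, trait_rate=1.0, seed=5)
        trials = ek.simulate_session(agent, standard_schedule, "constant")
        aggr = ek.aggregate_by_trajectory(trials)
        fda = ek.feedback_derived_accuracy(trials)
        merged = aggr.merge(fda, on=["participant_id", "trajectory_id"])
        np.testing.assert_allclose(merged["mu"], merged["feedback_mu"])


class TestGroupModel:
    def test_parameter_recovery(self):
        aggr = ek.synthetic_linear_cohort(n_agents=43, k_mean=0.10,
                                          alpha=0.30, seed=1)
        m = ek.fit_group_model(aggr)
        assert m.ci1[0] <= 0.30 <= m.ci1[1]
        assert m.ci0[0] <= 0.10 <= m.ci0[1]
        assert m.lrt_pvalue < 1e-6
        assert m.n_subjects == 43 and m.n_obs == 430

    def test_null_slope_recovered(self):
        aggr = ek.synthetic_linear_cohort(alpha=0.0, seed=3)
        m = ek.fit_group_model(aggr)
        assert m.ci1[0] <= 0.0 <= m.ci1[1]
        assert m.lrt_chi2 < 6.0

    def test_duplication_leaves_fixed_effects(self):
        aggr = ek.synthetic_linear_cohort(n_agents=10, seed=5)
        dup = aggr.copy()
        dup["participant_id"] += 1000
        m1 = ek.fit_group_model(aggr)
        m2 = ek.fit_group_model(pd.concat([aggr, dup], ignore_index=True))
        assert m2.beta0 == pytest.approx(m1.beta0, abs=0.02)
        assert m2.beta1 == pytest.approx(m1.beta1, abs=0.02)

    def test_variance_decomposition_fields(self):
        m = ek.fit_group_model(ek.synthetic_linear_cohort(seed=7))
        assert 0.0 <= m.icc <= 1.0
        assert 0.0 <= m.r2_conditional <= 1.0
        assert m.lrt_chi2 >= 0.0
        assert m.ci1[0] < m.ci1[1]
        assert len(m.subject_effects) == 43

    def test_too_few_participants(self):
        aggr = ek.synthetic_linear_cohort(n_agents=1, seed=0)
        with pytest.raises(ValueError):
            ek.fit_group_model(aggr)


class TestIndividualRegressions:
    def test_exact_linear_participant(self):
        aggr = pd.DataFrame({
            "participant_id": [1] * 5, "trajectory_id": range(5),
            "infogain": np.linspace(0.2, 1.0, 5),
            "request_prop": 0.1 + 0.3 * np.linspace(0.2, 1.0, 5)})
        out = ek.individual_regressions(aggr)
        assert out.iloc[0]["r"] == pytest.approx(1.0)
        assert out.iloc[0]["slope"] == pytest.approx(0.3)

    def test_degenerate_flagged(self):
        aggr = pd.DataFrame({
            "participant_id": [1] * 5, "trajectory_id": range(5),
            "infogain": np.linspace(0.2, 1.0, 5),
            "request_prop": [1.0] * 5})
        out = ek.individual_regressions(aggr)
        assert out.iloc[0]["degenerate"]
        assert np.isnan(out.iloc[0]["r"])

    def test_episodic_cohort_exceeds_null(self, episodic_aggregates):
        emp = ek.individual_regressions(episodic_aggregates)
        perm = ek.permutation_null(episodic_aggregates, n_perm=2000, seed=5)
        mean_emp = emp.loc[~emp["degenerate"], "r"].mean()
        assert mean_emp > perm.mean_r + 3 * perm.sd_r / np.sqrt(
            perm.n_participants)


class TestPermutationNull:
    def test_null_moments(self, episodic_aggregates):
        perm = ek.permutation_null(episodic_aggregates, n_perm=2000, seed=9)
        assert abs(perm.mean_r) < 0.02
        # SD -> 1/sqrt(n_points - 1) = 1/3 for 10 trajectories
        assert perm.sd_r == pytest.approx(1 / 3, abs=0.02)
        assert perm.crit_two_sided_05 > 0

    def test_permuted_data_mean_r_near_zero(self, episodic_aggregates):
        rng = np.random.default_rng(4)
        shuffled = episodic_aggregates.copy()
        shuffled["request_prop"] = (
            shuffled.groupby("participant_id")["request_prop"]
            .transform(lambda s: rng.permutation(s.to_numpy())))
        emp = ek.individual_regressions(shuffled)
        perm = ek.permutation_null(episodic_aggregates, n_perm=2000, seed=10)
        mean_r = emp.loc[~emp["degenerate"], "r"].mean()
        assert abs(mean_r) < 2 * perm.sd_r / np.sqrt(perm.n_participants) + 0.05

    def test_minimum_replicates_enforced(self, episodic_aggregates):
        with pytest.raises(ValueError):
            ek.permutation_null(episodic_aggregates, n_perm=500)

    def test_seeded_determinism(self, episodic_aggregates):
        p1 = ek.permutation_null(episodic_aggregates, n_perm=1000, seed=3)
        p2 = ek.permutation_null(episodic_aggregates, n_perm=1000, seed=3)
        np.testing.assert_array_equal(p1.null_rs, p2.null_rs)


def sticky_trials(n_agents=8, n_per_traj=80, p_after=0.6, p_other=0.3,
                  seed=0):
    """Agents whose request probability depends only on the previous
    same-trajectory request (Markov 'sticky' process)."""
    rng = np.random.default_rng(seed)
    rows = []
    trial = 0
    for pid in range(1, n_agents + 1):
        for tid in range(10):
            prev = 0
            for i in range(n_per_traj):
                trial += 1
                correct = int(rng.random() < 0.75)
                p = p_after if prev else p_other
                req = int(rng.random() < p)
                rows.append((pid, 1 + i // 10, trial, tid, correct, req))
                prev = req
    return tiny_trials(rows)


class TestConditionalRates:
    def test_iid_rates_equal(self, iid_cohort):
        out = ek.conditional_request_rates(iid_cohort, n_boot=500, seed=1)
        piv = out.pivot_table(index="trajectory_id", columns="condition",
                              values="rate")
        diff = (piv["prev_request"] - piv["prev_no_request"]).abs()
        assert diff.mean() < 0.05

    def test_sticky_agent_rates_recovered(self):
        out = ek.conditional_request_rates(sticky_trials(seed=2), n_boot=500,
                                           seed=3)
        piv = out.pivot_table(index="trajectory_id", columns="condition",
                              values="rate")
        assert piv["prev_request"].mean() == pytest.approx(0.6, abs=0.03)
        assert piv["prev_no_request"].mean() == pytest.approx(0.3, abs=0.03)

    def test_request_everything(self, standard_schedule):
        agent = ek.AgentSpec(participant_id=1, trait_rate=1.0, seed=2)
        trials = ek.simulate_session(agent, standard_schedule, "constant")
        out = ek.conditional_request_rates(trials, n_boot=200, seed=4)
        assert (out["rate"] == 1.0).all()
        assert "prev_no_request" not in set(out["condition"])


class TestBlockSummaries:
    def test_stationary_profile_flat(self, iid_cohort):
        out = ek.block_summaries(iid_cohort)
        assert len(out) == 8
        grand = out["accuracy"].mean()
        inside = ((out["accuracy_ci_low"] <= grand)
                  & (grand <= out["accuracy_ci_high"]))
        assert inside.all()

    def test_learning_agents_improve(self):
        agents = make_agents(12, 51, trait_rate=0.3, episodic_weight=0.0,
                             learning_halflife=15.0)
        trials = ek.simulate_cohort(agents, "constant", seed=52)
        out = ek.block_summaries(trials)
        assert out.iloc[0]["accuracy"] < out.iloc[-1]["accuracy"]
        assert out.iloc[-1]["accuracy_ci_low"] > out.iloc[0]["accuracy_ci_high"]

    def test_request_everything_rate_one(self, standard_schedule):
        agent = ek.AgentSpec(participant_id=1, trait_rate=1.0, seed=6)
        trials = ek.simulate_session(agent, standard_schedule, "constant")
        out = ek.block_summaries(trials)
        assert (out["request_rate"] == 1.0).all()


class TestFeedbackLearningRate:
    def test_stationary_rates_near_zero(self, iid_cohort):
        out, _ = ek.feedback_learning_rate(iid_cohort, fit_decay=False)
        assert out["normalized_rate"].abs().max() < 0.05

    def test_learning_cohort_decaying_positive(self):
        agents = make_agents(20, 61, trait_rate=0.4, episodic_weight=0.0,
                             learning_halflife=15.0)
        trials = ek.simulate_cohort(agents, "constant", seed=62)
        out, decay = ek.feedback_learning_rate(trials)
        assert out.iloc[0]["normalized_rate"] > out.iloc[-1]["normalized_rate"]
        assert out.iloc[0]["normalized_rate"] > 0
        assert decay is not None and decay["lam"] > 0

    def test_doubling_requests_halves_rate(self):
        rows = [(1, 1 + i // 100, i + 1, i % 10, int(i % 3 != 0), 0)
                for i in range(800)]
        base = tiny_trials(rows)
        quarter = base.copy()
        quarter["feedback_requested"] = (np.arange(800) % 4 == 0).astype(int)
        half = base.copy()
        half["feedback_requested"] = (np.arange(800) % 2 == 0).astype(int)
        r_q, _ = ek.feedback_learning_rate(quarter, fit_decay=False)
        r_h, _ = ek.feedback_learning_rate(half, fit_decay=False)
        np.testing.assert_allclose(r_h["normalized_rate"],
                                   r_q["normalized_rate"] / 2, atol=1e-12)


class TestPCA:
    def test_trait_only_cohort_dominated_by_first_component(self):
        rng = np.random.default_rng(71)
        agents = [ek.AgentSpec(participant_id=i + 1,
                               trait_rate=float(rng.uniform(0.05, 0.95)),
                               episodic_weight=0.0,
                               seed=int(rng.integers(2 ** 31)))
                  for i in range(40)]
        trials = ek.simulate_cohort(agents, "constant", seed=72)
        res = ek.pca_request_profiles(ek.aggregate_by_trajectory(trials))
        assert res.variance_shares[0] > 0.95
        # first component is the overall request rate: uniform-sign loadings
        assert (np.sign(res.first_loadings) == np.sign(
            res.first_loadings[0])).all()

    def test_two_orthogonal_factors(self):
        rng = np.random.default_rng(73)
        n = 60
        f1 = rng.normal(0, 1, n)
        f2 = rng.normal(0, 1, n)
        base = np.ones(10) / np.sqrt(10)
        contrast = np.array([1, -1] * 5) / np.sqrt(10)
        X = 0.5 + 0.1 * np.outer(f1, base) + 0.1 * np.outer(f2, contrast)
        aggr = pd.DataFrame({
            "participant_id": np.repeat(np.arange(n), 10),
            "trajectory_id": np.tile(np.arange(10), n),
            "request_prop": X.ravel()})
        res = ek.pca_request_profiles(aggr)
        assert res.variance_shares[0] == pytest.approx(
            res.variance_shares[1], rel=0.25)

    def test_shares_sum_to_one(self, episodic_aggregates):
        res = ek.pca_request_profiles(episodic_aggregates)
        assert res.variance_shares.sum() == pytest.approx(1.0, abs=1e-9)


class TestRequestHazard:
    def test_iid_hazard_flat(self, iid_cohort):
        hz = ek.request_hazard(iid_cohort, by_difficulty=False)
        hz = hz[hz["gap"] <= 8]
        assert hz["hazard"].max() - hz["hazard"].min() < 0.08
        assert hz["hazard"].mean() == pytest.approx(0.3, abs=0.03)

    def test_request_everything_hazard(self, standard_schedule):
        agent = ek.AgentSpec(participant_id=1, trait_rate=1.0, seed=8)
        trials = ek.simulate_session(agent, standard_schedule, "constant")
        hz = ek.request_hazard(trials, by_difficulty=False)
        assert list(hz["gap"]) == [1]
        assert hz.iloc[0]["hazard"] == 1.0

    def test_volatile_policy_hazard_increases(self):
        agents = make_agents(15, 81, trait_rate=0.05, episodic_weight=0.0,
                             parametric_weight=1.5, volatility=0.3)
        trials = ek.simulate_cohort(agents, "volatile-parametric", seed=82)
        hz = ek.request_hazard(trials, by_difficulty=False)
        early = hz[hz["gap"] == 1]
        late = hz[(hz["gap"] >= 6) & (hz["gap"] <= 8)]
        late_rate = late["n_requests"].sum() / late["n_at_risk"].sum()
        assert late_rate > float(early["hazard"].iloc[0]) + 0.05
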