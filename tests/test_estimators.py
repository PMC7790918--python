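import numpy as np
import pandas as pd
import pytest

import clustmsm as cm


class TestCumulativeIntensity:
    def test_toy_population_weighted_jumps(self, space, toy_table):
        # ACM: 1 / 3 at risk; TCM: (1*1) / (1*1 + (1/2)*2)
        acm = cm.cumulative_intensity(toy_table, space, "acm")
        tcm = cm.cumulative_intensity(toy_table, space, "tcm")
        assert acm.jumps_[0, 0] == pytest.approx(1 / 3)
        assert tcm.jumps_[0, 0] == pytest.approx(1 / 2)

    def test_no_transitions_gives_zero_estimate(self, space):
        df = pd.DataFrame({
            "cluster": [1], "id": [1], "entry": [0.0], "exit": [1.0],
            "from": [1], "to": [0],
        })
        est = cm.cumulative_intensity(df, space)
        assert est.predict([2.0]).sum() == 0.0

    def test_nondecreasing_and_zero_at_origin(self, space):
        df = cm.simulate_trial(cm.SimConfig(n_clusters=20, size_range=(2, 5)), seed=3)
        est = cm.cumulative_intensity(df, space)
        assert (np.diff(est.cum_, axis=0) >= -1e-12).all()
        assert est.predict([0.0]).sum() == 0.0


class TestTransitionProbability:
    def test_product_integral_hand_value(self, space):
        # jumps: dA12(1) = 1/2, dA13(2) = 1 on the survivor, dA23(2.5) = 1
        df = pd.DataFrame({
            "cluster": [1, 1, 1],
            "id": [1, 1, 2],
            "entry": [0.0, 1.0, 0.0],
            "exit": [1.0, 2.5, 2.0],
            "from": [1, 2, 1],
            "to": [2, 3, 3],
        })
        est = cm.transition_probability(df, space)
        P = est.predict([2.0])[0]
        assert P[0] == pytest.approx([0.0, 0.5, 0.5])
        P = est.predict([3.0])[0]
        assert P[0] == pytest.approx([0.0, 0.0, 1.0])

    def test_rows_stochastic_and_identity_at_origin(self, space):
        df = cm.simulate_trial(cm.SimConfig(n_clusters=25, size_range=(2, 6)), seed=7)
        est = cm.transition_probability(df, space)
        assert np.allclose(est.prob_.sum(axis=2), 1.0, atol=1e-10)
        assert (est.prob_ >= -1e-12).all()
        assert np.allclose(est.predict([0.0])[0], np.eye(3))
        # absorbing state stays put
        assert np.allclose(est.prob_[:, 2, 2], 1.0)

    def test_fixed_cluster_size_acm_equals_tcm(self, space):
        df = cm.simulate_trial(cm.SimConfig(n_clusters=30, size_range=(4, 4)), seed=8)
        a = cm.transition_probability(df, space, population="acm")
        t = cm.transition_probability(df, space, population="tcm")
        assert np.array_equal(a.prob_, t.prob_)

    def test_matches_iid_aalen_johansen(self, space):
        """Size-1 clusters reduce to the classical Aalen-Johansen estimator."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(12)
        n = 800
        T1 = rng.exponential(1.0, n)
        dest = np.where(rng.random(n) < 0.4, 3, 2)
        C = rng.uniform(0, 3, n)
        obs = T1 <= C
        df = pd.DataFrame({
            "cluster": np.arange(n), "id": np.arange(n), "entry": 0.0,
            "exit": np.minimum(T1, C), "from": 1,
            "to": np.where(obs, dest, 0),
        })
        est = cm.transition_probability(df, space)
        aj = lifelines.AalenJohansenFitter(calculate_variance=False)
        aj.fit(np.minimum(T1, C), np.where(obs, dest, 0), event_of_interest=2)
        grid = np.array([0.3, 0.8, 1.5, 2.5])
        ours = est.predict(grid)[:, 0, 1]
        ref_t = aj.cumulative_density_.index.values
        ref_v = aj.cumulative_density_.values[:, 0]
        theirs = ref_v[np.searchsorted(ref_t, grid, side="right") - 1]
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_landmark_equals_plain_when_everyone_qualifies(self, space):
        df = cm.simulate_trial(cm.SimConfig(n_clusters=15, size_range=(2, 4)), seed=5)
        plain = cm.transition_probability(df, space, 0.0)
        lm = cm.transition_probability(df, space, 0.0, landmark=1)
        assert np.allclose(plain.prob_, lm.prob_)

    def test_landmark_recovers_non_markov_transition_probability(self, space):
        """At s > 0 the landmark estimator is consistent; averaged over
        replicates it tracks the closed-form truth closely."""
        cfg = cm.SimConfig(n_clusters=300, size_range=(5, 15))
        tt = np.array([1.0, 2.0])
        truth = cm.true_transition_12(cfg, 0.5, tt, "acm")
        vals = np.zeros((10, 2))
        for r in range(10):
            df = cm.simulate_trial(cfg, seed=60 + r)
            est = cm.transition_probability(df, space, 0.5, landmark=1, validate=False)
            vals[r] = est.predict(tt)[:, 0, 1]
        assert np.abs(vals.mean(0) - truth).max() < 0.01


class TestProductIntegral:
    def test_zero_intensity_gives_identity(self, space):
        df = pd.DataFrame({
            "cluster": [1], "id": [1], "entry": [0.0], "exit": [1.0],
            "from": [1], "to": [0],
        })
        ci = cm.cumulative_intensity(df, space)
        tp = cm.product_integral(ci)
        assert np.allclose(tp.predict([0.5, 2.0]), np.eye(3))

    def test_composes_to_transition_probability(self, space):
        df = cm.simulate_trial(cm.SimConfig(n_clusters=15, size_range=(2, 5)), seed=4)
        ci = cm.cumulative_intensity(df, space)
        direct = cm.transition_probability(df, space)
        via = cm.product_integral(ci)
        assert np.array_equal(via.prob_, direct.prob_)
        assert np.allclose(via.prob_.sum(axis=2), 1.0, atol=1e-10)


class TestStateOccupation:
    def test_occupation_sums_to_one(self, space):
        df = cm.simulate_trial(cm.SimConfig(n_clusters=25, size_range=(2, 6)), seed=11)
        est = cm.state_occupation(df, space)
        assert np.allclose(est.occupation_.sum(axis=1), 1.0, atol=1e-10)

    def test_single_initial_state_reduces_to_transition_probability(self, space):
        df = cm.simulate_trial(cm.SimConfig(n_clusters=25, size_range=(2, 6)), seed=11)
        occ = cm.state_occupation(df, space)
        tp = cm.transition_probability(df, space)
        assert np.allclose(occ.curve(2), tp.curve(1, 2))
        assert occ.pi_ == 1.0

    def test_death_occupation_monotone(self, space):
        df = cm.simulate_trial(cm.SimConfig(n_clusters=25, size_range=(2, 6)), seed=13)
        est = cm.state_occupation(df, space)
        assert (np.diff(est.curve(3)) >= -1e-12).all()

    def test_fixed_cluster_size_acm_equals_tcm(self, space):
        df = cm.simulate_trial(cm.SimConfig(n_clusters=30, size_range=(5, 5)), seed=14)
        a = cm.state_occupation(df, space, "acm")
        t = cm.state_occupation(df, space, "tcm")
        assert np.array_equal(a.occupation_, t.occupation_)

    def test_estimator_consistency_improves_with_n(self, space):
        """Sup-distance to the closed-form truth shrinks with the number of
        clusters and is small at n=400."""
        grid = np.linspace(0.1, 2.0, 40)
        sup = {}
        for n in (100, 400):
            cfg = cm.SimConfig(n_clusters=n, size_range=(10, 30))
            truth = cm.true_occupation(cfg, grid, "acm")
            d = []
            for r in range(50):
                df = cm.simulate_trial(cfg, seed=1000 * n + r)
                est = cm.StateOccupation(space, "acm", validate=False).fit(df)
                d.append(np.abs(est.predict(grid)[:, 1] - truth).max())
            sup[n] = np.mean(d)
        assert sup[400] < sup[100]
        assert sup[400] < 0.02

    def test_truncation_subset_keeps_occupation_consistent(self, space):
        cfg = cm.SimConfig(n_clusters=400, size_range=(5, 15), truncation="mixed")
        grid = np.array([0.5, 1.0, 2.0])
        truth = cm.true_occupation(cfg, grid, "acm")
        vals = np.zeros((10, 3))
        for r in range(10):
            df = cm.simulate_trial(cfg, seed=300 + r)
            est = cm.StateOccupation(space, "acm", validate=False).fit(df)
            assert est.truncated_ and est.pi_ < 1.0
            vals[r] = est.predict(grid)[:, 1]
        assert np.abs(vals.mean(0) - truth).max() < 0.01


class TestPiHat:
    def test_one_without_truncation(self, space, toy_table):
        p = cm.build_cluster_processes(toy_table, space)
        assert cm.pi_hat(p) == 1.0

    def test_direct_formula_single_cluster(self, space):
        df = pd.DataFrame({
            "cluster": 1, "id": [1, 2, 3, 4],
            "entry": [0.0, 0.0, 0.0, 0.4], "exit": [1.0] * 4,
            "from": [1] * 4, "to": [0] * 4,
        })
        assert cm.pi_hat(cm.build_cluster_processes(df, space)) == pytest.approx(0.75)

    def test_direct_formula_two_clusters(self, space):
        df = pd.DataFrame({
            "cluster": [1, 1, 2, 2, 2, 2],
            "id": [1, 2, 3, 4, 5, 6],
            "entry": [0.0, 0.5, 0.0, 0.0, 0.0, 0.0],
            "exit": [1.0] * 6,
            "from": [1] * 6, "to": [0] * 6,
        })
        # (1/2 * 1 + 1/4 * 4) / 2 = 0.75
        assert cm.pi_hat(cm.build_cluster_processes(df, space)) == pytest.approx(0.75)


def test_acm_tcm_gap_driven_by_informative_cluster_size(space):
    """The ACM-TCM difference is systematic under the size-linked intensity
    shift and vanishes when the shift is removed."""
    t = np.array([1.0])
    with_ics = cm.SimConfig(n_clusters=80, size_range=(5, 15))
    no_ics = cm.SimConfig(n_clusters=80, size_range=(5, 15), ics_bump=1e-12)
    gap_true = cm.true_occupation(with_ics, t, "tcm") - cm.true_occupation(with_ics, t, "acm")
    assert gap_true[0] > 0.005
    assert np.abs(
        cm.true_occupation(no_ics, t, "tcm") - cm.true_occupation(no_ics, t, "acm")
    )[0] < 1e-12
    gaps = []
    for r in range(20):
        df = cm.simulate_trial(with_ics, seed=700 + r)
        a = cm.StateOccupation(space, "acm", validate=False).fit(df)
        tc = cm.StateOccupation(space, "tcm", validate=False).fit(df)
        gaps.append(tc.predict(t)[0, 1] - a.predict(t)[0, 1])
    assert np.mean(gaps) == pytest.approx(gap_true[0], abs=0.01)
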