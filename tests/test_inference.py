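import numpy as np
import pandas as pd
import pytest

import clustmsm as cm
from clustmsm.inference import (
    bootstrap_curves,
    cluster_bootstrap,
    confidence_band,
    influence_occupation,
    influence_transition,
    multiplier_draws,
    pointwise_ci,
    working_independence_influence,
    working_independence_variance,
)


@pytest.fixture(scope="module")
def fitted(space, sim_data):
    df, cfg = sim_data
    return cm.state_occupation(df, space, "acm")


class TestInfluence:
    def test_centering(self, fitted):
        infl = influence_occupation(fitted, 2)
        assert np.abs(infl.gamma.sum(axis=0)).max() < 1e-8

    def test_single_cluster_influence_vanishes(self, space):
        df = cm.simulate_trial(cm.SimConfig(n_clusters=1, size_range=(5, 5)), seed=2)
        est = cm.state_occupation(df, space)
        infl = influence_occupation(est, 2)
        assert np.abs(infl.gamma).max() < 1e-12

    def test_occupation_reduces_to_transition_without_truncation(self, space, fitted):
        psi = influence_occupation(fitted, 2)
        tp = cm.transition_probability(fitted.episodes_, space, validate=False)
        gam = influence_transition(tp, 1, 2)
        assert np.allclose(psi.gamma, gam.gamma)

    def test_invariant_to_cluster_relabeling_and_row_order(self, space):
        df = cm.simulate_trial(cm.SimConfig(n_clusters=20, size_range=(2, 5)), seed=6)
        v1 = influence_occupation(cm.state_occupation(df, space), 2).variance()
        shuffled = df.sample(frac=1.0, random_state=0)
        shuffled["cluster"] = 1000 - shuffled["cluster"]
        v2 = influence_occupation(cm.state_occupation(shuffled, space), 2).variance()
        assert np.allclose(v1, v2)

    def test_variance_matches_cluster_bootstrap(self, space, fitted):
        """Influence-function and cluster-bootstrap variances agree (the
        two inference routes estimate the same limit covariance)."""
        se_if = influence_occupation(fitted, 2).se()[-1]
        curves = bootstrap_curves(fitted, 2, 2000, seed=3)
        se_cb = curves[:, -1].std(ddof=1)
        assert se_if / se_cb == pytest.approx(1.0, abs=0.1)

    def test_size_one_clusters_match_independence_variance(self, space):
        """With size-1 clusters the cluster-robust variance agrees with the
        classical i.i.d. Greenwood-type variance."""
        cfg = cm.SimConfig(n_clusters=500, size_range=(1, 1))
        df = cm.simulate_trial(cfg, seed=8)
        est = cm.state_occupation(df, space)
        v_robust = influence_occupation(est, 2).se()[-1] ** 2
        v_naive = working_independence_variance(est, 2)[-1]
        assert v_robust / v_naive == pytest.approx(1.0, abs=0.1)

    def test_greenwood_recursion_matches_subject_influence(self, space, fitted):
        v_rec = working_independence_variance(fitted, 2)
        v_if = working_independence_influence(fitted, 2).se() ** 2
        ok = v_if > 0
        ratio = v_rec[ok] / v_if[ok]
        # the recursion drops between-time cross terms, so the two differ
        # slightly where risk sets are small (late times)
        assert np.median(ratio) == pytest.approx(1.0, abs=0.02)
        assert np.abs(ratio - 1.0).max() < 0.15


class TestMultiplier:
    def test_zero_influence_gives_zero_draws(self, fitted):
        infl = influence_occupation(fitted, 2)
        zero = cm.InfluenceSet(infl.kind, infl.population, infl.target,
                               infl.times, np.zeros_like(infl.gamma))
        out = multiplier_draws(zero, 50, seed=0)
        assert np.abs(out["processes"]).max() == 0.0

    def test_seeded_reproducibility(self, fitted):
        infl = influence_occupation(fitted, 2)
        a = multiplier_draws(infl, 25, seed=42)["processes"]
        b = multiplier_draws(infl, 25, seed=42)["processes"]
        assert np.array_equal(a, b)

    def test_conditional_normal_scale(self, fitted):
        """At fixed t the multiplier process is exactly normal with the
        influence-function variance, conditionally on the data."""
        infl = influence_occupation(fitted, 2)
        B = multiplier_draws(infl, 20000, seed=1)["processes"]
        target = np.sqrt((infl.gamma[:, -1] ** 2).sum() / infl.n)
        assert B[:, -1].std() == pytest.approx(target, rel=0.02)


class TestClusterBootstrap:
    def test_single_cluster_has_zero_variance(self, space):
        df = cm.simulate_trial(cm.SimConfig(n_clusters=1, size_range=(4, 4)), seed=1)
        vals, orig = cluster_bootstrap(df, 20, lambda t: t["id"].nunique(), seed=0)
        assert np.var(vals) == 0.0 and orig == 4

    def test_mean_cluster_size_variance_oracle(self, space):
        """Bootstrap variance of the mean cluster size approximates the
        closed form var(M)/n."""
        df = cm.simulate_trial(cm.SimConfig(n_clusters=60, size_range=(2, 12)), seed=5)
        sizes = df.groupby("cluster")["id"].nunique()
        stat = lambda t: t.groupby("cluster")["id"].nunique().mean()
        vals, _ = cluster_bootstrap(df, 4000, stat, seed=11)
        expected = sizes.var(ddof=1) / len(sizes)
        assert np.var(vals) == pytest.approx(expected, rel=0.15)

    def test_seeded_reproducibility(self, space):
        df = cm.simulate_trial(cm.SimConfig(n_clusters=10, size_range=(2, 4)), seed=5)
        stat = lambda t: t["exit"].sum()
        a, _ = cluster_bootstrap(df, 15, stat, seed=3)
        b, _ = cluster_bootstrap(df, 15, stat, seed=3)
        assert a == b

    def test_fast_curve_bootstrap_matches_table_bootstrap(self, space):
        """The vectorised process-level resampling is distributionally the
        same as rebuilding the episode table per resample."""
        df = cm.simulate_trial(cm.SimConfig(n_clusters=50, size_range=(2, 6)), seed=9)
        est = cm.state_occupation(df, space)
        tstar = est.times_[-1]
        fast = bootstrap_curves(est, 2, 800, seed=1)[:, -1]
        stat = lambda t: cm.StateOccupation(
            est.state_space, "acm", validate=False
        ).fit(t).predict([tstar])[0, 1]
        slow, _ = cluster_bootstrap(df, 800, stat, seed=2)
        assert np.std(fast) == pytest.approx(np.std(slow), rel=0.15)
        assert np.mean(fast) == pytest.approx(np.mean(slow), abs=0.01)


class TestPointwiseCI:
    def test_zero_variance_degenerates(self):
        lo, hi = pointwise_ci(0.4, 0.0)
        assert lo == hi == pytest.approx(0.4)

    def test_identity_transform_is_plain_wald(self):
        lo, hi = pointwise_ci(0.4, 0.01, transform="identity")
        assert lo == pytest.approx(0.4 - 1.959963984540054 * 0.1)
        assert hi == pytest.approx(0.4 + 1.959963984540054 * 0.1)

    def test_loglog_hand_value(self):
        # hand-computed transform-and-back values for p=0.5, se=0.05
        lo, hi = pointwise_ci(0.5, 0.05**2, transform="loglog")
        assert lo == pytest.approx(0.3986540641967188, abs=1e-12)
        assert hi == pytest.approx(0.5930812349979647, abs=1e-12)

    def test_boundary_estimate_returns_point_interval(self):
        lo, hi = pointwise_ci(0.0, 0.01, transform="loglog")
        assert lo == 0.0 and hi == 0.0


class TestConfidenceBand:
    def test_band_contains_estimate(self, fitted):
        band = confidence_band(fitted, 2, method="multiplier", n_draws=300, seed=4)
        assert (band.lower <= band.estimate + 1e-12).all()
        assert (band.upper >= band.estimate - 1e-12).all()
        assert (band.lower >= 0).all() and (band.upper <= 1).all()

    def test_critical_value_nested_in_interval(self, fitted):
        t1, t2 = np.quantile(fitted.times_, [0.3, 0.6])
        t2w = np.quantile(fitted.times_, 0.9)
        narrow = confidence_band(fitted, 2, interval=(t1, t2),
                                 method="multiplier", n_draws=500, seed=9)
        wide = confidence_band(fitted, 2, interval=(t1, t2w),
                               method="multiplier", n_draws=500, seed=9)
        assert narrow.c_alpha <= wide.c_alpha

    def test_multiplier_and_bootstrap_agree(self, fitted):
        """The two routes to the band critical value target the same
        limiting distribution (equivalence of the wild and cluster
        bootstrap)."""
        b1 = confidence_band(fitted, 2, method="multiplier", n_draws=2000, seed=1)
        b2 = confidence_band(fitted, 2, method="bootstrap", n_draws=2000, seed=2)
        assert b1.c_alpha / b2.c_alpha == pytest.approx(1.0, abs=0.05)

    def test_seeded_reproducibility(self, fitted):
        b1 = confidence_band(fitted, 2, method="bootstrap", n_draws=200, seed=7)
        b2 = confidence_band(fitted, 2, method="bootstrap", n_draws=200, seed=7)
        assert b1.c_alpha == b2.c_alpha
        assert np.array_equal(b1.lower, b2.lower)

    def test_few_draws_warns(self, fitted):
        with pytest.warns(UserWarning, match="fewer than 100"):
            confidence_band(fitted, 2, method="multiplier", n_draws=50, seed=0)
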