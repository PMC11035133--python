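"""Trajectory extraction, scenario clustering (k-means and PAM), labelling,
season weighting, and the weighted summaries."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import malisorghum as ms
from malisorghum.envirotyping import (
    EARLY_PREFLOWER_STRESS,
    FLOWERING_STRESS,
    N_INTERVALS,
    NO_STRESS,
    ScenarioAssignment,
    ScenarioLabelingError,
    TrajectoryExclusionError,
    _interval_index,
)

# ---------------------------------------------------------------------------
# Archetype trajectories (the three recurring drought patterns): flat no
# stress; decline starting ~200 degCd before flowering; decline starting at
# flowering.  Used as ground truth for cluster recovery.
# ---------------------------------------------------------------------------
ARCHETYPES = {
    NO_STRESS: np.ones(8),
    EARLY_PREFLOWER_STRESS: np.array([1.0, 1.0, 0.8, 0.6, 0.45, 0.35, 0.3, 0.25]),
    FLOWERING_STRESS: np.array([1.0, 1.0, 1.0, 1.0, 0.85, 0.65, 0.5, 0.4]),
}


def archetype_sample(n_per: int, noise_sd: float, seed: int):
    rng = np.random.default_rng(seed)
    X, labels = [], []
    for k, (name, base) in enumerate(ARCHETYPES.items()):
        for _ in range(n_per):
            x = np.clip(base + rng.normal(0, noise_sd, 8), 1e-3, 1.0)
            X.append(x)
            labels.append(k)
    return np.array(X), np.array(labels)


def brute_force_interval_means(sd, tt, flowering_index):
    """Oracle: day-by-day scan assigning each day's S/D to the 100-degCd
    interval containing its cumulative thermal distance from flowering."""
    cum = np.cumsum(tt)
    sums, counts = np.zeros(8), np.zeros(8)
    for i, s in enumerate(sd):
        p = cum[i] - cum[flowering_index]
        if p < -400 or p > 400:
            continue
        if p < 0:
            idx = min(int((p + 400) // 100), 3)
        else:
            idx = 4 if p == 0 else 4 + min(int(np.ceil(p / 100)) - 1, 3)
        sums[idx] += s
        counts[idx] += 1
    return sums / counts


class TestExtraction:
    def test_constant_unity_series(self):
        tt = np.full(80, 16.0)
        traj = ms.extract_trajectory(np.ones(80), tt, flowering_index=40)
        np.testing.assert_allclose(traj.values, np.ones(8))

    def test_step_at_flowering(self):
        tt = np.full(80, 16.0)
        sd = np.where(np.arange(80) <= 40, 1.0, 0.4)
        # flowering day itself lands in the first post-flowering interval
        traj = ms.extract_trajectory(sd, tt, flowering_index=40)
        np.testing.assert_allclose(traj.values[:4], 1.0)
        assert traj.values[4] < 1.0  # flowering day (sd=1) averaged with 0.4
        np.testing.assert_allclose(traj.values[5:], 0.4)

    def test_linear_decline_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        tt = rng.uniform(10, 19, 90)
        sd = np.clip(1.0 - 0.008 * np.arange(90) + rng.normal(0, 0.02, 90),
                     0.05, 1.0)
        traj = ms.extract_trajectory(sd, tt, flowering_index=45)
        np.testing.assert_allclose(
            traj.values, brute_force_interval_means(sd, tt, 45), atol=1e-12)

    def test_insufficient_preflowering_span_excluded(self):
        tt = np.full(60, 16.0)
        with pytest.raises(TrajectoryExclusionError, match="before"):
            ms.extract_trajectory(np.ones(60), tt, flowering_index=10)

    def test_insufficient_postflowering_span_excluded(self):
        tt = np.full(60, 16.0)
        with pytest.raises(TrajectoryExclusionError, match="after"):
            ms.extract_trajectory(np.ones(60), tt, flowering_index=50)

    def test_interval_edges(self):
        assert _interval_index(-400.0) == 0
        assert _interval_index(-100.0) == 3
        assert _interval_index(0.0) == 4
        assert _interval_index(100.0) == 4
        assert _interval_index(100.1) == 5
        assert _interval_index(400.0) == 7
        assert _interval_index(400.1) is None


class TestClustering:
    def test_k1_centroid_is_grand_mean(self):
        X, _ = archetype_sample(10, 0.03, seed=1)
        est = ms.DroughtScenarioClassifier(n_clusters=1).fit(X)
        np.testing.assert_allclose(est.cluster_centers_[0], X.mean(axis=0),
                                   atol=1e-9)

    @pytest.mark.parametrize("method", ["kmeans", "pam"])
    def test_recovers_archetype_labels_perfectly_when_separated(self, method):
        X, truth = archetype_sample(15, 0.03, seed=2)
        est = ms.DroughtScenarioClassifier(method=method, random_state=0)
        labels = est.fit_predict(X)
        assert adjusted_rand_score(truth, labels) == 1.0

    @pytest.mark.parametrize("method", ["kmeans", "pam"])
    def test_recovery_ari_above_090_with_noise(self, method):
        X, truth = archetype_sample(20, 0.05, seed=3)
        est = ms.DroughtScenarioClassifier(method=method, random_state=0)
        labels = est.fit_predict(X)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_kmeans_and_pam_agree_on_separated_data(self):
        X, _ = archetype_sample(12, 0.02, seed=4)
        a = ms.DroughtScenarioClassifier(method="kmeans", random_state=0).fit_predict(X)
        b = ms.DroughtScenarioClassifier(method="pam", random_state=0).fit_predict(X)
        assert adjusted_rand_score(a, b) == 1.0

    def test_deterministic_given_seed(self):
        X, _ = archetype_sample(10, 0.05, seed=5)
        a = ms.DroughtScenarioClassifier(random_state=7).fit(X)
        b = ms.DroughtScenarioClassifier(random_state=7).fit(X)
        np.testing.assert_array_equal(a.labels_, b.labels_)
        np.testing.assert_allclose(a.cluster_centers_, b.cluster_centers_)

    def test_too_few_distinct_points_rejected(self):
        X = np.ones((5, 8))
        with pytest.raises(ValueError, match="distinct"):
            ms.DroughtScenarioClassifier(n_clusters=3).fit(X)

    def test_estimator_params_roundtrip(self):
        est = ms.DroughtScenarioClassifier(n_clusters=4, method="pam")
        assert est.get_params()["n_clusters"] == 4
        est.set_params(method="kmeans")
        assert est.method == "kmeans"


class TestLabeling:
    def test_archetype_centroids_labelled_by_construction(self):
        names = list(ARCHETYPES)
        centroids = np.array([ARCHETYPES[n] for n in names])
        assert ms.label_scenarios(centroids) == tuple(names)

    def test_order_invariance(self):
        names = list(ARCHETYPES)
        centroids = np.array([ARCHETYPES[n] for n in names])
        perm = [2, 0, 1]
        permuted = ms.label_scenarios(centroids[perm])
        assert tuple(permuted[i] for i in np.argsort(perm)) == tuple(names)

    def test_all_flat_centroids_ambiguous(self):
        centroids = np.vstack([np.ones(8), np.full(8, 0.99), np.full(8, 0.97)])
        with pytest.raises(ScenarioLabelingError):
            ms.label_scenarios(centroids)


class TestWeighting:
    def test_symmetric_counts(self):
        spec = ms.WeightingSpec({"a": 10, "b": 10, "c": 10})
        for iso in "abc":
            assert ms.season_weight(spec, iso) == pytest.approx(1.0 / 30.0)

    def test_asymmetric_counts_equalise_totals(self):
        spec = ms.WeightingSpec({"a": 10, "b": 20})
        wa, wb = ms.season_weight(spec, "a"), ms.season_weight(spec, "b")
        assert wa == pytest.approx(20.0 / (30.0 * 10.0))
        assert wb == pytest.approx(20.0 / (30.0 * 20.0))
        assert 10 * wa == pytest.approx(20 * wb) == pytest.approx(2.0 / 3.0)

    def test_scale_invariant_shares(self):
        spec1 = ms.WeightingSpec({"a": 5, "b": 15})
        spec2 = ms.WeightingSpec({"a": 50, "b": 150})
        tot1 = {z: spec1.seasons_in_isohyet[z] * ms.season_weight(spec1, z)
                for z in "ab"}
        tot2 = {z: spec2.seasons_in_isohyet[z] * ms.season_weight(spec2, z)
                for z in "ab"}
        s1, s2 = sum(tot1.values()), sum(tot2.values())
        for z in "ab":
            assert tot1[z] / s1 == pytest.approx(tot2[z] / s2)

    def test_empty_isohyet_rejected(self):
        with pytest.raises(ValueError):
            ms.WeightingSpec({"a": 0, "b": 5})


def toy_assignment():
    """Four hand-built runs in two isohyets with known scenarios."""
    def traj(iso, soil, cv, vals):
        return ms.SDTrajectory(run_id=("s", 0, soil, cv),
                               values=np.array(vals), flowering_doy=250,
                               grain_yield=1000.0, isohyet=iso)
    flat = [1.0] * 8
    low = [1.0, 1.0, 1.0, 1.0, 0.8, 0.6, 0.5, 0.4]
    trajectories = [
        traj("a", "low", "x", flat), traj("a", "low", "x", low),
        traj("b", "low", "x", flat), traj("b", "low", "x", flat)]
    assignment = ScenarioAssignment(
        trajectories=trajectories,
        cluster_index=np.array([0, 1, 0, 0]),
        centroids=np.vstack([flat, low, [1.0]*4 + [0.5]*4]),
        scenario_names=(NO_STRESS, FLOWERING_STRESS, EARLY_PREFLOWER_STRESS),
        method="kmeans")
    return assignment, ms.WeightingSpec({"a": 2, "b": 2})


class TestSummaries:
    def test_single_scenario_is_100pct(self):
        assignment, spec = toy_assignment()
        only_b = ScenarioAssignment(
            trajectories=assignment.trajectories[2:],
            cluster_index=np.array([0, 0]),
            centroids=assignment.centroids,
            scenario_names=assignment.scenario_names, method="kmeans")
        table = ms.frequency_table(only_b, spec, group_by=("isohyet",))
        assert table.loc["b", NO_STRESS] == pytest.approx(100.0)
        assert table.loc["b", FLOWERING_STRESS] == 0.0

    def test_toy_percentages_match_weighted_count_oracle(self):
        assignment, spec = toy_assignment()
        table = ms.frequency_table(assignment, spec, group_by=("isohyet",))
        # isohyet a: one no-stress, one flowering-stress run, equal weights
        assert table.loc["a", NO_STRESS] == pytest.approx(50.0)
        assert table.loc["a", FLOWERING_STRESS] == pytest.approx(50.0)
        assert np.allclose(table.sum(axis=1), 100.0, atol=1e-9)

    def test_equal_weights_reduce_to_raw_proportions(self):
        assignment, _ = toy_assignment()
        spec = ms.WeightingSpec({"a": 7, "b": 7})  # equal -> equal weights
        table = ms.frequency_table(assignment, spec, group_by=("isohyet",))
        assert table.loc["a", NO_STRESS] == pytest.approx(50.0)
        assert table.loc["b", NO_STRESS] == pytest.approx(100.0)


class TestYieldCPF:
    def test_identical_yields_single_step(self):
        curve = ms.yield_cpf([1500.0, 1500.0, 1500.0])
        assert len(curve) == 1
        assert curve["cpf"].iloc[0] == pytest.approx(1.0)

    def test_unweighted_quartiles(self):
        curve = ms.yield_cpf([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(curve["cpf"], [0.25, 0.5, 0.75, 1.0])

    def test_weighted_matches_replication_oracle(self):
        yields = [10.0, 20.0, 30.0]
        weights = [1.0, 3.0, 2.0]
        weighted = ms.yield_cpf(yields, weights)
        replicated = ms.yield_cpf([10.0] + [20.0] * 3 + [30.0] * 2)
        pd.testing.assert_frame_equal(weighted, replicated)

    def test_monotone_non_decreasing(self):
        rng = np.random.default_rng(0)
        curve = ms.yield_cpf(rng.uniform(500, 3000, 50), rng.uniform(0.5, 2, 50))
        assert np.all(np.diff(curve["cpf"]) >= 0)
        assert curve["cpf"].iloc[-1] == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ms.yield_cpf([])
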