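import networkx as nx
import numpy as np
import pytest

import fcbrainage as f
import _oracles as orc
from fcbrainage.graphmetrics import (
    _GraphContext,
    _REGISTRY,
    default_catalog,
    vectors_to_frame,
)
from conftest import make_connectivity, random_z_matrix


class TestCatalog:
    def test_default_catalog_shape(self):
        cat = default_catalog()
        assert len(cat.entries) == 26
        assert sum(e.matrix_form == "binarized" for e in cat.entries) == 5
        assert len({e.name for e in cat.entries}) == 26

    def test_yaml_roundtrip(self, tmp_path):
        cat = default_catalog()
        cat.to_yaml(tmp_path / "cat.yaml")
        back = f.MetricCatalog.from_yaml(tmp_path / "cat.yaml")
        assert back.names == cat.names

    def test_unknown_metric_rejected(self):
        from fcbrainage.graphmetrics import MetricDef

        with pytest.raises(ValueError, match="unknown"):
            f.MetricCatalog([MetricDef("no_such_metric", "weighted", "mean")])


class TestThresholdDensity:
    @pytest.mark.parametrize("n", [10, 60, 238])
    def test_exact_edge_count(self, rng, n):
        z = random_z_matrix(rng, n)
        adj = f.threshold_density(z, 0.05)
        expected = int(round(0.05 * n * (n - 1) / 2))
        assert adj.sum() // 2 == expected
        if n == 238:
            assert expected == 1410

    def test_selects_largest_weights(self, rng):
        z = np.zeros((5, 5))
        iu = np.triu_indices(5, 1)
        z[iu] = np.arange(10, 0, -1, dtype=float)
        z = z + z.T
        adj = f.threshold_density(z, 0.2)
        # the 2 largest weights are at the first two upper-triangle slots
        assert adj[iu[0][0], iu[1][0]] == 1 and adj[iu[0][1], iu[1][1]] == 1
        assert adj.sum() == 4

    def test_tie_break_lexicographic(self):
        z = np.ones((6, 6)) - np.eye(6)
        adj = f.threshold_density(z, 0.2)  # round(0.2*15)=3 edges
        iu = np.triu_indices(6, 1)
        kept = [(i, j) for i, j in zip(*iu) if adj[i, j]]
        assert kept == [(0, 1), (0, 2), (0, 3)]

    def test_zero_edge_density_rejected(self, rng):
        with pytest.raises(ValueError, match="zero edges"):
            f.threshold_density(random_z_matrix(rng, 5), 0.01)


class TestSmallWorldness:
    def test_random_graph_near_unity(self):
        g = nx.gnm_random_graph(80, 400, seed=1)
        adj = nx.to_numpy_array(g)
        sw = f.small_worldness(adj, n_null=50, seed=0)
        assert 0.7 < sw < 1.3

    def test_watts_strogatz_exceeds_unity(self):
        g = nx.watts_strogatz_graph(100, 6, 0.1, seed=2)
        adj = nx.to_numpy_array(g)
        sw = f.small_worldness(adj, n_null=50, seed=0)
        assert sw > 1.0

    def test_null_count_stability(self):
        g = nx.watts_strogatz_graph(60, 6, 0.2, seed=3)
        adj = nx.to_numpy_array(g)
        values = [f.small_worldness(adj, n_null=20, seed=s) for s in range(6)]
        doubled = f.small_worldness(adj, n_null=40, seed=100)
        assert abs(doubled - np.mean(values)) < 2 * np.std(values) + 1e-9


class TestResilience:
    def test_power_law_exponent_recovered(self, rng):
        # degrees from P(k) ~ k^-2 on k in [1, 1000]
        u = rng.random(10000)
        kmax = 1000.0
        degrees = 1.0 / (1 - u * (1 - 1 / kmax))
        slope = f.resilience(degrees)
        assert slope == pytest.approx(-2.0, abs=0.2)

    def test_regular_graph_rejected(self):
        with pytest.raises(ValueError, match="degenerate|single"):
            f.resilience(np.full(50, 6.0))

    def test_count_scaling_invariance(self, rng):
        deg = rng.integers(1, 40, 500).astype(float)
        s1 = f.resilience(deg)
        s2 = f.resilience(np.repeat(deg, 3))  # triple every count
        assert s1 == pytest.approx(s2, abs=1e-8)


class TestMetricVector:
    def test_complete_graph_closed_forms(self):
        n = 8
        z = np.ones((n, n)) * 0.5
        np.fill_diagonal(z, 0.0)
        ctx = _GraphContext(z, density=0.3, n_null=10, seed=0)
        assert _REGISTRY["global_efficiency_weighted"](ctx) == pytest.approx(0.5)
        assert _REGISTRY["transitivity_weighted"](ctx) == pytest.approx(1.0)
        assert _REGISTRY["clustering_weighted"](ctx).mean() == pytest.approx(1.0)

    def test_disconnected_binary_graph_zero_clustering(self):
        z = np.zeros((10, 10))
        z[0, 1] = z[1, 0] = 1.0
        z[2, 3] = z[3, 2] = 0.9
        ctx = _GraphContext(z, density=0.05, n_null=10, seed=0)
        # round(0.05*45)=2 edges, no triangles anywhere
        assert _REGISTRY["clustering_binary"](ctx).sum() == 0.0

    def test_all_values_finite_and_catalog_keyed(self, rng):
        cm = make_connectivity(rng, n=24)
        vec = f.compute_metric_vector(cm, density=0.2, seed=0)
        cat = default_catalog()
        assert list(vec.values) == cat.names
        assert all(np.isfinite(v) for v in vec.values.values())

    def test_region_permutation_invariance(self, rng):
        z = random_z_matrix(rng, 14)
        perm = rng.permutation(14)
        zp = z[np.ix_(perm, perm)]
        labels = [f"R{i}" for i in range(14)]
        v1 = f.compute_metric_vector(
            f.ConnectivityMatrix("a", z, labels, 100, True), density=0.25, seed=0
        )
        v2 = f.compute_metric_vector(
            f.ConnectivityMatrix("b", zp, labels, 100, True), density=0.25, seed=0
        )
        # permutation-invariant up to thresholding/partition tie-breaks;
        # the partition-free weighted metrics must agree tightly
        for name in (
            "strength",
            "global_efficiency_weighted",
            "char_path_length_weighted",
            "subgraph_centrality_weighted",
            "positive_edge_density",
            "median_positive_weight",
            "transitivity_weighted",
            "clustering_weighted",
        ):
            assert v1.values[name] == pytest.approx(v2.values[name], abs=1e-9), name

    def test_determinism_same_seed(self, rng):
        cm = make_connectivity(rng, n=20)
        v1 = f.compute_metric_vector(cm, seed=4, density=0.2)
        v2 = f.compute_metric_vector(cm, seed=4, density=0.2)
        assert v1.values == v2.values


class TestOutlierExclusion:
    def _vectors(self, rng, n=40, shift_ids=()):
        cat = default_catalog()
        vecs = []
        for i in range(n):
            vals = {name: float(rng.normal(0, 1)) for name in cat.names}
            if i in shift_ids:
                vals[cat.names[3]] += 8.0  # ~8 sd shift on one metric
            vecs.append(f.GraphMetricVector(f"s{i}", vals, 10))
        return vecs

    def test_boundary_at_five_sd(self):
        rule = f.OutlierRule(means={"m": 0.0}, sds={"m": 1.0}, k_sd=5.0)
        assert rule.is_outlier(f.GraphMetricVector("a", {"m": 5.1}, 1)) == ["m"]
        assert rule.is_outlier(f.GraphMetricVector("b", {"m": 4.9}, 1)) == []

    def test_planted_corrupted_subjects_caught(self, rng):
        shift = {5, 17, 31}
        train = self._vectors(rng, n=100, shift_ids=shift)
        rule = f.OutlierRule.fit([v for i, v in enumerate(train) if i not in shift])
        retained, log = f.exclude_metric_outliers(train, rule)
        assert set(log) == {f"s{i}" for i in shift}
        assert len(retained) == 97

    def test_zero_training_sd_rejected(self):
        vecs = [f.GraphMetricVector(f"s{i}", {"m": 1.0}, 1) for i in range(5)]
        with pytest.raises(ValueError, match="zero training sd"):
            f.OutlierRule.fit(vecs)

    def test_rule_is_frozen_across_splits(self, rng):
        train = self._vectors(rng, n=50)
        rule = f.OutlierRule.fit(train)
        means_before = dict(rule.means)
        test = self._vectors(np.random.default_rng(1), n=20)
        f.exclude_metric_outliers(test, rule)
        assert rule.means == means_before


class TestAgeTrendThroughMetrics:
    def test_planted_direction_recovered(self, small_dataset):
        """Metric-level aging signal has a consistent, detectable direction."""
        from scipy import stats as sps

        import fcbrainage.connectome as cn

        out, spec = small_dataset
        import pandas as pd

        part = pd.read_csv(out / "participants.tsv", sep="\t")
        cms = []
        for sid in part.subject_id:
            ts = cn.load_timeseries(out, sid)
            cms.append(cn.correlation_fisher(ts, cn.scrub_frames(ts.fd)))
        mr = cn.fit_mean_regression(cms)
        vecs = [
            f.compute_metric_vector(cn.apply_mean_regression(mr, c), seed=0)
            for c in cms
        ]
        frame = vectors_to_frame(vecs)
        age = part.set_index("subject_id").loc[frame.index, "age"]
        # the dedifferentiation mechanism weakens residual magnitudes with
        # age: subject strength (median |z| strength) must decline
        r_val, p_val = sps.pearsonr(frame["strength"], age)
        assert r_val < 0 and p_val < 0.01


def test_registry_matches_brute_force_oracles(rng):
    """Every catalog metric equals its naive implementation on small graphs."""
    for rep in range(12):
        n = int(rng.integers(8, 13))
        z = random_z_matrix(rng, n)
        ctx = _GraphContext(z, density=0.3, n_null=5, seed=rep)
        W, B = ctx.W, ctx.B
        part_w = ctx.partition_w[0]
        checks = {
            "clustering_weighted": (np.ndarray, orc.clustering_weighted(W)),
            "strength": (np.ndarray, W.sum(axis=0)),
            "global_efficiency_weighted": (
                float,
                orc.efficiency_from_lengths(orc.weighted_lengths(W)),
            ),
            "local_efficiency_weighted": (np.ndarray, orc.local_efficiency_weighted(W)),
            "char_path_length_weighted": (float, orc.char_path_length(W)),
            "betweenness_weighted": (np.ndarray, orc.betweenness_weighted(W)),
            "eigenvector_centrality_weighted": (np.ndarray, orc.eigenvector_centrality(W)),
            "subgraph_centrality_weighted": (np.ndarray, orc.subgraph_centrality(W)),
            "participation_coefficient": (np.ndarray, orc.participation(W, part_w)),
            "within_module_degree_z": (np.ndarray, orc.within_module_z(W, part_w)),
            "assortativity_weighted": (float, orc.assortativity_weighted(ctx.z)),
            "transitivity_weighted": (float, orc.transitivity_weighted(W)),
            "modularity_weighted": (float, orc.modularity(W, part_w)),
            "closeness_weighted": (np.ndarray, orc.closeness_weighted(W)),
            "diversity_coefficient": (np.ndarray, orc.diversity(W, part_w)),
            "coreness": (np.ndarray, orc.coreness(B)),
            "rich_club_median_degree": (float, orc.rich_club(B)),
            "resilience": (float, orc.resilience_slope(B.sum(axis=0))),
            "degree_binary": (np.ndarray, B.sum(axis=0).astype(float)),
            "clustering_binary": (np.ndarray, orc.clustering_binary(B)),
            "global_efficiency_binary": (
                float,
                orc.efficiency_from_lengths(orc.binary_lengths(B)),
            ),
            "modularity_binary": (float, orc.modularity(B.astype(float), ctx.partition_b[0])),
            "assortativity_binary": (float, orc.degree_assortativity(B)),
        }
        for name, (_, expected) in checks.items():
            got = _REGISTRY[name](ctx)
            assert np.allclose(got, expected, atol=1e-8), f"{name} (rep {rep})"
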