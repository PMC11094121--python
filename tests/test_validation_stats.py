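import itertools

import numpy as np
import pytest

from trifuse.data_io import GeneSetCollection, InteractionNetwork, ValidationError
from trifuse.validation_stats import (
    gene_set_enrichment,
    mwu_one_sided,
    overlap_resampling,
    pathway_enrichment,
    shortest_paths_to_target,
)

from .conftest import make_network


def mwu_enumeration_oracle(x, y, alternative):
    """Exact one-sided MWU p by enumerating all rank splits (no ties)."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    nx = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    count = total = 0
    for xs_idx in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in xs_idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in xs_idx]
        u = u_stat(xs, ys)
        total += 1
        if alternative == "greater" and u >= u_obs:
            count += 1
        if alternative == "less" and u <= u_obs:
            count += 1
    return count / total


class TestMwu:
    def test_textbook_small_sample(self):
        res = mwu_one_sided([1, 2], [3, 4], alternative="less")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 6)

    def test_identical_samples_p_at_least_half(self):
        res = mwu_one_sided([1, 2, 3] * 10, [1, 2, 3] * 10, alternative="greater")
        assert res.p_value >= 0.5

    def test_strong_shift_tiny_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 1, 100)
        y = rng.normal(0, 1, 100)
        res = mwu_one_sided(x, y, alternative="greater")
        assert res.p_value < 1e-6
        assert res.method == "asymptotic"

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_path_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        nx = int(rng.integers(1, n))
        vals = rng.permutation(np.arange(1, n + 1)).astype(float)
        x, y = vals[:nx], vals[nx:]
        for alt in ("greater", "less"):
            res = mwu_one_sided(x, y, alternative=alt)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(
                mwu_enumeration_oracle(x, y, alt), rel=1e-12
            )

    def test_exact_and_asymptotic_agree_at_switch_point(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            vals = rng.permutation(np.arange(1, 13)).astype(float)
            x, y = vals[:6], vals[6:]
            p_exact = mwu_one_sided(x, y, "greater").p_value
            import scipy.stats

            p_asym = scipy.stats.mannwhitneyu(
                x, y, alternative="greater", method="asymptotic"
            ).pvalue
            assert abs(p_exact - p_asym) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mwu_one_sided([], [1.0], "greater")


class TestOverlapResampling:
    def test_sets_equal_to_tiny_universes_p_one(self):
        sets = [{"a", "b"}, {"a", "b"}]
        res = overlap_resampling(sets, [set(s) for s in sets], repetitions=200, seed=0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_overlap_p_one(self):
        res = overlap_resampling(
            [{"a"}, {"b"}], [{"a", "b", "c"}, {"a", "b", "c"}],
            repetitions=200, seed=0,
        )
        assert res.observed_overlap == 0
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_overlap_attains_minimum_p(self):
        universe = {f"g{i}" for i in range(2000)}
        shared = {f"g{i}" for i in range(50)}
        sets = [shared | {f"g{100 + 10 * j + i}" for i in range(5)} for j in range(4)]
        res = overlap_resampling(sets, [universe] * 4, repetitions=500, seed=0)
        assert res.p_value == pytest.approx(1 / 501)

    def test_invariant_to_relabeling(self):
        sets = [{"a", "b", "c"}, {"b", "c", "d"}]
        unis = [{chr(97 + i) for i in range(10)}] * 2
        relabel = {chr(97 + i): f"X{i}" for i in range(10)}
        sets2 = [{relabel[g] for g in s} for s in sets]
        unis2 = [{relabel[g] for g in u} for u in unis]
        a = overlap_resampling(sets, unis, repetitions=300, seed=7)
        b = overlap_resampling(sets2, unis2, repetitions=300, seed=7)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.null_overlaps, b.null_overlaps)

    def test_deterministic_given_seed(self):
        sets = [{"a", "b"}, {"b", "c"}]
        unis = [{chr(97 + i) for i in range(8)}] * 2
        a = overlap_resampling(sets, unis, repetitions=300, seed=3)
        b = overlap_resampling(sets, unis, repetitions=300, seed=3)
        np.testing.assert_array_equal(a.null_overlaps, b.null_overlaps)

    def test_few_repetitions_warns(self):
        with pytest.warns(UserWarning):
            overlap_resampling([{"a"}, {"a"}], [{"a", "b"}] * 2, repetitions=50, seed=0)


class TestShortestPaths:
    def test_path_graph_distances_and_mean(self):
        net = make_network("PPI", "abcd", {("a", "b"), ("b", "c"), ("c", "d")})
        res = shortest_paths_to_target(net, "a", {"grp": {"b", "c", "d"}})
        assert res.distances["grp"] == {"b": 1, "c": 2, "d": 3}
        assert res.group_means["grp"] == pytest.approx(2.0)

    def test_direct_neighbors_distance_one(self):
        net = make_network("PPI", "abc", {("a", "b"), ("a", "c")})
        res = shortest_paths_to_target(net, "a", {"nbrs": {"b", "c"}})
        assert set(res.distances["nbrs"].values()) == {1}

    def test_disconnected_gene_reported_unreachable(self):
        net = make_network("PPI", "abcx", {("a", "b"), ("b", "c")})
        res = shortest_paths_to_target(net, "a", {"grp": {"b", "x"}})
        assert res.unreachable["grp"] == ["x"]
        assert res.group_means["grp"] == pytest.approx(1.0)

    def test_target_excluded_from_group(self):
        net = make_network("PPI", "ab", {("a", "b")})
        res = shortest_paths_to_target(net, "a", {"grp": {"a", "b"}})
        assert "a" not in res.distances["grp"]

    def test_missing_target_rejected(self):
        net = make_network("PPI", "ab", {("a", "b")})
        with pytest.raises(ValidationError):
            shortest_paths_to_target(net, "z", {"grp": {"a"}})

    def test_bfs_triangle_inequality_on_random_graph(self):
        rng = np.random.default_rng(5)
        nodes = [f"g{i}" for i in range(30)]
        edges = {
            (nodes[i], nodes[j])
            for i in range(30)
            for j in range(i + 1, 30)
            if rng.random() < 0.12
        }
        net = make_network("PPI", nodes, edges)
        res = shortest_paths_to_target(net, nodes[0], {"all": set(nodes)})
        dist = dict(res.distances["all"])
        dist[nodes[0]] = 0
        for u, v in edges:
            if u in dist and v in dist:
                assert abs(dist[u] - dist[v]) <= 1


class TestGeneSetEnrichment:
    def test_predictions_all_annotated(self):
        preds = {"a", "b"}
        res = gene_set_enrichment(preds, {"a", "b", "c"}, {"c", "d", "e"})
        assert res.fraction == 1.0
        assert res.p_value < 0.5

    def test_no_overlap_fraction_zero_p_one(self):
        res = gene_set_enrichment({"a"}, {"z"}, {"b", "c", "z"})
        assert res.fraction == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_shared_oracle_value(self):
        genes = [f"g{i}" for i in range(20)]
        preds = set(genes[:4])
        annotated = set(genes[:3]) | {genes[10], genes[11]}
        res = gene_set_enrichment(preds, annotated, set(genes) - preds)
        assert res.p_value == pytest.approx(155 / 4845, rel=1e-12)


def bh_step_up_oracle(raw):
    """Benjamini-Hochberg adjusted p-values by the step-up formula."""
    raw = np.asarray(raw, float)
    m = raw.size
    order = np.argsort(raw, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, raw[i] * m / rank)
        adj[i] = running
    return adj


class TestPathwayEnrichment:
    def test_bh_adjustment_matches_step_up_oracle(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(50)]
        coll = GeneSetCollection(
            {
                f"P{j}": set(rng.choice(genes, size=int(rng.integers(3, 12)), replace=False))
                for j in range(6)
            }
        )
        preds = set(rng.choice(genes, size=10, replace=False))
        df = pathway_enrichment(preds, coll, set(genes) - preds)
        np.testing.assert_allclose(
            df["p_adjusted"], bh_step_up_oracle(df["p_value"]), rtol=1e-12
        )
        # the textbook step-up example: equally spaced raw ps all collapse
        np.testing.assert_allclose(
            bh_step_up_oracle([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_single_pathway_adjusted_equals_raw(self):
        genes = [f"g{i}" for i in range(30)]
        coll = GeneSetCollection({"P": set(genes[:5])})
        df = pathway_enrichment(set(genes[:5]), coll, set(genes[5:]))
        assert df.loc[0, "p_adjusted"] == pytest.approx(df.loc[0, "p_value"])

    def test_zero_overlap_ranked_last(self):
        genes = [f"g{i}" for i in range(30)]
        coll = GeneSetCollection(
            {"hit": set(genes[:5]), "miss": set(genes[20:25])}
        )
        df = pathway_enrichment(set(genes[:5]), coll, set(genes[5:]))
        assert list(df["pathway"]) == ["hit", "miss"]
        assert df.set_index("pathway").loc["miss", "p_value"] == pytest.approx(1.0)

    def test_bh_monotone_and_adjusted_at_least_raw(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(60)]
        sets = {
            f"P{j}": set(rng.choice(genes, size=int(rng.integers(4, 15)), replace=False))
            for j in range(8)
        }
        coll = GeneSetCollection(sets)
        preds = set(rng.choice(genes, size=12, replace=False))
        df = pathway_enrichment(preds, coll, set(genes) - preds)
        assert np.all(df["p_adjusted"] >= df["p_value"] - 1e-15)
        ordered = df.sort_values("p_value")
        assert np.all(np.diff(ordered["p_adjusted"]) >= -1e-15)
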