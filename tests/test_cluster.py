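"""Correlation-distance clustering: profiles, k-means, dendrograms, monophyly."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gocentric import (
    build_profiles,
    cluster_enrichment,
    cut_subclusters,
    hier_cluster,
    kmeans_correlation,
    parse_obo,
    propagate,
    sample_dendrogram,
    select_k,
    simulate_counts,
)
from gocentric.cluster import ExpressionProfile, correlation_distance, subcluster_means

from conftest import small_matrix


def profile_from_array(arr, genes=None, timepoints=None):
    arr = np.asarray(arr, dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    const = sd[:, 0] == 0
    sd[const] = 1.0
    z = (arr - mu) / sd
    z[const] = 0.0
    genes = genes or [f"g{i}" for i in range(len(arr))]
    timepoints = timepoints or [f"t{j}" for j in range(arr.shape[1])]
    return ExpressionProfile(pd.DataFrame(z, index=genes, columns=timepoints), set())


# --- profiles -----------------------------------------------------------


class TestBuildProfiles:
    def test_constant_gene_flagged_zero_vector(self):
        # constant CPM fractions at every sample -> flat profile
        cm = small_matrix(
            [[10, 10, 10, 10], [20, 20, 20, 20]],
            timepoints=["t0", "t0", "t1", "t1"],
        )
        ep = build_profiles(cm, factors=np.ones(4))
        assert "g0" in ep.constant_genes
        np.testing.assert_allclose(ep.values.loc["g0"], 0.0)

    def test_rows_are_z_scored(self):
        cm, _ = simulate_counts(n_genes=100, seed=9)
        ep = build_profiles(cm)
        live = ep.values.drop(index=list(ep.constant_genes)).to_numpy()
        np.testing.assert_allclose(live.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(live.std(axis=1), 1.0, atol=1e-9)

    def test_proportional_counts_give_identical_profiles(self):
        cm = small_matrix(
            [[10, 20, 40, 80], [30, 60, 120, 240]],
            timepoints=["t0", "t1", "t2", "t3"],
        )
        ep = build_profiles(cm, factors=np.ones(4), prior=0.0)
        np.testing.assert_allclose(ep.values.loc["g0"], ep.values.loc["g1"], atol=1e-9)

    def test_unknown_gene_rejected(self):
        cm = small_matrix([[5, 5], [9, 9]], timepoints=["a", "b"])
        with pytest.raises(KeyError):
            build_profiles(cm, genes=["nope"])


def test_correlation_distance_bounds_and_extremes():
    x = np.array([0.0, 1.0, 2.0, 4.0])
    ep = profile_from_array([x, -x, x * 3 + 1])
    d = correlation_distance(ep.values.to_numpy())
    assert d[0, 1] == pytest.approx(2.0, abs=1e-12)  # anti-correlated
    assert d[0, 2] == pytest.approx(0.0, abs=1e-12)  # affine copy
    assert np.all((d >= 0) & (d <= 2)) and np.allclose(np.diag(d), 0)


# --- k-means ------------------------------------------------------------


class TestKMeans:
    def test_anticorrelated_groups_perfectly_separated(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=6)
        rows = [base + rng.normal(0, 0.05, 6) for _ in range(5)]
        rows += [-base + rng.normal(0, 0.05, 6) for _ in range(5)]
        ep = profile_from_array(rows)
        ca = kmeans_correlation(ep, 2, seed=1)
        labels = ca.labels.to_numpy()
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_k_one_puts_everything_together(self):
        ep = profile_from_array(np.random.default_rng(1).normal(size=(6, 4)))
        ca = kmeans_correlation(ep, 1, seed=0)
        assert set(ca.labels) == {1}

    def test_same_seed_is_deterministic(self):
        ep = profile_from_array(np.random.default_rng(2).normal(size=(40, 4)))
        a = kmeans_correlation(ep, 4, seed=7)
        b = kmeans_correlation(ep, 4, seed=7)
        assert a.labels.equals(b.labels) and a.objective == b.objective

    def test_fewer_distinct_profiles_than_k_rejected(self):
        ep = profile_from_array([[0, 1, 2, 3]] * 4)
        with pytest.raises(ValueError, match="distinct"):
            kmeans_correlation(ep, 2)

    def test_more_restarts_never_worsen_objective(self):
        ep = profile_from_array(np.random.default_rng(3).normal(size=(60, 4)))
        few = kmeans_correlation(ep, 5, seed=0, restarts=1)
        many = kmeans_correlation(ep, 5, seed=0, restarts=20)
        assert many.objective <= few.objective + 1e-12


class TestSelectK:
    def test_three_planted_patterns_recovered(self):
        rng = np.random.default_rng(5)
        shapes = [np.array([0, 2, 2, 2]), np.array([0, -2, -2, -2]), np.array([0, 2, 0, 0])]
        rows = [s + rng.normal(0, 0.1, 4) for s in shapes for _ in range(15)]
        ep = profile_from_array(rows)
        chosen, table, _ = select_k(ep, range(2, 7), seed=0)
        assert chosen == 3
        assert table.loc[table.k == 3, "mean_silhouette"].iloc[0] == table.mean_silhouette.max()

    def test_chosen_k_maximises_mean_silhouette(self):
        ep = profile_from_array(np.random.default_rng(6).normal(size=(30, 5)))
        chosen, table, fits = select_k(ep, range(2, 6), seed=0)
        assert fits[chosen].mean_silhouette == pytest.approx(table.mean_silhouette.max())

    def test_out_of_range_k_rejected(self):
        ep = profile_from_array(np.random.default_rng(7).normal(size=(6, 4)))
        with pytest.raises(ValueError):
            select_k(ep, range(5, 11), seed=0)


def brute_silhouette(d, labels):
    """Silhouette from its definition, averaged over items."""
    n = len(labels)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([d[i, j] for j in same])
        b = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == lab])
            for lab in set(labels)
            if lab != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return np.array(vals)


def test_silhouette_matches_brute_force_oracle():
    rng = np.random.default_rng(8)
    ep = profile_from_array(rng.normal(size=(18, 5)))
    ca = kmeans_correlation(ep, 3, seed=0)
    d = correlation_distance(ep.values.to_numpy())
    expected = brute_silhouette(d, ca.labels.to_numpy())
    np.testing.assert_allclose(ca.silhouette.to_numpy(), expected, atol=1e-12)


# --- hierarchical / GO-centric -----------------------------------------


def brute_average_linkage(d):
    """Naive agglomerative average linkage; returns sorted merge heights."""
    clusters = {i: [i] for i in range(len(d))}
    heights = []
    nxt = len(d)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            h = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or h < best[0] - 1e-15:
                best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters[nxt] = clusters.pop(a) + clusters.pop(b)
        nxt += 1
    return sorted(heights)


class TestHierCluster:
    def test_identical_profiles_merge_at_zero(self):
        x = [0.0, 1.0, 3.0, 2.0]
        ep = profile_from_array([x, x, [5, 1, 0, 2]])
        gr = hier_cluster(ep)
        assert gr.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_opposite_profiles_merge_last_at_two(self):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        ep = profile_from_array([x, x + np.array([0, 0.1, 0, 0]), -x])
        gr = hier_cluster(ep)
        assert gr.linkage_matrix[-1, 2] == pytest.approx(2.0, abs=0.05)

    def test_average_linkage_matches_brute_force(self):
        rng = np.random.default_rng(10)
        ep = profile_from_array(rng.normal(size=(8, 5)))
        d = correlation_distance(ep.values.to_numpy())
        gr = hier_cluster(ep)
        np.testing.assert_allclose(
            sorted(gr.linkage_matrix[:, 2]), brute_average_linkage(d), atol=1e-12
        )

    def test_single_gene_degenerates_gracefully(self):
        ep = profile_from_array([[0, 1, 2, 3]])
        gr = hier_cluster(ep, term="GO:X")
        assert gr.linkage_matrix is None
        assert gr.to_newick().startswith("g0")

    def test_newick_contains_all_leaves(self):
        ep = profile_from_array(np.random.default_rng(11).normal(size=(5, 4)))
        nwk = hier_cluster(ep).to_newick()
        assert all(f"g{i}" in nwk for i in range(5))


class TestCutSubclusters:
    def test_k_one_and_k_n_limits(self):
        ep = profile_from_array(np.random.default_rng(12).normal(size=(6, 4)))
        gr = hier_cluster(ep)
        one = cut_subclusters(gr, 1)
        assert set(one.subclusters) == {1}
        n = cut_subclusters(gr, 6)
        assert sorted(n.subclusters) == [1, 2, 3, 4, 5, 6]
        with pytest.raises(ValueError):
            cut_subclusters(gr, 7)

    def test_planted_opposite_patterns_recovered_as_top_two(self):
        rng = np.random.default_rng(13)
        up = [np.array([0, 2, 2, 2]) + rng.normal(0, 0.2, 4) for _ in range(7)]
        down = [np.array([0, -2, -2, -2]) + rng.normal(0, 0.2, 4) for _ in range(5)]
        ep = profile_from_array(up + down)
        gr = cut_subclusters(hier_cluster(ep), 2)
        labels = gr.subclusters.to_numpy()
        assert len(set(labels[:7])) == 1 and len(set(labels[7:])) == 1
        assert labels[0] != labels[-1]
        assert gr.top_two == [1, 2]
        # label 1 is the larger subcluster
        assert (labels == 1).sum() == 7

    def test_subcluster_means_shapes(self):
        ep = profile_from_array(np.random.default_rng(14).normal(size=(6, 4)))
        gr = cut_subclusters(hier_cluster(ep), 2)
        means = subcluster_means(gr, ep)
        assert means.shape == (2, 4)


# --- per-cluster enrichment --------------------------------------------


class TestClusterEnrichment:
    DAG = (
        "format-version: 1.2\nontology: go\n\n"
        "[Term]\nid: GO:1\nname: root\nnamespace: biological_process\n\n"
        "[Term]\nid: GO:2\nname: module\nnamespace: biological_process\nis_a: GO:1\n"
    )

    def test_pure_cluster_ranks_planted_term_first(self):
        dag = parse_obo(self.DAG)
        genes = [f"g{i}" for i in range(40)]
        ann = propagate(dag, {g: {"GO:2" if i < 8 else "GO:1"} for i, g in enumerate(genes)})
        labels = pd.Series([1] * 8 + [2] * 32, index=genes)
        ca_like = type("CA", (), {})()
        from gocentric.cluster import ClusterAssignment

        ca = ClusterAssignment(labels, labels * np.nan, float("nan"), 0.0)
        res = cluster_enrichment(ca, set(genes), ann, dag, min_node_size=1)
        first = res[1].sort_values("p_classic").iloc[0]
        assert first.term == "GO:2" and first.p_classic < 1e-6

    def test_singleton_cluster_closed_form(self):
        dag = parse_obo(self.DAG)
        genes = [f"g{i}" for i in range(10)]
        ann = propagate(dag, {g: {"GO:2" if i < 4 else "GO:1"} for i, g in enumerate(genes)})
        from gocentric.cluster import ClusterAssignment

        labels = pd.Series([1] + [2] * 9, index=genes)
        ca = ClusterAssignment(labels, labels * np.nan, float("nan"), 0.0)
        res = cluster_enrichment(ca, set(genes), ann, dag, min_node_size=1)
        p = float(res[1].set_index("term").loc["GO:2", "p_classic"])
        assert p == pytest.approx(4 / 10, abs=1e-12)  # P(X >= 1) with n = 1


# --- sample-level clustering -------------------------------------------


class TestSampleDendrogram:
    def test_duplicated_columns_merge_at_zero(self):
        col = np.arange(1, 30)
        cm = small_matrix(
            np.column_stack([col, col, col * 3]), timepoints=["a", "a", "b"]
        )
        tree = sample_dendrogram(cm, factors=np.ones(3))
        assert tree.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_two_samples_trivially_monophyletic(self):
        cm = small_matrix(
            np.random.default_rng(15).poisson(20, size=(50, 2)) + 1,
            timepoints=["a", "b"],
        )
        tree = sample_dendrogram(cm, factors=np.ones(2))
        assert tree.all_monophyletic

    def test_strong_timepoint_effect_gives_full_monophyly(self):
        cm, _ = simulate_counts(n_genes=800, seed=21)
        tree = sample_dendrogram(cm)
        assert tree.all_monophyletic
        assert set(tree.monophyly) == {"0h", "24h", "48h", "72h"}
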