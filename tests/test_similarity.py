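"""Pair similarity, variance partitioning, UPGMA clustering."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.cluster import hierarchy

from ploidypheno.similarity import (
    count_pairs,
    label_pairs,
    pairwise_similarity,
    partition,
    scale_traits,
    to_newick,
    upgma_cluster,
)


class TestScaleTraits:
    def test_unit_variance(self):
        m = pd.DataFrame({"t1": [0.0, 2.0], "t2": [1.0, 5.0]}, index=["a", "b"])
        scaled = scale_traits(m)
        np.testing.assert_allclose(scaled.std(ddof=1), 1.0)

    def test_constant_column_dropped(self):
        m = pd.DataFrame({"t1": [0.0, 2.0, 1.0], "t2": [3.0, 3.0, 3.0]})
        with pytest.warns(UserWarning):
            scaled = scale_traits(m)
        assert list(scaled.columns) == ["t1"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.standard_normal((6, 4)))
        once = scale_traits(m)
        twice = scale_traits(once)
        pd.testing.assert_frame_equal(once, twice)


class TestPairwiseSimilarity:
    def test_identical_copy_r_one(self):
        rng = np.random.default_rng(1)
        profile = rng.standard_normal(8)
        m = pd.DataFrame([profile, profile, -profile], index=["a", "b", "c"])
        pairs = pairwise_similarity(m)
        lookup = pairs.set_index(["strain_a", "strain_b"])["r"]
        assert lookup[("a", "b")] == pytest.approx(1.0)
        assert lookup[("a", "c")] == pytest.approx(-1.0)

    def test_pair_count_for_study_panel(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.standard_normal((51, 6)),
                         index=[f"s{i}" for i in range(51)])
        pairs = pairwise_similarity(m)
        assert len(pairs) == comb(51, 2) == 1275

    def test_too_few_shared_traits_invalid(self):
        m = pd.DataFrame(
            [[1.0, 2.0, np.nan, np.nan], [np.nan, np.nan, 1.0, 2.0],
             [1.0, 2.0, 3.0, 4.0]],
            index=["a", "b", "c"],
        )
        pairs = pairwise_similarity(m).set_index(["strain_a", "strain_b"])
        assert not pairs.loc[("a", "b"), "valid"]
        assert pairs.loc[("a", "b"), "n_traits_used"] == 0

    def test_invariant_to_trait_order(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.standard_normal((5, 7)), index=list("abcde"))
        shuffled = m[rng.permutation(m.columns)]
        p1 = pairwise_similarity(m)["r"]
        p2 = pairwise_similarity(shuffled)["r"]
        np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestCountPairs:
    def test_study_sizes(self):
        assert count_pairs([24, 27], "within") == 627
        assert count_pairs([24, 27], "between") == 648

    def test_single_group(self):
        assert count_pairs([2], "within") == 1
        assert count_pairs([2], "between") == 0

    @given(st.lists(st.integers(min_value=0, max_value=20), min_size=1, max_size=6))
    @settings(derandomize=True, max_examples=80)
    def test_matches_enumeration(self, sizes):
        if sum(sizes) > 60:
            sizes = sizes[:3]
        labels = [g for g, n in enumerate(sizes) for _ in range(n)]
        within = sum(1 for a, b in itertools.combinations(labels, 2) if a == b)
        between = sum(1 for a, b in itertools.combinations(labels, 2) if a != b)
        assert count_pairs(sizes, "within") == within
        assert count_pairs(sizes, "between") == between


def _pair_frame(r_within, r_between):
    rows = []
    for i, r in enumerate(r_within):
        rows.append(dict(strain_a=f"w{i}", strain_b=f"w{i}x", r=r, group="within"))
    for i, r in enumerate(r_between):
        rows.append(dict(strain_a=f"b{i}", strain_b=f"b{i}x", r=r, group="between"))
    df = pd.DataFrame(rows)
    df["factor"] = "species"
    return df


class TestPartition:
    def test_null_case(self):
        rng = np.random.default_rng(0)
        res = partition(_pair_frame(rng.normal(0.5, 0.1, 200), rng.normal(0.5, 0.1, 200)))
        assert res.adj_r2 < 0.01
        assert res.p_value > 0.01

    def test_f_equals_squared_t(self):
        """Two-level ANOVA F is the square of the pooled two-sample t."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(0, 1, 30)
            y = rng.normal(0.4, 1, 25)
            res = partition(_pair_frame(x, y))
            t = stats.ttest_ind(x, y, equal_var=True).statistic
            assert res.F == pytest.approx(t**2, rel=1e-8)

    def test_group_counts_and_means(self):
        res = partition(_pair_frame([0.9, 0.8], [0.1, 0.2, 0.3]))
        assert res.n_within == 2 and res.n_between == 3
        assert res.group_means["within"] == pytest.approx(0.85)

    def test_empty_group_rejected(self):
        df = _pair_frame([0.5], []).iloc[:1]
        with pytest.raises(ValueError):
            partition(df)

    def test_monotone_in_gap(self):
        """Expected adjusted R^2 grows with the planted group-mean gap."""
        rng = np.random.default_rng(2)
        r2 = []
        for gap in (0.0, 0.1, 0.2, 0.4):
            vals = []
            for _ in range(30):
                w = rng.normal(0.5 + gap, 0.2, 100)
                b = rng.normal(0.5, 0.2, 100)
                vals.append(partition(_pair_frame(w, b)).adj_r2)
            r2.append(np.mean(vals))
        assert r2[0] < r2[1] < r2[2] < r2[3]


class TestLabelPairs:
    def test_within_between_and_universe(self):
        meta = pd.DataFrame(
            dict(strain_id=["a", "b", "c"], species=["s1", "s1", "s2"],
                 population=["p1", "p2", "p3"], source=["w", "w", "w"])
        )
        pairs = pd.DataFrame(
            dict(strain_a=["a", "a", "b"], strain_b=["b", "c", "c"],
                 r=[0.5, 0.4, 0.3], n_traits_used=[5, 5, 5], valid=[True] * 3)
        )
        lab = label_pairs(pairs, meta, "species")
        assert list(lab["group"]) == ["within", "between", "between"]
        lab2 = label_pairs(pairs, meta, "population", universe=["a", "b"])
        assert len(lab2) == 1 and lab2["group"].iloc[0] == "between"


def upgma_oracle(dist):
    """Naive average-linkage agglomeration; returns leaf-pair merge heights."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = {frozenset((i, j)): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        pair = min(d, key=lambda k: d[k])
        h = d[pair]
        a, b = tuple(pair)
        members = clusters[a] + clusters[b]
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        new = {}
        for c in clusters:
            if c in (a, b):
                continue
            na, nb = len(clusters[a]), len(clusters[b])
            new_d = (na * d[frozenset((a, c))] + nb * d[frozenset((b, c))]) / (na + nb)
            new[frozenset((next_id, c))] = new_d
        for k in list(d):
            if a in k or b in k:
                del d[k]
        d.update(new)
        clusters[next_id] = members
        del clusters[a], clusters[b]
        next_id += 1
    return coph


class TestUpgma:
    def test_three_strain_hand_case(self):
        # d(AB)=0.1, d(AC)=d(BC)=0.8 -> A,B merge at 0.1, then C at 0.8
        dist = np.array([[0, 0.1, 0.8], [0.1, 0, 0.8], [0.8, 0.8, 0]])
        from scipy.spatial.distance import squareform

        Z = hierarchy.linkage(squareform(dist), method="average")
        assert Z[0, 2] == pytest.approx(0.1)
        assert Z[1, 2] == pytest.approx(0.8)

    def test_identical_strains_zero_height(self):
        rng = np.random.default_rng(4)
        profile = rng.standard_normal(10)
        m = pd.DataFrame([profile, profile, rng.standard_normal(10)],
                         index=["a", "b", "c"])
        tree = upgma_cluster(m)
        assert tree.heights()[0] == pytest.approx(0.0, abs=1e-12)

    def test_heights_monotone(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.standard_normal((12, 9)),
                         index=[f"s{i}" for i in range(12)])
        tree = upgma_cluster(m)
        assert np.all(np.diff(tree.heights()) >= -1e-12)

    def test_matches_oracle_on_random_matrices(self):
        """Cophenetic distances equal a naive agglomeration oracle."""
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(6)
        for _ in range(25):
            n = 5
            d = rng.random((n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            Z = hierarchy.linkage(squareform(d, checks=False), method="average")
            coph = squareform(hierarchy.cophenet(Z))
            coph0 = upgma_oracle(d)
            np.testing.assert_allclose(coph, coph0, atol=1e-10)


class TestNewick:
    def test_roundtrip_with_independent_parser(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.standard_normal((6, 8)),
                         index=[f"s{i}" for i in range(6)])
        tree = upgma_cluster(m)
        newick = to_newick(tree)
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        taxa = sorted(leaf.taxon.label for leaf in parsed.leaf_node_iter())
        assert taxa == sorted(tree.labels)
        # ultrametric: root-to-leaf path length identical for all leaves
        depths = [leaf.distance_from_root() for leaf in parsed.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9

    def test_leaf_to_leaf_path_equals_merge_distance(self):
        dendropy = pytest.importorskip("dendropy")
        profile = np.arange(5.0)
        m = pd.DataFrame(
            [profile, profile[::-1], profile * 2 + 1], index=["a", "b", "c"]
        )
        tree = upgma_cluster(m)
        newick = to_newick(tree)
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        # a vs c are perfectly correlated -> distance 0; a vs b anticorrelated -> 2
        assert pdm.patristic_distance(taxa["a"], taxa["c"]) == pytest.approx(0.0, abs=1e-9)
        assert pdm.patristic_distance(taxa["a"], taxa["b"]) == pytest.approx(2.0, abs=1e-9)
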