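"""Age-group profiles, OM distances, linkage trees, Newick and bootstrap."""

import itertools
from functools import lru_cache

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ethotrace.cluster import (
    AgeGroupProfile,
    age_group_matrix,
    auto_k,
    bootstrap_support,
    cut_tree,
    euclidean_dist,
    linkage_tree,
    modal_hour_sequences,
    om_distance,
    om_distance_matrix,
    tree_to_newick,
)
from ethotrace.core import ValidationError


def day_table(day_rows):
    """Fly day-count table from {day: 6-count row}."""
    days = sorted(day_rows)
    return pd.DataFrame([day_rows[d] for d in days], index=days, columns=range(6))


def resting_day(n=1000):
    return [n, 0, 0, 0, 0, 0]


class TestAgeGroups:
    def test_three_profiles_for_thirty_days(self):
        table = day_table({d: resting_day() for d in range(1, 31)})
        profiles = age_group_matrix([table], 10.0)
        assert [p.label for p in profiles] == ["0-10", "10-20", "20-30"]

    def test_all_resting_fly_gives_unit_resting_share(self):
        table = day_table({d: resting_day() for d in range(1, 21)})
        for p in age_group_matrix([table], 10.0):
            assert np.allclose(p.shares, [1, 0, 0, 0, 0, 0])

    def test_fly_dead_at_day_12_contributes_to_first_two_groups(self):
        dead = day_table({d: resting_day() for d in range(1, 13)})
        survivor = day_table({d: resting_day() for d in range(1, 31)})
        profiles = age_group_matrix([dead, survivor], 10.0)
        assert [p.n_flies for p in profiles] == [2, 2, 1]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            age_group_matrix([], 10.0)


class TestEuclidean:
    def test_unit_vectors_sqrt2(self):
        a = AgeGroupProfile(0, 10, np.array([1, 0, 0, 0, 0, 0.0]), 1)
        b = AgeGroupProfile(10, 20, np.array([0, 1, 0, 0, 0, 0.0]), 1)
        D = euclidean_dist([a, b])
        assert D[0, 1] == pytest.approx(np.sqrt(2))
        assert D[0, 0] == 0.0

    def test_metric_axioms_on_random_profiles(self):
        rng = np.random.default_rng(0)
        shares = rng.dirichlet(np.ones(6), size=5)
        profs = [AgeGroupProfile(10 * i, 10 * i + 10, s, 1) for i, s in enumerate(shares)]
        D = euclidean_dist(profs)
        assert np.allclose(D, D.T)
        for i, j, k in itertools.permutations(range(5), 3):
            assert D[i, k] <= D[i, j] + D[j, k] + 1e-12


# ---------------------------------------------------------------------------
# OM distance oracles
# ---------------------------------------------------------------------------

def brute_force_om(a: tuple, b: tuple, sub: float, indel: float) -> float:
    """Exhaustive recursive edit-script cost (oracle for short sequences)."""

    @lru_cache(maxsize=None)
    def go(i, j):
        if i == len(a):
            return (len(b) - j) * indel
        if j == len(b):
            return (len(a) - i) * indel
        best = go(i + 1, j + 1) + (0.0 if a[i] == b[j] else sub)
        best = min(best, go(i + 1, j) + indel, go(i, j + 1) + indel)
        return best

    return go(0, 0)


def lcs_length(a, b):
    table = np.zeros((len(a) + 1, len(b) + 1), dtype=int)
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            table[i, j] = (
                table[i - 1, j - 1] + 1 if a[i - 1] == b[j - 1]
                else max(table[i - 1, j], table[i, j - 1])
            )
    return int(table[-1, -1])


class TestOMDistance:
    def test_identical_sequences_zero(self):
        assert om_distance([0, 1, 2], [0, 1, 2]) == 0.0

    def test_empty_versus_n_costs_n_indels(self):
        assert om_distance([], [1, 1, 1], indel_cost=1.5) == pytest.approx(4.5)

    def test_single_substitution_example(self):
        # R,R,W vs R,W,W: one substitution (cost 2) beats two indels only at equality
        assert om_distance([0, 0, 2], [0, 2, 2], sub_cost=2.0, indel_cost=1.0) == 2.0

    def test_equals_brute_force_on_all_short_pairs(self):
        """DP equals exhaustive edit-script enumeration for every pair of
        label sequences of length <= 4 over a 3-letter alphabet."""
        seqs = [
            tuple(s)
            for n in range(0, 5)
            for s in itertools.product(range(3), repeat=n)
        ]
        rng = np.random.default_rng(1)
        pool = rng.choice(len(seqs), size=(400, 2))
        for ia, ib in pool:
            a, b = seqs[ia], seqs[ib]
            assert om_distance(a, b, 2.0, 1.0) == pytest.approx(
                brute_force_om(a, b, 2.0, 1.0)
            )
            assert om_distance(a, b, 1.5, 1.0) == pytest.approx(
                brute_force_om(a, b, 1.5, 1.0)
            )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 5), max_size=20),
        st.lists(st.integers(0, 5), max_size=20),
        st.lists(st.integers(0, 5), max_size=20),
    )
    def test_metric_properties(self, a, b, c):
        d_ab = om_distance(a, b)
        assert d_ab >= 0
        assert d_ab == om_distance(b, a)
        assert (d_ab == 0) == (a == b)
        assert om_distance(a, c) <= d_ab + om_distance(b, c) + 1e-9

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 3), max_size=12),
        st.lists(st.integers(0, 3), max_size=12),
        st.floats(2.0, 5.0),
    )
    def test_lcs_closed_form_when_substitution_dominated(self, a, b, sub):
        """With sub_cost >= 2*indel_cost the OM distance collapses to the
        LCS form indel * (|a| + |b| - 2*LCS)."""
        indel = 1.0
        expected = indel * (len(a) + len(b) - 2 * lcs_length(a, b))
        assert om_distance(a, b, sub, indel) == pytest.approx(expected)

    def test_matrix_matches_pairwise_and_normalization_bounds(self):
        rng = np.random.default_rng(2)
        seqs = [rng.integers(0, 6, rng.integers(1, 15)).tolist() for _ in range(6)]
        D = om_distance_matrix(seqs)
        for i in range(6):
            for j in range(6):
                assert D[i, j] == pytest.approx(om_distance(seqs[i], seqs[j]))
        Dn = om_distance_matrix(seqs, normalize=True)
        assert (Dn <= 2.0 + 1e-9).all() and (Dn >= 0).all()

    def test_identical_sequences_zero_matrix(self):
        D = om_distance_matrix([[1, 2, 3]] * 4)
        assert (D == 0).all()


class TestLinkage:
    def test_two_leaves_merge_at_their_distance(self):
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        tree = linkage_tree(D, ["A", "B"])
        assert tree.Z.shape == (1, 4)
        assert tree.heights[0] == pytest.approx(3.0)

    def test_n_minus_one_merges(self):
        rng = np.random.default_rng(3)
        X = rng.random((7, 6))
        from scipy.spatial.distance import pdist, squareform

        tree = linkage_tree(squareform(pdist(X)))
        assert tree.Z.shape == (6, 4)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValidationError):
            linkage_tree(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValidationError):
            linkage_tree(-np.ones((3, 3)))

    def _planted_profiles(self, rng, per_group=4, spread=0.003):
        archetypes = [
            np.array([0.90, 0.06, 0.03, 0.01, 0.0, 0.0]),
            np.array([0.70, 0.10, 0.15, 0.05, 0.0, 0.0]),
            np.array([0.97, 0.02, 0.01, 0.00, 0.0, 0.0]),
        ]
        profs = []
        i = 0
        for arch in archetypes:
            for _ in range(per_group):
                noisy = np.abs(arch + rng.normal(0, spread, 6))
                profs.append(AgeGroupProfile(10 * i, 10 * i + 10, noisy / noisy.sum(), 1))
                i += 1
        return profs

    def test_planted_partition_recovered_at_k3(self):
        rng = np.random.default_rng(4)
        profs = self._planted_profiles(rng)
        tree = linkage_tree(euclidean_dist(profs), [p.label for p in profs])
        assign = cut_tree(tree, 3)
        blocks = [assign[:4], assign[4:8], assign[8:]]
        for block in blocks:
            assert len(set(block)) == 1
        assert len({b[0] for b in blocks}) == 3
        assert auto_k(tree) == 3

    def test_cut_extremes_and_range_check(self):
        rng = np.random.default_rng(5)
        profs = self._planted_profiles(rng, per_group=2)
        tree = linkage_tree(euclidean_dist(profs))
        assert len(set(cut_tree(tree, 1))) == 1
        assert len(set(cut_tree(tree, tree.n_leaves))) == tree.n_leaves
        with pytest.raises(ValidationError):
            cut_tree(tree, 0)


class TestNewick:
    def test_two_leaf_format(self):
        tree = linkage_tree(np.array([[0.0, 4.0], [4.0, 0.0]]), ["A", "B"])
        assert tree_to_newick(tree) == "(A:4,B:4);"

    def test_reparses_with_preserved_leaves_and_depth(self):
        rng = np.random.default_rng(6)
        X = rng.random((6, 6))
        from scipy.spatial.distance import pdist, squareform

        labels = [f"g{i}" for i in range(6)]
        tree = linkage_tree(squareform(pdist(X)), labels)
        parsed = dendropy.Tree.get(data=tree_to_newick(tree), schema="newick")
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == labels
        # ultrametric: every leaf sits at the root height
        root_h = tree.heights[-1]
        for leaf in parsed.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(root_h, rel=1e-4)


class TestBootstrap:
    def _phase_tables(self, rng, n_flies=8):
        # 3 age phases with distinct behavior mixes, 2 ten-day groups each
        mixes = {
            (1, 21): [900, 60, 30, 10, 0, 0],
            (21, 41): [700, 100, 150, 50, 0, 0],
            (41, 61): [970, 20, 10, 0, 0, 0],
        }
        tables = []
        for _ in range(n_flies):
            rows = {}
            for (d0, d1), mix in mixes.items():
                for d in range(d0, d1):
                    rows[d] = np.maximum(rng.poisson(mix), 0)
            tables.append(day_table(rows))
        return tables

    def test_supports_in_unit_interval_and_deterministic(self):
        rng = np.random.default_rng(7)
        tables = self._phase_tables(rng)
        t1 = bootstrap_support(tables, 10.0, B=25, seed=11)
        t2 = bootstrap_support(tables, 10.0, B=25, seed=11)
        assert t1.supports == t2.supports
        assert all(0.0 <= v <= 1.0 for v in t1.supports.values())

    def test_clean_separation_gives_high_root_split_support(self):
        rng = np.random.default_rng(8)
        tables = self._phase_tables(rng)
        tree = bootstrap_support(tables, 10.0, B=25, seed=3)
        clades = tree.clades()
        # the two children of the root: the larger one is a planted side
        root_children = clades[-1]
        assert len(root_children) == tree.n_leaves
        phase_clades = [c for c in tree.supports if len(c) == 2]
        assert phase_clades and max(tree.supports[c] for c in phase_clades) >= 0.9


class TestModalSequences:
    def test_modal_labels_by_hour(self):
        counts = np.zeros((6, 24))
        counts[0] = 5
        counts[2, 12] = 10  # walking dominates at noon
        (seq,) = modal_hour_sequences([counts])
        assert seq[12] == 2 and seq[0] == 0 and len(seq) == 24
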