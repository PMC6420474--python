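"""Connectivity matrices, Ward clustering, k vote, bootstrap, ARI."""

import numpy as np
import pytest

from sentnet.config import AnalysisConfig
from sentnet.cluster import (
    ConnectivityMatrix,
    MergeTree,
    Partition,
    adjusted_rand,
    alternative_partitions,
    bootstrap_support,
    choose_k,
    correlation_to_distance,
    cut_tree,
    fit_au,
    mean_connectivity,
    subject_connectivity,
    ward_cluster,
)
from sentnet.data import DataError


def _block_distance(sizes, within=0.1, between=0.9, jitter=0.0, seed=0):
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    d = np.where(labels[:, None] == labels[None, :], within, between)
    if jitter:
        rng = np.random.default_rng(seed)
        noise = rng.uniform(0, jitter, size=(n, n))
        d = d + (noise + noise.T) / 2
    np.fill_diagonal(d, 0.0)
    return d, labels + 1


def _names(n):
    return [f"R{i:02d}" for i in range(n)]


class TestSubjectConnectivity:
    def test_identical_columns_capped(self):
        x = np.random.default_rng(0).normal(size=50)
        mat = np.column_stack([x, x])
        r = subject_connectivity(mat, ["a", "b"]).values
        assert r[0, 1] == pytest.approx(1.0, abs=1e-11)
        assert r[0, 1] < 1.0  # capped for the Fisher transform

    def test_negated_column_capped(self):
        x = np.random.default_rng(1).normal(size=50)
        r = subject_connectivity(np.column_stack([x, -x]), ["a", "b"]).values
        assert r[0, 1] == pytest.approx(-1.0, abs=1e-11)
        assert r[0, 1] > -1.0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(size=(50, 5))
        got = subject_connectivity(mat, _names(5)).values
        centered = mat - mat.mean(axis=0)
        cov = centered.T @ centered / 50
        sd = np.sqrt(np.diag(cov))
        expected = cov / np.outer(sd, sd)
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_constant_column_names_region(self):
        mat = np.random.default_rng(3).normal(size=(30, 2))
        mat[:, 1] = 5.0
        with pytest.raises(DataError, match="b"):
            subject_connectivity(mat, ["a", "b"])


class TestMeanConnectivity:
    def _from_r(self, r):
        vals = np.array([[0.0, r], [r, 0.0]])
        return ConnectivityMatrix(vals, ["a", "b"], "pearson_r")

    def test_single_subject_is_atanh(self):
        m = mean_connectivity([self._from_r(0.3)])
        assert m.scale == "fisher_z"
        assert m.values[0, 1] == pytest.approx(np.arctanh(0.3))

    def test_zero_everywhere(self):
        m = mean_connectivity([self._from_r(0.0), self._from_r(0.0)])
        np.testing.assert_allclose(m.values, 0.0)

    def test_closed_form_average(self):
        m = mean_connectivity([self._from_r(0.5), self._from_r(0.5)])
        assert m.values[0, 1] == pytest.approx(np.arctanh(0.5))
        assert m.to_pearson().values[0, 1] == pytest.approx(0.5)

    def test_mixed_region_order_rejected(self):
        a = self._from_r(0.2)
        b = ConnectivityMatrix(a.values.copy(), ["b", "a"], "pearson_r")
        with pytest.raises(DataError, match="region order"):
            mean_connectivity([a, b])

    def test_commutes_with_subject_permutation(self):
        rng = np.random.default_rng(4)
        mats = [self._from_r(r) for r in rng.uniform(-0.8, 0.8, 7)]
        m1 = mean_connectivity(mats)
        m2 = mean_connectivity(mats[::-1])
        np.testing.assert_allclose(m1.values, m2.values)
        assert abs(m1.to_pearson().values[0, 1]) < 1


class TestDistance:
    @pytest.mark.parametrize("r,expected", [(1.0, 0.0), (-1.0, 1.0), (0.0, 0.5)])
    def test_endpoints(self, r, expected):
        r_capped = np.clip(r, -1 + 1e-12, 1 - 1e-12)
        mat = ConnectivityMatrix(
            np.array([[0.0, r_capped], [r_capped, 0.0]]), ["a", "b"]
        )
        d = correlation_to_distance(mat)
        assert d[0, 1] == pytest.approx(expected, abs=1e-9)


def brute_force_ward(dist):
    """Reference Ward agglomeration by exhaustive merge evaluation.

    Standard Lance-Williams update on squared distances; returns the
    merge sequence as frozensets.
    """
    d2 = (np.asarray(dist, float) ** 2).copy()
    clusters = {i: frozenset([i]) for i in range(len(dist))}
    sizes = {i: 1 for i in range(len(dist))}
    active = list(range(len(dist)))
    merges = []
    nxt = len(dist)
    while len(active) > 1:
        best = None
        for ai, a in enumerate(active):
            for b in active[ai + 1 :]:
                if best is None or d2[a, b] < best[0] - 1e-15:
                    best = (d2[a, b], a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append(merged)
        na, nb = sizes[a], sizes[b]
        d2 = np.pad(d2, ((0, 1), (0, 1)))
        for c in active:
            if c in (a, b):
                continue
            nc = sizes[c]
            d2[nxt, c] = d2[c, nxt] = (
                (na + nc) * d2[a, c] + (nb + nc) * d2[b, c] - nc * d2[a, b]
            ) / (na + nb + nc)
        clusters[nxt] = merged
        sizes[nxt] = na + nb
        active = [c for c in active if c not in (a, b)] + [nxt]
        nxt += 1
    return merges


class TestWard:
    def test_two_blocks_join_last(self):
        d, _ = _block_distance([4, 4])
        tree = ward_cluster(d, _names(8))
        clades = tree.clades()
        assert clades[-1] == frozenset(_names(8))
        part = cut_tree(tree, 2)
        assert sorted(map(len, [part.members(1), part.members(2)])) == [4, 4]

    def test_matches_brute_force_on_random_instances(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pts = rng.normal(size=(6, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            tree = ward_cluster(d, _names(6))
            ours = [frozenset(int(n[1:]) for n in c) for c in tree.clades()]
            assert ours == brute_force_ward(d)

    def test_equidistant_triple_merges_lowest_pair(self):
        d = np.full((3, 3), 1.0)
        np.fill_diagonal(d, 0.0)
        tree = ward_cluster(d, ["x", "y", "z"])
        assert tree.clades()[0] == frozenset({"x", "y"})

    def test_nonfinite_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(DataError, match="non-finite"):
            ward_cluster(d, ["a", "b", "c"])

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(12, 4))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        tree = ward_cluster(d, _names(12))
        assert (np.diff(tree.linkage[:, 2]) >= -1e-12).all()


class TestChooseKAndCut:
    @pytest.mark.parametrize("sizes,expected", [([6, 5, 5], 3), ([8, 8], 2)])
    def test_planted_blocks_win_vote(self, sizes, expected):
        d, _ = _block_distance(sizes, jitter=0.05, seed=1)
        tree = ward_cluster(d, _names(sum(sizes)))
        k, votes = choose_k(d, tree, (2, 6))
        assert k == expected
        assert votes.loc[expected, "vote"] >= votes["vote"].drop(expected).max()

    def test_cut_extremes(self):
        d, _ = _block_distance([3, 3], jitter=0.01)
        tree = ward_cluster(d, _names(6))
        assert cut_tree(tree, 1).k == 1
        assert cut_tree(tree, 6).k == 6
        with pytest.raises(DataError):
            cut_tree(tree, 7)

    def test_planted_sizes_recovered(self):
        d, _ = _block_distance([18, 8, 6], jitter=0.05, seed=2)
        tree = ward_cluster(d, _names(32))
        part = cut_tree(tree, 3)
        sizes = sorted(
            (len(part.members(lab)) for lab in (1, 2, 3)), reverse=True
        )
        assert sizes == [18, 8, 6]

    def test_cuts_are_nested(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(15, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        tree = ward_cluster(d, _names(15))
        for k in range(2, 15):
            coarse = cut_tree(tree, k - 1)
            fine = cut_tree(tree, k)
            # every fine cluster sits inside one coarse cluster
            for lab in range(1, k + 1):
                members = fine.members(lab)
                parents = {
                    coarse.labels[coarse.region_names.index(m)] for m in members
                }
                assert len(parents) == 1


class TestBootstrapSupport:
    def _subject_z(self, n_sub=30, sizes=(5, 4), seed=0):
        rng = np.random.default_rng(seed)
        n = sum(sizes)
        labels = np.repeat(np.arange(len(sizes)), sizes)
        base = np.where(labels[:, None] == labels[None, :], 0.6, -0.1)
        np.fill_diagonal(base, 0.0)
        z = np.arctanh(base * 0.999)
        stack = z[None] + rng.normal(0, 0.05, size=(n_sub, n, n))
        stack = (stack + stack.transpose(0, 2, 1)) / 2
        for s in range(n_sub):
            np.fill_diagonal(stack[s], 0.0)
        return stack, labels + 1

    def test_certain_cluster_has_unit_support(self):
        stack, labels = self._subject_z()
        names = _names(stack.shape[1])
        part = Partition(labels, names)
        cfg = AnalysisConfig(bootstrap_reps=150, seed=3)
        sup = bootstrap_support(stack, part, cfg, seed=11)
        assert (sup.table["au"] > 0.99).all()
        assert (sup.table["bp"] > 0.99).all()

    def test_flat_profile_identity(self):
        scales = [0.5, 0.7, 0.9, 1.0, 1.2, 1.4]
        v, c, au = fit_au([0.8] * 6, scales, 1000)
        assert c == 0.0
        assert au == pytest.approx(0.8, abs=1e-9)

    def test_au_monotone_in_v(self):
        from scipy import stats

        vs = np.linspace(-2, 2, 9)
        aus = [1 - stats.norm.cdf(v - 0.3) for v in vs]
        assert all(a > b for a, b in zip(aus, aus[1:]))

    def test_scale_too_small_rejected(self):
        stack, labels = self._subject_z(n_sub=4)
        part = Partition(labels, _names(stack.shape[1]))
        cfg = AnalysisConfig(
            bootstrap_reps=100, bootstrap_scales=(0.5, 1.0), seed=0
        )
        with pytest.raises(DataError, match="subjects"):
            bootstrap_support(stack, part, cfg, seed=1)


class TestAlternativesAndARI:
    def test_planted_blocks_recovered_by_all_methods(self):
        hits = {"average": 0, "gmm": 0, "kmeans": 0}
        n_seeds = 20
        for seed in range(n_seeds):
            d, labels = _block_distance([6, 5, 4], jitter=0.15, seed=seed)
            names = _names(15)
            truth = Partition(labels, names)
            r = 1.0 - 2.0 * d
            np.fill_diagonal(r, 0.0)
            mat = ConnectivityMatrix(np.clip(r, -0.999, 0.999), names)
            alts = alternative_partitions(d, mat, 3, seed=seed)
            for name, part in alts.items():
                hits[name] += adjusted_rand(part, truth) == 1.0
        for name, h in hits.items():
            assert h >= 0.8 * n_seeds, name

    def test_k_one_trivial(self):
        d, _ = _block_distance([3, 3])
        names = _names(6)
        r = 1.0 - 2.0 * d
        np.fill_diagonal(r, 0.0)
        mat = ConnectivityMatrix(np.clip(r, -0.999, 0.999), names)
        alts = alternative_partitions(d, mat, 1, seed=0)
        for part in alts.values():
            assert part.k == 1

    def test_identical_partitions(self):
        p = Partition([1, 1, 2, 2], ["a", "b", "c", "d"])
        assert adjusted_rand(p, p) == 1.0

    def test_hand_computed_value(self):
        """{a,b | c,d} vs {a,c | b,d} has ARI -1/2 by the pair-count formula."""
        p1 = Partition([1, 1, 2, 2], ["a", "b", "c", "d"])
        p2 = Partition([1, 2, 1, 2], ["a", "b", "c", "d"])
        assert adjusted_rand(p1, p2) == pytest.approx(-0.5)

    def test_label_permutation_invariance(self):
        p1 = Partition([1, 1, 2, 3, 3], list("abcde"))
        p2 = Partition([3, 3, 1, 2, 2], list("abcde"))
        assert adjusted_rand(p1, p2) == 1.0

    def test_label_permutation_property(self):
        from hypothesis import given, settings, strategies as st

        @settings(derandomize=True, max_examples=40, deadline=None)
        @given(
            st.lists(st.integers(0, 3), min_size=4, max_size=12),
            st.permutations(list(range(4))),
        )
        def check(raw, perm):
            names = [f"x{i}" for i in range(len(raw))]
            canon = {lab: i + 1 for i, lab in enumerate(dict.fromkeys(raw))}
            labels = [canon[l] for l in raw]
            permuted_raw = [perm[l - 1] for l in labels]
            canon2 = {
                lab: i + 1 for i, lab in enumerate(dict.fromkeys(permuted_raw))
            }
            p1 = Partition(labels, names)
            p2 = Partition([canon2[l] for l in permuted_raw], names)
            assert adjusted_rand(p1, p2) == pytest.approx(1.0)

        check()

    def test_leaf_mismatch_rejected(self):
        p1 = Partition([1, 2], ["a", "b"])
        p2 = Partition([1, 2], ["a", "c"])
        with pytest.raises(DataError):
            adjusted_rand(p1, p2)
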