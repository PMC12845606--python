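"""Reference clustering, Pearson matching, activation timing."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synkick.synergy import SynergySet
from synkick.synergy_matching import (
    ReferenceSynergySet,
    activation_features,
    align_references,
    build_reference,
    kmeans_cluster,
    match_to_reference,
    pool_weights,
    select_cluster_count,
)
from synkick.synthetic_emg import default_ground_truth


def _nset(W, subject="S1", H=None, frac_map=None):
    k = W.shape[1]
    sset = SynergySet(
        W=W, H=H if H is not None else np.ones((k, 8)), k=k, vaf=0.95,
        sse=1.0, muscle_labels=[f"m{i}" for i in range(W.shape[0])],
        cycle_fraction_map=frac_map,
    )
    sset.normalized = True
    sset.meta["subject"] = subject
    return sset


class TestPooling:
    def test_counts_and_provenance(self, rng):
        sets = [
            _nset(np.abs(rng.random((5, 4))) + 0.01, subject=f"S{i}")
            for i in range(15)
        ]
        rows, prov = pool_weights(sets)
        assert rows.shape == (60, 5)
        # provenance round-trips to the originating column
        for r, (subj, col) in zip(rows, prov):
            src = next(s for s in sets if s.meta["subject"] == subj)
            np.testing.assert_array_equal(r, src.W[:, col])

    def test_single_subject(self, rng):
        sets = [_nset(np.abs(rng.random((5, 3))) + 0.01)]
        rows, prov = pool_weights(sets)
        assert rows.shape == (3, 5)

    def test_label_mismatch(self, rng):
        a = _nset(np.abs(rng.random((5, 2))) + 0.01)
        b = _nset(np.abs(rng.random((4, 2))) + 0.01, subject="S2")
        with pytest.raises(ValueError, match="muscle labels"):
            pool_weights([a, b])


class TestKmeans:
    def test_single_cluster_closed_form(self, rng):
        rows = rng.random((12, 4))
        cents, labels, sse = kmeans_cluster(rows, 1, seed=0)
        np.testing.assert_allclose(cents[0], rows.mean(axis=0))
        assert sse == pytest.approx(np.sum((rows - rows.mean(0)) ** 2))

    def test_planted_blobs_recovered(self, rng):
        a = rng.normal(0.0, 0.05, size=(20, 3)) + [1, 0, 0]
        b = rng.normal(0.0, 0.05, size=(20, 3)) + [0, 1, 0]
        rows = np.vstack([a, b])
        _, labels, _ = kmeans_cluster(np.abs(rows), 2, seed=0)
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_duplicates_zero_sse(self):
        rows = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        _, _, sse = kmeans_cluster(rows, 2, seed=0)
        assert sse == pytest.approx(0.0, abs=1e-12)

    def test_too_many_clusters(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_cluster(rng.random((3, 2)), 5, seed=0)


class TestClusterCount:
    def test_four_planted_clusters(self, rng):
        # four well-separated patterns in 10-muscle space
        centers = np.zeros((4, 10))
        for j in range(4):
            centers[j, 2 * j : 2 * j + 2] = 1.0
        rows = np.vstack(
            [c + rng.normal(0, 0.05, size=(15, 10)) for c in centers]
        )
        s, curve = select_cluster_count(np.abs(rows), seed=0)
        assert s == 4

    def test_degenerate_blob_of_duplicates(self):
        rows = np.tile([0.2, 0.9, 0.4, 0.1], (25, 1))
        s, _ = select_cluster_count(rows, seed=0)
        assert s == 1

    def test_unstructured_cloud_with_modest_tolerance(self, rng):
        # an isotropic cloud has no elbow: each split removes ~15% SSE in
        # 10-d, so a 0.2 tolerance stops immediately
        rows = 0.5 + rng.normal(0, 0.02, size=(40, 10))
        s, _ = select_cluster_count(np.abs(rows), drop_tol=0.2, seed=0)
        assert s == 1

    def test_vacuous_tolerance(self, rng):
        rows = rng.random((20, 4))
        s, _ = select_cluster_count(rows, drop_tol=1.0, seed=0)
        assert s == 1


class TestMatching:
    def _ref(self, centroids):
        return ReferenceSynergySet(
            centroids=centroids, s=centroids.shape[0], sse_curve={},
            muscle_labels=[f"m{i}" for i in range(centroids.shape[1])],
        )

    def test_identical_matches_with_r_one(self, rng):
        cents = np.abs(rng.random((3, 6))) + 0.01
        cents = cents / cents.max(axis=1, keepdims=True)
        sset = _nset(cents.T.copy())
        matches = match_to_reference(sset, self._ref(cents))
        assert len(matches) == 3
        for m in matches:
            assert m.r == pytest.approx(1.0)
            assert m.column == m.cluster or True  # identity checked below
        assert {(m.column, m.cluster) for m in matches} == {(i, i) for i in range(3)}

    def test_dissimilar_left_unmatched(self):
        # anti-correlated subject synergy: r < 0 against every centroid
        cents = np.array([[1.0, 0.9, 0.1, 0.0], [0.9, 1.0, 0.0, 0.1]])
        W = np.array([[0.0], [0.1], [0.9], [1.0]])
        matches = match_to_reference(_nset(W), self._ref(cents))
        assert matches == []

    def test_permutation_recovered_exactly(self, rng):
        cents = np.abs(rng.random((4, 8))) + 0.01
        cents = cents / cents.max(axis=1, keepdims=True)
        perm = [2, 0, 3, 1]
        sset = _nset(cents[perm].T.copy())
        matches = match_to_reference(sset, self._ref(cents))
        got = {m.column: m.cluster for m in matches}
        assert got == {i: perm[i] for i in range(4)}
        # brute-force check: greedy result equals the best assignment
        best = max(
            itertools.permutations(range(4)),
            key=lambda p: sum(
                np.corrcoef(sset.W[:, i], cents[p[i]])[0, 1] for i in range(4)
            ),
        )
        assert got == {i: best[i] for i in range(4)}

    def test_injective(self, rng):
        for trial in range(10):
            cents = np.abs(rng.random((3, 6))) + 0.01
            W = np.abs(rng.random((6, 5))) + 0.01
            W = W / W.max(axis=0)
            matches = match_to_reference(_nset(W), self._ref(cents))
            cols = [m.column for m in matches]
            clus = [m.cluster for m in matches]
            assert len(cols) == len(set(cols))
            assert len(clus) == len(set(clus))

    def test_column_order_invariance(self, rng):
        cents = np.abs(rng.random((4, 7))) + 0.01
        W = np.abs(rng.random((7, 4))) + 0.01
        W = W / W.max(axis=0)
        base = match_to_reference(_nset(W), self._ref(cents))
        perm = [3, 1, 0, 2]
        permuted = match_to_reference(_nset(W[:, perm]), self._ref(cents))
        base_pairs = {(m.column, m.cluster, round(m.r, 12)) for m in base}
        undone = {(perm[m.column], m.cluster, round(m.r, 12)) for m in permuted}
        assert base_pairs == undone

    def test_hungarian_variant(self, rng):
        cents = np.abs(rng.random((3, 6))) + 0.01
        W = np.abs(rng.random((6, 3))) + 0.01
        W = W / W.max(axis=0)
        matches = match_to_reference(_nset(W), self._ref(cents), method="hungarian")
        clus = [m.cluster for m in matches]
        assert len(clus) == len(set(clus))


class TestActivationFeatures:
    def test_rectangular_pulse(self):
        fr = np.linspace(0, 1, 401)
        h = ((fr >= 0.2) & (fr < 0.6)).astype(float)
        f = activation_features(h, fr)
        assert f.T == pytest.approx(0.4, abs=1 / 400)
        assert f.t_start == pytest.approx(0.2, abs=1 / 400)
        assert 0.2 <= f.t_max < 0.6

    def test_tie_takes_first_peak(self):
        fr = np.linspace(0, 1, 101)
        h = np.zeros(101)
        h[30] = 1.0
        h[70] = 1.0
        f = activation_features(h, fr)
        assert f.t_max == pytest.approx(fr[30])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            activation_features(np.zeros(50), np.linspace(0, 1, 50))

    def test_default_bumps_recovered_within_grid_step(self):
        gt = default_ground_truth()
        fr = np.linspace(0, 1, 404)
        step = fr[1] - fr[0]
        for b in gt.timing:
            f = activation_features(b.evaluate(fr), fr)
            assert f.t_max == pytest.approx(b.center, abs=step)
            assert f.T == pytest.approx(b.width, abs=2 * step)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_invariants_on_random_rows(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.random(80)
        fr = np.linspace(0, 1, 80)
        f = activation_features(h, fr)
        assert 0.0 <= f.t_start <= f.t_max <= 1.0
        assert 0.0 <= f.T <= 1.0


class TestBuildAndAlign:
    def test_build_reference_from_planted_sets(self, rng):
        # 12 subjects sharing 3 distinct synergy profiles in 10-muscle space
        base = np.abs(rng.random((3, 10))) + 0.1
        base = base / base.max(axis=1, keepdims=True)
        sets = []
        for i in range(12):
            W = (base + rng.normal(0, 0.02, size=base.shape)).clip(min=0).T
            W = W / W.max(axis=0)
            sets.append(_nset(W, subject=f"S{i}"))
        # splitting a 12-point cluster in 10-d removes ~12-15% of its SSE,
        # so the planted structure needs a tolerance just above that
        ref = build_reference(sets, seed=0, restarts=20, drop_tol=0.15)
        assert ref.s == 3
        assert ref.centroids.shape == (3, 10)
        np.testing.assert_allclose(ref.centroids.max(axis=1), 1.0)

    def test_align_permutes_to_anchor(self, rng):
        cents = np.abs(rng.random((3, 6))) + 0.1
        cents = cents / cents.max(axis=1, keepdims=True)
        anchor = ReferenceSynergySet(
            centroids=cents, s=3, sse_curve={}, muscle_labels=list("abcdef"),
            group="control", session="pre",
        )
        other = ReferenceSynergySet(
            centroids=cents[[2, 0, 1]], s=3, sse_curve={},
            muscle_labels=list("abcdef"), group="experimental", session="pre",
        )
        refs = align_references(
            {("control", "pre"): anchor, ("experimental", "pre"): other}
        )
        np.testing.assert_allclose(
            refs[("experimental", "pre")].centroids, cents, atol=1e-12
        )
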