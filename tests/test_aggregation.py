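import numpy as np
import pytest

from gma.aggregation import (
    AggregationParams,
    aggregate_scale,
    coarsen,
    delta,
    label_hand,
    merged_sigma,
    order_edges,
    run_multiscale,
)
from gma.graph_core import ScaleGraph, Segment, build_lattice_graph, to_a_plane
from gma.similarity import Grid, gaussian_phi

from conftest import bimodal_rgb
from oracles import pooled_std


def toy_graph(values, edges, weights, sigmas=None):
    """Scale-0-like graph over scalar node values with explicit
    edges/weights (phi rows unused by the assignment pass)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    grid = Grid(-1.0, 2.0, 8)
    if sigmas is None:
        sigmas = np.full(n, 0.1)
    phi = np.full((n, 8), 1.0 / 3.0)
    return ScaleGraph(
        scale=0,
        grid=grid,
        counts=np.ones(n, dtype=np.int64),
        sum_a=values,
        sum_sq=values**2,
        centroids=np.stack([np.zeros(n), np.arange(n, dtype=float)], axis=1),
        sigma=np.asarray(sigmas, dtype=float),
        phi_rows=phi,
        edges=np.asarray(edges, dtype=np.int64),
        weights=np.asarray(weights, dtype=float),
    )


class TestOrderEdges:
    def test_two_weights(self):
        g = toy_graph([0, 0, 0], [[0, 1], [1, 2]], [0.1, 0.9])
        assert order_edges(g).tolist() == [[1, 2], [0, 1]]

    def test_ties_ascending_pairs(self):
        g = toy_graph([0, 0, 0, 0], [[2, 3], [0, 1], [1, 2]], [0.5, 0.5, 0.5])
        assert order_edges(g).tolist() == [[0, 1], [1, 2], [2, 3]]

    def test_matches_reference_sort(self, rng):
        for _ in range(20):
            n = 8
            edges = [[i, j] for i in range(n) for j in range(i + 1, n)]
            w = rng.random(len(edges))
            g = toy_graph(np.zeros(n), edges, w)
            ref = sorted(
                zip(w.tolist(), edges), key=lambda t: (-t[0], t[1][0], t[1][1])
            )
            assert order_edges(g).tolist() == [e for _, e in ref]


def make_segment(values, seg_id=0, sigma=None):
    values = np.asarray(values, dtype=float)
    grid = Grid(-100.0, 100.0, 64)
    return Segment(
        id=seg_id,
        scale=1,
        pixel_stats=(len(values), float(values.sum()), float((values**2).sum())),
        centroid=(0.0, 0.0),
        sigma=float(np.std(values)) if sigma is None else sigma,
        phi=gaussian_phi(float(values.mean()), 1.0, grid),
    )


class TestMergedSigma:
    def test_two_pixels(self):
        assert merged_sigma(make_segment([0.0]), make_segment([2.0])) == 1.0

    def test_identical_constant(self):
        a = make_segment([3.0, 3.0])
        assert merged_sigma(a, a) == 0.0

    def test_matches_concatenation_oracle(self, rng):
        for _ in range(30):
            va = rng.normal(0, 5, rng.integers(1, 40))
            vb = rng.normal(3, 2, rng.integers(1, 40))
            got = merged_sigma(make_segment(va), make_segment(vb))
            assert got == pytest.approx(pooled_std(va, vb), abs=1e-9)


class TestDelta:
    def test_zero_dispersion_merges(self):
        assert delta(0.0, 0.5, 0.9, 0.0) == 1

    def test_printed_arithmetic(self):
        assert delta(0.2, 0.1, 0.1, 0.01) == 0  # 0.2 > 0.11

    def test_equality_passes(self):
        for c in (0.0, 0.3, 2.0):
            assert delta(c, c, c, 0.0) == 1

    def test_weighted_reduces_to_plain_for_equal_weights(self):
        assert delta(0.3, 0.2, 0.45, 0.0, 1, 1) == delta(0.3, 0.2, 0.45, 0.0, 7, 7)

    def test_weighted_follows_large_part(self):
        # a 1-pixel part cannot zero out the criterion when the other
        # side carries thousands of pixels
        assert delta(0.1, 0.0, 0.1, 0.01, 1, 10_000) == 1
        assert delta(0.1, 0.0, 0.1, 0.01, 1, 1) == 0


class TestAggregateScale:
    def test_path_chain_merges(self):
        g = toy_graph(
            [1.0, 1.0, 1.0, 1.0],
            [[0, 1], [1, 2], [2, 3]],
            [0.9, 0.8, 0.7],
        )
        out = aggregate_scale(g, k=0.05)
        assert out.n_groups == 1
        assert len(set(out.labels.tolist())) == 1

    def test_all_rejected_all_singletons(self):
        g = toy_graph(
            [0.0, 10.0, 20.0, 30.0],
            [[0, 1], [1, 2], [2, 3]],
            [0.9, 0.8, 0.7],
            sigmas=[1e-3] * 4,
        )
        out = aggregate_scale(g, k=0.0)
        assert out.n_groups == 4
        assert out.merges == 0

    def test_partition_contract(self, rng):
        img = rng.random((8, 8, 3))
        g = build_lattice_graph(to_a_plane(img))
        out = aggregate_scale(g, k=0.02)
        assert set(out.labels.tolist()) == set(range(out.n_groups))
        nxt = coarsen(g, out.labels, out.n_groups)
        assert nxt.counts.sum() == 64
        assert np.all(nxt.counts >= 1)

    def test_isolated_nodes_become_singletons(self):
        g = toy_graph([0.0, 0.0, 5.0], [[0, 1]], [0.9], sigmas=[0.5, 0.5, 0.5])
        out = aggregate_scale(g, k=0.1)
        assert out.n_groups == 2  # {0,1} merged, node 2 unreached


class TestCoarsen:
    def test_centroids_in_hull(self, rng):
        img = rng.random((6, 6, 3))
        g = build_lattice_graph(to_a_plane(img))
        out = aggregate_scale(g, k=0.05)
        nxt = coarsen(g, out.labels, out.n_groups)
        assert np.all(nxt.centroids[:, 0] >= 0) and np.all(nxt.centroids[:, 0] <= 5)
        assert np.all(nxt.centroids[:, 1] >= 0) and np.all(nxt.centroids[:, 1] <= 5)

    def test_sigma_is_pooled_population_std(self, rng):
        img = rng.random((6, 6, 3))
        ap = to_a_plane(img)
        g = build_lattice_graph(ap)
        out = aggregate_scale(g, k=0.05)
        nxt = coarsen(g, out.labels, out.n_groups)
        flat = ap.a_values.ravel()
        members = np.bincount(out.labels, minlength=out.n_groups)
        for gid in range(out.n_groups):
            if members[gid] < 2:
                continue  # singleton carriers inherit the node dispersion
            vals = flat[out.labels == gid]
            assert nxt.sigma[gid] == pytest.approx(float(np.std(vals)), abs=1e-9)

    def test_phi_rows_unit_mass(self, rng):
        img = rng.random((6, 6, 3))
        g = build_lattice_graph(to_a_plane(img))
        out = aggregate_scale(g, k=0.05)
        nxt = coarsen(g, out.labels, out.n_groups)
        masses = nxt.phi_rows.sum(axis=1) * nxt.grid.spacing
        np.testing.assert_allclose(masses, 1.0, atol=1e-6)


class TestRunMultiscale:
    def test_bimodal_recovery(self, bimodal_image):
        rgb, truth = bimodal_image
        res = run_multiscale(rgb)
        assert res.n_segments == 2
        agree = max(
            (res.mask == truth).mean(), (res.mask == 1 - truth).mean()
        )
        assert agree >= 0.99

    def test_counts_strictly_decrease(self, bimodal_image):
        rgb, _ = bimodal_image
        res = run_multiscale(rgb)
        counts = res.trace.segment_counts()
        assert all(a > b for a, b in zip(counts, counts[1:]))

    def test_deterministic(self, bimodal_image):
        rgb, _ = bimodal_image
        a = run_multiscale(rgb)
        b = run_multiscale(rgb)
        np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_constant_image_degenerate(self):
        img = np.full((12, 12, 3), 0.4)
        res = run_multiscale(img)
        assert res.degenerate
        assert res.n_segments == 1
        assert res.mask.sum() == 0

    def test_pixel_count_conserved(self, bimodal_image):
        rgb, _ = bimodal_image
        res = run_multiscale(rgb)
        assert res.labels.size == rgb.shape[0] * rgb.shape[1]
        areas = np.bincount(res.labels.ravel())
        assert areas.sum() == rgb.shape[0] * rgb.shape[1]

    def test_k_zero_constant_image_reaches_one_segment(self):
        # no relaxation needed on a constant image: merges always fire
        img = np.full((10, 10, 3), 0.6)
        params = AggregationParams(k0=0.0, k_step=0.0, max_stuck_retries=0)
        res = run_multiscale(img, params)
        assert res.n_segments == 1

    def test_larger_k0_not_more_scales(self):
        rgb, _ = bimodal_rgb(height=20, width=20, noise=2.0, seed=3)
        n_scales = []
        for k0 in (0.01, 0.05, 0.15):
            res = run_multiscale(rgb, AggregationParams(k0=k0))
            n_scales.append(len(res.trace.records))
        assert n_scales[0] >= n_scales[1] >= n_scales[2]

    def test_tiny_image_rejected(self):
        from gma.errors import ContractError

        with pytest.raises(ContractError):
            run_multiscale(np.full((1, 1, 3), 0.5))


class TestLabelHand:
    def test_disk_vs_frame(self):
        labels = np.zeros((20, 20), dtype=int)
        rr, cc = np.mgrid[0:20, 0:20]
        disk = (rr - 10) ** 2 + (cc - 10) ** 2 <= 25
        labels[disk] = 1
        mask = label_hand(labels)
        np.testing.assert_array_equal(mask.astype(bool), disk)

    def test_vertical_halves_tie_break(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[:, 5:] = 1
        mask = label_hand(labels)
        # equal border fractions and areas: smallest id wins
        np.testing.assert_array_equal(mask.astype(bool), labels == 0)

    def test_single_segment_zero_mask(self):
        with pytest.warns(UserWarning):
            mask = label_hand(np.zeros((5, 5), dtype=int))
        assert mask.sum() == 0

    def test_skin_reference_override(self):
        from gma.graph_core import APlaneImage

        labels = np.zeros((10, 10), dtype=int)
        labels[:, 5:] = 1
        a = np.zeros((10, 10))
        a[:, 5:] = 18.0  # right half is skin-like
        ap = APlaneImage(10, 10, a)
        mask = label_hand(labels, a_plane=ap, skin_a_reference=17.0)
        np.testing.assert_array_equal(mask.astype(bool), labels == 1)
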