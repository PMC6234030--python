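import numpy as np
import pytest

from glomquant import (
    SpatialConfig,
    SynthConfig,
    assign_to_roi,
    density_map,
    generate_point_cloud,
    segment_regions,
)


def _two_cluster_cloud(seed=1, n=10_000, sep_um=20.0, sigma_um=3.0):
    centers = ((30.0, 30.0, 30.0), (30.0 + sep_um, 30.0, 30.0))
    cfg = SynthConfig(
        seed=seed,
        spatial=SpatialConfig(centers_um=centers, sigma_um=sigma_um, n_points=n),
    )
    points, labels = generate_point_cloud(cfg)
    return points, labels, np.asarray(centers) * 1000.0


def test_empty_cloud_rejected():
    with pytest.raises(ValueError, match="empty"):
        density_map(np.empty((0, 3)))


def test_single_point_single_nonzero_bin():
    grid = density_map(np.array([[500.0, 500.0, 500.0]]), 1000.0, 0.0)
    assert (grid.counts > 0).sum() == 1
    assert grid.counts.sum() == 1


def test_histogram_conserves_count_and_smoothing_conserves_mass():
    rng = np.random.default_rng(0)
    points = rng.uniform(0, 30_000, size=(5000, 3))
    grid = density_map(points, 1000.0, 2.0)
    assert grid.counts.sum() == 5000
    assert grid.density.sum() == pytest.approx(5000, rel=1e-6)


def test_uniform_cloud_smoothed_density_is_flat():
    rng = np.random.default_rng(1)
    points = rng.uniform(0, 50_000, size=(100_000, 3))
    grid = density_map(points, 1000.0, 2.0)
    # interior: away from the empty padding margin and the boundary roll-off
    m = 12
    interior = grid.density[m:-m, m:-m, m:-m]
    cv = interior.std() / interior.mean()
    assert cv < 0.2


def test_two_clusters_recovered_with_oracle_membership():
    points, true_labels, centers = _two_cluster_cloud(seed=1)
    grid = density_map(points, 1000.0, 2.0)
    seg = segment_regions(grid)
    assert seg.n_regions == 2
    oracle = np.argmin(
        ((points[:, None, :] - centers[None]) ** 2).sum(-1), axis=1
    )
    for r in (1, 2):
        mask = assign_to_roi(points, seg, r)
        cluster = np.bincount(oracle[mask]).argmax()
        recall = (mask & (oracle == cluster)).sum() / (oracle == cluster).sum()
        purity = (oracle[mask] == cluster).mean()
        assert recall > 0.95
        assert purity > 0.95


def test_k_clusters_recovered_at_six_sigma_separation():
    sigma = 3.0
    centers = tuple(
        (30.0 + 6 * sigma * k, 30.0, 30.0) for k in range(3)
    )
    cfg = SynthConfig(
        seed=2,
        spatial=SpatialConfig(centers_um=centers, sigma_um=sigma, n_points=15_000),
    )
    points, _ = generate_point_cloud(cfg)
    seg = segment_regions(density_map(points, 1000.0, 2.0))
    assert seg.n_regions == 3


def test_single_cluster_yields_one_region():
    cfg = SynthConfig(
        seed=3, spatial=SpatialConfig(centers_um=((30.0, 30.0, 30.0),), n_points=5000)
    )
    points, _ = generate_point_cloud(cfg)
    seg = segment_regions(density_map(points, 1000.0, 2.0))
    assert seg.n_regions == 1
    assert seg.regions.n_points.iloc[0] == pytest.approx(5000, abs=300)


def test_point_order_invariance():
    points, _, _ = _two_cluster_cloud(seed=4, n=4000)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(points))
    seg1 = segment_regions(density_map(points, 1000.0, 2.0))
    seg2 = segment_regions(density_map(points[perm], 1000.0, 2.0))
    assert (seg1.labels == seg2.labels).all()


def test_translation_equivariance():
    points, _, _ = _two_cluster_cloud(seed=5, n=4000)
    shift = np.array([7000.0, 3000.0, 11_000.0])
    seg1 = segment_regions(density_map(points, 1000.0, 2.0))
    seg2 = segment_regions(density_map(points + shift, 1000.0, 2.0))
    assert (seg1.labels == seg2.labels).all()
    np.testing.assert_allclose(seg2.origin - seg1.origin, shift)


def test_threshold_increase_shrinks_regions_monotonically():
    points, _, _ = _two_cluster_cloud(seed=6, n=4000)
    grid = density_map(points, 1000.0, 2.0)
    # pure-threshold mode (no watershed extension): monotone shrinkage
    prev = None
    for q in (0.3, 0.5, 0.7, 0.9):
        seg = segment_regions(grid, quantile=q, capture_quantile=None)
        total_voxels = (seg.labels > 0).sum()
        if prev is not None:
            assert total_voxels <= prev
        prev = total_voxels


def test_roi_assignment_matches_brute_force_voxel_lookup():
    points, _, _ = _two_cluster_cloud(seed=7, n=3000)
    grid = density_map(points, 1000.0, 2.0)
    seg = segment_regions(grid)
    voxels = np.floor((points - seg.origin) / seg.bin_size).astype(int)
    for r in range(1, seg.n_regions + 1):
        mask = assign_to_roi(points, seg, r)
        brute = np.array(
            [
                seg.labels[tuple(v)] == r
                if (v >= 0).all() and (v < seg.labels.shape).all()
                else False
                for v in voxels
            ]
        )
        assert (mask == brute).all()


def test_points_outside_grid_are_excluded_with_warning(caplog):
    points, _, _ = _two_cluster_cloud(seed=8, n=3000)
    grid = density_map(points, 1000.0, 2.0)
    seg = segment_regions(grid)
    outside = np.vstack([points, [[1e9, 1e9, 1e9]]])
    with caplog.at_level("WARNING"):
        mask = assign_to_roi(outside, seg, 1)
    assert not mask[-1]
    assert "outside" in caplog.text


def test_unknown_region_id_raises():
    points, _, _ = _two_cluster_cloud(seed=9, n=2000)
    seg = segment_regions(density_map(points, 1000.0, 2.0))
    with pytest.raises(ValueError, match="unknown region"):
        assign_to_roi(points, seg, 99)
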