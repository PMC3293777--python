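"""Seeding, edge potential, and geodesic active contour behavior."""

import numpy as np
import pytest

from mitoseg import LevelSetParams, generate_toy_polygons
from mitoseg.levelset import (
    edge_potential,
    run_geodesic_active_contour,
    seeds_from_contours,
)
from mitoseg.patches import ProbabilityMap

SPACING = (50.0, 10.0, 10.0)


def test_disc_seed_erosion_radius():
    """Eroding a 25 px disc interior by a 10 px disc leaves ~a 15 px disc."""
    c = generate_toy_polygons("circle", 0.25, plane=1, center_um=(0.5, 0.5))
    seeds = seeds_from_contours([c], (3, 100, 100), SPACING, erosion_px=10)
    assert seeds[0].sum() == 0 and seeds[2].sum() == 0
    area = seeds[1].sum()
    assert area == pytest.approx(np.pi * 15**2, rel=0.1)


def test_small_contour_vanishes_under_erosion():
    c = generate_toy_polygons("circle", 0.08, plane=0, center_um=(0.5, 0.5))
    seeds = seeds_from_contours([c], (1, 100, 100), SPACING, erosion_px=10)
    assert seeds.sum() == 0


def test_seeds_land_on_their_planes_only():
    c0 = generate_toy_polygons("circle", 0.2, plane=0, center_um=(0.5, 0.5))
    c3 = generate_toy_polygons("circle", 0.2, plane=3, center_um=(0.5, 0.5))
    seeds = seeds_from_contours([c0, c3], (5, 100, 100), SPACING, erosion_px=2)
    occupied = {z for z in range(5) if seeds[z].any()}
    assert occupied == {0, 3}
    with pytest.raises(ValueError):
        seeds_from_contours(
            [generate_toy_polygons("circle", 0.2, plane=9)], (5, 100, 100), SPACING, 2
        )


def test_constant_map_gives_uniform_maximal_speed():
    prob = ProbabilityMap(np.full((4, 20, 20), 0.7, dtype=np.float32), SPACING)
    speed = edge_potential(prob)
    assert (speed == 1.0).all()


def test_step_edge_minimizes_speed_on_the_step():
    data = np.zeros((3, 40, 40), dtype=np.float32)
    data[:, :, 20:] = 1.0
    speed = edge_potential(ProbabilityMap(data, SPACING))
    profile = speed[1, 20]
    assert profile.argmin() in (19, 20)
    assert profile[0] > 0.9 and profile[-1] > 0.9


def test_gradient_magnitude_matches_analytic_quadratic():
    """Spacing-aware finite differences against the exact gradient of a quadratic."""
    nz, ny, nx = 9, 16, 16
    dz, dy, dx = 5.0, 1.0, 1.0  # XY-pixel units of (50,10,10) nm
    z, y, x = np.meshgrid(
        np.arange(nz) * dz, np.arange(ny) * dy, np.arange(nx) * dx, indexing="ij"
    )
    f = 1e-4 * (z**2 + 2 * y**2 + 3 * x**2)
    assert f.max() < 1.0  # stays a valid probability: no clipping distortion
    prob = ProbabilityMap(f.astype(np.float64), SPACING)
    params = LevelSetParams(sigmoid_alpha=1.0, sigmoid_beta=0.0)
    speed = edge_potential(prob, params)
    # invert the sigmoid used by edge_potential to recover |grad|
    g = np.log(1.0 / speed.astype(np.float64) - 1.0)
    g_exact = np.sqrt(
        (2e-4 * z) ** 2 + (4e-4 * y) ** 2 + (6e-4 * x) ** 2
    )
    interior = (slice(1, -1),) * 3
    np.testing.assert_allclose(g[interior], g_exact[interior], atol=1e-6)


def test_empty_seeds_return_empty_labels_with_warning():
    seeds = np.zeros((3, 10, 10), dtype=bool)
    speed = np.ones((3, 10, 10), dtype=np.float32)
    with pytest.warns(UserWarning, match="no seed"):
        out = run_geodesic_active_contour(seeds, speed, LevelSetParams(), SPACING)
    assert out.data.sum() == 0


def test_propagation_only_growth_is_monotone_from_seeds():
    """Uniform speed, no advection/curvature: the front dilates outward."""
    seeds = np.zeros((5, 40, 40), dtype=bool)
    seeds[2, 18:22, 18:22] = True
    speed = np.ones(seeds.shape, dtype=np.float32)
    params = LevelSetParams(
        advection_scaling=0.0, curvature_scaling=0.0, propagation_scaling=1.0,
        max_iterations=60, rms_convergence_tolerance=1e-9,
    )
    out = run_geodesic_active_contour(seeds, speed, params, SPACING)
    grown = out.data.astype(bool)
    assert (grown & seeds).sum() == seeds.sum()  # contains all seeds
    assert grown.sum() > seeds.sum()             # and strictly grew


def test_single_iteration_stays_near_seed_band():
    seeds = np.zeros((3, 30, 30), dtype=bool)
    seeds[1, 10:20, 10:20] = True
    speed = np.ones(seeds.shape, dtype=np.float32)
    params = LevelSetParams(
        advection_scaling=0.0, curvature_scaling=0.0, max_iterations=1,
        rms_convergence_tolerance=1e-9,
    )
    out = run_geodesic_active_contour(seeds, speed, params, SPACING).data.astype(bool)
    # output deviates from the seed mask by at most a 1-voxel band
    from scipy.ndimage import binary_dilation

    assert (out & ~binary_dilation(seeds, iterations=2)).sum() == 0
    assert (~out & seeds).sum() <= seeds.sum() * 0.2


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        run_geodesic_active_contour(
            np.ones((2, 5, 5), dtype=bool),
            np.ones((2, 6, 5), dtype=np.float32),
            LevelSetParams(),
            SPACING,
        )


def test_fast_march_init_fills_blob_interior():
    """FM through a high-probability blob covers it before evolution starts."""
    prob = np.zeros((9, 60, 60), dtype=np.float32)
    zz, yy, xx = np.meshgrid(np.arange(9), np.arange(60), np.arange(60), indexing="ij")
    truth = (((xx - 30) / 20.0) ** 2 + ((yy - 30) / 15.0) ** 2 + ((zz - 4) / 3.0) ** 2) <= 1
    prob[truth] = 0.95
    seeds = np.zeros_like(truth)
    seeds[4, 25:35, 25:35] = True
    speed = edge_potential(ProbabilityMap(prob, SPACING))
    params = LevelSetParams(max_iterations=50)
    out = run_geodesic_active_contour(
        seeds, speed, params, SPACING, fast_march_speed=prob
    ).data.astype(bool)
    tpr = (out & truth).sum() / truth.sum()
    fpr = (out & ~truth).sum() / (~truth).sum()
    assert tpr > 0.9
    assert fpr < 0.02
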