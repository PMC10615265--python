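"""Field solver tests against closed forms and exact discrete identities."""

from __future__ import annotations

import numpy as np
import pytest

from fincount.field import (FishEllipsoid, TankGeometry, build_grid,
                            calibrate_sigma_water, delta_R_linearized,
                            depolarization_factors, dissipated_power,
                            embed_fish, fish_voxel_mask, midline_profiles,
                            prolong_potential, resistance_with_fish,
                            sensitivity_map, solve_field)

SIGMA = 0.05
FULL_WALL = TankGeometry(electrode_width=0.400)


@pytest.fixture(scope="module")
def full_wall_solution():
    grid = build_grid(FULL_WALL, h=0.02, sigma_water=SIGMA)
    return solve_field(grid)


@pytest.fixture(scope="module")
def strip_solution():
    grid = build_grid(TankGeometry(), h=0.01, sigma_water=SIGMA)
    return solve_field(grid)


def test_full_wall_resistance_matches_closed_form(full_wall_solution):
    # parallel plates: R = d / (sigma * A) = 0.24 / (0.05 * 0.4 * 0.2) = 60 ohm
    assert full_wall_solution.resistance == pytest.approx(60.0, rel=1e-9)


def test_resistance_scales_inversely_with_sigma():
    g1 = build_grid(TankGeometry(), h=0.02, sigma_water=SIGMA)
    g2 = build_grid(TankGeometry(), h=0.02, sigma_water=2 * SIGMA)
    r1 = solve_field(g1).resistance
    r2 = solve_field(g2).resistance
    assert r1 == pytest.approx(2 * r2, rel=1e-10)


def test_current_conservation(strip_solution):
    assert strip_solution.current_drive == pytest.approx(
        strip_solution.current_ground, rel=1e-6)


def test_reciprocity(strip_solution):
    grid = build_grid(TankGeometry(), h=0.01, sigma_water=SIGMA)
    other = solve_field(grid, drive_side=1)
    assert other.resistance == pytest.approx(strip_solution.resistance,
                                             rel=1e-3)


def test_power_identity(strip_solution):
    p = dissipated_power(strip_solution)
    expect = strip_solution.v_drive * strip_solution.total_current
    assert p == pytest.approx(expect, rel=1e-6)


def test_uniform_sensitivity_full_wall(full_wall_solution):
    sens = sensitivity_map(full_wall_solution)
    # uniform field: S = 1/A^2 = 1/(0.4*0.2)^2 = 156.25 m^-4 everywhere
    assert np.allclose(sens.S, 156.25, rtol=1e-9)


def test_sensitivity_integral_recovers_resistance(full_wall_solution):
    sens = sensitivity_map(full_wall_solution)
    grid = full_wall_solution.grid
    total = float(np.sum(sens.S / grid.sigma) * grid.h ** 3)
    assert total == pytest.approx(full_wall_solution.resistance, rel=1e-9)


def test_sensitivity_nonnegative(strip_solution):
    assert (sensitivity_map(strip_solution).S >= 0).all()


def test_sensitivity_peaks_at_electrodes(strip_solution):
    sens = sensitivity_map(strip_solution)
    grid = strip_solution.grid
    xi = np.argmin(np.abs(grid.axis_centers(0) - 0.2))
    zi = grid.shape[2] // 2
    prof = sens.S[xi, :, zi]
    assert max(prof[0], prof[-1]) > 3 * prof[grid.shape[1] // 2]


def test_build_grid_rejects_bad_inputs():
    with pytest.raises(ValueError):
        build_grid(TankGeometry(), h=-0.01, sigma_water=SIGMA)
    with pytest.raises(ValueError):
        build_grid(TankGeometry(), h=0.02, sigma_water=0.0)
    with pytest.raises(ValueError):
        build_grid(TankGeometry(), h=0.3, sigma_water=SIGMA)  # does not tile


def test_geometry_validation():
    with pytest.raises(ValueError):
        TankGeometry(width_y=0.0)
    with pytest.raises(ValueError):
        TankGeometry(electrode_width=0.5)   # exceeds the wall


# ---------------------------------------------------------------------------
# fish embedding and linearized resistance change
# ---------------------------------------------------------------------------

def test_fish_voxel_volume_close_to_ellipsoid():
    grid = build_grid(TankGeometry(), h=0.0025, sigma_water=SIGMA)
    fish = FishEllipsoid(center=(0.2, 0.12, 0.1))
    mask = fish_voxel_mask(grid, fish)
    vol = mask.sum() * grid.h ** 3
    expect = 4.0 / 3.0 * np.pi * 0.025 * 0.010 * 0.005
    assert vol == pytest.approx(expect, rel=0.20)


def test_embed_fish_heading_reversal_is_identical():
    grid = build_grid(TankGeometry(), h=0.005, sigma_water=SIGMA)
    m1 = fish_voxel_mask(grid, FishEllipsoid((0.2, 0.12, 0.1), heading=(1, 0, 0)))
    m2 = fish_voxel_mask(grid, FishEllipsoid((0.2, 0.12, 0.1), heading=(-1, 0, 0)))
    assert (m1 == m2).all()


def test_embed_fish_outside_water_warns_and_leaves_grid():
    grid = build_grid(TankGeometry(), h=0.01, sigma_water=SIGMA)
    fish = FishEllipsoid(center=(2.0, 2.0, 2.0))
    with pytest.warns(UserWarning):
        out = embed_fish(grid, fish)
    assert (out.sigma == grid.sigma).all()


def test_fish_lowers_resistance():
    # the fish center sits on a voxel center: at h = 10 mm the 10 mm-thick
    # ellipsoid covers voxel centers only when aligned with the grid
    fish = FishEllipsoid((0.195, 0.115, 0.095))
    baseline = resistance_with_fish(TankGeometry(), SIGMA, None, h=0.01)
    with_fish = resistance_with_fish(TankGeometry(), SIGMA, fish, h=0.01)
    assert with_fish < baseline


def test_delta_r_sign_and_proximity(strip_solution):
    sens = sensitivity_map(strip_solution)
    center = delta_R_linearized(sens, FishEllipsoid((0.195, 0.115, 0.095)), SIGMA)
    near = delta_R_linearized(sens, FishEllipsoid((0.195, 0.035, 0.095)), SIGMA)
    assert center < 0
    assert near < center            # deeper decay close to the electrode


def test_delta_r_zero_cases(strip_solution):
    sens = sensitivity_map(strip_solution)
    outside = FishEllipsoid(center=(5.0, 5.0, 5.0))
    assert delta_R_linearized(sens, outside, SIGMA) == 0.0
    same = FishEllipsoid(center=(0.2, 0.12, 0.1), sigma_fish=SIGMA)
    assert delta_R_linearized(sens, same, SIGMA) == 0.0


def test_delta_r_uncorrected_matches_plain_formula(strip_solution):
    sens = sensitivity_map(strip_solution)
    fish = FishEllipsoid((0.2, 0.12, 0.1))
    mask = fish_voxel_mask(strip_solution.grid, fish)
    expect = (1.0 / fish.sigma_fish - 1.0 / SIGMA) * sens.S[mask].sum() * 0.01 ** 3
    got = delta_R_linearized(sens, fish, SIGMA, corrected=False)
    assert got == pytest.approx(expect, rel=1e-12)


def test_corrected_surrogate_tracks_full_solve():
    """Corrected linearization within 30% of paired full solves (h = 5 mm).

    5 mm resolves the 10 mm-thick ellipsoid; at 10 mm the voxelized inclusion
    degenerates to a line of cubes and the paired comparison is meaningless.
    """
    geometry = TankGeometry()
    grid = build_grid(geometry, h=0.005, sigma_water=SIGMA)
    base = solve_field(grid)
    sens = sensitivity_map(base)
    for y in (0.0575, 0.1175):
        fish = FishEllipsoid((0.1975, y, 0.0975))
        full = solve_field(embed_fish(grid, fish)).resistance - base.resistance
        lin = delta_R_linearized(sens, fish, SIGMA)
        assert lin == pytest.approx(full, rel=0.30)


def test_depolarization_factors_sum_to_one():
    L = depolarization_factors((0.025, 0.010, 0.005))
    assert L.sum() == pytest.approx(1.0, rel=1e-10)
    assert L[0] < L[1] < L[2]       # longest axis has the smallest factor


def test_depolarization_factors_sphere():
    L = depolarization_factors((0.01, 0.01, 0.01))
    assert np.allclose(L, 1.0 / 3.0, rtol=1e-10)


# ---------------------------------------------------------------------------
# profiles, calibration, utilities
# ---------------------------------------------------------------------------

def test_midline_profiles_coarse_shapes():
    profs = midline_profiles((20 / 240, 1.0), TankGeometry(), h=0.01)
    y, db_narrow = profs[20 / 240]
    _, db_wide = profs[1.0]
    assert y.size == 24
    assert db_narrow.max() == pytest.approx(0.0, abs=1e-12)
    # narrow electrodes: strong near-wall maxima, central minimum
    assert np.argmin(db_narrow) in range(8, 16)
    assert np.ptp(db_narrow) > np.ptp(db_wide)


def test_midline_profiles_reject_nonpositive_ratio():
    with pytest.raises(ValueError):
        midline_profiles((0.0,), TankGeometry(), h=0.02)


def test_midline_profiles_clip_oversize_ratio():
    with pytest.warns(UserWarning):
        midline_profiles((2.0,), TankGeometry(), h=0.02)


def test_calibrate_sigma_water_roundtrip():
    r = resistance_with_fish(TankGeometry(), 0.08, None, h=0.01)
    sigma = calibrate_sigma_water(r, TankGeometry(), h=0.01)
    assert sigma == pytest.approx(0.08, rel=1e-10)
    r_back = resistance_with_fish(TankGeometry(), sigma, None, h=0.01)
    assert abs(r_back - r) < 0.050  # +/- 50 mOhm contract


def test_calibrate_sigma_water_rejects_bad_reading():
    with pytest.raises(ValueError):
        calibrate_sigma_water(-5.0, TankGeometry(), h=0.02)


def test_prolong_potential_shape_and_values():
    v = np.arange(8.0).reshape(2, 2, 2)
    p = prolong_potential(v)
    assert p.shape == (4, 4, 4)
    assert (p[0:2, 0:2, 0:2] == v[0, 0, 0]).all()


def test_warm_started_solve_matches_direct():
    grid = build_grid(TankGeometry(), h=0.01, sigma_water=SIGMA)
    coarse = solve_field(build_grid(TankGeometry(), h=0.02, sigma_water=SIGMA))
    x0 = prolong_potential(coarse.potential)
    warm = solve_field(grid, x0=x0.ravel())
    direct = solve_field(grid)
    assert warm.resistance == pytest.approx(direct.resistance, rel=1e-6)


def test_solve_field_input_validation():
    grid = build_grid(TankGeometry(), h=0.02, sigma_water=SIGMA)
    with pytest.raises(ValueError):
        solve_field(grid, v_drive=0.0)
    with pytest.raises(ValueError):
        solve_field(grid, drive_side=2)
    with pytest.raises(ValueError):
        solve_field(grid, x0=np.zeros(7))
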