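"""Order parameters: filament angle, pore dimension, RMSD/RMSF, Rg."""

import numpy as np
import pytest

from trifibril import (
    FibrilBlueprint,
    SyntheticTrajectoryConfig,
    TrajectoryFrames,
    angle_series,
    backbone_rmsd,
    backbone_rmsf,
    build_ideal_fibril,
    filament_axes,
    mean_axis_angle,
    mean_interfilament_angle,
    pairwise_axis_angles,
    pore_distance,
    pore_series,
    radius_of_gyration,
    residue_pair_distance,
    simulate_trajectory,
    superpose,
    twist_rate_from_angles,
)
from trifibril.errors import ArgumentError, GeometryError, SelectionError
from conftest import random_rotation


def kabsch_rmsd(a, b):
    """Independent SVD superposition oracle."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    u, s, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return float(np.sqrt(np.mean(np.sum((a @ rot - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Filament axes and angle
# ---------------------------------------------------------------------------

def test_ideal_axes_point_along_z(fibril, blueprint):
    axes = filament_axes(fibril.coord, fibril)
    expected = (blueprint.n_layers - 1) * blueprint.layer_spacing
    for ax in axes:
        np.testing.assert_allclose(ax.v, [0, 0, expected], atol=1e-12)


def test_axes_are_rotation_equivariant(fibril, rng):
    rot = random_rotation(rng)
    rotated = fibril.coord @ rot.T
    axes0 = filament_axes(fibril.coord, fibril)
    axes1 = filament_axes(rotated, fibril)
    for a0, a1 in zip(axes0, axes1):
        np.testing.assert_allclose(a1.v, rot @ a0.v, atol=1e-9)


def test_single_layer_has_no_axes():
    model = build_ideal_fibril(FibrilBlueprint(n_layers=1))
    with pytest.raises(ArgumentError):
        filament_axes(model.coord, model)


def test_parallel_axes_give_zero():
    assert mean_axis_angle([[0, 0, 1], [0, 0, 2], [0, 0, 5]]) == 0.0


def test_closed_form_axis_triple():
    """Axes at {0°, 30°, 30°} pairwise -> mean 20°."""
    tilted = [0, np.sin(np.radians(30)), np.cos(np.radians(30))]
    axes = [[0, 0, 1], [0, 0, 1], tilted]
    assert mean_axis_angle(axes) == pytest.approx(20.0, abs=1e-9)
    np.testing.assert_allclose(sorted(pairwise_axis_angles(axes)),
                               [0.0, 30.0, 30.0], atol=1e-9)


def test_zero_norm_axis_is_degenerate():
    with pytest.raises(GeometryError):
        mean_axis_angle([[0, 0, 1], [0, 0, 0], [0, 1, 0]])


def test_ideal_fibril_angle_is_zero(fibril):
    assert mean_interfilament_angle(fibril.coord, fibril) < 1e-6


def test_angle_matches_bruteforce_on_constructed_tilts(rng):
    """Mean angle equals the direct pairwise-acos oracle for random axes."""
    for _ in range(20):
        axes = rng.normal(size=(3, 3))
        expected = []
        for i in range(3):
            for j in range(i + 1, 3):
                c = axes[i] @ axes[j] / (np.linalg.norm(axes[i])
                                         * np.linalg.norm(axes[j]))
                expected.append(np.degrees(np.arccos(np.clip(c, -1, 1))))
        assert mean_axis_angle(axes) == pytest.approx(np.mean(expected),
                                                      abs=1e-9)


def test_twist_rate_recovery(fibril):
    cfg = SyntheticTrajectoryConfig(mode="twist", n_frames=100, amplitude=0.3,
                                    seed=11)
    frames = simulate_trajectory(fibril, cfg)
    series = angle_series(frames, fibril)
    rate = twist_rate_from_angles(series.phi, series.times)
    assert rate == pytest.approx(0.3, rel=0.05)
    # final angle matches the analytic pairwise mean of the applied tilt
    alpha = np.radians(0.3 * 99)
    phi = np.degrees(np.arccos(np.cos(alpha) ** 2 - 0.5 * np.sin(alpha) ** 2))
    assert series.phi[-1] == pytest.approx(phi, rel=0.05)


# ---------------------------------------------------------------------------
# Pore dimension
# ---------------------------------------------------------------------------

def test_equilateral_pore_triangle(fibril, blueprint):
    d = pore_distance(fibril.coord, fibril, layer=1)
    assert d == pytest.approx(blueprint.designed_pore_distance, abs=1e-9)
    assert d == pytest.approx(np.sqrt(3) * blueprint.pore_radius, abs=1e-9)


def test_pore_translation_invariance(fibril):
    shifted = fibril.coord + np.array([13.0, -7.0, 42.0])
    assert pore_distance(shifted, fibril, 1) == pytest.approx(
        pore_distance(fibril.coord, fibril, 1), abs=1e-9)


def test_pore_series_shape_and_layer_mean(fibril):
    frames = TrajectoryFrames(np.stack([fibril.coord] * 3))
    ps = pore_series(frames, fibril)
    assert ps.per_layer.shape == (3, fibril.n_layers)
    np.testing.assert_allclose(ps.mean, ps.per_layer.mean(axis=1))


def test_missing_met35_raises(fibril):
    with pytest.raises(SelectionError):
        pore_distance(fibril.coord, fibril, 1, met_atom="XX")


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------

def test_rmsd_identity_and_rigid_motion(fibril, rng):
    assert backbone_rmsd(fibril.coord, fibril.coord, fibril) < 1e-12
    rot = random_rotation(rng)
    moved = fibril.coord @ rot.T + np.array([5.0, -3.0, 1.0])
    assert backbone_rmsd(moved, fibril.coord, fibril) < 1e-9


def test_rmsd_is_symmetric(fibril, rng):
    a = fibril.coord
    b = a + rng.normal(0, 0.5, a.shape)
    ab = backbone_rmsd(a, b, fibril)
    ba = backbone_rmsd(b, a, fibril)
    assert ab == pytest.approx(ba, abs=1e-9)


def test_superpose_matches_kabsch_oracle(rng):
    for _ in range(25):
        a = rng.normal(size=(4, 3)) * 3
        b = rng.normal(size=(4, 3)) * 3
        _, rmsd = superpose(a, b)
        assert rmsd == pytest.approx(kabsch_rmsd(a, b), abs=1e-9)


def test_rmsf_zero_for_static_trajectory(fibril):
    frames = TrajectoryFrames(np.stack([fibril.coord] * 5))
    per_res, mean = backbone_rmsf(frames, fibril)
    assert mean == pytest.approx(0.0, abs=1e-12)
    assert all(v == pytest.approx(0.0, abs=1e-12) for v in per_res.values())


def test_rmsf_oscillating_atom_closed_form():
    """One atom moving ±d along x with superposition off -> RMSF d."""
    d = 0.75
    m = _two_point_model()
    frames = np.stack([m.coord] * 4)
    frames[[0, 2], 1, 0] += d
    frames[[1, 3], 1, 0] -= d
    per_res, _ = backbone_rmsf(TrajectoryFrames(frames), m,
                               residue_range=(1, 2), fit=False)
    assert per_res[2] == pytest.approx(d, abs=1e-12)
    assert per_res[1] == 0.0


def test_rmsf_gaussian_jitter_scaling(fibril):
    """Isotropic jitter of width σ gives a mean RMSF near σ√3."""
    sigma = 0.2
    cfg = SyntheticTrajectoryConfig(mode="stable", n_frames=120,
                                    jitter_sigma=sigma, seed=5)
    frames = simulate_trajectory(fibril, cfg)
    _, mean = backbone_rmsf(frames, fibril, fit=False)
    assert mean == pytest.approx(sigma * np.sqrt(3), rel=0.05)


def test_rmsf_needs_two_frames(fibril):
    with pytest.raises(ArgumentError):
        backbone_rmsf(TrajectoryFrames(fibril.coord[None]), fibril)


# ---------------------------------------------------------------------------
# Radius of gyration
# ---------------------------------------------------------------------------

def _two_point_model():
    from trifibril.structure_io import FibrilModel
    return FibrilModel([1, 2], ["CA", "CA"], ["GLY", "GLY"], [1, 2],
                       ["A", "A"], [[0, 0, 0], [2, 0, 0]], ["C", "C"])


def test_rg_two_unit_masses():
    m = _two_point_model()
    assert radius_of_gyration(m.coord, m) == pytest.approx(1.0, abs=1e-12)


def test_rg_scales_linearly():
    m = _two_point_model()
    assert radius_of_gyration(m.coord * 3.5, m) == pytest.approx(3.5, abs=1e-12)


def test_rg_matches_direct_sum_oracle(fibril):
    from trifibril.geometry_metrics import ATOMIC_MASSES
    masses = np.array([ATOMIC_MASSES.get(e.upper(), 12.011)
                       for e in fibril.element])
    com = (fibril.coord * masses[:, None]).sum(axis=0) / masses.sum()
    expected = np.sqrt((masses * ((fibril.coord - com) ** 2).sum(axis=1)).sum()
                       / masses.sum())
    assert radius_of_gyration(fibril.coord, fibril) == pytest.approx(
        expected, abs=1e-9)


def test_rg_per_layer_mean_between_bounds(fibril):
    whole = radius_of_gyration(fibril.coord, fibril, "whole")
    per_layer = radius_of_gyration(fibril.coord, fibril, "per_layer_mean")
    # a single in-register layer is radially as extended but axially thinner
    assert 0 < per_layer < whole * 1.5


# ---------------------------------------------------------------------------
# Residue-pair distances
# ---------------------------------------------------------------------------

def test_residue_pair_345(small_fibril):
    m = small_fibril
    frame = m.coord.copy()
    ia = m.atom_indices(chain_id="A", res_id=40)
    ib = m.atom_indices(chain_id="B", res_id=40)
    frame[ia] = [0.0, 0.0, 0.0]
    frame[ib] = [3.0, 4.0, 0.0]
    assert residue_pair_distance(frame, m, "A", 40, "B", 40) == pytest.approx(
        5.0, abs=1e-12)


def test_residue_pair_self_distance_zero(small_fibril):
    m = small_fibril
    d = residue_pair_distance(m.coord, m, "A", 35, "A", 35)
    assert d == 0.0


def test_named_atom_mode(small_fibril):
    m = small_fibril
    d = residue_pair_distance(m.coord, m, "A", 35, "B", 35,
                              mode="named_atoms", atoms=("SD", "SD"))
    assert d == pytest.approx(np.sqrt(3) * 11.5, abs=1e-9)
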