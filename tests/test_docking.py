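"""Grid discretisation, FFT correlation, electrostatics, pose sweep."""

import numpy as np
import pytest

from xlmapdock.docking import (
    DockGrid,
    DockSettings,
    charge_points,
    discretize,
    electrostatic_score,
    generate_poses,
    rotation_grid,
    shape_correlation,
)
from xlmapdock.structure_model import ChainModel, Residue, RigidTransform


def brute_force_correlation(static: np.ndarray, mobile: np.ndarray) -> np.ndarray:
    """Direct-space oracle: corr[t] = sum_x static[x] * mobile[x - t]
    with cyclic shifts, evaluated by explicit rolling."""
    dims = static.shape
    out = np.empty(dims)
    for tx in range(dims[0]):
        for ty in range(dims[1]):
            for tz in range(dims[2]):
                out[tx, ty, tz] = (static * np.roll(mobile, (tx, ty, tz), (0, 1, 2))).sum()
    return out


def _grid(shape_array, spacing=1.0):
    return DockGrid(spacing=spacing, origin=np.zeros(3), shape=shape_array)


def test_fft_equals_brute_force_on_random_grids():
    """50 random small grids: FFT correlation == direct triple loop."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        n = int(rng.integers(4, 9))
        a = rng.normal(size=(n, n, n)) * (rng.random((n, n, n)) < 0.3)
        b = rng.normal(size=(n, n, n)) * (rng.random((n, n, n)) < 0.3)
        fft = shape_correlation(_grid(a), _grid(b))
        brute = brute_force_correlation(a, b)
        scale = max(1.0, np.abs(brute).max())
        np.testing.assert_allclose(fft, brute, atol=1e-6 * scale)


def test_single_voxel_alignment():
    a = np.zeros((8, 8, 8)); a[3, 4, 5] = 1.0
    b = np.zeros((8, 8, 8)); b[1, 1, 1] = 1.0
    corr = shape_correlation(_grid(a), _grid(b))
    assert corr[2, 3, 4] == pytest.approx(1.0)
    assert corr.sum() == pytest.approx(1.0)


def test_mismatched_grids_rejected():
    with pytest.raises(ValueError):
        shape_correlation(_grid(np.zeros((4, 4, 4))), _grid(np.zeros((5, 5, 5))))


# ---------------------------------------------------------------------------
# discretisation

def test_discretize_single_atom_all_surface():
    model = ChainModel("A", [Residue(1, "ALA", {"CA": np.zeros(3)})])
    grid = discretize(model, spacing=1.0, surface_thickness=2.0, role="static")
    filled = grid.shape != 0
    assert filled.any()
    assert (grid.shape[filled] == 1.0).all()  # a small blob has no core


def test_discretize_rejects_empty_and_bad_role(small_monomer):
    with pytest.raises(ValueError):
        discretize(small_monomer, spacing=-1.0)
    with pytest.raises(ValueError):
        discretize(small_monomer, role="floating")


def test_core_is_penalised(small_monomer):
    grid = discretize(small_monomer, spacing=1.0, role="static", core_penalty=-15.0,
                      atom_radius=2.6)
    values = set(np.unique(grid.shape))
    assert values == {-15.0, 0.0, 1.0}
    # burying the mobile inside the core scores worse than surface contact
    assert (grid.shape == -15.0).sum() > 0


def test_filled_voxels_scale_with_spacing():
    """Halving the grid spacing multiplies filled-voxel count by ~8: the
    voxelised volume of a body converges to its true volume (checked on a
    sphere large relative to the spacing, where quantisation error is
    small)."""
    model = ChainModel("A", [Residue(1, "ALA", {"CA": np.zeros(3)})])
    coarse = discretize(model, spacing=1.0, role="mobile", with_charges=False, atom_radius=6.0)
    fine = discretize(model, spacing=0.5, role="mobile", with_charges=False, atom_radius=6.0)
    ratio = (fine.shape > 0).sum() / (coarse.shape > 0).sum()
    assert ratio == pytest.approx(8.0, rel=0.15)


# ---------------------------------------------------------------------------
# electrostatics

def test_opposite_charges_attract():
    a = np.array([[0.0, 0, 0]]); b = np.array([[10.0, 0, 0]])
    assert electrostatic_score(a, np.array([1.0]), b, np.array([-1.0])) < 0


def test_zero_charges_zero_score():
    a = np.array([[0.0, 0, 0]]); b = np.array([[10.0, 0, 0]])
    assert electrostatic_score(a, np.array([0.0]), b, np.array([0.0])) == 0.0


def test_bilinearity_in_charges():
    rng = np.random.default_rng(8)
    a, b = rng.normal(size=(4, 3)) * 5, rng.normal(size=(5, 3)) * 5 + 12
    qa, qb = rng.normal(size=4), rng.normal(size=5)
    base = electrostatic_score(a, qa, b, qb)
    assert electrostatic_score(a, 2 * qa, b, 2 * qb) == pytest.approx(4 * base)


def test_distance_floor_applied():
    a = np.array([[0.0, 0, 0]]); b = np.array([[0.1, 0, 0]])
    clashed = electrostatic_score(a, np.array([1.0]), b, np.array([1.0]))
    floored = electrostatic_score(a, np.array([1.0]), np.array([[2.0, 0, 0]]), np.array([1.0]))
    assert clashed == pytest.approx(floored)


def test_charge_points_residue_model(small_monomer):
    pts, q = charge_points(small_monomer)
    n_pos = sum(1 for r in small_monomer.residues if r.name in ("LYS", "ARG"))
    n_neg = sum(1 for r in small_monomer.residues if r.name in ("ASP", "GLU"))
    assert (q > 0).sum() == n_pos
    assert (q < 0).sum() == n_neg


# ---------------------------------------------------------------------------
# pose sweep

FAST = DockSettings(spacing=2.0, angle_step=60.0, retain=200, atom_radius=2.6,
                    keep_per_rotation=12, discard_repulsive=False)


def test_rotation_grid_prunes_duplicates():
    rots = rotation_grid(90.0)
    quats = set()
    for r in rots:
        q = r.as_quat()
        for c in q:
            if abs(c) > 1e-8:
                if c < 0:
                    q = -q
                break
        quats.add(tuple(np.round(q, 5)))
    assert len(quats) == len(rots)


def test_pose_count_equals_retention(small_monomer):
    poses = generate_poses(small_monomer, small_monomer, FAST)
    assert len(poses) == FAST.retain
    assert [p.rank for p in poses.poses] == list(range(FAST.retain))


def test_pose_sweep_is_deterministic(small_monomer):
    a = generate_poses(small_monomer, small_monomer, FAST)
    b = generate_poses(small_monomer, small_monomer, FAST)
    assert [p.pose_id for p in a.poses] == [p.pose_id for p in b.poses]
    for pa, pb in zip(a.poses, b.poses):
        np.testing.assert_array_equal(pa.rotation, pb.rotation)
        np.testing.assert_array_equal(pa.translation, pb.translation)
        assert pa.shape_score == pb.shape_score


def test_scores_invariant_under_integer_voxel_translation(small_monomer):
    """Moving both partners by a whole number of voxels leaves the score
    spectrum unchanged (grid re-discretisation is exact for such moves)."""
    moved = small_monomer.transformed(
        RigidTransform(np.eye(3), np.array([3 * FAST.spacing, -2 * FAST.spacing, FAST.spacing]))
    )
    a = generate_poses(small_monomer, small_monomer, FAST)
    b = generate_poses(moved, moved, FAST)
    assert [p.shape_score for p in a.poses] == [p.shape_score for p in b.poses]


def test_impossible_retention_raises(small_monomer):
    settings = DockSettings(spacing=2.0, angle_step=120.0, retain=10_000_000)
    with pytest.raises(ValueError):
        generate_poses(small_monomer, small_monomer, settings)


def test_core_burial_scores_below_surface_contact():
    """A translation burying the mobile partner in the static core scores
    lower than a surface-contact translation (the sign of the core
    penalty does its job)."""
    static = np.zeros((8, 8, 8))
    static[2:6, 2:6, 2:6] = 1.0      # surface shell
    static[3:5, 3:5, 3:5] = -15.0    # penalised core
    mobile = np.zeros((8, 8, 8)); mobile[0, 0, 0] = 1.0
    corr = shape_correlation(_grid(static), _grid(mobile))
    assert corr[3, 3, 3] == pytest.approx(-15.0)    # buried
    assert corr[2, 2, 2] == pytest.approx(1.0)      # surface contact
    assert corr[3, 3, 3] < corr[2, 2, 2]
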