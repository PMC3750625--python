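"""Restraint filtering, refinement, selection, interface metrics."""

import itertools
import math

import numpy as np
import pytest

from xlmapdock.docking import DockSettings, Pose, PoseSet, generate_poses
from xlmapdock.restraint_select import (
    apply_restraints,
    classify_orientation,
    interface_metrics,
    pose_energies,
    pose_energy,
    refine_pose,
    select_model,
    shrake_rupley_asa,
    softcore_minimum_distance,
)
from xlmapdock.structure_model import (
    ChainModel,
    DimerComplex,
    Residue,
    Restraint,
    RigidTransform,
)

FAST = DockSettings(spacing=2.0, angle_step=60.0, retain=100, atom_radius=2.6,
                    keep_per_rotation=8, discard_repulsive=False)


@pytest.fixture(scope="module")
def toy_poses(small_monomer):
    return generate_poses(small_monomer, small_monomer, FAST)


def _lysines(model):
    return [r.number for r in model.residues if r.name == "LYS"]


# ---------------------------------------------------------------------------
# restraint filtering

def test_zero_restraints_vacuous(toy_poses):
    filtered, report = apply_restraints(toy_poses, [])
    assert len(filtered) == len(toy_poses)
    assert report.n_satisfying == report.n_in


def test_restraint_filter_monotone_and_consistent(toy_poses, small_monomer):
    lys = _lysines(small_monomer)
    r1 = Restraint.homodimer(lys[0], lys[1], 21.3)
    r2 = Restraint.homodimer(lys[0], lys[2], 15.0)
    both, report = apply_restraints(toy_poses, [r1, r2])
    only1, _ = apply_restraints(toy_poses, [r1])
    ids_both = {p.pose_id for p in both.poses}
    ids_1 = {p.pose_id for p in only1.poses}
    assert ids_both <= ids_1  # conjunction can only shrink the set
    # every survivor's worst restrained distance respects the bounds
    assert all(w <= 21.3 + 1e-9 for w in report.worst_distance.values())


def test_restraint_filter_order_independent(toy_poses, small_monomer):
    lys = _lysines(small_monomer)
    restraints = [
        Restraint.homodimer(lys[0], lys[1], 21.3),
        Restraint.homodimer(lys[1], lys[2], 18.0),
        Restraint.homodimer(lys[0], lys[2], 16.0),
    ]
    reference = None
    for perm in itertools.permutations(restraints):
        filtered, _ = apply_restraints(toy_poses, list(perm))
        ids = [p.pose_id for p in filtered.poses]
        if reference is None:
            reference = ids
        assert ids == reference


def test_ambiguous_restraint_is_a_disjunction(toy_poses, small_monomer):
    lys = _lysines(small_monomer)
    strict = Restraint.homodimer(lys[0], lys[1], 12.0)
    relaxed = Restraint.homodimer(
        lys[0], lys[1], 12.0, extra_alternatives=[(lys[0], lys[2])]
    )
    s_set, _ = apply_restraints(toy_poses, [strict])
    r_set, _ = apply_restraints(toy_poses, [relaxed])
    assert {p.pose_id for p in s_set.poses} <= {p.pose_id for p in r_set.poses}


def test_missing_restraint_site_raises(toy_poses):
    with pytest.raises(KeyError):
        apply_restraints(toy_poses, [Restraint.homodimer(9999, 1, 21.3)])


# ---------------------------------------------------------------------------
# refinement

def _single_atom_chain(name, x):
    return ChainModel("A", [Residue(1, name, {"CA": np.array([x, 0.0, 0.0]),
                                              "CB": np.array([x + 0.01, 0.0, 0.0])})])


def test_two_atom_refinement_reaches_analytic_minimum():
    """Two neutral single-residue chains relax to the soft-core pair
    optimum r* = sqrt(sigma^2 * 2^(1/3) - lambda)."""
    static = ChainModel("A", [Residue(1, "ALA", {"CA": np.zeros(3)})])
    mobile = ChainModel("A", [Residue(1, "ALA", {"CA": np.zeros(3)})])
    start = Pose(0, np.eye(3), np.array([2.4, 0.0, 0.0]), 0.0, 0.0)  # 1 A clash
    refined = refine_pose(start, static, mobile)
    d = np.linalg.norm(refined.pose.translation)
    assert d == pytest.approx(softcore_minimum_distance(), abs=0.05)
    # the clash was relieved and the energy is the analytic well depth -eps
    assert refined.energy == pytest.approx(-0.1, abs=1e-3)


def test_refinement_never_increases_energy(toy_poses, small_monomer):
    for pose in toy_poses.poses[:3]:
        e0 = pose_energy(pose, small_monomer, small_monomer)
        refined = refine_pose(pose, small_monomer, small_monomer)
        assert refined.energy <= e0 + 1e-9


def test_refinement_respects_trust_region(toy_poses, small_monomer):
    pose = toy_poses.poses[0]
    refined = refine_pose(pose, small_monomer, small_monomer,
                          max_translation=1.0, max_rotation=0.05)
    shift = np.linalg.norm(refined.pose.translation - pose.translation)
    # rotation bounded by 0.05 rad about the centroid adds at most ~r*theta
    coords, _ = small_monomer.atom_coords()
    radius = np.linalg.norm(coords - coords.mean(0), axis=1).max()
    assert shift <= math.sqrt(3) * 1.0 + 0.05 * radius + 1e-6


def test_pose_energies_batch_matches_single(toy_poses, small_monomer):
    batch = pose_energies(toy_poses.poses[:12], small_monomer, small_monomer)
    singles = [pose_energy(p, small_monomer, small_monomer) for p in toy_poses.poses[:12]]
    np.testing.assert_allclose(batch, singles, atol=1e-8)


# ---------------------------------------------------------------------------
# selection

def test_select_model_prefers_lower_energy(small_monomer):
    from xlmapdock.restraint_select import RefinedPose

    p1 = Pose(1, np.eye(3), np.array([0.0, 22.0, 0.0]), 0, 0)
    p2 = Pose(2, np.eye(3), np.array([0.0, 24.0, 0.0]), 0, 0)
    refined = [RefinedPose(p1, energy=-5.0, converged=True, n_iterations=1),
               RefinedPose(p2, energy=-9.0, converged=True, n_iterations=1)]
    complex_, chosen = select_model(refined, small_monomer, small_monomer)
    assert chosen.pose.pose_id == 2
    assert complex_.provenance == "pose 2"


def test_select_model_breaks_energy_ties_by_burial(small_monomer):
    """Equal energies: the pose burying more surface area wins."""
    from xlmapdock.restraint_select import RefinedPose

    near = Pose(7, np.eye(3), np.array([0.0, 12.0, 0.0]), 0, 0)   # big interface
    far = Pose(3, np.eye(3), np.array([0.0, 30.0, 0.0]), 0, 0)    # tiny interface
    refined = [RefinedPose(far, -1.0, True, 1), RefinedPose(near, -1.0, True, 1)]
    _, chosen = select_model(refined, small_monomer, small_monomer, asa_points=120)
    assert chosen.pose.pose_id == 7


def test_select_model_empty_raises(small_monomer):
    with pytest.raises(ValueError):
        select_model([], small_monomer, small_monomer)


# ---------------------------------------------------------------------------
# solvent accessibility

def test_isolated_sphere_asa_analytic():
    """One atom: ASA = 4 pi (r + probe)^2 up to sphere-point discretisation."""
    for r in (1.5, 1.9):
        asa = shrake_rupley_asa(np.zeros((1, 3)), np.array([r]), n_points=960)
        assert asa[0] == pytest.approx(4 * math.pi * (r + 1.4) ** 2, rel=1e-6)


def test_two_touching_spheres_buried_cap():
    """Two identical spheres at distance d: each loses a spherical cap of
    area 2 pi R h with h = R - d/2 (R = radius + probe); the sphere-point
    estimate must agree within 5%."""
    radius, probe, d = 1.8, 1.4, 3.0
    R = radius + probe
    coords = np.array([[0.0, 0, 0], [d, 0, 0]])
    asa = shrake_rupley_asa(coords, np.array([radius, radius]), n_points=960, probe=probe)
    h = R - d / 2
    expected = 4 * math.pi * R ** 2 - 2 * math.pi * R * h
    assert asa[0] == pytest.approx(expected, rel=0.05)
    assert asa[1] == pytest.approx(expected, rel=0.05)


def test_delta_asa_zero_for_separated_chains(small_monomer):
    far = small_monomer.transformed(
        RigidTransform(np.eye(3), np.array([500.0, 0, 0])), chain_id="B"
    )
    report = interface_metrics(DimerComplex(small_monomer, far), n_points=240)
    assert report.delta_asa == pytest.approx(0.0, abs=1e-6)
    assert report.n_interface_a == 0 and report.n_interface_b == 0


def test_interface_report_on_contact_dimer(small_dimer):
    complex_, _ = small_dimer
    report = interface_metrics(complex_, n_points=240)
    assert report.delta_asa > 50
    assert report.n_interface_a > 0 and report.n_interface_b > 0
    assert all(burial > 0 for _, burial in report.interface_residues_a)
    assert report.contact_pairs  # chains touch


def test_delta_asa_rigid_invariance(small_dimer):
    """A common rigid transform of the whole complex changes the buried
    area by < 0.5% (sphere-point sampling is orientation-dependent only
    weakly)."""
    complex_, _ = small_dimer
    base = interface_metrics(complex_, n_points=480).delta_asa
    from scipy.spatial.transform import Rotation

    T = RigidTransform(Rotation.from_euler("zyx", [31, 17, -52], degrees=True).as_matrix(),
                       np.array([7.0, -3.0, 11.0]))
    moved = DimerComplex(complex_.chain_a.transformed(T), complex_.chain_b.transformed(T))
    rotated = interface_metrics(moved, n_points=480).delta_asa
    assert rotated == pytest.approx(base, rel=0.005)


# ---------------------------------------------------------------------------
# orientation

def test_translated_copy_is_parallel(small_monomer):
    b = small_monomer.transformed(
        RigidTransform(np.eye(3), np.array([0.0, 25.0, 0.0])), chain_id="B"
    )
    label, angle, c2 = classify_orientation(DimerComplex(small_monomer, b))
    assert label == "parallel"
    assert angle == pytest.approx(0.0, abs=1e-6)


def test_flipped_copy_is_antiparallel(small_monomer):
    R = np.diag([1.0, -1.0, -1.0])  # 180 degrees about x
    cm = small_monomer.atom_coords()[0].mean(0)
    T = RigidTransform(R, cm - R @ cm + np.array([0.0, 25.0, 0.0]))
    b = small_monomer.transformed(T, chain_id="B")
    label, angle, _ = classify_orientation(DimerComplex(small_monomer, b))
    assert label == "antiparallel"
    assert angle > 90.0


def test_orientation_rejects_dissimilar_chains(small_monomer):
    truncated = ChainModel("B", [Residue(r.number + 500, r.name, dict(r.atoms))
                                 for r in small_monomer.residues[:5]])
    with pytest.raises(ValueError):
        classify_orientation(DimerComplex(small_monomer, truncated))
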