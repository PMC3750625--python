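"""Restraint filtering, rigid-body refinement, model selection and
interface characterisation of docked homodimer poses.

A crosslink-derived restraint is an upper bound on a cross-chain
Cbeta-Cbeta distance, possibly with site ambiguity; a pose survives only
if every restraint has at least one alternative pair within bound.
Survivors are locally refined in the six rigid-body degrees of freedom
against a soft-core van der Waals plus screened-Coulomb potential, and
the lowest-energy refined pose is selected (ties broken by larger buried
surface area, then pose id).  The interface of the selected complex is
characterised by Shrake-Rupley solvent accessibility (buried area,
per-residue burial, contact pairs) and the relative orientation of the
two chains is classified parallel/antiparallel from their end-to-end
reference vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .docking import Pose, PoseSet, atom_radii, charge_points, electrostatic_score
from .structure_model import (
    ChainModel,
    DimerComplex,
    Restraint,
    resolve_site_atom,
    superpose_rmsd,
)

__all__ = [
    "FilterReport",
    "RefinedPose",
    "InterfaceReport",
    "apply_restraints",
    "refine_pose",
    "select_model",
    "shrake_rupley_asa",
    "interface_metrics",
    "classify_orientation",
    "softcore_minimum_distance",
]


@dataclass
class FilterReport:
    n_in: int
    n_satisfying: int
    per_restraint_counts: dict[str, int]
    worst_distance: dict[int, float]  # pose id -> worst restrained distance (survivors)


@dataclass
class RefinedPose:
    pose: Pose
    energy: float
    converged: bool
    n_iterations: int
    restraints_ok: bool = True


@dataclass
class InterfaceReport:
    delta_asa: float
    interface_residues_a: list[tuple[int, float]]
    interface_residues_b: list[tuple[int, float]]
    contact_pairs: list[tuple[int, int, float]]
    orientation_label: str
    orientation_angle: float
    c2_residual: float

    @property
    def n_interface_a(self) -> int:
        return len(self.interface_residues_a)

    @property
    def n_interface_b(self) -> int:
        return len(self.interface_residues_b)


# ---------------------------------------------------------------------------
# Restraint filtering

def _site_coords(model: ChainModel, residues: Sequence[int], atom_rule: str) -> np.ndarray:
    return np.asarray([resolve_site_atom(model, r, atom_rule) for r in residues])


def apply_restraints(
    poses: PoseSet,
    restraints: Sequence[Restraint],
    atom_rule: str = "lys_cb",
) -> tuple[PoseSet, FilterReport]:
    """Keep poses for which every restraint has an alternative within bound.

    Distances are measured cross-chain on each posed complex: static chain
    residue vs transformed mobile chain residue.  Site ambiguity (several
    alternative pairs per restraint) is a disjunction; restraints combine
    as a conjunction, so the surviving set is order-independent.
    """
    if not restraints:
        report = FilterReport(len(poses), len(poses), {}, {p.pose_id: 0.0 for p in poses.poses})
        return poses, report
    for r in restraints:
        for sa, sb in r.alternatives:
            if not poses.static.has_residue(sa):
                raise KeyError(f"restraint site {sa} missing from static chain")
            if not poses.mobile.has_residue(sb):
                raise KeyError(f"restraint site {sb} missing from mobile chain")

    P = len(poses.poses)
    Rs = np.array([p.rotation for p in poses.poses])      # (P,3,3)
    ts = np.array([p.translation for p in poses.poses])   # (P,3)

    satisfied = np.ones(P, dtype=bool)
    worst = np.zeros(P)
    per_restraint: dict[str, int] = {}
    for r in restraints:
        a_res = [a for a, _ in r.alternatives]
        b_res = [b for _, b in r.alternatives]
        A = _site_coords(poses.static, a_res, atom_rule)   # (K,3)
        B = _site_coords(poses.mobile, b_res, atom_rule)   # (K,3)
        Bp = np.einsum("pij,kj->pki", Rs, B) + ts[:, None, :]
        d = np.linalg.norm(Bp - A[None, :, :], axis=-1)    # (P,K)
        best = d.min(axis=1)
        ok = best <= r.max_distance + 1e-9
        per_restraint[r.origin or f"{r.alternatives}"] = int(ok.sum())
        satisfied &= ok
        worst = np.maximum(worst, best)

    survivors = [p for p, keep in zip(poses.poses, satisfied) if keep]
    filtered = PoseSet(static=poses.static, mobile=poses.mobile, poses=survivors,
                       settings=poses.settings)
    report = FilterReport(
        n_in=P,
        n_satisfying=len(survivors),
        per_restraint_counts=per_restraint,
        worst_distance={p.pose_id: float(w) for p, w, keep in
                        zip(poses.poses, worst, satisfied) if keep},
    )
    return filtered, report


# ---------------------------------------------------------------------------
# Rigid-body refinement

_SOFTCORE_EPS = 0.1     # kcal/mol well depth
_SOFTCORE_SIGMA = 3.4   # A
_SOFTCORE_LAMBDA = 1.0  # A^2 core softening
_VDW_CUTOFF = 10.0      # A


def softcore_minimum_distance(
    sigma: float = _SOFTCORE_SIGMA, lam: float = _SOFTCORE_LAMBDA
) -> float:
    """Analytic pair-distance minimising the soft-core 12-6 potential.

    E(r) = 4 eps (u^2 - u) with u = (sigma^2 / (r^2 + lambda))^3, whose
    minimum sits at u = 1/2, i.e. r* = sqrt(sigma^2 * 2^(1/3) - lambda).
    """
    return math.sqrt(sigma * sigma * 2.0 ** (1.0 / 3.0) - lam)


def _interaction_energy(
    s_coords: np.ndarray, m_coords: np.ndarray,
    s_pts: np.ndarray, s_q: np.ndarray, m_pts: np.ndarray, m_q: np.ndarray,
) -> float:
    from scipy.spatial.distance import cdist

    r2 = cdist(s_coords, m_coords, "sqeuclidean")
    r2 = r2[r2 < _VDW_CUTOFF ** 2]
    u = (_SOFTCORE_SIGMA ** 2 / (r2 + _SOFTCORE_LAMBDA)) ** 3
    e_vdw = float((4.0 * _SOFTCORE_EPS * (u * u - u)).sum())
    e_el = electrostatic_score(s_pts, s_q, m_pts, m_q) if len(s_q) and len(m_q) else 0.0
    return e_vdw + e_el


def pose_energy(pose: Pose, static: ChainModel, mobile: ChainModel,
                charge_termini: bool = False) -> float:
    """Single-point interaction energy of a pose (no minimisation).

    Used to screen large surviving pose sets cheaply before the full
    rigid-body refinement of the best candidates.
    """
    s_coords, _ = static.atom_coords()
    m_coords, _ = mobile.atom_coords()
    s_pts, s_q = charge_points(static, include_termini=charge_termini)
    m_pts, m_q = charge_points(mobile, include_termini=charge_termini)
    mc = m_coords @ pose.rotation.T + pose.translation
    mp = m_pts @ pose.rotation.T + pose.translation if len(m_q) else m_pts
    return _interaction_energy(s_coords, mc, s_pts, s_q, mp, m_q)


def pose_energies(poses: Sequence[Pose], static: ChainModel, mobile: ChainModel,
                  charge_termini: bool = False, chunk: int = 256) -> np.ndarray:
    """Vectorised single-point interaction energies for a pose list."""
    s_coords, _ = static.atom_coords()
    m_coords, _ = mobile.atom_coords()
    s_pts, s_q = charge_points(static, include_termini=charge_termini)
    m_pts, m_q = charge_points(mobile, include_termini=charge_termini)
    out = np.empty(len(poses))
    for lo in range(0, len(poses), chunk):
        batch = poses[lo:lo + chunk]
        Rs = np.array([p.rotation for p in batch])
        ts = np.array([p.translation for p in batch])
        mc = np.einsum("pij,aj->pai", Rs, m_coords) + ts[:, None, :]
        diff = s_coords[None, :, None, :] - mc[:, None, :, :]
        r2 = (diff ** 2).sum(axis=-1)
        u = (_SOFTCORE_SIGMA ** 2 / (r2 + _SOFTCORE_LAMBDA)) ** 3
        u[r2 >= _VDW_CUTOFF ** 2] = 0.0
        e_vdw = (4.0 * _SOFTCORE_EPS * (u * u - u)).sum(axis=(1, 2))
        if len(s_q) and len(m_q):
            mp = np.einsum("pij,aj->pai", Rs, m_pts) + ts[:, None, :]
            d = np.sqrt(((s_pts[None, :, None, :] - mp[:, None, :, :]) ** 2).sum(axis=-1))
            d = np.maximum(d, 2.0)
            qq = s_q[:, None] * m_q[None, :]
            e_el = 332.0637 * (qq[None, :, :] / (4.0 * d * d)).sum(axis=(1, 2))
        else:
            e_el = np.zeros(len(batch))
        out[lo:lo + len(batch)] = e_vdw + e_el
    return out


def refine_pose(
    pose: Pose,
    static: ChainModel,
    mobile: ChainModel,
    max_rotation: float = 0.35,   # rad, trust bound on the local search
    max_translation: float = 4.0,  # A
    max_iterations: int = 60,
    charge_termini: bool = False,
) -> RefinedPose:
    """Local six-degree-of-freedom minimisation of the interaction energy.

    The search is bounded (a trust region in rotation-vector and
    translation increments about the input pose) and the best energy seen
    is always returned, so the refined energy never exceeds the input
    pose's energy.
    """
    s_coords, _ = static.atom_coords()
    m_coords0, _ = mobile.atom_coords()
    cm = m_coords0.mean(axis=0)
    s_pts, s_q = charge_points(static, include_termini=charge_termini)
    m_pts0, m_q = charge_points(mobile, include_termini=charge_termini)

    R0, t0 = pose.rotation, pose.translation

    def placed(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # increment applied about the posed mobile centroid c:
        # x' = dR (R0 x + t0 - c) + c + dt
        dR = Rotation.from_rotvec(x[:3]).as_matrix()
        c = R0 @ cm + t0
        R = dR @ R0
        t = dR @ (t0 - c) + c + x[3:]
        return R, t

    best = {"energy": math.inf, "x": np.zeros(6)}

    def energy(x: np.ndarray) -> float:
        R, t = placed(x)
        mc = m_coords0 @ R.T + t
        mp = m_pts0 @ R.T + t if len(m_q) else m_pts0
        e = _interaction_energy(s_coords, mc, s_pts, s_q, mp, m_q)
        if e < best["energy"]:
            best["energy"] = e
            best["x"] = x.copy()
        return e

    bounds = [(-max_rotation, max_rotation)] * 3 + [(-max_translation, max_translation)] * 3
    res = minimize(
        energy, np.zeros(6), method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iterations, "eps": 1e-4},
    )
    R, t = placed(best["x"])
    refined = Pose(
        pose_id=pose.pose_id, rotation=R, translation=t,
        shape_score=pose.shape_score, elec_score=pose.elec_score, rank=pose.rank,
    )
    return RefinedPose(
        pose=refined, energy=float(best["energy"]),
        converged=bool(res.success), n_iterations=int(res.nit),
    )


def refine_pose_multistart(
    pose: Pose,
    static: ChainModel,
    mobile: ChainModel,
    register_offset: float = 4.5,
    **refine_kwargs,
) -> RefinedPose:
    """Rigid-body refinement with a register scan.

    Packed interfaces (helix against helix) have periodic near-native
    minima separated by roughly half a helix spacing; a single local
    minimisation can stall one register off.  This variant starts the
    minimiser from the pose itself and from +-``register_offset``
    displacements along the two directions perpendicular to the
    centroid-centroid axis of the posed complex, returning the deepest
    refined result.
    """
    cs = static.centroid()
    cb = pose.rotation @ mobile.centroid() + pose.translation
    axis = cb - cs
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
    helper = np.array([0.0, 0.0, 1.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(axis, helper); e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    best: RefinedPose | None = None
    for off in (np.zeros(3), register_offset * e1, -register_offset * e1,
                register_offset * e2, -register_offset * e2):
        start = Pose(pose.pose_id, pose.rotation, pose.translation + off,
                     pose.shape_score, pose.elec_score, pose.rank)
        refined = refine_pose(start, static, mobile, **refine_kwargs)
        if best is None or refined.energy < best.energy:
            best = refined
    return best


# ---------------------------------------------------------------------------
# Selection

def select_model(
    refined: Sequence[RefinedPose],
    static: ChainModel,
    mobile: ChainModel,
    energy_tie_tolerance: float = 1e-6,
    asa_points: int = 240,
) -> tuple[DimerComplex, RefinedPose]:
    """Pick the lowest-energy refined pose.

    Energy ties (within ``energy_tie_tolerance``) are broken by larger
    buried surface area, then by pose id.  Raises ValueError on an empty
    pose list — the no-restraint-compatible-pose outcome is handled by
    the caller as a distinguished result, not an exception from here.
    """
    if not refined:
        raise ValueError("no surviving pose to select from")
    best_energy = min(r.energy for r in refined)
    contenders = [r for r in refined if r.energy <= best_energy + energy_tie_tolerance]
    if len(contenders) > 1:
        def burial(r: RefinedPose) -> float:
            c = _build_complex(r, static, mobile)
            return _delta_asa_only(c, n_points=asa_points)
        contenders.sort(key=lambda r: (-burial(r), r.pose.pose_id))
    chosen = contenders[0]
    return _build_complex(chosen, static, mobile), chosen


def _build_complex(r: RefinedPose, static: ChainModel, mobile: ChainModel) -> DimerComplex:
    chain_a = static.with_chain_id("A")
    chain_b = r.pose.place(mobile, chain_id="B")
    return DimerComplex(chain_a=chain_a, chain_b=chain_b, provenance=f"pose {r.pose.pose_id}")


# ---------------------------------------------------------------------------
# Solvent accessibility (Shrake-Rupley)

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (Fibonacci spiral)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def shrake_rupley_asa(
    coords: np.ndarray,
    radii: np.ndarray,
    n_points: int = 960,
    probe: float = 1.4,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area by sphere-point sampling.

    Each atom's solvent sphere (vdW radius + probe) is sampled with a
    deterministic Fibonacci spiral; points inside any neighbour's solvent
    sphere are occluded.  Returns areas in A^2.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n_atoms = len(coords)
    if n_atoms == 0:
        return np.zeros(0)
    sphere = _sphere_points(n_points)
    solv = radii + probe
    tree = cKDTree(coords)
    max_reach = 2.0 * solv.max()
    asa = np.zeros(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + solv[i] * sphere
        neighbours = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        if neighbours:
            nb = np.asarray(neighbours)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=-1)
            buried = (d2 < (solv[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        asa[i] = 4.0 * math.pi * solv[i] ** 2 * frac
    return asa


def _chain_asa(chains: Sequence[ChainModel], n_points: int, probe: float):
    coords_list, radii_list, owner, resnum = [], [], [], []
    for ci, chain in enumerate(chains):
        coords, labels = chain.atom_coords()
        coords_list.append(coords)
        radii_list.append(atom_radii(labels))
        owner += [ci] * len(labels)
        resnum += [lab[0] for lab in labels]
    coords = np.vstack(coords_list)
    radii = np.concatenate(radii_list)
    asa = shrake_rupley_asa(coords, radii, n_points=n_points, probe=probe)
    return asa, np.asarray(owner), np.asarray(resnum)


def _delta_asa_only(complex_: DimerComplex, n_points: int = 240, probe: float = 1.4) -> float:
    asa_ab, _, _ = _chain_asa([complex_.chain_a, complex_.chain_b], n_points, probe)
    asa_a, _, _ = _chain_asa([complex_.chain_a], n_points, probe)
    asa_b, _, _ = _chain_asa([complex_.chain_b], n_points, probe)
    return float(asa_a.sum() + asa_b.sum() - asa_ab.sum())


def interface_metrics(
    complex_: DimerComplex,
    n_points: int = 960,
    probe: float = 1.4,
    burial_floor: float = 0.1,
    contact_cutoff: float = 4.5,
) -> InterfaceReport:
    """Buried surface area, interface residues and chain orientation.

    delta ASA = ASA(A) + ASA(B) - ASA(AB); a residue is an interface
    residue when it buries more than ``burial_floor`` A^2 on complex
    formation.  Contact pairs are residue pairs with any inter-chain
    atom-atom distance below ``contact_cutoff``.
    """
    asa_ab, owner, resnum = _chain_asa([complex_.chain_a, complex_.chain_b], n_points, probe)
    asa_a, _, resnum_a = _chain_asa([complex_.chain_a], n_points, probe)
    asa_b, _, resnum_b = _chain_asa([complex_.chain_b], n_points, probe)

    def residue_burial(free_asa, free_res, chain_index):
        sel = owner == chain_index
        bound = {}
        for a, rn in zip(asa_ab[sel], resnum[sel]):
            bound[rn] = bound.get(rn, 0.0) + a
        free = {}
        for a, rn in zip(free_asa, free_res):
            free[rn] = free.get(rn, 0.0) + a
        out = []
        for rn in sorted(free):
            buried = free[rn] - bound.get(rn, 0.0)
            if buried > burial_floor:
                out.append((int(rn), round(float(buried), 2)))
        return out

    iface_a = residue_burial(asa_a, resnum_a, 0)
    iface_b = residue_burial(asa_b, resnum_b, 1)
    delta = float(asa_a.sum() + asa_b.sum() - asa_ab.sum())

    a_coords, a_labels = complex_.chain_a.atom_coords()
    b_coords, b_labels = complex_.chain_b.atom_coords()
    tree = cKDTree(b_coords)
    closest: dict[tuple[int, int], float] = {}
    for i, (rn_a, _, _) in enumerate(a_labels):
        for j in tree.query_ball_point(a_coords[i], contact_cutoff):
            key = (rn_a, b_labels[j][0])
            d = float(np.linalg.norm(a_coords[i] - b_coords[j]))
            if d < closest.get(key, math.inf):
                closest[key] = d
    contact_list = [(a, b, round(d, 2)) for (a, b), d in sorted(closest.items())]

    label, angle, c2 = classify_orientation(complex_)
    return InterfaceReport(
        delta_asa=delta,
        interface_residues_a=iface_a,
        interface_residues_b=iface_b,
        contact_pairs=contact_list,
        orientation_label=label,
        orientation_angle=angle,
        c2_residual=c2,
    )


def classify_orientation(complex_: DimerComplex) -> tuple[str, float, float]:
    """Parallel/antiparallel label from the chains' end-to-end vectors.

    Each chain's reference vector runs from the first to the last Calpha
    of the residue span shared by both chains; the angle between the two
    vectors classifies the arrangement (< 90 degrees: parallel).  Also
    reports the C2-axis residual: how far the A->B superposition
    transform is from an exact two-fold (RMSD of applying it twice).
    """
    a, b = complex_.chain_a, complex_.chain_b
    shared = sorted(set(a.residue_numbers) & set(b.residue_numbers))
    if len(shared) < max(2, int(0.8 * max(len(a), len(b)))):
        raise ValueError("chains too dissimilar to pair for orientation analysis")

    def ref_vector(chain: ChainModel) -> np.ndarray:
        nums = [n for n in shared if "CA" in chain.residue(n).atoms]
        v = chain.residue(nums[-1]).coord("CA") - chain.residue(nums[0]).coord("CA")
        return v / np.linalg.norm(v)

    va, vb = ref_vector(a), ref_vector(b)
    cosang = float(np.clip(np.dot(va, vb), -1.0, 1.0))
    angle = math.degrees(math.acos(cosang))
    label = "parallel" if angle < 90.0 else "antiparallel"

    ca_a = np.asarray([a.residue(n).coord("CA") for n in shared if "CA" in a.residue(n).atoms
                       and "CA" in b.residue(n).atoms])
    ca_b = np.asarray([b.residue(n).coord("CA") for n in shared if "CA" in a.residue(n).atoms
                       and "CA" in b.residue(n).atoms])
    transform, _ = superpose_rmsd(ca_a, ca_b)
    twice = transform.compose(transform)
    c2_residual = float(np.sqrt(((twice.apply(ca_a) - ca_a) ** 2).sum(axis=1).mean()))
    return label, angle, c2_residual
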