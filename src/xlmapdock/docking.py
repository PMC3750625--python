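"""Rigid-body pose generation by FFT shape correlation plus electrostatics.

The two monomers are digitised on a cubic grid: the static partner gets a
thin favourable surface layer (weight 1) over a strongly penalised core
(weight rho << 0), the mobile partner is a uniform body of weight 1.  The
product summed over a relative translation then rewards surface-surface
contact and punishes interpenetration, and evaluating it for *all*
translations at once is a cross-correlation computable with forward and
inverse FFTs.  A deterministic sweep over a Euler-angle rotation grid,
keeping the best translations per rotation, yields a ranked pose set;
an additive Coulomb term with a distance-dependent dielectric is used to
discard electrostatically repulsive poses, not added to the shape score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import fft as _fft
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .structure_model import ChainModel, RigidTransform

__all__ = [
    "DockGrid",
    "DockSettings",
    "Pose",
    "PoseSet",
    "VDW_RADII",
    "atom_radii",
    "charge_points",
    "discretize",
    "shape_correlation",
    "electrostatic_score",
    "rotation_grid",
    "generate_poses",
]

VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
    "P": 1.80, "SE": 1.90, "ZN": 1.39,
}
_DEFAULT_RADIUS = 1.70


def atom_radii(labels: Sequence[tuple[int, str, str]], override: float | None = None) -> np.ndarray:
    """Van der Waals radius per atom from the atom-name element guess."""
    if override is not None:
        return np.full(len(labels), float(override))
    out = np.empty(len(labels))
    for i, (_, _, atom_name) in enumerate(labels):
        key = atom_name[:2] if atom_name[:2] in ("SE", "ZN") else atom_name[0]
        out[i] = VDW_RADII.get(key, _DEFAULT_RADIUS)
    return out


@dataclass
class DockGrid:
    """A digitised molecule: shape channel plus summed charges per voxel."""

    spacing: float
    origin: np.ndarray  # world coordinates of voxel (0,0,0) center
    shape: np.ndarray   # (N,N,N) float
    charge: np.ndarray | None = None
    role: str = "static"

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.shape.shape


@dataclass(frozen=True)
class DockSettings:
    """Sweep parameters.

    Defaults follow classic grid-correlation docking practice: 1 A grid,
    1.5 A surface layer, core penalty -15, 15 degree Euler step, and
    10,000 retained poses.
    """

    spacing: float = 1.0
    surface_thickness: float = 1.5
    core_penalty: float = -15.0
    angle_step: float = 15.0
    retain: int = 10000
    keep_per_rotation: int | None = None
    discard_repulsive: bool = True
    atom_radius: float | None = None
    margin: float = 3.0
    dedup_c2: bool = True
    charge_termini: bool = False

    def resolved_keep_per_rotation(self, n_rotations: int) -> int:
        if self.keep_per_rotation is not None:
            return self.keep_per_rotation
        return max(3, math.ceil(3.0 * self.retain / max(n_rotations, 1)))


@dataclass
class Pose:
    """A rigid placement of the mobile monomer: x -> R @ x + t (world frame)."""

    pose_id: int
    rotation: np.ndarray
    translation: np.ndarray
    shape_score: float
    elec_score: float
    rank: int = -1

    @property
    def transform(self) -> RigidTransform:
        return RigidTransform(self.rotation, self.translation)

    def euler_deg(self) -> np.ndarray:
        import warnings

        with warnings.catch_warnings():
            # gimbal lock at beta = 0/180 is expected; the convention picks
            # gamma = 0 deterministically
            warnings.simplefilter("ignore", UserWarning)
            return Rotation.from_matrix(self.rotation).as_euler("zyz", degrees=True)

    def place(self, mobile: ChainModel, chain_id: str = "B") -> ChainModel:
        return mobile.transformed(self.transform, chain_id=chain_id)


@dataclass
class PoseSet:
    static: ChainModel
    mobile: ChainModel
    poses: list[Pose]
    settings: DockSettings

    def __len__(self) -> int:
        return len(self.poses)

    def to_records(self) -> list[dict]:
        recs = []
        for p in self.poses:
            a, b, g = p.euler_deg()
            recs.append(
                {
                    "pose_id": p.pose_id, "rank": p.rank,
                    "euler_alpha": round(a, 3), "euler_beta": round(b, 3), "euler_gamma": round(g, 3),
                    "tx": round(p.translation[0], 3), "ty": round(p.translation[1], 3),
                    "tz": round(p.translation[2], 3),
                    "shape_score": p.shape_score, "elec_score": round(p.elec_score, 6),
                }
            )
        return recs


# ---------------------------------------------------------------------------
# Discretisation

def _fill_occupancy(
    coords: np.ndarray, radii: np.ndarray, origin: np.ndarray, dims: tuple[int, int, int],
    spacing: float,
) -> np.ndarray:
    """Mark voxels whose center lies within an atom's vdW radius."""
    occ = np.zeros(dims, dtype=bool)
    centers = np.rint((coords - origin) / spacing).astype(int)
    # group atoms by radius so the sphere stencil is built once per radius
    for r in np.unique(np.round(radii, 3)):
        k = int(math.ceil(r / spacing))
        rng = np.arange(-k, k + 1)
        ox, oy, oz = np.meshgrid(rng, rng, rng, indexing="ij")
        stencil = np.stack([ox, oy, oz], axis=-1).reshape(-1, 3)
        stencil = stencil[np.linalg.norm(stencil, axis=1) * spacing <= r + 1e-9]
        sel = centers[np.round(radii, 3) == r]
        idx = (sel[:, None, :] + stencil[None, :, :]).reshape(-1, 3)
        ok = np.all((idx >= 0) & (idx < np.array(dims)), axis=1)
        idx = idx[ok]
        occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return occ


def discretize(
    model: ChainModel,
    spacing: float = 1.0,
    surface_thickness: float = 1.5,
    role: str = "static",
    core_penalty: float = -15.0,
    origin: np.ndarray | None = None,
    dims: tuple[int, int, int] | None = None,
    atom_radius: float | None = None,
    with_charges: bool = True,
) -> DockGrid:
    """Digitise a chain onto a cubic grid.

    The static role separates the occupied volume into a surface layer
    (weight 1, within ``surface_thickness`` of solvent) and a penalised
    core (``core_penalty``); the mobile role is uniformly 1 so that core
    overlap with the static partner is punished exactly once.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if role not in ("static", "mobile"):
        raise ValueError("role must be 'static' or 'mobile'")
    coords, labels = model.atom_coords()
    if coords.size == 0:
        raise ValueError("empty model")
    radii = atom_radii(labels, override=atom_radius)

    if origin is None or dims is None:
        pad = radii.max() + surface_thickness + 2 * spacing
        lo = coords.min(axis=0) - pad
        hi = coords.max(axis=0) + pad
        n = int(np.ceil((hi - lo).max() / spacing)) + 1
        dims = (n, n, n)
        origin = lo
    origin = np.asarray(origin, dtype=float)

    occ = _fill_occupancy(coords, radii, origin, dims, spacing)
    if role == "mobile":
        shape = occ.astype(np.float64)
    else:
        depth = ndimage.distance_transform_edt(occ, sampling=spacing)
        surface = occ & (depth <= surface_thickness + 1e-9)
        shape = np.where(surface, 1.0, 0.0)
        shape[occ & ~surface] = core_penalty

    charge = None
    if with_charges:
        charge = np.zeros(dims)
        pts, q = charge_points(model)
        if len(q):
            ci = np.rint((pts - origin) / spacing).astype(int)
            ok = np.all((ci >= 0) & (ci < np.array(dims)), axis=1)
            np.add.at(charge, (ci[ok, 0], ci[ok, 1], ci[ok, 2]), q[ok])
    return DockGrid(spacing=spacing, origin=origin, shape=shape, charge=charge, role=role)


# ---------------------------------------------------------------------------
# Charges

_POS = {"LYS": ("NZ", "CB", "CA"), "ARG": ("CZ", "CB", "CA")}
_NEG = {"ASP": (("OD1", "OD2"), "CG", "CB", "CA"), "GLU": (("OE1", "OE2"), "CD", "CB", "CA")}


def charge_points(model: ChainModel, include_termini: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Residue-level formal charges: Lys/Arg +1, Asp/Glu -1, His 0.

    The charge sits on the terminal side-chain atom (midpoint of the
    carboxylate oxygens for Asp/Glu) with Cbeta/Calpha fallback for
    reduced representations.
    """
    pts, qs = [], []
    for res in model.residues:
        if res.name in _POS:
            for name in _POS[res.name]:
                if name in res.atoms:
                    pts.append(res.atoms[name]); qs.append(1.0)
                    break
        elif res.name in _NEG:
            spec = _NEG[res.name]
            placed = False
            pair = spec[0]
            if all(n in res.atoms for n in pair):
                pts.append((res.atoms[pair[0]] + res.atoms[pair[1]]) / 2); qs.append(-1.0)
                placed = True
            else:
                for name in spec[1:]:
                    if name in res.atoms:
                        pts.append(res.atoms[name]); qs.append(-1.0)
                        placed = True
                        break
            if not placed:
                continue
    if include_termini and model.residues:
        first, last = model.residues[0], model.residues[-1]
        for res, q in ((first, 1.0), (last, -1.0)):
            for name in ("N" if q > 0 else "C", "CA"):
                if name in res.atoms:
                    pts.append(res.atoms[name]); qs.append(q)
                    break
    if not pts:
        return np.zeros((0, 3)), np.zeros(0)
    return np.asarray(pts, dtype=float), np.asarray(qs, dtype=float)


_COULOMB = 332.0637  # kcal mol^-1 A e^-2


def electrostatic_score(
    coords_a: np.ndarray, charges_a: np.ndarray,
    coords_b: np.ndarray, charges_b: np.ndarray,
    dielectric_slope: float = 4.0, distance_floor: float = 2.0,
) -> float:
    """Screened Coulomb interaction sum q_i q_j / (eps(r) r), eps(r) = slope*r.

    Distances are floored at ``distance_floor`` to avoid the singularity.
    Negative is favourable.  Bilinear in the charges.
    """
    if len(charges_a) == 0 or len(charges_b) == 0:
        return 0.0
    diff = coords_a[:, None, :] - coords_b[None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=-1))
    r = np.maximum(r, distance_floor)
    return float(_COULOMB * (charges_a[:, None] * charges_b[None, :] / (dielectric_slope * r * r)).sum())


# ---------------------------------------------------------------------------
# Correlation

def shape_correlation(static: DockGrid, mobile: DockGrid) -> np.ndarray:
    """Correlation score for every cyclic voxel shift of the mobile grid.

    ``corr[t] = sum_x static[x] * mobile[x - t]``: entry ``t`` scores the
    mobile body translated by ``+t`` voxels.  Computed with forward and
    inverse FFTs; identical to the direct-space triple sum.
    """
    if static.dims != mobile.dims or static.spacing != mobile.spacing:
        raise ValueError("grids must share dimensions and spacing")
    fs = _fft.rfftn(static.shape)
    fm = _fft.rfftn(mobile.shape)
    return _fft.irfftn(fs * np.conj(fm), s=static.dims)


def rotation_grid(angle_step: float) -> list[Rotation]:
    """Deterministic Euler zyz sweep with duplicate-rotation pruning."""
    alphas = np.arange(0.0, 360.0, angle_step)
    betas = np.arange(0.0, 180.0 + 1e-9, angle_step)
    gammas = np.arange(0.0, 360.0, angle_step)
    seen = set()
    rotations = []
    for b in betas:
        for a in alphas:
            for g in gammas:
                rot = Rotation.from_euler("zyz", [a, b, g], degrees=True)
                q = rot.as_quat()
                # canonical sign: first significant component positive
                for c in q:
                    if abs(c) > 1e-8:
                        if c < 0:
                            q = -q
                        break
                key = tuple(np.round(q, 5))
                if key in seen:
                    continue
                seen.add(key)
                rotations.append(rot)
    return rotations


def _signed_shift(flat_idx: np.ndarray, dims: tuple[int, int, int]) -> np.ndarray:
    t = np.stack(np.unravel_index(flat_idx, dims), axis=-1).astype(int)
    n = np.array(dims)
    return ((t + n // 2) % n) - n // 2


def _canonical_pose_key(R: np.ndarray, t: np.ndarray, grid: float) -> tuple:
    def key_of(Rm, tm):
        q = Rotation.from_matrix(Rm).as_quat()
        for c in q:
            if abs(c) > 1e-8:
                if c < 0:
                    q = -q
                break
        return tuple(np.round(q, 2)) + tuple(np.round(tm / grid).astype(int))

    k1 = key_of(R, t)
    Rt = R.T
    k2 = key_of(Rt, -Rt @ t)
    return min(k1, k2)


def generate_poses(
    static: ChainModel, mobile: ChainModel, settings: DockSettings = DockSettings()
) -> PoseSet:
    """Deterministic rotation/translation sweep returning the top-ranked poses.

    For each rotation of the mobile monomer the best translations of the
    shape correlation are kept; globally the best ``settings.retain``
    poses are retained, electrostatically repulsive ones last, ranked by
    shape score with (elec score, pose id) tie-breaks.  With identical
    static and mobile monomers, chain-swap (C2) duplicates are removed by
    canonicalising each pose transform at grid resolution.
    """
    h = settings.spacing
    s_coords, s_labels = static.atom_coords()
    m_coords, m_labels = mobile.atom_coords()
    if s_coords.size == 0 or m_coords.size == 0:
        raise ValueError("empty model")
    s_radii = atom_radii(s_labels, settings.atom_radius)
    m_radii = atom_radii(m_labels, settings.atom_radius)
    cs = s_coords.mean(axis=0)
    cm = m_coords.mean(axis=0)
    rs = np.linalg.norm(s_coords - cs, axis=1).max() + s_radii.max()
    rm = np.linalg.norm(m_coords - cm, axis=1).max() + m_radii.max()
    L = 2.0 * (rs + rm) + 2 * settings.surface_thickness + settings.margin
    n = _fft.next_fast_len(int(math.ceil(L / h)) + 1, real=True)
    dims = (n, n, n)
    origin = cs - (n // 2) * h

    static_grid = discretize(
        static, spacing=h, surface_thickness=settings.surface_thickness, role="static",
        core_penalty=settings.core_penalty, origin=origin, dims=dims,
        atom_radius=settings.atom_radius, with_charges=False,
    )
    fs = _fft.rfftn(static_grid.shape)

    rotations = rotation_grid(settings.angle_step)
    keep = settings.resolved_keep_per_rotation(len(rotations))
    m_centered = m_coords - cm

    cand_rot, cand_flat, cand_score = [], [], []
    for ri, rot in enumerate(rotations):
        R = rot.as_matrix()
        placed = m_centered @ R.T + cs
        occ = _fill_occupancy(placed, m_radii, origin, dims, h).astype(np.float64)
        corr = _fft.irfftn(fs * np.conj(_fft.rfftn(occ)), s=dims)
        flat = corr.reshape(-1)
        k = min(keep, flat.size)
        top = np.argpartition(-flat, k - 1)[:k]
        cand_rot.append(np.full(k, ri, dtype=np.int64))
        cand_flat.append(top.astype(np.int64))
        cand_score.append(flat[top])
    rot_idx = np.concatenate(cand_rot)
    flat_idx = np.concatenate(cand_flat)
    scores = np.concatenate(cand_score)
    if rot_idx.size < settings.retain:
        raise ValueError(
            f"settings yield only {rot_idx.size} candidate poses (< retain={settings.retain}); "
            "decrease angle_step or increase keep_per_rotation"
        )

    # round scores to suppress FFT noise so ties are broken deterministically
    scores = np.round(scores, 6)
    pose_ids = rot_idx * np.int64(n ** 3) + flat_idx
    order = np.lexsort((pose_ids, -scores))
    rot_idx, flat_idx, scores, pose_ids = (
        rot_idx[order], flat_idx[order], scores[order], pose_ids[order]
    )

    shifts = _signed_shift(flat_idx, dims) * h
    rot_mats = np.array([r.as_matrix() for r in rotations])

    s_pts, s_q = charge_points(static, include_termini=settings.charge_termini)
    m_pts, m_q = charge_points(mobile, include_termini=settings.charge_termini)
    m_pts_centered = m_pts - cm if len(m_q) else m_pts

    same_monomer = (s_coords.shape == m_coords.shape) and np.allclose(s_coords, m_coords)
    dedup = settings.dedup_c2 and same_monomer
    seen_keys: set = set()
    # electrostatics is only evaluated when it acts as a filter; with the
    # discard disabled the (python-level) per-pose sum is skipped entirely
    want_elec = settings.discard_repulsive and len(m_q) > 0 and len(s_q) > 0

    attractive: list[Pose] = []
    repulsive: list[Pose] = []
    needed = settings.retain
    for i in range(rot_idx.size):
        R = rot_mats[rot_idx[i]]
        t = cs + shifts[i] - R @ cm
        if dedup:
            key = _canonical_pose_key(R, t, h)
            if key in seen_keys:
                continue
            seen_keys.add(key)
        if want_elec:
            placed_pts = m_pts_centered @ R.T + cs + shifts[i]
            elec = electrostatic_score(s_pts, s_q, placed_pts, m_q)
        else:
            elec = 0.0
        pose = Pose(
            pose_id=int(pose_ids[i]), rotation=R, translation=t,
            shape_score=float(scores[i]), elec_score=elec,
        )
        if settings.discard_repulsive and elec > 1e-9:
            repulsive.append(pose)
        else:
            attractive.append(pose)
        if len(attractive) >= needed:
            break

    selected = attractive[:needed]
    if len(selected) < needed:
        # not enough non-repulsive candidates: backfill with the least bad
        selected += repulsive[: needed - len(selected)]
    if len(selected) < needed:
        raise ValueError(
            f"only {len(selected)} poses available after deduplication (< retain={needed})"
        )
    selected.sort(key=lambda p: (-p.shape_score, p.elec_score, p.pose_id))
    for rank, p in enumerate(selected):
        p.rank = rank
    return PoseSet(static=static, mobile=mobile, poses=selected, settings=settings)
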