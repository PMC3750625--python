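"""Structure I/O, crosslink-site geometry and rigid superposition.

Atomic models are read with gemmi and held in a light chain container
suited to the distance/docking arithmetic used here.  Crosslink distances
follow the XL-MS convention of measuring between lysine Cbeta atoms
(Calpha fallback when the side chain is truncated, Calpha for glycine,
SG for cysteine reagents).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Residue",
    "ChainModel",
    "DimerComplex",
    "LinkSite",
    "Restraint",
    "RigidTransform",
    "read_structure",
    "write_pdb",
    "edit_mse_to_met",
    "resolve_site_atom",
    "site_distance",
    "classify_crosslinks",
    "cys_crosslink_feasible",
    "superpose_rmsd",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R @ x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self.compose(other)).apply(x) == self.apply(other.apply(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


@dataclass
class Residue:
    number: int
    name: str
    atoms: dict[str, np.ndarray]

    def coord(self, atom_name: str) -> np.ndarray:
        return self.atoms[atom_name]


@dataclass
class ChainModel:
    """One polypeptide chain: ordered residues with atom coordinates (A)."""

    chain_id: str
    residues: list[Residue]
    _index: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {r.number: i for i, r in enumerate(self.residues)}
        if len(self._index) != len(self.residues):
            raise ValueError("duplicate residue numbers in chain")
        for r in self.residues:
            for name, xyz in r.atoms.items():
                xyz = np.asarray(xyz, dtype=float).reshape(3)
                if not np.all(np.isfinite(xyz)):
                    raise ValueError(f"non-finite coordinates at {r.number}:{name}")
                r.atoms[name] = xyz

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, number: int) -> Residue:
        try:
            return self.residues[self._index[number]]
        except KeyError:
            raise KeyError(f"residue {number} not in chain {self.chain_id}") from None

    def has_residue(self, number: int) -> bool:
        return number in self._index

    @property
    def residue_numbers(self) -> list[int]:
        return [r.number for r in self.residues]

    def atom_coords(self) -> tuple[np.ndarray, list[tuple[int, str, str]]]:
        """All coordinates plus (residue number, residue name, atom name) labels."""
        coords, labels = [], []
        for r in self.residues:
            for name, xyz in r.atoms.items():
                coords.append(xyz)
                labels.append((r.number, r.name, name))
        return np.asarray(coords, dtype=float), labels

    def coords_of(self, atom_name: str) -> np.ndarray:
        """Coordinates of one named atom per residue (residues lacking it skipped)."""
        return np.asarray(
            [r.atoms[atom_name] for r in self.residues if atom_name in r.atoms], dtype=float
        )

    def centroid(self) -> np.ndarray:
        return self.atom_coords()[0].mean(axis=0)

    def transformed(self, transform: RigidTransform, chain_id: str | None = None) -> "ChainModel":
        residues = [
            Residue(r.number, r.name, {n: transform.apply(x) for n, x in r.atoms.items()})
            for r in self.residues
        ]
        return ChainModel(chain_id=chain_id or self.chain_id, residues=residues)

    def with_chain_id(self, chain_id: str) -> "ChainModel":
        return self.transformed(RigidTransform.identity(), chain_id=chain_id)


@dataclass
class DimerComplex:
    chain_a: ChainModel
    chain_b: ChainModel
    provenance: str = ""

    def chain(self, chain_id: str) -> ChainModel:
        for c in (self.chain_a, self.chain_b):
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in complex")

    def min_interchain_distance(self) -> float:
        from scipy.spatial import cKDTree

        a, _ = self.chain_a.atom_coords()
        b, _ = self.chain_b.atom_coords()
        return float(cKDTree(a).query(b)[0].min())


@dataclass(frozen=True)
class LinkSite:
    """A crosslink attachment site resolvable to one reference atom."""

    chain_id: str
    residue_number: int
    atom_rule: str = "lys_cb"  # lys_cb | ca | sg | n


@dataclass(frozen=True)
class Restraint:
    """An upper-bound distance restraint with site ambiguity.

    ``alternatives`` is a set of (residue on chain A, residue on chain B)
    pairs; the restraint is satisfied when ANY alternative pair is within
    ``max_distance``.  For a homodimer an observed pair (i, j) is measured
    in both orders, so build alternatives {(i, j), (j, i)}.
    """

    alternatives: tuple[tuple[int, int], ...]
    max_distance: float
    origin: str = ""

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise ValueError("restraint needs at least one alternative site pair")
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")

    @classmethod
    def homodimer(
        cls, site_1: int, site_2: int, max_distance: float, origin: str = "",
        extra_alternatives: Iterable[tuple[int, int]] = (),
    ) -> "Restraint":
        alts = {(site_1, site_2), (site_2, site_1)}
        for a, b in extra_alternatives:
            alts.update({(a, b), (b, a)})
        return cls(tuple(sorted(alts)), max_distance, origin or f"K{site_1}-K{site_2}")


# ---------------------------------------------------------------------------
# I/O

def read_structure(path, chain: str | None = None, model_index: int = 0) -> ChainModel:
    """Read one chain from a PDB/mmCIF file (highest-occupancy altlocs).

    HETATM records are retained, so selenomethionine (MSE) residues come
    through and can be converted with :func:`edit_mse_to_met`.  Waters are
    dropped.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[model_index]
    names = [ch.name for ch in model]
    if chain is None:
        chain = names[0]
    if chain not in names:
        raise KeyError(f"chain {chain!r} not found in {path}; available: {names}")

    residues: list[Residue] = []
    for res in model[chain]:
        if res.name in ("HOH", "WAT"):
            continue
        atoms: dict[str, np.ndarray] = {}
        best_occ: dict[str, float] = {}
        for atom in res:
            if atom.name in atoms and atom.occ <= best_occ[atom.name]:
                continue
            atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            best_occ[atom.name] = atom.occ
        if atoms:
            residues.append(Residue(res.seqid.num, res.name, atoms))
    if not residues:
        raise ValueError(f"chain {chain!r} in {path} contains no residues")
    return ChainModel(chain_id=chain, residues=residues)


_ELEMENTS = {"SE": "Se", "ZN": "Zn", "FE": "Fe", "MG": "Mg", "MN": "Mn"}


def _element_of(residue_name: str, atom_name: str) -> str:
    if atom_name in _ELEMENTS:
        return _ELEMENTS[atom_name]
    return atom_name[0]


def write_pdb(path, chains: Sequence[ChainModel]) -> None:
    """Write chains as a single-model PDB file via gemmi."""
    st = gemmi.Structure()
    st.name = "xlmapdock"
    model = gemmi.Model("1")
    for chain_model in chains:
        ch = gemmi.Chain(chain_model.chain_id)
        for r in chain_model.residues:
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.number, " ")
            for name, xyz in r.atoms.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.pos = gemmi.Position(*xyz)
                atom.element = gemmi.Element(_element_of(r.name, name))
                atom.occ = 1.0
                res.add_atom(atom)
            ch.add_residue(res)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def edit_mse_to_met(model: ChainModel) -> tuple[ChainModel, int]:
    """Rename selenomethionine residues to methionine (SE atom -> SD).

    Returns the edited chain and the number of residues changed.
    """
    edited = 0
    residues = []
    for r in model.residues:
        if r.name == "MSE":
            atoms = {("SD" if n == "SE" else n): xyz.copy() for n, xyz in r.atoms.items()}
            residues.append(Residue(r.number, "MET", atoms))
            edited += 1
        else:
            residues.append(Residue(r.number, r.name, {n: x.copy() for n, x in r.atoms.items()}))
    return ChainModel(model.chain_id, residues), edited


# ---------------------------------------------------------------------------
# Site geometry

def resolve_site_atom(model: ChainModel, residue_number: int, atom_rule: str = "lys_cb") -> np.ndarray:
    """Coordinates of a link site's reference atom.

    ``lys_cb``: Cbeta, falling back to Calpha (glycine, or truncated side
    chain — common in crystal structures; a warning is emitted for the
    latter).  ``sg``: cysteine SG with Cbeta/Calpha fallback.  ``ca``,
    ``n``: those backbone atoms directly.
    """
    res = model.residue(residue_number)
    if atom_rule == "lys_cb":
        if "CB" in res.atoms:
            return res.coord("CB")
        if res.name != "GLY":
            warnings.warn(
                f"residue {residue_number} ({res.name}) lacks CB; using CA", stacklevel=2
            )
        if "CA" in res.atoms:
            return res.coord("CA")
        raise KeyError(f"residue {residue_number} has neither CB nor CA")
    if atom_rule == "sg":
        for name in ("SG", "CB", "CA"):
            if name in res.atoms:
                return res.coord(name)
        raise KeyError(f"residue {residue_number} has no SG/CB/CA")
    if atom_rule in ("ca", "n"):
        name = atom_rule.upper()
        if name in res.atoms:
            return res.coord(name)
        raise KeyError(f"residue {residue_number} has no {name} atom")
    raise ValueError(f"unknown atom rule {atom_rule!r}")


def site_distance(
    structure: ChainModel | DimerComplex,
    site1: LinkSite,
    site2: LinkSite,
) -> float:
    """Euclidean distance between two link-site reference atoms."""
    def chain_of(site: LinkSite) -> ChainModel:
        if isinstance(structure, ChainModel):
            return structure
        return structure.chain(site.chain_id)

    a = resolve_site_atom(chain_of(site1), site1.residue_number, site1.atom_rule)
    b = resolve_site_atom(chain_of(site2), site2.residue_number, site2.atom_rule)
    return float(np.linalg.norm(a - b))


def classify_crosslinks(
    site_pairs: Iterable[tuple[int, int]],
    monomer: ChainModel,
    xl,
    dimer_evidence: Iterable[tuple[int, int]] = (),
) -> list[dict]:
    """Label observed site pairs against the monomer structure.

    A pair is ``monomer-compatible`` when its within-chain distance fits
    the linker's bound, ``requires-intermolecular`` when it cannot occur
    within one chain (identical residues, or distance beyond the bound),
    and ``ambiguous`` when independent dimer evidence exists for a pair
    that would also fit within the monomer.
    """
    evidence = {tuple(sorted(p)) for p in dimer_evidence}
    out = []
    for s1, s2 in site_pairs:
        if s1 == s2:
            out.append({"site_1": s1, "site_2": s2, "distance": math.nan,
                        "label": "requires-intermolecular"})
            continue
        d = site_distance(
            monomer, LinkSite(monomer.chain_id, s1), LinkSite(monomer.chain_id, s2)
        )
        if d <= xl.max_site_distance:
            label = "ambiguous" if tuple(sorted((s1, s2))) in evidence else "monomer-compatible"
        else:
            label = "requires-intermolecular"
        out.append({"site_1": s1, "site_2": s2, "distance": round(d, 2), "label": label})
    return out


def cys_crosslink_feasible(
    complex_: DimerComplex, residue_number: int, spacer: float, slack: float = 0.0,
    atom_rule: str = "sg",
) -> tuple[float, bool]:
    """Distance between the same residue on both chains and whether a
    maleimide crosslinker of the given spacer could bridge it."""
    d = site_distance(
        complex_,
        LinkSite(complex_.chain_a.chain_id, residue_number, atom_rule),
        LinkSite(complex_.chain_b.chain_id, residue_number, atom_rule),
    )
    return d, d <= spacer + slack


# ---------------------------------------------------------------------------
# Superposition

def superpose_rmsd(
    mobile: ChainModel | np.ndarray,
    reference: ChainModel | np.ndarray,
    atom_name: str = "CA",
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch, proper rotation only).

    Returns the transform mapping mobile onto reference and the RMSD of
    the transformed mobile coordinates.
    """
    X = mobile.coords_of(atom_name) if isinstance(mobile, ChainModel) else np.asarray(mobile, float)
    Y = reference.coords_of(atom_name) if isinstance(reference, ChainModel) else np.asarray(reference, float)
    if X.shape != Y.shape or X.shape[0] < 3:
        raise ValueError("need equal numbers of paired atoms, at least 3")
    cx, cy = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - cx, Y - cy
    if np.linalg.matrix_rank(Xc, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) atom set")
    rot, rssd = Rotation.align_vectors(Yc, Xc)
    R = rot.as_matrix()
    t = cy - R @ cx
    rmsd = rssd / math.sqrt(X.shape[0])
    return RigidTransform(R, t), float(rmsd)
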