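"""In-silico proteolysis and crosslinked-peptide mass arithmetic.

Implements the mass-spectrometry side of a lysine-crosslinking experiment
with an NHS-ester reagent such as BS3: digestion of the target protein with
trypsin or chymotrypsin, enumeration of the theoretical reaction products
(dead-ends, looplinks, inter-peptide links), matching of theoretical masses
against an observed peak list, subtraction of the unmodified control
digest, and b/y fragment-ion generation for the matched products.

Conventions
-----------
* Residue masses come from pyteomics' standard tables; peptide neutral
  mass is the residue sum plus one water.
* A crosslinker bridge adds its bridge mass to the summed peptide masses;
  a hydrolysed dead-end adds the bridge mass plus water.
* Peptide positions are expressed in the parent protein's own coordinate
  system.  The start position may be any integer (construct numbering is
  sometimes offset relative to a deposited structure; see
  :func:`Peptide.shifted`).
* A lysine whose side chain carries the crosslinker is not cleaved by
  trypsin, so for tryptic peptides a reactive residue sitting at the
  C-terminal cleavage position is not a valid link site.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mass as _pmass

__all__ = [
    "WATER_MONO",
    "WATER_AVG",
    "PROTON",
    "ResidueMassTable",
    "CrosslinkerSpec",
    "Peptide",
    "CrosslinkProduct",
    "PeakList",
    "MassMatch",
    "digest",
    "peptide_mass",
    "reactive_link_sites",
    "enumerate_products",
    "theoretical_mz",
    "match_peaks",
    "differential_products",
    "fragment_ions",
]

WATER_MONO = _pmass.calculate_mass(formula="H2O")
WATER_AVG = _pmass.calculate_mass(formula="H2O", average=True)
PROTON = 1.00727646688

_STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: protease -> (residues cleaved after, residues blocking cleavage when next)
PROTEASES = {
    "trypsin": ("KR", "P"),
    "chymotrypsin": ("FYWLM", "P"),
}


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic and average residue masses for the 20 standard residues."""

    masses: dict[str, tuple[float, float]]
    water_mono: float = WATER_MONO
    water_avg: float = WATER_AVG
    proton: float = PROTON

    def __post_init__(self) -> None:
        missing = set(_STANDARD_RESIDUES) - set(self.masses)
        if missing:
            raise ValueError(f"mass table missing residues: {sorted(missing)}")
        for res, (mono, avg) in self.masses.items():
            if mono > avg:
                raise ValueError(f"monoisotopic > average for residue {res}")

    @classmethod
    def default(cls) -> "ResidueMassTable":
        masses = {
            res: (
                _pmass.std_aa_mass[res],
                _pmass.calculate_mass(composition=_pmass.std_aa_comp[res], average=True),
            )
            for res in _STANDARD_RESIDUES
        }
        return cls(masses=masses)

    def mono(self, residue: str) -> float:
        try:
            return self.masses[residue][0]
        except KeyError:
            raise ValueError(f"unknown residue letter {residue!r}") from None

    def avg(self, residue: str) -> float:
        try:
            return self.masses[residue][1]
        except KeyError:
            raise ValueError(f"unknown residue letter {residue!r}") from None


_DEFAULT_TABLE: ResidueMassTable | None = None


def default_mass_table() -> ResidueMassTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = ResidueMassTable.default()
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class CrosslinkerSpec:
    """A homobifunctional crosslinker.

    ``bridge_mass`` is the mass added when both reactive ends have formed a
    bond (the intact spacer); ``deadend_mass`` when one end has hydrolysed.
    ``max_site_distance`` is the distance bound (between the reference atoms
    of two linked residues) considered productive for this spacer;
    for BS3 the widely used Cbeta-Cbeta bound is 21.3 A.
    """

    name: str
    reactive_residues: frozenset[str]
    bridge_mass_mono: float
    bridge_mass_avg: float
    deadend_mass_mono: float
    deadend_mass_avg: float
    spacer_length: float
    max_site_distance: float
    n_term_reactive: bool = False
    excluded_sites: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.spacer_length <= 0:
            raise ValueError("spacer_length must be positive")
        if self.max_site_distance < self.spacer_length:
            raise ValueError("max_site_distance must be >= spacer_length")
        if self.deadend_mass_mono <= self.bridge_mass_mono:
            raise ValueError("dead-end mass must exceed bridge mass (hydrolysis adds water)")


@dataclass(frozen=True)
class Peptide:
    """A proteolytic fragment located in its parent protein.

    ``start``/``end`` are inclusive positions in the parent's numbering;
    they may be any integers as long as the span matches the sequence
    length (construct numbering can start at 0 or carry an offset).
    """

    sequence: str
    start: int
    end: int
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"span {self.start}-{self.end} inconsistent with length {len(self.sequence)}"
            )
        bad = set(self.sequence) - set(_STANDARD_RESIDUES)
        if bad:
            raise ValueError(f"unknown residue letter(s) {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def residue_at(self, position: int) -> str:
        if not self.contains(position):
            raise ValueError(f"position {position} outside {self.start}-{self.end}")
        return self.sequence[position - self.start]

    def positions_of(self, residues: Iterable[str]) -> list[int]:
        wanted = set(residues)
        return [self.start + i for i, aa in enumerate(self.sequence) if aa in wanted]

    def shifted(self, offset: int) -> "Peptide":
        """Same fragment renumbered by a constant offset (construct -> PDB)."""
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class CrosslinkProduct:
    """A theoretical crosslinking reaction product.

    kind is one of ``deadend`` (one linked site, hydrolysed second end),
    ``looplink`` (both ends on the same peptide) or ``interlink`` (ends on
    two peptides, possibly two copies of the same one).
    """

    kind: str
    peptide_1: Peptide
    peptide_2: Peptide | None
    linked_sites: tuple[int, ...]
    neutral_mass_mono: float
    neutral_mass_avg: float

    def __post_init__(self) -> None:
        if self.kind not in ("deadend", "looplink", "interlink"):
            raise ValueError(f"unknown product kind {self.kind!r}")
        if self.kind == "deadend" and len(self.linked_sites) != 1:
            raise ValueError("dead-end must have exactly one linked site")
        if self.kind in ("looplink", "interlink") and len(self.linked_sites) != 2:
            raise ValueError(f"{self.kind} must have exactly two linked sites")
        if self.kind == "looplink":
            s1, s2 = self.linked_sites
            if s1 == s2:
                raise ValueError("looplink sites must be distinct")
            if not (self.peptide_1.contains(s1) and self.peptide_1.contains(s2)):
                raise ValueError("looplink sites must lie inside the peptide")
        if self.kind == "interlink" and self.peptide_2 is None:
            raise ValueError("interlink requires two peptides")

    @property
    def site_pair(self) -> tuple[int, ...]:
        return tuple(sorted(self.linked_sites))


@dataclass(frozen=True)
class PeakList:
    """An observed peak list (m/z ascending) with a charge convention."""

    mz: np.ndarray
    intensity: np.ndarray
    charge_convention: str = "[M+H]+"

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.ndim != 1 or mz.shape != inten.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and mz.min() <= 0:
            raise ValueError("m/z values must be positive")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])

    def __len__(self) -> int:
        return int(self.mz.size)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]], **kw) -> "PeakList":
        arr = np.array(list(pairs), dtype=float).reshape(-1, 2)
        return cls(mz=arr[:, 0], intensity=arr[:, 1], **kw)

    @classmethod
    def read(cls, path, **kw) -> "PeakList":
        """Read a two-column whitespace/TSV text peak list (m/z, intensity)."""
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                rows.append((float(parts[0]), float(parts[1]) if len(parts) > 1 else 1.0))
        arr = np.array(rows, dtype=float).reshape(-1, 2)
        return cls(mz=arr[:, 0], intensity=arr[:, 1], **kw)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# charge convention: {self.charge_convention}\n")
            for m, i in zip(self.mz, self.intensity):
                fh.write(f"{m:.6f}\t{i:.4f}\n")


@dataclass(frozen=True)
class MassMatch:
    product: CrosslinkProduct
    observed_mz: float
    theoretical_mz: float
    charge: int
    error_da: float
    error_ppm: float


def digest(
    sequence: str,
    protease: str = "trypsin",
    max_missed: int = 0,
    start: int = 1,
) -> list[Peptide]:
    """Digest ``sequence`` with a site-specific protease.

    Trypsin cleaves C-terminal to K/R, chymotrypsin C-terminal to
    F/Y/W/L/M; neither cleaves when the next residue is proline.  Returns
    every fragment with up to ``max_missed`` internal missed cleavages,
    numbered from ``start``.
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - set(_STANDARD_RESIDUES)
    if bad:
        raise ValueError(f"unknown residue letter(s) {sorted(bad)}")
    try:
        cleave_after, block_next = PROTEASES[protease]
    except KeyError:
        raise ValueError(f"unknown protease {protease!r}; choose from {sorted(PROTEASES)}") from None

    boundaries = [0]
    for i in range(len(sequence) - 1):
        if sequence[i] in cleave_after and sequence[i + 1] not in block_next:
            boundaries.append(i + 1)
    boundaries.append(len(sequence))

    peptides = []
    for a in range(len(boundaries) - 1):
        for missed in range(max_missed + 1):
            b = a + missed + 1
            if b >= len(boundaries):
                break
            lo, hi = boundaries[a], boundaries[b]
            peptides.append(
                Peptide(
                    sequence=sequence[lo:hi],
                    start=start + lo,
                    end=start + hi - 1,
                    missed_cleavages=missed,
                )
            )
    return peptides


def peptide_mass(
    peptide: Peptide,
    modifications: Sequence[tuple[int, float]] = (),
    table: ResidueMassTable | None = None,
) -> tuple[float, float]:
    """Neutral peptide mass (monoisotopic, average) with optional mass shifts.

    ``modifications`` is a list of (protein position, delta mass in Da); the
    same delta is applied to both mass types.
    """
    table = table or default_mass_table()
    for pos, _ in modifications:
        if not peptide.contains(pos):
            raise ValueError(f"modification position {pos} outside peptide span")
    mono = sum(table.mono(aa) for aa in peptide.sequence) + table.water_mono
    avg = sum(table.avg(aa) for aa in peptide.sequence) + table.water_avg
    delta = sum(d for _, d in modifications)
    return mono + delta, avg + delta


def reactive_link_sites(
    peptide: Peptide,
    xl: CrosslinkerSpec,
    protease: str | None = None,
    parent_end: int | None = None,
) -> list[int]:
    """Protein positions in ``peptide`` that can carry the crosslinker.

    For tryptic peptides a reactive K/R at the C-terminal cleavage position
    is excluded: a modified lysine is not cleaved, so a genuinely linked
    lysine must sit at a missed-cleavage (internal) position.  The terminal
    residue is kept only when it is the parent protein's C-terminus
    (``parent_end``).
    """
    sites = peptide.positions_of(xl.reactive_residues)
    sites = [s for s in sites if s not in xl.excluded_sites]
    if protease == "trypsin":
        cleave_after, _ = PROTEASES[protease]
        if (
            peptide.sequence[-1] in cleave_after
            and peptide.end in sites
            and peptide.end != parent_end
        ):
            sites.remove(peptide.end)
    if xl.n_term_reactive and peptide.start == 1 and 1 not in sites:
        sites.insert(0, 1)
    return sites


def enumerate_products(
    peptides: Sequence[Peptide],
    xl: CrosslinkerSpec,
    kinds: Iterable[str] = ("deadend", "looplink", "interlink"),
    protease: str | None = None,
    parent_end: int | None = None,
    table: ResidueMassTable | None = None,
) -> list[CrosslinkProduct]:
    """Enumerate theoretical crosslink products over a peptide list.

    Interlinks are formed over unordered peptide pairs *including a peptide
    with itself* — in a homodimer the same lysine of the two chains can be
    bridged (e.g. a K24-K24 product), which appears here as a self-pair
    with an identical site on both ends.
    """
    kinds = set(kinds)
    unknown = kinds - {"deadend", "looplink", "interlink"}
    if unknown:
        raise ValueError(f"unknown product kind(s) {sorted(unknown)}")
    table = table or default_mass_table()

    site_map = [reactive_link_sites(p, xl, protease=protease, parent_end=parent_end) for p in peptides]
    masses = [peptide_mass(p, table=table) for p in peptides]

    products: list[CrosslinkProduct] = []
    if "deadend" in kinds:
        for pep, sites, (mono, avg) in zip(peptides, site_map, masses):
            for s in sites:
                products.append(
                    CrosslinkProduct(
                        kind="deadend",
                        peptide_1=pep,
                        peptide_2=None,
                        linked_sites=(s,),
                        neutral_mass_mono=mono + xl.deadend_mass_mono,
                        neutral_mass_avg=avg + xl.deadend_mass_avg,
                    )
                )
    if "looplink" in kinds:
        for pep, sites, (mono, avg) in zip(peptides, site_map, masses):
            for s1, s2 in itertools.combinations(sites, 2):
                products.append(
                    CrosslinkProduct(
                        kind="looplink",
                        peptide_1=pep,
                        peptide_2=None,
                        linked_sites=(s1, s2),
                        neutral_mass_mono=mono + xl.bridge_mass_mono,
                        neutral_mass_avg=avg + xl.bridge_mass_avg,
                    )
                )
    if "interlink" in kinds:
        for i, j in itertools.combinations_with_replacement(range(len(peptides)), 2):
            if not site_map[i] or not site_map[j]:
                continue
            if i == j:
                # two copies of the same peptide: identical-site pairs allowed
                site_pairs = itertools.combinations_with_replacement(site_map[i], 2)
            else:
                site_pairs = itertools.product(site_map[i], site_map[j])
            seen = set()
            for s1, s2 in site_pairs:
                key = (min(s1, s2), max(s1, s2))
                if i == j and key in seen:
                    continue
                seen.add(key)
                products.append(
                    CrosslinkProduct(
                        kind="interlink",
                        peptide_1=peptides[i],
                        peptide_2=peptides[j],
                        linked_sites=(s1, s2),
                        neutral_mass_mono=masses[i][0] + masses[j][0] + xl.bridge_mass_mono,
                        neutral_mass_avg=masses[i][1] + masses[j][1] + xl.bridge_mass_avg,
                    )
                )
    return products


def theoretical_mz(neutral_mass: float, charge: int) -> float:
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + charge * PROTON) / charge


def match_peaks(
    products: Sequence[CrosslinkProduct],
    peaks: PeakList,
    tolerance: float,
    unit: str = "ppm",
    charges: Iterable[int] = (1,),
    mass_type: str = "mono",
) -> list[MassMatch]:
    """Match theoretical product masses against an observed peak list.

    For every product and charge z the theoretical m/z is
    (M + z*proton)/z; every observed peak within ``tolerance`` (ppm of the
    theoretical m/z, or absolute Da) yields a match.  Matches are returned
    sorted by absolute error (in the tolerance's own unit).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if unit not in ("ppm", "Da"):
        raise ValueError("unit must be 'ppm' or 'Da'")
    charges = sorted(set(int(z) for z in charges))
    if not charges:
        raise ValueError("empty charge set")

    matches: list[MassMatch] = []
    mz = peaks.mz
    for product in products:
        neutral = product.neutral_mass_mono if mass_type == "mono" else product.neutral_mass_avg
        for z in charges:
            theo = theoretical_mz(neutral, z)
            tol_da = theo * tolerance * 1e-6 if unit == "ppm" else tolerance
            lo = np.searchsorted(mz, theo - tol_da, side="left")
            hi = np.searchsorted(mz, theo + tol_da, side="right")
            for k in range(lo, hi):
                err_da = float(mz[k] - theo)
                matches.append(
                    MassMatch(
                        product=product,
                        observed_mz=float(mz[k]),
                        theoretical_mz=theo,
                        charge=z,
                        error_da=err_da,
                        error_ppm=err_da / theo * 1e6,
                    )
                )
    key = (lambda m: abs(m.error_ppm)) if unit == "ppm" else (lambda m: abs(m.error_da))
    matches.sort(key=key)
    return matches


def differential_products(
    crosslinked_matches: Sequence[MassMatch],
    control_peaks: PeakList,
    tolerance: float,
    unit: str = "ppm",
) -> list[MassMatch]:
    """Retain matches whose observed m/z is absent from the control digest.

    This is the crosslinked-minus-control design: a peak also present in
    the unmodified digest carries no crosslinking information.
    """
    if unit not in ("ppm", "Da"):
        raise ValueError("unit must be 'ppm' or 'Da'")
    mz = control_peaks.mz
    kept = []
    for m in crosslinked_matches:
        tol_da = m.observed_mz * tolerance * 1e-6 if unit == "ppm" else tolerance
        lo = np.searchsorted(mz, m.observed_mz - tol_da, side="left")
        hi = np.searchsorted(mz, m.observed_mz + tol_da, side="right")
        if hi == lo:
            kept.append(m)
    return kept


def _linear_fragments(
    sequence: str,
    fixed_mods: dict[int, float],
    series: str,
    charges: Sequence[int],
    table: ResidueMassTable,
    label_prefix: str = "",
    suppressed: tuple[int, int] | None = None,
) -> list[tuple[str, float]]:
    """b/y ions of one peptide; ``fixed_mods`` maps 0-based residue index to
    a mass shift; ``suppressed`` is a 0-based [lo, hi) cleavage-index window
    where fragmentation yields no linear ion (unopened looplink ring)."""
    n = len(sequence)
    res = [table.mono(aa) + fixed_mods.get(i, 0.0) for i, aa in enumerate(sequence)]
    prefix = np.cumsum(res)
    total = prefix[-1]
    out = []
    for i in range(1, n):  # cleavage between residue i-1 and i
        if suppressed is not None and suppressed[0] < i <= suppressed[1]:
            continue
        for z in charges:
            if "b" in series:
                out.append((f"{label_prefix}b{i}+{z}", (prefix[i - 1] + z * PROTON) / z))
            if "y" in series:
                neutral = total - prefix[i - 1] + table.water_mono
                out.append((f"{label_prefix}y{n - i}+{z}", (neutral + z * PROTON) / z))
    return out


def fragment_ions(
    product: CrosslinkProduct,
    series: Iterable[str] = ("b", "y"),
    charges: Iterable[int] = (1,),
    xl: CrosslinkerSpec | None = None,
    table: ResidueMassTable | None = None,
) -> list[tuple[str, float]]:
    """Theoretical b/y fragment ions of a crosslink product.

    Dead-ends carry the dead-end mass as a fixed modification on the linked
    residue.  For interlinks, each peptide is fragmented with the *entire*
    partner peptide plus the bridge riding on the linked residue (labels
    prefixed ``A:``/``B:``).  For looplinks, backbone cleavage between the
    two linked residues produces no linear fragment (the ring is not
    opened), so those ions are suppressed and all fragments spanning the
    ring carry the bridge mass.
    """
    series = set(series)
    if not series <= {"b", "y"}:
        raise ValueError(f"unsupported ion series {sorted(series - {'b', 'y'})}")
    table = table or default_mass_table()
    charges = sorted(set(int(z) for z in charges))
    if xl is None:
        from .reference_data import BS3  # default reagent

        xl = BS3

    p1 = product.peptide_1
    if product.kind == "deadend":
        (site,) = product.linked_sites
        mods = {site - p1.start: xl.deadend_mass_mono}
        return _linear_fragments(p1.sequence, mods, series, charges, table)

    if product.kind == "looplink":
        s1, s2 = sorted(product.linked_sites)
        i1, i2 = s1 - p1.start, s2 - p1.start
        mods = {i1: xl.bridge_mass_mono}  # bridge counted once, on the first site
        return _linear_fragments(
            p1.sequence, mods, series, charges, table, suppressed=(i1, i2)
        )

    # interlink: fragment both peptides, partner rides on the link site
    p2 = product.peptide_2
    assert p2 is not None
    s1, s2 = product.linked_sites
    m2 = peptide_mass(p2, table=table)[0]
    m1 = peptide_mass(p1, table=table)[0]
    out = _linear_fragments(
        p1.sequence,
        {s1 - p1.start: m2 + xl.bridge_mass_mono},
        series,
        charges,
        table,
        label_prefix="A:",
    )
    out += _linear_fragments(
        p2.sequence,
        {s2 - p2.start: m1 + xl.bridge_mass_mono},
        series,
        charges,
        table,
        label_prefix="B:",
    )
    return out
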