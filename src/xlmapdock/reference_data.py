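"""Reference inputs for the Mo-MLV integrase NTD dimer analysis.

This module collects, as plain data, the inputs reported for the
BS3-crosslinking analysis of the Moloney murine leukemia virus integrase
N-terminal domain (IN 1-105): the crosslinker definitions, the reported
looplinked and intermolecular crosslinked peptides with their lysine
sites, and the distance restraints used to filter docked dimer poses.

The peptide strings are anchored on their reported lysine numbering, so
site pairs enumerated from them land on the reported residue numbers.
The reported distances are carried along as reference context for the
run report; they are *measured* quantities of the authors' model and are
never used as inputs to any computation here.

The reference crystal structure of the monomer (PDB entry 3NNQ) is not
redistributed; ``load_reference_monomer`` expects it under
``data/reference/`` and ``scripts/fetch_reference.py`` can download it on
a machine with network access.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from pyteomics import mass as _pmass

from .peptide_chem import CrosslinkerSpec, Peptide

__all__ = [
    "BS3",
    "BMOE",
    "BMPEG2",
    "LINKERS",
    "REPORTED_LOOPLINKS",
    "REPORTED_INTERLINKS",
    "DIMER_RESTRAINT_SITE_PAIRS",
    "ReportedLooplink",
    "ReportedInterlink",
    "reference_monomer_path",
    "load_reference_monomer",
]


def _formula_mass(formula: str, average: bool = False) -> float:
    return _pmass.calculate_mass(formula=formula, average=average)


#: BS3 (bis[sulfosuccinimidyl] suberate): amine-reactive NHS ester,
#: 11.4 A spacer; the intact bridge adds a C8H10O2 suberate linkage
#: (+138.068 Da mono), the hydrolysed dead-end additionally one water
#: (+156.0786 Da mono).  21.3 A is the standard productive Cbeta-Cbeta
#: bound for BS3-linked lysines.
BS3 = CrosslinkerSpec(
    name="BS3",
    reactive_residues=frozenset("K"),
    bridge_mass_mono=_formula_mass("C8H10O2"),
    bridge_mass_avg=_formula_mass("C8H10O2", average=True),
    deadend_mass_mono=_formula_mass("C8H12O3"),
    deadend_mass_avg=_formula_mass("C8H12O3", average=True),
    spacer_length=11.4,
    max_site_distance=21.3,
)

# Maleimide cysteine crosslinkers used to discriminate dimer models via a
# K104C mutant.  The zinc-coordinated C94/C96 of the HHCC motif are
# unreactive and excluded.  Bridge/dead-end masses are the full reagent
# adduct; only the geometric fields matter for feasibility analysis.
BMOE = CrosslinkerSpec(
    name="BMOE",
    reactive_residues=frozenset("C"),
    bridge_mass_mono=_formula_mass("C10H8N2O4"),
    bridge_mass_avg=_formula_mass("C10H8N2O4", average=True),
    deadend_mass_mono=_formula_mass("C10H10N2O5"),
    deadend_mass_avg=_formula_mass("C10H10N2O5", average=True),
    spacer_length=8.0,
    max_site_distance=8.0,
    excluded_sites=frozenset({94, 96}),
)

BMPEG2 = CrosslinkerSpec(
    name="BM(PEG)2",
    reactive_residues=frozenset("C"),
    bridge_mass_mono=_formula_mass("C14H16N2O6"),
    bridge_mass_avg=_formula_mass("C14H16N2O6", average=True),
    deadend_mass_mono=_formula_mass("C14H18N2O7"),
    deadend_mass_avg=_formula_mass("C14H18N2O7", average=True),
    spacer_length=14.7,
    max_site_distance=14.7,
    excluded_sites=frozenset({94, 96}),
)

LINKERS = {"bs3": BS3, "bmoe": BMOE, "bmpeg2": BMPEG2}


@dataclass(frozen=True)
class ReportedLooplink:
    peptide: Peptide
    protease: str
    sites: tuple[int, int]
    reported_monomer_distance: float  # Cbeta-Cbeta on the monomer crystal structure, A


@dataclass(frozen=True)
class ReportedInterlink:
    peptide_1: Peptide
    peptide_2: Peptide
    protease: str
    sites: tuple[int, int]
    ambiguous_alternative: tuple[int, int] | None
    reported_model_distance: float  # Cbeta-Cbeta on the authors' dimer model, A


def _pep(sequence: str, start: int) -> Peptide:
    return Peptide(sequence=sequence, start=start, end=start + len(sequence) - 1)


#: Reported intramolecular (looplinked) tryptic peptides of IN 1-105 and
#: the lysine pairs they localize.  Anchors: K88 at the 3rd residue of
#: TLKNITETCKACAQVNASKS, K31 at the 6th of LGAYDKTKK, K95 at the 7th of
#: NITETCKACAQVNASKS.
REPORTED_LOOPLINKS = (
    ReportedLooplink(_pep("TLKNITETCKACAQVNASKS", 86), "trypsin", (88, 95), 15.45),
    ReportedLooplink(_pep("LGAYDKTKK", 26), "trypsin", (31, 33), 7.32),
    ReportedLooplink(_pep("NITETCKACAQVNASKS", 89), "trypsin", (95, 104), 16.15),
    ReportedLooplink(_pep("TLKNITETCKACAQVNASKS", 86), "trypsin", (88, 104), 20.74),
)

#: Reported intermolecular crosslinked peptides of the IN 1-105 dimer.
#: The construct's own numbering places K20 at the 21st residue of the
#: N-terminal peptide, i.e. the reported numbers are offset by one from
#: the printed string; peptides are anchored so their reported site
#: numbers are reproduced (the N-terminal peptide then starts at 0).
REPORTED_INTERLINKS = (
    ReportedInterlink(
        _pep("TVTDIKDLTKLGAIY", 15), _pep("TKL", 23), "chymotrypsin", (24, 24), None, 15.14
    ),
    ReportedInterlink(
        _pep("LGAYDKTK", 26),
        _pep("MIENSSPYTSEHFHYTVTDIKDLTKLGAIYDK", 0),
        "trypsin",
        (31, 20),
        (31, 24),
        20.02,
    ),
    ReportedInterlink(
        _pep("DKTKKY", 30), _pep("TVTDIKDLTKL", 15), "chymotrypsin", (31, 20), None, 20.02
    ),
    ReportedInterlink(
        _pep("MKALLER", 67), _pep("TLKNITETCK", 86), "trypsin", (68, 88), None, 13.57
    ),
)

#: The three intermolecular restraints used to filter dimer poses
#: (Lys20-Lys31, Lys24-Lys24 and Lys68-Lys88, Cbeta-Cbeta <= 21.3 A).
DIMER_RESTRAINT_SITE_PAIRS = ((20, 31), (24, 24), (68, 88))


def reference_monomer_path(root: str | os.PathLike | None = None) -> str:
    """Expected location of the 3NNQ coordinate file (not redistributed).

    Defaults to ``data/reference/3nnq.pdb`` under the repository root
    (the directory containing ``src/``)."""
    if root is None:
        root = os.path.dirname(os.path.dirname(os.path.dirname(os.path.dirname(
            os.path.abspath(__file__)))))
    return os.path.join(os.fspath(root), "data", "reference", "3nnq.pdb")


def load_reference_monomer(root: str | os.PathLike | None = None, chain: str = "A"):
    """Load 3NNQ chain A with selenomethionines edited to methionine.

    Raises FileNotFoundError with fetch instructions when the coordinate
    file has not been downloaded yet.
    """
    from .structure_model import edit_mse_to_met, read_structure

    path = reference_monomer_path(root)
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"reference structure not found at {path}; download PDB entry 3NNQ "
            "with `python scripts/fetch_reference.py` (requires network access) "
            "or place the PDB file there yourself"
        )
    model, _ = edit_mse_to_met(read_structure(path, chain=chain))
    return model
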