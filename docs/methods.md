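# Methods

`xlmapdock` re-implements, as one tested pipeline, the workflow that
turns a lysine-crosslinking mass-spectrometry experiment on a
homodimeric protein into a restraint-filtered rigid-body dimer model:
theoretical crosslinked-peptide enumeration and mass matching, crosslink
site validation on a monomer structure, grid-correlation docking, distance-
restraint pose filtering, rigid-body refinement, model selection, and
interface/orientation analysis. The concrete system it targets is the
N-terminal domain (NTD, residues 1–105) of Moloney murine leukemia virus
integrase, crosslinked with BS³ and modelled on the 3NNQ crystal monomer.

## Crosslink chemistry model

BS³ is a homobifunctional NHS ester reacting with lysine ε-amines
(optionally the protein α-amine; off by default since only lysine links
are reported for this system). Reaction products are classified as

* **dead-end** — one end reacted, the other hydrolysed; adds the bridge
  plus one water, C₈H₁₂O₃ = +156.0786 Da (monoisotopic);
* **looplink** — both ends on lysines of the same peptide; adds the
  intact suberate bridge, C₈H₁₀O₂ = +138.0681 Da;
* **interlink** — the bridge spans two peptides (possibly two copies of
  the same peptide, as for a two-fold-symmetric homodimer site); mass is
  the sum of both peptide masses plus the bridge.

Masses come from pyteomics' standard residue tables; monoisotopic is the
default, average masses are carried in parallel. A crosslinker-modified
lysine is not cleaved by trypsin, so for tryptic peptides a reactive
lysine at the C-terminal cleavage position is excluded as a link site
(it must instead appear as a missed cleavage). Chymotrypsin specificity
is fixed to F/Y/W/L/M with no cleavage before proline; both rules are
cross-checked against pyteomics' cleavage engine in the tests.

Geometric feasibility uses the field-standard Cβ–Cβ upper bound of
**21.3 Å** for BS³ (spacer 11.4 Å); per-linker bounds live on the
`CrosslinkerSpec` (BMOE 8 Å and BM(PEG)₂ 14.7 Å are included for
cysteine crosslinking feasibility analysis, with the zinc-coordinated
C94/C96 excluded as unreactive).

Peak matching computes (M + z·H⁺)/z per charge and accepts peaks within
a ppm or Da tolerance (defaults 20 ppm LC-MS, 0.5 Da MALDI; the source
data state none). With Gaussian mass noise of σ ppm, a tolerance of kσ
recovers 2Φ(k)−1 of true peaks — 95.45 % at 2σ, 98.8 % at 2.5σ — and
the tests assert that binomial model rather than a nominal round
number. Differential analysis removes any match whose observed m/z also
appears in the unmodified control digest, mirroring the
crosslinked-minus-control design. Fragment-ion generation covers b/y
series; interlink fragments carry the whole partner peptide plus bridge
on the linked residue, and looplink fragments between the two linked
residues are suppressed (the ring is not opened by one backbone cleavage).

### Numbering

Peptide positions are in the construct's own coordinates. The reported
peptide strings are anchored on their printed lysine numbers (the
N-terminal peptide then starts at 0 — the construct numbering is offset
by one from the printed string); a configurable integer offset maps
construct numbering onto PDB numbering, which is authoritative for all
structure operations.

## Structure operations

Structures are read with gemmi (PDB/mmCIF, highest-occupancy altlocs,
HETATM selenomethionines retained). `edit_mse_to_met` renames MSE→MET
and SE→SD, reproducing the standard preparation of the 3NNQ chain A
monomer. Link sites resolve to Cβ for lysine restraints (Cα for glycine
or truncated side chains, with a warning), SG for cysteine reagents.
Superposition is least-squares Kabsch (proper rotations only) via
scipy's `Rotation.align_vectors`.

## Docking

The pose generator is a grid-correlation (Katchalski-Katzir-style)
search written here in full:

* **Discretisation.** Atoms fill voxels within their van der Waals
  radius. The static partner is split into a surface layer (weight 1,
  within `surface_thickness` of solvent, via a Euclidean distance
  transform) and a penalised core (ρ = −15); the mobile partner is a
  uniform body of weight 1. Defaults: 1.0 Å spacing, 1.5 Å surface,
  classic values for this algorithm family (the source names the
  algorithm but no parameters).
* **Correlation.** For each rotation the score of *every* integer
  translation is the cross-correlation of the two shape channels,
  computed with forward/inverse real FFTs; a direct-space triple-loop
  oracle verifies equality to 1e-6 in the tests. The cubic box is sized
  to hold both bodies plus the mobile diameter so cyclic wrap-around
  cannot alias genuine contacts.
* **Rotation sweep.** A deterministic Euler-zyz grid (default 15°) with
  quaternion-canonical duplicate pruning. No randomness anywhere in the
  sweep: pose ids are (rotation index, translation index) encodings and
  runs are bit-reproducible.
* **Retention.** The best `keep_per_rotation` translations per rotation
  enter a global ranking; the top `retain` (default **10,000**) poses
  are kept, ranked by shape score with (electrostatic score, pose id)
  tie-breaks. Electrostatics — residue-level formal charges (Lys/Arg +1,
  Asp/Glu −1 on the terminal side-chain position, His 0), screened
  Coulomb q᷊q᷆/(ε(r)·r) with ε(r) = 4r and a 2 Å floor — acts as a
  filter (repulsive poses are deprioritised, never added to the shape
  score). For identical partners, chain-swap (C2) duplicate transforms
  are canonicalised away at grid resolution.

## Restraint filtering, refinement, selection

A `Restraint` is a set of alternative cross-chain residue pairs with an
upper distance bound; a pose survives iff **every** restraint has at
least one alternative within bound (ambiguous assignments such as
31–20/24 are disjunctions; homodimer restraints are measured in both
chain orders). Filtering is vectorised over the whole pose set and, as a
pure conjunction, order-independent.

Survivors are selected coarse-to-fine: a vectorised single-point
interaction energy screens every survivor; the best `n_refine` are then
refined in the six rigid-body degrees of freedom (bounded L-BFGS on a
soft-core 12-6 potential, ε = 0.1 kcal/mol, σ = 3.4 Å, λ = 1 Å²
softening, 10 Å cutoff, plus the screened Coulomb term). The soft-core
pair optimum is analytic, r* = √(σ²·2^⅓ − λ) ≈ 3.68 Å, and the
refinement test drives a two-atom system onto it. Because tightly packed
helical interfaces have register-periodic near-native minima, the
refiner also restarts from ±4.5 Å offsets perpendicular to the
centroid–centroid axis and keeps the deepest result. Restraints are
re-checked after refinement. Side-chain repacking is deliberately out of
scope — the selection signal here is rigid-body level, and the soft core
stands in for side-chain give.

The selected model is the minimum-energy refined pose; exact energy ties
break toward larger buried surface area, then pose id. An empty
surviving set is a distinguished outcome (pipeline exit code 2), not an
error.

## Interface analysis

Solvent accessibility is Shrake–Rupley sphere-point sampling written
here (960 points/atom on a deterministic Fibonacci spiral, probe 1.4 Å,
element-based van der Waals radii): ΔASA = ASA(A) + ASA(B) − ASA(AB),
per-residue burials above a 0.1 Å² reporting floor define the interface
residue lists, and residue contact pairs use a 4.5 Å atom-atom cutoff.
The tests pin the implementation to the closed-form single-sphere area
and the two-sphere buried-cap formula (within 5 %), and to <0.5 % drift
under a common rigid transform.

Orientation is classified from the chains' end-to-end Cα vectors over
their shared residue span: angle < 90° ⇒ parallel. The report also
carries a C2-axis residual (how far the A→B superposition transform is
from an exact two-fold, as the RMSD of applying it twice).

## Synthetic data: what it emulates and what it does not

The generator builds an idealised α-helical bundle (1.5 Å rise,
100°/residue, pseudo-Cβ 1.53 Å radially out from Cα; helices on a 9 Å
square lattice, 2×2 for the default four-helix bundle) of **4 × 24 = 96
residues — deliberately the size of the 95-residue integrase NTD
construct, so the 21.3 Å restraint bound carries comparable
information**. Coordinates get 0.15 Å Gaussian jitter; sequences avoid
proline, put R at helix ends and Y/F mid-helix so both proteases cut.

Two design choices matter for interpreting the recovery results:

* **Charged interface ladders.** Outward-facing surface positions carry
  lysines and glutamates following a fixed aperiodic, anti-palindromic
  sign code over 3 Å height buckets (one face the code, the opposite
  face its negation). Exactly one register of any face-to-face contact —
  a parallel slide or an antiparallel flip — pairs every K with an E.
  This mirrors the modelled system, whose dimer interface is reported to
  be stabilised by electrostatic and van der Waals contacts, and it
  gives the scoring problem a well-defined answer: a neutral reduced
  model has register-degenerate packing minima that *no* selection
  energy could tell apart, which is a property of the CA/CB
  representation, not of the pipeline under test.
* **Relaxed planting.** The planted chain-B transform is the
  lowest-energy clash-free contact over the bundle's faces and several
  register offsets, each relaxed by the same rigid-body minimiser the
  pipeline uses (a redocking design: the target sits in a genuine
  minimum of the energy surface, as a real complex sits in a minimum of
  its real one).

Simulated observations digest the sequence (trypsin, ≤2 missed
cleavages), emit [M+H]⁺ control peaks for the plain digest, add every
enumerated looplink/interlink compatible with the planted geometry at
the linker bound, then Gaussian ppm mass noise (default 20 ppm) and
uniform decoy peaks (default 0.2 per true peak). A truth table maps
every planted peak to its product. All outputs are pure functions of the
seed.

What passing the recovery test therefore shows: the sweep covers the
relevant pose space, the restraint filter and energy screen surface the
right candidates, refinement converges into the planted basin, and the
selection and orientation calls are correct — on a reduced-representation
body with an electrostatically self-complementary interface. What it
does not show: performance on all-atom surfaces with flexible side
chains, crystallographic waters, or interfaces whose signature is purely
steric; nor anything about MS/MS spectrum-level identification, which is
out of scope throughout.

## Desk-scale study settings

The planted-dimer study (`RECOVERY_DOCK_SETTINGS`) uses a 1.5 Å grid,
30° rotation sweep (the grid contains the exact 180° flip), bead radius
2.6 Å for the CA/CB toys, 20,000 retained poses with no electrostatic
discard (reduced-model charges are too sparse for that filter to be
meaningful — it would discard the lysine-bearing planted interface),
energy screening of all survivors and register-scan refinement of the
top 8. One replicate runs in ~20 s; the 20-seed study reported by
`analysis/03_synthetic_recovery.py` recovers the planted transform
within 5 Å ligand-RMSD (chain-swap allowed, CAPRI-style "acceptable"
scale) in 20/20 runs with 20/20 orientation agreement.

## Numerical and degenerate-input conventions

* Correlation scores are rounded to 1e-6 before ranking so FFT noise
  cannot perturb tie-breaking; all orderings end in the deterministic
  pose id.
* Distances are reported to 2 decimals, matching the precision of the
  reported tables.
* Glycine and truncated side chains fall back Cβ→Cα (with a warning for
  the latter); a residue missing from a chain raises.
* Zero restraints filter nothing (vacuous conjunction); an identical-site
  pair (K24–K24 style) is always classified requires-intermolecular.
* The 4999.5366 m/z species reported for the tryptic dimer digest is not
  treated as ground truth: it is not recovered by summing the reported
  peptide sequences plus the bridge, consistent with an unpublished
  purification-tag sequence on the construct; any such mismatch is
  flagged rather than asserted.

## Known limitations

* The refinement potential is a declared stand-in for the original
  suite's interface refinement; "most stable interface" is defined here
  as minimum soft-core + screened-Coulomb energy. Reported
  model-dependent quantities (exact interface ΔASA of 484 Å², 16/17
  interface residue counts, the 15.14/20.02/13.57 Å model distances,
  PISA solvation ΔG) depend on the authors' unshipped coordinates and
  are carried as reference context only.
* Rigid bodies throughout: no side-chain repacking, no backbone
  flexibility, no solvation term.
* The deposited 3NNQ coordinates are not redistributed; the three
  structure-dependent checks require a one-time fetch
  (`scripts/fetch_reference.py`).
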