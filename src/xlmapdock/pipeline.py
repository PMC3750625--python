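"""End-to-end orchestration: config validation, the staged run
(enumerate -> match -> classify -> dock -> filter -> refine -> select ->
interface), and the synthetic planted-dimer recovery experiment.

A run is a pure function of its config (the docking sweep is
deterministic), so identical configs produce identical artifacts.
The distinguished no-restraint-compatible-pose outcome is reported with
exit code 2 rather than raised.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tomllib
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from . import peptide_chem as pc
from . import reference_data as refdata
from .docking import DockSettings, PoseSet, generate_poses
from .restraint_select import (
    FilterReport,
    InterfaceReport,
    apply_restraints,
    interface_metrics,
    pose_energy,
    refine_pose,
    select_model,
)
from .structure_model import (
    ChainModel,
    LinkSite,
    Restraint,
    classify_crosslinks,
    edit_mse_to_met,
    read_structure,
    site_distance,
    write_pdb,
)
from .synthetic_data import ToySpec, make_toy_monomer, make_true_dimer

__all__ = [
    "PipelineConfig",
    "RunReport",
    "validate_config",
    "load_config",
    "run_pipeline",
    "ligand_rmsd",
    "recovery_experiment",
]


@dataclass
class PipelineConfig:
    structure_path: str
    output_dir: str
    sequence_path: str | None = None
    crosslinked_peaks_path: str | None = None
    control_peaks_path: str | None = None
    restraints_path: str | None = None
    chain: str | None = None
    protease: str = "trypsin"
    max_missed: int = 2
    linker: str = "bs3"
    tolerance: float = 0.5
    tolerance_unit: str = "Da"
    charges: tuple[int, ...] = (1,)
    numbering_offset: int = 0
    max_restraint_distance: float | None = None
    n_refine: int = 10
    seed: int = 0
    dock: DockSettings = field(default_factory=DockSettings)


@dataclass
class RunReport:
    config: PipelineConfig
    exit_code: int
    outcome: str
    stage_counts: dict[str, int]
    looplink_table: pd.DataFrame | None = None
    interlink_table: pd.DataFrame | None = None
    filter_report: FilterReport | None = None
    interface: InterfaceReport | None = None
    selected_pose_id: int | None = None
    artifacts: dict[str, str] = field(default_factory=dict)


def load_config(path) -> PipelineConfig:
    """Read a TOML config; the [dock] table maps onto DockSettings."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    dock = DockSettings(**raw.pop("dock", {}))
    if "charges" in raw:
        raw["charges"] = tuple(raw["charges"])
    return PipelineConfig(dock=dock, **raw)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems; empty means runnable."""
    problems = []
    if not config.structure_path:
        problems.append("structure_path: missing")
    elif not os.path.exists(config.structure_path):
        problems.append(f"structure_path: file not found ({config.structure_path})")
    for name in ("sequence_path", "crosslinked_peaks_path", "control_peaks_path",
                 "restraints_path"):
        value = getattr(config, name)
        if value and not os.path.exists(value):
            problems.append(f"{name}: file not found ({value})")
    if config.tolerance <= 0:
        problems.append("tolerance: must be positive")
    if config.linker.lower() not in refdata.LINKERS:
        problems.append(f"linker: unknown ({config.linker}); choose from {sorted(refdata.LINKERS)}")
    if config.protease not in pc.PROTEASES:
        problems.append(f"protease: unknown ({config.protease})")
    if config.dock.retain < 1:
        problems.append("dock.retain: must be >= 1")
    if not config.crosslinked_peaks_path and not config.restraints_path:
        problems.append("need either crosslinked_peaks_path (MS route) or restraints_path (bypass)")
    return problems


def _read_fasta(path) -> str:
    from Bio import SeqIO

    record = next(SeqIO.parse(path, "fasta"))
    return str(record.seq).upper()


def read_restraints_tsv(path, default_max: float) -> list[Restraint]:
    """Restraint TSV: columns site_a, site_b, optional max_dist, alt_sites.

    ``alt_sites`` encodes ambiguity as slash-separated alternatives for
    site_b (e.g. ``20/24``)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, row in df.iterrows():
        max_d = float(row["max_dist"]) if "max_dist" in df.columns and pd.notna(row.get("max_dist")) else default_max
        extra = []
        if "alt_sites" in df.columns and pd.notna(row.get("alt_sites")):
            for alt in str(row["alt_sites"]).split("/"):
                alt = alt.strip()
                if alt:
                    extra.append((int(row["site_a"]), int(alt)))
        out.append(
            Restraint.homodimer(int(row["site_a"]), int(row["site_b"]), max_d,
                                extra_alternatives=extra)
        )
    return out


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full crosslink-guided docking pipeline.

    MS stages run when peak lists are supplied; otherwise restraints are
    read from a TSV (the documented bypass).  The final report carries a
    looplink-style table (intra-chain pairs with monomer distances) and
    an interlink-style table (restraint pairs with distances on the
    selected dimer model).
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    os.makedirs(config.output_dir, exist_ok=True)
    xl = refdata.LINKERS[config.linker.lower()]
    max_dist = config.max_restraint_distance or xl.max_site_distance
    counts: dict[str, int] = {}
    artifacts: dict[str, str] = {}

    monomer = read_structure(config.structure_path, chain=config.chain)
    monomer, n_mse = edit_mse_to_met(monomer)
    counts["mse_edited"] = n_mse
    offset = config.numbering_offset

    looplink_df = None
    interlink_pairs: list[tuple[int, int]] = []
    if config.crosslinked_peaks_path:
        sequence = _read_fasta(config.sequence_path)
        peptides = pc.digest(sequence, config.protease, config.max_missed)
        products = pc.enumerate_products(
            peptides, xl, kinds=("looplink", "interlink"),
            protease=config.protease, parent_end=len(sequence),
        )
        counts["peptides"] = len(peptides)
        counts["products_enumerated"] = len(products)
        peaks = pc.PeakList.read(config.crosslinked_peaks_path)
        matches = pc.match_peaks(products, peaks, config.tolerance,
                                 unit=config.tolerance_unit, charges=config.charges)
        counts["matches"] = len(matches)
        if config.control_peaks_path:
            control = pc.PeakList.read(config.control_peaks_path)
            matches = pc.differential_products(matches, control, config.tolerance,
                                               unit=config.tolerance_unit)
        counts["differential_matches"] = len(matches)
        match_df = pd.DataFrame(
            [
                {
                    "kind": m.product.kind,
                    "pep1": m.product.peptide_1.sequence,
                    "pep2": m.product.peptide_2.sequence if m.product.peptide_2 else "",
                    "site_1": m.product.site_pair[0], "site_2": m.product.site_pair[-1],
                    "neutral_mono": round(m.product.neutral_mass_mono, 4),
                    "theo_mz": round(m.theoretical_mz, 4),
                    "obs_mz": round(m.observed_mz, 4),
                    "error_ppm": round(m.error_ppm, 2),
                }
                for m in matches
            ]
        )
        artifacts["matches"] = os.path.join(config.output_dir, "matches.tsv")
        match_df.to_csv(artifacts["matches"], sep="\t", index=False)

        unique_pairs = sorted({(m.product.site_pair[0], m.product.site_pair[-1])
                               for m in matches})
        pdb_pairs = [(a + offset, b + offset) for a, b in unique_pairs]
        classification = classify_crosslinks(pdb_pairs, monomer, xl)
        class_df = pd.DataFrame(classification)
        artifacts["classification"] = os.path.join(config.output_dir, "classification.tsv")
        class_df.to_csv(artifacts["classification"], sep="\t", index=False)
        counts["site_pairs"] = len(classification)
        looplink_df = class_df[class_df["label"] == "monomer-compatible"].copy()
        interlink_pairs = [
            (row["site_1"], row["site_2"]) for row in classification
            if row["label"] != "monomer-compatible"
        ]
        restraints = [Restraint.homodimer(a, b, max_dist) for a, b in interlink_pairs]
    else:
        restraints = read_restraints_tsv(config.restraints_path, max_dist)
        restraints = [
            dataclasses.replace(
                r, alternatives=tuple((a + offset, b + offset) for a, b in r.alternatives)
            )
            for r in restraints
        ]
        interlink_pairs = [r.alternatives[0] for r in restraints]
    counts["restraints"] = len(restraints)

    poses = generate_poses(monomer, monomer, config.dock)
    counts["poses_generated"] = len(poses)
    pose_df = pd.DataFrame(poses.to_records())
    artifacts["poses"] = os.path.join(config.output_dir, "poses.tsv")
    pose_df.to_csv(artifacts["poses"], sep="\t", index=False)

    survivors, filter_report = apply_restraints(poses, restraints)
    counts["poses_surviving"] = len(survivors)

    if len(survivors) == 0:
        report = RunReport(
            config=config, exit_code=2, outcome="no restraint-compatible pose",
            stage_counts=counts, looplink_table=looplink_df,
            filter_report=filter_report, artifacts=artifacts,
        )
        _write_text_report(report, restraints, None)
        return report

    # coarse-then-fine shortlist: single-point energy screen of every
    # survivor, full rigid-body refinement of the best candidates
    to_refine = sorted(
        survivors.poses,
        key=lambda p: (pose_energy(p, monomer, monomer), p.pose_id),
    )[: config.n_refine]
    refined = [refine_pose(p, poses.static, poses.mobile) for p in to_refine]
    # re-check restraints after the rigid-body minimisation
    recheck = PoseSet(static=poses.static, mobile=poses.mobile,
                      poses=[r.pose for r in refined], settings=poses.settings)
    ok_set, _ = apply_restraints(recheck, restraints)
    ok_ids = {p.pose_id for p in ok_set.poses}
    refined_ok = [r for r in refined if r.pose.pose_id in ok_ids]
    for r in refined:
        r.restraints_ok = r.pose.pose_id in ok_ids
    counts["poses_refined_ok"] = len(refined_ok)
    if not refined_ok:
        report = RunReport(
            config=config, exit_code=2,
            outcome="no pose satisfies restraints after refinement",
            stage_counts=counts, looplink_table=looplink_df,
            filter_report=filter_report, artifacts=artifacts,
        )
        _write_text_report(report, restraints, None)
        return report

    complex_, chosen = select_model(refined_ok, poses.static, poses.mobile)
    artifacts["selected_pdb"] = os.path.join(config.output_dir, "selected.pdb")
    write_pdb(artifacts["selected_pdb"], [complex_.chain_a, complex_.chain_b])

    interlink_df = pd.DataFrame(
        [
            {
                "site_1": a, "site_2": b,
                "model_distance": round(min(
                    site_distance(complex_, LinkSite("A", a), LinkSite("B", b)),
                    site_distance(complex_, LinkSite("A", b), LinkSite("B", a)),
                ), 2),
                "max_dist": max_dist,
            }
            for a, b in interlink_pairs
        ]
    )
    iface = interface_metrics(complex_)
    artifacts["interface"] = os.path.join(config.output_dir, "interface.json")
    with open(artifacts["interface"], "w") as fh:
        json.dump(
            {
                "delta_asa": round(iface.delta_asa, 1),
                "n_interface_residues_a": iface.n_interface_a,
                "n_interface_residues_b": iface.n_interface_b,
                "interface_residues_a": iface.interface_residues_a,
                "interface_residues_b": iface.interface_residues_b,
                "orientation": iface.orientation_label,
                "orientation_angle_deg": round(iface.orientation_angle, 1),
                "c2_residual": round(iface.c2_residual, 2),
            },
            fh, indent=2,
        )

    report = RunReport(
        config=config, exit_code=0, outcome="model selected",
        stage_counts=counts, looplink_table=looplink_df, interlink_table=interlink_df,
        filter_report=filter_report, interface=iface,
        selected_pose_id=chosen.pose.pose_id, artifacts=artifacts,
    )
    _write_text_report(report, restraints, interlink_df)
    return report


def _write_text_report(report: RunReport, restraints, interlink_df) -> None:
    path = os.path.join(report.config.output_dir, "report.txt")
    lines = ["crosslink-guided docking run", "=" * 32, ""]
    lines.append(f"outcome: {report.outcome} (exit code {report.exit_code})")
    lines.append("")
    lines.append("stage counts:")
    for k, v in report.stage_counts.items():
        lines.append(f"  {k}: {v}")
    if report.looplink_table is not None and len(report.looplink_table):
        lines += ["", "monomer-compatible (looplink) pairs:",
                  report.looplink_table.to_string(index=False)]
    if interlink_df is not None and len(interlink_df):
        lines += ["", "intermolecular restraints on the selected model:",
                  interlink_df.to_string(index=False)]
    if report.interface is not None:
        i = report.interface
        lines += [
            "",
            f"interface: dASA {i.delta_asa:.1f} A^2, "
            f"{i.n_interface_a}+{i.n_interface_b} interface residues, "
            f"{i.orientation_label} ({i.orientation_angle:.1f} deg), "
            f"C2 residual {i.c2_residual:.2f} A",
        ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    report.artifacts["report"] = path


# ---------------------------------------------------------------------------
# Synthetic recovery experiment

#: desk-scale sweep used for the planted-dimer recovery study: coarse
#: 30-degree rotations (the grid contains the exact 180-degree flip),
#: 1.5 A grid, bead-like atom radii suited to the CA/CB toy models.
RECOVERY_DOCK_SETTINGS = DockSettings(
    spacing=1.5, angle_step=30.0, retain=20000, atom_radius=2.6,
    keep_per_rotation=200, margin=4.0, dedup_c2=False,
    # residue-level charges on a reduced CA/CB toy are too sparse for the
    # repulsive-pose discard to be meaningful (a planted lysine-bearing
    # interface would be thrown away); keep all poses, ranked by shape
    discard_repulsive=False,
)


def ligand_rmsd(
    mobile: ChainModel, pose_transform, truth_transform, allow_swap: bool = True
) -> float:
    """RMSD of the mobile chain's CA trace between a pose and the truth.

    The static chains are identical by construction, so this is the
    CAPRI-style ligand RMSD.  For a homodimer the chain-swap equivalent
    of the truth (the inverse transform) is also accepted.
    """
    X = mobile.coords_of("CA")
    d1 = pose_transform.apply(X) - truth_transform.apply(X)
    best = float(np.sqrt((d1 ** 2).sum(axis=1).mean()))
    if allow_swap:
        d2 = pose_transform.apply(X) - truth_transform.inverse().apply(X)
        best = min(best, float(np.sqrt((d2 ** 2).sum(axis=1).mean())))
    return best


def recovery_experiment(
    spec: ToySpec,
    dock_settings: DockSettings = RECOVERY_DOCK_SETTINGS,
    n_restraints: int = 3,
    n_refine: int = 8,
    rmsd_threshold: float = 5.0,
    xl=None,
) -> dict:
    """Plant a dimer, dock with crosslink restraints, and score recovery.

    The ``n_restraints`` shortest distinct inter-chain lysine pairs of
    the planted complex serve as (correct) restraints at the linker's
    distance bound.  Recovery succeeds when the selected pose is within
    ``rmsd_threshold`` ligand-RMSD of the planted transform (chain-swap
    allowed).
    """
    xl = xl or refdata.BS3
    sequence, monomer = make_toy_monomer(spec)
    complex_, truth = make_true_dimer(
        monomer, orientation=spec.orientation,
        contact_distance=spec.contact_distance, crosslink_cutoff=xl.max_site_distance,
    )
    # restraint choice mimics informative crosslink data: the pairs whose
    # true distance sits close under the bound carry the most register
    # information (a short pair leaves the bound slack and excludes little);
    # a 2.5 A safety margin keeps grid-resolution near-native poses inside.
    # Greedy spread over unused lysine sites pins the whole interface.
    eligible = [p for p in truth.crosslinkable_pairs
                if p[2] <= xl.max_site_distance - 2.5]
    pairs = sorted(eligible or truth.crosslinkable_pairs,
                   key=lambda p: (-p[2], p[0], p[1]))
    chosen_pairs: list[tuple[int, int]] = []
    used_sites: set[int] = set()
    for prefer_fresh in (True, False):
        for i, j, _ in pairs:
            if len(chosen_pairs) >= n_restraints:
                break
            key = (min(i, j), max(i, j))
            if key in chosen_pairs:
                continue
            if prefer_fresh and ({i, j} & used_sites):
                continue
            chosen_pairs.append(key)
            used_sites.update((i, j))
    restraints = [
        Restraint.homodimer(a, b, xl.max_site_distance) for a, b in chosen_pairs
    ]

    poses = generate_poses(monomer, monomer, dock_settings)
    survivors, filter_report = apply_restraints(poses, restraints)
    result = {
        "seed": spec.seed,
        "orientation_true": truth.orientation,
        "n_restraints": len(restraints),
        "n_poses": len(poses),
        "n_survivors": len(survivors),
        "recovered": False,
        "ligand_rmsd": float("nan"),
        "orientation_pred": None,
        "orientation_match": False,
    }
    if len(survivors) == 0:
        return result
    # coarse-then-fine: vectorised single-point energy screen of every
    # survivor, then register-scan rigid-body refinement of the best
    from .restraint_select import pose_energies, refine_pose_multistart

    energies = pose_energies(survivors.poses, monomer, monomer)
    order = np.lexsort((np.array([p.pose_id for p in survivors.poses]), energies))
    shortlist = [survivors.poses[i] for i in order[:n_refine]]
    refined = [refine_pose_multistart(p, monomer, monomer) for p in shortlist]
    recheck = PoseSet(static=monomer, mobile=monomer,
                      poses=[r.pose for r in refined], settings=poses.settings)
    ok_set, _ = apply_restraints(recheck, restraints)
    ok_ids = {p.pose_id for p in ok_set.poses}
    refined_ok = [r for r in refined if r.pose.pose_id in ok_ids] or refined
    complex_sel, chosen = select_model(refined_ok, monomer, monomer)
    lrmsd = ligand_rmsd(monomer, chosen.pose.transform, truth.transform)
    from .restraint_select import classify_orientation

    final_set = PoseSet(static=monomer, mobile=monomer, poses=[chosen.pose],
                        settings=poses.settings)
    _, final_report = apply_restraints(final_set, restraints)
    worst = final_report.worst_distance.get(chosen.pose.pose_id, float("nan"))
    label, angle, _ = classify_orientation(complex_sel)
    result.update(
        recovered=bool(lrmsd <= rmsd_threshold),
        ligand_rmsd=round(lrmsd, 2),
        orientation_pred=label,
        orientation_angle=round(angle, 1),
        orientation_match=(label == truth.orientation),
        selected_pose_id=chosen.pose.pose_id,
        selected_worst_restraint=round(float(worst), 2),
    )
    return result
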