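"""End-to-end analysis runs: config → structures → tables → report.

A :class:`RunConfig` (built directly or loaded from YAML) names either a
synthetic system (sequence, fiber form, PS sites, trajectory recipe) or
input PDB files.  :func:`run_analysis` produces an :class:`AnalysisReport`
holding every table the conformational analysis generates — per-step
helical parameters with distribution summaries, torsion/pucker tables,
backbone-substate populations, RMSD/RMSF, inter-strand phosphate
distances, clustering and the A/B form call — and writes them as CSV/JSON
artifacts.  Runs are deterministic given the seed; the log records a
config hash.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .backbone import torsion_table
from .core import Structure, Trajectory
from .ensemble import (distribution_summary, gromos_cluster,
                       interstrand_p_distances, rmsd_series, rmsf)
from .fiber import FORMS, SequenceSpec, build_duplex, duplex_pairing
from .frames import pair_frames_for
from .helical import (HELICAL_COLUMNS, STEP_COLUMNS, classify_form,
                      interior_steps, steps_table)
from .pdbio import read_pdb
from .simulate import TrajectorySpec, TwoStateSpec, generate_trajectory

ALL_PARAMS = STEP_COLUMNS + HELICAL_COLUMNS


@dataclass
class RunConfig:
    """Validated run recipe; see ``from_yaml`` for the file layout."""

    sequence: Optional[str] = None
    strand1_type: str = "DNA"
    strand2_type: str = "DNA"
    form: str = "B"
    ps_sites: Tuple[Tuple[str, int], ...] = ()
    structure_path: Optional[str] = None
    trajectory_path: Optional[str] = None
    n_frames: int = 0
    sigma: Dict[str, float] = field(default_factory=dict)
    twist_two_state: Optional[Dict] = None
    seed: int = 0
    cluster_cutoff_nm: float = 0.2
    cluster_selection: str = "heavy"
    strict_incl: bool = False
    compare_natural: bool = False
    output_dir: Optional[str] = None

    def __post_init__(self):
        if self.sequence is None and self.structure_path is None and \
                self.trajectory_path is None:
            raise ValueError("config needs a sequence or an input file")
        if self.sequence is not None and self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}")
        if self.n_frames < 0:
            raise ValueError("n_frames must be >= 0")
        self.ps_sites = tuple((str(s), int(i)) for s, i in self.ps_sites)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sys_cfg = raw.get("system", {})
        traj = raw.get("trajectory", {})
        clus = raw.get("clustering", {})
        thr = raw.get("thresholds", {})
        return cls(
            sequence=sys_cfg.get("sequence"),
            strand1_type=sys_cfg.get("strand1_type", "DNA"),
            strand2_type=sys_cfg.get("strand2_type", "DNA"),
            form=sys_cfg.get("form", "B"),
            ps_sites=tuple(tuple(x) for x in sys_cfg.get("ps_sites", [])),
            structure_path=raw.get("input", {}).get("structure"),
            trajectory_path=raw.get("input", {}).get("trajectory"),
            n_frames=traj.get("n_frames", 0),
            sigma=traj.get("sigma", {}),
            twist_two_state=traj.get("twist_two_state"),
            seed=raw.get("seed", 0),
            cluster_cutoff_nm=clus.get("cutoff_nm", 0.2),
            cluster_selection=clus.get("selection", "heavy"),
            strict_incl=thr.get("strict_incl", False),
            compare_natural=raw.get("compare_natural", False),
            output_dir=raw.get("output_dir"),
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    helical: pd.DataFrame                 # (frame, step) x ten parameters
    summaries: pd.DataFrame               # per-step, per-parameter DistSummary
    torsions: pd.DataFrame                # (frame, strand, residue) torsions/puckers
    substate_populations: pd.DataFrame    # BI/BII and alpha/gamma fractions
    rmsd: pd.DataFrame
    rmsf: pd.DataFrame
    p_distances: pd.DataFrame
    cluster_assignments: pd.DataFrame
    form_call: Dict
    paired_deltas: Optional[pd.DataFrame]
    log: Dict


def _resolve_inputs(config: RunConfig):
    if config.sequence is not None:
        seq = SequenceSpec(config.sequence, config.strand1_type,
                           config.strand2_type,
                           ps_sites=frozenset(config.ps_sites))
        structure = build_duplex(seq, FORMS[config.form])
        pairing = duplex_pairing(seq)
    else:
        obj = read_pdb(config.trajectory_path or config.structure_path)
        if isinstance(obj, Trajectory):
            return obj.topology, obj, None
        structure, pairing = obj, None
    if config.n_frames > 0:
        ts = None
        if config.twist_two_state:
            t = dict(config.twist_two_state)
            ts = TwoStateSpec(low_mean=t["low_mean"], high_mean=t["high_mean"],
                              switch_prob=t["switch_prob"],
                              steps=frozenset(t["steps"]))
        spec = TrajectorySpec(n_frames=config.n_frames, sigma=dict(config.sigma),
                              twist_two_state=ts, seed=config.seed)
        traj = generate_trajectory(structure, spec, pairing=pairing)
    else:
        traj = Trajectory(frames=[structure])
    return structure, traj, pairing


def _helical_tables(traj: Trajectory, pairing) -> pd.DataFrame:
    rows = []
    for f_idx, frame in enumerate(traj.frames):
        pf = pair_frames_for(frame, pairing)
        t = steps_table(pf)
        t.insert(0, "frame", f_idx)
        rows.append(t)
    return pd.concat(rows, ignore_index=True)


def _summaries(helical: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for step, grp in helical.groupby("step"):
        for param in ALL_PARAMS:
            s = distribution_summary(grp[param].to_numpy())
            rows.append({
                "step": step, "parameter": param, "mean": s.mean, "sd": s.sd,
                "bimodal": s.bimodal,
                "component_low": s.component_means[0] if s.bimodal else np.nan,
                "component_high": s.component_means[1] if s.bimodal else np.nan,
            })
    return pd.DataFrame(rows)


def _torsion_tables(traj: Trajectory) -> pd.DataFrame:
    rows = []
    for f_idx, frame in enumerate(traj.frames):
        t = torsion_table(frame)
        t.insert(0, "frame", f_idx)
        rows.append(t)
    return pd.concat(rows, ignore_index=True)


def _populations(torsions: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (strand, res), grp in torsions.groupby(["strand", "residue"]):
        n = len(grp)
        row = {"strand": strand, "residue": res,
               "BI": (grp.bi_bii == "BI").sum() / n,
               "BII": (grp.bi_bii == "BII").sum() / n}
        ag = grp.alpha_gamma.value_counts(normalize=True)
        row["ag_canonical"] = float(ag.get("g-/g+", 0.0))
        row["ag_top_state"] = ag.index[0] if len(ag) else None
        pk = grp.pucker_name.value_counts(normalize=True)
        row["pucker_top"] = pk.index[0] if len(pk) else None
        row["c2_endo_family"] = float(sum(
            frac for name, frac in pk.items()
            if name in ("C2'-endo", "C3'-exo", "C1'-exo")))
        rows.append(row)
    return pd.DataFrame(rows)


def run_analysis(config: RunConfig) -> AnalysisReport:
    """Execute the full conformational analysis for one configuration."""
    t0 = time.time()
    timings = {}
    structure, traj, pairing = _resolve_inputs(config)
    if pairing is None:
        from .frames import detect_pairing
        pairing = detect_pairing(structure)
    timings["inputs"] = time.time() - t0

    t1 = time.time()
    helical = _helical_tables(traj, pairing)
    summaries = _summaries(helical)
    timings["helical"] = time.time() - t1

    t2 = time.time()
    torsions = _torsion_tables(traj)
    populations = _populations(torsions)
    timings["backbone"] = time.time() - t2

    t3 = time.time()
    rmsd = pd.DataFrame({"frame": range(traj.n_frames),
                         "rmsd_P": rmsd_series(traj, structure, "P")})
    fluct = rmsf(traj, "heavy")
    pdist = interstrand_p_distances(traj, pairing)
    cluster = gromos_cluster(traj, config.cluster_cutoff_nm,
                             config.cluster_selection)
    cluster_df = pd.DataFrame({"frame": range(traj.n_frames),
                               "cluster": cluster.assignments})
    timings["ensemble"] = time.time() - t3

    mean_interior = interior_steps(
        helical.groupby("step")[ALL_PARAMS].mean().reset_index())
    pucker_names = torsions["pucker_name"].dropna().tolist()
    call = classify_form(mean_interior, pucker_names,
                         strict_incl=config.strict_incl)
    form_call = {"label": call.label, "means": call.means}

    paired_deltas = None
    if config.compare_natural and config.sequence is not None:
        natural = RunConfig(**{**config.__dict__, "ps_sites": (),
                               "compare_natural": False, "output_dir": None})
        nat_report = run_analysis(natural)
        mine = helical.groupby("step")[ALL_PARAMS].mean()
        theirs = nat_report.helical.groupby("step")[ALL_PARAMS].mean()
        delta = (mine - theirs).reset_index().melt(
            id_vars="step", var_name="parameter", value_name="delta")
        paired_deltas = delta

    log = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_frames": traj.n_frames,
        "n_pairs": len(pairing),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    report = AnalysisReport(
        helical=helical, summaries=summaries, torsions=torsions,
        substate_populations=populations, rmsd=rmsd, rmsf=fluct,
        p_distances=pdist, cluster_assignments=cluster_df,
        form_call=form_call, paired_deltas=paired_deltas, log=log,
    )
    if config.output_dir:
        _write_artifacts(report, Path(config.output_dir))
    return report


def _write_artifacts(report: AnalysisReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.helical.to_csv(outdir / "helical_params.csv", index=False)
    report.summaries.to_csv(outdir / "helical_summaries.csv", index=False)
    report.torsions.to_csv(outdir / "torsions.csv", index=False)
    report.substate_populations.to_csv(outdir / "substate_populations.csv",
                                       index=False)
    report.rmsd.to_csv(outdir / "rmsd.csv", index=False)
    report.rmsf.to_csv(outdir / "rmsf.csv", index=False)
    report.p_distances.to_csv(outdir / "p_distances.csv", index=False)
    report.cluster_assignments.to_csv(outdir / "clusters.csv", index=False)
    if report.paired_deltas is not None:
        report.paired_deltas.to_csv(outdir / "ps_vs_natural_deltas.csv",
                                    index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump({"form_call": report.form_call, "log": report.log}, fh,
                  indent=2, default=float)
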