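"""Orchestration: analysis configuration, per-trajectory standard errors,
and the end-to-end pipeline that runs structure -> binding -> bilayer ->
clustering on a system and writes tabular artifacts.

Every reported quantity that the analyses express as "value +/- error" is
emitted as an (estimate, SE, n_trajectories) triple; the trajectory -- not
the peptide copy -- is the independent-sample unit, so both copies within a
trajectory contribute to that trajectory's single mean.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import binding as _binding
from . import bilayer as _bilayer
from . import clustering as _clustering
from . import peptide as _peptide
from .core import TrajectorySet, load_system, peptide_views

logger = logging.getLogger("membind")


@dataclass
class AnalysisConfig:
    """Analysis parameters; the defaults are the conventional values."""

    contact_cutoff: float = 4.5      # A, heavy-atom contact
    hbond_distance: float = 3.5      # A, donor-acceptor
    hbond_angle: float = 120.0       # deg, D-H-A
    surface_margin: float = 6.5      # A above z_P
    r_c: float = 13.0                # A, binding footprint radius
    rmsd_cutoff: float = 5.4         # A, Daura clustering
    cluster_stride: int = 10         # every 10th structure
    populated_threshold: float = 0.01
    grid_dr: float = 1.0             # A
    grid_dz: float = 1.0             # A
    window_fraction: float = 1.0     # trailing fraction of frames analyzed
    seed: int = 0

    def __post_init__(self):
        for name in ("contact_cutoff", "hbond_distance", "hbond_angle",
                     "surface_margin", "r_c", "rmsd_cutoff", "grid_dr",
                     "grid_dz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.window_fraction <= 1:
            raise ValueError("window_fraction must be in (0, 1]")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SummaryWithSE:
    estimate: float
    se: float | None
    n_trajectories: int

    def as_tuple(self):
        return (self.estimate, self.se, self.n_trajectories)


def summarize_with_se(per_trajectory_means) -> SummaryWithSE:
    """Mean of per-trajectory means with its standard error.

    SE = sample SD of the per-trajectory means / sqrt(n); undefined
    (reported as missing, with a warning) for a single trajectory.
    """
    means = np.asarray(per_trajectory_means, float)
    if means.size == 0:
        raise ValueError("need at least one trajectory mean")
    n = means.size
    if n == 1:
        logger.warning("single trajectory: standard error undefined")
        return SummaryWithSE(float(means[0]), None, 1)
    return SummaryWithSE(float(means.mean()),
                         float(means.std(ddof=1) / np.sqrt(n)), n)


def apply_window(trajset: TrajectorySet,
                 window_fraction: float) -> TrajectorySet:
    """Restrict every trajectory to its trailing frame fraction."""
    if window_fraction >= 1.0:
        return trajset
    out = []
    for t in trajset.trajectories:
        k = max(1, int(round(t.n_frames * window_fraction)))
        out.append(dataclasses.replace(t, coords=t.coords[-k:],
                                       box=t.box[-k:]))
    return TrajectorySet(topology=trajset.topology, trajectories=out)


def run_pipeline(config: AnalysisConfig, trajset=None, topology_path=None,
                 trajectory_paths=None, out_dir="membind_out",
                 ss_paths=None, stages=("structure", "binding", "bilayer",
                                        "clustering")) -> dict:
    """Execute the analysis stages and write CSV/JSON artifacts.

    Either an in-memory ``trajset`` or ``topology_path`` +
    ``trajectory_paths`` must be given.  Returns the report dict (also
    written to ``report.json``).  Any stage failure aborts with a
    stage-tagged error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if trajset is None:
        if topology_path is None or trajectory_paths is None:
            raise FileNotFoundError(
                "stage=load: missing topology/trajectory input")
        try:
            trajset = load_system(topology_path, trajectory_paths)
        except Exception as e:
            raise RuntimeError(f"stage=load: {e}") from e
    trajset = apply_window(trajset, config.window_fraction)
    report = {"config": dataclasses.asdict(config),
              "config_hash": config.hash(),
              "n_trajectories": trajset.n_trajectories,
              "n_frames_analyzed": trajset.total_frames()}
    import membind
    report["version"] = getattr(membind, "__version__", "dev")
    views = peptide_views(trajset)

    if "structure" in stages:
        try:
            table = _peptide.intrapeptide_contacts(
                views, cutoff=config.contact_cutoff)
            table.to_csv(out / "intrapeptide_contacts.csv")
            rg = [float(np.mean(_peptide.radius_of_gyration(
                v.coords[:, v.topology.peptide_heavy_mask(v.copy)])))
                for v in views]
            ree = [float(np.mean(_peptide.end_to_end(v))) for v in views]
            report["structure"] = {
                "mean_contacts_per_frame": table.mean_contacts_per_frame(),
                "radius_of_gyration": _by_traj(views, rg).as_tuple(),
                "end_to_end": _by_traj(views, ree).as_tuple(),
            }
            if ss_paths:
                assigns = [_peptide.parse_stride(p) for p in ss_paths]
                ss = _peptide.ss_summary(assigns)
                report["structure"]["turn_propensity"] = (
                    ss.mean_turn, ss.se_turn, len(assigns))
                report["structure"]["n_beta"] = ss.n_beta
                report["structure"]["n_gamma"] = ss.n_gamma
        except Exception as e:
            raise RuntimeError(f"stage=structure: {e}") from e

    if "binding" in stages:
        try:
            depths = _binding.residue_depths(views)
            states = _binding.classify_states(
                depths, margin=config.surface_margin)
            _states_csv(states, out / "state_probabilities.csv")
            grid, edges = _binding.depth_histogram(depths)
            np.savetxt(out / "depth_histogram.csv", grid, delimiter=",")
            prof = _binding.lipid_contacts(
                views, cutoff=config.contact_cutoff,
                hbond_distance=config.hbond_distance,
                hbond_angle=config.hbond_angle)
            prof.to_csv(out / "lipid_contacts.csv")
            water_mean, water_se, _ = _binding.water_contacts(
                views, cutoff=config.contact_cutoff)
            report["binding"] = {
                "binding_probability": (states.binding_probability,
                                        states.binding_se,
                                        states.n_trajectories),
                "mean_P_inserted": float(states.P_inserted.mean()),
                "mean_P_surface": float(states.P_surface.mean()),
                "mean_P_unbound": float(states.P_unbound.mean()),
                "water_contacts": (water_mean, water_se,
                                   trajset.n_trajectories),
            }
        except Exception as e:
            raise RuntimeError(f"stage=binding: {e}") from e

    if "bilayer" in stages:
        try:
            fld = _bilayer.density_field(views, dr=config.grid_dr,
                                         dz=config.grid_dz)
            fld.to_csv(out / "density_lipid.csv", "lipid")
            fld.to_csv(out / "density_water.csv", "water")
            near, away = _bilayer.region_density(fld, r_c=config.r_c)
            th = _bilayer.thickness_profile(fld, r_c=config.r_c)
            th.to_csv(out / "thickness_profile.csv")
            op = _bilayer.s_cd(views, contact_split=True,
                               cutoff=config.contact_cutoff)
            op.to_csv(out / "s_cd.csv")
            report["bilayer"] = {
                "density_near": near, "density_away": away,
                "density_drop_percent": 100.0 * (1 - near / away),
                "delta_D_near": th.delta_D_near,
                "delta_D_center": th.delta_D_center,
                "minus_scd_no_contact": op.mean_minus_scd(False),
                "minus_scd_contact": op.mean_minus_scd(True),
            }
        except Exception as e:
            raise RuntimeError(f"stage=bilayer: {e}") from e

    if "clustering" in stages:
        try:
            sample = _clustering.sample_structures(
                trajset, frame_stride=config.cluster_stride)
            M = _clustering.pairwise_rmsd(sample)
            res = _clustering.daura_cluster(
                M, cutoff=config.rmsd_cutoff,
                populated_threshold=config.populated_threshold,
                sample=sample)
            profs = _clustering.cluster_profiles(res, trajset)
            _clusters_csv(res, out / "clusters.csv")
            report["clustering"] = {
                "n_structures": int(M.shape[0]),
                "n_clusters": len(res.clusters),
                "n_populated": res.n_populated,
                "capture_fraction": res.capture_fraction(),
                "populated": [
                    {"cluster": p.cluster, "probability": p.probability,
                     "mean_rg": p.mean_rg, "mean_ree": p.mean_ree,
                     "mean_contacts": p.mean_contacts}
                    for p in profs],
            }
        except Exception as e:
            raise RuntimeError(f"stage=clustering: {e}") from e

    (out / "report.json").write_text(json.dumps(report, indent=1))
    logger.info("pipeline finished: %s (config %s)", out, config.hash())
    return report


def _by_traj(views, values) -> SummaryWithSE:
    per = {}
    for v, val in zip(views, values):
        per.setdefault(v.trajectory_id, []).append(val)
    return summarize_with_se([np.mean(x) for x in per.values()])


def _states_csv(states, path):
    import pandas as pd
    n = len(states.P_inserted)
    pd.DataFrame({
        "residue": np.arange(1, n + 1),
        "P_inserted": states.P_inserted, "P_inserted_se": states.se[0],
        "P_surface": states.P_surface, "P_surface_se": states.se[1],
        "P_unbound": states.P_unbound, "P_unbound_se": states.se[2],
    }).to_csv(path, index=False)


def _clusters_csv(res, path):
    import pandas as pd
    s = res.sample
    pd.DataFrame({
        "structure": np.arange(len(res.membership)),
        "trajectory": s.trajectory_id, "copy": s.copy, "frame": s.frame,
        "cluster": res.membership,
    }).to_csv(path, index=False)
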