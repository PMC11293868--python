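"""End-to-end orchestration: load -> cluster -> geometry -> thermo ->
contacts -> graphs from a single validated configuration, with a
machine-readable run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, aggregates, contacts, geometry, graphs, model_io, thermo
from .constants import CONTACT_CUTOFF_NM, DEFAULT_TEMPERATURE

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of a full analysis run."""

    topology: str
    trajectory: str | None = None
    output_dir: str = "dropletkit_out"
    start_ps: float = 0.0
    end_ps: float = float("inf")
    stride: int = 1
    chain_contact_cutoff_nm: float = CONTACT_CUTOFF_NM
    residue_contact_cutoff_nm: float = CONTACT_CUTOFF_NM
    neighbour_cutoff_nm: float = CONTACT_CUTOFF_NM
    dilute_max: int = 3
    dense_min: int = 6
    temperature_k: float = DEFAULT_TEMPERATURE
    volume_convention: str = "sqrt-lambda"
    min_droplet_frames: int = 10
    graph_ensemble_size: int = 500
    use_pbc: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dense_min <= self.dilute_max:
            raise ValueError("dense_min must be > dilute_max")
        for name in ("chain_contact_cutoff_nm", "residue_contact_cutoff_nm",
                     "neighbour_cutoff_nm", "temperature_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.volume_convention not in thermo.VOLUME_CONVENTIONS:
            raise ValueError(f"unknown volume convention {self.volume_convention!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, system: model_io.BeadSystem | None = None) -> dict:
    """Execute the full analysis and write results under the output directory.

    Returns the manifest. A ``system`` already in memory (e.g. synthetic)
    may be passed instead of loading from disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
        "status": "running",
    }

    def checkpoint() -> None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    stage = "load"
    try:
        if system is None:
            system = model_io.load_trajectory(
                config.topology,
                config.trajectory,
                model_io.FrameRange(config.start_ps, config.end_ps, config.stride),
            )
        manifest["stages"][stage] = {"n_frames": system.n_frames, "n_chains": system.n_chains}

        stage = "aggregates"
        assignments = aggregates.assign_all_frames(
            system,
            cutoff=config.chain_contact_cutoff_nm,
            dilute_max=config.dilute_max,
            dense_min=config.dense_min,
            use_pbc=config.use_pbc,
        )
        monomers = aggregates.monomer_count_series(system, assignments=assignments)
        model_io.write_table(
            [
                {"frame": a.frame_index, "time_ps": system.time[a.frame_index],
                 "n_clusters": len(a.clusters), "n_free_monomers": a.n_free_monomers,
                 "largest_cluster_size": a.largest_cluster_size}
                for a in assignments
            ],
            out / "clusters.csv",
        )
        manifest["stages"][stage] = {
            "mean_free_monomers": monomers["mean_free_monomers"],
            "mean_largest_cluster": monomers["mean_largest_cluster"],
        }

        stage = "thermo"
        conc_rows = []
        for a in assignments:
            pc = thermo.phase_concentrations(
                system, a, convention=config.volume_convention, use_pbc=config.use_pbc
            )
            conc_rows.append(
                {"frame": pc.frame_index, "c_dense_uM": pc.c_dense_uM,
                 "c_dilute_uM": pc.c_dilute_uM, "n_dense": pc.n_dense,
                 "n_dilute": pc.n_dilute, "v_dense_total_nm3": pc.v_dense_total_nm3}
            )
        model_io.write_table(conc_rows, out / "phase_concentrations.csv")
        dense_vals = [r["c_dense_uM"] for r in conc_rows if r["c_dense_uM"]]
        dilute_vals = [r["c_dilute_uM"] for r in conc_rows if r["c_dilute_uM"] > 0]
        dg = None
        if dense_vals and dilute_vals:
            dg = thermo.delta_g_transfer(
                float(np.mean(dilute_vals)), float(np.mean(dense_vals)), config.temperature_k
            )
        tensions = thermo.droplet_surface_tensions(
            system, assignments,
            temperature=config.temperature_k,
            min_droplet_frames=config.min_droplet_frames,
            use_pbc=config.use_pbc,
        )
        manifest["stages"][stage] = {
            "mean_c_dense_uM": float(np.mean(dense_vals)) if dense_vals else None,
            "mean_c_dilute_uM": float(np.mean(dilute_vals)) if dilute_vals else None,
            "delta_g_transfer_kJ_mol": dg,
            "surface_tension": thermo.pooled_surface_tension(tensions),
            "n_droplet_segments": len(tensions),
        }

        stage = "geometry"
        rg = geometry.chain_rg_by_phase(system, assignments, use_pbc=config.use_pbc)
        model_io.write_table(rg, out / "chain_rg.csv")
        angles = geometry.neighbour_orientation_angles(
            system, assignments,
            neighbour_cutoff=config.neighbour_cutoff_nm,
            use_pbc=config.use_pbc,
        )
        model_io.write_table(angles, out / "orientation_angles.csv", allow_empty=True)
        manifest["stages"][stage] = {
            "rg_mean_by_phase": {
                k: float(v) for k, v in rg.groupby("phase")["rg_nm"].mean().items()
            },
            "n_angle_samples": len(angles),
        }

        stage = "contacts"
        contact_summary: dict = {}
        try:
            dense_map = contacts.intra_contact_map(
                system, assignments, "dense",
                cutoff=config.residue_contact_cutoff_nm, use_pbc=config.use_pbc,
            )
            dilute_map = contacts.intra_contact_map(
                system, assignments, "dilute",
                cutoff=config.residue_contact_cutoff_nm, use_pbc=config.use_pbc,
            )
            diff = contacts.difference_map(dense_map, dilute_map)
            np.savetxt(out / "difference_map.csv", diff, delimiter=",")
            contact_summary["difference_map_mean"] = float(diff.mean())
        except contacts.EmptyMapError as exc:
            contact_summary["skipped"] = str(exc)
        manifest["stages"][stage] = contact_summary

        stage = "graphs"
        sw = graphs.droplet_small_worldness(
            system, assignments,
            cutoff=config.chain_contact_cutoff_nm,
            min_cluster_size=config.dense_min,
            ensemble_size=config.graph_ensemble_size,
            seed=config.seed,
            use_pbc=config.use_pbc,
        )
        model_io.write_table(
            [{"S": s.S, "C": s.C, "L": s.L, "C_rand": s.C_rand, "L_rand": s.L_rand,
              "n_nodes": s.n_nodes, "n_edges": s.n_edges} for s in sw],
            out / "small_worldness.csv",
            allow_empty=True,
        )
        manifest["stages"][stage] = {
            "n_droplet_graphs": len(sw),
            "mean_S": float(np.mean([s.S for s in sw])) if sw else None,
        }

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        checkpoint()
        raise
    finally:
        checkpoint()
    return manifest
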