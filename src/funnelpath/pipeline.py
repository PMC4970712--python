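"""End-to-end orchestration: config, run directory, report bundle.

``run_pipeline`` ties the stages together — funnel profile, interaction
scan, slice statistics, ligand RMSD histogram, state classification —
and writes plain-text TSV/JSON outputs plus a MANIFEST into an output
directory.  Numeric outputs are deterministic for a given config and
seed; log text never interleaves with them.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .axis import AxisFrame, build_axis
from .interactions import DetectorParams, scan_trajectory
from .io import read_trajectory
from .models import ConfigError, Trajectory
from .pore import SearchParams, funnel_profile
from .profiles import (
    SliceGrid,
    interaction_probability_profile,
    ligand_rmsd_trace,
    rmsd_occurrence_histogram,
)
from .states import classify_state
from .synth import default_translocation_schedule, make_translocation

logger = logging.getLogger("funnelpath")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: str
    topology: str | None = None
    trajectory: str | None = None
    preset: str | None = None  # "translocation" generates inputs in-memory
    ligand_resnames: list = field(default_factory=list)
    axis_mode: str = "fixed"  # fixed (lab z) | inertia
    z_min: float = -15.0
    z_max: float = 15.0
    dz: float = 0.5
    slice_width: float = 1.0
    threshold: float = 0.20
    frames: str | None = None
    seed: int = 0
    r_open: float = 2.0
    r_semi: float = 1.2
    n_blocks: int = 3
    bin_width: float = 0.5
    detector: dict = field(default_factory=dict)
    search: dict = field(default_factory=dict)
    preset_frames_per: int = 20  # dwell frames per slice of the synthetic preset

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate(self) -> None:
        if self.preset is None:
            if not self.topology or not self.trajectory:
                raise ConfigError("either a preset or topology+trajectory paths are required")
            for p in (self.topology, self.trajectory):
                if not os.path.exists(p):
                    raise ConfigError(f"input path does not exist: {p}")
        elif self.preset != "translocation":
            raise ConfigError(f"unknown preset {self.preset!r}")
        if self.z_min >= self.z_max:
            raise ConfigError("z_min must be below z_max")
        if not 0 <= self.threshold <= 1:
            raise ConfigError("threshold must lie in [0, 1]")


def _load_inputs(config: RunConfig) -> tuple[Trajectory, object]:
    if config.preset == "translocation":
        schedule = default_translocation_schedule(
            seed=config.seed, frames_per=config.preset_frames_per
        )
        traj, gt = make_translocation(schedule)
        return traj, gt
    traj = read_trajectory(
        config.topology,
        config.trajectory,
        ligand_resnames=config.ligand_resnames or None,
    )
    return traj, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns the MANIFEST dictionary.  On a stage failure, partial
    outputs are kept and the MANIFEST names the failing stage.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    with open(os.path.join(config.out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)

    manifest: dict = {"stages": [], "failed_stage": None, "outputs": []}

    def emit(name: str) -> str:
        path = os.path.join(config.out_dir, name)
        manifest["outputs"].append(name)
        return path

    stage = "load"
    try:
        traj, gt = _load_inputs(config)
        if gt is not None:
            gt.to_json(emit("ground_truth.json"))
        manifest["stages"].append(stage)

        stage = "profile"
        if config.axis_mode == "fixed":
            axis = AxisFrame(origin=np.zeros(3), axis=np.array([0.0, 0.0, 1.0]))
            axis_mode = "fixed"
        else:
            axis, axis_mode = None, "inertia"
        search = SearchParams(seed=config.seed, **config.search)
        profile = funnel_profile(
            traj,
            axis=axis,
            z_min=config.z_min,
            z_max=config.z_max,
            dz=config.dz,
            frames=config.frames or "last:0.1ns",
            params=search,
            axis_mode=axis_mode,
        )
        profile.to_tsv(emit("funnel_profile.tsv"))
        profile.to_json(emit("funnel_profile.json"))
        manifest["stages"].append(stage)

        stage = "classify"
        state = classify_state(profile, r_open=config.r_open, r_semi=config.r_semi)
        with open(emit("state.json"), "w") as fh:
            json.dump(
                {
                    "label": state.label,
                    "of_min_radius": round(state.of_min_radius, 6),
                    "if_min_radius": round(state.if_min_radius, 6),
                    "r_open": state.r_open,
                    "r_semi": state.r_semi,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        manifest["stages"].append(stage)

        stage = "contacts"
        scan_axis = axis or build_axis(traj.frames[0], mode="inertia")
        params = DetectorParams(**config.detector)
        table = scan_trajectory(traj, scan_axis, params=params)
        table.to_tsv(emit("interactions.tsv"))
        manifest["stages"].append(stage)

        stage = "slices"
        n_slices = int(round((config.z_max - config.z_min) / config.slice_width))
        grid = SliceGrid(z_min=config.z_min, width=config.slice_width, n_slices=n_slices)
        slices = interaction_probability_profile([table], grid, threshold=config.threshold)
        slices.to_tsv(emit("slice_profile.tsv"))
        slices.to_json(emit("slice_profile.json"))
        manifest["stages"].append(stage)

        stage = "rmsd"
        series = ligand_rmsd_trace(traj, traj.frames[-1])
        hist = rmsd_occurrence_histogram(
            series, bin_width=config.bin_width, n_blocks=config.n_blocks
        )
        hist.to_tsv(emit("rmsd_histogram.tsv"))
        np.savetxt(
            emit("rmsd_ligand.tsv"),
            np.column_stack([np.arange(series.size), series]),
            fmt=("%d", "%.6f"),
            delimiter="\t",
            header="frame\trmsd",
            comments="",
        )
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(os.path.join(config.out_dir, "MANIFEST.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise

    manifest["seed"] = config.seed
    with open(os.path.join(config.out_dir, "MANIFEST.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %s", config.out_dir)
    return manifest
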