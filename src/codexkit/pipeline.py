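"""End-to-end orchestration: phantom -> process -> segment -> cluster -> QC -> spatial.

One YAML config drives the whole chain; every stage's parameters, outputs,
checksums, and timing go into a machine-readable run report, so two runs
with the same config and seed can be compared checksum-for-checksum.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .phantom import PhantomConfig, generate_tissue_phantom, write_phantom
from .preprocess import process
from .segmentation import SegmentationParams, segment_cells, quantify_cells
from .clustering import ClusterParams, cluster_cells, prepare_features, profile_clusters
from .stack_io import read_experiment, write_cell_table

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

_STAGES = ("phantom", "process", "segment", "cluster", "spatial")


@dataclass
class RunConfig:
    output_dir: str = "codex_run"
    input_dir: str | None = None  # read an existing experiment instead of phantom
    cell_table: str | None = None  # skip straight to clustering
    seed: int = 0
    stages: dict = field(default_factory=lambda: {
        "phantom": True, "process": True, "segment": True,
        "cluster": True, "spatial": False,
    })
    phantom: dict = field(default_factory=dict)
    process: dict = field(default_factory=dict)
    segment: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    spatial: dict = field(default_factory=dict)

    def validate(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        on = {s for s in _STAGES if self.stages.get(s)}
        if "process" in on and not (self.stages.get("phantom") or self.input_dir):
            raise ValueError("process stage needs a phantom stage or an input_dir")
        if "segment" in on and "process" not in on:
            raise ValueError("segment stage needs the process stage")
        if "cluster" in on and "segment" not in on and not self.cell_table:
            raise ValueError("cluster stage needs a segment stage or a cell_table path")
        if "spatial" in on and "cluster" not in on:
            raise ValueError("spatial stage needs the cluster stage")

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write a run report.

    Each stage consumes the previous stage's outputs; a stage failure
    halts the run, with the report covering completed stages.  The report
    (also written as ``report.json``) records per-stage parameters, output
    files with SHA-256 checksums, and durations.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    def record(stage: str, t0: float, outputs: list[Path], params: dict) -> None:
        report["stages"][stage] = {
            "status": "ok",
            "duration_s": round(time.perf_counter() - t0, 3),
            "params": {k: str(v) for k, v in params.items()},
            "outputs": {p.name: _sha256(p) for p in outputs},
        }

    try:
        stack = truth = None
        if config.stages.get("phantom"):
            t0 = time.perf_counter()
            pcfg = PhantomConfig(**config.phantom)
            pcfg.seed = config.seed
            stack, truth = generate_tissue_phantom(pcfg)
            phantom_dir = out_dir / "phantom"
            write_phantom(phantom_dir, stack, truth)
            record("phantom", t0, sorted(phantom_dir.glob("*.csv")), config.phantom)
        elif config.input_dir:
            stack = read_experiment(config.input_dir)

        mosaic = None
        if config.stages.get("process"):
            t0 = time.perf_counter()
            mosaic, drift = process(stack, **config.process)
            tifffile.imwrite(out_dir / "mosaic.tif", mosaic.data.astype(np.float32))
            drift.per_tile.to_csv(out_dir / "drift.csv", index=False)
            (out_dir / "provenance.json").write_text(json.dumps({
                "log": mosaic.log, "planes": mosaic.plane_names,
                "config_hash": config.config_hash(), "version": __version__,
            }, indent=2))
            record("process", t0,
                   [out_dir / "mosaic.tif", out_dir / "drift.csv"], config.process)

        cells = None
        if config.stages.get("segment"):
            t0 = time.perf_counter()
            params = SegmentationParams(**{
                k: v for k, v in config.segment.items() if k != "membrane_channel"
            })
            membrane_name = config.segment.get("membrane_channel")
            membrane = mosaic.plane(membrane_name) if membrane_name else None
            labels = segment_cells(mosaic.plane(mosaic.plane_names[0]), membrane, params)
            cells = quantify_cells(labels, mosaic)
            tifffile.imwrite(out_dir / "labels.tif", labels.astype(np.int32))
            write_cell_table(cells, out_dir / "cells.csv")
            write_cell_table(cells, out_dir / "cells.fcs", format="fcs")
            record("segment", t0, [out_dir / "cells.csv"], config.segment)
        elif config.cell_table:
            cells = pd.read_csv(config.cell_table)

        if config.stages.get("cluster"):
            t0 = time.perf_counter()
            cparams = ClusterParams(**config.cluster)
            cparams.seed = config.seed
            X, markers = prepare_features(cells, cparams)
            result = cluster_cells(X, cparams)
            cells = cells.copy()
            cells["cluster"] = result.labels
            write_cell_table(cells, out_dir / "clusters.csv")
            profile_clusters(result, cells.drop(columns="cluster"), cparams).to_csv(
                out_dir / "cluster_profiles.csv", index=False
            )
            record("cluster", t0,
                   [out_dir / "clusters.csv", out_dir / "cluster_profiles.csv"],
                   {**config.cluster, "n_clusters": result.n_clusters})

        if config.stages.get("spatial"):
            from .spatial import sample_density, density_correlation

            t0 = time.perf_counter()
            shape = mosaic.data.shape[1:]
            sp = dict(config.spatial)
            counts = sample_density(
                cells, shape,
                window=int(sp.get("window", 100)),
                n_windows=int(sp.get("n_windows", 500)),
                seed=config.seed,
            )
            corr = density_correlation(counts)
            corr.rho.to_csv(out_dir / "density_rho.csv")
            record("spatial", t0, [out_dir / "density_rho.csv"], config.spatial)
    except Exception as exc:  # report what completed, then re-raise
        report["error"] = f"{type(exc).__name__}: {exc}"
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        raise

    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report
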