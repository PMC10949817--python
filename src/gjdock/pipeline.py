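"""Pipeline orchestration: run the full docking analysis from one config.

A single YAML config names the input trajectory, the stages to run (sc,
hbonds, disulfides, rmsd, pore, graph) and per-stage options, plus a
``params:`` block overriding :class:`~gjdock.core.AnalysisParameters`
defaults. Each stage writes its TSV output and a JSON summary; the run is
reproducible given the seed, and a structured run log records parameter
values, input hashes and per-stage wall time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    AnalysisParameters,
    ConnexinAnnotation,
    GJDockError,
    Trajectory,
)
from .interactions import (
    detect_cys_cys_hbonds,
    detect_cys_interface_hbonds,
    detect_disulfides,
    detect_trans_gj_hbonds,
    hbond_timeseries,
)
from .io import read_trajectory
from .pore import min_diameter_series
from .scgraph import build_sc_graph, export_graph
from .stabcenters import filter_extracellular, sc_timeseries
from .geometry import extracellular_rmsd_series

log = logging.getLogger(__name__)

VALID_STAGES = ("sc", "hbonds", "disulfides", "rmsd", "pore", "graph")

_HBOND_DETECTORS = {
    "trans_gj": detect_trans_gj_hbonds,
    "cys_cys": detect_cys_cys_hbonds,
    "cys_interface": detect_cys_interface_hbonds,
}


class PipelineError(GJDockError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    trajectory: str
    output_dir: str = "gjdock_out"
    stages: tuple[str, ...] = VALID_STAGES
    frame_interval_ps: float = 10.0
    seed: int = 0
    log_level: str = "INFO"
    params: AnalysisParameters = field(default_factory=AnalysisParameters)
    options: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in VALID_STAGES]
        if unknown:
            raise PipelineError(
                f"unknown stage(s) {unknown}; valid stages: {VALID_STAGES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        params = AnalysisParameters.from_mapping(raw.pop("params", {}))
        options = {s: raw.pop(s) for s in VALID_STAGES if s in raw}
        stages = tuple(raw.pop("stages", VALID_STAGES))
        known = {"trajectory", "output_dir", "frame_interval_ps", "seed",
                 "log_level"}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        if "trajectory" not in raw:
            raise PipelineError("config must name a trajectory")
        return cls(stages=stages, params=params, options=options, **raw)


def _file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_sc(traj: Trajectory, cfg: PipelineConfig, outdir: Path,
              annotation: ConnexinAnnotation) -> tuple[dict, pd.DataFrame]:
    opts = cfg.options.get("sc", {})
    scope_kind = opts.get("scope", "all")
    stride = int(opts.get("stride", 1))
    min_fraction = float(opts.get("min_fraction",
                                  cfg.params.sc_min_stability_fraction))
    scope = None
    if scope_kind == "extracellular":
        topo = traj.topology
        scope = {(c, r) for c, r, _, _ in topo.residues()
                 if annotation.is_extracellular(r)}
    elif scope_kind != "all":
        raise PipelineError(f"sc: unknown scope {scope_kind!r}")
    table, records = sc_timeseries(traj, scope=scope, params=cfg.params,
                                   stride=stride)
    filtered = filter_extracellular(table, annotation, min_fraction)
    table.to_csv(outdir / "sc.tsv", sep="\t", index=False)
    filtered.to_csv(outdir / "sc_extracellular.tsv", sep="\t", index=False)
    per_frame = pd.DataFrame([{
        "frame": r.frame_index,
        "chain_a": r.res_a[0], "res_a": r.res_a[1], "name_a": r.res_a[2],
        "chain_b": r.res_b[0], "res_b": r.res_b[1], "name_b": r.res_b[2],
        "d_min": r.min_heavy_distance,
        "trans_gj": r.is_trans_gj, "subunit_pair": r.subunit_pair_label,
    } for r in records])
    per_frame.to_csv(outdir / "sc_frames.tsv", sep="\t", index=False)
    summary = {
        "n_pairs": int(len(table)),
        "n_extracellular_reportable": int(len(filtered)),
        "n_trans_gj": int((table["class"] == "trans-GJ").sum())
        if len(table) else 0,
    }
    return summary, table


def _stage_hbonds(traj: Trajectory, cfg: PipelineConfig, outdir: Path,
                  annotation: ConnexinAnnotation) -> dict:
    opts = cfg.options.get("hbonds", {})
    categories = opts.get("categories", list(_HBOND_DETECTORS))
    chains_counted = opts.get("chains_counted", "all")
    if chains_counted == "A-F":
        chains_counted = "ABCDEF"
    summary: dict[str, Any] = {}
    for cat in categories:
        detector = _HBOND_DETECTORS.get(cat)
        if detector is None:
            raise PipelineError(f"hbonds: unknown category {cat!r}")
        kwargs: dict[str, Any] = {"params": cfg.params}
        if cat in ("trans_gj", "cys_interface"):
            kwargs["annotation"] = annotation
        counts, presence, _ = hbond_timeseries(
            traj, detector, chains_counted=chains_counted, **kwargs)
        counts.to_csv(outdir / f"hbonds_{cat}.tsv", sep="\t", index=False)
        presence.to_csv(outdir / f"hbonds_{cat}_presence.tsv", sep="\t")
        summary[cat] = {
            "mean_count": float(counts["n_bonds"].mean()),
            "max_count": int(counts["n_bonds"].max()),
            "n_pair_labels": int(presence.shape[1]),
        }
    return summary


def _stage_disulfides(traj: Trajectory, cfg: PipelineConfig,
                      outdir: Path) -> dict:
    frame = traj.frame(0)
    bonds = detect_disulfides(frame, params=cfg.params)
    rows = [dataclasses.asdict(b) for b in bonds]
    pd.DataFrame(rows, columns=["chain_a", "res_a", "chain_b", "res_b",
                                "sg_sg_distance", "state", "canonical"]
                 ).to_csv(outdir / "disulfides.tsv", sep="\t", index=False)
    summary = {
        "n_bonds": len(bonds),
        "n_canonical": sum(b.canonical for b in bonds),
    }
    (outdir / "disulfides.json").write_text(json.dumps(summary, indent=2))
    return summary


def _stage_rmsd(traj: Trajectory, cfg: PipelineConfig, outdir: Path,
                annotation: ConnexinAnnotation) -> dict:
    opts = cfg.options.get("rmsd", {})
    chains = opts.get("chains")
    series = extracellular_rmsd_series(traj, annotation, chains=chains)
    pd.DataFrame({
        "frame": np.arange(traj.n_frames),
        "time_ps": traj.times,
        "rmsd_A": series,
    }).to_csv(outdir / "rmsd.tsv", sep="\t", index=False)
    return {"max_A": float(series.max()), "final_A": float(series[-1])}


def _stage_pore(traj: Trajectory, cfg: PipelineConfig, outdir: Path,
                annotation: ConnexinAnnotation) -> dict:
    opts = cfg.options.get("pore", {})
    table, _ = min_diameter_series(
        traj,
        step=float(opts.get("step", 0.5)),
        window=opts.get("window"),
        r_max=float(opts.get("r_max", 15.0)),
        seed=cfg.seed,
        params=cfg.params,
        annotation=annotation,
    )
    table.to_csv(outdir / "pore.tsv", sep="\t", index=False)
    return {
        "min_diam_A": float(np.nanmin(table["min_diam_A"])),
        "mean_min_diam_A": float(np.nanmean(table["min_diam_A"])),
    }


def _stage_graph(sc_table: pd.DataFrame, cfg: PipelineConfig, outdir: Path,
                 annotation: ConnexinAnnotation) -> dict:
    opts = cfg.options.get("graph", {})
    min_fraction = float(opts.get("min_fraction",
                                  cfg.params.sc_min_stability_fraction))
    filtered = filter_extracellular(sc_table, annotation, min_fraction)
    graph = build_sc_graph(filtered)
    export_graph(graph, outdir / "graph.graphml", format="graphml")
    export_graph(graph, outdir / "graph_edges.tsv", format="tsv")
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_cys_nodes": sum(1 for _, d in graph.nodes(data=True)
                           if d.get("is_cys")),
    }


def run_pipeline(config: PipelineConfig | str | Path,
                 annotation: ConnexinAnnotation | None = None) -> dict:
    """Run the configured stages and write a JSON report plus per-stage TSVs.

    Stage outputs are identical whether a stage runs alone or within a full
    pipeline. Any stage failure aborts with the stage name and cause.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    annotation = annotation or ConnexinAnnotation()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("gjdock")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        log.info("gjdock %s pipeline start; seed=%d", __version__, config.seed)
        log.info("parameters: %s", dataclasses.asdict(config.params))
        log.info("input %s sha256=%s", config.trajectory,
                 _file_sha256(config.trajectory))
        traj = read_trajectory(config.trajectory,
                               frame_interval_ps=config.frame_interval_ps)
        log.info("trajectory: %d frames x %d atoms, dt=%.1f ps",
                 traj.n_frames, len(traj.topology), traj.frame_interval_ps)
        report: dict[str, Any] = {
            "version": __version__,
            "seed": config.seed,
            "input": {"path": str(config.trajectory),
                      "sha256": _file_sha256(config.trajectory),
                      "n_frames": traj.n_frames,
                      "n_atoms": len(traj.topology)},
            "stages": {},
        }
        sc_table: pd.DataFrame | None = None
        for stage in config.stages:
            t0 = time.perf_counter()
            try:
                if stage == "sc":
                    summary, sc_table = _stage_sc(traj, config, outdir,
                                                  annotation)
                elif stage == "hbonds":
                    summary = _stage_hbonds(traj, config, outdir, annotation)
                elif stage == "disulfides":
                    summary = _stage_disulfides(traj, config, outdir)
                elif stage == "rmsd":
                    summary = _stage_rmsd(traj, config, outdir, annotation)
                elif stage == "pore":
                    summary = _stage_pore(traj, config, outdir, annotation)
                elif stage == "graph":
                    if sc_table is None:
                        _, sc_table = _stage_sc(traj, config, outdir,
                                                annotation)
                    summary = _stage_graph(sc_table, config, outdir,
                                           annotation)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
            dt = time.perf_counter() - t0
            log.info("stage %s done in %.2f s: %s", stage, dt, summary)
            report["stages"][stage] = summary
        (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                       sort_keys=True))
        return report
    finally:
        root.removeHandler(handler)
        handler.close()
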