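"""Pipeline orchestration: config, seed derivation, manifests, reports.

``run_pipeline`` ties the stages together (simulate -> reconstruction grid
-> VOI analysis -> optimization -> report).  Every stage is deterministic
given the config seed: acquisition seeds are derived from the master seed
by hashing the stage and acquisition name, grid cells are keyed by a
content hash of their inputs and settings (making reruns idempotent and
resumable), and the manifest records config and artifact hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .optimize import (
    AcquisitionSpec,
    GridConfig,
    compare_protocols,
    curves_from_results,
    run_grid,
)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "derive_seed",
    "run_pipeline",
    "make_report",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def derive_seed(master_seed: int, stage: str, ident: str) -> int:
    """Per-stage, per-acquisition child seed below 2**31."""
    h = zlib.crc32(f"{stage}:{ident}".encode())
    return (int(master_seed) ^ h) % (2**31)


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (see ``from_yaml``)."""

    acquisitions: list[dict] = field(default_factory=list)
    ladder_updates: tuple = (12, 30, 60)
    corrections: tuple = ("AC", "SCAC")
    postfilters_mm: tuple = (12.0,)
    spacing_mm: float = 4.8
    grid_shape: tuple = (64, 64, 40)
    n_views: int = 24
    subsample: int = 2
    seed: int = 1
    output_dir: str = "pipeline_out"
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("ladder_updates", "corrections", "postfilters_mm",
                    "grid_shape"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def grid_config(self) -> GridConfig:
        acqs = [
            AcquisitionSpec(
                name=a["name"],
                system=a["system"],
                concentration_kbq_per_ml=float(a["concentration"]),
                t_view_s=float(a.get("t_view_s", 30.0)),
                seed=derive_seed(self.seed, "simulate", a["name"]),
            )
            for a in self.acquisitions
        ]
        return GridConfig(
            acquisitions=acqs,
            ladder_updates=tuple(self.ladder_updates),
            corrections=tuple(self.corrections),
            postfilters_mm=tuple(self.postfilters_mm),
            spacing_mm=self.spacing_mm,
            grid_shape=tuple(self.grid_shape),
            n_views=self.n_views,
            subsample=self.subsample,
            output_dir=str(Path(self.output_dir) / "grid"),
        )

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    started: str
    finished: str = ""
    artifacts: dict = field(default_factory=dict)

    def record(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
        self.artifacts[name] = {"path": str(path), "sha256": digest}

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _log(outdir: Path, stage: str, **fields) -> None:
    entry = {"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **fields}
    with (outdir / "pipeline.log.jsonl").open("a") as fh:
        fh.write(json.dumps(entry) + "\n")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run all stages; idempotent and resumable through cell caching."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.content_hash(),
        version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    grid_cfg = config.grid_config()
    try:
        _log(outdir, "grid", planned=grid_cfg.n_planned())
        results = run_grid(grid_cfg)
    except Exception as exc:  # noqa: BLE001 - stage-tagged rethrow
        raise PipelineError("grid", str(exc)) from exc

    results_path = outdir / "results.csv"
    results.to_csv(results_path, index=False)
    manifest.record("results", results_path)
    _log(outdir, "analyze", rows=len(results))

    try:
        report_paths = make_report(outdir, results=results,
                                   n_views=config.n_views,
                                   plots=config.make_plots)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("report", str(exc)) from exc
    for name, p in report_paths.items():
        manifest.record(name, p)
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.save(outdir / "manifest.json")
    _log(outdir, "done")
    return manifest


def make_report(results_dir, results: pd.DataFrame | None = None,
                n_views: int | None = None, plots: bool = False) -> dict:
    """Write the comparison tables (and optional SSR plots).

    Produces ``ranking.csv`` (protocols sorted by aggregate SSR at their
    optimum), ``optimal_updates.csv`` (an optimum per protocol/correction/
    filter matrix), ``max_rates.csv`` (largest-sphere normalized maximum
    rates at the optimum) and ``curves.csv``.  Missing or empty results
    yield empty-but-valid tables with a warning column.
    """
    results_dir = Path(results_dir)
    results_dir.mkdir(parents=True, exist_ok=True)
    if results is None:
        path = results_dir / "results.csv"
        results = pd.read_csv(path) if path.exists() else pd.DataFrame()
    paths: dict[str, Path] = {}

    ranking_path = results_dir / "ranking.csv"
    updates_path = results_dir / "optimal_updates.csv"
    rates_path = results_dir / "max_rates.csv"
    curves_path = results_dir / "curves.csv"
    if results.empty:
        warn = pd.DataFrame({"warning": ["no results available"]})
        for p in (ranking_path, updates_path, rates_path, curves_path):
            warn.to_csv(p, index=False)
            paths[p.stem] = p
        return paths

    ranking = compare_protocols(results, n_views=n_views)
    ranking.to_csv(ranking_path, index=False)
    paths["ranking"] = ranking_path

    updates_tbl = ranking.pivot_table(
        index=["correction", "postfilter_mm"], columns="acquisition",
        values="optimal_updates", aggfunc="first",
    )
    updates_tbl.to_csv(updates_path)
    paths["optimal_updates"] = updates_path

    rates_tbl = ranking.pivot_table(
        index=["correction", "postfilter_mm"], columns="acquisition",
        values="largest_sphere_max_rate", aggfunc="first",
    )
    rates_tbl.to_csv(rates_path)
    paths["max_rates"] = rates_path

    curve_rows = []
    combos = results[["acquisition", "correction", "postfilter_mm"]].drop_duplicates()
    for _, row in combos.iterrows():
        for c in curves_from_results(results, row["acquisition"],
                                     row["correction"], row["postfilter_mm"]):
            for lvl, val, flag in zip(
                c.update_levels, c.ssr_values,
                c.has_local_max_flags if c.has_local_max_flags is not None
                else [None] * len(c.update_levels),
            ):
                curve_rows.append(
                    {
                        "acquisition": row["acquisition"],
                        "correction": row["correction"],
                        "postfilter_mm": row["postfilter_mm"],
                        "sphere": c.sphere_id, "updates": lvl, "ssr": val,
                        "has_local_max": flag,
                    }
                )
    pd.DataFrame(curve_rows).to_csv(curves_path, index=False)
    paths["curves"] = curves_path

    if plots:
        paths.update(_plot_curves(results_dir, pd.DataFrame(curve_rows)))
    return paths


def _plot_curves(results_dir: Path, curves: pd.DataFrame) -> dict:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = {}
    for (acq, corr, pf), grp in curves.groupby(
        ["acquisition", "correction", "postfilter_mm"]
    ):
        fig, ax = plt.subplots(figsize=(5, 4))
        for sphere, sg in grp.groupby("sphere"):
            sg = sg.sort_values("updates")
            u = sg["updates"].to_numpy()
            v = sg["ssr"].to_numpy()
            flags = sg["has_local_max"].to_numpy()
            ax.plot(u, v, "-", label=f"sphere {sphere}")
            if flags is not None and not all(f in (True, None) for f in flags):
                missing = np.asarray([f is False or f == False for f in flags])  # noqa: E712
                ax.plot(u[missing], v[missing], "--", color=ax.lines[-1].get_color())
        ax.set_xscale("log")
        ax.set_xlabel("OSEM updates")
        ax.set_ylabel("SSR")
        ax.set_title(f"{acq} {corr} {pf:g} mm")
        ax.legend(fontsize=7)
        p = results_dir / f"ssr_{acq}_{corr}_{pf:g}mm.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths[p.stem] = p
    return paths
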