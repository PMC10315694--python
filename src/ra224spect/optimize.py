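"""SSR-vs-updates curves, the combined-normalized-SSR objective, and the
acquisition/reconstruction comparison grid.

The optimal number of OSEM updates for a protocol is the ladder level
maximizing the *combined normalized SSR*: each sphere's SSR-versus-updates
curve is smoothed with a 3-element floating average, normalized to its own
maximum, and the normalized curves are summed with equal weight, omitting
spheres whose smoothed curve shows no interior local maximum.  Protocols
(collimator x energy window x correction x postfilter) are then compared at
their individually optimal update level.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import compute_voi_stats, place_sphere_voi
from .phantom import PhantomSpec, background_voi, voxelize, MU_WATER_PER_CM
from .recon import (
    DEFAULT_LADDER_UPDATES,
    ReconSettings,
    gaussian_postfilter,
    osem,
)
from .simulate import AcquisitionProtocol, preset_systems, simulate_acquisition

__all__ = [
    "SSRCurve",
    "OptimizationResult",
    "AcquisitionSpec",
    "GridConfig",
    "smooth3",
    "curve_has_interior_max",
    "combined_normalized_ssr",
    "default_study_config",
    "run_grid",
    "compare_protocols",
]

BACKGROUND_SPHERE_MARGIN_MM = 40.2
BACKGROUND_HULL_MARGIN_MM = 26.8


class NoOptimumError(RuntimeError):
    """All spheres were excluded from the aggregate objective."""


def smooth3(values) -> np.ndarray:
    """Centered 3-element floating average; endpoints average the 2
    available elements.  [0, 3, 0] -> [1.5, 1, 1.5]."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise ValueError("smooth3 expects a non-empty 1-D sequence")
    if v.size == 1:
        return v.copy()
    out = np.empty_like(v)
    out[0] = v[:2].mean()
    out[-1] = v[-2:].mean()
    if v.size > 2:
        out[1:-1] = (v[:-2] + v[1:-1] + v[2:]) / 3.0
    return out


def curve_has_interior_max(smoothed) -> bool:
    """True when the (smoothed) curve's first argmax is interior."""
    v = np.asarray(smoothed, dtype=float)
    if v.size < 3:
        return False
    i = int(np.argmax(v))
    return 0 < i < v.size - 1


@dataclass
class SSRCurve:
    """SSR as a function of OSEM updates for one sphere."""

    sphere_id: int
    update_levels: tuple[int, ...]
    ssr_values: np.ndarray
    has_local_max_flags: np.ndarray | None = None  # image-domain flags

    def __post_init__(self) -> None:
        self.ssr_values = np.asarray(self.ssr_values, dtype=float)
        if len(self.update_levels) != self.ssr_values.size:
            raise ValueError("levels and values length mismatch")
        if np.any(self.ssr_values < 0):
            raise ValueError("SSR values must be >= 0")
        if self.has_local_max_flags is not None:
            self.has_local_max_flags = np.asarray(self.has_local_max_flags, bool)

    @property
    def smoothed(self) -> np.ndarray:
        return smooth3(self.ssr_values)

    @property
    def curve_has_interior_max(self) -> bool:
        return curve_has_interior_max(self.smoothed)


@dataclass
class OptimizationResult:
    """Aggregate objective and its optimum for one protocol.

    ``aggregate_curve`` is the scale-free optimization objective (sum of
    smoothed, self-normalized sphere curves over included spheres);
    ``total_ssr_curve`` is the sum of the raw smoothed SSRs of all spheres,
    the quantity protocols are compared on at their optima.
    """

    update_levels: tuple[int, ...]
    aggregate_curve: np.ndarray
    total_ssr_curve: np.ndarray
    optimal_updates: int
    included_spheres: tuple[int, ...]
    excluded_spheres: tuple[int, ...]
    optimal_settings: ReconSettings | None = None

    @property
    def optimal_index(self) -> int:
        return self.update_levels.index(self.optimal_updates)

    @property
    def aggregate_at_optimum(self) -> float:
        return float(self.aggregate_curve[self.optimal_index])

    @property
    def total_ssr_at_optimum(self) -> float:
        return float(self.total_ssr_curve[self.optimal_index])


def combined_normalized_ssr(
    curves: list[SSRCurve],
    n_views: int | None = None,
    scatter_correction: bool = False,
    postfilter_fwhm: float = 0.0,
) -> OptimizationResult:
    """Smooth, self-normalize, and sum the per-sphere SSR curves.

    Spheres whose smoothed curve has no interior local maximum are omitted.
    The optimum is the argmax of the sum; ties resolve to the fewest
    updates.  When ``n_views`` is given the optimal ladder level is also
    factorized into :class:`ReconSettings`.
    """
    if not curves:
        raise ValueError("at least one curve required")
    levels = curves[0].update_levels
    for c in curves:
        if c.update_levels != levels:
            raise ValueError("all curves must share the update ladder")
    included, excluded, parts = [], [], []
    total_ssr = np.zeros(len(levels))
    for c in curves:
        sm = c.smoothed
        total_ssr += sm
        if curve_has_interior_max(sm) and sm.max() > 0:
            included.append(c.sphere_id)
            parts.append(sm / sm.max())
        else:
            excluded.append(c.sphere_id)
    if not parts:
        raise NoOptimumError("no sphere curve has an interior local maximum")
    agg = np.sum(parts, axis=0)
    idx = int(np.argmax(agg))  # first max = fewest updates on an ascending ladder
    settings = None
    if n_views is not None:
        settings = ReconSettings.for_protocol(
            levels[idx], n_views, scatter_correction, postfilter_fwhm
        )
    return OptimizationResult(
        update_levels=levels,
        aggregate_curve=agg,
        total_ssr_curve=total_ssr,
        optimal_updates=levels[idx],
        included_spheres=tuple(included),
        excluded_spheres=tuple(excluded),
        optimal_settings=settings,
    )


# ---------------------------------------------------------------------------
# grid runner
# ---------------------------------------------------------------------------

@dataclass
class AcquisitionSpec:
    """One physical acquisition of the study."""

    name: str
    system: str  # preset key: ME80 | HE80 | ME240 | HE240
    concentration_kbq_per_ml: float
    t_view_s: float = 30.0
    seed: int = 0

    @property
    def collimator(self) -> str:
        return self.system[:2]

    @property
    def window(self) -> str:
        return self.system[2:] + " keV"


@dataclass
class GridConfig:
    """Specification of the reconstruction grid.

    The desk-scale profile defaults (64-voxel transaxial grid, 4.8-mm
    voxels, 24 views) keep a full grid cell tractable; the study-scale
    profile (128+, 2.4 mm, 60 views) is opt-in via the fields below.
    """

    acquisitions: list[AcquisitionSpec] = field(default_factory=list)
    ladder_updates: tuple[int, ...] = DEFAULT_LADDER_UPDATES
    corrections: tuple[str, ...] = ("AC", "SCAC")
    postfilters_mm: tuple[float, ...] = (9.0, 12.0, 16.0)
    spacing_mm: float = 4.8
    grid_shape: tuple[int, int, int] = (64, 64, 40)
    n_views: int = 24
    subsample: int = 2
    background_concentration: float = 0.0
    output_dir: str | None = None

    def n_planned(self) -> int:
        return (
            len(self.acquisitions)
            * len(self.ladder_updates)
            * len(self.corrections)
            * len(self.postfilters_mm)
        )


def default_study_config(seed: int = 0, **overrides) -> GridConfig:
    """The nine-acquisition study: four collimator/window systems at 90 and
    30 kBq/mL (30 s/view) plus the short-scan ME240 acquisition at
    20 kBq/mL and 3 s/view."""
    acquisitions = []
    k = 0
    for conc in (90.0, 30.0):
        for sysname in ("HE80", "HE240", "ME80", "ME240"):
            acquisitions.append(
                AcquisitionSpec(
                    name=f"{sysname}_{conc:g}",
                    system=sysname,
                    concentration_kbq_per_ml=conc,
                    t_view_s=30.0,
                    seed=seed + k,
                )
            )
            k += 1
    acquisitions.append(
        AcquisitionSpec(
            name="ME240_2eq", system="ME240",
            concentration_kbq_per_ml=20.0, t_view_s=3.0, seed=seed + k,
        )
    )
    return GridConfig(acquisitions=acquisitions, **overrides)


def _cell_key(acq: AcquisitionSpec, updates: int, correction: str,
              postfilter: float, config: GridConfig) -> str:
    payload = json.dumps(
        [asdict(acq), updates, correction, postfilter, config.spacing_mm,
         list(config.grid_shape), config.n_views, config.subsample],
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _window_energy(system_name: str) -> int:
    return int(system_name[2:])


def run_grid(config: GridConfig, dry_run: bool = False,
             progress: bool = False) -> pd.DataFrame:
    """Execute (or just enumerate) every reconstruction of the grid.

    Returns a tidy frame: one row per (acquisition, updates, correction,
    postfilter, sphere) with the VOI statistics.  In dry-run mode the frame
    enumerates the planned reconstructions without executing them.  With
    ``config.output_dir`` set, finished cells are persisted under
    ``cells/<hash>.csv`` and reloaded instead of recomputed.
    """
    plan = []
    for acq in config.acquisitions:
        for updates in config.ladder_updates:
            for corr in config.corrections:
                for pf in config.postfilters_mm:
                    plan.append((acq, updates, corr, pf))
    if dry_run:
        return pd.DataFrame(
            [
                {
                    "acquisition": a.name, "system": a.system,
                    "updates": u, "correction": c, "postfilter_mm": p,
                }
                for a, u, c, p in plan
            ]
        )

    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        (outdir / "cells").mkdir(parents=True, exist_ok=True)

    systems = preset_systems()
    spec_cache: dict[float, tuple] = {}
    rows = []

    def phantom_for(conc: float):
        if conc not in spec_cache:
            spec_cache[conc] = PhantomSpec(
                sphere_concentrations=(conc,) * 6,
                background_concentration=config.background_concentration,
            )
        return spec_cache[conc]

    acq_data: dict[str, dict] = {}
    for acq in config.acquisitions:
        system = systems[acq.system]
        spec = phantom_for(acq.concentration_kbq_per_ml)
        mu = MU_WATER_PER_CM[_window_energy(acq.system)]
        act_vol, mu_vol = voxelize(
            spec, config.spacing_mm, mu, shape=config.grid_shape,
            subsample=config.subsample,
        )
        protocol = AcquisitionProtocol(
            n_views=config.n_views, t_view=acq.t_view_s,
            matrix=config.grid_shape[0], bin_size=config.spacing_mm,
            windows=system.windows,
        )
        projections = simulate_acquisition(act_vol, mu_vol, system, protocol,
                                           seed=acq.seed)
        bg = background_voi(
            spec, config.spacing_mm, BACKGROUND_SPHERE_MARGIN_MM,
            BACKGROUND_HULL_MARGIN_MM, shape=config.grid_shape,
        )
        acq_data[acq.name] = {
            "spec": spec, "mu_vol": mu_vol, "projections": projections,
            "background": bg.values, "protocol": protocol,
        }

    recon_cache: dict[tuple, object] = {}
    for acq, updates, corr, pf in plan:
        key = _cell_key(acq, updates, corr, pf, config)
        cell_path = outdir / "cells" / f"{key}.csv" if outdir else None
        if cell_path and cell_path.exists():
            rows.append(pd.read_csv(cell_path))
            continue
        data = acq_data[acq.name]
        sc = corr == "SCAC"
        settings = ReconSettings.for_protocol(
            updates, config.n_views, scatter_correction=sc, postfilter_fwhm=pf
        )
        # AC reconstructions are filter-independent before postfiltering and
        # can be shared across the three postfilter levels; SC cells differ
        # through the paired prefilter.
        cache_key = (acq.name, updates, corr,
                     settings.scatter_prefilter_fwhm if sc else None)
        if cache_key not in recon_cache:
            recon_cache[cache_key] = osem(
                data["projections"], data["mu_vol"], settings
            )
        vol = gaussian_postfilter(recon_cache[cache_key], pf)
        spec = data["spec"]
        cell_rows = []
        for s_idx in range(6):
            voi = place_sphere_voi(
                vol, spec.sphere_centers[s_idx], spec.sphere_diameters[s_idx]
            )
            stats = compute_voi_stats(
                vol, voi, data["background"],
                concentration_kbq_per_ml=acq.concentration_kbq_per_ml,
                duration_h=data["protocol"].duration_h,
            )
            cell_rows.append(
                {
                    "acquisition": acq.name, "system": acq.system,
                    "collimator": acq.collimator, "window": acq.window,
                    "concentration": acq.concentration_kbq_per_ml,
                    "t_view_s": acq.t_view_s, "seed": acq.seed,
                    "updates": updates, "iterations": settings.iterations,
                    "subsets": settings.subsets, "correction": corr,
                    "postfilter_mm": pf, "sphere": s_idx,
                    "diameter_mm": spec.sphere_diameters[s_idx],
                    "max": stats.max, "mean": stats.mean,
                    "peak_background": stats.peak_background,
                    "ssr": stats.ssr, "has_local_max": stats.has_local_max,
                    "normalized_max_rate": stats.normalized_max_rate,
                }
            )
        cell = pd.DataFrame(cell_rows)
        # round-trip through the CSV representation so cached and freshly
        # computed cells are bit-identical
        if cell_path:
            cell.to_csv(cell_path, index=False)
            cell = pd.read_csv(cell_path)
        else:
            buf = io.StringIO()
            cell.to_csv(buf, index=False)
            buf.seek(0)
            cell = pd.read_csv(buf)
        rows.append(cell)
        if progress:
            print(f"done: {acq.name} u={updates} {corr} pf={pf}")
    return pd.concat(rows, ignore_index=True)


def curves_from_results(results: pd.DataFrame, acquisition: str,
                        correction: str, postfilter: float) -> list[SSRCurve]:
    sub = results[
        (results["acquisition"] == acquisition)
        & (results["correction"] == correction)
        & (results["postfilter_mm"] == postfilter)
    ]
    curves = []
    for s_idx, grp in sub.groupby("sphere"):
        grp = grp.sort_values("updates")
        curves.append(
            SSRCurve(
                sphere_id=int(s_idx),
                update_levels=tuple(int(u) for u in grp["updates"]),
                ssr_values=grp["ssr"].to_numpy(),
                has_local_max_flags=grp["has_local_max"].to_numpy(),
            )
        )
    return curves


def compare_protocols(results: pd.DataFrame, n_views: int | None = None
                      ) -> pd.DataFrame:
    """Rank protocols by aggregate SSR at their individual optimum.

    One row per (acquisition, correction, postfilter): the optimal update
    count, the summed per-sphere SSR there (``aggregate_ssr``, the
    comparison quantity), the combined normalized objective value, and the
    largest sphere's normalized maximum count rate; sorted by
    ``aggregate_ssr`` descending.  Protocols with no optimum (all spheres
    excluded) appear with NaN scores at the bottom.
    """
    out = []
    combos = results[["acquisition", "correction", "postfilter_mm"]].drop_duplicates()
    for _, row in combos.iterrows():
        acq, corr, pf = row["acquisition"], row["correction"], row["postfilter_mm"]
        curves = curves_from_results(results, acq, corr, pf)
        sub = results[
            (results["acquisition"] == acq)
            & (results["correction"] == corr)
            & (results["postfilter_mm"] == pf)
        ]
        rec = {
            "acquisition": acq, "system": sub["system"].iloc[0],
            "correction": corr, "postfilter_mm": pf,
            "optimal_updates": np.nan, "aggregate_ssr": np.nan,
            "combined_normalized_ssr": np.nan,
            "largest_sphere_max_rate": np.nan, "n_included_spheres": 0,
        }
        try:
            res = combined_normalized_ssr(curves, n_views=n_views,
                                          scatter_correction=corr == "SCAC",
                                          postfilter_fwhm=pf)
        except NoOptimumError:
            out.append(rec)
            continue
        at_opt = sub[(sub["updates"] == res.optimal_updates)
                     & (sub["sphere"] == 5)]
        rec.update(
            optimal_updates=res.optimal_updates,
            aggregate_ssr=res.total_ssr_at_optimum,
            combined_normalized_ssr=res.aggregate_at_optimum,
            largest_sphere_max_rate=float(at_opt["normalized_max_rate"].iloc[0]),
            n_included_spheres=len(res.included_spheres),
        )
        out.append(rec)
    frame = pd.DataFrame(out)
    return frame.sort_values("aggregate_ssr", ascending=False,
                             na_position="last").reset_index(drop=True)
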