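"""In-silico study design: parameter sweeps, growth curves, regime analysis.

Reproduces the simulation study around the modified Eden model: a grid sweep
over jump distance sigma and jump rate k_s with seeded replicates, each run
pushed through the same morphology pipeline as an imaged colony; population
(colony size) versus time curves with across-replicate mean +/- SD bands;
late-time power-law growth exponents (an Eden colony grows like N ~ t^3,
satellite-forming colonies faster); and a compact / satellite / dispersed
regime classification of each grid cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from . import eden_core
from .eden_core import SimParams, SimResult, Trajectory
from .fixtures import lattice_to_stack
from .morphology import MorphologyReport, PipelineConfig, analyze

__all__ = [
    "RegimeThresholds",
    "SweepSpec",
    "ReplicateRecord",
    "SweepSummary",
    "analyze_result",
    "run_replicate",
    "run_sweep",
    "population_curve",
    "PopulationCurve",
    "growth_exponent",
    "ExponentFit",
    "classify_replicate",
    "classify_cell",
    "compare_regimes",
    "RegimeComparison",
]

COMPACT = "compact"
SATELLITE = "satellite"
DISPERSED = "dispersed"
_REGIME_ORDER = {COMPACT: 0, SATELLITE: 1, DISPERSED: 2}


@dataclass(frozen=True)
class RegimeThresholds:
    """Cutoffs for the morphology-regime labels.

    A colony (or grid cell, on replicate means) is *dispersed* when the main
    object holds less than ``dispersed_main_fraction`` of the total filtered
    volume, *compact* when it has fewer than ``compact_max_satellites``
    satellites, and *satellite* otherwise.
    """

    compact_max_satellites: float = 0.5
    dispersed_main_fraction: float = 0.5


@dataclass(frozen=True)
class SweepSpec:
    """A sigma x k_s grid with seeded replicates.

    The default grid is the four-by-four study grid (sigma in {2, 5, 7, 10},
    k_s in {0.001, 0.05, 0.1, 0.2}) with 30 replicates per cell.  Replicate
    seeds are ``base_seed + cell_index * replicates + replicate`` with cells
    enumerated row-major over (sigma, k_s), so any single run can be redone
    in isolation.
    """

    sigma_values: tuple = (2.0, 5.0, 7.0, 10.0)
    ks_values: tuple = (0.001, 0.05, 0.1, 0.2)
    replicates: int = 30
    base_params: SimParams = field(default_factory=lambda: SimParams())
    base_seed: int = 0
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    thresholds: RegimeThresholds = field(default_factory=RegimeThresholds)
    store_trajectories: bool = True

    def __post_init__(self) -> None:
        if not self.sigma_values or not self.ks_values:
            raise ValueError("sigma_values and ks_values must be nonempty")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1 (got {self.replicates})")

    @property
    def cells(self) -> list:
        return [(s, k) for s in self.sigma_values for k in self.ks_values]

    def seed_for(self, sigma: float, ks: float, replicate: int) -> int:
        cell_index = self.cells.index((sigma, ks))
        return int(self.base_seed + cell_index * self.replicates + replicate)

    def params_for(self, sigma: float, ks: float, replicate: int) -> SimParams:
        return replace(
            self.base_params,
            sigma=float(sigma),
            k_s=float(ks),
            seed=self.seed_for(sigma, ks, replicate),
            boundary_margin=None,
        )


@dataclass
class ReplicateRecord:
    """One simulated + analysed colony inside a sweep."""

    sigma: float
    ks: float
    replicate: int
    seed: int
    status: str
    final_n_cells: int
    final_time: float
    n_satellites: int
    total_volume: float
    main_volume: float
    main_fraction: float
    satellite_volumes: list
    com_distances: list
    regime: str
    trajectory: Optional[Trajectory] = None

    def to_row(self) -> dict:
        return {
            "sigma": self.sigma,
            "k_s": self.ks,
            "replicate": self.replicate,
            "seed": self.seed,
            "status": self.status,
            "final_n_cells": self.final_n_cells,
            "final_time": self.final_time,
            "n_satellites": self.n_satellites,
            "total_volume_um3": self.total_volume,
            "main_volume_um3": self.main_volume,
            "main_fraction": self.main_fraction,
            "regime": self.regime,
        }


def analyze_result(
    result: SimResult, pipeline: Optional[PipelineConfig] = None
) -> MorphologyReport:
    """Push a simulation result through the imaging pipeline.

    The lattice is rendered as a binary stack (thresholding is skipped for
    simulated colonies, which are binary per se) and analysed exactly like a
    voxel stack.
    """
    if pipeline is None:
        pipeline = PipelineConfig()
    stack = lattice_to_stack(result.state.sites_array)
    return analyze(stack, pipeline)


def classify_replicate(
    report: MorphologyReport, thresholds: Optional[RegimeThresholds] = None
) -> str:
    """Regime label for a single analysed colony."""
    if thresholds is None:
        thresholds = RegimeThresholds()
    if report.main_fraction < thresholds.dispersed_main_fraction:
        return DISPERSED
    if report.n_satellites < thresholds.compact_max_satellites:
        return COMPACT
    return SATELLITE


def classify_cell(
    mean_satellites: float,
    mean_main_fraction: float,
    thresholds: Optional[RegimeThresholds] = None,
) -> str:
    """Regime label for a grid cell, on replicate means."""
    if thresholds is None:
        thresholds = RegimeThresholds()
    if mean_main_fraction < thresholds.dispersed_main_fraction:
        return DISPERSED
    if mean_satellites < thresholds.compact_max_satellites:
        return COMPACT
    return SATELLITE


def run_replicate(spec: SweepSpec, sigma: float, ks: float, replicate: int) -> ReplicateRecord:
    """Simulate and analyse one replicate of one grid cell."""
    params = spec.params_for(sigma, ks, replicate)
    result = eden_core.run(params)
    report = analyze_result(result, spec.pipeline)
    return ReplicateRecord(
        sigma=float(sigma),
        ks=float(ks),
        replicate=replicate,
        seed=params.seed,
        status=result.status,
        final_n_cells=result.n_cells,
        final_time=float(result.state.t),
        n_satellites=report.n_satellites,
        total_volume=report.total_volume,
        main_volume=report.main_volume,
        main_fraction=report.main_fraction,
        satellite_volumes=list(report.satellite_volumes),
        com_distances=list(report.com_distances),
        regime=classify_replicate(report, spec.thresholds),
        trajectory=result.trajectory if spec.store_trajectories else None,
    )


@dataclass
class SweepSummary:
    """All replicate records of a sweep plus per-cell aggregates."""

    spec: SweepSpec
    records: list

    def cell_records(self, sigma: float, ks: float) -> list:
        return [r for r in self.records if r.sigma == sigma and r.ks == ks]

    def table(self):
        """Replicate-level table."""
        import pandas as pd

        return pd.DataFrame([r.to_row() for r in self.records])

    def aggregate(self):
        """Per-cell means/SDs, volume CV and the regime label."""
        import pandas as pd

        rows = []
        for sigma, ks in self.spec.cells:
            recs = self.cell_records(sigma, ks)
            if not recs:
                continue
            sats = np.array([r.n_satellites for r in recs], dtype=float)
            vols = np.array([r.total_volume for r in recs], dtype=float)
            fracs = np.array([r.main_fraction for r in recs], dtype=float)
            pops = np.array([r.final_n_cells for r in recs], dtype=float)
            cv = float(vols.std(ddof=1) / vols.mean()) if len(vols) > 1 and vols.mean() > 0 else 0.0
            rows.append(
                {
                    "sigma": sigma,
                    "k_s": ks,
                    "n_replicates": len(recs),
                    "n_truncated": sum(r.status != "completed" for r in recs),
                    "mean_satellites": float(sats.mean()),
                    "sd_satellites": float(sats.std(ddof=1)) if len(sats) > 1 else 0.0,
                    "mean_final_n_cells": float(pops.mean()),
                    "mean_total_volume_um3": float(vols.mean()),
                    "cv_total_volume": cv,
                    "mean_main_fraction": float(fracs.mean()),
                    "regime": classify_cell(
                        float(sats.mean()), float(fracs.mean()), self.spec.thresholds
                    ),
                }
            )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "grid": {
                "sigma_values": list(self.spec.sigma_values),
                "ks_values": list(self.spec.ks_values),
                "replicates": self.spec.replicates,
                "base_seed": self.spec.base_seed,
            },
            "cells": self.aggregate().to_dict(orient="records"),
            "replicates": [r.to_row() for r in self.records],
        }


def run_sweep(spec: SweepSpec, progress: bool = False) -> SweepSummary:
    """Run every replicate of every grid cell and analyse each colony.

    Truncated runs (colony reached the lattice guard band) are recorded with
    their status and kept; they never abort the sweep.  The whole sweep is
    reproducible bit-for-bit from ``base_seed``.
    """
    records = []
    for sigma, ks in spec.cells:
        for rep in range(spec.replicates):
            rec = run_replicate(spec, sigma, ks, rep)
            records.append(rec)
            if progress:  # pragma: no cover
                print(
                    f"sigma={sigma} k_s={ks} rep={rep}: {rec.status}, "
                    f"N={rec.final_n_cells}, satellites={rec.n_satellites}"
                )
    return SweepSummary(spec=spec, records=records)


@dataclass
class PopulationCurve:
    """Population step functions resampled on a common uniform time grid."""

    times: np.ndarray  # (n_points,)
    values: np.ndarray  # (n_replicates, n_points)
    mean: np.ndarray
    sd: np.ndarray


def _step_eval(traj: Trajectory, grid: np.ndarray, n0: int = 1) -> np.ndarray:
    times = np.concatenate(([0.0], traj.times))
    pops = np.concatenate(([n0], traj.populations))
    idx = np.searchsorted(times, grid, side="right") - 1
    return pops[np.clip(idx, 0, len(pops) - 1)]


def population_curve(
    trajectories: Union[Trajectory, Sequence[Trajectory]],
    n_points: int = 200,
    t_max: Optional[float] = None,
) -> PopulationCurve:
    """Evaluate population-vs-time on a uniform grid, with mean +/- SD bands.

    The grid spans [0, t_max]; by default t_max is the *minimum* final time
    across the replicates, so every curve is defined on the whole grid.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    trajectories = list(trajectories)
    if not trajectories or any(len(t) == 0 for t in trajectories):
        raise ValueError("population_curve needs nonempty trajectories")
    if t_max is None:
        t_max = min(float(t.times[-1]) for t in trajectories)
    grid = np.linspace(0.0, t_max, n_points)
    values = np.vstack([_step_eval(t, grid) for t in trajectories]).astype(float)
    return PopulationCurve(
        times=grid,
        values=values,
        mean=values.mean(axis=0),
        sd=values.std(axis=0, ddof=1) if len(trajectories) > 1 else np.zeros(n_points),
    )


@dataclass
class ExponentFit:
    """Late-time power-law fit N ~ t^alpha.

    ``r2_loglog`` is the fit quality of log N vs log t; ``r2_semilog`` of
    log N vs t (an exponential would win there). ``is_power_law`` compares
    the two.
    """

    exponent: float
    r2_loglog: float
    r2_semilog: float
    n_points: int
    window: tuple

    @property
    def is_power_law(self) -> bool:
        return self.r2_loglog >= self.r2_semilog


def growth_exponent(
    times: np.ndarray,
    populations: np.ndarray,
    window: float = 0.5,
) -> ExponentFit:
    """Least-squares slope of log N vs log t over the final ``window``
    fraction of the time range.

    Points with t <= 0 are dropped (the single seed cell sits at t = 0).
    """
    times = np.asarray(times, dtype=float)
    populations = np.asarray(populations, dtype=float)
    if times.shape != populations.shape or times.ndim != 1:
        raise ValueError("times and populations must be matching 1D arrays")
    if np.any(populations <= 0):
        raise ValueError("populations must be positive")
    if not 0 < window <= 1:
        raise ValueError(f"window must be in (0, 1] (got {window})")
    keep = times > 0
    times, populations = times[keep], populations[keep]
    if len(times) < 10:
        raise ValueError("need >= 10 positive-time points to fit")
    t0, t1 = times[0], times[-1]
    t_lo = t0 + (1.0 - window) * (t1 - t0)
    sel = times >= t_lo
    if sel.sum() < 10:
        raise ValueError("fewer than 10 points in the fit window")
    t_w, n_w = times[sel], populations[sel]
    fit_ll = stats.linregress(np.log(t_w), np.log(n_w))
    fit_sl = stats.linregress(t_w, np.log(n_w))
    return ExponentFit(
        exponent=float(fit_ll.slope),
        r2_loglog=float(fit_ll.rvalue**2),
        r2_semilog=float(fit_sl.rvalue**2),
        n_points=int(sel.sum()),
        window=(float(t_lo), float(t1)),
    )


@dataclass
class RegimeComparison:
    """Two-cell comparison: final sizes, volume spread, satellite counts."""

    cell_a: tuple
    cell_b: tuple
    n_a: int
    n_b: int
    mean_final_pop_a: float
    mean_final_pop_b: float
    mean_final_pop_diff: float
    cv_volume_a: float
    cv_volume_b: float
    cv_ratio: float  # a / b; inf when b has zero spread
    satellite_test_stat: float
    satellite_test_p: float
    alternative: str


def compare_regimes(
    summary: SweepSummary,
    cell_a: tuple,
    cell_b: tuple,
    min_replicates: int = 5,
    alternative: str = "two-sided",
) -> RegimeComparison:
    """Compare two grid cells: mean final population, total-volume CV ratio,
    and a Mann-Whitney rank test on satellite counts.

    ``alternative`` follows scipy's convention for the satellite-count test
    (e.g. "greater" tests cell_a > cell_b). No biological claim attached.
    """
    recs_a = summary.cell_records(*cell_a)
    recs_b = summary.cell_records(*cell_b)
    if len(recs_a) < min_replicates or len(recs_b) < min_replicates:
        raise ValueError(
            f"need >= {min_replicates} replicates per cell "
            f"(got {len(recs_a)} and {len(recs_b)})"
        )
    pops_a = np.array([r.final_n_cells for r in recs_a], dtype=float)
    pops_b = np.array([r.final_n_cells for r in recs_b], dtype=float)
    vols_a = np.array([r.total_volume for r in recs_a], dtype=float)
    vols_b = np.array([r.total_volume for r in recs_b], dtype=float)
    sats_a = np.array([r.n_satellites for r in recs_a], dtype=float)
    sats_b = np.array([r.n_satellites for r in recs_b], dtype=float)
    cv_a = float(vols_a.std(ddof=1) / vols_a.mean()) if vols_a.mean() > 0 else 0.0
    cv_b = float(vols_b.std(ddof=1) / vols_b.mean()) if vols_b.mean() > 0 else 0.0
    cv_ratio = cv_a / cv_b if cv_b > 0 else (np.inf if cv_a > 0 else 1.0)
    if np.all(sats_a == sats_a[0]) and np.all(sats_b == sats_b[0]) and sats_a[0] == sats_b[0]:
        # degenerate: identical constant samples; no evidence of difference
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.mannwhitneyu(sats_a, sats_b, alternative=alternative)
    return RegimeComparison(
        cell_a=tuple(cell_a),
        cell_b=tuple(cell_b),
        n_a=len(recs_a),
        n_b=len(recs_b),
        mean_final_pop_a=float(pops_a.mean()),
        mean_final_pop_b=float(pops_b.mean()),
        mean_final_pop_diff=float(pops_a.mean() - pops_b.mean()),
        cv_volume_a=cv_a,
        cv_volume_b=cv_b,
        cv_ratio=float(cv_ratio),
        satellite_test_stat=float(stat),
        satellite_test_p=float(p),
        alternative=alternative,
    )
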