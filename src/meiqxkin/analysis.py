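"""Ensemble predictions: dose sweeps, bioactivation/detoxification balance,
ratio-versus-dose curves, metabolism times, CYP1A2 perturbation and a local
parameter sensitivity scan.

All operations act on a family of parameter sets (the filtered ensemble) and
report per-model values plus ensemble mean/std/median, since the calibration
data constrain the model only up to a family of equally good fits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import DETOX_SPECIES
from .model import FIXED_PARAM_NAMES, SPECIES, ParameterSet, SimulationError, Trajectory, simulate

__all__ = [
    "DEFAULT_DOSES_UM",
    "EnsembleBalanceTable",
    "MetabolismTimes",
    "dose_sweep",
    "ratio_curve",
    "metabolism_times",
    "perturb_cyp1a2",
    "sensitivity_scan",
]

log = logging.getLogger(__name__)

#: dose grid (µM) used for ensemble simulations
DEFAULT_DOSES_UM = (0.05, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 15.0, 30.0, 50.0, 75.0, 100.0)

#: horizon (h) by which every fitted model has reached steady state
DEFAULT_T_END_H = 180.0

#: output grid resolution for the 180 h sweeps
SWEEP_GRID_POINTS = 721

#: "complete metabolism" threshold: residual MeIQx fraction of the dose
DEFAULT_COMPLETION_FRACTION = 0.005

_IDX_DETOX = [SPECIES.index(s) for s in DETOX_SPECIES]
_IDX_PGC = SPECIES.index("potential_genotoxic")
_IDX_MEIQX = SPECIES.index("meiqx")
_IDX_HONH = SPECIES.index("honh_meiqx")


@dataclass
class EnsembleBalanceTable:
    """Balance records per (model, dose) plus per-dose ensemble statistics.

    ``per_model`` columns: model_id, dose_uM, time_h, detoxification_uM,
    bioactivation_uM, ratio, percent_bioactivated, percent_detoxified,
    percent_residual.  ``summary`` aggregates mean/std/median over models.
    """

    per_model: pd.DataFrame
    summary: pd.DataFrame


@dataclass(frozen=True)
class MetabolismTimes:
    """Threshold-crossing times (h); NaN when the horizon is too short."""

    t50: float
    t90: float
    t_complete: float

    @property
    def complete(self) -> bool:
        return not math.isnan(self.t_complete)


def _as_models(models) -> list[tuple[str, ParameterSet]]:
    if hasattr(models, "accepted"):  # Ensemble
        return [(f"fit-{f.start_index}", f.params) for f in models.accepted]
    out = []
    for i, m in enumerate(models):
        if isinstance(m, ParameterSet):
            out.append((f"model-{i}", m))
        else:
            out.append((str(m[0]), m[1]))
    return out


def _balance_row(state: np.ndarray, dose_M: float) -> dict:
    detox = float(state[_IDX_DETOX].sum()) * 1e6
    bioact = float(state[_IDX_PGC]) * 1e6
    residual = float(state[_IDX_MEIQX] + state[_IDX_HONH]) * 1e6
    dose_uM = dose_M * 1e6
    return {
        "detoxification_uM": detox,
        "bioactivation_uM": bioact,
        "ratio": bioact / detox if detox > 0 else np.nan,
        "percent_detoxified": 100.0 * detox / dose_uM if dose_uM > 0 else 0.0,
        "percent_bioactivated": 100.0 * bioact / dose_uM if dose_uM > 0 else 0.0,
        "percent_residual": 100.0 * residual / dose_uM if dose_uM > 0 else 0.0,
    }


def dose_sweep(
    models,
    doses_uM: Sequence[float] = DEFAULT_DOSES_UM,
    t_end: float = DEFAULT_T_END_H,
) -> EnsembleBalanceTable:
    """Simulate every model at every dose and tabulate the balance at t_end.

    Models whose simulation fails at some dose are excluded with a warning,
    attributed to their model_id.
    """
    pairs = _as_models(models)
    if not pairs:
        raise ValueError("dose_sweep needs a non-empty ensemble")
    t_grid = np.linspace(0.0, t_end, SWEEP_GRID_POINTS)
    rows = []
    for model_id, params in pairs:
        model_rows = []
        try:
            for dose in doses_uM:
                traj = simulate(params, dose * 1e-6, t_grid=t_grid)
                row = {"model_id": model_id, "dose_uM": float(dose), "time_h": t_end}
                row.update(_balance_row(traj.states[-1], dose * 1e-6))
                model_rows.append(row)
        except SimulationError as exc:
            log.warning("excluding %s from sweep: %s", model_id, exc)
            continue
        rows.extend(model_rows)
    if not rows:
        raise SimulationError("every ensemble member failed to simulate the sweep")
    per_model = pd.DataFrame(rows)
    summary = (
        per_model.groupby("dose_uM")
        .agg(
            detoxification_uM_mean=("detoxification_uM", "mean"),
            detoxification_uM_std=("detoxification_uM", "std"),
            bioactivation_uM_mean=("bioactivation_uM", "mean"),
            bioactivation_uM_std=("bioactivation_uM", "std"),
            ratio_mean=("ratio", "mean"),
            ratio_median=("ratio", "median"),
            percent_bioactivated_mean=("percent_bioactivated", "mean"),
            percent_detoxified_mean=("percent_detoxified", "mean"),
            percent_residual_mean=("percent_residual", "mean"),
            n_models=("model_id", "nunique"),
        )
        .reset_index()
    )
    summary[["detoxification_uM_std", "bioactivation_uM_std"]] = summary[
        ["detoxification_uM_std", "bioactivation_uM_std"]
    ].fillna(0.0)
    return EnsembleBalanceTable(per_model=per_model, summary=summary)


@dataclass
class RatioCurve:
    """Bioactivation/detoxification ratio per (model, dose, time)."""

    table: pd.DataFrame
    argmax: pd.DataFrame  # dose of maximal ratio per (model_id, time_h)

    def median_curve(self, time_h: float) -> pd.Series:
        t = self.table[self.table["time_h"] == time_h]
        return t.groupby("dose_uM")["ratio"].median()


def ratio_curve(
    models,
    doses_uM: Sequence[float] = DEFAULT_DOSES_UM,
    times_h: Sequence[float] = (6.0, 24.0, 72.0, 120.0),
) -> RatioCurve:
    """Ratio-versus-dose table at the requested exposure times."""
    pairs = _as_models(models)
    if not pairs:
        raise ValueError("ratio_curve needs a non-empty ensemble")
    times_h = sorted(float(t) for t in times_h)
    t_grid = np.unique(np.concatenate([np.linspace(0.0, times_h[-1], SWEEP_GRID_POINTS), times_h]))
    rows = []
    for model_id, params in pairs:
        try:
            for dose in doses_uM:
                traj = simulate(params, dose * 1e-6, t_grid=t_grid)
                for t in times_h:
                    state = traj.states[int(np.searchsorted(t_grid, t))]
                    row = {"model_id": model_id, "dose_uM": float(dose), "time_h": t}
                    row.update(_balance_row(state, dose * 1e-6))
                    rows.append(row)
        except SimulationError as exc:
            log.warning("excluding %s from ratio curve: %s", model_id, exc)
    if not rows:
        raise SimulationError("every ensemble member failed to simulate the ratio curve")
    table = pd.DataFrame(rows)
    defined = table.dropna(subset=["ratio"])
    argmax = (
        defined.loc[defined.groupby(["model_id", "time_h"])["ratio"].idxmax()]
        [["model_id", "time_h", "dose_uM", "ratio"]]
        .rename(columns={"dose_uM": "argmax_dose_uM", "ratio": "max_ratio"})
        .reset_index(drop=True)
    )
    return RatioCurve(table=table, argmax=argmax)


def _cross_down(times: np.ndarray, y: np.ndarray, threshold: float) -> float:
    """First time a non-increasing signal reaches ``threshold``, linearly
    interpolated; NaN when never crossed within the grid."""
    below = np.nonzero(y <= threshold)[0]
    if len(below) == 0:
        return float("nan")
    j = int(below[0])
    if j == 0:
        return float(times[0])
    t0, t1, y0, y1 = times[j - 1], times[j], y[j - 1], y[j]
    if y0 == y1:
        return float(t1)
    return float(t0 + (y0 - threshold) * (t1 - t0) / (y0 - y1))


def metabolism_times(
    traj: Trajectory, completion_fraction: float = DEFAULT_COMPLETION_FRACTION
) -> MetabolismTimes:
    """Times at which 50%, 90% and (1 - completion_fraction) of the parent
    MeIQx has been metabolised; thresholds never crossed are NaN-flagged."""
    if not 0.0 < completion_fraction < 1.0:
        raise ValueError("completion_fraction must be in (0, 1)")
    y = traj.species("meiqx")
    d = traj.dose
    return MetabolismTimes(
        t50=_cross_down(traj.times, y, 0.5 * d),
        t90=_cross_down(traj.times, y, 0.1 * d),
        t_complete=_cross_down(traj.times, y, completion_fraction * d),
    )


def perturb_cyp1a2(
    models,
    factor: float,
    doses_uM: Sequence[float] = (1.0, 10.0, 100.0),
    t_end: float = DEFAULT_T_END_H,
) -> EnsembleBalanceTable:
    """Rescale every member's total CYP1A2 concentration and re-run the
    dose sweep (the Fig-10-style in-silico knockdown/overexpression)."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    pairs = _as_models(models)
    perturbed = [(mid, p.with_cyp1a2_scaled(factor)) for mid, p in pairs]
    return dose_sweep(perturbed, doses_uM=doses_uM, t_end=t_end)


def sensitivity_scan(
    params: ParameterSet,
    factor: float = 10.0,
    dose_uM: float = 10.0,
    t_end: float = DEFAULT_T_END_H,
) -> pd.DataFrame:
    """Perturb each of the 16 kinetic parameters by x factor and / factor
    and report the relative change of the genotoxic pool at t_end,
    ranked by largest absolute effect."""
    if factor <= 1.0:
        raise ValueError("factor must be > 1")
    from dataclasses import replace

    dose_M = dose_uM * 1e-6
    t_grid = np.linspace(0.0, t_end, SWEEP_GRID_POINTS)
    base = simulate(params, dose_M, t_grid=t_grid).states[-1, _IDX_PGC]
    rows = []
    for name in FIXED_PARAM_NAMES:
        effects = {}
        for tag, f in (("up", factor), ("down", 1.0 / factor)):
            p = replace(params, **{name: getattr(params, name) * f})
            pgc = simulate(p, dose_M, t_grid=t_grid).states[-1, _IDX_PGC]
            effects[tag] = (pgc - base) / base if base > 0 else np.nan
        rows.append(
            {
                "parameter": name,
                "rel_change_up": effects["up"],
                "rel_change_down": effects["down"],
                "max_abs_effect": max(abs(effects["up"]), abs(effects["down"])),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("max_abs_effect", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
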