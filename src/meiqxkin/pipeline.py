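"""End-to-end orchestration: prepare -> fit -> filter -> predict -> report.

Runs the full analysis from a single configuration: assemble the
calibration set (packaged HL-1 table or a user CSV), fit the requested
enzyme-partition hypotheses by multistart least squares, filter the fits
into ensembles, simulate dose sweeps and CYP1A2 perturbations with the
accepted ensemble, and write all tables plus a reproducibility manifest
(config hash, seed, library versions, per-stage record counts).

The single global seed is expanded into independent per-stage seeds with
``numpy.random.SeedSequence(seed).spawn``, so each stage is individually
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import DEFAULT_DOSES_UM, dose_sweep, perturb_cyp1a2, ratio_curve
from .dataset import (
    RAW_VOCABULARY,
    ObservationSet,
    hl1_dataset,
    observations_from_table,
    percent_to_concentration,
)
from .fitting import (
    P_VALUE_GATE,
    Ensemble,
    filter_fits,
    fit_multistart,
    _local_chi2_table,
)

__all__ = ["RunConfig", "run_pipeline", "validate_input"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    seed: int
    data: str = "hl1"  # 'hl1' builtin or a CSV path
    hypotheses: tuple[str, ...] = ("saturation", "dose_dependent")
    n_starts: int = 1000
    doses_uM: tuple[float, ...] = DEFAULT_DOSES_UM
    t_end: float = 180.0
    perturbation_factors: tuple[float, ...] = (0.1, 10.0)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for hyp in self.hypotheses:
            if hyp not in ("saturation", "dose_dependent"):
                raise ValueError(f"unknown hypothesis {hyp!r}")
        if self.data != "hl1" and not Path(self.data).exists():
            raise ValueError(f"data path does not exist: {self.data}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("hypotheses", "doses_uM", "perturbation_factors"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        """Digest of the analysis-relevant configuration (output location
        excluded: it does not change what is computed)."""
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_input(csv_path) -> pd.DataFrame:
    """Load and schema-check a measurement CSV.

    Required columns: dose_uM, time_h, compound, concentration_uM (or a
    ``value`` column paired with ``value_kind`` in {percent, concentration}).
    All row-level problems are collected and reported together; nothing is
    loaded partially.
    """
    path = Path(csv_path)
    if not path.exists():
        raise ValueError(f"data file not found: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: file contains no measurement rows")

    errors: list[str] = []
    if "value_kind" in df.columns:
        needed = {"dose_uM", "time_h", "compound", "value", "value_kind"}
    else:
        needed = {"dose_uM", "time_h", "compound", "concentration_uM"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    for i, row in df.iterrows():
        if row["compound"] not in RAW_VOCABULARY:
            errors.append(
                f"row {i}: unknown compound {row['compound']!r} "
                f"(allowed: {sorted(RAW_VOCABULARY)})"
            )
        try:
            dose = float(row["dose_uM"])
            t = float(row["time_h"])
            if dose < 0 or t < 0:
                errors.append(f"row {i}: dose/time must be >= 0")
        except (TypeError, ValueError):
            errors.append(f"row {i}: non-numeric dose or time")
            continue
        if "value_kind" in df.columns:
            kind = row["value_kind"]
            if kind not in ("percent", "concentration"):
                errors.append(f"row {i}: value_kind must be percent|concentration")
            elif kind == "percent" and not 0 <= float(row["value"]) <= 100:
                errors.append(f"row {i}: percent {row['value']} outside [0, 100]")
            elif float(row["value"]) < 0:
                errors.append(f"row {i}: negative concentration")
        elif float(row["concentration_uM"]) < 0:
            errors.append(f"row {i}: negative concentration")
    if errors:
        raise ValueError(f"{path}: invalid measurement table:\n" + "\n".join(errors))

    if "value_kind" in df.columns:
        conc = [
            percent_to_concentration(float(r["value"]), float(r["dose_uM"]))
            if r["value_kind"] == "percent"
            else float(r["value"])
            for _, r in df.iterrows()
        ]
        df = df.assign(concentration_uM=conc)
    return df


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Independent per-stage substreams below 2^31 from one global seed."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and return (and write) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
        "status": "running",
    }
    stage = "prepare"
    try:
        t0 = time.time()
        if cfg.data == "hl1":
            obs = hl1_dataset()
        else:
            obs = observations_from_table(validate_input(cfg.data))
        obs.table.to_csv(out / "observations.csv", index=False)
        manifest["stages"]["prepare"] = {
            "n_records": len(obs),
            "doses_uM": obs.doses_uM,
            "seconds": round(time.time() - t0, 2),
        }

        seeds = _stage_seeds(cfg.seed, len(cfg.hypotheses))
        ensembles: dict[str, Ensemble] = {}
        selection_rows = []
        local_tables = []
        for hyp, hseed in zip(cfg.hypotheses, seeds):
            stage = f"fit:{hyp}"
            t0 = time.time()
            fits = fit_multistart(hyp, obs, n_starts=cfg.n_starts, seed=hseed)
            stage = f"filter:{hyp}"
            ens = filter_fits(fits, obs)
            ens.to_json(out / f"ensemble_{hyp}.json")
            ensembles[hyp] = ens
            local_tables.append(_local_chi2_table(fits[0], obs, hyp))
            selection_rows.append(
                {
                    "hypothesis": hyp,
                    "best_chi2": fits[0].chi2,
                    "best_p_value": fits[0].p_value,
                    "n_fits": len(fits),
                    "n_passing_gate": sum(f.p_value >= P_VALUE_GATE for f in fits),
                    "n_accepted": len(ens),
                    "verdict": "accepted" if len(ens) else "rejected",
                }
            )
            manifest["stages"][f"fit:{hyp}"] = {
                "seed": hseed,
                "n_starts": cfg.n_starts,
                "n_accepted": len(ens),
                "best_chi2": fits[0].chi2,
                "seconds": round(time.time() - t0, 2),
            }
        stage = "report"
        pd.DataFrame(selection_rows).to_csv(out / "model_selection.csv", index=False)
        pd.concat(local_tables, ignore_index=True).to_csv(
            out / "local_chi2.csv", index=False
        )

        # predictions with the best available ensemble (prefer dose-dependent)
        pred_ens = None
        for hyp in ("dose_dependent", "saturation"):
            if hyp in ensembles and len(ensembles[hyp]):
                pred_ens = ensembles[hyp]
                break
        if pred_ens is None:
            manifest["stages"]["predict"] = {"skipped": "no accepted models"}
            log.warning("no accepted models; skipping prediction stages")
        else:
            stage = "sweep"
            t0 = time.time()
            sweep = dose_sweep(pred_ens, doses_uM=cfg.doses_uM, t_end=cfg.t_end)
            sweep.per_model.to_csv(out / "balance_per_model.csv", index=False)
            sweep.summary.to_csv(out / "balance_summary.csv", index=False)
            rc = ratio_curve(pred_ens, doses_uM=cfg.doses_uM)
            rc.table.to_csv(out / "ratio_curve.csv", index=False)
            manifest["stages"]["sweep"] = {
                "ensemble": pred_ens.hypothesis,
                "n_models": len(pred_ens),
                "n_rows": len(sweep.per_model),
                "seconds": round(time.time() - t0, 2),
            }
            stage = "perturb"
            for factor in cfg.perturbation_factors:
                t0 = time.time()
                pert = perturb_cyp1a2(pred_ens, factor, t_end=cfg.t_end)
                tag = str(factor).replace(".", "p")
                pert.summary.to_csv(out / f"perturb_cyp1a2_{tag}.csv", index=False)
                manifest["stages"][f"perturb:{factor}"] = {
                    "seconds": round(time.time() - t0, 2)
                }
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=float)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)
    return manifest
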