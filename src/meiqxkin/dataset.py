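"""Calibration data handling: the in-house HL-1 hepatocyte measurement table,
percentage-to-concentration conversion, compound aggregation, mass-balance
closure and detoxification/bioactivation summaries.

The packaged fixture holds the measured metabolite concentrations (µM) in
HL-1 human hepatocytes 24 h after treatment with 1, 10 and 50 µM MeIQx.
Two pairs of chemically related metabolites are aggregated into generic
pools: IQx-8-COOH + 8-CH2-OH-IQx -> C-Hydroxy-MeIQx (all C8-hydroxylated
compounds) and 7-oxo-MeIQx + N-desmethyl-7-oxo-MeIQx -> oxo-MeIQx.  The
labile intermediates (8-CH2-OH-IQx, HONH-MeIQx) were not detected at 24 h
and enter as zeros.  Treating the culture as a closed system, the
unmeasured Potential-Genotoxic-Compound pool is estimated by difference:
PGC = dose - sum(measured species at 24 h).

The assembled calibration set has 8 compounds x 2 time points x 3 doses
= 48 records; t=0 rows are the known initial condition (dose, 0, ..., 0).
Fitting operates on log concentrations with a constant log-scale weight
(sigma = 0.3 natural-log units); zeros are floored at 1e-10 M before the
log transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import SPECIES

__all__ = [
    "RAW_VOCABULARY",
    "MEASURED_SPECIES",
    "DETOX_SPECIES",
    "ObservationSet",
    "BalanceRecord",
    "percent_to_concentration",
    "aggregate_compounds",
    "close_mass_balance",
    "balance_summary",
    "hl1_dataset",
    "observations_from_table",
]

#: raw compound vocabulary -> reduced model species
RAW_VOCABULARY: dict[str, str] = {
    "MeIQx": "meiqx",
    "IQx-8-COOH": "c_hydroxy_meiqx",
    "8-CH2-OH-IQx": "c_hydroxy_meiqx",
    "C-Hydroxy-MeIQx": "c_hydroxy_meiqx",
    "MeIQx-N2-Gl": "meiqx_n2_gl",
    "MeIQx-N2-SO3H": "meiqx_n2_so3h",
    "7-oxo-MeIQx": "oxo_meiqx",
    "N-desmethyl-7-oxo-MeIQx": "oxo_meiqx",
    "oxo-MeIQx": "oxo_meiqx",
    "HONH-MeIQx": "honh_meiqx",
    "HON-MeIQx-N2-Gl": "hon_meiqx_n2_gl",
    "Potential-Genotoxic-Compound": "potential_genotoxic",
}

#: canonical display name per reduced species (inverse of the aggregation)
DISPLAY_NAMES: dict[str, str] = {
    "meiqx": "MeIQx",
    "c_hydroxy_meiqx": "C-Hydroxy-MeIQx",
    "meiqx_n2_gl": "MeIQx-N2-Gl",
    "meiqx_n2_so3h": "MeIQx-N2-SO3H",
    "oxo_meiqx": "oxo-MeIQx",
    "honh_meiqx": "HONH-MeIQx",
    "hon_meiqx_n2_gl": "HON-MeIQx-N2-Gl",
    "potential_genotoxic": "Potential-Genotoxic-Compound",
}

#: reduced species measured directly at 24 h (everything but HONH and PGC)
MEASURED_SPECIES = (
    "meiqx",
    "meiqx_n2_gl",
    "meiqx_n2_so3h",
    "oxo_meiqx",
    "c_hydroxy_meiqx",
    "hon_meiqx_n2_gl",
)

#: species whose sum defines the detoxification pool
DETOX_SPECIES = (
    "meiqx_n2_gl",
    "meiqx_n2_so3h",
    "oxo_meiqx",
    "c_hydroxy_meiqx",
    "hon_meiqx_n2_gl",
)

#: constant log-scale measurement weight.  The source measurements are
#: single-replicate LC-MS quantifications printed at 1-2 significant figures
#: and were fitted after log transformation with toolbox-estimated errors;
#: 0.3 natural-log units (~30-35% relative, ~0.13 decades) is the constant
#: weight consistent with that processing.  See docs/methods.md.
DEFAULT_SIGMA_LOG = 0.3
DEFAULT_LOG_FLOOR_M = 1e-10


@dataclass(frozen=True)
class BalanceRecord:
    """Detoxification/bioactivation totals (µM) and their ratio at one dose."""

    dose_uM: float
    detoxification_uM: float
    bioactivation_uM: float
    ratio: float
    ratio_defined: bool = True

    def rounded_ratio(self) -> float:
        """Ratio at 3 decimals, round-half-up (table reporting convention:
        5/16 = 0.3125 prints as 0.313)."""
        from decimal import ROUND_HALF_UP, Decimal

        return float(Decimal(repr(self.ratio)).quantize(Decimal("0.001"), ROUND_HALF_UP))


@dataclass(frozen=True)
class ObservationSet:
    """Calibration records: one row per (compound, time, dose).

    ``table`` columns: compound (reduced species name), time_h, dose_uM,
    y_obs_M, sigma_log.  Rows are sorted by (dose, time, species order) so
    residual vectors are reproducible.
    """

    table: pd.DataFrame
    sigma_log: float = DEFAULT_SIGMA_LOG
    log_floor_M: float = DEFAULT_LOG_FLOOR_M

    def __post_init__(self) -> None:
        required = {"compound", "time_h", "dose_uM", "y_obs_M", "sigma_log"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"observation table lacks columns: {sorted(missing)}")
        unknown = set(self.table["compound"]) - set(SPECIES)
        if unknown:
            raise ValueError(f"unknown reduced species: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def doses_uM(self) -> list[float]:
        return sorted(self.table["dose_uM"].unique().tolist())

    @property
    def times_h(self) -> list[float]:
        return sorted(self.table["time_h"].unique().tolist())

    def value(self, compound: str, time_h: float, dose_uM: float) -> float:
        """Observed concentration (M) for a single record."""
        t = self.table
        m = (
            (t["compound"] == compound)
            & (t["time_h"] == time_h)
            & (t["dose_uM"] == dose_uM)
        )
        rows = t.loc[m, "y_obs_M"]
        if len(rows) != 1:
            raise KeyError(f"no unique record ({compound}, {time_h} h, {dose_uM} µM)")
        return float(rows.iloc[0])


def percent_to_concentration(percent: float, dose_uM: float) -> float:
    """Convert percent-of-initial-dose to µM: c = dose * percent / 100."""
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"percent must lie in [0, 100], got {percent}")
    if dose_uM < 0.0:
        raise ValueError(f"dose must be >= 0, got {dose_uM}")
    return dose_uM * percent / 100.0


def aggregate_compounds(measurements: Mapping[str, float]) -> dict[str, float]:
    """Reduce raw compound measurements to the 8 model species by summing
    the C8-hydroxylated pair and the oxo pair; other names pass through."""
    out: dict[str, float] = {}
    for name, value in measurements.items():
        if name not in RAW_VOCABULARY:
            raise ValueError(
                f"unknown compound {name!r}; expected one of {sorted(RAW_VOCABULARY)}"
            )
        species = RAW_VOCABULARY[name]
        out[species] = out.get(species, 0.0) + float(value)
    return out


def close_mass_balance(
    measured: Mapping[str, float] | Iterable[float], dose_uM: float, tol: float = 1e-9
) -> float:
    """Potential-Genotoxic-Compound (µM) as the closed-system remainder
    ``dose - sum(measured at 24 h)``."""
    values = list(measured.values()) if isinstance(measured, Mapping) else list(measured)
    total = math.fsum(float(v) for v in values)
    if total > dose_uM + tol:
        raise ValueError(
            f"measured species sum to {total:g} µM which exceeds the dose "
            f"{dose_uM:g} µM: inconsistent with a closed system"
        )
    return max(dose_uM - total, 0.0)


def balance_summary(reduced: Mapping[str, float], dose_uM: float) -> BalanceRecord:
    """Detoxification/bioactivation totals from the 8 reduced species (µM).

    Detoxification = MeIQx-N2-Gl + MeIQx-N2-SO3H + oxo + C-Hydroxy + HON-Gl;
    Bioactivation = Potential-Genotoxic-Compound; ratio = bioact/detox.
    """
    missing = set(SPECIES) - set(reduced)
    if missing:
        raise ValueError(f"balance_summary needs all 8 species; missing {sorted(missing)}")
    detox = math.fsum(float(reduced[s]) for s in DETOX_SPECIES)
    bioact = float(reduced["potential_genotoxic"])
    if detox > 0.0:
        return BalanceRecord(dose_uM, detox, bioact, bioact / detox)
    if bioact == 0.0:
        return BalanceRecord(dose_uM, 0.0, 0.0, 0.0)
    return BalanceRecord(dose_uM, 0.0, bioact, float("nan"), ratio_defined=False)


def observations_from_table(
    measured: pd.DataFrame,
    sigma_log: float = DEFAULT_SIGMA_LOG,
    log_floor_M: float = DEFAULT_LOG_FLOOR_M,
) -> ObservationSet:
    """Assemble a calibration :class:`ObservationSet` from a measurement
    table (columns dose_uM, time_h, compound, concentration_uM; raw or
    reduced compound names, concentrations in µM).

    Per dose and measured time point the raw compounds are aggregated,
    HONH-MeIQx is set to zero where undetected, the genotoxic pool is
    closed by mass balance, and noise-free t=0 rows (dose, 0, ..., 0) are
    synthesised.
    """
    records: list[tuple[str, float, float, float]] = []
    for dose, dose_df in measured.groupby("dose_uM"):
        dose = float(dose)
        records.extend((sp, 0.0, dose, (dose if sp == "meiqx" else 0.0)) for sp in SPECIES)
        for time_h, tdf in dose_df.groupby("time_h"):
            time_h = float(time_h)
            if time_h == 0.0:
                continue
            reduced = aggregate_compounds(
                dict(zip(tdf["compound"], tdf["concentration_uM"]))
            )
            reduced.setdefault("honh_meiqx", 0.0)
            if "potential_genotoxic" not in reduced:
                reduced["potential_genotoxic"] = close_mass_balance(reduced, dose)
            missing = set(SPECIES) - set(reduced)
            if missing:
                raise ValueError(
                    f"dose {dose} µM, t={time_h} h: missing species {sorted(missing)}"
                )
            records.extend((sp, time_h, dose, reduced[sp]) for sp in SPECIES)

    table = pd.DataFrame(records, columns=["compound", "time_h", "dose_uM", "conc_uM"])
    table["y_obs_M"] = table["conc_uM"] * 1e-6
    table["sigma_log"] = sigma_log
    table = table.drop(columns="conc_uM")
    order = {sp: i for i, sp in enumerate(SPECIES)}
    table = (
        table.assign(_k=table["compound"].map(order))
        .sort_values(["dose_uM", "time_h", "_k"], kind="mergesort")
        .drop(columns="_k")
        .reset_index(drop=True)
    )
    return ObservationSet(table=table, sigma_log=sigma_log, log_floor_M=log_floor_M)


def hl1_dataset(
    sigma_log: float = DEFAULT_SIGMA_LOG,
    log_floor_M: float = DEFAULT_LOG_FLOOR_M,
) -> ObservationSet:
    """The packaged HL-1 hepatocyte calibration set (48 records)."""
    with resources.files("meiqxkin.data").joinpath("hl1_table1.csv").open() as fh:
        raw = pd.read_csv(fh)
    return observations_from_table(raw, sigma_log=sigma_log, log_floor_M=log_floor_M)


def balance_records_from_observations(obs: ObservationSet, time_h: float = 24.0) -> list[BalanceRecord]:
    """Per-dose balance summaries computed from an observation set."""
    out = []
    for dose in obs.doses_uM:
        reduced = {
            sp: obs.value(sp, time_h, dose) * 1e6  # back to µM
            for sp in SPECIES
        }
        out.append(balance_summary(reduced, dose))
    return out
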