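"""IPCC pool aggregation, CO2 conversion, indicator tables and LULUCF
accounting arithmetic.

Sign convention: a carbon stock gain is a removal (negative emission);
emissions = -(delta C) x 44/12, so a net sink plots below zero.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pools import IPCC_CATEGORIES, PoolVector

CO2_PER_C = 44.0 / 12.0
IPCC_POOL_NAMES = tuple(IPCC_CATEGORIES)


@dataclass
class AnnualResult:
    """Per-year outcome of one simulated scenario year.

    Stock changes are t C (positive = gain); harvest is t C of removed
    products plus extracted residues, volumes in Mm3; emissions in
    Mt CO2 eq. (positive = source).
    """

    year: int
    stock_change: dict[str, float]                 # per IPCC pool, t C
    stocks: dict[str, float]                       # end-of-year totals, t C
    harvest_c: dict[tuple[str, str], float]        # (dist_id, forest_type) -> t C
    harvest_volume: dict[tuple[str, str], float]   # (dist_id, forest_type) -> Mm3
    deficit: dict[tuple[str, str], float]          # (dist_id, forest_type) -> t C
    demand: dict[tuple[str, str], float]           # (dist_id, forest_type) -> t C
    area_by_type: dict[str, float]                 # ha
    area_by_age_class: dict[int, float]            # 10-yr class index -> ha
    nai: dict[str, float]                          # m3/ha/yr
    growth_c: float = 0.0                          # t C entering live pools
    atm_flux_c: float = 0.0                        # decay + burn flux, t C
    products_c: float = 0.0                        # removals incl. residues, t C

    @property
    def total_stock_change(self) -> float:
        return sum(self.stock_change.values())

    @property
    def emissions_mtco2(self) -> float:
        return stock_change_to_emissions(self.total_stock_change / 1e6)

    @property
    def total_harvest_c(self) -> float:
        return sum(self.harvest_c.values())

    @property
    def sanitary_share(self) -> float:
        tot = self.total_harvest_c
        if tot == 0:
            return 0.0
        san = sum(v for (d, _), v in self.harvest_c.items() if d in ("3a", "3b"))
        return san / tot


@dataclass
class AccountingReport:
    """LULUCF accounting arithmetic for one commitment period."""

    period: tuple[int, int]
    cumulative_balance: float      # Mt CO2 eq., projected emissions sum
    frl_annual: float              # Mt CO2 eq./yr (magnitude used)
    offsets_annual: float          # HWP + afforestation, Mt CO2 eq./yr
    frl_units: float               # |frl_annual| x period length
    offset_units: float            # |offsets_annual| x period length
    gross_deficit: float           # cumulative + FRL units
    net_deficit: float             # gross - offsets
    annual_mean: float

    def as_dict(self) -> dict:
        return {
            "period": list(self.period),
            "cumulative_balance_mtco2": self.cumulative_balance,
            "frl_annual_mtco2": self.frl_annual,
            "offsets_annual_mtco2": self.offsets_annual,
            "frl_units_mtco2": self.frl_units,
            "offset_units_mtco2": self.offset_units,
            "gross_deficit_mtco2": self.gross_deficit,
            "net_deficit_mtco2": self.net_deficit,
            "annual_mean_mtco2": self.annual_mean,
        }


def aggregate_ipcc(state) -> dict[str, float]:
    """Total t C in the four IPCC categories (living biomass, deadwood,
    litter, soil); their sum equals the sum over all model pools."""
    totals = {name: 0.0 for name in IPCC_CATEGORIES}
    for c in state.cohorts:
        a = c.pools.a * c.area
        for name, idx in IPCC_CATEGORIES.items():
            totals[name] += float(a[list(idx)].sum())
    return totals


def stock_change_to_emissions(delta_c_mt: float) -> float:
    """Convert a carbon stock change (Mt C) to Mt CO2 eq.; stock gain is
    a negative emission (sink)."""
    return -float(delta_c_mt) * CO2_PER_C


def accounting_arithmetic(
    emissions: dict[int, float] | pd.Series,
    frl_annual: float,
    offsets_annual: float,
    period: tuple[int, int],
) -> AccountingReport:
    """Cumulative accounting balance of a period against a reference level.

    ``emissions`` maps year -> Mt CO2 eq. and must cover the period.
    Period units = |frl_annual| x period length; offset contribution =
    |offsets_annual| x period length; gross deficit = cumulative balance
    + FRL units; net = gross - offsets.
    """
    y0, y1 = period
    years = list(range(y0, y1 + 1))
    if not years:
        raise ValueError("empty accounting period")
    if isinstance(emissions, pd.Series):
        emissions = emissions.to_dict()
    missing = [y for y in years if y not in emissions]
    if missing:
        raise ValueError(f"emission series missing years {missing}")
    cumulative = float(sum(emissions[y] for y in years))
    n = len(years)
    frl_units = abs(frl_annual) * n
    offset_units = abs(offsets_annual) * n
    gross = cumulative + frl_units
    return AccountingReport(
        period=period,
        cumulative_balance=cumulative,
        frl_annual=frl_annual,
        offsets_annual=offsets_annual,
        frl_units=frl_units,
        offset_units=offset_units,
        gross_deficit=gross,
        net_deficit=gross - offset_units,
        annual_mean=cumulative / n,
    )


# ---------------------------------------------------------------------------
# indicator tables

def emissions_table(results: list[AnnualResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"year": r.year}
        for name in IPCC_POOL_NAMES:
            row[f"d_{name}_tc"] = r.stock_change[name]
        row["total_dc_tc"] = r.total_stock_change
        row["net_co2_mt"] = r.emissions_mtco2
        rows.append(row)
    return pd.DataFrame(rows)


def harvest_table(results: list[AnnualResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        dists = sorted({d for d, _ in r.harvest_c})
        for d in dists:
            c = sum(v for (dd, _), v in r.harvest_c.items() if dd == d)
            v = sum(v for (dd, _), v in r.harvest_volume.items() if dd == d)
            rows.append({"year": r.year, "dist_id": d, "harvest_tc": c,
                         "harvest_mm3": v})
    return pd.DataFrame(rows)


def species_share_table(results: list[AnnualResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        total = sum(r.area_by_type.values())
        for ft, a in sorted(r.area_by_type.items()):
            rows.append({"year": r.year, "forest_type": ft, "area_ha": a,
                         "area_share": a / total if total else 0.0})
    return pd.DataFrame(rows)


def growing_stock_index(results: list[AnnualResult]) -> pd.DataFrame:
    """Living-biomass carbon relative to the first simulated year."""
    base = results[0].stocks["living_biomass"]
    return pd.DataFrame(
        {
            "year": [r.year for r in results],
            "living_biomass_tc": [r.stocks["living_biomass"] for r in results],
            "index": [r.stocks["living_biomass"] / base for r in results],
        }
    )


def age_structure_table(results: list[AnnualResult],
                        years: tuple[int, ...] = (2018, 2040, 2070)) -> pd.DataFrame:
    rows = []
    for r in results:
        if r.year not in years:
            continue
        for cls, a in sorted(r.area_by_age_class.items()):
            rows.append({"year": r.year, "age_class": cls,
                         "age_lo": cls * 10, "age_hi": cls * 10 + 9, "area_ha": a})
    return pd.DataFrame(rows)


def nai_table(results: list[AnnualResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for ft, v in sorted(r.nai.items()):
            rows.append({"year": r.year, "forest_type": ft, "nai_m3ha": v})
    return pd.DataFrame(rows)


def report_indicators(results: list[AnnualResult]) -> dict[str, pd.DataFrame]:
    """The standard per-scenario indicator tables."""
    if not results:
        raise ValueError("empty result sequence")
    return {
        "emissions": emissions_table(results),
        "harvest": harvest_table(results),
        "species_shares": species_share_table(results),
        "growing_stock": growing_stock_index(results),
        "age_structure": age_structure_table(results),
        "nai": nai_table(results),
    }


def write_reports(results: list[AnnualResult], out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in report_indicators(results).items():
        df.to_csv(out / f"{name}.csv", index=False)


def write_accounting(report: AccountingReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.as_dict(), fh, indent=2)
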