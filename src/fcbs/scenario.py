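"""Scenario engines: harvest-demand construction, sanitary-priority
allocation, species change and the annual orchestration loop.

Four management/dieback scenarios are supported:

* **Green** — optimistic: the calamity attenuates along per-region
  Gaussian fits of the observed harvest (extrapolated 2022 onwards),
  the harvest regime switches to the sustainable logging potential in
  2030 (target about 17 Mm3/yr), and healthy old stands (120 yr
  conifers / 140 yr broadleaves) are retained from 2025.
* **Red** — pessimistic: regional harvest stays at the observed 2021
  intensities until the region-specific end of the disturbance episode,
  then switches to the potential regime (about 16 Mm3/yr).
* **Black** — as Red, with spruce sanitary logging increased by 20%
  over 2021 levels in the regions where the calamity still spreads.
* **Black rep.** — as Black, plus two-year calamity episodes recurring
  every ten years from 2038, with spruce sanitary demand set to the
  mean of the observed 2018 and 2019 volumes, and planned demand for
  non-fir, non-spruce species escalated by +10/15/20%.

Demand is expressed in t C of merchantable carbon per (year, region,
forest type, disturbance type). Allocation fills sanitary demand first
(oldest eligible cohorts first), then standing mortality, thinning and
final cut; shortfalls are recorded as deficits, never errors. Species
change happens on every sanitary or final-cut clearing of spruce.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import carbon_dynamics as cd
from .accounting import AnnualResult, aggregate_ipcc
from .disturbance import (
    DEFAULT_MATRICES,
    DisturbanceEvent,
    HarvestFlux,
    PLANNED_DISTS,
    SANITARY_DISTS,
    apply_disturbance,
    process_snag_backlog,
    reforest,
)
from .forest_state import ForestState, Region, StandCohort, YieldCurveSet
from .pools import DOM, LIVE, MERCH, SNAG_STEM, PoolVector
from .species import BROADLEAF_TYPES, CONIFER_TYPES, LIVE_TYPES

DEMAND_DISTS = ("2", "3a", "3b", "4")
#: minimum stand age attacked by bark-beetle salvage; younger replanted
#: stands are considered not yet infestable
SALVAGE_MIN_AGE = 40


# ---------------------------------------------------------------------------
# scenario specification

@dataclass
class ScenarioSpec:
    """Configuration of one management/dieback scenario."""

    name: str
    target_removal_mm3: float
    retention: bool = False
    retention_conifer_age: int = 120
    retention_broadleaf_age: int = 140
    retention_from: int = 2025
    spread: bool = False
    spread_factor: float = 1.2
    recurrence: bool = False
    first_episode: int = 2038
    episode_period: int = 10
    episode_length: int = 2
    escalation: tuple = ()
    potential_window: int = 20
    thin_interval: int = 10
    potential_dist_split: dict = field(default_factory=lambda: {
        "3a": 0.15, "3b": 0.10, "2": 0.25, "4": 0.50})
    sanitary_cap: float = 1.0 / 3.0
    green_transition_year: int = 2030

    def __post_init__(self):
        if self.escalation and not self.recurrence:
            raise ValueError("demand escalation requires the recurrence flag")
        san = sum(v for d, v in self.potential_dist_split.items()
                  if d in SANITARY_DISTS)
        if san > self.sanitary_cap + 1e-9:
            raise ValueError(
                f"sanitary share {san:.3f} of the potential-regime split exceeds "
                f"the one-third cap")

    def in_episode(self, year: int) -> bool:
        if not self.recurrence or year < self.first_episode:
            return False
        return (year - self.first_episode) % self.episode_period < self.episode_length

    def escalation_factor(self, year: int) -> float:
        for lo, hi, f in self.escalation:
            if lo <= year <= hi:
                return f
        return 1.0


def green() -> ScenarioSpec:
    return ScenarioSpec(name="green", target_removal_mm3=17.0, retention=True)


def red() -> ScenarioSpec:
    return ScenarioSpec(name="red", target_removal_mm3=16.0)


def black() -> ScenarioSpec:
    return ScenarioSpec(name="black", target_removal_mm3=16.0, spread=True)


def black_rep() -> ScenarioSpec:
    return ScenarioSpec(
        name="black-rep", target_removal_mm3=16.0, spread=True, recurrence=True,
        escalation=((2038, 2047, 1.10), (2048, 2057, 1.15), (2058, 2070, 1.20)),
    )


SCENARIOS = {"green": green, "red": red, "black": black, "black-rep": black_rep}


# ---------------------------------------------------------------------------
# calamity curve fitting

@dataclass
class CalamityCurveFit:
    """Normal-curve fit of one region's total harvest series."""

    region_id: str
    amplitude: float   # Mm3/yr
    peak_year: float
    width: float       # yr
    residual_norm: float
    degenerate: bool = False

    def predict(self, year) -> float:
        return float(
            self.amplitude
            * np.exp(-((year - self.peak_year) ** 2) / (2.0 * self.width ** 2))
        )


def _gauss(t, a, mu, sigma):
    return a * np.exp(-((t - mu) ** 2) / (2.0 * sigma ** 2))


def fit_calamity_curve(series, region_id: str = "") -> CalamityCurveFit:
    """Least-squares normal-curve fit v(t) = A exp(-(t-mu)^2 / (2 sigma^2)).

    ``series`` is a sequence of (year, volume) pairs (>= 4 points).
    Deterministic: initial guesses are A = max, mu = argmax year,
    sigma = 2. An all-zero series yields a zero-amplitude fit flagged
    as degenerate.
    """
    arr = np.asarray(list(series), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 4:
        raise ValueError("need at least 4 (year, volume) pairs")
    years, vols = arr[:, 0], arr[:, 1]
    if np.all(vols == 0):
        return CalamityCurveFit(region_id, 0.0, float(years.mean()), 1.0, 0.0,
                                degenerate=True)
    # the pulse peak is constrained to the observation window: the fit
    # drives the post-calamity extrapolation, which presumes the episode
    # culminated within the observed years
    p0 = (float(vols.max()), float(years[int(np.argmax(vols))]), 2.0)
    lo = (0.0, years.min() - 20.0, 0.05)
    hi = (10.0 * max(p0[0], 1e-9), years.max(), 50.0)
    popt, _ = curve_fit(_gauss, years, vols, p0=p0, bounds=(lo, hi), maxfev=20000)
    resid = float(np.linalg.norm(vols - _gauss(years, *popt)))
    return CalamityCurveFit(region_id, float(popt[0]), float(popt[1]),
                            float(abs(popt[2])), resid)


def extrapolate_demand(fits: dict[str, CalamityCurveFit], years,
                       floors: dict[str, float] | None = None) -> dict:
    """Regional total-harvest extrapolation (Mm3) for the given years:
    the fitted curve value, floored at the region's post-calamity
    sustainable level."""
    floors = floors or {}
    out = {}
    for rid, fit in sorted(fits.items()):
        for year in years:
            out[(year, rid)] = max(fit.predict(year), floors.get(rid, 0.0))
    return out


def interpolate_shares(shares_start: dict, shares_end: dict, year,
                       t0: int = 2021, t1: int = 2031,
                       zero_floor: float = 1e-6) -> dict:
    """Exponential interpolation of composition shares, renormalised.

    s(t) = s0 (s1/s0)^((t-t0)/(t1-t0)); the midpoint is the geometric
    mean of the endpoints (before renormalisation). Zero start shares
    with a nonzero end are floored at ``zero_floor`` first.
    """
    if set(shares_start) != set(shares_end):
        raise ValueError("share key sets differ")
    u = (year - t0) / (t1 - t0)
    raw = {}
    for k in shares_start:
        s0, s1 = shares_start[k], shares_end[k]
        if s0 <= 0.0 and s1 <= 0.0:
            raw[k] = 0.0
        else:
            s0 = max(s0, zero_floor)
            s1 = max(s1, zero_floor)
            raw[k] = s0 * (s1 / s0) ** u
    total = sum(raw.values())
    if total <= 0:
        return {k: 0.0 for k in raw}
    return {k: v / total for k, v in raw.items()}


# ---------------------------------------------------------------------------
# sustainable logging potential

def sustainable_potential(
    state: ForestState,
    curves: YieldCurveSet,
    params: cd.DynamicsParams | None = None,
    window: int = 20,
    thin_interval: int = 10,
) -> dict[tuple[str, str], float]:
    """Sustainable harvest potential (t C/yr) per (region, forest type).

    Final-cut potential amortises the merchantable carbon of cohorts at
    or beyond rotation age over the planning window; stands reaching
    rotation age within the window contribute prorated by the fraction
    of the window they are eligible (standard sustained-yield
    smoothing). Thinning potential amortises one thinning intensity per
    thinning interval over the share of the window a stand spends inside
    the thinning age range, and is capped at the increment carbon so
    thinning does not draw down standing stock. Retained old-growth
    cohorts are excluded.
    """
    params = params or cd.DEFAULT_PARAMS
    final: dict[tuple[str, str], float] = {}
    thin: dict[tuple[str, str], float] = {}
    nai_c: dict[tuple[str, str], float] = {}
    for c in state.cohorts:
        if c.forest_type not in LIVE_TYPES or c.area <= 0 or c.retained:
            continue
        key = (c.region_id, c.forest_type)
        merch_total = c.pools.a[MERCH] * c.area
        rot = params.rotation_age(c.forest_type)
        eligible_years = min(window, max(0, c.age + window - rot))
        if eligible_years > 0:
            final[key] = final.get(key, 0.0) + (
                merch_total * eligible_years / window ** 2
            )
        thin_years = max(
            0,
            min(c.age + window, params.thinning_max_age + 1)
            - max(c.age, params.thinning_min_age),
        )
        if thin_years > 0:
            thin[key] = thin.get(key, 0.0) + (
                params.thinning_intensity * merch_total * thin_years
                / (thin_interval * window)
            )
        inc = curves[c.forest_type].increment(c.age)
        nai_c[key] = nai_c.get(key, 0.0) + (
            inc * params.density(c.forest_type) * c.area
        )
    out = {}
    for key in sorted(set(final) | set(thin)):
        thin_amort = min(thin.get(key, 0.0), nai_c.get(key, 0.0))
        out[key] = final.get(key, 0.0) + thin_amort
    return out


def potential_regime_demand(
    potential: dict[tuple[str, str], float],
    spec: ScenarioSpec,
    params: cd.DynamicsParams,
) -> dict[tuple[str, str, str], float]:
    """Split the sustainable potential into per-disturbance demand cells,
    scaled down so the national total does not exceed the scenario's
    removal target (potential below target is used as-is)."""
    total_vol = sum(v / params.density(ft) for (_, ft), v in potential.items())
    target_vol = spec.target_removal_mm3 * 1e6
    scale = min(1.0, target_vol / total_vol) if total_vol > 0 else 0.0
    out = {}
    for (rid, ft), pot in sorted(potential.items()):
        for d, share in spec.potential_dist_split.items():
            val = pot * scale * share
            if val > 0:
                out[(rid, ft, d)] = val
    return out


# ---------------------------------------------------------------------------
# demand construction

@dataclass
class DemandContext:
    """Precomputed inputs for annual demand construction."""

    regions: dict[str, Region]
    obs_tc: dict            # (year, rid, ft, dist) -> t C (incl. dist 6)
    fits: dict              # rid -> CalamityCurveFit (total harvest, Mm3)
    shares_2021: dict       # rid -> {(ft, dist): volume share}
    end_shares: dict        # rid -> {(ft, dist): volume share} (potential regime)
    floors_mm3: dict        # rid -> post-calamity sustainable total (Mm3)
    episode_tc: dict        # (rid, dist) -> t C (mean 2018/19 spruce sanitary)


def build_demand_context(
    state: ForestState,
    observed: pd.DataFrame,
    spec: ScenarioSpec,
    curves: YieldCurveSet,
    params: cd.DynamicsParams,
) -> DemandContext:
    required = {"year", "region_id", "forest_type", "dist_id", "volume_mm3"}
    missing = required - set(observed.columns)
    if missing:
        raise ValueError(f"observed harvest table missing columns {sorted(missing)}")
    obs = observed.copy()
    obs["dist_id"] = obs["dist_id"].astype(str)
    years = set(obs["year"])
    if not set(range(2012, 2022)) <= years:
        raise ValueError("observed harvest series must cover 2012-2021")

    obs_tc = {}
    for row in obs.itertuples(index=False):
        key = (int(row.year), row.region_id, row.forest_type, row.dist_id)
        obs_tc[key] = obs_tc.get(key, 0.0) + (
            row.volume_mm3 * 1e6 * params.density(row.forest_type)
        )

    harvest = obs[obs["dist_id"].isin(DEMAND_DISTS)]
    fits = {}
    for rid in state.regions:
        sub = harvest[harvest["region_id"] == rid]
        series = [
            (y, sub[sub["year"] == y]["volume_mm3"].sum())
            for y in range(2012, 2022)
        ]
        fits[rid] = fit_calamity_curve(series, region_id=rid)

    # potential-regime structure of the initial state
    potential = sustainable_potential(state, curves, params,
                                      window=spec.potential_window,
                                      thin_interval=spec.thin_interval)
    pot_cells = potential_regime_demand(potential, spec, params)
    floors_mm3: dict[str, float] = {}
    end_shares: dict[str, dict] = {}
    all_keys = [(ft, d) for ft in LIVE_TYPES for d in DEMAND_DISTS]
    for rid in state.regions:
        vols = {
            (ft, d): pot_cells.get((rid, ft, d), 0.0) / params.density(ft)
            for ft, d in all_keys
        }
        total = sum(vols.values())
        floors_mm3[rid] = total / 1e6
        end_shares[rid] = (
            {k: v / total for k, v in vols.items()} if total > 0
            else {k: 0.0 for k in vols}
        )

    shares_2021: dict[str, dict] = {}
    h21 = harvest[harvest["year"] == 2021]
    for rid in state.regions:
        sub = h21[h21["region_id"] == rid]
        vols = {}
        for ft, d in all_keys:
            m = sub[(sub["forest_type"] == ft) & (sub["dist_id"] == d)]
            vols[(ft, d)] = float(m["volume_mm3"].sum())
        total = sum(vols.values())
        shares_2021[rid] = (
            {k: v / total for k, v in vols.items()} if total > 0
            else dict(end_shares[rid])
        )

    # recurring-episode intensity: the average total spruce harvest
    # volume of 2018 and 2019, executed as sanitary logging
    episode_tc = {}
    ep = harvest[
        (harvest["year"].isin((2018, 2019)))
        & (harvest["forest_type"] == "SP")
    ]
    san_total = sum(
        spec.potential_dist_split.get(d, 0.0) for d in SANITARY_DISTS
    ) or 1.0
    for rid in state.regions:
        sub = ep[ep["region_id"] == rid]
        mean_mm3 = float(
            sub.groupby("year")["volume_mm3"].sum()
            .reindex([2018, 2019], fill_value=0.0).mean()
        )
        for d in SANITARY_DISTS:
            share = spec.potential_dist_split.get(d, 0.0) / san_total
            episode_tc[(rid, d)] = mean_mm3 * share * 1e6 * params.density("SP")

    return DemandContext(
        regions=dict(state.regions),
        obs_tc=obs_tc,
        fits=fits,
        shares_2021=shares_2021,
        end_shares=end_shares,
        floors_mm3=floors_mm3,
        episode_tc=episode_tc,
    )


def demand_for_year(
    year: int,
    spec: ScenarioSpec,
    state: ForestState,
    ctx: DemandContext,
    curves: YieldCurveSet,
    params: cd.DynamicsParams,
    potential: dict | None = None,
) -> dict[tuple[str, str, str], float]:
    """Demand cells (region, forest type, dist) -> t C for one year.

    2018-2021 reproduce the observed series verbatim for every scenario;
    later years follow the scenario rules. ``potential`` may be passed
    to reuse a per-year sustainable-potential computation.
    """
    if 2018 <= year <= 2021:
        out = {}
        for (y, rid, ft, d), v in ctx.obs_tc.items():
            if y == year:
                out[(rid, ft, d)] = out.get((rid, ft, d), 0.0) + v
        return out

    if potential is None:
        potential = sustainable_potential(state, curves, params,
                                          window=spec.potential_window,
                                          thin_interval=spec.thin_interval)
    pot_cells = potential_regime_demand(potential, spec, params)

    out: dict[tuple[str, str, str], float] = {}
    for rid, region in sorted(ctx.regions.items()):
        if spec.name == "green":
            if year < spec.green_transition_year:
                total_mm3 = max(ctx.fits[rid].predict(year), ctx.floors_mm3[rid])
                shares = interpolate_shares(ctx.shares_2021[rid],
                                            ctx.end_shares[rid], year)
                for (ft, d), s in shares.items():
                    v = total_mm3 * s * 1e6 * params.density(ft)
                    if v > 0:
                        out[(rid, ft, d)] = v
            else:
                for (r2, ft, d), v in pot_cells.items():
                    if r2 == rid:
                        out[(rid, ft, d)] = v
            continue

        # pessimistic scenarios
        in_episode = spec.name == "black-rep" and spec.in_episode(year)
        if year <= region.end_year:
            for (y, r2, ft, d), v in ctx.obs_tc.items():
                if y == 2021 and r2 == rid and d in DEMAND_DISTS:
                    if (spec.spread and region.spread_flag and ft == "SP"
                            and d in SANITARY_DISTS):
                        v = v * spec.spread_factor
                    out[(rid, ft, d)] = out.get((rid, ft, d), 0.0) + v
        else:
            for (r2, ft, d), v in pot_cells.items():
                if r2 == rid:
                    out[(rid, ft, d)] = v
        if in_episode:
            # recurring outbreak: all spruce harvest is sanitary, at the
            # mean 2018/19 intensity
            for d in DEMAND_DISTS:
                out.pop((rid, "SP", d), None)
            for d in SANITARY_DISTS:
                out[(rid, "SP", d)] = ctx.episode_tc[(rid, d)]
        if spec.name == "black-rep" and spec.escalation:
            f = spec.escalation_factor(year)
            if f != 1.0:
                for (r2, ft, d) in list(out):
                    if r2 == rid and d in PLANNED_DISTS and ft not in ("AA", "SP"):
                        out[(r2, ft, d)] *= f
    return out


@dataclass
class HarvestDemand:
    """Complete demand schedule: (year, region, forest type, dist) -> t C,
    with a provenance tag per entry."""

    data: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def add(self, year, rid, ft, dist, value, tag):
        if value < 0:
            raise ValueError("negative demand")
        key = (year, rid, ft, dist)
        self.data[key] = self.data.get(key, 0.0) + value
        self.provenance[key] = tag

    def total_tc(self, year=None) -> float:
        if year is None:
            return sum(self.data.values())
        return sum(v for (y, *_), v in self.data.items() if y == year)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"year": y, "region_id": r, "forest_type": ft, "dist_id": d,
             "demand_tc": v, "provenance": self.provenance[(y, r, ft, d)]}
            for (y, r, ft, d), v in sorted(self.data.items())
        ]
        return pd.DataFrame(rows)


def build_demand_schedule(
    scenario: ScenarioSpec,
    state: ForestState,
    observed: pd.DataFrame,
    curves: YieldCurveSet,
    params: cd.DynamicsParams | None = None,
    horizon: tuple[int, int] = (2018, 2070),
) -> HarvestDemand:
    """Static demand schedule for the whole horizon, built from the
    initial (spun-up) state. Inside :func:`run_scenario` the potential-
    regime portion is recomputed annually from the evolving state; this
    static schedule serves inspection and demand-side tests."""
    params = params or cd.DEFAULT_PARAMS
    ctx = build_demand_context(state, observed, scenario, curves, params)
    potential = sustainable_potential(state, curves, params,
                                      window=scenario.potential_window,
                                      thin_interval=scenario.thin_interval)
    demand = HarvestDemand()
    for year in range(horizon[0], horizon[1] + 1):
        cells = demand_for_year(year, scenario, state, ctx, curves, params,
                                potential=potential)
        tag = _provenance_tag(scenario, year, ctx)
        for (rid, ft, d), v in cells.items():
            demand.add(year, rid, ft, d, v, tag)
    return demand


def _provenance_tag(spec: ScenarioSpec, year: int, ctx: DemandContext) -> str:
    if 2018 <= year <= 2021:
        return "observed"
    if spec.name == "green":
        return ("fitted-extrapolation+interpolated-share"
                if year < spec.green_transition_year else "potential-regime")
    if spec.name == "black-rep" and spec.in_episode(year):
        return "recurrence"
    return "observed-2021-level/potential-regime"


# ---------------------------------------------------------------------------
# allocation

@dataclass
class SpeciesChangeRule:
    """Replanting composition after spruce clearing.

    'ENHANCED' resolves to the region's enhanced species (fir or oak),
    'OTHER' to the other of the two.
    """

    sanitary: dict = field(default_factory=lambda: {
        "BE": 0.20, "ENHANCED": 0.30, "OTHER": 0.10, "LLB": 0.20, "SLB": 0.20})
    final: dict = field(default_factory=lambda: {
        "SP": 0.50, "AA": 0.10, "BE": 0.20, "LLB": 0.20})

    def __post_init__(self):
        for name, table in (("sanitary", self.sanitary), ("final", self.final)):
            s = sum(table.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"{name} replanting fractions sum to {s}")

    def composition(self, origin_type: str, trigger: str, region: Region) -> dict:
        if origin_type not in ("SP", "SPx"):
            return {origin_type: 1.0}
        table = self.sanitary if trigger == "sanitary" else self.final
        enhanced = "AA" if region.enhanced_species == "Fir" else "OA"
        other = "OA" if enhanced == "AA" else "AA"
        out: dict[str, float] = {}
        for key, frac in table.items():
            ft = {"ENHANCED": enhanced, "OTHER": other}.get(key, key)
            out[ft] = out.get(ft, 0.0) + frac
        return out


def _eligible(cohort: StandCohort, dist: str, params: cd.DynamicsParams) -> bool:
    if cohort.area <= 0 or cohort.forest_type not in LIVE_TYPES:
        return False
    if dist in SANITARY_DISTS:
        return (not cohort.retained and cohort.age >= SALVAGE_MIN_AGE
                and cohort.pools.a[MERCH] > 0)
    if dist == "2":
        return (params.thinning_min_age <= cohort.age <= params.thinning_max_age
                and cohort.pools.a[MERCH] > 0)
    if dist == "4":
        return (not cohort.retained
                and cohort.age >= params.rotation_age(cohort.forest_type)
                and cohort.pools.a[MERCH] > 0)
    if dist == "6":
        return cohort.age >= SALVAGE_MIN_AGE and cohort.pools.a[MERCH] > 0
    return False


ALLOCATION_ORDER = ("3a", "3b", "6", "2", "4")


def allocate_harvest(
    state: ForestState,
    demand: dict[tuple[str, str, str], float],
    spec: ScenarioSpec,
    params: cd.DynamicsParams | None = None,
    year: int = 0,
    matrices: dict | None = None,
) -> tuple[list[DisturbanceEvent], dict, dict]:
    """Allocate one year's demand to cohorts and apply the events.

    Sanitary demand is filled first, from the oldest eligible
    non-retained cohorts; events are clipped to availability and the
    shortfall is returned as a deficit (deficit + allocated = demand
    exactly). Returns (events, deficits, fluxes) with deficits and
    fluxes keyed by (region, forest type, dist).

    The state is modified in place; cleared areas appear as CLEARCUT
    (or SPx, for standing mortality) cohorts tagged for species change.
    """
    params = params or cd.DEFAULT_PARAMS
    matrices = matrices or DEFAULT_MATRICES
    events: list[DisturbanceEvent] = []
    deficits: dict[tuple[str, str, str], float] = {}
    fluxes: dict[tuple[str, str, str], HarvestFlux] = {}

    for dist in ALLOCATION_ORDER:
        cells = sorted(k for k in demand if k[2] == dist)
        for (rid, ft, _) in cells:
            remaining = demand[(rid, ft, dist)]
            if remaining <= 0:
                deficits[(rid, ft, dist)] = 0.0
                continue
            matrix = matrices[dist]
            pool = [
                c for c in state.cohorts
                if c.region_id == rid and c.forest_type == ft
                and _eligible(c, dist, params)
            ]
            pool.sort(key=lambda c: (-c.age, -c.area))
            flux_cell = fluxes.setdefault((rid, ft, dist), HarvestFlux())
            for cohort in pool:
                if remaining <= 1e-9:
                    break
                merch_total = cohort.pools.a[MERCH] * cohort.area
                if dist == "6":
                    merch_ha = cohort.pools.a[MERCH]
                    take_area = min(cohort.area, remaining / merch_ha)
                    replaced, flux = apply_disturbance(
                        cohort, matrix, take_area, year=year)
                    taken = take_area * merch_ha
                    event_target = take_area
                else:
                    if dist == "2":
                        cap = params.thinning_intensity * merch_total
                    elif dist == "3b":
                        cap = matrix.affected_fraction * merch_total
                    else:  # 3a, 4
                        cap = matrix.merch_to_products * merch_total
                    taken = min(remaining, cap)
                    if taken <= 0:
                        continue
                    replaced, flux = apply_disturbance(
                        cohort, matrix, taken, year=year)
                    event_target = taken
                _merge_replacement(state, cohort, replaced)
                flux_cell += flux
                remaining -= taken
                events.append(DisturbanceEvent(year, rid, ft, dist, event_target))
            deficits[(rid, ft, dist)] = max(remaining, 0.0)
    state.cohorts = [c for c in state.cohorts if c.area > 1e-9]
    return events, deficits, fluxes


def _merge_replacement(state: ForestState, cohort: StandCohort,
                       replaced: list[StandCohort]) -> None:
    """Splice the result of apply_disturbance back into the state."""
    for c in replaced:
        if c is not cohort:
            state.cohorts.append(c)
    if not any(c is cohort for c in replaced):
        cohort.area = 0.0


def apply_species_change(
    cleared: list[StandCohort],
    rules: SpeciesChangeRule,
    regions: dict[str, Region],
) -> list[StandCohort]:
    """Replant cleared (CLEARCUT/processed-SPx) cohorts.

    Spruce-origin areas follow the sanitary or final-cut replacement
    fractions (the region's enhanced species receiving the 30% share);
    other origins are replanted to their own type. DOM pools and any
    live seed-tree residual are inherited per hectare.
    """
    out: list[StandCohort] = []
    for c in cleared:
        if c.area <= 0:
            continue
        region = regions.get(c.region_id)
        if region is None:
            raise KeyError(f"region {c.region_id!r} has no metadata entry")
        origin = c.origin_type or "SP"
        trigger = c.trigger or "sanitary"
        comp = rules.composition(origin, trigger, region)
        dom = PoolVector()
        dom.a[DOM] = c.pools.a[DOM]
        live = PoolVector()
        live.a[LIVE] = c.pools.a[LIVE]
        out.extend(reforest(c.area, comp, region, dom_per_ha=dom,
                            live_per_ha=live))
    return out


# ---------------------------------------------------------------------------
# annual orchestration

def run_scenario(
    state: ForestState,
    spec: ScenarioSpec,
    curves: YieldCurveSet,
    observed: pd.DataFrame,
    params: cd.DynamicsParams | None = None,
    horizon: tuple[int, int] = (2018, 2070),
    seed: int = 0,
    rules: SpeciesChangeRule | None = None,
    matrices: dict | None = None,
) -> list[AnnualResult]:
    """Run one scenario over the horizon on a spun-up state.

    Annual order: retention update, growth, turnover, decay, snag
    backlog, demand allocation and disturbance application, species
    change, bookkeeping. Deterministic given the inputs; ``seed`` is
    carried for interface uniformity (all stochasticity lives in the
    synthetic inputs).
    """
    del seed  # the projection itself is deterministic
    params = params or cd.DEFAULT_PARAMS
    rules = rules or SpeciesChangeRule()
    matrices = matrices or DEFAULT_MATRICES
    state = state.copy()
    ctx = build_demand_context(state, observed, spec, curves, params)
    results: list[AnnualResult] = []
    prev_stocks = aggregate_ipcc(state)

    for year in range(horizon[0], horizon[1] + 1):
        # 1. old-growth retention (Green adaptation measure)
        if spec.retention and year >= spec.retention_from:
            for c in state.cohorts:
                if c.retained or c.forest_type not in LIVE_TYPES:
                    continue
                limit = (spec.retention_conifer_age
                         if c.forest_type in CONIFER_TYPES
                         else spec.retention_broadleaf_age)
                if c.age >= limit:
                    c.retained = True

        # 2. growth, turnover, decay
        growth_c = 0.0
        atm_c = 0.0
        for c in state.cohorts:
            g, f = cd.step_cohort(c, curves[c.forest_type], params)
            growth_c += g * c.area
            atm_c += f * c.area

        # 3. snag backlog: harvest 90% of last year's unprocessed snags,
        #    then replant the processed stands
        backlog_flux = HarvestFlux()
        processed: list[StandCohort] = []
        snag_events = process_snag_backlog(state, year)
        if snag_events:
            snag_cohorts = [
                c for c in state.cohorts
                if c.forest_type == "SPx" and c.created_year == year - 1
                and c.pools.a[SNAG_STEM] * c.area > 0
            ]
            for c in snag_cohorts:
                target = 0.90 * c.pools.a[SNAG_STEM] * c.area
                _, flux = apply_disturbance(c, matrices["7"], target, year=year)
                backlog_flux += flux
                c.trigger = "sanitary"
                c.origin_type = "SP"
                processed.append(c)
            done = {id(c) for c in processed}
            state.cohorts = [c for c in state.cohorts if id(c) not in done]

        # 4. demand construction and allocation
        potential = sustainable_potential(
            state, curves, params, window=spec.potential_window,
            thin_interval=spec.thin_interval)
        demand = demand_for_year(year, spec, state, ctx, curves, params,
                                 potential=potential)
        events, deficits, fluxes = allocate_harvest(
            state, demand, spec, params, year=year, matrices=matrices)

        # 5. species change on all cleared areas (incl. processed snags
        #    and any clear-cut cohorts present at the start of the run)
        cleared = [c for c in state.cohorts if c.forest_type == "CLEARCUT"]
        cleared += processed
        state.cohorts = [c for c in state.cohorts if c.forest_type != "CLEARCUT"]
        state.cohorts.extend(apply_species_change(cleared, rules, state.regions))

        state.compact()

        # 6. bookkeeping
        stocks = aggregate_ipcc(state)
        stock_change = {k: stocks[k] - prev_stocks[k] for k in stocks}
        prev_stocks = stocks
        harvest_c: dict[tuple[str, str], float] = {}
        harvest_vol: dict[tuple[str, str], float] = {}
        products_c = 0.0
        burn_c = 0.0
        for (rid, ft, d), flux in fluxes.items():
            key = (d, ft)
            harvest_c[key] = harvest_c.get(key, 0.0) + flux.removed
            harvest_vol[key] = harvest_vol.get(key, 0.0) + (
                flux.products / params.density(ft) / 1e6
            )
            products_c += flux.removed
            burn_c += flux.to_atmosphere
        if backlog_flux.removed > 0:
            harvest_c[("7", "SP")] = harvest_c.get(("7", "SP"), 0.0) + backlog_flux.removed
            harvest_vol[("7", "SP")] = harvest_vol.get(("7", "SP"), 0.0) + (
                backlog_flux.products / params.density("SP") / 1e6
            )
            products_c += backlog_flux.removed
            burn_c += backlog_flux.to_atmosphere

        deficit_agg: dict[tuple[str, str], float] = {}
        demand_agg: dict[tuple[str, str], float] = {}
        for (rid, ft, d), v in deficits.items():
            deficit_agg[(d, ft)] = deficit_agg.get((d, ft), 0.0) + v
        for (rid, ft, d), v in demand.items():
            demand_agg[(d, ft)] = demand_agg.get((d, ft), 0.0) + v

        area_age: dict[int, float] = {}
        for c in state.cohorts:
            cls = c.age // 10
            area_age[cls] = area_age.get(cls, 0.0) + c.area

        results.append(AnnualResult(
            year=year,
            stock_change=stock_change,
            stocks=stocks,
            harvest_c=harvest_c,
            harvest_volume=harvest_vol,
            deficit=deficit_agg,
            demand=demand_agg,
            area_by_type=state.area_by_type(),
            area_by_age_class=area_age,
            nai=cd.compute_nai(state, curves),
            growth_c=growth_c,
            atm_flux_c=atm_c + burn_c,
            products_c=products_c,
        ))
    return results
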