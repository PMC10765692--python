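"""Disturbance transfer matrices and event application.

Eight event types are supported, mirroring classical Central-European
management plus the calamity-specific interventions:

=====  ==========================  =====================================
id     name                        effect
=====  ==========================  =====================================
2      thinning                    proportional removal of 10-30% of
                                   biomass in mid-aged stands
3a     salvage with clear-cut      100% of merch of the affected area to
                                   products; area resets to CLEARCUT
3b     salvage without clear-cut   selective merch removal, no stand
                                   reset
4      final cut                   95% of merch to products, 5% seed
                                   trees stay live; area resets
5      clear-cut with slash burn   spinup initialisation only: 85% of
                                   merch to products, slash burned
6      100% standing mortality     live stand dies in place; merch moves
                                   to the snag stem pool (area-defined)
7      snag harvest                removal of snag stemwood to products
8      reforestation               area-defined replanting (see
                                   :func:`reforest`)
=====  ==========================  =====================================

Targets are t C of merchantable carbon except for types 6 and 8, which
are defined by area (ha). Every event closes its mass balance: carbon
before equals carbon retained plus products, extracted residues and
atmosphere flux.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .pools import (
    AG_FAST,
    AG_VFAST,
    BG_FAST,
    BG_VFAST,
    COARSE,
    FINE,
    FOLIAGE,
    LIVE,
    MEDIUM,
    MERCH,
    N_POOLS,
    OTHER,
    POOLS,
    SNAG_BRANCH,
    SNAG_STEM,
    PoolVector,
)
from .forest_state import ForestState, Region, StandCohort

DIST_IDS = ("2", "3a", "3b", "4", "5", "6", "7", "8")
SANITARY_DISTS = ("3a", "3b")
PLANNED_DISTS = ("2", "4")

# Felled-tree routing of non-extracted live components to DOM: branches
# and stumps become coarse ground debris, foliage and half the fine roots
# enter the very fast litter pool, roots go belowground.
FELLED_ROUTING = {
    OTHER: ((MEDIUM, 1.0),),
    FOLIAGE: ((AG_VFAST, 1.0),),
    COARSE: ((BG_FAST, 1.0),),
    FINE: ((AG_VFAST, 0.5), (BG_VFAST, 0.5)),
}
# Standing mortality keeps the crown aloft: branches become snag branches.
STANDING_ROUTING = {
    OTHER: ((SNAG_BRANCH, 1.0),),
    FOLIAGE: ((AG_VFAST, 1.0),),
    COARSE: ((BG_FAST, 1.0),),
    FINE: ((AG_VFAST, 0.5), (BG_VFAST, 0.5)),
}
# Residue pools eligible for extraction or slash burning (aboveground).
RESIDUE_POOLS = (OTHER, FOLIAGE)


@dataclass
class DisturbanceMatrix:
    """Proportional source -> sink transfer table for one event type."""

    dist_id: str
    name: str
    unit: str                     # 'carbon' or 'area'
    merch_to_products: float = 0.0
    merch_to_live: float = 0.0    # seed trees left standing
    merch_to_snag: float = 0.0
    merch_to_dom: float = 0.0     # unmerchantable felled residue -> medium DOM
    merch_to_atm: float = 0.0
    residue_extraction: float = 0.0  # share of aboveground residues to products
    residue_burn: float = 0.0        # share of aboveground residues burned
    snag_to_products: float = 0.0    # for snag harvest (source pool: snag_stem)
    affected_fraction: float = 1.0   # biomass share touched (proportional events)
    area_reset: bool = False         # harvested area becomes a CLEARCUT cohort
    standing: bool = False           # route crown to snag pools (mortality)
    min_age: int | None = None
    max_age: int | None = None
    min_merch: float = 0.0           # t C/ha eligibility floor

    def live_routing(self):
        return STANDING_ROUTING if self.standing else FELLED_ROUTING

    def rows(self) -> dict[str, dict[str, float]]:
        """Source-pool distributions of the affected biomass (shares to
        pools / products / atmosphere); every row must sum to 1. Only
        pools the event actually touches appear as sources."""
        rows: dict[str, dict[str, float]] = {}
        touches_live = (
            self.merch_to_products + self.merch_to_snag + self.merch_to_dom
            + self.merch_to_atm
        ) > 0.0
        if touches_live:
            rows["merch_stem"] = {
                "products": self.merch_to_products,
                "merch_stem": self.merch_to_live,
                "snag_stem": self.merch_to_snag,
                "medium_dom": self.merch_to_dom,
                "atmosphere": self.merch_to_atm,
            }
            residue_rest = 1.0 - self.residue_extraction - self.residue_burn
            for pool in RESIDUE_POOLS:
                row = {
                    "products": self.residue_extraction,
                    "atmosphere": self.residue_burn,
                }
                for dest, share in self.live_routing()[pool]:
                    row[POOLS[dest]] = row.get(POOLS[dest], 0.0) + residue_rest * share
                rows[POOLS[pool]] = row
            for pool in (COARSE, FINE):
                row = {}
                for dest, share in self.live_routing()[pool]:
                    row[POOLS[dest]] = row.get(POOLS[dest], 0.0) + share
                rows[POOLS[pool]] = row
        if self.snag_to_products > 0.0:
            rows["snag_stem"] = {"products": self.snag_to_products}
        return rows

    def validate(self) -> None:
        if self.dist_id not in DIST_IDS:
            raise ValueError(f"unknown disturbance id {self.dist_id!r}")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected fraction outside [0, 1]")
        for name, row in self.rows().items():
            s = sum(row.values())
            if abs(s - 1.0) > 1e-12:
                raise ValueError(f"{self.dist_id}: source row {name} sums to {s}")
        if self.residue_extraction + self.residue_burn > 1.0 + 1e-12:
            raise ValueError("residue extraction + burn exceeds 1")


@dataclass
class DisturbanceEvent:
    """A scheduled intervention: target is t C of merchantable carbon for
    harvest types, hectares for types 6 and 8."""

    year: int
    region_id: str
    forest_type: str
    dist_id: str
    target: float

    def __post_init__(self):
        if self.target < 0:
            raise ValueError("negative event target")
        if self.dist_id not in DIST_IDS:
            raise ValueError(f"unknown disturbance id {self.dist_id!r}")

    @property
    def unit(self) -> str:
        return "area" if self.dist_id in ("6", "8") else "carbon"


@dataclass
class HarvestFlux:
    """Carbon fluxes (t C) of one applied event."""

    products: float = 0.0        # removed merchantable carbon
    residues: float = 0.0        # extracted harvest residues
    to_dom: float = 0.0
    to_atmosphere: float = 0.0

    def __iadd__(self, other: "HarvestFlux") -> "HarvestFlux":
        self.products += other.products
        self.residues += other.residues
        self.to_dom += other.to_dom
        self.to_atmosphere += other.to_atmosphere
        return self

    @property
    def removed(self) -> float:
        return self.products + self.residues


_DEFAULTS: dict[str, dict] = {
    "2": dict(name="thinning", unit="carbon", merch_to_products=1.0,
              affected_fraction=0.20, min_age=20, max_age=59),
    "3a": dict(name="salvage with clear-cut", unit="carbon",
               merch_to_products=1.0, residue_extraction=0.20,
               residue_burn=0.0, area_reset=True),
    "3b": dict(name="salvage without clear-cut", unit="carbon",
               merch_to_products=1.0, residue_extraction=0.20,
               affected_fraction=0.30),
    "4": dict(name="final cut", unit="carbon", merch_to_products=0.95,
              merch_to_live=0.05, residue_extraction=0.25, residue_burn=0.0,
              area_reset=True),
    "5": dict(name="clear-cut with slash burn", unit="carbon",
              merch_to_products=0.85, merch_to_dom=0.15, residue_burn=1.0,
              area_reset=True),
    "6": dict(name="standing mortality", unit="area", merch_to_snag=1.0,
              standing=True),
    "7": dict(name="snag harvest", unit="carbon", snag_to_products=1.0),
    "8": dict(name="reforestation", unit="area"),
}


def build_disturbance_matrix(dist_id: str, config: dict | None = None) -> DisturbanceMatrix:
    """Build the transfer matrix for one event type, with optional field
    overrides (e.g. thinning intensity, residue burn fraction)."""
    if dist_id not in _DEFAULTS:
        raise ValueError(f"unknown disturbance id {dist_id!r}")
    kwargs = dict(_DEFAULTS[dist_id])
    kwargs.update(config or {})
    if dist_id == "2":
        frac = kwargs.get("affected_fraction", 0.20)
        if not 0.10 <= frac <= 0.30:
            raise ValueError(f"thinning intensity {frac} outside [0.10, 0.30]")
    m = DisturbanceMatrix(dist_id=dist_id, **kwargs)
    m.validate()
    return m


DEFAULT_MATRICES = {d: build_disturbance_matrix(d) for d in DIST_IDS}


def _transfer_live(per_ha: np.ndarray, fraction: float, matrix: DisturbanceMatrix,
                   flux: HarvestFlux, area: float) -> np.ndarray:
    """Move ``fraction`` of the live pools of ``per_ha`` according to the
    matrix; returns the delta applied to a per-ha pool array. Fluxes are
    accumulated in absolute t C (scaled by ``area``)."""
    delta = np.zeros(N_POOLS)
    merch = per_ha[MERCH] * fraction
    delta[MERCH] -= merch - merch * matrix.merch_to_live
    delta[SNAG_STEM] += merch * matrix.merch_to_snag
    delta[MEDIUM] += merch * matrix.merch_to_dom
    flux.products += merch * matrix.merch_to_products * area
    flux.to_atmosphere += merch * matrix.merch_to_atm * area
    flux.to_dom += merch * (matrix.merch_to_snag + matrix.merch_to_dom) * area
    routing = matrix.live_routing()
    for pool in (OTHER, FOLIAGE, COARSE, FINE):
        amt = per_ha[pool] * fraction
        if amt == 0.0:
            continue
        delta[pool] -= amt
        if pool in RESIDUE_POOLS:
            extracted = amt * matrix.residue_extraction
            burned = amt * matrix.residue_burn
            flux.residues += extracted * area
            flux.to_atmosphere += burned * area
            rest = amt - extracted - burned
        else:
            rest = amt
        for dest, share in routing[pool]:
            delta[dest] += rest * share
        flux.to_dom += rest * area
    return delta


def apply_disturbance(
    cohort: StandCohort,
    matrix: DisturbanceMatrix,
    target: float,
    year: int | None = None,
) -> tuple[list[StandCohort], HarvestFlux]:
    """Apply one event to one cohort.

    Returns the resulting cohort(s) (clear-cut events split the cohort:
    the harvested area becomes a CLEARCUT cohort at age 0 awaiting
    species change; standing mortality becomes an SPx cohort) and the
    harvest flux. The caller must clip ``target`` to availability.
    """
    flux = HarvestFlux()
    if target == 0.0:
        return [cohort], flux
    if target < 0.0:
        raise ValueError("negative target")
    if matrix.min_age is not None and cohort.age < matrix.min_age:
        raise ValueError(
            f"cohort age {cohort.age} below minimum {matrix.min_age} for "
            f"disturbance {matrix.dist_id}"
        )
    if matrix.max_age is not None and cohort.age > matrix.max_age:
        raise ValueError(
            f"cohort age {cohort.age} above maximum {matrix.max_age} for "
            f"disturbance {matrix.dist_id}"
        )
    a = cohort.pools.a
    if matrix.dist_id == "7":
        avail = a[SNAG_STEM] * cohort.area
        if target > avail * (1 + 1e-9):
            raise ValueError("snag harvest target exceeds snag stock")
        removed_ha = target / cohort.area
        a[SNAG_STEM] -= removed_ha
        flux.products += target * matrix.snag_to_products
        return [cohort], flux

    if matrix.unit == "area":
        if matrix.dist_id == "8":
            raise ValueError("reforestation is applied via reforest()")
        # standing mortality: convert `target` hectares to an SPx cohort
        area = min(cohort.area, target)
        dead = StandCohort(
            region_id=cohort.region_id,
            forest_type="SPx",
            age=cohort.age,
            area=area,
            pools=cohort.pools.copy(),
            origin_type=cohort.forest_type,
            created_year=year,
        )
        delta = _transfer_live(dead.pools.a, 1.0, matrix, flux, area)
        dead.pools.a += delta
        dead.pools.validate()
        cohort.area -= area
        out = [dead] if cohort.area <= 1e-9 else [cohort, dead]
        return out, flux

    merch_ha = a[MERCH]
    if cohort.pools.a[MERCH] * cohort.area < matrix.min_merch * cohort.area:
        raise ValueError("cohort below minimum merchantable carbon")
    if merch_ha <= 0.0:
        raise ValueError("no merchantable carbon to disturb")

    if matrix.area_reset:
        # clear-cut style: peel off the harvested area
        area = target / (merch_ha * matrix.merch_to_products)
        if area > cohort.area * (1 + 1e-9):
            raise ValueError("target exceeds available stock on cohort area")
        area = min(area, cohort.area)
        cleared = StandCohort(
            region_id=cohort.region_id,
            forest_type="CLEARCUT",
            age=0,
            area=area,
            pools=cohort.pools.copy(),
            origin_type=cohort.forest_type,
            trigger="sanitary" if matrix.dist_id in SANITARY_DISTS else "final",
            created_year=year,
        )
        delta = _transfer_live(cleared.pools.a, 1.0, matrix, flux, area)
        cleared.pools.a += delta
        cleared.pools.validate()
        cohort.area -= area
        out = [cleared] if cohort.area <= 1e-9 else [cohort, cleared]
        return out, flux

    # proportional events (thinning, selective salvage)
    fraction = target / (merch_ha * matrix.merch_to_products * cohort.area)
    if fraction > matrix.affected_fraction + 1e-9:
        raise ValueError(
            f"target implies removing {fraction:.3f} of the stand, above the "
            f"affected fraction {matrix.affected_fraction} for Dist. {matrix.dist_id}"
        )
    fraction = min(fraction, 1.0)
    delta = _transfer_live(a, fraction, matrix, flux, cohort.area)
    a += delta
    cohort.pools.validate()
    return [cohort], flux


def process_snag_backlog(
    state: ForestState,
    year: int,
    window: tuple[int, int] = (2017, 2021),
    removal_fraction: float = 0.90,
) -> list[DisturbanceEvent]:
    """Schedule snag harvest of last year's unprocessed dead stands.

    For every SPx cohort created in ``year - 1`` (within the backlog
    window of creation years), 90% of its snag stemwood carbon is removed
    the following year; the remainder is left to decomposition.
    """
    events = []
    lo, hi = window
    for c in state.cohorts:
        if c.forest_type != "SPx" or c.created_year is None:
            continue
        if c.created_year != year - 1 or not lo <= c.created_year <= hi:
            continue
        stock = c.pools.a[SNAG_STEM] * c.area
        if stock <= 0:
            continue
        events.append(
            DisturbanceEvent(year, c.region_id, "SPx", "7", removal_fraction * stock)
        )
    return events


def reforest(
    area: float,
    composition: dict[str, float],
    region: Region,
    dom_per_ha: PoolVector | None = None,
    live_per_ha: PoolVector | None = None,
) -> list[StandCohort]:
    """Create age-0 cohorts on a cleared area.

    ``composition`` maps forest type to area fraction (must sum to 1).
    DOM pools (and any live seed-tree residual) are inherited per hectare
    from the cleared cohort.
    """
    if area < 0:
        raise ValueError("negative area")
    if area == 0:
        return []
    total = sum(composition.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"composition fractions sum to {total}, expected 1")
    cohorts = []
    for ft, frac in sorted(composition.items()):
        if frac <= 0:
            continue
        pv = PoolVector()
        if dom_per_ha is not None:
            pv.a += dom_per_ha.a
        if live_per_ha is not None:
            pv.a += live_per_ha.a
        cohorts.append(
            StandCohort(
                region_id=region.region_id,
                forest_type=ft,
                age=0,
                area=area * frac,
                pools=pv,
            )
        )
    return cohorts
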