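"""Annual carbon dynamics: yield-driven growth, biomass expansion,
live-pool turnover to dead organic matter, and first-order DOM decay.

Growth is driven by merchantable-volume yield curves; the annual volume
increment is converted to carbon with a forest-type carbon density
(t C per m3 under bark) and expanded to the non-merchantable live pools
with fixed component ratios. Turnover moves constant annual fractions of
the live pools to designated DOM pools (mass conserving, no atmosphere
flux). Decay removes a constant fraction of each DOM pool per year; a
pool-specific share of the decayed carbon is released to the atmosphere
and the remainder is humified into the downstream (slow) pool. The two
slow pools release all decayed carbon to the atmosphere. Climate
modifiers on growth or decay are deliberately not modelled.

The fixed sub-annual operation order is grow -> turnover -> decay ->
disturbances.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .pools import (
    AG_FAST,
    AG_SLOW,
    AG_VFAST,
    BG_FAST,
    BG_SLOW,
    BG_VFAST,
    COARSE,
    DOM,
    FINE,
    FOLIAGE,
    LIVE,
    MEDIUM,
    MERCH,
    OTHER,
    POOLS,
    POOL_INDEX,
    N_POOLS,
    SNAG_BRANCH,
    SNAG_STEM,
    PoolVector,
)
from .species import FOREST_TYPES, HARDWOOD_TYPES, SOFTWOOD_TYPES, is_softwood


@dataclass(frozen=True)
class TurnoverRule:
    """Annual fraction of a live pool moved to DOM destination pools.

    ``destinations`` is a tuple of (pool index, share); shares sum to 1.
    """

    fraction: float
    destinations: tuple[tuple[int, float], ...]

    def validate(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"turnover fraction {self.fraction} outside [0, 1]")
        if abs(sum(s for _, s in self.destinations) - 1.0) > 1e-9:
            raise ValueError("turnover destination shares must sum to 1")
        for idx, _ in self.destinations:
            if not 0 <= idx < N_POOLS:
                raise ValueError(f"unknown destination pool index {idx}")


@dataclass(frozen=True)
class DecayRule:
    """First-order decay of one DOM pool.

    ``rate`` is the annual decayed fraction; of the decayed carbon,
    ``atm_frac`` is emitted and the rest moves to ``downstream``
    (required unless atm_frac == 1).
    """

    rate: float
    atm_frac: float
    downstream: int | None = None

    def validate(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"decay rate {self.rate} outside [0, 1]")
        if not 0.0 <= self.atm_frac <= 1.0:
            raise ValueError(f"atmosphere fraction {self.atm_frac} outside [0, 1]")
        if self.atm_frac < 1.0 and self.downstream is None:
            raise ValueError("downstream pool required when atm_frac < 1")


@dataclass
class DynamicsParams:
    """Parameter set for growth conversion, turnover and decay.

    carbon_density: t C per m3 merchantable volume, per forest type.
    ratios: (other_wood, foliage, coarse_roots, fine_roots) as fractions
        of merchantable stem carbon, per forest type.
    turnover_softwood / turnover_hardwood: per live pool index.
    decay: per DOM pool index.
    rotation: historic rotation age (yr) per forest type, used for the
        spinup disturbance-return interval and final-cut eligibility.
    """

    carbon_density: dict[str, float]
    ratios: dict[str, tuple[float, float, float, float]]
    turnover_softwood: dict[int, TurnoverRule]
    turnover_hardwood: dict[int, TurnoverRule]
    decay: dict[int, DecayRule]
    rotation: dict[str, int]
    thinning_min_age: int = 20
    thinning_max_age: int = 59
    thinning_intensity: float = 0.20

    def density(self, forest_type: str) -> float:
        try:
            return self.carbon_density[forest_type]
        except KeyError:
            raise KeyError(f"unknown forest type {forest_type!r}") from None

    def ratio(self, forest_type: str) -> tuple[float, float, float, float]:
        try:
            return self.ratios[forest_type]
        except KeyError:
            raise KeyError(f"unknown forest type {forest_type!r}") from None

    def turnover(self, softwood: bool) -> dict[int, TurnoverRule]:
        return self.turnover_softwood if softwood else self.turnover_hardwood

    def rotation_age(self, forest_type: str) -> int:
        return self.rotation[forest_type]

    def validate(self) -> None:
        for table in (self.turnover_softwood, self.turnover_hardwood):
            for rule in table.values():
                rule.validate()
        for rule in self.decay.values():
            rule.validate()
        if self.decay[BG_SLOW].atm_frac != 1.0:
            raise ValueError("bg_slow must be terminal (atmosphere fraction 1)")
        for ft, d in self.carbon_density.items():
            if d <= 0:
                raise ValueError(f"non-positive carbon density for {ft}")
        for fracs in self.ratios.values():
            if any(f < 0 for f in fracs):
                raise ValueError("negative component ratio")


def _default_turnover(softwood: bool) -> dict[int, TurnoverRule]:
    foliage_frac = 0.10 if softwood else 1.0  # deciduous foliage drops annually
    return {
        MERCH: TurnoverRule(0.005, ((SNAG_STEM, 1.0),)),
        OTHER: TurnoverRule(0.04, ((AG_FAST, 1.0),)),
        FOLIAGE: TurnoverRule(foliage_frac, ((AG_VFAST, 1.0),)),
        COARSE: TurnoverRule(0.02, ((BG_FAST, 1.0),)),
        FINE: TurnoverRule(0.64, ((AG_VFAST, 0.5), (BG_VFAST, 0.5))),
    }


def default_params() -> DynamicsParams:
    """Shipped default parameter set.

    Magnitudes follow the published CBM parameter archives for temperate
    European conditions (carbon density 0.22 t C/m3 softwood, 0.28
    hardwood; decay classes very fast 0.355/yr, fast 0.14, medium 0.037,
    slow 0.015, snags 0.03; 83% of decayed carbon emitted except for the
    slow pools which are fully emitted). Exact national calibration is
    out of scope and every value can be overridden from a config file.
    """
    density = {}
    ratios = {}
    for ft in FOREST_TYPES:
        sw = is_softwood(ft)
        density[ft] = 0.22 if sw else 0.28
        ratios[ft] = (0.30, 0.05, 0.20, 0.02) if sw else (0.35, 0.03, 0.22, 0.025)
    decay = {
        SNAG_STEM: DecayRule(0.03, 0.83, AG_SLOW),
        SNAG_BRANCH: DecayRule(0.03, 0.83, AG_SLOW),
        MEDIUM: DecayRule(0.037, 0.83, AG_SLOW),
        AG_FAST: DecayRule(0.14, 0.83, AG_SLOW),
        AG_VFAST: DecayRule(0.355, 0.83, AG_SLOW),
        AG_SLOW: DecayRule(0.015, 1.0, None),
        BG_FAST: DecayRule(0.14, 0.83, BG_SLOW),
        BG_VFAST: DecayRule(0.355, 0.83, BG_SLOW),
        BG_SLOW: DecayRule(0.015, 1.0, None),
    }
    rotation = {
        "SP": 100,
        "PI": 100,
        "AA": 100,
        "BE": 120,
        "OA": 120,
        "LLB": 120,
        "SLB": 120,
        "CLEARCUT": 100,
        "SPx": 100,
    }
    params = DynamicsParams(
        carbon_density=density,
        ratios=ratios,
        turnover_softwood=_default_turnover(True),
        turnover_hardwood=_default_turnover(False),
        decay=decay,
        rotation=rotation,
    )
    params.validate()
    return params


def params_from_dict(overrides: dict, base: DynamicsParams | None = None) -> DynamicsParams:
    """Apply a (possibly partial) structured-config override to a base set.

    Recognised keys: carbon_density, ratios, rotation (per forest type),
    decay (per pool name: {rate, atm_frac, downstream}), turnover_softwood
    / turnover_hardwood (per pool name: {fraction, destinations: {pool:
    share}}), thinning_{min_age,max_age,intensity}.
    """
    p = base or default_params()
    density = dict(p.carbon_density)
    density.update(overrides.get("carbon_density", {}))
    ratios = dict(p.ratios)
    for ft, r in overrides.get("ratios", {}).items():
        ratios[ft] = tuple(r)
    rotation = dict(p.rotation)
    rotation.update(overrides.get("rotation", {}))
    decay = dict(p.decay)
    for pool, spec in overrides.get("decay", {}).items():
        down = spec.get("downstream")
        decay[POOL_INDEX[pool]] = DecayRule(
            spec["rate"], spec["atm_frac"], POOL_INDEX[down] if down else None
        )

    def _turn(table: dict[int, TurnoverRule], key: str) -> dict[int, TurnoverRule]:
        table = dict(table)
        for pool, spec in overrides.get(key, {}).items():
            dest = tuple((POOL_INDEX[k], v) for k, v in spec["destinations"].items())
            table[POOL_INDEX[pool]] = TurnoverRule(spec["fraction"], dest)
        return table

    out = DynamicsParams(
        carbon_density=density,
        ratios=ratios,
        turnover_softwood=_turn(p.turnover_softwood, "turnover_softwood"),
        turnover_hardwood=_turn(p.turnover_hardwood, "turnover_hardwood"),
        decay=decay,
        rotation=rotation,
        thinning_min_age=overrides.get("thinning_min_age", p.thinning_min_age),
        thinning_max_age=overrides.get("thinning_max_age", p.thinning_max_age),
        thinning_intensity=overrides.get("thinning_intensity", p.thinning_intensity),
    )
    out.validate()
    return out


DEFAULT_PARAMS = default_params()


# ---------------------------------------------------------------------------
# operations

def volume_to_carbon(volume: float, forest_type: str, params: DynamicsParams) -> PoolVector:
    """Expand a merchantable volume (m3/ha) into the five live pools.

    Linear and invertible for volume > 0: merch = volume x density,
    other live pools = merch x component ratio.
    """
    if volume < 0:
        raise ValueError(f"negative volume {volume}")
    merch = volume * params.density(forest_type)
    other, fol, coarse, fine = params.ratio(forest_type)
    pv = PoolVector()
    pv.a[MERCH] = merch
    pv.a[OTHER] = merch * other
    pv.a[FOLIAGE] = merch * fol
    pv.a[COARSE] = merch * coarse
    pv.a[FINE] = merch * fine
    return pv


def carbon_to_volume(merch_carbon, forest_type: str, params: DynamicsParams) -> float:
    """Inverse of the stem part of :func:`volume_to_carbon` (m3/ha)."""
    if isinstance(merch_carbon, PoolVector):
        merch_carbon = merch_carbon.a[MERCH]
    return float(merch_carbon) / params.density(forest_type)


def grow_annual(cohort, curve, params: DynamicsParams):
    """Advance a cohort one year along its yield curve (in place).

    Ages beyond the curve domain sit on the plateau and receive zero
    increment. DOM pools are untouched.
    """
    age = cohort.age
    inc = float(curve(age + 1)) - float(curve(age))
    if inc < -1e-9:
        raise ValueError(
            f"decreasing yield curve segment at age {age} for {cohort.forest_type}"
        )
    inc = max(inc, 0.0)
    if inc > 0.0:
        cohort.pools.a[LIVE] += volume_to_carbon(inc, cohort.forest_type, params).a[LIVE]
    cohort.age = age + 1
    return cohort


def apply_turnover(cohort, params: DynamicsParams):
    """Move annual turnover fractions of live pools to their DOM pools.

    Mass conserving: live totals decrease by exactly what DOM gains.
    """
    a = cohort.pools.a
    rules = params.turnover(cohort.softwood)
    moved = np.zeros(N_POOLS)
    for pool, rule in rules.items():
        amt = a[pool] * rule.fraction
        if amt == 0.0:
            continue
        moved[pool] -= amt
        for dest, share in rule.destinations:
            moved[dest] += amt * share
    a += moved
    return cohort


def decay_dom(cohort, params: DynamicsParams):
    """Apply one year of first-order DOM decay (simultaneous update).

    Returns (cohort, atmosphere flux in t C/ha). Losses are computed on
    the pre-step stocks so an isolated pool follows stock x (1-rate)^n
    exactly.
    """
    a = cohort.pools.a
    flux = 0.0
    delta = np.zeros(N_POOLS)
    for pool, rule in params.decay.items():
        loss = a[pool] * rule.rate
        if loss == 0.0:
            continue
        delta[pool] -= loss
        flux += loss * rule.atm_frac
        if rule.atm_frac < 1.0:
            delta[rule.downstream] += loss * (1.0 - rule.atm_frac)
    a += delta
    return cohort, flux


def step_cohort(cohort, curve, params: DynamicsParams) -> tuple[float, float]:
    """Grow, turn over and decay one cohort for one year (in place).

    Returns (growth input, atmosphere flux), both t C/ha, for the
    mass-balance ledger.
    """
    live_before = cohort.pools.a[LIVE].sum()
    grow_annual(cohort, curve, params)
    growth = cohort.pools.a[LIVE].sum() - live_before
    apply_turnover(cohort, params)
    _, flux = decay_dom(cohort, params)
    return float(growth), float(flux)


def compute_nai(state, curves) -> dict[str, float]:
    """Area-weighted net annual increment (m3/ha/yr) per forest type.

    The increment is the local yield-curve slope at each cohort's current
    age; zero-area forest types are omitted.
    """
    acc: dict[str, list[float]] = {}
    for c in state.cohorts:
        if c.area <= 0:
            continue
        curve = curves[c.forest_type]
        inc = float(curve(c.age + 1)) - float(curve(c.age))
        area, tot = acc.get(c.forest_type, (0.0, 0.0))
        acc[c.forest_type] = (area + c.area, tot + c.area * inc)
    return {ft: tot / area for ft, (area, tot) in sorted(acc.items()) if area > 0}
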