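"""Domain types, inventory ingestion/validation and DOM spinup.

The simulation state is a collection of stand cohorts, each a (region,
forest type, age, area) record carrying a per-hectare pool vector, plus
per-region metadata (mean altitude, enhanced replanting species, end of
the disturbance episode, calamity-spread flag). Total forest area is
constant through the projection; afforestation and deforestation are out
of scope.

Dead-organic-matter pools are initialised by a spinup: repeated cycles of
growth to the historic rotation age followed by a clear-cut-with-slash-
burn disturbance, iterated until the belowground slow pool reaches a
fixed point, then regrowth to each cohort's inventory age. Live pools
always match the inventory volume; the spinup only fills DOM.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import carbon_dynamics as cd
from .pools import (
    AG_VFAST,
    BG_FAST,
    BG_VFAST,
    BG_SLOW,
    COARSE,
    DOM,
    FINE,
    FOLIAGE,
    LIVE,
    MERCH,
    OTHER,
    POOLS,
    SNAG_BRANCH,
    SNAG_STEM,
    PoolVector,
)
from .species import FOREST_TYPES, is_softwood


@dataclass
class Region:
    """Metadata of one NUTS3-like regional unit."""

    region_id: str
    name: str
    altitude_m: float
    enhanced_species: str  # 'Oak' or 'Fir': who receives the 30% replanting share
    end_year: int          # end of the disturbance episode (pessimistic scenarios)
    spread_flag: bool      # calamity spread considered (Black scenarios)

    def __post_init__(self):
        if self.enhanced_species not in ("Oak", "Fir"):
            raise ValueError(
                f"region {self.region_id}: enhanced_species must be 'Oak' or 'Fir', "
                f"got {self.enhanced_species!r}"
            )


@dataclass
class StandCohort:
    """One age cohort of one forest type in one region.

    ``pools`` holds per-hectare carbon; multiply by ``area`` for totals.
    ``retained`` marks old-growth cohorts excluded from sanitary logging
    and final cut. ``origin_type``/``trigger`` tag CLEARCUT cohorts
    awaiting species-change replanting; ``created_year`` tags SPx cohorts
    for the snag-backlog rule.
    """

    region_id: str
    forest_type: str
    age: int
    area: float
    pools: PoolVector = field(default_factory=PoolVector)
    retained: bool = False
    origin_type: str | None = None
    trigger: str | None = None
    created_year: int | None = None

    def __post_init__(self):
        if self.forest_type not in FOREST_TYPES:
            raise ValueError(f"unknown forest type {self.forest_type!r}")
        if self.area < 0:
            raise ValueError(f"negative area {self.area}")
        if self.age < 0:
            raise ValueError(f"negative age {self.age}")

    @property
    def softwood(self) -> bool:
        if self.forest_type == "CLEARCUT" and self.origin_type:
            return is_softwood(self.origin_type)
        return is_softwood(self.forest_type)

    def total_carbon(self) -> float:
        return self.pools.total() * self.area

    def copy(self) -> "StandCohort":
        return StandCohort(
            region_id=self.region_id,
            forest_type=self.forest_type,
            age=self.age,
            area=self.area,
            pools=self.pools.copy(),
            retained=self.retained,
            origin_type=self.origin_type,
            trigger=self.trigger,
            created_year=self.created_year,
        )


class YieldCurve:
    """Merchantable volume (m3/ha under bark) as a function of age.

    Piecewise-linear on the tabulated grid (decadal grids are thereby
    linearly interpolated); constant at the plateau beyond the last age.
    Must start at volume(0) = 0 and be non-decreasing.
    """

    def __init__(self, forest_type: str, ages, volumes):
        self.forest_type = forest_type
        self.ages = np.asarray(ages, dtype=float)
        self.volumes = np.asarray(volumes, dtype=float)
        if self.ages.ndim != 1 or self.ages.shape != self.volumes.shape:
            raise ValueError("ages and volumes must be matching 1-d sequences")
        if self.ages.size == 0:
            raise ValueError("empty yield curve")
        order = np.argsort(self.ages)
        self.ages = self.ages[order]
        self.volumes = self.volumes[order]
        if self.ages[0] > 0:
            self.ages = np.insert(self.ages, 0, 0.0)
            self.volumes = np.insert(self.volumes, 0, 0.0)
        if abs(self.volumes[0]) > 1e-9:
            raise ValueError(f"{forest_type}: volume at age 0 must be 0")
        if np.any(np.diff(self.volumes) < -1e-9):
            raise ValueError(f"{forest_type}: decreasing yield curve")

    def __call__(self, age):
        return float(np.interp(age, self.ages, self.volumes))

    def increment(self, age) -> float:
        return self(age + 1) - self(age)

    @property
    def plateau(self) -> float:
        return float(self.volumes[-1])


ZERO_CURVE_TYPES = ("CLEARCUT", "SPx")


def zero_curve(forest_type: str) -> YieldCurve:
    return YieldCurve(forest_type, [0.0, 200.0], [0.0, 0.0])


class YieldCurveSet(dict):
    """Mapping forest_type -> YieldCurve; bookkeeping types default to a
    zero curve (an SPx stand does not grow)."""

    def __missing__(self, key):
        if key in ZERO_CURVE_TYPES:
            curve = zero_curve(key)
            self[key] = curve
            return curve
        raise KeyError(f"no yield curve for forest type {key!r}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "YieldCurveSet":
        required = {"forest_type", "age", "volume_m3ha"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"yield curve table missing columns {sorted(missing)}")
        out = cls()
        for ft, grp in df.groupby("forest_type"):
            out[ft] = YieldCurve(ft, grp["age"].to_numpy(), grp["volume_m3ha"].to_numpy())
        return out

    @classmethod
    def read_csv(cls, path) -> "YieldCurveSet":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ft, curve in sorted(self.items()):
            for a, v in zip(curve.ages, curve.volumes):
                rows.append({"forest_type": ft, "age": a, "volume_m3ha": v})
        return pd.DataFrame(rows)


class ForestState:
    """Collection of stand cohorts plus region metadata."""

    def __init__(self, cohorts: list[StandCohort], regions: dict[str, Region],
                 validation: list[str] | None = None):
        self.cohorts = list(cohorts)
        self.regions = dict(regions)
        self.validation = list(validation or [])
        for c in self.cohorts:
            if c.region_id not in self.regions:
                raise ValueError(
                    f"cohort references region {c.region_id!r} absent from region table"
                )

    def copy(self) -> "ForestState":
        return ForestState(
            [c.copy() for c in self.cohorts], self.regions, self.validation
        )

    def total_area(self) -> float:
        return float(sum(c.area for c in self.cohorts))

    def total_carbon(self) -> float:
        return float(sum(c.total_carbon() for c in self.cohorts))

    def pool_totals(self) -> np.ndarray:
        """Total t C per pool, summed over cohorts."""
        out = np.zeros(len(POOLS))
        for c in self.cohorts:
            out += c.pools.a * c.area
        return out

    def area_by_type(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for c in self.cohorts:
            out[c.forest_type] = out.get(c.forest_type, 0.0) + c.area
        return out

    def merch_volume_by_type(self, params: cd.DynamicsParams) -> dict[str, float]:
        """Standing merchantable volume (m3) per forest type (snag volume
        for SPx, since its merchantable carbon sits in the snag pool)."""
        out: dict[str, float] = {}
        for c in self.cohorts:
            pool = SNAG_STEM if c.forest_type == "SPx" else MERCH
            vol = c.pools.a[pool] * c.area / params.density(c.forest_type)
            out[c.forest_type] = out.get(c.forest_type, 0.0) + vol
        return out

    def area_shares(self) -> dict[str, float]:
        total = self.total_area()
        if total == 0:
            return {}
        return {ft: a / total for ft, a in sorted(self.area_by_type().items())}

    def compact(self, tol: float = 1e-9) -> None:
        """Merge cohorts with identical keys (region, type, age, flags),
        area-weighting the pools; exact mass conservation."""
        groups: dict[tuple, StandCohort] = {}
        for c in self.cohorts:
            if c.area <= 0:
                continue
            key = (c.region_id, c.forest_type, c.age, c.retained, c.origin_type,
                   c.trigger, c.created_year)
            if key in groups:
                g = groups[key]
                tot = g.area + c.area
                g.pools.a[:] = (g.pools.a * g.area + c.pools.a * c.area) / tot
                g.area = tot
            else:
                groups[key] = c.copy()
        self.cohorts = list(groups.values())

    # -- serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cohorts:
            row = {
                "region_id": c.region_id,
                "forest_type": c.forest_type,
                "age": c.age,
                "area_ha": c.area,
                "retained": c.retained,
            }
            row.update(c.pools.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, regions: dict[str, Region]) -> "ForestState":
        cohorts = []
        for _, row in df.iterrows():
            pv = PoolVector([row[p] for p in POOLS])
            cohorts.append(
                StandCohort(
                    region_id=row["region_id"],
                    forest_type=row["forest_type"],
                    age=int(row["age"]),
                    area=float(row["area_ha"]),
                    pools=pv,
                    retained=bool(row.get("retained", False)),
                )
            )
        return cls(cohorts, regions)


def read_region_table(df: pd.DataFrame) -> dict[str, Region]:
    required = {"region_id", "altitude_m", "enhanced_species", "end_year", "spread_flag"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"region table missing columns {sorted(missing)}")
    regions = {}
    for i, row in df.iterrows():
        flag = row["spread_flag"]
        if isinstance(flag, str):
            flag = flag.strip().lower() in ("1", "true", "yes", "y")
        regions[str(row["region_id"])] = Region(
            region_id=str(row["region_id"]),
            name=str(row.get("name", row["region_id"])),
            altitude_m=float(row["altitude_m"]),
            enhanced_species=str(row["enhanced_species"]),
            end_year=int(row["end_year"]),
            spread_flag=bool(flag),
        )
    return regions


def load_inventory(
    stand_table: pd.DataFrame,
    region_table: pd.DataFrame,
    params: cd.DynamicsParams | None = None,
) -> ForestState:
    """Build a ForestState from tabular inventory records.

    Live pools are initialised from merchantable volume via the carbon
    conversion; DOM pools are zero pending spinup. SPx volume is loaded
    into the snag stem pool with the same conversion. Rejects unknown
    forest types, negative areas/volumes and undescribed regions with
    row-level messages; a validation report is attached to the state.
    """
    params = params or cd.DEFAULT_PARAMS
    regions = read_region_table(region_table)
    required = {"region_id", "forest_type", "age", "area_ha", "merch_volume_m3ha"}
    missing = required - set(stand_table.columns)
    if missing:
        raise ValueError(f"stand table missing columns {sorted(missing)}")

    errors: list[str] = []
    report: list[str] = []
    cohorts: list[StandCohort] = []
    for i, row in stand_table.iterrows():
        ft = str(row["forest_type"])
        if ft not in FOREST_TYPES:
            errors.append(f"row {i}: unknown forest_type {ft!r}")
            continue
        area = float(row["area_ha"])
        vol = float(row["merch_volume_m3ha"])
        if area < 0:
            errors.append(f"row {i}: negative area {area}")
            continue
        if vol < 0:
            errors.append(f"row {i}: negative volume {vol}")
            continue
        rid = str(row["region_id"])
        if rid not in regions:
            errors.append(f"row {i}: region {rid!r} referenced but not described")
            continue
        pv = PoolVector()
        if ft == "SPx":
            # unprocessed standing dead spruce: merchantable carbon in snags
            pv.a[SNAG_STEM] = vol * params.density(ft)
            cohort = StandCohort(rid, ft, int(row["age"]), area, pv, created_year=2017)
        else:
            pv.a[:] = cd.volume_to_carbon(vol, ft, params).a
            cohort = StandCohort(rid, ft, int(row["age"]), area, pv)
            if ft == "CLEARCUT":
                cohort.origin_type = "SP"
                cohort.trigger = "sanitary"
        cohorts.append(cohort)
    if errors:
        raise ValueError("invalid inventory:\n" + "\n".join(errors))
    state = ForestState(cohorts, regions, validation=report)
    report.append(
        f"loaded {len(cohorts)} cohorts, total area {state.total_area()/1e3:.0f} kha"
    )
    return state


# ---------------------------------------------------------------------------
# DOM spinup

def _simulate_year(pools: PoolVector, softwood: bool, ft: str, age: int,
                   curve: YieldCurve, params: cd.DynamicsParams) -> None:
    """One grow+turnover+decay year on a bare pool vector (helper for the
    spinup, which runs outside any ForestState)."""
    proxy = StandCohort("_", ft, age, 1.0, pools)
    cd.grow_annual(proxy, curve, params)
    cd.apply_turnover(proxy, params)
    cd.decay_dom(proxy, params)


def _dist5(pools: PoolVector) -> None:
    """Initialisation disturbance: clear-cut with slash burn.

    85% of merchantable stems leave as products, the remaining 15% fall
    as coarse debris; slash (other wood + foliage) is burned; roots enter
    the belowground DOM pools; stand resets to age 0.
    """
    from .pools import MEDIUM  # local import to keep header tidy

    a = pools.a
    a[MEDIUM] += 0.15 * a[MERCH]
    a[BG_FAST] += a[COARSE]
    a[AG_VFAST] += 0.5 * a[FINE]
    a[BG_VFAST] += 0.5 * a[FINE]
    # merch 85% -> products (leaves the system); other_wood + foliage burned
    a[MERCH] = 0.0
    a[OTHER] = 0.0
    a[FOLIAGE] = 0.0
    a[COARSE] = 0.0
    a[FINE] = 0.0


def spinup_dom(
    state: ForestState,
    curves: YieldCurveSet,
    params: cd.DynamicsParams | None = None,
    tolerance: float = 1e-6,
    max_cycles: int = 200,
) -> ForestState:
    """Initialise DOM pools to the historic-regime fixed point.

    For each forest type, grow-to-rotation / clear-cut-with-slash-burn
    cycles are iterated until the belowground slow pool changes by less
    than ``tolerance`` (relative) between cycles; the state is then
    regrown to each cohort's inventory age. Live pools are left exactly
    as loaded. SPx cohorts additionally receive the standing-mortality
    conversion of their would-be live crown and root pools; CLEARCUT
    cohorts take the immediately-post-disturbance DOM.
    """
    params = params or cd.DEFAULT_PARAMS
    out = state.copy()

    # distinct spinup groups: bookkeeping types ride on the spruce regime
    def group_type(ft: str) -> str:
        return "SP" if ft in ZERO_CURVE_TYPES else ft

    needed: dict[str, set[int]] = {}
    for c in out.cohorts:
        needed.setdefault(group_type(c.forest_type), set()).add(c.age)

    dom_by_age: dict[tuple[str, int], np.ndarray] = {}
    for ft, ages in sorted(needed.items()):
        curve = curves[ft]
        rot = params.rotation_age(ft)
        pools = PoolVector()
        prev_slow = None
        for cycle in range(max_cycles):
            for age in range(rot):
                _simulate_year(pools, is_softwood(ft), ft, age, curve, params)
            _dist5(pools)
            slow = pools.a[BG_SLOW]
            if prev_slow is not None:
                residual = abs(slow - prev_slow) / max(abs(prev_slow), 1e-12)
                if residual < tolerance:
                    break
            prev_slow = slow
        else:
            raise RuntimeError(
                f"spinup for {ft} did not converge in {max_cycles} cycles "
                f"(last relative residual {residual:.3e})"
            )
        # regrow to every needed inventory age, recording DOM snapshots
        traj = pools.copy()
        snapshots = {0: traj.a[DOM].copy()}
        for age in range(max(ages) if ages else 0):
            _simulate_year(traj, is_softwood(ft), ft, age, curve, params)
            snapshots[age + 1] = traj.a[DOM].copy()
        for age in ages:
            dom_by_age[(ft, age)] = snapshots[age]

    for c in out.cohorts:
        gt = group_type(c.forest_type)
        dom = dom_by_age[(gt, c.age)].copy()
        live_backup = c.pools.a[LIVE].copy()
        snag_backup = c.pools.a[SNAG_STEM]
        c.pools.a[DOM] = dom
        c.pools.a[LIVE] = live_backup
        if c.forest_type == "SPx":
            # standing mortality of the former live stand: crown and roots
            # of the curve-implied biomass move to DOM, snags keep the
            # inventory-loaded merchantable carbon
            c.pools.a[SNAG_STEM] += snag_backup
            live = cd.volume_to_carbon(curves["SP"](c.age), "SP", params).a
            c.pools.a[SNAG_BRANCH] += live[OTHER]
            c.pools.a[AG_VFAST] += live[FOLIAGE] + 0.5 * live[FINE]
            c.pools.a[BG_VFAST] += 0.5 * live[FINE]
            c.pools.a[BG_FAST] += live[COARSE]
    out.validation = state.validation + ["spinup complete"]
    return out
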