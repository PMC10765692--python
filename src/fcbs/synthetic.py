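"""Seeded synthetic national datasets.

Generates the four inputs every other stage consumes — initial stand
inventory, merchantable-volume yield curves, region metadata, and the
observed 2012-2021 harvest series — with the statistical structure the
analysis assumes: a 14-region domain, seven living forest types plus
clear-cut and standing-dead-spruce bookkeeping types with configured
area/volume shares, and regional harvest series shaped as a planned
baseline plus a Gaussian bark-beetle calamity pulse that peaks near
2020, with sanitary logging crowding out planned harvest at the peak.

Everything is reproducible from (config, seed). The inventory and yield
curves are deterministic given the config (area allocation uses
largest-remainder rounding, ages sit at 10-year class midpoints);
the seed drives only the observation noise of the harvest series.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .forest_state import YieldCurve, YieldCurveSet

# The 14-region domain: NUTS3-like units with total area (kha), forest
# cover share, enhanced replanting species, mean altitude (m A.S.L.),
# end of the pessimistic-scenario disturbance episode, and whether
# further calamity spread is assumed for the Black scenarios.
REGION_TABLE: tuple[dict, ...] = (
    dict(region_id="CZ010", name="Hl. m. Praha", area_kha=50, cover=0.096,
         enhanced="Oak", altitude=286, end_year=2037, spread=False),
    dict(region_id="CZ020", name="Stredocesky", area_kha=1093, cover=0.269,
         enhanced="Oak", altitude=414, end_year=2025, spread=True),
    dict(region_id="CZ031", name="Jihocesky", area_kha=1006, cover=0.370,
         enhanced="Fir", altitude=631, end_year=2030, spread=True),
    dict(region_id="CZ032", name="Plzensky", area_kha=765, cover=0.398,
         enhanced="Fir", altitude=609, end_year=2035, spread=True),
    dict(region_id="CZ041", name="Karlovarsky", area_kha=331, cover=0.426,
         enhanced="Fir", altitude=684, end_year=2023, spread=True),
    dict(region_id="CZ042", name="Ustecky", area_kha=534, cover=0.297,
         enhanced="Oak", altitude=516, end_year=2030, spread=True),
    dict(region_id="CZ051", name="Liberecky", area_kha=316, cover=0.432,
         enhanced="Oak", altitude=522, end_year=2036, spread=True),
    dict(region_id="CZ052", name="Kralovehradecky", area_kha=476, cover=0.306,
         enhanced="Oak", altitude=548, end_year=2047, spread=True),
    dict(region_id="CZ053", name="Pardubicky", area_kha=452, cover=0.290,
         enhanced="Oak", altitude=486, end_year=2033, spread=True),
    dict(region_id="CZ063", name="Vysocina", area_kha=680, cover=0.300,
         enhanced="Fir", altitude=574, end_year=2022, spread=False),
    dict(region_id="CZ064", name="Jihomoravsky", area_kha=719, cover=0.268,
         enhanced="Oak", altitude=378, end_year=2021, spread=False),
    dict(region_id="CZ071", name="Olomoucky", area_kha=527, cover=0.344,
         enhanced="Fir", altitude=592, end_year=2032, spread=False),
    dict(region_id="CZ072", name="Zlinsky", area_kha=396, cover=0.392,
         enhanced="Oak", altitude=503, end_year=2031, spread=False),
    dict(region_id="CZ080", name="Moravskoslezsky", area_kha=543, cover=0.347,
         enhanced="Fir", altitude=591, end_year=2036, spread=False),
)

DEFAULT_AREA_SHARES = {
    "SP": 0.496, "PI": 0.202, "BE": 0.086, "OA": 0.074, "LLB": 0.061,
    "SLB": 0.053, "AA": 0.014, "CLEARCUT": 0.012, "SPx": 0.002,
}
DEFAULT_VOLUME_SHARES = {
    "SP": 0.595, "PI": 0.199, "BE": 0.067, "OA": 0.054, "LLB": 0.040,
    "SLB": 0.026, "AA": 0.015,
}
# Chapman-Richards shape (k, p) per forest type; the asymptote is
# calibrated, not configured.
DEFAULT_CR_SHAPES = {
    "SP": (0.020, 2.2), "PI": (0.022, 2.0), "BE": (0.016, 2.4),
    "OA": (0.015, 2.4), "LLB": (0.018, 2.3), "SLB": (0.035, 2.0),
    "AA": (0.019, 2.2),
}
# 10-yr age-class weights (classes 0-11, i.e. ages 0-119), favouring
# classes 3-6 as in the pre-calamity national age structure.
DEFAULT_AGE_WEIGHTS = (2, 4, 6, 8, 9, 9, 8, 6, 4, 3, 2, 1)


@dataclass
class SynthConfig:
    """Configuration of the synthetic national dataset."""

    total_area_ha: float = 2_610_000.0
    area_shares: dict = field(default_factory=lambda: dict(DEFAULT_AREA_SHARES))
    volume_shares: dict = field(default_factory=lambda: dict(DEFAULT_VOLUME_SHARES))
    age_class_weights: tuple = DEFAULT_AGE_WEIGHTS
    regions: tuple = REGION_TABLE
    spruce_altitude_gamma: float = 1.5   # spruce share scales with altitude^gamma
    cr_shapes: dict = field(default_factory=lambda: dict(DEFAULT_CR_SHAPES))
    spruce_nai_target: float = 11.0      # m3/ha/yr on the default age structure
    spx_age: int = 75
    baseline_total_mm3: float = 15.5     # pre-calamity national harvest
    peak_total_mm3: float = 35.8         # national maximum (2020)
    peak_year: int = 2020
    years: tuple = tuple(range(2012, 2022))
    dist_split: dict = field(default_factory=lambda: {
        "2": 0.25, "4": 0.50, "3a": 0.15, "3b": 0.10})
    pulse_sanitary_split: dict = field(default_factory=lambda: {"3a": 0.7, "3b": 0.3})
    unprocessed_fraction: float = 0.08   # dist 6 share of the spruce pulse, 2018-21
    noise_sd: float = 0.05               # multiplicative noise on harvest volumes

    def validate(self) -> None:
        if abs(sum(self.area_shares.values()) - 1.0) > 1e-9:
            raise ValueError("area shares must sum to 1")
        if self.total_area_ha <= 0:
            raise ValueError("non-positive total area")
        if any(w < 0 for w in self.age_class_weights):
            raise ValueError("negative age-class weight")

    @property
    def live_types(self) -> tuple[str, ...]:
        return tuple(t for t in self.area_shares if t not in ("CLEARCUT", "SPx"))


def mini_config() -> SynthConfig:
    """Two-region, three-type preset for fast unit tests."""
    shares = {"SP": 0.6, "PI": 0.25, "BE": 0.13, "CLEARCUT": 0.01, "SPx": 0.01}
    vol = {"SP": 0.68, "PI": 0.22, "BE": 0.10}
    return SynthConfig(
        total_area_ha=60_000.0,
        area_shares=shares,
        volume_shares=vol,
        age_class_weights=(1, 2, 3, 3, 2, 1),
        regions=REGION_TABLE[1:3],  # one Oak-enhanced spread, one Fir-enhanced spread
        baseline_total_mm3=0.35,
        peak_total_mm3=0.9,
    )


def largest_remainder(values, total: float, unit: float = 1.0) -> np.ndarray:
    """Scale non-negative ``values`` to sum exactly to ``total`` in
    multiples of ``unit`` via the largest-remainder method (deterministic
    tie-break by index)."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("negative value")
    if v.sum() == 0:
        raise ValueError("all-zero values")
    scaled = v * (total / v.sum()) / unit
    floors = np.floor(scaled)
    deficit = int(round(total / unit - floors.sum()))
    rem = scaled - floors
    order = np.lexsort((np.arange(len(v)), -rem))
    floors[order[:deficit]] += 1
    return floors * unit


# ---------------------------------------------------------------------------
# internal structure shared by the generators

def _region_frame(config: SynthConfig) -> pd.DataFrame:
    rows = []
    for r in config.regions:
        rows.append({
            "region_id": r["region_id"],
            "name": r["name"],
            "altitude_m": r["altitude"],
            "enhanced_species": r["enhanced"],
            "end_year": r["end_year"],
            "spread_flag": r["spread"],
            "forest_area_ha": r["area_kha"] * 1e3 * r["cover"],
        })
    return pd.DataFrame(rows)


def _type_areas(config: SynthConfig) -> pd.DataFrame:
    """Area (ha) per (region, forest type): spruce follows the altitude
    gradient, the remaining area is split by the national shares."""
    reg = _region_frame(config)
    area_r = reg["forest_area_ha"].to_numpy()
    area_r = area_r * (config.total_area_ha / area_r.sum())
    alt = reg["altitude_m"].to_numpy()
    total = config.total_area_ha
    sp_total = config.area_shares.get("SP", 0.0) * total
    w = area_r * (alt / alt.mean()) ** config.spruce_altitude_gamma
    sp_r = w * (sp_total / w.sum())
    sp_r = np.minimum(sp_r, 0.85 * area_r)
    sp_r *= sp_total / sp_r.sum()

    out = {}
    out["SP"] = sp_r
    for aux in ("SPx", "CLEARCUT"):
        if aux in config.area_shares:
            out[aux] = sp_r * (config.area_shares[aux] * total / sp_r.sum())
    used = sum(out.values())
    rem_r = np.maximum(area_r - used, 0.0)
    others = [t for t in config.area_shares if t not in out]
    qsum = sum(config.area_shares[t] for t in others)
    for t in others:
        out[t] = rem_r * (config.area_shares[t] / qsum)
    rows = []
    for i, r in reg.iterrows():
        for t, arr in out.items():
            rows.append({"region_id": r["region_id"], "forest_type": t,
                         "area_ha": float(arr[i])})
    return pd.DataFrame(rows)


def _age_midpoints(config: SynthConfig) -> np.ndarray:
    return np.array([10 * k + 5 for k in range(len(config.age_class_weights))],
                    dtype=float)


def _age_weights(config: SynthConfig) -> np.ndarray:
    w = np.asarray(config.age_class_weights, dtype=float)
    return w / w.sum()


def generate_yield_curves(config: SynthConfig | None = None) -> YieldCurveSet:
    """Chapman-Richards yield curves v(a) = Vmax (1 - e^(-k a))^p.

    The shape (k, p) is configured per forest type; the asymptotes are
    calibrated so that (i) the area-weighted spruce net annual increment
    on the configured age structure hits the target (default 11 m3/ha/yr)
    and (ii) the standing-volume shares across types match the configured
    volume shares on the configured area shares and age structure.
    """
    config = config or SynthConfig()
    config.validate()
    ages_mid = _age_midpoints(config)
    w = _age_weights(config)
    vol_shares = {t: config.volume_shares[t] for t in config.live_types}

    def phi(t, a):
        k, p = config.cr_shapes[t]
        return (1.0 - np.exp(-k * np.asarray(a, dtype=float))) ** p

    # unit-asymptote standing stock and increment on the age structure
    u = {t: float((phi(t, ages_mid) * w).sum()) for t in vol_shares}
    dphi = {t: float(((phi(t, ages_mid + 1) - phi(t, ages_mid)) * w).sum())
            for t in vol_shares}
    vmax = {}
    vmax["SP"] = config.spruce_nai_target / dphi["SP"]
    area = {t: config.area_shares[t] * config.total_area_ha for t in vol_shares}
    c = vmax["SP"] * area["SP"] * u["SP"] / vol_shares["SP"]
    for t in vol_shares:
        if t == "SP":
            continue
        vmax[t] = c * vol_shares[t] / (area[t] * u[t])

    # species-change replanting can introduce any of the seven live
    # types; give the ones absent from the config a curve with the
    # standard shape and the mean calibrated asymptote of their wood class
    from .species import LIVE_TYPES, is_softwood

    for t in LIVE_TYPES:
        if t in vmax:
            continue
        same_class = [v for ft, v in vmax.items() if is_softwood(ft) == is_softwood(t)]
        ref = same_class or list(vmax.values())
        vmax[t] = float(np.mean(ref))

    def phi_any(t, a):
        k, p = config.cr_shapes.get(t, DEFAULT_CR_SHAPES[t])
        return (1.0 - np.exp(-k * np.asarray(a, dtype=float))) ** p

    grid = np.arange(0.0, 151.0, 5.0)
    curves = YieldCurveSet()
    for t, vm in vmax.items():
        curves[t] = YieldCurve(t, grid, vm * phi_any(t, grid))
    return curves


def generate_inventory(config: SynthConfig | None = None, seed: int = 0
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stand and region tables of the initial (2018) inventory.

    Areas follow the configured type shares (largest-remainder rounded to
    whole hectares so the configured total is met exactly); ages sit at
    10-yr class midpoints with the configured class weights; volumes lie
    on the generated yield curves. Deterministic given the config; the
    seed is accepted for interface symmetry with the other generators.
    """
    config = config or SynthConfig()
    config.validate()
    curves = generate_yield_curves(config)
    type_areas = _type_areas(config)
    ages_mid = _age_midpoints(config)
    w = _age_weights(config)

    rows = []
    for _, tr in type_areas.iterrows():
        ft = tr["forest_type"]
        if ft == "CLEARCUT":
            rows.append((tr["region_id"], ft, 0, tr["area_ha"], 0.0))
        elif ft == "SPx":
            vol = curves["SP"](config.spx_age)
            rows.append((tr["region_id"], ft, config.spx_age, tr["area_ha"], vol))
        else:
            for k, a in enumerate(ages_mid):
                rows.append((tr["region_id"], ft, int(a), tr["area_ha"] * w[k],
                             curves[ft](a)))
    df = pd.DataFrame(rows, columns=["region_id", "forest_type", "age", "area_ha",
                                     "merch_volume_m3ha"])
    df["area_ha"] = largest_remainder(df["area_ha"].to_numpy(), config.total_area_ha)
    df = df[df["area_ha"] > 0].reset_index(drop=True)
    region_df = _region_frame(config).drop(columns=["forest_area_ha"])
    return df, region_df


def _standing_volume(config: SynthConfig) -> pd.DataFrame:
    """Standing merchantable volume (m3) per (region, forest type)."""
    curves = generate_yield_curves(config)
    type_areas = _type_areas(config)
    ages_mid = _age_midpoints(config)
    w = _age_weights(config)
    per_ha = {t: float(sum(w[k] * curves[t](a) for k, a in enumerate(ages_mid)))
              for t in config.live_types}
    df = type_areas[type_areas["forest_type"].isin(config.live_types)].copy()
    df["volume_m3"] = [
        per_ha[t] * a for t, a in zip(df["forest_type"], df["area_ha"])
    ]
    return df


def _pulse_params(config: SynthConfig) -> pd.DataFrame:
    """Per-region Gaussian pulse: unit amplitude proportional to the
    regional spruce volume, peak year and width tied to the configured
    episode end year (earlier end -> earlier, sharper pulse)."""
    vols = _standing_volume(config)
    sp = vols[vols["forest_type"] == "SP"].set_index("region_id")["volume_m3"]
    reg = _region_frame(config)
    peak, width, amp = [], [], []
    for _, r in reg.iterrows():
        ey = r["end_year"]
        if ey <= 2025:
            mu = 2019.0
        elif ey <= 2033:
            mu = 2020.0
        else:
            mu = 2021.0
        peak.append(mu)
        width.append(float(np.clip(1.4 + 0.03 * (ey - 2021), 1.4, 2.2)))
        amp.append(float(sp[r["region_id"]]))
    out = reg[["region_id"]].copy()
    out["amp_unit"] = np.asarray(amp) / np.sum(amp)
    out["peak_year"] = peak
    out["width"] = width
    # normalise so the summed unit pulse at the national peak year is 1
    g = out["amp_unit"] * np.exp(
        -((config.peak_year - out["peak_year"]) ** 2) / (2 * out["width"] ** 2)
    )
    out["amp_unit"] /= g.sum()
    return out


def generate_observed_harvest(config: SynthConfig | None = None, seed: int = 0
                              ) -> pd.DataFrame:
    """Observed harvest series 2012-2021 (volume in Mm3 under bark).

    Per region: a planned baseline split across forest types by standing
    volume and across logging types by the configured split, plus a
    Gaussian spruce-sanitary calamity pulse. Planned harvest is crowded
    out exponentially as the pulse grows, so the national 2020 total hits
    the configured maximum with a sanitary share near 95%. A fraction of
    the 2018-2021 spruce pulse is reported as standing mortality
    (dist 6): dead stands left unprocessed for one year. Gaussian noise
    (sd = noise_sd, multiplicative) is applied with the given seed.
    """
    config = config or SynthConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    vols = _standing_volume(config)
    pulse = _pulse_params(config).set_index("region_id")
    vol_rt = vols.set_index(["region_id", "forest_type"])["volume_m3"]
    vol_r = vol_rt.groupby("region_id").sum()
    total_vol = vol_r.sum()

    base_total = config.baseline_total_mm3
    planned_share = config.dist_split["2"] + config.dist_split["4"]

    def national_total_2020(scale: float) -> float:
        tot = 0.0
        for rid in vol_r.index:
            base_r = base_total * vol_r[rid] / total_vol
            g = scale * pulse.loc[rid, "amp_unit"]  # pulse at national peak year
            g *= np.exp(-((config.peak_year - pulse.loc[rid, "peak_year"]) ** 2)
                        / (2 * pulse.loc[rid, "width"] ** 2))
            damp = np.exp(-g / base_r) if base_r > 0 else 0.0
            tot += base_r * planned_share * damp + base_r * (1 - planned_share) + g
        return tot

    if national_total_2020(0.0) >= config.peak_total_mm3 - 1e-9:
        scale = 0.0  # no calamity pulse needed to reach the configured maximum
    else:
        lo, hi = 0.0, 4.0 * config.peak_total_mm3
        scale = brentq(lambda s: national_total_2020(s) - config.peak_total_mm3,
                       lo, hi, xtol=1e-10)

    san_split = {d: config.dist_split[d] / (1 - planned_share)
                 for d in ("3a", "3b")}
    rows = []
    for rid in vol_r.index:
        base_r = base_total * vol_r[rid] / total_vol
        amp = scale * pulse.loc[rid, "amp_unit"]
        mu = pulse.loc[rid, "peak_year"]
        sig = pulse.loc[rid, "width"]
        for year in config.years:
            g = amp * np.exp(-((year - mu) ** 2) / (2 * sig ** 2))
            damp = np.exp(-g / base_r) if base_r > 0 else 0.0
            for ft in config.live_types:
                base_ft = base_total * vol_rt[(rid, ft)] / total_vol
                for d, share in config.dist_split.items():
                    v = base_ft * share * (damp if d in ("2", "4") else 1.0)
                    if ft == "SP" and d in ("3a", "3b"):
                        v += g * config.pulse_sanitary_split[d] / (
                            config.pulse_sanitary_split["3a"]
                            + config.pulse_sanitary_split["3b"]
                        )
                    if config.noise_sd > 0:
                        v *= max(0.0, rng.normal(1.0, config.noise_sd))
                    if v > 0:
                        rows.append((year, rid, ft, d, v))
            if year >= 2018 and config.unprocessed_fraction > 0 and g > 0:
                v6 = g * config.unprocessed_fraction
                if config.noise_sd > 0:
                    v6 *= max(0.0, rng.normal(1.0, config.noise_sd))
                if v6 > 0:
                    rows.append((year, rid, "SP", "6", v6))
    return pd.DataFrame(rows, columns=["year", "region_id", "forest_type",
                                       "dist_id", "volume_mm3"])
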