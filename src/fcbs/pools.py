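"""Named carbon pools of a stand cohort.

The model tracks 14 named per-hectare carbon pools per cohort: five live
biomass pools (merchantable stem incl. bark, other wood, foliage, coarse
roots >= 5 mm, fine roots < 5 mm), two standing-dead (snag) pools, and
seven dead-organic-matter (DOM) pools spanning woody debris, litter
horizons and mineral-soil organic matter.

In the CBM-CFS3 scheme the live and snag pool families are duplicated for
softwoods and hardwoods (5 x 2 + 2 x 2 + 7 shared = 21 model pools); here
a cohort carries a softwood/hardwood flag on its leading species instead,
so exactly one family of the duplicated pools is ever populated and the
14-slot vector is an exact representation of the 21-pool structure.

All pool values are t C per hectare and must be non-negative.
"""
from __future__ import annotations

import numpy as np

POOLS: tuple[str, ...] = (
    "merch_stem",
    "other_wood",
    "foliage",
    "coarse_roots",
    "fine_roots",
    "snag_stem",
    "snag_branch",
    "medium_dom",
    "ag_fast",
    "ag_very_fast",
    "ag_slow",
    "bg_fast",
    "bg_very_fast",
    "bg_slow",
)
N_POOLS = len(POOLS)

(
    MERCH,
    OTHER,
    FOLIAGE,
    COARSE,
    FINE,
    SNAG_STEM,
    SNAG_BRANCH,
    MEDIUM,
    AG_FAST,
    AG_VFAST,
    AG_SLOW,
    BG_FAST,
    BG_VFAST,
    BG_SLOW,
) = range(N_POOLS)

LIVE = slice(0, 5)
DOM = slice(5, N_POOLS)
LIVE_POOLS = POOLS[LIVE]
DOM_POOLS = POOLS[DOM]
POOL_INDEX = {name: i for i, name in enumerate(POOLS)}

# IPCC category mapping: deadwood includes the snag pools, coarse woody
# debris on the ground and dead coarse roots in mineral soil; litter holds
# the aboveground fast/very fast pools plus the F/H/O horizons (ag_slow);
# soil is dead fine roots in mineral soil plus humified soil organic matter.
IPCC_LIVING = (MERCH, OTHER, FOLIAGE, COARSE, FINE)
IPCC_DEADWOOD = (SNAG_STEM, SNAG_BRANCH, MEDIUM, BG_FAST)
IPCC_LITTER = (AG_FAST, AG_VFAST, AG_SLOW)
IPCC_SOIL = (BG_VFAST, BG_SLOW)
IPCC_CATEGORIES = {
    "living_biomass": IPCC_LIVING,
    "deadwood": IPCC_DEADWOOD,
    "litter": IPCC_LITTER,
    "soil": IPCC_SOIL,
}


class PoolVector:
    """Per-hectare carbon masses (t C/ha) for the pools of one cohort."""

    __slots__ = ("a",)

    def __init__(self, values=None):
        if values is None:
            self.a = np.zeros(N_POOLS)
        else:
            self.a = np.asarray(values, dtype=float).copy()
            if self.a.shape != (N_POOLS,):
                raise ValueError(f"expected {N_POOLS} pool values, got {self.a.shape}")

    @classmethod
    def zeros(cls) -> "PoolVector":
        return cls()

    @classmethod
    def from_dict(cls, d: dict) -> "PoolVector":
        pv = cls()
        for name, val in d.items():
            pv[name] = val
        return pv

    def __getitem__(self, key):
        if isinstance(key, str):
            key = POOL_INDEX[key]
        return self.a[key]

    def __setitem__(self, key, value):
        if isinstance(key, str):
            key = POOL_INDEX[key]
        self.a[key] = value

    def copy(self) -> "PoolVector":
        return PoolVector(self.a)

    def total(self) -> float:
        return float(self.a.sum())

    def live_total(self) -> float:
        return float(self.a[LIVE].sum())

    def dom_total(self) -> float:
        return float(self.a[DOM].sum())

    def as_dict(self) -> dict:
        return {name: float(v) for name, v in zip(POOLS, self.a)}

    def validate(self) -> None:
        if not np.all(np.isfinite(self.a)):
            raise ValueError("non-finite pool value")
        if np.any(self.a < -1e-9):
            bad = [POOLS[i] for i in np.where(self.a < -1e-9)[0]]
            raise ValueError(f"negative pool value in {bad}")
        # clamp tiny numerical negatives
        np.clip(self.a, 0.0, None, out=self.a)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        nz = {k: round(v, 4) for k, v in self.as_dict().items() if v}
        return f"PoolVector({nz})"


def aggregate_ipcc_array(a: np.ndarray) -> dict:
    """Sum a pool array (last axis = pools) into the four IPCC categories."""
    out = {}
    for name, idx in IPCC_CATEGORIES.items():
        out[name] = float(a[..., list(idx)].sum())
    return out
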