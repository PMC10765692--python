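"""Forest-type taxonomy used to categorise tree species.

Seven living forest types (groups of tree species) plus two bookkeeping
types: CLEARCUT for temporarily unforested areas awaiting replanting and
SPx for unprocessed standing dead spruce stands whose merchantable carbon
sits in the snag stem pool.
"""
from __future__ import annotations

FOREST_TYPES: tuple[str, ...] = (
    "SP",        # Norway spruce
    "PI",        # Scots/black pine
    "BE",        # European beech
    "OA",        # oaks
    "LLB",       # long-lived broadleaves (lime, ash, sycamore, hornbeam)
    "SLB",       # short-lived broadleaves (birch, alder, poplar)
    "AA",        # fir group (silver fir, Douglas fir)
    "CLEARCUT",  # temporarily unforested area after clear-cut
    "SPx",       # unprocessed standing dead spruce
)

LIVE_TYPES = ("SP", "PI", "BE", "OA", "LLB", "SLB", "AA")

SOFTWOOD_TYPES = frozenset({"SP", "PI", "AA", "SPx"})
HARDWOOD_TYPES = frozenset({"BE", "OA", "LLB", "SLB"})

CONIFER_TYPES = frozenset({"SP", "PI", "AA"})
BROADLEAF_TYPES = HARDWOOD_TYPES


def is_softwood(forest_type: str) -> bool:
    """CLEARCUT defaults to softwood bookkeeping (calamity clearcuts are
    overwhelmingly of spruce origin); the flag only selects parameter
    families, it carries no carbon of its own."""
    if forest_type in SOFTWOOD_TYPES:
        return True
    if forest_type in HARDWOOD_TYPES:
        return False
    if forest_type == "CLEARCUT":
        return True
    raise KeyError(f"unknown forest type {forest_type!r}")
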