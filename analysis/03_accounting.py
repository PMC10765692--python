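#!/usr/bin/env python
"""LULUCF accounting arithmetic for the 2021-2025 and 2026-2030 pentads.

Reads the Green-scenario emission series written by 02_run_scenarios.py
and performs the commitment-period arithmetic against the forest
reference level (FRL, -4.739 Mt CO2 eq./yr excluding harvested wood
products) with the joint HWP + afforestation offset (-1.75 Mt CO2
eq./yr). Writes results/accounting.json.
"""
import argparse
import json
from pathlib import Path

import pandas as pd

from fcbs import accounting as acc

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--frl", type=float, default=-4.739)
    ap.add_argument("--offsets", type=float, default=-1.75)
    args = ap.parse_args()

    em_path = ROOT / "results" / "scenarios" / "green" / "emissions.csv"
    if not em_path.exists():
        raise SystemExit("run analysis/02_run_scenarios.py first")
    em = pd.read_csv(em_path)
    series = dict(zip(em["year"], em["net_co2_mt"]))

    pentad = acc.accounting_arithmetic(series, args.frl, args.offsets,
                                       (2021, 2025))
    second = acc.accounting_arithmetic(series, 0.0, 0.0, (2026, 2030))

    print(f"2021-2025: cumulative balance {pentad.cumulative_balance:.1f} "
          f"Mt CO2 eq.; FRL adds {pentad.frl_units:.1f} units")
    print(f"           gross deficit {pentad.gross_deficit:.1f}; offsets "
          f"contribute {pentad.offset_units:.1f} -> net "
          f"{pentad.net_deficit:.1f} Mt CO2 eq.")
    print(f"2026-2030: cumulative {second.cumulative_balance:.1f} Mt CO2 eq. "
          f"({second.annual_mean:.1f} annually)")

    out = ROOT / "results" / "accounting.json"
    with open(out, "w") as fh:
        json.dump({"pentad_2021_2025": pentad.as_dict(),
                   "pentad_2026_2030": second.as_dict()}, fh, indent=2)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
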