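#!/usr/bin/env python
"""Build the synthetic national inputs.

Generates the four tables every later step consumes — stand inventory,
region metadata, yield curves and the observed 2012-2021 harvest series
— and reports the structural calibrations: forest-type area/volume
shares, spruce net annual increment, and the calamity-peak harvest.

Writes results/inputs/*.csv.
"""
import argparse
from pathlib import Path

from fcbs import carbon_dynamics as cd
from fcbs import forest_state as fs
from fcbs import synthetic as syn

OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()

    cfg = syn.SynthConfig()
    curves = syn.generate_yield_curves(cfg)
    stand, regions = syn.generate_inventory(cfg, seed=args.seed)
    observed = syn.generate_observed_harvest(cfg, seed=args.seed)

    OUT.mkdir(parents=True, exist_ok=True)
    stand.to_csv(OUT / "stand_table.csv", index=False)
    regions.to_csv(OUT / "region_table.csv", index=False)
    curves.to_frame().to_csv(OUT / "yield_curves.csv", index=False)
    observed.to_csv(OUT / "observed_harvest.csv", index=False)

    state = fs.load_inventory(stand, regions)
    shares = state.area_shares()
    vols = state.merch_volume_by_type(cd.DEFAULT_PARAMS)
    total_vol = sum(vols.values())
    nai = cd.compute_nai(state, curves)

    print(f"inventory: {len(state.cohorts)} cohorts over "
          f"{state.total_area()/1e3:.0f} kha in {len(state.regions)} regions")
    print(f"standing volume {total_vol/1e6:.0f} Mm3; spruce NAI "
          f"{nai['SP']:.2f} m3/ha/yr")
    print("area shares (%):", {k: round(100*v, 1) for k, v in shares.items()})
    print("volume shares (%):",
          {k: round(100*v/total_vol, 1) for k, v in sorted(vols.items())})

    harvest = observed[observed["dist_id"] != "6"]
    t = harvest.groupby("year")["volume_mm3"].sum()
    h2020 = harvest[harvest["year"] == 2020]
    san = h2020[h2020["dist_id"].isin(["3a", "3b"])]["volume_mm3"].sum()
    print(f"observed harvest: {t[2012]:.1f} Mm3 in 2012 rising to a "
          f"{t[2020]:.1f} Mm3 maximum in 2020 "
          f"({100*san/t[2020]:.0f}% sanitary), {t[2021]:.1f} Mm3 in 2021")
    print(f"wrote 4 tables to {OUT}")


if __name__ == "__main__":
    main()
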