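#!/usr/bin/env python
"""Characterize non-carcinogenic risk: hazard quotients per metal and
chronic hazard indices pooled and per brand/color stratum.

Reads results/doses.csv and the assessed concentration table; writes
results/risk.csv.
"""

from pathlib import Path

import pandas as pd

from dermrisk import reference
from dermrisk.data_io import read_concentration_table, read_survey_table
from dermrisk.pipeline import make_config, resolve_exposure_factors, risk_frame
from dermrisk.risk import characterize, maximal_stratum, stratified_risk

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20140


def main() -> None:
    doses_df = pd.read_csv(ROOT / "doses.csv")
    pooled_doses = {str(r.metal): float(r.median) for r in doses_df.itertuples()}
    rfds = reference.rfd_table()
    decisions = pd.read_csv(ROOT / "lod_decisions.csv")
    excluded = tuple(decisions.loc[decisions["excluded"], "metal"])
    table = read_concentration_table(ROOT / "data" / "concentrations_assessed.csv")
    survey = read_survey_table(ROOT / "data" / "survey.csv")
    factors = resolve_exposure_factors(make_config(), survey)

    pooled = characterize(pooled_doses, rfds, "pooled", excluded=excluded)
    brand = stratified_risk(table, "brand", rfds, factors, seed=SEED + 200, excluded=excluded)
    color = stratified_risk(table, "color", rfds, factors, seed=SEED + 300, excluded=excluded)
    risk_frame(pooled, brand, color).to_csv(ROOT / "risk.csv", index=False)

    print("pooled hazard quotients (dermal RfD basis, median dose):")
    for metal, hq in sorted(pooled.hq.items(), key=lambda kv: -kv[1]):
        print(f"  {metal:2s}: HQ = {hq:.3e}")
    print(f"pooled HI = {pooled.hi:.3e} -> {pooled.classification}"
          f" (lower bound: {pooled.hi_is_lower_bound}, excluded: {', '.join(pooled.excluded)})")
    mb, mc = maximal_stratum(brand), maximal_stratum(color)
    print(f"\nhighest-HI brand: {mb} (HI = {brand[mb].hi:.3e})")
    print(f"highest-HI color: {mc} (HI = {color[mc].hi:.3e})")
    assert all(r.hi < 1 for r in list(brand.values()) + list(color.values()))
    print("every brand and color stratum has HI < 1: no probable non-carcinogenic risk")
    print(f"wrote {ROOT / 'risk.csv'}")


if __name__ == "__main__":
    main()
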