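#!/usr/bin/env python
"""Apply the censoring policy, summarize concentrations, and select the
best-fitting distribution family per metal.

Reads results/data/; writes results/summaries.csv and results/fits.csv.
"""

from pathlib import Path

import pandas as pd

from dermrisk import reference
from dermrisk.data_io import (
    ConcentrationTable, apply_lod_policy_all, read_concentration_table,
    summarize_concentrations, write_concentration_csv,
)
from dermrisk.distributions import select_best
from dermrisk.pipeline import fits_frame

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = read_concentration_table(ROOT / "data" / "concentrations.csv")
    table, decisions = apply_lod_policy_all(table)
    for d in decisions:
        if d.excluded:
            print(f"excluded {d.metal}: {d.censored_fraction:.1%} of measurements below LOD")
        elif d.n_imputed:
            print(f"{d.metal}: {d.n_imputed} censored value(s) set to LOD/2")
    rfds = reference.rfd_table()
    no_rfd = [m for m in table.metals if m not in rfds]
    if no_rfd:
        print(f"no reference dose for {', '.join(no_rfd)}: summarized but not assessed")
    table = ConcentrationTable(table.df.loc[table.df["metal"].isin(rfds)])
    write_concentration_csv(table, ROOT / "data" / "concentrations_assessed.csv")
    pd.DataFrame([vars(d) for d in decisions]).to_csv(ROOT / "lod_decisions.csv", index=False)

    summaries = pd.concat([
        summarize_concentrations(table),
        summarize_concentrations(table, "brand"),
        summarize_concentrations(table, "color"),
    ], ignore_index=True)
    summaries.to_csv(ROOT / "summaries.csv", index=False)

    fits = {m: select_best(table.values(m)) for m in table.metals}
    fits_frame(fits).to_csv(ROOT / "fits.csv", index=False)
    print("\nbest-fitting family per assessed metal (KS statistic):")
    for metal, sel in fits.items():
        b = sel.best
        print(f"  {metal:2s}: {b.family:10s} KS={b.ks_stat:.3f}  AD={b.ad_stat:.2f}")
    print(f"\nwrote {ROOT / 'summaries.csv'} and {ROOT / 'fits.csv'}")


if __name__ == "__main__":
    main()
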