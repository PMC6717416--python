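"""Packaged study reference tables.

Small CSVs shipped with the package: the pooled per-metal summary with
goodness-of-fit winners and reference doses, the per-brand and per-color
mean±SD cells (below-LOD cells marked), and the instrument detection limits.
All concentrations keep the unit column in which they were reported (ppm or
ppb); loaders convert on request.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .data_io import RfDEntry, to_mg_per_kg

#: metals retained for risk assessment
ASSESSED_METALS = ("Al", "Ba", "Cd", "Cu", "Fe", "Pb")
#: metals dropped because >= 20% of measurements fell below the detection limit
EXCLUDED_METALS = ("Ag", "Co", "Cr", "Mn")

BRANDS = tuple(f"brand_{i}" for i in range(1, 9))
COLORS = ("black", "blonde", "light_brown", "dark_brown")


def _read(name: str) -> pd.DataFrame:
    with resources.files("dermrisk.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def pooled_summary() -> pd.DataFrame:
    """Pooled per-metal summary: n, mean, sd, median, range, 90th percentile,
    best-fitting family, and both reference doses (units as reported)."""
    return _read("pooled_summary.csv")


def brand_cells() -> pd.DataFrame:
    """Per-(brand, metal) mean±SD cells; ``censored`` marks >20%-below-LOD cells."""
    return _read("brand_cells.csv")


def color_cells() -> pd.DataFrame:
    """Per-(color, metal) mean±SD cells; ``censored`` marks >20%-below-LOD cells."""
    return _read("color_cells.csv")


def detection_limits() -> dict[str, float]:
    """Per-metal detection limit in canonical mg·kg⁻¹."""
    df = _read("lod.csv")
    return {str(r.metal): float(to_mg_per_kg(r.lod, r.unit)) for r in df.itertuples()}


def rfd_table() -> dict[str, RfDEntry]:
    """Reference doses (ingestion and dermal, mg·kg⁻¹·day⁻¹) per assessed metal."""
    df = pooled_summary()
    return {str(r.metal): RfDEntry(str(r.metal), float(r.rfd_ing), float(r.rfd_derm))
            for r in df.itertuples()}


def pooled_median_mg_per_kg() -> dict[str, float]:
    """Pooled median concentration per metal, converted to mg·kg⁻¹."""
    df = pooled_summary()
    return {str(r.metal): float(to_mg_per_kg(r.median, r.unit)) for r in df.itertuples()}


def pooled_brand_mean(metal: str, unit: str | None = None) -> float:
    """Equal-weight average of the per-brand means for one metal.

    With every brand contributing the same number of samples the pooled mean
    of the raw data equals the unweighted mean of the brand means; censored
    brand cells carry no mean and make the pooled value unrecoverable, so
    they raise.
    """
    df = brand_cells()
    sub = df.loc[df["metal"] == metal]
    if sub.empty:
        raise KeyError(f"metal {metal!r} not in brand table")
    if sub["censored"].any():
        raise ValueError(f"{metal}: pooled mean not recoverable, brand cell(s) censored")
    return float(sub["mean"].mean())
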