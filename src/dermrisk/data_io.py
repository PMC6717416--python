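"""Reading, validation, unit normalization and censoring policy for input tables.

The canonical internal concentration unit is mg·kg⁻¹ (ppm); ppb (µg·kg⁻¹)
inputs are divided by 1000 at ingest.  Left-censored (below detection limit)
measurements carry their LOD and no concentration until a substitution rule
replaces them; an analyte whose censored fraction reaches the exclusion
threshold is dropped from assessment entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: unit name -> factor converting to mg·kg⁻¹
UNIT_FACTORS = {"ppm": 1.0, "ppb": 1e-3}

CONCENTRATION_COLUMNS = (
    "sample_id", "brand", "country", "color", "metal", "value", "unit", "below_lod", "lod",
)

SURVEY_COLUMNS = (
    "respondent_id", "uses_dye", "uses_chemical_dye", "age_start",
    "frequency_per_year", "body_weight_kg", "color_pref", "brand_pref",
)


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class ValidationError(ValueError):
    """A row violates a value constraint."""


def to_mg_per_kg(value, unit: str):
    """Convert a concentration from ``unit`` (ppm/ppb) to mg·kg⁻¹."""
    try:
        return value * UNIT_FACTORS[unit]
    except KeyError:
        raise SchemaError(f"unknown concentration unit {unit!r}; expected one of {sorted(UNIT_FACTORS)}")


def from_mg_per_kg(value, unit: str):
    """Convert a canonical mg·kg⁻¹ concentration back to ``unit``."""
    try:
        return value / UNIT_FACTORS[unit]
    except KeyError:
        raise SchemaError(f"unknown concentration unit {unit!r}; expected one of {sorted(UNIT_FACTORS)}")


@dataclass(frozen=True)
class MetalMeasurement:
    """One laboratory measurement of one metal in one sample (canonical mg·kg⁻¹)."""

    sample_id: str
    brand: str
    country: str
    color: str
    metal: str
    concentration: float | None  # None while censored and not yet imputed
    below_lod: bool
    lod: float | None = None
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.below_lod:
            if self.lod is None or not self.lod > 0:
                raise ValidationError(f"{self.sample_id}/{self.metal}: censored row requires lod > 0")
        elif self.concentration is None or not self.concentration > 0:
            raise ValidationError(
                f"{self.sample_id}/{self.metal}: concentration must be > 0, got {self.concentration!r}"
            )


@dataclass(frozen=True)
class RfDEntry:
    """Reference doses for one metal (mg·kg⁻¹·day⁻¹), ingestion and dermal."""

    metal: str
    rfd_ing: float
    rfd_derm: float

    def __post_init__(self) -> None:
        if not (self.rfd_ing > 0 and self.rfd_derm > 0):
            raise ValidationError(f"{self.metal}: reference doses must be > 0")

    def basis(self, which: str) -> float:
        if which == "dermal":
            return self.rfd_derm
        if which == "ingestion":
            return self.rfd_ing
        raise ValueError(f"unknown RfD basis {which!r}")


class ConcentrationTable:
    """Ordered collection of measurements with brand/color/metal accessors.

    Internally a DataFrame with columns sample_id, brand, country, color,
    metal, concentration (mg·kg⁻¹; NaN while censored), below_lod, lod
    (mg·kg⁻¹), imputed.
    """

    _COLS = ("sample_id", "brand", "country", "color", "metal",
             "concentration", "below_lod", "lod", "imputed")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self._COLS if c not in df.columns]
        if missing:
            raise SchemaError(f"concentration table missing columns {missing}")
        df = df.loc[:, list(self._COLS)].reset_index(drop=True)
        dup = df.duplicated(subset=["brand", "color", "metal", "sample_id"])
        if dup.any():
            raise ValidationError(
                f"duplicate (brand, color, metal, sample_id) rows at positions {list(df.index[dup])}"
            )
        uncens = df.loc[~df["below_lod"].astype(bool)]
        bad = uncens.index[~(uncens["concentration"] > 0)]
        if len(bad):
            raise ValidationError(f"non-positive concentration in rows {list(bad)}")
        cens = df.loc[df["below_lod"].astype(bool)]
        bad = cens.index[~(cens["lod"] > 0)]
        if len(bad):
            raise ValidationError(f"censored rows without positive LOD at {list(bad)}")
        self.df = df

    # -- basic container behaviour --------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def measurements(self) -> list[MetalMeasurement]:
        return [
            MetalMeasurement(
                sample_id=str(r.sample_id), brand=str(r.brand), country=str(r.country),
                color=str(r.color), metal=str(r.metal),
                concentration=None if pd.isna(r.concentration) else float(r.concentration),
                below_lod=bool(r.below_lod),
                lod=None if pd.isna(r.lod) else float(r.lod),
                imputed=bool(r.imputed),
            )
            for r in self.df.itertuples()
        ]

    @property
    def metals(self) -> list[str]:
        return sorted(self.df["metal"].unique())

    @property
    def brands(self) -> list[str]:
        return sorted(self.df["brand"].unique())

    @property
    def colors(self) -> list[str]:
        return sorted(self.df["color"].unique())

    def _subset(self, mask) -> "ConcentrationTable":
        return ConcentrationTable(self.df.loc[mask])

    def by_brand(self, brand: str) -> "ConcentrationTable":
        return self._subset(self.df["brand"] == brand)

    def by_color(self, color: str) -> "ConcentrationTable":
        return self._subset(self.df["color"] == color)

    def by_metal(self, metal: str) -> "ConcentrationTable":
        return self._subset(self.df["metal"] == metal)

    def values(self, metal: str, include_censored: bool = False) -> np.ndarray:
        """Concentrations for one metal (mg·kg⁻¹); censored, unimputed rows dropped
        unless ``include_censored`` substitutes their LOD."""
        sub = self.df.loc[self.df["metal"] == metal]
        if include_censored:
            v = sub["concentration"].where(~sub["below_lod"] | sub["imputed"], sub["lod"])
            return v.to_numpy(dtype=float)
        return sub.loc[sub["concentration"].notna(), "concentration"].to_numpy(dtype=float)

    def censored_fraction(self, metal: str) -> float:
        sub = self.df.loc[self.df["metal"] == metal]
        if sub.empty:
            raise KeyError(f"metal {metal!r} not present in table")
        return float((sub["below_lod"] & ~sub["imputed"]).mean())


def read_concentration_table(path: str | Path, unit_map: dict[str, str] | None = None) -> ConcentrationTable:
    """Read a concentration CSV and normalize all values to mg·kg⁻¹.

    The CSV carries its units either in a ``unit`` column or through
    ``unit_map`` (metal -> 'ppm'|'ppb'); a unit column takes precedence.
    Censored rows have ``below_lod`` true, an empty value, and a positive
    ``lod`` in the same unit.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = [c for c in CONCENTRATION_COLUMNS if c not in ("unit",)]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    if df.empty:
        empty = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            ConcentrationTable._COLS,
            [str, str, str, str, str, float, bool, float, bool])})
        return ConcentrationTable(empty)

    if "unit" in df.columns:
        units = df["unit"].astype(str)
    elif unit_map is not None:
        units = df["metal"].map(unit_map)
        if units.isna().any():
            missing_metals = sorted(df.loc[units.isna(), "metal"].unique())
            raise SchemaError(f"{path.name}: no unit declared for metals {missing_metals}")
    else:
        raise SchemaError(f"{path.name}: no 'unit' column and no unit_map given")
    factors = units.map(UNIT_FACTORS)
    if factors.isna().any():
        bad = sorted(units[factors.isna()].unique())
        raise SchemaError(f"{path.name}: unknown unit(s) {bad}")

    below = df["below_lod"].astype(bool)
    conc = pd.to_numeric(df["value"], errors="coerce") * factors
    lod = pd.to_numeric(df.get("lod"), errors="coerce") * factors
    bad = df.index[~below & ~(conc > 0)]
    if len(bad):
        raise ValidationError(f"{path.name}: non-positive or missing concentration in rows {list(bad)}")
    out = pd.DataFrame({
        "sample_id": df["sample_id"].astype(str),
        "brand": df["brand"].astype(str),
        "country": df["country"].astype(str),
        "color": df["color"].astype(str),
        "metal": df["metal"].astype(str),
        "concentration": conc.where(~below),
        "below_lod": below,
        "lod": lod,
        "imputed": False,
    })
    return ConcentrationTable(out)


def write_concentration_csv(table: ConcentrationTable, path: str | Path, unit: str = "ppm") -> None:
    """Write a table back to the standard CSV layout in a single unit."""
    df = table.df
    out = pd.DataFrame({
        "sample_id": df["sample_id"],
        "brand": df["brand"],
        "country": df["country"],
        "color": df["color"],
        "metal": df["metal"],
        "value": from_mg_per_kg(df["concentration"], unit),
        "unit": unit,
        "below_lod": df["below_lod"],
        "lod": from_mg_per_kg(df["lod"], unit),
    })
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# censoring (below-LOD) policy
# ---------------------------------------------------------------------------

SUBSTITUTION_RULES = ("half-lod", "zero", "full-lod")


@dataclass(frozen=True)
class LodDecision:
    """Record of how the censoring policy treated one metal."""

    metal: str
    n_total: int
    n_censored: int
    censored_fraction: float
    excluded: bool
    substitution: str | None = None
    n_imputed: int = 0


def apply_lod_policy(
    table: ConcentrationTable,
    metal: str,
    exclusion_fraction: float = 0.20,
    substitution: str = "half-lod",
) -> tuple[ConcentrationTable, LodDecision]:
    """Exclude ``metal`` when its censored fraction reaches the threshold,
    otherwise substitute censored values.

    Exclusion is all-or-nothing per metal; substituted rows keep their
    censored flag and are additionally marked imputed.  ``zero`` substitution
    removes the censored rows (a zero concentration cannot enter the
    log-scale fits).
    """
    if not (0 < exclusion_fraction <= 1):
        raise ValueError("exclusion_fraction must be in (0, 1]")
    if substitution not in SUBSTITUTION_RULES:
        raise ValueError(f"substitution must be one of {SUBSTITUTION_RULES}")
    frac = table.censored_fraction(metal)
    sub = table.df["metal"] == metal
    n_total = int(sub.sum())
    n_cens = int((table.df.loc[sub, "below_lod"] & ~table.df.loc[sub, "imputed"]).sum())

    if frac >= exclusion_fraction:
        remaining = ConcentrationTable(table.df.loc[~sub])
        return remaining, LodDecision(metal, n_total, n_cens, frac, excluded=True)

    df = table.df.copy()
    mask = sub & df["below_lod"] & ~df["imputed"]
    if substitution == "zero":
        df = df.loc[~mask]
    else:
        factor = 0.5 if substitution == "half-lod" else 1.0
        df.loc[mask, "concentration"] = df.loc[mask, "lod"] * factor
        df.loc[mask, "imputed"] = True
    return ConcentrationTable(df), LodDecision(
        metal, n_total, n_cens, frac, excluded=False,
        substitution=substitution, n_imputed=n_cens,
    )


def apply_lod_policy_all(
    table: ConcentrationTable,
    exclusion_fraction: float = 0.20,
    substitution: str = "half-lod",
) -> tuple[ConcentrationTable, list[LodDecision]]:
    """Apply the censoring policy to every metal in the table, in sorted order."""
    decisions = []
    for metal in table.metals:
        table, decision = apply_lod_policy(table, metal, exclusion_fraction, substitution)
        decisions.append(decision)
    return table, decisions


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def _summary_row(v: np.ndarray) -> dict:
    return {
        "n": int(v.size),
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
        "median": float(np.median(v)),
        "min": float(np.min(v)),
        "max": float(np.max(v)),
        "p90": float(np.quantile(v, 0.9)),  # linear interpolation ("type 7")
    }


def summarize_concentrations(table: ConcentrationTable, group_by: str | None = None) -> pd.DataFrame:
    """Per-metal summary statistics, pooled or per brand/color stratum.

    Only resolved concentrations (measured or imputed) enter the statistics;
    a group with no resolved values is absent from the output rather than
    reported as zero.  The 90th percentile uses linear interpolation between
    order statistics.
    """
    if group_by not in (None, "brand", "color"):
        raise ValueError("group_by must be None, 'brand' or 'color'")
    rows = []
    df = table.df.loc[table.df["concentration"].notna()]
    keys = ["metal"] if group_by is None else [group_by, "metal"]
    for key, sub in df.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        v = sub["concentration"].to_numpy(dtype=float)
        if group_by is None:
            row = {"group": "pooled", "metal": key[0]}
        else:
            row = {"group": key[0], "metal": key[1]}
        row.update(_summary_row(v))
        rows.append(row)
    return pd.DataFrame(rows, columns=["group", "metal", "n", "mean", "sd", "median", "min", "max", "p90"])


def read_rfd_table(path: str | Path) -> dict[str, RfDEntry]:
    """Read a reference-dose CSV (metal, rfd_ing, rfd_derm in mg·kg⁻¹·day⁻¹)."""
    df = pd.read_csv(path)
    missing = [c for c in ("metal", "rfd_ing", "rfd_derm") if c not in df.columns]
    if missing:
        raise SchemaError(f"RfD table missing column(s) {missing}")
    return {str(r.metal): RfDEntry(str(r.metal), float(r.rfd_ing), float(r.rfd_derm))
            for r in df.itertuples()}


def read_survey_table(path: str | Path) -> pd.DataFrame:
    """Read a survey CSV and validate the basic respondent constraints."""
    df = pd.read_csv(path)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"survey table missing column(s) {missing}")
    if (df["body_weight_kg"] <= 0).any():
        raise ValidationError("survey body weights must be > 0")
    if (df["age_start"] < 0).any() or (df["frequency_per_year"] < 0).any():
        raise ValidationError("survey age_start and frequency_per_year must be >= 0")
    return df
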