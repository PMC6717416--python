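"""Synthetic study generator.

The laboratory campaign behind the packaged summary tables measured 8 hair
dye brands × 4 colors (32 samples) for ten metals, of which four (Ag, Co,
Cr, Mn) were dropped because at least 20% of their measurements fell below
the detection limit.  Raw measurements were never published, so this module
generates concentration tables and survey populations with the same
statistical shape: per-cell lognormal concentrations moment-matched to the
published mean±SD cells, detection-limit censoring, and questionnaire
marginals matching the published respondent shares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from . import reference
from .data_io import ConcentrationTable, SURVEY_COLUMNS, to_mg_per_kg
from .distributions import DistributionSpec


class DesignError(ValueError):
    """Raised for inconsistent study-design parameters."""


def moment_matched_lognormal(mean: float, sd: float) -> DistributionSpec:
    """The lognormal whose analytic mean and SD equal the given pair.

    sigma² = ln(1 + sd²/mean²), mu = ln(mean) − sigma²/2.  A zero SD returns
    a degenerate point mass at the mean.
    """
    if not mean > 0:
        raise DesignError(f"mean must be > 0, got {mean!r}")
    if sd < 0:
        raise DesignError(f"sd must be >= 0, got {sd!r}")
    if sd == 0:
        return DistributionSpec("point", {"value": float(mean)})
    sigma2 = math.log1p((sd / mean) ** 2)
    return DistributionSpec(
        "lognormal",
        {"mu": math.log(mean) - sigma2 / 2.0, "sigma": math.sqrt(sigma2)},
    )


def moment_matched(family: str, mean: float, sd: float) -> DistributionSpec:
    """Moment-match any supported family to a (mean, sd) pair.

    Used to turn the published per-metal summary cells into generators under
    the family the study's fitting step selected.  Raises ``DesignError``
    when the family cannot attain the pair (e.g. log-gamma needs mean > 1
    because its support starts at 1; log-Laplace and Pareto need the implied
    second moment to stay finite).
    """
    if family == "lognormal":
        return moment_matched_lognormal(mean, sd)
    if not (mean > 0 and sd > 0):
        raise DesignError("moment matching needs mean > 0 and sd > 0")
    m2 = mean * mean + sd * sd
    if family == "weibull":
        cv2 = (sd / mean) ** 2

        def f(k):
            g1 = special.gamma(1 + 1 / k)
            return special.gamma(1 + 2 / k) / g1 ** 2 - 1 - cv2

        k = optimize.brentq(f, 0.08, 60.0)
        return DistributionSpec("weibull", {"shape": k, "scale": mean / special.gamma(1 + 1 / k)})
    if family == "pareto":
        cv2 = (sd / mean) ** 2
        alpha = 1.0 + math.sqrt(1.0 + 1.0 / cv2)
        return DistributionSpec("pareto", {"xmin": mean * (alpha - 1) / alpha, "alpha": alpha})
    if family == "loglaplace":
        target = m2 / mean ** 2

        def g(b):
            return (1 - b * b) ** 2 / (1 - 4 * b * b) - target

        b = optimize.brentq(g, 1e-9, 0.5 - 1e-9)
        return DistributionSpec("loglaplace", {"mu": math.log(mean * (1 - b * b)), "b": b})
    if family == "loggamma":
        if mean <= 1:
            raise DesignError("loggamma cannot attain a mean <= 1 (support starts at 1)")
        lm, lm2 = math.log(mean), math.log(m2)

        def h(beta):
            alpha = lm / -math.log1p(-1.0 / beta)
            return -alpha * math.log1p(-2.0 / beta) - lm2

        beta = optimize.brentq(h, 2.0 + 1e-9, 1e6)
        return DistributionSpec(
            "loggamma", {"alpha": lm / -math.log1p(-1.0 / beta), "beta": beta})
    if family == "gamma":
        return DistributionSpec("gamma", {"shape": (mean / sd) ** 2, "rate": mean / sd ** 2})
    if family == "normal":
        return DistributionSpec("normal", {"mu": mean, "sigma": sd})
    raise DesignError(f"moment matching not supported for family {family!r}")


def _sub_lod_lognormal(lod: float, sub_lod_prob: float, sigma: float = 1.0) -> DistributionSpec:
    """Lognormal whose probability mass below ``lod`` equals ``sub_lod_prob``."""
    from scipy.stats import norm

    mu = math.log(lod) - sigma * norm.ppf(sub_lod_prob)
    return DistributionSpec("lognormal", {"mu": mu, "sigma": sigma})


@dataclass(frozen=True)
class StudyDesign:
    """Generating design for a synthetic concentration table.

    ``cells`` maps (stratum label, metal) to the generating distribution in
    canonical mg·kg⁻¹; ``stratify_by`` says whether stratum labels are brands
    or colors.  With brand strata, each of a brand's color samples is an
    independent draw from the brand cell (and vice versa for color strata).
    """

    brands: tuple[tuple[str, str], ...]          # (label, country)
    colors: tuple[str, ...]
    replicates: int
    stratify_by: str                             # "brand" | "color"
    cells: dict[tuple[str, str], DistributionSpec]
    lods: dict[str, float] = field(default_factory=dict)   # mg·kg⁻¹

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise DesignError("replicates must be >= 1")
        if self.stratify_by not in ("brand", "color"):
            raise DesignError("stratify_by must be 'brand' or 'color'")
        if not self.brands or not self.colors:
            raise DesignError("design needs at least one brand and one color")

    @property
    def metals(self) -> tuple[str, ...]:
        return tuple(sorted({metal for _, metal in self.cells}))

    @property
    def n_samples(self) -> int:
        return len(self.brands) * len(self.colors) * self.replicates


def _cells_from_frame(df: pd.DataFrame, label_col: str, sub_lod_prob: float) -> dict:
    cells = {}
    for r in df.itertuples():
        label, metal = str(getattr(r, label_col)), str(r.metal)
        lod = reference.detection_limits()[metal]
        if bool(r.censored):
            # a ">20% below LOD" cell: concentrate most mass below the LOD
            cells[(label, metal)] = _sub_lod_lognormal(lod, sub_lod_prob=0.75, sigma=0.5)
        else:
            mean = to_mg_per_kg(float(r.mean), str(r.unit))
            sd = to_mg_per_kg(float(r.sd), str(r.unit))
            cells[(label, metal)] = moment_matched_lognormal(mean, sd)
    return cells


def default_design(sub_lod_prob: float = 0.25) -> StudyDesign:
    """The packaged brand-parameterized design: 8 brands × 4 colors × 1 replicate.

    Assessed metals draw from per-brand moment-matched lognormals; the four
    metals excluded by the study's censoring rule draw from lognormals whose
    sub-LOD mass is ``sub_lod_prob`` so the exclusion branch of the policy is
    exercised end to end.
    """
    brands_df = reference.brand_cells()
    cells = _cells_from_frame(brands_df, "brand", sub_lod_prob)
    lods = reference.detection_limits()
    countries = dict(zip(brands_df["brand"], brands_df["country"]))
    for metal in reference.EXCLUDED_METALS:
        spec = _sub_lod_lognormal(lods[metal], sub_lod_prob)
        for brand in reference.BRANDS:
            cells[(brand, metal)] = spec
    return StudyDesign(
        brands=tuple((b, str(countries[b])) for b in reference.BRANDS),
        colors=reference.COLORS,
        replicates=1,
        stratify_by="brand",
        cells=cells,
        lods=lods,
    )


def color_design(sub_lod_prob: float = 0.25) -> StudyDesign:
    """Alternate design parameterized by the per-color cells."""
    colors_df = reference.color_cells()
    cells = _cells_from_frame(colors_df, "color", sub_lod_prob)
    lods = reference.detection_limits()
    countries = dict(zip(reference.brand_cells()["brand"], reference.brand_cells()["country"]))
    for metal in reference.EXCLUDED_METALS:
        spec = _sub_lod_lognormal(lods[metal], sub_lod_prob)
        for color in reference.COLORS:
            cells[(color, metal)] = spec
    return StudyDesign(
        brands=tuple((b, str(countries[b])) for b in reference.BRANDS),
        colors=reference.COLORS,
        replicates=1,
        stratify_by="color",
        cells=cells,
        lods=lods,
    )


def table1_generators() -> dict[str, tuple[DistributionSpec, str]]:
    """Pooled per-metal generators under the published best-fit families.

    Each assessed metal gets the family the study's fitting step selected,
    moment-matched to the pooled mean±SD, in the unit of that metal's
    reported row (Ba is matched on the µg·kg⁻¹ scale, where the log-gamma
    support constraint can be met).  Returns metal -> (spec, unit).
    """
    out = {}
    for r in reference.pooled_summary().itertuples():
        metal, family, unit = str(r.metal), str(r.family), str(r.unit)
        mean, sd = float(r.mean), float(r.sd)
        if family == "loggamma" and mean <= 1 and unit == "ppm":
            mean, sd, unit = mean * 1000.0, sd * 1000.0, "ppb"
        out[metal] = (moment_matched(family, mean, sd), unit)
    return out


def generate_concentrations(design: StudyDesign, seed: int) -> ConcentrationTable:
    """Draw one synthetic concentration table from a study design.

    One measurement per (brand, color, metal, replicate), drawn in a fixed
    iteration order from a single seeded generator, so identical seed and
    design give byte-identical tables.  Draws below a metal's detection
    limit are stored censored, carrying the LOD and no concentration.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for metal in design.metals:
        lod = design.lods.get(metal)
        for brand, country in design.brands:
            for color in design.colors:
                stratum = brand if design.stratify_by == "brand" else color
                try:
                    spec = design.cells[(stratum, metal)]
                except KeyError:
                    raise DesignError(f"design has no cell for ({stratum!r}, {metal!r})")
                draws = spec.rvs(design.replicates, rng)
                for rep, value in enumerate(draws, start=1):
                    censored = lod is not None and value < lod
                    rows.append({
                        "sample_id": f"{brand}:{color}:r{rep}",
                        "brand": brand,
                        "country": country,
                        "color": color,
                        "metal": metal,
                        "concentration": np.nan if censored else float(value),
                        "below_lod": censored,
                        "lod": lod if lod is not None else np.nan,
                        "imputed": False,
                    })
    return ConcentrationTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# survey population
# ---------------------------------------------------------------------------

#: questionnaire marginals: respondent shares by preferred color / brand and
#: the dye-use probabilities; numeric fields as moment-matched lognormals
DEFAULT_SURVEY_GENERATORS: dict = {
    "uses_dye": 0.9219,
    "uses_chemical_dye": 0.495,
    "age_start": {"12": 0.195, "19": 0.347},      # remainder uniform over 13–30
    "frequency_per_year": moment_matched_lognormal(12.0, 4.0),
    "body_weight_kg": moment_matched_lognormal(68.0, 12.0),
    "color_pref": {"blonde": 0.336, "light_brown": 0.274, "dark_brown": 0.196, "black": 0.14},
    "brand_pref": {
        "brand_1": 0.197, "brand_2": 0.136, "brand_3": 0.083, "brand_4": 0.068,
        "brand_5": 0.068, "brand_6": 0.053, "brand_7": 0.053, "brand_8": 0.053,
    },
}


def _draw_categorical(rng: np.random.Generator, n: int, weights: dict[str, float]) -> np.ndarray:
    labels = sorted(weights)
    w = np.array([weights[k] for k in labels], dtype=float)
    if (w < 0).any() or w.sum() > 1 + 1e-12:
        raise DesignError(f"categorical weights must be nonnegative and sum to <= 1, got {weights}")
    labels.append("other")
    w = np.append(w, max(0.0, 1.0 - w.sum()))
    return rng.choice(np.array(labels, dtype=object), size=n, p=w / w.sum())


def generate_survey(n: int, generators: dict | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate ``n`` synthetic questionnaire records.

    ``generators`` overrides entries of :data:`DEFAULT_SURVEY_GENERATORS`:
    probabilities for the boolean fields, label->weight dicts for the
    categorical fields (weights sum to <= 1; the remainder becomes "other"),
    and :class:`DistributionSpec` for the numeric fields.
    """
    if n < 1:
        raise DesignError("n must be >= 1")
    gen = dict(DEFAULT_SURVEY_GENERATORS)
    if generators:
        gen.update(generators)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    uses_dye = rng.random(n) < float(gen["uses_dye"])
    uses_chem = rng.random(n) < float(gen["uses_chemical_dye"])

    age_weights = dict(gen["age_start"])
    picks = _draw_categorical(rng, n, {str(k): float(v) for k, v in age_weights.items()})
    ages = np.where(picks == "other", rng.integers(13, 31, size=n), -1).astype(float)
    for label in age_weights:
        ages[picks == str(label)] = float(label)

    freq = gen["frequency_per_year"].rvs(n, rng)
    bw = gen["body_weight_kg"].rvs(n, rng)
    color_pref = _draw_categorical(rng, n, gen["color_pref"])
    brand_pref = _draw_categorical(rng, n, gen["brand_pref"])

    return pd.DataFrame({
        "respondent_id": [f"R{i:04d}" for i in range(1, n + 1)],
        "uses_dye": uses_dye,
        "uses_chemical_dye": uses_chem,
        "age_start": ages,
        "frequency_per_year": freq,
        "body_weight_kg": bw,
        "color_pref": color_pref,
        "brand_pref": brand_pref,
    }, columns=list(SURVEY_COLUMNS))
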