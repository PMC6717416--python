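"""Non-carcinogenic risk characterization.

Per metal the hazard quotient is HQ = D_dermal / RfD; per stratum (pooled,
brand or color) the chronic hazard index is the sum of the stratum's HQs.
An index above 1 flags a potentially significant non-carcinogenic risk; at
or below 1 the risk is classified "not-probable".  Metals excluded by the
censoring policy contribute nothing to the index and are listed explicitly,
so a stratum's HI is a lower bound whenever exclusions exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .data_io import ConcentrationTable, RfDEntry
from .distributions import DistributionSpec
from .exposure import ExposureFactors, dermal_dose, simulate_dose, summarize_dose

import numpy as np


class RfDLookupError(KeyError):
    """A dosed metal has no reference-dose entry."""


def hazard_quotient(dose: float, rfd: float) -> float:
    """HQ = dose / RfD (both mg·kg⁻¹·day⁻¹; the quotient is unitless)."""
    if not rfd > 0:
        raise ValueError(f"RfD must be > 0, got {rfd!r}")
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose!r}")
    return dose / rfd


def hazard_index(hqs) -> float:
    """Chronic hazard index: the sum of the hazard quotients."""
    hqs = list(hqs)
    if not hqs:
        raise ValueError("need at least one hazard quotient")
    return float(sum(hqs))


def classify(index: float) -> str:
    """'significant' strictly above 1, else 'not-probable'."""
    return "significant" if index > 1.0 else "not-probable"


@dataclass(frozen=True)
class RiskResult:
    """Risk characterization of one stratum."""

    stratum: str
    hq: dict[str, float]                   # metal -> hazard quotient
    dose: dict[str, float]                 # metal -> point dose (mg·kg⁻¹·day⁻¹)
    rfd_basis: str                         # "dermal" | "ingestion"
    point_estimate_used: str               # "median" | "mean"
    excluded: tuple[str, ...] = ()         # metals dropped by the censoring policy
    assessable: bool = True

    @property
    def hi(self) -> float:
        return hazard_index(self.hq.values()) if self.hq else 0.0

    @property
    def classification(self) -> str:
        return classify(self.hi)

    @property
    def hi_is_lower_bound(self) -> bool:
        return bool(self.excluded)


def characterize(
    doses: dict[str, float],
    rfd_table: dict[str, RfDEntry],
    stratum: str = "pooled",
    rfd_basis: str = "dermal",
    point_estimate_used: str = "median",
    excluded=(),
) -> RiskResult:
    """Hazard quotients and index for a set of per-metal point doses.

    Every dosed metal must have a reference dose; a missing entry raises
    rather than silently dropping the metal.
    """
    hq = {}
    for metal in sorted(doses):
        if metal not in rfd_table:
            raise RfDLookupError(f"no reference dose for metal {metal!r}")
        hq[metal] = hazard_quotient(doses[metal], rfd_table[metal].basis(rfd_basis))
    return RiskResult(
        stratum=stratum, hq=hq, dose=dict(doses), rfd_basis=rfd_basis,
        point_estimate_used=point_estimate_used, excluded=tuple(sorted(excluded)),
        assessable=bool(hq),
    )


def _point_dose(
    c_point: float,
    factors: ExposureFactors,
    n_iter: int,
    seed: int,
    point_estimate: str,
) -> float:
    """Point dose for a fixed concentration: deterministic when every factor
    is fixed, otherwise the Monte Carlo central value."""
    if not factors.varying():
        return dermal_dose(c_point, factors)
    d = simulate_dose(DistributionSpec("point", {"value": c_point}), factors,
                      n_iter=n_iter, seed=seed)
    return summarize_dose(d, point_estimate)


def stratified_risk(
    table: ConcentrationTable,
    by: str,
    rfd_table: dict[str, RfDEntry],
    factors: ExposureFactors,
    n_iter: int = 20_000,
    seed: int = 0,
    point_estimate: str = "median",
    rfd_basis: str = "dermal",
    excluded=(),
) -> dict[str, RiskResult]:
    """One RiskResult per brand or color stratum.

    Each stratum's concentration point estimate (median or mean of its
    resolved measurements) is pushed through the same dose pipeline as the
    pooled assessment.  A stratum with no resolved metals is returned
    not-assessable; excluded metals are carried on every result.
    """
    if by not in ("brand", "color"):
        raise ValueError("by must be 'brand' or 'color'")
    strata = table.brands if by == "brand" else table.colors
    results: dict[str, RiskResult] = {}
    for i, stratum in enumerate(strata):
        sub = table.by_brand(stratum) if by == "brand" else table.by_color(stratum)
        doses = {}
        for metal in sub.metals:
            v = sub.values(metal)
            if v.size == 0:
                continue
            c_point = float(np.median(v) if point_estimate == "median" else np.mean(v))
            doses[metal] = _point_dose(c_point, factors, n_iter, seed + i, point_estimate)
        results[stratum] = characterize(
            doses, rfd_table, stratum=stratum, rfd_basis=rfd_basis,
            point_estimate_used=point_estimate, excluded=excluded,
        )
    return results


def maximal_stratum(results: dict[str, RiskResult]) -> str:
    """The assessable stratum with the largest hazard index (ties: first label)."""
    assessable = {k: r for k, r in results.items() if r.assessable}
    if not assessable:
        raise ValueError("no assessable stratum")
    return max(sorted(assessable), key=lambda k: assessable[k].hi)
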