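"""Dermal dose model.

The average daily dose absorbed through the scalp is

    D_dermal = C · SA · SL · ABS · EF · ED / (BW · AT) · 1e-6
    AT       = ED · 365

with C the product concentration (mg·kg⁻¹), SA the exposed scalp area
(cm²), SL the product adherence to skin (mg·cm⁻²), ABS the absorbed
fraction (unitless, in (0, 1]), EF the exposure frequency (days·year⁻¹),
ED the exposure duration (years), BW body weight (kg) and AT the averaging
time (days).  The 1e-6 factor converts the mg·(mg·kg⁻¹)·cm²·(mg·cm⁻²)
product chain onto the mg·kg⁻¹·day⁻¹ dose scale.  Because AT = ED·365, the
duration cancels and the dose is invariant to ED.

Each factor is either a fixed positive value or a distribution; when any
input is distributional the dose is propagated by seeded Monte Carlo with
one independent random stream per factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .distributions import DistributionSpec

#: canonical factor order; also fixes each factor's random stream index
FACTOR_NAMES = ("C", "SA", "SL", "ABS", "EF", "ED", "BW")

FactorValue = float | DistributionSpec


class DoseDomainError(ValueError):
    """A dose-equation input violates its domain."""


def averaging_time(ed: float) -> float:
    """Averaging time in days for an exposure duration of ``ed`` years."""
    if not ed > 0:
        raise DoseDomainError(f"ED must be > 0 years, got {ed!r}")
    return ed * 365.0


@dataclass(frozen=True)
class ExposureFactors:
    """The dose-equation inputs other than concentration.

    Each field is a fixed positive value or a :class:`DistributionSpec`.
    Units: SA cm², SL mg·cm⁻², ABS unitless in (0, 1], EF day·year⁻¹,
    ED years, BW kg.
    """

    SA: FactorValue = 580.0
    SL: FactorValue = 1.45
    ABS: FactorValue = 0.001
    EF: FactorValue = 12.0
    ED: FactorValue = 20.0
    BW: FactorValue = 60.0

    def value_of(self, name: str) -> FactorValue:
        return getattr(self, name)

    def fixed(self) -> dict[str, float]:
        """The fixed factors as floats; raises if any factor is distributional."""
        out = {}
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if isinstance(v, DistributionSpec):
                raise DoseDomainError(f"factor {f.name} is distributional, not fixed")
            out[f.name] = float(v)
        return out

    def varying(self) -> list[str]:
        return [f.name for f in dc_fields(self) if isinstance(getattr(self, f.name), DistributionSpec)]

    def to_dict(self) -> dict:
        return {
            f.name: (getattr(self, f.name).to_dict()
                     if isinstance(getattr(self, f.name), DistributionSpec)
                     else float(getattr(self, f.name)))
            for f in dc_fields(self)
        }


def _check_fixed(name: str, value: float) -> None:
    if not value > 0:
        raise DoseDomainError(f"factor {name} must be > 0, got {value!r}")
    if name == "ABS" and value > 1:
        raise DoseDomainError(f"ABS must lie in (0, 1], got {value!r}")


def dermal_dose(c: float, f: ExposureFactors) -> float:
    """Deterministic dermal dose (mg·kg⁻¹·day⁻¹) for fixed factors and C >= 0."""
    if c < 0:
        raise DoseDomainError(f"concentration must be >= 0, got {c!r}")
    v = f.fixed()
    for name, value in v.items():
        _check_fixed(name, value)
    at = averaging_time(v["ED"])
    return c * v["SA"] * v["SL"] * v["ABS"] * v["EF"] * v["ED"] / (v["BW"] * at) * 1e-6


@dataclass
class DoseDistribution:
    """Monte Carlo sample of the dermal dose for one metal."""

    metal: str
    draws: np.ndarray
    n_iter: int
    seed: int
    summaries: dict[str, float]
    varying: tuple[str, ...]
    rejections: int = 0
    inputs: pd.DataFrame | None = field(default=None, repr=False)


def _summaries(draws: np.ndarray) -> dict[str, float]:
    q = np.quantile(draws, [0.05, 0.25, 0.5, 0.75, 0.95])
    return {
        "mean": float(np.mean(draws)),
        "median": float(q[2]),
        "p5": float(q[0]), "p25": float(q[1]), "p75": float(q[3]), "p95": float(q[4]),
    }


def _factor_rng(seed: int, name: str) -> np.random.Generator:
    # one named, reproducible stream per factor, independent across factors
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(FACTOR_NAMES.index(name),)))


def _valid(name: str, x: np.ndarray) -> np.ndarray:
    ok = x > 0
    if name == "ABS":
        ok &= x <= 1
    return ok


def simulate_dose(
    c_dist: DistributionSpec,
    f: ExposureFactors,
    n_iter: int = 20_000,
    seed: int = 0,
    retain_inputs: bool = False,
    metal: str = "",
) -> DoseDistribution:
    """Propagate the dose equation by Monte Carlo.

    Every distributional input (the concentration and any distributional
    factor) is sampled from its own named stream derived from ``seed``, so
    runs are reproducible and the streams stay independent for sensitivity
    analysis.  Realizations outside a factor's domain (possible only for
    unbounded user-supplied families) are rejected and redrawn from the same
    stream, up to 10 × ``n_iter`` attempts per factor; the rejection count
    is reported.  ``retain_inputs`` stores the per-draw input matrix needed
    by the sensitivity module.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    specs: dict[str, FactorValue] = {"C": c_dist}
    for name in FACTOR_NAMES[1:]:
        specs[name] = f.value_of(name)

    columns: dict[str, np.ndarray] = {}
    rejections = 0
    for name in FACTOR_NAMES:
        v = specs[name]
        if isinstance(v, DistributionSpec):
            rng = _factor_rng(seed, name)
            x = np.asarray(v.rvs(n_iter, rng), dtype=float)
            if name == "C":
                bad = ~np.isfinite(x) | (x < 0)
            else:
                bad = ~_valid(name, x)
            attempts = n_iter
            while bad.any():
                k = int(bad.sum())
                if attempts + k > 10 * n_iter:
                    raise DoseDomainError(
                        f"factor {name}: could not realize a valid value within 10x n_iter draws")
                x[bad] = v.rvs(k, rng)
                rejections += k
                attempts += k
                bad = (~np.isfinite(x) | (x < 0)) if name == "C" else ~_valid(name, x)
            columns[name] = x
        else:
            value = float(v)
            if name != "C":
                _check_fixed(name, value)
            columns[name] = np.full(n_iter, value)

    at = columns["ED"] * 365.0
    draws = (columns["C"] * columns["SA"] * columns["SL"] * columns["ABS"]
             * columns["EF"] * columns["ED"] / (columns["BW"] * at) * 1e-6)
    varying = tuple(n for n in FACTOR_NAMES if isinstance(specs[n], DistributionSpec))
    inputs = pd.DataFrame({n: columns[n] for n in varying}) if retain_inputs else None
    return DoseDistribution(
        metal=metal, draws=draws, n_iter=n_iter, seed=seed,
        summaries=_summaries(draws), varying=varying,
        rejections=rejections, inputs=inputs,
    )


def summarize_dose(d: DoseDistribution, point_estimate: str = "median") -> float:
    """Central dose value: the distribution median (default) or mean."""
    if d.draws.size == 0:
        raise ValueError("dose distribution has no draws")
    if point_estimate == "median":
        return float(np.median(d.draws))
    if point_estimate == "mean":
        return float(np.mean(d.draws))
    raise ValueError(f"point_estimate must be 'median' or 'mean', got {point_estimate!r}")
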