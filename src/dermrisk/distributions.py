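"""Parametric distribution families for exposure inputs.

Concentration and exposure-factor uncertainty is represented by a small set
of named families, each with a full density / cumulative / quantile /
sampling contract, maximum-likelihood fitting, and a deterministic
goodness-of-fit ranking (Kolmogorov–Smirnov primary, Anderson–Darling
tie-break, chi-square reported).

Parameterizations
-----------------
lognormal(mu, sigma)
    ln X ~ Normal(mu, sigma); support (0, inf).
loggamma(alpha, beta)
    ln X ~ Gamma(shape alpha, rate beta); support [1, inf).  An optional
    log-scale location shift exists but is disabled by default.
weibull(shape, scale)
    Standard two-parameter Weibull; support (0, inf).
pareto(xmin, alpha)
    Pareto type I with minimum xmin and tail index alpha; support [xmin, inf).
loglaplace(mu, b)
    ln X ~ Laplace(location mu, scale b); support (0, inf).
normal(mu, sigma), gamma(shape, rate), exponential(rate)
    Generic alternates for user-supplied exposure factors.
point(value)
    Degenerate point mass, used for fixed factors and zero-spread cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class ParameterError(ValueError):
    """Raised when distribution parameters violate family constraints."""


class FitError(ValueError):
    """Raised when maximum-likelihood fitting is impossible on a sample."""


class SupportError(FitError):
    """Raised when a sample lies outside the family's support."""


#: parameter names, in canonical order, per family
PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "lognormal": ("mu", "sigma"),
    "loggamma": ("alpha", "beta"),
    "weibull": ("shape", "scale"),
    "pareto": ("xmin", "alpha"),
    "loglaplace": ("mu", "b"),
    "normal": ("mu", "sigma"),
    "gamma": ("shape", "rate"),
    "exponential": ("rate",),
    "point": ("value",),
}

#: the candidate families used for concentration fitting by default
DEFAULT_CANDIDATES: tuple[str, ...] = (
    "lognormal",
    "loggamma",
    "weibull",
    "pareto",
    "loglaplace",
)


def _positive(name: str, value: float) -> None:
    if not (value > 0 and math.isfinite(value)):
        raise ParameterError(f"parameter {name!r} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class DistributionSpec:
    """A named parametric family with concrete parameter values."""

    family: str
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in PARAM_NAMES:
            raise ParameterError(f"unknown family {self.family!r}")
        names = PARAM_NAMES[self.family]
        missing = [n for n in names if n not in self.params]
        if missing:
            raise ParameterError(f"{self.family}: missing parameters {missing}")
        extra = [n for n in self.params if n not in names]
        if extra:
            raise ParameterError(f"{self.family}: unknown parameters {extra}")
        p = self.params
        if self.family in ("lognormal", "normal"):
            if not (p["sigma"] > 0):
                raise ParameterError("sigma must be > 0")
        elif self.family == "loggamma":
            _positive("alpha", p["alpha"])
            _positive("beta", p["beta"])
        elif self.family == "weibull":
            _positive("shape", p["shape"])
            _positive("scale", p["scale"])
        elif self.family == "pareto":
            _positive("xmin", p["xmin"])
            _positive("alpha", p["alpha"])
        elif self.family == "loglaplace":
            _positive("b", p["b"])
        elif self.family == "gamma":
            _positive("shape", p["shape"])
            _positive("rate", p["rate"])
        elif self.family == "exponential":
            _positive("rate", p["rate"])
        elif self.family == "point":
            if not math.isfinite(p["value"]):
                raise ParameterError("point mass value must be finite")

    # -- support ---------------------------------------------------------
    def support(self) -> tuple[float, float]:
        p = self.params
        if self.family == "normal":
            return (-math.inf, math.inf)
        if self.family == "loggamma":
            return (1.0, math.inf)
        if self.family == "pareto":
            return (p["xmin"], math.inf)
        if self.family == "point":
            return (p["value"], p["value"])
        return (0.0, math.inf)

    # -- scipy bridge ----------------------------------------------------
    def _frozen(self):
        """The equivalent frozen scipy distribution (None for point mass)."""
        p = self.params
        f = self.family
        if f == "lognormal":
            return stats.lognorm(p["sigma"], scale=math.exp(p["mu"]))
        if f == "loggamma":
            # handled by log-scale transform of a gamma; no direct frozen rv
            return None
        if f == "weibull":
            return stats.weibull_min(p["shape"], scale=p["scale"])
        if f == "pareto":
            return stats.pareto(p["alpha"], scale=p["xmin"])
        if f == "loglaplace":
            return stats.loglaplace(1.0 / p["b"], scale=math.exp(p["mu"]))
        if f == "normal":
            return stats.norm(p["mu"], p["sigma"])
        if f == "gamma":
            return stats.gamma(p["shape"], scale=1.0 / p["rate"])
        if f == "exponential":
            return stats.expon(scale=1.0 / p["rate"])
        return None

    def _log_gamma(self):
        p = self.params
        return stats.gamma(p["alpha"], scale=1.0 / p["beta"])

    # -- contract --------------------------------------------------------
    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        if self.family == "point":
            return np.where(x == self.params["value"], math.inf, 0.0)
        if self.family == "loggamma":
            out = np.zeros_like(x)
            ok = x >= 1.0
            with np.errstate(divide="ignore"):
                out = np.where(ok, self._log_gamma().pdf(np.log(np.where(ok, x, 1.0))) / np.where(ok, x, 1.0), 0.0)
            return out
        return self._frozen().pdf(x)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        if self.family == "point":
            return np.where(x >= self.params["value"], 1.0, 0.0)
        if self.family == "loggamma":
            return np.where(x >= 1.0, self._log_gamma().cdf(np.log(np.maximum(x, 1.0))), 0.0)
        return self._frozen().cdf(x)

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.family == "point":
            return np.full_like(q, self.params["value"])
        if self.family == "loggamma":
            return np.exp(self._log_gamma().ppf(q))
        return self._frozen().ppf(q)

    def rvs(self, n: int, rng: np.random.Generator | int) -> np.ndarray:
        """Draw ``n`` reproducible samples using ``rng`` (Generator or seed)."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        if self.family == "point":
            return np.full(n, self.params["value"], dtype=float)
        if self.family == "loggamma":
            return np.exp(self._log_gamma().rvs(size=n, random_state=rng))
        return self._frozen().rvs(size=n, random_state=rng)

    def mean(self) -> float:
        if self.family == "point":
            return self.params["value"]
        if self.family == "loggamma":
            a, b = self.params["alpha"], self.params["beta"]
            if b <= 1:
                return math.inf
            # E exp(G) = MGF of Gamma(a, rate b) at t=1
            return (1.0 - 1.0 / b) ** (-a)
        return float(self._frozen().mean())

    def sd(self) -> float:
        if self.family == "point":
            return 0.0
        if self.family == "loggamma":
            a, b = self.params["alpha"], self.params["beta"]
            if b <= 2:
                return math.inf
            m = self.mean()
            m2 = (1.0 - 2.0 / b) ** (-a)
            return math.sqrt(max(m2 - m * m, 0.0))
        return float(self._frozen().std())

    def median(self) -> float:
        return float(self.ppf(0.5))

    def to_dict(self) -> dict:
        """JSON-serializable form: family, named params, support."""
        lo, hi = self.support()
        return {
            "family": self.family,
            "params": {k: float(v) for k, v in self.params.items()},
            "support": [lo, None if math.isinf(hi) else hi],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        return cls(d["family"], {k: float(v) for k, v in d["params"].items()})


def evaluate(dist: DistributionSpec, x: float) -> tuple[float, float]:
    """Density and cumulative probability at ``x`` (0 / side-clamped outside support)."""
    return float(dist.pdf(x)), float(dist.cdf(x))


def sample(dist: DistributionSpec, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Seed-reproducible draws from ``dist``."""
    return dist.rvs(n, seed)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _as_sample(samples) -> np.ndarray:
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 3:
        raise FitError(f"need at least 3 observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise FitError("sample contains non-finite values")
    return x


def fit_mle(samples, family: str) -> DistributionSpec:
    """Maximum-likelihood fit of ``family`` to a 1-d sample.

    Log-scale families (lognormal, loglaplace, loggamma) are fitted by the
    closed-form / standard MLE of the corresponding location–scale family on
    the log observations; Weibull and gamma use scipy's numeric MLE with the
    location pinned at zero; Pareto uses the closed form with xmin fixed at
    the sample minimum.
    """
    x = _as_sample(samples)
    if family not in PARAM_NAMES or family == "point":
        raise FitError(f"cannot fit family {family!r}")
    if np.ptp(x) == 0.0 and family != "normal":
        raise FitError(f"{family}: degenerate sample (all values equal)")

    if family == "normal":
        if np.ptp(x) == 0.0:
            raise FitError("normal: degenerate sample (all values equal)")
        return DistributionSpec("normal", {"mu": float(np.mean(x)), "sigma": float(np.std(x))})

    if np.any(x <= 0):
        raise SupportError(f"{family}: sample must be strictly positive")

    if family == "lognormal":
        lx = np.log(x)
        return DistributionSpec("lognormal", {"mu": float(np.mean(lx)), "sigma": float(np.std(lx))})
    if family == "loglaplace":
        lx = np.log(x)
        mu = float(np.median(lx))
        return DistributionSpec("loglaplace", {"mu": mu, "b": float(np.mean(np.abs(lx - mu)))})
    if family == "loggamma":
        if np.any(x < 1.0):
            raise SupportError("loggamma: sample must be >= 1 (log-scale gamma support)")
        lx = np.log(x)
        if np.any(lx <= 0):
            raise SupportError("loggamma: sample must be > 1 for a positive log")
        a, _loc, sc = stats.gamma.fit(lx, floc=0.0)
        return DistributionSpec("loggamma", {"alpha": float(a), "beta": float(1.0 / sc)})
    if family == "weibull":
        shape, _loc, scale = stats.weibull_min.fit(x, floc=0.0)
        return DistributionSpec("weibull", {"shape": float(shape), "scale": float(scale)})
    if family == "gamma":
        a, _loc, sc = stats.gamma.fit(x, floc=0.0)
        return DistributionSpec("gamma", {"shape": float(a), "rate": float(1.0 / sc)})
    if family == "exponential":
        return DistributionSpec("exponential", {"rate": float(1.0 / np.mean(x))})
    if family == "pareto":
        xmin = float(np.min(x))
        logs = np.log(x / xmin)
        s = float(np.sum(logs))
        if s <= 0:
            raise FitError("pareto: degenerate sample (all values at the minimum)")
        return DistributionSpec("pareto", {"xmin": xmin, "alpha": float(x.size / s)})
    raise FitError(f"unhandled family {family!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# goodness of fit and model selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GofReport:
    """Fit quality of one candidate family on one sample."""

    family: str
    spec: DistributionSpec
    ks_stat: float
    ad_stat: float
    chi2_stat: float
    chi2_bins: int
    rank: int


@dataclass(frozen=True)
class FitFailure:
    family: str
    reason: str


@dataclass(frozen=True)
class SelectionResult:
    """Ranked goodness-of-fit reports plus any recorded fit failures."""

    reports: tuple[GofReport, ...]
    failures: tuple[FitFailure, ...]

    @property
    def best(self) -> GofReport:
        if not self.reports:
            raise FitError(
                "all candidate families failed to fit: "
                + "; ".join(f"{f.family}: {f.reason}" for f in self.failures)
            )
        return self.reports[0]


def anderson_darling(x: np.ndarray, dist: DistributionSpec) -> float:
    """A² statistic of the sample against a fully specified cdf."""
    u = np.sort(np.clip(dist.cdf(np.sort(np.asarray(x, dtype=float))), 1e-12, 1 - 1e-12))
    n = u.size
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1]))))


def chi_square_stat(x: np.ndarray, dist: DistributionSpec, n_bins: int | None = None) -> tuple[float, int]:
    """Chi-square statistic on equal-probability bins under the fitted cdf."""
    x = np.asarray(x, dtype=float)
    n = x.size
    k = n_bins if n_bins is not None else math.ceil(1 + math.log2(n))
    edges = dist.ppf(np.linspace(0.0, 1.0, k + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    observed, _ = np.histogram(x, bins=edges)
    expected = n / k
    return float(np.sum((observed - expected) ** 2 / expected)), k


def select_best(samples, candidates=DEFAULT_CANDIDATES) -> SelectionResult:
    """Fit every candidate family and rank by (KS, AD, chi-square).

    Families that cannot be fitted on the sample (support violations,
    degenerate samples) are recorded as failures, never silently dropped.
    """
    x = _as_sample(samples)
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    scored: list[tuple[float, float, float, int, str, DistributionSpec]] = []
    failures: list[FitFailure] = []
    for family in candidates:
        try:
            spec = fit_mle(x, family)
            ks = float(stats.kstest(x, spec.cdf).statistic)
            ad = anderson_darling(x, spec)
            chi2, k = chi_square_stat(x, spec)
        except (FitError, ParameterError) as exc:
            failures.append(FitFailure(family, str(exc)))
            continue
        scored.append((ks, ad, chi2, k, family, spec))
    scored.sort(key=lambda t: (t[0], t[1], t[2], t[4]))
    reports = tuple(
        GofReport(family=family, spec=spec, ks_stat=ks, ad_stat=ad,
                  chi2_stat=chi2, chi2_bins=k, rank=i + 1)
        for i, (ks, ad, chi2, k, family, spec) in enumerate(scored)
    )
    return SelectionResult(reports=reports, failures=tuple(failures))
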