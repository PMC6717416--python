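"""Rank-correlation sensitivity analysis of the Monte Carlo dose.

For each distributional input the Spearman rank correlation with the dose
draws measures monotone influence; inputs are ordered by absolute
correlation (the sign is reported separately, body weight acts negatively).
Fixed inputs are reported as not-applicable rather than zero.  Exposure
duration is reported faithfully even though the averaging-time convention
cancels it out of the dose, so its correlation is indistinguishable from
zero by construction; the result carries a note saying so.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exposure import FACTOR_NAMES, DoseDistribution


class RetentionError(RuntimeError):
    """The simulation was run without per-draw input retention."""


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (average ranks for ties).

    Returns NaN when either vector is constant, where the correlation is
    undefined; callers report that as not-applicable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    return float(stats.spearmanr(x, y).statistic)


@dataclass(frozen=True)
class SensitivityResult:
    """Per-input rank correlations with the dose for one metal."""

    metal: str
    rho: dict[str, float | None]       # factor -> correlation; None = not applicable
    ordering: tuple[str, ...]          # varying inputs by descending |rho|
    tied: tuple[str, ...] = ()         # inputs involved in an |rho| tie
    notes: dict[str, str] | None = None


def sensitivity_analysis(sim: DoseDistribution) -> SensitivityResult:
    """Rank-correlate each retained input with the dose draws.

    Requires a simulation run with ``retain_inputs=True``; ordering is by
    absolute correlation, ties broken alphabetically and flagged.
    """
    if sim.inputs is None:
        raise RetentionError(
            "simulation was run without input retention; rerun simulate_dose with retain_inputs=True")
    rho: dict[str, float | None] = {}
    notes: dict[str, str] = {}
    for name in FACTOR_NAMES:
        if name not in sim.varying:
            rho[name] = None
            notes[name] = "fixed input: not applicable"
            continue
        if sim.draws.size < 3:
            rho[name] = None
            notes[name] = "fewer than 3 draws: correlation not estimable"
            continue
        r = spearman_rho(sim.inputs[name].to_numpy(), sim.draws)
        rho[name] = None if math.isnan(r) else r
        if name == "ED":
            notes[name] = ("ED cancels out of the dose through the averaging time; "
                           "its correlation is zero by construction")
        if math.isnan(r):
            notes[name] = "constant realization: correlation undefined"

    scored = sorted(
        ((name, r) for name, r in rho.items() if r is not None),
        key=lambda t: (-abs(t[1]), t[0]),
    )
    ordering = tuple(name for name, _ in scored)
    tied_set: set[str] = set()
    for (a, ra), (b, rb) in zip(scored, scored[1:]):
        if abs(ra) == abs(rb):
            tied_set.update((a, b))
    return SensitivityResult(metal=sim.metal, rho=rho, ordering=ordering,
                             tied=tuple(sorted(tied_set)), notes=notes)
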