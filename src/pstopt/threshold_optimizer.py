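"""Optimal and constrained p-value significance thresholds.

The optimal threshold for a design is the two-tailed t cut-off minimizing
the weighted error cost; reported on the p-value scale it is the flexible
significance threshold for that design.  The constrained variant
additionally demands a maximum acceptable type-I error (default 0.05) and a
minimum acceptable power (default 0.8).

Two conventions for imposing the constraints are provided:

``"filter"`` (default)
    The unconstrained optimum is computed and the design is declared
    infeasible if that optimum violates either constraint.  This is the
    convention that reproduces the published grid of constrained
    thresholds, including its infeasible cells: a design such as
    (n1, n2) = (50, 100) at d = 0.5 admits cut-offs satisfying both
    constraints, yet its cost-optimal cut-off is under-powered, so it is
    reported as infeasible.

``"clamp"``
    The optimum is projected onto the feasible cut-off interval
    [t(alpha_max), t(power_min)]; infeasible only when that interval is
    empty.  Because the cost is unimodal, the projection is the
    cost-minimizing feasible cut-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .error_model import (
    ErrorRates,
    StudyDesign,
    cost,
    effect_to_delta,
    pst_to_t,
    type2_error,
)

__all__ = [
    "ConstraintSpec",
    "ThresholdResult",
    "optimize_threshold",
    "constrain_threshold",
    "threshold_table",
    "threshold_sweep",
]

#: search interval floor for the cut-off; widened adaptively with delta
T_UPPER_MIN = 12.0
#: grid points for the pre-scan bracketing the minimum
GRID_POINTS = 4001


@dataclass(frozen=True)
class ConstraintSpec:
    """Acceptability constraints on the optimized threshold."""

    alpha_max: float = 0.05
    power_min: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_max < 1.0:
            raise ValueError(f"alpha_max must lie in (0, 1), got {self.alpha_max}")
        if not 0.0 < self.power_min < 1.0:
            raise ValueError(f"power_min must lie in (0, 1), got {self.power_min}")


@dataclass(frozen=True)
class ThresholdResult:
    """An optimized significance threshold with its error profile.

    ``pst_opt`` is the type-I error at ``t_opt`` — the two scales are the
    same quantity.  ``degenerate`` flags boundary optima (``C*pr == 0``
    pushes the optimum to t -> infinity; ``pr == 1`` to t = 0) where the
    reported numbers are limits, not interior minima.  For constrained
    results, ``feasible`` records whether the constraints can be met.
    """

    t_opt: float
    pst_opt: float
    alpha: float
    beta: float
    power: float
    cost: float
    design: StudyDesign
    constrained: bool = False
    feasible: bool = True
    degenerate: bool = False

    @property
    def neg_log10_pst(self) -> float:
        return -math.log10(self.pst_opt) if self.pst_opt > 0 else math.inf

    def summary(self) -> str:
        lines = [
            f"n1={self.design.n1}  n2={self.design.n2}  nu={self.design.nu}  "
            f"d={self.design.d}  pr={self.design.pr}  C={self.design.C}",
            f"t_opt      {self.t_opt:.4f}",
            f"threshold  {self.pst_opt:.6g}",
            f"alpha      {self.alpha:.6g}",
            f"power      {self.power:.4f}",
            f"cost       {self.cost:.6g}",
        ]
        if self.constrained:
            lines.append(f"feasible   {self.feasible}")
        if self.degenerate:
            lines.append("degenerate boundary optimum")
        return "\n".join(lines)


def _search_upper(delta: float) -> float:
    # the optimum sits below delta once delta is large; keep headroom
    return max(T_UPPER_MIN, delta + 8.0)


def optimize_threshold(design: StudyDesign, *, xatol: float = 1e-8) -> ThresholdResult:
    """Minimize the weighted error cost over the two-tailed cut-off.

    A vectorized grid pre-scan brackets the minimum, which a bounded scalar
    minimization then refines to ``xatol`` on t.  Degenerate weightings are
    reported as flagged boundary results instead of spurious interior
    minima: with ``C*pr == 0`` and ``pr < 1`` the cost is proportional to
    alpha alone and decreases without bound in t (threshold -> 0); with
    ``pr == 1`` the cost is proportional to beta alone and is minimized at
    t = 0 (threshold 1).
    """
    delta = effect_to_delta(design)

    if design.C * design.pr == 0.0 and design.pr < 1.0:
        return ThresholdResult(
            t_opt=math.inf, pst_opt=0.0, alpha=0.0, beta=1.0, power=0.0,
            cost=0.0, design=design, degenerate=True,
        )
    if design.pr == 1.0:
        rates = ErrorRates.at(0.0, design, delta)
        return ThresholdResult(
            t_opt=0.0, pst_opt=rates.alpha, alpha=rates.alpha, beta=rates.beta,
            power=rates.power, cost=rates.cost, design=design, degenerate=True,
        )

    upper = _search_upper(delta)
    grid = np.linspace(0.0, upper, GRID_POINTS)
    costs = cost(grid, design, delta)
    i = int(np.argmin(costs))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, GRID_POINTS - 1)]
    res = minimize_scalar(
        lambda t: cost(t, design, delta),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": xatol},
    )
    t_opt = float(res.x)
    rates = ErrorRates.at(t_opt, design, delta)
    return ThresholdResult(
        t_opt=t_opt, pst_opt=rates.alpha, alpha=rates.alpha, beta=rates.beta,
        power=rates.power, cost=rates.cost, design=design,
    )


def feasible_interval(
    design: StudyDesign, spec: ConstraintSpec = ConstraintSpec()
) -> tuple[float, float]:
    """Cut-off interval [t_lo, t_hi] satisfying both constraints.

    ``t_lo`` enforces alpha <= alpha_max; ``t_hi`` is the largest cut-off
    with beta <= 1 - power_min (beta is non-decreasing in t).  The interval
    is empty (t_lo > t_hi) for under-powered designs.
    """
    delta = effect_to_delta(design)
    nu = design.nu
    t_lo = float(pst_to_t(spec.alpha_max, nu))
    beta_max = 1.0 - spec.power_min
    upper = _search_upper(delta)
    if type2_error(0.0, nu, delta) > beta_max:
        return t_lo, -math.inf
    if type2_error(upper, nu, delta) <= beta_max:
        return t_lo, upper
    t_hi = brentq(lambda t: type2_error(t, nu, delta) - beta_max, 0.0, upper, xtol=1e-10)
    return t_lo, float(t_hi)


def constrain_threshold(
    result: ThresholdResult,
    spec: ConstraintSpec = ConstraintSpec(),
    *,
    rule: str = "filter",
) -> ThresholdResult:
    """Impose the alpha/power constraints on an optimized threshold.

    With ``rule="filter"`` the result is marked infeasible when its
    unconstrained optimum violates a constraint; the optimum itself is
    never moved.  With ``rule="clamp"`` the optimum is projected onto the
    feasible interval and infeasibility means the interval is empty.
    """
    if rule not in ("filter", "clamp"):
        raise ValueError(f"unknown constraint rule {rule!r}")
    if result.degenerate:
        return replace(result, constrained=True, feasible=False)

    if rule == "filter":
        ok = result.alpha <= spec.alpha_max and result.power >= spec.power_min
        return replace(result, constrained=True, feasible=ok)

    t_lo, t_hi = feasible_interval(result.design, spec)
    if t_lo > t_hi:
        return replace(result, constrained=True, feasible=False)
    t_c = min(max(result.t_opt, t_lo), t_hi)
    rates = ErrorRates.at(t_c, result.design)
    return ThresholdResult(
        t_opt=t_c, pst_opt=rates.alpha, alpha=rates.alpha, beta=rates.beta,
        power=rates.power, cost=rates.cost, design=result.design,
        constrained=True, feasible=True,
    )


def optimize_constrained(
    design: StudyDesign, spec: ConstraintSpec = ConstraintSpec(), *, rule: str = "filter"
) -> ThresholdResult:
    """Convenience composition: optimize, then impose the constraints."""
    return constrain_threshold(optimize_threshold(design), spec, rule=rule)


def threshold_table(
    n1_list: Sequence[int],
    n2_list: Sequence[int],
    d: float = 0.5,
    pr: float = 0.5,
    C: float = 0.25,
    spec: ConstraintSpec = ConstraintSpec(),
    *,
    rule: str = "filter",
) -> pd.DataFrame:
    """Grid of ``-log10`` constrained thresholds over arm-size combinations.

    Returns a DataFrame indexed by n1 with n2 columns; infeasible designs
    are NaN (serialized as the "NA" sentinel, never a number).
    """
    table = np.full((len(n1_list), len(n2_list)), np.nan)
    cache: dict[tuple[int, int], float] = {}
    for i, n1 in enumerate(n1_list):
        for j, n2 in enumerate(n2_list):
            key = (min(n1, n2), max(n1, n2))  # symmetric under equal variances
            if key not in cache:
                res = optimize_constrained(
                    StudyDesign(n1=key[0], n2=key[1], d=d, pr=pr, C=C), spec, rule=rule
                )
                cache[key] = res.neg_log10_pst if res.feasible else np.nan
            table[i, j] = cache[key]
    return pd.DataFrame(table, index=pd.Index(n1_list, name="n1"),
                        columns=pd.Index(n2_list, name="n2"))


def threshold_sweep(
    d_values: Sequence[float],
    odds_values: Sequence[float],
    n_range: Sequence[int],
    spec: ConstraintSpec = ConstraintSpec(),
    C: float = 0.25,
    *,
    rule: str = "filter",
) -> pd.DataFrame:
    """Constrained-threshold curves versus per-arm sample size.

    One curve per (effect size, prior odds) pair, equal arms and equal
    variances; prior odds are converted to a probability as
    ``pr = odds / (1 + odds)``.  Infeasible points are omitted.  Returns a
    tidy DataFrame with columns d, prior_odds, n, threshold, neg_log10,
    alpha, power.
    """
    rows = []
    for d in d_values:
        for odds in odds_values:
            pr = odds / (1.0 + odds)
            for n in n_range:
                res = optimize_constrained(
                    StudyDesign(n1=n, n2=n, d=d, pr=pr, C=C), spec, rule=rule
                )
                if not res.feasible:
                    continue
                rows.append(
                    {"d": d, "prior_odds": odds, "n": n, "threshold": res.pst_opt,
                     "neg_log10": res.neg_log10_pst, "alpha": res.alpha, "power": res.power}
                )
    return pd.DataFrame(rows, columns=["d", "prior_odds", "n", "threshold",
                                       "neg_log10", "alpha", "power"])
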