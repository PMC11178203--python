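"""Error probabilities and the weighted-error cost for the two-tailed two-sample t test.

For a two-arm trial analysed with a two-tailed Student's t test, a cut-off
``t`` on the test statistic fixes both error probabilities:

* type-I error  ``alpha(t) = 2 F(-t, nu)``  (two symmetric tails of the
  central t distribution with ``nu = n1 + n2 - 2`` degrees of freedom), and
* type-II error ``beta(t) = F(t - delta, nu) - F(-t - delta, nu)``, the mass
  of the alternative distribution — the central t shifted by ``delta``, the
  minimum acceptable effect size re-expressed on the t-statistic scale —
  falling inside the acceptance region.

The weighted error cost combines the two with the prior probability ``pr``
that a true effect exists and the relative seriousness ``C`` of a type-II
versus a type-I error::

    cost(t) = C * pr * beta(t) + (1 - pr) * alpha(t)

``delta`` comes from the standardized minimum acceptable effect ``d``
(Cohen's d, in units of the arm-1 standard deviation) divided by the
standard error of the difference of the group means.  With equal group
variances this reduces to ``delta = d / sqrt(1/n1 + 1/n2)``.

All probability functions are vectorized over the cut-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import stdtr, stdtrit

__all__ = [
    "StudyDesign",
    "ErrorRates",
    "InvalidDesignError",
    "pooled_sd",
    "se_diff",
    "effect_to_delta",
    "type1_error",
    "type2_error",
    "cost",
    "t_to_pst",
    "pst_to_t",
]


class InvalidDesignError(ValueError):
    """Raised when study-design parameters are outside their valid domain."""


@dataclass(frozen=True)
class StudyDesign:
    """Design parameters of a two-arm trial analysed with a two-tailed t test.

    Parameters
    ----------
    n1, n2 : int
        Participants per arm.  Each must be >= 2 so that ``nu >= 2``.
    d : float
        Minimum acceptable standardized effect size (Cohen's d), in units
        of the arm-1 standard deviation.  Must be positive.
    s1, s2 : float, optional
        Standard deviations of the two arms, in outcome units.  Either both
        are given (unequal-variance route, pooled-SD rescaling) or both are
        omitted (equal variances assumed).  Only the ratio ``s2/s1``
        matters for ``delta``.
    pr : float
        Prior probability that a true effect exists, in [0, 1].
    C : float
        Seriousness of a type-II error relative to a type-I error (>= 0).
        The conventional alpha 0.05 / power 0.8 tolerances imply C = 0.25.
    """

    n1: int
    n2: int
    d: float
    s1: float | None = None
    s2: float | None = None
    pr: float = 0.5
    C: float = 0.25

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise InvalidDesignError(
                f"each arm needs at least 2 participants, got n1={self.n1}, n2={self.n2}"
            )
        if not self.d > 0:
            raise InvalidDesignError(f"minimum acceptable effect size must be > 0, got {self.d}")
        if (self.s1 is None) != (self.s2 is None):
            raise InvalidDesignError("provide both arm standard deviations or neither")
        if self.s1 is not None:
            if self.s1 <= 0 or self.s2 <= 0:
                raise InvalidDesignError("arm standard deviations must be positive")
        if not 0.0 <= self.pr <= 1.0:
            raise InvalidDesignError(f"prior probability must lie in [0, 1], got {self.pr}")
        if self.C < 0:
            raise InvalidDesignError(f"error-seriousness weight must be >= 0, got {self.C}")

    @property
    def nu(self) -> int:
        """Degrees of freedom, ``n1 + n2 - 2``."""
        return self.n1 + self.n2 - 2

    @property
    def equal_variances(self) -> bool:
        return self.s1 is None

    @property
    def delta(self) -> float:
        """Minimum acceptable effect size on the t-statistic scale."""
        return effect_to_delta(self)


@dataclass(frozen=True)
class ErrorRates:
    """Error probabilities and weighted cost at one cut-off."""

    t: float
    alpha: float
    beta: float
    power: float
    cost: float
    design: StudyDesign = field(repr=False, compare=False, default=None)

    @classmethod
    def at(cls, t: float, design: StudyDesign, delta: float | None = None) -> "ErrorRates":
        """Evaluate all error quantities for ``design`` at cut-off ``t``."""
        if delta is None:
            delta = effect_to_delta(design)
        a = float(type1_error(t, design.nu))
        b = float(type2_error(t, design.nu, delta))
        eps = design.C * design.pr * b + (1.0 - design.pr) * a
        return cls(t=float(t), alpha=a, beta=b, power=1.0 - b, cost=eps, design=design)


def pooled_sd(n1: int, s1: float, n2: int, s2: float) -> float:
    """Pooled standard deviation of two arms with dof weights.

    ``sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2))``
    """
    if n1 + n2 <= 2:
        raise InvalidDesignError("pooled SD needs n1 + n2 > 2")
    if s1 < 0 or s2 < 0:
        raise InvalidDesignError("standard deviations must be non-negative")
    return math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))


def se_diff(s: float, n1: int, n2: int) -> float:
    """Standard error of the difference of two group means, ``sqrt(s^2 (1/n1 + 1/n2))``."""
    if n1 < 1 or n2 < 1:
        raise InvalidDesignError("arm sizes must be >= 1")
    if s < 0:
        raise InvalidDesignError("standard deviation must be non-negative")
    return math.sqrt(s**2 * (1.0 / n1 + 1.0 / n2))


def effect_to_delta(design: StudyDesign) -> float:
    """Rescale the minimum acceptable effect size onto the t-statistic scale.

    With arm standard deviations, ``delta = d * s1 / se_diff(pooled_sd)``;
    the arm-1 SD is the unit in which ``d`` is expressed, so swapping arms
    with unequal SDs legitimately changes ``delta``.  Only the ratio
    ``s2/s1`` matters: the result is invariant under ``(s1, s2) -> (k s1,
    k s2)``.  Without arm SDs, equal variances are assumed and the
    expression collapses to ``delta = d / sqrt(1/n1 + 1/n2)``.
    """
    if design.equal_variances:
        return design.d / math.sqrt(1.0 / design.n1 + 1.0 / design.n2)
    s = pooled_sd(design.n1, design.s1, design.n2, design.s2)
    se = se_diff(s, design.n1, design.n2)
    if se == 0.0:
        raise InvalidDesignError("zero standard error of the mean difference: delta undefined")
    return design.d * design.s1 / se


def type1_error(t, nu):
    """Two-tailed type-I error probability ``2 F(-t, nu)`` at cut-off ``t >= 0``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("two-tailed cut-offs are non-negative")
    out = 2.0 * stdtr(nu, -t)
    return float(out) if out.ndim == 0 else out


def type2_error(t, nu, delta):
    """Type-II error probability ``F(t - delta, nu) - F(-t - delta, nu)``.

    The alternative is modelled as the central t distribution shifted by
    ``delta`` (not the noncentral t), so the acceptance-region mass is a
    difference of two shifted central CDF values.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("two-tailed cut-offs are non-negative")
    out = stdtr(nu, t - delta) - stdtr(nu, -t - delta)
    return float(out) if out.ndim == 0 else out


def cost(t, design: StudyDesign, delta: float | None = None):
    """Weighted error ``C pr beta(t) + (1 - pr) alpha(t)`` for ``design``."""
    if delta is None:
        delta = effect_to_delta(design)
    return design.C * design.pr * type2_error(t, design.nu, delta) + (
        1.0 - design.pr
    ) * type1_error(t, design.nu)


def t_to_pst(t, nu):
    """p-value significance threshold equivalent to cut-off ``t`` (alias of the two-tailed tail mass)."""
    return type1_error(t, nu)


def pst_to_t(p, nu):
    """Cut-off on the t scale equivalent to a p-value threshold ``p`` in (0, 1]."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-value thresholds must lie in (0, 1]")
    out = stdtrit(nu, 1.0 - p / 2.0)
    # stdtrit(nu, 0.5) can return a tiny negative rounding residue for p=1
    out = np.where(np.abs(out) < 1e-12, 0.0, out)
    return float(out) if out.ndim == 0 else out
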