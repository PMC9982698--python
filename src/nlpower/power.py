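"""Analytic two-proportion power under nondifferential outcome misclassification.

The chain of ideas:

1. A classifier with sensitivity *se* and specificity *sp*, applied
   nondifferentially to both arms, maps a true outcome proportion *p* to an
   expected observed proportion (the Devine forward map)

       p_obs = se * p + (1 - sp) * (1 - p),

   which is affine in *p* with slope ``se + sp - 1``.  When that slope is
   positive the map is invertible and power analysis on the observed
   proportions is meaningful; when ``se + sp <= 1`` the classifier is
   non-identifiable and the detectable difference is undefined.

2. The power of the two-sided Pearson chi-squared test of equal proportions
   is approximated by the usual normal formula.  Two variance conventions are
   provided: ``"unpooled"`` (the Wald form, variance under the alternative on
   both sides of the rejection boundary — the default, which reproduces the
   published detectable differences for this class of design) and
   ``"pooled-null"`` (pooled variance under H0, unpooled under H1).

3. The detectable risk difference at a target power is the root in the true
   intervention-arm proportion of ``power(p1_obs, p2_obs) - target``, found
   by bisection/Brent to 1e-6 in the risk difference.  ``detectable_rd_percent``
   additionally applies the reporting convention of an iterative grid search:
   the smallest risk difference on a 0.1-percentage-point grid whose power
   reaches the target.
"""

from __future__ import annotations

from dataclasses import dataclass
import math
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .design import (
    ClassifierPerformance,
    PowerResult,
    RDSolution,
    SolveStatus,
    TrialDesign,
)

__all__ = [
    "observed_proportion",
    "power_two_proportions",
    "power_result",
    "solve_detectable_rd",
    "detectable_rd_percent",
    "rd_surface",
    "RDGrid",
]

#: Absolute tolerance, in risk-difference units, of the continuous solver.
RD_TOL = 1e-6

#: Grid step of the published-style percent reporting (0.1 percentage point).
REPORT_STEP = 1e-3


def observed_proportion(true_prop: float, perf: ClassifierPerformance) -> float:
    """Expected observed proportion under misclassification (Devine map).

    ``p_obs = se * p + (1 - sp) * (1 - p)``.  Affine in ``p``; equals ``p``
    for a perfect classifier and 0.5 everywhere for the uninformative
    ``se = sp = 0.5``.
    """
    p = float(true_prop)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"true_prop must lie in [0, 1], got {p}")
    return perf.sensitivity * p + (1.0 - perf.specificity) * (1.0 - p)


def _power_normal(
    n1: int,
    n2: int,
    p1: float,
    p2: float,
    alpha: float,
    variance: str,
) -> float:
    """Normal-approximation power of the two-sided test of H0: p1 == p2.

    Both rejection tails are included; the far tail only matters for tiny
    effects, where it keeps power(delta=0) == alpha exact.
    """
    d = p2 - p1
    s1 = math.sqrt(p1 * (1.0 - p1) / n1 + p2 * (1.0 - p2) / n2)
    if variance == "unpooled":
        s0 = s1
    elif variance == "pooled-null":
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s0 = math.sqrt(pbar * (1.0 - pbar) * (1.0 / n1 + 1.0 / n2))
    else:
        raise ValueError(f"unknown variance convention {variance!r}")
    if s1 == 0.0:  # both proportions degenerate at 0 or 1
        return 1.0 if d != 0.0 else alpha
    za = norm.ppf(1.0 - alpha / 2.0)
    return float(norm.cdf((d - za * s0) / s1) + norm.cdf((-d - za * s0) / s1))


def power_two_proportions(
    design: TrialDesign, p2: float, *, variance: str = "unpooled"
) -> float:
    """Power of the two-sided level-alpha test of equal proportions.

    Evaluated at the design's control proportion ``p1`` versus ``p2``, with
    no continuity correction.  Symmetric in (p1, p2) when n1 == n2; at
    ``p2 == p1`` it returns the size of the test, approximately alpha.
    """
    if not 0.0 < p2 < 1.0:
        raise ValueError(f"p2 must lie strictly in (0, 1), got {p2}")
    return _power_normal(design.n1, design.n2, design.p1, p2, design.alpha, variance)


def power_result(
    design: TrialDesign,
    p2: float,
    perf: ClassifierPerformance,
    *,
    variance: str = "unpooled",
) -> PowerResult:
    """Misclassification-adjusted power: transform both arms, then test.

    The test is applied to the observed proportions produced by the Devine
    map, which is how an analysis of classifier-measured outcomes actually
    behaves.
    """
    o1 = observed_proportion(design.p1, perf)
    o2 = observed_proportion(p2, perf)
    power = _power_normal(design.n1, design.n2, o1, o2, design.alpha, variance)
    return PowerResult(power=power, p2=p2, observed_p1=o1, observed_p2=o2)


def solve_detectable_rd(
    design: TrialDesign,
    perf: ClassifierPerformance = ClassifierPerformance(1.0, 1.0),
    *,
    variance: str = "unpooled",
) -> RDSolution:
    """Smallest true risk difference detectable at the design's target power.

    Solves ``power(p1_obs, (p1 + rd)_obs) == target_power`` for ``rd`` by
    Brent's method on (0, 1 - p1), to absolute tolerance 1e-6; power is
    strictly increasing in ``rd`` for identifiable classifiers, so the root
    is unique.  Returns an :class:`RDSolution` whose status distinguishes a
    non-identifiable classifier (undefined) from a design whose power never
    reaches the target before ``p1 + rd`` hits 1 (unattainable).
    """
    if not perf.identifiable:
        return RDSolution(rd=math.nan, status=SolveStatus.NON_IDENTIFIABLE)

    target = design.target_power

    def gap(rd: float) -> float:
        return power_result(design, design.p1 + rd, perf, variance=variance).power - target

    hi = 1.0 - design.p1 - 1e-12
    if gap(hi) < 0.0:
        return RDSolution(rd=math.nan, status=SolveStatus.UNATTAINABLE)
    root = brentq(gap, 1e-12, hi, xtol=RD_TOL)
    return RDSolution(rd=float(root), status=SolveStatus.OK)


def detectable_rd_percent(
    design: TrialDesign,
    perf: ClassifierPerformance = ClassifierPerformance(1.0, 1.0),
    *,
    variance: str = "unpooled",
    step: float = REPORT_STEP,
) -> float:
    """Detectable risk difference in percent, by the grid-search convention.

    Iterating the true intervention-arm proportion upward on a grid of
    ``step`` (default 0.1 percentage point) and reporting the first value
    whose power reaches the target is the workflow of study-design software
    that tabulates power over candidate effect sizes.  Because power is
    monotone in the risk difference, this equals the continuous root rounded
    *up* to the grid.  Raises on non-identifiable or unattainable designs.
    """
    sol = solve_detectable_rd(design, perf, variance=variance)
    if not sol.defined:
        raise ValueError(f"detectable RD is {sol.status.value} for {perf}")
    return round(math.ceil(sol.rd / step - 1e-9) * step * 100.0, 10)


@dataclass(frozen=True)
class RDGrid:
    """Detectable-RD surface over sensitivity/specificity grids.

    ``detectable_rd[i, j]`` is the fraction for ``(se_values[i], sp_values[j])``,
    NaN where the status is not OK; ``status`` holds the matching
    :class:`SolveStatus` strings.
    """

    se_values: np.ndarray
    sp_values: np.ndarray
    detectable_rd: np.ndarray
    status: np.ndarray

    def to_frame(self):
        """Long-format table with columns se, sp, detectable_rd, status."""
        import pandas as pd

        se, sp = np.meshgrid(self.se_values, self.sp_values, indexing="ij")
        return pd.DataFrame(
            {
                "se": se.ravel(),
                "sp": sp.ravel(),
                "detectable_rd": self.detectable_rd.ravel(),
                "status": self.status.ravel(),
            }
        )


def rd_surface(
    design: TrialDesign,
    se_values: Sequence[float],
    sp_values: Sequence[float],
    *,
    variance: str = "unpooled",
) -> RDGrid:
    """Element-wise :func:`solve_detectable_rd` over a performance grid.

    Non-identifiable and unattainable cells are data (NaN + status), not
    errors, so a whole surface can be mapped in one call.
    """
    se_arr = np.asarray(list(se_values), dtype=float)
    sp_arr = np.asarray(list(sp_values), dtype=float)
    rd = np.full((se_arr.size, sp_arr.size), np.nan)
    status = np.empty((se_arr.size, sp_arr.size), dtype=object)
    for i, se in enumerate(se_arr):
        for j, sp in enumerate(sp_arr):
            sol = solve_detectable_rd(
                design, ClassifierPerformance(se, sp), variance=variance
            )
            if sol.defined:
                rd[i, j] = sol.rd
            status[i, j] = sol.status.value
    return RDGrid(se_values=se_arr, sp_values=sp_arr, detectable_rd=rd, status=status)
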