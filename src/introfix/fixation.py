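"""Fixation probabilities under decaying hybrid fitness effects.

Two complementary approximations for the probability that the introgressed
*B* allele ultimately fixes:

* **Diffusion** — Kimura's fixation probability for a semidominant allele,
  with the initial frequency rescaled by the compounded HFE factor alpha:
  ``u(x) = (1 - exp(-4*Ne*s*alpha*x)) / (1 - exp(-4*Ne*s))``. Valid for any
  sign of ``s``; for ``s = 0`` the limit is ``alpha * x``.

* **Branching process** — a time-heterogeneous Galton-Watson process with
  Poisson offspring whose mean in generation ``t`` is the heterozygote
  fitness ``w_AB,t``. The survival probability by generation ``t`` is
  ``u_t = 1 - G_t(0)`` computed by the backward extinction recursion; the
  infinite-horizon limit approximates the fixation probability of a
  beneficial allele introduced as a single copy in a large population.

The iso-probability contour analysis locates, for each heterosis strength,
the DMI strength that exactly cancels it (branching fixation probability
equal to the classical no-HFE value) and summarises the contour by an
ordinary-least-squares slope, which approaches 4/3 in the weak-effect limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    HFEParams,
    SelectionModel,
    alpha,
    fitness_at,
)

__all__ = [
    "FixationEstimate",
    "ContourResult",
    "diffusion_fixation_prob",
    "branching_survival_by_t",
    "branching_fixation_prob",
    "iso_probability_contour",
]

#: generations of explicit time-inhomogeneity; beyond this the decay terms
#: are < 1e-14 and the offspring mean is the constant classical 1 + s
HFE_HORIZON = 50


@dataclass(frozen=True)
class FixationEstimate:
    """A fixation (or survival) probability with its provenance.

    ``std_error`` is the Monte-Carlo standard error and is 0 for the two
    analytic methods. ``in_regime`` is False when the requested method is
    formally outside its domain of validity (e.g. branching with s <= 0),
    in which case ``note`` explains the caveat.
    """

    probability: float
    method: str  # "diffusion" | "branching" | "simulation"
    hfe: HFEParams
    sel: SelectionModel
    std_error: float = 0.0
    in_regime: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("probability must lie in [0, 1]")
        if self.std_error < 0.0:
            raise ValueError("std_error must be >= 0")


def diffusion_fixation_prob(hfe: HFEParams, sel: SelectionModel) -> FixationEstimate:
    """Alpha-rescaled Kimura fixation probability.

    The compounded HFE factor multiplies the effective initial frequency
    ``x = q0``; with no HFEs (alpha = 1) this is exactly the classical
    semidominant diffusion result. For ``s = 0`` the analytic limit
    ``alpha * x`` (capped at 1) is returned.
    """
    a = alpha(hfe)
    x = sel.q0
    s, ne = sel.s, sel.Ne
    if s == 0.0:
        p = min(1.0, a * x)
    else:
        num_arg = -4.0 * ne * s * a * x
        den_arg = -4.0 * ne * s
        if max(num_arg, den_arg) > 700.0:
            # strongly deleterious: both expm1 terms overflow; their ratio
            # reduces to exp(num_arg - den_arg) up to O(exp(-den_arg))
            p = math.exp(min(0.0, num_arg - den_arg))
        else:
            p = math.expm1(num_arg) / math.expm1(den_arg)
    p = min(1.0, max(0.0, p))
    return FixationEstimate(probability=p, method="diffusion", hfe=hfe, sel=sel)


def _offspring_mean(hfe: HFEParams, sel: SelectionModel, t: int) -> float:
    """Poisson offspring mean lambda_t = w_AB,t (constant 1+2hs after decay)."""
    if t > HFE_HORIZON:
        return max(0.0, 1.0 + 2.0 * sel.h * sel.s)
    return fitness_at(hfe, sel, t).w_AB


def branching_survival_by_t(hfe: HFEParams, sel: SelectionModel, t: int) -> float:
    """Survival probability u_t = 1 - G_t(0) of the branching process.

    Backward recursion on the extinction probability: seed ``g = 0`` at the
    horizon boundary, then ``g <- exp(lambda_tau * (g - 1))`` for
    ``tau = t`` down to 1. The extinction probability ``1 - u_t`` is
    non-decreasing in ``t``.
    """
    if int(t) != t or t < 1:
        raise ValueError("t must be an integer >= 1")
    g = 0.0
    for tau in range(int(t), 0, -1):
        g = math.exp(_offspring_mean(hfe, sel, tau) * (g - 1.0))
    return 1.0 - g


def _supercritical_survival(lam: float, tol: float = 1e-14) -> float:
    """Positive root of ``u = 1 - exp(-lam*u)`` for lam > 1 (Newton from u=1).

    This is the long-run survival probability of a homogeneous Poisson
    branching process; ``h(u) = u + expm1(-lam*u)`` is convex, so Newton
    started at 1 decreases monotonically to the root.
    """
    if lam <= 1.0:
        return 0.0
    u = 1.0
    for _ in range(200):
        h = u + math.expm1(-lam * u)
        hp = 1.0 - lam * math.exp(-lam * u)
        step = h / hp
        u -= step
        if abs(step) < tol:
            break
    return min(1.0, max(0.0, u))


def branching_fixation_prob(hfe: HFEParams, sel: SelectionModel) -> FixationEstimate:
    """Infinite-horizon survival probability of the branching process.

    The constant tail (offspring mean ``1 + s`` once the HFEs have decayed)
    is solved first as a fixed point; the explicitly time-inhomogeneous
    first generations are then folded in by the backward recursion. For a
    single founding copy in a large population this survival probability
    approximates the fixation probability and tends to ``2*alpha*s`` for
    weak effects.

    For ``s <= 0`` the long-run survival probability of the branching
    process is 0; the estimate is returned flagged as outside the regime
    (drift-driven fixation of non-beneficial alleles is not captured).
    """
    lam_inf = max(0.0, 1.0 + 2.0 * sel.h * sel.s)
    if sel.s <= 0.0:
        return FixationEstimate(
            probability=0.0, method="branching", hfe=hfe, sel=sel,
            in_regime=False,
            note="branching survival approximates fixation only for s > 0",
        )
    g = 1.0 - _supercritical_survival(lam_inf)
    for tau in range(HFE_HORIZON, 0, -1):
        g = math.exp(_offspring_mean(hfe, sel, tau) * (g - 1.0))
    return FixationEstimate(
        probability=min(1.0, max(0.0, 1.0 - g)),
        method="branching", hfe=hfe, sel=sel,
    )


@dataclass(frozen=True)
class ContourResult:
    """The iso-probability line in (eta1, |delta1|) space and its OLS summary.

    ``slope``/``intercept``/``r_squared`` describe the headline regression of
    eta1 on |delta1| (absolute values); ``slope_reversed`` is the slope of
    the opposite orientation, reported for completeness. ``omitted`` lists
    eta1 grid values for which no compensating |delta1| exists in [0, 1].
    """

    s: float
    points: np.ndarray = field(repr=False)  # (n, 2): columns eta1, |delta1|
    slope: float
    intercept: float
    r_squared: float
    slope_reversed: float
    omitted: tuple[float, ...] = ()

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.points, columns=["eta1", "abs_delta1"])


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def iso_probability_contour(
    s: float,
    eta_grid: np.ndarray | None = None,
    tolerance: float = 1e-10,
    Ne: int = 10_000,
) -> ContourResult:
    """Locate the contour where HFEs exactly cancel and fit its slope.

    For each heterosis strength eta1 on the grid, bisect on ``|delta1|`` in
    [0, 1] until the infinite-horizon branching fixation probability equals
    the classical no-HFE value (to ``tolerance`` on the probability scale).
    The contour points are summarised by OLS of eta1 on |delta1|; near the
    origin the contour follows eta1 = (4/3)*|delta1| and the fitted slope
    stays close to that ratio.
    """
    if s <= 0.0:
        raise ValueError("the contour analysis requires s > 0")
    if eta_grid is None:
        eta_grid = np.linspace(0.0, 1.0, 50)
    eta_grid = np.asarray(eta_grid, dtype=float)
    if eta_grid.size == 0 or eta_grid.min() < 0.0 or eta_grid.max() > 1.0:
        raise ValueError("eta_grid must be non-empty within [0, 1]")

    sel = SelectionModel(s=s, Ne=Ne)
    target = branching_fixation_prob(HFEParams(0.0, 0.0), sel).probability

    def prob(eta1: float, d: float) -> float:
        return branching_fixation_prob(HFEParams(eta1, -d), sel).probability

    points: list[tuple[float, float]] = []
    omitted: list[float] = []
    for eta1 in eta_grid:
        if eta1 == 0.0:
            points.append((0.0, 0.0))
            continue
        lo, hi = 0.0, 1.0
        if prob(eta1, hi) - target > tolerance:
            omitted.append(float(eta1))  # even delta1 = -1 cannot cancel
            continue
        # p is monotone decreasing in d; bisect until the probability gap
        # (or the bracket) is below tolerance
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            diff = prob(eta1, mid) - target
            if abs(diff) <= tolerance or (hi - lo) < 1e-15:
                break
            if diff > 0.0:
                lo = mid
            else:
                hi = mid
        points.append((float(eta1), mid))

    pts = np.array(points)
    slope, intercept, r2 = _ols_line(pts[:, 1], pts[:, 0])
    slope_rev, _, _ = _ols_line(pts[:, 0], pts[:, 1])
    return ContourResult(
        s=s, points=pts, slope=slope, intercept=intercept, r_squared=r2,
        slope_reversed=slope_rev, omitted=tuple(omitted),
    )
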