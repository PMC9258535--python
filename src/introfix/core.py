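"""Hybrid fitness effects (HFEs): decay laws, time-dependent fitnesses, and α.

A single introgressed marker allele *B* enters a recipient population fixed
for *A* as one copy in an F1 hybrid. Besides its intrinsic (semidominant)
selection coefficient ``s``, carriers experience genome-wide hybrid fitness
effects: heterosis of initial strength ``eta1`` (masking of recessive
deleterious alleles) and Dobzhansky-Muller incompatibilities of initial
strength ``delta1`` (deleterious epistasis between alleles fixed in the two
source populations). Repeated backcrossing halves the introgressed fraction
of hybrid genomes every generation, so both effects decay: heterosis halves
each generation while DMI effects decay slightly slower (the number of
possible incompatible pairs shrinks sub-geometrically).

Generations are indexed from ``t = 1`` (the F1). Genotype fitnesses at
generation ``t`` are

    w_AA = 1
    w_AB = (1 + 2*h*s) * (1 + eta_t + delta_t)
    w_BB = (1 + 2*s)   * (1 + eta_t + delta_t)

with ``h = 0.5`` (semidominance) throughout unless overridden. When the HFE
factor ``1 + eta_t + delta_t`` drops to zero or below, hybrids carrying *B*
are sterile or inviable and both fitnesses are clamped to exactly 0.

The compounded HFE factor

    alpha = prod_t max(0, 1 + eta_t + delta_t)

acts as a linear rescaling of the allele's effective initial frequency; the
product is effectively converged after ~20 generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "HFEParams",
    "SelectionModel",
    "GenotypeFitness",
    "FitnessTrajectory",
    "heterosis_at",
    "dmi_at",
    "hfe_factor_at",
    "fitness_at",
    "alpha",
    "alpha_weak_approx",
    "fitness_trajectory",
]

#: generations after which the decay terms are < 1e-14 and the product in
#: :func:`alpha` has converged far beyond float precision
DEFAULT_ALPHA_TRUNCATION = 20


@dataclass(frozen=True)
class HFEParams:
    """Initial strengths of the two hybrid fitness effects.

    Parameters
    ----------
    eta1
        Heterosis strength in the F1 generation. Canonically >= 0
        (hybrid vigor), but any finite value is accepted.
    delta1
        DMI strength in the F1 generation. Canonically <= 0
        (hybrid breakdown), but any finite value is accepted.
    """

    eta1: float = 0.0
    delta1: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.eta1) and math.isfinite(self.delta1)):
            raise ValueError("eta1 and delta1 must be finite")

    @property
    def is_classical(self) -> bool:
        """True when both HFE strengths are zero (textbook single-locus model)."""
        return self.eta1 == 0.0 and self.delta1 == 0.0


@dataclass(frozen=True)
class SelectionModel:
    """Single-locus selection parameters for the marker allele.

    Parameters
    ----------
    s
        Per-copy selection coefficient of the *B* allele. Heterozygote
        fitness is ``1 + 2*h*s``, homozygote fitness ``1 + 2*s``.
    Ne
        Effective population size (diploid individuals).
    q0
        Initial *B*-allele frequency; defaults to a single copy, ``1/(2*Ne)``.
    h
        Dominance coefficient of the marker allele; 0.5 is semidominance
        and is the only value the model's closed forms are tuned for.
    """

    s: float = 0.0
    Ne: int = 10_000
    q0: float | None = None
    h: float = 0.5

    def __post_init__(self) -> None:
        if not math.isfinite(self.s) or self.s <= -1.0:
            raise ValueError("s must be finite and > -1")
        if int(self.Ne) != self.Ne or self.Ne < 1:
            raise ValueError("Ne must be a positive integer")
        object.__setattr__(self, "Ne", int(self.Ne))
        if self.q0 is None:
            object.__setattr__(self, "q0", 1.0 / (2 * self.Ne))
        if not (0.0 < self.q0 < 1.0):
            raise ValueError("q0 must lie in (0, 1)")


@dataclass(frozen=True)
class GenotypeFitness:
    """Genotype fitnesses and HFE terms at one generation."""

    t: int
    eta_t: float
    delta_t: float
    w_AA: float
    w_AB: float
    w_BB: float


def _check_generation(t: int) -> int:
    if isinstance(t, bool) or int(t) != t or t < 1:
        raise ValueError(f"generation index must be an integer >= 1, got {t!r}")
    return int(t)


def heterosis_at(params: HFEParams, t: int) -> float:
    """Heterosis strength ``eta_t = eta1 * 2**-(t-1)``.

    Masked recessive deleterious alleles are proportional to the introgressed
    genome fraction, which halves with every backcross generation.
    """
    t = _check_generation(t)
    return params.eta1 * 2.0 ** -(t - 1)


def dmi_at(params: HFEParams, t: int) -> float:
    """DMI strength ``delta_t = delta1 * (2**t - 1) * 2**(2 - 2*t)``.

    The first component, ``2**-(t-1)``, counts interactions between
    introgressed and native alleles inherited from different parents and
    halves each generation like heterosis; the second,
    ``(1 - 2**-(t-1)) * 2**-(t-1)``, counts interactions between alleles
    inherited from the same (recombinant) parent. Their sum decays slightly
    slower than a halving: delta2/delta1 = 3/4, delta3/delta1 = 7/16, ...
    """
    t = _check_generation(t)
    half = 2.0 ** -(t - 1)
    return params.delta1 * (half + (1.0 - half) * half)


def hfe_factor_at(params: HFEParams, t: int) -> float:
    """The multiplicative HFE term ``max(0, 1 + eta_t + delta_t)``.

    Clamped at zero: a combined effect at or below -1 means sterility or
    lethality of hybrids carrying the marker allele.
    """
    return max(0.0, 1.0 + heterosis_at(params, t) + dmi_at(params, t))


def fitness_at(hfe: HFEParams, sel: SelectionModel, t: int) -> GenotypeFitness:
    """Genotype fitnesses at generation ``t``.

    ``w_AA`` is exactly 1: the introgression event is rare, so HFEs do not
    measurably touch the resident genotype. Fitnesses of *B* carriers are
    clamped at 0 when the HFE factor is non-positive.
    """
    t = _check_generation(t)
    eta_t = heterosis_at(hfe, t)
    delta_t = dmi_at(hfe, t)
    H = 1.0 + eta_t + delta_t
    if H <= 0.0:
        w_ab = w_bb = 0.0
    else:
        w_ab = max(0.0, (1.0 + 2.0 * sel.h * sel.s) * H)
        w_bb = max(0.0, (1.0 + 2.0 * sel.s) * H)
    return GenotypeFitness(t=t, eta_t=eta_t, delta_t=delta_t,
                           w_AA=1.0, w_AB=w_ab, w_BB=w_bb)


def alpha(hfe: HFEParams, truncation: int = DEFAULT_ALPHA_TRUNCATION) -> float:
    """Compounded HFE factor ``alpha = prod_{t=1..truncation} max(0, 1+eta_t+delta_t)``.

    If any factor is zero (lethal hybrids) the product is zero. The default
    truncation of 20 generations is converged to well below 1e-6.
    """
    if int(truncation) != truncation or truncation < 1:
        raise ValueError("truncation must be a positive integer")
    out = 1.0
    for t in range(1, int(truncation) + 1):
        factor = hfe_factor_at(hfe, t)
        if factor == 0.0:
            return 0.0
        out *= factor
    return out


def alpha_weak_approx(hfe: HFEParams) -> float:
    """First-order approximation ``1 + 2*eta1 + (8/3)*delta1``.

    Follows from log-linearising the product: the decay series sum to
    ``sum eta_t = 2*eta1`` and ``sum delta_t = (8/3)*delta1``. Accurate for
    small effect strengths; in particular alpha >= 1 exactly when heterosis
    is initially at least 4/3 times as strong as the DMI effects.
    """
    return 1.0 + 2.0 * hfe.eta1 + (8.0 / 3.0) * hfe.delta1


@dataclass(frozen=True)
class FitnessTrajectory:
    """Per-generation genotype fitnesses over a horizon of ``T`` generations."""

    horizon: int
    entries: tuple[GenotypeFitness, ...] = field(repr=False)

    def __iter__(self) -> Iterator[GenotypeFitness]:
        return iter(self.entries)

    def __len__(self) -> int:
        return self.horizon

    def to_frame(self) -> pd.DataFrame:
        """Tabulate as columns t, eta_t, delta_t, w_AA, w_AB, w_BB."""
        return pd.DataFrame(
            {
                "t": [e.t for e in self.entries],
                "eta_t": [e.eta_t for e in self.entries],
                "delta_t": [e.delta_t for e in self.entries],
                "w_AA": [e.w_AA for e in self.entries],
                "w_AB": [e.w_AB for e in self.entries],
                "w_BB": [e.w_BB for e in self.entries],
            }
        )


def fitness_trajectory(hfe: HFEParams, sel: SelectionModel,
                       horizon: int = 20) -> FitnessTrajectory:
    """Evaluate :func:`fitness_at` for ``t = 1..horizon``."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    entries = tuple(fitness_at(hfe, sel, t) for t in range(1, horizon + 1))
    return FitnessTrajectory(horizon=horizon, entries=entries)


def heterozygote_fitness_schedule(hfe: HFEParams, sel: SelectionModel,
                                  horizon: int) -> np.ndarray:
    """Vector of w_AB for t = 1..horizon (the branching-process offspring means)."""
    return np.array(
        [fitness_at(hfe, sel, t).w_AB for t in range(1, horizon + 1)]
    )
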