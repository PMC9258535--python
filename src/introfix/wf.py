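"""Wright-Fisher forward simulation of the introgressed allele.

A single-locus frequency process in a diploid population of constant size
``Ne`` with discrete non-overlapping generations: Hardy-Weinberg genotype
formation, deterministic viability selection with the time-varying genotype
fitnesses of :mod:`introfix.core`, then binomial resampling of ``2*Ne``
allele copies. The hybrid fitness effects decay deterministically (infinite
chromosomes/loci; every backcross halves the introgressed fraction), so all
replicates share the same fitness schedule and can be stepped as one cohort.

Frequencies 0 and 1 are absorbing; each replicate records its absorption
generation, yielding empirical fixation probabilities and sojourn-time
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GenotypeFitness, HFEParams, SelectionModel, hfe_factor_at
from .fixation import HFE_HORIZON, FixationEstimate

__all__ = [
    "SimulationConfig",
    "SimulationOutcome",
    "wf_step",
    "run_replicates",
    "estimate_fixation_prob",
    "sojourn_time_distributions",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a batch of Wright-Fisher replicates.

    ``max_generations`` caps each replicate; at the default of 100,000
    (about 10*Ne for the default Ne of 10,000) unresolved replicates are
    essentially impossible. The seed fully determines every random draw.
    """

    hfe: HFEParams
    sel: SelectionModel
    replicates: int
    seed: int
    max_generations: int = 100_000
    record_trajectories: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")


@dataclass(frozen=True)
class SimulationOutcome:
    """Absorption counts and times for a batch of replicates."""

    replicates: int
    fixed: int
    lost: int
    unresolved: int
    fixation_times: np.ndarray = field(repr=False)
    extinction_times: np.ndarray = field(repr=False)
    trajectories: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        assert self.fixed + self.lost + self.unresolved == self.replicates

    def summary(self) -> dict:
        """Mean/median/quartiles of the sojourn times per absorption class."""
        out: dict = {
            "replicates": self.replicates,
            "fixed": self.fixed,
            "lost": self.lost,
            "unresolved": self.unresolved,
        }
        for name, times in (
            ("fixation", self.fixation_times),
            ("extinction", self.extinction_times),
        ):
            if len(times):
                q25, q50, q75 = np.percentile(times, [25, 50, 75])
                out[name] = {
                    "n": int(len(times)),
                    "mean": float(np.mean(times)),
                    "median": float(q50),
                    "q25": float(q25),
                    "q75": float(q75),
                }
            else:
                out[name] = {"n": 0}
        return out


def wf_step(
    q: float | np.ndarray,
    fitness: GenotypeFitness,
    Ne: int,
    rng: np.random.Generator,
) -> float | np.ndarray:
    """One Wright-Fisher generation: selection then binomial drift.

    Post-selection frequency
    ``q* = (q^2 w_BB + q(1-q) w_AB) / (q^2 w_BB + 2 q(1-q) w_AB + (1-q)^2 w_AA)``
    followed by a Binomial(2*Ne, q*)/2*Ne draw. 0 and 1 are absorbing;
    w_AA = 1 guarantees positive mean fitness whenever q < 1.
    """
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr < 0.0) or np.any(q_arr > 1.0):
        raise ValueError("allele frequency must lie in [0, 1]")
    num = q_arr**2 * fitness.w_BB + q_arr * (1.0 - q_arr) * fitness.w_AB
    den = num + q_arr * (1.0 - q_arr) * fitness.w_AB + (1.0 - q_arr) ** 2 * fitness.w_AA
    q_star = np.divide(num, den, out=q_arr.copy(), where=den > 0.0)
    nxt = rng.binomial(2 * Ne, q_star) / (2 * Ne)
    nxt = np.where(q_arr == 0.0, 0.0, np.where(q_arr == 1.0, 1.0, nxt))
    return float(nxt) if np.isscalar(q) else nxt


def _simulate_cohort(
    hfe: HFEParams,
    s: np.ndarray,
    h: float,
    Ne: int,
    q0: float,
    max_generations: int,
    rng: np.random.Generator,
    record_trajectories: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Step all replicates together through the shared fitness schedule.

    ``s`` is per-replicate (the conditional-DFE analysis draws a different
    selection coefficient for every replicate); the HFE factor is a shared
    scalar each generation. Returns (outcome, absorption_time, trajectories)
    where outcome is +1 fixed, -1 lost, 0 unresolved and absorption_time is
    0 for unresolved replicates.
    """
    n = s.shape[0]
    two_ne = 2 * Ne
    q = np.full(n, q0)
    outcome = np.zeros(n, dtype=np.int8)
    abs_time = np.zeros(n, dtype=np.int64)
    active = np.arange(n)
    traj = [q.copy()] if record_trajectories else None

    for t in range(1, max_generations + 1):
        if active.size == 0:
            break
        H = hfe_factor_at(hfe, t) if t <= HFE_HORIZON else 1.0
        s_a = s[active]
        w_ab = np.maximum(0.0, (1.0 + 2.0 * h * s_a) * H)
        w_bb = np.maximum(0.0, (1.0 + 2.0 * s_a) * H)
        qa = q[active]
        num = qa * qa * w_bb + qa * (1.0 - qa) * w_ab
        den = num + qa * (1.0 - qa) * w_ab + (1.0 - qa) ** 2
        qa = rng.binomial(two_ne, num / den) / two_ne
        q[active] = qa

        fixed_now = active[qa == 1.0]
        lost_now = active[qa == 0.0]
        outcome[fixed_now] = 1
        outcome[lost_now] = -1
        abs_time[fixed_now] = t
        abs_time[lost_now] = t
        active = active[(qa > 0.0) & (qa < 1.0)]
        if record_trajectories:
            traj.append(q.copy())

    trajectories = np.array(traj) if record_trajectories else None
    return outcome, abs_time, trajectories


def run_replicates(config: SimulationConfig) -> SimulationOutcome:
    """Run all replicates to absorption (or ``max_generations``).

    Fitness follows the decaying HFE schedule for the first generations and
    the constant classical values afterwards. Identical config and seed
    reproduce the outcome exactly.
    """
    rng = np.random.default_rng(config.seed)
    s = np.full(config.replicates, config.sel.s)
    outcome, abs_time, traj = _simulate_cohort(
        config.hfe, s, config.sel.h, config.sel.Ne, config.sel.q0,
        config.max_generations, rng, config.record_trajectories,
    )
    return SimulationOutcome(
        replicates=config.replicates,
        fixed=int(np.sum(outcome == 1)),
        lost=int(np.sum(outcome == -1)),
        unresolved=int(np.sum(outcome == 0)),
        fixation_times=abs_time[outcome == 1],
        extinction_times=abs_time[outcome == -1],
        trajectories=traj,
    )


def estimate_fixation_prob(config: SimulationConfig) -> FixationEstimate:
    """Empirical fixation probability with its binomial standard error.

    Unresolved replicates are counted as neither fixed nor lost; the
    estimate carries a note when any are present (raise ``max_generations``
    until none remain for headline numbers).
    """
    out = run_replicates(config)
    p = out.fixed / out.replicates
    se = float(np.sqrt(p * (1.0 - p) / out.replicates))
    note = ""
    if out.unresolved:
        note = f"{out.unresolved} replicates unresolved at max_generations"
    return FixationEstimate(
        probability=p, method="simulation", hfe=config.hfe, sel=config.sel,
        std_error=se, note=note,
    )


def sojourn_time_distributions(config: SimulationConfig) -> SimulationOutcome:
    """Absorption-time samples for histogramming (alias for run_replicates).

    The returned outcome's :meth:`SimulationOutcome.summary` gives per-class
    means, medians and quartiles.
    """
    return run_replicates(config)
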