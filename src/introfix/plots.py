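"""Figure-style summaries (optional; requires matplotlib).

Side-effect-only convenience views of objects produced elsewhere in the
package — none of the plotted numbers originate here.
"""

from __future__ import annotations

import numpy as np

from .core import FitnessTrajectory
from .fixation import ContourResult
from .wf import SimulationOutcome

__all__ = ["plot_trajectory", "plot_contour", "plot_sojourn_times"]


def _get_axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_trajectory(traj: FitnessTrajectory, ax=None):
    """Heterozygote fitness and the HFE terms over time."""
    ax = _get_axes(ax)
    df = traj.to_frame()
    ax.plot(df["t"], df["w_AB"], label="$w_{AB,t}$", color="tab:blue")
    ax.plot(df["t"], df["eta_t"], label=r"$\eta_t$", color="0.4", ls="--")
    ax.plot(df["t"], df["delta_t"], label=r"$\delta_t$", color="0.6", ls=":")
    ax.axhline(1.0, color="k", lw=0.5)
    ax.set_xlabel("generations since hybridization")
    ax.set_ylabel("fitness / effect strength")
    ax.legend()
    return ax


def plot_contour(result: ContourResult, ax=None):
    """Iso-probability points and the fitted line in (|delta1|, eta1) space."""
    ax = _get_axes(ax)
    d, e = result.points[:, 1], result.points[:, 0]
    ax.plot(d, e, "o", ms=3, color="k", label="contour")
    xs = np.linspace(d.min(), d.max(), 50)
    ax.plot(xs, result.intercept + result.slope * xs, color="tab:red",
            label=f"OLS slope {result.slope:.2f} ($R^2$={result.r_squared:.3f})")
    ax.set_xlabel(r"$|\delta_1|$")
    ax.set_ylabel(r"$\eta_1$")
    ax.legend()
    return ax


def plot_sojourn_times(outcome: SimulationOutcome, ax=None, bins=50):
    """Histograms of extinction and fixation times (log-scaled counts)."""
    ax = _get_axes(ax)
    if len(outcome.extinction_times):
        ax.hist(outcome.extinction_times, bins=bins, alpha=0.6,
                label=f"lost (n={outcome.lost})", color="tab:red")
    if len(outcome.fixation_times):
        ax.hist(outcome.fixation_times, bins=bins, alpha=0.6,
                label=f"fixed (n={outcome.fixed})", color="tab:blue")
    ax.set_yscale("log")
    ax.set_xlabel("absorption generation")
    ax.set_ylabel("replicates")
    ax.legend()
    return ax
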