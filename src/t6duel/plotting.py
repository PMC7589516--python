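"""Basic diagnostic plots: pairwise invasibility maps and sweep outcomes."""

from __future__ import annotations

from .invasion import PIPResult

__all__ = ["plot_pip", "plot_sweep_outcomes"]


def plot_pip(pip: PIPResult, ax=None, band: float = 0.0):
    """Render a pairwise invasibility plot: +1 invade / -1 repelled regions.

    Resident rate on the x axis, mutant rate on y.  Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    region = pip.region(band).T  # rows become mutant axis
    ax.pcolormesh(pip.k_resident, pip.k_mutant, region,
                  cmap="RdYlBu_r", vmin=-1, vmax=1, shading="nearest")
    ax.plot(pip.k_resident, pip.k_resident, color="k", lw=0.8)
    ax.set_xlabel("resident firing rate (h$^{-1}$)")
    ax.set_ylabel("mutant firing rate (h$^{-1}$)")
    ax.set_title(f"{pip.scale} invasion, {pip.replicates} replicate(s)")
    return ax


def plot_sweep_outcomes(frame, x: str, y: str, ax=None):
    """Scatter per-seed sweep outcomes with their per-condition means."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(frame[x], frame[y], alpha=0.5, label="replicates")
    means = frame.groupby(x)[y].mean()
    ax.plot(means.index.to_numpy(), means.to_numpy(), "o-", color="k",
            label="mean")
    ax.axhline(0.5, color="grey", lw=0.8, ls="--")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return ax
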