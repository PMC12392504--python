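"""Optional rendered outputs: streamline portraits, friction cuts,
hopping histograms.  Matplotlib only; nothing here is required by the
analysis pipeline."""

from __future__ import annotations

import numpy as np

from .inference import DriftField, PhasePortrait
from .observables import FrictionCut, HoppingStats


def plot_portrait(field: DriftField, portrait: PhasePortrait, ax=None):
    """Color map of F(x, v) with streamlines, terminals, separatrices."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    X, V = np.meshgrid(field.x_edges, field.v_edges, indexing="ij")
    pc = ax.pcolormesh(X, V, np.ma.masked_invalid(field.F),
                       cmap="RdBu_r", shading="flat")
    plt.colorbar(pc, ax=ax, label=r"$F(x,v)$ [$\mu$m/min$^2$]")
    for line in portrait.streamlines:
        if len(line) > 1:
            ax.plot(line[:, 0], line[:, 1], color="k", lw=0.4, alpha=0.5)
    if len(portrait.terminal_points):
        groups = portrait.terminal_group
        cmap = ["tab:red", "tab:blue", "tab:green", "tab:orange"]
        for g in np.unique(groups):
            pts = portrait.terminal_points[groups == g]
            ax.plot(pts[:, 0], pts[:, 1], "x",
                    color=cmap[int(g) % len(cmap)], ms=8, mew=2)
    for sep in portrait.separatrices:
        ax.plot(sep[:, 0], sep[:, 1], "k-", lw=1.5)
    ax.set_xlabel(r"$x$ [$\mu$m]")
    ax.set_ylabel(r"$v$ [$\mu$m/min]")
    ax.set_title(f"label: {portrait.label}")
    return ax


def plot_friction_cut(cut: FrictionCut, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    good = cut.counts > 0
    ax.plot(cut.v[good], cut.F[good], "o-")
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel(r"$v$ [$\mu$m/min]")
    ax.set_ylabel(r"$F(x\to 0, v)$ [$\mu$m/min$^2$]")
    ax.set_title(f"small-|v| slope = {cut.slope:+.3g} min$^{{-1}}$")
    return ax


def plot_hopping_histogram(stats: HoppingStats, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    hist, edges = stats.histogram()
    if len(hist):
        ax.stairs(hist, edges, fill=True, alpha=0.6)
    ax.set_xlabel("dwell time [min]")
    ax.set_ylabel("count")
    return ax
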