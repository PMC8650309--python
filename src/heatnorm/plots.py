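"""Optional matplotlib views of the derived genetic parameters."""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_heritability", "plot_reaction_norms", "plot_env_correlation"]


def plot_heritability(h2: pd.DataFrame, ax=None, env_name: str = "ENV"):
    """Heritability trajectory along the gradient (one line, shaded h2 axis)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    x = h2["value"] if "value" in h2.columns else np.arange(len(h2))
    ax.plot(x, h2["h2"], lw=2, color="tab:blue")
    ax.set_xlabel(env_name)
    ax.set_ylabel("h$^2$")
    ax.set_ylim(0, min(1.0, float(h2["h2"].max()) * 1.4 + 0.02))
    return ax


def plot_reaction_norms(curves: pd.DataFrame, ax=None, env_name: str = "ENV"):
    """Sire reaction norms: tolerant (blue), susceptible (red), population mean (black)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    colors = {"tolerant": "tab:blue", "susceptible": "tab:red",
              "population": "black", "eligible": "tab:gray"}
    for (animal, group), grp in curves.groupby(["animal", "group"]):
        ax.plot(grp["value"], grp["gebv"], color=colors.get(group, "tab:gray"),
                lw=2.5 if group == "population" else 1.0,
                alpha=1.0 if group == "population" else 0.8)
    ax.set_xlabel(env_name)
    ax.set_ylabel("GEBV")
    return ax


def plot_env_correlation(corr: pd.DataFrame, ax=None, env_name: str = "ENV"):
    """Heatmap of additive genetic correlations across the gradient."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 3.6))
    vals = corr.to_numpy()
    grid = corr.attrs.get("values", np.arange(len(corr)))
    im = ax.imshow(vals, vmin=-1, vmax=1, cmap="RdBu_r", origin="lower",
                   extent=[grid[0], grid[-1], grid[0], grid[-1]], aspect="auto")
    ax.figure.colorbar(im, ax=ax, label="genetic correlation")
    ax.set_xlabel(env_name)
    ax.set_ylabel(env_name)
    return ax
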