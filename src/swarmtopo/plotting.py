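"""Crocker contour plots: time horizontally, scale eps on a log axis."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .tda import Crocker

#: Saturation caps used in the reference renderings: Betti values above
#: these show as white.
DEFAULT_SATURATION = {0: 150, 1: 2}


def plot_crocker(crocker: Crocker, out_path=None, saturation: int | None = None,
                 dt: float = 0.05, ax=None):
    """Filled-contour rendering of a crocker matrix.

    Values above the per-dimension saturation cap (b0 > 150, b1 > 2 by
    default) are clipped and drawn white.
    """
    if saturation is None:
        saturation = DEFAULT_SATURATION.get(crocker.k, None)
    z = crocker.betti.astype(float)
    if saturation is not None:
        z = np.where(z > saturation, np.nan, z)
    times = (np.asarray(crocker.frame_indices) + 1) * dt

    created = ax is None
    if created:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    if np.isfinite(z).any():
        top = (saturation if saturation is not None
               else z[np.isfinite(z)].max())
        levels = np.arange(-0.5, top + 1.5)
        if len(levels) < 2:
            levels = np.array([-0.5, 0.5])
        cs = ax.contourf(times, crocker.grid.values, z, levels=levels,
                         cmap="viridis", extend="neither")
        fig.colorbar(cs, ax=ax)
    # entirely saturated matrices render as a blank (white) panel
    ax.set_yscale("log")
    ax.set_xlim(times[0], times[-1])
    ax.set_ylim(crocker.grid.values[0], crocker.grid.values[-1])
    ax.set_xlabel("t")
    ax.set_ylabel(r"$\epsilon$")
    ax.set_title(f"$b_{crocker.k}$ crocker ({crocker.embedding})")
    if out_path is not None:
        fig.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax
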