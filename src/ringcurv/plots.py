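"""Decorative QC plots (not part of the quantitative pipeline)."""

from __future__ import annotations

import numpy as np

from .curvature import CurvatureProfile
from .segmentation import RingSkeleton


def plot_curvature_ring(skel: RingSkeleton, profile: CurvatureProfile,
                        out_path, dpi: int = 120) -> None:
    """Save a curvature-colour-coded rendering of the traced ring."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    pts = profile.points
    segs = np.stack([pts, np.roll(pts, -1, axis=0)], axis=1)
    lc = LineCollection(segs, cmap="inferno", linewidths=3)
    lc.set_array(profile.kappa)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.add_collection(lc)
    for path, _ in skel.branches:
        ax.plot(path[:, 0], path[:, 1], color="0.6", lw=1)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.invert_yaxis()  # image convention
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    cb = fig.colorbar(lc, ax=ax, shrink=0.8)
    cb.set_label("local curvature (µm$^{-1}$)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=dpi)
    plt.close(fig)
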