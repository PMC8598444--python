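"""Heterogeneity-map rendering: one colour per combination, grid overlay."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import BoundaryNorm, ListedColormap
from matplotlib.patches import Patch

from .core_stats import GridPartition
from .errors import InputError
from .trait_calling import NONE_LABEL, TraitCombinationMatrix

#: Above this many combinations the legend is omitted (it would be unreadable).
DEFAULT_MAX_LEGEND = 20


def render_heterogeneity_map(
    matrix: TraitCombinationMatrix,
    partition: GridPartition | None,
    out_path: str | Path,
    max_legend: int = DEFAULT_MAX_LEGEND,
    dpi: int = 150,
) -> Path:
    """Render the label map as a raster image with region-boundary grid lines.

    Empty positions are left blank; each combination gets a fixed colour from
    a categorical colormap. 3D matrices are drawn as one panel per z-slice.
    A legend mapping colours to trait subsets is drawn only when the number of
    combinations does not exceed ``max_legend``.
    """
    labels = matrix.labels
    if labels.ndim not in (2, 3):
        raise InputError("only 2D and 3D matrices can be rendered")
    n_slices = 1 if labels.ndim == 2 else labels.shape[2]

    C = matrix.C
    base = plt.get_cmap("tab20").colors if C <= 20 else [
        plt.get_cmap("hsv")(i / C) for i in range(C)
    ]
    colors = [base[i % len(base)] for i in range(C)]
    cmap = ListedColormap(colors)
    norm = BoundaryNorm(np.arange(0.5, C + 1.5), C)

    fig, axes = plt.subplots(
        1, n_slices, figsize=(4 * n_slices + 2, 4.4), squeeze=False
    )
    for k in range(n_slices):
        ax = axes[0, k]
        plane = labels if labels.ndim == 2 else labels[:, :, k]
        masked = np.ma.masked_equal(plane, NONE_LABEL)
        # transpose so axis 0 runs along the image x-axis
        ax.imshow(masked.T, cmap=cmap, norm=norm, origin="upper", interpolation="none")
        if partition is not None:
            sx, sy = partition.region_size[0], partition.region_size[1]
            for gx in range(sx, plane.shape[0], sx):
                ax.axvline(gx - 0.5, color="0.3", lw=0.6)
            for gy in range(sy, plane.shape[1], sy):
                ax.axhline(gy - 0.5, color="0.3", lw=0.6)
        ax.set_xticks([])
        ax.set_yticks([])
        if labels.ndim == 3:
            ax.set_title(f"z = {k}", fontsize=9)

    if C <= max_legend:
        handles = [
            Patch(
                facecolor=colors[lab - 1],
                label="+".join(matrix.decoding.get(lab, (f"label_{lab}",))),
            )
            for lab in range(1, C + 1)
            if lab in matrix.decoding
        ]
        fig.legend(handles=handles, loc="center right", fontsize=8, frameon=False)
        fig.subplots_adjust(right=0.8)

    out_path = Path(out_path)
    fig.savefig(out_path, dpi=dpi, metadata={"Software": None})
    plt.close(fig)
    return out_path
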