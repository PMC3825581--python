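"""Quick-look orthogonal-slice plots for StatVolumes."""

from __future__ import annotations

import numpy as np

from .grids import StatVolume


def plot_stat_slices(vol: StatVolume, cut_mm=(0.0, 0.0, 0.0), cmap="RdBu_r",
                     overlay: StatVolume | None = None, ax=None):
    """Plot the three orthogonal slices through a world coordinate.

    ``overlay`` (a MASK volume, e.g. surviving clusters or a seed) is drawn
    as a contour.  Returns the matplotlib figure.
    """
    import matplotlib.pyplot as plt

    grid = vol.grid
    ijk = np.clip(grid.mm_to_voxel(np.asarray(cut_mm, float)),
                  0, np.asarray(grid.shape) - 1)
    if ax is None:
        fig, axes = plt.subplots(1, 3, figsize=(10, 3.4))
    else:
        axes = np.atleast_1d(ax)
        fig = axes[0].figure
    data = np.where(grid.mask, vol.data, np.nan)
    vmax = np.nanmax(np.abs(data)) or 1.0
    slicers = [(0, ijk[0]), (1, ijk[1]), (2, ijk[2])]
    names = "xyz"
    for axis_obj, (axn, cut) in zip(axes, slicers):
        sl = [slice(None)] * 3
        sl[axn] = int(cut)
        img = data[tuple(sl)].T
        axis_obj.imshow(img, origin="lower", cmap=cmap, vmin=-vmax, vmax=vmax)
        if overlay is not None:
            ov = overlay.binary[tuple(sl)].T.astype(float)
            if ov.any():
                axis_obj.contour(ov, levels=[0.5], colors="k", linewidths=1)
        axis_obj.set_title(f"{names[axn]} = {cut_mm[axn]:g} mm", fontsize=9)
        axis_obj.axis("off")
    fig.suptitle(f"{vol.kind} map", fontsize=10)
    return fig
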