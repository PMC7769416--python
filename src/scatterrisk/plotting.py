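"""Plot helpers for DVHs and depth-dose curves (matplotlib)."""

from __future__ import annotations

import numpy as np

from .dosimetry import DVH
from .transport import DoseGrid


def plot_cumulative_dvh(dvhs: list[DVH], ax=None, logx: bool = False):
    """Cumulative DVHs (% volume receiving >= D) for several organs."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for dvh in dvhs:
        edges, cum = dvh.cumulative()
        ax.step(edges, cum, where="post", label=dvh.organ)
    ax.set_xlabel("Dose [Gy]")
    ax.set_ylabel("Volume [%]")
    if logx:
        ax.set_xscale("log")
    ax.legend(fontsize="small")
    return ax


def plot_depth_dose(dose: DoseGrid, axis: int = 1, ax=None):
    """Dose profile along one grid axis through the dose maximum."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    idx = np.unravel_index(np.argmax(dose.dose.values), dose.dose.shape)
    slicer = list(idx)
    slicer[axis] = slice(None)
    profile = dose.dose.values[tuple(slicer)]
    coords = dose.dose.axis_coords(axis)
    ax.plot(coords, profile)
    ax.set_xlabel(f"axis {axis} position [mm]")
    ax.set_ylabel(f"Dose [{dose.dose.units}]")
    return ax
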