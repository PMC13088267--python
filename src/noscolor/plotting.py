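"""Matplotlib helpers for slide colours and separation metrics.

Each function draws on a provided (or fresh) ``Axes`` and returns it, in
the style of the plotting accessors of scanpy/statsmodels.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_spectrum", "plot_chromaticity_trajectory",
           "plot_group_iou_violin"]


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_spectrum(spectrum, ax=None, **line_kw):
    """Reflectance vs wavelength for one simulated spectrum."""
    ax = _get_ax(ax)
    ax.plot(spectrum.wavelengths_nm, spectrum.values, **line_kw)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("reflectance")
    ax.set_ylim(0, 1)
    return ax


def plot_chromaticity_trajectory(colors, ax=None, annotate_ends=True):
    """CIE 1931 (x, y) trajectory of a parameter sweep.

    *colors* is a sequence of :class:`~noscolor.slide.SlideColor`; markers
    take each point's own rendered sRGB colour.
    """
    ax = _get_ax(ax)
    xy = np.array([c.xy for c in colors])
    rgb = np.array([c.srgb.as_array() for c in colors])
    ax.plot(xy[:, 0], xy[:, 1], color="0.6", lw=0.8, zorder=1)
    ax.scatter(xy[:, 0], xy[:, 1], c=rgb, edgecolors="k", lw=0.3, zorder=2)
    if annotate_ends and len(colors) > 1:
        ax.annotate("start", xy[0], fontsize=8)
        ax.annotate("end", xy[-1], fontsize=8)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    return ax


def plot_group_iou_violin(comparisons, labels=None, ax=None):
    """Violin plot of pairwise IoU values for several group comparisons."""
    ax = _get_ax(ax)
    data = [np.asarray(c.iou_matrix).ravel() for c in comparisons]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(data) + 1),
                  labels or [f"group {i}" for i in range(1, len(data) + 1)])
    ax.set_ylabel("KDE-IoU")
    ax.set_ylim(0, 1)
    return ax
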