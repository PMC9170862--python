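"""Overlay plots of index traces, reference tracks and state transitions."""

from __future__ import annotations

import numpy as np

from .model import IndexTrace

__all__ = ["plot_index_overlay"]


def plot_index_overlay(
    trace: IndexTrace,
    ref: np.ndarray | None = None,
    sqi: np.ndarray | None = None,
    annotations=None,
    ax=None,
):
    """Plot an index trace against its reference, with state intervals shaded.

    ``ref`` and ``sqi`` are 1 Hz tracks (element k at second k + 1);
    ``annotations`` is a list of (t_start, t_end, state).  Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    ax.plot(trace.t, trace.value, label="index", lw=1.2)
    if ref is not None:
        ax.plot(np.arange(1, len(ref) + 1), ref, label="reference", lw=1.0, alpha=0.8)
    if sqi is not None:
        ax.plot(
            np.arange(1, len(sqi) + 1), sqi, label="SQI", lw=0.8, ls=":", color="grey"
        )
    shades = {"AW": "#2ca02c", "LA": "#bcbd22", "MA": "#ff7f0e", "DA": "#d62728"}
    for (t0, t1, state) in annotations or ():
        ax.axvspan(t0, t1, color=shades.get(state, "grey"), alpha=0.12)
        ax.text((t0 + t1) / 2, 97, state, ha="center", fontsize=8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("index (0-100)")
    ax.set_ylim(0, 105)
    ax.legend(loc="lower right", fontsize=8)
    return ax
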