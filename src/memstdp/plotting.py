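"""Figure-style plots: input rasters, conductance trajectories, STDP windows."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from .protocol import SpikeSession
from .simulator import ExperimentResult


def _ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_raster(session: SpikeSession, ax=None, span_ms: Optional[tuple[float, float]] = None):
    """Spike raster; synchronized rows of the first epoch drawn thicker."""
    ax = _ax(ax)
    sync = session.sync_by_epoch[0]
    for r, onsets in enumerate(session.onsets):
        o = onsets
        if span_ms is not None:
            o = o[(o >= span_ms[0]) & (o < span_ms[1])]
        ax.vlines(o, r + 0.1, r + 0.9, lw=2.5 if r in sync else 1.0)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("input row")
    return ax


def plot_trajectory(result: ExperimentResult, sync_rows: Sequence[int] = (), ax=None):
    """Per-device conductance vs epoch, synchronized rows thicker."""
    ax = _ax(ax)
    sync = set(sync_rows)
    epochs = np.arange(result.g_trajectory.shape[0])
    for r in range(result.g_trajectory.shape[1]):
        ax.plot(epochs, result.g_trajectory[:, r], lw=2.5 if r in sync else 0.8)
    ax.set_xlabel("epoch")
    ax.set_ylabel("conductance (µS)")
    return ax


def plot_stdp_window(window: np.ndarray, ax=None):
    """ΔG/G0 (%) vs pre/post lag Δt (ms)."""
    ax = _ax(ax)
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.axvline(0.0, color="0.7", lw=0.8)
    ax.plot(window[:, 0], window[:, 1], "o-")
    ax.set_xlabel("Δt = t_post − t_pre (ms)")
    ax.set_ylabel("ΔG/G₀ (%)")
    return ax
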