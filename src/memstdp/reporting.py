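"""Group-level summaries and detection metrics over conductance trajectories."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .simulator import ExperimentResult

__all__ = [
    "GroupSummary",
    "summarize_groups",
    "detection_success",
    "relative_change",
    "first_crossing_epoch",
    "trial_success_count",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-epoch mean conductance per named group, plus overall mean and total.

    ``table`` is indexed by epoch (0 = initial state) with one column per
    group, an ``all`` column (mean over every row) and a ``total`` column
    (sum over every row, i.e. n_rows × the overall mean).
    """

    table: pd.DataFrame
    groups: dict[str, tuple[int, ...]]

    def mean(self, group: str) -> np.ndarray:
        return self.table[group].to_numpy()


def summarize_groups(result: ExperimentResult,
                     groups: Mapping[str, Sequence[int]]) -> GroupSummary:
    """Arithmetic group means and the all-device mean/total, per epoch."""
    traj = result.g_trajectory
    n_rows = traj.shape[1]
    cols: dict[str, np.ndarray] = {}
    clean: dict[str, tuple[int, ...]] = {}
    for name, rows in groups.items():
        rows = tuple(sorted({int(r) for r in rows}))  # canonical order: permutation-invariant
        if not rows:
            raise ConfigurationError(f"group {name!r} is empty")
        if not set(rows) <= set(range(n_rows)):
            raise ConfigurationError(f"group {name!r} has rows outside [0, {n_rows})")
        cols[name] = traj[:, rows].mean(axis=1)
        clean[name] = rows
    cols["all"] = traj.mean(axis=1)
    cols["total"] = traj.sum(axis=1)
    table = pd.DataFrame(cols, index=pd.RangeIndex(traj.shape[0], name="epoch"))
    return GroupSummary(table, clean)


def detection_success(summary: GroupSummary, sync_group: str = "sync",
                      noise_group: str = "noise") -> bool:
    """True iff the final-epoch sync mean strictly exceeds the noise mean."""
    return bool(summary.table[sync_group].iloc[-1] > summary.table[noise_group].iloc[-1])


def relative_change(result: ExperimentResult, at_epoch: int) -> np.ndarray:
    """Per-row ``(G(at_epoch) - G(0)) / G(0)`` relative to the initial state."""
    n_epochs = result.g_trajectory.shape[0] - 1
    if not 0 < at_epoch <= n_epochs:
        raise ConfigurationError(f"at_epoch must lie in (0, {n_epochs}], got {at_epoch}")
    g0 = result.g_trajectory[0]
    return (result.g_trajectory[at_epoch] - g0) / g0


def first_crossing_epoch(summary: GroupSummary, sync_group: str = "sync",
                         noise_group: str = "noise") -> Optional[int]:
    """First epoch at which the sync mean exceeds the noise mean, or None."""
    above = summary.table[sync_group].to_numpy() > summary.table[noise_group].to_numpy()
    idx = np.flatnonzero(above)
    return int(idx[0]) if idx.size else None


def trial_success_count(results: Sequence[ExperimentResult],
                        groups: Mapping[str, Sequence[int]],
                        sync_group: str = "sync", noise_group: str = "noise") -> int:
    """Number of trials that end with successful detection."""
    return sum(
        detection_success(summarize_groups(r, groups), sync_group, noise_group)
        for r in results)
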