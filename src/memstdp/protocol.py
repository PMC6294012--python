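"""Synthetic spike-input generator: frames, epochs, synchronized and noise rows.

The input to the crossbar is organized into *frames* of ``frame_duration``
(default 840 ms); an *epoch* is ``frames_per_epoch`` frames (default 10).  A
designated set of synchronized rows emits exactly one spike per frame at a
common reference phase (optionally jittered per row per frame), repeating every
frame.  Every other row is an uncorrelated "noise" input that emits at most one
spike per frame with probability ``p_spike``, at its own staggered reference
phase plus a uniform random offset in ``[0, offset_max]`` (plus jitter).

The per-row staggered noise phases (``noise_phase_shift + rank *
noise_phase_step`` after the synchronized reference) make the zero-offset
protocol the fully deterministic, non-overlapping raster: noise spikes then
never coincide with each other or with the synchronized event, which is the
baseline condition of the noise-sensitivity sweep.  Increasing ``offset_max``
lets noise spikes drift and overlap by chance, up to the point where all noise
inputs can coincide.

Randomness is driven by per-(epoch, frame) sub-streams derived from the session
seed, so extending ``n_epochs`` never changes earlier frames, and per-row draws
within a frame have fixed positions in the stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ProtocolError

__all__ = [
    "ProtocolConfig",
    "SpikeSession",
    "generate_frame",
    "generate_session",
    "generate_two_pattern_session",
    "expected_rate",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Parameters of the frame/epoch spike protocol.

    Times are in ms.  ``p_spike`` is the per-noise-row, per-frame spike
    probability; ``t_jitter_max`` the per-row uniform jitter bound;
    ``offset_max`` the uniform in-frame offset bound for noise spikes.
    ``reference_phase`` is the nominal in-frame onset of the synchronized
    event; noise row *rank* (position among noise rows, ascending row index)
    ``r`` has reference phase ``reference_phase + noise_phase_shift +
    r * noise_phase_step``.  With ``signed_jitter`` the jitter is uniform on
    ``[-t_jitter_max, +t_jitter_max]`` instead of one-sided.
    """

    n_rows: int = 20
    frame_duration: float = 840.0
    frames_per_epoch: int = 10
    n_epochs: int = 20
    synchronized_rows: tuple[int, ...] = (10, 11, 12, 13, 14)
    p_spike: float = 1.0
    t_jitter_max: float = 0.0
    offset_max: float = 0.0
    reference_phase: float = 0.0
    noise_phase_shift: float = 64.0
    noise_phase_step: float = 15.0
    signed_jitter: bool = False
    pre_pulse_duration: float = 38.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "synchronized_rows", tuple(sorted(self.synchronized_rows)))

    @property
    def noise_rows(self) -> tuple[int, ...]:
        sync = set(self.synchronized_rows)
        return tuple(r for r in range(self.n_rows) if r not in sync)

    def noise_phases(self, noise_rows: Optional[Sequence[int]] = None) -> dict[int, float]:
        """Map noise row index -> its in-frame reference phase."""
        rows = tuple(noise_rows) if noise_rows is not None else self.noise_rows
        base = self.reference_phase + self.noise_phase_shift
        return {r: base + rank * self.noise_phase_step for rank, r in enumerate(sorted(rows))}

    def validate(self) -> None:
        if self.n_rows < 1 or self.frames_per_epoch < 1 or self.n_epochs < 1:
            raise ConfigurationError("n_rows, frames_per_epoch and n_epochs must be >= 1")
        if not 0.0 <= self.p_spike <= 1.0:
            raise ConfigurationError(f"p_spike must lie in [0, 1], got {self.p_spike}")
        if self.t_jitter_max < 0 or self.offset_max < 0:
            raise ConfigurationError("jitter and offset bounds must be non-negative")
        if not set(self.synchronized_rows) <= set(range(self.n_rows)):
            raise ConfigurationError("synchronized_rows must lie in [0, n_rows)")
        # No cross-frame overlap: every pulse, at its largest possible offset and
        # jitter, must end inside its own frame (this also guarantees same-row
        # onset gaps of at least the pulse duration).
        if self.reference_phase + self.t_jitter_max + self.pre_pulse_duration > self.frame_duration:
            raise ConfigurationError("synchronized pulses could extend past the frame")
        phases = self.noise_phases()
        phi_max = max(phases.values()) if phases else 0.0
        if phi_max + self.offset_max + self.t_jitter_max + self.pre_pulse_duration > self.frame_duration:
            raise ConfigurationError(
                "noise pulses could extend past the frame "
                "(reduce offset_max, jitter or the noise phase span)")
        if self.seed < 0:
            raise ConfigurationError("seed must be a non-negative integer")


@dataclass(frozen=True)
class SpikeSession:
    """Per-row absolute spike onset times (ms), organized in frames and epochs."""

    onsets: tuple[np.ndarray, ...]
    epoch_boundaries: np.ndarray
    config: ProtocolConfig
    sync_by_epoch: tuple[frozenset, ...]

    @property
    def n_rows(self) -> int:
        return len(self.onsets)

    @property
    def duration(self) -> float:
        """Nominal session span (ms); pulses may spill slightly past it."""
        return float(self.epoch_boundaries[-1])

    def to_table(self) -> pd.DataFrame:
        rows = np.concatenate([np.full(len(o), r) for r, o in enumerate(self.onsets)])
        times = np.concatenate(list(self.onsets)) if self.n_rows else np.empty(0)
        df = pd.DataFrame({"row_index": rows.astype(int), "onset_ms": times})
        return df.sort_values(["onset_ms", "row_index"]).reset_index(drop=True)


def expected_rate(cfg: ProtocolConfig) -> float:
    """Long-run spikes per second per noise row: ``p_spike / frame_duration`` in Hz."""
    return cfg.p_spike / cfg.frame_duration * 1000.0


def _frame_rng(seed: int, epoch: int, frame: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, epoch, frame]))


def generate_frame(cfg: ProtocolConfig, rng: np.random.Generator,
                   sync_rows: Optional[Sequence[int]] = None) -> list[np.ndarray]:
    """In-frame onset times for one frame, one array per row (0 or 1 entries).

    Synchronized rows always emit exactly one spike at ``reference_phase`` plus
    jitter; each noise row emits with probability ``p_spike`` at its staggered
    phase plus offset plus jitter.  Draw layout is fixed (three length-n_rows
    vectors) so row streams are stable regardless of role assignment.
    """
    sync = frozenset(sync_rows if sync_rows is not None else cfg.synchronized_rows)
    if cfg.signed_jitter:
        jit = rng.uniform(-cfg.t_jitter_max, cfg.t_jitter_max, cfg.n_rows)
    else:
        jit = rng.uniform(0.0, cfg.t_jitter_max, cfg.n_rows)
    emit = rng.random(cfg.n_rows) < cfg.p_spike
    off = rng.uniform(0.0, cfg.offset_max, cfg.n_rows)
    noise = sorted(set(range(cfg.n_rows)) - sync)
    phases = cfg.noise_phases(noise)
    onsets: list[np.ndarray] = [np.empty(0)] * cfg.n_rows
    for r in sync:
        onsets[r] = np.array([cfg.reference_phase + jit[r]])
    for r in noise:
        if emit[r]:
            onsets[r] = np.array([phases[r] + off[r] + jit[r]])
    return onsets


def _build_session(cfg: ProtocolConfig, sync_by_epoch: Sequence[frozenset]) -> SpikeSession:
    cfg.validate()
    per_row: list[list[float]] = [[] for _ in range(cfg.n_rows)]
    for e in range(cfg.n_epochs):
        for f in range(cfg.frames_per_epoch):
            rng = _frame_rng(cfg.seed, e, f)
            t0 = (e * cfg.frames_per_epoch + f) * cfg.frame_duration
            for r, o in enumerate(generate_frame(cfg, rng, sync_by_epoch[e])):
                per_row[r].extend(t0 + o)
    onsets = tuple(np.asarray(o, dtype=float) for o in per_row)
    for r, o in enumerate(onsets):
        if o.size > 1 and np.any(np.diff(o) < cfg.pre_pulse_duration - 1e-9):
            raise ProtocolError(f"row {r} has overlapping pulse instances")
    boundaries = np.arange(cfg.n_epochs + 1) * cfg.frames_per_epoch * cfg.frame_duration
    return SpikeSession(onsets, boundaries, cfg, tuple(sync_by_epoch))


def generate_session(cfg: ProtocolConfig) -> SpikeSession:
    """Concatenate ``n_epochs * frames_per_epoch`` frames; deterministic given seed."""
    return _build_session(cfg, [frozenset(cfg.synchronized_rows)] * cfg.n_epochs)


def generate_two_pattern_session(cfg: ProtocolConfig,
                                 pattern1_rows: Sequence[int],
                                 pattern2_rows: Sequence[int],
                                 switch_epoch: int) -> SpikeSession:
    """Session whose synchronized set switches from pattern 1 to pattern 2.

    Epochs ``[0, switch_epoch)`` synchronize ``pattern1_rows``; the rest
    synchronize ``pattern2_rows``.  Rows of the retired pattern become ordinary
    noise rows (Bernoulli ``p_spike`` at staggered phases).  ``switch_epoch ==
    n_epochs`` degenerates to a plain single-pattern session.
    """
    if not 0 < switch_epoch <= cfg.n_epochs:
        raise ConfigurationError(f"switch_epoch must lie in (0, n_epochs], got {switch_epoch}")
    p1, p2 = frozenset(pattern1_rows), frozenset(pattern2_rows)
    for p in (p1, p2):
        if not p <= set(range(cfg.n_rows)):
            raise ConfigurationError("pattern rows must lie in [0, n_rows)")
    schedule = [p1 if e < switch_epoch else p2 for e in range(cfg.n_epochs)]
    return _build_session(cfg, schedule)
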