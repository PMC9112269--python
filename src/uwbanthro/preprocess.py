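"""Clutter removal and envelope extraction.

Static echoes (walls, furniture) dominate the raw frames; they are removed
with an exponentially weighted running background estimate

    C_n[k] = alpha * C_{n-1}[k] + (1 - alpha) * x_n[k]
    y_n[k] = x_n[k] - C_n[k]

with alpha = 0.95 by default.  The default order updates the background with
the current frame *before* subtracting, so for a step input the residual is
alpha * (x_n - C_{n-1}); the ``legacy_order`` variant subtracts first.  The
target envelope is the magnitude of the analytic signal along the range axis
of each residual frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .signal_sim import SessionRecording

DEFAULT_ALPHA = 0.95


@dataclass
class ClutterState:
    """Running background estimate for one sensor."""

    C: np.ndarray
    alpha: float = DEFAULT_ALPHA
    frame_count: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        self.C = np.asarray(self.C, dtype=float)


def update_clutter(state: ClutterState, frame: np.ndarray,
                   legacy_order: bool = False) -> tuple[ClutterState, np.ndarray]:
    """One filter step: returns the new state and the clutter-free residual.

    Default order: update C with the current frame, then subtract, so
    ``y = alpha * (x - C_prev)``.  ``legacy_order=True`` subtracts the
    previous background first, then updates.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != state.C.shape:
        raise ValueError(f"frame shape {frame.shape} != state shape {state.C.shape}")
    a = state.alpha
    if legacy_order:
        y = frame - state.C
        C_new = a * state.C + (1.0 - a) * frame
    else:
        C_new = a * state.C + (1.0 - a) * frame
        y = frame - C_new
    return ClutterState(C=C_new, alpha=a, frame_count=state.frame_count + 1), y


def subtract_background(recording: SessionRecording, alpha: float = DEFAULT_ALPHA,
                        init: str = "first_frame",
                        legacy_order: bool = False) -> SessionRecording:
    """Filter every sensor independently; output shape equals input shape.

    ``init`` seeds the background estimate: ``"first_frame"`` (default, so
    the static scene is almost fully absent from frame 0 onward) or
    ``"zero"``.
    """
    if recording.n_frames == 0:
        raise ValueError("empty recording")
    if init not in ("first_frame", "zero"):
        raise ValueError(f"unknown init policy {init!r}")

    def filter_sensor(frames: np.ndarray) -> np.ndarray:
        C0 = frames[0].copy() if init == "first_frame" else np.zeros(frames.shape[1])
        state = ClutterState(C=C0, alpha=alpha)
        out = np.empty_like(frames, dtype=float)
        for n in range(frames.shape[0]):
            state, out[n] = update_clutter(state, frames[n], legacy_order=legacy_order)
        return out

    return recording.map_frames(filter_sensor)


def envelope(residual: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal along the range (last) axis."""
    residual = np.asarray(residual, dtype=float)
    if not np.all(np.isfinite(residual)):
        raise ValueError("residual contains non-finite values")
    if residual.size == 0:
        return residual.copy()
    return np.abs(hilbert(residual, axis=-1))
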