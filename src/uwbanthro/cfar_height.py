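"""Environment-adapted CA-CFAR threshold and ceiling-sensor height estimation.

The threshold is calibrated from envelope frames recorded in the empty room:
per range bin, T[k] = mu[k] + beta * sigma[k] (mean and sample standard
deviation over the calibration stack; ``convention="literal"`` swaps the
roles, T[k] = beta*mu[k] + sigma[k]).  Height follows from the ceiling
sensor: the first threshold crossing marks the head echo, the crossing is
refined to the envelope peak of that echo, and

    height = room_height - detected_range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import envelope
from .signal_sim import SPEED_OF_LIGHT, ConfigurationError, SessionRecording
from . import metrics as _metrics

NO_DETECTION = -1


class CalibrationError(ValueError):
    """Calibration stack unusable (too few frames)."""


class EstimationError(RuntimeError):
    """Too few valid per-frame detections, or degenerate geometry."""


@dataclass
class CalibrationBuffer:
    """Stack of N_c empty-room envelope frames, one row per frame."""

    H: np.ndarray

    def __post_init__(self) -> None:
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))
        if np.any(self.H < 0):
            raise ValueError("envelope frames must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.H.shape[0]

    @classmethod
    def from_recording(cls, recording: SessionRecording, sensor: int | str = 0
                       ) -> "CalibrationBuffer":
        """Envelope stack of one sensor's (already background-subtracted) frames."""
        return cls(H=envelope(recording.sensor(sensor)))


@dataclass
class ThresholdProfile:
    """Per-bin CFAR threshold with its calibration statistics."""

    T: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    beta: float
    n_calibration: int = 0


def range_resolution(sampling_rate: float) -> float:
    """Meters per range bin: c / (2 * sampling_rate)."""
    if sampling_rate <= 0:
        raise ConfigurationError("sampling_rate must be positive")
    return SPEED_OF_LIGHT / (2.0 * sampling_rate)


def calibrate_threshold(buffer: CalibrationBuffer, beta: float = 3.0,
                        convention: str = "standard") -> ThresholdProfile:
    """Per-bin threshold from empty-room envelope statistics.

    ``standard`` (default): T[k] = mean[k] + beta * std[k] (ddof=1).
    ``literal``: T[k] = beta * mean[k] + std[k].
    """
    if buffer.n_frames < 2:
        raise CalibrationError("need at least 2 calibration frames for a std estimate")
    mu = buffer.H.mean(axis=0)
    sigma = buffer.H.std(axis=0, ddof=1)
    if convention == "standard":
        T = mu + beta * sigma
    elif convention == "literal":
        T = beta * mu + sigma
    else:
        raise ConfigurationError(f"unknown threshold convention {convention!r}")
    return ThresholdProfile(T=T, mu=mu, sigma=sigma, beta=beta,
                            n_calibration=buffer.n_frames)


def detect_first_crossing(env: np.ndarray, threshold: ThresholdProfile | np.ndarray,
                          min_run: int = 2) -> int:
    """Smallest bin index starting >= min_run consecutive bins with env > T.

    Returns ``NO_DETECTION`` (-1) when no such run exists.
    """
    T = threshold.T if isinstance(threshold, ThresholdProfile) else np.asarray(threshold)
    env = np.asarray(env, dtype=float)
    if env.shape != T.shape:
        raise ValueError("envelope and threshold lengths differ")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    above = env > T
    if min_run == 1:
        idx = np.flatnonzero(above)
        return int(idx[0]) if idx.size else NO_DETECTION
    # run of length >= min_run starting at k <=> all of above[k : k+min_run]
    windows = np.lib.stride_tricks.sliding_window_view(above, min_run)
    starts = np.flatnonzero(windows.all(axis=1))
    return int(starts[0]) if starts.size else NO_DETECTION


@dataclass
class HeightEstimate:
    """Aggregated ceiling-sensor height estimate for one acquisition."""

    height: float                       # cm
    detected_bin: float
    detected_range: float               # m
    per_frame_bins: list[int] = field(default_factory=list)
    n_frames_used: int = 0


def estimate_height(recording: SessionRecording, threshold: ThresholdProfile,
                    ceiling_sensor: int | str = 0, room_height: float = 2.5,
                    sampling_rate: float = 23.328e9, aggregator: str = "median",
                    min_run: int = 2, refine: bool = True,
                    refine_window: int = 48) -> HeightEstimate:
    """Estimate standing height from background-subtracted ceiling frames.

    Per frame: envelope -> first CFAR crossing -> (optionally) refine to the
    envelope argmax within ``refine_window`` bins after the crossing, which
    pins the echo peak independent of its amplitude.  Frames without a
    detection are dropped; more than 50% missing aborts.  The per-frame bins
    are aggregated (median or mode), converted to range and subtracted from
    the known ceiling height.
    """
    frames = recording.sensor(ceiling_sensor)
    res = range_resolution(sampling_rate)
    env_frames = envelope(frames)
    bins: list[int] = []
    n_missing = 0
    for env in env_frames:
        k = detect_first_crossing(env, threshold, min_run=min_run)
        if k == NO_DETECTION:
            n_missing += 1
            continue
        if refine:
            stop = min(k + refine_window, env.shape[0])
            k = k + int(np.argmax(env[k:stop]))
        bins.append(k)
    n_total = env_frames.shape[0]
    if n_missing > 0.5 * n_total:
        raise EstimationError(
            f"no detection in {n_missing}/{n_total} frames (>50%)")
    if aggregator == "median":
        agg_bin = float(np.median(bins))
    elif aggregator == "mode":
        vals, counts = np.unique(bins, return_counts=True)
        agg_bin = float(vals[np.argmax(counts)])
    else:
        raise ConfigurationError(f"unknown aggregator {aggregator!r}")
    detected_range = agg_bin * res
    height_cm = (room_height - detected_range) * 100.0
    if not 0.0 < height_cm < room_height * 100.0:
        raise EstimationError(
            f"estimated height {height_cm:.1f} cm outside (0, {room_height * 100:.0f})")
    return HeightEstimate(height=height_cm, detected_bin=agg_bin,
                          detected_range=detected_range, per_frame_bins=bins,
                          n_frames_used=len(bins))


def evaluate_height_cohort(estimates, references):
    """Agreement report (RMSE/MAE/ICC/r^2) for estimated vs reference heights."""
    est = np.asarray([e.height if isinstance(e, HeightEstimate) else e
                      for e in estimates], dtype=float)
    ref = np.asarray(references, dtype=float)
    return _metrics.agreement_report(est, ref, parameter="height", units="cm")
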