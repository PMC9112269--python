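"""Map 5 s residual buffers from the three sensors to CNN input images.

Each acquisition yields three (100 frames x 400 bins) residual buffers.  The
triple is rescaled jointly to 8-bit (one global min/max across all three
sensors, so relative echo strength between sensors survives), mapped through
a 256-entry colormap to RGB, and resized to (227, 227, 3).  Images stay as
lossless uint8 arrays end to end (PNG on disk); an optional JPEG path exists
for compatibility but is never used for the numeric pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .signal_sim import SessionRecording, SubjectProfile, ConfigurationError

BUFFER_SHAPE = (100, 400)
IMAGE_SHAPE = (227, 227, 3)


def _jet_table() -> np.ndarray:
    import matplotlib
    cmap = matplotlib.colormaps["jet"]
    table = (cmap(np.arange(256) / 255.0)[:, :3] * 255.0)
    return np.floor(table + 0.5).astype(np.uint8)


def _gray_table() -> np.ndarray:
    ramp = np.arange(256, dtype=np.uint8)
    return np.stack([ramp, ramp, ramp], axis=1)


_COLORMAPS: dict[str, np.ndarray] | None = None


def colormap_table(name: str) -> np.ndarray:
    """256 x 3 uint8 lookup table for a named colormap."""
    global _COLORMAPS
    if _COLORMAPS is None:
        _COLORMAPS = {"jet": _jet_table(), "gray": _gray_table()}
    try:
        return _COLORMAPS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown colormap {name!r}; available: {sorted(_COLORMAPS)}") from None


@dataclass
class RadarBuffer:
    """One sensor's (100, 400) residual-amplitude matrix."""

    data: np.ndarray
    sensor_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("buffer contains non-finite values")


@dataclass
class FusionImageSet:
    """Three (227, 227, 3) uint8 images for one acquisition, plus its label."""

    images: list[np.ndarray]
    label: SubjectProfile | None = None
    acquisition_id: str = ""

    def __post_init__(self) -> None:
        if len(self.images) != 3:
            raise ValueError(f"expected 3 images, got {len(self.images)}")
        for img in self.images:
            if img.shape != IMAGE_SHAPE:
                raise ValueError(f"image shape {img.shape} != {IMAGE_SHAPE}")
            if img.min() < 0 or img.max() > 255:
                raise ValueError("channel values outside [0, 255]")


def build_buffer(recording: SessionRecording, sensor: int | str,
                 window_s: float = 5.0) -> RadarBuffer:
    """First `fps*window_s` frames x first 400 bins of one sensor's residuals."""
    n_frames = int(round(recording.fps * window_s))
    frames = recording.sensor(sensor)
    if frames.shape[0] < n_frames:
        raise ValueError(
            f"recording has {frames.shape[0]} frames, need {n_frames} for a "
            f"{window_s} s window at {recording.fps} fps")
    if frames.shape[1] < BUFFER_SHAPE[1]:
        raise ValueError(f"recording has {frames.shape[1]} bins, need >= {BUFFER_SHAPE[1]}")
    sid = sensor if isinstance(sensor, str) else recording.sensor_ids[sensor]
    return RadarBuffer(data=frames[:n_frames, :BUFFER_SHAPE[1]].copy(), sensor_id=sid)


def stack_and_rescale(buffers: list[RadarBuffer], per_sensor: bool = False
                      ) -> list[np.ndarray]:
    """Linear map of the stacked triple onto [0, 255] integers.

    Default: one global min/max over all three buffers (min -> 0, max -> 255,
    round half up).  A constant stack maps to all zeros.  ``per_sensor=True``
    normalizes each buffer by its own extrema instead.
    """
    mats = [np.asarray(b.data if isinstance(b, RadarBuffer) else b, dtype=float)
            for b in buffers]
    shapes = {m.shape for m in mats}
    if len(shapes) > 1:
        raise ValueError(f"buffers disagree on shape: {shapes}")
    for m in mats:
        if not np.all(np.isfinite(m)):
            raise ValueError("buffer contains non-finite values")

    def rescale(ms: list[np.ndarray], lo: float, hi: float) -> list[np.ndarray]:
        if hi == lo:
            return [np.zeros(m.shape, dtype=np.uint8) for m in ms]
        return [np.floor((m - lo) / (hi - lo) * 255.0 + 0.5).astype(np.uint8)
                for m in ms]

    if per_sensor:
        return [rescale([m], m.min(), m.max())[0] for m in mats]
    stack = np.stack(mats)
    return rescale(mats, float(stack.min()), float(stack.max()))


def colorize(matrix8: np.ndarray, colormap: str = "jet") -> np.ndarray:
    """Per-pixel lookup of an 8-bit matrix in a 256-entry RGB table."""
    matrix8 = np.asarray(matrix8)
    if matrix8.min() < 0 or matrix8.max() > 255:
        raise ValueError("values outside [0, 255]")
    table = colormap_table(colormap)
    return table[matrix8.astype(np.intp)]


def resize_to_input(image: np.ndarray, size: tuple[int, int] = (227, 227)) -> np.ndarray:
    """Bilinear resize of an RGB image to (227, 227, 3) uint8."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got {image.shape}")
    pil = Image.fromarray(image.astype(np.uint8), mode="RGB")
    out = pil.resize((size[1], size[0]), resample=Image.BILINEAR)
    return np.asarray(out)


def images_for_recording(recording: SessionRecording, colormap: str = "jet",
                         window_s: float = 5.0, per_sensor: bool = False,
                         acquisition_id: str = "") -> FusionImageSet:
    """Full imaging path for one (background-subtracted) acquisition."""
    buffers = [build_buffer(recording, i, window_s=window_s)
               for i in range(recording.n_sensors)]
    mats8 = stack_and_rescale(buffers, per_sensor=per_sensor)
    images = [resize_to_input(colorize(m, colormap)) for m in mats8]
    return FusionImageSet(images=images, label=recording.subject,
                          acquisition_id=acquisition_id)
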