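"""Synthetic IR-UWB radar scenes: pulse model, room geometry, cohort sampling.

The received frame of sensor *i* at slow-time index *n* is modelled as a
superposition of delayed, scaled copies of the transmitted pulse plus static
clutter and additive white Gaussian noise::

    x_{i,n}[k] = sum_m A_{m,i,n} * S[k - tau_{m,i,n}] + clutter_i[k] + N[k]

where *k* indexes range bins (fast time).  Body paths get their delays from
the room geometry (the ceiling sensor sees the head at nadir, the wall
sensors see the torso) and their amplitudes from a radar-cross-section proxy
that grows with body surface area.  Respiration modulates the torso-path
delay sinusoidally; the head inherits a damped copy of that micromotion, so
a standing subject is never perfectly static.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

SPEED_OF_LIGHT = 299792458.0  # m/s

DEFAULT_CENTER_FREQUENCY = 8.748e9  # Hz
DEFAULT_BANDWIDTH = 1.5e9  # Hz
DEFAULT_SAMPLING_RATE = 23.328e9  # samples/s
DEFAULT_FPS = 20.0
DEFAULT_N_BINS = 400


class GeometryError(ValueError):
    """Subject/sensor placement incompatible with the room."""


class ConfigurationError(ValueError):
    """Invalid distribution or model parameters."""


def _gaussian_cosine(center_frequency: float, bandwidth: float,
                     sampling_rate: float) -> tuple[Callable[[np.ndarray], np.ndarray], float]:
    """Gaussian-modulated cosine template centered on its envelope peak.

    Returns ``(s, support)`` where ``s(u)`` evaluates the waveform at sample
    offset ``u`` from the nominal path delay and ``support`` is the total
    nonzero length in samples (the template is truncated at +-4 sigma).
    Centering the envelope peak at u = 0 means a path of delay tau puts its
    echo peak exactly at bin tau, so detected peak bins map directly to
    range.  Sigma is set so the -3 dB power bandwidth matches ``bandwidth``.
    """
    sigma_t = np.sqrt(2.0 * np.log(2.0)) / (np.pi * bandwidth)  # seconds
    sigma = sigma_t * sampling_rate  # samples
    half = 4.0 * sigma
    omega = 2.0 * np.pi * center_frequency / sampling_rate  # rad/sample

    def s(u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        out = np.exp(-(u ** 2) / (2.0 * sigma ** 2)) * np.cos(omega * u)
        return np.where(np.abs(u) <= half, out, 0.0)

    return s, 2.0 * half


@dataclass(frozen=True)
class PulseModel:
    """Transmitted impulse waveform S[k] and acquisition constants."""

    center_frequency: float = DEFAULT_CENTER_FREQUENCY
    bandwidth: float = DEFAULT_BANDWIDTH
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    template: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.bandwidth <= 0:
            raise ConfigurationError("bandwidth must be positive")

    @property
    def waveform(self) -> Callable[[np.ndarray], np.ndarray]:
        if self.template is not None:
            return self.template
        return _gaussian_cosine(self.center_frequency, self.bandwidth, self.sampling_rate)[0]

    @property
    def support(self) -> float:
        """Template length in samples (zero outside [0, support])."""
        if self.template is not None:
            return float(self.__dict__.get("_support", 64.0))
        return _gaussian_cosine(self.center_frequency, self.bandwidth, self.sampling_rate)[1]

    @property
    def half_support(self) -> float:
        """Samples from the envelope peak to the truncation point."""
        return self.support / 2.0

    def sampled(self, n: int | None = None) -> np.ndarray:
        """Discretized template over its support (for inspection/plots)."""
        if n is None:
            n = int(np.ceil(self.support)) + 1
        return self.waveform(np.arange(n, dtype=float) - (n - 1) / 2.0)

    def range_resolution(self) -> float:
        return SPEED_OF_LIGHT / (2.0 * self.sampling_rate)


@dataclass(frozen=True)
class RoomGeometry:
    """Rectangular room with three sensors: ceiling center + two opposing walls."""

    width: float = 3.0
    depth: float = 3.0
    height: float = 2.5
    sensor_positions: tuple[tuple[float, float, float], ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sensor_positions is None:
            object.__setattr__(self, "sensor_positions", (
                (self.width / 2.0, self.depth / 2.0, self.height),   # ceiling center
                (self.width / 2.0, 0.0, 1.0),                        # wall A
                (self.width / 2.0, self.depth, 1.0),                 # wall B (opposing)
            ))
        for (x, y, z) in self.sensor_positions:
            if not (0 <= x <= self.width and 0 <= y <= self.depth and 0 <= z <= self.height):
                raise GeometryError(f"sensor at {(x, y, z)} lies outside the room")

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_positions)

    @property
    def center(self) -> tuple[float, float]:
        return (self.width / 2.0, self.depth / 2.0)


@dataclass(frozen=True)
class SubjectProfile:
    """The seven anthropometric regression targets."""

    height: float          # cm
    weight: float          # kg
    bmi: float             # kg/m^2
    muscle_pct: float
    skeletal_muscle_pct: float
    body_water_pct: float
    body_fat_pct: float

    PARAMETERS = ("height", "weight", "bmi", "muscle_pct",
                  "skeletal_muscle_pct", "body_water_pct", "body_fat_pct")

    def __post_init__(self) -> None:
        if not 100.0 < self.height < 220.0:
            raise ValueError(f"height {self.height} cm outside (100, 220)")
        if not 20.0 < self.weight < 200.0:
            raise ValueError(f"weight {self.weight} kg outside (20, 200)")
        expected_bmi = self.weight / (self.height / 100.0) ** 2
        if abs(self.bmi - expected_bmi) > 1e-6 * max(1.0, abs(expected_bmi)):
            raise ValueError("bmi inconsistent with weight/(height/100)^2")
        for name in ("muscle_pct", "skeletal_muscle_pct", "body_water_pct", "body_fat_pct"):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise ValueError(f"{name}={v} outside (0, 100)")
        if self.body_water_pct + self.body_fat_pct > 100.0:
            raise ValueError("body water + body fat percentages exceed 100")

    @classmethod
    def from_height_weight(cls, height: float, weight: float, **pct: float) -> "SubjectProfile":
        bmi = weight / (height / 100.0) ** 2
        defaults = dict(muscle_pct=39.2, skeletal_muscle_pct=22.7,
                        body_water_pct=30.6, body_fat_pct=17.9)
        defaults.update(pct)
        return cls(height=height, weight=weight, bmi=bmi, **defaults)

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in self.PARAMETERS}

    def body_surface_area(self) -> float:
        """Mosteller body surface area, m^2: sqrt(height_cm * weight_kg / 3600)."""
        return float(np.sqrt(self.height * self.weight / 3600.0))


@dataclass(frozen=True)
class Breathing:
    """Sinusoidal respiratory micromotion of the torso surface."""

    rate: float = 0.25       # Hz
    amplitude: float = 5.0   # mm, peak displacement
    phase: float = 0.0       # rad

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude <= 20.0:
            raise ValueError("breathing amplitude must lie in [0, 20] mm")
        if self.rate < 0:
            raise ValueError("breathing rate must be nonnegative")


@dataclass(frozen=True)
class Path:
    """One propagation path: amplitude, delay (fractional bins) and motion."""

    amplitude: float
    delay: float                    # range-bin index, fractional allowed
    breathing_gain: float = 0.0     # fraction of breathing displacement seen by this path


@dataclass
class ScatterScene:
    """Per-sensor path lists plus clutter and noise for one acquisition."""

    paths: list[list[Path]]                       # one list per sensor
    clutter_profiles: list[np.ndarray] | None = None
    noise_sd: float = 0.01
    breathing: Breathing = field(default_factory=Breathing)
    n_bins: int = DEFAULT_N_BINS

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for sensor_paths in self.paths:
            for p in sensor_paths:
                if not 0.0 <= p.delay < self.n_bins:
                    raise ValueError(f"path delay {p.delay} outside [0, {self.n_bins})")

    @property
    def n_sensors(self) -> int:
        return len(self.paths)

    def without_target(self) -> "ScatterScene":
        """Empty-room version of this scene: clutter and noise only."""
        return ScatterScene(paths=[[] for _ in self.paths],
                            clutter_profiles=self.clutter_profiles,
                            noise_sd=self.noise_sd,
                            breathing=self.breathing,
                            n_bins=self.n_bins)


@dataclass
class SessionRecording:
    """Per-sensor (n_frames, n_bins) amplitude matrices plus metadata."""

    frames: list[np.ndarray]
    fps: float = DEFAULT_FPS
    sensor_ids: tuple[str, ...] = ("ceiling", "wall_a", "wall_b")
    subject: SubjectProfile | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"sensors disagree on frame shape: {shapes}")
        for f in self.frames:
            if not np.all(np.isfinite(f)):
                raise ValueError("recording contains non-finite values")
        if len(self.sensor_ids) != len(self.frames):
            self.sensor_ids = tuple(f"sensor{i}" for i in range(len(self.frames)))

    @property
    def n_sensors(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return self.frames[0].shape[0]

    @property
    def n_bins(self) -> int:
        return self.frames[0].shape[1]

    def sensor(self, ident: int | str) -> np.ndarray:
        if isinstance(ident, str):
            ident = self.sensor_ids.index(ident)
        return self.frames[ident]

    def map_frames(self, fn: Callable[[np.ndarray], np.ndarray]) -> "SessionRecording":
        return SessionRecording(frames=[fn(f) for f in self.frames], fps=self.fps,
                                sensor_ids=self.sensor_ids, subject=self.subject,
                                seed=self.seed)


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

#: Median and IQR-derived spread (IQR/1.349) of the emulated cohort, per
#: parameter.  Height/BMI are sampled; weight is derived, never sampled.
DEFAULT_POPULATION = {
    "height": (164.00, 8.80),            # cm
    "bmi": (22.80, 4.03),                # kg/m^2
    "muscle_pct": (39.20, 8.0),
    "skeletal_muscle_pct": (22.70, 5.0),
    "body_water_pct": (30.60, 6.0),
    "body_fat_pct": (17.90, 5.37),
}

_PCT_BOUNDS = {
    "muscle_pct": (15.0, 70.0),
    "skeletal_muscle_pct": (8.0, 45.0),
    "body_water_pct": (10.0, 60.0),
    "body_fat_pct": (4.0, 45.0),
}


def sample_population(n_subjects: int, seed: int,
                      population: dict | None = None) -> list[SubjectProfile]:
    """Draw a reproducible synthetic cohort.

    Height and BMI are sampled (truncated normal around the population
    medians); weight is recomputed as bmi*(height_m)^2 so the BMI identity
    holds exactly and height and weight are positively correlated.  Body-fat
    percentage co-varies with BMI and muscle percentage against it, so body
    composition leaves a physically plausible imprint on the echo model.
    """
    if n_subjects < 0:
        raise ConfigurationError("n_subjects must be nonnegative")
    pop = dict(DEFAULT_POPULATION)
    if population:
        pop.update(population)
    for name, (med, spread) in pop.items():
        if spread <= 0:
            raise ConfigurationError(f"non-positive spread for {name}")
    rng = np.random.default_rng(seed)
    subjects: list[SubjectProfile] = []
    while len(subjects) < n_subjects:
        h = rng.normal(*pop["height"])
        if not 140.0 < h < 200.0:
            continue
        bmi = rng.normal(*pop["bmi"])
        if not 15.0 < bmi < 45.0:
            continue
        w = bmi * (h / 100.0) ** 2
        dbmi = bmi - pop["bmi"][0]
        pct = {}
        ok = True
        for name in _PCT_BOUNDS:
            med, spread = pop[name]
            # fat tracks BMI; muscle/water run mildly against it
            slope = {"body_fat_pct": 0.9, "muscle_pct": -0.5,
                     "skeletal_muscle_pct": -0.3, "body_water_pct": -0.3}[name]
            v = med + slope * dbmi + rng.normal(0.0, 0.5 * spread)
            lo, hi = _PCT_BOUNDS[name]
            if not lo < v < hi:
                ok = False
                break
            pct[name] = v
        if not ok or pct["body_water_pct"] + pct["body_fat_pct"] > 100.0:
            continue
        subjects.append(SubjectProfile(height=h, weight=w,
                                       bmi=w / (h / 100.0) ** 2, **pct))
    return subjects


def body_scattering(subject: SubjectProfile, n_sensors: int = 3) -> np.ndarray:
    """Per-sensor echo amplitude scale, strictly increasing in body surface area.

    The radar cross section of a standing person grows with reflecting area;
    we use Mosteller BSA normalized to a 1.80 m^2 reference.  The ceiling
    sensor sees only head/shoulders and gets a reduced share.
    """
    bsa = subject.body_surface_area()
    base = bsa / 1.80
    scales = np.full(n_sensors, base)
    if n_sensors >= 1:
        # ceiling: head + shoulders; head area varies far less with body
        # size than the torso, so this view grows sub-linearly with BSA
        scales[0] = 0.6 * base ** 0.25
    return scales


# ---------------------------------------------------------------------------
# scene construction and rendering
# ---------------------------------------------------------------------------

def default_clutter(n_sensors: int, n_bins: int, seed: int,
                    amplitude: float = 4.0) -> list[np.ndarray]:
    """Smooth static per-sensor clutter, larger than the target echo."""
    rng = np.random.default_rng(seed)
    profiles = []
    for _ in range(n_sensors):
        raw = rng.normal(0.0, 1.0, n_bins)
        kernel = np.exp(-0.5 * (np.arange(-12, 13) / 4.0) ** 2)
        smooth = np.convolve(raw, kernel / kernel.sum(), mode="same")
        profiles.append(amplitude * smooth)
    return profiles


def scene_for_subject(subject: SubjectProfile, geometry: RoomGeometry,
                      pulse: PulseModel, seed: int,
                      noise_sd: float = 0.01,
                      breathing: Breathing | None = None,
                      clutter_amplitude: float = 4.0,
                      n_bins: int = DEFAULT_N_BINS) -> ScatterScene:
    """Build the multipath scene for a subject standing at the room center.

    Ceiling sensor: one head path at range ``room_height - subject_height``
    with damped respiratory micromotion.  Wall sensors: a small fan of torso
    paths whose spread grows with BMI (a wider body subtends more bins) and
    whose secondary amplitudes carry a linear body-composition imprint.
    """
    height_m = subject.height / 100.0
    if height_m >= geometry.height:
        raise GeometryError("subject taller than the room")
    res = pulse.range_resolution()
    rng = np.random.default_rng(seed)
    if breathing is None:
        breathing = Breathing(rate=0.25, amplitude=5.0,
                              phase=float(rng.uniform(0.0, 2.0 * np.pi)))
    scales = body_scattering(subject, geometry.n_sensors)
    cx, cy = geometry.center

    # linear body-composition modulation of the secondary torso reflection
    comp = (1.0
            + 0.008 * (subject.muscle_pct - 39.2)
            + 0.008 * (subject.body_water_pct - 30.6)
            - 0.006 * (subject.body_fat_pct - 17.9))
    comp = max(comp, 0.1)
    half_width_m = 0.17 * np.sqrt(subject.bmi / 22.8)  # torso half-width proxy

    paths: list[list[Path]] = []
    for i, (sx, sy, sz) in enumerate(geometry.sensor_positions):
        sensor_paths: list[Path] = []
        if i == 0:  # ceiling: head at nadir
            rng_m = geometry.height - height_m
            sensor_paths.append(Path(amplitude=scales[i], delay=rng_m / res,
                                     breathing_gain=0.25))
            # shoulder return slightly below the head
            sensor_paths.append(Path(amplitude=0.5 * scales[i],
                                     delay=(rng_m + 0.25) / res,
                                     breathing_gain=0.25))
        else:  # wall sensor: torso fan at chest height
            d0 = float(np.hypot(np.hypot(sx - cx, sy - cy), sz - 1.2))
            # fan of returns across the torso: extra path length grows
            # toward the flanks, so band width in range encodes body width
            fracs = np.linspace(0.0, 1.0, 7)
            amps = scales[i] * (1.0 - 0.55 * fracs)
            for frac, amp in zip(fracs, amps):
                sensor_paths.append(Path(amplitude=float(amp),
                                         delay=(d0 + frac * half_width_m) / res,
                                         breathing_gain=1.0))
            # secondary (deeper) reflection carrying body composition
            sensor_paths.append(Path(amplitude=float(0.35 * scales[i] * comp),
                                     delay=(d0 + 0.12) / res,
                                     breathing_gain=0.8))
        paths.append(sensor_paths)

    clutter = default_clutter(geometry.n_sensors, n_bins, seed=seed,
                              amplitude=clutter_amplitude)
    return ScatterScene(paths=paths, clutter_profiles=clutter,
                        noise_sd=noise_sd, breathing=breathing, n_bins=n_bins)


def render_scene(scene: ScatterScene, pulse: PulseModel, duration_s: float,
                 fps: float, seed: int, range_resolution: float | None = None
                 ) -> list[np.ndarray]:
    """Evaluate the superposition model frame by frame for every sensor."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n_frames = int(round(fps * duration_s))
    n_bins = scene.n_bins
    if range_resolution is None:
        range_resolution = pulse.range_resolution()
    k = np.arange(n_bins, dtype=float)
    t = np.arange(n_frames, dtype=float) / fps
    br = scene.breathing
    disp_bins = (br.amplitude / 1000.0 / range_resolution) * np.sin(
        2.0 * np.pi * br.rate * t + br.phase)
    rng = np.random.default_rng(seed)
    wave = pulse.waveform

    out: list[np.ndarray] = []
    for i, sensor_paths in enumerate(scene.paths):
        frames = np.zeros((n_frames, n_bins))
        for p in sensor_paths:
            delays = p.delay + p.breathing_gain * disp_bins  # (n_frames,)
            frames += p.amplitude * wave(k[None, :] - delays[:, None])
        if scene.clutter_profiles is not None:
            frames += scene.clutter_profiles[i][None, :]
        if scene.noise_sd > 0:
            frames += rng.normal(0.0, scene.noise_sd, frames.shape)
        out.append(frames)
    return out


def simulate_session(subject: SubjectProfile, geometry: RoomGeometry | None = None,
                     pulse: PulseModel | None = None,
                     scene: ScatterScene | None = None,
                     duration_s: float = 5.0, fps: float = DEFAULT_FPS,
                     seed: int = 0) -> SessionRecording:
    """Simulate one acquisition of a subject standing at the room center."""
    geometry = geometry or RoomGeometry()
    pulse = pulse or PulseModel()
    if scene is None:
        scene = scene_for_subject(subject, geometry, pulse, seed=seed)
    elif subject.height / 100.0 >= geometry.height:
        raise GeometryError("subject taller than the room")
    frames = render_scene(scene, pulse, duration_s, fps, seed=seed)
    return SessionRecording(frames=frames, fps=fps, subject=subject, seed=seed)


def simulate_empty_room(geometry: RoomGeometry | None = None,
                        pulse: PulseModel | None = None,
                        scene: ScatterScene | None = None,
                        duration_s: float = 300.0, fps: float = DEFAULT_FPS,
                        seed: int = 0, noise_sd: float = 0.01,
                        n_bins: int = DEFAULT_N_BINS) -> SessionRecording:
    """Simulate the target-free environment used for CFAR calibration."""
    geometry = geometry or RoomGeometry()
    pulse = pulse or PulseModel()
    if scene is None:
        clutter = default_clutter(geometry.n_sensors, n_bins, seed=seed)
        scene = ScatterScene(paths=[[] for _ in range(geometry.n_sensors)],
                             clutter_profiles=clutter, noise_sd=noise_sd,
                             n_bins=n_bins)
    else:
        scene = scene.without_target()
    frames = render_scene(scene, pulse, duration_s, fps, seed=seed)
    return SessionRecording(frames=frames, fps=fps, subject=None, seed=seed)
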