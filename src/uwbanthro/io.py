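"""Persistence and the end-to-end pipeline.

HDF5 layout for a recording: one group per sensor (``/sensor{i}/frames`` of
shape (n_frames, n_bins)), file attributes ``fps``, ``seed``, ``sensor_ids``
and, when the true subject is known, a ``subject`` JSON attribute.  Cohort
reference values go to CSV, one row per subject with the seven parameter
columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import cfar_height, fusion_cnn, imaging, metrics, preprocess, signal_sim
from .signal_sim import SessionRecording, SubjectProfile


class FormatError(ValueError):
    """Missing group or attribute in a recording file."""


def write_recording(recording: SessionRecording, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["fps"] = recording.fps
        f.attrs["sensor_ids"] = json.dumps(list(recording.sensor_ids))
        if recording.seed is not None:
            f.attrs["seed"] = recording.seed
        if recording.subject is not None:
            f.attrs["subject"] = json.dumps(recording.subject.as_dict())
        for i, frames in enumerate(recording.frames):
            f.create_group(f"sensor{i}").create_dataset("frames", data=frames)


def read_recording(path: str | Path) -> SessionRecording:
    with h5py.File(path, "r") as f:
        if "fps" not in f.attrs:
            raise FormatError("missing attribute 'fps'")
        frames = []
        i = 0
        while f"sensor{i}" in f:
            grp = f[f"sensor{i}"]
            if "frames" not in grp:
                raise FormatError(f"missing dataset 'sensor{i}/frames'")
            frames.append(grp["frames"][()])
            i += 1
        if not frames:
            raise FormatError("no sensor groups found")
        subject = None
        if "subject" in f.attrs:
            subject = SubjectProfile(**json.loads(f.attrs["subject"]))
        sensor_ids = tuple(json.loads(f.attrs["sensor_ids"])) \
            if "sensor_ids" in f.attrs else tuple(f"sensor{j}" for j in range(i))
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
        return SessionRecording(frames=frames, fps=float(f.attrs["fps"]),
                                sensor_ids=sensor_ids, subject=subject, seed=seed)


def write_cohort(subjects: list[SubjectProfile], path: str | Path) -> None:
    rows = [{"subject_id": f"S{i:03d}", **s.as_dict()}
            for i, s in enumerate(subjects)]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# fixtures and dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(n_subjects: int, n_reps: int, seed: int,
                     duration_s: float = 5.0, noise_sd: float = 0.01,
                     alpha: float = preprocess.DEFAULT_ALPHA,
                     colormap: str = "jet") -> tuple[
                         list[SubjectProfile], list[imaging.FusionImageSet],
                         list[str]]:
    """Simulate a cohort end to end: subjects -> sessions -> residuals -> images.

    Returns (subjects, image sets, subject id per image set).  Repetitions
    of one subject differ in noise, breathing phase and acquisition seed.
    """
    subjects = signal_sim.sample_population(n_subjects, seed=seed)
    geometry = signal_sim.RoomGeometry()
    pulse = signal_sim.PulseModel()
    sets: list[imaging.FusionImageSet] = []
    ids: list[str] = []
    for si, subject in enumerate(subjects):
        for rep in range(n_reps):
            acq_seed = (seed * 100003 + si * 1009 + rep * 17) % (2 ** 31)
            scene = signal_sim.scene_for_subject(subject, geometry, pulse,
                                                 seed=acq_seed, noise_sd=noise_sd)
            rec = signal_sim.simulate_session(subject, geometry, pulse, scene,
                                              duration_s=duration_s, seed=acq_seed)
            resid = preprocess.subtract_background(rec, alpha=alpha)
            sets.append(imaging.images_for_recording(
                resid, colormap=colormap, acquisition_id=f"S{si:03d}_r{rep}"))
            ids.append(f"S{si:03d}")
    return subjects, sets, ids


def make_fixtures(seed: int, out_dir: str | Path | None = None,
                  n_subjects: int = 4, n_reps: int = 2) -> dict:
    """Tiny self-contained dataset: cohort CSV, per-acquisition HDF5, calibration.

    With ``out_dir=None`` nothing touches disk and the in-memory objects are
    returned.  Generation is deterministic in the seed.
    """
    subjects = signal_sim.sample_population(n_subjects, seed=seed)
    geometry = signal_sim.RoomGeometry()
    pulse = signal_sim.PulseModel()
    recordings = []
    for si, subject in enumerate(subjects):
        for rep in range(n_reps):
            acq_seed = (seed * 100003 + si * 1009 + rep * 17) % (2 ** 31)
            rec = signal_sim.simulate_session(subject, geometry, pulse,
                                              seed=acq_seed)
            recordings.append((f"S{si:03d}_r{rep}", rec))
    empty = signal_sim.simulate_empty_room(geometry, pulse, duration_s=30.0,
                                           seed=seed + 1)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort(subjects, out_dir / "cohort.csv")
        for name, rec in recordings:
            write_recording(rec, out_dir / f"{name}.h5")
        write_recording(empty, out_dir / "empty_room.h5")
    return {"subjects": subjects, "recordings": recordings, "empty_room": empty}


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything needed to run simulate -> preprocess -> estimate -> report."""

    n_subjects: int = 8
    n_reps: int = 2
    seed: int = 0
    duration_s: float = 5.0
    noise_sd: float = 0.01
    alpha: float = preprocess.DEFAULT_ALPHA
    beta: float = 3.0
    colormap: str = "jet"
    parameters: tuple[str, ...] = ("height", "weight")
    epochs: int = 8
    depth: int = 2
    n_filters: int = 8
    fc_out: int = 64
    train_frac: float = 0.75
    split_mode: str = "subject"

    def as_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> pd.DataFrame:
    """Full chain on a synthetic cohort; writes report.csv and returns it.

    Height is estimated by CFAR signal processing on the ceiling sensor (one
    data point per subject, first repetition); every requested parameter is
    additionally regressed by the fusion CNN with a held-out validation
    split, and the report carries one agreement row per parameter.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects, sets, ids = generate_dataset(config.n_subjects, config.n_reps,
                                           seed=config.seed,
                                           duration_s=config.duration_s,
                                           noise_sd=config.noise_sd,
                                           alpha=config.alpha,
                                           colormap=config.colormap)
    write_cohort(subjects, out_dir / "cohort.csv")

    geometry = signal_sim.RoomGeometry()
    pulse = signal_sim.PulseModel()
    empty = signal_sim.simulate_empty_room(geometry, pulse, duration_s=30.0,
                                           seed=config.seed + 1,
                                           noise_sd=config.noise_sd)
    resid_empty = preprocess.subtract_background(empty, alpha=config.alpha)
    calib = cfar_height.CalibrationBuffer.from_recording(resid_empty, sensor=0)
    threshold = cfar_height.calibrate_threshold(calib, beta=config.beta)

    rows = []
    # signal-processing height: one data point per subject
    est_heights, ref_heights = [], []
    for si, subject in enumerate(subjects):
        acq_seed = (config.seed * 100003 + si * 1009) % (2 ** 31)
        rec = signal_sim.simulate_session(subject, geometry, pulse,
                                          seed=acq_seed,
                                          duration_s=config.duration_s)
        resid = preprocess.subtract_background(rec, alpha=config.alpha)
        est = cfar_height.estimate_height(resid, threshold,
                                          room_height=geometry.height,
                                          sampling_rate=pulse.sampling_rate)
        est_heights.append(est.height)
        ref_heights.append(subject.height)
    report = metrics.agreement_report(est_heights, ref_heights,
                                      parameter="height_sigproc", units="cm")
    rows.append(report.as_dict())

    # CNN regression per parameter
    spec = fusion_cnn.NetworkSpec(depth=config.depth, n_filters=config.n_filters,
                                  fc_out=config.fc_out)
    hyper = fusion_cnn.TrainHyper(epochs=config.epochs, seed=config.seed)
    for parameter in config.parameters:
        ds = fusion_cnn.LabeledDataset.from_image_sets(sets, parameter, ids)
        tr, va = fusion_cnn.split_dataset(ds, train_frac=config.train_frac,
                                          seed=config.seed, mode=config.split_mode)
        net = fusion_cnn.build_network(spec, seed=config.seed)
        model = fusion_cnn.train(net, tr, hyper)
        est = fusion_cnn.predict(model, [s for s, _ in va.items])
        rep = metrics.agreement_report(est, va.targets(), parameter=parameter)
        rows.append(rep.as_dict())

    frame = pd.DataFrame(rows)
    frame.to_csv(out_dir / "report.csv", index=False)
    return frame
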