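import numpy as np
import pytest

import uwbanthro as u


@pytest.fixture(scope="session")
def pulse():
    return u.PulseModel()


@pytest.fixture(scope="session")
def geometry():
    return u.RoomGeometry()


@pytest.fixture(scope="session")
def subject():
    return u.SubjectProfile.from_height_weight(164.0, 62.2)


@pytest.fixture(scope="session")
def recording(subject, geometry, pulse):
    return u.simulate_session(subject, geometry, pulse, seed=42)


@pytest.fixture(scope="session")
def residuals(recording):
    return u.subtract_background(recording)


@pytest.fixture(scope="session")
def threshold(geometry, pulse):
    empty = u.simulate_empty_room(geometry, pulse, duration_s=30.0, seed=43)
    resid = u.subtract_background(empty)
    buf = u.CalibrationBuffer.from_recording(resid, sensor=0)
    return u.calibrate_threshold(buf, beta=3.0)


class MiniImageSet:
    """Lightweight stand-in for FusionImageSet with arbitrary image sizes.

    Synthetic: lets CNN unit tests run on small images where the full
    (227, 227, 3) input would be needlessly slow.
    """

    def __init__(self, images, label=None, acquisition_id=""):
        self.images = images
        self.label = label
        self.acquisition_id = acquisition_id


def make_synthetic_cnn_dataset(n_items, side=24, seed=0, n_subjects=None):
    """Small random-image dataset whose target is a linear functional of the
    images, so a working conv net can fit it quickly."""
    rng = np.random.default_rng(seed)
    if n_subjects is None:
        n_subjects = n_items
    sets, ids, targets = [], [], []
    for i in range(n_items):
        imgs = [rng.integers(0, 256, (side, side, 3)).astype(np.uint8)
                for _ in range(3)]
        target = float(np.mean([im.mean() for im in imgs]))
        sets.append(MiniImageSet(imgs))
        ids.append(f"S{i % n_subjects:03d}")
        targets.append(target)
    from uwbanthro.fusion_cnn import LabeledDataset
    items = list(zip(sets, targets))
    return LabeledDataset(items=items, parameter="synthetic", subject_ids=ids)
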