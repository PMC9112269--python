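"""Three-branch late-fusion CNN regression of anthropometric parameters.

One network per parameter.  Each sensor image feeds its own branch — a stack
of ``depth`` blocks of (3x3 valid convolution -> ReLU -> 2x2 average
pooling) with unshared weights, because each sensor views the body from a
different aspect.  The flattened branch features are concatenated (the CAT
layer), scaled by 1/sqrt(d) so the fully connected layer's effective step
size is independent of its very large fan-in d, passed through one fully
connected layer of width ``fc_out`` and a single-unit linear regression
head.  The ReLU nonlinearity lives in the convolution blocks; the fully
connected stage is linear, which avoids the dead-unit collapse that a ReLU
on all-positive pooled features invites.

Inputs are standardized per branch and channel with statistics estimated
on the training set (stored on the trained model and re-applied at
prediction).  Training minimizes mean squared error on z-scored targets
with Adam at the stated learning rate; every stochastic choice (weight
init, minibatch order) is a pure function of the seed.

The implementation is pure numpy: convolutions run as im2col plus one
GEMM per layer, which keeps both the forward and the backward pass inside
BLAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .imaging import FusionImageSet
from .signal_sim import ConfigurationError
from . import metrics as _metrics


# ---------------------------------------------------------------------------
# specs and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the fusion regressor."""

    n_branches: int = 3
    depth: int = 3            # conv blocks per branch
    n_filters: int = 16       # filters per conv layer
    filter_size: int = 3
    fc_out: int = 1024        # width of the fully connected layer after CAT
    input_shape: tuple[int, int, int] = (227, 227, 3)

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if self.n_filters < 1 or self.fc_out < 1 or self.n_branches < 1:
            raise ConfigurationError("n_filters, fc_out, n_branches must be >= 1")

    def branch_output_size(self) -> int:
        """Flattened feature length of one branch; validates the depth."""
        h, w, _ = self.input_shape
        for _ in range(self.depth):
            h, w = (h - self.filter_size + 1) // 2, (w - self.filter_size + 1) // 2
            if h < 1 or w < 1:
                raise ConfigurationError(
                    f"depth {self.depth} pools a {self.input_shape[:2]} input away")
        return h * w * self.n_filters

    def parameter_count(self) -> int:
        """Total learnable parameters (weights + biases), a pure function of the spec."""
        k, f = self.filter_size, self.n_filters
        c_in = self.input_shape[2]
        per_branch = 0
        c = c_in
        for _ in range(self.depth):
            per_branch += k * k * c * f + f
            c = f
        cat = self.n_branches * self.branch_output_size()
        fc = cat * self.fc_out + self.fc_out
        head = self.fc_out * 1 + 1
        return self.n_branches * per_branch + fc + head


@dataclass(frozen=True)
class TrainHyper:
    """Optimization hyperparameters."""

    learning_rate: float = 0.001
    minibatch: int = 8
    epochs: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.minibatch < 1 or self.epochs < 1:
            raise ConfigurationError("invalid hyperparameters")


@dataclass
class LabeledDataset:
    """(FusionImageSet, target) pairs for one anthropometric parameter."""

    items: list[tuple[FusionImageSet, float]]
    parameter: str
    subject_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.items) != len(self.subject_ids):
            raise ValueError("one subject id per item required")
        for _, t in self.items:
            if not np.isfinite(t):
                raise ValueError("targets must be finite")

    def __len__(self) -> int:
        return len(self.items)

    @classmethod
    def from_image_sets(cls, sets: Sequence[FusionImageSet], parameter: str,
                        subject_ids: Sequence[str]) -> "LabeledDataset":
        items = [(s, float(getattr(s.label, parameter))) for s in sets]
        return cls(items=items, parameter=parameter, subject_ids=list(subject_ids))

    def targets(self) -> np.ndarray:
        return np.array([t for _, t in self.items], dtype=float)


# ---------------------------------------------------------------------------
# layers (numpy forward/backward)
# ---------------------------------------------------------------------------

class _Conv:
    """kxk valid convolution, stride 1, via im2col + a single GEMM.

    The patch matrix is cached on the forward pass and reused for the
    weight gradient, so each step costs one im2col copy and three GEMMs.
    """

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int, k: int,
                 needs_input_grad: bool = True):
        fan_in = k * k * c_in
        # row layout (C, k, k) to match sliding_window_view's window axes
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (c_in * k * k, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in
        self.needs_input_grad = needs_input_grad

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, H, W_, C = x.shape
        k = self.k
        Ho, Wo = H - k + 1, W_ - k + 1
        windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        cols = windows.reshape(B * Ho * Wo, C * k * k)
        self._cols = cols
        self._shape = (B, Ho, Wo, C, H, W_)
        return (cols @ self.W + self.b).reshape(B, Ho, Wo, -1)

    def backward(self, dy: np.ndarray):
        B, Ho, Wo, C, H, W_ = self._shape
        k = self.k
        dyf = dy.reshape(B * Ho * Wo, -1)
        dW = self._cols.T @ dyf
        db = dyf.sum(axis=0)
        if not self.needs_input_grad:  # first layer of a branch
            return None, [dW, db]
        dcols = (dyf @ self.W.T).reshape(B, Ho, Wo, C, k, k)
        dx = np.zeros((B, H, W_, C), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dx[:, i:i + Ho, j:j + Wo, :] += dcols[:, :, :, :, i, j]
        return dx, [dW, db]


class _ReLU:
    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask, []


class _AvgPool2:
    """2x2 average pooling, stride 2; trailing odd row/column dropped."""

    def params(self):
        return []

    def forward(self, x):
        B, H, W_, C = x.shape
        Ho, Wo = H // 2, W_ // 2
        self._in_shape = x.shape
        xt = x[:, :2 * Ho, :2 * Wo, :]
        return 0.25 * ((xt[:, ::2, ::2] + xt[:, 1::2, ::2])
                       + (xt[:, ::2, 1::2] + xt[:, 1::2, 1::2]))

    def backward(self, dy):
        B, H, W_, C = self._in_shape
        Ho, Wo = dy.shape[1], dy.shape[2]
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        up = np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) * 0.25
        dx[:, :2 * Ho, :2 * Wo, :] = up
        return dx, []


class _Dense:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int,
                 scale: float | None = None):
        if scale is None:
            scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        dW = self._x.T @ dy
        db = dy.sum(axis=0)
        dx = dy @ self.W.T
        return dx, [dW, db]


class FusionNetwork:
    """The assembled three-branch regressor with its learnable parameters."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        spec.branch_output_size()  # validates depth vs input size
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.branches: list[list] = []
        for _ in range(spec.n_branches):
            layers: list = []
            c = spec.input_shape[2]
            for d in range(spec.depth):
                layers += [_Conv(rng, c, spec.n_filters, spec.filter_size,
                                 needs_input_grad=(d > 0)),
                           _ReLU(), _AvgPool2()]
                c = spec.n_filters
            self.branches.append(layers)
        cat = spec.n_branches * spec.branch_output_size()
        self.cat_scale = np.float32(1.0 / np.sqrt(cat))
        self.fc = _Dense(rng, cat, spec.fc_out)
        self.head = _Dense(rng, spec.fc_out, 1)

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        ps: list[np.ndarray] = []
        for layers in self.branches:
            for layer in layers:
                ps += layer.params()
        ps += self.fc.params() + self.head.params()
        return ps

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- forward / backward -------------------------------------------------
    def forward(self, xs: list[np.ndarray]) -> np.ndarray:
        """xs: one (B, H, W, 3) float32 array per branch -> (B,) predictions."""
        if len(xs) != self.spec.n_branches:
            raise ValueError(f"expected {self.spec.n_branches} branch inputs")
        feats = []
        for layers, x in zip(self.branches, xs):
            h = x
            for layer in layers:
                h = layer.forward(h)
            feats.append(h.reshape(h.shape[0], -1))
        self._feat_shapes = [f.shape[1] for f in feats]
        cat = np.concatenate(feats, axis=1) * self.cat_scale
        return self.head.forward(self.fc.forward(cat))[:, 0]

    def backward(self, dout: np.ndarray) -> list[np.ndarray]:
        """Gradients w.r.t. parameters, ordered as in ``parameters()``."""
        dy = dout[:, None].astype(np.float32)
        dh, g_head = self.head.backward(dy)
        dcat, g_fc = self.fc.backward(dh)
        dcat = dcat * self.cat_scale
        grads_branches: list[list[np.ndarray]] = []
        offset = 0
        for layers, width in zip(self.branches, self._feat_shapes):
            d = dcat[:, offset:offset + width]
            offset += width
            # restore the conv feature-map shape before the flatten
            last_pool = layers[-1]
            B = d.shape[0]
            Ho = last_pool._in_shape[1] // 2
            Wo = last_pool._in_shape[2] // 2
            d = d.reshape(B, Ho, Wo, self.spec.n_filters)
            gs: list[np.ndarray] = []
            for layer in reversed(layers):
                d, g = layer.backward(d)
                gs = g + gs
            grads_branches.append(gs)
        grads: list[np.ndarray] = []
        for gs in grads_branches:
            grads += gs
        grads += g_fc + g_head
        return grads


def build_network(spec: NetworkSpec, seed: int = 0) -> FusionNetwork:
    """Seeded He-style initialization of the three-branch regressor."""
    return FusionNetwork(spec, seed=seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted network plus its normalization constants and loss history."""

    network: FusionNetwork
    target_mean: float
    target_sd: float
    history: list[float] = field(default_factory=list)
    parameter: str = ""
    input_mean: np.ndarray | None = None  # (n_branches, n_channels)
    input_sd: np.ndarray | None = None


def _branch_inputs(sets: Sequence[FusionImageSet]) -> list[np.ndarray]:
    """Stack image sets into per-branch (B, H, W, 3) float32 tensors in [0, 1]."""
    n_branches = len(sets[0].images)
    return [np.stack([s.images[b] for s in sets]).astype(np.float32) / 255.0
            for b in range(n_branches)]


def _input_stats(xs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch, per-channel mean and standard deviation."""
    mean = np.stack([x.mean(axis=(0, 1, 2)) for x in xs])
    sd = np.stack([x.std(axis=(0, 1, 2)) for x in xs])
    return mean, np.maximum(sd, 1e-6)


def _standardize(xs: list[np.ndarray], mean: np.ndarray, sd: np.ndarray
                 ) -> list[np.ndarray]:
    return [((x - mean[b]) / sd[b]).astype(np.float32)
            for b, x in enumerate(xs)]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def train(network: FusionNetwork, dataset: LabeledDataset,
          hyper: TrainHyper = TrainHyper()) -> TrainedModel:
    """Fit by minibatch Adam on MSE of z-scored targets.

    The final partial minibatch is kept (not dropped).  The recorded history
    is the mean normalized-target MSE per epoch, one entry per epoch.
    """
    if len(dataset) == 0:
        raise ValueError("empty training set")
    targets = dataset.targets()
    mu = float(targets.mean())
    sd = float(targets.std())
    if sd == 0.0:
        sd = 1.0
    z = ((targets - mu) / sd).astype(np.float32)
    sets = [s for s, _ in dataset.items]
    xs_all = _branch_inputs(sets)
    in_mean, in_sd = _input_stats(xs_all)
    xs_all = _standardize(xs_all, in_mean, in_sd)
    params = network.parameters()
    opt = _Adam(params, hyper.learning_rate)
    rng = np.random.default_rng(hyper.seed)
    n = len(dataset)
    history: list[float] = []
    for _ in range(hyper.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, hyper.minibatch):
            idx = order[start:start + hyper.minibatch]
            xb = [x[idx] for x in xs_all]
            yb = z[idx]
            pred = network.forward(xb)
            err = pred - yb
            losses.append(float(np.mean(err ** 2)))
            if hyper.learning_rate > 0:
                grads = network.backward((2.0 / idx.size) * err)
                opt.step(params, grads)
        history.append(float(np.mean(losses)))
    return TrainedModel(network=network, target_mean=mu, target_sd=sd,
                        history=history, parameter=dataset.parameter,
                        input_mean=in_mean, input_sd=in_sd)


def predict(model: TrainedModel, items: Sequence[FusionImageSet]) -> np.ndarray:
    """De-normalized scalar prediction per image set, in the target's units."""
    if len(items) == 0:
        return np.array([])
    out = []
    for start in range(0, len(items), 32):
        xs = _branch_inputs(items[start:start + 32])
        if model.input_mean is not None:
            xs = _standardize(xs, model.input_mean, model.input_sd)
        out.append(model.network.forward(xs))
    z = np.concatenate(out)
    return z * model.target_sd + model.target_mean


# ---------------------------------------------------------------------------
# dataset splitting and the architecture sweep
# ---------------------------------------------------------------------------

def split_dataset(dataset: LabeledDataset, train_frac: float = 0.75,
                  seed: int = 0, mode: str = "subject"
                  ) -> tuple[LabeledDataset, LabeledDataset]:
    """Disjoint, exhaustive train/validation split.

    ``acquisition`` mode permutes individual acquisitions (the study
    protocol's random 75/25 split over all items, which can place
    repetitions of one subject on both sides).  ``subject`` mode — the
    default — keeps every repetition of a subject on one side, which is the
    leakage-safe choice for recovery experiments.
    """
    if not 0.0 < train_frac < 1.0:
        raise ConfigurationError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(dataset)

    def subset(idx: Iterable[int]) -> LabeledDataset:
        idx = list(idx)
        return LabeledDataset(items=[dataset.items[i] for i in idx],
                              parameter=dataset.parameter,
                              subject_ids=[dataset.subject_ids[i] for i in idx])

    if mode == "acquisition":
        order = rng.permutation(n)
        n_train = int(round(train_frac * n))
        return subset(sorted(order[:n_train])), subset(sorted(order[n_train:]))
    if mode == "subject":
        uniq = list(dict.fromkeys(dataset.subject_ids))
        order = rng.permutation(len(uniq))
        n_train_subj = int(round(train_frac * len(uniq)))
        train_subj = {uniq[i] for i in order[:n_train_subj]}
        tr = [i for i, s in enumerate(dataset.subject_ids) if s in train_subj]
        va = [i for i, s in enumerate(dataset.subject_ids) if s not in train_subj]
        return subset(tr), subset(va)
    raise ConfigurationError(f"unknown split mode {mode!r}")


def sweep_architectures(dataset: LabeledDataset,
                        depths: Sequence[int] = (2, 3),
                        filters: Sequence[int] = (16, 32, 64, 128),
                        fc_widths: Sequence[int] = (256, 512, 1024),
                        hyper: TrainHyper = TrainHyper(),
                        seed: int = 0, train_frac: float = 0.75,
                        mode: str = "subject",
                        input_shape: tuple[int, int, int] = (227, 227, 3)
                        ) -> pd.DataFrame:
    """Validation RMSE over the depth x filters x fc grid, common split.

    Returns a DataFrame with columns (depth, filters, fc, rmse), one row per
    grid cell.
    """
    cells = [(d, f, w) for d in depths for f in filters for w in fc_widths]
    if not cells:
        raise ConfigurationError("empty architecture grid")
    train_ds, val_ds = split_dataset(dataset, train_frac=train_frac,
                                     seed=seed, mode=mode)
    rows = []
    for d, f, w in cells:
        spec = NetworkSpec(depth=d, n_filters=f, fc_out=w, input_shape=input_shape)
        net = build_network(spec, seed=seed)
        model = train(net, train_ds, hyper)
        est = predict(model, [s for s, _ in val_ds.items])
        rows.append({"depth": d, "filters": f, "fc": w,
                     "rmse": _metrics.rmse(est, val_ds.targets())})
    return pd.DataFrame(rows)
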