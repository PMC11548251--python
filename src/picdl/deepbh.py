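"""Prior-model module: training loss, architecture description, and a
desk-scale trainable prior model.

The prior-generation stage of the pipeline maps a streaky, beam-hardened
reconstruction to an artifact-corrected image.  At scanner scale this is the
role of a U-Net-style network with a ResNet-34 encoder and a pixel-shuffle
(ICNR-initialised) decoder; :class:`NetworkSpec` records that layout as
validated configuration data.  The trainable model bundled here is a compact
two-stage residual CNN written in numpy (3×3 convolutions, ReLU, manual
backpropagation, AdamW, Kaiming-uniform init) — small enough to train on a
handful of synthetic slices in seconds while exercising the same loss,
two-phase fine-tuning schedule and seeding contract as a full-scale model.

Everything else in the toolkit treats the prior as an opaque image, so
:func:`predict_prior` and :func:`~picdl.polysim.fabricate_prior` are
interchangeable prior providers.

Per the half-size protocol, models operate at half the reconstruction grid:
inputs are produced with :func:`~picdl.geometry.downsample_half` and outputs
go through :func:`~picdl.geometry.upsample_bilinear` before reaching the
solver, which limits the transfer of hallucinated detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Image2D

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "PriorModel",
    "smooth_l1_loss",
    "train_prior_model",
    "predict_prior",
]


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def smooth_l1_loss(x: np.ndarray, u: np.ndarray) -> float:
    """Smooth L1 (Huber at unit transition): mean over elements of
    0.5·r² for |r| ≤ 1 and |r| − 0.5 otherwise, r = x − u.

    Quadratic near zero (stable updates for small residuals), linear in the
    tails (bounded gradients for outliers); continuous at |r| = 1.
    """
    x = np.asarray(x, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    if x.shape != u.shape:
        raise ValueError("prediction and target shapes must match")
    if x.size == 0:
        raise ValueError("empty inputs")
    r = np.abs(x - u)
    per = np.where(r <= 1.0, 0.5 * r * r, r - 0.5)
    return float(per.mean())


def _smooth_l1_grad(x: np.ndarray, u: np.ndarray) -> np.ndarray:
    """d(mean smooth-L1)/dx = clip(x − u, −1, 1)/N."""
    return np.clip(x - u, -1.0, 1.0) / x.size


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkSpec:
    """Full-scale encoder–decoder layout for scanner-scale prior models.

    Encoder: initial 7×7 convolution followed by residual stages; decoder:
    per-stage sub-pixel (pixel-shuffle) upsampling with resize-consistent
    (ICNR) initialisation, each followed by two conv+ReLU blocks, with
    stage-wise skip connections.  Single-channel in and out; operates at half
    the reconstruction grid.
    """

    encoder_stages: tuple[int, ...] = (3, 4, 6, 3)  # residual blocks per stage
    initial_kernel: int = 7
    decoder_upsampling: str = "pixel_shuffle_icnr"
    decoder_convs_per_stage: int = 2
    skip_connections: bool = True
    channels_in: int = 1
    channels_out: int = 1
    input_scale: float = 0.5  # fraction of the reconstruction grid

    def __post_init__(self) -> None:
        if len(self.encoder_stages) == 0 or any(s < 1 for s in self.encoder_stages):
            raise ValueError("encoder stages must be positive counts")
        if self.channels_in != self.channels_out:
            raise ValueError("prior model must preserve the channel count")
        if not 0 < self.input_scale <= 1:
            raise ValueError("input_scale must be in (0, 1]")


@dataclass
class TrainConfig:
    """Two-phase fine-tuning schedule.

    Phase 1 trains only the encoder (a configuration switch selects the
    conventional decoder-first reading instead); phase 2 trains end-to-end at
    a much smaller rate.  Weights are AdamW-regularised and Kaiming-uniform
    initialised from ``seed`` before any data is seen.
    """

    lr_phase1: float = 1e-4
    lr_phase2: float = 1e-7
    epochs_phase1: int = 50
    epochs_phase2: int = 20
    weight_decay: float = 1e-2
    phase1_trains: str = "encoder"  # or "decoder"
    hidden_channels: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_phase1 <= 0 or self.lr_phase2 <= 0:
            raise ValueError("learning rates must be positive")
        if self.phase1_trains not in ("encoder", "decoder"):
            raise ValueError("phase1_trains must be 'encoder' or 'decoder'")


# ---------------------------------------------------------------------------
# numpy conv blocks
# ---------------------------------------------------------------------------


def _conv3x3(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-size 3×3 convolution, zero padding; x (C,H,W), W (O,C,3,3)."""
    C, H, Wd = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    out = np.broadcast_to(b[:, None, None], (W.shape[0], H, Wd)).copy()
    for di in range(3):
        for dj in range(3):
            out += np.einsum(
                "oc,chw->ohw", W[:, :, di, dj], xp[:, di : di + H, dj : dj + Wd]
            )
    return out


def _conv3x3_backward(x, W, d_out):
    """Gradients of _conv3x3 wrt (x, W, b) given upstream d_out (O,H,W)."""
    C, H, Wd = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    dW = np.zeros_like(W)
    dxp = np.zeros_like(xp)
    for di in range(3):
        for dj in range(3):
            patch = xp[:, di : di + H, dj : dj + Wd]
            dW[:, :, di, dj] = np.einsum("ohw,chw->oc", d_out, patch)
            dxp[:, di : di + H, dj : dj + Wd] += np.einsum(
                "oc,ohw->chw", W[:, :, di, dj], d_out
            )
    return dxp[:, 1:-1, 1:-1], dW, d_out.sum(axis=(1, 2))


def _kaiming_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class _Adam:
    """AdamW with decoupled weight decay (biases excluded from decay)."""

    def __init__(self, params: dict[str, np.ndarray], weight_decay: float):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.wd = weight_decay

    def step(self, params, grads, lr, subset):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in subset:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
            if k.startswith("W"):
                params[k] -= lr * self.wd * params[k]


@dataclass
class PriorModel:
    """Trained compact residual CNN in normalised units:
    y = x + dec(relu(enc2(relu(enc1(x))))), all 3×3 convolutions."""

    params: dict[str, np.ndarray]
    norm_mean: float
    norm_std: float
    input_shape: tuple[int, int]
    loss_curve: list[float] = field(default_factory=list)

    def _forward(self, xn: np.ndarray):
        z1 = _conv3x3(xn[None], self.params["W1"], self.params["b1"])
        a1 = np.maximum(z1, 0.0)
        z2 = _conv3x3(a1, self.params["W2"], self.params["b2"])
        a2 = np.maximum(z2, 0.0)
        z3 = _conv3x3(a2, self.params["W3"], self.params["b3"])
        return xn + z3[0], (xn, z1, a1, z2, a2)

    def predict(self, x: np.ndarray) -> np.ndarray:
        xn = (x - self.norm_mean) / self.norm_std
        yn, _ = self._forward(xn)
        return yn * self.norm_std + self.norm_mean


def train_prior_model(
    pairs: list[tuple[Image2D, Image2D]],
    spec: NetworkSpec | None = None,
    cfg: TrainConfig | None = None,
) -> PriorModel:
    """Fit the prior model on (degraded slice, clean target) pairs.

    Full-batch gradient over all pairs per epoch; deterministic for a fixed
    ``cfg.seed``.  Returns the model handle with its per-epoch loss curve
    (phase 1 followed by phase 2).
    """
    spec = spec or NetworkSpec()
    cfg = cfg or TrainConfig()
    if len(pairs) < 2:
        raise ValueError("need at least two training pairs")
    shapes = {p[0].shape for p in pairs} | {p[1].shape for p in pairs}
    if len(shapes) != 1:
        raise ValueError("all training slices must share one shape")
    (shape,) = shapes

    xs = np.stack([p[0].values for p in pairs])
    us = np.stack([p[1].values for p in pairs])
    mean = float(xs.mean())
    std = float(xs.std()) or 1.0
    xn, un = (xs - mean) / std, (us - mean) / std

    rng = np.random.default_rng(cfg.seed)
    ch = cfg.hidden_channels
    params = {
        "W1": _kaiming_uniform(rng, (ch, 1, 3, 3)),
        "b1": np.zeros(ch),
        "W2": _kaiming_uniform(rng, (ch, ch, 3, 3)),
        "b2": np.zeros(ch),
        "W3": _kaiming_uniform(rng, (1, ch, 3, 3)),
        "b3": np.zeros(1),
    }
    model = PriorModel(params, mean, std, shape)
    opt = _Adam(params, cfg.weight_decay)
    encoder, decoder = ("W1", "b1", "W2", "b2"), ("W3", "b3")
    phase1 = encoder if cfg.phase1_trains == "encoder" else decoder

    def epoch(lr: float, subset) -> float:
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        total = 0.0
        for x_i, u_i in zip(xn, un):
            y, (x0, z1, a1, z2, a2) = model._forward(x_i)
            total += smooth_l1_loss(y, u_i)
            dy = _smooth_l1_grad(y, u_i)
            da2, dW3, db3 = _conv3x3_backward(a2, params["W3"], dy[None])
            dz2 = da2 * (z2 > 0)
            da1, dW2, db2 = _conv3x3_backward(a1, params["W2"], dz2)
            dz1 = da1 * (z1 > 0)
            _, dW1, db1 = _conv3x3_backward(x0[None], params["W1"], dz1)
            for k, g in (
                ("W1", dW1), ("b1", db1), ("W2", dW2),
                ("b2", db2), ("W3", dW3), ("b3", db3),
            ):
                grads[k] += g
        opt.step(params, grads, lr, subset)
        return total / len(pairs)

    for _ in range(cfg.epochs_phase1):
        model.loss_curve.append(epoch(cfg.lr_phase1, phase1))
    for _ in range(cfg.epochs_phase2):
        model.loss_curve.append(epoch(cfg.lr_phase2, encoder + decoder))
    return model


def save_model(model: PriorModel, path) -> None:
    """Write a model checkpoint (.npz with weights and normalisation)."""
    np.savez(
        path,
        **model.params,
        norm_mean=model.norm_mean,
        norm_std=model.norm_std,
        input_shape=np.array(model.input_shape),
    )


def load_model(path) -> PriorModel:
    data = np.load(path)
    keys = ("W1", "b1", "W2", "b2", "W3", "b3")
    return PriorModel(
        params={k: data[k] for k in keys},
        norm_mean=float(data["norm_mean"]),
        norm_std=float(data["norm_std"]),
        input_shape=tuple(int(s) for s in data["input_shape"]),
    )


def predict_prior(model: PriorModel, fbp_slice: Image2D) -> Image2D:
    """Prior image from a (half-size) degraded slice; shape-preserving."""
    if fbp_slice.shape != model.input_shape:
        raise ValueError(
            f"input scale {fbp_slice.shape} does not match the model's "
            f"training scale {model.input_shape}"
        )
    out = model.predict(fbp_slice.values)
    if not np.all(np.isfinite(out)):
        raise ValueError("model produced non-finite values")
    return Image2D(out, fbp_slice.pixel_size)
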