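"""Encoder-decoder (U-Net-style) regression network for image denoising.

The network maps a single-channel normalized image to a single-channel
prediction of the clinical-standard image.  Architecture: ``depth``
encoder levels of two same-padded convolutions + ReLU with 2x2 max
pooling between levels and channel doubling; a decoder mirroring them
with 2x2 stride-2 transposed convolutions and skip concatenation; a final
1x1 convolution with linear activation.

Weights are He-normal initialized.  A max-norm constraint (default 3.0)
is applied to the incoming-weight vector of every hidden unit after each
optimizer update, matching the Keras ``max_norm`` kernel constraint on
all ReLU layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import layers as L

__all__ = ["ModelConfig", "DnifModel", "build_model", "denoise", "parameter_count"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters."""

    depth: int = 4
    base_channels: int = 16
    kernel_size: int = 3
    max_weight_norm: float = 3.0
    input_shape: tuple[int, int] = (64, 64)
    seed: int = 0
    #: Predict input + correction instead of the image directly.  Adds no
    #: parameters (the skip is an identity); greatly speeds convergence of
    #: short CPU schedules by building brightness fidelity in from step 0.
    residual: bool = False

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.max_weight_norm <= 0:
            raise ValueError("max_weight_norm must be > 0")

    @property
    def divisor(self) -> int:
        """Spatial dims must be divisible by this after padding."""
        return 2 ** (self.depth - 1)

    def channels(self, level: int) -> int:
        return self.base_channels * 2**level


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _layer_plan(cfg: ModelConfig) -> list[dict]:
    """Ordered parameter plan; each entry names one weighted layer."""
    k = cfg.kernel_size
    plan: list[dict] = []
    in_ch = 1
    for d in range(cfg.depth):
        ch = cfg.channels(d)
        plan.append(dict(name=f"enc{d}_conv0", kind="conv", in_ch=in_ch, out_ch=ch, k=k, hidden=True))
        plan.append(dict(name=f"enc{d}_conv1", kind="conv", in_ch=ch, out_ch=ch, k=k, hidden=True))
        in_ch = ch
    for d in range(cfg.depth - 2, -1, -1):
        ch = cfg.channels(d)
        plan.append(dict(name=f"dec{d}_up", kind="upconv", in_ch=in_ch, out_ch=ch, k=2, hidden=True))
        plan.append(dict(name=f"dec{d}_conv0", kind="conv", in_ch=2 * ch, out_ch=ch, k=k, hidden=True))
        plan.append(dict(name=f"dec{d}_conv1", kind="conv", in_ch=ch, out_ch=ch, k=k, hidden=True))
        in_ch = ch
    plan.append(dict(name="out", kind="conv", in_ch=in_ch, out_ch=1, k=1, hidden=False))
    return plan


def parameter_count(cfg: ModelConfig) -> int:
    """Total number of trainable scalars, a pure function of the config."""
    total = 0
    for spec in _layer_plan(cfg):
        total += spec["out_ch"] * spec["in_ch"] * spec["k"] ** 2 + spec["out_ch"]
    return total


@dataclass
class DnifModel:
    """The denoising filter: config, parameters, and training history."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    training_history: list[float] = field(default_factory=list)
    _plan: list[dict] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self._plan:
            self._plan = _layer_plan(self.config)

    # -- persistence ----------------------------------------------------
    def save(self, path: str) -> None:
        meta = dict(
            config=dict(
                depth=self.config.depth,
                base_channels=self.config.base_channels,
                kernel_size=self.config.kernel_size,
                max_weight_norm=self.config.max_weight_norm,
                input_shape=list(self.config.input_shape),
                seed=self.config.seed,
                residual=self.config.residual,
            ),
            training_history=self.training_history,
        )
        np.savez_compressed(path, __meta__=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path: str) -> "DnifModel":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["__meta__"]))
            params = {k: f[k] for k in f.files if k != "__meta__"}
        c = meta["config"]
        c["input_shape"] = tuple(c["input_shape"])
        model = cls(config=ModelConfig(**c), params=params)
        model.training_history = list(meta["training_history"])
        return model

    # -- constraint -----------------------------------------------------
    def apply_max_norm(self) -> None:
        """Rescale hidden-unit incoming weights to norm <= max_weight_norm."""
        c = self.config.max_weight_norm
        for spec in self._plan:
            if not spec["hidden"]:
                continue
            w = self.params[spec["name"] + "_w"]
            if spec["kind"] == "conv":
                flat = w.reshape(w.shape[0], -1)  # (out, in*k*k)
                norms = np.linalg.norm(flat, axis=1)
                scale = np.minimum(1.0, c / np.maximum(norms, 1e-30))
                w *= scale[:, None, None, None]
            else:  # upconv: (in, out, 2, 2), incoming weights per out channel
                flat = w.transpose(1, 0, 2, 3).reshape(w.shape[1], -1)
                norms = np.linalg.norm(flat, axis=1)
                scale = np.minimum(1.0, c / np.maximum(norms, 1e-30))
                w *= scale[None, :, None, None]

    def hidden_unit_norms(self) -> dict[str, np.ndarray]:
        """Per-unit incoming-weight norms of every hidden layer."""
        out = {}
        for spec in self._plan:
            if not spec["hidden"]:
                continue
            w = self.params[spec["name"] + "_w"]
            if spec["kind"] == "conv":
                out[spec["name"]] = np.linalg.norm(w.reshape(w.shape[0], -1), axis=1)
            else:
                out[spec["name"]] = np.linalg.norm(
                    w.transpose(1, 0, 2, 3).reshape(w.shape[1], -1), axis=1
                )
        return out

    # -- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Run the network on an NCHW batch (C = 1).

        Spatial dims must be divisible by ``config.divisor``; use
        :func:`denoise` for automatic padding.
        """
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("expected NCHW input with 1 channel")
        h, w = x.shape[2:]
        div = self.config.divisor
        if h % div or w % div:
            raise ValueError(
                f"spatial dims {(h, w)} must be divisible by {div} "
                f"(depth {self.config.depth}); pad the input first"
            )
        p = self.params
        cache: dict[str, object] = {"x": x}
        skips = []
        cur = x
        for d in range(self.config.depth):
            for i in range(2):
                name = f"enc{d}_conv{i}"
                z, cols = L.conv2d(cur, p[name + "_w"], p[name + "_b"])
                cache[name + "_cols"] = cols
                cache[name + "_z"] = z
                cache[name + "_xshape"] = cur.shape
                cur = L.relu(z)
            if d < self.config.depth - 1:
                skips.append(cur)
                cur, idx = L.maxpool2x2(cur)
                cache[f"pool{d}_idx"] = idx
                cache[f"pool{d}_xshape"] = skips[-1].shape
        for d in range(self.config.depth - 2, -1, -1):
            name = f"dec{d}_up"
            cache[name + "_x"] = cur
            cur = L.conv_transpose2x2(cur, p[name + "_w"], p[name + "_b"])
            skip = skips[d]
            cache[f"dec{d}_split"] = skip.shape[1]
            cur = np.concatenate([skip, cur], axis=1)
            for i in range(2):
                name = f"dec{d}_conv{i}"
                z, cols = L.conv2d(cur, p[name + "_w"], p[name + "_b"])
                cache[name + "_cols"] = cols
                cache[name + "_z"] = z
                cache[name + "_xshape"] = cur.shape
                cur = L.relu(z)
        z, cols = L.conv2d(cur, p["out_w"], p["out_b"])
        cache["out_cols"] = cols
        cache["out_xshape"] = cur.shape
        y = z + x if self.config.residual else z  # linear output activation
        return (y, cache) if want_cache else y

    def backward(self, dy: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. every parameter."""
        p = self.params
        grads: dict[str, np.ndarray] = {}

        def conv_back(name: str, d: np.ndarray) -> np.ndarray:
            dx, dw, db = L.conv2d_backward(
                d, cache[name + "_cols"], p[name + "_w"], cache[name + "_xshape"]
            )
            grads[name + "_w"] = dw
            grads[name + "_b"] = db
            return dx

        d = conv_back("out", dy)
        for d_level in range(0, self.config.depth - 1):
            for i in (1, 0):
                name = f"dec{d_level}_conv{i}"
                d = conv_back(name, L.relu_backward(d, cache[name + "_z"]))
            split = cache[f"dec{d_level}_split"]
            d_skip, d_up = d[:, :split], d[:, split:]
            name = f"dec{d_level}_up"
            d, dw, db = L.conv_transpose2x2_backward(d_up, cache[name + "_x"], p[name + "_w"])
            grads[name + "_w"] = dw
            grads[name + "_b"] = db
            # skip gradient flows into the encoder at this level
            cache[f"_dskip{d_level}"] = d_skip

        for d_level in range(self.config.depth - 1, -1, -1):
            if d_level < self.config.depth - 1:
                d = L.maxpool2x2_backward(
                    d, cache[f"pool{d_level}_idx"], cache[f"pool{d_level}_xshape"]
                )
                d = d + cache.pop(f"_dskip{d_level}")
            for i in (1, 0):
                name = f"enc{d_level}_conv{i}"
                d = conv_back(name, L.relu_backward(d, cache[name + "_z"]))
        return grads


def build_model(config: ModelConfig) -> DnifModel:
    """He-normal initialize a fresh model; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    params: dict[str, np.ndarray] = {}
    for spec in _layer_plan(config):
        k, in_ch, out_ch = spec["k"], spec["in_ch"], spec["out_ch"]
        fan_in = in_ch * k * k
        if spec["kind"] == "conv":
            params[spec["name"] + "_w"] = _he_normal(rng, (out_ch, in_ch, k, k), fan_in)
        else:
            params[spec["name"] + "_w"] = _he_normal(rng, (in_ch, out_ch, k, k), fan_in)
        params[spec["name"] + "_b"] = np.zeros(out_ch)
    model = DnifModel(config=config, params=params)
    model.apply_max_norm()  # constraint holds from initialization onward
    return model


def _pad_to_divisible(img: np.ndarray, div: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = img.shape
    ph = (-h) % div
    pw = (-w) % div
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
    return img, (h, w)


def denoise(model: DnifModel, img: np.ndarray) -> np.ndarray:
    """Apply the trained filter to one normalized 2D image.

    Inputs whose size is not divisible by ``2**(depth-1)`` are
    reflect-padded and the prediction cropped back, so arbitrary sizes
    are accepted.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("denoise expects a single 2D image")
    if not np.isfinite(img).all():
        raise ValueError("input image contains NaN or infinite values")
    if img.max() > 1.0 + 1e-6 or img.min() < -1e-6:
        raise ValueError("input image must be normalized to [0, 1]")
    padded, (h, w) = _pad_to_divisible(img, model.config.divisor)
    y = model.forward(padded[None, None])
    return y[0, 0, :h, :w]
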