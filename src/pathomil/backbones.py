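"""Frozen convolutional feature backbones for patch encoding.

Two presets are shipped, both pure-NumPy forward passes over a fixed
(frozen) parameter set:

``paper``
    The 34-layer residual network layout (7x7 stem, four stages of basic
    blocks [3, 4, 6, 3] with 64/128/256/512 channels, global average pool),
    producing 512-dimensional patch features.  Weights are either randomly
    initialized (seeded) or loaded from an ``.npz`` file, so externally
    pre-trained weights can be plugged in without any framework dependency.

``tiny``
    A small two-layer convolutional net whose features are channel statistics
    of random filter responses; fast enough to featurize thousands of patches
    per minute on one CPU, used for desk-scale experiments and tests.

Backbones are frozen by contract: they expose no update method and their
parameter fingerprint lets callers assert bit-identical weights across
training.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class BackboneError(ValueError):
    pass


@dataclass
class BackboneSpec:
    architecture: str = "paper"  # "paper" | "tiny"
    weights_source: str = "random"  # "random" | "file"
    weights_path: str | None = None
    frozen: bool = True
    seed: int = 0

    @property
    def feature_dim(self) -> int:
        return {"paper": 512, "tiny": TinyBackbone.FEATURE_DIM}[self.architecture]


def make_backbone(spec: BackboneSpec | str):
    if isinstance(spec, str):
        spec = BackboneSpec(architecture=spec)
    if spec.architecture == "tiny":
        backbone = TinyBackbone(seed=spec.seed)
    elif spec.architecture == "paper":
        backbone = ResidualBackbone(seed=spec.seed)
    else:
        raise BackboneError(f"unknown backbone architecture {spec.architecture!r}")
    if spec.weights_source == "file":
        if not spec.weights_path:
            raise BackboneError("weights_source='file' requires weights_path")
        backbone.load_weights(spec.weights_path)
    return backbone


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int = 1, pad: int = 0) -> np.ndarray:
    """Batched cross-correlation: x (n,h,w,cin), w (kh,kw,cin,cout)."""
    kh, kw, cin, cout = w.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    v = sliding_window_view(x, (kh, kw), axis=(1, 2))  # (n,oh,ow,cin,kh,kw)
    v = v[:, ::stride, ::stride]
    n, oh, ow = v.shape[:3]
    cols = v.transpose(0, 1, 2, 4, 5, 3).reshape(n * oh * ow, kh * kw * cin)
    out = cols @ w.reshape(kh * kw * cin, cout)
    return (out + b).reshape(n, oh, ow, cout)


def _maxpool(x: np.ndarray, size: int, stride: int) -> np.ndarray:
    v = sliding_window_view(x, (size, size), axis=(1, 2))[:, ::stride, ::stride]
    return v.max(axis=(-2, -1))


def _meanpool(x: np.ndarray, size: int) -> np.ndarray:
    n, h, w, c = x.shape
    return x[:, : h - h % size, : w - w % size].reshape(
        n, h // size, size, w // size, size, c
    ).mean(axis=(2, 4))


def _to_float(tiles: np.ndarray) -> np.ndarray:
    x = np.asarray(tiles)
    if x.ndim == 3:
        x = x[None]
    if x.dtype == np.uint8:
        x = x.astype(np.float32) / 255.0
    return x.astype(np.float32, copy=False)


class _FrozenBackbone:
    params: dict[str, np.ndarray]
    feature_dim: int

    def fingerprint(self) -> str:
        digest = hashlib.sha256()
        for name in sorted(self.params):
            digest.update(name.encode())
            digest.update(np.ascontiguousarray(self.params[name]).tobytes())
        return digest.hexdigest()

    def load_weights(self, path) -> None:
        loaded = dict(np.load(path))
        missing = set(self.params) - set(loaded)
        if missing:
            raise BackboneError(f"weights file missing parameters: {sorted(missing)[:5]}")
        for name, value in self.params.items():
            if loaded[name].shape != value.shape:
                raise BackboneError(
                    f"parameter {name}: expected shape {value.shape}, got {loaded[name].shape}"
                )
            self.params[name] = loaded[name].astype(np.float32)

    def save_weights(self, path) -> None:
        np.savez(path, **self.params)

    def features(self, tiles: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, tiles: np.ndarray) -> np.ndarray:
        return self.features(tiles)


class TinyBackbone(_FrozenBackbone):
    """Random-filter statistics backbone for desk-scale experiments.

    Input tiles are mean-pooled 4x, passed through two seeded random 3x3
    convolution layers with ReLU, and summarized by per-channel means and
    standard deviations (plus raw-colour statistics).  The resulting
    54-dimensional features separate textures that differ in colour, scale
    or local structure, which is what the synthetic gland textures vary.
    """

    FEATURE_DIM = 54
    _C1, _C2 = 8, 16

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.params = {
            "conv1.w": (rng.standard_normal((3, 3, 3, self._C1)) / np.sqrt(27)).astype(np.float32),
            "conv1.b": np.zeros(self._C1, dtype=np.float32),
            "conv2.w": (rng.standard_normal((3, 3, self._C1, self._C2)) / np.sqrt(9 * self._C1)).astype(np.float32),
            "conv2.b": np.zeros(self._C2, dtype=np.float32),
        }
        self.feature_dim = self.FEATURE_DIM

    def features(self, tiles: np.ndarray) -> np.ndarray:
        x = _to_float(tiles)
        stats = [x.mean(axis=(1, 2)), x.std(axis=(1, 2))]
        x = _meanpool(x, 4)  # 224 -> 56
        x = np.maximum(_conv2d(x, self.params["conv1.w"], self.params["conv1.b"], pad=1), 0)
        stats += [x.mean(axis=(1, 2)), x.std(axis=(1, 2))]
        x = _meanpool(x, 4)  # 56 -> 14
        x = np.maximum(_conv2d(x, self.params["conv2.w"], self.params["conv2.b"], pad=1), 0)
        stats += [x.mean(axis=(1, 2)), x.std(axis=(1, 2))]
        return np.concatenate(stats, axis=1).astype(np.float64)


class ResidualBackbone(_FrozenBackbone):
    """34-layer residual network layout producing 512-d patch features.

    Basic blocks (two 3x3 convolutions with batch-norm, identity or 1x1
    projection shortcut), stage plan [3, 4, 6, 3] over 64/128/256/512
    channels, 7x7/2 stem with 3x3/2 max pool, global average pool.  Forward
    only; batch-norm uses stored running statistics.
    """

    STAGES = ((64, 3), (128, 4), (256, 6), (512, 3))

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        self._add_conv(rng, "stem", 7, 3, 64)
        in_ch = 64
        for s, (ch, blocks) in enumerate(self.STAGES):
            for b in range(blocks):
                prefix = f"s{s}b{b}"
                self._add_conv(rng, f"{prefix}.conv1", 3, in_ch, ch)
                self._add_conv(rng, f"{prefix}.conv2", 3, ch, ch)
                if in_ch != ch:
                    self._add_conv(rng, f"{prefix}.proj", 1, in_ch, ch)
                in_ch = ch
        self.feature_dim = 512

    def _add_conv(self, rng, name: str, k: int, cin: int, cout: int) -> None:
        fan_in = k * k * cin
        self.params[f"{name}.w"] = (
            rng.standard_normal((k, k, cin, cout)) * np.sqrt(2.0 / fan_in)
        ).astype(np.float32)
        self.params[f"{name}.bn.gamma"] = np.ones(cout, dtype=np.float32)
        self.params[f"{name}.bn.beta"] = np.zeros(cout, dtype=np.float32)
        self.params[f"{name}.bn.mean"] = np.zeros(cout, dtype=np.float32)
        self.params[f"{name}.bn.var"] = np.ones(cout, dtype=np.float32)

    def _conv_bn(self, x, name: str, stride: int = 1, pad: int = 0, relu: bool = True):
        p = self.params
        out = _conv2d(x, p[f"{name}.w"], np.zeros(p[f"{name}.w"].shape[-1], dtype=np.float32), stride=stride, pad=pad)
        out = (out - p[f"{name}.bn.mean"]) / np.sqrt(p[f"{name}.bn.var"] + 1e-5)
        out = out * p[f"{name}.bn.gamma"] + p[f"{name}.bn.beta"]
        return np.maximum(out, 0) if relu else out

    def features(self, tiles: np.ndarray) -> np.ndarray:
        x = _to_float(tiles)
        x = self._conv_bn(x, "stem", stride=2, pad=3)
        x = _maxpool(np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0))), 3, 2)
        in_ch = 64
        for s, (ch, blocks) in enumerate(self.STAGES):
            for b in range(blocks):
                prefix = f"s{s}b{b}"
                stride = 2 if (b == 0 and in_ch != ch) else 1
                out = self._conv_bn(x, f"{prefix}.conv1", stride=stride, pad=1)
                out = self._conv_bn(out, f"{prefix}.conv2", pad=1, relu=False)
                if in_ch != ch:
                    shortcut = self._conv_bn(x, f"{prefix}.proj", stride=stride, relu=False)
                else:
                    shortcut = x
                x = np.maximum(out + shortcut, 0)
                in_ch = ch
        return x.mean(axis=(1, 2)).astype(np.float64)
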