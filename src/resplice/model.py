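"""Declarative construction of the residual channel-attention splice network.

The network is a five-stage 1-D residual CNN over one-hot DNA windows:

* **stem** — 64 convolution kernels of size 7 spanning all 4 input channels,
  'same' padding, followed by batch normalization and ReLU;
* **stages 2-5** — one ConvBlock and one IdentityBlock each, with
  64/128/128/256 kernels of size 7, and average-pool downsampling of window
  1/3/4/4. Both block types use two stride-1 convolutions in pre-activation
  order (BN -> ReLU -> Conv) with an efficient-channel-attention (ECA) gate
  on the residual branch before the additive merge. The ConvBlock pools
  between its two convolutions and projects the shortcut with a 1x1
  convolution followed by the same pooling; the IdentityBlock's shortcut is
  the identity;
* **head** — global average pooling and a 2-way dense layer with softmax
  (splice site vs non-site).

Downsampling by stride-1 convolution + average pooling (instead of strided
convolution) and the delayed onset of pooling (stage 3) preserve positional
information in the sequence; the ECA gate reweights channels using a small
1-D convolution across the channel axis whose kernel size grows with the
channel count.

:func:`cost_report` accounts parameters and forward-pass FLOPs analytically
from the spec — no network is instantiated — under the convention that one
multiply-accumulate is 2 FLOPs, counted over convolution and dense layers
(pooling, BN and activations excluded), and that batch normalization carries
4 parameters per channel (scale, shift, moving mean/variance).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import nn

__all__ = [
    "ECAConfig",
    "StageConfig",
    "NetworkSpec",
    "CostReport",
    "eca_kernel_size",
    "build_eca_block",
    "build_conv_block",
    "build_identity_block",
    "build_network",
    "Network",
    "cost_report",
    "stage_output_lengths",
]


class SpecError(ValueError):
    """Raised when a network spec is internally inconsistent."""


@dataclass(frozen=True)
class ECAConfig:
    """Constants of the adaptive ECA kernel-size rule."""

    gamma: int = 2
    b: int = 1

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise SpecError("ECA gamma must be positive")


@dataclass(frozen=True)
class StageConfig:
    """One convolution stage: N kernels of (odd) size K, pooling window P.

    ``p == 1`` means no downsampling.
    """

    n: int
    k: int = 7
    p: int = 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SpecError(f"kernel count must be >= 1, got {self.n}")
        if self.k % 2 == 0 or self.k < 1:
            raise SpecError(f"kernel height must be odd and >= 1, got {self.k}")
        if self.p < 1:
            raise SpecError(f"pooling window must be >= 1, got {self.p}")


@dataclass(frozen=True)
class NetworkSpec:
    """The full computational graph, declaratively.

    Defaults are the selected hyperparameters of the reference architecture:
    stem 64 kernels of 7 x 4; residual stages with N = 64, 128, 128, 256,
    K = 7 x 1 and P = 1, 3, 4, 4; 402 x 4 input.
    """

    window_length: int = 402
    stem: StageConfig = field(default_factory=lambda: StageConfig(n=64, k=7))
    stages: tuple[StageConfig, ...] = field(
        default_factory=lambda: (
            StageConfig(n=64, k=7, p=1),
            StageConfig(n=128, k=7, p=3),
            StageConfig(n=128, k=7, p=4),
            StageConfig(n=256, k=7, p=4),
        )
    )
    eca: ECAConfig = field(default_factory=ECAConfig)
    n_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.stages) != 4:
            raise SpecError(f"expected 4 residual stages, got {len(self.stages)}")
        if self.window_length < 2:
            raise SpecError("window length must be >= 2")

    @classmethod
    def default(cls) -> "NetworkSpec":
        return cls()

    @classmethod
    def reduced(cls, widths: Sequence[int] = (8, 16, 16, 32), stem_n: int = 8) -> "NetworkSpec":
        """A width-reduced variant (same depth, pooling and kernel sizes)
        for CPU-scale training on synthetic fixtures."""
        return cls(
            stem=StageConfig(n=stem_n, k=7),
            stages=tuple(
                StageConfig(n=w, k=7, p=p) for w, p in zip(widths, (1, 3, 4, 4))
            ),
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "window_length": self.window_length,
            "stem": asdict(self.stem),
            "stages": [asdict(s) for s in self.stages],
            "eca": asdict(self.eca),
            "n_classes": self.n_classes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(
            window_length=d.get("window_length", 402),
            stem=StageConfig(**d["stem"]),
            stages=tuple(StageConfig(**s) for s in d["stages"]),
            eca=ECAConfig(**d.get("eca", {})),
            n_classes=d.get("n_classes", 2),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def eca_kernel_size(channels: int, eca: ECAConfig = ECAConfig()) -> int:
    """Adaptive ECA kernel size: ``t = int((log2(C) + b) / gamma)`` rounded
    up to the nearest odd integer (minimum 1)."""
    if channels < 1:
        raise SpecError(f"channel count must be >= 1, got {channels}")
    t = int((math.log2(channels) + eca.b) / eca.gamma)
    k = t if t % 2 == 1 else t + 1
    return max(k, 1)


# ---------------------------------------------------------------------------
# Block builders
# ---------------------------------------------------------------------------

def build_eca_block(channels: int, eca: ECAConfig = ECAConfig(),
                    rng: np.random.Generator | None = None) -> nn.ECA:
    rng = rng if rng is not None else np.random.default_rng(0)
    return nn.ECA(channels, eca_kernel_size(channels, eca), rng)


def build_conv_block(stage: StageConfig, in_channels: int,
                     eca: ECAConfig, rng: np.random.Generator) -> nn.Residual:
    """Projecting residual block: BN-ReLU-Conv, pool(P), BN-ReLU-Conv, ECA on
    the residual branch; 1x1 conv + pool(P) on the shortcut."""
    n, k, p = stage.n, stage.k, stage.p
    residual = nn.Sequential([
        nn.BatchNorm(in_channels),
        nn.ReLU(),
        nn.Conv1D(in_channels, n, k, rng),
        nn.AvgPool(p),
        nn.BatchNorm(n),
        nn.ReLU(),
        nn.Conv1D(n, n, k, rng),
        build_eca_block(n, eca, rng),
    ])
    shortcut = nn.Sequential([
        nn.Conv1D(in_channels, n, 1, rng),
        nn.AvgPool(p),
    ])
    return nn.Residual(residual, shortcut)


def build_identity_block(stage: StageConfig, in_channels: int,
                         eca: ECAConfig, rng: np.random.Generator) -> nn.Residual:
    """Identity-shortcut residual block; requires matched channel counts."""
    if in_channels != stage.n:
        raise SpecError(
            f"IdentityBlock channel mismatch: input {in_channels} != N {stage.n}"
        )
    n, k = stage.n, stage.k
    residual = nn.Sequential([
        nn.BatchNorm(n),
        nn.ReLU(),
        nn.Conv1D(n, n, k, rng),
        nn.BatchNorm(n),
        nn.ReLU(),
        nn.Conv1D(n, n, k, rng),
        build_eca_block(n, eca, rng),
    ])
    return nn.Residual(residual, None)


class Network:
    """An instantiated network: forward logits, softmax probabilities and a
    full backward pass to the input (used by training, attribution and
    Grad-CAM alike)."""

    def __init__(self, spec: NetworkSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        eca = spec.eca
        layers: list[nn.Layer] = [
            nn.Conv1D(4, spec.stem.n, spec.stem.k, rng),
            nn.BatchNorm(spec.stem.n),
            nn.ReLU(),
        ]
        cin = spec.stem.n
        for i, stage in enumerate(spec.stages):
            try:
                layers.append(build_conv_block(stage, cin, eca, rng))
                layers.append(build_identity_block(stage, stage.n, eca, rng))
            except (SpecError, ValueError) as exc:
                raise SpecError(f"stage {i + 2}: {exc}") from exc
            cin = stage.n
        layers.append(nn.GlobalAvgPool())
        layers.append(nn.Dense(cin, spec.n_classes, rng))
        self.body = nn.Sequential(layers)
        # the final convolutional layer (Grad-CAM target): last Conv1D in
        # the last identity block's residual branch
        self.final_conv = [l for l in self.body.layers() if isinstance(l, nn.Conv1D)][-1]

    # -- forward / backward -------------------------------------------------

    def logits(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        # float64 inputs are honoured (attribution accuracy); everything
        # else runs in float32
        X = np.asarray(X)
        if X.dtype != np.float64:
            X = X.astype(np.float32)
        return self.body.forward(X, training)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Softmax probabilities, rows summing to 1; column 0 is the
        splice-site class."""
        return nn.softmax(self.logits(X, training=False))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backpropagate a gradient w.r.t. the logits; returns the gradient
        w.r.t. the one-hot input of the preceding forward pass."""
        return self.body.backward(dlogits)

    def zero_grads(self) -> None:
        self.body.zero_grads()

    def input_gradient(self, X: np.ndarray, class_index: int = 0) -> np.ndarray:
        """d(logit[class_index]) / d(input), inference-mode BN."""
        out = self.logits(X, training=False)
        self.zero_grads()
        dlogits = np.zeros_like(out)
        dlogits[:, class_index] = 1.0
        return self.backward(dlogits)

    # -- weights ------------------------------------------------------------

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        state = []
        for layer in self.body.layers():
            d = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, nn.BatchNorm):
                d["moving_mean"] = layer.moving_mean.copy()
                d["moving_var"] = layer.moving_var.copy()
            state.append(d)
        return state

    def set_weights(self, state: list[dict[str, np.ndarray]]) -> None:
        layers = list(self.body.layers())
        if len(layers) != len(state):
            raise ValueError("weight state does not match network structure")
        for layer, d in zip(layers, state):
            for k in layer.params:
                layer.params[k] = d[k].copy()
            if isinstance(layer, nn.BatchNorm):
                layer.moving_mean = d["moving_mean"].copy()
                layer.moving_var = d["moving_var"].copy()

    def save_weights(self, path: str | Path) -> None:
        """Weights as an .npz archive with a JSON sidecar describing the spec."""
        path = Path(path)
        arrays = {}
        for i, d in enumerate(self.get_weights()):
            for k, v in d.items():
                arrays[f"{i}/{k}"] = v
        np.savez(path, **arrays)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump({"spec": self.spec.to_dict()}, fh, indent=2)

    @classmethod
    def load_weights(cls, path: str | Path) -> "Network":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            spec = NetworkSpec.from_dict(json.load(fh)["spec"])
        net = cls(spec)
        data = np.load(path if path.suffix == ".npz" else f"{path}.npz")
        state: list[dict[str, np.ndarray]] = [{} for _ in list(net.body.layers())]
        for key in data.files:
            i, name = key.split("/", 1)
            state[int(i)][name] = data[key]
        net.set_weights(state)
        return net


def build_network(spec: NetworkSpec, seed: int = 0) -> Network:
    """Instantiate the network described by ``spec`` with seeded weights."""
    return Network(spec, seed=seed)


# ---------------------------------------------------------------------------
# Analytic cost accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CostReport:
    """Parameter and forward-pass FLOP totals, with a per-layer breakdown."""

    params: int
    flops: int
    breakdown: tuple[tuple[str, int, int], ...]  # (layer, params, flops)

    @property
    def params_m(self) -> float:
        return round(self.params / 1e6, 2)

    @property
    def flops_g(self) -> float:
        return round(self.flops / 1e9, 2)

    def as_table(self) -> str:
        lines = [f"{'Layer':<28}{'Params':>12}{'FLOPs':>16}"]
        for name, p, f in self.breakdown:
            lines.append(f"{name:<28}{p:>12,}{f:>16,}")
        lines.append(f"{'total':<28}{self.params:>12,}{self.flops:>16,}")
        lines.append(f"Params (M): {self.params_m:.2f}    FLOPs (G): {self.flops_g:.2f}")
        return "\n".join(lines)


def stage_output_lengths(spec: NetworkSpec) -> list[int]:
    """Sequence length after the stem and after each residual stage
    (floor division by each stage's pooling window)."""
    lengths = [spec.window_length]
    L = spec.window_length
    for stage in spec.stages:
        L = L // stage.p
        lengths.append(L)
    return lengths


def cost_report(spec: NetworkSpec) -> CostReport:
    """Analytic parameter/FLOP accounting; a pure function of the spec.

    Conventions: conv parameters ``K*Cin*Cout + Cout`` (bias), dense
    ``Cin*Cout + Cout``, BN ``4*C``, ECA ``k``; FLOPs are
    ``2 * output_positions * K * Cin * Cout`` per convolution (the ECA
    channel convolution contributes ``2 * C * k``) plus ``2 * Cin * Cout``
    for the dense head. Pooling, BN and activations are excluded from FLOPs.
    """
    rows: list[tuple[str, int, int]] = []
    L = spec.window_length

    def conv(name: str, L_out: int, k: int, cin: int, cout: int) -> None:
        rows.append((name, k * cin * cout + cout, 2 * L_out * k * cin * cout))

    # stem: kernels span all 4 one-hot channels, 'same' padding
    conv("stem conv 7x4", L, spec.stem.k * 4, 1, spec.stem.n)
    rows.append(("stem BN", 4 * spec.stem.n, 0))

    cin = spec.stem.n
    for i, stage in enumerate(spec.stages, start=2):
        n, k, p = stage.n, stage.k, stage.p
        L_mid = L // p
        k_eca = eca_kernel_size(n, spec.eca)
        # ConvBlock residual branch
        rows.append((f"s{i} ConvBlock BN1", 4 * cin, 0))
        conv(f"s{i} ConvBlock conv1", L, k, cin, n)
        rows.append((f"s{i} ConvBlock BN2", 4 * n, 0))
        conv(f"s{i} ConvBlock conv2", L_mid, k, n, n)
        rows.append((f"s{i} ConvBlock ECA", k_eca, 2 * n * k_eca))
        # ConvBlock shortcut: 1x1 conv at the input length, then pooling
        conv(f"s{i} ConvBlock shortcut", L, 1, cin, n)
        # IdentityBlock at the pooled length
        rows.append((f"s{i} IdentityBlock BN1", 4 * n, 0))
        conv(f"s{i} IdentityBlock conv1", L_mid, k, n, n)
        rows.append((f"s{i} IdentityBlock BN2", 4 * n, 0))
        conv(f"s{i} IdentityBlock conv2", L_mid, k, n, n)
        rows.append((f"s{i} IdentityBlock ECA", k_eca, 2 * n * k_eca))
        L, cin = L_mid, n

    rows.append((
        "dense head",
        cin * spec.n_classes + spec.n_classes,
        2 * cin * spec.n_classes,
    ))
    total_p = sum(r[1] for r in rows)
    total_f = sum(r[2] for r in rows)
    return CostReport(params=total_p, flops=total_f, breakdown=tuple(rows))
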