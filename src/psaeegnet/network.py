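"""PSAEEGNet: a compact four-stage CNN for single-trial P300 detection.

Stage 1 (PTFE, primary temporal feature extraction): a bank of F1 temporal
convolutions (kernel 1 x 125 at 250 Hz, i.e. half a second) applied to the
raw 62 x 250 epoch, followed by batch normalisation.

Stage 2 (PSFE, primary spatial feature extraction): a depthwise spatial
convolution with a full-height 62 x 1 kernel and depth multiplier D (so
F2 = F1 * D spatial filters), batch norm + ELU, an optional pyramid squeeze
attention block (kernels 3/5/7/9) bracketed by a second batch norm + ELU,
average pooling (1, 8) down to 31 time steps, and dropout.

Stage 3 (DTFE, deep temporal feature extraction): a separable convolution -
depthwise 1 x 16 then an optional PSA block (kernels 1/3/5/7 in the default
final model) then a pointwise 1 x 1 mixing convolution - with batch norm,
ELU, a second (1, 8) average pool down to 4 time steps, and dropout.

Stage 4: flatten (16 * 4 = 64 features) and a two-unit affine classifier
with softmax, emitting target / non-target probabilities.

Pooling conventions follow the reference layer table: the first pool
truncates (250 -> 31), the second right-pads its final window minimally
(31 -> 4) so the flattened classifier input is 64. ``pool_out_lengths``
makes both explicit and overridable. All convolutions are bias-free (batch
norm absorbs offsets); the classifier keeps its bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _nn
from ._nn import (AvgPoolTime, BatchNorm2d, Dropout, ELU, Flatten, Linear,
                  Sequential, Softmax, SpatialDepthwiseConv, TemporalConv)
from .attention import PSAConfig, PyramidSqueezeAttention
from .preprocessing import EpochSet

#: the five pyramid kernel sets swept for the second PSA block
KERNEL_SETS: dict[str, tuple[int, ...]] = {
    "A": (3, 5, 7, 9),
    "B": (1, 3, 5, 7),
    "C": (5, 7, 9, 11),
    "D": (7, 9, 11, 13),
    "E": (9, 11, 13, 15),
}

VARIANT_NAMES = ("A+A", "A+0", "0+A", "EEGNet")


@dataclass
class NetworkConfig:
    n_channels: int = 62
    n_samples: int = 250
    temporal_filters: int = 8          # F1
    temporal_kernel: int = 125
    depth_multiplier: int = 2          # D; F2 = F1 * D
    separable_kernel: int = 16
    pool_size: int = 8
    pool_out_lengths: tuple[int, int] | None = None
    dropout_p: float = 0.5
    psa_psfe: PSAConfig | None = field(default_factory=lambda: PSAConfig((3, 5, 7, 9)))
    psa_dtfe: PSAConfig | None = field(default_factory=lambda: PSAConfig((1, 3, 5, 7)))
    n_classes: int = 2

    @property
    def f2(self) -> int:
        return self.temporal_filters * self.depth_multiplier

    def pools(self) -> tuple[int, int]:
        """Output lengths of the two average pools (truncate, then ceil)."""
        if self.pool_out_lengths is not None:
            return tuple(self.pool_out_lengths)
        p1 = self.n_samples // self.pool_size
        p2 = math.ceil(p1 / self.pool_size)
        return p1, p2

    @property
    def n_features(self) -> int:
        return self.f2 * self.pools()[1]

    def validate(self) -> None:
        if self.n_channels < 1 or self.n_samples < 1:
            raise ValueError("epoch dimensions must be positive")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.temporal_filters < 1 or self.depth_multiplier < 1:
            raise ValueError("filter counts must be >= 1")
        p1, p2 = self.pools()
        if p1 < 1 or p2 < 1 or p1 > self.n_samples or (p2 - 1) * self.pool_size >= p1:
            raise ValueError(f"pool output lengths ({p1}, {p2}) are inconsistent "
                             f"with n_samples={self.n_samples}, pool={self.pool_size}")
        if self.psa_psfe is not None:
            self.psa_psfe.validate(self.f2)
        if self.psa_dtfe is not None:
            self.psa_dtfe.validate(self.f2)
        if self.n_classes != 2:
            raise ValueError("the classifier is binary (target / non-target)")


@dataclass
class AblationSpec:
    """One ablation variant: which PSA blocks exist and the second block's
    pyramid kernel set (letter key into KERNEL_SETS)."""

    name: str = "A+A"
    second_psa_kernels: str = "A"

    def validate(self) -> None:
        if self.name not in VARIANT_NAMES:
            raise ValueError(f"variant must be one of {VARIANT_NAMES}")
        if self.second_psa_kernels not in KERNEL_SETS:
            raise ValueError(f"kernel set must be one of {sorted(KERNEL_SETS)}")

    @property
    def label(self) -> str:
        if self.name == "A+A" and self.second_psa_kernels != "A":
            return f"A+{self.second_psa_kernels}"
        return self.name


def variant_config(base: NetworkConfig, spec: AblationSpec) -> NetworkConfig:
    """Derive a variant configuration from a base one."""
    spec.validate()
    psfe = PSAConfig((3, 5, 7, 9))
    dtfe = PSAConfig(KERNEL_SETS[spec.second_psa_kernels])
    if spec.name == "A+A":
        return replace(base, psa_psfe=psfe, psa_dtfe=dtfe)
    if spec.name == "A+0":
        return replace(base, psa_psfe=psfe, psa_dtfe=None)
    if spec.name == "0+A":
        return replace(base, psa_psfe=None, psa_dtfe=dtfe)
    return replace(base, psa_psfe=None, psa_dtfe=None)  # EEGNet control


class Network:
    """A built PSAEEGNet with forward/backward and (de)serialisable state."""

    def __init__(self, config: NetworkConfig, seed: int | None = 0,
                 dtype=np.float32):
        config.validate()
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        c = config
        p1, p2 = c.pools()
        layers: list[tuple[str, _nn.Layer]] = [
            ("temporal_conv", TemporalConv(1, c.temporal_filters, c.temporal_kernel,
                                           padding="same", rng=rng, dtype=dtype)),
            ("bn1", BatchNorm2d(c.temporal_filters, dtype=dtype)),
            ("spatial_depthwise", SpatialDepthwiseConv(c.temporal_filters,
                                                       c.n_channels,
                                                       c.depth_multiplier,
                                                       rng=rng, dtype=dtype)),
            ("bn2", BatchNorm2d(c.f2, dtype=dtype)),
            ("elu1", ELU()),
        ]
        if c.psa_psfe is not None:
            layers += [
                ("psa_psfe", PyramidSqueezeAttention(c.f2, c.psa_psfe, rng=rng,
                                                     dtype=dtype)),
                ("bn3", BatchNorm2d(c.f2, dtype=dtype)),
                ("elu2", ELU()),
            ]
        layers += [
            ("pool1", AvgPoolTime(c.pool_size, p1)),
            ("drop1", Dropout(c.dropout_p)),
            ("separable_depthwise", TemporalConv(c.f2, c.f2, c.separable_kernel,
                                                 groups=c.f2, padding="same",
                                                 rng=rng, dtype=dtype)),
        ]
        if c.psa_dtfe is not None:
            layers.append(("psa_dtfe", PyramidSqueezeAttention(c.f2, c.psa_dtfe,
                                                               rng=rng, dtype=dtype)))
        layers += [
            ("pointwise_conv", TemporalConv(c.f2, c.f2, 1, padding="same",
                                            rng=rng, dtype=dtype)),
            ("bn4", BatchNorm2d(c.f2, dtype=dtype)),
            ("elu3", ELU()),
            ("pool2", AvgPoolTime(c.pool_size, p2)),
            ("drop2", Dropout(c.dropout_p)),
            ("flatten", Flatten()),
            ("classifier", Linear(c.n_features, c.n_classes, bias=True,
                                  rng=rng, dtype=dtype)),
            ("softmax", Softmax()),
        ]
        self.net = Sequential(layers)

    # ---- data plumbing ---------------------------------------------------
    def _as_input(self, epochs) -> np.ndarray:
        x = epochs.epochs if isinstance(epochs, EpochSet) else np.asarray(epochs)
        if x.ndim == 2:
            x = x[None]
        c = self.config
        if x.ndim != 3 or x.shape[1] != c.n_channels or x.shape[2] != c.n_samples:
            raise ValueError(
                f"expected epochs shaped (trials, {c.n_channels}, {c.n_samples}), "
                f"got {x.shape}")
        return x.reshape(x.shape[0], 1, c.n_channels, c.n_samples).astype(
            self.dtype, copy=False)

    def forward(self, epochs, mode: str = "eval",
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Class probability matrix (trials, 2); column 1 is the target class."""
        if mode not in ("train", "eval"):
            raise ValueError("mode must be 'train' or 'eval'")
        return self.net.forward(self._as_input(epochs), training=(mode == "train"),
                                rng=rng)

    def backward(self, dprobs: np.ndarray) -> np.ndarray:
        return self.net.backward(dprobs)

    def predict_proba(self, epochs, batch_size: int = 64) -> np.ndarray:
        """Deterministic eval-mode scores, computed in batches."""
        x = self._as_input(epochs)
        out = [self.net.forward(x[i:i + batch_size], training=False)
               for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(out, axis=0)

    def stage_outputs(self, epochs) -> list[tuple[str, np.ndarray]]:
        """Forward pass recording every layer's output (eval mode)."""
        x = self._as_input(epochs)
        outs = [("reshape", x)]
        for name, layer in self.net.layers:
            x = layer.forward(x, training=False)
            outs.append((name, x))
        return outs

    # ---- bookkeeping -----------------------------------------------------
    def named_params(self) -> dict[str, np.ndarray]:
        return dict(self.net.named_params(""))

    def parameter_count(self) -> int:
        return int(sum(v.size for v in self.named_params().values()))

    def get_state(self) -> dict:
        return _nn.get_state(self.net)

    def set_state(self, state: dict) -> None:
        _nn.set_state(self.net, state)


def build(config: NetworkConfig | None = None, seed: int | None = 0,
          dtype=np.float32) -> Network:
    """Construct a PSAEEGNet from a configuration (validated first)."""
    return Network(config or NetworkConfig(), seed=seed, dtype=dtype)


def stage_shapes(config: NetworkConfig | None = None) -> list[tuple[str, tuple]]:
    """Symbolic layer-by-layer output shapes, without running any data.

    Shapes are per trial, (channels, height, width) for feature maps and
    (n,) for vectors; reproduces the reference layer table for the default
    configuration.
    """
    c = config or NetworkConfig()
    c.validate()
    p1, p2 = c.pools()
    rows: list[tuple[str, tuple]] = [
        ("input", (c.n_channels, c.n_samples)),
        ("reshape", (1, c.n_channels, c.n_samples)),
        ("temporal_conv", (c.temporal_filters, c.n_channels, c.n_samples)),
        ("bn1", (c.temporal_filters, c.n_channels, c.n_samples)),
        ("spatial_depthwise", (c.f2, 1, c.n_samples)),
        ("bn2", (c.f2, 1, c.n_samples)),
        ("elu1", (c.f2, 1, c.n_samples)),
    ]
    if c.psa_psfe is not None:
        rows += [("psa_psfe", (c.f2, 1, c.n_samples)),
                 ("bn3", (c.f2, 1, c.n_samples)),
                 ("elu2", (c.f2, 1, c.n_samples))]
    rows += [("pool1", (c.f2, 1, p1)),
             ("drop1", (c.f2, 1, p1)),
             ("separable_depthwise", (c.f2, 1, p1))]
    if c.psa_dtfe is not None:
        rows.append(("psa_dtfe", (c.f2, 1, p1)))
    rows += [
        ("pointwise_conv", (c.f2, 1, p1)),
        ("bn4", (c.f2, 1, p1)),
        ("elu3", (c.f2, 1, p1)),
        ("pool2", (c.f2, 1, p2)),
        ("drop2", (c.f2, 1, p2)),
        ("flatten", (c.n_features,)),
        ("classifier", (c.n_classes,)),
        ("softmax", (c.n_classes,)),
    ]
    return rows
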