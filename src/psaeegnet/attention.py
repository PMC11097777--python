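"""Pyramid squeeze attention (PSA) for temporal feature maps.

The block recalibrates a (batch, C, H, W) feature map in four steps:

1. *Squeeze and concat* — the C channels are split into S contiguous groups
   and each group is convolved along time with its own kernel size, so each
   branch sees the signal at a different temporal scale.
2. *Squeeze-and-excitation* — each branch is summarised by global average
   pooling and passed through a two-layer bottleneck (rectifier between,
   logistic output) to produce a per-channel attention logit in (0, 1).
3. *Cross-branch softmax* — for every channel slot the S branch logits are
   normalised with a softmax, so the scales compete for weight.
4. *Recalibration* — each branch's feature map is multiplied elementwise by
   its normalised weights and the branches are concatenated back to C
   channels. Output shape always equals input shape.

An optional full-channel variant lets every branch read all C input
channels (while still emitting C/S); the split variant is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Layer, Linear, ReLU, Sigmoid, TemporalConv


def cross_branch_softmax(z: np.ndarray) -> np.ndarray:
    """Softmax across the branch axis (axis 1) of a (B, S, C/S) array.

    Computed with max subtraction for stability; for every (batch, channel
    slot) the S weights sum to one.
    """
    z = np.asarray(z)
    m = z.max(axis=1, keepdims=True)
    e = np.exp(z - m)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class PSAConfig:
    """Architectural parameters of one PSA block.

    kernel_sizes are temporal extents (1 x k kernels), one per branch;
    se_hidden defaults to max((C/S) // 4, 1); branch_groups is the group
    count of each branch convolution (1 = plain convolution);
    split_channels=False gives every branch the full C input channels.
    """

    kernel_sizes: tuple[int, ...] = (3, 5, 7, 9)
    se_hidden: int | None = None
    branch_groups: int = 1
    split_channels: bool = True

    def validate(self, n_channels: int) -> None:
        s = len(self.kernel_sizes)
        if s < 1:
            raise ValueError("PSA needs at least one branch")
        if n_channels % s:
            raise ValueError(
                f"channel count {n_channels} not divisible by {s} branches")
        for k in self.kernel_sizes:
            if k < 1 or k % 2 == 0:
                raise ValueError(f"branch kernel sizes must be odd and >= 1, got {k}")
        if self.se_hidden is not None and self.se_hidden < 1:
            raise ValueError("se_hidden must be >= 1")


class PyramidSqueezeAttention(Layer):
    """PSA block as a differentiable layer (see module docstring)."""

    def __init__(self, n_channels: int, config: PSAConfig | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.config = config or PSAConfig()
        self.config.validate(n_channels)
        self.C = n_channels
        self.S = len(self.config.kernel_sizes)
        self.Cb = n_channels // self.S
        self.hidden = (self.config.se_hidden if self.config.se_hidden is not None
                       else max(self.Cb // 4, 1))
        rng = rng or np.random.default_rng()
        in_ch = self.Cb if self.config.split_channels else self.C
        self.convs = [TemporalConv(in_ch, self.Cb, k,
                                   groups=self.config.branch_groups,
                                   padding="same", rng=rng, dtype=dtype)
                      for k in self.config.kernel_sizes]
        self.fc1 = [Linear(self.Cb, self.hidden, rng=rng, dtype=dtype)
                    for _ in range(self.S)]
        self.relu = [ReLU() for _ in range(self.S)]
        self.fc2 = [Linear(self.hidden, self.Cb, rng=rng, dtype=dtype)
                    for _ in range(self.S)]
        self.sig = [Sigmoid() for _ in range(self.S)]
        self._cache = None

    # ---- the four steps, individually callable --------------------------
    def squeeze_concat(self, x: np.ndarray) -> list[np.ndarray]:
        """Step 1: per-branch multi-scale convolution of the channel groups."""
        if x.shape[1] != self.C:
            raise ValueError(f"expected {self.C} channels, got {x.shape[1]}")
        branches = []
        for i, conv in enumerate(self.convs):
            xin = (x[:, i * self.Cb:(i + 1) * self.Cb]
                   if self.config.split_channels else x)
            branches.append(conv.forward(xin))
        return branches

    def se_logits(self, branch: np.ndarray, i: int) -> np.ndarray:
        """Step 2 for branch i: pooled bottleneck attention in (0, 1)."""
        g = branch.mean(axis=(2, 3))
        h = self.relu[i].forward(self.fc1[i].forward(g))
        return self.sig[i].forward(self.fc2[i].forward(h))

    def forward(self, x, training=False, rng=None):
        branches = self.squeeze_concat(x)
        z = np.stack([self.se_logits(b, i) for i, b in enumerate(branches)], axis=1)
        w = cross_branch_softmax(z)  # (B, S, Cb)
        out = np.concatenate(
            [branches[i] * w[:, i][:, :, None, None] for i in range(self.S)], axis=1)
        self._cache = (x.shape, branches, w)
        return out

    def backward(self, dy):
        xshape, branches, w = self._cache
        B = dy.shape[0]
        hw = branches[0].shape[2] * branches[0].shape[3]
        dz = np.empty((B, self.S, self.Cb), dtype=dy.dtype)
        dbranch_mul = []
        dw = np.empty_like(dz)
        for i in range(self.S):
            dyi = dy[:, i * self.Cb:(i + 1) * self.Cb]
            dbranch_mul.append(dyi * w[:, i][:, :, None, None])
            dw[:, i] = (dyi * branches[i]).sum(axis=(2, 3))
        # softmax jacobian across the branch axis
        dz = w * (dw - (dw * w).sum(axis=1, keepdims=True))
        dx_parts = []
        dx_full = None
        for i in range(self.S):
            ds = self.sig[i].backward(dz[:, i])
            dh = self.relu[i].backward(self.fc2[i].backward(ds))
            dg = self.fc1[i].backward(dh)
            dbranch = dbranch_mul[i] + dg[:, :, None, None] / hw
            dxi = self.convs[i].backward(dbranch)
            if self.config.split_channels:
                dx_parts.append(dxi)
            else:
                dx_full = dxi if dx_full is None else dx_full + dxi
        return np.concatenate(dx_parts, axis=1) if self.config.split_channels else dx_full

    def named_params(self, prefix: str):
        for i in range(self.S):
            p = f"{prefix}.branch{i}" if prefix else f"branch{i}"
            yield from self.convs[i].named_params(f"{p}.conv")
            yield from self.fc1[i].named_params(f"{p}.fc1")
            yield from self.fc2[i].named_params(f"{p}.fc2")

    def named_grads(self, prefix: str):
        for i in range(self.S):
            p = f"{prefix}.branch{i}" if prefix else f"branch{i}"
            yield from self.convs[i].named_grads(f"{p}.conv")
            yield from self.fc1[i].named_grads(f"{p}.fc1")
            yield from self.fc2[i].named_grads(f"{p}.fc2")


# -- functional views used by tests and docs ------------------------------

def squeeze_concat(psa: PyramidSqueezeAttention, x: np.ndarray) -> list[np.ndarray]:
    return psa.squeeze_concat(x)


def se_weight(psa: PyramidSqueezeAttention, branch: np.ndarray, i: int) -> np.ndarray:
    return psa.se_logits(branch, i)


def psa_forward(psa: PyramidSqueezeAttention, x: np.ndarray) -> np.ndarray:
    return psa.forward(x)
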