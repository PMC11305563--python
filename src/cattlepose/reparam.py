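"""Structural reparameterization (RepVGG-style).

During training a unit runs three parallel branches -- a dense 3x3 conv + BN,
a pointwise 1x1 conv + BN, and (when shapes permit) an identity BN branch --
summed before a ReLU.  For inference the branches collapse algebraically into
a single 3x3 convolution with bias that is forward-equivalent to the
multibranch form:

  * BN folding:     W' = W * gamma / sqrt(var + eps),
                    b' = beta - gamma * mean / sqrt(var + eps)
  * a 1x1 kernel embeds into a 3x3 kernel as its center tap
  * the identity branch is a Dirac (one-hot center) 3x3 kernel
  * parallel branches with identical geometry sum kernel-wise.

`RepBlock` stacks N such units (the first unit may change the channel count);
`reparameterize_network` fuses every unit of a model in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .nn import BatchNorm2d, Conv2d, Module, Parameter, ReLU, Tensor


class InvalidBNError(ValueError):
    """Batch-norm parameters are unusable (e.g. negative running variance)."""


class FusionStateError(RuntimeError):
    """Fusion requested in an invalid state (training mode / already fused)."""


@dataclass
class ConvKernel:
    """A plain convolution kernel: (out, in/groups, k, k) weights."""

    weights: np.ndarray
    stride: int = 1
    padding: int = 0
    groups: int = 1

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 4 or self.weights.shape[2] != self.weights.shape[3]:
            raise ValueError("kernel must be (out, in/groups, k, k)")

    @property
    def k(self) -> int:
        return self.weights.shape[2]

    @property
    def out_channels(self) -> int:
        return self.weights.shape[0]


@dataclass
class BNParams:
    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray
    eps: float = 1e-3

    def __post_init__(self):
        for name in ("gamma", "beta", "running_mean", "running_var"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if np.any(self.running_var < 0):
            raise InvalidBNError("negative running variance")


def fuse_conv_bn(kernel: ConvKernel, bn: BNParams) -> tuple[ConvKernel, np.ndarray]:
    """Fold inference-mode batch normalization into the preceding convolution."""
    n = kernel.out_channels
    if not (len(bn.gamma) == len(bn.beta) == len(bn.running_mean)
            == len(bn.running_var) == n):
        raise InvalidBNError("BN vector length != out_channels")
    std = np.sqrt(bn.running_var + bn.eps)
    scale = bn.gamma / std
    weights = kernel.weights * scale[:, None, None, None]
    bias = bn.beta - bn.gamma * bn.running_mean / std
    return ConvKernel(weights, kernel.stride, kernel.padding, kernel.groups), bias


def embed_1x1_in_3x3(kernel: ConvKernel) -> ConvKernel:
    """Place a 1x1 kernel at the center tap of a zero 3x3 kernel."""
    if kernel.k != 1:
        raise ValueError("kernel must be 1x1")
    out, cin, _, _ = kernel.weights.shape
    weights = np.zeros((out, cin, 3, 3), dtype=np.float64)
    weights[:, :, 1, 1] = kernel.weights[:, :, 0, 0]
    return ConvKernel(weights, kernel.stride, padding=1, groups=kernel.groups)


def identity_as_3x3(channels: int, groups: int = 1) -> ConvKernel:
    """Dirac 3x3 kernel: convolution with it (stride 1, pad 1) is the identity."""
    if channels % groups:
        raise ValueError("channels not divisible by groups")
    cin_g = channels // groups
    weights = np.zeros((channels, cin_g, 3, 3), dtype=np.float64)
    for o in range(channels):
        weights[o, o % cin_g, 1, 1] = 1.0
    return ConvKernel(weights, stride=1, padding=1, groups=groups)


class RepVGGBlock(Module):
    """Trainable multibranch unit: 3x3+BN, 1x1+BN, optional identity BN; ReLU.

    The identity branch exists only when in_channels == out_channels and
    stride == 1.  ``fuse()`` converts the unit in place into a single 3x3
    convolution with bias; fusing twice or fusing in training mode raises
    :class:`FusionStateError`.
    """

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 groups: int = 1):
        super().__init__()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.stride, self.groups = stride, groups
        self.dense = Conv2d(in_channels, out_channels, 3, stride=stride,
                            padding=1, groups=groups, bias=False)
        self.dense_bn = BatchNorm2d(out_channels)
        self.pointwise = Conv2d(in_channels, out_channels, 1, stride=stride,
                                padding=0, groups=groups, bias=False)
        self.pointwise_bn = BatchNorm2d(out_channels)
        self.has_identity = in_channels == out_channels and stride == 1
        if self.has_identity:
            self.identity_bn = BatchNorm2d(out_channels)
        self.act = ReLU()
        self.fused: Optional[Conv2d] = None

    def forward(self, x: Tensor) -> Tensor:
        if self.fused is not None:
            return self.act(self.fused(x))
        y = self.dense_bn(self.dense(x)) + self.pointwise_bn(self.pointwise(x))
        if self.has_identity:
            y = y + self.identity_bn(x)
        return self.act(y)

    # -- fusion --------------------------------------------------------------
    def _bn_params(self, bn: BatchNorm2d) -> BNParams:
        return BNParams(bn.weight.data, bn.bias.data, bn.running_mean,
                        bn.running_var, bn.eps)

    def fused_kernel(self) -> tuple[np.ndarray, np.ndarray]:
        """Equivalent single 3x3 kernel and bias of the multibranch unit."""
        if self.fused is not None:
            raise FusionStateError("unit already fused")
        k3, b3 = fuse_conv_bn(
            ConvKernel(self.dense.weight.data, self.stride, 1, self.groups),
            self._bn_params(self.dense_bn))
        k1, b1 = fuse_conv_bn(
            ConvKernel(self.pointwise.weight.data, self.stride, 0, self.groups),
            self._bn_params(self.pointwise_bn))
        k1 = embed_1x1_in_3x3(k1)
        weights = k3.weights + k1.weights
        bias = b3 + b1
        if self.has_identity:
            kid, bid = fuse_conv_bn(identity_as_3x3(self.out_channels, self.groups),
                                    self._bn_params(self.identity_bn))
            weights = weights + kid.weights
            bias = bias + bid
        return weights, bias

    def fuse(self) -> "RepVGGBlock":
        """Collapse the branches into a single 3x3 convolution, in place."""
        if self.training:
            raise FusionStateError("fuse() requires inference mode")
        weights, bias = self.fused_kernel()
        conv = Conv2d(self.in_channels, self.out_channels, 3, stride=self.stride,
                      padding=1, groups=self.groups, bias=True)
        conv.weight = Parameter(weights.astype(np.float32))
        conv.bias = Parameter(bias.astype(np.float32))
        self.fused = conv
        # drop the branch parameters from the module tree
        for name in ("dense", "dense_bn", "pointwise", "pointwise_bn",
                     "identity_bn"):
            self._modules.pop(name, None)
        self._modules["fused"] = conv
        conv.train(self.training)
        return self


class RepBlock(Module):
    """A stack of ``n`` RepVGG units; the first may change the channel count."""

    def __init__(self, in_channels: int, out_channels: int, n: int = 1):
        super().__init__()
        from .nn import Sequential
        units = [RepVGGBlock(in_channels, out_channels)]
        units += [RepVGGBlock(out_channels, out_channels) for _ in range(n - 1)]
        self.units = Sequential(*units)

    def forward(self, x):
        return self.units(x)


def reparameterize_network(model: Module) -> Module:
    """Fuse every RepVGG unit of ``model`` in place.

    The model must be in inference mode; a second invocation (no unfused unit
    left while fused ones exist) raises :class:`FusionStateError`.
    """
    if getattr(model, "training", False):
        raise FusionStateError("model must be in inference mode")
    unfused = [m for m in model.modules()
               if isinstance(m, RepVGGBlock) and m.fused is None]
    fused = [m for m in model.modules()
             if isinstance(m, RepVGGBlock) and m.fused is not None]
    if not unfused and fused:
        raise FusionStateError("network already reparameterized")
    for m in unfused:
        m.fuse()
    return model
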