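"""Parameter-free SimAM attention.

Each neuron t of a feature map X in R^{C x H x W} is scored by a closed-form
energy derived from its linear separability from the other neurons of the same
channel.  With the channel mean eps and population variance sigma^2 over the
M = H*W neurons and a regularizer omega, the minimal energy is

    e_t = 4 (sigma^2 + omega) / ((t - eps)^2 + 2 sigma^2 + 2 omega)

and the importance of the neuron is its inverse,

    1/e_t = (t - eps)^2 / (4 (sigma^2 + omega)) + 1/2 ,

so every neuron scores at least 1/2 and neurons far from the channel mean score
higher.  The refined map is X * sigmoid(1/E): a 3-D (per-neuron) re-weighting
with zero learnable parameters.

Statistics are pooled over all M neurons of a channel of a single sample,
never across a batch.  Channels with a single neuron have no variance and are
rejected as degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Module, Tensor
from .nn import autograd as ag


class DegenerateChannelError(ValueError):
    """Raised when a channel holds fewer than two neurons (variance undefined)."""


@dataclass(frozen=True)
class SimAMConfig:
    """Configuration of the attention operator.

    omega: positive regularization coefficient added to the channel variance
    (default 1e-4).
    """

    omega: float = 1e-4

    def __post_init__(self):
        if not self.omega > 0:
            raise ValueError("omega must be > 0")


def _check_map(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 3:
        raise ValueError("activation map must be C x H x W")
    if not np.all(np.isfinite(values)):
        raise ValueError("activation map must be finite")
    if values.shape[1] * values.shape[2] < 2:
        raise DegenerateChannelError(
            "channel needs at least 2 neurons for variance")
    return values


def channel_statistics(values: np.ndarray, channel_index: int) -> tuple[float, float]:
    """Mean and population variance (divisor M) of one channel of a C x H x W map."""
    values = _check_map(values)
    chan = values[channel_index]
    mean = float(chan.mean())
    var = float(((chan - mean) ** 2).mean())
    return mean, var


def simam_importance(values: np.ndarray, config: SimAMConfig = SimAMConfig()) -> np.ndarray:
    """Per-neuron importance 1/e_t for a C x H x W map; every entry >= 1/2."""
    values = _check_map(values)
    mean = values.mean(axis=(1, 2), keepdims=True)
    var = ((values - mean) ** 2).mean(axis=(1, 2), keepdims=True)
    return (values - mean) ** 2 / (4.0 * (var + config.omega)) + 0.5


def simam_refine(values: np.ndarray, config: SimAMConfig = SimAMConfig()) -> np.ndarray:
    """Refined map X * sigmoid(1/E); shape preserved, zero parameters."""
    imp = simam_importance(values, config)
    return np.asarray(values, dtype=np.float64) / (1.0 + np.exp(-imp))


class SimAM(Module):
    """In-network SimAM operator on batched NCHW tensors (autograd-aware)."""

    def __init__(self, omega: float = 1e-4):
        super().__init__()
        if not omega > 0:
            raise ValueError("omega must be > 0")
        self.omega = omega

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        m = h * w
        if m < 2:
            raise DegenerateChannelError(
                "channel needs at least 2 neurons for variance")
        mu = ag.mean(x, axis=(2, 3), keepdims=True)
        d = x - mu
        var = ag.mean(d * d, axis=(2, 3), keepdims=True)
        importance = (d * d) / ((var + self.omega) * 4.0) + 0.5
        return x * ag.sigmoid(importance)
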