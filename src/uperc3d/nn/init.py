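"""Weight-initialization schemes for convolutional layers.

Five named schemes are supported.  The fan-based Kaiming/Xavier variants use
their standard definitions (ReLU gain sqrt(2) for Kaiming; zero biases).  The
``default_uniform`` scheme draws weights *and* biases from U(-k, k) with

    k = (C_in * prod_i K_i)^{-1}

i.e. the reciprocal of the fan-in, taken literally; set
``legacy_sqrt_bound=True`` for the conventional reciprocal square root
(k = fan_in^{-1/2}) instead.
"""

from __future__ import annotations

import math

import numpy as np

from .modules import Conv3d, Module

INIT_METHODS = (
    "kaiming_uniform", "kaiming_normal",
    "xavier_uniform", "xavier_normal",
    "default_uniform",
)

__all__ = ["INIT_METHODS", "init_conv", "init_module"]


def _fans(conv: Conv3d) -> tuple[int, int]:
    rf = int(np.prod(conv.kernel_size))
    return conv.in_channels * rf, conv.out_channels * rf


def init_conv(conv: Conv3d, method: str, rng: np.random.Generator,
              legacy_sqrt_bound: bool = False) -> None:
    if method not in INIT_METHODS:
        raise ValueError(
            f"unknown init method {method!r}; valid methods: {', '.join(INIT_METHODS)}")
    fan_in, fan_out = _fans(conv)
    wshape = conv.weight.shape
    if method == "kaiming_uniform":
        bound = math.sqrt(6.0 / fan_in)
        w = rng.uniform(-bound, bound, size=wshape)
    elif method == "kaiming_normal":
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=wshape)
    elif method == "xavier_uniform":
        bound = math.sqrt(6.0 / (fan_in + fan_out))
        w = rng.uniform(-bound, bound, size=wshape)
    elif method == "xavier_normal":
        w = rng.normal(0.0, math.sqrt(2.0 / (fan_in + fan_out)), size=wshape)
    else:  # default_uniform
        k = 1.0 / math.sqrt(fan_in) if legacy_sqrt_bound else 1.0 / fan_in
        w = rng.uniform(-k, k, size=wshape)
        if conv.bias is not None:
            conv.bias.data = rng.uniform(-k, k, size=conv.bias.shape).astype(np.float32)
    conv.weight.data = w.astype(np.float32)
    if method != "default_uniform" and conv.bias is not None:
        conv.bias.data = np.zeros(conv.bias.shape, dtype=np.float32)


def init_module(module: Module, method: str, seed: int,
                legacy_sqrt_bound: bool = False) -> Module:
    """Re-initialize every Conv3d in ``module`` (traversal order), deterministically."""
    rng = np.random.default_rng(seed)
    stack = [module]
    while stack:
        m = stack.pop(0)
        if isinstance(m, Conv3d):
            init_conv(m, method, rng, legacy_sqrt_bound)
        stack.extend(child for _, child in m.children())
    return module
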