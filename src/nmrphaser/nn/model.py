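"""Tandem phase-error classifier: CNN front end + vision transformer.

Two instances of the same architecture are trained independently — one to
classify the sign of the zeroth-order phase error (PH0), one for the
first-order error (PH1).  The CNN captures local lineshape features (the
asymmetry "dip" next to an imperfectly phased peak) while reducing the
sequence length by ``downsample_factor``; the transformer then correlates
those features across the full spectral width, which is what makes small
and first-order errors detectable.  A relative positional bias keeps the
attention translation invariant, and global average pooling over tokens
lets one set of weights process spectra of any length up to
``max_field_of_view`` points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import List, Optional

import numpy as np

from ..spectrum import Spectrum1D
from .layers import (
    Conv1d,
    Layer,
    LayerNorm,
    Linear,
    ReLU,
    TransformerBlock,
    relative_bucket_index,
    softmax,
)

__all__ = [
    "NetConfig",
    "PhaseClassifier",
    "build_model",
    "preprocess_input",
    "relative_position_bias",
]

#: Fixed output class order.
CLASS_ORDER = ("negative", "zero", "positive")


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters (scaled-down defaults).

    ``downsample_factor`` is the points-per-token reduction of the CNN
    stack; ``max_field_of_view / downsample_factor`` is the maximum token
    count the transformer ever sees.  The published parameter count of the
    original model is not reproduced — layer internals are unpublished —
    but the architecture family is the same.
    """

    downsample_factor: int = 32
    embed_dim: int = 64
    n_layers: int = 4
    n_heads: int = 4
    rel_bias_buckets: int = 32
    max_field_of_view: int = 131072
    n_classes: int = 3
    dropout: float = 0.1
    ffn_mult: int = 4
    #: "mean" = plain global average pooling; "mean+moment" additionally
    #: feeds the first spatial moment of the tokens (ramp-weighted mean) to
    #: the head — the natural summary statistic for a phase error that
    #: varies linearly across the spectrum.
    pooling: str = "mean"
    conv_channels: tuple = (16, 32, 48, 64)
    conv_kernels: tuple = (7, 5, 5, 5)
    conv_strides: tuple = (4, 2, 2, 2)
    in_channels: int = 2  # real + imaginary; set 1 for real-only ablation
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_classes != 3:
            raise ValueError("the classifier is strictly 3-class")
        if int(np.prod(self.conv_strides)) != self.downsample_factor:
            raise ValueError("product of conv_strides must equal downsample_factor")
        if self.conv_channels[-1] != self.embed_dim:
            raise ValueError("last conv channel count must equal embed_dim")
        if len(self.conv_channels) != len(self.conv_kernels) or len(
            self.conv_channels
        ) != len(self.conv_strides):
            raise ValueError("conv_channels/kernels/strides lengths must match")
        if self.max_field_of_view % self.downsample_factor:
            raise ValueError("max_field_of_view must be divisible by downsample_factor")
        if self.pooling not in ("mean", "mean+moment"):
            raise ValueError("pooling must be 'mean' or 'mean+moment'")

    @property
    def max_tokens(self) -> int:
        return self.max_field_of_view // self.downsample_factor

    def np_dtype(self):
        return np.dtype(self.dtype)


def preprocess_input(spec: Spectrum1D, cfg: Optional[NetConfig] = None) -> np.ndarray:
    """Spectrum -> (channels, N) network input.

    Two channels (real, imaginary), both divided by ``max |real|`` so the
    representation is invariant to uniform intensity scaling.  Rejects
    spectra longer than the transformer's maximum field of view and
    degenerate all-zero input.
    """
    cfg = cfg or NetConfig()
    n = len(spec)
    if n > cfg.max_field_of_view:
        raise ValueError(
            f"spectrum has {n} points, exceeding the maximum field of view "
            f"of {cfg.max_field_of_view}"
        )
    scale = float(np.max(np.abs(spec.real)))
    if scale == 0.0:
        raise ValueError("degenerate input: real part is identically zero")
    out = np.stack([spec.real, spec.imag])[: cfg.in_channels] / scale
    return out.astype(cfg.np_dtype())


def relative_position_bias(
    n_tokens: int, cfg: NetConfig, table: Optional[np.ndarray] = None
) -> np.ndarray:
    """(n_heads, T, T) additive attention-bias matrix.

    ``bias[h, i, j]`` depends only on the signed offset ``i - j`` through a
    per-head table of ``2 * rel_bias_buckets + 1`` learned scalars with
    log-spaced distance buckets.  With ``table=None`` a fresh zero table is
    used (the structure, not the values, is what this function defines).
    """
    if n_tokens < 1:
        raise ValueError("n_tokens must be >= 1")
    if table is None:
        table = np.zeros((2 * cfg.rel_bias_buckets + 1, cfg.n_heads))
    idx = relative_bucket_index(n_tokens, cfg.rel_bias_buckets, cfg.max_tokens)
    return table[idx].transpose(2, 0, 1)


class PhaseClassifier:
    """CNN + transformer + global-average-pooling 3-class model."""

    def __init__(self, cfg: NetConfig, seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        dt = cfg.np_dtype()
        self.conv_stack: List[Layer] = []
        c_prev = cfg.in_channels
        for c, k, s in zip(cfg.conv_channels, cfg.conv_kernels, cfg.conv_strides):
            self.conv_stack.append(Conv1d(c_prev, c, k, s, rng, dt))
            self.conv_stack.append(ReLU())
            c_prev = c
        self.token_norm = LayerNorm(cfg.embed_dim, dt)
        self.blocks = [
            TransformerBlock(
                cfg.embed_dim,
                cfg.n_heads,
                cfg.ffn_mult,
                cfg.rel_bias_buckets,
                cfg.max_tokens,
                rng,
                dt,
                dropout=cfg.dropout,
                seed=seed * 1000 + 2 * i,
            )
            for i in range(cfg.n_layers)
        ]
        self.final_norm = LayerNorm(cfg.embed_dim, dt)
        head_in = cfg.embed_dim * (2 if cfg.pooling == "mean+moment" else 1)
        self.head = Linear(head_in, cfg.n_classes, rng, dt)

    # -- plumbing ----------------------------------------------------------

    def layers(self) -> List[Layer]:
        out = list(self.conv_stack) + [self.token_norm]
        for b in self.blocks:
            out.extend(b.children())
        out += [self.final_norm, self.head]
        return out

    def parameters(self):
        """Flat (name, layer, key) list over all trainable arrays."""
        out = []
        for i, layer in enumerate(self.layers()):
            for key in layer.params:
                out.append((f"layer{i}.{key}", layer, key))
        return out

    def n_params(self) -> int:
        return sum(layer.params[k].size for _, layer, k in self.parameters())

    def zero_grad(self) -> None:
        for layer in self.layers():
            layer.zero_grad()

    def set_training(self, mode: bool) -> None:
        """Enable/disable dropout (inference is always deterministic)."""
        for block in self.blocks:
            for d in block.dropout_layers():
                d.training = mode

    def state_dict(self) -> dict:
        return {name: layer.params[k].copy() for name, layer, k in self.parameters()}

    def load_state_dict(self, state: dict) -> None:
        for name, layer, k in self.parameters():
            if name not in state:
                raise KeyError(f"checkpoint is missing parameter {name}")
            if state[name].shape != layer.params[k].shape:
                raise ValueError(
                    f"shape mismatch for {name}: checkpoint "
                    f"{state[name].shape} vs model {layer.params[k].shape}"
                )
            layer.params[k] = state[name].astype(layer.params[k].dtype)

    # -- forward / backward ------------------------------------------------

    def _pad_length(self, n: int) -> int:
        f = self.cfg.downsample_factor
        return ((n + f - 1) // f) * f

    def forward(self, x: np.ndarray, keep_attention: bool = False) -> np.ndarray:
        """(B, C, L) batch -> (B, 3) logits.

        Inputs whose length is not a multiple of the downsample factor are
        zero-padded on the right before the conv stack.
        """
        B, C, L = x.shape
        if L > self.cfg.max_field_of_view:
            raise ValueError(
                f"input length {L} exceeds the maximum field of view "
                f"{self.cfg.max_field_of_view}"
            )
        Lp = self._pad_length(L)
        if Lp != L:
            x = np.pad(x, ((0, 0), (0, 0), (0, Lp - L)))
        h = x
        for layer in self.conv_stack:
            h = layer.forward(h)
        tokens = h.transpose(0, 2, 1)  # (B, T, E)
        tokens = self.token_norm.forward(tokens)
        for block in self.blocks:
            tokens = block.forward(tokens, keep_attention)
        tokens = self.final_norm.forward(tokens)
        T = tokens.shape[1]
        self._n_tokens = T
        pooled = tokens.mean(axis=1)  # global average pooling
        if self.cfg.pooling == "mean+moment":
            ramp = np.linspace(-1.0, 1.0, T, dtype=tokens.dtype)
            self._ramp = ramp
            moment = (tokens * ramp[None, :, None]).mean(axis=1)
            pooled = np.concatenate([pooled, moment], axis=-1)
        return self.head.forward(pooled)

    def backward(self, g_logits: np.ndarray) -> None:
        g = self.head.backward(g_logits)
        T = self._n_tokens
        if self.cfg.pooling == "mean+moment":
            E = self.cfg.embed_dim
            g_mean, g_mom = g[:, :E], g[:, E:]
            g_tokens = (
                np.repeat(g_mean[:, None, :], T, axis=1)
                + g_mom[:, None, :] * self._ramp[None, :, None]
            ) / T
        else:
            g_tokens = np.repeat(g[:, None, :], T, axis=1) / T
        g_tokens = self.final_norm.backward(g_tokens)
        for block in reversed(self.blocks):
            g_tokens = block.backward(g_tokens)
        g_tokens = self.token_norm.backward(g_tokens)
        g_h = g_tokens.transpose(0, 2, 1)
        for layer in reversed(self.conv_stack):
            g_h = layer.backward(g_h)

    def attention_maps(self, x: np.ndarray) -> np.ndarray:
        """(n_layers, n_heads, T, T) row-stochastic attention for one input.

        ``x`` is a single preprocessed spectrum, shape (C, L).
        """
        self.forward(x[None], keep_attention=True)
        return np.stack([b.attn.last_attention[0] for b in self.blocks])


def default_net_config(task: str) -> NetConfig:
    """Per-task default architecture.

    Both tasks share the CNN/transformer trunk; the first-order classifier
    additionally feeds the first spatial moment of the tokens to the head
    ("mean+moment" pooling), since a first-order phase error is a linear
    trend across the spectrum that plain token averaging cancels out.
    """
    if task not in ("ph0", "ph1"):
        raise ValueError("task must be 'ph0' or 'ph1'")
    if task == "ph1":
        return NetConfig(pooling="mean+moment")
    return NetConfig()


def build_model(cfg: Optional[NetConfig] = None, seed: int = 0,
                verbose: bool = True) -> PhaseClassifier:
    """Construct a classifier and log its trainable-parameter count."""
    cfg = cfg or NetConfig()
    model = PhaseClassifier(cfg, seed=seed)
    n = model.n_params()
    if verbose:
        import logging

        logging.getLogger(__name__).info(
            "built PhaseClassifier with %d trainable parameters", n
        )
    return model
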