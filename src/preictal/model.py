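"""Conv + CBAM + dual-GRU seizure-prediction network.

The classifier takes one 30-s multichannel EEG spectrogram — a
``(n_eeg_channels, 59, 114)`` magnitude STFT tensor — and outputs the
probability that the window is preictal. Architecture:

1. Three convolutional blocks (batch norm → valid conv → ReLU → 2×2 max pool):
   16 kernels of ``n×5×5`` at stride 2×2, then 32 and 64 kernels of 3×3 at
   stride 1. A 59×114 input reduces to a 64×2×5 feature map.
2. A convolutional block attention module (CBAM): channel attention (shared
   two-layer MLP over global max- and average-pooled descriptors, reduction 4)
   followed by spatial attention (1×1 conv over stacked channel-wise max/avg
   maps). Ablation variants can apply either half alone, swap the order, or
   skip attention entirely.
3. The 64×2×5 map read as a sequence of T=2 time steps of 320 features, into a
   256-unit GRU (all states) → dropout → 64-unit sigmoid dense per step →
   128-unit GRU (last state) → dropout → 2-unit dense → softmax.

The GRU gate equations follow the exact arithmetic this architecture was
defined with: the reset gate multiplies *after* the recurrent product
(``(h·W_hh) ⊙ r``) and the update gate weights the candidate state
(``h_t = (1-u)·h_{t-1} + u·h̃``). A ``standard_gru`` flag switches to the
conventional formulation for comparison.

All trainable arithmetic runs on the in-package autodiff engine; the functional
single-sample operations here are the public forward API, and
:mod:`preictal.reference` holds independent loop-based oracles for each of them.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import h5py
import numpy as np
import yaml

from . import autodiff as ad
from .autodiff import Tensor

VARIANTS = ("cbam", "cam_only", "sam_only", "sam_then_cam", "none")
Variant = Literal["cbam", "cam_only", "sam_only", "sam_then_cam", "none"]

EXPECTED_INPUT_HW = (59, 114)
EXPECTED_FEATURE_SHAPE = (64, 2, 5)


class ConfigurationError(ValueError):
    """Raised when layer shape arithmetic cannot produce the required feature map."""


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConvBlockParams:
    """Batch norm statistics + conv kernels for one block (BN→conv→ReLU→pool)."""

    bn_gamma: np.ndarray      # (C_in,)
    bn_beta: np.ndarray       # (C_in,)
    bn_running_mean: np.ndarray
    bn_running_var: np.ndarray
    kernels: np.ndarray       # (C_out, C_in, kh, kw)
    bias: np.ndarray          # (C_out,)
    stride: tuple[int, int]
    pool: tuple[int, int]
    l2_coeff: float = 1e-4
    bn_steps: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(1, dtype=np.float32))


@dataclasses.dataclass
class CbamParams:
    """Shared channel-attention MLP (reduction 4) and 1×1 spatial conv."""

    mlp_w1: np.ndarray        # (C, C//4), row-vector convention
    mlp_b1: np.ndarray        # (C//4,)
    mlp_w2: np.ndarray        # (C//4, C)
    mlp_b2: np.ndarray        # (C,)
    spatial_kernel: np.ndarray  # (1, 2, 1, 1)
    spatial_bias: np.ndarray    # (1,)


@dataclasses.dataclass
class GruParams:
    """Gate matrices in row-vector convention: h_next = f(h @ W_h + x @ W_x)."""

    W_rx: np.ndarray
    W_rh: np.ndarray
    b_r: np.ndarray
    W_ux: np.ndarray
    W_uh: np.ndarray
    b_u: np.ndarray
    W_xh: np.ndarray
    W_hh: np.ndarray
    nh: int


@dataclasses.dataclass
class DenseParams:
    W: np.ndarray             # (n_in, n_out)
    b: np.ndarray             # (n_out,)


# ---------------------------------------------------------------------------
# Functional forward operations (numpy in / numpy out, single sample)
# ---------------------------------------------------------------------------

def conv_output_shape(hw: tuple[int, int], kernel: tuple[int, int],
                      stride: tuple[int, int], pool: tuple[int, int]) -> tuple[int, int]:
    h = (hw[0] - kernel[0]) // stride[0] + 1
    w = (hw[1] - kernel[1]) // stride[1] + 1
    return h // pool[0], w // pool[1]


def conv_block_forward(x: np.ndarray, p: ConvBlockParams, training: bool = False) -> np.ndarray:
    """BN → valid conv → ReLU → max pool on a single (C, H, W) feature map.

    This functional API computes in float64 (reference precision); the batched
    training path in :class:`CbamGruNet` runs in float32.
    """
    if np.isnan(x).any():
        raise ValueError("NaN in conv block input")
    p64 = dataclasses.replace(
        p, bn_gamma=p.bn_gamma.astype(np.float64), bn_beta=p.bn_beta.astype(np.float64),
        bn_running_mean=p.bn_running_mean.astype(np.float64),
        bn_running_var=p.bn_running_var.astype(np.float64),
        kernels=p.kernels.astype(np.float64), bias=p.bias.astype(np.float64),
        bn_steps=p.bn_steps.copy())
    xt = Tensor(x[None].astype(np.float64))
    out = _conv_block_graph(xt, _tensorize_block(p64), p64, training=training, rng=None)
    if training:   # propagate updated statistics back to the caller's params
        p.bn_running_mean[...] = p64.bn_running_mean
        p.bn_running_var[...] = p64.bn_running_var
        p.bn_steps[...] = p64.bn_steps
    return out.data[0]


def _tensorize_block(p: ConvBlockParams) -> dict[str, Tensor]:
    return {
        "gamma": Tensor(p.bn_gamma), "beta": Tensor(p.bn_beta),
        "kernels": Tensor(p.kernels), "bias": Tensor(p.bias),
    }


def _conv_block_graph(x: Tensor, t: dict[str, Tensor], p: ConvBlockParams,
                      training: bool, rng) -> Tensor:
    h = ad.batch_norm(x, t["gamma"], t["beta"], p.bn_running_mean, p.bn_running_var,
                      training=training, steps=p.bn_steps)
    h = ad.conv2d(h, t["kernels"], t["bias"], stride=p.stride)
    h = ad.relu(h)
    return ad.maxpool2d(h, p.pool)


def channel_attention(F: np.ndarray, p: CbamParams) -> tuple[np.ndarray, np.ndarray]:
    """Channel attention weights CE ∈ (0,1)^C and the re-weighted map F′ = CE ⊙ F."""
    Ft = Tensor(F[None])
    ce = _channel_attention_graph(Ft, _tensorize_cbam(p))
    Fp = ad.mul(ce, Ft)
    return ce.data[0, :, 0, 0], Fp.data[0]


def _tensorize_cbam(p: CbamParams) -> dict[str, Tensor]:
    return {
        "w1": Tensor(p.mlp_w1), "b1": Tensor(p.mlp_b1),
        "w2": Tensor(p.mlp_w2), "b2": Tensor(p.mlp_b2),
        "sk": Tensor(p.spatial_kernel), "sb": Tensor(p.spatial_bias),
    }


def _channel_attention_graph(F: Tensor, t: dict[str, Tensor]) -> Tensor:
    n, c = F.shape[0], F.shape[1]

    def mlp(desc: Tensor) -> Tensor:
        h = ad.relu(ad.add(ad.matmul(desc, t["w1"]), t["b1"]))
        return ad.add(ad.matmul(h, t["w2"]), t["b2"])

    mx = F.max(axis=3).max(axis=2)          # (N, C)
    av = F.mean(axis=(2, 3))                # (N, C)
    ce = ad.sigmoid(ad.add(mlp(mx), mlp(av)))
    return ce.reshape(n, c, 1, 1)


def spatial_attention(Fp: np.ndarray, p: CbamParams) -> tuple[np.ndarray, np.ndarray]:
    """Spatial attention weights SE ∈ (0,1)^{H×W} and F″ = SE ⊙ F′."""
    Ft = Tensor(Fp[None])
    se = _spatial_attention_graph(Ft, _tensorize_cbam(p))
    Fpp = ad.mul(se, Ft)
    return se.data[0, 0], Fpp.data[0]


def _spatial_attention_graph(Fp: Tensor, t: dict[str, Tensor]) -> Tensor:
    mx = Fp.max(axis=1, keepdims=True)       # (N, 1, H, W)
    av = Fp.mean(axis=1, keepdims=True)
    stacked = ad.concat([mx, av], axis=1)    # (N, 2, H, W)
    return ad.sigmoid(ad.conv2d(stacked, t["sk"], t["sb"], stride=(1, 1)))


def cbam(F: np.ndarray, p: CbamParams, variant: Variant = "cbam") -> np.ndarray:
    """Apply the configured attention variant to a (C, H, W) feature map."""
    Ft = Tensor(F[None])
    out = _cbam_graph(Ft, _tensorize_cbam(p), variant)
    return out.data[0]


def _cbam_graph(F: Tensor, t: dict[str, Tensor], variant: Variant) -> Tensor:
    if variant not in VARIANTS:
        raise ValueError(f"unknown attention variant {variant!r}; expected one of {VARIANTS}")

    def cam(x: Tensor) -> Tensor:
        return ad.mul(_channel_attention_graph(x, t), x)

    def sam(x: Tensor) -> Tensor:
        return ad.mul(_spatial_attention_graph(x, t), x)

    if variant == "cbam":
        return sam(cam(F))
    if variant == "cam_only":
        return cam(F)
    if variant == "sam_only":
        return sam(F)
    if variant == "sam_then_cam":
        return cam(sam(F))
    return F  # none


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, p: GruParams,
             standard: bool = False) -> np.ndarray:
    """One GRU update for a single time step (1-D input and state vectors)."""
    h = _gru_step_graph(Tensor(x_t[None]), Tensor(h_prev[None]), _tensorize_gru(p), standard)
    return h.data[0]


def _tensorize_gru(p: GruParams) -> dict[str, Tensor]:
    return {k: Tensor(getattr(p, k)) for k in
            ("W_rx", "W_rh", "b_r", "W_ux", "W_uh", "b_u", "W_xh", "W_hh")}


def _gru_step_graph(x: Tensor, h: Tensor, t: dict[str, Tensor], standard: bool) -> Tensor:
    r = ad.sigmoid(ad.add(ad.add(ad.matmul(h, t["W_rh"]), ad.matmul(x, t["W_rx"])), t["b_r"]))
    u = ad.sigmoid(ad.add(ad.add(ad.matmul(h, t["W_uh"]), ad.matmul(x, t["W_ux"])), t["b_u"]))
    if standard:
        cand = ad.tanh(ad.add(ad.matmul(ad.mul(r, h), t["W_hh"]), ad.matmul(x, t["W_xh"])))
        return ad.add(ad.mul(u, h), ad.mul(ad.add(Tensor(1.0), ad.mul(u, Tensor(-1.0))), cand))
    cand = ad.tanh(ad.add(ad.mul(ad.matmul(h, t["W_hh"]), r), ad.matmul(x, t["W_xh"])))
    one_minus_u = ad.add(Tensor(1.0), ad.mul(u, Tensor(-1.0)))
    return ad.add(ad.mul(one_minus_u, h), ad.mul(u, cand))


def gru_forward(xs: np.ndarray, p: GruParams, h0: np.ndarray | None = None,
                return_mode: Literal["all", "last"] = "all",
                standard: bool = False) -> np.ndarray:
    """Left fold of :func:`gru_step` over a (T, n_in) sequence."""
    if len(xs) == 0:
        raise ValueError("gru_forward requires a nonempty sequence")
    h = np.zeros(p.nh, dtype=np.float32) if h0 is None else h0
    states = []
    for x_t in xs:
        h = gru_step(np.asarray(x_t, dtype=np.float32), h, p, standard=standard)
        states.append(h)
    return np.stack(states) if return_mode == "all" else states[-1]


def _gru_sequence_graph(X: Tensor, t: dict[str, Tensor], nh: int, standard: bool,
                        return_all: bool) -> Tensor:
    """Batched GRU over (N, T, n_in); returns (N, T, nh) or (N, nh)."""
    n, T = X.shape[0], X.shape[1]
    h = Tensor(np.zeros((n, nh), dtype=np.float32))
    states = []
    for step in range(T):
        h = _gru_step_graph(X[:, step, :], h, t, standard)
        states.append(h)
    return ad.stack(states, axis=1) if return_all else states[-1]


# ---------------------------------------------------------------------------
# The trainable network
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return (q * np.sign(np.diag(r))).astype(np.float32)


class CbamGruNet:
    """Trainable conv + CBAM + dual-GRU binary classifier.

    Parameters
    ----------
    n_channels : number of EEG channels in the spectrogram input.
    input_hw : spatial size (time frames, frequency bins). Must reduce to the
        64×2×5 feature map through the fixed conv stack; anything else raises
        :class:`ConfigurationError` listing the computed shape chain.
    variant : attention ablation variant.
    l2_coeff : L2 penalty applied to conv kernels in the training loss.
    seed : controls weight initialisation.
    """

    GRU1_UNITS = 256
    GRU2_UNITS = 128
    FC1_UNITS = 64

    def __init__(self, n_channels: int = 22, input_hw: tuple[int, int] = EXPECTED_INPUT_HW,
                 variant: Variant = "cbam", l2_coeff: float = 1e-4,
                 dropout_rate: float = 0.5, standard_gru: bool = False,
                 seed: int = 0):
        if variant not in VARIANTS:
            raise ValueError(f"unknown attention variant {variant!r}")
        self.n_channels = int(n_channels)
        self.input_hw = tuple(input_hw)
        self.variant: Variant = variant
        self.l2_coeff = float(l2_coeff)
        self.dropout_rate = float(dropout_rate)
        self.standard_gru = bool(standard_gru)
        self.seed = int(seed)

        blocks_cfg = [  # (out_filters, kernel, stride, pool)
            (16, (5, 5), (2, 2), (2, 2)),
            (32, (3, 3), (1, 1), (2, 2)),
            (64, (3, 3), (1, 1), (2, 2)),
        ]
        chain = [self.input_hw]
        hw = self.input_hw
        for _, k, s, pl in blocks_cfg:
            hw = conv_output_shape(hw, k, s, pl)
            chain.append(hw)
        if hw != EXPECTED_FEATURE_SHAPE[1:]:
            raise ConfigurationError(
                f"input spatial size {self.input_hw} does not reduce to "
                f"{EXPECTED_FEATURE_SHAPE[1:]} through the conv stack; computed chain: "
                + " -> ".join(str(c) for c in chain)
            )
        self.shape_chain = chain

        rng = np.random.default_rng(seed)
        self.conv_blocks: list[ConvBlockParams] = []
        c_in = self.n_channels
        for c_out, k, s, pl in blocks_cfg:
            fan_in = c_in * k[0] * k[1]
            fan_out = c_out * k[0] * k[1]
            self.conv_blocks.append(ConvBlockParams(
                bn_gamma=np.ones(c_in, dtype=np.float32),
                bn_beta=np.zeros(c_in, dtype=np.float32),
                bn_running_mean=np.zeros(c_in, dtype=np.float32),
                bn_running_var=np.ones(c_in, dtype=np.float32),
                kernels=_glorot(rng, (c_out, c_in) + k, fan_in, fan_out),
                bias=np.zeros(c_out, dtype=np.float32),
                stride=s, pool=pl, l2_coeff=self.l2_coeff,
            ))
            c_in = c_out

        C = 64
        self.cbam_params = CbamParams(
            mlp_w1=_glorot(rng, (C, C // 4), C, C // 4),
            mlp_b1=np.zeros(C // 4, dtype=np.float32),
            mlp_w2=_glorot(rng, (C // 4, C), C // 4, C),
            mlp_b2=np.zeros(C, dtype=np.float32),
            spatial_kernel=_glorot(rng, (1, 2, 1, 1), 2, 1),
            spatial_bias=np.zeros(1, dtype=np.float32),
        )

        n_in1 = EXPECTED_FEATURE_SHAPE[0] * EXPECTED_FEATURE_SHAPE[2]  # 64*5 = 320
        self.gru1 = self._init_gru(rng, n_in1, self.GRU1_UNITS)
        self.fc1 = DenseParams(
            W=_glorot(rng, (self.GRU1_UNITS, self.FC1_UNITS), self.GRU1_UNITS, self.FC1_UNITS),
            b=np.zeros(self.FC1_UNITS, dtype=np.float32))
        self.gru2 = self._init_gru(rng, self.FC1_UNITS, self.GRU2_UNITS)
        self.fc2 = DenseParams(
            W=_glorot(rng, (self.GRU2_UNITS, 2), self.GRU2_UNITS, 2),
            b=np.zeros(2, dtype=np.float32))

        self._build_tensors()

    @staticmethod
    def _init_gru(rng: np.random.Generator, n_in: int, nh: int) -> GruParams:
        def g(shape):
            return _glorot(rng, shape, shape[0], shape[1])
        return GruParams(
            W_rx=g((n_in, nh)), W_rh=_orthogonal(rng, nh), b_r=np.zeros(nh, dtype=np.float32),
            W_ux=g((n_in, nh)), W_uh=_orthogonal(rng, nh), b_u=np.zeros(nh, dtype=np.float32),
            W_xh=g((n_in, nh)), W_hh=_orthogonal(rng, nh), nh=nh,
        )

    # -- parameter bookkeeping ------------------------------------------------
    def _build_tensors(self) -> None:
        """Wrap every trainable array in a shared-memory autodiff Tensor."""
        self._t: dict[str, Tensor] = {}
        self._decay_exempt: set[str] = set()
        self._conv_kernel_names: list[str] = []

        def reg(name: str, arr: np.ndarray, exempt: bool = False) -> Tensor:
            t = Tensor.__new__(Tensor)
            t.data = arr
            t.grad = None
            t.requires_grad = True
            t._backward = None
            t._parents = ()
            self._t[name] = t
            if exempt:
                self._decay_exempt.add(name)
            return t

        for i, blk in enumerate(self.conv_blocks):
            reg(f"conv{i}.gamma", blk.bn_gamma, exempt=True)
            reg(f"conv{i}.beta", blk.bn_beta, exempt=True)
            reg(f"conv{i}.kernels", blk.kernels)
            reg(f"conv{i}.bias", blk.bias, exempt=True)
            self._conv_kernel_names.append(f"conv{i}.kernels")
        cb = self.cbam_params
        reg("cbam.w1", cb.mlp_w1); reg("cbam.b1", cb.mlp_b1, exempt=True)
        reg("cbam.w2", cb.mlp_w2); reg("cbam.b2", cb.mlp_b2, exempt=True)
        reg("cbam.sk", cb.spatial_kernel); reg("cbam.sb", cb.spatial_bias, exempt=True)
        for name, gru in (("gru1", self.gru1), ("gru2", self.gru2)):
            for field in ("W_rx", "W_rh", "W_ux", "W_uh", "W_xh", "W_hh"):
                reg(f"{name}.{field}", getattr(gru, field))
            for field in ("b_r", "b_u"):
                reg(f"{name}.{field}", getattr(gru, field), exempt=True)
        reg("fc1.W", self.fc1.W); reg("fc1.b", self.fc1.b, exempt=True)
        reg("fc2.W", self.fc2.W); reg("fc2.b", self.fc2.b, exempt=True)

    @property
    def parameters(self) -> dict[str, Tensor]:
        return self._t

    def decay_mask(self) -> dict[str, bool]:
        """True where decoupled weight decay applies (biases/BN exempt)."""
        return {name: name not in self._decay_exempt for name in self._t}

    def n_parameters(self) -> int:
        return int(sum(t.data.size for t in self._t.values()))

    def zero_grad(self) -> None:
        for t in self._t.values():
            t.grad = None

    # -- forward --------------------------------------------------------------
    def _cbam_tensors(self) -> dict[str, Tensor]:
        return {"w1": self._t["cbam.w1"], "b1": self._t["cbam.b1"],
                "w2": self._t["cbam.w2"], "b2": self._t["cbam.b2"],
                "sk": self._t["cbam.sk"], "sb": self._t["cbam.sb"]}

    def _gru_tensors(self, name: str) -> dict[str, Tensor]:
        return {f: self._t[f"{name}.{f}"] for f in
                ("W_rx", "W_rh", "b_r", "W_ux", "W_uh", "b_u", "W_xh", "W_hh")}

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Batched forward pass; x is (N, C, H, W); returns logits (N, 2)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.n_channels or x.shape[2:] != self.input_hw:
            raise ValueError(
                f"expected input (N, {self.n_channels}, {self.input_hw[0]}, "
                f"{self.input_hw[1]}), got {x.shape}")
        if np.isnan(x).any():
            raise ValueError("NaN in network input")
        h = Tensor(x)
        for i, blk in enumerate(self.conv_blocks):
            tb = {"gamma": self._t[f"conv{i}.gamma"], "beta": self._t[f"conv{i}.beta"],
                  "kernels": self._t[f"conv{i}.kernels"], "bias": self._t[f"conv{i}.bias"]}
            h = _conv_block_graph(h, tb, blk, training=training, rng=rng)
        h = _cbam_graph(h, self._cbam_tensors(), self.variant)
        # (N, 64, 2, 5) -> sequence of T=2 steps × 320 features (time axis = H)
        n = h.shape[0]
        T = EXPECTED_FEATURE_SHAPE[1]
        h = h.transpose((0, 2, 1, 3)).reshape(n, T, -1)
        h = _gru_sequence_graph(h, self._gru_tensors("gru1"), self.GRU1_UNITS,
                                self.standard_gru, return_all=True)   # (N, T, 256)
        h = ad.dropout(h, self.dropout_rate, rng, training)
        h = h.reshape(n * T, self.GRU1_UNITS)
        h = ad.sigmoid(ad.add(ad.matmul(h, self._t["fc1.W"]), self._t["fc1.b"]))
        h = h.reshape(n, T, self.FC1_UNITS)
        h = _gru_sequence_graph(h, self._gru_tensors("gru2"), self.GRU2_UNITS,
                                self.standard_gru, return_all=False)  # (N, 128)
        h = ad.dropout(h, self.dropout_rate, rng, training)
        logits = ad.add(ad.matmul(h, self._t["fc2.W"]), self._t["fc2.b"])
        return logits

    def loss(self, x: np.ndarray, labels: np.ndarray,
             rng: np.random.Generator | None = None) -> Tensor:
        """Cross-entropy + L2 penalty on conv kernels, as an autodiff scalar."""
        logits = self.forward(x, training=True, rng=rng)
        loss = ad.softmax_cross_entropy(logits, np.asarray(labels, dtype=np.int64))
        for name in self._conv_kernel_names:
            k = self._t[name]
            loss = ad.add(loss, ad.mul(ad.mul(k, k).sum(), Tensor(self.l2_coeff)))
        return loss

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """(N, 2) softmax probabilities (p_interictal, p_preictal), inference mode."""
        x = np.asarray(x, dtype=np.float32)
        out = []
        for lo in range(0, len(x), batch_size):
            logits = self.forward(x[lo:lo + batch_size], training=False)
            probs = ad.softmax(logits, axis=1)
            out.append(probs.data)
            ad.release(probs)
        return np.concatenate(out, axis=0)

    # -- serialization --------------------------------------------------------
    def config(self) -> dict:
        return {
            "n_channels": self.n_channels, "input_hw": list(self.input_hw),
            "variant": self.variant, "l2_coeff": self.l2_coeff,
            "dropout_rate": self.dropout_rate, "standard_gru": self.standard_gru,
            "seed": self.seed,
        }

    def save(self, weights_path, config_path=None) -> None:
        with h5py.File(weights_path, "w") as f:
            for name, t in self._t.items():
                f.create_dataset(name, data=t.data)
            for i, blk in enumerate(self.conv_blocks):
                f.create_dataset(f"conv{i}.running_mean", data=blk.bn_running_mean)
                f.create_dataset(f"conv{i}.running_var", data=blk.bn_running_var)
                f.create_dataset(f"conv{i}.bn_steps", data=blk.bn_steps)
            f.attrs["config"] = yaml.safe_dump(self.config())
        if config_path is not None:
            with open(config_path, "w") as fh:
                yaml.safe_dump(self.config(), fh)

    @classmethod
    def load(cls, weights_path) -> "CbamGruNet":
        with h5py.File(weights_path, "r") as f:
            cfg = yaml.safe_load(f.attrs["config"])
            cfg["input_hw"] = tuple(cfg["input_hw"])
            net = cls(**cfg)
            for name, t in net._t.items():
                t.data[...] = f[name][...]
            for i, blk in enumerate(net.conv_blocks):
                blk.bn_running_mean[...] = f[f"conv{i}.running_mean"][...]
                blk.bn_running_var[...] = f[f"conv{i}.running_var"][...]
                blk.bn_steps[...] = f[f"conv{i}.bn_steps"][...]
        return net

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: t.data.copy() for name, t in self._t.items()}
        for i, blk in enumerate(self.conv_blocks):
            d[f"conv{i}.running_mean"] = blk.bn_running_mean.copy()
            d[f"conv{i}.running_var"] = blk.bn_running_var.copy()
            d[f"conv{i}.bn_steps"] = blk.bn_steps.copy()
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for name, t in self._t.items():
            t.data[...] = d[name]
        for i, blk in enumerate(self.conv_blocks):
            blk.bn_running_mean[...] = d[f"conv{i}.running_mean"]
            blk.bn_running_var[...] = d[f"conv{i}.running_var"]
            blk.bn_steps[...] = d[f"conv{i}.bn_steps"]


def network_forward(window: np.ndarray, net: CbamGruNet) -> tuple[float, float]:
    """Single-window probability pair (p_interictal, p_preictal)."""
    p = net.predict_proba(window[None])[0]
    return float(p[0]), float(p[1])
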