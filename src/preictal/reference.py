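"""Slow, loop-based reference forwards used as independent oracles.

Every operation of the classifier is re-implemented here with explicit nested
loops and scalar arithmetic, sharing no code with the vectorised im2col/BLAS
implementations in :mod:`preictal.model`. The loops are compiled with numba so
that agreement can be checked over many random instances at full input size;
the algorithmic route (per-element accumulation in float64) stays independent
of the production path. Inference-mode batch normalisation (running
statistics) is used throughout.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .model import CbamGruNet, CbamParams, ConvBlockParams, GruParams

BN_EPS = 1e-3


@njit(cache=True)
def _conv_block_kernel(x, rm, rv, gamma, beta, kernels, bias, sh, sw, ph, pw):
    c_in, H, W = x.shape
    xn = np.empty((c_in, H, W), dtype=np.float64)
    for c in range(c_in):
        inv = 1.0 / math.sqrt(rv[c] + BN_EPS)
        for i in range(H):
            for j in range(W):
                xn[c, i, j] = (x[c, i, j] - rm[c]) * inv * gamma[c] + beta[c]
    c_out, _, kh, kw = kernels.shape
    oh = (H - kh) // sh + 1
    ow = (W - kw) // sw + 1
    conv = np.zeros((c_out, oh, ow), dtype=np.float64)
    for o in range(c_out):
        for i in range(oh):
            for j in range(ow):
                acc = bias[o]
                for c in range(c_in):
                    for a in range(kh):
                        for b in range(kw):
                            acc += kernels[o, c, a, b] * xn[c, i * sh + a, j * sw + b]
                conv[o, i, j] = acc if acc > 0.0 else 0.0  # ReLU fused
    poh = oh // ph
    pow_ = ow // pw
    out = np.zeros((c_out, poh, pow_), dtype=np.float64)
    for o in range(c_out):
        for i in range(poh):
            for j in range(pow_):
                m = -1e300
                for a in range(ph):
                    for b in range(pw):
                        v = conv[o, i * ph + a, j * pw + b]
                        if v > m:
                            m = v
                out[o, i, j] = m
    return out


def conv_block_reference(x: np.ndarray, p: ConvBlockParams) -> np.ndarray:
    """BN (running stats) → valid conv → ReLU → floor max-pool, all loops."""
    return _conv_block_kernel(
        np.asarray(x, dtype=np.float64),
        p.bn_running_mean.astype(np.float64), p.bn_running_var.astype(np.float64),
        p.bn_gamma.astype(np.float64), p.bn_beta.astype(np.float64),
        p.kernels.astype(np.float64), p.bias.astype(np.float64),
        p.stride[0], p.stride[1], p.pool[0], p.pool[1])


@njit(cache=True)
def _channel_attention_kernel(F, w1, b1, w2, b2):
    C, H, W = F.shape
    r = w1.shape[1]
    mx = np.empty(C, dtype=np.float64)
    av = np.empty(C, dtype=np.float64)
    for c in range(C):
        m = -1e300
        s = 0.0
        for i in range(H):
            for j in range(W):
                v = F[c, i, j]
                if v > m:
                    m = v
                s += v
        mx[c] = m
        av[c] = s / (H * W)
    logits = np.zeros(C, dtype=np.float64)
    for desc_idx in range(2):
        desc = mx if desc_idx == 0 else av
        hid = np.zeros(r, dtype=np.float64)
        for k in range(r):
            acc = b1[k]
            for c in range(C):
                acc += desc[c] * w1[c, k]
            hid[k] = acc if acc > 0.0 else 0.0
        for c in range(C):
            acc = b2[c]
            for k in range(r):
                acc += hid[k] * w2[k, c]
            logits[c] += acc
    ce = np.empty(C, dtype=np.float64)
    for c in range(C):
        ce[c] = 1.0 / (1.0 + math.exp(-logits[c]))
    Fp = np.empty((C, H, W), dtype=np.float64)
    for c in range(C):
        for i in range(H):
            for j in range(W):
                Fp[c, i, j] = ce[c] * F[c, i, j]
    return ce, Fp


def channel_attention_reference(F: np.ndarray, p: CbamParams) -> tuple[np.ndarray, np.ndarray]:
    """Scalar-loop channel attention: CE = σ(MLP(max) + MLP(avg)); F′ = CE⊙F."""
    return _channel_attention_kernel(
        np.asarray(F, dtype=np.float64),
        p.mlp_w1.astype(np.float64), p.mlp_b1.astype(np.float64),
        p.mlp_w2.astype(np.float64), p.mlp_b2.astype(np.float64))


@njit(cache=True)
def _spatial_attention_kernel(Fp, w_max, w_avg, bias):
    C, H, W = Fp.shape
    se = np.empty((H, W), dtype=np.float64)
    for i in range(H):
        for j in range(W):
            m = -1e300
            s = 0.0
            for c in range(C):
                v = Fp[c, i, j]
                if v > m:
                    m = v
                s += v
            se[i, j] = 1.0 / (1.0 + math.exp(-(w_max * m + w_avg * (s / C) + bias)))
    Fpp = np.empty((C, H, W), dtype=np.float64)
    for c in range(C):
        for i in range(H):
            for j in range(W):
                Fpp[c, i, j] = se[i, j] * Fp[c, i, j]
    return se, Fpp


def spatial_attention_reference(Fp: np.ndarray, p: CbamParams) -> tuple[np.ndarray, np.ndarray]:
    """Scalar-loop spatial attention: SE = σ(conv1×1([max_C; avg_C])); F″ = SE⊙F′."""
    return _spatial_attention_kernel(
        np.asarray(Fp, dtype=np.float64),
        float(p.spatial_kernel[0, 0, 0, 0]), float(p.spatial_kernel[0, 1, 0, 0]),
        float(p.spatial_bias[0]))


def cbam_reference(F: np.ndarray, p: CbamParams, variant: str = "cbam") -> np.ndarray:
    if variant == "none":
        return np.asarray(F, dtype=np.float64)
    if variant == "cam_only":
        return channel_attention_reference(F, p)[1]
    if variant == "sam_only":
        return spatial_attention_reference(F, p)[1]
    if variant == "sam_then_cam":
        return channel_attention_reference(spatial_attention_reference(F, p)[1], p)[1]
    return spatial_attention_reference(channel_attention_reference(F, p)[1], p)[1]


@njit(cache=True)
def _gru_step_kernel(x_t, h_prev, W_rx, W_rh, b_r, W_ux, W_uh, b_u, W_xh, W_hh, standard):
    nx = x_t.shape[0]
    nh = h_prev.shape[0]
    r = np.empty(nh, dtype=np.float64)
    u = np.empty(nh, dtype=np.float64)
    for k in range(nh):
        acc_r = b_r[k]
        acc_u = b_u[k]
        for j in range(nx):
            acc_r += x_t[j] * W_rx[j, k]
            acc_u += x_t[j] * W_ux[j, k]
        for j in range(nh):
            acc_r += h_prev[j] * W_rh[j, k]
            acc_u += h_prev[j] * W_uh[j, k]
        r[k] = 1.0 / (1.0 + math.exp(-acc_r))
        u[k] = 1.0 / (1.0 + math.exp(-acc_u))
    h_next = np.empty(nh, dtype=np.float64)
    for k in range(nh):
        xw = 0.0
        for j in range(nx):
            xw += x_t[j] * W_xh[j, k]
        if standard:
            rhw = 0.0
            for j in range(nh):
                rhw += r[j] * h_prev[j] * W_hh[j, k]
            cand = math.tanh(rhw + xw)
            h_next[k] = u[k] * h_prev[k] + (1.0 - u[k]) * cand
        else:
            hw = 0.0
            for j in range(nh):
                hw += h_prev[j] * W_hh[j, k]
            cand = math.tanh(hw * r[k] + xw)
            h_next[k] = (1.0 - u[k]) * h_prev[k] + u[k] * cand
    return h_next


def gru_step_reference(x_t: np.ndarray, h_prev: np.ndarray, p: GruParams,
                       standard: bool = False) -> np.ndarray:
    """Scalar evaluation of the gate equations (reset applied after h·W_hh)."""
    return _gru_step_kernel(
        np.asarray(x_t, dtype=np.float64), np.asarray(h_prev, dtype=np.float64),
        p.W_rx.astype(np.float64), p.W_rh.astype(np.float64), p.b_r.astype(np.float64),
        p.W_ux.astype(np.float64), p.W_uh.astype(np.float64), p.b_u.astype(np.float64),
        p.W_xh.astype(np.float64), p.W_hh.astype(np.float64), standard)


def gru_forward_reference(xs: np.ndarray, p: GruParams, h0: np.ndarray | None = None,
                          return_mode: str = "all", standard: bool = False) -> np.ndarray:
    h = np.zeros(p.nh, dtype=np.float64) if h0 is None else np.asarray(h0, dtype=np.float64)
    states = []
    for x_t in xs:
        h = gru_step_reference(np.asarray(x_t, dtype=np.float64), h, p, standard=standard)
        states.append(h)
    return np.stack(states) if return_mode == "all" else states[-1]


def _sigmoid(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-v))


def network_forward_reference(window: np.ndarray, net: CbamGruNet) -> tuple[float, float]:
    """Full inference forward of one window composed from the loop oracles."""
    h = np.asarray(window, dtype=np.float64)
    for blk in net.conv_blocks:
        h = conv_block_reference(h, blk)
    h = cbam_reference(h, net.cbam_params, net.variant)
    C, T, W = h.shape
    seq = np.stack([h[:, t, :].reshape(-1) for t in range(T)])        # (T, C*W)
    states = gru_forward_reference(seq, net.gru1, return_mode="all",
                                   standard=net.standard_gru)          # (T, 256)
    fc1_out = np.zeros((T, net.FC1_UNITS))
    for t in range(T):
        for k in range(net.FC1_UNITS):
            acc = float(net.fc1.b[k])
            for j in range(net.GRU1_UNITS):
                acc += states[t, j] * float(net.fc1.W[j, k])
            fc1_out[t, k] = _sigmoid(acc)
    last = gru_forward_reference(fc1_out, net.gru2, return_mode="last",
                                 standard=net.standard_gru)            # (128,)
    logits = np.zeros(2)
    for k in range(2):
        acc = float(net.fc2.b[k])
        for j in range(net.GRU2_UNITS):
            acc += last[j] * float(net.fc2.W[j, k])
        logits[k] = acc
    z = logits - logits.max()
    e = np.exp(z)
    probs = e / e.sum()
    return float(probs[0]), float(probs[1])
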