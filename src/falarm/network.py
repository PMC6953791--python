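"""The per-modality feature-extraction network and the fusion head.

Each modality (ECG lead II, ABP, PPG) gets its own network:

    segment (n=200 samples)
      -> 1D conv, 32 filters, kernel 2, stride 1, ReLU
      -> max pool, region 2, stride 2
      -> 1D conv, 64 filters, kernel 2, stride 1, ReLU
      -> adaptive pool along time to L slices               -> C_t in R^{L x D}
      -> additive attention over the L slices, conditioned
         on the previous top-layer LSTM hidden state        -> context c_t in R^D
      -> 2-layer LSTM, 256 units per layer                  -> h_t
      (after the last segment)
      -> fully connected 256, ReLU                          -> embedding e
      -> softmax over {false alarm, true alarm}             -> probs

The attention score for slice i is the standard additive form
``score_i = v . tanh(W_h h_{t-1} + W_C C_{t,i})``; a softmax over the L
scores yields the importance weights alpha_{t,i} and the context is their
weighted sum of slices.  The literal convolution stack maps 200 samples to
98 temporal positions, which an adaptive pool over contiguous near-equal
bins reduces to the configured L (5 by default; 10 matches the "fixed
predefined parts" variant).  Bins are sum-pooled by default: with
non-negative ReLU activations, averaging ~20 positions attenuates the
forward signal by an order of magnitude, which starves the downstream
LSTM/readout of gradient at desk-scale epoch budgets; ``slice_pool="avg"``
selects plain averaging.

The fusion head averages the three 256-dim modality embeddings elementwise,
applies FC-256 + ReLU, dropout (p = 0.5, training only), and a 2-class
softmax.

Everything is plain NumPy with hand-derived backpropagation; gradients are
validated against finite differences in the test suite.  All randomness is
drawn from explicitly seeded generators, so forward passes, initialization
and training are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .exceptions import ContractError, InsufficientDataError, ShapeError
from .preprocessing import SegmentBatch

__all__ = [
    "ModalConfig",
    "ModalNet",
    "FusionHead",
    "FeatureSlices",
    "AttentionState",
    "cnn_features",
    "attention_step",
    "forward_modal",
    "fuse_forward",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModalConfig:
    """Architecture hyperparameters for one modality network."""

    n: int = 200  # segment length in samples
    conv1_filters: int = 32
    conv2_filters: int = 64  # D, the slice feature dimension
    kernel: int = 2
    pool: int = 2
    n_slices: int = 10  # L
    slice_pool: str = "sum"  # "sum" (scale-preserving) or "avg"
    attention_width: int = 64  # A
    lstm_size: int = 256
    fc_size: int = 256
    n_classes: int = 2
    attention_enabled: bool = True  # False -> uniform alpha (ablation)
    dtype: str = "float32"

    @property
    def conv1_len(self) -> int:
        return self.n - self.kernel + 1

    @property
    def pool_len(self) -> int:
        return self.conv1_len // self.pool

    @property
    def conv2_len(self) -> int:
        return self.pool_len - self.kernel + 1

    @property
    def slice_edges(self) -> np.ndarray:
        m, L = self.conv2_len, self.n_slices
        if m < L:
            raise ShapeError(f"conv output length {m} shorter than n_slices {L}")
        return np.round(np.linspace(0, m, L + 1)).astype(int)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype,
            gain: float = 1.0) -> np.ndarray:
    """Glorot-style uniform init; ReLU layers use gain sqrt(2) (He scaling)."""
    fan_in, fan_out = shape[0], shape[-1]
    limit = gain * np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _orthogonal(rng: np.random.Generator, size: int, dtype) -> np.ndarray:
    """Random orthogonal matrix (QR of a Gaussian), sign-fixed for uniqueness."""
    q, r = np.linalg.qr(rng.standard_normal((size, size)))
    return (q * np.sign(np.diag(r))).astype(dtype)


from scipy.special import expit as _sigmoid


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, T, C) -> (B, T - k + 1, k * C) patch matrix for a stride-1 conv."""
    w = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (B, T-k+1, C, k)
    return np.ascontiguousarray(w.transpose(0, 1, 3, 2)).reshape(
        x.shape[0], x.shape[1] - k + 1, k * x.shape[2]
    )


@dataclass
class FeatureSlices:
    """The L x D matrix of CNN feature vectors for one segment."""

    C: np.ndarray

    @property
    def L(self) -> int:
        return self.C.shape[0]

    @property
    def D(self) -> int:
        return self.C.shape[1]


@dataclass
class AttentionState:
    """Importance weights over the L slices and the resulting context vector."""

    alpha: np.ndarray  # (L,), non-negative, sums to 1
    context: np.ndarray  # (D,)


class ModalNet:
    """One modality's feature-extraction network (parameters + forward/backward).

    ``frozen`` networks are never updated by an optimizer step; ``stripped``
    networks have had their softmax head removed (Algorithm step between
    pre-training and fusion) and refuse class-probability queries.
    """

    #: parameter names in a fixed order (checkpoint layout, optimizer slots)
    PARAM_NAMES = (
        "W_conv1", "b_conv1", "W_conv2", "b_conv2",
        "W_h", "W_C", "v_att",
        "W_lstm1", "b_lstm1", "W_lstm2", "b_lstm2",
        "W_fc", "b_fc", "W_out", "b_out",
    )

    def __init__(self, config: ModalConfig, seed: int):
        self.config = config
        self.seed = seed
        self.frozen = False
        self.stripped = False
        self.provenance: dict = {}
        c = config
        dt = np.dtype(c.dtype)
        rng = np.random.default_rng(seed)
        H, D, A, F = c.lstm_size, c.conv2_filters, c.attention_width, c.fc_size
        p: dict[str, np.ndarray] = {}
        relu_gain = np.sqrt(2.0)
        p["W_conv1"] = _glorot(rng, (c.kernel, c.conv1_filters), dt, relu_gain)
        p["b_conv1"] = np.zeros(c.conv1_filters, dt)
        p["W_conv2"] = _glorot(rng, (c.kernel * c.conv1_filters, c.conv2_filters), dt, relu_gain)
        p["b_conv2"] = np.zeros(c.conv2_filters, dt)
        p["W_h"] = _glorot(rng, (A, H), dt)
        p["W_C"] = _glorot(rng, (A, D), dt)
        p["v_att"] = _glorot(rng, (A,), dt)
        for name, inp in (("lstm1", D + H), ("lstm2", 2 * H)):
            # glorot input block + orthogonal recurrent block per gate, the
            # standard recipe for trainable LSTMs
            W = np.empty((inp, 4 * H), dtype=dt)
            W[: inp - H] = _glorot(rng, (inp - H, 4 * H), dt)
            for g in range(4):
                W[inp - H :, g * H : (g + 1) * H] = _orthogonal(rng, H, dt)
            p[f"W_{name}"] = W
            b = np.zeros(4 * H, dt)
            b[H : 2 * H] = 1.0  # forget-gate bias 1: remember by default
            p[f"b_{name}"] = b
        p["W_fc"] = _glorot(rng, (H, F), dt, relu_gain)
        p["b_fc"] = np.zeros(F, dt)
        p["W_out"] = _glorot(rng, (F, c.n_classes), dt, relu_gain)
        p["b_out"] = np.zeros(c.n_classes, dt)
        self.params = p

    # -- state -----------------------------------------------------------

    def trainable_params(self) -> dict[str, np.ndarray]:
        if self.frozen:
            return {}
        names = self.PARAM_NAMES if not self.stripped else self.PARAM_NAMES[:-2]
        return {k: self.params[k] for k in names}

    def copy(self) -> "ModalNet":
        new = ModalNet.__new__(ModalNet)
        new.config = self.config
        new.seed = self.seed
        new.frozen = self.frozen
        new.stripped = self.stripped
        new.provenance = dict(self.provenance)
        new.params = {k: v.copy() for k, v in self.params.items()}
        return new

    # -- forward ---------------------------------------------------------

    def _cnn_forward(self, X2: np.ndarray, cache: Optional[dict]) -> np.ndarray:
        c, p = self.config, self.params
        k = c.kernel
        col1 = _im2col(X2[:, :, None], k)
        z1 = col1 @ p["W_conv1"] + p["b_conv1"]
        a1 = np.maximum(z1, 0)
        lp = c.pool_len
        pooled_src = a1[:, : lp * c.pool].reshape(a1.shape[0], lp, c.pool, -1)
        if c.pool == 2:  # fast path: pairwise max, ties go to the first sample
            left, right = pooled_src[:, :, 0], pooled_src[:, :, 1]
            arg = left < right
            p1 = np.where(arg, right, left)
        else:
            arg = pooled_src.argmax(axis=2)
            p1 = np.take_along_axis(pooled_src, arg[:, :, None, :], axis=2)[:, :, 0, :]
        col2 = _im2col(p1, k)
        z2 = col2 @ p["W_conv2"] + p["b_conv2"]
        a2 = np.maximum(z2, 0)
        edges = c.slice_edges
        reduce = np.sum if c.slice_pool == "sum" else np.mean
        C = np.stack(
            [reduce(a2[:, edges[i] : edges[i + 1]], axis=1) for i in range(c.n_slices)],
            axis=1,
        )
        if cache is not None:
            cache.update(
                col1=col1, mask1=z1 > 0, arg=arg, col2=col2, mask2=z2 > 0, edges=edges,
                a1_shape=a1.shape,
            )
        return C

    def _attention_forward(self, C: np.ndarray, h: np.ndarray, caches: Optional[list]):
        c, p = self.config, self.params
        if c.attention_enabled:
            u = np.tanh((h @ p["W_h"].T)[:, None, :] + C @ p["W_C"].T)  # (B, L, A)
            s = u @ p["v_att"]
            alpha = _softmax(s, axis=1)
        else:
            u = None
            alpha = np.full(C.shape[:2], 1.0 / C.shape[1], dtype=C.dtype)
        ctx = np.einsum("bl,bld->bd", alpha, C)
        if caches is not None:
            caches.append((C, u, alpha, h))
        return alpha, ctx

    @staticmethod
    def _lstm_forward(x, h, c_state, W, b, H, caches: Optional[list]):
        X_cat = np.concatenate([x, h], axis=1)
        Z = X_cat @ W + b
        i = _sigmoid(Z[:, :H])
        f = _sigmoid(Z[:, H : 2 * H])
        g = np.tanh(Z[:, 2 * H : 3 * H])
        o = _sigmoid(Z[:, 3 * H :])
        c_new = f * c_state + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        if caches is not None:
            caches.append((X_cat, i, f, g, o, c_state, tc))
        return h_new, c_new

    def forward(self, X: np.ndarray, need_cache: bool = False):
        """Run the network on a batch.

        Parameters
        ----------
        X : (B, T, n) array of normalized segments, ordered in time.

        Returns
        -------
        probs : (B, n_classes) or None when the softmax head is stripped.
        embedding : (B, fc_size) FC output after ReLU.
        cache : intermediate values for backprop (or None).
        """
        c, p = self.config, self.params
        X = np.asarray(X, dtype=c.dtype)
        if X.ndim != 3 or X.shape[2] != c.n:
            raise ShapeError(f"expected (B, T, {c.n}) segments, got {X.shape}")
        B, T, _ = X.shape
        if T < 1:
            raise InsufficientDataError("empty segment sequence")
        H = c.lstm_size
        cache: Optional[dict] = {"att": [], "lstm1": [], "lstm2": []} if need_cache else None
        C_all = self._cnn_forward(X.reshape(B * T, c.n), cache)
        C_all = C_all.reshape(B, T, c.n_slices, c.conv2_filters)
        h1 = np.zeros((B, H), dtype=c.dtype)
        c1 = np.zeros_like(h1)
        h2 = np.zeros_like(h1)
        c2 = np.zeros_like(h1)
        for t in range(T):
            _, ctx = self._attention_forward(
                C_all[:, t], h2, cache["att"] if cache else None
            )
            h1, c1 = self._lstm_forward(
                ctx, h1, c1, p["W_lstm1"], p["b_lstm1"], H,
                cache["lstm1"] if cache else None,
            )
            h2, c2 = self._lstm_forward(
                h1, h2, c2, p["W_lstm2"], p["b_lstm2"], H,
                cache["lstm2"] if cache else None,
            )
        e_pre = h2 @ p["W_fc"] + p["b_fc"]
        emb = np.maximum(e_pre, 0)
        probs = None
        if not self.stripped:
            logits = emb @ p["W_out"] + p["b_out"]
            probs = _softmax(logits, axis=1)
        if cache is not None:
            cache.update(h2_T=h2, fc_mask=e_pre > 0, emb=emb, probs=probs, shape=(B, T))
        return probs, emb, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.stripped:
            raise ContractError(
                "softmax head was stripped; this network only produces embeddings"
            )
        probs, _, _ = self.forward(X)
        return probs

    def embed(self, X: np.ndarray) -> np.ndarray:
        _, emb, _ = self.forward(X)
        return emb

    # -- backward --------------------------------------------------------

    def backward(self, cache: dict, dprobs: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss wrt every parameter, given d(loss)/d(probs)."""
        if self.stripped:
            raise ContractError("cannot backprop through a stripped softmax head")
        c, p = self.config, self.params
        B, T = cache["shape"]
        H = c.lstm_size
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        probs, emb = cache["probs"], cache["emb"]
        dprobs = dprobs.astype(c.dtype)

        dlogits = probs * (dprobs - np.sum(dprobs * probs, axis=1, keepdims=True))
        grads["W_out"] += emb.T @ dlogits
        grads["b_out"] += dlogits.sum(0)
        de = dlogits @ p["W_out"].T
        de_pre = de * cache["fc_mask"]
        grads["W_fc"] += cache["h2_T"].T @ de_pre
        grads["b_fc"] += de_pre.sum(0)

        dh2 = de_pre @ p["W_fc"].T
        dh1 = np.zeros((B, H), dtype=c.dtype)
        dc1 = np.zeros_like(dh1)
        dc2 = np.zeros_like(dh1)
        dC_all = np.zeros((B, T, c.n_slices, c.conv2_filters), dtype=c.dtype)
        for t in range(T - 1, -1, -1):
            dx2, dh2_rec, dc2 = self._lstm_backward(
                cache["lstm2"][t], dh2, dc2, p["W_lstm2"], grads, "lstm2", H
            )
            dctx, dh1, dc1 = self._lstm_backward(
                cache["lstm1"][t], dh1 + dx2, dc1, p["W_lstm1"], grads, "lstm1", H
            )
            dh2_att = self._attention_backward(cache["att"][t], dctx, grads, dC_all[:, t])
            dh2 = dh2_rec + dh2_att
        self._cnn_backward(cache, dC_all.reshape(B * T, c.n_slices, -1), grads)
        return grads

    @staticmethod
    def _lstm_backward(step_cache, dh, dc_in, W, grads, name, H):
        X_cat, i, f, g, o, c_prev, tc = step_cache
        do = dh * tc
        dc = dc_in + dh * o * (1.0 - tc**2)
        dZ = np.concatenate(
            [
                dc * g * i * (1.0 - i),
                dc * c_prev * f * (1.0 - f),
                dc * i * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        grads[f"W_{name}"] += X_cat.T @ dZ
        grads[f"b_{name}"] += dZ.sum(0)
        dX_cat = dZ @ W.T
        n_in = X_cat.shape[1] - H
        return dX_cat[:, :n_in], dX_cat[:, n_in:], dc * f

    def _attention_backward(self, step_cache, dctx, grads, dC_out):
        c, p = self.config, self.params
        C, u, alpha, h_prev = step_cache
        dC_out += alpha[:, :, None] * dctx[:, None, :]
        if not c.attention_enabled:
            return np.zeros_like(h_prev)
        dalpha = np.einsum("bd,bld->bl", dctx, C)
        ds = alpha * (dalpha - np.sum(dalpha * alpha, axis=1, keepdims=True))
        du = ds[:, :, None] * p["v_att"] * (1.0 - u**2)  # (B, L, A)
        grads["v_att"] += np.einsum("bl,bla->a", ds, u)
        grads["W_C"] += np.einsum("bla,bld->ad", du, C)
        dC_out += du @ p["W_C"]
        du_sum = du.sum(axis=1)
        grads["W_h"] += du_sum.T @ h_prev
        return du_sum @ p["W_h"]

    def _cnn_backward(self, cache, dC, grads):
        c, p = self.config, self.params
        k = c.kernel
        edges = cache["edges"]
        BT = dC.shape[0]
        da2 = np.zeros((BT, c.conv2_len, c.conv2_filters), dtype=c.dtype)
        for i in range(c.n_slices):
            lo, hi = edges[i], edges[i + 1]
            if c.slice_pool == "sum":
                da2[:, lo:hi] += dC[:, i : i + 1]
            else:
                da2[:, lo:hi] += dC[:, i : i + 1] / (hi - lo)
        dz2 = da2 * cache["mask2"]
        col2 = cache["col2"]
        grads["W_conv2"] += col2.reshape(-1, col2.shape[2]).T @ dz2.reshape(-1, dz2.shape[2])
        grads["b_conv2"] += dz2.sum(axis=(0, 1))
        dcol2 = (dz2 @ p["W_conv2"].T).reshape(BT, c.conv2_len, k, c.conv1_filters)
        dp1 = np.zeros((BT, c.pool_len, c.conv1_filters), dtype=c.dtype)
        for j in range(k):
            dp1[:, j : j + c.conv2_len] += dcol2[:, :, j]
        dpool_src = np.zeros((BT, c.pool_len, c.pool, c.conv1_filters), dtype=c.dtype)
        if c.pool == 2:
            arg = cache["arg"]
            dpool_src[:, :, 1] = np.where(arg, dp1, 0)
            dpool_src[:, :, 0] = np.where(arg, 0, dp1)
        else:
            np.put_along_axis(dpool_src, cache["arg"][:, :, None, :], dp1[:, :, None, :], axis=2)
        da1 = np.zeros(cache["a1_shape"], dtype=c.dtype)
        da1[:, : c.pool_len * c.pool] = dpool_src.reshape(BT, c.pool_len * c.pool, -1)
        dz1 = da1 * cache["mask1"]
        col1 = cache["col1"]
        grads["W_conv1"] += col1.reshape(-1, k).T @ dz1.reshape(-1, c.conv1_filters)
        grads["b_conv1"] += dz1.sum(axis=(0, 1))


class FusionHead:
    """FC-256 + dropout + softmax over the averaged modality embeddings."""

    PARAM_NAMES = ("W_fc", "b_fc", "W_out", "b_out")

    def __init__(self, embed_size: int, seed: int, fc_size: int = 256,
                 n_classes: int = 2, dropout: float = 0.5, dtype: str = "float32"):
        dt = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self.dropout = dropout
        self.params = {
            "W_fc": _glorot(rng, (embed_size, fc_size), dt),
            "b_fc": np.zeros(fc_size, dt),
            "W_out": _glorot(rng, (fc_size, n_classes), dt),
            "b_out": np.zeros(n_classes, dt),
        }

    def trainable_params(self) -> dict[str, np.ndarray]:
        return self.params

    def forward(self, emb: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None, need_cache: bool = False):
        p = self.params
        emb = np.asarray(emb, dtype=p["W_fc"].dtype)
        if emb.ndim != 2 or emb.shape[1] != p["W_fc"].shape[0]:
            raise ShapeError(f"expected (B, {p['W_fc'].shape[0]}) embeddings, got {emb.shape}")
        z = emb @ p["W_fc"] + p["b_fc"]
        a = np.maximum(z, 0)
        if training and self.dropout > 0:
            if rng is None:
                raise ContractError("training-mode dropout needs an explicit rng")
            keep = (rng.random(a.shape) >= self.dropout).astype(a.dtype)
            a = a * keep / (1.0 - self.dropout)
        else:
            keep = None
        logits = a @ p["W_out"] + p["b_out"]
        probs = _softmax(logits, axis=1)
        cache = {"emb": emb, "mask": z > 0, "keep": keep, "a": a, "probs": probs} if need_cache else None
        return probs, cache

    def backward(self, cache: dict, dprobs: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        probs, a = cache["probs"], cache["a"]
        dlogits = probs * (dprobs.astype(probs.dtype) - np.sum(dprobs * probs, axis=1, keepdims=True))
        grads = {
            "W_out": a.T @ dlogits,
            "b_out": dlogits.sum(0),
        }
        da = dlogits @ p["W_out"].T
        if cache["keep"] is not None:
            da = da * cache["keep"] / (1.0 - self.dropout)
        dz = da * cache["mask"]
        grads["W_fc"] = cache["emb"].T @ dz
        grads["b_fc"] = dz.sum(0)
        return grads


# -- functional views of the spec operations ------------------------------


def cnn_features(segment: np.ndarray, net: ModalNet) -> FeatureSlices:
    """CNN feature slices C_t for a single segment."""
    segment = np.asarray(segment, dtype=net.config.dtype)
    if segment.ndim != 1 or segment.shape[0] != net.config.n:
        raise ShapeError(f"expected a length-{net.config.n} segment, got {segment.shape}")
    C = net._cnn_forward(segment[None], None)[0]
    return FeatureSlices(C=C)


def attention_step(C: FeatureSlices | np.ndarray, h_prev: np.ndarray, net: ModalNet) -> AttentionState:
    """One attention evaluation: alpha over slices and the context vector."""
    Cm = C.C if isinstance(C, FeatureSlices) else np.asarray(C)
    cfg = net.config
    if Cm.ndim != 2 or Cm.shape[1] != cfg.conv2_filters:
        raise ShapeError(f"expected (L, {cfg.conv2_filters}) slices, got {Cm.shape}")
    if h_prev.shape != (cfg.lstm_size,):
        raise ShapeError(f"expected a length-{cfg.lstm_size} hidden state")
    alpha, ctx = net._attention_forward(
        Cm[None].astype(cfg.dtype), h_prev[None].astype(cfg.dtype), None
    )
    return AttentionState(alpha=alpha[0], context=ctx[0])


def forward_modal(batch: SegmentBatch, net: ModalNet):
    """Full pass over one record's segment sequence.

    Returns (embedding, probs); probs is None for a stripped network.
    """
    probs, emb, _ = net.forward(batch.segments[None])
    return emb[0], (None if probs is None else probs[0])


def fuse_forward(e_ecg, e_abp, e_ppg, head: FusionHead, training: bool = False,
                 rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Average the three modality embeddings and classify with the fusion head."""
    es = [np.asarray(e) for e in (e_ecg, e_abp, e_ppg)]
    if len({e.shape for e in es}) != 1:
        raise ShapeError("embedding dimensions differ")
    mean = np.mean(es, axis=0)
    single = mean.ndim == 1
    probs, _ = head.forward(mean[None] if single else mean, training=training, rng=rng)
    return probs[0] if single else probs


# -- checkpoints -----------------------------------------------------------


def save_checkpoint(net: ModalNet, path) -> Path:
    """Self-describing .npz container: config JSON + every parameter array."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    meta = {
        "config": asdict(net.config),
        "seed": net.seed,
        "frozen": net.frozen,
        "stripped": net.stripped,
        "provenance": net.provenance,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **net.params)
    return path


def load_checkpoint(path) -> ModalNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {k: data[k] for k in data.files if k != "__meta__"}
    net = ModalNet(ModalConfig(**meta["config"]), seed=meta["seed"])
    net.params = params
    net.frozen = meta["frozen"]
    net.stripped = meta["stripped"]
    net.provenance = meta.get("provenance", {})
    return net
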