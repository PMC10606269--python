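"""Compact NumPy runtime for the architecture descriptions in :mod:`network`.

Executes a :class:`~partprune.network.NetworkSpec` as an actual convolutional
network: forward pass, reverse-mode gradients (for training and for
gradient-based saliency), and an Adam optimizer.  Everything runs in float64
on (N, H, W, C) arrays.

Layer semantics
---------------
conv / output_head : 'same'-padded cross-correlation + bias; plain ``conv``
    layers apply ReLU, the output head emits raw per-class scores.
downsample : 2x2 max pooling (first-index tie-break, deterministic).
upsample   : 2x nearest-neighbour.
skip_merge : channel concatenation with a cached encoder output.

The runtime is deliberately small: networks here are desk-scale (tens of
thousands of parameters, 64x64 inputs), where an im2col matmul convolution
is fast enough on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import CONV_KINDS, NetworkSpec, count_params


# ---------------------------------------------------------------------------
# Weight storage


@dataclass
class WeightStore:
    """Per-layer weight arrays keyed by ``layer_id``.

    Convolutional layers hold ``w`` of shape ``(k_h, k_w, C_in, C_out)`` and
    ``b`` of shape ``(C_out,)``.  The canonical flat ordering of a layer's
    parameters is ``w.ravel()`` followed by ``b.ravel()``; pruning tie-breaks
    rely on it.
    """

    arrays: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)

    def n_params(self, layer_id: int | None = None) -> int:
        if layer_id is not None:
            return sum(a.size for a in self.arrays[layer_id].values())
        return sum(self.n_params(lid) for lid in self.arrays)

    def n_nonzero(self) -> int:
        return int(sum(np.count_nonzero(a) for d in self.arrays.values()
                       for a in d.values()))

    def flat(self, layer_id: int) -> np.ndarray:
        d = self.arrays[layer_id]
        return np.concatenate([d["w"].ravel(), d["b"].ravel()])

    def set_flat(self, layer_id: int, values: np.ndarray) -> None:
        d = self.arrays[layer_id]
        nw = d["w"].size
        d["w"] = values[:nw].reshape(d["w"].shape)
        d["b"] = values[nw:].reshape(d["b"].shape)

    def copy(self) -> "WeightStore":
        return WeightStore({lid: {k: a.copy() for k, a in d.items()}
                            for lid, d in self.arrays.items()})

    def validate_against(self, spec: NetworkSpec) -> None:
        for layer in spec.layers:
            expected = count_params(layer)
            if expected == 0:
                continue
            got = self.n_params(layer.layer_id)
            if got != expected:
                raise ValueError(
                    f"layer {layer.layer_id}: {got} weight elements, "
                    f"spec says {expected}"
                )


def init_weights(spec: NetworkSpec, seed: int) -> WeightStore:
    """Glorot-uniform weights, zero biases, fully determined by ``seed``."""
    rng = np.random.default_rng(seed)
    store = WeightStore()
    for layer in spec.layers:
        if layer.kind not in CONV_KINDS:
            continue
        k_h, k_w = layer.kernel  # type: ignore[misc]
        fan_in = k_h * k_w * layer.channels_in
        fan_out = k_h * k_w * layer.channels_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        w = rng.uniform(-limit, limit, size=(k_h, k_w, layer.channels_in,
                                             layer.channels_out))
        store.arrays[layer.layer_id] = {"w": w, "b": np.zeros(layer.channels_out)}
    return store


# ---------------------------------------------------------------------------
# Primitive ops (forward + backward)


def _im2col(xp: np.ndarray, k_h: int, k_w: int) -> np.ndarray:
    """(N, Hp, Wp, C) padded input -> (N*H*W, C*k_h*k_w) patch matrix."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k_h, k_w), axis=(1, 2))
    n, h, w = win.shape[:3]
    return np.ascontiguousarray(win).reshape(n * h * w, -1), (n, h, w)


def _conv_forward(x, w, b):
    k_h, k_w = w.shape[:2]
    ph, pw = (k_h - 1) // 2, (k_w - 1) // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    cols, (n, h, ww) = _im2col(xp, k_h, k_w)
    w2 = w.transpose(2, 0, 1, 3).reshape(-1, w.shape[3])
    out = cols @ w2 + b
    return out.reshape(n, h, ww, -1), (cols, w2, xp.shape, (ph, pw))


def _conv_backward(dout, cache, w):
    cols, w2, xp_shape, (ph, pw) = cache
    k_h, k_w, c_in, c_out = w.shape
    n, h, ww = dout.shape[:3]
    dflat = dout.reshape(-1, c_out)
    dw2 = cols.T @ dflat
    dw = dw2.reshape(c_in, k_h, k_w, c_out).transpose(1, 2, 0, 3)
    db = dflat.sum(axis=0)
    dcols = (dflat @ w2.T).reshape(n, h, ww, c_in, k_h, k_w)
    dxp = np.zeros(xp_shape)
    for i in range(k_h):
        for j in range(k_w):
            dxp[:, i:i + h, j:j + ww, :] += dcols[:, :, :, :, i, j]
    dx = dxp[:, ph:xp_shape[1] - ph, pw:xp_shape[2] - pw, :]
    return dx, dw, db


def _maxpool_forward(x):
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    xr = xr.reshape(n, h // 2, w // 2, c, 4)
    idx = xr.argmax(axis=-1)  # first max wins ties
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def _maxpool_backward(dout, cache):
    idx, (n, h, w, c) = cache
    dxr = np.zeros((n, h // 2, w // 2, c, 4))
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dxr = dxr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    return dxr.reshape(n, h, w, c)


def _upsample_forward(x):
    return x.repeat(2, axis=1).repeat(2, axis=2)


def _upsample_backward(dout):
    n, h, w, c = dout.shape
    return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


# ---------------------------------------------------------------------------
# Network executor


class Model:
    """Executable binding of a :class:`NetworkSpec` and a :class:`WeightStore`."""

    def __init__(self, spec: NetworkSpec, weights: WeightStore):
        weights.validate_against(spec)
        self.spec = spec
        self.weights = weights

    # -- forward ------------------------------------------------------------

    def forward(self, x: np.ndarray, keep_tape: bool = False):
        """Run the network on ``x`` of shape (N, H, W, C_in).

        Returns per-pixel per-class scores (N, H, W, n_classes); with
        ``keep_tape`` also a tape for :meth:`backward` that records every
        layer's output activation under ``tape.acts[layer_id]``.
        """
        if x.ndim == 3:
            x = x[..., None]
        tape = _Tape(x=x)
        cur = x
        for layer in self.spec.layers:
            lid = layer.layer_id
            if layer.kind in CONV_KINDS:
                d = self.weights.arrays[lid]
                out, cache = _conv_forward(cur, d["w"], d["b"])
                if layer.kind == "conv":
                    relu_mask = out > 0
                    out = out * relu_mask
                    tape.caches[lid] = (cache, relu_mask)
                else:
                    tape.caches[lid] = (cache, None)
            elif layer.kind == "downsample":
                out, cache = _maxpool_forward(cur)
                tape.caches[lid] = cache
            elif layer.kind == "upsample":
                out = _upsample_forward(cur)
            else:  # skip_merge
                enc = tape.acts[layer.merge_with]
                tape.caches[lid] = cur.shape[-1]
                out = np.concatenate([cur, enc], axis=-1)
            tape.acts[lid] = out
            cur = out
        if keep_tape:
            return cur, tape
        return cur

    # -- backward -----------------------------------------------------------

    def backward(self, tape: "_Tape", dscores: np.ndarray,
                 capture: set[int] | None = None):
        """Reverse-mode sweep from output-score gradients.

        Returns ``(grads, captured)`` where ``grads`` maps layer_id to
        ``{"w": dW, "b": db}`` and ``captured`` maps each requested layer_id
        to the gradient of the objective w.r.t. that layer's output.
        """
        capture = capture or set()
        grads: dict[int, dict[str, np.ndarray]] = {}
        captured: dict[int, np.ndarray] = {}
        # Gradient flowing into each layer's *output*; merged additively for
        # tensors consumed twice (encoder outputs feeding a skip merge).
        dact: dict[int, np.ndarray] = {self.spec.layers[-1].layer_id: dscores}
        layers = self.spec.layers
        for i in range(len(layers) - 1, -1, -1):
            layer = layers[i]
            lid = layer.layer_id
            dout = dact.pop(lid, None)
            if dout is None:
                continue
            if lid in capture:
                captured[lid] = dout.copy()
            prev_id = layers[i - 1].layer_id if i > 0 else None
            if layer.kind in CONV_KINDS:
                cache, relu_mask = tape.caches[lid]
                if relu_mask is not None:
                    dout = dout * relu_mask
                d = self.weights.arrays[lid]
                dx, dw, db = _conv_backward(dout, cache, d["w"])
                grads[lid] = {"w": dw, "b": db}
            elif layer.kind == "downsample":
                dx = _maxpool_backward(dout, tape.caches[lid])
            elif layer.kind == "upsample":
                dx = _upsample_backward(dout)
            else:  # skip_merge
                c_main = tape.caches[lid]
                dx, denc = dout[..., :c_main], dout[..., c_main:]
                eid = layer.merge_with
                dact[eid] = dact.get(eid, 0) + denc
            if prev_id is not None:
                dact[prev_id] = dact.get(prev_id, 0) + dx
            else:
                tape.dx = dx
        return grads, captured

    def forward_from(self, tape: "_Tape", layer_id: int,
                     activation: np.ndarray) -> np.ndarray:
        """Re-run the tail of the network with ``layer_id``'s output replaced.

        Earlier activations (e.g. encoder outputs referenced by skip merges)
        are taken from ``tape``.  Used by finite-difference checks of
        gradient-based saliency.
        """
        idx = next(i for i, l in enumerate(self.spec.layers)
                   if l.layer_id == layer_id)
        cur = activation
        acts = dict(tape.acts)
        acts[layer_id] = cur
        for layer in self.spec.layers[idx + 1:]:
            lid = layer.layer_id
            if layer.kind in CONV_KINDS:
                d = self.weights.arrays[lid]
                out, _ = _conv_forward(cur, d["w"], d["b"])
                if layer.kind == "conv":
                    out = np.maximum(out, 0.0)
            elif layer.kind == "downsample":
                out, _ = _maxpool_forward(cur)
            elif layer.kind == "upsample":
                out = _upsample_forward(cur)
            else:
                out = np.concatenate([cur, acts[layer.merge_with]], axis=-1)
            acts[lid] = out
            cur = out
        return cur


@dataclass
class _Tape:
    x: np.ndarray
    acts: dict[int, np.ndarray] = field(default_factory=dict)
    caches: dict = field(default_factory=dict)
    dx: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Optimizer


class Adam:
    """Adam with optional per-layer gradient masks (pruned weights stay zero)."""

    def __init__(self, weights: WeightStore, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.w = weights
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {lid: {k: np.zeros_like(a) for k, a in d.items()}
                  for lid, d in weights.arrays.items()}
        self.v = {lid: {k: np.zeros_like(a) for k, a in d.items()}
                  for lid, d in weights.arrays.items()}

    def step(self, grads: dict[int, dict[str, np.ndarray]],
             mask: "object | None" = None) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for lid, d in grads.items():
            layer_mask = mask.arrays.get(lid) if mask is not None else None
            for key, g in d.items():
                if layer_mask is not None:
                    g = g * layer_mask[key]
                m = self.m[lid][key] = self.b1 * self.m[lid][key] + (1 - self.b1) * g
                v = self.v[lid][key] = self.b2 * self.v[lid][key] + (1 - self.b2) * g * g
                upd = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
                a = self.w.arrays[lid][key]
                a -= upd
                if layer_mask is not None:
                    np.multiply(a, layer_mask[key], out=a)
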