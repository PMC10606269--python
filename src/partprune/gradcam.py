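"""Gradient-weighted class activation mapping (Grad-CAM) for segmentation.

For a trained model f, an input x and a class c, the method inspects a late
convolutional layer's activation A (H x W x K):

1. a class score ``Y_c`` is formed; for segmentation this package sums the
   class-c pre-softmax scores over the pixels *predicted* as c (standard
   seg-Grad-CAM practice — classification Grad-CAM has a single logit, a
   dense predictor does not),
2. channel weights ``alpha_k`` are the spatial means of ``dY_c / dA_k``,
3. the weighted activation ``L = sum_k alpha_k A_k`` is rectified
   (``ReLU``), bilinearly upsampled to the input resolution, and min-max
   normalized with the same epsilon convention as the attention maps so the
   two are directly fusable.

The default target layer is the last full-resolution convolution before the
output head.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .attention import DEFAULT_EPSILON, normalize
from .nn import Model


@dataclass
class Heatmap:
    values: np.ndarray  # 2-D
    normalized: bool
    resolution: tuple[int, int]


def class_score(model_output: np.ndarray, c: int,
                predicted_mask: np.ndarray) -> float:
    """Sum of class-c scores over pixels predicted as c.

    ``model_output`` holds per-pixel pre-softmax scores (H, W, n_classes).
    Returns 0 with a warning when no pixel is predicted as c.
    """
    if not 0 <= c < model_output.shape[-1]:
        raise ValueError(f"class {c} outside range")
    sel = predicted_mask == c
    if not sel.any():
        warnings.warn(f"no pixel predicted as class {c}; class score is 0")
        return 0.0
    return float(model_output[..., c][sel].sum())


def channel_weights(gradients: np.ndarray) -> np.ndarray:
    """alpha_k = spatial mean of channel k's gradients (H, W, K) -> (K,)."""
    if gradients.ndim != 3 or gradients.shape[0] == 0 or gradients.shape[1] == 0:
        raise ValueError("gradients must be H x W x K with nonempty extent")
    return gradients.mean(axis=(0, 1))


def weighted_activation(a: np.ndarray, alpha: np.ndarray) -> Heatmap:
    """L(i, j) = sum_k alpha_k * A(i, j, k); unnormalized, pre-ReLU."""
    if a.shape[-1] != alpha.shape[0]:
        raise ValueError("channel count mismatch between A and alpha")
    values = np.tensordot(a, alpha, axes=([-1], [0]))
    return Heatmap(values=values, normalized=False, resolution=values.shape)


def relu_heatmap(heatmap: Heatmap) -> Heatmap:
    """Elementwise max(0, .); idempotent."""
    return Heatmap(values=np.maximum(heatmap.values, 0.0), normalized=False,
                   resolution=heatmap.resolution)


def default_target_layer(model: Model) -> int:
    """Last full-resolution conv before the output head."""
    convs = [l for l in model.spec.layers if l.kind == "conv" and l.depth_level == 0]
    if not convs:
        raise ValueError("model has no full-resolution conv layer")
    return convs[-1].layer_id


def gradcam(model: Model, x: np.ndarray, c: int,
            target_layer: int | None = None,
            epsilon: float = DEFAULT_EPSILON) -> Heatmap:
    """Full Grad-CAM pipeline at input resolution, normalized to [0, 1).

    A degenerate constant map (e.g. zero gradients everywhere) normalizes
    to all zeros, with a warning.
    """
    if target_layer is None:
        target_layer = default_target_layer(model)
    model.spec.layer(target_layer)  # raises KeyError if absent
    if x.ndim == 2:
        x = x[None, ..., None]
    elif x.ndim == 3:
        x = x[None]
    scores, tape = model.forward(x, keep_tape=True)
    pred = scores[0].argmax(axis=-1)
    # Seed gradient of Y_c = sum of class-c scores over pixels predicted c.
    dscores = np.zeros_like(scores)
    sel = pred == c
    if not sel.any():
        warnings.warn(f"no pixel predicted as class {c}; Grad-CAM map is zero")
    dscores[0, ..., c][sel] = 1.0
    _, captured = model.backward(tape, dscores, capture={target_layer})
    grads = captured[target_layer][0]       # H x W x K
    acts = tape.acts[target_layer][0]
    alpha = channel_weights(grads)
    hm = relu_heatmap(weighted_activation(acts, alpha))
    h, w = x.shape[1:3]
    values = hm.values
    if values.shape != (h, w):
        values = resize(values, (h, w), order=1, mode="edge",
                        anti_aliasing=False, preserve_range=True)
    if np.ptp(values) == 0:
        warnings.warn("constant Grad-CAM map; normalizing to all zeros")
    values = normalize(values, epsilon)
    return Heatmap(values=values, normalized=True, resolution=(h, w))
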