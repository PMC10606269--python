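"""Equal-weight fusion of Grad-CAM and attention heatmaps, plus overlays.

The fused saliency is the pixelwise arithmetic mean of the two normalized
maps, so prediction-influential regions (Grad-CAM) and the designated region
of interest (Gaussian attention) contribute equally.  A ``weights`` override
exists but the default is the even split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

from .attention import AttentionHeatmap
from .gradcam import Heatmap


@dataclass
class FusedHeatmap:
    values: np.ndarray  # in [0, 1]
    provenance: tuple[str, str]


def fuse(h_gradcam: Heatmap, h_attention: AttentionHeatmap,
         weights: tuple[float, float] = (0.5, 0.5)) -> FusedHeatmap:
    """H_fusion(i, j) = (H_gradcam(i, j) + H_attention(i, j)) / 2.

    Both inputs must be normalized to [0, 1) and share a shape.  Non-default
    ``weights`` must still sum to 1.
    """
    g, a = h_gradcam.values, h_attention.values
    if g.shape != a.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {a.shape}")
    if not h_gradcam.normalized:
        raise ValueError("Grad-CAM heatmap must be normalized before fusion")
    for arr, name in ((g, "Grad-CAM"), (a, "attention")):
        if arr.min() < 0 or arr.max() >= 1:
            raise ValueError(f"{name} heatmap is not normalized to [0, 1)")
    wg, wa = weights
    if abs(wg + wa - 1.0) > 1e-12:
        raise ValueError("fusion weights must sum to 1")
    return FusedHeatmap(values=wg * g + wa * a,
                        provenance=("gradcam", "attention"))


def overlay(image: np.ndarray, heatmap: np.ndarray, alpha: float = 0.5,
            cmap: str = "jet") -> np.ndarray:
    """Blend a grayscale image with a colormapped heatmap.

    ``alpha`` = 0 returns the (RGB-replicated) input; ``alpha`` = 1 the pure
    colormapped heatmap.  Deterministic: fixed inputs give identical bytes.
    Returns uint8 RGB of shape (H, W, 3).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if image.shape != heatmap.shape:
        raise ValueError("image and heatmap shapes must match")
    lo, hi = float(image.min()), float(image.max())
    gray = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image, dtype=float)
    base = np.stack([gray] * 3, axis=-1)
    colored = colormaps[cmap](np.clip(heatmap, 0.0, 1.0))[..., :3]
    blended = (1.0 - alpha) * base + alpha * colored
    return np.clip(np.round(blended * 255.0), 0, 255).astype(np.uint8)
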