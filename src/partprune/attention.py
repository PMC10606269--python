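"""Gaussian attention heatmaps around a chosen center of attention.

A unit impulse is placed at the attention center, smoothed with a Gaussian
filter of standard deviation sigma (truncated at 4 sigma, reflect boundary),
and min-max normalized with a small epsilon in the denominator so values lie
in [0, 1) and a constant map degenerates to all zeros.  Centers are
pixel-indexed, row-major, 0-based.

The impulse initialization is this package's reading of "an empty heatmap
followed by Gaussian filtering": a literally empty (all-zero) map would stay
zero under any linear filter, whereas an impulse yields the intended
Gaussian bump around the center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

DEFAULT_EPSILON = 1e-8
DEFAULT_TRUNCATE = 4.0  # kernel truncation radius, in units of sigma


@dataclass
class AttentionConfig:
    shape: tuple[int, int]
    center: tuple[int, int]  # (row, col), 0-based
    sigma: float
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        h, w = self.shape
        r, c = self.center
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"center {self.center} outside shape {self.shape}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class AttentionHeatmap:
    values: np.ndarray  # in [0, 1)
    center: tuple[int, int]
    sigma: float


def impulse_map(shape: tuple[int, int], center: tuple[int, int]) -> np.ndarray:
    """All-zero map with a single 1 at the attention center."""
    h, w = shape
    r, c = center
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"center {center} outside shape {shape}")
    a = np.zeros(shape)
    a[r, c] = 1.0
    return a


def gaussian_smooth(a: np.ndarray, sigma: float,
                    truncate: float = DEFAULT_TRUNCATE) -> np.ndarray:
    """Convolve with a sum-one Gaussian kernel (reflect boundaries)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return ndimage.gaussian_filter(a, sigma=sigma, mode="reflect",
                                   truncate=truncate)


def normalize(a: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Min-max normalization ``(a - min) / (max - min + epsilon)``.

    Output range is a subset of [0, 1); a constant input maps to all zeros.
    The argmax is preserved for non-constant inputs.
    """
    lo = a.min()
    return (a - lo) / (a.max() - lo + epsilon)


def attention_heatmap(config: AttentionConfig) -> AttentionHeatmap:
    """Impulse -> Gaussian smoothing -> normalization, per the config."""
    a = impulse_map(config.shape, config.center)
    a = gaussian_smooth(a, config.sigma)
    a = normalize(a, config.epsilon)
    return AttentionHeatmap(values=a, center=config.center, sigma=config.sigma)


def choose_center(predicted_mask: np.ndarray, target_label: int) -> tuple[int, int]:
    """Integer centroid of the target label's pixels (half rounds toward 0).

    Convenience rule for picking an attention center from a predicted mask;
    raises with guidance when the label is absent so callers can supply an
    explicit center instead.
    """
    rows, cols = np.nonzero(predicted_mask == target_label)
    if rows.size == 0:
        raise ValueError(
            f"label {target_label} absent from the mask; pass an explicit "
            f"center (e.g. --center ROW,COL)"
        )
    # round half toward the origin: 4.5 -> 4
    return (int(math.ceil(rows.mean() - 0.5)), int(math.ceil(cols.mean() - 0.5)))
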