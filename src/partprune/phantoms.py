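"""Seeded CT-like kidney/tumor phantoms with ground-truth masks.

Each phantom is a 2-D grayscale slice containing two elliptical "kidneys"
at randomized positions and orientations, with one disc-shaped "tumor"
embedded entirely inside a kidney.  Intensities are piecewise constant in
HU-like arbitrary units with additive Gaussian noise; labels are
0 = background, 1 = kidney, 2 = tumor.  Every sample is fully determined by
``(seed, index)``, so datasets are reproducible across runs and platforms.

Samples round-trip through NIfTI-1 image/mask file pairs, matching the
format of the kidney-tumor CT segmentation challenge data this generator
emulates.  The generator does not attempt realistic CT texture (no beam
hardening, streaks, or cysts) — it provides geometry and contrast that a
segmentation network must genuinely learn, at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from skimage.draw import disk, ellipse

from .attention import DEFAULT_EPSILON

BACKGROUND, KIDNEY, TUMOR = 0, 1, 2


@dataclass
class PhantomConfig:
    image_size: tuple[int, int] = (64, 64)
    n_samples: int = 40
    kidney_axes_range: tuple[tuple[int, int], tuple[int, int]] = ((9, 13), (6, 9))
    tumor_radius_range: tuple[int, int] = (2, 5)
    intensity: dict = field(default_factory=lambda: {
        "background": 50.0, "kidney": 120.0, "tumor": 190.0, "noise_sd": 10.0})
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_radius_range[1] >= self.kidney_axes_range[1][0]:
            raise ValueError(
                "largest tumor radius must stay below the smallest kidney "
                "semi-axis so containment is feasible"
            )
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class SegmentationSample:
    image: np.ndarray  # float32, HU-like units
    mask: np.ndarray   # uint8 labels {0, 1, 2}
    sample_id: str
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    meta: dict = field(default_factory=dict)  # generator provenance


def generate_sample(config: PhantomConfig, index: int) -> SegmentationSample:
    """One phantom, fully determined by ``(config.seed, index)``."""
    rng = np.random.default_rng([config.seed, index])
    h, w = config.image_size
    (a_lo, a_hi), (b_lo, b_hi) = config.kidney_axes_range
    mask = np.zeros((h, w), dtype=np.uint8)

    # Two kidneys, one per lateral half, mirroring abdominal anatomy.
    kidney_params = []
    for half in (0, 1):
        a = rng.integers(a_lo, a_hi + 1)
        b = rng.integers(b_lo, b_hi + 1)
        r = rng.integers(a_hi, h - a_hi)
        lo = half * (w // 2) + a_hi
        c = rng.integers(lo, lo + w // 2 - 2 * a_hi)
        rot = rng.uniform(-0.6, 0.6)
        rr, cc = ellipse(r, c, a, b, shape=(h, w), rotation=rot)
        mask[rr, cc] = KIDNEY
        kidney_params.append((r, c, a, b, rot))

    # One tumor disc fully inside a kidney, by rejection sampling.
    t_lo, t_hi = config.tumor_radius_range
    for attempt in range(100):
        kr, kc, ka, kb, _ = kidney_params[rng.integers(0, 2)]
        radius = int(rng.integers(t_lo, t_hi + 1))
        tr = int(kr + rng.integers(-ka // 2, ka // 2 + 1))
        tc = int(kc + rng.integers(-kb // 2, kb // 2 + 1))
        # require a one-pixel kidney margin so the tumor is strictly interior
        mr, mc = disk((tr, tc), radius + 1, shape=(h, w))
        rr, cc = disk((tr, tc), radius, shape=(h, w))
        if rr.size and np.all(mask[mr, mc] == KIDNEY):
            mask[rr, cc] = TUMOR
            tumor_meta = {"tumor_center": (tr, tc), "tumor_radius": radius}
            break
    else:
        raise RuntimeError(
            f"no feasible tumor placement after 100 attempts (sample {index})"
        )

    levels = config.intensity
    image = np.choose(mask, [levels["background"], levels["kidney"],
                             levels["tumor"]]).astype(np.float64)
    image += rng.normal(0.0, levels["noise_sd"], size=(h, w))
    return SegmentationSample(image=image.astype(np.float32), mask=mask,
                              sample_id=f"phantom_{config.seed}_{index:04d}",
                              meta=tumor_meta)


def apportion(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of ``n`` items across fractions."""
    quotas = [n * f for f in fractions]
    counts = [int(q) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: quotas[i] - counts[i],
                   reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def generate_dataset(config: PhantomConfig) -> dict[str, list[SegmentationSample]]:
    """Disjoint train/val/test splits with largest-remainder counts."""
    if config.n_samples < 3:
        raise ValueError("need at least 3 samples to split")
    samples = [generate_sample(config, i) for i in range(config.n_samples)]
    n_train, n_val, n_test = apportion(config.n_samples, config.split_fractions)
    return {
        "train": samples[:n_train],
        "val": samples[n_train:n_train + n_val],
        "test": samples[n_train + n_val:],
    }


def normalize_intensity(image: np.ndarray,
                        epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Per-image min-max normalization to [0, 1); constant images -> zeros."""
    lo = image.min()
    return (image - lo) / (image.max() - lo + epsilon)


_AUGMENTS = ("identity", "rot90", "rot180", "rot270", "hflip", "vflip")


def augment(sample: SegmentationSample, seed: int) -> SegmentationSample:
    """Seeded right-angle rotation or flip, applied to image and mask alike."""
    rng = np.random.default_rng(seed)
    op = _AUGMENTS[rng.integers(0, len(_AUGMENTS))]
    return apply_augment(sample, op)


def apply_augment(sample: SegmentationSample, op: str) -> SegmentationSample:
    fns = {
        "identity": lambda a: a,
        "rot90": lambda a: np.rot90(a, 1),
        "rot180": lambda a: np.rot90(a, 2),
        "rot270": lambda a: np.rot90(a, 3),
        "hflip": lambda a: a[:, ::-1],
        "vflip": lambda a: a[::-1, :],
    }
    if op not in fns:
        raise ValueError(f"unknown augmentation {op!r}")
    f = fns[op]
    return SegmentationSample(image=np.ascontiguousarray(f(sample.image)),
                              mask=np.ascontiguousarray(f(sample.mask)),
                              sample_id=f"{sample.sample_id}+{op}",
                              affine=sample.affine.copy())


class NiftiFormatError(ValueError):
    """Raised when a NIfTI image/mask pair is malformed."""


def write_nifti(sample: SegmentationSample, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>_image.nii.gz`` and ``<prefix>_mask.nii.gz``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    img_path = prefix.with_name(prefix.name + "_image.nii.gz")
    mask_path = prefix.with_name(prefix.name + "_mask.nii.gz")
    nib.save(nib.Nifti1Image(sample.image.astype(np.float32), sample.affine),
             img_path)
    nib.save(nib.Nifti1Image(sample.mask.astype(np.uint8), sample.affine),
             mask_path)
    return img_path, mask_path


def read_nifti(prefix: str | Path) -> SegmentationSample:
    """Read an image/mask NIfTI pair written by :func:`write_nifti`."""
    prefix = Path(prefix)
    img_path = prefix.with_name(prefix.name + "_image.nii.gz")
    mask_path = prefix.with_name(prefix.name + "_mask.nii.gz")
    for p in (img_path, mask_path):
        if not p.exists():
            raise NiftiFormatError(f"missing file: {p}")
    img = nib.load(img_path)
    msk = nib.load(mask_path)
    image = np.asarray(img.dataobj, dtype=np.float32)
    mask = np.asarray(msk.dataobj)
    if image.shape != mask.shape:
        raise NiftiFormatError(
            f"shape mismatch: image {image.shape} vs mask {mask.shape}"
        )
    if not np.issubdtype(mask.dtype, np.integer):
        raise NiftiFormatError(f"mask dtype {mask.dtype} is not integer")
    if not np.allclose(img.affine, msk.affine):
        raise NiftiFormatError("image and mask affines differ")
    return SegmentationSample(image=image, mask=mask.astype(np.uint8),
                              sample_id=prefix.name, affine=img.affine)
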