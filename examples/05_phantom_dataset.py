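"""Generate a reproducible phantom dataset and round-trip it through NIfTI.

Each phantom is a CT-like 2-D slice with two elliptical kidneys and one
tumor disc embedded in a kidney; labels are 0 background, 1 kidney, 2 tumor.
"""

import tempfile
from pathlib import Path

import numpy as np

from partprune import (PhantomConfig, generate_dataset, read_nifti,
                       write_nifti)

cfg = PhantomConfig(n_samples=20, seed=42)
splits = generate_dataset(cfg)
print({k: len(v) for k, v in splits.items()})  # 70/15/15 split -> 14/3/3

s = splits["train"][0]
labels, counts = np.unique(s.mask, return_counts=True)
print(f"sample {s.sample_id}: labels {labels.tolist()}, "
      f"pixel counts {counts.tolist()}")
print(f"tumor radius drawn: {s.meta['tumor_radius']} px "
      f"at {s.meta['tumor_center']}")

with tempfile.TemporaryDirectory() as d:
    write_nifti(s, Path(d) / "case0")
    back = read_nifti(Path(d) / "case0")
    print("NIfTI round-trip bit-exact:",
          np.array_equal(back.image, s.image)
          and np.array_equal(back.mask, s.mask))
# The dataset is fully determined by (seed, index): regenerating with the
# same config reproduces every voxel, which is what makes the training and
# acceptance runs reproducible.
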