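"""Profile a U-Net's per-layer complexity and partition it into submodels.

Builds a depth-5 encoder-decoder, computes each layer's parameter count,
FLOPs and complexity (their product), then splits the layer sequence into at
most 3 contiguous submodels under a 10-million-FLOP per-submodel cap.
"""

from partprune import PartitionConfig, build_unet, partition, profile

spec = build_unet(depth=5, base_channels=8, in_shape=(64, 64), n_classes=3)
prof = profile(spec)

print(f"layers: {len(spec.layers)}")
print(f"total trainable parameters: {prof.total_params:,}")
print(f"total FLOPs: {prof.total_flops:,}")
print(f"total complexity (sum of P_i * FLOPs_i): {prof.total:,}")

plan = partition(prof,
                 PartitionConfig(max_c=10_000_000, max_p=3,
                                 budget_basis="flops"),
                 network=spec)
print(f"\npartitioned into {plan.n_segments} submodels "
      f"(even-split target {float(plan.target_c):,.0f} FLOPs, "
      f"effective cap {plan.effective_cap:,.0f}):")
for i, seg in enumerate(plan.segments):
    print(f"  submodel {i + 1}: layers {seg.layer_ids[0]}-{seg.layer_ids[-1]}, "
          f"{seg.params:,} params, {seg.flops:,} FLOPs, "
          f"levels {seg.depth_span}")
if plan.flags:
    print("flags:", *plan.flags, sep="\n  ")
print("\nSkip tensors crossing submodel boundaries (extra segment I/O):",
      plan.crossing_tensors)
# Each submodel is a contiguous run of layers; segment FLOPs sum exactly to
# the network total, and flags mark any segment the cap could not fit.
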