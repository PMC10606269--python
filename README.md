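# partprune

Resource-aware training and explanation of encoder–decoder segmentation
networks, exercised end-to-end on synthetic CT-like kidney/tumor phantoms.

Deep U-Nets for volumetric medical segmentation are often too large for the
hardware they must eventually run on. `partprune` implements a recipe for
producing compact, interpretable segmentation models:

1. **Complexity profiling** — every layer *L_i* is scored by
   *c_i = P_i × FLOPs_i*, the product of its learnable-parameter count and
   its inference cost.
2. **Adaptive partitioning** — the layer sequence is split into at most
   *max_p* contiguous submodels, each under the budget
   min(*target_c*, *max_c*) with *target_c* = TotalComplexity / *max_p*.
   Budgets can be expressed in complexity units or raw FLOPs (the
   10-million-FLOP per-submodel cap with 3 partitions is the reference
   setting).
3. **Progressive depth growth** — a shallow stage is trained first, then
   deepened at the bottleneck; with a channel-doubling schedule every
   existing layer keeps its shape, so trained weights transfer
   bit-identically and only the new deepest level starts fresh.
4. **Magnitude weight pruning** — the fraction *r* (reference value 0.2) of
   smallest-|w| weights is set to exactly zero and held there through
   fine-tuning by masking gradients; counts are exact:
   round(*r*·N) weights per scope unit.
5. **Explainability** — Grad-CAM adapted to segmentation
   (α_k = mean spatial gradient of the class score Y_c w.r.t. activation
   channel k; H = ReLU(Σ_k α_k A_k)), a Gaussian attention bump around a
   chosen center (A′ = G_σ ∗ A, min–max–ε normalized), and their
   equal-weight fusion H_fusion = (H_GradCAM + H_attention)/2.

Everything runs on plain NumPy in float64 — the network runtime (forward,
reverse-mode gradients, Adam) is part of the package — so results are exactly
reproducible from a seed on any machine, with no GPU or framework required.
A seeded phantom generator supplies CT-like kidney/tumor slices with ground
truth (labels: 0 background, 1 kidney, 2 tumor) in NIfTI-1, so the whole
pipeline is testable without any external dataset.

## Worked example

`examples/03_progressive_training.py` trains progressively on 40 seeded
64×64 phantoms, prunes 20% and fine-tunes (about two minutes on one CPU
core):

```
stage 1 (depth 2): 6,499 params, test dice 0.940
stage 2 (depth 3): 29,635 params, test dice 0.969
after pruning: sparsity 20.0%, non-zero params 23,707
test dice (kidney): 0.991
test dice (tumor):  0.955
pixel accuracy:     0.998
```

Reading: growth from depth 2 to 3 raises mean foreground dice from 0.940 to
0.969; removing a fifth of the weights and fine-tuning leaves tumor dice at
0.955 — pruning at this ratio costs essentially nothing on this task.

`examples/04_explainability.py` then locates the tumor with the fused
saliency map:

```
true tumor bounding box: rows 17-21, cols 46-50
Grad-CAM peak: (19, 48)
attention center (predicted tumor centroid): (19, 48)
fused peak: (19, 48)
```

The fused peak lands inside the true tumor box. The other examples cover
profiling/partitioning (`01`), exact pruning arithmetic (`02`) and the
phantom generator with NIfTI round-trips (`05`).

## Command line

A thin CLI wraps the library:

```bash
partprune profile --depth 5
partprune partition --depth 5 --max-p 3 --max-c 10000000
partprune prune --ratio 0.2
partprune simulate --n 16 --out phantoms/
partprune run pipeline.yaml     # simulate -> profile -> partition ->
                                # progressive train+prune -> explain -> report
```

Exit codes: 0 success, 2 configuration error, 3 stage failure.

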