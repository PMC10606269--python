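# Methods

This note documents the models, conventions and design choices behind
`partprune`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open choices were made.

## Complexity model

A network is an ordered list of layers in topological order. Per layer:

* **Parameters** `P_i`: for a convolution (including the 1×1 output head),
  `k_h·k_w·C_in·C_out + C_out`; biases count. Downsampling, upsampling and
  skip-merge layers are parameter-free.
* **FLOPs** `FLOPs_i`: `2·k_h·k_w·C_in·C_out·H_out·W_out` for convolutions
  (one multiply–accumulate = 2 FLOPs; bias adds and activations excluded;
  the factor is configurable), and one operation per output element
  (`H_out·W_out·C_out`) for parameter-free layers. FLOP conventions differ
  across the literature; this one is stated explicitly so numbers are
  comparable across runs of this package.
* **Complexity** `c_i = P_i × FLOPs_i`, and the network total is the exact
  sum. All counting is integer arithmetic: products exceed 10¹² even for
  small networks and floating point would silently lose precision.

The canonical substrate is 2-D (H×W slices). The layer format admits a
third spatial dimension in principle, but all shipped generators, tests and
studies are 2-D.

## Partitioning

The even-split target is `target_c = TotalComplexity / max_p`, kept as an
exact rational so cap comparisons carry no rounding slack. The partition
algorithm is **greedy contiguous accumulation** in topological order: a
segment closes when adding the next layer would push it over the effective
cap `min(target_c, max_c)`. This choice (over, say, dynamic programming for
the optimal contiguous partition) favors determinism and transparency; the
exhaustive-search optimum is retained in the test suite as an oracle, where
greedy is verified to stay within 2× of optimal on all small profiles and
to match it exactly on crafted fixtures.

Two budget bases are supported: `complexity` (the `c_i` units above) and
`flops` (summed `FLOPs_i`), the latter being the default and the basis of
the reference setting *max_c* = 10⁷ FLOPs, *max_p* = 3. If no contiguous
split can respect the cap, the final segment absorbs the remaining layers
and the plan is **flagged rather than rejected** — the bound on the number
of partitions is treated as the primary contract. Skip connections whose
endpoints fall in different segments are recorded as explicit extra segment
inputs/outputs, so segments can execute sequentially on one device.

## Progressive growth

Stages have strictly increasing depth, ending at the full depth, with at
most *max_p* stages (depth sequence 2, 3, …, full — e.g. 2→3→5 for a
depth-5 target with three stages). Growth happens at the **bottleneck**:
with the channel-doubling schedule (`C_level = base·2^level`), deepening
adds a new deepest level (downsample, two encoder convolutions, upsample,
skip merge, two decoder convolutions) while every pre-existing layer keeps
its exact shape. Trained weights therefore transfer **bit-identically**;
new layers are Glorot-uniform initialized from a caller-supplied seed.
Layer matching across depths uses stable role tags (`enc0/conv1`, …), not
indices.

How a "consistent parameter count" is maintained while deepening is an open
design point; here each stage carries a parameter budget and is pruned back
to at most that many non-zero weights after training (prune-to-budget).

## Pruning

Unstructured magnitude pruning: the `round(ratio·N)` smallest-|w| weights
(half rounds away from zero, so a 0.2 ratio is exact whenever N is
divisible by 5) are set to exactly zero. Ties in |w| break
deterministically by (layer, flat index), a layer's flat order being kernel
then bias. Biases participate like any other weight. The default scope is
**per-layer** — a single large layer cannot absorb the entire quota —
with a global scope available.

The iterative loop splits the target ratio evenly across iterations, each
round pruning `ratio/iterations` of the *currently kept* weights and then
fine-tuning with gradients masked, so pruned weights stay exactly zero
through training (verified by the tests before and after every epoch). The
cumulative sparsity after k rounds is `1 − (1 − ratio/k)^k`, marginally
below the single-shot ratio for k > 1 (e.g. 0.19 for ratio 0.2 in two
rounds); single-shot pruning (iterations = 1, the default) hits the ratio
exactly up to rounding. Whether pruning precedes or follows a growth stage
is configurable; the shipped pipeline prunes after the final growth and
fine-tunes, matching the post-growth reading of the recipe.

No sparse kernels are used: pruning reduces *counts*, and the package
reports counts, not wall-clock speedups.

## Network runtime

The runtime executes layer lists directly in NumPy/float64: 'same'-padded
im2col convolutions with ReLU, 2×2 max pooling (first-index tie-break), 2×
nearest-neighbour upsampling, channel concatenation, and a linear 1×1
head. Reverse-mode gradients are implemented per primitive and verified
against central finite differences (relative error ~10⁻⁶ at ε = 10⁻⁶).
Float64 everywhere makes runs bit-reproducible from a seed on one CPU and
gives finite-difference oracles enough headroom. At the desk scale this
package targets (≤ 10⁵ parameters, 64×64 inputs), the im2col matmuls are
fast enough that a training study completes in minutes on one core.

## Training

Adam (lr 3·10⁻³ by default; the reference protocol leaves the rate
unstated) minimizes a segmentation loss over the foreground classes
(kidney, tumor). **Pure soft-dice from random initialization is unstable
for very small structures**: once the softmax saturates against the tumor
class, the dice gradient is damped by the class probability itself and the
collapsed channel cannot recover — observed as tumor dice pinned at 0.
The default objective is therefore the standard compound
`dice + cross-entropy` with a 5-epoch CE-only warmup; pure dice remains
available (`loss="dice"`), and `paper_protocol()` configures the
published-style 100-epoch/batch-12 pure-dice run. Desk-scale defaults are
20 epochs, batch 2, 64×64 slices: small batches give the optimizer enough
steps (≈280) for the tumor class to lift off within 20 epochs.

Soft dice uses smoothing s = 1.0 and batch-aggregated sums per class,
averaged over the foreground classes. Argmax ties in prediction resolve to
the lowest label, so an untrained all-zero model predicts background.
Metrics with zero denominators (e.g. dice when neither mask contains the
label) are reported as *undefined* (`None`), never as 0.

## Saliency

* **Grad-CAM for segmentation.** Classification Grad-CAM needs a scalar
  class score; a dense predictor has none. Here
  `Y_c = Σ_{p: pred(p)=c} score_c(p)` — the sum of class-c pre-softmax
  scores over pixels *predicted* as c — which is differentiable and follows
  common seg-Grad-CAM practice. Channel weights are spatial means of
  `∂Y_c/∂A`; the weighted activation map is rectified, bilinearly upsampled
  to input resolution, and min–max–ε normalized. The default target layer
  is the last full-resolution convolution before the head (selectable).
  The autodiff gradients are validated against central finite differences
  of `Y_c` on a two-convolution toy network (relative error ≤ 10⁻³).
* **Gaussian attention.** A literal "empty heatmap" smoothed by a Gaussian
  stays identically zero; this package places a **unit impulse at the
  attention center** so smoothing yields the intended Gaussian bump — the
  only reading that highlights a region around the center. σ is truncated
  at 4σ with reflect boundaries; normalization uses
  `(A′ − min)/(max − min + ε)` with ε = 10⁻⁸, mapping constants to zero and
  keeping values in [0, 1). Centers are 0-based (row, col) pixels; a
  convenience rule picks the predicted-mask centroid of a target label
  (half-pixel ties round toward the origin).
* **Fusion.** The pixelwise mean of the two normalized maps; both inputs
  must share the input resolution and be normalized, enforced at the call.
  Weights are fixed at ½ each by default, with an override.

## Phantom generator

Each phantom is a 2-D slice with two elliptical "kidneys" (randomized
positions, semi-axes and orientation, one per lateral half) and one tumor
disc placed by rejection sampling strictly inside a kidney (one-pixel
margin). Intensities are piecewise constant in arbitrary HU-like units
(background 50, kidney 120, tumor 190, Gaussian noise σ = 10) — separable
but noisy, so a model must genuinely learn the geometry. Labels: 0/1/2.
Defaults: 64×64, 40 samples, 70/15/15 split by largest-remainder
apportionment (the split fractions mirror a 342/73/73 case division).
Every sample is fully determined by (seed, index) via a counter-based RNG
stream, so datasets reproduce bit-exactly across platforms.

What the generator does **not** emulate: real CT texture (beam hardening,
streaks), cysts, 3-D anatomy, or inter-scanner intensity variation.
Passing tests on phantoms demonstrates that the mechanics — profiling,
partitioning, growth, pruning, training, saliency — behave as specified;
they say nothing about segmentation accuracy on clinical CT.

## Problem sizes and numerical choices

The shipped studies use depth-2→3 U-Nets with base width 8 (29,635
parameters at depth 3) on 40 phantoms for 20 epochs — sizes chosen so the
full train/prune/compare study runs in about two minutes on a single CPU
core while still exhibiting the phenomena of interest (transfer, prune
robustness, saliency localization). Dice comparisons between the pruned
model and its dense baseline use identical schedules and update counts
(the baseline trains the same extra epochs the pruned model spends
fine-tuning). ε-conventions, kernel truncation, tie-breaks and rounding
rules are all stated above and fixed in code; none is load-bearing for
correctness, only for reproducibility.

## Known limitations

* Greedy partitioning is not optimal; it is deterministic and within 2× of
  the contiguous optimum on small profiles (tested), which suffices for
  budget-respecting splits.
* The runtime is CPU/NumPy only and desk-scale by design; it is not a
  general training framework.
* Sparsity is logical (zeros), not physical (no sparse storage/kernels).
* Heatmap quality is assessed by tumor-box localization only; no deletion/
  insertion or pointing-game metrics are implemented.
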