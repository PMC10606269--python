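"""Magnitude pruning: exact counts, magnitude ordering, mask persistence."""

import numpy as np
import pytest

from partprune import (
    PruneConfig,
    PruneMask,
    apply_mask,
    build_unet,
    init_weights,
    iterative_prune_finetune,
    magnitude_prune,
)
from partprune.nn import WeightStore


def store_from(values, layer_id=0):
    """Single-layer store whose flat order equals ``values`` (bias empty)."""
    w = np.asarray(values, dtype=float)
    return WeightStore({layer_id: {"w": w, "b": np.zeros(0)}})


class TestMagnitudePrune:
    def test_keeps_two_largest_magnitudes(self):
        ws = store_from([0.5, -0.1, 0.3, 0.05])
        mask = magnitude_prune(ws, PruneConfig(ratio=0.5, scope="global"))
        kept = apply_mask(ws, mask).arrays[0]["w"]
        assert set(kept[kept != 0]) == {0.5, 0.3}

    @pytest.mark.parametrize("ratio, n_zero", [(0.0, 0), (1.0, 6)])
    def test_boundary_ratios(self, ratio, n_zero):
        ws = store_from([1, -2, 3, -4, 5, -6])
        mask = magnitude_prune(ws, PruneConfig(ratio=ratio))
        assert mask.n_pruned() == n_zero

    def test_ratio_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            PruneConfig(ratio=1.5)

    def test_twenty_percent_of_1000_weights_is_exactly_200(self, rng):
        ws = store_from(rng.normal(size=1000))
        mask = magnitude_prune(ws, PruneConfig(ratio=0.2, scope="global"))
        pruned = apply_mask(ws, mask)
        assert int((pruned.arrays[0]["w"] == 0).sum()) == 200

    def test_pruned_count_is_round_ratio_n(self, rng):
        """round(ratio*N), half away from zero, over random (N, ratio)."""
        for _ in range(50):
            n = int(rng.integers(1, 400))
            ratio = float(rng.uniform(0, 1))
            ws = store_from(rng.normal(size=n))
            mask = magnitude_prune(ws, PruneConfig(ratio=ratio, scope="global"))
            assert mask.n_pruned() == int(np.floor(ratio * n + 0.5))

    def test_magnitude_order_within_each_scope_unit(self, rng):
        net = build_unet(2, 4, (16, 16), 3)
        ws = init_weights(net, 11)
        for scope in ("per_layer", "global"):
            mask = magnitude_prune(ws, PruneConfig(ratio=0.3, scope=scope))
            units = (list(ws.arrays) if scope == "per_layer"
                     else [list(ws.arrays)])
            for unit in units:
                lids = unit if isinstance(unit, list) else [unit]
                w = np.concatenate([ws.flat(l) for l in lids])
                m = np.concatenate([mask.flat(l) for l in lids])
                pruned, kept = np.abs(w[m == 0]), np.abs(w[m == 1])
                if pruned.size and kept.size:
                    assert pruned.max() <= kept.min()

    def test_tie_break_by_layer_then_index(self):
        ws = WeightStore({
            0: {"w": np.array([0.5, 0.1]), "b": np.zeros(0)},
            1: {"w": np.array([0.1, 0.9]), "b": np.zeros(0)},
        })
        mask = magnitude_prune(ws, PruneConfig(ratio=0.25, scope="global"))
        # one weight pruned; the |0.1| tie resolves to layer 0, index 1
        assert mask.arrays[0]["w"].tolist() == [1.0, 0.0]
        assert mask.arrays[1]["w"].tolist() == [1.0, 1.0]

    def test_per_layer_scope_prunes_each_layer(self):
        ws = WeightStore({
            0: {"w": np.linspace(1, 10, 10), "b": np.zeros(0)},
            1: {"w": np.linspace(100, 1000, 10), "b": np.zeros(0)},
        })
        mask = magnitude_prune(ws, PruneConfig(ratio=0.2, scope="per_layer"))
        assert mask.n_pruned(0) == 2 and mask.n_pruned(1) == 2


class TestApplyMask:
    def test_all_ones_identity(self, toy_weights):
        mask = PruneMask.ones_like(toy_weights)
        out = apply_mask(toy_weights, mask)
        for lid in toy_weights.arrays:
            for k in toy_weights.arrays[lid]:
                assert np.array_equal(out.arrays[lid][k],
                                      toy_weights.arrays[lid][k])

    def test_all_zeros_gives_zero_store(self, toy_weights):
        mask = PruneMask.ones_like(toy_weights)
        for d in mask.arrays.values():
            for k in d:
                d[k][:] = 0
        out = apply_mask(toy_weights, mask)
        assert out.n_nonzero() == 0

    def test_idempotent(self, toy_weights):
        mask = magnitude_prune(toy_weights, PruneConfig(ratio=0.4))
        once = apply_mask(toy_weights, mask)
        twice = apply_mask(once, mask)
        for lid in once.arrays:
            for k in once.arrays[lid]:
                assert np.array_equal(once.arrays[lid][k], twice.arrays[lid][k])

    def test_shape_mismatch_rejected(self, toy_weights):
        mask = PruneMask.ones_like(toy_weights)
        lid = next(iter(mask.arrays))
        mask.arrays[lid]["w"] = mask.arrays[lid]["w"][..., :1]
        with pytest.raises(ValueError):
            apply_mask(toy_weights, mask)


class TestIterativePruneFinetune:
    def test_degenerate_loop_equals_single_prune(self, toy_unet, toy_weights):
        cfg = PruneConfig(ratio=0.2, iterations=1,
                          finetune_epochs_per_iteration=0)
        w_it, mask_it, _ = iterative_prune_finetune(
            (toy_unet, toy_weights), None, cfg)
        mask_direct = magnitude_prune(toy_weights, PruneConfig(ratio=0.2))
        w_direct = apply_mask(toy_weights, mask_direct)
        for lid in w_it.arrays:
            for k in w_it.arrays[lid]:
                assert np.array_equal(w_it.arrays[lid][k],
                                      w_direct.arrays[lid][k])

    def test_cumulative_two_iterations_reach_19_percent(self):
        ws = store_from(np.random.default_rng(3).normal(size=1000))
        spec = None  # no training, spec unused with 0 fine-tune epochs
        cfg = PruneConfig(ratio=0.2, iterations=2, scope="global",
                          finetune_epochs_per_iteration=0)
        _, mask, hist = iterative_prune_finetune((spec, ws), None, cfg)
        # 10% of 1000, then 10% of the remaining 900 -> 190 of 1000
        assert mask.n_pruned() == 190
        assert [h["sparsity"] for h in hist] == [0.1, 0.19]

    def test_sparsity_nondecreasing_and_zeros_persist_through_finetune(
            self, tiny_dataset):
        from partprune import TrainConfig, build_unet, init_weights

        spec = build_unet(2, 4, (32, 32), 3)
        ws = init_weights(spec, 2)
        cfg = PruneConfig(ratio=0.2, iterations=2,
                          finetune_epochs_per_iteration=1)
        tc = TrainConfig(epochs=1, seed=2)
        w, mask, hist = iterative_prune_finetune(
            (spec, ws), tiny_dataset["train"][:2], cfg, tc)
        sparsities = [h["sparsity"] for h in hist]
        assert sparsities == sorted(sparsities)
        # every masked weight is exactly zero after training epochs
        for lid in w.arrays:
            for k in w.arrays[lid]:
                zero_set = mask.arrays[lid][k] == 0
                assert np.all(w.arrays[lid][k][zero_set] == 0.0)
        assert w.n_nonzero() <= mask.n_total() - mask.n_pruned()
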