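"""Adaptive partitioning, the even-split target, and progressive growth."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from partprune import (
    PartitionConfig,
    build_unet,
    init_weights,
    partition,
    profile,
    progressive_schedule,
    target_complexity,
)
from partprune.network import ComplexityProfile, count_params
from partprune.partition import deepen, grow_submodel, stage_depths


def make_profile(values):
    """Profile from raw per-layer values, used as both complexity and FLOPs."""
    per = tuple((i, v) for i, v in enumerate(values))
    return ComplexityProfile(per_layer=per, total=sum(values),
                             per_layer_params=tuple((i, 1) for i, _ in per),
                             per_layer_flops=per)


def brute_force_best_max_segment(values, k):
    """Minimal largest-segment sum over all contiguous k-partitions."""
    n = len(values)
    best = None
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        worst = max(sum(values[a:b]) for a, b in zip(bounds, bounds[1:]))
        best = worst if best is None else min(best, worst)
    return best


class TestTargetComplexity:
    @pytest.mark.parametrize("total, max_p, expected", [
        (30, 3, 10),
        (0, 5, 0),
        (7, 2, Fraction(7, 2)),  # non-integer quotient preserved exactly
    ])
    def test_quotient(self, total, max_p, expected):
        assert target_complexity(total, max_p) == expected

    def test_zero_partitions_rejected(self):
        with pytest.raises(ValueError):
            target_complexity(10, 0)


class TestPartition:
    def test_exact_thirds(self):
        plan = partition(make_profile([5, 5, 5]), PartitionConfig(max_p=3))
        assert [s.layer_ids for s in plan.segments] == [(0,), (1,), (2,)]
        assert plan.target_c == 5

    def test_balanced_halves(self):
        plan = partition(make_profile([1, 1, 1, 1]), PartitionConfig(max_p=2))
        assert [s.layer_ids for s in plan.segments] == [(0, 1), (2, 3)]

    def test_greedy_matches_bruteforce_on_crafted_fixture(self):
        values = [3, 1, 3, 1]
        plan = partition(make_profile(values), PartitionConfig(max_p=2))
        greedy_worst = max(s.flops for s in plan.segments)
        assert greedy_worst == brute_force_best_max_segment(values, 2)

    def test_greedy_within_2x_of_bruteforce(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 9))
            values = [int(v) for v in rng.integers(1, 100, size=n)]
            k = int(rng.integers(1, n + 1))
            plan = partition(make_profile(values), PartitionConfig(max_p=k))
            greedy_worst = max(s.flops for s in plan.segments)
            assert greedy_worst <= 2 * brute_force_best_max_segment(values, min(k, n))

    def test_coverage_and_conservation(self, rng):
        for _ in range(100):
            values = [int(v) for v in rng.integers(0, 50, size=rng.integers(1, 12))]
            prof = make_profile(values)
            plan = partition(prof, PartitionConfig(max_p=int(rng.integers(1, 5))))
            covered = [i for s in plan.segments for i in s.layer_ids]
            assert covered == list(range(len(values)))  # disjoint, ordered, total
            assert sum(s.complexity for s in plan.segments) == prof.total

    def test_cap_respected_when_feasible(self):
        values = [4, 4, 4, 4, 4, 4]
        plan = partition(make_profile(values), PartitionConfig(max_p=3))
        assert plan.target_c == 8
        assert all(s.flops <= plan.target_c for s in plan.segments)
        assert plan.flags == []

    def test_infeasible_budget_flags_not_raises(self):
        plan = partition(make_profile([10, 10, 10, 10]),
                         PartitionConfig(max_p=2, max_c=5))
        assert plan.n_segments <= 2
        assert plan.flags  # violations recorded, contract on count kept

    def test_partition_count_never_exceeds_max_p(self, rng):
        for _ in range(50):
            values = [int(v) for v in rng.integers(1, 30, size=rng.integers(1, 10))]
            k = int(rng.integers(1, 5))
            plan = partition(make_profile(values), PartitionConfig(max_p=k))
            assert plan.n_segments <= k

    def test_deterministic(self):
        prof = make_profile([3, 9, 2, 7, 1])
        cfg = PartitionConfig(max_p=3)
        a, b = partition(prof, cfg), partition(prof, cfg)
        assert [s.layer_ids for s in a.segments] == [s.layer_ids for s in b.segments]

    def test_crossing_skips_recorded(self):
        net = build_unet(3, 4, (32, 32), 3)
        prof = profile(net)
        plan = partition(prof, PartitionConfig(max_p=3, budget_basis="complexity"),
                         network=net)
        seg_of = {lid: k for k, s in enumerate(plan.segments) for lid in s.layer_ids}
        expected = [(a, b) for a, b in net.skip_pairs if seg_of[a] != seg_of[b]]
        assert plan.crossing_tensors == expected

    def test_plan_serializes_to_json(self, tmp_path):
        plan = partition(make_profile([5, 5, 5]), PartitionConfig(max_p=3))
        path = tmp_path / "plan.json"
        plan.save(path)
        import json

        loaded = json.loads(path.read_text())
        assert len(loaded["segments"]) == 3


class TestGrowth:
    def test_empty_growth_is_identity(self, toy_unet, toy_weights):
        spec, weights = grow_submodel(toy_unet, toy_weights, [])
        assert spec is toy_unet and weights is toy_weights

    def test_transferred_weights_bit_identical(self, toy_unet, toy_weights):
        new_spec, transfer, new_layers = deepen(toy_unet)
        grown_spec, grown = grow_submodel(toy_unet, toy_weights, new_layers, seed=3)
        assert grown_spec.depth == toy_unet.depth + 1
        for old_id, new_id in transfer.items():
            if old_id in toy_weights.arrays:
                for key, a in toy_weights.arrays[old_id].items():
                    assert np.array_equal(grown.arrays[new_id][key], a)

    def test_grown_param_count_adds_new_layers(self, toy_unet, toy_weights):
        _, _, new_layers = deepen(toy_unet)
        grown_spec, grown = grow_submodel(toy_unet, toy_weights, new_layers)
        assert grown.n_params() == toy_weights.n_params() + sum(
            count_params(l) for l in new_layers)

    def test_wrong_layers_rejected(self, toy_unet, toy_weights):
        from partprune.network import InvalidSpecError, LayerSpec

        bogus = [LayerSpec(99, "conv", 0, 4, 4, (16, 16), kernel=(3, 3),
                           role="nonsense")]
        with pytest.raises(InvalidSpecError):
            grow_submodel(toy_unet, toy_weights, bogus)


class TestProgressiveSchedule:
    def test_stage_depths_mirror_2_3_5(self):
        assert stage_depths(5, 3) == [2, 3, 5]

    def test_three_stage_plan_for_depth5(self):
        full = build_unet(5, 2, (64, 64), 3)
        plan = progressive_schedule(full, PartitionConfig(max_p=3),
                                    budget=full.total_params)
        assert plan.depths == [2, 3, 5]

    def test_single_stage_when_budget_ample(self):
        full = build_unet(2, 4, (32, 32), 3)
        plan = progressive_schedule(full, PartitionConfig(max_p=3),
                                    budget=full.total_params)
        assert plan.depths == [2]
        assert plan.stages[0].required_prune_ratio == 0.0

    def test_budget_below_first_stage_rejected(self):
        full = build_unet(3, 4, (32, 32), 3)
        with pytest.raises(ValueError):
            progressive_schedule(full, PartitionConfig(max_p=3), budget=10)

    def test_transfer_maps_are_injective_and_shape_preserving(self):
        full = build_unet(4, 2, (32, 32), 3)
        plan = progressive_schedule(full, PartitionConfig(max_p=3),
                                    budget=full.total_params)
        for prev, stage in zip(plan.stages, plan.stages[1:]):
            tm = stage.transfer_map
            assert len(set(tm.values())) == len(tm)
            prev_by_id = {l.layer_id: l for l in prev.spec.layers}
            new_by_id = {l.layer_id: l for l in stage.spec.layers}
            for old, new in tm.items():
                a, b = prev_by_id[old], new_by_id[new]
                assert (a.kind, a.kernel, a.channels_in, a.channels_out) == \
                       (b.kind, b.kernel, b.channels_in, b.channels_out)

    def test_post_prune_counts_within_budget(self):
        """Every stage can be pruned back under the parameter budget."""
        from partprune import PruneConfig, apply_mask, magnitude_prune

        full = build_unet(3, 4, (32, 32), 3)
        budget = build_unet(2, 4, (32, 32), 3).total_params
        plan = progressive_schedule(full, PartitionConfig(max_p=3), budget=budget)
        for stage in plan.stages:
            w = init_weights(stage.spec, 0)
            if stage.required_prune_ratio > 0:
                mask = magnitude_prune(w, PruneConfig(
                    ratio=stage.required_prune_ratio, scope="global"))
                w = apply_mask(w, mask)
            assert w.n_nonzero() <= stage.budget
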