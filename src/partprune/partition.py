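"""Adaptive partitioning of a profiled network and progressive depth growth.

Partitioning splits the layer sequence into at most ``max_p`` contiguous
submodels.  The per-submodel budget is the smaller of the even-split target
``target_c = total / max_p`` and a hard cap ``max_c``; accumulation is greedy
left-to-right in topological order: a segment closes when adding the next
layer would exceed the effective cap.  If the cap is infeasible the final
segment absorbs the remaining layers and the plan is flagged rather than
rejected — the partition-count contract is primary.  Budgets can be
expressed in complexity units (``P_i * FLOPs_i``) or raw FLOPs; FLOPs is the
convention used with the 10-million-FLOP per-submodel cap.

Progressive growth trains a shallow stage first, then deepens it at the
bottleneck: with a channel-doubling schedule every existing layer keeps its
shape, so trained weights transfer bit-identically and only the new deepest
level is freshly initialized.  A parameter budget is maintained across
stages by pruning each deepened stage back under the budget.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

from .network import (
    ComplexityProfile,
    InvalidSpecError,
    LayerSpec,
    NetworkSpec,
    build_unet,
    count_params,
)
from .nn import WeightStore, init_weights


@dataclass
class PartitionConfig:
    max_c: float = float("inf")  # per-submodel cap, in budget_basis units
    max_p: int = 3
    budget_basis: str = "flops"  # or "complexity"

    def __post_init__(self) -> None:
        if self.max_p < 1:
            raise ValueError("max_p must be >= 1")
        if not self.max_c > 0:
            raise ValueError("max_c must be positive")
        if self.budget_basis not in ("flops", "complexity"):
            raise ValueError(f"unknown budget_basis {self.budget_basis!r}")


@dataclass
class Segment:
    layer_ids: tuple[int, ...]
    complexity: int
    flops: int
    params: int
    depth_span: tuple[int, int]  # (min, max) resolution level


@dataclass
class SubmodelPlan:
    segments: list[Segment]
    crossing_tensors: list[tuple[int, int]]  # skip pairs cut by a boundary
    target_c: Fraction
    basis: str
    effective_cap: float = float("inf")  # min(target_c, max_c) actually used
    flags: list[str] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def to_dict(self) -> dict:
        return {
            "basis": self.basis,
            "target_c": float(self.target_c),
            "effective_cap": self.effective_cap,
            "segments": [
                {"layer_ids": list(s.layer_ids), "complexity": s.complexity,
                 "flops": s.flops, "params": s.params,
                 "depth_span": list(s.depth_span)}
                for s in self.segments
            ],
            "crossing_tensors": [list(p) for p in self.crossing_tensors],
            "flags": self.flags,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def target_complexity(total: int, max_p: int) -> Fraction:
    """Even-split per-submodel budget ``total / max_p``, kept exact.

    Returned as an exact rational so cap comparisons carry no rounding
    slack; ``float()`` gives the real value for reporting.
    """
    if max_p < 1:
        raise ValueError("max_p must be >= 1")
    return Fraction(total, max_p)


def partition(profile: ComplexityProfile, config: PartitionConfig,
              network: NetworkSpec | None = None) -> SubmodelPlan:
    """Greedily split a profiled network into <= max_p contiguous submodels.

    ``network`` is optional metadata: when given, skip connections crossing
    segment boundaries are recorded as explicit extra segment inputs/outputs
    and per-segment depth spans use real resolution levels.
    """
    if not profile.per_layer:
        raise ValueError("empty profile")
    ids = [lid for lid, _ in profile.per_layer]
    comp = dict(profile.per_layer)
    flops = dict(profile.per_layer_flops)
    params = dict(profile.per_layer_params)
    basis_vals = flops if config.budget_basis == "flops" else comp
    total_basis = sum(basis_vals[i] for i in ids)
    target = target_complexity(total_basis, config.max_p)
    cap = target if config.max_c == float("inf") else min(target, Fraction(config.max_c))

    segments_ids: list[list[int]] = [[]]
    acc = 0
    for lid in ids:
        v = basis_vals[lid]
        last_open = len(segments_ids) == config.max_p
        if segments_ids[-1] and not last_open and acc + v > cap:
            segments_ids.append([])
            acc = 0
        segments_ids[-1].append(lid)
        acc += v

    levels = ({l.layer_id: l.depth_level for l in network.layers}
              if network is not None else {i: 0 for i in ids})
    flags: list[str] = []
    segments: list[Segment] = []
    for seg_ids in segments_ids:
        seg_basis = sum(basis_vals[i] for i in seg_ids)
        if seg_basis > cap and len(seg_ids) > 1:
            flags.append(
                f"segment {len(segments)} exceeds cap: {seg_basis} > {float(cap):g}"
            )
        elif seg_basis > cap:
            flags.append(
                f"segment {len(segments)} is a single layer above the cap "
                f"({seg_basis} > {float(cap):g}); kept whole"
            )
        lv = [levels[i] for i in seg_ids]
        segments.append(Segment(
            layer_ids=tuple(seg_ids),
            complexity=sum(comp[i] for i in seg_ids),
            flops=sum(flops[i] for i in seg_ids),
            params=sum(params[i] for i in seg_ids),
            depth_span=(min(lv), max(lv)),
        ))

    crossing: list[tuple[int, int]] = []
    if network is not None:
        seg_of = {lid: k for k, seg in enumerate(segments_ids) for lid in seg}
        crossing = [(a, b) for a, b in network.skip_pairs
                    if seg_of.get(a) != seg_of.get(b)]

    return SubmodelPlan(segments=segments, crossing_tensors=crossing,
                        target_c=target, basis=config.budget_basis,
                        effective_cap=float(cap), flags=flags)


# ---------------------------------------------------------------------------
# Progressive depth growth


def deepen(spec: NetworkSpec):
    """Derive the one-level-deeper architecture and the weight-transfer map.

    Requires generator metadata on the spec (it must come from
    :func:`~partprune.network.build_unet`).  Returns
    ``(new_spec, transfer_map, new_layers)`` where ``transfer_map`` maps old
    layer_id -> new layer_id for every parameterized old layer (all of which
    keep their exact shapes under the channel-doubling schedule) and
    ``new_layers`` are the freshly added bottleneck-level layers.
    """
    if spec.base_channels is None or spec.in_shape is None:
        raise InvalidSpecError("spec lacks generator metadata; cannot deepen")
    new_spec = build_unet(spec.depth + 1, spec.base_channels, spec.in_shape,
                          spec.n_classes, spec.in_channels)
    by_role_new = {l.role: l for l in new_spec.layers}
    transfer: dict[int, int] = {}
    matched_new = set()
    for old in spec.layers:
        new = by_role_new.get(old.role)
        if new is None:
            raise InvalidSpecError(f"role {old.role!r} missing after deepening")
        if (old.kind, old.kernel, old.channels_in, old.channels_out) != \
           (new.kind, new.kernel, new.channels_in, new.channels_out):
            raise InvalidSpecError(f"role {old.role!r} changed shape when deepening")
        transfer[old.layer_id] = new.layer_id
        matched_new.add(new.layer_id)
    new_layers = [l for l in new_spec.layers if l.layer_id not in matched_new]
    return new_spec, transfer, new_layers


def grow_submodel(stage_spec: NetworkSpec, trained: WeightStore,
                  new_layers: list[LayerSpec], seed: int = 0):
    """Insert ``new_layers`` at the bottleneck, transferring trained weights.

    All pre-existing weights are carried over bit-identically; the new
    layers are Glorot-initialized from ``seed``.  With ``new_layers`` empty
    the spec and weights are returned unchanged.  Raises if ``new_layers``
    is not the shape-compatible bottleneck extension of ``stage_spec``.
    """
    if not new_layers:
        return stage_spec, trained
    new_spec, transfer, expected = deepen(stage_spec)
    expected_sig = {(l.role, l.kind, l.kernel, l.channels_in, l.channels_out)
                    for l in expected}
    got_sig = {(l.role, l.kind, l.kernel, l.channels_in, l.channels_out)
               for l in new_layers}
    if got_sig != expected_sig:
        raise InvalidSpecError(
            "new_layers are not a shape-compatible bottleneck extension"
        )
    fresh = init_weights(new_spec, seed)
    out = WeightStore()
    transferred_targets = set()
    for old_id, new_id in transfer.items():
        if old_id in trained.arrays:
            out.arrays[new_id] = {k: a.copy()
                                  for k, a in trained.arrays[old_id].items()}
            transferred_targets.add(new_id)
    for lid, d in fresh.arrays.items():
        if lid not in transferred_targets:
            out.arrays[lid] = d
    return new_spec, out


@dataclass
class Stage:
    spec: NetworkSpec
    transfer_map: dict[int, int]  # previous-stage layer_id -> this stage's
    budget: int
    required_prune_ratio: float  # prune fraction restoring params <= budget


@dataclass
class ProgressivePlan:
    stages: list[Stage]

    @property
    def depths(self) -> list[int]:
        return [s.spec.depth for s in self.stages]


def stage_depths(full_depth: int, max_p: int, start_depth: int = 2) -> list[int]:
    """Stage depth sequence: start shallow, add one level per intermediate
    stage, finish at the full depth, never more than ``max_p`` stages."""
    start = min(start_depth, full_depth)
    depths = []
    d = start
    while len(depths) < max_p - 1 and d < full_depth:
        depths.append(d)
        d += 1
    depths.append(full_depth)
    return depths


def progressive_schedule(full_network: NetworkSpec, config: PartitionConfig,
                         budget: int) -> ProgressivePlan:
    """Plan stages of strictly increasing depth ending at the full network.

    Each stage after the first inherits the previous stage's weights at the
    transferred layers; a scheduled prune restores the stage's non-zero
    parameter count to at most ``budget``.  The first (shallowest) stage
    must fit the budget outright.
    """
    if full_network.base_channels is None:
        raise InvalidSpecError("full network lacks generator metadata")
    depths = stage_depths(full_network.depth, config.max_p)
    specs = [build_unet(d, full_network.base_channels, full_network.in_shape,
                        full_network.n_classes, full_network.in_channels)
             for d in depths]
    if budget < specs[0].total_params:
        raise ValueError(
            f"budget {budget} is below the shallowest stage's "
            f"{specs[0].total_params} parameters"
        )
    stages: list[Stage] = []
    for k, spec in enumerate(specs):
        if k == 0:
            transfer: dict[int, int] = {}
        else:
            cur = specs[k - 1]
            transfer = {}
            # Compose one-level transfer maps across possibly multi-level jumps.
            chain = [dict()]
            while cur.depth < spec.depth:
                cur, step_map, _ = deepen(cur)
                chain.append(step_map)
            transfer = {l.layer_id: l.layer_id for l in specs[k - 1].layers}
            for step_map in chain[1:]:
                transfer = {old: step_map[mid] for old, mid in transfer.items()
                            if mid in step_map}
        p = spec.total_params
        ratio = max(0.0, 1.0 - budget / p)
        stages.append(Stage(spec=spec, transfer_map=transfer, budget=budget,
                            required_prune_ratio=ratio))
    return ProgressivePlan(stages=stages)
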