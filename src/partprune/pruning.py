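"""Magnitude-based weight pruning with an iterative prune/fine-tune loop.

The smallest-magnitude weights of a model are set to exactly zero and held
there through any subsequent fine-tuning by masking both the weights and
their gradients.  The pruned count is ``round(ratio * N)`` with
round-half-away-from-zero, so a 20% ratio removes exactly one fifth of the
weights whenever N is divisible by 5.  Ties in |w| are broken
deterministically by (layer_id, flat index) ascending; a layer's flat order
is its kernel followed by its bias.

Scope ``per_layer`` (default) applies the rule within each layer
independently, which prevents one large layer from absorbing the entire
quota; ``global`` ranks all weights together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .nn import WeightStore


@dataclass
class PruneConfig:
    ratio: float = 0.2
    scope: str = "per_layer"  # or "global"
    iterations: int = 1
    finetune_epochs_per_iteration: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError(f"ratio must be in [0, 1], got {self.ratio}")
        if self.scope not in ("per_layer", "global"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class PruneMask:
    """Binary retention masks (1 = keep) matching a WeightStore's layout."""

    arrays: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def ones_like(cls, weights: WeightStore) -> "PruneMask":
        return cls({lid: {k: np.ones_like(a) for k, a in d.items()}
                    for lid, d in weights.arrays.items()})

    def flat(self, layer_id: int) -> np.ndarray:
        d = self.arrays[layer_id]
        return np.concatenate([d["w"].ravel(), d["b"].ravel()])

    def n_total(self) -> int:
        return sum(a.size for d in self.arrays.values() for a in d.values())

    def n_pruned(self, layer_id: int | None = None) -> int:
        if layer_id is not None:
            d = self.arrays[layer_id]
            return int(sum(a.size - np.count_nonzero(a) for a in d.values()))
        return int(sum(self.n_pruned(lid) for lid in self.arrays))

    @property
    def sparsity(self) -> float:
        return self.n_pruned() / self.n_total()

    def sparsity_per_layer(self) -> dict[int, float]:
        return {lid: self.n_pruned(lid) / sum(a.size for a in d.values())
                for lid, d in self.arrays.items()}

    def combine(self, other: "PruneMask") -> "PruneMask":
        """Elementwise AND: pruned in either mask stays pruned."""
        return PruneMask({lid: {k: self.arrays[lid][k] * other.arrays[lid][k]
                                for k in self.arrays[lid]}
                          for lid in self.arrays})


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _mask_from_flat(weights: WeightStore, keep_flags: dict[int, np.ndarray]) -> PruneMask:
    mask = PruneMask()
    for lid, d in weights.arrays.items():
        flags = keep_flags[lid]
        nw = d["w"].size
        mask.arrays[lid] = {
            "w": flags[:nw].reshape(d["w"].shape).astype(float),
            "b": flags[nw:].reshape(d["b"].shape).astype(float),
        }
    return mask


def magnitude_prune(weights: WeightStore, config: PruneConfig,
                    prior_mask: PruneMask | None = None) -> PruneMask:
    """Mask the ``round(ratio * N)`` smallest-|w| weights.

    With ``prior_mask`` given, only currently-kept weights are ranked and
    counted (N = number kept), and the returned mask includes the prior
    pruning — this supports cumulative iterative schedules.
    """
    if not weights.arrays:
        raise ValueError("empty weight store")
    keep_flags: dict[int, np.ndarray] = {}
    if config.scope == "per_layer":
        for lid, d in sorted(weights.arrays.items()):
            flat = np.concatenate([d["w"].ravel(), d["b"].ravel()])
            prior = (prior_mask.flat(lid) > 0 if prior_mask is not None
                     else np.ones(flat.size, dtype=bool))
            eligible = np.flatnonzero(prior)
            n_prune = _round_half_away(config.ratio * eligible.size)
            order = eligible[np.argsort(np.abs(flat[eligible]), kind="stable")]
            flags = prior.copy()
            flags[order[:n_prune]] = False
            keep_flags[lid] = flags
    else:
        entries = []  # (|w|, layer_id, idx) rows for lexicographic ranking
        for lid, d in sorted(weights.arrays.items()):
            flat = np.concatenate([d["w"].ravel(), d["b"].ravel()])
            prior = (prior_mask.flat(lid) > 0 if prior_mask is not None
                     else np.ones(flat.size, dtype=bool))
            idx = np.flatnonzero(prior)
            entries.append((lid, idx, np.abs(flat[idx])))
            keep_flags[lid] = prior.copy()
        mags = np.concatenate([m for _, _, m in entries])
        lids = np.concatenate([np.full(i.size, lid) for lid, i, _ in entries])
        idxs = np.concatenate([i for _, i, _ in entries])
        n_prune = _round_half_away(config.ratio * mags.size)
        order = np.lexsort((idxs, lids, mags))[:n_prune]
        for k in order:
            keep_flags[int(lids[k])][int(idxs[k])] = False
    return _mask_from_flat(weights, keep_flags)


def apply_mask(weights: WeightStore, mask: PruneMask) -> WeightStore:
    """Zero the masked entries; kept entries pass through bit-identically."""
    out = WeightStore()
    for lid, d in weights.arrays.items():
        md = mask.arrays[lid]
        for key in d:
            if d[key].shape != md[key].shape:
                raise ValueError(f"layer {lid}: mask/weight shape mismatch")
        out.arrays[lid] = {k: np.where(md[k] > 0, d[k], 0.0) for k in d}
    return out


def iterative_prune_finetune(model_stage, dataset, config: PruneConfig,
                             train_config=None):
    """Iteratively prune and fine-tune a trainable stage.

    ``model_stage`` is ``(spec, weights)``.  The target ``config.ratio`` is
    split evenly across iterations: each of the ``iterations`` rounds prunes
    a fraction ``ratio / iterations`` of the *currently kept* weights, so the
    cumulative sparsity after k rounds is ``1 - (1 - ratio/iterations)**k``
    (slightly under ``ratio`` for more than one round).  Pruned weights stay
    exactly zero through fine-tuning via gradient masking.

    Returns ``(weights, mask, history)``; history records per-iteration
    sparsity and the fine-tuning epoch log.
    """
    from .training import TrainConfig, train  # deferred: avoids import cycle

    spec, weights = model_stage
    weights = weights.copy()
    per_iter = PruneConfig(ratio=config.ratio / config.iterations,
                           scope=config.scope, iterations=1, seed=config.seed)
    mask = PruneMask.ones_like(weights)
    history: list[dict] = []
    for it in range(config.iterations):
        mask = magnitude_prune(weights, per_iter, prior_mask=mask)
        weights = apply_mask(weights, mask)
        epoch_log = []
        if config.finetune_epochs_per_iteration > 0 and dataset is not None:
            tc = train_config or TrainConfig()
            tc = TrainConfig(**{**tc.__dict__,
                                "epochs": config.finetune_epochs_per_iteration,
                                "seed": config.seed + it})
            weights, epoch_log = train((spec, weights), dataset, tc, mask=mask)
        history.append({"iteration": it + 1, "sparsity": mask.sparsity,
                        "finetune": epoch_log})
    return weights, mask, history
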