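"""Architecture descriptions for layered encoder-decoder segmentation networks.

A network is an ordered list of :class:`LayerSpec` records in topological
order.  Each record carries enough geometry (kernel, channels, output shape)
to compute its parameter count ``P_i`` and inference cost ``FLOPs_i``; the
per-layer *complexity* is their product ``c_i = P_i * FLOPs_i``, used to rank
and partition layers.  All counting is exact integer arithmetic: the products
routinely exceed 10**12 and floating point would lose precision.

Conventions (documented, configurable where noted):

* A convolution counts ``2 * k_h * k_w * C_in * C_out * H_out * W_out`` FLOPs
  (one multiply-accumulate = 2 FLOPs; bias and activation excluded).  The
  factor 2 is the ``mac_factor`` argument of :func:`count_flops`.
* Parameter-free layers (downsample, upsample, skip merge) count one
  operation per output element: ``H_out * W_out * C_out``.
* Bias terms count toward ``P_i``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

CONV_KINDS = ("conv", "output_head")
PARAM_FREE_KINDS = ("downsample", "upsample", "skip_merge")
LAYER_KINDS = CONV_KINDS + PARAM_FREE_KINDS


class InvalidSpecError(ValueError):
    """Raised when a layer or network description is internally inconsistent."""


@dataclass(frozen=True)
class LayerSpec:
    """One layer of an encoder-decoder network.

    Parameters
    ----------
    layer_id : int
        Ordinal index in topological order.
    kind : str
        One of ``conv``, ``downsample``, ``upsample``, ``skip_merge``,
        ``output_head``.
    depth_level : int
        Resolution level, 0 = full resolution.
    kernel : tuple[int, int] or None
        ``(k_h, k_w)`` for convolutional kinds, ``None`` otherwise.
    channels_in, channels_out : int
        Channel counts entering and leaving the layer.  For ``skip_merge``
        ``channels_out = channels_in + channels of the merged encoder tensor``.
    out_shape : tuple[int, int]
        ``(H_out, W_out)`` spatial output shape.
    role : str
        Stable human-readable tag (``enc0/conv1`` ...) used to match layers
        across architectures of different depth during progressive growth.
    merge_with : int or None
        For ``skip_merge`` layers, the encoder ``layer_id`` whose output is
        concatenated in.
    """

    layer_id: int
    kind: str
    depth_level: int
    channels_in: int
    channels_out: int
    out_shape: tuple[int, int]
    kernel: tuple[int, int] | None = None
    role: str = ""
    merge_with: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise InvalidSpecError(f"unknown layer kind {self.kind!r}")
        if self.kind in CONV_KINDS:
            if self.kernel is None:
                raise InvalidSpecError(f"layer {self.layer_id}: conv needs a kernel")
            if self.channels_in <= 0 or self.channels_out <= 0:
                raise InvalidSpecError(
                    f"layer {self.layer_id}: conv channel counts must be positive"
                )
        if self.out_shape is None or len(self.out_shape) != 2:
            raise InvalidSpecError(f"layer {self.layer_id}: out_shape must be (H, W)")

    @property
    def param_count(self) -> int:
        return count_params(self)

    @property
    def flops(self) -> int:
        return count_flops(self)


def count_params(layer: LayerSpec) -> int:
    """Number of learnable parameters ``P_i`` of a layer.

    Convolutions (including the 1x1 output head) use
    ``k_h * k_w * C_in * C_out + C_out`` (bias included); all other kinds are
    parameter-free and return 0.
    """
    if layer.kind in PARAM_FREE_KINDS:
        return 0
    k_h, k_w = layer.kernel  # type: ignore[misc]
    return k_h * k_w * layer.channels_in * layer.channels_out + layer.channels_out


def count_flops(layer: LayerSpec, mac_factor: int = 2) -> int:
    """Inference cost ``FLOPs_i`` of a layer.

    ``mac_factor`` FLOPs per multiply-accumulate for convolutions (default 2,
    bias and activation excluded); parameter-free kinds cost one operation
    per output element.
    """
    if layer.out_shape is None:
        raise InvalidSpecError(f"layer {layer.layer_id}: out_shape unknown")
    h, w = layer.out_shape
    if layer.kind in PARAM_FREE_KINDS:
        return h * w * layer.channels_out
    k_h, k_w = layer.kernel  # type: ignore[misc]
    return mac_factor * k_h * k_w * layer.channels_in * layer.channels_out * h * w


def layer_complexity(layer: LayerSpec) -> int:
    """Layer complexity ``c_i = P_i * FLOPs_i`` (exact integer product)."""
    return count_params(layer) * count_flops(layer)


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered architecture description of an encoder-decoder network."""

    layers: tuple[LayerSpec, ...]
    skip_pairs: tuple[tuple[int, int], ...]
    depth: int
    n_classes: int
    # Generator metadata: lets a spec be re-derived one level deeper with the
    # same channel schedule (progressive growth).  None for hand-built specs.
    base_channels: int | None = None
    in_shape: tuple[int, int] | None = None
    in_channels: int = 1

    def __post_init__(self) -> None:
        ids = [l.layer_id for l in self.layers]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise InvalidSpecError("layer_ids must be strictly increasing")
        heads = [l for l in self.layers if l.kind == "output_head"]
        if len(heads) != 1 or self.layers[-1].kind != "output_head":
            raise InvalidSpecError("exactly one output_head required, last in order")
        by_id = {l.layer_id: l for l in self.layers}
        for enc_id, dec_id in self.skip_pairs:
            if by_id[enc_id].out_shape != by_id[dec_id].out_shape:
                raise InvalidSpecError(
                    f"skip pair ({enc_id}, {dec_id}) connects unequal shapes"
                )

    def layer(self, layer_id: int) -> LayerSpec:
        for l in self.layers:
            if l.layer_id == layer_id:
                return l
        raise KeyError(layer_id)

    @property
    def total_params(self) -> int:
        return sum(count_params(l) for l in self.layers)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["layers"] = [dataclasses.asdict(l) for l in self.layers]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        layers = tuple(
            LayerSpec(
                **{
                    **ld,
                    "out_shape": tuple(ld["out_shape"]),
                    "kernel": tuple(ld["kernel"]) if ld.get("kernel") else None,
                }
            )
            for ld in d["layers"]
        )
        return cls(
            layers=layers,
            skip_pairs=tuple((a, b) for a, b in d["skip_pairs"]),
            depth=d["depth"],
            n_classes=d["n_classes"],
            base_channels=d.get("base_channels"),
            in_shape=tuple(d["in_shape"]) if d.get("in_shape") else None,
            in_channels=d.get("in_channels", 1),
        )

    def save(self, path: str | Path) -> None:
        """Serialize to JSON or YAML depending on the file suffix."""
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(_plain(d), sort_keys=False))
        else:
            path.write_text(json.dumps(_plain(d), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkSpec":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(d)


def _plain(obj):
    """Recursively convert tuples to lists for clean YAML/JSON output."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


@dataclass(frozen=True)
class ComplexityProfile:
    """Per-layer complexities ``c_i = P_i * FLOPs_i`` and their exact sum.

    Also carries the per-layer parameter and FLOP counts so downstream
    partitioning can budget on either basis.
    """

    per_layer: tuple[tuple[int, int], ...]  # (layer_id, c_i)
    total: int
    per_layer_params: tuple[tuple[int, int], ...] = ()
    per_layer_flops: tuple[tuple[int, int], ...] = ()

    @property
    def total_flops(self) -> int:
        return sum(f for _, f in self.per_layer_flops)

    @property
    def total_params(self) -> int:
        return sum(p for _, p in self.per_layer_params)


def profile(network: NetworkSpec) -> ComplexityProfile:
    """Profile every layer of a network: ``c_i``, ``P_i`` and ``FLOPs_i``."""
    if not network.layers:
        raise InvalidSpecError("cannot profile an empty network")
    per = tuple((l.layer_id, layer_complexity(l)) for l in network.layers)
    return ComplexityProfile(
        per_layer=per,
        total=sum(c for _, c in per),
        per_layer_params=tuple((l.layer_id, count_params(l)) for l in network.layers),
        per_layer_flops=tuple((l.layer_id, count_flops(l)) for l in network.layers),
    )


def level_channels(base_channels: int, level: int) -> int:
    """Channel schedule: doubling per resolution level."""
    return base_channels * (1 << level)


def build_unet(
    depth: int,
    base_channels: int,
    in_shape: tuple[int, int],
    n_classes: int,
    in_channels: int = 1,
) -> NetworkSpec:
    """Generate a symmetric encoder-decoder (U-Net) architecture description.

    ``depth`` resolution levels with channel doubling, two 3x3 convolutions
    per level, 2x max-pool downsampling, 2x nearest-neighbour upsampling,
    concatenation skip connections at every level above the bottleneck, and a
    1x1 output head.  Deterministic for fixed arguments.
    """
    if depth < 1:
        raise InvalidSpecError("depth must be >= 1")
    h, w = in_shape
    div = 1 << (depth - 1)
    if h % div or w % div:
        raise InvalidSpecError(
            f"input shape {in_shape} not divisible by 2**(depth-1) = {div}"
        )

    layers: list[LayerSpec] = []
    skip_pairs: list[tuple[int, int]] = []
    enc_out: dict[int, int] = {}  # level -> layer_id of last encoder conv
    lid = 0

    def add(**kw) -> LayerSpec:
        nonlocal lid
        layer = LayerSpec(layer_id=lid, **kw)
        layers.append(layer)
        lid += 1
        return layer

    # Encoder, top level down to the bottleneck.
    c_prev = in_channels
    for level in range(depth):
        hw = (h >> level, w >> level)
        c = level_channels(base_channels, level)
        if level > 0:
            add(kind="downsample", depth_level=level, channels_in=c_prev,
                channels_out=c_prev, out_shape=hw, role=f"enc{level}/down")
        add(kind="conv", depth_level=level, channels_in=c_prev, channels_out=c,
            out_shape=hw, kernel=(3, 3), role=f"enc{level}/conv0")
        last = add(kind="conv", depth_level=level, channels_in=c, channels_out=c,
                   out_shape=hw, kernel=(3, 3), role=f"enc{level}/conv1")
        enc_out[level] = last.layer_id
        c_prev = c

    # Decoder, bottleneck back up to full resolution.
    for level in range(depth - 2, -1, -1):
        hw = (h >> level, w >> level)
        c_skip = level_channels(base_channels, level)
        add(kind="upsample", depth_level=level, channels_in=c_prev,
            channels_out=c_prev, out_shape=hw, role=f"dec{level}/up")
        merge = add(kind="skip_merge", depth_level=level, channels_in=c_prev,
                    channels_out=c_prev + c_skip, out_shape=hw,
                    role=f"dec{level}/merge", merge_with=enc_out[level])
        skip_pairs.append((enc_out[level], merge.layer_id))
        add(kind="conv", depth_level=level, channels_in=c_prev + c_skip,
            channels_out=c_skip, out_shape=hw, kernel=(3, 3),
            role=f"dec{level}/conv0")
        add(kind="conv", depth_level=level, channels_in=c_skip,
            channels_out=c_skip, out_shape=hw, kernel=(3, 3),
            role=f"dec{level}/conv1")
        c_prev = c_skip

    add(kind="output_head", depth_level=0, channels_in=c_prev,
        channels_out=n_classes, out_shape=(h, w), kernel=(1, 1), role="head")

    return NetworkSpec(
        layers=tuple(layers),
        skip_pairs=tuple(skip_pairs),
        depth=depth,
        n_classes=n_classes,
        base_channels=base_channels,
        in_shape=(h, w),
        in_channels=in_channels,
    )
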