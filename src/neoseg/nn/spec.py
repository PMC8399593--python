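"""Declarative layer plan for the 42-layer segmentation network.

The architecture is an encoder-decoder with residual downsampling:

* stem — 7x7 convolution (32 filters, stride 1, same padding) + batch
  norm + ReLU; a wide first kernel suits the high-resolution input;
* 2x2 max-pool (stride 2), then two residual blocks (64, 128 filters)
  that downsample by setting stride 2 in both the 3x3 main-path and the
  1x1 skip-path convolutions, reaching 1/8 resolution;
* a 1x1 bottleneck convolution at the lowest resolution;
* three x2 transposed-convolution upsampling stages (64, 64, 32 filters)
  back to full resolution;
* one depth concatenation joining the final upsampled maps with the stem
  activation (equal spatial size, 32 + 32 = 64 channels);
* two 3x3 convolution + batch norm + ReLU trios, a final 1x1 convolution
  to 2 channels, and a per-pixel softmax over {NotNeo, Neo}.

Counting every layer from the input through the softmax (and not the
classification loss) gives exactly 42 layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "ResidualBlockSpec",
    "build_reference_spec",
    "infer_shapes",
    "count_parameters",
    "NetworkSpecError",
]


class NetworkSpecError(ValueError):
    """The layer plan violates an architectural invariant."""


@dataclass(frozen=True)
class LayerSpec:
    """One layer descriptor: what it is, its shape parameters, its inputs."""

    name: str
    kind: str  # input | conv | bn | relu | maxpool | tconv | concat | add | softmax
    inputs: tuple[str, ...] = ()
    filters: int | None = None
    kernel: tuple[int, int] | None = None
    stride: int = 1


@dataclass(frozen=True)
class ResidualBlockSpec:
    """Residual block with optional simultaneous x2 downsampling.

    Main path: 3x3 conv (stride per spec) + BN + ReLU + 3x3 conv (stride 1)
    + BN.  Skip path: identity when stride 1 and channels match, otherwise
    a 1x1 convolution at the block stride + BN, so both paths meet at the
    addition with identical shapes.  Output = ReLU(main + skip).
    """

    in_filters: int
    out_filters: int
    stride: int = 1

    def __post_init__(self) -> None:
        if self.stride not in (1, 2):
            raise NetworkSpecError("residual block stride must be 1 or 2")

    @property
    def projects(self) -> bool:
        """True when the skip path needs the 1x1 projection convolution."""
        return self.stride != 1 or self.in_filters != self.out_filters


def _residual_plan(prefix: str, block: ResidualBlockSpec, input_name: str) -> list[LayerSpec]:
    f = block.out_filters
    plan = [
        LayerSpec(f"{prefix}_conv1", "conv", (input_name,), f, (3, 3), block.stride),
        LayerSpec(f"{prefix}_bn1", "bn", (f"{prefix}_conv1",)),
        LayerSpec(f"{prefix}_relu1", "relu", (f"{prefix}_bn1",)),
        LayerSpec(f"{prefix}_conv2", "conv", (f"{prefix}_relu1",), f, (3, 3), 1),
        LayerSpec(f"{prefix}_bn2", "bn", (f"{prefix}_conv2",)),
    ]
    if block.projects:
        plan += [
            LayerSpec(f"{prefix}_skip_conv", "conv", (input_name,), f, (1, 1), block.stride),
            LayerSpec(f"{prefix}_skip_bn", "bn", (f"{prefix}_skip_conv",)),
        ]
        skip = f"{prefix}_skip_bn"
    else:
        skip = input_name
    plan += [
        LayerSpec(f"{prefix}_add", "add", (f"{prefix}_bn2", skip)),
        LayerSpec(f"{prefix}_relu2", "relu", (f"{prefix}_add",)),
    ]
    return plan


@dataclass(frozen=True)
class NetworkSpec:
    """Full declarative plan plus the input geometry it was built for."""

    input_height: int
    input_width: int
    layer_plan: tuple[LayerSpec, ...]
    stem_filters: int = 32
    stage_filters: tuple[int, ...] = (64, 128)
    n_classes: int = 2

    @property
    def n_layers(self) -> int:
        return len(self.layer_plan)

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_height": self.input_height,
                "input_width": self.input_width,
                "stem_filters": self.stem_filters,
                "stage_filters": list(self.stage_filters),
                "n_classes": self.n_classes,
                "layer_plan": [asdict(l) for l in self.layer_plan],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        plan = tuple(
            LayerSpec(
                name=l["name"],
                kind=l["kind"],
                inputs=tuple(l["inputs"]),
                filters=l["filters"],
                kernel=tuple(l["kernel"]) if l["kernel"] else None,
                stride=l["stride"],
            )
            for l in d["layer_plan"]
        )
        return cls(
            input_height=d["input_height"],
            input_width=d["input_width"],
            layer_plan=plan,
            stem_filters=d["stem_filters"],
            stage_filters=tuple(d["stage_filters"]),
            n_classes=d["n_classes"],
        )


def build_reference_spec(
    input_height: int,
    input_width: int,
    stem_filters: int = 32,
    stage_filters: tuple[int, int] = (64, 128),
) -> NetworkSpec:
    """Emit the reference 42-layer plan for the given input geometry."""
    if input_height % 8 or input_width % 8:
        raise NetworkSpecError(
            f"input dimensions must be divisible by 8, got {input_height}x{input_width}"
        )
    s = stem_filters
    f1, f2 = stage_filters
    plan: list[LayerSpec] = [
        LayerSpec("input", "input"),
        LayerSpec("stem_conv", "conv", ("input",), s, (7, 7), 1),
        LayerSpec("stem_bn", "bn", ("stem_conv",)),
        LayerSpec("stem_relu", "relu", ("stem_bn",)),
        LayerSpec("pool1", "maxpool", ("stem_relu",)),
    ]
    plan += _residual_plan("rb1", ResidualBlockSpec(s, f1, stride=2), "pool1")
    plan += _residual_plan("rb2", ResidualBlockSpec(f1, f2, stride=2), "rb1_relu2")
    plan += [
        LayerSpec("bottleneck_conv", "conv", ("rb2_relu2",), f2, (1, 1), 1),
        LayerSpec("bottleneck_bn", "bn", ("bottleneck_conv",)),
        LayerSpec("bottleneck_relu", "relu", ("bottleneck_bn",)),
        LayerSpec("up1_tconv", "tconv", ("bottleneck_relu",), f1, (4, 4), 2),
        LayerSpec("up1_bn", "bn", ("up1_tconv",)),
        LayerSpec("up1_relu", "relu", ("up1_bn",)),
        LayerSpec("up2_tconv", "tconv", ("up1_relu",), f1, (4, 4), 2),
        LayerSpec("up2_bn", "bn", ("up2_tconv",)),
        LayerSpec("up2_relu", "relu", ("up2_bn",)),
        LayerSpec("up3_tconv", "tconv", ("up2_relu",), s, (4, 4), 2),
        LayerSpec("skip_concat", "concat", ("up3_tconv", "stem_relu")),
        # the head keeps the full 2s-channel width delivered by the concat
        LayerSpec("head_conv1", "conv", ("skip_concat",), 2 * s, (3, 3), 1),
        LayerSpec("head_bn1", "bn", ("head_conv1",)),
        LayerSpec("head_relu1", "relu", ("head_bn1",)),
        LayerSpec("head_conv2", "conv", ("head_relu1",), 2 * s, (3, 3), 1),
        LayerSpec("head_bn2", "bn", ("head_conv2",)),
        LayerSpec("head_relu2", "relu", ("head_bn2",)),
        LayerSpec("head_conv3", "conv", ("head_relu2",), 2, (1, 1), 1),
        LayerSpec("softmax", "softmax", ("head_conv3",)),
    ]
    spec = NetworkSpec(
        input_height=input_height,
        input_width=input_width,
        layer_plan=tuple(plan),
        stem_filters=stem_filters,
        stage_filters=tuple(stage_filters),
    )
    validate_spec(spec)
    return spec


def infer_shapes(spec: NetworkSpec) -> dict[str, tuple[int, int, int]]:
    """Propagate (channels, height, width) through the plan."""
    shapes: dict[str, tuple[int, int, int]] = {}
    for layer in spec.layer_plan:
        if layer.kind == "input":
            shapes[layer.name] = (1, spec.input_height, spec.input_width)
            continue
        ins = [shapes[n] for n in layer.inputs]
        c, h, w = ins[0]
        if layer.kind == "conv":
            shapes[layer.name] = (layer.filters, -(-h // layer.stride), -(-w // layer.stride))
        elif layer.kind == "tconv":
            shapes[layer.name] = (layer.filters, 2 * h, 2 * w)
        elif layer.kind == "maxpool":
            shapes[layer.name] = (c, h // 2, w // 2)
        elif layer.kind == "concat":
            (c2, h2, w2) = ins[1]
            if (h, w) != (h2, w2):
                raise NetworkSpecError("concat inputs differ in spatial size")
            shapes[layer.name] = (c + c2, h, w)
        elif layer.kind == "add":
            if ins[0] != ins[1]:
                raise NetworkSpecError("addition inputs differ in shape")
            shapes[layer.name] = ins[0]
        elif layer.kind in ("bn", "relu", "softmax"):
            shapes[layer.name] = (c, h, w)
        else:
            raise NetworkSpecError(f"unknown layer kind {layer.kind!r}")
    return shapes


def validate_spec(spec: NetworkSpec) -> None:
    """Check the architectural invariants of the plan."""
    shapes = infer_shapes(spec)
    last = spec.layer_plan[-1]
    if last.kind != "softmax":
        raise NetworkSpecError("plan must end in a softmax layer")
    c, h, w = shapes[last.name]
    if (h, w) != (spec.input_height, spec.input_width):
        raise NetworkSpecError("output spatial size must equal the input size")
    if c != spec.n_classes or spec.n_classes != 2:
        raise NetworkSpecError("network must emit exactly 2 class maps (Neo/NotNeo)")
    concats = [l for l in spec.layer_plan if l.kind == "concat"]
    if len(concats) != 1 or len(concats[0].inputs) != 2:
        raise NetworkSpecError("plan must contain exactly one two-input concat")
    n_down = sum(1 for l in spec.layer_plan if l.kind == "maxpool") + sum(
        1 for l in spec.layer_plan if l.kind == "conv" and l.stride == 2
        and not l.name.endswith("skip_conv")
    )
    n_up = sum(1 for l in spec.layer_plan if l.kind == "tconv")
    if n_down != n_up:
        raise NetworkSpecError("each x2 downsampling must be matched by one x2 upsampling")


def count_parameters(spec: NetworkSpec) -> int:
    """Total learnable weights and biases implied by the plan.

    Convolutions and transposed convolutions carry kh*kw*c_in*c_out
    weights plus c_out biases; batch norm carries scale and shift per
    channel (running statistics are not learnable).  Independent of the
    input size by weight sharing.
    """
    shapes = infer_shapes(spec)
    total = 0
    for layer in spec.layer_plan:
        if layer.kind in ("conv", "tconv"):
            c_in = shapes[layer.inputs[0]][0]
            kh, kw = layer.kernel
            total += kh * kw * c_in * layer.filters + layer.filters
        elif layer.kind == "bn":
            total += 2 * shapes[layer.name][0]
    return total
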