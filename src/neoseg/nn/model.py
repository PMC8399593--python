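"""Executable segmentation network built from a declarative layer plan.

The model interprets a :class:`~neoseg.nn.spec.NetworkSpec` as a directed
acyclic graph and runs it with the numpy primitives in
:mod:`neoseg.nn.layers`.  Parameters live in a flat ``{layer: {name:
array}}`` dictionary so the momentum optimizer and checkpointing can treat
them uniformly.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import numpy as np

from . import layers as L
from .spec import NetworkSpec, ResidualBlockSpec, build_reference_spec, infer_shapes, validate_spec

__all__ = ["SegmentationNetwork", "residual_block_forward", "init_residual_block_params"]


DTYPE = np.float32  # single precision: ample for SGD and ~2x faster on BLAS

# Initialization gain on the He standard deviation for every convolution
# except the final classifier.  Batch normalization makes the forward
# pass invariant to the weight magnitude of those layers while the
# effective gradient-descent step scales as lr/||w||^2, so a sub-He gain
# is what lets the fixed small learning rate of the training regime
# (5e-4) move the features within a practical iteration budget.
INIT_GAIN = 0.05


def _he_conv(rng, f, c, kh, kw, gain=1.0):
    std = gain * np.sqrt(2.0 / (c * kh * kw))
    return {
        "w": rng.normal(0.0, std, size=(f, c, kh, kw)).astype(DTYPE),
        "b": np.zeros(f, dtype=DTYPE),
    }


def _he_tconv(rng, c, f, kh, kw, gain=1.0):
    std = gain * np.sqrt(2.0 / (c * kh * kw))
    return {
        "w": rng.normal(0.0, std, size=(c, f, kh, kw)).astype(DTYPE),
        "b": np.zeros(f, dtype=DTYPE),
    }


def _bn_params(c):
    return {
        "gamma": np.ones(c, dtype=DTYPE),
        "beta": np.zeros(c, dtype=DTYPE),
        "running_mean": np.zeros(c, dtype=DTYPE),
        "running_var": np.ones(c, dtype=DTYPE),
    }


class SegmentationNetwork:
    """Per-pixel two-class segmentation network.

    Fully convolutional: any input whose sides are divisible by 8 is
    accepted, regardless of the geometry the spec was built for.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0, init_gain: float = INIT_GAIN):
        validate_spec(spec)
        self.spec = spec
        self.shapes = infer_shapes(spec)
        self.params: dict[str, dict[str, np.ndarray]] = {}
        rng = np.random.default_rng(seed)
        final_conv = [l.name for l in spec.layer_plan if l.kind == "conv"][-1]
        for layer in spec.layer_plan:
            gain = 1.0 if layer.name == final_conv else init_gain
            if layer.kind == "conv":
                c_in = self.shapes[layer.inputs[0]][0]
                kh, kw = layer.kernel
                self.params[layer.name] = _he_conv(
                    rng, layer.filters, c_in, kh, kw, gain
                )
            elif layer.kind == "tconv":
                c_in = self.shapes[layer.inputs[0]][0]
                kh, kw = layer.kernel
                self.params[layer.name] = _he_tconv(
                    rng, c_in, layer.filters, kh, kw, gain
                )
            elif layer.kind == "bn":
                self.params[layer.name] = _bn_params(self.shapes[layer.name][0])

    @classmethod
    def reference(
        cls,
        input_height: int,
        input_width: int,
        seed: int = 0,
        init_gain: float = INIT_GAIN,
    ) -> "SegmentationNetwork":
        return cls(build_reference_spec(input_height, input_width), seed=seed, init_gain=init_gain)

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False):
        """Run the graph; returns (probabilities, caches).

        ``x``: (N, 1, H, W) float, or a bare (H, W) single-channel raster
        (uint8 rasters are scaled to [0, 1]).  Output: (N, 2, H, W)
        per-pixel class probabilities summing to 1.
        """
        x = self.prepare_input(x)
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ValueError("input spatial dimensions must be divisible by 8")
        acts: dict[str, np.ndarray] = {}
        caches: dict[str, object] = {}
        for layer in self.spec.layer_plan:
            kind = layer.kind
            if kind == "input":
                acts[layer.name] = x
            elif kind == "conv":
                p = self.params[layer.name]
                acts[layer.name], caches[layer.name] = L.conv2d_forward(
                    acts[layer.inputs[0]], p["w"], p["b"], layer.stride
                )
            elif kind == "tconv":
                p = self.params[layer.name]
                acts[layer.name], caches[layer.name] = L.conv_transpose2d_forward(
                    acts[layer.inputs[0]], p["w"], p["b"]
                )
            elif kind == "bn":
                p = self.params[layer.name]
                acts[layer.name], caches[layer.name] = L.batchnorm_forward(
                    acts[layer.inputs[0]],
                    p["gamma"],
                    p["beta"],
                    p["running_mean"],
                    p["running_var"],
                    training,
                )
            elif kind == "relu":
                acts[layer.name], caches[layer.name] = L.relu_forward(acts[layer.inputs[0]])
            elif kind == "maxpool":
                acts[layer.name], caches[layer.name] = L.maxpool2x2_forward(
                    acts[layer.inputs[0]]
                )
            elif kind == "concat":
                acts[layer.name], caches[layer.name] = L.concat_forward(
                    acts[layer.inputs[0]], acts[layer.inputs[1]]
                )
            elif kind == "add":
                acts[layer.name], _ = L.add_forward(
                    acts[layer.inputs[0]], acts[layer.inputs[1]]
                )
            elif kind == "softmax":
                acts[layer.name], caches[layer.name] = L.softmax_forward(
                    acts[layer.inputs[0]]
                )
        return acts[self.spec.layer_plan[-1].name], caches

    def backward(self, dlogits: np.ndarray, caches: dict) -> dict[str, dict[str, np.ndarray]]:
        """Backpropagate from the pre-softmax logits; returns gradients.

        The softmax is fused with the cross-entropy loss, so the seed
        gradient enters at the softmax layer's input.
        """
        grads_act: dict[str, np.ndarray] = {}
        grads: dict[str, dict[str, np.ndarray]] = {}
        softmax_layer = self.spec.layer_plan[-1]
        grads_act[softmax_layer.inputs[0]] = dlogits

        def accumulate(name, g):
            if name in grads_act:
                grads_act[name] = grads_act[name] + g
            else:
                grads_act[name] = g

        for layer in reversed(self.spec.layer_plan[:-1]):
            dy = grads_act.pop(layer.name, None)
            if dy is None or layer.kind == "input":
                continue
            if layer.kind == "conv":
                dx, dw, db = L.conv2d_backward(dy, caches[layer.name])
                grads[layer.name] = {"w": dw, "b": db}
                accumulate(layer.inputs[0], dx)
            elif layer.kind == "tconv":
                dx, dw, db = L.conv_transpose2d_backward(dy, caches[layer.name])
                grads[layer.name] = {"w": dw, "b": db}
                accumulate(layer.inputs[0], dx)
            elif layer.kind == "bn":
                dx, dgamma, dbeta = L.batchnorm_backward(dy, caches[layer.name])
                grads[layer.name] = {"gamma": dgamma, "beta": dbeta}
                accumulate(layer.inputs[0], dx)
            elif layer.kind == "relu":
                accumulate(layer.inputs[0], L.relu_backward(dy, caches[layer.name]))
            elif layer.kind == "maxpool":
                accumulate(layer.inputs[0], L.maxpool2x2_backward(dy, caches[layer.name]))
            elif layer.kind == "concat":
                da, db_ = L.concat_backward(dy, caches[layer.name])
                accumulate(layer.inputs[0], da)
                accumulate(layer.inputs[1], db_)
            elif layer.kind == "add":
                accumulate(layer.inputs[0], dy)
                accumulate(layer.inputs[1], dy)
        return grads

    # -- convenience -------------------------------------------------------

    @staticmethod
    def prepare_input(x: np.ndarray) -> np.ndarray:
        """Coerce a raster or batch to (N, 1, H, W) float in [0, 1]."""
        arr = np.asarray(x)
        scale = 255.0 if arr.dtype == np.uint8 else 1.0
        arr = arr.astype(DTYPE) / scale
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:
            arr = arr[:, None]
        if arr.ndim != 4 or arr.shape[1] != 1:
            raise ValueError("expected (H, W), (N, H, W) or (N, 1, H, W) input")
        return arr

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        probs, _ = self.forward(x, training=False)
        return probs

    def copy_params(self) -> dict:
        return copy.deepcopy(self.params)

    def set_params(self, params: dict) -> None:
        self.params = copy.deepcopy(params)

    # -- checkpointing -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: spec JSON + every parameter array."""
        flat = {
            f"{layer}/{key}": arr for layer, d in self.params.items() for key, arr in d.items()
        }
        np.savez(path, __spec__=np.frombuffer(self.spec.to_json().encode(), dtype=np.uint8), **flat)

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationNetwork":
        try:
            with np.load(path) as data:
                spec = NetworkSpec.from_json(bytes(data["__spec__"]).decode())
                model = cls(spec, seed=0)
                for key in data.files:
                    if key == "__spec__":
                        continue
                    layer, pname = key.split("/", 1)
                    model.params[layer][pname] = data[key].copy()
        except (OSError, KeyError, json.JSONDecodeError) as exc:
            raise ValueError(f"unreadable or corrupt checkpoint {path}: {exc}") from exc
        return model


def init_residual_block_params(block: ResidualBlockSpec, seed: int = 0) -> dict:
    """Freshly initialized parameters for a standalone residual block."""
    rng = np.random.default_rng(seed)
    p = {
        "conv1": _he_conv(rng, block.out_filters, block.in_filters, 3, 3),
        "bn1": _bn_params(block.out_filters),
        "conv2": _he_conv(rng, block.out_filters, block.out_filters, 3, 3),
        "bn2": _bn_params(block.out_filters),
    }
    if block.projects:
        p["skip_conv"] = _he_conv(rng, block.out_filters, block.in_filters, 1, 1)
        p["skip_bn"] = _bn_params(block.out_filters)
    return p


def residual_block_forward(
    x: np.ndarray, block: ResidualBlockSpec, params: dict, training: bool = False
) -> np.ndarray:
    """Standalone forward pass of the (optionally downsampling) block.

    Main path: 3x3 conv (block stride) + BN + ReLU + 3x3 conv + BN; skip
    path: identity, or 1x1 conv (block stride) + BN when projecting.
    Output: ReLU(main + skip).
    """
    if x.shape[1] != block.in_filters:
        raise ValueError(
            f"input has {x.shape[1]} channels, block expects {block.in_filters}"
        )
    h, _ = L.conv2d_forward(x, params["conv1"]["w"], params["conv1"]["b"], block.stride)
    h, _ = L.batchnorm_forward(
        h, params["bn1"]["gamma"], params["bn1"]["beta"],
        params["bn1"]["running_mean"], params["bn1"]["running_var"], training,
    )
    h, _ = L.relu_forward(h)
    h, _ = L.conv2d_forward(h, params["conv2"]["w"], params["conv2"]["b"], 1)
    h, _ = L.batchnorm_forward(
        h, params["bn2"]["gamma"], params["bn2"]["beta"],
        params["bn2"]["running_mean"], params["bn2"]["running_var"], training,
    )
    if block.projects:
        skip, _ = L.conv2d_forward(
            x, params["skip_conv"]["w"], params["skip_conv"]["b"], block.stride
        )
        skip, _ = L.batchnorm_forward(
            skip, params["skip_bn"]["gamma"], params["skip_bn"]["beta"],
            params["skip_bn"]["running_mean"], params["skip_bn"]["running_var"], training,
        )
    else:
        skip = x
    summed, _ = L.add_forward(h, skip)
    out, _ = L.relu_forward(summed)
    return out
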