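"""The padded-VGG16 fully convolutional segmentation network.

The stack is the FCN-32s adaptation of VGG16: a 100-px zero-padding
layer, the five VGG convolution blocks with a *valid* first convolution,
ceil-mode 2×2 max pooling, the two fully connected layers converted to
7×7 and 1×1 convolutions (with dropout), a 1×1 scoring convolution, one
kernel-64 / stride-32 transposed convolution back to input resolution,
and a crop to the input frame. For a 512-px input the feature sizes run
712 → 710 → 355 → 178 → 89 → 45 → 23 → 17 → 576 → 512.

``width_multiplier`` scales every channel width (spatial sizes are
unaffected), which makes desk-scale training and testing of the identical
topology possible on a CPU.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np

from .layers import (CenterCrop, Conv2D, ConvTranspose2D, Dropout, Layer,
                     MaxPool2x2Ceil, ReLU, ZeroPad)

__all__ = ["LayerSpec", "NetworkConfig", "ConfigurationError", "shape_trace",
           "FCNModel", "build_network"]

# channel widths of the full VGG16-FCN stack, keyed by conv name
_VGG_WIDTHS = {
    "conv1_1": 64, "conv1_2": 64,
    "conv2_1": 128, "conv2_2": 128,
    "conv3_1": 256, "conv3_2": 256, "conv3_3": 256,
    "conv4_1": 512, "conv4_2": 512, "conv4_3": 512,
    "conv5_1": 512, "conv5_2": 512, "conv5_3": 512,
    "conv6": 4096, "conv7": 4096,
}


class ConfigurationError(ValueError):
    """A layer stack that cannot propagate the requested input size."""


@dataclass(frozen=True)
class LayerSpec:
    """Declarative description of one layer row of the architecture table."""

    name: str
    kind: str  # pad | conv | relu | pool | dropout | deconv | crop
    kernel: Union[int, str] = "-"
    stride: Union[int, str] = "-"
    out_channels: int = 0
    padding: int = 0


def _scaled(width: int, multiplier: float) -> int:
    return max(1, math.ceil(width * multiplier))


@dataclass
class NetworkConfig:
    """Full network description; the default reproduces the published stack."""

    n_classes: int = 3
    width_multiplier: float = 1.0
    input_px: int = 512
    crop_offset: int = 32  # symmetric crop of the 576-px deconv output; 19 = classic FCN
    dropout: float = 0.5
    layers: List[LayerSpec] = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 < self.width_multiplier <= 1.0:
            raise ConfigurationError("width_multiplier must be in (0, 1]")
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if not self.layers:
            self.layers = self._default_layers()

    def _default_layers(self) -> List[LayerSpec]:
        wm = self.width_multiplier
        specs: List[LayerSpec] = [LayerSpec("pad", "pad", padding=100)]
        blocks = [("1", 2), ("2", 2), ("3", 3), ("4", 3), ("5", 3)]
        first = True
        for blk, n_convs in blocks:
            for i in range(1, n_convs + 1):
                name = f"conv{blk}_{i}"
                specs.append(LayerSpec(
                    name, "conv", kernel=3, stride=1,
                    out_channels=_scaled(_VGG_WIDTHS[name], wm),
                    padding=0 if first else 1))
                specs.append(LayerSpec(f"relu{blk}_{i}", "relu"))
                first = False
            specs.append(LayerSpec(f"pool{blk}", "pool", kernel=2, stride=2))
        specs += [
            LayerSpec("conv6", "conv", kernel=7, stride=1,
                      out_channels=_scaled(_VGG_WIDTHS["conv6"], wm), padding=0),
            LayerSpec("relu6", "relu"),
            LayerSpec("drop6", "dropout"),
            LayerSpec("conv7", "conv", kernel=1, stride=1,
                      out_channels=_scaled(_VGG_WIDTHS["conv7"], wm), padding=0),
            LayerSpec("relu7", "relu"),
            LayerSpec("drop7", "dropout"),
            LayerSpec("conv8", "conv", kernel=1, stride=1,
                      out_channels=self.n_classes, padding=0),
            LayerSpec("deconv9", "deconv", kernel=64, stride=32,
                      out_channels=self.n_classes),
            LayerSpec("crop", "crop"),
        ]
        return specs

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("layers")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


def shape_trace(cfg: NetworkConfig, input_px: Optional[int] = None
                ) -> List[Tuple[str, int, int, int]]:
    """Arithmetic feature-size propagation, no tensors allocated.

    Returns ``(name, H, W, C)`` rows including ``input`` and the final
    ``output`` class-map row (C = 1). ReLU and dropout rows are merged
    into their convolution, mirroring the architecture table.
    """
    n = cfg.input_px if input_px is None else input_px
    h = n
    c = 3
    rows: List[Tuple[str, int, int, int]] = [("input", h, h, c)]
    for spec in cfg.layers:
        if spec.kind == "pad":
            h = h + 2 * spec.padding
        elif spec.kind == "conv":
            h = h - int(spec.kernel) + 1 + 2 * spec.padding
            c = spec.out_channels
        elif spec.kind == "pool":
            h = math.ceil(h / 2)
        elif spec.kind == "deconv":
            h = (h - 1) * int(spec.stride) + int(spec.kernel)
            c = spec.out_channels
        elif spec.kind == "crop":
            if cfg.crop_offset + n > h:
                raise ConfigurationError(
                    f"layer {spec.name!r}: cannot crop {n} px at offset "
                    f"{cfg.crop_offset} from a {h}-px map")
            h = n
        elif spec.kind in ("relu", "dropout"):
            continue
        else:
            raise ConfigurationError(f"unknown layer kind {spec.kind!r}")
        if h <= 0:
            raise ConfigurationError(
                f"layer {spec.name!r} produces non-positive size {h} "
                f"for input {n}")
        rows.append((spec.name, h, h, c))
    rows.append(("output", n, n, 1))
    return rows


def normalize_tile(tile: np.ndarray) -> np.ndarray:
    """Map an 8-bit RGB tile to optical-density-like network input.

    ``x = 1 − rgb/255``: stained (dark) material becomes positive signal
    and bright glass approaches zero, so the network's zero padding reads
    as background rather than as maximally dark tissue.
    """
    return 1.0 - (tile.astype(np.float32) / 255.0).transpose(2, 0, 1)


class FCNModel:
    """Instantiated network: ordered numpy layers plus its config."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.layers: List[Layer] = []
        self.n_tile_evals = 0  # instrumentation: predict_tile call counter
        self._coarse_scores: Optional[np.ndarray] = None
        c_in = 3
        for spec in cfg.layers:
            if spec.kind == "pad":
                self.layers.append(ZeroPad(spec.name, spec.padding))
            elif spec.kind == "conv":
                self.layers.append(Conv2D(spec.name, c_in, spec.out_channels,
                                          int(spec.kernel), pad=spec.padding))
                c_in = spec.out_channels
            elif spec.kind == "relu":
                self.layers.append(ReLU(spec.name))
            elif spec.kind == "pool":
                self.layers.append(MaxPool2x2Ceil(spec.name))
            elif spec.kind == "dropout":
                drop = Dropout(spec.name, cfg.dropout)
                drop.rng = self.rng
                self.layers.append(drop)
            elif spec.kind == "deconv":
                self.layers.append(ConvTranspose2D(
                    spec.name, c_in, spec.out_channels,
                    int(spec.kernel), int(spec.stride)))
                c_in = spec.out_channels
            elif spec.kind == "crop":
                self.layers.append(CenterCrop(spec.name, cfg.crop_offset,
                                              cfg.input_px))

    def layer(self, name: str) -> Layer:
        for lyr in self.layers:
            if lyr.name == name:
                return lyr
        raise KeyError(name)

    def forward(self, x: np.ndarray, train: bool = False,
                record_shapes: Optional[list] = None) -> np.ndarray:
        """Run the stack on a ``(3, H, W)`` float32 image; returns class scores."""
        for lyr in self.layers:
            x = lyr.forward(x, train=train)
            if lyr.name == "conv8":
                # coarse stride-32 score map, kept for introspection/tests
                self._coarse_scores = x
            if record_shapes is not None:
                record_shapes.append((lyr.name, x.shape))
        return x

    def backward(self, dscores: np.ndarray) -> None:
        g = dscores
        for lyr in reversed(self.layers):
            g = lyr.backward(g)

    def predict_tile(self, tile: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Segment one 8-bit RGB tile of the configured input size.

        Returns ``(class_map, scores)``: the per-pixel argmax labels
        (uint8, ties broken toward the lowest class index) and the raw
        pre-softmax score planes ``(n_classes, H, W)``. Dropout is
        disabled; inference is deterministic.
        """
        n = self.cfg.input_px
        tile = np.asarray(tile)
        if tile.shape != (n, n, 3):
            raise ValueError(
                f"expected {n}x{n}x3 RGB tile, got {tile.shape}")
        x = normalize_tile(tile)
        scores = self.forward(x, train=False)
        class_map = scores.argmax(axis=0).astype(np.uint8)
        self.n_tile_evals += 1
        return class_map, scores

    # -- persistence ------------------------------------------------------

    def save(self, path: Union[str, Path]) -> None:
        """Single-file ``.npz`` checkpoint plus a JSON config sidecar."""
        path = Path(path)
        arrays = {}
        for i, lyr in enumerate(self.layers):
            for pname, arr in lyr.params.items():
                arrays[f"{i}:{lyr.name}:{pname}"] = arr
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(
            {"config": self.cfg.to_dict(), "seed": self.seed}, indent=2))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "FCNModel":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text())
        model = cls(NetworkConfig.from_dict(meta["config"]), seed=meta["seed"])
        with np.load(path) as data:
            for key in data.files:
                i, lname, pname = key.split(":")
                lyr = model.layers[int(i)]
                assert lyr.name == lname
                lyr.params[pname] = data[key]
        return model

    def parameters(self):
        """Yield ``(layer, param_name)`` pairs for every trainable array."""
        for lyr in self.layers:
            for pname in lyr.params:
                yield lyr, pname


def build_network(cfg: NetworkConfig, seed: int = 0,
                  scheme: str = "random") -> FCNModel:
    """Instantiate the network and initialize its weights.

    ``scheme`` is forwarded to :func:`ptcscreen.training.init_weights`
    (``random`` or ``pretrained_backbone``); builds with the same seed
    produce identical weights.
    """
    from ..training import init_weights

    model = FCNModel(cfg, seed=seed)
    init_weights(model, scheme=scheme, seed=seed)
    return model
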