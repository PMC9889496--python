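"""The two network shapes used by the pipeline.

Both consume 2.5D inputs: three neighbouring slices stacked as
channels.  ``SliceRegressor`` is a small convolutional encoder ending
in a global-average-pooled linear head (per-slice scalar outputs);
``UNet2p5`` is an encoder-decoder with skip connections (dense
per-pixel outputs), used for tissue segmentation and for landmark
heatmaps on coronal reconstructions.

Input height/width must be multiples of 4 (two pooling stages).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    ReLU,
    Upsample2d,
)

__all__ = ["UNet2p5", "SliceRegressor", "save_model", "load_model"]


class _Module:
    """Composite of named layers with state_dict plumbing."""

    def __init__(self):
        self._layers: dict[str, object] = {}

    def add(self, name, layer):
        self._layers[name] = layer
        setattr(self, name, layer)
        return layer

    def set_train(self, mode: bool):
        for layer in self._layers.values():
            layer.train_mode = mode

    def params(self):
        out = []
        for name, layer in self._layers.items():
            for pname, val, grad in layer.params():
                out.append((f"{name}.{pname}", val, grad))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: val for name, val, _ in self.params()}
        for lname, layer in self._layers.items():
            if isinstance(layer, BatchNorm2d):
                state[f"{lname}.running_mean"] = layer.running_mean
                state[f"{lname}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, val, _ in self.params():
            val[...] = state[name]
        for lname, layer in self._layers.items():
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"{lname}.running_mean"]
                layer.running_var[...] = state[f"{lname}.running_var"]


class _ConvBlock:
    """Conv -> BatchNorm -> ReLU."""

    def __init__(self, cin, cout, rng, k=3):
        self.conv = Conv2d(cin, cout, k=k, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.relu = ReLU()

    @property
    def train_mode(self):
        return self.bn.train_mode

    @train_mode.setter
    def train_mode(self, mode):
        for l in (self.conv, self.bn, self.relu):
            l.train_mode = mode

    def params(self):
        out = []
        for lname, l in (("conv", self.conv), ("bn", self.bn)):
            for pname, v, g in l.params():
                out.append((f"{lname}.{pname}", v, g))
        return out

    def forward(self, x):
        return self.relu.forward(self.bn.forward(self.conv.forward(x)))

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))


# expose running stats of nested blocks through _Module.state_dict
def _block_bn_state(module: _Module) -> dict[str, np.ndarray]:
    state = {}
    for lname, layer in module._layers.items():
        if isinstance(layer, _ConvBlock):
            state[f"{lname}.bn.running_mean"] = layer.bn.running_mean
            state[f"{lname}.bn.running_var"] = layer.bn.running_var
    return state


class UNet2p5(_Module):
    """Two-scale U-Net: enc(b) -> enc(2b) -> mid(4b) -> dec(2b) -> dec(b) -> 1x1."""

    def __init__(self, in_channels: int = 3, out_channels: int = 3, base: int = 8,
                 seed: int = 0, zero_head: bool = False):
        super().__init__()
        rng = np.random.default_rng(seed)
        b = base
        self.config = {
            "kind": "unet", "in_channels": in_channels,
            "out_channels": out_channels, "base": base, "zero_head": zero_head,
        }
        self.add("e0", _ConvBlock(in_channels, b, rng))
        self.add("pool0", MaxPool2d())
        self.add("e1", _ConvBlock(b, 2 * b, rng))
        self.add("pool1", MaxPool2d())
        self.add("mid", _ConvBlock(2 * b, 4 * b, rng))
        self.add("up1", Upsample2d())
        self.add("d1", _ConvBlock(4 * b + 2 * b, 2 * b, rng))
        self.add("up0", Upsample2d())
        self.add("d0", _ConvBlock(2 * b + b, b, rng))
        head = Conv2d(b, out_channels, k=1, rng=rng)
        if zero_head:
            # dense regression (heatmaps): start from the all-zero map
            # instead of spending early steps unlearning init noise
            head.w *= 0.0
        self.add("head", head)

    def state_dict(self):
        state = super().state_dict()
        state.update(_block_bn_state(self))
        return state

    def load_state_dict(self, state):
        super().load_state_dict(state)
        for lname, layer in self._layers.items():
            if isinstance(layer, _ConvBlock):
                layer.bn.running_mean[...] = state[f"{lname}.bn.running_mean"]
                layer.bn.running_var[...] = state[f"{lname}.bn.running_var"]

    def forward(self, x: np.ndarray) -> np.ndarray:
        a0 = self.e0.forward(x)
        a1 = self.e1.forward(self.pool0.forward(a0))
        m = self.mid.forward(self.pool1.forward(a1))
        u1 = self.up1.forward(m)
        self._c1 = a1.shape[1]
        d1 = self.d1.forward(np.concatenate([u1, a1], axis=1))
        u0 = self.up0.forward(d1)
        self._c0 = a0.shape[1]
        d0 = self.d0.forward(np.concatenate([u0, a0], axis=1))
        return self.head.forward(d0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dd0 = self.head.backward(dy)
        dcat0 = self.d0.backward(dd0)
        du0, da0_skip = dcat0[:, : -self._c0], dcat0[:, -self._c0 :]
        dd1 = self.up0.backward(du0)
        dcat1 = self.d1.backward(dd1)
        du1, da1_skip = dcat1[:, : -self._c1], dcat1[:, -self._c1 :]
        dm = self.up1.backward(du1)
        da1 = self.pool1.backward(self.mid.backward(dm)) + da1_skip
        da0 = self.pool0.backward(self.e1.backward(da1)) + da0_skip
        return self.e0.backward(da0)


class SliceRegressor(_Module):
    """Conv encoder with a linear head producing per-image scalars."""

    def __init__(self, in_channels: int = 3, n_outputs: int = 2, base: int = 8,
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        b = base
        self.config = {
            "kind": "regressor", "in_channels": in_channels,
            "n_outputs": n_outputs, "base": base,
        }
        self.add("c0", _ConvBlock(in_channels, b, rng))
        self.add("pool0", MaxPool2d())
        self.add("c1", _ConvBlock(b, 2 * b, rng))
        self.add("pool1", MaxPool2d())
        self.add("c2", _ConvBlock(2 * b, 4 * b, rng))
        self.add("pool2", MaxPool2d())
        self.add("gap", GlobalAvgPool())
        self.add("fc", Linear(4 * b, n_outputs, rng=rng))

    def state_dict(self):
        state = super().state_dict()
        state.update(_block_bn_state(self))
        return state

    def load_state_dict(self, state):
        super().load_state_dict(state)
        for lname, layer in self._layers.items():
            if isinstance(layer, _ConvBlock):
                layer.bn.running_mean[...] = state[f"{lname}.bn.running_mean"]
                layer.bn.running_var[...] = state[f"{lname}.bn.running_var"]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.pool0.forward(self.c0.forward(x))
        h = self.pool1.forward(self.c1.forward(h))
        h = self.pool2.forward(self.c2.forward(h))
        return self.fc.forward(self.gap.forward(h))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.gap.backward(self.fc.backward(dy))
        dh = self.c2.backward(self.pool2.backward(dh))
        dh = self.c1.backward(self.pool1.backward(dh))
        return self.c0.backward(self.pool0.backward(dh))


def save_model(model, path) -> None:
    """Persist weights (.npz) with the model config embedded as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path, __config__=np.frombuffer(
            json.dumps(model.config).encode(), dtype=np.uint8
        ), **model.state_dict()
    )


def load_model(path):
    with np.load(path) as data:
        config = json.loads(bytes(data["__config__"]).decode())
        state = {k: data[k] for k in data.files if k != "__config__"}
    if config["kind"] == "unet":
        model = UNet2p5(config["in_channels"], config["out_channels"], config["base"],
                        zero_head=config.get("zero_head", False))
    else:
        model = SliceRegressor(config["in_channels"], config["n_outputs"], config["base"])
    model.load_state_dict(state)
    model.set_train(False)
    return model
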