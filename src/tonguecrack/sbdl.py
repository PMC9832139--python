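"""The two-stage crack network: segmentation stage plus decision stage.

The segmentation network turns a tongue crop into a single-channel crack
logit map at 1/8 of the input resolution together with its final
1024-channel feature volume.  It stacks 11 convolutions and 3 max-pooling
layers: two 5x5/32 convolutions, pool, three 5x5/64, pool, four 5x5/64,
pool, one wide 15x15/1024 convolution (the large receptive field is what
lets thin, low-contrast cracks be told apart from papillae and contour
edges), and a 1x1 head producing the logit map.  Every convolution except
the head is followed by batch normalisation and ReLU; dropout is not used.

The decision network classifies the whole image as cracked / non-cracked
from the channel concatenation of the feature volume and the logit map
(1024 + 1 = 1025 channels).  Its trunk is pool, 5x5/8, pool, 5x5/16, pool,
5x5/32; global max- and average-pooling of the 32 trunk channels (64
values) and of the logit map (2 values) feed a 66-input fully connected
layer that emits one logit; ``sigmoid(logit)`` is the crack probability.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "SegOutput",
    "SegNet",
    "DecNet",
    "SegNetParams",
    "DecNetParams",
    "init_params",
    "seg_forward",
    "dec_forward",
    "save_checkpoint",
    "load_checkpoint",
]

DOWNSAMPLE = 8  # three 2x2 pools
FEATURE_CHANNELS = 1024
TRUNK_IN_CHANNELS = FEATURE_CHANNELS + 1
FC_IN = 2 * 32 + 2

#: (kernel, c_in, c_out, batch-norm+relu) for the 11 segmentation convolutions;
#: ``None`` marks a pooling layer.
_SEG_PLAN = (
    (5, 3, 32, True),
    (5, 32, 32, True),
    None,
    (5, 32, 64, True),
    (5, 64, 64, True),
    (5, 64, 64, True),
    None,
    (5, 64, 64, True),
    (5, 64, 64, True),
    (5, 64, 64, True),
    (5, 64, 64, True),
    None,
    (15, 64, FEATURE_CHANNELS, True),
    (1, FEATURE_CHANNELS, 1, False),
)

_DEC_PLAN = ((5, TRUNK_IN_CHANNELS, 8), (5, 8, 16), (5, 16, 32))

#: Initial bias of the 1x1 head; sigmoid(-2) ~ 0.12, a sensible prior for the
#: fraction of crack cells in a cracked tongue crop.
HEAD_BIAS_INIT = -2.0


@dataclass
class SegOutput:
    """Segmentation result for one image: logit map and feature volume.

    ``logit_map`` has shape (H/8, W/8); ``features`` has shape
    (H/8, W/8, 1024).
    """

    logit_map: np.ndarray
    features: np.ndarray

    def __post_init__(self):
        if self.logit_map.shape != self.features.shape[:2]:
            raise ValueError(
                "logit map shape "
                f"{self.logit_map.shape} does not match feature volume spatial "
                f"shape {self.features.shape[:2]}"
            )


def _check_divisible(h, w):
    for name, size in (("height", h), ("width", w)):
        if size % DOWNSAMPLE != 0:
            raise ValueError(
                f"input {name} {size} is not divisible by {DOWNSAMPLE}; the "
                "three 2x2 poolings require multiples of 8 (inputs are "
                "rejected rather than silently padded)"
            )


def _as_float_image(image):
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {image.shape}")
    if image.dtype == np.uint8:
        return image.astype(np.float32) / 255.0
    return image.astype(np.float32, copy=False)


class SegNet(nn.Layer):
    """Segmentation network; see the module docstring for the layer plan."""

    def __init__(self, rng=None, dtype=np.float32):
        self.convs = []
        self.bns = []
        self.sequence = []  # (kind, layer) in forward order
        ci = 0
        for spec in _SEG_PLAN:
            if spec is None:
                self.sequence.append(("pool", nn.MaxPool2d()))
                continue
            k, c_in, c_out, bnrelu = spec
            conv = nn.Conv2d(c_in, c_out, k, rng=rng, dtype=dtype)
            self.convs.append(conv)
            self.sequence.append(("conv", conv))
            if bnrelu:
                bn = nn.BatchNorm2d(c_out, dtype=dtype)
                self.bns.append(bn)
                self.sequence.append(("bn", bn))
                self.sequence.append(("relu", nn.ReLU()))
        assert len(self.convs) == 11
        self.head = self.convs[-1]
        self.head.b[...] = HEAD_BIAS_INIT

    # -- parameter plumbing -------------------------------------------------
    def _named_layers(self):
        for i, conv in enumerate(self.convs, start=1):
            yield f"conv{i}.", conv
        for i, bn in enumerate(self.bns, start=1):
            yield f"bn{i}.", bn

    def params(self):
        out = []
        for prefix, layer in self._named_layers():
            out.extend((prefix + n, v, g) for n, v, g in layer.params())
        return out

    def zero_grad(self):
        for _, layer in self._named_layers():
            layer.zero_grad()

    def state_dict(self, prefix=""):
        state = {}
        for name, layer in self._named_layers():
            state.update(layer.state_dict(prefix + name))
        return state

    def load_state(self, state, prefix=""):
        for name, layer in self._named_layers():
            layer.load_state(state, prefix + name)

    # -- forward / backward -------------------------------------------------
    def forward(self, x, train=False):
        """Run a batch (N, H, W, 3) -> (logits (N, h, w, 1), features)."""
        _check_divisible(x.shape[1], x.shape[2])
        feats = None
        for kind, layer in self.sequence:
            if kind == "conv":
                if layer is self.head:
                    feats = x
                x = layer.forward(x, keep_cache=train)
            elif kind == "bn":
                x = layer.forward(x, train=train)
            else:
                x = layer.forward(x)
        return x, feats

    def backward(self, dlogits):
        """Backpropagate the loss gradient on the logit map; accumulates
        parameter gradients and discards the input gradient."""
        grad = dlogits
        first_conv = self.convs[0]
        for kind, layer in reversed(self.sequence):
            if kind == "conv":
                grad = layer.backward(grad, need_dx=layer is not first_conv)
            else:
                grad = layer.backward(grad)


class DecNet(nn.Layer):
    """Decision network on top of frozen segmentation outputs."""

    def __init__(self, rng=None, dtype=np.float32):
        self.pools = [nn.MaxPool2d() for _ in range(3)]
        self.convs = [nn.Conv2d(ci, co, k, rng=rng, dtype=dtype) for k, ci, co in _DEC_PLAN]
        self.relus = [nn.ReLU() for _ in range(3)]
        self.fc = nn.Linear(FC_IN, 1, rng=rng, dtype=dtype)

    def _named_layers(self):
        for i in range(3):
            yield f"conv{i + 1}.", self.convs[i]
        yield "fc.", self.fc

    def params(self):
        out = []
        for prefix, layer in self._named_layers():
            out.extend((prefix + n, v, g) for n, v, g in layer.params())
        return out

    def zero_grad(self):
        for _, layer in self._named_layers():
            layer.zero_grad()

    def state_dict(self, prefix=""):
        state = {}
        for name, layer in self._named_layers():
            state.update(layer.state_dict(prefix + name))
        return state

    def load_state(self, state, prefix=""):
        for name, layer in self._named_layers():
            layer.load_state(state, prefix + name)

    def forward(self, features, logits, train=False):
        """(N, h, w, 1024) features + (N, h, w, 1) logits -> (N, 1) logit."""
        if features.shape[:3] != logits.shape[:3]:
            raise ValueError(
                f"feature volume spatial shape {features.shape[1:3]} does not "
                f"match logit map shape {logits.shape[1:3]}"
            )
        x = np.concatenate([features, logits], axis=-1)
        assert x.shape[-1] == TRUNK_IN_CHANNELS
        for pool, conv, relu in zip(self.pools, self.convs, self.relus):
            x = pool.forward(x)
            x = conv.forward(x, keep_cache=train)
            x = relu.forward(x)
        n, th, tw, tc = x.shape
        flat = x.reshape(n, th * tw, tc)
        self._argmax = flat.argmax(axis=1)
        self._trunk_shape = x.shape
        gmax = np.take_along_axis(flat, self._argmax[:, None, :], axis=1)[:, 0, :]
        gavg = flat.mean(axis=1)
        lflat = logits.reshape(n, -1)
        lmax = lflat.max(axis=1, keepdims=True)
        lavg = lflat.mean(axis=1, keepdims=True)
        vec = np.concatenate([gmax, gavg, lmax, lavg], axis=1)
        assert vec.shape[1] == FC_IN
        return self.fc.forward(vec)

    def backward(self, dout):
        """Backpropagate (N, 1) logit gradients; the gradient with respect to
        the (frozen) segmentation outputs is not formed."""
        dvec = self.fc.backward(dout)
        n, th, tw, tc = self._trunk_shape
        dflat = np.zeros((n, th * tw, tc), dtype=dvec.dtype)
        np.put_along_axis(dflat, self._argmax[:, None, :], dvec[:, None, :32], axis=1)
        dflat += dvec[:, None, 32:64] / (th * tw)
        grad = dflat.reshape(n, th, tw, tc)
        for i in reversed(range(3)):
            grad = self.relus[i].backward(grad)
            grad = self.convs[i].backward(grad, need_dx=i > 0)
            if i > 0:
                grad = self.pools[i].backward(grad)
        self._argmax = None


# The spec-level parameter containers are the network objects themselves.
SegNetParams = SegNet
DecNetParams = DecNet


def init_params(seed):
    """Deterministically initialise both networks from one integer seed."""
    rng = np.random.default_rng(seed)
    return SegNet(rng=rng), DecNet(rng=rng)


def seg_forward(image, params):
    """Run the segmentation network on one RGB image (evaluation mode).

    Parameters
    ----------
    image : (H, W, 3) uint8 or float array, H and W divisible by 8.
    params : SegNet

    Returns
    -------
    SegOutput with ``logit_map`` (H/8, W/8) and ``features`` (H/8, W/8, 1024).
    """
    x = _as_float_image(image)[None]
    logits, feats = params.forward(x, train=False)
    return SegOutput(logit_map=logits[0, :, :, 0], features=feats[0])


def dec_forward(seg_out, params):
    """Run the decision network on one segmentation output; returns the
    scalar crack logit (``sigmoid`` of it is the crack probability)."""
    feats = seg_out.features[None]
    logits = seg_out.logit_map[None, :, :, None]
    out = params.forward(feats, logits, train=False)
    return float(out[0, 0])


# -- checkpointing ----------------------------------------------------------

def architecture_hash():
    """Stable hash of the layer plan, recorded next to checkpoints."""
    desc = json.dumps({"seg": _SEG_PLAN, "dec": _DEC_PLAN, "fc_in": FC_IN})
    return hashlib.sha256(desc.encode()).hexdigest()[:16]


def save_checkpoint(path, seg, dec, config=None):
    """Save both networks to ``path`` (.npz) plus a JSON sidecar."""
    path = str(path)
    state = seg.state_dict("seg.")
    state.update(dec.state_dict("dec."))
    np.savez(path if path.endswith(".npz") else path + ".npz", **state)
    sidecar = {"architecture_hash": architecture_hash(), "config": config or {}}
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path):
    """Load a checkpoint saved by :func:`save_checkpoint`."""
    path = str(path)
    npz = path if path.endswith(".npz") else path + ".npz"
    with np.load(npz) as data:
        state = {k: data[k] for k in data.files}
    seg, dec = SegNet(), DecNet()
    seg.load_state(state, "seg.")
    dec.load_state(state, "dec.")
    return seg, dec
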