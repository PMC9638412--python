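"""The multi-resolution encoder-decoder used for both segmentation tasks.

The network keeps several parallel branches at resolutions 1, 1/2, 1/4, ...
(high-resolution-network style): a full-resolution stem of A-blocks
(conv + batch norm + ReLU) and bottleneck B-blocks feeds the first branch;
each further branch is opened by a stride-2 convolution from the previous one
and refined by basic C-blocks.  In the final stage every branch is bilinearly
upsampled back to full resolution, the representations are concatenated, and
a 1x1 convolution with a sigmoid head produces one probability channel, so the
output range contract (values in [0, 1]) is structural.

The same architecture is instantiated twice in the pipeline — once trained for
nerve fibers, once for PNI signal; the two models share no weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ..errors import ShapeError, ValidationError
from . import _nn
from ._nn import Tensor

__all__ = ["SegModelConfig", "SegModel", "build_model", "DESK_SCALE_CONFIG"]


@dataclass(frozen=True)
class SegModelConfig:
    """Architecture hyperparameters.

    input_size
        Spatial size (H, W) of one RGB training patch.
    base_channels
        Channel width C of the full-resolution branch; branch i carries
        C * 2**i channels.
    n_branches
        Number of resolution branches; branch i runs at scale 1 / 2**i.
    block_layout
        Per-type block counts: "A" stem conv blocks, "B" bottleneck blocks at
        the stem, "C" basic blocks per branch.
    """

    input_size: tuple[int, int] = (256, 256)
    base_channels: int = 32
    n_branches: int = 4
    block_layout: dict = field(default_factory=lambda: {"A": 2, "B": 4, "C": 2})

    def __post_init__(self):
        h, w = self.input_size
        div = 2 ** (self.n_branches - 1)
        if h % div or w % div:
            raise ValidationError(
                f"input size {self.input_size} must be divisible by {div} "
                f"for {self.n_branches} branches"
            )
        if self.base_channels < 1 or self.n_branches < 1:
            raise ValidationError("base_channels and n_branches must be >= 1")
        if any(self.block_layout.get(k, 0) < 0 for k in "ABC"):
            raise ValidationError("block counts must be >= 0")
        if self.block_layout.get("A", 0) < 1:
            raise ValidationError("need at least one stem A-block")


#: reduced profile that trains in minutes on one CPU
DESK_SCALE_CONFIG = SegModelConfig(
    input_size=(64, 64), base_channels=8, n_branches=2, block_layout={"A": 2, "B": 2, "C": 2}
)


class _Conv:
    def __init__(self, params, bns, name, cin, cout, k, stride, rng, bn=True):
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = Tensor(rng.normal(0.0, std, size=(cout, cin, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        params[f"{name}.w"] = self.w
        params[f"{name}.b"] = self.b
        self.stride = stride
        self.bn = None
        if bn:
            self.gamma = Tensor(np.ones(cout), requires_grad=True)
            self.beta = Tensor(np.zeros(cout), requires_grad=True)
            params[f"{name}.gamma"] = self.gamma
            params[f"{name}.beta"] = self.beta
            self.bn = _nn.BatchNormState(cout)
            bns[f"{name}.bn"] = self.bn

    def __call__(self, x, training, activate=True):
        y = _nn.conv2d(x, self.w, self.b, stride=self.stride)
        if self.bn is not None:
            y = _nn.batchnorm2d(y, self.gamma, self.beta, self.bn, training)
        return _nn.relu(y) if activate else y


class _Bottleneck:
    """1x1 reduce -> 3x3 -> 1x1 expand with a residual connection."""

    def __init__(self, params, bns, name, channels, rng):
        mid = max(channels // 2, 1)
        self.c1 = _Conv(params, bns, f"{name}.c1", channels, mid, 1, 1, rng)
        self.c2 = _Conv(params, bns, f"{name}.c2", mid, mid, 3, 1, rng)
        self.c3 = _Conv(params, bns, f"{name}.c3", mid, channels, 1, 1, rng)

    def __call__(self, x, training):
        y = self.c1(x, training)
        y = self.c2(y, training)
        y = self.c3(y, training, activate=False)
        return _nn.relu(_nn.add(x, y))


class _Basic:
    """Two 3x3 convolutions with a residual connection."""

    def __init__(self, params, bns, name, channels, rng):
        self.c1 = _Conv(params, bns, f"{name}.c1", channels, channels, 3, 1, rng)
        self.c2 = _Conv(params, bns, f"{name}.c2", channels, channels, 3, 1, rng)

    def __call__(self, x, training):
        y = self.c1(x, training)
        y = self.c2(y, training, activate=False)
        return _nn.relu(_nn.add(x, y))


class SegModel:
    """One instantiated network: parameters, running statistics, forward."""

    def __init__(self, config: SegModelConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}
        self.bn_states: dict[str, _nn.BatchNormState] = {}
        p, s = self.params, self.bn_states
        c = config.base_channels
        layout = config.block_layout

        self.stem = []
        cin = 3
        for i in range(layout.get("A", 0)):
            self.stem.append(_Conv(p, s, f"stem.a{i}", cin, c, 3, 1, rng))
            cin = c
        self.stem_b = [
            _Bottleneck(p, s, f"stem.b{i}", c, rng) for i in range(layout.get("B", 0))
        ]
        self.downs = []
        self.branches = []
        for br in range(config.n_branches):
            ch = c * 2**br
            if br > 0:
                self.downs.append(_Conv(p, s, f"down{br}", ch // 2, ch, 3, 2, rng))
            self.branches.append(
                [_Basic(p, s, f"br{br}.c{i}", ch, rng) for i in range(layout.get("C", 0))]
            )
        total = sum(c * 2**br for br in range(config.n_branches))
        self.head = _Conv(p, s, "head", total, 1, 1, 1, rng, bn=False)

    # -- forward ------------------------------------------------------------

    def forward(self, x: np.ndarray | Tensor, training: bool = False) -> Tensor:
        """x: (N, 3, H, W) float in [0, 1] -> (N, 1, H, W) in (0, 1)."""
        t = x if isinstance(x, Tensor) else Tensor(x)
        n, ch, h, w = t.data.shape
        if ch != 3 or (h, w) != self.config.input_size:
            raise ShapeError(
                f"expected (N, 3, {self.config.input_size[0]}, "
                f"{self.config.input_size[1]}) input, got {t.data.shape}"
            )
        for blk in self.stem:
            t = blk(t, training)
        for blk in self.stem_b:
            t = blk(t, training)
        outs = []
        cur = t
        for br in range(self.config.n_branches):
            if br > 0:
                cur = self.downs[br - 1](cur, training)
            y = cur
            for blk in self.branches[br]:
                y = blk(y, training)
            outs.append(y if br == 0 else _nn.upsample_bilinear(y, (h, w)))
            if br > 0:
                cur = y  # next branch descends from the refined representation
        fused = outs[0] if len(outs) == 1 else _nn.concat(outs)
        logits = self.head(fused, training, activate=False)
        return _nn.sigmoid(logits)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Inference on (N, H, W, 3) images (uint8 or [0, 1] float);
        returns (N, H, W) probabilities using running BN statistics."""
        x = np.asarray(images, dtype=float)
        if x.max() > 1.0:
            x = x / 255.0
        x = x.transpose(0, 3, 1, 2)
        with _nn.no_grad():
            out = self.forward(x, training=False)
        return out.data[:, 0]

    # -- bookkeeping ----------------------------------------------------------

    @property
    def num_params(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def save(self, path) -> None:
        """Single-file checkpoint: weights, BN running stats, config."""
        arrays = {f"param:{k}": v.data for k, v in self.params.items()}
        for k, st in self.bn_states.items():
            arrays[f"state:{k}.mean"] = st.mean
            arrays[f"state:{k}.var"] = st.var
        meta = {
            "format_version": 1,
            "seed": self.seed,
            "config": {
                "input_size": list(self.config.input_size),
                "base_channels": self.config.base_channels,
                "n_branches": self.config.n_branches,
                "block_layout": self.config.block_layout,
            },
        }
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SegModel":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["meta"].tobytes()).decode())
            cfg = meta["config"]
            config = SegModelConfig(
                input_size=tuple(cfg["input_size"]),
                base_channels=cfg["base_channels"],
                n_branches=cfg["n_branches"],
                block_layout=dict(cfg["block_layout"]),
            )
            model = cls(config, seed=meta["seed"])
            for k, tensor in model.params.items():
                tensor.data = archive[f"param:{k}"].copy()
            for k, st in model.bn_states.items():
                st.mean = archive[f"state:{k}.mean"].copy()
                st.var = archive[f"state:{k}.var"].copy()
        return model


def build_model(config: SegModelConfig, seed: int = 0) -> SegModel:
    """Instantiate the network with seeded He-normal initialization."""
    return SegModel(config, seed=seed)
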