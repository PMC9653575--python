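"""2-D dilated residual U-Net for multi-organ CT slice segmentation.

Encoder and decoder are each five cascades of residual blocks (two 3x3
convolutions per block, batch-normalized, with a projected shortcut when
channel counts change). Downsampling is 2x2 max pooling, upsampling is
bilinear interpolation, and shortcut (skip) connections concatenate the
encoder feature map of each resolution onto the corresponding decoder
input. The fifth decoder cascade runs at full resolution ahead of a 1x1
classification convolution, so the class map has the same spatial shape as
the input slice; the input itself is concatenated onto the final feature
map (a shortcut from input to output) so the classifier always sees the
raw intensity alongside the learned context features. Per-level dilation rates are configurable; by default all
convolutions are undilated, with an optional dilated-bottleneck preset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .nn import BilinearUp2, Conv2d, MaxPool2, Param, ResidualBlock, softmax

__all__ = ["UNetConfig", "ResidualUNet", "build_residual_unet", "save_model", "load_model"]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters of the residual U-Net.

    ``n_classes`` counts background plus the four target structures
    (brain, heart, kidneys as a single class, bladder); the kidneys are
    split into left/right downstream by component position, so the
    network never has to tell two intensity-identical organs apart.
    Channel width at level i is ``min(base_channels * channel_growth**i,
    max_channels)``. ``dilations`` gives the dilation rate of each encoder
    level (the preset ``dilated_bottleneck()`` uses rates 2 and 4 on the
    two deepest levels).
    """

    in_channels: int = 1
    n_classes: int = 5
    depth: int = 5
    base_channels: int = 8
    channel_growth: int = 2
    max_channels: int = 64
    dilations: tuple[int, ...] = (1, 1, 1, 1, 1)
    batch_norm: bool = True

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ConfigurationError("depth must be >= 2")
        if len(self.dilations) != self.depth:
            raise ConfigurationError("need one dilation rate per level")
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")

    @property
    def widths(self) -> tuple[int, ...]:
        return tuple(
            min(self.base_channels * self.channel_growth ** i, self.max_channels)
            for i in range(self.depth)
        )

    @property
    def divisor(self) -> int:
        """Input spatial sizes must be divisible by this (2**(depth-1))."""
        return 2 ** (self.depth - 1)

    @classmethod
    def dilated_bottleneck(cls, **kwargs) -> "UNetConfig":
        depth = kwargs.pop("depth", 5)
        dil = tuple([1] * (depth - 2) + [2, 4])
        return cls(depth=depth, dilations=dil, **kwargs)


class ResidualUNet:
    """The segmentation network; see module docstring for the topology."""

    def __init__(self, config: UNetConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        w = config.widths
        d = config.depth
        cin = config.in_channels
        self.enc: list[ResidualBlock] = []
        for i in range(d):
            self.enc.append(ResidualBlock(
                cin if i == 0 else w[i - 1], w[i], dilation=config.dilations[i],
                batch_norm=config.batch_norm, rng=rng, name=f"enc{i}"))
        self.pools = [MaxPool2() for _ in range(d - 1)]
        self.ups = [BilinearUp2() for _ in range(d - 1)]
        self.dec: list[ResidualBlock] = []
        for i in range(d - 2, -1, -1):
            self.dec.append(ResidualBlock(
                w[i + 1] + w[i], w[i], batch_norm=config.batch_norm,
                rng=rng, name=f"dec{i}"))
        # fifth decoder cascade at full resolution
        self.dec_final = ResidualBlock(w[0], w[0], batch_norm=config.batch_norm,
                                       rng=rng, name="dec_final")
        # the input slice is concatenated onto the final features before the
        # 1x1 classifier: an input->output shortcut that guarantees the
        # (intensity-coded) classes a direct gradient path even if the
        # narrow learned features momentarily collapse two tissues together
        self.classifier = Conv2d(w[0] + cin, config.n_classes, k=1, rng=rng,
                                 name="classifier")
        self._skip_channels: list[int] = []

    # -- parameters -------------------------------------------------------
    def params(self) -> list[Param]:
        out: list[Param] = []
        for blk in self.enc + self.dec + [self.dec_final]:
            out += blk.params()
        out += self.classifier.params()
        return out

    def head_params(self) -> list[Param]:
        """Parameters of the final (classification) layer only."""
        return self.classifier.params()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def reset_head(self, rng: np.random.Generator) -> None:
        """Re-randomize the final 1x1 classification layer."""
        cfg = self.config
        std = np.sqrt(2.0 / (cfg.widths[0] + cfg.in_channels))
        self.classifier.w.data = rng.normal(0.0, std, self.classifier.w.data.shape).astype(np.float32)
        if self.classifier.b is not None:
            self.classifier.b.data[...] = 0.0
        for p in self.classifier.params():
            p.m[...] = 0.0
            p.v[...] = 0.0

    # -- forward / backward ----------------------------------------------
    def _check_shape(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ConfigurationError(f"expected (N,{self.config.in_channels},H,W), got {x.shape}")
        if x.shape[2] % self.config.divisor or x.shape[3] % self.config.divisor:
            raise ConfigurationError(
                f"spatial size {x.shape[2:]}, must be divisible by {self.config.divisor}")

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits (N, n_classes, H, W) for a batch of slices."""
        self._check_shape(x)
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips: list[np.ndarray] = []
        h = x
        for i, blk in enumerate(self.enc):
            h = blk.forward(h, train)
            if i < len(self.pools):
                skips.append(h)
                h = self.pools[i].forward(h, train)
        self._skip_channels = [s.shape[1] for s in skips]
        for j, blk in enumerate(self.dec):
            lvl = len(self.ups) - 1 - j
            h = self.ups[lvl].forward(h, train)
            h = np.concatenate([h, skips[lvl]], axis=1)
            h = blk.forward(h, train)
        h = self.dec_final.forward(h, train)
        h = np.concatenate([h, x], axis=1)
        return self.classifier.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.classifier.backward(dlogits)
        g = np.ascontiguousarray(g[:, :g.shape[1] - self.config.in_channels])
        g = self.dec_final.backward(g)
        skip_grads: dict[int, np.ndarray] = {}
        for j in range(len(self.dec) - 1, -1, -1):
            lvl = len(self.ups) - 1 - j
            g = self.dec[j].backward(g)
            up_ch = g.shape[1] - self._skip_channels[lvl]
            skip_grads[lvl] = g[:, up_ch:]
            g = self.ups[lvl].backward(np.ascontiguousarray(g[:, :up_ch]))
        for i in range(len(self.enc) - 1, -1, -1):
            if i < len(self.pools):
                g = self.pools[i].backward(g)
                g = g + skip_grads[i]
            g = self.enc[i].backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities in eval mode (running batch-norm statistics)."""
        return softmax(self.forward(x, train=False), axis=1)

    def predict_labels(self, x: np.ndarray) -> np.ndarray:
        """Argmax class labels (N, H, W) in eval mode."""
        return np.argmax(self.forward(x, train=False), axis=1)

    # -- persistence ------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {f"param/{i}/{p.name}": p.data for i, p in enumerate(self.params())}
        bns = self._batchnorms()
        for i, bn in enumerate(bns):
            out[f"bn/{i}/mean"] = bn.running_mean
            out[f"bn/{i}/var"] = bn.running_var
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            key = f"param/{i}/{p.name}"
            if key not in arrays or arrays[key].shape != p.data.shape:
                raise ConfigurationError(f"checkpoint incompatible at {key}")
            p.data = np.ascontiguousarray(arrays[key], dtype=np.float32)
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean = np.ascontiguousarray(arrays[f"bn/{i}/mean"], dtype=np.float32)
            bn.running_var = np.ascontiguousarray(arrays[f"bn/{i}/var"], dtype=np.float32)

    def _batchnorms(self):
        out = []
        for blk in self.enc + self.dec + [self.dec_final]:
            for bn in (blk.bn1, blk.bn2, blk.proj_bn):
                if bn is not None:
                    out.append(bn)
        return out


def build_residual_unet(config: UNetConfig | None = None, seed: int = 0) -> ResidualUNet:
    """Construct a randomly initialized residual U-Net."""
    return ResidualUNet(config or UNetConfig(), seed=seed)


def save_model(model: ResidualUNet, path: str) -> None:
    """Single-file checkpoint (.npz) with the architecture config embedded."""
    cfg = json.dumps(model.config.__dict__ | {"dilations": list(model.config.dilations)})
    np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
             **model.state_arrays())


def load_model(path: str) -> ResidualUNet:
    with np.load(path) as data:
        cfg_json = bytes(data["__config__"]).decode()
        d = json.loads(cfg_json)
        d["dilations"] = tuple(d["dilations"])
        model = ResidualUNet(UNetConfig(**d))
        model.load_state_arrays({k: data[k] for k in data.files if k != "__config__"})
    return model
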