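"""HeadNet: stacked-hourglass keypoint detector with attention residual modules.

The network takes a grayscale cephalogram, produces one heatmap per landmark
(Ba, Ar, A', PNS) per hourglass stack, and converts each heatmap into a
continuous coordinate by integral regression (spatial soft-argmax), so the
whole pipeline is differentiable down to pixel coordinates.

Architecture: a convolutional stem (7x7/stride-2 conv, 1x1 channel expansion,
max-pool down to the heatmap resolution) feeds ``n_stacks`` hourglass modules.
Each hourglass is an encoder-decoder of bottleneck residual modules with
identity skip connections; attention residual modules (channel gate followed
by spatial gate, CBAM-style) sit at the entry and exit of every stack.
A 1x1 head maps features to one heatmap per keypoint; intermediate stacks are
re-merged into the feature stream so every stack can be supervised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from . import nn
from .geometry import KEYPOINT_NAMES, Point2D

__all__ = [
    "LAYER_TABLE",
    "ModelConfig",
    "ResidualModule",
    "AttentionResidualModule",
    "Hourglass",
    "HeadNet",
    "build_model",
    "integral_coordinates",
    "save_checkpoint",
    "load_checkpoint",
]

#: Reference convolution-layer table at full scale (kernel, stride, out channels).
#: C1-C3 belong to the trunk/head, C3-C5 to residual modules, C6-C7 to the
#: attention gates. Width-reduced models scale the channel counts proportionally.
LAYER_TABLE: Dict[str, Dict[str, int]] = {
    "C1": {"kernel": 7, "stride": 2, "out_channels": 64},
    "C2": {"kernel": 1, "stride": 1, "out_channels": 4},
    "C3": {"kernel": 1, "stride": 1, "out_channels": 256},
    "C4": {"kernel": 1, "stride": 1, "out_channels": 128},
    "C5": {"kernel": 3, "stride": 1, "out_channels": 128},
    "C6": {"kernel": 1, "stride": 1, "out_channels": 16},
    "C7": {"kernel": 7, "stride": 1, "out_channels": 1},
}


class ConfigError(ValueError):
    """Inconsistent model configuration."""


@dataclass
class ModelConfig:
    """Hyperparameters of the keypoint network.

    ``width`` is the feature-channel count inside the hourglasses (256 at full
    scale); the residual bottleneck is ``width // 2`` (128 at full scale) and
    the channel-attention bottleneck defaults to 16, matching the reference
    layer table. ``input_size / heatmap_size`` must be a power of two >= 2
    (the stride-2 stem conv plus max-pools provide the downsampling).
    """

    input_size: int = 256
    heatmap_size: int = 64
    n_keypoints: int = 4
    n_stacks: int = 2
    hourglass_depth: int = 4
    width: int = 256
    use_attention: bool = True
    channel_attention_bottleneck: int = 16
    spatial_attention_kernel: int = 7
    stem_channels: int = 64
    layer_params: Dict[str, Dict[str, int]] = field(default_factory=lambda: {
        k: dict(v) for k, v in LAYER_TABLE.items()
    })

    def __post_init__(self) -> None:
        if self.input_size % self.heatmap_size:
            raise ConfigError("input_size must be a multiple of heatmap_size")
        f = self.input_size // self.heatmap_size
        if f < 2 or f & (f - 1):
            raise ConfigError("input_size / heatmap_size must be a power of two >= 2")
        # heatmap must survive hourglass_depth halvings
        if self.heatmap_size % (1 << self.hourglass_depth):
            raise ConfigError("heatmap_size must be divisible by 2**hourglass_depth")
        if self.width < 2 or self.n_stacks < 1 or self.n_keypoints < 1:
            raise ConfigError("width, n_stacks and n_keypoints must be positive")

    @property
    def bottleneck(self) -> int:
        return self.width // 2

    @property
    def n_stem_pools(self) -> int:
        """Max-pools after the stride-2 stem conv to reach heatmap_size."""
        return (self.input_size // self.heatmap_size // 2).bit_length() - 1

    @property
    def scale(self) -> int:
        """Heatmap-to-input coordinate conversion factor."""
        return self.input_size // self.heatmap_size

    def to_dict(self) -> dict:
        return {
            "input_size": self.input_size, "heatmap_size": self.heatmap_size,
            "n_keypoints": self.n_keypoints, "n_stacks": self.n_stacks,
            "hourglass_depth": self.hourglass_depth, "width": self.width,
            "use_attention": self.use_attention,
            "channel_attention_bottleneck": self.channel_attention_bottleneck,
            "spatial_attention_kernel": self.spatial_attention_kernel,
            "stem_channels": self.stem_channels, "layer_params": self.layer_params,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


class ResidualModule(nn.Module):
    """Bottleneck residual block: 1x1 down, 3x3, 1x1 up, identity shortcut.

    Every convolution is followed by a ReLU; with all weights zero the block
    is the identity map.
    """

    def __init__(self, width: int, bottleneck: int, rng: np.random.Generator):
        self.reduce = nn.Conv2d(width, bottleneck, 1, rng=rng)   # C4 role
        self.conv = nn.Conv2d(bottleneck, bottleneck, 3, rng=rng)  # C5 role
        self.expand = nn.Conv2d(bottleneck, width, 1, rng=rng)   # C3 role

    def branch(self, x: nn.Tensor) -> nn.Tensor:
        h = nn.relu(self.reduce(x))
        h = nn.relu(self.conv(h))
        return nn.relu(self.expand(h))

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return x + self.branch(x)


class AttentionResidualModule(ResidualModule):
    """Residual block whose branch is gated by channel then spatial attention.

    Channel gate: global average pool -> 1x1 (width -> bottleneck, C6 role)
    -> ReLU -> 1x1 (-> width) -> sigmoid, broadcast over space.
    Spatial gate: per-pixel channel mean and max -> 7x7 conv to one channel
    (C7 role) -> sigmoid, broadcast over channels.
    """

    def __init__(self, width: int, bottleneck: int, rng: np.random.Generator,
                 ca_bottleneck: int = 16, sa_kernel: int = 7):
        super().__init__(width, bottleneck, rng)
        self.ca_reduce = nn.Conv2d(width, ca_bottleneck, 1, rng=rng)  # C6 role
        self.ca_expand = nn.Conv2d(ca_bottleneck, width, 1, rng=rng)
        self.sa_conv = nn.Conv2d(2, 1, sa_kernel, rng=rng)            # C7 role

    def channel_gate(self, h: nn.Tensor) -> nn.Tensor:
        g = nn.reduce_mean(h, axis=(2, 3), keepdims=True)
        g = nn.relu(self.ca_reduce(g))
        return nn.sigmoid(self.ca_expand(g))

    def spatial_gate(self, h: nn.Tensor) -> nn.Tensor:
        pooled = nn.concat(
            [nn.reduce_mean(h, axis=1, keepdims=True),
             nn.reduce_max(h, axis=1, keepdims=True)], axis=1)
        return nn.sigmoid(self.sa_conv(pooled))

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = self.branch(x)
        h = h * self.channel_gate(h)
        h = h * self.spatial_gate(h)
        return x + h


class Hourglass(nn.Module):
    """Recursive encoder-decoder of residual modules with skip connections."""

    def __init__(self, width: int, bottleneck: int, depth: int, rng: np.random.Generator):
        self.depth = depth
        self.skip = ResidualModule(width, bottleneck, rng)
        self.down = ResidualModule(width, bottleneck, rng)
        if depth > 1:
            self.inner: nn.Module = Hourglass(width, bottleneck, depth - 1, rng)
        else:
            self.inner = ResidualModule(width, bottleneck, rng)
        self.up = ResidualModule(width, bottleneck, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        skip = self.skip(x)
        low = self.down(nn.maxpool2x2(x))
        low = self.inner(low)
        low = self.up(low)
        return skip + nn.upsample2x(low)


class HeadNet(nn.Module):
    """The full stacked-hourglass landmark detector."""

    def __init__(self, cfg: ModelConfig, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        w, b = cfg.width, cfg.bottleneck
        self.stem_conv = nn.Conv2d(1, cfg.stem_channels, 7, stride=2, rng=rng)  # C1
        self.stem_expand = nn.Conv2d(cfg.stem_channels, w, 1, rng=rng)          # C3 role

        def edge_module():
            if cfg.use_attention:
                return AttentionResidualModule(
                    w, b, rng, ca_bottleneck=cfg.channel_attention_bottleneck,
                    sa_kernel=cfg.spatial_attention_kernel)
            return ResidualModule(w, b, rng)

        self.entries = [edge_module() for _ in range(cfg.n_stacks)]
        self.hourglasses = [Hourglass(w, b, cfg.hourglass_depth, rng)
                            for _ in range(cfg.n_stacks)]
        self.exits = [edge_module() for _ in range(cfg.n_stacks)]
        self.heads = [nn.Conv2d(w, cfg.n_keypoints, 1, rng=rng)                 # C2
                      for _ in range(cfg.n_stacks)]
        for head in self.heads:
            # small head init keeps initial heatmaps near-uniform, so integral
            # regression starts near the grid center instead of a saturated
            # softmax at an arbitrary pixel
            head.w.data *= 0.05
        self.feat_merge = [nn.Conv2d(w, w, 1, rng=rng)
                           for _ in range(cfg.n_stacks - 1)]
        self.hm_merge = [nn.Conv2d(cfg.n_keypoints, w, 1, rng=rng)
                         for _ in range(cfg.n_stacks - 1)]

    def forward(self, images) -> Tuple[List[nn.Tensor], List[nn.Tensor]]:
        """Run the network.

        Parameters
        ----------
        images : array or Tensor, shape (N, H, W) or (N, 1, H, W), values in [0, 1].

        Returns
        -------
        heatmaps : list of per-stack Tensors (N, K, Hh, Wh), raw scores.
        coords : list of per-stack Tensors (N, K, 2) of (x, y) in heatmap units.
        """
        x = images if isinstance(images, nn.Tensor) else nn.Tensor(
            np.asarray(images, dtype=np.float32))
        if x.data.ndim == 3:
            x = nn.Tensor(x.data[:, None, :, :], _parents=(x,),
                          _bwd=lambda g: x._accumulate(g[:, 0]))
        N, C, H, W = x.data.shape
        if H != self.cfg.input_size or W != self.cfg.input_size or C != 1:
            raise ValueError(
                f"expected (N, 1, {self.cfg.input_size}, {self.cfg.input_size}) "
                f"input, got {x.data.shape}")
        h = nn.relu(self.stem_conv(x))
        h = nn.relu(self.stem_expand(h))
        for _ in range(self.cfg.n_stem_pools):
            h = nn.maxpool2x2(h)
        heatmaps: List[nn.Tensor] = []
        coords: List[nn.Tensor] = []
        for i in range(self.cfg.n_stacks):
            f = self.entries[i](h)
            f = self.hourglasses[i](f)
            f = self.exits[i](f)
            hm = self.heads[i](f)
            heatmaps.append(hm)
            coords.append(nn.soft_argmax2d(hm))
            if i < self.cfg.n_stacks - 1:
                h = h + self.feat_merge[i](f) + self.hm_merge[i](hm)
        return heatmaps, coords

    def predict(self, images) -> np.ndarray:
        """Inference: (N, K, 2) landmark coordinates in input-image pixels."""
        _, coords = self.forward(np.asarray(images, dtype=np.float32))
        return coords[-1].data * self.cfg.scale

    def predict_landmarks(self, image) -> Dict[str, Tuple[float, float]]:
        """Single-image inference keyed by landmark name."""
        out = self.predict(np.asarray(image)[None])[0]
        return {name: (float(x), float(y))
                for name, (x, y) in zip(KEYPOINT_NAMES, out)}


def build_model(cfg: ModelConfig, seed: Optional[int] = None) -> HeadNet:
    """Construct a HeadNet with He-initialized weights from ``seed``."""
    return HeadNet(cfg, rng=np.random.default_rng(seed))


def integral_coordinates(heatmap) -> Union[Point2D, nn.Tensor]:
    """Integral regression of a single heatmap grid to a continuous point.

    Scores are softmax-normalized over all pixels and the expectation of the
    pixel-center coordinates is returned; the result is always strictly
    inside the grid. For a plain array a :class:`Point2D` is returned; for a
    :class:`~adenoceph.nn.Tensor` the differentiable (2,) coordinate tensor.
    """
    if isinstance(heatmap, nn.Tensor):
        H, W = heatmap.data.shape
        wrapped = nn.Tensor(heatmap.data[None, None], _parents=(heatmap,),
                            _bwd=lambda g: heatmap._accumulate(g[0, 0]))
        return nn.soft_argmax2d(wrapped)[0, 0]
    grid = np.asarray(heatmap, dtype=np.float64)
    if grid.ndim != 2:
        raise ValueError(f"expected a 2-D grid, got shape {grid.shape}")
    out = nn.soft_argmax2d(nn.Tensor(grid[None, None])).data[0, 0]
    return Point2D(float(out[0]), float(out[1]))


def save_checkpoint(model: HeadNet, path, extra: Optional[dict] = None) -> None:
    """Serialize config + weights (+ provenance metadata) to an .npz file."""
    meta = {"config": model.cfg.to_dict(), "extra": extra or {}}
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> Tuple[HeadNet, dict]:
    """Rebuild a model from :func:`save_checkpoint` output."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        n = len([k for k in z.files if k.startswith("param_")])
        arrays = [z[f"param_{i}"] for i in range(n)]
    model = HeadNet(ModelConfig.from_dict(meta["config"]))
    model.load_state_arrays(arrays)
    return model, meta.get("extra", {})
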