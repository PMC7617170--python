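"""Physics-informed 3-D U-Net.

A patch-based encoder/decoder segmentation network conditioned on the
acquisition parameters of the image it segments.  The encoded physics
vector (see :func:`physeg.simulate.physics_vector`) passes through two
fully connected layers, and the result is tiled over the spatial
dimensions and concatenated to the feature maps at two points: after the
second convolution of the encoder and after the second-to-last
convolution of the decoder.  Optional Monte-Carlo dropout provides
epistemic uncertainty sampling; an optional sigma branch (softplus-
terminated, mirroring the output block) predicts per-voxel, per-class
heteroscedastic noise scales.

Feature channels start at ``base_channels`` and double after each
contracting block (30 -> 60 -> 120 -> 240 at the bottleneck for the
default four-level configuration).  Downsampling is a stride-2 first
convolution per contracting block; upsampling is non-parametric trilinear
interpolation with skip concatenations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concat
from .layers import Adam, Conv3d, Dropout, Linear, Module, upsample2x

__all__ = ["NetworkConfig", "NetworkOutput", "PhysicsUNet3D", "build_network"]


@dataclass
class NetworkConfig:
    base_channels: int = 30
    n_levels: int = 4
    n_classes: int = 4
    #: length of the physics conditioning vector (4 MPRAGE, 6 SPGR);
    #: None disables the physics branch entirely.
    physics_len: int | None = 4
    physics_width: int = 40
    dropout_rate: float = 0.5
    first_layer_dropout_rate: float = 0.05
    heteroscedastic: bool = False
    leaky_slope: float = 0.01
    #: parameter/activation precision; float32 is the training default,
    #: float64 supports tight finite-difference verification
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("need at least one resolution level")
        for r in (self.dropout_rate, self.first_layer_dropout_rate):
            if not 0 <= r < 1:
                raise ValueError("dropout rates must lie in [0, 1)")

    @property
    def channel_schedule(self) -> list[int]:
        return [self.base_channels * 2**i for i in range(self.n_levels)]

    @property
    def bottleneck_channels(self) -> int:
        return self.channel_schedule[-1]

    @classmethod
    def smoke(cls, **overrides) -> "NetworkConfig":
        """Desk-scale preset for CPU training."""
        kw = dict(base_channels=8, n_levels=2, physics_width=16,
                  dropout_rate=0.1, first_layer_dropout_rate=0.05)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class NetworkOutput:
    """Per-voxel class logits, optional sigma, and the features entering
    the final output convolution (used by the stratification loss)."""

    logits: Tensor
    sigma: Tensor | None
    penultimate_features: Tensor


class _ConvBlock(Module):
    """(conv3 + leaky-ReLU + dropout) x 2; optional stride-2 first conv."""

    def __init__(self, cin, cout, rng, stride=1, slope=0.01,
                 rates=(0.5, 0.5), dtype=np.float32):
        self.c1 = Conv3d(cin, cout, rng, stride=stride, dtype=dtype)
        self.c2 = Conv3d(cout, cout, rng, dtype=dtype)
        self.d1 = Dropout(rates[0])
        self.d2 = Dropout(rates[1])
        self.slope = slope

    def __call__(self, x, rng):
        x = self.d1(self.c1(x).leaky_relu(self.slope), rng)
        x = self.d2(self.c2(x).leaky_relu(self.slope), rng)
        return x


class PhysicsUNet3D(Module):
    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.channel_schedule
        r = config.dropout_rate
        r0 = config.first_layer_dropout_rate
        slope = config.leaky_slope

        dtype = np.dtype(config.dtype).type
        self.dtype = dtype
        phys_ch = config.physics_width if config.physics_len else 0
        if config.physics_len:
            self.fc1 = Linear(config.physics_len, config.physics_width, rng,
                              dtype=dtype)
            self.fc2 = Linear(config.physics_width, config.physics_width, rng,
                              dtype=dtype)

        # encoder: stride-2 first conv per contracting block
        self.enc = []
        cin = 1
        for i, c in enumerate(ch):
            rates = (r0, r) if i == 0 else (r, r)
            # physics features are concatenated after block 0
            extra = phys_ch if i == 1 else 0
            self.enc.append(
                _ConvBlock(cin + extra, c, rng, stride=2, slope=slope,
                           rates=rates, dtype=dtype)
            )
            cin = c
        self.bottleneck = _ConvBlock(ch[-1], ch[-1], rng, slope=slope,
                                     rates=(r, r), dtype=dtype)

        # decoder: upsample + concat skip + conv pair
        self.dec = []
        cprev = ch[-1]
        for c in reversed(ch[:-1]):
            self.dec.append(_ConvBlock(cprev + c, c, rng, slope=slope,
                                       rates=(r, r), dtype=dtype))
            cprev = c
        # final expansive block back to full resolution (no skip there:
        # the first encoder conv already halved the grid)
        self.dec.append(_ConvBlock(cprev, ch[0], rng, slope=slope,
                                   rates=(r, r), dtype=dtype))

        self.out_conv = Conv3d(ch[0] + phys_ch, config.n_classes, rng,
                               kernel=1, dtype=dtype)
        if config.heteroscedastic:
            self.sigma_block = _ConvBlock(cprev, ch[0], rng, slope=slope,
                                          rates=(r, r), dtype=dtype)
            self.sigma_conv = Conv3d(ch[0], config.n_classes, rng, kernel=1,
                                     dtype=dtype)

    # -- forward -----------------------------------------------------------
    def _tile_physics(self, h: Tensor, feat: Tensor) -> Tensor:
        """Broadcast FC output (N, P) over the spatial grid of ``feat``."""
        N, P = h.shape
        spatial = feat.shape[2:]
        tiled = h.reshape(N, P, 1, 1, 1) * Tensor(
            np.ones((1, 1) + spatial, dtype=self.dtype)
        )
        return concat([feat, tiled], axis=1)

    def forward(self, image, physics=None, mode: str = "eval",
                rng: np.random.Generator | None = None) -> NetworkOutput:
        """Run the network on a patch.

        ``image``: (N, 1, D, H, W) array or Tensor with D, H, W divisible
        by 2**n_levels.  ``physics``: (N, physics_len) array, required iff
        the physics branch exists.  ``mode``: 'train', 'eval' or
        'mc-dropout'; dropout masks are resampled from ``rng`` in 'train'
        and 'mc-dropout' modes.
        """
        cfg = self.config
        x = image if isinstance(image, Tensor) else Tensor(
            np.asarray(image, dtype=self.dtype)
        )
        if x.data.ndim != 5:
            raise ValueError("image must have shape (N, 1, D, H, W)")
        for d in x.shape[2:]:
            if d % 2**cfg.n_levels:
                raise ValueError(
                    f"patch dimension {d} not divisible by {2**cfg.n_levels}"
                )
        if mode not in ("train", "eval", "mc-dropout"):
            raise ValueError(f"unknown mode {mode!r}")
        drop_rng = rng if mode in ("train", "mc-dropout") else None
        if mode != "eval" and drop_rng is None:
            raise ValueError(f"mode {mode!r} requires an rng")

        h = None
        if cfg.physics_len:
            if physics is None:
                raise ValueError("network has a physics branch: physics required")
            pv = physics if isinstance(physics, Tensor) else Tensor(
                np.asarray(physics, dtype=self.dtype)
            )
            if pv.shape[-1] != cfg.physics_len:
                raise ValueError(
                    f"physics vector length {pv.shape[-1]} != configured "
                    f"{cfg.physics_len}"
                )
            h = self.fc2(self.fc1(pv).leaky_relu(cfg.leaky_slope)).leaky_relu(
                cfg.leaky_slope
            )

        skips = []
        for i, block in enumerate(self.enc):
            if i == 1 and h is not None:
                x = self._tile_physics(h, x)
            x = block(x, drop_rng)
            skips.append(x)
        x = self.bottleneck(x, drop_rng)

        for i, block in enumerate(self.dec):
            x = upsample2x(x)
            skip_idx = len(self.enc) - 2 - i
            if skip_idx >= 0:
                x = concat([skips[skip_idx], x], axis=1)
            if i == len(self.dec) - 1:
                sigma_in = x
            x = block(x, drop_rng)

        features = x  # activations entering the final 1x1x1 convolution
        if h is not None:
            x = self._tile_physics(h, x)
        logits = self.out_conv(x)

        sigma = None
        if cfg.heteroscedastic:
            s = self.sigma_block(sigma_in, drop_rng)
            sigma = self.sigma_conv(s).softplus()
        return NetworkOutput(logits=logits, sigma=sigma,
                             penultimate_features=features)

    def optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.parameters(), lr=lr)


def build_network(config: NetworkConfig) -> PhysicsUNet3D:
    """Construct the network; deterministic for a fixed config seed."""
    return PhysicsUNet3D(config)


def softmax_probs(logits: Tensor | np.ndarray, axis: int = 1) -> np.ndarray:
    """Softmax over the class axis, as a plain array."""
    z = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
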