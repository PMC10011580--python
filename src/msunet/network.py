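"""Multi-arm 3D U-Net with dense input and skip connectivity.

The network segments T2 hyperintense lesions from three co-registered MRI
channels.  Three encoder arms extract features in parallel:

* arm 1 sees all three channels (T1p, T2w, FLAIR) jointly,
* arm 2 sees FLAIR only and arm 3 T2w only, capturing the partly disjoint
  lesion evidence in the two T2-weighted contrasts.

Each arm is a stack of anisotropic residual blocks (1x3x3 + 3x3x3
convolutions, BN, ReLU), four levels deep by default.  Connectivity:

* dense encoder inputs — the block at level d receives the *sum* of the
  features of all shallower levels, each brought to level-d resolution by a
  strided 1x1x1 convolution;
* at every level the three arms' features are concatenated and reduced by a
  1x1x1 projection to the level width — these are the skip features;
* dense skips — the decoder's skip input at depth d is the sum of all
  projected skips resampled to depth-d resolution (trilinear up /
  strided 1x1x1 conv down);
* a single decoder upsamples by trilinear interpolation, concatenates the
  dense skip, and refines with a residual block;
* sigmoid prediction heads (preceded by dropout) at the finest
  ``supervision_levels`` resolutions provide deep supervision, and the same
  dropout layers drive Monte-Carlo sampling at inference.

Anisotropy: with ~1x1x3 mm voxels the first level keeps full z resolution
(stride 1,2,2) so that the receptive field in millimetres is roughly
isotropic (see :func:`receptive_field`).

A plain single-encoder 3D U-Net of the same level widths
(:class:`PlainUNet3d`) is included as the parameter-count baseline; the
multi-arm design has fewer parameters because each arm runs at roughly a
third of the level width before the concatenation/projection step.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import (Conv3d, Dropout, Module, ResidualBlock, Tensor, concat,
                 linear_resize)

__all__ = [
    "NetworkConfig", "ModelHandle", "MultiArmUNet", "PlainUNet3d",
    "build_model", "build_plain_unet", "count_parameters", "receptive_field",
    "save_checkpoint", "load_checkpoint",
]

ARM_INPUTS = {"enc1": ("T1p", "T2w", "FLAIR"), "enc2": ("FLAIR",),
              "enc3": ("T2w",)}
# channel indices into the canonical (T1p, T2w, FLAIR) stack
ARM_CHANNEL_IDX = {"enc1": (0, 1, 2), "enc2": (2,), "enc3": (1,)}


@dataclass
class NetworkConfig:
    depth: int = 4
    filters_per_level: tuple[int, ...] = (32, 64, 128, 256)
    arm_filters_per_level: tuple[int, ...] | None = None  # default ceil(F/3)
    dropout_rate: float = 0.2
    supervision_levels: int = 3
    downsample_strides: tuple[tuple[int, int, int], ...] | None = None
    isotropic_convs: bool = False
    in_channels_per_encoder: dict = field(
        default_factory=lambda: {"enc1": 3, "enc2": 1, "enc3": 1})

    def __post_init__(self):
        self.filters_per_level = tuple(int(f) for f in self.filters_per_level)
        if len(self.filters_per_level) != self.depth:
            raise ValueError("filters_per_level length must equal depth")
        if any(b < a for a, b in zip(self.filters_per_level,
                                     self.filters_per_level[1:])):
            raise ValueError("filters_per_level must be non-decreasing")
        if self.arm_filters_per_level is None:
            self.arm_filters_per_level = tuple(
                max(1, math.ceil(f / 3)) for f in self.filters_per_level)
        else:
            self.arm_filters_per_level = tuple(
                int(f) for f in self.arm_filters_per_level)
            if len(self.arm_filters_per_level) != self.depth:
                raise ValueError("arm_filters_per_level length must equal depth")
        if self.downsample_strides is None:
            # full z resolution at the first transition: 3 mm slices
            self.downsample_strides = tuple(
                (1, 2, 2) if d == 0 else (2, 2, 2)
                for d in range(self.depth - 1))
        else:
            self.downsample_strides = tuple(
                tuple(int(s) for s in st) for st in self.downsample_strides)
            if len(self.downsample_strides) != self.depth - 1:
                raise ValueError("need depth-1 downsample strides")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 1 <= self.supervision_levels <= self.depth:
            raise ValueError("supervision_levels must be in [1, depth]")

    def cumulative_stride(self, level: int) -> tuple[int, int, int]:
        """Product of strides from level 0 down to ``level``."""
        cum = np.ones(3, dtype=int)
        for st in self.downsample_strides[:level]:
            cum *= st
        return tuple(int(c) for c in cum)

    def stride_between(self, lo: int, hi: int) -> tuple[int, int, int]:
        cum = np.ones(3, dtype=int)
        for st in self.downsample_strides[lo:hi]:
            cum *= st
        return tuple(int(c) for c in cum)

    def to_dict(self) -> dict:
        return {
            "depth": self.depth,
            "filters_per_level": list(self.filters_per_level),
            "arm_filters_per_level": list(self.arm_filters_per_level),
            "dropout_rate": self.dropout_rate,
            "supervision_levels": self.supervision_levels,
            "downsample_strides": [list(s) for s in self.downsample_strides],
            "isotropic_convs": self.isotropic_convs,
            "in_channels_per_encoder": dict(self.in_channels_per_encoder),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if d.get("downsample_strides") is not None:
            d["downsample_strides"] = [tuple(s) for s in d["downsample_strides"]]
        return cls(**d)


class _EncoderArm(Module):
    """One encoder arm with dense strided-1x1x1 input connectivity."""

    def __init__(self, in_ch: int, widths, config: NetworkConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.depth = config.depth
        self.blocks = []
        self.down = {}  # (src_level, dst_level) -> conv
        for d in range(self.depth):
            block_in = in_ch if d == 0 else widths[d]
            blk = ResidualBlock(block_in, widths[d], rng,
                                isotropic=config.isotropic_convs)
            setattr(self, f"block{d}", blk)
            self.blocks.append(blk)
            for src in range(d):
                conv = Conv3d(widths[src], widths[d], (1, 1, 1), rng,
                              stride=config.stride_between(src, d),
                              padding=(0, 0, 0))
                setattr(self, f"down{src}_{d}", conv)
                self.down[(src, d)] = conv

    def __call__(self, x: Tensor) -> list[Tensor]:
        feats: list[Tensor] = []
        for d in range(self.depth):
            if d == 0:
                inp = x
            else:
                inp = None
                for src in range(d):
                    piece = self.down[(src, d)](feats[src])
                    inp = piece if inp is None else inp + piece
            feats.append(self.blocks[d](inp))
        return feats


class MultiArmUNet(Module):
    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        widths = config.filters_per_level
        arm_w = config.arm_filters_per_level
        self.arms = []
        for arm_name, n_in in config.in_channels_per_encoder.items():
            arm = _EncoderArm(n_in, arm_w, config, rng)
            setattr(self, arm_name, arm)
            self.arms.append(arm)
        n_arms = len(self.arms)
        # concat of arms -> level width (skip features)
        self.proj = []
        for d in range(config.depth):
            conv = Conv3d(n_arms * arm_w[d], widths[d], (1, 1, 1), rng)
            setattr(self, f"proj{d}", conv)
            self.proj.append(conv)
        # dense skip resampling convs (width adaptation)
        self.skip_adapt = {}
        for dst in range(config.depth):
            for src in range(config.depth):
                if src == dst:
                    continue
                if src < dst:  # fine -> coarse: strided 1x1x1 conv
                    conv = Conv3d(widths[src], widths[dst], (1, 1, 1), rng,
                                  stride=config.stride_between(src, dst),
                                  padding=(0, 0, 0))
                else:          # coarse -> fine: trilinear up + 1x1x1 conv
                    conv = Conv3d(widths[src], widths[dst], (1, 1, 1), rng)
                setattr(self, f"skip{src}_{dst}", conv)
                self.skip_adapt[(src, dst)] = conv
        # decoder
        self.dec_blocks = {}
        for d in range(config.depth - 2, -1, -1):
            blk = ResidualBlock(widths[d + 1] + widths[d], widths[d], rng,
                                isotropic=config.isotropic_convs)
            setattr(self, f"dec{d}", blk)
            self.dec_blocks[d] = blk
        # deep-supervision heads with dropout
        self.head_convs = {}
        self.head_drops = {}
        for d in range(config.supervision_levels):
            drop = Dropout(config.dropout_rate)
            conv = Conv3d(widths[d], 1, (1, 1, 1), rng)
            setattr(self, f"head_drop{d}", drop)
            setattr(self, f"head_conv{d}", conv)
            self.head_drops[d] = drop
            self.head_convs[d] = conv

    # -- forward -----------------------------------------------------------

    def _level_shapes(self, spatial) -> list[tuple[int, int, int]]:
        shapes = [tuple(spatial)]
        for st in self.config.downsample_strides:
            prev = shapes[-1]
            if any(p % s for p, s in zip(prev, st)):
                raise ValueError(
                    f"input shape {tuple(spatial)} incompatible with stride "
                    f"plan {self.config.downsample_strides}")
            shapes.append(tuple(p // s for p, s in zip(prev, st)))
        return shapes

    def __call__(self, x) -> list[Tensor]:
        """Input (B, 3, D, H, W); returns supervision_levels sigmoid maps,
        finest first."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        shapes = self._level_shapes(x.shape[2:])
        cfg = self.config
        arm_feats = []
        for arm_name, arm in zip(cfg.in_channels_per_encoder, self.arms):
            idx = ARM_CHANNEL_IDX[arm_name]
            arm_feats.append(arm(x[:, list(idx)]))
        skips = []
        for d in range(cfg.depth):
            cat = concat([feats[d] for feats in arm_feats], axis=1)
            skips.append(self.proj[d](cat))
        # dense skip fusion
        fused = []
        for dst in range(cfg.depth):
            acc = skips[dst]
            for src in range(cfg.depth):
                if src == dst:
                    continue
                if src < dst:
                    acc = acc + self.skip_adapt[(src, dst)](skips[src])
                else:
                    up = linear_resize(skips[src], shapes[dst])
                    acc = acc + self.skip_adapt[(src, dst)](up)
            fused.append(acc)
        # decoder
        dec = fused[cfg.depth - 1]
        dec_feats = {cfg.depth - 1: dec}
        for d in range(cfg.depth - 2, -1, -1):
            up = linear_resize(dec, shapes[d])
            dec = self.dec_blocks[d](concat([up, fused[d]], axis=1))
            dec_feats[d] = dec
        outputs = []
        for d in range(cfg.supervision_levels):
            h = self.head_drops[d](dec_feats[d])
            outputs.append(self.head_convs[d](h).sigmoid())
        return outputs

    # -- dropout control ---------------------------------------------------

    def set_mc_dropout(self, active: bool, seed: int | None = None) -> None:
        """Toggle inference-time (Monte-Carlo) dropout; reseed streams."""
        drops = [m for m in self.modules() if isinstance(m, Dropout)]
        if seed is not None:
            seqs = np.random.SeedSequence(seed).spawn(len(drops))
            for m, s in zip(drops, seqs):
                m.rng = np.random.default_rng(s)
        for m in drops:
            m.force_active = active

    def encoder_features(self, x) -> Tensor:
        """Deepest fused encoder output (for receptive-field probing)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        cfg = self.config
        arm_feats = []
        for arm_name, arm in zip(cfg.in_channels_per_encoder, self.arms):
            idx = ARM_CHANNEL_IDX[arm_name]
            arm_feats.append(arm(x[:, list(idx)]))
        cat = concat([feats[cfg.depth - 1] for feats in arm_feats], axis=1)
        return self.proj[cfg.depth - 1](cat)


class PlainUNet3d(Module):
    """Single-encoder 3D U-Net baseline with the same level widths and the
    same residual blocks; plain skips (no dense connectivity)."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        widths = config.filters_per_level
        in_ch = config.in_channels_per_encoder.get("enc1", 3)
        self.enc_blocks = {}
        self.down = {}
        for d in range(config.depth):
            blk = ResidualBlock(in_ch if d == 0 else widths[d], widths[d],
                                rng, isotropic=config.isotropic_convs)
            setattr(self, f"enc{d}", blk)
            self.enc_blocks[d] = blk
            if d < config.depth - 1:
                conv = Conv3d(widths[d], widths[d + 1], (1, 1, 1), rng,
                              stride=config.downsample_strides[d],
                              padding=(0, 0, 0))
                setattr(self, f"down{d}", conv)
                self.down[d] = conv
        self.dec_blocks = {}
        for d in range(config.depth - 2, -1, -1):
            blk = ResidualBlock(widths[d + 1] + widths[d], widths[d], rng,
                                isotropic=config.isotropic_convs)
            setattr(self, f"dec{d}", blk)
            self.dec_blocks[d] = blk
        self.head_convs = {}
        self.head_drops = {}
        for d in range(config.supervision_levels):
            drop = Dropout(config.dropout_rate)
            conv = Conv3d(widths[d], 1, (1, 1, 1), rng)
            setattr(self, f"head_drop{d}", drop)
            setattr(self, f"head_conv{d}", conv)
            self.head_drops[d] = drop
            self.head_convs[d] = conv

    def __call__(self, x) -> list[Tensor]:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        cfg = self.config
        shapes = [tuple(x.shape[2:])]
        for st in cfg.downsample_strides:
            shapes.append(tuple(p // s for p, s in zip(shapes[-1], st)))
        skips = []
        h = x
        for d in range(cfg.depth):
            h = self.enc_blocks[d](h)
            skips.append(h)
            if d < cfg.depth - 1:
                h = self.down[d](h)
        dec = skips[-1]
        dec_feats = {cfg.depth - 1: dec}
        for d in range(cfg.depth - 2, -1, -1):
            up = linear_resize(dec, shapes[d])
            dec = self.dec_blocks[d](concat([up, skips[d]], axis=1))
            dec_feats[d] = dec
        return [self.head_convs[d](self.head_drops[d](dec_feats[d])).sigmoid()
                for d in range(cfg.supervision_levels)]


@dataclass
class ModelHandle:
    model: Module
    config: NetworkConfig
    parameter_count: int


def build_model(config: NetworkConfig, seed: int = 0) -> ModelHandle:
    """Construct the multi-arm U-Net; deterministic given ``seed``."""
    model = MultiArmUNet(config, seed=seed)
    return ModelHandle(model, config, model.num_parameters())


def build_plain_unet(config: NetworkConfig, seed: int = 0) -> ModelHandle:
    model = PlainUNet3d(config, seed=seed)
    return ModelHandle(model, config, model.num_parameters())


def count_parameters(handle: ModelHandle | Module) -> int:
    model = handle.model if isinstance(handle, ModelHandle) else handle
    return model.num_parameters()


def receptive_field(config: NetworkConfig,
                    spacing_mm=(3.0, 1.0, 1.0)) -> dict:
    """Analytic receptive field of the deepest encoder output.

    Standard recursion: rf += (k - 1) * jump per conv; jump *= stride per
    downsampling step (the 1x1x1 strided convolutions grow no extent).
    Returns per-axis extents in voxels and mm plus the mm max/min ratio.
    """
    rf = np.ones(3, dtype=int)
    jump = np.ones(3, dtype=int)
    k_small = (3, 3, 3) if config.isotropic_convs else (1, 3, 3)
    for d in range(config.depth):
        for kern in (k_small, (3, 3, 3)):  # the two convs of a residual block
            rf += (np.array(kern) - 1) * jump
        if d < config.depth - 1:
            jump *= np.array(config.downsample_strides[d])
    mm = rf * np.asarray(spacing_mm)
    return {
        "voxels": tuple(int(v) for v in rf),
        "mm": tuple(float(v) for v in mm),
        "mm_ratio": float(mm.max() / mm.min()),
    }


def save_checkpoint(path, handle: ModelHandle, extra: dict | None = None):
    """Single-file versioned checkpoint (npz with a JSON config entry)."""
    path = Path(path)
    meta = {"format_version": 1, "config": handle.config.to_dict(),
            "kind": type(handle.model).__name__}
    if extra:
        meta["extra"] = extra
    state = handle.model.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> ModelHandle:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    config = NetworkConfig.from_dict(meta["config"])
    cls = {"MultiArmUNet": MultiArmUNet, "PlainUNet3d": PlainUNet3d}[meta["kind"]]
    model = cls(config, seed=0)
    model.load_state_dict(state)
    return ModelHandle(model, config, model.num_parameters())
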