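"""Composite segmentation loss: weighted smooth truncated cross-entropy + soft dice.

The total loss for one supervised level is

    L = alpha * L_FG-ST + beta * L_BG-ST + L_dice

where L_FG-ST / L_BG-ST are means of the smooth truncated cross-entropy over
foreground / background voxels (the background term is evaluated at the
predicted background probability 1 - p), and L_dice is the soft dice loss

    L_dice = 1 - 2 sum(p q) / (sum(p^2) + sum(q^2)).

The truncated cross-entropy replaces -log(p) below a threshold gamma by a
quadratic, capping the influence of confidently-wrong voxels:

    ST(p) = -log(gamma) + (1 - p^2/gamma^2)/2   for p < gamma
    ST(p) = -log(p)                              for p >= gamma

The p >= gamma branch is the unique choice making ST C1-continuous at the
knot (both one-sided derivatives equal -1/gamma).  The constant branch
ST(p) = -log(gamma) for p >= gamma, which is gradient-free, is available via
``variant="printed"`` for comparison.

Schedules: gamma ramps linearly over training epochs; the foreground weight
alpha decays sigmoidally with the patch lesion volume from alpha_max towards
1 (small lesions weighted heavily), and beta grows sigmoidally towards
beta_max.  Deep-supervision totals from the supervised levels are summed
without weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor

__all__ = [
    "LossConfig", "LossBreakdown", "smooth_truncated_ce", "soft_dice_loss",
    "schedules", "composite_loss", "downsample_target",
]

DICE_EPS = 1e-6


@dataclass
class LossConfig:
    gamma_start: float = 0.02
    gamma_end: float = 0.15
    alpha_max: float = 100.0
    beta_max: float = 1.0
    schedule_midpoint_volume: float = 100.0  # v0, foreground voxels
    schedule_steepness: float = 50.0         # s
    total_epochs: int = 30
    truncated_variant: str = "smooth"        # "smooth" | "printed"

    def __post_init__(self):
        if not (0 < self.gamma_start <= self.gamma_end < 1):
            raise ValueError("need 0 < gamma_start <= gamma_end < 1")
        if self.alpha_max < 1:
            raise ValueError("alpha_max must be >= 1")
        if self.schedule_steepness <= 0:
            raise ValueError("schedule_steepness must be > 0")
        if self.truncated_variant not in ("smooth", "printed"):
            raise ValueError(f"unknown variant {self.truncated_variant!r}")


@dataclass
class LossBreakdown:
    """Per-term values at the finest supervised level."""

    dice: float
    fg_st: float
    bg_st: float
    alpha: float
    beta: float
    gamma: float
    total: float


def smooth_truncated_ce(p, gamma: float, variant: str = "smooth"):
    """Smooth truncated cross-entropy of true-class probability ``p``.

    Vectorised over ``p``; raises on values outside [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if not (0 < gamma < 1):
        raise ValueError("gamma must lie in (0, 1)")
    below = p < gamma
    quad = -np.log(gamma) + 0.5 * (1.0 - p**2 / gamma**2)
    if variant == "printed":
        upper = np.full_like(p, -np.log(gamma))
    else:
        upper = -np.log(np.maximum(p, gamma))
    return np.where(below, quad, upper)


def _st_tensor(p: Tensor, gamma: float, variant: str) -> Tensor:
    """Autodiff version of :func:`smooth_truncated_ce`."""
    below = Tensor((p.data < gamma).astype(p.data.dtype))
    quad = (1.0 - (p * p) * (1.0 / gamma**2)) * 0.5 + (-np.log(gamma))
    if variant == "printed":
        upper = Tensor(np.full_like(p.data, -np.log(gamma)))
    else:
        # clip is exact on the branch where it is used (p >= gamma)
        upper = -(p.clip(gamma, 1.0).log())
    return below * quad + (1.0 - below) * upper


def soft_dice_loss(p, q, eps: float = DICE_EPS) -> float:
    """Soft dice loss 1 - 2 sum(pq) / (sum(p^2) + sum(q^2) + eps)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have equal shapes")
    num = 2.0 * float((p * q).sum()) + eps
    den = float((p**2).sum() + (q**2).sum()) + eps
    return 1.0 - num / den


def _soft_dice_tensor(p: Tensor, q: np.ndarray, eps: float = DICE_EPS) -> Tensor:
    qt = Tensor(q.astype(p.data.dtype))
    num = (p * qt).sum() * 2.0 + eps
    den = (p * p).sum() + float((q.astype(float)**2).sum()) + eps
    return 1.0 - num / den


def _logistic(x):
    from scipy.special import expit
    return expit(x)


def schedules(epoch: int, patch_foreground_volume: float,
              config: LossConfig) -> tuple[float, float, float]:
    """(gamma, alpha, beta) for a given epoch and patch lesion volume."""
    if not 0 <= epoch < config.total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.total_epochs})")
    if config.total_epochs == 1:
        frac = 0.0
    else:
        frac = epoch / (config.total_epochs - 1)
    gamma = config.gamma_start + frac * (config.gamma_end - config.gamma_start)
    v = float(patch_foreground_volume)
    z = (v - config.schedule_midpoint_volume) / config.schedule_steepness
    alpha = 1.0 + (config.alpha_max - 1.0) * _logistic(-z)
    beta = config.beta_max * _logistic(z)
    return float(gamma), float(alpha), float(beta)


def downsample_target(target: np.ndarray, shape) -> np.ndarray:
    """Max-pool a binary target to a coarser level shape.

    Max-pooling (rather than nearest) keeps small lesions present at coarse
    supervision scales.  Requires integer block factors.
    """
    target = np.asarray(target)
    factors = []
    for t, s in zip(target.shape, shape):
        if t % s:
            raise ValueError(f"target shape {target.shape} not divisible "
                             f"into {tuple(shape)}")
        factors.append(t // s)
    fz, fy, fx = factors
    z, y, x = shape
    return target.reshape(z, fz, y, fy, x, fx).max(axis=(1, 3, 5))


def composite_loss(pred_levels, target: np.ndarray, epoch: int,
                   config: LossConfig):
    """Deep-supervision composite loss.

    Parameters
    ----------
    pred_levels : list of Tensor or ndarray
        Probability maps, finest first; coarser maps at the corresponding
        encoder resolutions.  Arrays are wrapped as constants.
    target : ndarray of {0,1}
        Full-resolution target; max-pooled to each level's shape.
    epoch : int
        Training epoch (drives the gamma schedule).
    config : LossConfig

    Returns
    -------
    (total, breakdown) : (Tensor, LossBreakdown)
        ``total`` is the unweighted sum of level totals (autodiff node);
        ``breakdown`` reports the finest level's terms.
    """
    target = np.asarray(target)
    v = float(target.sum())
    gamma, alpha, beta = schedules(epoch, v, config)
    total: Tensor | None = None
    breakdown = None
    for li, pred in enumerate(pred_levels):
        p = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred))
        while p.data.ndim > 3 and p.shape[0] == 1:  # strip batch/channel dims
            p = p.reshape(*p.shape[1:])
        tgt = downsample_target(target, p.shape)
        fg = tgt > 0
        st_all = _st_tensor(p, gamma, config.truncated_variant)
        if fg.any():
            fg_term = st_all[fg].mean()
        else:
            fg_term = Tensor(np.zeros(()))
        bg = ~fg
        if bg.any():
            st_bg = _st_tensor(1.0 - p, gamma, config.truncated_variant)
            bg_term = st_bg[bg].mean()
        else:
            bg_term = Tensor(np.zeros(()))
        dice = _soft_dice_tensor(p, tgt)
        level_total = fg_term * alpha + bg_term * beta + dice
        total = level_total if total is None else total + level_total
        if li == 0:
            breakdown = LossBreakdown(
                dice=float(dice.data), fg_st=float(fg_term.data),
                bg_st=float(bg_term.data), alpha=alpha, beta=beta,
                gamma=gamma, total=float(level_total.data))
    return total, breakdown
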