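"""Boundary-label generation and the joint training objective.

Boundary supervision targets are derived from the ground-truth region mask by
a morphological gradient: dilation minus erosion with a 3x3 square structuring
element. Out-of-image pixels are treated as background (zero padding), so an
object touching the image border produces boundary pixels there. The total
objective is L_total = L_seg + lambda * L_bnd with L_seg the pixel-wise
two-class cross-entropy and L_bnd binary cross-entropy on the boundary logits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .errors import ConfigError, InputError, ShapeError

__all__ = [
    "LossWeights", "LossBundle", "morphological_gradient",
    "boundary_loss", "segmentation_loss", "total_loss", "SE_3X3",
]

SE_3X3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class LossWeights:
    """Boundary-loss weight lambda; 0 disables boundary supervision exactly."""
    lambda_bnd: float = 0.5

    def __post_init__(self):
        if self.lambda_bnd < 0:
            raise ConfigError("lambda_bnd must be non-negative")


@dataclass(frozen=True)
class LossBundle:
    l_seg: float
    l_bnd: float
    l_total: float


def _check_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise InputError("mask must be strictly binary {0,1}")
    return mask.astype(bool)


def morphological_gradient(mask: np.ndarray) -> np.ndarray:
    """Dilation minus erosion of a binary mask with the 3x3 square element.

    Borders are zero padded, so the result marks every pixel whose 3x3
    neighbourhood (clipped to the padded image) contains both classes.
    Constant-zero masks produce an empty boundary; a constant-one mask
    produces its one-pixel border frame.
    """
    m = _check_binary(mask)
    dil = ndimage.binary_dilation(m, structure=SE_3X3, border_value=0)
    ero = ndimage.binary_erosion(m, structure=SE_3X3, border_value=0)
    return (dil & ~ero).astype(np.uint8)


def boundary_loss(logits: np.ndarray, target: np.ndarray,
                  pos_weight: float | None = None) -> float:
    """Mean binary cross-entropy evaluated in logit space.

    Stabilised form per pixel: max(x,0) - x*t + log(1 + exp(-|x|)). The
    optional positive-class weight is off by default (plain BCE).
    """
    x = np.asarray(logits, dtype=float)
    t = np.asarray(target, dtype=float)
    if x.shape != t.shape:
        raise ShapeError(f"logits {x.shape} vs target {t.shape}")
    per_pixel = np.maximum(x, 0.0) - x * t + np.log1p(np.exp(-np.abs(x)))
    if pos_weight is not None:
        # reweight the positive-class term: -w*t*log(sigma) - (1-t)*log(1-sigma)
        log_sig = -(np.maximum(-x, 0.0) + np.log1p(np.exp(-np.abs(x))))
        per_pixel = per_pixel + (pos_weight - 1.0) * t * (-log_sig)
    return float(per_pixel.mean())


def segmentation_loss(seg_logits: np.ndarray, mask: np.ndarray) -> float:
    """Mean pixel-wise two-class cross-entropy.

    ``seg_logits`` carries the class axis last (H x W x 2 or N x H x W x 2);
    ``mask`` holds the {0,1} labels on the same grid.
    """
    x = np.asarray(seg_logits, dtype=float)
    t = np.asarray(mask)
    if x.shape[-1] != 2 or x.shape[:-1] != t.shape:
        raise ShapeError(f"logits {x.shape} vs mask {t.shape}")
    m = x.max(axis=-1)
    lse = m + np.log(np.exp(x[..., 0] - m) + np.exp(x[..., 1] - m))
    picked = np.take_along_axis(x, t[..., None].astype(int), axis=-1)[..., 0]
    return float((lse - picked).mean())


def total_loss(l_seg: float, l_bnd: float, weights: LossWeights) -> LossBundle:
    """L_total = L_seg + lambda * L_bnd; lambda = 0 returns L_seg exactly."""
    if weights.lambda_bnd < 0:
        raise ConfigError("lambda_bnd must be non-negative")
    lam = weights.lambda_bnd
    lt = l_seg if lam == 0 else l_seg + lam * l_bnd
    return LossBundle(l_seg=float(l_seg), l_bnd=float(l_bnd), l_total=float(lt))


def boundary_probability(logits: np.ndarray) -> np.ndarray:
    """Sigmoid of the boundary logits, for map export."""
    return expit(np.asarray(logits, dtype=float))
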