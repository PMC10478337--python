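"""Segmentation losses and the two branch objectives.

The common segmentation loss is L_seg = 0.5 x (L_dice + L_BCE).  The clean
(strongly supervised) branch minimises

    L_clean = L_mseg + lambda x L_pseg-clean

where L_mseg is L_seg on the expert-labelled images and L_pseg-clean is L_seg
of the clean branch's prediction on pseudo-labelled images against the
HU-derived pseudo-label.  The noisy (weakly supervised) branch minimises

    L_noisy = lambda x L_pseg-noisy

against whatever target the switching module currently selects.  lambda
follows the usual sigmoid ramp of semi-supervised mean-teacher training
(unspecified in the source method, so configurable).

Every loss here also exposes an analytic gradient with respect to the
predicted probabilities, which is what the NumPy backbone consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossBreakdown",
    "dice_loss",
    "bce_loss",
    "seg_loss",
    "seg_loss_grad",
    "clean_branch_loss",
    "noisy_branch_loss",
    "lambda_schedule",
    "EPS_P",
]

EPS_P = 1e-6  # probability clamp for logarithms


def _pair(p, g) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return p, g


def dice_loss(p, g, smooth: float = 1.0) -> float:
    """Soft Dice loss 1 - (2 sum(pg) + s) / (sum(p) + sum(g) + s)."""
    p, g = _pair(p, g)
    num = 2.0 * float((p * g).sum()) + smooth
    den = float(p.sum()) + float(g.sum()) + smooth
    return 1.0 - num / den


def dice_loss_grad(p, g, smooth: float = 1.0) -> np.ndarray:
    """d(dice_loss)/dp, elementwise."""
    p, g = _pair(p, g)
    num = 2.0 * (p * g).sum() + smooth
    den = p.sum() + g.sum() + smooth
    return (num / den**2) - (2.0 * g / den)


def bce_loss(p, g) -> float:
    """Mean binary cross-entropy with probabilities clamped to [EPS_P, 1-EPS_P]."""
    p, g = _pair(p, g)
    pc = np.clip(p, EPS_P, 1.0 - EPS_P)
    return float(-(g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)).mean())


def bce_loss_grad(p, g) -> np.ndarray:
    """d(bce_loss)/dp; zero where the clamp is active."""
    p, g = _pair(p, g)
    pc = np.clip(p, EPS_P, 1.0 - EPS_P)
    grad = (-g / pc + (1.0 - g) / (1.0 - pc)) / p.size
    grad[(p < EPS_P) | (p > 1.0 - EPS_P)] = 0.0
    return grad


def seg_loss(p, g, smooth: float = 1.0) -> float:
    """0.5 x (dice_loss + bce_loss), the shared segmentation objective."""
    return 0.5 * (dice_loss(p, g, smooth) + bce_loss(p, g))


def seg_loss_grad(p, g, smooth: float = 1.0) -> np.ndarray:
    return 0.5 * (dice_loss_grad(p, g, smooth) + bce_loss_grad(p, g))


@dataclass
class LossBreakdown:
    """Components of the two branch objectives for one training step."""

    l_mseg: float = 0.0
    l_pseg_clean: float = 0.0
    l_pseg_noisy: float = 0.0
    lambda_weight: float = 0.0
    l_clean: float = 0.0
    l_noisy: float = 0.0


def clean_branch_loss(
    p_labeled, g_manual, p_pseudo, g_pseudo, lambda_weight: float, smooth: float = 1.0
) -> LossBreakdown:
    """Clean-branch objective: L_clean = L_mseg + lambda x L_pseg-clean.

    Inputs may be single images or batches (the loss is computed per image
    and averaged over the batch before composition).
    """
    if lambda_weight < 0:
        raise ValueError("lambda_weight must be >= 0")
    l_mseg = _batch_seg_loss(p_labeled, g_manual, smooth)
    l_pseg = _batch_seg_loss(p_pseudo, g_pseudo, smooth) if p_pseudo is not None else 0.0
    return LossBreakdown(
        l_mseg=l_mseg,
        l_pseg_clean=l_pseg,
        lambda_weight=lambda_weight,
        l_clean=l_mseg + lambda_weight * l_pseg,
    )


def noisy_branch_loss(p_pseudo_noisy, gt_atst, lambda_weight: float,
                      smooth: float = 1.0) -> LossBreakdown:
    """Noisy-branch objective: L_noisy = lambda x L_pseg-noisy."""
    if lambda_weight < 0:
        raise ValueError("lambda_weight must be >= 0")
    l_pseg_noisy = _batch_seg_loss(p_pseudo_noisy, gt_atst, smooth)
    return LossBreakdown(
        l_pseg_noisy=l_pseg_noisy,
        lambda_weight=lambda_weight,
        l_noisy=lambda_weight * l_pseg_noisy,
    )


def batch_seg_losses_and_grad(P, G, smooth: float = 1.0):
    """Vectorised per-image seg losses and the gradient of their mean.

    ``P`` (n, H, W) probabilities, ``G`` matching {0,1} masks.  Returns
    ``(losses, grad)`` where ``losses[i] = seg_loss(P[i], G[i])`` and
    ``grad = d(mean_i seg_loss)/dP``.  Matches the per-image functions above.
    """
    P = np.asarray(P, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    if P.shape != G.shape or P.ndim != 3:
        raise ValueError("P and G must be matching (n, H, W) arrays")
    n = P.shape[0]
    npix = P[0].size
    ax = (1, 2)
    s_pg = (P * G).sum(axis=ax)
    s_p = P.sum(axis=ax)
    s_g = G.sum(axis=ax)
    num = 2.0 * s_pg + smooth
    den = s_p + s_g + smooth
    dice = 1.0 - num / den
    Pc = np.clip(P, EPS_P, 1.0 - EPS_P)
    bce = -(G * np.log(Pc) + (1.0 - G) * np.log(1.0 - Pc)).mean(axis=ax)
    losses = 0.5 * (dice + bce)
    # gradient of the batch mean
    d_dice = (num / den**2)[:, None, None] - 2.0 * G / den[:, None, None]
    d_bce = (-G / Pc + (1.0 - G) / (1.0 - Pc)) / npix
    d_bce[(P < EPS_P) | (P > 1.0 - EPS_P)] = 0.0
    grad = 0.5 * (d_dice + d_bce) / n
    return losses, grad


def batch_seg_losses_and_logit_grad(P, G, smooth: float = 1.0):
    """Per-image seg losses and the gradient of their mean w.r.t. the logits.

    For probabilities produced by a sigmoid, the cross-entropy gradient in
    logit space is simply (p - g)/npix, which never vanishes on saturated
    pixels — computing it directly avoids the dead-gradient trap of chaining
    a clamped-probability gradient through p(1-p).  The Dice term is chained
    through the sigmoid as usual.
    """
    P = np.asarray(P, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    if P.shape != G.shape or P.ndim != 3:
        raise ValueError("P and G must be matching (n, H, W) arrays")
    n = P.shape[0]
    npix = P[0].size
    ax = (1, 2)
    s_pg = (P * G).sum(axis=ax)
    s_p = P.sum(axis=ax)
    s_g = G.sum(axis=ax)
    num = 2.0 * s_pg + smooth
    den = s_p + s_g + smooth
    dice = 1.0 - num / den
    Pc = np.clip(P, EPS_P, 1.0 - EPS_P)
    bce = -(G * np.log(Pc) + (1.0 - G) * np.log(1.0 - Pc)).mean(axis=ax)
    losses = 0.5 * (dice + bce)
    d_dice_dp = (num / den**2)[:, None, None] - 2.0 * G / den[:, None, None]
    dz = 0.5 * (d_dice_dp * P * (1.0 - P) + (P - G) / npix) / n
    return losses, dz


def _batch_seg_loss(p, g, smooth: float) -> float:
    p = np.asarray(p)
    g = np.asarray(g)
    if p.ndim == 2:
        return seg_loss(p, g, smooth)
    return float(np.mean([seg_loss(pi, gi, smooth) for pi, gi in zip(p, g)]))


def lambda_schedule(i: int, iters: int, lambda_max: float = 1.0,
                    ramp_fraction: float = 0.1) -> float:
    """Sigmoid ramp of the pseudo-label weight over the first part of training.

    lambda(i) = lambda_max * exp(-5 (1 - i/T)^2) for i < T = ramp_fraction x iters,
    then lambda_max.  Monotone non-decreasing; lambda(0) = lambda_max * e^-5.
    """
    if iters <= 0:
        raise ValueError("iters must be positive")
    if not 0 <= i <= iters:
        raise ValueError(f"iteration {i} outside [0, {iters}]")
    ramp_len = ramp_fraction * iters
    if ramp_len <= 0 or i >= ramp_len:
        return lambda_max
    frac = i / ramp_len
    return float(lambda_max * np.exp(-5.0 * (1.0 - frac) ** 2))
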