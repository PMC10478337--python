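"""Automatic transfer of supervised targets (ATST).

The weak branch initially learns from HU-threshold pseudo-labels.  As the
strong (clean) branch improves, its prediction on a pseudo-labelled image may
become more faithful than the noisy HU label.  Each pseudo-labelled image is
scored with

    S_lovasz = LEV(GT_pseudo, P_clean) / exp(div(GT_pseudo, P_noisy))

where LEV is the Lovasz extension of the Jaccard (IoU) loss evaluated at the
clean branch's probabilities, and div is a symmetric divergence between the
pseudo-label (lifted to a probability map) and the noisy branch's prediction.
A sliding window of recent scores defines a percentile threshold tau; once
the window has filled, an image whose score satisfies S - tau >= 0 has its
weak supervision target switched from the pseudo-label to the binarised
clean-branch prediction:

    GT = P_clean (binarised)   if S_lovasz - tau >= 0
       = GT_pseudo             otherwise.

Before the window fills, tau is unset and the pseudo-label is always used —
early training relies on the HU-based labels.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .io import LabelMask
from .losses import EPS_P

__all__ = [
    "ATSTState",
    "ATSTTarget",
    "lovasz_extension_value",
    "sym_divergence",
    "s_lovasz",
    "update_tau",
    "select_target",
]


def lovasz_extension_value(g, p) -> float:
    """Lovasz extension of the Jaccard loss at the per-pixel error vector.

    The error vector is m_i = 1 - p_i on foreground pixels and m_i = p_i on
    background pixels.  Errors are sorted in decreasing order and accumulated
    against the discrete gradient of the Jaccard set function along that
    order; the result lies in [0, 1] and coincides with 1 - IoU whenever p is
    binary (the extension agrees with the set function on hypercube
    vertices).  An all-background ground truth makes the Jaccard loss
    degenerate; the value is then defined as the mean error.
    """
    g = np.asarray(g.voxels if isinstance(g, LabelMask) else g, dtype=np.float64).ravel()
    p = np.asarray(p, dtype=np.float64).ravel()
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {p.shape}")
    m = np.where(g > 0.5, 1.0 - p, p)
    total_fg = g.sum()
    if total_fg == 0:
        return float(m.mean())
    order = np.argsort(-m, kind="stable")
    m_sorted = m[order]
    g_sorted = g[order]
    intersection = total_fg - np.cumsum(g_sorted)
    union = total_fg + np.cumsum(1.0 - g_sorted)
    jaccard = 1.0 - intersection / union
    jaccard[1:] = jaccard[1:] - jaccard[:-1]
    return float(np.dot(m_sorted, jaccard))


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=np.float64), EPS_P, 1.0 - EPS_P)


def sym_divergence(p, q, kind: Literal["symkl", "js"] = "symkl") -> float:
    """Mean per-pixel symmetric divergence of Bernoulli(p) vs Bernoulli(q).

    ``symkl`` (default) is 0.5 KL(p||q) + 0.5 KL(q||p); ``js`` is the
    Jensen-Shannon divergence.  Non-negative, zero iff p == q, symmetric.
    """
    p = _clamp(p)
    q = _clamp(q)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")

    def kl(a, b):
        return a * np.log(a / b) + (1.0 - a) * np.log((1.0 - a) / (1.0 - b))

    if kind == "symkl":
        d = 0.5 * kl(p, q) + 0.5 * kl(q, p)
    elif kind == "js":
        m = 0.5 * (p + q)
        d = 0.5 * kl(p, m) + 0.5 * kl(q, m)
    else:
        raise ValueError(f"unknown divergence kind: {kind}")
    return float(d.mean())


def s_lovasz(gt_pseudo, p_clean, p_noisy, divergence: str = "symkl") -> float:
    """Score of one pseudo-labelled image: LEV / exp(div).

    The pseudo-label is lifted to a clamped probability map before the
    divergence so both arguments are distributions.
    """
    g = np.asarray(gt_pseudo.voxels if isinstance(gt_pseudo, LabelMask) else gt_pseudo,
                   dtype=np.float64)
    lev = lovasz_extension_value(g, p_clean)
    div = sym_divergence(g, p_noisy, kind=divergence)
    return float(lev / np.exp(div))


@dataclass
class ATSTState:
    """Sliding score window and the percentile threshold tau derived from it.

    tau stays None ("unset") until ``window_len`` scores have been observed.
    """

    window_len: int = 100
    h_percentile: float = 50.0
    s_history: deque = field(default_factory=deque)
    tau: float | None = None

    def __post_init__(self) -> None:
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if not 0 < self.h_percentile < 100:
            raise ValueError("h_percentile must be in (0, 100)")
        self.s_history = deque(self.s_history, maxlen=self.window_len)


def update_tau(state: ATSTState, s: float) -> ATSTState:
    """Append a score; once the window is full, tau = h-th percentile of it.

    Mutates and returns ``state``.  The oldest score is evicted at capacity;
    the percentile uses linear interpolation.
    """
    if not np.isfinite(s) or s < 0:
        raise ValueError(f"score must be finite and >= 0, got {s}")
    state.s_history.append(float(s))
    if len(state.s_history) >= state.window_len:
        state.tau = float(np.percentile(list(state.s_history), state.h_percentile))
    return state


@dataclass
class ATSTTarget:
    """The supervision target chosen for one pseudo-labelled image."""

    mask: LabelMask
    source: Literal["pseudo_label", "clean_prediction"]
    score: float


def select_target(
    s: float,
    state: ATSTState,
    p_clean,
    gt_pseudo: LabelMask | np.ndarray,
    binarize_thr: float = 0.5,
) -> ATSTTarget:
    """Pick the weak branch's target: pseudo-label, or the clean prediction.

    The clean branch's prediction (binarised at ``binarize_thr``) is selected
    iff tau is set and s - tau >= 0 (ties switch).  Otherwise — including the
    whole warm-up before the score window fills — the HU pseudo-label is kept.
    """
    gp = gt_pseudo if isinstance(gt_pseudo, LabelMask) else LabelMask(
        np.asarray(gt_pseudo, dtype=np.uint8), role="pseudo")
    if state.tau is not None and s - state.tau >= 0:
        mask = LabelMask((np.asarray(p_clean) >= binarize_thr).astype(np.uint8), role="gt")
        return ATSTTarget(mask=mask, source="clean_prediction", score=float(s))
    return ATSTTarget(mask=gp, source="pseudo_label", score=float(s))
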