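"""Adaptive exponential-moving-average coupling of the two branches.

The noisy branch's weights theta' track the clean branch's weights theta via

    theta'_t = eps * theta'_{t-1} + (1 - eps) * theta_t

with an adaptive smoothing coefficient

    eps(i) = 1 - 0.2 * exp(-8 i / iters),

which starts at 0.8 (fast transfer from the clean branch early on) and rises
towards 1 (the noisy branch stabilises, resisting turbulence from dirty
samples late in training).  Note the transfer direction: the noisy branch is
the moving average of the clean one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EMASchedule", "adaptive_coef", "ema_update"]


@dataclass(frozen=True)
class EMASchedule:
    """Parameters of the adaptive coefficient: eps = 1 - amplitude * exp(-rate i/iters)."""

    iters: int
    amplitude: float = 0.2
    rate: float = 8.0

    def __post_init__(self) -> None:
        if self.iters < 1:
            raise ValueError("iters must be >= 1")


def adaptive_coef(i: int | float, sched: EMASchedule) -> float:
    """eps(i) = 1 - amplitude * exp(-rate * i / iters); strictly increasing in i."""
    if not 0 <= i <= sched.iters:
        raise ValueError(f"iteration {i} outside [0, {sched.iters}]")
    return float(1.0 - sched.amplitude * np.exp(-sched.rate * i / sched.iters))


def ema_update(theta_noisy, theta_clean, eps: float):
    """Elementwise theta' <- eps * theta' + (1 - eps) * theta.

    Accepts flat arrays or lists of arrays (one per parameter tensor);
    returns the same structure.  A convex combination for eps in [0, 1].
    """
    if not 0.0 <= eps <= 1.0:
        raise ValueError(f"eps must be in [0, 1], got {eps}")
    if isinstance(theta_noisy, (list, tuple)):
        if len(theta_noisy) != len(theta_clean):
            raise ValueError("branch parameter lists differ in length")
        return [ema_update(tn, tc, eps) for tn, tc in zip(theta_noisy, theta_clean)]
    tn = np.asarray(theta_noisy)
    tc = np.asarray(theta_clean)
    if tn.shape != tc.shape:
        raise ValueError(f"parameter shape mismatch: {tn.shape} vs {tc.shape}")
    return eps * tn + (1.0 - eps) * tc
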