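"""Segmentation evaluation: Dice similarity coefficient and Hausdorff distances.

DSC(A, B) = 2|A n B| / (|A| + |B|) x 100, reported in percent.  The Hausdorff
distance is the symmetric max of the two directed point-set distances
h(A, B) = max_a min_b ||a - b||, computed on foreground voxel coordinates in
pixel units.  HD95 takes the 95th percentile of the pooled directed
point-to-set distances (both directions), which removes the influence of a
few boundary outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import LabelMask

__all__ = [
    "dsc",
    "directed_hd",
    "hd",
    "hd95",
    "evaluate_benchmark",
    "MetricsReport",
]


def _fg(mask: LabelMask | np.ndarray) -> np.ndarray:
    m = mask.voxels if isinstance(mask, LabelMask) else np.asarray(mask)
    return m.astype(bool)


def _check_shapes(a, b) -> tuple[np.ndarray, np.ndarray]:
    fa, fb = _fg(a), _fg(b)
    if fa.shape != fb.shape:
        raise ValueError(f"shape mismatch: {fa.shape} vs {fb.shape}")
    return fa, fb


def dsc(a: LabelMask | np.ndarray, b: LabelMask | np.ndarray) -> float:
    """Dice similarity coefficient in percent.

    Both masks empty is degenerate (0/0) and returns 100 by convention;
    exactly one empty mask returns 0.
    """
    fa, fb = _check_shapes(a, b)
    na, nb = int(fa.sum()), int(fb.sum())
    if na + nb == 0:
        return 100.0
    inter = int((fa & fb).sum())
    return 200.0 * inter / (na + nb)


def _directed_distances(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """Euclidean distance from every foreground point of A to the set B."""
    # exact Euclidean distance transform of the complement of B, sampled at A
    dt = ndimage.distance_transform_edt(~fb)
    return dt[fa]


def directed_hd(a, b) -> float:
    """Directed Hausdorff distance h(A, B) = max_a min_b ||a - b|| in pixels."""
    fa, fb = _check_shapes(a, b)
    if not fa.any() or not fb.any():
        raise ValueError("directed_hd requires both masks non-empty")
    return float(_directed_distances(fa, fb).max())


def hd(a, b) -> float:
    """Symmetric Hausdorff distance H(A,B) = max(h(A,B), h(B,A))."""
    return max(directed_hd(a, b), directed_hd(b, a))


def hd95(a, b, pooled: bool = True, empty_sentinel: float | None = None) -> float:
    """95th percentile Hausdorff distance in pixels.

    By default the two directed point-to-set distance lists are pooled before
    the percentile (linear interpolation); ``pooled=False`` takes the max of
    the two per-direction 95th percentiles instead.  If either mask is empty
    the volume diagonal (or ``empty_sentinel``) is returned as a flagged
    worst case.
    """
    fa, fb = _check_shapes(a, b)
    if not fa.any() or not fb.any():
        if empty_sentinel is not None:
            return float(empty_sentinel)
        return float(np.linalg.norm(fa.shape))
    d_ab = _directed_distances(fa, fb)
    d_ba = _directed_distances(fb, fa)
    if pooled:
        return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


@dataclass
class MetricsReport:
    """Per-case DSC/HD95 rows plus mean +/- standard deviation aggregates."""

    per_case: pd.DataFrame
    dsc_mean: float = field(init=False)
    dsc_std: float = field(init=False)
    hd95_mean: float = field(init=False)
    hd95_std: float = field(init=False)

    def __post_init__(self) -> None:
        self.dsc_mean = float(self.per_case["dsc"].mean())
        self.dsc_std = float(self.per_case["dsc"].std(ddof=0))
        self.hd95_mean = float(self.per_case["hd95"].mean())
        self.hd95_std = float(self.per_case["hd95"].std(ddof=0))

    def to_csv(self, path) -> None:
        agg = pd.DataFrame(
            [{"case": "mean", "dsc": self.dsc_mean, "hd95": self.hd95_mean},
             {"case": "std", "dsc": self.dsc_std, "hd95": self.hd95_std}]
        )
        pd.concat([self.per_case, agg], ignore_index=True).to_csv(path, index=False)


def evaluate_benchmark(
    predictions: list,
    truths: list,
    case_ids: list[str] | None = None,
) -> MetricsReport:
    """Evaluate matched prediction/truth mask lists case by case."""
    if len(predictions) == 0 or len(predictions) != len(truths):
        raise ValueError("need equal-length, non-empty prediction/truth lists")
    if case_ids is None:
        case_ids = [f"case_{i:03d}" for i in range(len(predictions))]
    rows = []
    for cid, p, t in zip(case_ids, predictions, truths):
        rows.append({"case": cid, "dsc": dsc(p, t), "hd95": hd95(p, t)})
    return MetricsReport(per_case=pd.DataFrame(rows))
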