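"""HU-threshold pseudo-labels, GGO/consolidation subtyping and infection quantification.

Infected lung tissue shows up on CT inside a characteristic attenuation band:
ground-glass opacity (GGO) roughly in [-750, -300] HU and consolidation in
[-300, 50] HU.  Thresholding the HU values inside the lung therefore yields a
zero-cost — but noisy — lesion label, because some healthy structures
(vessels, airway walls) share the same attenuation range.  These pseudo-labels
are deliberately left uncleaned: the downstream training method is designed to
cope with, and progressively replace, exactly this kind of label noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .io import HUVolume, LabelMask

__all__ = [
    "HUInterval",
    "LESION_INTERVAL",
    "GGO_INTERVAL",
    "CONSOLIDATION_INTERVAL",
    "SubtypeMask",
    "LesionReport",
    "generate_pseudolabel",
    "classify_lesion_subtypes",
    "simple_lung_mask",
    "quantify_infection",
]

GGO_CODE = 1
CONSOLIDATION_CODE = 2


@dataclass(frozen=True)
class HUInterval:
    """Closed HU interval [lo, hi] with a descriptive label."""

    lo: float
    hi: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"require lo < hi, got [{self.lo}, {self.hi}]")

    def contains(self, hu: np.ndarray) -> np.ndarray:
        return (np.asarray(hu) >= self.lo) & (np.asarray(hu) <= self.hi)


# The overall lesion band and its two clinical subtypes.  The boundary value
# -300 HU belongs to consolidation: GGO is treated as the half-open
# [-750, -300) so the split partitions the lesion band deterministically.
LESION_INTERVAL = HUInterval(-750.0, 50.0, "lesion")
GGO_INTERVAL = HUInterval(-750.0, -300.0, "ggo")
CONSOLIDATION_INTERVAL = HUInterval(-300.0, 50.0, "consolidation")


@dataclass
class SubtypeMask:
    """Voxel codes: 0 background, 1 GGO, 2 consolidation."""

    voxels: np.ndarray
    n_unclassified: int = 0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.uint8)

    def counts(self) -> tuple[int, int]:
        return int((self.voxels == GGO_CODE).sum()), int((self.voxels == CONSOLIDATION_CODE).sum())


@dataclass
class LesionReport:
    """Volumetric summary of the infection inside the lung."""

    lung_volume_ml: float
    lesion_volume_ml: float
    infection_ratio: float | None
    ggo_volume_ml: float
    consolidation_volume_ml: float
    n_lesion_outside_lung: int = 0
    empty_lung: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def generate_pseudolabel(
    volume: HUVolume,
    lung: LabelMask | None,
    interval: HUInterval = LESION_INTERVAL,
    gate_by_lung: bool = True,
) -> LabelMask:
    """Lesion pseudo-label: voxels with HU in ``interval``, gated by the lung mask.

    A voxel is foreground iff it lies inside the lung mask and its HU value is
    within the closed interval.  Set ``gate_by_lung=False`` (or pass
    ``lung=None``) to threshold the whole volume.
    """
    inside = interval.contains(volume.voxels)
    if gate_by_lung and lung is not None:
        if tuple(lung.shape) != tuple(volume.shape):
            raise ValueError(f"lung shape {lung.shape} != volume shape {volume.shape}")
        inside &= lung.voxels.astype(bool)
    return LabelMask(voxels=inside.astype(np.uint8), role="pseudo", spacing=volume.spacing)


def classify_lesion_subtypes(volume: HUVolume, lesion: LabelMask) -> SubtypeMask:
    """Split lesion voxels into GGO ([-750, -300) HU) and consolidation ([-300, 50] HU).

    Lesion voxels whose HU falls outside the lesion band are left as
    background and tallied in ``n_unclassified``.
    """
    if tuple(lesion.shape) != tuple(volume.shape):
        raise ValueError(f"lesion shape {lesion.shape} != volume shape {volume.shape}")
    fg = lesion.voxels.astype(bool)
    hu = volume.voxels
    out = np.zeros(volume.shape, dtype=np.uint8)
    ggo = fg & (hu >= GGO_INTERVAL.lo) & (hu < CONSOLIDATION_INTERVAL.lo)
    cons = fg & (hu >= CONSOLIDATION_INTERVAL.lo) & (hu <= CONSOLIDATION_INTERVAL.hi)
    out[ggo] = GGO_CODE
    out[cons] = CONSOLIDATION_CODE
    n_unclassified = int(fg.sum() - ggo.sum() - cons.sum())
    return SubtypeMask(voxels=out, n_unclassified=n_unclassified)


def simple_lung_mask(
    volume: HUVolume,
    air_hi: float = -320.0,
    min_component_fraction: float = 0.005,
    closing_radius: int = 2,
) -> tuple[LabelMask, bool]:
    """Morphological lung mask: threshold, drop border-connected air, keep large blobs.

    Returns ``(mask, warning)`` where ``warning`` is True when no plausible
    lung component was found (empty mask).  This is a deliberately simple
    fallback; externally computed lung masks can be supplied everywhere one is
    accepted.
    """
    air = volume.voxels < air_hi
    labeled, n = ndimage.label(air)
    if n == 0:
        return LabelMask(np.zeros(volume.shape, dtype=np.uint8), role="lung",
                         spacing=volume.spacing), True
    # discard components touching the in-plane border (exterior air); the z
    # faces are exempt because lungs routinely continue past the scan range
    border_labels = set()
    for axis in range(2):
        for idx in (0, -1):
            face = np.take(labeled, idx, axis=axis)
            border_labels.update(np.unique(face[face > 0]).tolist())
    sizes = ndimage.sum_labels(air, labeled, index=np.arange(1, n + 1))
    min_size = min_component_fraction * volume.voxels.size
    keep = [
        lab for lab in range(1, n + 1)
        if lab not in border_labels and sizes[lab - 1] >= min_size
    ]
    if not keep:
        return LabelMask(np.zeros(volume.shape, dtype=np.uint8), role="lung",
                         spacing=volume.spacing), True
    mask = np.isin(labeled, keep)
    # morphology is applied in-plane: slice thickness is typically much
    # larger than the pixel pitch, and 3D closing at the z faces would erode
    # the end slices.  Dense lesions exceed the air threshold and leave
    # interior holes, so each slice is hole-filled after closing.
    struct2d = ndimage.generate_binary_structure(2, 1)
    for k in range(mask.shape[2]):
        sl = mask[:, :, k]
        if closing_radius > 0 and sl.any():
            sl = ndimage.binary_closing(sl, structure=struct2d,
                                        iterations=closing_radius)
        mask[:, :, k] = ndimage.binary_fill_holes(sl)
    return LabelMask(mask.astype(np.uint8), role="lung", spacing=volume.spacing), False


def quantify_infection(
    lung: LabelMask,
    lesion: LabelMask,
    subtypes: SubtypeMask | None,
    spacing: tuple[float, float, float],
) -> LesionReport:
    """Volumes (ml), infection ratio and GGO/consolidation split.

    Volume = foreground voxel count x voxel volume (product of the spacing
    components, mm^3).  Lesion voxels outside the lung are intersected away
    and counted.  An empty lung mask makes the ratio undefined (None).
    """
    if tuple(lung.shape) != tuple(lesion.shape):
        raise ValueError(f"lung shape {lung.shape} != lesion shape {lesion.shape}")
    if subtypes is not None and tuple(subtypes.voxels.shape) != tuple(lung.shape):
        raise ValueError("subtype mask shape mismatch")
    vox_ml = float(np.prod(spacing)) / 1000.0  # mm^3 -> ml
    lung_fg = lung.voxels.astype(bool)
    lesion_fg = lesion.voxels.astype(bool)
    outside = int((lesion_fg & ~lung_fg).sum())
    lesion_fg = lesion_fg & lung_fg
    lung_n = int(lung_fg.sum())
    lesion_n = int(lesion_fg.sum())
    if subtypes is not None:
        ggo_n = int(((subtypes.voxels == GGO_CODE) & lesion_fg).sum())
        cons_n = int(((subtypes.voxels == CONSOLIDATION_CODE) & lesion_fg).sum())
    else:
        ggo_n = cons_n = 0
    empty = lung_n == 0
    ratio = None if empty else lesion_n / lung_n
    return LesionReport(
        lung_volume_ml=lung_n * vox_ml,
        lesion_volume_ml=lesion_n * vox_ml,
        infection_ratio=ratio,
        ggo_volume_ml=ggo_n * vox_ml,
        consolidation_volume_ml=cons_n * vox_ml,
        n_lesion_outside_lung=outside,
        empty_lung=empty,
    )
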