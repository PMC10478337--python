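"""CT volume and mask I/O plus intensity preprocessing.

Volumes are handled in Hounsfield units (HU): air is about -1000, water 0,
soft tissue about +40.  Before slices are fed to a network the HU range is
clipped to a fixed window and linearly mapped to the 8-bit grayscale range,
the standard preparation for lung CT.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
from skimage.transform import resize

__all__ = [
    "HUVolume",
    "NormalizedImage",
    "LabelMask",
    "read_volume",
    "write_mask",
    "hu_clip_normalize",
    "to_model_input",
    "HU_CLIP_LO",
    "HU_CLIP_HI",
]

# Default HU window applied before normalisation to [0, 255].
HU_CLIP_LO = -1200.0
HU_CLIP_HI = 600.0

MaskRole = Literal["lung", "lesion", "pseudo", "gt"]


@dataclass
class HUVolume:
    """A 3D voxel grid in Hounsfield units with physical spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError(f"voxels must be a non-empty 3D array, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive components, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class NormalizedImage:
    """Grayscale image/volume with values guaranteed inside [0, 255]."""

    pixels: np.ndarray
    value_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        lo, hi = self.value_range
        if self.pixels.size and (self.pixels.min() < lo - 1e-6 or self.pixels.max() > hi + 1e-6):
            raise ValueError("pixel values outside the declared value_range")


@dataclass
class LabelMask:
    """Binary voxel mask ({0,1}) tied to a source volume's geometry."""

    voxels: np.ndarray
    role: MaskRole = "lesion"
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        uniq = np.unique(vox)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be exactly 0 or 1, found {uniq[:10]}")
        self.voxels = vox.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    def foreground_count(self) -> int:
        return int(self.voxels.sum())


def _read_dicom_series(path: Path) -> HUVolume:
    import pydicom

    files = sorted(p for p in path.iterdir()
                   if p.suffix.lower() in (".dcm", ".ima") or p.suffix == "")
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    if not datasets:
        raise ValueError(f"no DICOM series found under {path}")
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"mixed DICOM series under {path}: {sorted(map(str, uids))}")
    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) > 1:
        raise ValueError(f"incomplete/inconsistent DICOM series under {path}: "
                         f"slice shapes {sorted(shapes)}")

    def z_of(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=z_of)
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    # (z, rows, cols) -> (x=cols, y=rows, z)
    vox = np.stack(slices).transpose(2, 1, 0)
    ds0 = datasets[0]
    px = getattr(ds0, "PixelSpacing", [1.0, 1.0])
    if len(datasets) > 1:
        dz = abs(z_of(datasets[1]) - z_of(datasets[0])) or 1.0
    else:
        dz = float(getattr(ds0, "SliceThickness", 1.0) or 1.0)
    return HUVolume(voxels=vox, spacing=(float(px[1]), float(px[0]), dz))


def read_volume(path: str | os.PathLike) -> HUVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    DICOM stored values are converted to HU with the rescale slope/intercept
    from the headers (handled by the series reader).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such volume: {p}")
    if p.is_dir():
        return _read_dicom_series(p)
    img = nib.load(str(p))
    vox = np.asanyarray(img.dataobj).astype(np.float32)
    if vox.ndim == 2:
        vox = vox[..., None]
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3:
        zooms = tuple(zooms) + (1.0,) * (3 - len(zooms))
    return HUVolume(voxels=vox, spacing=tuple(float(z) for z in zooms), affine=img.affine)


def read_mask(path: str | os.PathLike, role: MaskRole = "lesion") -> LabelMask:
    """Read a binary mask from NIfTI; any nonzero voxel becomes foreground."""
    vol = read_volume(path)
    return LabelMask(voxels=(vol.voxels > 0.5).astype(np.uint8), role=role, spacing=vol.spacing)


def write_mask(mask: LabelMask, path: str | os.PathLike, reference: HUVolume) -> None:
    """Write a mask as uint8 NIfTI with geometry copied from ``reference``."""
    if tuple(mask.shape) != tuple(reference.shape):
        raise ValueError(f"mask shape {mask.shape} != reference shape {reference.shape}")
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine=reference.affine)
    img.header.set_zooms(reference.spacing)
    nib.save(img, str(path))


def write_volume(volume: HUVolume, path: str | os.PathLike) -> None:
    """Write an HU volume as float32 NIfTI."""
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), affine=volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def hu_clip_normalize(
    volume: HUVolume | np.ndarray, lo: float = HU_CLIP_LO, hi: float = HU_CLIP_HI
) -> NormalizedImage:
    """Clip HU values to [lo, hi] and map them affinely to [0, 255].

    ``lo`` maps exactly to 0 and ``hi`` exactly to 255; the map is monotone
    non-decreasing in the input HU.
    """
    if lo >= hi:
        raise ValueError(f"require lo < hi, got lo={lo}, hi={hi}")
    vox = volume.voxels if isinstance(volume, HUVolume) else np.asarray(volume)
    clipped = np.clip(vox.astype(np.float64), lo, hi)
    pixels = 255.0 * (clipped - lo) / (hi - lo)
    return NormalizedImage(pixels=pixels.astype(np.float32))


def to_model_input(image: NormalizedImage | np.ndarray, side: int = 256) -> np.ndarray:
    """Resample 2D slices to ``side`` x ``side`` and rescale to [0, 1].

    Accepts a single 2D slice, a 3D stack with slices along the last axis, or
    an (n, H, W) stack; returns float32 with the slice axis first.
    Continuous images are resampled bilinearly.
    """
    if side < 8:
        raise ValueError(f"side must be at least 8, got {side}")
    px = image.pixels if isinstance(image, NormalizedImage) else np.asarray(image)
    if px.size == 0:
        raise ValueError("empty image")
    if px.ndim == 2:
        stack = px[None]
    elif px.ndim == 3:
        # heuristics: NIfTI order keeps the slice axis last
        stack = np.moveaxis(px, -1, 0)
    else:
        raise ValueError(f"expected 2D or 3D input, got ndim={px.ndim}")
    out = np.empty((stack.shape[0], side, side), dtype=np.float32)
    for i, sl in enumerate(stack):
        if sl.shape == (side, side):
            out[i] = sl
        else:
            out[i] = resize(sl.astype(np.float64), (side, side), order=1,
                            preserve_range=True, anti_aliasing=False)
    return np.clip(out / 255.0, 0.0, 1.0).astype(np.float32)


def resize_mask(mask: np.ndarray, side: int) -> np.ndarray:
    """Nearest-neighbour resize for a 2D binary mask (keeps binarity)."""
    m = np.asarray(mask)
    if m.shape == (side, side):
        return m.astype(np.uint8)
    out = resize(m.astype(np.float64), (side, side), order=0, preserve_range=True,
                 anti_aliasing=False)
    return (out > 0.5).astype(np.uint8)
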