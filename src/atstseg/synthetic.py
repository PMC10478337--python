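"""Synthetic chest-CT phantoms with known ground truth.

Each phantom is a thin 3D HU volume: a soft-tissue body (~+40 HU) containing
two ellipsoidal low-attenuation lungs (~-850 HU), surrounded by exterior air
(-1000 HU).  Lesions are blobby ellipsoids placed strictly inside the lungs;
their voxels draw HU values from the ground-glass-opacity band (Normal(-550,
80) truncated to [-750, -301]) or the consolidation band (Normal(-150, 60)
truncated to [-300, 50]).  Distractor structures — small vessel-like discs
near the lung interior with consolidation-range HU — reproduce the real
failure mode of HU-threshold pseudo-labels: healthy dense tissue that falls
inside the lesion attenuation window and is wrongly captured as foreground.
Additive Gaussian noise models acquisition noise.

These phantoms make no attempt at anatomical realism (no projection or
reconstruction physics); they exist so that pseudo-labelling, training,
target switching and evaluation can all be exercised end-to-end with exact
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .io import HUVolume, LabelMask, write_mask, write_volume
from .pseudolabel import (CONSOLIDATION_CODE, GGO_CODE, SubtypeMask,
                          generate_pseudolabel)

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "generate_dataset",
    "pseudo_label_noise_rate",
    "make_slice_dataset",
]


@dataclass
class PhantomSpec:
    """Distributional description of one phantom family."""

    shape: tuple[int, int, int] = (64, 64, 8)
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)
    body_hu: tuple[float, float] = (40.0, 15.0)      # mean, sd
    lung_hu: tuple[float, float] = (-850.0, 40.0)
    air_hu: float = -1000.0
    lesion_count: tuple[int, int] = (1, 3)           # inclusive range
    lesion_radius: tuple[float, float] = (5.0, 12.0)  # voxels, in-plane
    ggo_fraction: float = 0.5
    ggo_hu: tuple[float, float] = (-550.0, 80.0)
    ggo_range: tuple[float, float] = (-750.0, -301.0)
    consolidation_hu: tuple[float, float] = (-150.0, 60.0)
    consolidation_range: tuple[float, float] = (-300.0, 50.0)
    distractor_count: int = 3
    distractor_radius: tuple[float, float] = (1.0, 2.0)
    noise_sd: float = 10.0
    seed: int = 0


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    """Rejection-sampled truncated normal (the bands are wide, so cheap)."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    for _ in range(100):
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return np.clip(out, lo, hi)


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[HUVolume, LabelMask, LabelMask, SubtypeMask]:
    """Build one phantom: (HU volume, lung mask, true lesion mask, subtype mask).

    Deterministic given ``spec.seed``.  Raises if a requested lesion cannot
    be placed inside the lungs after a bounded number of attempts.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    vol = np.full(spec.shape, spec.air_hu, dtype=np.float64)

    # per-case anatomical variation: body size, lung shape/position and mean
    # attenuation all jitter between cases, so a small labelled subset does
    # not exhaust the anatomy distribution (the premise of semi-supervised
    # training: unlabelled cases must still be informative)
    body_r = (rng.uniform(0.42, 0.49) * nx, rng.uniform(0.42, 0.49) * ny)
    body_mu = spec.body_hu[0] + rng.uniform(-20.0, 20.0)
    lung_mu = spec.lung_hu[0] + rng.uniform(-40.0, 40.0)

    # soft-tissue body: an elliptic cylinder spanning the volume
    body = _ellipsoid(spec.shape, (nx / 2 - 0.5, ny / 2 - 0.5, nz / 2 - 0.5),
                      (body_r[0], body_r[1], max(nz, 4) * 2.0))
    vol[body] = rng.normal(body_mu, spec.body_hu[1], size=int(body.sum()))

    # two ellipsoidal lungs inside the body, each with its own shape
    lung = np.zeros(spec.shape, dtype=bool)
    for cx0 in (0.30, 0.70):
        cx = (cx0 + rng.uniform(-0.03, 0.03)) * nx
        cy = (0.5 + rng.uniform(-0.05, 0.05)) * ny - 0.5
        radii = (rng.uniform(0.13, 0.19) * nx, rng.uniform(0.24, 0.36) * ny,
                 rng.uniform(0.45, 0.60) * nz)
        lung |= _ellipsoid(spec.shape, (cx, cy, nz / 2 - 0.5), radii)
    lung &= body
    vol[lung] = rng.normal(lung_mu, spec.lung_hu[1], size=int(lung.sum()))

    lung_idx = np.argwhere(lung)
    # lesion blobs strictly inside the lungs
    lesion = np.zeros(spec.shape, dtype=bool)
    subtype = np.zeros(spec.shape, dtype=np.uint8)
    n_lesions = int(rng.integers(spec.lesion_count[0], spec.lesion_count[1] + 1))
    for _ in range(n_lesions):
        placed = False
        for _attempt in range(200):
            c = lung_idx[rng.integers(len(lung_idx))]
            r_xy = rng.uniform(*spec.lesion_radius)
            r_z = max(1.0, r_xy / 3.0)
            blob = _ellipsoid(spec.shape, c, (r_xy, r_xy, r_z)) & lung
            if blob.sum() >= 4 and (blob.sum() / max(_ellipsoid(
                    spec.shape, c, (r_xy, r_xy, r_z)).sum(), 1)) > 0.6:
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place a lesion inside the lungs")
        new = blob & ~lesion
        lesion |= blob
        idx = np.argwhere(new)
        is_ggo = rng.random(len(idx)) < spec.ggo_fraction
        ggo_vals = _truncated_normal(rng, *spec.ggo_hu, *spec.ggo_range,
                                     size=int(is_ggo.sum()))
        con_vals = _truncated_normal(rng, *spec.consolidation_hu,
                                     *spec.consolidation_range,
                                     size=int((~is_ggo).sum()))
        gi, ci_ = idx[is_ggo], idx[~is_ggo]
        vol[gi[:, 0], gi[:, 1], gi[:, 2]] = ggo_vals
        vol[ci_[:, 0], ci_[:, 1], ci_[:, 2]] = con_vals
        subtype[gi[:, 0], gi[:, 1], gi[:, 2]] = GGO_CODE
        subtype[ci_[:, 0], ci_[:, 1], ci_[:, 2]] = CONSOLIDATION_CODE

    # vessel-like distractors: healthy tissue inside the lesion HU window
    free = lung & ~lesion
    free_idx = np.argwhere(free)
    for _ in range(spec.distractor_count):
        if len(free_idx) == 0:
            break
        c = free_idx[rng.integers(len(free_idx))]
        r = rng.uniform(*spec.distractor_radius)
        tube = _ellipsoid(spec.shape, c, (r, r, max(1.0, nz * 0.3))) & free
        vals = _truncated_normal(rng, *spec.consolidation_hu,
                                 *spec.consolidation_range, size=int(tube.sum()))
        ti = np.argwhere(tube)
        vol[ti[:, 0], ti[:, 1], ti[:, 2]] = vals

    vol += rng.normal(0.0, spec.noise_sd, size=spec.shape)
    volume = HUVolume(voxels=vol.astype(np.float32), spacing=spec.spacing)
    return (
        volume,
        LabelMask(lung.astype(np.uint8), role="lung", spacing=spec.spacing),
        LabelMask(lesion.astype(np.uint8), role="lesion", spacing=spec.spacing),
        SubtypeMask(voxels=subtype),
    )


def pseudo_label_noise_rate(true_mask: LabelMask | np.ndarray,
                            pseudo_mask: LabelMask | np.ndarray):
    """(false-positive fraction of the pseudo-label, false-negative fraction).

    FP = |pseudo \\ true| / |pseudo|, FN = |true \\ pseudo| / |true|; an empty
    denominator yields None for that fraction.
    """
    t = (true_mask.voxels if isinstance(true_mask, LabelMask) else np.asarray(true_mask)) > 0
    p = (pseudo_mask.voxels if isinstance(pseudo_mask, LabelMask) else np.asarray(pseudo_mask)) > 0
    if t.shape != p.shape:
        raise ValueError("shape mismatch")
    n_p, n_t = int(p.sum()), int(t.sum())
    fp = None if n_p == 0 else int((p & ~t).sum()) / n_p
    fn = None if n_t == 0 else int((t & ~p).sum()) / n_t
    return fp, fn


def generate_dataset(n_cases: int, spec: PhantomSpec, out_dir,
                     fractions: tuple[float, float, float] = (0.25, 0.5, 0.25)) -> dict:
    """Write ``n_cases`` phantoms as NIfTI files with a JSON manifest.

    Cases are split into labelled / pseudo-labelled / test subsets by
    ``fractions`` (the default 1:2:1 mirrors a small expert-labelled core
    assisted by twice as many HU-labelled cases).  The pseudo subset ships
    the HU-derived pseudo-label as its training mask; labelled and test
    subsets ship the true lesion mask.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(spec.seed)
    case_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(n_cases)]
    n_lab = max(1, int(round(fractions[0] * n_cases)))
    n_pse = int(round(fractions[1] * n_cases))
    manifest = {"n_cases": n_cases, "root_seed": spec.seed, "cases": []}
    for i, cs in enumerate(case_seeds):
        case_spec = PhantomSpec(**{**asdict(spec), "seed": cs})
        vol, lung, lesion, subtype = generate_phantom(case_spec)
        subset = "labeled" if i < n_lab else ("pseudo" if i < n_lab + n_pse else "test")
        cid = f"case_{i:03d}"
        write_volume(vol, out / f"{cid}_volume.nii.gz")
        write_mask(lung, out / f"{cid}_lung.nii.gz", vol)
        write_mask(lesion, out / f"{cid}_lesion.nii.gz", vol)
        write_mask(LabelMask((subtype.voxels > 0).astype(np.uint8), role="lesion"),
                   out / f"{cid}_subtype_fg.nii.gz", vol)
        entry = {"id": cid, "seed": cs, "subset": subset}
        if subset == "pseudo":
            pl = generate_pseudolabel(vol, lung)
            write_mask(pl, out / f"{cid}_pseudo.nii.gz", vol)
            entry["train_mask"] = f"{cid}_pseudo.nii.gz"
        else:
            entry["train_mask"] = f"{cid}_lesion.nii.gz"
        manifest["cases"].append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def make_slice_dataset(n_labeled: int, n_pseudo: int, n_test: int,
                       spec: PhantomSpec | None = None, side: int = 64,
                       seed: int = 0) -> dict:
    """In-memory benchmark: phantom cases cut into model-ready slices.

    Labelled slices carry the true lesion mask; pseudo slices carry the
    HU-threshold pseudo-label; test cases keep their true masks for
    evaluation.  Returns a dict with ``labeled``, ``pseudo`` (images, masks)
    pairs and a ``test`` list of per-case slice stacks.
    """
    from .trainer import extract_training_slices

    if spec is None:
        spec = PhantomSpec()
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in root.spawn(n_labeled + n_pseudo + n_test)]
    xs_l, ys_l, xs_p, ys_p, test = [], [], [], [], []
    for i, cs in enumerate(seeds):
        case_spec = PhantomSpec(**{**asdict(spec), "seed": cs})
        vol, lung, lesion, _ = generate_phantom(case_spec)
        if i < n_labeled:
            x, y = extract_training_slices(vol, lesion, lung, side)
            xs_l.append(x); ys_l.append(y)
        elif i < n_labeled + n_pseudo:
            pl = generate_pseudolabel(vol, lung)
            x, y = extract_training_slices(vol, pl, lung, side)
            xs_p.append(x); ys_p.append(y)
        else:
            x, y = extract_training_slices(vol, lesion, lung, side)
            test.append({"images": x, "masks": y, "volume": vol,
                         "lung": lung, "lesion": lesion})
    return {
        "labeled": (np.concatenate(xs_l), np.concatenate(ys_l)),
        "pseudo": (np.concatenate(xs_p), np.concatenate(ys_p)) if xs_p else
                  (np.empty((0, side, side), np.float32), np.empty((0, side, side), np.uint8)),
        "test": test,
    }
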