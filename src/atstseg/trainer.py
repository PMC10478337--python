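"""Dual-branch semi-supervised training loop, exposed as a scikit-learn estimator.

Two structurally identical U-Nets are trained jointly: the *clean* branch on
expert-labelled slices (plus, weighted by lambda, HU pseudo-labelled slices)
and the *noisy* branch on pseudo-labelled slices whose supervision target is
chosen per image by the Lovasz-score switching rule.  The noisy branch's
weights additionally track the clean branch through the adaptive EMA.  At
inference only the clean (strong) branch is used.

Every mechanism — the pseudo-label loss term, the noisy-branch gradient step,
the EMA (fixed or adaptive), and the target switching — can be switched off
independently, which reproduces the ablation arms: with everything off the
loop reduces exactly to a single-branch supervised U-Net.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator

from . import atst as atst_mod
from . import losses as losses_mod
from .ema import EMASchedule, adaptive_coef
from .io import HUVolume, LabelMask, hu_clip_normalize, to_model_input
from .nn import SGD, BackboneConfig, UNet, build_backbone

__all__ = [
    "TrainConfig",
    "ATSTSegmenter",
    "augment",
    "binarize",
    "train",
    "predict_volume",
    "extract_training_slices",
]


@dataclass
class TrainConfig:
    """Full training configuration.

    ``published_profile`` carries the published constants (256x256 slices, 40K
    SGD iterations at lr 0.01, batches of 64 labelled + 64 pseudo-labelled);
    ``desk_profile`` is the scaled-down default used throughout the test
    suite (64x64, 400 iterations, 4+4).
    """

    side: int = 64
    base_width: int = 8
    depth: int = 3
    iters: int = 400
    lr: float = 0.05
    momentum: float = 0.9
    lr_decay_total: float = 0.1  # lr multiplier reached at the final iteration
    batch_labeled: int = 4
    batch_pseudo: int = 4
    lambda_max: float = 1.0
    ramp_fraction: float = 0.1
    dice_smooth: float = 1.0
    augment: bool = True
    crop_scale: tuple[float, float] = (0.8, 1.0)
    use_ema: bool = True
    adaptive_ema: bool = True
    fixed_eps: float = 0.99
    ema_amplitude: float = 0.2
    ema_rate: float = 8.0
    noisy_grad: bool = True
    use_atst: bool = True
    window_len: int = 100
    h_percentile: float = 50.0
    binarize_thr: float = 0.5
    divergence: str = "symkl"
    clean_pseudo_target: str = "hu"  # "hu" (HU pseudo-label) or "noisy" (consistency)
    consistency_weight: float = 0.0
    norm: str = "group"
    seed: int = 0

    @staticmethod
    def published_profile(**overrides) -> "TrainConfig":
        base = dict(side=256, base_width=16, depth=4, iters=40000,
                    batch_labeled=64, batch_pseudo=64, lr=0.01,
                    lr_decay_total=0.01)
        base.update(overrides)
        return TrainConfig(**base)

    @staticmethod
    def desk_profile(**overrides) -> "TrainConfig":
        return TrainConfig(**overrides)


def binarize(p: np.ndarray, thr: float = 0.5) -> np.ndarray:
    """Threshold a probability map at ``thr`` (inclusive) to a {0,1} mask."""
    if not 0.0 < thr < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {thr}")
    p = np.asarray(p)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return (p >= thr).astype(np.uint8)


def _crop_resize(img: np.ndarray, top: int, left: int, h: int, w: int,
                 side: int, order: int) -> np.ndarray:
    """Crop then resize back to side x side; bilinear (order 1) or nearest (0)."""
    patch = img[top:top + h, left:left + w]
    r = (np.arange(side) + 0.5) * h / side - 0.5
    c = (np.arange(side) + 0.5) * w / side - 0.5
    if order == 0:
        ri = np.clip(np.rint(r).astype(np.intp), 0, h - 1)
        ci = np.clip(np.rint(c).astype(np.intp), 0, w - 1)
        return patch[np.ix_(ri, ci)]
    r0 = np.clip(np.floor(r).astype(np.intp), 0, h - 1)
    c0 = np.clip(np.floor(c).astype(np.intp), 0, w - 1)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr = np.clip(r - r0, 0.0, 1.0)[:, None].astype(np.float32)
    fc = np.clip(c - c0, 0.0, 1.0)[None, :].astype(np.float32)
    p00 = patch[np.ix_(r0, c0)]
    p01 = patch[np.ix_(r0, c1)]
    p10 = patch[np.ix_(r1, c0)]
    p11 = patch[np.ix_(r1, c1)]
    top_row = p00 + (p01 - p00) * fc
    bot_row = p10 + (p11 - p10) * fc
    return top_row + (bot_row - top_row) * fr


def augment(images: np.ndarray, masks: np.ndarray, rng: np.random.Generator,
            crop_scale: tuple[float, float] = (0.8, 1.0)) -> tuple[np.ndarray, np.ndarray]:
    """Random crop (resized back) and left-right flip, identical on image and mask.

    Images are interpolated bilinearly, masks nearest-neighbour (so they stay
    binary).  Deterministic given the generator state.
    """
    images = np.asarray(images)
    masks = np.asarray(masks)
    side = images.shape[-1]
    out_i = np.empty_like(images, dtype=np.float32)
    out_m = np.empty_like(masks, dtype=np.uint8)
    for n in range(images.shape[0]):
        flip = rng.random() < 0.5
        scale = rng.uniform(*crop_scale)
        h = max(1, int(round(side * scale)))
        w = max(1, int(round(side * scale)))
        top = int(rng.integers(0, side - h + 1))
        left = int(rng.integers(0, side - w + 1))
        if (h, w) == (side, side):
            im, mk = images[n].astype(np.float32), masks[n].astype(np.uint8)
        else:
            im = _crop_resize(images[n], top, left, h, w, side, order=1).astype(np.float32)
            mk = (_crop_resize(masks[n], top, left, h, w, side, order=0) > 0.5).astype(np.uint8)
        if flip:
            im = im[:, ::-1]
            mk = mk[:, ::-1]
        out_i[n] = im
        out_m[n] = mk
    return out_i, out_m


class ATSTSegmenter(BaseEstimator):
    """Semi-supervised dual-branch lesion segmenter with target switching.

    Follows the scikit-learn estimator protocol: all hyper-parameters are
    constructor keywords, :meth:`fit` consumes arrays, and fitted state lives
    in trailing-underscore attributes.

    Parameters mirror :class:`TrainConfig`; ``X`` is an ``(n, side, side)``
    stack of normalised slices in [0, 1], ``y`` the matching {0,1} masks, and
    ``is_pseudo`` marks which samples carry HU pseudo-labels rather than
    expert annotations.

    Attributes
    ----------
    clean_weights_, noisy_weights_ : list of ndarray
        Parameters of the two branches after training.
    history_ : pandas.DataFrame
        One row per iteration: losses, lambda, s_mean, tau, eps, lr and the
        fraction of weak targets switched to the clean prediction.
    atst_state_ : ATSTState
        Final sliding-window state of the switching rule.
    """

    def __init__(self, side=64, base_width=8, depth=3, iters=400, lr=0.05,
                 momentum=0.9, lr_decay_total=0.1, batch_labeled=4, batch_pseudo=4,
                 lambda_max=1.0, ramp_fraction=0.1, dice_smooth=1.0,
                 augment=True, crop_scale=(0.8, 1.0),
                 use_ema=True, adaptive_ema=True, fixed_eps=0.99,
                 ema_amplitude=0.2, ema_rate=8.0, noisy_grad=True,
                 use_atst=True, window_len=100, h_percentile=50.0,
                 binarize_thr=0.5, divergence="symkl",
                 clean_pseudo_target="hu", consistency_weight=0.0,
                 norm="group", random_state=0):
        self.side = side
        self.base_width = base_width
        self.depth = depth
        self.iters = iters
        self.lr = lr
        self.momentum = momentum
        self.lr_decay_total = lr_decay_total
        self.batch_labeled = batch_labeled
        self.batch_pseudo = batch_pseudo
        self.lambda_max = lambda_max
        self.ramp_fraction = ramp_fraction
        self.dice_smooth = dice_smooth
        self.augment = augment
        self.crop_scale = crop_scale
        self.use_ema = use_ema
        self.adaptive_ema = adaptive_ema
        self.fixed_eps = fixed_eps
        self.ema_amplitude = ema_amplitude
        self.ema_rate = ema_rate
        self.noisy_grad = noisy_grad
        self.use_atst = use_atst
        self.window_len = window_len
        self.h_percentile = h_percentile
        self.binarize_thr = binarize_thr
        self.divergence = divergence
        self.clean_pseudo_target = clean_pseudo_target
        self.norm = norm
        self.consistency_weight = consistency_weight
        self.random_state = random_state

    @classmethod
    def from_config(cls, cfg: TrainConfig) -> "ATSTSegmenter":
        d = asdict(cfg)
        d["random_state"] = d.pop("seed")
        return cls(**d)

    # ------------------------------------------------------------------
    def _validate(self, X, y, is_pseudo):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape[1:] != (self.side, self.side):
            raise ValueError(f"X must be (n, {self.side}, {self.side}), got {X.shape}")
        if y.shape != X.shape:
            raise ValueError("y must match X in shape")
        if X.size and (X.min() < 0 or X.max() > 1):
            raise ValueError("X must be normalised to [0, 1]")
        y = (y > 0.5).astype(np.uint8)
        if is_pseudo is None:
            is_pseudo = np.zeros(X.shape[0], dtype=bool)
        is_pseudo = np.asarray(is_pseudo, dtype=bool)
        if is_pseudo.shape != (X.shape[0],):
            raise ValueError("is_pseudo must be one flag per sample")
        return X, y, is_pseudo

    def _pseudo_stream_active(self) -> bool:
        return self.lambda_max > 0 or self.use_atst or self.use_ema or self.noisy_grad

    def fit(self, X, y, *, is_pseudo=None):
        """Train both branches for ``iters`` SGD iterations."""
        X, y, is_pseudo = self._validate(X, y, is_pseudo)
        labeled_idx = np.flatnonzero(~is_pseudo)
        pseudo_idx = np.flatnonzero(is_pseudo)
        if labeled_idx.size == 0:
            raise ValueError("need at least one expert-labelled sample")
        use_pseudo = self._pseudo_stream_active() and pseudo_idx.size > 0

        ss = np.random.SeedSequence(self.random_state)
        s_init, s_lab, s_pse, s_aug_lab, s_aug_pse = ss.spawn(5)
        cfg = BackboneConfig(side=self.side, base_width=self.base_width,
                             depth=self.depth, norm=self.norm)
        clean = build_backbone(cfg, s_init)
        noisy = UNet(cfg, np.random.default_rng(0))  # placeholder init, overwritten
        noisy.set_weights(clean.get_weights())       # branches start identical
        opt_clean = SGD(clean.params, self.lr, self.momentum)
        opt_noisy = SGD(noisy.params, self.lr, self.momentum)
        rng_lab = np.random.default_rng(s_lab)
        rng_pse = np.random.default_rng(s_pse)
        rng_aug_lab = np.random.default_rng(s_aug_lab)
        rng_aug_pse = np.random.default_rng(s_aug_pse)

        state = atst_mod.ATSTState(window_len=self.window_len,
                                   h_percentile=self.h_percentile)
        sched = EMASchedule(iters=self.iters, amplitude=self.ema_amplitude,
                            rate=self.ema_rate)
        smooth = self.dice_smooth
        nb_l, nb_p = self.batch_labeled, self.batch_pseudo
        log: list[dict] = []

        for it in range(self.iters):
            lr_it = self.lr * self.lr_decay_total ** (it / self.iters)
            opt_clean.lr = lr_it
            opt_noisy.lr = lr_it
            lam = losses_mod.lambda_schedule(it, self.iters, self.lambda_max,
                                             self.ramp_fraction)

            bi = rng_lab.choice(labeled_idx, size=nb_l, replace=True)
            xb, yb = X[bi], y[bi]
            if self.augment:
                xb, yb = augment(xb, yb, rng_aug_lab, self.crop_scale)

            if use_pseudo:
                pj = rng_pse.choice(pseudo_idx, size=nb_p, replace=True)
                xp, yp = X[pj], y[pj]
                if self.augment:
                    xp, yp = augment(xp, yp, rng_aug_pse, self.crop_scale)
                x_all = np.concatenate([xb, xp], axis=0)
            else:
                xp = yp = None
                x_all = xb

            probs, cache = clean.forward(x_all, want_grad=True)
            p_lab = probs[:nb_l]
            p_pse_clean = probs[nb_l:] if use_pseudo else None

            # ---- noisy branch forward + ATST ---------------------------
            s_mean = np.nan
            switch_fraction = 0.0
            need_noisy = use_pseudo and (
                self.use_atst or (self.noisy_grad and lam > 0)
                or self.consistency_weight > 0
                or (self.clean_pseudo_target == "noisy" and lam > 0))
            p_pse_noisy = cache_noisy = None
            targets = None
            if need_noisy:
                if self.noisy_grad and lam > 0:
                    p_pse_noisy, cache_noisy = noisy.forward(xp, want_grad=True)
                else:
                    p_pse_noisy = noisy.forward(xp)
                if self.use_atst:
                    scores = [atst_mod.s_lovasz(yp[j], p_pse_clean[j], p_pse_noisy[j],
                                                divergence=self.divergence)
                              for j in range(nb_p)]
                    s_mean = float(np.mean(scores))
                    atst_mod.update_tau(state, s_mean)
                    sel = [atst_mod.select_target(scores[j], state, p_pse_clean[j],
                                                  yp[j], self.binarize_thr)
                           for j in range(nb_p)]
                    targets = np.stack([t.mask.voxels for t in sel])
                    switch_fraction = float(np.mean(
                        [t.source == "clean_prediction" for t in sel]))
                else:
                    targets = yp

            # ---- clean branch losses and gradient (in logit space) -----
            lab_losses, lab_grad = losses_mod.batch_seg_losses_and_logit_grad(
                p_lab, yb, smooth)
            l_mseg = float(lab_losses.mean())
            dlogits = np.zeros_like(probs)
            dlogits[:nb_l] = lab_grad
            l_pseg_clean = 0.0
            if use_pseudo and lam > 0:
                # the clean branch's pseudo-stream target: either the noisy
                # branch's soft prediction (consistency, the mean-teacher
                # reading; soft targets avoid the self-sharpening collapse
                # that binarised self-targets produce) or the HU pseudo-label
                if self.clean_pseudo_target == "noisy" and p_pse_noisy is not None:
                    target_clean = p_pse_noisy
                elif self.clean_pseudo_target in ("hu", "noisy"):
                    target_clean = yp
                else:
                    raise ValueError(
                        f"unknown clean_pseudo_target: {self.clean_pseudo_target}")
                pse_losses, pse_grad = losses_mod.batch_seg_losses_and_logit_grad(
                    p_pse_clean, target_clean, smooth)
                l_pseg_clean = float(pse_losses.mean())
                dlogits[nb_l:] = lam * pse_grad
            if use_pseudo and self.consistency_weight > 0 and p_pse_noisy is not None:
                diff = p_pse_clean - p_pse_noisy
                dlogits[nb_l:] += (self.consistency_weight * 2.0 * diff
                                   * p_pse_clean * (1.0 - p_pse_clean)
                                   / diff[0].size / nb_p)
            l_clean = l_mseg + lam * l_pseg_clean
            if not np.isfinite(l_clean):
                raise FloatingPointError(f"non-finite clean loss at iteration {it}")
            opt_clean.step(clean.backward(cache, dlogits, wrt="logits"))

            # ---- noisy branch gradient ---------------------------------
            l_pseg_noisy = 0.0
            if use_pseudo and self.noisy_grad and lam > 0 and targets is not None:
                noisy_losses, noisy_grad = losses_mod.batch_seg_losses_and_logit_grad(
                    p_pse_noisy, targets, smooth)
                l_pseg_noisy = float(noisy_losses.mean())
                if not np.isfinite(l_pseg_noisy):
                    raise FloatingPointError(f"non-finite noisy loss at iteration {it}")
                opt_noisy.step(noisy.backward(cache_noisy, lam * noisy_grad,
                                              wrt="logits"))

            # ---- EMA coupling ------------------------------------------
            eps = np.nan
            if self.use_ema:
                eps = (adaptive_coef(it + 1, sched) if self.adaptive_ema
                       else self.fixed_eps)
                # in-place ema_update: theta' <- eps theta' + (1-eps) theta
                for pn, pc in zip(noisy.params, clean.params):
                    pn *= eps
                    pn += (1.0 - eps) * pc

            log.append({
                "iteration": it, "l_mseg": l_mseg, "l_pseg_clean": l_pseg_clean,
                "l_pseg_noisy": l_pseg_noisy, "l_clean": l_clean,
                "l_noisy": lam * l_pseg_noisy, "lambda": lam, "s_mean": s_mean,
                "tau": np.nan if state.tau is None else state.tau,
                "eps": eps, "lr": lr_it, "switch_fraction": switch_fraction,
            })

        self._clean_net_ = clean
        self._noisy_net_ = noisy
        self.clean_weights_ = clean.get_weights()
        self.noisy_weights_ = noisy.get_weights()
        self.atst_state_ = state
        self.history_ = pd.DataFrame(log)
        self.n_iter_ = self.iters
        return self

    # ------------------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        """Clean-branch foreground probabilities for (n, side, side) slices."""
        if not hasattr(self, "_clean_net_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        return self._clean_net_.forward(X)

    def predict(self, X) -> np.ndarray:
        """Binary masks: probabilities thresholded at ``binarize_thr``."""
        return binarize(self.predict_proba(X), self.binarize_thr)

    def score(self, X, y) -> float:
        """Mean per-slice Dice similarity coefficient (percent)."""
        from .metrics import dsc
        pred = self.predict(X)
        y = (np.asarray(y) > 0.5).astype(np.uint8)
        return float(np.mean([dsc(p, t) for p, t in zip(pred, y)]))


def train(cfg: TrainConfig, labeled_set, pseudo_set) -> ATSTSegmenter:
    """Functional wrapper: train an :class:`ATSTSegmenter` from slice datasets.

    ``labeled_set`` and ``pseudo_set`` are ``(images, masks)`` pairs of
    ``(n, side, side)`` arrays; the pseudo set may be ``None`` or empty.
    """
    xl, yl = labeled_set
    if len(xl) == 0:
        raise ValueError("labeled set must be non-empty")
    if pseudo_set is None:
        xp = np.empty((0,) + np.asarray(xl).shape[1:], dtype=np.float32)
        yp = xp.astype(np.uint8)
    else:
        xp, yp = pseudo_set
    X = np.concatenate([np.asarray(xl), np.asarray(xp)], axis=0)
    y = np.concatenate([np.asarray(yl), np.asarray(yp)], axis=0)
    is_pseudo = np.zeros(len(X), dtype=bool)
    is_pseudo[len(xl):] = True
    return ATSTSegmenter.from_config(cfg).fit(X, y, is_pseudo=is_pseudo)


def extract_training_slices(volume: HUVolume, label: LabelMask, lung: LabelMask,
                            side: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalise a volume and cut it into model-ready slices.

    Slices whose lung mask is empty carry no trainable anatomy and are
    dropped.  Returns ``(images, masks)`` with shapes ``(n, side, side)``.
    """
    from .io import resize_mask
    norm = hu_clip_normalize(volume)
    imgs = to_model_input(norm, side=side)
    keep, masks = [], []
    for k in range(volume.shape[2]):
        if lung.voxels[:, :, k].sum() == 0:
            continue
        keep.append(imgs[k])
        masks.append(resize_mask(label.voxels[:, :, k], side))
    if not keep:
        return (np.empty((0, side, side), dtype=np.float32),
                np.empty((0, side, side), dtype=np.uint8))
    return np.stack(keep), np.stack(masks)


def predict_volume(model: ATSTSegmenter, volume: HUVolume,
                   lung: LabelMask | None = None, gate_by_lung: bool = True) -> np.ndarray:
    """Slice-wise inference on an HU volume, reassembled to volume geometry.

    Each slice goes through the HU window + resize pipeline, the clean branch
    produces probabilities, and the result is resampled back to the original
    in-plane shape.  With a lung mask, probabilities outside the lung are
    zeroed.
    """
    norm = hu_clip_normalize(volume)
    imgs = to_model_input(norm, side=model.side)
    probs = model.predict_proba(imgs)
    nx, ny, nz = volume.shape
    out = np.empty((nx, ny, nz), dtype=np.float32)
    for k in range(nz):
        pk = probs[k]
        if pk.shape != (nx, ny):
            pk = _sk_resize(pk.astype(np.float64), (nx, ny), order=1,
                            preserve_range=True, anti_aliasing=False)
        out[:, :, k] = np.clip(pk, 0.0, 1.0)
    if gate_by_lung and lung is not None:
        if tuple(lung.shape) != tuple(volume.shape):
            raise ValueError("lung mask geometry mismatch")
        out *= lung.voxels
    return out
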