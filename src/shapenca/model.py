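"""Multi-scale NCA segmentation model with shape guidance, and its training loop.

The pipeline trains at a heavily downscaled resolution and refines on
random aligned patches at finer scales so full-resolution gradients are
never materialized: the input is downscaled by ``d`` for ``n`` iterations,
a wide-kernel fused NCA rule (k = 7 -> k = 3) runs at the coarsest scale,
the full cell state is upsampled between levels, and a k = 3 base-block
rule refines each finer level (patches during training, full frames at
inference).  The final feature state is refined once by the shape-guided
block (SLIC superpixel pool/unpool, residual) before a shared 1 x 1
classification layer produces the probability map.

Training optimizes the combined Dice + BCE loss on the patch predictions
of every scale with Adam, duplicates each batch so stochastic firing
yields diverse gradients, and early-stops when the validation loss stops
improving.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import autograd as ag
from .metrics import LossConfig, combined_loss, dice_coefficient
from .nca import NCARule
from .sgs import default_n_segments, slic_oversegment

__all__ = [
    "ScaleSchedule",
    "TrainConfig",
    "TrainingDivergenceError",
    "downscale_shape",
    "downscale_image",
    "upscale_mask",
    "patchify",
    "batch_duplicate",
    "ShapeGuidedNCASegmenter",
    "forward_full",
    "train",
]


class TrainingDivergenceError(RuntimeError):
    """Raised when the loss becomes non-finite; the last checkpoint is kept."""


def downscale_shape(shape, d: int, n: int) -> tuple[int, ...]:
    """Each dimension maps to floor(dim / d**n); errors if any vanishes."""
    if d < 1:
        raise ValueError("downscaling factor d must be >= 1")
    if n < 0:
        raise ValueError("iteration count n must be >= 0")
    factor = d**n
    out = tuple(int(s) // factor for s in shape)
    if any(s < 1 for s in out):
        raise ValueError(f"downscaling {tuple(shape)} by {factor} collapses a dimension")
    return out


@dataclass(frozen=True)
class ScaleSchedule:
    """Downscaling factor, iteration count and the level shapes they induce."""

    d: int
    n: int
    base_shape: tuple[int, int]
    min_size: int = 7  # coarsest level must accommodate the perception kernel

    @property
    def levels(self) -> list[tuple[int, ...]]:
        """Shapes from full resolution down to the coarsest level."""
        return [downscale_shape(self.base_shape, self.d, i) for i in range(self.n + 1)]

    def validate(self) -> None:
        coarsest = self.levels[-1]
        if min(coarsest) < self.min_size:
            raise ValueError(
                f"coarsest level {coarsest} is smaller than the perception kernel"
            )


def _block_mean(image: np.ndarray, d: int) -> np.ndarray:
    h, w = image.shape[-2:]
    hh, ww = h // d, w // d
    trimmed = image[..., : hh * d, : ww * d]
    shp = trimmed.shape[:-2] + (hh, d, ww, d)
    return trimmed.reshape(shp).mean(axis=(-3, -1))


def downscale_image(image: np.ndarray, d: int, n: int) -> np.ndarray:
    """Iterated area-average downscaling to floor(shape / d**n)."""
    image = np.asarray(image, dtype=float)
    target = downscale_shape(image.shape[-2:], d, n)
    out = image
    for _ in range(n):
        if d == 1:
            break
        out = _block_mean(out, d)
    if out.shape[-2:] != target:  # non-divisible sizes: trimming already applied
        raise AssertionError("internal downscaling shape error")
    return out


def upscale_mask(segmented: np.ndarray, u: int, v: int, method: str = "nearest") -> np.ndarray:
    """Upscale by integer factors (u rows, v cols).

    Nearest-neighbour replication for masks (exactly invertible by
    block-mean downscaling), bilinear interpolation for probability maps.
    """
    if u < 1 or v < 1:
        raise ValueError("upscaling factors must be >= 1")
    arr = np.asarray(segmented)
    if method == "nearest":
        return arr.repeat(u, axis=-2).repeat(v, axis=-1)
    if method == "bilinear":
        from skimage.transform import resize

        target = arr.shape[:-2] + (arr.shape[-2] * u, arr.shape[-1] * v)
        return resize(arr.astype(float), target, order=1, preserve_range=True,
                      anti_aliasing=False)
    raise ValueError(f"unknown method {method!r}")


def patchify(image: np.ndarray, mask: np.ndarray, patch: tuple[int, int],
             rng: np.random.Generator):
    """Aligned random crop of image and mask; returns (img, mask, offset)."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    ph, pw = patch
    h, w = image.shape[-2:]
    if ph > h or pw > w:
        raise ValueError(f"patch {patch} larger than image {(h, w)}")
    oy = int(rng.integers(0, h - ph + 1))
    ox = int(rng.integers(0, w - pw + 1))
    return (
        image[..., oy : oy + ph, ox : ox + pw],
        mask[..., oy : oy + ph, ox : ox + pw],
        (oy, ox),
    )


def batch_duplicate(batch, m: int):
    """Repeat every item of a batch m times (bit-identical copies)."""
    if m < 1:
        raise ValueError("duplication factor must be >= 1")
    if isinstance(batch, np.ndarray):
        return np.concatenate([batch] * m, axis=0)
    return list(batch) * m


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults follow the reference training recipe."""

    learning_rate: float = 0.000015625
    max_epochs: int = 3000
    early_stop_patience: int = 20
    checkpoint_every: int = 10
    batch_size: int = 8
    duplication_factor: int = 2
    alpha: float = 0.5
    seed: int = 0
    steps_per_epoch: int | None = None

    def validate(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.duplication_factor < 1:
            raise ValueError("duplication factor must be >= 1")


class ShapeGuidedNCASegmenter(BaseEstimator):
    """Multi-scale NCA segmenter with optional superpixel shape guidance.

    Parameters
    ----------
    n_hidden : hidden channels of the cell state (total channels are
        image + logit + hidden).
    hidden_width : width of the update rule's intermediate layer.
    fire_rate : per-cell probability of applying an update each step.
    scale_factor, n_levels : downscaling factor d and iteration count n;
        the coarsest training scale is the input shape / d**n.
    steps_coarse, steps_fine : NCA iterations at the coarsest level and
        at each refinement level.
    use_sgb : apply the shape-guided block before classification.
    n_segments : SLIC superpixel count (None scales 100-per-256^2 with area).
    compactness : SLIC compactness, calibrated for unit-range images.
    alpha : Dice weight in the combined Dice/BCE loss.
    learning_rate, max_epochs, early_stop_patience, checkpoint_every,
    batch_size, duplication, steps_per_epoch : optimization settings.
    validation_fraction : share of the training set held out to monitor
        early stopping.
    threshold : probability cut for ``predict``.
    """

    def __init__(
        self,
        n_hidden: int = 16,
        hidden_width: int = 32,
        fire_rate: float = 0.5,
        scale_factor: int = 2,
        n_levels: int = 2,
        steps_coarse: int = 10,
        steps_fine: int = 10,
        use_sgb: bool = True,
        n_segments: int | None = None,
        compactness: float = 0.2,
        learning_rate: float = 0.000015625,
        max_epochs: int = 3000,
        steps_per_epoch: int | None = None,
        batch_size: int = 8,
        duplication: int = 2,
        alpha: float = 0.5,
        early_stop_patience: int = 20,
        checkpoint_every: int = 10,
        validation_fraction: float = 0.2,
        threshold: float = 0.5,
        augment: bool = False,
        lr_schedule: str = "constant",
        final_loss_weight: float = 1.0,
        restore_best: str = "loss",
        inference_runs: int = 1,
        random_state: int = 0,
    ):
        self.n_hidden = n_hidden
        self.hidden_width = hidden_width
        self.fire_rate = fire_rate
        self.scale_factor = scale_factor
        self.n_levels = n_levels
        self.steps_coarse = steps_coarse
        self.steps_fine = steps_fine
        self.use_sgb = use_sgb
        self.n_segments = n_segments
        self.compactness = compactness
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.steps_per_epoch = steps_per_epoch
        self.batch_size = batch_size
        self.duplication = duplication
        self.alpha = alpha
        self.early_stop_patience = early_stop_patience
        self.checkpoint_every = checkpoint_every
        self.validation_fraction = validation_fraction
        self.threshold = threshold
        self.augment = augment
        self.lr_schedule = lr_schedule
        self.final_loss_weight = final_loss_weight
        self.restore_best = restore_best
        self.inference_runs = inference_runs
        self.random_state = random_state

    # -- construction helpers -----------------------------------------
    @property
    def n_channels_(self) -> int:
        return 2 + self.n_hidden

    def _init_params(self, rng: np.random.Generator) -> None:
        c = self.n_channels_
        self.coarse_rule_ = NCARule(
            c, self.hidden_width, kernel=7, out_kernel=3, dense_mix=False,
            fire_rate=self.fire_rate, rng=rng,
        )
        self.fine_rule_ = NCARule(
            c, self.hidden_width, kernel=3, out_kernel=1, dense_mix=True,
            fire_rate=self.fire_rate, rng=rng,
        )
        self.cls_w_ = ag.parameter(np.zeros((1, c, 1, 1), dtype=np.float32))
        self.cls_b_ = ag.parameter(np.zeros(1, dtype=np.float32))

    def _parameters(self):
        return (
            self.coarse_rule_.parameters()
            + self.fine_rule_.parameters()
            + [self.cls_w_, self.cls_b_]
        )

    def _snapshot(self) -> dict:
        return {
            "coarse": {k: v.copy() for k, v in self.coarse_rule_.state_arrays().items()},
            "fine": {k: v.copy() for k, v in self.fine_rule_.state_arrays().items()},
            "cls_w": self.cls_w_.data.copy(),
            "cls_b": self.cls_b_.data.copy(),
        }

    def _restore(self, snap: dict) -> None:
        self.coarse_rule_.load_state_arrays(snap["coarse"])
        self.fine_rule_.load_state_arrays(snap["fine"])
        self.cls_w_.data = snap["cls_w"].copy()
        self.cls_b_.data = snap["cls_b"].copy()

    # -- forward pass --------------------------------------------------
    def _pad_to_grid(self, arr: np.ndarray, mode: str) -> np.ndarray:
        f = self.scale_factor**self.n_levels
        h, w = arr.shape[-2:]
        ph = (-h) % f
        pw = (-w) % f
        if ph == 0 and pw == 0:
            return arr
        pad = [(0, 0)] * (arr.ndim - 2) + [(0, ph), (0, pw)]
        return np.pad(arr, pad, mode=mode)

    def _step(self, x, rule: NCARule, rng, chan_keep, training: bool):
        update = rule.update(x, training=training)
        n, _, h, w = x.data.shape
        # training draws one mask per batch item so duplicated inputs
        # decorrelate; inference shares the mask across the batch so the
        # output is invariant to batch duplication under a shared RNG state
        rows = n if training else 1
        if rule.fire_rate >= 1.0:
            fire = np.ones((rows, 1, h, w), dtype=np.float32)
        else:
            fire = (rng.random((rows, 1, h, w)) < rule.fire_rate).astype(np.float32)
        return x + update * ag.constant(fire) * chan_keep

    def _level_loss(self, logits, mask_region: np.ndarray):
        target = mask_region[:, None].astype(np.float32)
        p = ag.sigmoid(logits)
        tgt = ag.constant(target)
        inter = (p * tgt).sum()
        eps = 1e-6
        dice = (2.0 * inter + eps) / (p.sum() + ag.constant(np.float32(target.sum())) + eps)
        dice_l = 1.0 - dice
        bce = ag.bce_with_logits(logits, target)
        return self.alpha * dice_l + (1.0 - self.alpha) * bce

    def _forward(self, imgs: np.ndarray, masks: np.ndarray | None,
                 rng: np.random.Generator, training: bool):
        """Shared multi-scale forward; returns (loss Tensor | None, probs)."""
        imgs = np.asarray(imgs, dtype=np.float32)
        if imgs.ndim == 2:
            imgs = imgs[None]
        n_img, h_orig, w_orig = imgs.shape
        d, n_lv = self.scale_factor, self.n_levels
        padded = self._pad_to_grid(imgs, "edge")
        schedule = ScaleSchedule(d, n_lv, padded.shape[-2:])
        schedule.validate()

        lv_imgs = [padded]
        for _ in range(n_lv):
            lv_imgs.insert(0, _block_mean(lv_imgs[0], d))
        lv_masks = None
        if masks is not None:
            mpad = self._pad_to_grid(np.asarray(masks, dtype=np.float32), "edge")
            lv_masks = [mpad]
            for _ in range(n_lv):
                lv_masks.insert(0, _block_mean(lv_masks[0], d))

        self.coarse_rule_.reset_step()
        self.fine_rule_.reset_step()
        c = self.n_channels_
        h0, w0 = lv_imgs[0].shape[-2:]
        state0 = np.zeros((n_img, c, h0, w0), dtype=np.float32)
        state0[:, 0] = lv_imgs[0]
        x = ag.constant(state0)
        chan_keep = ag.constant(_channel_keep(c))

        losses = []
        for _ in range(self.steps_coarse):
            x = self._step(x, self.coarse_rule_, rng, chan_keep, training)
        oy = ox = 0
        if lv_masks is not None:
            logits = ag.conv2d(x, self.cls_w_, self.cls_b_)
            losses.append(self._level_loss(logits, lv_masks[0]))

        for level in range(1, n_lv + 1):
            x = ag.upsample_nearest(x, d)
            oy, ox = oy * d, ox * d
            hh, ww = x.data.shape[-2:]
            if training:
                dy = int(rng.integers(0, hh - h0 + 1))
                dx = int(rng.integers(0, ww - w0 + 1))
                x = ag.crop2d(x, dy, dx, h0, w0)
                oy, ox = oy + dy, ox + dx
                hh, ww = h0, w0
            img_region = lv_imgs[level][:, oy : oy + hh, ox : ox + ww]
            inject = np.zeros((n_img, c, hh, ww), dtype=np.float32)
            inject[:, 0] = img_region
            x = x * chan_keep + ag.constant(inject)
            for _ in range(self.steps_fine):
                x = self._step(x, self.fine_rule_, rng, chan_keep, training)
            final = level == n_lv
            x_cls = x
            if final and self.use_sgb:
                labels = self._superpixels(img_region)
                x_cls = x + ag.superpixel_smooth(x, labels)
            if lv_masks is not None:
                logits = ag.conv2d(x_cls, self.cls_w_, self.cls_b_)
                losses.append(self._level_loss(
                    logits, lv_masks[level][:, oy : oy + hh, ox : ox + ww]))
            if final and lv_masks is None:
                logits = ag.conv2d(x_cls, self.cls_w_, self.cls_b_)

        if n_lv == 0:
            x_cls = x
            if self.use_sgb:
                labels = self._superpixels(lv_imgs[0])
                x_cls = x + ag.superpixel_smooth(x, labels)
            logits = ag.conv2d(x_cls, self.cls_w_, self.cls_b_)
            if lv_masks is not None:
                losses[:] = [self._level_loss(logits, lv_masks[0])]

        loss = None
        if losses:
            weights = [1.0] * len(losses)
            weights[-1] = self.final_loss_weight
            total = losses[0] * weights[0]
            for wgt, extra in zip(weights[1:], losses[1:]):
                total = total + extra * wgt
            loss = total * (1.0 / sum(weights))

        probs = None
        if not training:
            probs = _sigmoid(logits.data[:, 0])[:, :h_orig, :w_orig]
        return loss, probs

    def _superpixels(self, guidance: np.ndarray) -> np.ndarray:
        k = self.n_segments or default_n_segments(guidance.shape[-2:])
        return np.stack(
            [
                slic_oversegment(img, k, self.compactness).labels
                for img in guidance
            ]
        )

    def initialize(self, random_state: int | None = None) -> "ShapeGuidedNCASegmenter":
        """Build untrained parameters (zero output projections, zero
        classification weights) so the forward pass can run without fit."""
        self._init_params(np.random.default_rng(
            self.random_state if random_state is None else random_state))
        return self

    # -- sklearn API ---------------------------------------------------
    def fit(self, X, y):
        """Train on images X (n, H, W) in [0, 1] with binary masks y."""
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        if X.ndim != 3 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty stack of 2D images")
        if X.shape != y.shape:
            raise ValueError("X and y must share a shape")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")

        rng = np.random.default_rng(self.random_state)
        self._init_params(rng)
        n = X.shape[0]
        n_val = int(round(n * self.validation_fraction)) if n >= 2 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]

        opt = ag.Adam(self._parameters(), lr=self.learning_rate)
        steps = self.steps_per_epoch or max(1, math.ceil(len(Xtr) / self.batch_size))
        history = []
        best_val = np.inf
        best_state = None
        last_checkpoint = self._snapshot()
        since_improve = 0
        stopped_at = self.max_epochs

        best_dice = -np.inf
        for epoch in range(self.max_epochs):
            if self.lr_schedule == "cosine":
                frac = epoch / max(1, self.max_epochs - 1)
                opt.lr = self.learning_rate * (0.05 + 0.95 * 0.5 * (1 + math.cos(math.pi * frac)))
            epoch_losses = []
            for _ in range(steps):
                bsz = min(self.batch_size, len(Xtr))
                idx = rng.choice(len(Xtr), size=bsz, replace=False)
                imgs, msks = Xtr[idx], ytr[idx]
                if self.augment:
                    imgs, msks = self._elastic_augment(imgs, msks, rng)
                imgs = batch_duplicate(imgs, self.duplication)
                msks = batch_duplicate(msks, self.duplication)
                loss, _ = self._forward(imgs, msks, rng, training=True)
                if not np.isfinite(loss.data):
                    self._restore(last_checkpoint)
                    raise TrainingDivergenceError(
                        f"non-finite loss at epoch {epoch}; last checkpoint restored"
                    )
                opt.zero_grad()
                ag.backward(loss)
                opt.step()
                epoch_losses.append(float(loss.data))

            if len(Xval):
                val_loss, val_dice = self._validation_metrics(Xval, yval, rng)
            else:
                val_loss, val_dice = float(np.mean(epoch_losses)), np.nan
            history.append(
                {
                    "epoch": epoch,
                    "train_loss": float(np.mean(epoch_losses)),
                    "val_loss": val_loss,
                    "val_dice": val_dice,
                }
            )
            if (epoch + 1) % self.checkpoint_every == 0:
                last_checkpoint = self._snapshot()
            if self.restore_best == "dice" and np.isfinite(val_dice) and val_dice > best_dice:
                best_dice = val_dice
                best_state = self._snapshot()
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                if self.restore_best != "dice":
                    best_state = self._snapshot()
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= self.early_stop_patience:
                    stopped_at = epoch + 1
                    break

        if best_state is not None:
            self._restore(best_state)
        self.history_ = pd.DataFrame(history)
        self.n_epochs_ = min(stopped_at, len(history))
        return self

    def _elastic_augment(self, imgs, masks, rng):
        """Training-only elastic deformation, magnitude scaled with size."""
        from .preprocessing import PreprocConfig, elastic_deform

        side = min(imgs.shape[-2:])
        cfg_base = dict(
            elastic_alpha=34.0 * side / 256, elastic_sigma=max(1.0, 4.0 * side / 256)
        )
        out_i, out_m = [], []
        for img, msk in zip(imgs, masks):
            cfg = PreprocConfig(seed=int(rng.integers(0, 2**31 - 1)), **cfg_base)
            wi, wm = elastic_deform(img, msk, cfg)
            out_i.append(wi)
            out_m.append(wm)
        return (np.asarray(out_i, dtype=np.float32),
                np.asarray(out_m, dtype=np.float32))

    def _validation_metrics(self, Xval, yval, rng):
        # average a few stochastic passes so early stopping tracks the
        # model, not the firing noise (validation mirrors ensemble inference)
        n_runs = min(2, max(1, int(self.inference_runs)))
        probs = np.mean(
            [self._predict_proba_rng(Xval, rng) for _ in range(n_runs)], axis=0
        )
        cfg = LossConfig(alpha=self.alpha)
        losses = [combined_loss(m, p, cfg) for m, p in zip(yval, probs)]
        dices = [
            dice_coefficient((p >= self.threshold).astype(float), m) for m, p in zip(yval, probs)
        ]
        return float(np.mean(losses)), float(np.mean(dices))

    def _predict_proba_rng(self, X, rng, chunk: int = 8) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        single = X.ndim == 2
        if single:
            X = X[None]
        out = []
        for i in range(0, len(X), chunk):
            _, probs = self._forward(X[i : i + chunk], None, rng, training=False)
            out.append(probs)
        probs = np.concatenate(out, axis=0)
        return probs[0] if single else probs

    def predict_proba(self, X, rng: np.random.Generator | None = None) -> np.ndarray:
        """Probability maps for a stack of images.

        With ``inference_runs > 1`` this is a pseudo-ensemble: the
        stochastic forward pass is repeated and the maps averaged.
        """
        self._check_fitted()
        rng = rng or np.random.default_rng(self.random_state)
        runs = max(1, int(self.inference_runs))
        if runs == 1:
            return self._predict_proba_rng(X, rng)
        return np.mean([self._predict_proba_rng(X, rng) for _ in range(runs)], axis=0)

    def predict(self, X, rng: np.random.Generator | None = None) -> np.ndarray:
        """Binary masks thresholded at ``threshold``."""
        return (self.predict_proba(X, rng) >= self.threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean hard Dice over the stack."""
        preds = self.predict(X)
        y = np.asarray(y)
        return float(
            np.mean([dice_coefficient(p.astype(float), m.astype(float)) for p, m in zip(preds, y)])
        )

    def _check_fitted(self):
        if not hasattr(self, "coarse_rule_"):
            raise RuntimeError("model is not fitted; call fit() or load()")

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: weights plus embedded JSON config."""
        self._check_fitted()
        arrays = {}
        for prefix, src in (
            ("coarse", self.coarse_rule_.state_arrays()),
            ("fine", self.fine_rule_.state_arrays()),
        ):
            for k, v in src.items():
                arrays[f"{prefix}__{k}"] = v
        arrays["cls_w"] = self.cls_w_.data
        arrays["cls_b"] = self.cls_b_.data
        cfg = json.dumps(self.get_params())
        np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "ShapeGuidedNCASegmenter":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            model = cls(**cfg)
            model._init_params(np.random.default_rng(cfg.get("random_state", 0)))
            coarse = {
                k.split("__", 1)[1]: data[k] for k in data.files if k.startswith("coarse__")
            }
            fine = {
                k.split("__", 1)[1]: data[k] for k in data.files if k.startswith("fine__")
            }
            model.coarse_rule_.load_state_arrays(coarse)
            model.fine_rule_.load_state_arrays(fine)
            model.cls_w_.data = data["cls_w"].copy()
            model.cls_b_.data = data["cls_b"].copy()
        model.history_ = pd.DataFrame()
        return model


def _channel_keep(n_channels: int, c_in: int = 1) -> np.ndarray:
    keep = np.ones((1, n_channels, 1, 1), dtype=np.float32)
    keep[0, :c_in] = 0.0
    return keep


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return ag._sigmoid_np(z.astype(np.float32))


def forward_full(
    model: ShapeGuidedNCASegmenter, image: np.ndarray, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Full inference pipeline on one preprocessed image -> probability map."""
    image = np.asarray(image, dtype=float)
    if image.min() < -1e-6 or image.max() > 1 + 1e-6:
        raise ValueError("image must be preprocessed to [0, 1]")
    return model.predict_proba(image, rng=rng)


def train(model: ShapeGuidedNCASegmenter, dataset, cfg: TrainConfig | None = None):
    """Fit ``model`` on a dataset of (image, mask) pairs under ``cfg``.

    ``dataset`` may be a pair of stacked arrays (X, y) or an iterable of
    (image, mask) tuples.  Returns the fitted model and its history.
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    if isinstance(dataset, tuple) and len(dataset) == 2:
        X, y = dataset
    else:
        pairs = list(dataset)
        if not pairs:
            raise ValueError("empty dataset")
        X = np.stack([p[0] for p in pairs])
        y = np.stack([p[1] for p in pairs])
    model.set_params(
        learning_rate=cfg.learning_rate,
        max_epochs=cfg.max_epochs,
        early_stop_patience=cfg.early_stop_patience,
        checkpoint_every=cfg.checkpoint_every,
        batch_size=cfg.batch_size,
        duplication=cfg.duplication_factor,
        alpha=cfg.alpha,
        random_state=cfg.seed,
        steps_per_epoch=cfg.steps_per_epoch,
    )
    model.fit(X, y)
    return model, model.history_
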