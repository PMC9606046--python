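"""Training, prediction and cross-validation for mu-map enhancement.

The estimator learns a mapping from joint-reconstruction (MLACF) mu-maps to
reference mu-maps from paired volumes. Each input volume is z-scored (the
same stats are applied to its paired target so the mapping lives in the
input's normalised space and can be inverted at prediction time); training
samples paired patches preferentially from the body and optionally augments
them with shared geometric zoom/rotation; prediction tiles the full volume
with overlapping patches and Hann blending, then denormalises and clamps at
zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from ..core import ConfigurationError, ValidationError, VoxelVolume, substream
from .net import LOSSES, Adam, NetConfig, UNet
from .patches import (AugmentRanges, augment, blend_window, denormalize,
                      normalize, sample_patches, tile_starts)


@dataclass(frozen=True)
class TrainConfig:
    loss: str = "mae"
    lr: float = 1e-3
    epochs: int = 60
    batch_size: int = 8
    patches_per_volume: int = 8
    augment: AugmentRanges = AugmentRanges()
    augment_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.loss not in LOSSES:
            raise ValidationError(f"unknown loss {self.loss!r}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")


class UNetEnhancer(BaseEstimator):
    """Patch-based mu-map enhancement network (sklearn-style estimator).

    Parameters mirror :class:`NetConfig` and :class:`TrainConfig`; fitted
    state lives in ``net_`` and ``loss_curve_``.
    """

    def __init__(self, levels: int = 5, base_channels: int = 16,
                 patch_size: int = 64, ndim: int = 2, loss: str = "mae",
                 lr: float = 1e-3, epochs: int = 60, batch_size: int = 8,
                 patches_per_volume: int = 8, augment_scale: float = 0.2,
                 augment_rotation_deg: float = 10.0,
                 augment_prob: float = 0.5, seed: int = 0):
        self.levels = levels
        self.base_channels = base_channels
        self.patch_size = patch_size
        self.ndim = ndim
        self.loss = loss
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.patches_per_volume = patches_per_volume
        self.augment_scale = augment_scale
        self.augment_rotation_deg = augment_rotation_deg
        self.augment_prob = augment_prob
        self.seed = seed

    # ------------------------------------------------------------------
    def _net_config(self) -> NetConfig:
        return NetConfig(levels=self.levels, base_channels=self.base_channels,
                         patch_size=self.patch_size, ndim=self.ndim)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            loss=self.loss, lr=self.lr, epochs=self.epochs,
            batch_size=self.batch_size,
            patches_per_volume=self.patches_per_volume,
            augment=AugmentRanges(self.augment_scale,
                                  self.augment_rotation_deg),
            augment_prob=self.augment_prob, seed=self.seed)

    @staticmethod
    def _values(v) -> np.ndarray:
        return v.values if isinstance(v, VoxelVolume) else np.asarray(v, float)

    def fit(self, inputs: Sequence, targets: Sequence) -> "UNetEnhancer":
        """Train on paired volumes (lists of VoxelVolume or arrays)."""
        if len(inputs) != len(targets) or len(inputs) == 0:
            raise ValidationError("need equal, non-empty input/target lists")
        net_cfg = self._net_config()
        tr = self._train_config()
        rng = substream(tr.seed, "train")

        # per-volume normalisation; target shares the input's stats
        pairs = []
        for iv, tv in zip(inputs, targets):
            x = self._values(iv)
            y = self._values(tv)
            if x.ndim != net_cfg.ndim:
                raise ValidationError("volume dimensionality != network ndim")
            xn, stats = normalize(x)
            yn = (y - stats.mean) / stats.std
            pairs.append((xn, yn))

        net = UNet(net_cfg, seed=int(rng.integers(2 ** 31)))
        opt = Adam(net.params, lr=tr.lr)
        loss_fn = LOSSES[tr.loss]
        loss_curve: List[float] = []
        for epoch in range(tr.epochs):
            xs, ys = [], []
            for vol_idx, (xn, yn) in enumerate(pairs):
                px, py = sample_patches(
                    xn, yn, net_cfg.patch_size, tr.patches_per_volume,
                    seed=int(rng.integers(2 ** 31)))
                for a, b in zip(px, py):
                    if (tr.augment.scale or tr.augment.rotation_deg) and \
                            rng.uniform() < tr.augment_prob:
                        a, b = augment(a, b, tr.augment,
                                       seed=int(rng.integers(2 ** 31)),
                                       order=1)
                    xs.append(a)
                    ys.append(b)
            xs = np.stack(xs)[:, None]
            ys = np.stack(ys)[:, None]
            order = rng.permutation(len(xs))
            epoch_loss, n_batches = 0.0, 0
            for lo in range(0, len(xs), tr.batch_size):
                idx = order[lo:lo + tr.batch_size]
                pred = net.forward(xs[idx])
                loss, dloss = loss_fn(pred, ys[idx])
                if not np.isfinite(loss):
                    raise ValidationError(
                        f"training diverged at epoch {epoch} (loss={loss})")
                net.backward(dloss)
                opt.step(net.grads)
                epoch_loss += loss
                n_batches += 1
            loss_curve.append(epoch_loss / n_batches)

        self.net_ = net
        self.loss_curve_ = loss_curve
        return self

    # ------------------------------------------------------------------
    def predict(self, volume, stride: Optional[int] = None) -> VoxelVolume:
        """Enhance a full mu-map via overlapping-patch tiling.

        ``stride`` sets the tiling grid spacing (default: half a patch);
        overlapping predictions are blended with a Hann window.
        """
        if not hasattr(self, "net_"):
            raise ValidationError("estimator is not fitted")
        vol = volume if isinstance(volume, VoxelVolume) else None
        x = self._values(volume)
        cfg = self.net_.cfg
        if x.ndim != cfg.ndim:
            raise ValidationError("volume dimensionality != network ndim")
        xn, stats = normalize(x)

        ps = cfg.patch_size
        pad = [(0, max(0, ps - s)) for s in xn.shape]
        xp = np.pad(xn, pad, mode="reflect")
        stride = stride or ps // 2
        starts = [tile_starts(s, ps, stride) for s in xp.shape]
        win = blend_window(ps, cfg.ndim)
        acc = np.zeros_like(xp)
        wacc = np.zeros_like(xp)
        import itertools

        for corner in itertools.product(*starts):
            sl = tuple(slice(c, c + ps) for c in corner)
            patch = xp[sl]
            out = self.net_.forward(patch[None, None])[0, 0]
            acc[sl] += out * win
            wacc[sl] += win
        merged = acc / wacc
        unpad = tuple(slice(0, s) for s in xn.shape)
        result = np.clip(denormalize(merged[unpad], stats), 0.0, None)
        if vol is not None:
            return VoxelVolume(result, vol.voxel_size_mm, "mu_map", 511.0)
        return VoxelVolume(result, 1.65, "mu_map", 511.0)

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        if not hasattr(self, "net_"):
            raise ValidationError("estimator is not fitted")
        meta = {"params": self.get_params(),
                "loss_curve": list(self.loss_curve_)}
        arrays = {f"p{i}": a for i, a in enumerate(self.net_.state_arrays())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "UNetEnhancer":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            arrays = [z[f"p{i}"] for i in range(len(z.files) - 1)]
        est = cls(**meta["params"])
        est.net_ = UNet(est._net_config(), seed=0)
        est.net_.load_state(arrays)
        est.loss_curve_ = meta["loss_curve"]
        return est


# ---------------------------------------------------------------- folds

@dataclass
class FoldPlan:
    """k-fold split of subject ids with disjoint test sets."""

    subject_ids: List
    folds: List[Tuple[List, List]]  # (train_ids, test_ids) per fold

    def validate(self) -> None:
        all_ids = set(self.subject_ids)
        seen = []
        for train, test in self.folds:
            if set(train) & set(test):
                raise ValidationError("train/test overlap within a fold")
            if set(train) | set(test) != all_ids:
                raise ValidationError("fold does not cover all subjects")
            seen.extend(test)
        if sorted(seen) != sorted(self.subject_ids):
            raise ValidationError("test sets do not partition the subjects")


def crossval(subject_ids: Sequence, k: int = 5, seed: int = 0) -> FoldPlan:
    """As-equal-as-possible k-fold plan with disjoint test sets."""
    ids = list(subject_ids)
    if k > len(ids):
        raise ConfigurationError(f"k={k} exceeds {len(ids)} subjects")
    rng = substream(seed, "crossval")
    order = [ids[i] for i in rng.permutation(len(ids))]
    folds = []
    sizes = np.full(k, len(ids) // k)
    sizes[: len(ids) % k] += 1
    pos = 0
    for s in sizes:
        test = order[pos:pos + s]
        train = [i for i in order if i not in test]
        folds.append((train, test))
        pos += s
    plan = FoldPlan(ids, folds)
    plan.validate()
    return plan


def run_crossval(inputs: Dict, targets: Dict, plan: FoldPlan,
                 estimator_factory, metric) -> List[Dict]:
    """Train per fold on training subjects only; evaluate on test subjects.

    ``estimator_factory(fold_index)`` returns a fresh unfitted estimator;
    ``metric(pred_volume, target_volume)`` returns a float (e.g. body rMAE).
    Returns one record per fold with per-subject before/after metrics.
    """
    records = []
    for f, (train, test) in enumerate(plan.folds):
        est = estimator_factory(f)
        est.fit([inputs[i] for i in train], [targets[i] for i in train])
        fold = {"fold": f, "train_ids": list(train), "test_ids": list(test),
                "input_metric": {}, "enhanced_metric": {}}
        for sid in test:
            pred = est.predict(inputs[sid])
            fold["input_metric"][sid] = float(metric(inputs[sid], targets[sid]))
            fold["enhanced_metric"][sid] = float(metric(pred, targets[sid]))
        fold["estimator"] = est
        records.append(fold)
    return records
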