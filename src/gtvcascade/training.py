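"""Training recipe: augmentation, CE+Dice loss, SGD with poly learning-rate
decay and gradient accumulation, cross-validation and fine-tuning.

Both stage networks are trained independently with the same optimizer
settings (SGD, momentum 0.99, batch size 1, parameters updated every 2
samples by gradient accumulation) under the poly schedule
``lr = lr_ini * (1 - epoch/epoch_max)^0.9``.  Stage 1 draws uniformly random
sliding-window patches; stage 2 draws ground-truth-centred crops with +-3
voxel jitter.  Fine-tuning resumes from a checkpoint for 60 epochs at
lr_ini = 0.001 on a seeded 70/30 split of the new cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cascade import CascadeModel, sample_patch_stage1, sample_patch_stage2
from .config import AugmentSpec, PipelineConfig, TrainSpec
from .grids import BinaryMask, ImageVolume
from .network import SegNetwork, build_network, initialize
from .preprocessing import (compute_foreground_stats, normalize,
                            preprocess_case)

__all__ = ["augment", "loss", "loss_and_grad", "lr_at", "SGD", "TrainResult",
           "train_stage", "train_cascade", "fold_assignment", "crossval",
           "fine_tune", "FineTuneResult"]


# ---------------------------------------------------------------------------
# augmentation

def _spatial_transform(patch, label, transform, order_img):
    out_p = np.stack([transform(patch[c], order_img) for c in range(patch.shape[0])])
    out_l = transform(label, 0)
    return out_p.astype(np.float32), out_l


def augment(patch: np.ndarray, label: np.ndarray, spec: AugmentSpec,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random augmentation of an aligned (C, X, Y, Z) patch / (X, Y, Z) label.

    Order: scale -> elastic -> rotate -> flip -> noise; each transform fires
    independently with probability ``gate_p``.  Spatial transforms use
    (linear) spline interpolation for the image and nearest-neighbour for
    the label; noise touches the image only.
    """
    patch = np.asarray(patch, dtype=np.float32)
    label = np.asarray(label, dtype=np.float32)

    if rng.random() < spec.gate_p:  # random scaling about the patch centre
        f = rng.uniform(*spec.scale_range)
        center = (np.asarray(patch.shape[1:]) - 1) / 2.0
        matrix = np.eye(3) / f
        offset = center - matrix @ center

        def tf(a, order):
            return ndimage.affine_transform(a, matrix, offset=offset, order=order,
                                            mode="nearest")
        patch, label = _spatial_transform(patch, label, tf, 1)

    if rng.random() < spec.gate_p:  # random elastic deformation
        shape = patch.shape[1:]
        disp = [ndimage.gaussian_filter(rng.uniform(-1, 1, shape), spec.elastic_sigma)
                * spec.elastic_alpha for _ in range(3)]
        coords = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
        coords = [c + d for c, d in zip(coords, disp)]

        def tf(a, order):
            return ndimage.map_coordinates(a, coords, order=order, mode="nearest")
        patch, label = _spatial_transform(patch, label, tf, 1)

    if rng.random() < spec.gate_p:  # random in-plane rotation
        angle = rng.uniform(*spec.rotation_deg)

        def tf(a, order):
            return ndimage.rotate(a, angle, axes=(0, 1), reshape=False, order=order,
                                  mode="nearest")
        patch, label = _spatial_transform(patch, label, tf, 1)

    if spec.flip and rng.random() < spec.gate_p:  # random flips
        for ax in range(3):
            if rng.random() < 0.5:
                patch = np.flip(patch, axis=ax + 1)
                label = np.flip(label, axis=ax)
        patch, label = np.ascontiguousarray(patch), np.ascontiguousarray(label)

    if rng.random() < spec.gate_p:  # random noise, image only
        if rng.random() < 0.5:
            sigma = rng.uniform(0.0, spec.noise_gaussian_sigma_max)
            patch = patch + rng.normal(0.0, sigma, patch.shape).astype(np.float32)
        else:
            lim = spec.noise_uniform_limit
            patch = patch + rng.uniform(-lim, lim, patch.shape).astype(np.float32)

    return patch.astype(np.float32), (label > 0.5).astype(np.float32)


# ---------------------------------------------------------------------------
# loss and schedule

def loss(pred: np.ndarray, label: np.ndarray, eps: float = 1e-5) -> float:
    """Binary cross-entropy plus soft-Dice loss (1 - Dice), summed 1:1.

    ``pred`` holds probabilities in (0, 1); BCE is averaged over voxels and
    the Dice term uses smoothing ``eps`` in numerator and denominator.
    """
    pred = np.asarray(pred, dtype=np.float64)
    label = np.asarray(label, dtype=np.float64)
    if pred.shape != label.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {label.shape}")
    p = np.clip(pred, 1e-12, 1 - 1e-12)
    bce = -np.mean(label * np.log(p) + (1 - label) * np.log(1 - p))
    inter = float((p * label).sum())
    dice = (2 * inter + eps) / (p.sum() + label.sum() + eps)
    return float(bce + (1.0 - dice))


def _sigmoid64(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def loss_and_grad(logits: np.ndarray, label: np.ndarray,
                  eps: float = 1e-5) -> tuple[float, np.ndarray]:
    """(loss value, dLoss/dlogits) for the CE+Dice loss, computed from
    pre-sigmoid scores for numerical stability."""
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(label, dtype=np.float64)
    if z.shape[0] == 1 and y.ndim == 3:
        y = y[None]
    if z.shape != y.shape:
        raise ValueError(f"shape mismatch: {z.shape} vs {y.shape}")
    n = z.size
    p = _sigmoid64(z)
    # stable BCE from logits: max(z,0) - z*y + log(1+exp(-|z|))
    bce = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    sp, sy, spy = p.sum(), y.sum(), (p * y).sum()
    denom = sp + sy + eps
    dice = (2 * spy + eps) / denom
    total = bce + (1.0 - dice)
    ddice_dp = (2 * y * denom - (2 * spy + eps)) / denom**2
    dz = (p - y) / n - ddice_dp * p * (1 - p)
    return total, dz.astype(np.float32)


def lr_at(epoch: int, spec: TrainSpec, epoch_max: int | None = None,
          lr_ini: float | None = None) -> float:
    """Poly schedule: ``lr_ini * (1 - epoch/epoch_max)^0.9``."""
    epoch_max = spec.epochs if epoch_max is None else epoch_max
    lr_ini = spec.lr_ini if lr_ini is None else lr_ini
    if not 0 <= epoch <= epoch_max:
        raise ValueError(f"epoch {epoch} outside [0, {epoch_max}]")
    return float(lr_ini * (1.0 - epoch / epoch_max) ** spec.poly_exponent)


# ---------------------------------------------------------------------------
# optimizer and loops

class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list, momentum: float = 0.99):
        self.params = params
        self.momentum = momentum
        self.velocity = {name: np.zeros_like(p.data) for name, p in params}

    def step(self, lr: float) -> None:
        for name, p in self.params:
            v = self.velocity[name]
            v *= self.momentum
            v += p.grad
            p.data -= (lr * v).astype(p.data.dtype)


Case = tuple[ImageVolume, BinaryMask]


@dataclass
class TrainResult:
    net: SegNetwork
    history: list[float] = field(default_factory=list)
    seed: int = 0


def _sample(stage: int, case: Case, cfg: PipelineConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    vol, gt = case
    if stage == 1:
        return sample_patch_stage1(vol, gt, cfg.stage1_patch, rng)
    return sample_patch_stage2(vol, gt, cfg.stage2_patch, cfg.jitter_range, rng)


def train_stage(net: SegNetwork, cases: list[Case], cfg: PipelineConfig,
                stage: int, seed: int | None = None,
                epochs: int | None = None, lr_ini: float | None = None,
                use_augment: bool = True) -> TrainResult:
    """Train one stage network on preprocessed, normalized cases.

    Per epoch, ``patches_per_case * len(cases)`` patches are drawn with the
    stage-appropriate sampler; gradients are averaged over ``accumulation``
    consecutive samples per optimizer step; the learning rate follows the
    poly schedule.  A non-finite loss aborts with a diagnostic.
    """
    if not cases:
        raise ValueError("need at least one training case")
    ts = cfg.train
    seed = ts.seed if seed is None else seed
    epochs = ts.epochs if epochs is None else epochs
    rng = np.random.default_rng(seed)
    net.set_dropout_rng(rng)
    opt = SGD(net.parameters(), ts.momentum)
    n_per_epoch = max(ts.patches_per_case * len(cases), ts.accumulation)
    history = []
    for epoch in range(epochs):
        lr = lr_at(epoch, ts, epoch_max=epochs, lr_ini=lr_ini)
        losses = []
        since_step = 0
        for i in range(n_per_epoch):
            case = cases[int(rng.integers(len(cases)))]
            patch, label = _sample(stage, case, cfg, rng)
            if use_augment:
                patch, label = augment(patch, label, ts.augment, rng)
            logits = net.forward_logits(patch, train=True)
            value, dz = loss_and_grad(logits, label, ts.dice_eps)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"divergent loss at epoch {epoch}, sample {i}: {value}")
            losses.append(value)
            net.backward(dz / ts.accumulation)
            since_step += 1
            if since_step == ts.accumulation or i == n_per_epoch - 1:
                opt.step(lr)
                net.zero_grad()
                since_step = 0
        history.append(float(np.mean(losses)))
    return TrainResult(net=net, history=history, seed=seed)


def train_cascade(raw_cases: list[Case], cfg: PipelineConfig,
                  seed: int | None = None, epochs: int | None = None,
                  use_augment: bool = True) -> CascadeModel:
    """Preprocess a training cohort, freeze pooled foreground statistics,
    and train both stage networks independently."""
    seed = cfg.seed if seed is None else seed
    prepped = []
    for vol, gt in raw_cases:
        v, body, g = preprocess_case(vol, cfg.target_spacing, cfg.hu_threshold, gt=gt)
        prepped.append((v, body, g))
    stats = compute_foreground_stats([p[0] for p in prepped], [p[1] for p in prepped])
    cases = [(normalize(v, stats), g) for v, _, g in prepped]

    log = {"seed": int(seed), "n_train": len(cases)}
    nets = {}
    for stage, spec in ((1, cfg.stage1_network), (2, cfg.stage2_network)):
        net = initialize(build_network(spec), seed=seed + stage)
        res = train_stage(net, cases, cfg, stage, seed=seed + 10 * stage,
                          epochs=epochs, use_augment=use_augment)
        nets[stage] = res.net
        log[f"stage{stage}_loss"] = res.history
    return CascadeModel(stage1=nets[1], stage2=nets[2], stats=stats,
                        config=cfg, log=log)


# ---------------------------------------------------------------------------
# cross-validation and fine-tuning

def fold_assignment(n: int, k: int, seed: int) -> np.ndarray:
    """Balanced random partition: fold index per case, sizes differing <= 1."""
    if k > n:
        raise ValueError(f"cannot split {n} cases into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    folds = np.empty(n, dtype=int)
    start = 0
    for f, s in enumerate(sizes):
        folds[perm[start:start + s]] = f
        start += s
    return folds


def crossval(cases: list, k: int, seed: int, runner) -> tuple[np.ndarray, list]:
    """k-fold cross-validation: every case is tested exactly once.

    ``runner(train_cases, test_cases, fold)`` performs one round (training
    included, so per-fold statistics never see test cases) and returns its
    per-case results; the pooled list preserves case order within folds.
    """
    folds = fold_assignment(len(cases), k, seed)
    pooled = []
    for f in range(k):
        train = [c for c, g in zip(cases, folds) if g != f]
        test = [c for c, g in zip(cases, folds) if g == f]
        pooled.extend(runner(train, test, f))
    return folds, pooled


@dataclass
class FineTuneResult:
    net: SegNetwork
    train_indices: np.ndarray
    test_indices: np.ndarray
    history: list[float]


def fine_tune(net: SegNetwork, cases: list[Case], cfg: PipelineConfig,
              stage: int, seed: int, epochs: int | None = None,
              use_augment: bool = True) -> FineTuneResult:
    """Transfer learning: resume from trained weights on a new cohort.

    The cohort is split (seeded) into fine-tuning and held-out fractions
    (default 70/30); training resumes at the reduced fine-tuning learning
    rate for the configured number of epochs (0 = evaluation-only, weights
    untouched)."""
    ts = cfg.train
    epochs = ts.finetune_epochs if epochs is None else epochs
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(cases))
    n_train = int(round(ts.finetune_train_fraction * len(cases)))
    train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    history: list[float] = []
    if epochs > 0:
        res = train_stage(net, [cases[i] for i in train_idx], cfg, stage,
                          seed=seed, epochs=epochs, lr_ini=ts.finetune_lr_ini,
                          use_augment=use_augment)
        history = res.history
    return FineTuneResult(net=net, train_indices=train_idx,
                          test_indices=test_idx, history=history)
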