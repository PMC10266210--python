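"""Two-step training: pretext pre-training then MMD-regularized adaptation.

Step 1 (:func:`pretrain`) jointly trains the shared feature extractor and a
domain discriminator on the self-supervised pretext task of telling source
(label 0) from target (label 1) segments, by minimizing binary
cross-entropy.  Step 2 (:func:`adapt`) warm-starts a domain-specific
extractor from the pretrained weights and minimizes

    L = MSE(source predictions, source labels) + alpha * MMD(align_s, align_t)

over paired source/target batches, so the regression is fitted on the
labeled source domain while the alignment projections of the two domains
are pulled together.  Target labels are never read during either step;
:func:`fine_tune` optionally unlocks a stated fraction of them for the
semi-supervised experiment.

Optimization is SGD with momentum 0.9 and weight decay 0.001 under a
warm-up-plus-cosine learning-rate schedule (linear ramp over the first 10
epochs, then a cosine between 0.05 and 0.001 with a 100-epoch half-period).
Random segment offsets are re-drawn every epoch when recordings (rather
than fixed segments) are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .evaluate import classification_metrics, discretize, rmse
from .losses import LossConfig, mmd_loss, mse_loss, pretext_ce_loss
from .model import FatigueNet, ModelSpec, build_model
from .nn.autograd import Tensor, no_grad
from .preprocess import normalize, random_offset_segments, rms_normalize
from .types import EEGRecording, Segment, stack_labels, stack_windows

__all__ = [
    "TrainSpec",
    "lr_schedule",
    "SGD",
    "pretrain",
    "adapt",
    "fine_tune",
    "predict",
    "cross_validate",
    "make_folds",
]

ABLATIONS = ("no_attention", "no_gru", "no_pretraining")


@dataclass
class TrainSpec:
    """Optimization hyperparameters; defaults are the full-scale constants
    (epoch counts are configurable and default to desk scale)."""

    epochs: int = 30
    batch: int = 32
    lr_max: float = 0.05
    lr_min: float = 0.001
    warmup_epochs: int = 10
    cosine_half_period_epochs: int = 100
    momentum: float = 0.9
    weight_decay: float = 0.001
    alpha: float = 0.3
    seed: int = 0
    folds: int = 5
    runs: int = 10
    ablation: frozenset = frozenset()
    label_fraction: float = 0.0
    segment_len: int = 1024
    holdout_fraction: float = 0.25
    normalization: str = "rms"  # "rms" (keep channel-gain pattern) | "zscore"

    def __post_init__(self) -> None:
        if not (0 < self.lr_min <= self.lr_max):
            raise ValueError("require 0 < lr_min <= lr_max")
        if self.batch < 1:
            raise ValueError("batch must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not (0.0 <= self.label_fraction <= 1.0):
            raise ValueError("label_fraction must lie in [0, 1]")
        if self.normalization not in ("rms", "zscore"):
            raise ValueError("normalization must be 'rms' or 'zscore'")
        self.ablation = frozenset(self.ablation)
        unknown = self.ablation - set(ABLATIONS)
        if unknown:
            raise ValueError(f"unknown ablation switches: {sorted(unknown)}")

    def loss_config(self) -> LossConfig:
        return LossConfig(alpha=self.alpha)


def lr_schedule(epoch: int, spec: TrainSpec) -> float:
    """Warm-up-plus-cosine learning rate for a (0-based) epoch index.

    Epochs 0..warmup-1 ramp linearly from lr_min to the cosine curve's
    starting value (lr_max); from the warm-up epoch on, the rate follows
    lr_min + (lr_max - lr_min) * (1 + cos(pi (epoch - warmup)/half)) / 2.
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    w = spec.warmup_epochs
    if epoch < w:
        return spec.lr_min + (spec.lr_max - spec.lr_min) * epoch / w
    phase = np.pi * (epoch - w) / spec.cosine_half_period_epochs
    return spec.lr_min + (spec.lr_max - spec.lr_min) * (1 + np.cos(phase)) / 2


class SGD:
    """Stochastic gradient descent with classical momentum, L2 weight decay
    (decay added to the gradient, the standard SGD formulation) and global
    gradient-norm clipping for stability with small, noisy batches."""

    def __init__(self, params: list[Tensor], momentum: float = 0.9,
                 weight_decay: float = 0.0, clip_norm: float = 5.0):
        self.params = params
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad**2).sum())
                                for p in self.params if p.grad is not None))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def _draw_segments(items, T: int, rng: np.random.Generator,
                   norm: str = "rms") -> list[Segment]:
    """Fresh normalized segments: recordings get a new random offset each
    call; pre-cut segments pass through normalized."""
    if not items:
        raise ValueError("empty domain: no recordings or segments supplied")
    segs: list[Segment] = []
    for item in items:
        if isinstance(item, EEGRecording):
            segs.extend(random_offset_segments(item, T=T, rng=rng))
        elif isinstance(item, Segment):
            segs.append(item)
        else:
            raise TypeError(f"expected EEGRecording or Segment, got {type(item)!r}")
    fn = rms_normalize if norm == "rms" else normalize
    return [fn(s) for s in segs]


def _holdout_split(items, fraction: float):
    n_hold = max(1, int(round(len(items) * fraction))) if len(items) > 1 else 0
    if n_hold == 0:
        return list(items), list(items)  # too small to hold out; report on train
    return list(items[:-n_hold]), list(items[-n_hold:])


def _apply_ablation(model_spec: ModelSpec, train_spec: TrainSpec) -> ModelSpec:
    spec = model_spec
    if "no_attention" in train_spec.ablation:
        spec = replace(spec, use_attention=False)
    if "no_gru" in train_spec.ablation:
        spec = replace(spec, use_gru=False)
    return spec


# ---------------------------------------------------------------------------
# step 1: pretext pre-training
# ---------------------------------------------------------------------------

def pretrain(source, target, model_spec: ModelSpec, train_spec: TrainSpec):
    """Train extractor + domain discriminator on the pretext task.

    Returns ``(model, report)``; the report has per-epoch training loss and
    held-out discrimination accuracy.
    """
    model_spec = _apply_ablation(model_spec, train_spec)
    rng = np.random.default_rng(train_spec.seed)
    model = build_model(model_spec, seed=int(rng.integers(2**31)))
    opt = SGD(model.parameters(), train_spec.momentum, train_spec.weight_decay)

    src_train, src_hold = _holdout_split(source, train_spec.holdout_fraction)
    tgt_train, tgt_hold = _holdout_split(target, train_spec.holdout_fraction)
    hold_rng = np.random.default_rng(train_spec.seed + 1)
    hold_segs = (
        _draw_segments(src_hold, train_spec.segment_len, hold_rng,
                       train_spec.normalization)
        + _draw_segments(tgt_hold, train_spec.segment_len, hold_rng,
                         train_spec.normalization)
    )
    hold_x = stack_windows(hold_segs)
    hold_y = np.array([1.0 if s.domain == "target" else 0.0 for s in hold_segs])

    report = {"epoch": [], "loss": [], "holdout_accuracy": []}
    for epoch in range(train_spec.epochs):
        lr = lr_schedule(epoch, train_spec)
        segs = (
            _draw_segments(src_train, train_spec.segment_len, rng,
                           train_spec.normalization)
            + _draw_segments(tgt_train, train_spec.segment_len, rng,
                             train_spec.normalization)
        )
        y = np.array([1.0 if s.domain == "target" else 0.0 for s in segs])
        order = rng.permutation(len(segs))
        model.train()
        losses = []
        for lo in range(0, len(order), train_spec.batch):
            idx = order[lo : lo + train_spec.batch]
            if idx.size < 2:
                continue
            x = stack_windows([segs[i] for i in idx])
            feats = model.features(x)
            p = model.discriminate(feats)
            loss = pretext_ce_loss(p, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step(lr)
            losses.append(loss.item())
        acc = _discrimination_accuracy(model, hold_x, hold_y)
        report["epoch"].append(epoch)
        report["loss"].append(float(np.mean(losses)))
        report["holdout_accuracy"].append(acc)
    return model, report


def _discrimination_accuracy(model: FatigueNet, x: np.ndarray, y: np.ndarray,
                             batch: int = 64) -> float:
    model.eval()
    preds = []
    with no_grad():
        for lo in range(0, x.shape[0], batch):
            p = model.discriminate(model.features(x[lo : lo + batch]))
            preds.append(p.data)
    p = np.concatenate(preds)
    return float(np.mean((p >= 0.5) == (y == 1.0)))


# ---------------------------------------------------------------------------
# step 2: domain-specific adaptation
# ---------------------------------------------------------------------------

def adapt(pretrained: FatigueNet | None, labeled_source, unlabeled_target,
          model_spec: ModelSpec, train_spec: TrainSpec):
    """Fit the regression under the MMD-regularized objective.

    The domain-specific extractor is warm-started from the pretrained
    shared extractor unless ``no_pretraining`` is ablated (then random
    init).  Target labels are never read; segments carrying evaluation-only
    labels contribute only to the MMD term, except those whose labels have
    been explicitly unlocked for fine-tuning.
    """
    model_spec = _apply_ablation(model_spec, train_spec)
    rng = np.random.default_rng(train_spec.seed + 2)
    model = build_model(model_spec, seed=int(rng.integers(2**31)))
    if pretrained is not None and "no_pretraining" not in train_spec.ablation:
        model.extractor.load_state_dict(pretrained.extractor.state_dict())
    opt = SGD(model.parameters(), train_spec.momentum, train_spec.weight_decay)
    cfg = train_spec.loss_config()

    report = {"epoch": [], "mse": [], "mmd": [], "total": [], "lr": []}
    for epoch in range(train_spec.epochs):
        lr = lr_schedule(epoch, train_spec)
        src = _draw_segments(labeled_source, train_spec.segment_len, rng,
                             train_spec.normalization)
        tgt = _draw_segments(unlabeled_target, train_spec.segment_len, rng,
                             train_spec.normalization)
        y_src = stack_labels(src, training=True)
        src_order = rng.permutation(len(src))
        tgt_order = rng.permutation(len(tgt))
        n_batches = min(len(src_order), len(tgt_order)) // train_spec.batch
        n_batches = max(n_batches, 1)
        model.train()
        ep_mse, ep_mmd, ep_tot = [], [], []
        for b in range(n_batches):
            si = src_order[b * train_spec.batch : (b + 1) * train_spec.batch]
            ti = tgt_order[b * train_spec.batch : (b + 1) * train_spec.batch]
            if si.size < 2 or ti.size < 2:
                continue
            xs = stack_windows([src[i] for i in si])
            xt = stack_windows([tgt[i] for i in ti])
            fs = model.features(xs)
            ft = model.features(xt)
            pred = model.regress(fs)
            sup_loss = mse_loss(pred, y_src[si])
            # fine-tuning: unlocked target labels join the supervised term
            unlocked = [j for j in ti if not tgt[j].label_eval_only]
            if unlocked:
                xu = stack_windows([tgt[j] for j in unlocked])
                yu = stack_labels([tgt[j] for j in unlocked], training=True)
                sup_loss = sup_loss + mse_loss(model.regress(model.features(xu)), yu)
            mmd_total = None
            for hs, ht in zip(model.align(fs), model.align(ft)):
                term = mmd_loss(hs, ht, cfg)
                mmd_total = term if mmd_total is None else mmd_total + term
            loss = sup_loss + cfg.alpha * mmd_total
            opt.zero_grad()
            loss.backward()
            opt.step(lr)
            ep_mse.append(sup_loss.item())
            ep_mmd.append(mmd_total.item())
            ep_tot.append(loss.item())
        report["epoch"].append(epoch)
        report["mse"].append(float(np.mean(ep_mse)))
        report["mmd"].append(float(np.mean(ep_mmd)))
        report["total"].append(float(np.mean(ep_tot)))
        report["lr"].append(lr)
    return model, report


def fine_tune(model: FatigueNet, labeled_source, target, fraction: float,
              train_spec: TrainSpec, model_spec: ModelSpec | None = None):
    """Continue adaptation with ``round(fraction * N_t)`` target segments'
    labels unlocked (sampled with the run seed); the rest stay unlabeled in
    the MMD term."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(train_spec.seed + 3)
    tgt_segs = _materialize_segments(target, train_spec.segment_len, rng)
    n_unlock = int(round(fraction * len(tgt_segs)))
    unlock_idx = set(rng.choice(len(tgt_segs), size=n_unlock, replace=False).tolist())
    unlocked = [
        replace(s, label_eval_only=False) if i in unlock_idx else s
        for i, s in enumerate(tgt_segs)
    ]
    spec = model_spec or model.spec
    tuned, report = adapt(model, labeled_source, unlocked, spec, train_spec)
    report["n_unlocked"] = n_unlock
    return tuned, report


def _materialize_segments(items, T: int, rng: np.random.Generator) -> list[Segment]:
    out: list[Segment] = []
    for item in items:
        if isinstance(item, EEGRecording):
            out.extend(random_offset_segments(item, T=T, rng=rng))
        else:
            out.append(item)
    return out


# ---------------------------------------------------------------------------
# inference and cross-validation
# ---------------------------------------------------------------------------

def predict(model: FatigueNet, items, segment_len: int = 1024,
            seed: int = 0, batch: int = 64, normalization: str = "rms"):
    """Predicted (clipped) index and true index for a list of recordings or
    segments; truth comes from assessment labels."""
    rng = np.random.default_rng(seed)
    fn = rms_normalize if normalization == "rms" else normalize
    segs = [fn(s) for s in _materialize_segments(items, segment_len, rng)]
    x = stack_windows(segs)
    truth = np.array([s.label for s in segs])
    model.eval()
    preds = []
    with no_grad():
        for lo in range(0, x.shape[0], batch):
            p = model.regress(model.features(x[lo : lo + batch]))
            preds.append(p.data)
    pred = np.clip(np.concatenate(preds), 0.0, 1.0)
    return pred, truth


def make_folds(n_items: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition of item indices into ``folds`` near-equal folds."""
    if n_items < folds:
        raise ValueError(f"cannot split {n_items} recordings into {folds} folds")
    perm = rng.permutation(n_items)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def cross_validate(source, target, model_spec: ModelSpec,
                   train_spec: TrainSpec) -> dict:
    """Recording-level k-fold cross-validation repeated over seeded runs.

    Folds split the target recordings (never individual segments, which
    would leak windows of one recording across folds); each run re-seeds
    data sampling and training with ``base_seed + run``.  Returns mean and
    sd of accuracy and RMSE plus the per-fold reports.
    """
    if len(target) < train_spec.folds:
        raise ValueError("need at least `folds` target recordings")
    results = {"accuracy": [], "rmse": [], "per_fold": []}
    for run in range(train_spec.runs):
        run_seed = train_spec.seed + run
        rng = np.random.default_rng(run_seed)
        folds = make_folds(len(target), train_spec.folds, rng)
        for f, test_idx in enumerate(folds):
            test_set = set(test_idx.tolist())
            tgt_train = [t for i, t in enumerate(target) if i not in test_set]
            tgt_test = [t for i, t in enumerate(target) if i in test_set]
            spec_f = replace(train_spec, seed=run_seed * 31 + f)
            pre, _ = pretrain(source, tgt_train, model_spec, spec_f)
            mdl, _ = adapt(pre, source, tgt_train, model_spec, spec_f)
            pred, truth = predict(mdl, tgt_test, spec_f.segment_len,
                                  seed=spec_f.seed)
            rep = classification_metrics(discretize(pred), discretize(truth),
                                         pred_index=pred, true_index=truth)
            results["accuracy"].append(rep.accuracy)
            results["rmse"].append(rep.rmse)
            results["per_fold"].append({"run": run, "fold": f,
                                        "metrics": rep.to_dict()})
    return {
        "accuracy_mean": float(np.mean(results["accuracy"])),
        "accuracy_sd": float(np.std(results["accuracy"])),
        "rmse_mean": float(np.mean(results["rmse"])),
        "rmse_sd": float(np.std(results["rmse"])),
        "n_fits": len(results["per_fold"]),
        "per_fold": results["per_fold"],
    }
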