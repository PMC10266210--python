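"""Training objectives: MMD, MSE, their weighted total, and the pretext
binary cross-entropy.

The MMD is the squared distance between kernel mean embeddings of the source
and target representation samples, estimated with the biased (V-statistic)
plug-in form

    MMD^2 = mean(K_ss) + mean(K_tt) - 2 mean(K_st).

The kernel is configurable: an RBF with the median-pairwise-distance
bandwidth heuristic (default), an RBF with fixed bandwidth, or the linear
kernel, under which MMD^2 reduces exactly to the squared difference of the
sample means.  The total adaptation loss is ``MSE + alpha * MMD`` with
``alpha = 0.3`` by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .nn.autograd import Tensor

__all__ = ["LossConfig", "mmd", "mmd_loss", "mse", "total_loss", "pretext_ce"]


@dataclass
class LossConfig:
    """``kernel="linear"`` (default) is the plug-in mean-embedding form in
    which the learned alignment projection itself plays the feature map phi;
    RBF variants (median-bandwidth or fixed sigma) are available for a
    nonparametric comparison."""

    alpha: float = 0.3
    kernel: str = "linear"  # linear | rbf_median | rbf_fixed
    sigma: float = 1.0  # bandwidth when kernel == "rbf_fixed"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.kernel not in ("rbf_median", "rbf_fixed", "linear"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.kernel == "rbf_fixed" and self.sigma <= 0:
            raise ValueError("sigma must be positive for a fixed RBF kernel")


def _pairwise_sq_dists(a: Tensor, b: Tensor) -> Tensor:
    a2 = (a * a).sum(axis=1).reshape(-1, 1)
    b2 = (b * b).sum(axis=1).reshape(1, -1)
    return a2 + b2 - 2.0 * (a @ b.transpose(1, 0))


def _median_bandwidth(xs: np.ndarray, xt: np.ndarray) -> float:
    """Median pairwise squared distance over the pooled sample (no gradient)."""
    z = np.vstack([xs, xt])
    d2 = ((z[:, None, :] - z[None, :, :]) ** 2).sum(-1)
    upper = d2[np.triu_indices_from(d2, k=1)]
    med = float(np.median(upper)) if upper.size else 1.0
    return med if med > 0 else 1.0


def mmd_loss(rep_s: Tensor, rep_t: Tensor, cfg: LossConfig | None = None) -> Tensor:
    """Differentiable biased MMD^2 between two representation batches."""
    cfg = cfg or LossConfig()
    if rep_s.shape[1] != rep_t.shape[1]:
        raise ValueError(
            f"representation dimension mismatch: {rep_s.shape[1]} vs {rep_t.shape[1]}"
        )
    if cfg.kernel == "linear":
        mu = rep_s.mean(axis=0) - rep_t.mean(axis=0)
        return (mu * mu).sum()
    if cfg.kernel == "rbf_median":
        sigma2 = _median_bandwidth(rep_s.data, rep_t.data)
    else:
        sigma2 = cfg.sigma**2
    gamma = 1.0 / (2.0 * sigma2)
    k_ss = ((_pairwise_sq_dists(rep_s, rep_s)) * (-gamma)).exp().mean()
    k_tt = ((_pairwise_sq_dists(rep_t, rep_t)) * (-gamma)).exp().mean()
    k_st = ((_pairwise_sq_dists(rep_s, rep_t)) * (-gamma)).exp().mean()
    return k_ss + k_tt - 2.0 * k_st


def mmd(rep_s, rep_t, cfg: LossConfig | None = None) -> float:
    """Biased MMD^2 between two (n x d) samples (non-negative scalar).

    Accepts a single pair of arrays or two matched lists of per-head
    representations, in which case per-head MMDs are summed.
    """
    if isinstance(rep_s, (list, tuple)):
        if len(rep_s) != len(rep_t):
            raise ValueError("mismatched numbers of representation heads")
        return float(sum(mmd(a, b, cfg) for a, b in zip(rep_s, rep_t)))
    a = np.atleast_2d(np.asarray(rep_s, dtype=float))
    b = np.atleast_2d(np.asarray(rep_t, dtype=float))
    return float(mmd_loss(Tensor(a), Tensor(b), cfg).item())


def mse(pred, truth) -> float:
    """Mean squared error (1/n) sum (pred - truth)^2."""
    p = np.asarray(pred, dtype=float).ravel()
    t = np.asarray(truth, dtype=float).ravel()
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    return float(np.mean((p - t) ** 2))


def total_loss(mse_val: float, mmd_val: float, cfg: LossConfig | None = None) -> float:
    """Adaptation objective: MSE + alpha * MMD."""
    cfg = cfg or LossConfig()
    return float(mse_val + cfg.alpha * mmd_val)


def pretext_ce(p_target, domain_labels) -> float:
    """Mean binary cross-entropy of the domain-discrimination pretext task.

    ``domain_labels`` are 0 for source and 1 for target.
    """
    p = np.asarray(p_target, dtype=float).ravel()
    y = np.asarray(domain_labels, dtype=float).ravel()
    if p.shape != y.shape:
        raise ValueError("probability/label length mismatch")
    if np.any((y != 0) & (y != 1)):
        raise ValueError("domain labels must be 0 (source) or 1 (target)")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def pretext_ce_loss(p_target: Tensor, domain_labels: np.ndarray,
                    eps: float = 1e-12) -> Tensor:
    """Differentiable binary cross-entropy on predicted P(target)."""
    y = np.asarray(domain_labels, dtype=float).ravel()
    p = p_target * (1.0 - 2.0 * eps) + eps  # keep log() away from 0
    return -(Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()).mean()


def mse_loss(pred: Tensor, truth: np.ndarray) -> Tensor:
    """Differentiable MSE against fixed targets."""
    r = pred - Tensor(np.asarray(truth, dtype=float).ravel())
    return (r * r).mean()
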