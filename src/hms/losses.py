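"""Objective components: focal-weighted BCE, co-activation penalty,
NT-Xent, geometric / distributional alignment losses, prototype loss and
the weighted composite used by the cross-modal bridge.

Every loss accepts numpy arrays or autograd Tensors and returns a scalar
Tensor; all are non-negative, zero on their perfect-alignment input, and
differentiable almost everywhere under the documented epsilon guards
(probability clamp 1e-7, norm guard 1e-12).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .nn import Tensor

__all__ = ["FocalConfig", "BridgeLossWeights", "focal_bce",
           "co_activation_penalty", "nt_xent", "pairwise_alignment_losses",
           "kl_align_loss", "mmd_loss", "coral_loss", "prototype_loss",
           "bridge_composite"]

PROB_EPS = 1e-7
NORM_EPS = 1e-12


@dataclass
class FocalConfig:
    """gamma=0, alpha=1, smoothing=0 recovers plain mean BCE."""

    alpha: float | np.ndarray = 1.0
    gamma: float = 2.0
    label_smoothing: float = 0.05

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0.0 <= self.label_smoothing < 0.5:
            raise ValueError("label_smoothing must lie in [0, 0.5)")


@dataclass
class BridgeLossWeights:
    """Weights of the seven bridge components (cycle optional, default off).

    Defaults: the contrastive term at 1.0 and the MSE term at 10.0
    dominate, with the remaining regularizers at 0.5 inside [0.1, 1.0].
    """

    mse: float = 10.0
    cos: float = 0.5
    kl: float = 0.5
    infonce: float = 1.0
    proto: float = 0.5
    mmd: float = 0.5
    coral: float = 0.5
    cycle: float = 0.0

    COMPONENTS = ("mse", "cos", "kl", "infonce", "proto", "mmd", "coral")

    def __post_init__(self):
        for name in self.COMPONENTS + ("cycle",):
            if getattr(self, name) < 0:
                raise ValueError(f"negative weight for {name}")

    def drop(self, name: str) -> "BridgeLossWeights":
        """Leave-one-out ablation: zero exactly one component weight."""
        if name not in self.COMPONENTS + ("cycle",):
            raise KeyError(f"unknown component {name!r}")
        return replace(self, **{name: 0.0})


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def focal_bce(logits, targets, cfg: FocalConfig | None = None) -> Tensor:
    """Focal-weighted binary cross-entropy over an N x C batch.

    (1/NC) sum alpha_c (1-p_t)^gamma (-log p_t) with p_t = p for y=1 and
    1-p for y=0; label smoothing maps y to y(1-eps) + eps/2 first, which
    turns each element into the corresponding mixture of the two focal
    terms.  The -log p_t terms are evaluated in log space (softplus of the
    logit), so the loss and its gradient stay finite even for saturated
    logits -- no clamping dead zone; the modulating factor uses
    probabilities clamped to [1e-7, 1-1e-7].
    """
    cfg = cfg or FocalConfig()
    logits = _t(logits)
    targets = _t(targets)
    if logits.shape != targets.shape:
        raise ValueError(f"shape mismatch {logits.shape} vs {targets.shape}")
    eps = cfg.label_smoothing
    y = targets * (1.0 - eps) + eps / 2.0
    alpha = Tensor(np.asarray(cfg.alpha, dtype=logits.dtype))
    nlog_p = (-logits).softplus()        # -log sigmoid(x)
    nlog_1p = logits.softplus()          # -log (1 - sigmoid(x))
    if cfg.gamma == 0:
        loss = alpha * (y * nlog_p + (1.0 - y) * nlog_1p)
    else:
        p = logits.sigmoid().clip(PROB_EPS, 1.0 - PROB_EPS)
        pos = (1.0 - p) ** cfg.gamma * nlog_p
        neg = p ** cfg.gamma * nlog_1p
        loss = alpha * (y * pos + (1.0 - y) * neg)
    return loss.mean()


def co_activation_penalty(p_amd, p_dr) -> Tensor:
    """Rco = E[p_AMD * p_DR]: discourages joint AMD-DR confidence.

    A soft regularizer only; strong evidence for both diseases can still
    produce simultaneous high-confidence predictions.
    """
    p_amd, p_dr = _t(p_amd), _t(p_dr)
    if p_amd.shape != p_dr.shape:
        raise ValueError("p_amd and p_dr must have equal length")
    return (p_amd * p_dr).mean()


def nt_xent(query, key, queue, tau: float = 0.07) -> Tensor:
    """Normalized temperature-scaled cross-entropy with queue negatives.

    Equivalent to softmax cross-entropy with the positive similarity at
    index 0 and the queue similarities after it; batched inputs average
    over queries.  All inputs are assumed unit-norm.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    q, k, neg = _t(query), _t(key), _t(queue)
    if q.ndim == 1:
        q = q.reshape(1, -1)
        k = k.reshape(1, -1)
    pos = (q * k).sum(axis=1, keepdims=True)          # N x 1
    negs = q @ neg.T                                  # N x K
    logits = Tensor.concatenate([pos, negs], axis=1) * (1.0 / tau)
    shifted = logits - Tensor(logits.data.max(axis=1, keepdims=True))
    logsumexp = shifted.exp().sum(axis=1, keepdims=True).log() \
        + Tensor(logits.data.max(axis=1, keepdims=True))
    return (logsumexp - logits[:, 0:1]).mean()


def pairwise_alignment_losses(u, v) -> tuple[Tensor, Tensor]:
    """(MSE, 1 - cosine) between matched vectors or batches of vectors."""
    u, v = _t(u), _t(v)
    if u.shape != v.shape:
        raise ValueError("u and v must have equal shape")
    mse = ((u - v) ** 2).mean()
    if u.ndim == 1:
        u = u.reshape(1, -1)
        v = v.reshape(1, -1)
    dot = (u * v).sum(axis=1)
    nu = ((u**2).sum(axis=1) + NORM_EPS) ** 0.5
    nv = ((v**2).sum(axis=1) + NORM_EPS) ** 0.5
    cosine = dot / (nu * nv)
    return mse, (1.0 - cosine).mean()


def _log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    s = x - shift
    return s - s.exp().sum(axis=axis, keepdims=True).log()


def kl_align_loss(U, V, tau_kl: float = 1.0) -> Tensor:
    """Mean KL( softmax(u/tau) || softmax(v/tau) ) over the batch."""
    if tau_kl <= 0:
        raise ValueError("tau_kl must be positive")
    U, V = _t(U), _t(V)
    if U.shape != V.shape:
        raise ValueError("U and V must have equal shape")
    if U.ndim == 1:
        U = U.reshape(1, -1)
        V = V.reshape(1, -1)
    logp = _log_softmax(U * (1.0 / tau_kl))
    logq = _log_softmax(V * (1.0 / tau_kl))
    p = logp.exp()
    return (p * (logp - logq)).sum(axis=1).mean()


def _median_bandwidth(X: np.ndarray, Y: np.ndarray) -> float:
    """sigma = sqrt(median squared pairwise distance / 2) over X union Y."""
    Z = np.concatenate([X, Y], axis=0)
    sq = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(-1)
    med = np.median(sq[np.triu_indices(len(Z), k=1)]) if len(Z) > 1 else 1.0
    return float(np.sqrt(max(med, NORM_EPS) / 2.0))


def mmd_loss(X, Y, sigma: float | None = None) -> Tensor:
    """Biased V-statistic squared MMD with an RBF kernel.

    The bandwidth defaults to the median heuristic computed once per call
    over the pooled sample; pass ``sigma`` to override (e.g. in tests).
    """
    X, Y = _t(X), _t(Y)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if Y.ndim == 1:
        Y = Y.reshape(-1, 1)
    if len(X.data) == 0 or len(Y.data) == 0:
        raise ValueError("empty batch")
    if sigma is None:
        sigma = _median_bandwidth(X.data, Y.data)
    gamma = 1.0 / (2.0 * sigma**2)

    def kernel_mean(A: Tensor, B: Tensor) -> Tensor:
        sq = ((A.reshape(len(A.data), 1, -1) - B.reshape(1, len(B.data), -1)) ** 2
              ).sum(axis=2)
        return (-(sq * gamma)).exp().mean()

    return kernel_mean(X, X) + kernel_mean(Y, Y) - 2.0 * kernel_mean(X, Y)


def _covariance(X: Tensor) -> Tensor:
    n = len(X.data)
    mu = X.mean(axis=0, keepdims=True)
    Xc = X - mu
    return (Xc.T @ Xc) * (1.0 / (n - 1))


def coral_loss(X, Y) -> Tensor:
    """||C_X - C_Y||_F^2 / (4 d^2) with sample covariances (n-1 denominator)."""
    X, Y = _t(X), _t(Y)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if Y.ndim == 1:
        Y = Y.reshape(-1, 1)
    if len(X.data) < 2 or len(Y.data) < 2:
        raise ValueError("coral_loss needs at least 2 rows per batch")
    d = X.shape[1]
    diff = _covariance(X) - _covariance(Y)
    return (diff**2).sum() * (1.0 / (4.0 * d * d))


def prototype_loss(E, labels, prototypes: dict) -> Tensor:
    """Mean squared Euclidean distance from each embedding to its class
    prototype (sum over dimensions, mean over the batch)."""
    E = _t(E)
    if E.ndim == 1:
        E = E.reshape(1, -1)
    labels = np.asarray(labels)
    missing = {int(l) for l in labels} - {int(k) for k in prototypes}
    if missing:
        raise KeyError(f"no prototype for class(es) {sorted(missing)}")
    P = Tensor(np.stack([np.asarray(prototypes[int(l)], dtype=np.float64)
                         for l in labels]))
    return ((E - P) ** 2).sum(axis=1).mean()


def bridge_composite(components: dict, weights: BridgeLossWeights) -> Tensor:
    """Weighted sum of named component losses; linear in each component."""
    total = Tensor(np.float64(0.0))
    for name in BridgeLossWeights.COMPONENTS + ("cycle",):
        if name not in components:
            if name == "cycle":
                continue
            raise KeyError(f"missing component {name!r}")
        total = total + getattr(weights, name) * _t(components[name])
    return total
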