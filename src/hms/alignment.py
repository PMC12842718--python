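"""Stage-1 contrastive alignment of the OCT and fundus latent spaces.

A MoCo-style setup: query projection heads are trained with NT-Xent
against keys from slowly-updated momentum copies, with a FIFO queue of
past keys serving as negatives.  Positives are built WITHOUT ground-truth
pairs -- the training corpora are strictly unpaired -- using either
same-state augmented views within a modality, cross-modal
class-conditional positives (an OCT and a fundus sample sharing the same
label signature), or both.  The paired hold-out is used only to track
Recall@1 and select the best checkpoint, never for gradients.

The conv encoders are frozen here and embeddings precomputed once; the
alignment itself lives in the projection heads.  This keeps the fundus
embedding space -- on which the fundus staging head and the bridge's
regression targets depend -- fixed after the fundus stager is trained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .encoders import ProjectionHead, encode
from .losses import nt_xent
from .types import DatasetBundle, stack_pixels

__all__ = ["AlignmentConfig", "NegativeQueue", "MomentumPair",
           "momentum_update", "enqueue", "recall_at_k", "train_alignment",
           "AlignmentResult"]


@dataclass
class AlignmentConfig:
    momentum: float = 0.999
    queue_size: int = 512
    temperature: float = 0.07
    batch_size: int = 64
    lr: float = 3e-3
    positive_strategy: str = "both"   # augmented | class_conditional | both

    def __post_init__(self):
        if not 0.0 <= self.momentum <= 1.0:
            raise ValueError("momentum must lie in [0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.queue_size < 1:
            raise ValueError("queue_size must be >= 1")


class NegativeQueue:
    """Fixed-capacity FIFO buffer of unit-norm key vectors."""

    def __init__(self, capacity: int):
        self.capacity = capacity
        self.buffer: list[np.ndarray] = []

    def __len__(self):
        return len(self.buffer)

    def as_array(self) -> np.ndarray:
        return np.stack(self.buffer)


def enqueue(q: NegativeQueue, batch: np.ndarray) -> NegativeQueue:
    """Append keys (detached), dropping the oldest beyond capacity."""
    batch = np.asarray(batch)
    if batch.ndim == 1:
        batch = batch[None]
    if len(batch) > q.capacity:
        warnings.warn("batch larger than queue capacity; keeping newest entries")
        batch = batch[-q.capacity:]
    for row in batch:
        q.buffer.append(np.array(row))   # copy: no gradient path survives
    overflow = len(q.buffer) - q.capacity
    if overflow > 0:
        del q.buffer[:overflow]
    return q


@dataclass
class MomentumPair:
    """Query module and its momentum key copy (never directly trained)."""

    query: nn.Module
    key: nn.Module

    @classmethod
    def from_module(cls, query: nn.Module, key: nn.Module) -> "MomentumPair":
        key.load_state_dict(query.state_dict())
        return cls(query, key)


def momentum_update(pair: MomentumPair, m: float) -> MomentumPair:
    """key <- m * key + (1 - m) * query, elementwise over every tensor."""
    if not 0.0 <= m <= 1.0:
        raise ValueError("momentum must lie in [0, 1]")
    qs = pair.query.state_dict()
    ks = pair.key.state_dict()
    for name in ks:
        if ks[name].shape != qs[name].shape:
            raise ValueError(f"shape mismatch for parameter {name}")
        ks[name] = m * ks[name] + (1.0 - m) * qs[name]
    pair.key.load_state_dict(ks)
    return pair


def recall_at_k(oct_embs: np.ndarray, fundus_embs: np.ndarray,
                k: int = 1) -> float:
    """Fraction of OCT rows whose index-matched fundus partner is among
    the k nearest fundus rows by cosine similarity."""
    oct_embs = np.asarray(oct_embs, dtype=np.float64)
    fundus_embs = np.asarray(fundus_embs, dtype=np.float64)
    n = len(oct_embs)
    if not 1 <= k <= n:
        raise ValueError("k must lie in [1, N]")
    a = oct_embs / (np.linalg.norm(oct_embs, axis=1, keepdims=True) + 1e-12)
    b = fundus_embs / (np.linalg.norm(fundus_embs, axis=1, keepdims=True) + 1e-12)
    sim = a @ b.T
    order = np.argsort(-sim, axis=1, kind="stable")
    hits = (order[:, :k] == np.arange(n)[:, None]).any(axis=1)
    return float(hits.mean())


class _LabeledQueue(NegativeQueue):
    """Negative queue that remembers each entry's label signature so that
    same-class entries can be masked out of the denominator (they are
    false negatives under class-conditional positives)."""

    def __init__(self, capacity: int):
        super().__init__(capacity)
        self.sigs: list[int] = []

    def push(self, batch: np.ndarray, sigs) -> None:
        enqueue(self, batch)
        self.sigs.extend(int(s) for s in np.atleast_1d(sigs))
        del self.sigs[:len(self.sigs) - len(self.buffer)]

    def sig_array(self) -> np.ndarray:
        return np.asarray(self.sigs)


def _masked_nt_xent(q: Tensor, k: np.ndarray, queue: _LabeledQueue,
                    q_sigs: np.ndarray, tau: float) -> Tensor:
    """NT-Xent with queue negatives sharing the query's label signature
    excluded from the denominator."""
    pos = (q * Tensor(k)).sum(axis=1, keepdims=True)
    negs = q @ Tensor(queue.as_array()).T
    mask = (q_sigs[:, None] == queue.sig_array()[None, :])
    logits = Tensor.concatenate([pos, negs], axis=1) * (1.0 / tau)
    penalty = np.concatenate([np.zeros((len(q_sigs), 1)),
                              np.where(mask, -1e9, 0.0)], axis=1)
    logits = logits + Tensor(penalty.astype(logits.dtype))
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    lse = (logits - shift).exp().sum(axis=1, keepdims=True).log() + shift
    return (lse - logits[:, 0:1]).mean()


@dataclass
class AlignmentResult:
    proj_oct: ProjectionHead
    proj_fundus: ProjectionHead
    history: list          # dicts: epoch, loss, recall_at_1
    best_epoch: int
    best_recall: float


def _augmented_embeddings(samples, encoder, config, rng, n_views=2):
    """Embeddings of n_views light augmentations per sample (flip + jitter)."""
    views = []
    for v in range(n_views):
        x = stack_pixels(samples)
        flip = rng.random(len(x)) < 0.5
        x[flip] = x[flip, :, :, ::-1]
        x = np.clip(x + rng.uniform(-0.05, 0.05, size=(len(x), 1, 1, 1)).astype(
            np.float32), 0.0, 1.0)
        views.append(encode(x, encoder))
    return views


def train_alignment(bundle: DatasetBundle, enc_oct, enc_fundus,
                    cfg: AlignmentConfig | None = None, epochs: int = 10,
                    seed: int = 0) -> AlignmentResult:
    """Train OCT/fundus projection heads contrastively on unpaired corpora.

    Records per-epoch NT-Xent loss and paired-holdout Recall@1 and returns
    the heads at the epoch maximizing hold-out Recall@1.
    """
    if not bundle.oct_train or not bundle.fundus_train:
        raise ValueError("empty training corpus")
    cfg = cfg or AlignmentConfig()
    rng = np.random.default_rng([seed, 11])
    d_oct = enc_oct.config.embedding_dim
    d_fun = enc_fundus.config.embedding_dim

    proj_oct = ProjectionHead(d_oct, np.random.default_rng([seed, 12]))
    proj_fun = ProjectionHead(d_fun, np.random.default_rng([seed, 13]))
    key_oct = MomentumPair.from_module(
        proj_oct, ProjectionHead(d_oct, np.random.default_rng([seed, 14])))
    key_fun = MomentumPair.from_module(
        proj_fun, ProjectionHead(d_fun, np.random.default_rng([seed, 15])))

    # frozen encoders: precompute embeddings (2 augmented views each)
    oct_views = _augmented_embeddings(bundle.oct_train, enc_oct, cfg, rng)
    fun_views = _augmented_embeddings(bundle.fundus_train, enc_fundus, cfg, rng)
    oct_sig = np.array([int("".join(map(str, s.labels.y))) for s in bundle.oct_train])
    fun_sig = np.array([int("".join(map(str, s.labels.y))) for s in bundle.fundus_train])
    # class-conditional positive candidates: fundus indices per label signature
    sig_to_fun = {sig: np.where(fun_sig == sig)[0] for sig in set(fun_sig)}
    sig_to_oct = {sig: np.where(oct_sig == sig)[0] for sig in set(oct_sig)}

    ho_oct = np.stack([p[0].pixels for p in bundle.paired_holdout])[:, None] \
        if bundle.paired_holdout else None
    ho_fun = np.stack([p[1].pixels for p in bundle.paired_holdout])[:, None] \
        if bundle.paired_holdout else None

    opt = nn.AdamW(proj_oct.parameters() + proj_fun.parameters(), lr=cfg.lr)
    queue_fun = _LabeledQueue(cfg.queue_size)
    queue_oct = _LabeledQueue(cfg.queue_size)

    def project(head: nn.Module, embs: np.ndarray, train: bool) -> Tensor:
        head.train(train)
        if train:
            return head(Tensor(embs))
        with nn.no_grad():
            return head(Tensor(embs))

    def keys_for(pair: MomentumPair, embs: np.ndarray) -> np.ndarray:
        with nn.no_grad():
            return pair.key(Tensor(embs)).data

    # prefill queues before the loss is applied
    n0f = min(cfg.queue_size, len(fun_views[0]))
    n0o = min(cfg.queue_size, len(oct_views[0]))
    queue_fun.push(keys_for(key_fun, fun_views[0][:n0f]), fun_sig[:n0f])
    queue_oct.push(keys_for(key_oct, oct_views[0][:n0o]), oct_sig[:n0o])

    history = []
    best = (-1.0, 0, None, None)
    n_oct = len(oct_views[0])
    steps = max(1, n_oct // cfg.batch_size)
    total_steps = epochs * steps

    for epoch in range(epochs):
        perm = rng.permutation(n_oct)
        losses_epoch = []
        for step in range(steps):
            idx = perm[step * cfg.batch_size:(step + 1) * cfg.batch_size]
            if len(idx) == 0:
                continue
            opt.lr = nn.cosine_annealing(cfg.lr, epoch * steps + step, total_steps)
            opt.zero_grad()
            loss = Tensor(np.float64(0.0))
            n_terms = 0
            if cfg.positive_strategy in ("class_conditional", "both"):
                # OCT query vs class-matched fundus key; queue negatives of
                # the query's own class are masked (false negatives)
                fidx = np.array([
                    rng.choice(sig_to_fun[sig]) if sig in sig_to_fun
                    else rng.integers(len(fun_sig)) for sig in oct_sig[idx]])
                q = project(proj_oct, oct_views[0][idx], True)
                kf = keys_for(key_fun, fun_views[1][fidx])
                loss = loss + _masked_nt_xent(q, kf, queue_fun, oct_sig[idx],
                                              cfg.temperature)
                # fundus query vs class-matched OCT key
                oidx = np.array([
                    rng.choice(sig_to_oct[sig]) if sig in sig_to_oct
                    else rng.integers(len(oct_sig)) for sig in fun_sig[fidx]])
                qf = project(proj_fun, fun_views[0][fidx], True)
                ko = keys_for(key_oct, oct_views[1][oidx])
                loss = loss + _masked_nt_xent(qf, ko, queue_oct, fun_sig[fidx],
                                              cfg.temperature)
                n_terms += 2
                queue_fun.push(kf, fun_sig[fidx])
                queue_oct.push(ko, oct_sig[oidx])
            if cfg.positive_strategy in ("augmented", "both"):
                # instance discrimination: same-class entries stay in the
                # denominator here -- they are true negatives for a
                # same-image positive, and they preserve the within-class
                # structure that pseudo-pairing later relies on
                q = project(proj_oct, oct_views[0][idx], True)
                k2 = keys_for(key_oct, oct_views[1][idx])
                loss = loss + nt_xent(q, k2, queue_oct.as_array(),
                                      cfg.temperature)
                n_terms += 1
            loss = loss * (1.0 / max(n_terms, 1))
            loss.backward()
            opt.step()
            momentum_update(key_oct, cfg.momentum)
            momentum_update(key_fun, cfg.momentum)
            losses_epoch.append(loss.item())

        rec = np.nan
        if ho_oct is not None:
            zo = project(proj_oct, encode(ho_oct, enc_oct), False).data
            zf = project(proj_fun, encode(ho_fun, enc_fundus), False).data
            rec = recall_at_k(zo, zf, 1)
        history.append({"epoch": epoch, "loss": float(np.mean(losses_epoch)),
                        "recall_at_1": rec})
        if ho_oct is not None and rec > best[0]:
            best = (rec, epoch, proj_oct.state_dict(), proj_fun.state_dict())

    if best[2] is not None:
        proj_oct.load_state_dict(best[2])
        proj_fun.load_state_dict(best[3])
    return AlignmentResult(proj_oct=proj_oct, proj_fundus=proj_fun,
                           history=history, best_epoch=best[1],
                           best_recall=float(best[0]))
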