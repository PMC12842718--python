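"""Stage-2 OCT-to-fundus latent bridge.

A small regression projector g maps OCT embeddings into the fundus
encoder's embedding space.  Because the corpora are unpaired, regression
targets are *pseudo-pairs*: each OCT embedding is matched to its top-1
cosine neighbour among fundus embeddings in the stage-1 aligned
projection space.  Training minimizes the seven-component composite loss
(MSE, cosine, KL, InfoNCE, prototype, MMD, CORAL; optional cycle term).

At inference a QC score q -- the maximum cosine similarity between the
projected embedding and the fitted per-stage prototype bank -- gates
OCT-only DR staging: q >= 0.8 accepts, otherwise the case defers to
fundus imaging.  The paired hold-out is used only for checkpoint
selection and reported agreement, never for gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .alignment import AlignmentResult, NegativeQueue, enqueue
from .encoders import StagingHead, encode
from .losses import (BridgeLossWeights, bridge_composite, coral_loss,
                     kl_align_loss, mmd_loss, nt_xent,
                     pairwise_alignment_losses, prototype_loss)
from .types import DatasetBundle

__all__ = ["BridgeProjector", "PrototypeBank", "BridgeOutput", "pseudo_pair",
           "train_bridge", "project_with_qc", "fundus_agreement", "qc_score",
           "BridgeResult", "ablate_bridge"]

Q_THRESHOLD_DEFAULT = 0.8


class BridgeProjector(nn.Module):
    """2-layer MLP regression map g: R^d_oct -> R^d_fundus (hidden 4d)."""

    def __init__(self, d_oct: int, d_fundus: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        hidden = 4 * d_oct
        self.fc1 = nn.Linear(d_oct, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, d_fundus, rng=rng)

    def forward(self, z: Tensor) -> Tensor:
        return self.fc2(self.fc1(z).relu())

    def project(self, z: np.ndarray) -> np.ndarray:
        with nn.no_grad():
            return self(Tensor(np.atleast_2d(np.asarray(z, dtype=np.float32)))).data


@dataclass
class PrototypeBank:
    """Per-DR-stage mean fundus embeddings (the QC reference set).

    The bank also stores a "healthy" reference point: the mean embedding
    of the non-staged (non-DR) fitting samples.  QC cosines are computed
    on vectors centered at this point, so each prototype direction reads
    as "departure from healthy appearance toward stage s".  Uncentered
    cosines saturate near 1 for every input (all embeddings share a
    dominant mean direction), and centering at the global mean makes the
    mild prototype nearly collinear with healthy eyes -- both render the
    score non-discriminative.
    """

    prototypes: dict = field(default_factory=dict)   # stage -> vector
    center: np.ndarray | None = None                 # healthy reference

    @classmethod
    def fit(cls, fundus_embs: np.ndarray, stages) -> "PrototypeBank":
        stages = np.asarray(stages)
        staged = stages >= 0
        protos = {}
        for stage in sorted({int(s) for s in stages[staged]}):
            protos[stage] = fundus_embs[stages == stage].mean(axis=0)
        if len(fundus_embs):
            ref = fundus_embs[~staged] if (~staged).any() else fundus_embs
            center = ref.mean(axis=0)
        else:
            center = None
        return cls(protos, center)

    def as_dict(self) -> dict:
        return self.prototypes

    def matrix(self, centered: bool = False) -> np.ndarray:
        if not self.prototypes:
            raise ValueError("empty prototype bank")
        P = np.stack([self.prototypes[k] for k in sorted(self.prototypes)])
        if centered and self.center is not None:
            P = P - self.center
        return P


@dataclass
class BridgeOutput:
    projected: np.ndarray
    q: float
    accepted: bool


def _cos_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    a = A / (np.linalg.norm(A, axis=1, keepdims=True) + 1e-12)
    b = B / (np.linalg.norm(B, axis=1, keepdims=True) + 1e-12)
    return a @ b.T


def pseudo_pair(oct_embs: np.ndarray, fundus_embs: np.ndarray):
    """Top-1 cosine matches (index pairs + similarities) in aligned space."""
    oct_embs = np.atleast_2d(np.asarray(oct_embs, dtype=np.float64))
    fundus_embs = np.atleast_2d(np.asarray(fundus_embs, dtype=np.float64))
    if len(fundus_embs) == 0:
        raise ValueError("empty fundus embedding set")
    sim = _cos_matrix(oct_embs, fundus_embs)
    j = sim.argmax(axis=1)
    matches = [(int(i), int(jj)) for i, jj in enumerate(j)]
    sims = sim[np.arange(len(j)), j]
    return matches, sims


def qc_score(projected: np.ndarray, bank: PrototypeBank) -> np.ndarray:
    """q = max over bank prototypes of the cosine between the projected
    embedding and the prototype, both centered at the bank's healthy
    reference point.

    A projection that resembles a genuinely stageable (macula-correlated)
    DR fundus departs from the healthy reference along some stage
    direction and scores high; a normal-looking projection -- including
    the peripheral-only DR eyes whose B-scans carry no DR cue -- has no
    such departure and scores low, which is exactly what the deferral
    gate needs.
    """
    P = bank.matrix(centered=True)
    V = np.atleast_2d(projected)
    if bank.center is not None:
        V = V - bank.center
    return _cos_matrix(V, P).max(axis=1)


def project_with_qc(oct_image, enc_oct, projector: BridgeProjector,
                    bank: PrototypeBank,
                    q_threshold: float = Q_THRESHOLD_DEFAULT) -> BridgeOutput:
    """Project an OCT image into fundus space and gate it by the QC score."""
    if not bank.prototypes:
        raise ValueError("empty prototype bank")
    z = encode(oct_image, enc_oct)
    proj = projector.project(z)[0]
    q = float(qc_score(proj, bank)[0])
    return BridgeOutput(projected=proj, q=q, accepted=q >= q_threshold)


def fundus_agreement(paired_holdout, enc_oct, enc_fundus,
                     projector: BridgeProjector,
                     staging_head: StagingHead) -> float:
    """Fraction of hold-out pairs whose DR-stage argmax agrees between the
    projected OCT embedding and the true fundus embedding (ties resolve to
    the lowest stage index)."""
    if not paired_holdout:
        raise ValueError("empty paired hold-out")
    z_oct = encode([p[0] for p in paired_holdout], enc_oct)
    z_fun = encode([p[1] for p in paired_holdout], enc_fundus)
    proj = projector.project(z_oct)
    s_proj = staging_head.probabilities(proj.astype(np.float32)).argmax(axis=1)
    s_fun = staging_head.probabilities(z_fun.astype(np.float32)).argmax(axis=1)
    return float((s_proj == s_fun).mean())


@dataclass
class BridgeResult:
    projector: BridgeProjector
    bank: PrototypeBank
    history: list            # per-epoch dict of component losses + metrics
    best_epoch: int
    best_agreement: float


def train_bridge(bundle: DatasetBundle, enc_oct, enc_fundus,
                 align: AlignmentResult, staging_head: StagingHead,
                 weights: BridgeLossWeights | None = None, epochs: int = 15,
                 seed: int = 0, batch_size: int = 64,
                 drop_component: str | None = None,
                 candidate_pool: int = 512,
                 oct_severity: np.ndarray | None = None) -> BridgeResult:
    """Fit the bridge projector with the composite objective.

    Pseudo-pairs are refreshed every epoch over a resampled fundus
    candidate pool; the prototype bank is recomputed each epoch from the
    current fundus embeddings (constant here because the fundus encoder is
    frozen, but recomputed regardless).  The best checkpoint is chosen by
    hold-out fundus agreement.

    ``oct_severity`` optionally supplies an unsupervised per-sample
    severity proxy for the OCT training corpus (e.g. the parent model's
    DR probability).  When given, DR-positive OCT samples are matched to
    DR-positive fundus candidates by severity *rank* (quantile matching
    against the staging head's expected stage) instead of raw cosine:
    class-conditional alignment cannot order eyes within a class, and
    without a severity-consistent target the projector would regress
    every DR eye onto the class mean, losing the stage signal entirely.
    """
    if align is None:
        raise ValueError("missing stage-1 alignment checkpoint")
    weights = weights or BridgeLossWeights()
    if drop_component is not None:
        weights = weights.drop(drop_component)
    rng = np.random.default_rng([seed, 21])

    z_oct = encode(bundle.oct_train, enc_oct)
    z_fun = encode(bundle.fundus_train, enc_fundus)
    with nn.no_grad():
        p_oct = align.proj_oct(Tensor(z_oct)).data
        p_fun = align.proj_fundus(Tensor(z_fun)).data
    oct_is_dr = np.array([s.labels.y[2] == 1 for s in bundle.oct_train])
    fun_is_dr = np.array([s.labels.y[2] == 1 for s in bundle.fundus_train])
    stage_probs_fun = staging_head.probabilities(z_fun.astype(np.float32))
    fun_severity = stage_probs_fun @ np.arange(staging_head.K)

    fun_stages = np.array([-1 if s.stage is None else s.stage
                           for s in bundle.fundus_train])
    bank = PrototypeBank.fit(z_fun, fun_stages)
    # pseudo class for the prototype term: staging-head argmax of the target
    fun_cls = staging_head.probabilities(z_fun.astype(np.float32)).argmax(axis=1)

    d_oct = enc_oct.config.embedding_dim
    d_fun = enc_fundus.config.embedding_dim
    projector = BridgeProjector(d_oct, d_fun, np.random.default_rng([seed, 22]))
    inverse = BridgeProjector(d_fun, d_oct, np.random.default_rng([seed, 23])) \
        if weights.cycle > 0 else None
    params = projector.parameters() + (inverse.parameters() if inverse else [])
    opt = nn.AdamW(params, lr=1e-3)
    queue = NegativeQueue(capacity=256)

    def norm_rows(t: Tensor) -> Tensor:
        n = ((t**2).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
        return t / n

    n = len(z_oct)
    history = []
    best = (-1.0, 0, None)
    for epoch in range(epochs):
        pool = rng.choice(len(z_fun), size=min(candidate_pool, len(z_fun)),
                          replace=False)
        matches, _ = pseudo_pair(p_oct, p_fun[pool])
        target_idx = pool[np.array([j for _, j in matches])]
        if oct_severity is not None:
            dr_pool = pool[fun_is_dr[pool]]
            dr_oct = np.where(oct_is_dr)[0]
            if len(dr_pool) >= 2 and len(dr_oct) >= 1:
                # quantile-match severities within the DR class
                order_oct = dr_oct[np.argsort(oct_severity[dr_oct],
                                              kind="stable")]
                order_fun = dr_pool[np.argsort(fun_severity[dr_pool],
                                               kind="stable")]
                ranks = np.linspace(0, len(order_fun) - 1,
                                    len(order_oct)).round().astype(int)
                target_idx[order_oct] = order_fun[ranks]
        bank = PrototypeBank.fit(z_fun, fun_stages)

        perm = rng.permutation(n)
        comps_epoch: dict[str, list] = {}
        for start in range(0, n, batch_size):
            idx = perm[start:start + batch_size]
            if len(idx) < 4:
                continue
            zb = z_oct[idx].astype(np.float64)
            tb = z_fun[target_idx[idx]].astype(np.float64)
            cb = fun_cls[target_idx[idx]]
            fb = z_fun[rng.choice(len(z_fun), size=len(idx), replace=False)]

            projector.train()
            g = projector(Tensor(zb.astype(np.float32)))
            mse, cos = pairwise_alignment_losses(g, Tensor(tb))
            if len(queue) < 8:
                enqueue(queue, (fb / (np.linalg.norm(fb, axis=1, keepdims=True)
                                      + 1e-12))[:8])
            # KL compares stage distributions, not raw coordinates: the
            # frozen fundus staging head reads both the projection and its
            # pseudo-target, and the projection is pushed to reproduce the
            # target's stage profile (semantic distillation through the
            # head the bridge ultimately feeds)
            with nn.no_grad():
                head_t = staging_head(Tensor(tb.astype(np.float32))).data
            comps = {
                "mse": mse,
                "cos": cos,
                "kl": kl_align_loss(Tensor(head_t.astype(np.float64)),
                                    staging_head(g)),
                "infonce": nt_xent(norm_rows(g),
                                   norm_rows(Tensor(tb)).detach(),
                                   queue.as_array(), 0.07),
                "proto": prototype_loss(g, cb, bank.as_dict()),
                "mmd": mmd_loss(g, Tensor(fb)),
                "coral": coral_loss(g, Tensor(fb)),
            }
            if inverse is not None:
                back = inverse(g)
                comps["cycle"] = ((back - Tensor(zb)) ** 2).mean()
            loss = bridge_composite(comps, weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
            tbn = tb / (np.linalg.norm(tb, axis=1, keepdims=True) + 1e-12)
            enqueue(queue, tbn)
            for k, v in comps.items():
                comps_epoch.setdefault(k, []).append(v.item())
            comps_epoch.setdefault("total", []).append(loss.item())

        agreement = fundus_agreement(bundle.paired_holdout, enc_oct,
                                     enc_fundus, projector, staging_head) \
            if bundle.paired_holdout else np.nan
        proj_all = projector.project(z_oct)
        mean_q = float(qc_score(proj_all, bank).mean())
        record = {k: float(np.mean(v)) for k, v in comps_epoch.items()}
        record.update({"epoch": epoch, "fundus_agreement": agreement,
                       "mean_q": mean_q})
        history.append(record)
        if bundle.paired_holdout and agreement >= best[0]:
            best = (agreement, epoch, projector.state_dict())

    staging_head.zero_grad()   # distillation pushes grads it never uses
    if best[2] is not None:
        projector.load_state_dict(best[2])
    return BridgeResult(projector=projector, bank=bank, history=history,
                        best_epoch=best[1], best_agreement=float(best[0]))


def ablate_bridge(bundle: DatasetBundle, enc_oct, enc_fundus,
                  align: AlignmentResult, staging_head: StagingHead,
                  weights: BridgeLossWeights | None = None, epochs: int = 4,
                  seed: int = 0):
    """Leave-one-out ablation over the seven composite-loss components.

    Trains the full bridge once and then seven variants, each with one
    component weight zeroed, and tabulates the hold-out fundus agreement
    plus its delta against the full objective (positive delta = the
    component helped).
    """
    import pandas as pd

    weights = weights or BridgeLossWeights()
    full = train_bridge(bundle, enc_oct, enc_fundus, align, staging_head,
                        weights, epochs=epochs, seed=seed)
    rows = []
    for name in BridgeLossWeights.COMPONENTS:
        res = train_bridge(bundle, enc_oct, enc_fundus, align, staging_head,
                           weights, epochs=epochs, seed=seed,
                           drop_component=name)
        rows.append({"component": name, "agreement": res.best_agreement,
                     "agreement_full": full.best_agreement,
                     "delta": full.best_agreement - res.best_agreement})
    return pd.DataFrame(rows)
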