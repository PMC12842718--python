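"""Training, conditional routing, inference and evaluation harnesses.

The parent multi-label model screens OCT scans for {NORM, AMD, DR, DME};
positive cases route to specialist staging (AMD on OCT directly, DR via
the OCT-to-fundus latent bridge behind a QC gate), with conservative
referral on near-threshold probabilities or QC failure.  ``HMSModel`` /
``HMSResults`` wrap the whole workflow in a fit/results pair.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nn
from .nn import Tensor
from .alignment import AlignmentConfig, train_alignment
from .bridge import BridgeResult, project_with_qc, qc_score, train_bridge
from .calibration import ThresholdSet, ece, optimize_thresholds
from .encoders import (EncoderConfig, ParentHead, StagingHead, build_encoder,
                       encode)
from .losses import BridgeLossWeights, FocalConfig, co_activation_penalty, focal_bce
from .metrics import evaluate_multilabel, multilabel_summary
from .types import (AMD, CLASS_NAMES, DR, DatasetBundle, ImageSample,
                    stack_labels, stack_pixels)

__all__ = ["RoutingDecision", "DiagnosisReport", "TrainConfig", "route",
           "train_parent", "train_staging", "train_fundus_model", "infer",
           "domain_transfer_eval", "loso_eval", "ParentModel", "StagingModel",
           "HMSModel", "HMSResults", "PipelineConfig",
           "softmax_cross_entropy"]

ACTIONS = ("LOW_RISK", "AMD_STAGING", "DR_STAGING_OCT_ONLY",
           "DEFER_FUNDUS_REQUIRED", "DME_FLAG", "REFERRAL")


# ---------------------------------------------------------------------------
# routing
# ---------------------------------------------------------------------------

@dataclass
class RoutingDecision:
    actions: set
    uncertainty_flags: dict

    def __contains__(self, action: str) -> bool:
        return action in self.actions


def route(parent_probs, thresholds: ThresholdSet, q: float | None = None,
          near_band: float = 0.05, q_threshold: float = 0.8) -> RoutingDecision:
    """Pure routing function: thresholded flags -> staging actions.

    A pathology c is flagged iff p_c >= T_c.  No flags -> LOW_RISK.  An
    AMD flag routes to AMD staging; a DR flag routes to OCT-only DR
    staging when the bridge QC score passes (q >= q_threshold) and defers
    to fundus imaging otherwise; DME raises a monitoring flag.  REFERRAL
    is added when any flagged class sits within ``near_band`` of its
    threshold or when the QC gate fails.
    """
    p = np.asarray(parent_probs, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    t = thresholds.as_array()
    flagged = {c: p[i] >= t[i] for i, c in enumerate(CLASS_NAMES)}
    pathology = [c for c in ("AMD", "DR", "DME") if flagged[c]]
    near = {c: bool(abs(p[i] - t[i]) < near_band and flagged[c])
            for i, c in enumerate(CLASS_NAMES)}

    actions = set()
    if not pathology:
        return RoutingDecision({"LOW_RISK"}, near)
    qc_failed = False
    if "AMD" in pathology:
        actions.add("AMD_STAGING")
    if "DR" in pathology:
        if q is None:
            raise ValueError("DR flagged but no QC score supplied; "
                             "run the bridge and pass q")
        if q >= q_threshold:
            actions.add("DR_STAGING_OCT_ONLY")
        else:
            actions.add("DEFER_FUNDUS_REQUIRED")
            qc_failed = True
    if "DME" in pathology:
        actions.add("DME_FLAG")
    if qc_failed or any(near[c] for c in pathology):
        actions.add("REFERRAL")
    return RoutingDecision(actions, near)


@dataclass
class DiagnosisReport:
    parent_probs: dict
    thresholds: dict
    routing: RoutingDecision
    amd_stage_probs: list | None = None
    dr_stage_probs: list | None = None
    q: float | None = None
    audit: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "parent_probs": self.parent_probs,
            "thresholds": self.thresholds,
            "actions": sorted(self.routing.actions),
            "uncertainty_flags": self.routing.uncertainty_flags,
            "amd_stage_probs": self.amd_stage_probs,
            "dr_stage_probs": self.dr_stage_probs,
            "q": self.q,
            "audit": self.audit,
        }
        return json.dumps(payload)


# ---------------------------------------------------------------------------
# training configuration and helpers
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 48
    lr: float = 3e-3
    weight_decay: float = 1e-4
    rco_weight: float = 0.1
    augment: bool = True
    focal: FocalConfig = field(default_factory=lambda: FocalConfig(
        alpha=np.array([1.0, 1.0, 1.0, 2.5]), gamma=2.0, label_smoothing=0.05))


def _augment_batch(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random horizontal flips, +/-10 degree rotations, brightness and
    contrast jitter within +/-0.1."""
    x = x.copy()
    n = len(x)
    flip = rng.random(n) < 0.5
    x[flip] = x[flip, :, :, ::-1]
    angles = rng.uniform(-10, 10, size=n)
    rotate = rng.random(n) < 0.5
    for i in np.where(rotate)[0]:
        x[i, 0] = ndimage.rotate(x[i, 0], angles[i], reshape=False,
                                 order=1, mode="nearest")
    brightness = rng.uniform(-0.1, 0.1, size=(n, 1, 1, 1)).astype(np.float32)
    contrast = (1.0 + rng.uniform(-0.1, 0.1, size=(n, 1, 1, 1))).astype(np.float32)
    mean = x.mean(axis=(2, 3), keepdims=True)
    x = (x - mean) * contrast + mean + brightness
    return np.clip(x, 0.0, 1.0)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    labels = np.asarray(labels, dtype=int)
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    s = logits - shift
    lse = s.exp().sum(axis=1, keepdims=True).log()
    picked = s[np.arange(len(labels)), labels].reshape(-1, 1)
    return (lse - picked).mean()


class ParentModel(nn.Module):
    """Shared encoder + 4-logit multi-label head."""

    def __init__(self, encoder, rng: np.random.Generator | None = None):
        super().__init__()
        self.encoder = encoder
        self.head = ParentHead(encoder.config.embedding_dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.encoder(x))

    def predict_probs(self, samples) -> np.ndarray:
        z = encode(samples, self.encoder)
        return self.head.probabilities(z.astype(np.float32))

    def predict_logits(self, samples) -> np.ndarray:
        z = encode(samples, self.encoder)
        with nn.no_grad():
            return self.head(Tensor(z.astype(np.float32))).data


def _macro_f1_at(probs: np.ndarray, labels: np.ndarray,
                 thresholds: ThresholdSet) -> float:
    from .calibration import f1_score_binary
    pred = thresholds.apply(probs)
    return float(np.mean([f1_score_binary(labels[:, c], pred[:, c])
                          for c in range(labels.shape[1])]))


def train_parent(bundle: DatasetBundle, encoder=None,
                 cfg: TrainConfig | None = None, seed: int = 0,
                 modality: str = "oct"):
    """Train a multi-label screen on one modality's training split: the
    parent model on OCT, and -- with ``modality="fundus"`` -- the fundus
    encoder pre-training, whose corpus carries the same label space.

    Objective: focal-weighted BCE plus ``rco_weight`` times the AMD-DR
    co-activation penalty.  AdamW with cosine annealing and
    flip/rotation/brightness-contrast augmentation.  The checkpoint with
    the best validation macro-F1 (fixed 0.5 thresholds) is kept.
    """
    train_split = getattr(bundle, f"{modality}_train")
    val_split = getattr(bundle, f"{modality}_val")
    if not train_split:
        raise ValueError(f"empty {modality.upper()} training split")
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng([seed, 31])
    encoder = encoder or build_encoder(EncoderConfig(),
                                       np.random.default_rng([seed, 32]))
    model = ParentModel(encoder, rng=np.random.default_rng([seed, 33]))
    opt = nn.AdamW(model.parameters(), lr=cfg.lr,
                   weight_decay=cfg.weight_decay)

    x_train = stack_pixels(train_split)
    y_train = stack_labels(train_split)
    y_val = stack_labels(val_split) if val_split else None

    n = len(x_train)
    steps = max(1, n // cfg.batch_size)
    total = cfg.epochs * steps
    history = []
    best = (-1.0, None)
    for epoch in range(cfg.epochs):
        model.train()
        perm = rng.permutation(n)
        focal_log, rco_log = [], []
        for step in range(steps):
            idx = perm[step * cfg.batch_size:(step + 1) * cfg.batch_size]
            xb = x_train[idx]
            if cfg.augment:
                xb = _augment_batch(xb, rng)
            opt.lr = nn.cosine_annealing(cfg.lr, epoch * steps + step, total)
            opt.zero_grad()
            logits = model(Tensor(xb))
            lf = focal_bce(logits, Tensor(y_train[idx].astype(np.float32)),
                           cfg.focal)
            probs = logits.sigmoid()
            rco = co_activation_penalty(probs[:, AMD], probs[:, DR])
            loss = lf + cfg.rco_weight * rco
            loss.backward()
            opt.step()
            focal_log.append(lf.item())
            rco_log.append(rco.item())
        record = {"epoch": epoch, "focal": float(np.mean(focal_log)),
                  "rco": float(np.mean(rco_log)),
                  "loss": float(np.mean(focal_log)
                                + cfg.rco_weight * np.mean(rco_log))}
        if y_val is not None:
            val_probs = model.predict_probs(val_split)
            record["val_macro_f1"] = _macro_f1_at(val_probs, y_val,
                                                  ThresholdSet.fixed(0.5))
            if record["val_macro_f1"] > best[0]:
                best = (record["val_macro_f1"], model.state_dict())
        history.append(record)
    if best[1] is not None:
        model.load_state_dict(best[1])
    model.eval()
    return model, history


@dataclass
class StagingModel:
    task: str                     # "amd" | "dr"
    K: int
    encoder: object               # specialist encoder (OCT) or fundus encoder
    head: StagingHead
    parent: ParentModel | None    # frozen context encoder (AMD fusion only)
    confusion: np.ndarray | None = None
    accuracy: float | None = None
    history: list = field(default_factory=list)

    def stage_probs(self, samples) -> np.ndarray:
        z = encode(samples, self.encoder)
        if self.parent is not None:
            zp = encode(samples, self.parent.encoder)
            z = np.concatenate([z, zp], axis=1)
        return self.head.probabilities(z.astype(np.float32))


def train_staging(bundle: DatasetBundle, parent: ParentModel | None, K: int,
                  cfg: TrainConfig | None = None, task: str = "amd",
                  seed: int = 0, encoder=None,
                  freeze_encoder: bool = False) -> StagingModel:
    """Train a K-way staging specialist with softmax cross-entropy.

    AMD (K=5): a specialist OCT encoder whose embedding is concatenated
    with the frozen parent embedding (hybrid feature fusion).  DR (K=4):
    the fundus encoder with a plain softmax head on its embedding -- this
    head is reused verbatim by the bridge, so it must act on the fundus
    embedding alone.  With ``freeze_encoder`` the supplied encoder stays
    fixed and only the head is fitted (used when the fundus encoder has
    been pre-trained on the multi-label task).
    """
    cfg = cfg or TrainConfig()
    if task == "amd":
        train = [s for s in bundle.oct_train if s.labels.y[AMD] == 1
                 and s.stage is not None]
        test = [s for s in bundle.oct_test if s.labels.y[AMD] == 1
                and s.stage is not None]
    elif task == "dr":
        train = [s for s in bundle.fundus_train if s.labels.y[DR] == 1
                 and s.stage is not None]
        test = [s for s in bundle.fundus_test if s.labels.y[DR] == 1
                and s.stage is not None]
    else:
        raise ValueError(f"unknown staging task {task!r}")
    if not train:
        raise ValueError(f"no stage-labelled training samples for {task}")

    rng = np.random.default_rng([seed, 41])
    encoder = encoder or build_encoder(EncoderConfig(),
                                       np.random.default_rng([seed, 42]))
    d = encoder.config.embedding_dim
    fuse = task == "amd" and parent is not None
    head = StagingHead(2 * d if fuse else d, K,
                       rng=np.random.default_rng([seed, 43]))
    params = head.parameters() if freeze_encoder \
        else encoder.parameters() + head.parameters()
    opt = nn.AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay)

    x = stack_pixels(train)
    y = np.array([s.stage for s in train], dtype=int)
    zp = encode(train, parent.encoder) if fuse else None
    z_frozen = encode(train, encoder) if freeze_encoder else None
    epochs = cfg.epochs * (4 if freeze_encoder else 1)   # head-only is cheap

    n = len(x)
    bs = min(cfg.batch_size, n)
    steps = max(1, n // bs)
    total = epochs * steps
    history = []
    for epoch in range(epochs):
        if not freeze_encoder:
            encoder.train()
        perm = rng.permutation(n)
        losses = []
        for step in range(steps):
            idx = perm[step * bs:(step + 1) * bs]
            opt.lr = nn.cosine_annealing(cfg.lr, epoch * steps + step, total)
            opt.zero_grad()
            if freeze_encoder:
                z = Tensor(z_frozen[idx].astype(np.float32))
            else:
                xb = x[idx]
                if cfg.augment:
                    xb = _augment_batch(xb, rng)
                z = encoder(Tensor(xb))
            if fuse:
                z = Tensor.concatenate([z, Tensor(zp[idx].astype(np.float32))],
                                       axis=1)
            loss = softmax_cross_entropy(head(z), y[idx])
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append({"epoch": epoch, "loss": float(np.mean(losses))})
    encoder.eval()

    model = StagingModel(task=task, K=K, encoder=encoder, head=head,
                         parent=parent if fuse else None, history=history)
    if test:
        probs = model.stage_probs(test)
        pred = probs.argmax(axis=1)
        truth = np.array([s.stage for s in test], dtype=int)
        conf = np.zeros((K, K), dtype=int)
        np.add.at(conf, (truth, pred), 1)
        model.confusion = conf
        model.accuracy = float((pred == truth).mean())
    return model


def train_fundus_model(bundle: DatasetBundle, cfg: TrainConfig | None = None,
                       seed: int = 0, K: int = 4,
                       encoder=None) -> StagingModel:
    """Train the fundus model multi-task: the multi-label screen over the
    whole fundus corpus plus ICDR stage cross-entropy on its DR subset.

    One encoder then carries both structures the downstream stages need:
    full class separation (alignment positives, prototype bank, a staging
    head that behaves consistently on non-DR eyes) and stage
    discrimination (DR severity).  The stage head acts on the fundus
    embedding alone so the bridge can feed it projected OCT embeddings.
    """
    if not bundle.fundus_train:
        raise ValueError("empty fundus training split")
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng([seed, 51])
    encoder = encoder or build_encoder(EncoderConfig(),
                                       np.random.default_rng([seed, 52]))
    d = encoder.config.embedding_dim
    label_head = ParentHead(d, rng=np.random.default_rng([seed, 53]))
    stage_head = StagingHead(d, K, rng=np.random.default_rng([seed, 54]))
    params = (encoder.parameters() + label_head.parameters()
              + stage_head.parameters())
    opt = nn.AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay)

    x = stack_pixels(bundle.fundus_train)
    y = stack_labels(bundle.fundus_train)
    stages = np.array([-1 if s.stage is None else s.stage
                       for s in bundle.fundus_train])
    n = len(x)
    steps = max(1, n // cfg.batch_size)
    total = cfg.epochs * steps
    history = []
    for epoch in range(cfg.epochs):
        encoder.train()
        perm = rng.permutation(n)
        losses = []
        for step in range(steps):
            idx = perm[step * cfg.batch_size:(step + 1) * cfg.batch_size]
            xb = x[idx]
            if cfg.augment:
                xb = _augment_batch(xb, rng)
            opt.lr = nn.cosine_annealing(cfg.lr, epoch * steps + step, total)
            opt.zero_grad()
            z = encoder(Tensor(xb))
            loss = focal_bce(label_head(z), Tensor(y[idx].astype(np.float32)),
                             cfg.focal)
            staged = np.where(stages[idx] >= 0)[0]
            if len(staged):
                loss = loss + softmax_cross_entropy(stage_head(z[staged]),
                                                    stages[idx][staged])
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append({"epoch": epoch, "loss": float(np.mean(losses))})
    encoder.eval()

    model = StagingModel(task="dr", K=K, encoder=encoder, head=stage_head,
                         parent=None, history=history)
    test = [s for s in bundle.fundus_test if s.labels.y[DR] == 1
            and s.stage is not None]
    if test:
        probs = model.stage_probs(test)
        pred = probs.argmax(axis=1)
        truth = np.array([s.stage for s in test], dtype=int)
        conf = np.zeros((K, K), dtype=int)
        np.add.at(conf, (truth, pred), 1)
        model.confusion = conf
        model.accuracy = float((pred == truth).mean())
    return model


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def infer(oct_sample: ImageSample, parent: ParentModel,
          thresholds: ThresholdSet, amd_stager: StagingModel | None = None,
          dr_stager: StagingModel | None = None, projector=None, bank=None,
          near_band: float = 0.05, q_threshold: float = 0.8,
          audit_log: str | Path | None = None, seed: int | None = None,
          config_hash: str | None = None) -> DiagnosisReport:
    """Full single-scan inference: screen, gate, stage, report, audit."""
    probs = parent.predict_probs([oct_sample])[0]
    q = None
    projected = None
    if probs[DR] >= thresholds["DR"]:
        if projector is None or bank is None:
            raise ValueError("DR flagged but bridge projector/bank missing")
        out = project_with_qc(oct_sample, parent.encoder, projector, bank,
                              q_threshold)
        q, projected = out.q, out.projected
    decision = route(probs, thresholds, q=q, near_band=near_band,
                     q_threshold=q_threshold)

    amd_probs = dr_probs = None
    if "AMD_STAGING" in decision:
        if amd_stager is None:
            raise ValueError("AMD staging routed but no AMD stager fitted")
        amd_probs = amd_stager.stage_probs([oct_sample])[0].tolist()
    if "DR_STAGING_OCT_ONLY" in decision:
        if dr_stager is None:
            raise ValueError("DR staging routed but no DR stager fitted")
        dr_probs = dr_stager.head.probabilities(
            projected[None].astype(np.float32))[0].tolist()

    report = DiagnosisReport(
        parent_probs={c: float(probs[i]) for i, c in enumerate(CLASS_NAMES)},
        thresholds={c: float(thresholds[c]) for c in CLASS_NAMES},
        routing=decision, amd_stage_probs=amd_probs, dr_stage_probs=dr_probs,
        q=q,
        audit={"domain_id": oct_sample.domain_id, "eye_id": oct_sample.eye_id,
               "seed": seed, "config_hash": config_hash,
               "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")})
    if audit_log is not None:
        with open(audit_log, "a") as fh:
            fh.write(report.to_json() + "\n")
    return report


# ---------------------------------------------------------------------------
# domain transfer harnesses
# ---------------------------------------------------------------------------

def _filter_domain(samples, domain_id):
    return [s for s in samples if s.domain_id == domain_id]


def _domain_view(bundle: DatasetBundle, domain_id: str) -> DatasetBundle:
    view = DatasetBundle(
        oct_train=_filter_domain(bundle.oct_train, domain_id),
        oct_val=_filter_domain(bundle.oct_val, domain_id),
        oct_test=_filter_domain(bundle.oct_test, domain_id),
        fundus_train=_filter_domain(bundle.fundus_train, domain_id),
        fundus_val=_filter_domain(bundle.fundus_val, domain_id),
        fundus_test=_filter_domain(bundle.fundus_test, domain_id))
    return view


def _eval_parent_on(model: ParentModel, samples, thresholds: ThresholdSet):
    probs = model.predict_probs(samples)
    y = stack_labels(samples).astype(int)
    pred = thresholds.apply(probs)
    accuracy = float((pred == y).mean())      # per-label accuracy
    aurocs = []
    from sklearn.metrics import roc_auc_score
    for c in range(y.shape[1]):
        if len(np.unique(y[:, c])) == 2:
            aurocs.append(roc_auc_score(y[:, c], probs[:, c]))
    auroc = float(np.mean(aurocs)) if aurocs else np.nan
    macro_f1 = _macro_f1_at(probs, y, thresholds)
    return accuracy, auroc, macro_f1


def domain_transfer_eval(bundle: DatasetBundle, cfg: TrainConfig | None = None,
                         seed: int = 0,
                         protocols=("A->B", "B->A")) -> pd.DataFrame:
    """Cross-domain harness: train on the source domain's OCT corpus, tune
    thresholds on the source validation split only, evaluate on both the
    source and held-out target test splits."""
    cfg = cfg or TrainConfig(epochs=4)
    rows = []
    for proto in protocols:
        src, dst = proto.split("->")
        view = _domain_view(bundle, src)
        if not view.oct_train or not _filter_domain(bundle.oct_test, dst):
            raise ValueError(f"empty domain in protocol {proto}")
        model, _ = train_parent(view, cfg=cfg, seed=seed)
        val_probs = model.predict_probs(view.oct_val)
        thresholds = optimize_thresholds(val_probs, stack_labels(view.oct_val))
        for where, samples in (("within", view.oct_test),
                               ("transfer", _filter_domain(bundle.oct_test, dst))):
            acc, auroc, mf1 = _eval_parent_on(model, samples, thresholds)
            rows.append({"protocol": proto, "eval": where, "accuracy": acc,
                         "auroc": auroc, "macro_f1": mf1})
    return pd.DataFrame(rows)


def loso_eval(sources: dict[str, DatasetBundle], cfg: TrainConfig | None = None,
              seed: int = 0) -> pd.DataFrame:
    """Leave-one-source-out: train the parent on all sources but one,
    tune thresholds on the pooled validation split, test on the held-out
    source.  One row per held-out source."""
    cfg = cfg or TrainConfig(epochs=4)
    rows = []
    for held_out in sources:
        train_bundle = DatasetBundle()
        for name, b in sources.items():
            if name == held_out:
                continue
            train_bundle.oct_train += b.oct_train
            train_bundle.oct_val += b.oct_val
        if not train_bundle.oct_train:
            raise ValueError("LOSO needs at least two populated sources")
        model, _ = train_parent(train_bundle, cfg=cfg, seed=seed)
        val_probs = model.predict_probs(train_bundle.oct_val)
        thresholds = optimize_thresholds(val_probs,
                                         stack_labels(train_bundle.oct_val))
        acc, auroc, mf1 = _eval_parent_on(model, sources[held_out].oct_test,
                                          thresholds)
        rows.append({"held_out": held_out, "accuracy": acc, "auroc": auroc,
                     "macro_f1": mf1})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    parent: TrainConfig = field(default_factory=TrainConfig)
    staging: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=8))
    fundus_model: TrainConfig = field(default_factory=TrainConfig)
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    align_epochs: int = 40
    bridge_weights: BridgeLossWeights = field(default_factory=BridgeLossWeights)
    bridge_epochs: int = 20
    near_band: float = 0.05
    q_threshold: float = 0.8
    n_bootstrap: int = 200

    def hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)
        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


class HMSModel:
    """End-to-end hierarchical screening model over a dataset bundle.

    ``fit`` trains every component in dependency order -- parent screen,
    AMD stager, fundus DR stager, stage-1 alignment, stage-2 bridge --
    then calibrates thresholds on the validation split and evaluates on
    the held-out test split.  Returns an :class:`HMSResults`.
    """

    def __init__(self, bundle: DatasetBundle,
                 config: PipelineConfig | None = None):
        self.bundle = bundle
        self.config = config or PipelineConfig()

    def fit(self, seed: int = 0) -> "HMSResults":
        cfg = self.config
        bundle = self.bundle
        enc_oct = build_encoder(cfg.encoder, np.random.default_rng([seed, 1]))
        parent, parent_hist = train_parent(bundle, enc_oct, cfg.parent, seed)

        amd = train_staging(bundle, parent, K=5, cfg=cfg.staging, task="amd",
                            seed=seed)
        enc_fun = build_encoder(cfg.encoder, np.random.default_rng([seed, 2]))
        dr = train_fundus_model(bundle, cfg.fundus_model, seed,
                                encoder=enc_fun)

        align = train_alignment(bundle, parent.encoder, dr.encoder,
                                cfg.alignment, epochs=cfg.align_epochs,
                                seed=seed)
        # unsupervised severity proxy for severity-rank pseudo-pairing
        oct_severity = parent.predict_probs(bundle.oct_train)[:, DR]
        bridge_res = train_bridge(bundle, parent.encoder, dr.encoder, align,
                                  dr.head, cfg.bridge_weights,
                                  epochs=cfg.bridge_epochs, seed=seed,
                                  oct_severity=oct_severity)

        val_probs = parent.predict_probs(bundle.oct_val)
        val_labels = stack_labels(bundle.oct_val)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            thresholds = optimize_thresholds(val_probs, val_labels)

        test_probs = parent.predict_probs(bundle.oct_test)
        test_labels = stack_labels(bundle.oct_test)
        table = evaluate_multilabel(test_probs, thresholds, test_labels,
                                    n_bootstrap=cfg.n_bootstrap, seed=seed)
        table_05 = evaluate_multilabel(test_probs, ThresholdSet.fixed(0.5),
                                       test_labels, n_bootstrap=0, seed=seed)
        calib = ece(test_probs, test_labels)

        return HMSResults(
            model=self, parent=parent, amd_stager=amd, dr_stager=dr,
            align=align, bridge=bridge_res, thresholds=thresholds,
            metrics=table, metrics_fixed05=table_05, calibration=calib,
            parent_history=parent_hist, seed=seed,
            test_probs=test_probs, test_labels=test_labels)


@dataclass
class HMSResults:
    """Fitted components, calibrated thresholds and held-out metrics."""

    model: HMSModel
    parent: ParentModel
    amd_stager: StagingModel
    dr_stager: StagingModel
    align: object
    bridge: BridgeResult
    thresholds: ThresholdSet
    metrics: pd.DataFrame
    metrics_fixed05: pd.DataFrame
    calibration: object
    parent_history: list
    seed: int
    test_probs: np.ndarray
    test_labels: np.ndarray

    # -- headline numbers -----------------------------------------------------
    @property
    def macro_f1(self) -> float:
        return multilabel_summary(self.metrics)["macro_f1"]

    @property
    def macro_f1_fixed05(self) -> float:
        return multilabel_summary(self.metrics_fixed05)["macro_f1"]

    def holdout_recall_at_1(self) -> float:
        return float(self.align.best_recall)

    def holdout_agreement(self) -> float:
        return float(self.bridge.best_agreement)

    def qc_coverage(self, q_threshold: float | None = None) -> float:
        """Fraction of hold-out OCT projections passing the QC gate."""
        qt = q_threshold or self.model.config.q_threshold
        qs = self.holdout_q_scores()
        return float((qs >= qt).mean())

    def holdout_q_scores(self) -> np.ndarray:
        pairs = self.model.bundle.paired_holdout
        z = encode([p[0] for p in pairs], self.parent.encoder)
        proj = self.bridge.projector.project(z)
        return qc_score(proj, self.bridge.bank)

    def infer(self, oct_sample: ImageSample, audit_log=None) -> DiagnosisReport:
        return infer(oct_sample, self.parent, self.thresholds,
                     self.amd_stager, self.dr_stager,
                     self.bridge.projector, self.bridge.bank,
                     near_band=self.model.config.near_band,
                     q_threshold=self.model.config.q_threshold,
                     audit_log=audit_log, seed=self.seed,
                     config_hash=self.model.config.hash())

    def summary(self) -> pd.DataFrame:
        """Key held-out numbers in one table."""
        rows = [
            ("test macro-F1 (calibrated thresholds)", self.macro_f1),
            ("test macro-F1 (fixed 0.5)", self.macro_f1_fixed05),
            ("test micro-F1", multilabel_summary(self.metrics)["micro_f1"]),
            ("test ECE", self.calibration.ece),
            ("hold-out Recall@1", self.holdout_recall_at_1()),
            ("hold-out fundus agreement", self.holdout_agreement()),
            ("QC coverage (q >= gate)", self.qc_coverage()),
            ("AMD staging accuracy", self.amd_stager.accuracy),
            ("DR staging accuracy", self.dr_stager.accuracy),
        ]
        for name in CLASS_NAMES:
            rows.append((f"threshold {name}", self.thresholds[name]))
        return pd.DataFrame(rows, columns=["quantity", "value"])
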