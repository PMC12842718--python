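# Methods

This note documents the models, the synthetic data the package is
exercised on, the numerical choices, and the limits of what the test
suite demonstrates.

## The screening model

An OCT B-scan `x` is encoded by a small CNN into an embedding
`z = f(x) ∈ R^d` (d = 64 by default) and screened by four independent
sigmoid heads for {NORM, AMD, DR, DME}. Multi-label sigmoids rather than
a softmax allow comorbidity: probabilities do not compete for mass.

The parent objective is focal-weighted binary cross-entropy

    L = (1/NC) Σ_n Σ_c α_c (1 − p_t)^γ (−log p_t),
    p_t = p_{nc} if y_{nc} = 1 else 1 − p_{nc},

with a focusing factor γ = 2, per-class weights α (default
(1, 1, 1, 2.5): DME is the rare class at 8.6% prevalence and receives
the largest weight), and label smoothing ε = 0.05 applied as
y ← y(1−ε) + ε/2. The −log p_t terms are evaluated in log space
(softplus of the logit). This matters: clamping probabilities and
masking the gradient outside the clamp creates a dead zone in which a
saturated logit can never recover — we observed exactly this failure on
the rare DME class before switching to the log-space form. A soft
co-activation penalty R_co = E[p_AMD · p_DR] (weight 0.1, configurable,
0 disables it) discourages unsupported joint AMD–DR confidence without
forbidding true comorbidity.

Staging specialists are softmax heads over K classes: AMD staging
(K = 5, AREDS-style stages) runs on OCT with hybrid feature fusion —
the specialist embedding concatenated with the frozen parent embedding —
while DR staging (K = 4, ICDR stages MILD_NPDR..PDR) is a fundus model.
The DR head deliberately acts on the fundus embedding alone, because the
bridge must be able to feed it projected OCT embeddings. The fundus
model is trained multi-task: focal multi-label loss over the whole
fundus corpus (which carries the same label space) plus stage
cross-entropy on its DR subset, sharing one encoder. This matters twice
over: a stage-only fundus encoder leaves non-DR fundus embeddings
unstructured, which scatters the class-conditional alignment positives
and makes the staging head's behaviour on normal eyes arbitrary (the
bridge-agreement metric then measures noise), while a multi-label-only
encoder compresses away the severity detail the stage head needs. The
joint objective keeps both structures in one embedding space.

## The cross-modal bridge

Stage 1 aligns the OCT and fundus latent spaces contrastively with
NT-Xent, a momentum key encoder (m = 0.999) and a FIFO queue of 512
negatives. Because the corpora are strictly unpaired, positives are
constructed without ground-truth pairs, by strategy (configurable):
same-state augmented views within a modality, and cross-modal
class-conditional positives — an OCT and a fundus sample sharing the
same 4-bit label signature count as a positive pair. Under
class-conditional positives, queue entries with the query's own
signature are false negatives; they are masked out of the NT-Xent
denominator (as in supervised contrastive learning), otherwise the loss
has a floor at roughly the log of the same-class queue fraction and
learning stalls. The conv encoders stay frozen in stage 1 and the
alignment lives in the projection heads: the fundus embedding space must
not move after the DR stager is trained on it, and the bridge's
regression targets live in that space. The paired hold-out (3% of eyes)
is used only to track Recall@1 and select the best checkpoint.

Stage 2 trains a small regression projector g (2-layer MLP,
hidden = 4d) from OCT embeddings into the fundus embedding space.
Regression targets are pseudo-pairs: each OCT embedding is matched to
its top-1 cosine neighbour among a per-epoch resampled fundus candidate
pool, in the stage-1 projection space. Class-level matching alone has a
blind spot: within the DR class the matched stage is random, so the
projector regresses every DR eye onto the class mean and no severity
information crosses the bridge. DR-positive OCT samples are therefore
re-matched by severity *rank*: OCT eyes ordered by the parent model's
DR probability (an unsupervised severity proxy — it rises with lesion
burden), fundus candidates by the staging head's expected stage, paired
by quantile. No ground-truth pairing and no OCT stage labels enter; the
unpaired protocol is intact.

The objective is the weighted seven-component composite

    L = λ_mse·L_MSE + λ_cos·L_cos + λ_kl·L_KL + λ_nce·L_InfoNCE
      + λ_proto·L_proto + λ_mmd·L_MMD + λ_coral·L_CORAL  (+ λ_cyc·L_cycle)

with λ_InfoNCE = 1.0, λ_MSE = 10.0 and the remaining weights 0.5
(inside the stated [0.1, 1.0] band); the cycle term is implemented but
off by default. Which distributions the KL term should compare was a
genuinely open choice; here it is semantic distillation: the KL between
the frozen fundus staging head's softmax on the pseudo-target and on
the projection, pushing the projection to reproduce the target's stage
profile as read by the very head the bridge ultimately feeds (an
embedding-coordinate KL variant matched geometry but not stage
semantics). The prototype term pulls each projection toward the
per-stage mean fundus embedding of the class pseudo-labelled by the
fundus staging head on the matched target (the true DR stage of an
unpaired OCT eye is unknown by construction). MMD uses a biased
V-statistic with an RBF kernel and a median-heuristic bandwidth
(overridable); CORAL uses sample covariances with the n−1 denominator
and the 1/(4d²) normalization.

### QC gate

At inference, an OCT-only DR staging is accepted only if the projection
quality q ≥ 0.8, where q is the maximum cosine similarity between the
projected embedding and a per-stage prototype bank fitted on fundus
training embeddings. Two interpretation choices here were genuinely
open: (i) with no fundus image available at OCT-only inference, the
"reference fundus embedding" is taken to be the nearest bank prototype;
(ii) the cosine is evaluated on vectors centered at a *healthy
reference point* — the mean embedding of the non-DR fundus training
samples — so each prototype direction reads as "departure from healthy
appearance toward stage s". Raw embedding-space cosines saturate near 1
for every input (all embeddings share a dominant mean direction), and
centering at the global fundus mean leaves the mild prototype nearly
collinear with healthy eyes; both alternatives render the score
non-discriminative. Peripheral-only DR eyes
(whose B-scans carry no DR cue) project near the normal cluster, far
from every DR-stage prototype, and therefore receive lower q — the gate
defers exactly the cases OCT cannot stage.

## Calibration

Per-class decision thresholds maximize F1 on the validation split only,
by exhaustive search over the unique predicted probabilities; F1 ties
break to the smallest threshold (screening favours recall). A class
without positive validation labels falls back to 0.5 with a warning.
Expected calibration error uses B = 15 equal-width bins per class; the
reported number is the unweighted mean of per-class binary ECEs (the
binning count and the aggregation rule are both package choices).
Temperature scaling (bounded 1-D search on log T ∈ [log 0.05, log 20])
and per-class isotonic regression are provided as post-hoc baselines.
A vacuously perfect class (no positives, no predicted positives) counts
F1 = 1.

## Routing

Routing is a pure function of (probabilities, thresholds, q): a
pathology c is flagged iff p_c ≥ T_c; no flags → LOW_RISK; AMD →
AMD staging; DR → OCT-only DR staging if q ≥ 0.8, otherwise deferral to
fundus imaging; DME → monitoring flag. A REFERRAL marker is added when
any flagged probability sits within 0.05 of its threshold (the
near-threshold band is a package default; configurable) or when the QC
gate fails. Staging ties resolve to the lowest stage index —
conservative under-staging is surfaced through referral rather than
silent escalation.

## Synthetic cohort

The generator renders a shared per-eye latent disease state into both
modalities and is the package's study condition, not a photorealistic
simulator. Defaults: 2400 eyes, 64×64 pixels, AMD prevalence 0.55, DR
0.25, DME marginal 0.086, AMD–DR comorbidity 0.02, paired hold-out
fraction 0.03, peripheral-only DR fraction 0.08 (of DR eyes; the order
of magnitude of cross-modal discrepancies a paired review would flag),
two scanner domains A/B differing in gamma (1.0 vs 0.8), blur (0 vs
0.5 px) and additive noise (0 vs 0.04). DME marginal prevalence is
sampled directly and forces DR (edema implies retinopathy), so the DR
marginal is slightly above its nominal 0.25. Severities are
stage-conditional Poisson counts and Gamma areas with monotone means,
so staging errors concentrate on adjacent stages.

OCT rendering: curved layered bands; drusen bumps (early/intermediate
AMD), thinning with hypertransmission (atrophy), a bright subretinal
blob (nAMD), a bright wedge (fibrosis); DME thickens the retina and
carves dark intraretinal cysts scaled by fluid area; DR adds small
hyperreflective dots scaled by lesion count — except peripheral-only DR
eyes, whose OCT renders bit-identically to a DR-free eye (per-feature
random substreams make this an exact construction, not an
approximation). Fundus rendering: optic disc, radial vessels, dark
dots/blobs for DR (placed outside the central region for
peripheral-only eyes), tortuous squiggles for PDR, central pale specks
for AMD.

What the generator does not emulate: real speckle statistics, 3-D
volumes, vessel topology, acquisition artifacts, inter-grader label
noise. Passing tests therefore demonstrate that the machinery —
losses, alignment, bridge, calibration, routing — behaves as specified
on a controlled cohort, not that the pipeline reaches clinical
performance on real scanners.

## Training protocol and problem sizes

AdamW with cosine annealing throughout. The parent screen and the
multi-task fundus model train with batch 48 at lr 3e-3 for 20 epochs
with the augmentations a screening protocol would use (random
horizontal flips, ±10° rotations, brightness/contrast jitter ±0.1); the
lr is higher than the 3e-4 customary for fine-tuning ImageNet-pretrained
backbones because these tiny CNNs train from scratch on a small cohort.
The AMD specialist trains 8 epochs; alignment 40 epochs over cached
embeddings (the encoders being frozen, each image's two augmented views
are embedded once, so alignment epochs cost almost nothing); the bridge
20 epochs over embeddings. The default end-to-end
run (2400 eyes) fits on one CPU core in under ten minutes; the tiny
backbone (3 conv blocks, widths 8/16/64, batchnorm, max-pool) uses a
readout that concatenates global average and global max pooling —
average pooling alone dilutes few-pixel lesions by the spatial grid
size and measurably depresses detection of the dot-like DR/DME cues.

## Numerical choices

- Probability guard in focal terms: log-space softplus (no clamping of
  the log terms); modulating factors use probabilities clamped to
  [1e-7, 1−1e-7].
- Cosine/normalization epsilon 1e-12 everywhere.
- The exhaustive F1 threshold search uses the unique probabilities as
  the candidate set; this cannot do worse on validation than any fixed
  threshold that induces the same decision set (0.5 included).
- Bootstrap CIs: percentile method, 1000 resamples (reduced in the
  end-to-end facade for runtime), seeded.
- All randomness flows from integer seeds through independent
  `numpy` substreams keyed by (seed, eye index, purpose), so dataset
  generation is order-independent and byte-reproducible.

## Known limitations

- Recall@1 of the stage-1 alignment at this cohort scale is modest
  (class-conditional positives can align classes, not instances); it is
  well above the 1/N chance level but far from instance-level
  retrieval.
- The DR staging specialist sees only a few hundred fundus images;
  its absolute accuracy is limited, which also bounds the
  bridge-agreement metric (argmax agreement of a weak head is noisier
  than of a strong one).
- The QC score is a one-dimensional summary; it gates distributional
  outliers well (peripheral-only DR) but cannot detect every semantic
  mismatch.
- Temperature scaling and isotonic regression are fitted per class on
  validation data and compared by validation BCE / monotone fit only;
  no claim is made that one dominates in general.
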