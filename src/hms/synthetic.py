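"""Synthetic dual-modality retina generator.

Renders a shared per-eye latent disease state into OCT-like B-scans and
fundus-like en-face images, with AMD-heavy class imbalance, rare DME, a
small paired hold-out kept strictly out of training, scanner-style domain
shift, and a configurable fraction of "peripheral-only" DR eyes whose DR
signs appear only in the fundus rendering (macular OCT cannot see them).

Geometry is parameterized in relative coordinates so ``image_size`` is a
free choice; 64x64 is the default working size.  Every eye draws from its
own counter-derived random substream, so generation is order-independent
and a (config, seed) pair reproduces a bundle byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .types import (AMD, DME, DR, FUNDUS, NORM, OCT, DatasetBundle,
                    ImageSample, LatentEyeState)

__all__ = ["GenConfig", "sample_eye_state", "render_oct", "render_fundus",
           "apply_domain_shift", "build_dataset", "export_dataset"]

# Stage-conditional severity parameters.  Counts are Poisson, areas/sizes
# Gamma; means rise monotonically with stage so that stages are separable
# but adjacent stages overlap (misclassifications should land on
# neighbours, as they do clinically).
AMD_STAGE_PROBS = (0.30, 0.28, 0.16, 0.16, 0.10)
DR_STAGE_PROBS = (0.35, 0.30, 0.20, 0.15)
DRUSEN_COUNT_MEAN = (4.0, 9.0, 1.0, 2.0, 2.0)   # per AMD stage
DRUSEN_SIZE_SHAPE = 3.0
DRUSEN_SIZE_SCALE = (0.5, 0.9, 0.3, 0.4, 0.4)
FLUID_AREA_SHAPE = 4.0
FLUID_AREA_SCALE = 0.8
LESION_COUNT_BASE = 2.0      # Poisson mean = base + slope * dr_stage, +1
LESION_COUNT_SLOPE = 7.0


@dataclass
class GenConfig:
    """Study conditions for one synthetic cohort.

    ``prevalence`` gives marginal label probabilities; DME implies DR, so
    DME-positive eyes are forced DR-positive.  ``dme_given_dr`` is used
    only when ``prevalence['dme']`` is None.  Default prevalences follow
    an AMD-heavy screening cohort (AMD > 50%, DME 8.6%).
    """

    n_eyes: int = 2400
    prevalence: dict = field(default_factory=lambda: {
        "amd": 0.55, "dr": 0.25, "dme": 0.086})
    amd_dr_comorbidity_rate: float = 0.02
    dme_given_dr: float | None = None
    paired_fraction: float = 0.03
    peripheral_only_fraction: float = 0.08
    image_size: int = 64
    domain_probs: dict = field(default_factory=lambda: {"A": 0.5, "B": 0.5})
    noise_level: dict = field(default_factory=lambda: {"A": 0.0, "B": 0.04})
    contrast_gamma: dict = field(default_factory=lambda: {"A": 1.0, "B": 0.8})
    blur: dict = field(default_factory=lambda: {"A": 0.0, "B": 0.5})
    seed: int = 0

    def __post_init__(self):
        probs = [self.amd_dr_comorbidity_rate, self.paired_fraction,
                 self.peripheral_only_fraction]
        probs += [v for v in self.prevalence.values() if v is not None]
        if self.dme_given_dr is not None:
            probs.append(self.dme_given_dr)
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        pa = self.prevalence.get("amd", 0.0)
        pd = self.prevalence.get("dr", 0.0)
        r = self.amd_dr_comorbidity_rate
        if r > min(pa, pd) + 1e-12:
            raise ValueError("comorbidity rate exceeds a marginal prevalence")

    def domains(self):
        return sorted(self.domain_probs)


# ---------------------------------------------------------------------------
# latent state sampling
# ---------------------------------------------------------------------------

def sample_eye_state(config: GenConfig, rng: np.random.Generator,
                     eye_id: str = "eye00000") -> LatentEyeState:
    """Draw one latent eye state from the configured cohort distribution."""
    prev = config.prevalence
    if prev.get("norm") == 1.0:
        domain = _pick_domain(config, rng)
        return LatentEyeState(eye_id=eye_id, domain_id=domain)

    pa = prev.get("amd", 0.0)
    pd = prev.get("dr", 0.0)
    r = config.amd_dr_comorbidity_rate
    # joint (AMD, DR) with the requested marginals and joint mass
    u = rng.random()
    if u < r:
        has_amd, has_dr = True, True
    elif u < pa:
        has_amd, has_dr = True, False
    elif u < pa + pd - r:
        has_amd, has_dr = False, True
    else:
        has_amd, has_dr = False, False

    p_dme = prev.get("dme")
    if p_dme is not None:
        has_dme = rng.random() < p_dme
        if has_dme:
            has_dr = True           # DME implies DR
    else:
        has_dme = has_dr and rng.random() < (config.dme_given_dr or 0.0)

    amd_stage = int(rng.choice(5, p=AMD_STAGE_PROBS)) if has_amd else None
    dr_stage = int(rng.choice(4, p=DR_STAGE_PROBS)) if has_dr else None

    drusen_count = drusen_size = 0.0
    if has_amd:
        drusen_count = float(rng.poisson(DRUSEN_COUNT_MEAN[amd_stage]))
        drusen_size = float(rng.gamma(DRUSEN_SIZE_SHAPE,
                                      DRUSEN_SIZE_SCALE[amd_stage]))
    fluid_area = float(rng.gamma(FLUID_AREA_SHAPE, FLUID_AREA_SCALE)) \
        if has_dme else 0.0
    lesion_count = 0
    peripheral = False
    if has_dr:
        lesion_count = 1 + int(rng.poisson(
            LESION_COUNT_BASE + LESION_COUNT_SLOPE * dr_stage))
        peripheral = rng.random() < config.peripheral_only_fraction

    return LatentEyeState(
        eye_id=eye_id, has_amd=has_amd, amd_stage=amd_stage, has_dr=has_dr,
        dr_stage=dr_stage, has_dme=has_dme, drusen_count=drusen_count,
        drusen_size=drusen_size, fluid_area=fluid_area,
        lesion_count=lesion_count, peripheral_only_dr=peripheral,
        domain_id=_pick_domain(config, rng))


def _pick_domain(config: GenConfig, rng: np.random.Generator) -> str:
    names = config.domains()
    p = np.array([config.domain_probs[d] for d in names], dtype=float)
    return str(rng.choice(names, p=p / p.sum()))


# ---------------------------------------------------------------------------
# OCT rendering
# ---------------------------------------------------------------------------

def _gaussian_blob(canvas, cy, cx, sy, sx, amplitude):
    s = canvas.shape[0]
    yy, xx = np.mgrid[0:s, 0:canvas.shape[1]]
    canvas += amplitude * np.exp(-(((yy - cy) / sy) ** 2
                                   + ((xx - cx) / sx) ** 2) / 2.0)


def render_oct(state: LatentEyeState, config: GenConfig,
               rng: np.random.Generator, return_masks: bool = False):
    """Render a layered-band B-scan from a latent state.

    AMD adds stage-dependent structure (drusen bumps, thinning with
    hypertransmission, a bright subretinal blob, a bright wedge), DME dark
    intraretinal cysts scaled by fluid_area, and DR small hyperreflective
    dots scaled by lesion_count -- unless the eye is peripheral-only DR,
    in which case the B-scan carries no DR cue at all.
    """
    s = int(config.image_size)
    # independent substreams so skipping one feature never shifts another
    r_geom, r_drusen, r_blob, r_cyst, r_dot, r_noise = rng.spawn(6)

    img = np.full((s, s), 0.04, dtype=np.float64)
    x = np.arange(s)
    xn = x / (s - 1)
    curve = 0.10 * (4 * (xn - 0.5) ** 2) + r_geom.uniform(-0.02, 0.02)
    surface = ((0.32 + curve) * s).astype(int)  # ILM row per column

    thin = 0.6 if (state.has_amd and state.amd_stage == 2) else 1.0
    if state.has_dme:    # macular edema thickens the retina
        thin *= min(1.8, 1.25 + 0.15 * state.fluid_area)
    t_inner = max(2, int(0.10 * s * thin))
    t_onl = max(2, int(0.12 * s * thin))
    rows = np.arange(s)[:, None]
    ilm = surface[None, :]
    rpe = ilm + t_inner + t_onl

    img[(rows >= ilm) & (rows < ilm + 2)] = 0.55                  # ILM line
    img[(rows >= ilm + 2) & (rows < ilm + t_inner)] = 0.35        # inner retina
    img[(rows >= ilm + t_inner) & (rows < rpe)] = 0.15            # ONL (dark)
    img[(rows >= rpe) & (rows < rpe + 2)] = 0.85                  # RPE line
    choroid = (rows >= rpe + 2) & (rows < rpe + 2 + int(0.12 * s))
    img[choroid] = 0.30

    masks = {"drusen": np.zeros((s, s), bool), "blob": np.zeros((s, s), bool),
             "fluid": np.zeros((s, s), bool), "lesion": np.zeros((s, s), bool)}

    if state.has_amd:
        stage = state.amd_stage
        if stage in (0, 1):     # drusen bumps at the RPE
            for _ in range(int(state.drusen_count)):
                cx = int(r_drusen.uniform(0.15, 0.85) * s)
                w = max(1.2, state.drusen_size * s / 64.0)
                cy = rpe[0, cx]
                before = img.copy()
                _gaussian_blob(img, cy - w * 0.4, cx, w * 0.7, w, 0.5)
                masks["drusen"] |= (img - before) > 0.1
        elif stage == 2:        # atrophy: hypertransmission below the RPE
            c0, c1 = int(0.3 * s), int(0.7 * s)
            band = (rows >= rpe + 2) & (rows < rpe + 2 + int(0.16 * s))
            band &= (np.arange(s)[None, :] >= c0) & (np.arange(s)[None, :] < c1)
            img[band] = np.maximum(img[band], 0.75)
        elif stage == 3:        # nAMD: bright subretinal blob
            cx = int(r_blob.uniform(0.38, 0.62) * s)
            cy = rpe[0, cx] - int(0.04 * s)
            before = img.copy()
            _gaussian_blob(img, cy, cx, 0.06 * s, 0.09 * s, 0.8)
            masks["blob"] = (img - before) > 0.1
        else:                   # subretinal fibrosis: bright wedge
            cx = int(r_blob.uniform(0.4, 0.6) * s)
            half = int(0.16 * s)
            for dy in range(int(0.08 * s)):
                lo = max(0, cx - half + 2 * dy)
                hi = min(s, cx + half - 2 * dy)
                row = rpe[0, cx] - dy
                if 0 <= row < s and lo < hi:
                    img[row, lo:hi] = 0.9
                    masks["blob"][row, lo:hi] = True

    if state.has_dme:
        n_cysts = 2 + int(state.fluid_area)
        yy, xx = np.mgrid[0:s, 0:s]
        for _ in range(n_cysts):
            cx = int(r_cyst.uniform(0.2, 0.8) * s)
            cy = ilm[0, cx] + int(r_cyst.uniform(0.4, 1.2) * t_inner)
            ay = (2.0 + 1.2 * state.fluid_area) * s / 64.0
            ax = ay * r_cyst.uniform(1.3, 2.2)
            ell = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
            img[ell] = 0.0
            masks["fluid"] |= ell

    if state.has_dr and not state.peripheral_only_dr:
        for _ in range(int(state.lesion_count)):
            cx = int(r_dot.uniform(0.1, 0.9) * s)
            cy = int(ilm[0, cx] + r_dot.uniform(0.15, 0.85) * (t_inner + t_onl))
            cy = min(s - 3, cy)
            img[cy:cy + 3, max(0, cx - 1):cx + 2] = 1.0
            masks["lesion"][cy:cy + 3, max(0, cx - 1):cx + 2] = True

    img = img + r_noise.normal(0.0, 0.05, size=(s, s))   # speckle
    img = np.clip(img, 0.0, 1.0)

    sample = ImageSample(pixels=img, modality=OCT, labels=state.labels(),
                         eye_id=state.eye_id, domain_id=state.domain_id,
                         stage=state.amd_stage)
    return (sample, masks) if return_masks else sample


# ---------------------------------------------------------------------------
# fundus rendering
# ---------------------------------------------------------------------------

def render_fundus(state: LatentEyeState, config: GenConfig,
                  rng: np.random.Generator, return_masks: bool = False):
    """Render an en-face fundus image: disc, radial vessels, DR lesions.

    DR renders dark dots/blobs scaled by lesion_count plus tortuous vessel
    squiggles for PDR; peripheral-only eyes receive all their lesions
    outside the central macular region.  AMD renders central pale specks.
    """
    s = int(config.image_size)
    r_geom, r_vessel, r_lesion, r_squiggle, r_amd, r_noise = rng.spawn(6)

    yy, xx = np.mgrid[0:s, 0:s]
    cy, cx = s / 2, s / 2
    radius = np.hypot(yy - cy, xx - cx)
    img = np.clip(0.45 - 0.25 * (radius / (0.7 * s)) ** 2, 0.1, None)

    # optic disc near the nasal edge
    dy, dx = s * 0.5 + r_geom.uniform(-2, 2), s * 0.82
    disc = np.hypot(yy - dy, xx - dx) < 0.09 * s
    img[disc] = 0.85
    vessel_mask = np.zeros((s, s), bool)
    for k in range(7):
        ang = np.pi * (0.55 + 0.9 * k / 6) + r_vessel.uniform(-0.08, 0.08)
        t = np.linspace(0, 1.1 * s, 4 * s)
        bend = r_vessel.uniform(-0.25, 0.25)
        py = dy + t * np.sin(ang) + bend * t**2 / s
        px = dx - t * np.abs(np.cos(ang))
        ok = (py > 0) & (py < s - 1) & (px > 0) & (px < s - 1)
        vessel_mask[py[ok].astype(int), px[ok].astype(int)] = True
    vessel_mask = ndimage.binary_dilation(vessel_mask)
    img[vessel_mask] = 0.16

    masks = {"disc": disc, "vessel": vessel_mask,
             "lesion": np.zeros((s, s), bool),
             "squiggle": np.zeros((s, s), bool),
             "amd": np.zeros((s, s), bool)}

    if state.has_amd:      # central pale specks (macular drusen, en face)
        for _ in range(max(3, int(state.drusen_count))):
            ly = int(cy + r_amd.normal(0, 0.07 * s))
            lx = int(cx + r_amd.normal(0, 0.07 * s))
            if 1 <= ly < s - 1 and 1 <= lx < s - 1:
                img[ly - 1:ly + 1, lx - 1:lx + 1] = 0.75
                masks["amd"][ly - 1:ly + 1, lx - 1:lx + 1] = True

    if state.has_dr:
        central_r, peripheral_r = 0.22 * s, 0.32 * s
        for _ in range(int(state.lesion_count)):
            if state.peripheral_only_dr:
                rr = r_lesion.uniform(peripheral_r, 0.48 * s)
            else:
                rr = r_lesion.uniform(0.02 * s, central_r)
            ang = r_lesion.uniform(0, 2 * np.pi)
            ly, lx = int(cy + rr * np.sin(ang)), int(cx + rr * np.cos(ang))
            if not (1 <= ly < s - 3 and 1 <= lx < s - 3):
                continue
            # dot (microaneurysm) vs blob (hemorrhage); hemorrhages grow
            # with severity, separating the NPDR grades visually
            blob = r_lesion.random() > 0.6
            sz = 1 + (1 + (state.dr_stage >= 2)) * blob
            img[ly:ly + sz + 1, lx:lx + sz + 1] = 0.05
            masks["lesion"][ly:ly + sz + 1, lx:lx + sz + 1] = True
        if state.dr_stage == 3:    # PDR: tortuous neovascular squiggles
            for _ in range(5):
                py = dy + r_squiggle.uniform(-0.12, 0.12) * s
                px = dx - 0.12 * s
                for _ in range(int(0.7 * s)):
                    py += r_squiggle.normal(0, 1.4)
                    px -= abs(r_squiggle.normal(0.7, 0.5))
                    iy, ix = int(py), int(px)
                    if 0 <= iy < s and 0 <= ix < s:
                        img[iy, ix] = 0.05
                        masks["squiggle"][iy, ix] = True

    img = img + r_noise.normal(0.0, 0.03, size=(s, s))
    img = np.clip(img, 0.0, 1.0)

    sample = ImageSample(pixels=img, modality=FUNDUS, labels=state.labels(),
                         eye_id=state.eye_id, domain_id=state.domain_id,
                         stage=state.dr_stage)
    return (sample, masks) if return_masks else sample


# ---------------------------------------------------------------------------
# domain shift
# ---------------------------------------------------------------------------

def apply_domain_shift(sample: ImageSample, domain_id: str, config: GenConfig,
                       rng: np.random.Generator | None = None) -> ImageSample:
    """Re-render a sample under a domain's gamma/blur/noise; labels unchanged.

    Neutral parameters (gamma 1, blur 0, noise 0) return the pixels
    untouched, so domain "shift" with identity settings is a no-op.
    """
    for table in (config.contrast_gamma, config.blur, config.noise_level):
        if domain_id not in table:
            raise KeyError(f"unknown domain {domain_id!r}")
    gamma = config.contrast_gamma[domain_id]
    blur = config.blur[domain_id]
    noise = config.noise_level[domain_id]
    px = sample.pixels
    if gamma != 1.0:
        px = np.power(px, gamma)
    if blur > 0:
        px = ndimage.gaussian_filter(px, sigma=blur)
    if noise > 0:
        rng = rng or np.random.default_rng(0)
        px = px + rng.normal(0.0, noise, size=px.shape)
    px = np.clip(px, 0.0, 1.0)
    return replace(sample, pixels=px, domain_id=domain_id)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def build_dataset(config: GenConfig) -> DatasetBundle:
    """Render a full mostly-unpaired bundle with a paired hold-out.

    Unpaired eyes are rendered in exactly one modality and split
    eye-disjointly 70/15/15 into train/val/test; a ``paired_fraction``
    subset is rendered in both modalities and placed only in
    ``paired_holdout``.  A 5-fold eye assignment is also emitted.
    """
    n = config.n_eyes
    n_paired = int(round(n * config.paired_fraction))
    if config.paired_fraction > 0 and n_paired < 1:
        raise ValueError("n_eyes too small to honor paired_fraction")
    if n - n_paired < 10:
        raise ValueError("too few unpaired eyes to build training splits")

    assign_rng = np.random.default_rng([config.seed, 2**20])
    order = assign_rng.permutation(n)
    paired_ids = set(order[:n_paired].tolist())
    modality_flip = assign_rng.random(n) < 0.5    # True -> OCT corpus

    bundle = DatasetBundle()
    unpaired_rank: dict[int, int] = {}
    rank = 0
    for i in order:
        if i not in paired_ids:
            unpaired_rank[int(i)] = rank
            rank += 1
    n_unpaired = rank
    n_train = int(0.7 * n_unpaired)
    n_val = int(0.15 * n_unpaired)

    for i in range(n):
        eye_id = f"eye{i:05d}"
        state = sample_eye_state(
            config, np.random.default_rng([config.seed, i, 0]), eye_id)
        bundle.states[eye_id] = state
        bundle.folds[eye_id] = i % 5
        if i in paired_ids:
            o = render_oct(state, config, np.random.default_rng([config.seed, i, 1]))
            f = render_fundus(state, config, np.random.default_rng([config.seed, i, 2]))
            o = apply_domain_shift(o, state.domain_id, config,
                                   np.random.default_rng([config.seed, i, 3]))
            f = apply_domain_shift(f, state.domain_id, config,
                                   np.random.default_rng([config.seed, i, 4]))
            o = replace(o, paired=True)
            f = replace(f, paired=True)
            bundle.paired_holdout.append((o, f))
            continue
        r = unpaired_rank[i]
        split = ("train" if r < n_train else
                 "val" if r < n_train + n_val else "test")
        if modality_flip[i]:
            img = render_oct(state, config, np.random.default_rng([config.seed, i, 1]))
            img = apply_domain_shift(img, state.domain_id, config,
                                     np.random.default_rng([config.seed, i, 3]))
            getattr(bundle, f"oct_{split}").append(img)
        else:
            img = render_fundus(state, config, np.random.default_rng([config.seed, i, 2]))
            img = apply_domain_shift(img, state.domain_id, config,
                                     np.random.default_rng([config.seed, i, 4]))
            getattr(bundle, f"fundus_{split}").append(img)

    bundle.check_disjoint()
    return bundle


def export_dataset(bundle: DatasetBundle, outdir, write_png: bool = True):
    """Write PNGs, an NPZ archive and a manifest CSV for a bundle."""
    import csv
    from pathlib import Path

    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arrays = {}
    rows = []

    def add(sample: ImageSample, split: str):
        key = f"{sample.eye_id}_{sample.modality}"
        arrays[key] = sample.pixels.astype(np.float32)
        if write_png:
            img8 = (np.clip(sample.pixels, 0, 1) * 255).astype(np.uint8)
            Image.fromarray(img8, mode="L").save(outdir / f"{key}.png")
        rows.append({
            "eye_id": sample.eye_id, "modality": sample.modality,
            "norm": sample.labels.y[NORM], "amd": sample.labels.y[AMD],
            "dr": sample.labels.y[DR], "dme": sample.labels.y[DME],
            "stage": "" if sample.stage is None else sample.stage,
            "domain": sample.domain_id, "split": split,
            "paired": int(sample.paired),
        })

    for name, samples in bundle.splits().items():
        for s in samples:
            add(s, name.split("_")[1])
    for o, f in bundle.paired_holdout:
        add(o, "paired_holdout")
        add(f, "paired_holdout")

    np.savez_compressed(outdir / "images.npz", **arrays)
    with open(outdir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return outdir
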