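"""Generator contracts: sampling distributions, rendering rules, pairing
discipline and byte-level determinism."""

import dataclasses

import numpy as np
import pytest

from hms.synthetic import (GenConfig, apply_domain_shift, build_dataset,
                           render_fundus, render_oct, sample_eye_state)
from hms.types import LatentEyeState


def states(config, n, seed=0):
    return [sample_eye_state(config, np.random.default_rng([seed, i, 0]),
                             f"eye{i:05d}") for i in range(n)]


class TestSampling:
    def test_zero_comorbidity_excludes_joint_amd_dr(self):
        cfg = GenConfig(n_eyes=50, amd_dr_comorbidity_rate=0.0,
                        prevalence={"amd": 0.5, "dr": 0.3, "dme": None})
        for s in states(cfg, 400):
            assert not (s.has_amd and s.has_dr)

    def test_all_norm_config(self):
        cfg = GenConfig(n_eyes=50, prevalence={"norm": 1.0},
                        amd_dr_comorbidity_rate=0.0)
        for s in states(cfg, 100):
            assert s.norm
            assert s.drusen_count == 0 and s.fluid_area == 0
            assert s.lesion_count == 0

    def test_dme_marginal_within_three_binomial_sd(self):
        cfg = GenConfig(n_eyes=50)
        n = 10_000
        freq = np.mean([s.has_dme for s in states(cfg, n)])
        p = 0.086
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(freq - p) < 3 * sd

    def test_amd_marginal_matches_prevalence(self):
        cfg = GenConfig(n_eyes=50)
        n = 10_000
        freq = np.mean([s.has_amd for s in states(cfg, n)])
        sd = np.sqrt(0.55 * 0.45 / n)
        assert abs(freq - 0.55) < 3 * sd

    def test_lesion_count_increases_with_dr_stage(self):
        cfg = GenConfig(n_eyes=50)
        by_stage = {k: [] for k in range(4)}
        for s in states(cfg, 6000):
            if s.has_dr:
                by_stage[s.dr_stage].append(s.lesion_count)
        means = [np.mean(by_stage[k]) for k in range(4)]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            GenConfig(paired_fraction=1.5)
        with pytest.raises(ValueError):
            GenConfig(prevalence={"amd": 0.1, "dr": 0.1, "dme": 0.05},
                      amd_dr_comorbidity_rate=0.2)

    def test_state_invariants(self):
        with pytest.raises(ValueError):
            LatentEyeState(eye_id="e", has_amd=True)  # missing stage
        s = LatentEyeState(eye_id="e", has_dr=False, peripheral_only_dr=True)
        assert not s.peripheral_only_dr   # only meaningful with DR


class TestRenderOCT:
    cfg = GenConfig(n_eyes=50)

    def test_norm_state_has_no_pathology_masks(self):
        s = LatentEyeState(eye_id="e0")
        _, masks = render_oct(s, self.cfg, np.random.default_rng(0),
                              return_masks=True)
        for name in ("drusen", "blob", "fluid", "lesion"):
            assert not masks[name].any()

    def test_bit_identical_for_same_state_and_seed(self):
        s = LatentEyeState(eye_id="e0", has_amd=True, amd_stage=1,
                           drusen_count=5, drusen_size=1.5)
        a = render_oct(s, self.cfg, np.random.default_rng(77)).pixels
        b = render_oct(s, self.cfg, np.random.default_rng(77)).pixels
        np.testing.assert_array_equal(a, b)

    def test_rendered_dot_count_increases_with_stage(self):
        cfg = self.cfg
        counts = []
        for stage in range(4):
            tot = 0.0
            for i in range(500):
                rng = np.random.default_rng([stage, i])
                lesions = 1 + int(rng.poisson(2.0 + 4.0 * stage))
                s = LatentEyeState(eye_id="e", has_dr=True, dr_stage=stage,
                                   lesion_count=lesions)
                _, masks = render_oct(s, cfg, np.random.default_rng([9, i]),
                                      return_masks=True)
                tot += masks["lesion"].sum()
            counts.append(tot / 500)
        assert all(a < b for a, b in zip(counts, counts[1:]))

    def test_peripheral_only_dr_leaves_no_dr_cue(self):
        """A peripheral-only DR eye renders identically to the same eye
        with DR removed: macular OCT carries no DR-correlated pixels."""
        cfg = self.cfg
        s_per = LatentEyeState(eye_id="e", has_dr=True, dr_stage=3,
                               lesion_count=12, peripheral_only_dr=True)
        s_none = LatentEyeState(eye_id="e", has_dr=False)
        a, masks = render_oct(s_per, cfg, np.random.default_rng(5),
                              return_masks=True)
        b = render_oct(s_none, cfg, np.random.default_rng(5))
        assert not masks["lesion"].any()
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_pixels_bounded(self):
        s = LatentEyeState(eye_id="e", has_amd=True, amd_stage=3)
        img = render_oct(s, self.cfg, np.random.default_rng(1)).pixels
        assert img.min() >= 0.0 and img.max() <= 1.0


class TestRenderFundus:
    cfg = GenConfig(n_eyes=50)

    def test_norm_has_no_lesions_outside_disc_and_vessels(self):
        s = LatentEyeState(eye_id="e0")
        _, masks = render_fundus(s, self.cfg, np.random.default_rng(0),
                                 return_masks=True)
        assert not masks["lesion"].any()
        assert not masks["squiggle"].any()

    def test_peripheral_only_lesions_avoid_central_region(self):
        s = LatentEyeState(eye_id="e", has_dr=True, dr_stage=2,
                           lesion_count=12, peripheral_only_dr=True)
        _, masks = render_fundus(s, self.cfg, np.random.default_rng(3),
                                 return_masks=True)
        size = self.cfg.image_size
        yy, xx = np.mgrid[0:size, 0:size]
        central = np.hypot(yy - size / 2, xx - size / 2) < 0.22 * size
        assert masks["lesion"].any()
        assert not (masks["lesion"] & central).any()

    def test_pdr_squiggles_present_only_for_stage_3(self):
        for stage in range(4):
            s = LatentEyeState(eye_id="e", has_dr=True, dr_stage=stage,
                               lesion_count=6)
            _, masks = render_fundus(s, self.cfg, np.random.default_rng(4),
                                     return_masks=True)
            if stage == 3:
                assert masks["squiggle"].sum() > 0
            else:
                assert masks["squiggle"].sum() == 0


class TestDomainShift:
    cfg = GenConfig(n_eyes=50,
                    noise_level={"A": 0.0, "B": 0.05, "I": 0.0},
                    contrast_gamma={"A": 1.0, "B": 0.7, "I": 1.0},
                    blur={"A": 0.0, "B": 0.5, "I": 0.0},
                    domain_probs={"A": 0.5, "B": 0.5})

    def _sample(self, value=0.5):
        s = LatentEyeState(eye_id="e0")
        sample = render_oct(s, self.cfg, np.random.default_rng(0))
        sample.pixels = np.full_like(sample.pixels, value)
        return sample

    def test_identity_domain_is_noop(self):
        sample = self._sample()
        out = apply_domain_shift(sample, "I", self.cfg)
        np.testing.assert_array_equal(out.pixels, sample.pixels)

    def test_gamma_on_constant_image(self):
        sample = self._sample(0.5)
        cfg = dataclasses.replace(self.cfg,
                                  blur={"A": 0, "B": 0, "I": 0},
                                  noise_level={"A": 0, "B": 0, "I": 0})
        out = apply_domain_shift(sample, "B", cfg)
        np.testing.assert_allclose(out.pixels, 0.5**0.7, rtol=1e-12)

    def test_labels_invariant(self):
        s = LatentEyeState(eye_id="e", has_amd=True, amd_stage=0,
                           drusen_count=3, drusen_size=1.0)
        sample = render_oct(s, self.cfg, np.random.default_rng(0))
        out = apply_domain_shift(sample, "B", self.cfg,
                                 np.random.default_rng(1))
        np.testing.assert_array_equal(out.labels.y, sample.labels.y)

    def test_unknown_domain_rejected(self):
        with pytest.raises(KeyError):
            apply_domain_shift(self._sample(), "Z", self.cfg)


class TestBuildDataset:
    def test_paired_fraction_zero(self):
        b = build_dataset(GenConfig(n_eyes=60, paired_fraction=0.0, seed=0))
        assert b.paired_holdout == []

    def test_paired_holdout_size_rounds(self):
        b = build_dataset(GenConfig(n_eyes=300, paired_fraction=0.03, seed=0))
        assert len(b.paired_holdout) == 9

    def test_too_small_for_pairing_raises(self):
        with pytest.raises(ValueError):
            build_dataset(GenConfig(n_eyes=12, paired_fraction=0.01))

    def test_eye_disjoint_splits_and_folds(self, small_bundle):
        small_bundle.check_disjoint()
        fold_values = set(small_bundle.folds.values())
        assert fold_values == {0, 1, 2, 3, 4}
        # paired eyes never appear in any training corpus
        train_ids = {s.eye_id for s in small_bundle.oct_train
                     + small_bundle.fundus_train}
        paired_ids = {p[0].eye_id for p in small_bundle.paired_holdout}
        assert not (train_ids & paired_ids)

    def test_byte_for_byte_determinism(self):
        cfg = GenConfig(n_eyes=80, seed=9)
        a = build_dataset(cfg)
        b = build_dataset(GenConfig(n_eyes=80, seed=9))
        assert len(a.oct_train) == len(b.oct_train)
        for s1, s2 in zip(a.oct_train + a.fundus_test,
                          b.oct_train + b.fundus_test):
            assert s1.eye_id == s2.eye_id
            np.testing.assert_array_equal(s1.pixels, s2.pixels)
        for (o1, f1), (o2, f2) in zip(a.paired_holdout, b.paired_holdout):
            np.testing.assert_array_equal(o1.pixels, o2.pixels)
            np.testing.assert_array_equal(f1.pixels, f2.pixels)

    def test_label_counts_logged_per_split(self, small_bundle):
        counts = small_bundle.label_counts()
        assert set(counts) >= {"oct_train", "fundus_train", "paired_holdout"}
        assert counts["oct_train"].shape == (4,)


def test_two_layer_cnn_learns_amd_from_default_renders():
    """Learnability bound: a small 2-conv-block CNN separates AMD from
    non-AMD at AUROC > 0.9 on 1000 default-config OCT renders."""
    from sklearn.metrics import roc_auc_score

    from hms import nn
    from hms.nn import Tensor

    cfg = GenConfig(n_eyes=50)
    states_1k = states(cfg, 1000, seed=77)
    x = np.stack([
        render_oct(s, cfg, np.random.default_rng([77, i, 1])).pixels
        for i, s in enumerate(states_1k)])[:, None].astype(np.float32)
    y = np.array([s.has_amd for s in states_1k], dtype=np.float32)

    rng = np.random.default_rng(0)
    net = nn.Sequential(
        nn.Conv2d(1, 8, 3, padding=1, rng=rng), nn.ReLU(), nn.MaxPool2d(2),
        nn.Conv2d(8, 16, 3, padding=1, rng=rng), nn.ReLU(), nn.MaxPool2d(2))
    head = nn.Linear(32, 1, rng=rng)
    opt = nn.AdamW(net.parameters() + head.parameters(), lr=3e-3)

    def features(xb):
        maps = net(Tensor(xb)).reshape(len(xb), 16, -1)
        return Tensor.concatenate([maps.mean(axis=2), maps.max(axis=2)],
                                  axis=1)

    order = np.random.default_rng(1).permutation(1000)
    train, test = order[:800], order[800:]
    for epoch in range(6):
        perm = np.random.default_rng(epoch).permutation(train)
        for start in range(0, len(perm), 64):
            idx = perm[start:start + 64]
            opt.zero_grad()
            logits = head(features(x[idx]))
            yt = Tensor(y[idx].reshape(-1, 1))
            loss = (yt * (-logits).softplus()
                    + (1.0 - yt) * logits.softplus()).mean()
            loss.backward()
            opt.step()
    with nn.no_grad():
        scores = head(features(x[test])).data.ravel()
    assert roc_auc_score(y[test], scores) > 0.9


def test_export_dataset_writes_npz_and_manifest(tmp_path):
    b = build_dataset(GenConfig(n_eyes=40, seed=4))
    out = tmp_path / "data"
    from hms.synthetic import export_dataset
    export_dataset(b, out, write_png=False)
    import csv
    with open(out / "manifest.csv") as fh:
        rows = list(csv.DictReader(fh))
    arrays = np.load(out / "images.npz")
    assert len(arrays.files) == len(rows)
    assert {r["split"] for r in rows} >= {"train", "val", "test"}
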