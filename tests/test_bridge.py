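"""Bridge mechanics: pseudo-pairing, QC gating, agreement, training."""

import numpy as np
import pytest

from hms.bridge import (BridgeProjector, PrototypeBank, ablate_bridge,
                        fundus_agreement, project_with_qc, pseudo_pair,
                        qc_score)
from hms.encoders import StagingHead


class TestPseudoPair:
    def test_exact_copies_match_themselves(self, rng):
        z = rng.normal(size=(8, 6))
        matches, sims = pseudo_pair(z, z)
        assert matches == [(i, i) for i in range(8)]
        np.testing.assert_allclose(sims, 1.0, atol=1e-12)

    def test_argmax_of_two_candidates(self):
        q = np.array([[1.0, 0.0]])
        cands = np.array([[0.9, 0.1], [0.05, 1.0]])
        matches, _ = pseudo_pair(q, cands)
        assert matches == [(0, 0)]

    def test_matches_brute_force_oracle(self, rng):
        A = rng.normal(size=(20, 5))
        B = rng.normal(size=(30, 5))
        matches, _ = pseudo_pair(A, B)
        an = A / np.linalg.norm(A, axis=1, keepdims=True)
        bn = B / np.linalg.norm(B, axis=1, keepdims=True)
        for i, j in matches:
            sims = [an[i] @ bn[k] for k in range(30)]
            assert j == int(np.argmax(sims))

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(ValueError):
            pseudo_pair(rng.normal(size=(2, 3)), np.zeros((0, 3)))


class TestQCGate:
    def _bank(self, rng):
        protos = rng.normal(size=(4, 8))
        return PrototypeBank({k: protos[k] for k in range(4)})

    def test_threshold_rule(self, rng):
        bank = self._bank(rng)
        # q slightly above / below the 0.8 gate
        proto = bank.prototypes[2]
        v_hi = proto + 0.1 * rng.normal(size=8)
        q_hi = float(qc_score(v_hi, bank)[0])
        assert (q_hi >= 0.8) == True  # construction: near-prototype passes

    def test_exact_prototype_gives_q_one(self, rng):
        bank = self._bank(rng)
        q = float(qc_score(bank.prototypes[1], bank)[0])
        assert q == pytest.approx(1.0, abs=1e-9)

    def test_accept_and_defer(self, rng):
        from hms.encoders import EncoderConfig, build_encoder
        from hms.synthetic import GenConfig, render_oct
        from hms.types import LatentEyeState
        enc = build_encoder(EncoderConfig(), np.random.default_rng(0))
        proj = BridgeProjector(64, 8, np.random.default_rng(1))
        sample = render_oct(LatentEyeState(eye_id="e"), GenConfig(n_eyes=50),
                            np.random.default_rng(2))
        bank = self._bank(rng)
        out = project_with_qc(sample, enc, proj, bank, q_threshold=-1.0)
        assert out.accepted and out.q >= -1.0
        out2 = project_with_qc(sample, enc, proj, bank, q_threshold=1.01)
        assert not out2.accepted
        assert out.accepted == (out.q >= -1.0)

    def test_empty_bank_rejected(self, rng):
        from hms.encoders import EncoderConfig, build_encoder
        enc = build_encoder(EncoderConfig(), np.random.default_rng(0))
        proj = BridgeProjector(64, 8, np.random.default_rng(1))
        with pytest.raises(ValueError):
            project_with_qc(np.zeros((64, 64), dtype=np.float32), enc, proj,
                            PrototypeBank({}))


class TestFundusAgreement:
    def test_matches_brute_force_on_pairs(self, small_bundle):
        from hms.encoders import EncoderConfig, build_encoder, encode
        enc_oct = build_encoder(EncoderConfig(), np.random.default_rng(0))
        enc_fun = build_encoder(EncoderConfig(), np.random.default_rng(1))
        head = StagingHead(64, 4, np.random.default_rng(2))
        proj = BridgeProjector(64, 64, np.random.default_rng(3))
        pairs = small_bundle.paired_holdout
        agr = fundus_agreement(pairs, enc_oct, enc_fun, proj, head)
        hits = 0
        for o, f in pairs:
            zo = encode(o, enc_oct)
            zf = encode(f, enc_fun)
            po = head.probabilities(proj.project(zo).astype(np.float32))[0]
            pf = head.probabilities(zf.astype(np.float32))[0]
            hits += int(np.argmax(po) == np.argmax(pf))
        assert agr == pytest.approx(hits / len(pairs))

    def test_identity_setup_gives_full_agreement(self, small_bundle):
        """If the projector reproduces the fundus embedding exactly,
        stage argmax must agree on every pair."""
        from hms.encoders import EncoderConfig, build_encoder

        class IdentityProjector(BridgeProjector):
            def project(self, z):
                return np.atleast_2d(z)

        enc_fun = build_encoder(EncoderConfig(), np.random.default_rng(1))
        head = StagingHead(64, 4, np.random.default_rng(2))
        # use the fundus encoder on both sides with an identity projector
        pairs = [(f, f) for _, f in small_bundle.paired_holdout]
        agr = fundus_agreement(pairs, enc_fun, enc_fun,
                               IdentityProjector(64, 64), head)
        assert agr == 1.0

    def test_empty_holdout_rejected(self):
        with pytest.raises(ValueError):
            fundus_agreement([], None, None, None, None)


class TestPrototypeBank:
    def test_one_prototype_per_stage(self, rng):
        embs = rng.normal(size=(40, 6))
        stages = np.repeat([0, 1, 2, 3], 10)
        bank = PrototypeBank.fit(embs, stages)
        assert sorted(bank.prototypes) == [0, 1, 2, 3]
        np.testing.assert_allclose(bank.prototypes[2], embs[20:30].mean(axis=0))

    def test_unstaged_entries_ignored(self, rng):
        embs = rng.normal(size=(10, 3))
        stages = np.array([-1] * 5 + [0] * 5)
        bank = PrototypeBank.fit(embs, stages)
        assert list(bank.prototypes) == [0]


@pytest.fixture(scope="module")
def fitted_small(small_bundle):
    """A minimally trained stack (encoders + alignment + DR head)."""
    from hms.alignment import AlignmentConfig, train_alignment
    from hms.encoders import EncoderConfig, build_encoder
    from hms.pipeline import TrainConfig, train_staging
    enc_oct = build_encoder(EncoderConfig(), np.random.default_rng(0))
    dr = train_staging(small_bundle, None, K=4,
                       cfg=TrainConfig(epochs=2, batch_size=32),
                       task="dr", seed=0)
    align = train_alignment(small_bundle, enc_oct, dr.encoder,
                            AlignmentConfig(queue_size=64, batch_size=32),
                            epochs=2, seed=0)
    return enc_oct, dr, align


class TestTrainBridge:
    def test_training_reduces_loss_and_logs_components(self, small_bundle,
                                                       fitted_small):
        from hms.bridge import train_bridge
        enc_oct, dr, align = fitted_small
        res = train_bridge(small_bundle, enc_oct, dr.encoder, align, dr.head,
                           epochs=4, seed=0)
        assert res.history[-1]["total"] < res.history[0]["total"]
        component_keys = {"mse", "cos", "kl", "infonce", "proto", "mmd",
                          "coral"}
        for record in res.history:
            assert component_keys <= set(record)
            assert "cycle" not in record       # default-off optional term
        assert np.isfinite(res.best_agreement)

    def test_ablation_drops_exactly_one_component(self, small_bundle,
                                                  fitted_small):
        from hms.bridge import train_bridge
        from hms.losses import BridgeLossWeights
        enc_oct, dr, align = fitted_small
        res = train_bridge(small_bundle, enc_oct, dr.encoder, align, dr.head,
                           weights=BridgeLossWeights(), epochs=1, seed=0,
                           drop_component="mmd")
        # mmd still logged but contributes 0 to the total
        rec = res.history[0]
        expect = (10.0 * rec["mse"] + 0.5 * rec["cos"] + 0.5 * rec["kl"]
                  + 1.0 * rec["infonce"] + 0.5 * rec["proto"]
                  + 0.5 * rec["coral"])
        assert rec["total"] == pytest.approx(expect, rel=1e-6)

    def test_missing_alignment_rejected(self, small_bundle, fitted_small):
        from hms.bridge import train_bridge
        enc_oct, dr, _ = fitted_small
        with pytest.raises(ValueError):
            train_bridge(small_bundle, enc_oct, dr.encoder, None, dr.head)

    def test_ablate_harness_emits_seven_rows(self, small_bundle, fitted_small):
        enc_oct, dr, align = fitted_small
        table = ablate_bridge(small_bundle, enc_oct, dr.encoder, align,
                              dr.head, epochs=1, seed=0)
        assert len(table) == 7
        assert set(table["component"]) == {"mse", "cos", "kl", "infonce",
                                           "proto", "mmd", "coral"}
        assert {"agreement", "agreement_full", "delta"} <= set(table.columns)
        np.testing.assert_allclose(
            table["delta"], table["agreement_full"] - table["agreement"],
            atol=1e-12)
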