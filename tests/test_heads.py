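"""Cox losses against oracles, head architectures, and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

import somno._autograd as ag
from somno._autograd import Tensor
from somno.heads import (DemographicsMLP, ModalityFusion, PatientTensor,
                         PooledClassifierHead, SequenceHead, StagingHead,
                         SurvivalHead, coxph_loss, coxph_loss_reference,
                         cross_entropy, encoder_checksum, fit_survival_head,
                         fuse_modalities, multilabel_coxph_loss,
                         predict_survival_scores)
from somno.labels import SurvivalLabelSet

from conftest import finite_difference_grad


class TestCoxLoss:
    def test_zero_hazard_three_patients(self, fp64):
        """h = 0 with all events reduces to mean log risk-set size."""
        loss = coxph_loss(Tensor(np.zeros(3)), [1, 1, 1], [1.0, 2.0, 3.0])
        assert float(loss.data) == pytest.approx((np.log(3) + np.log(2)) / 3,
                                                 abs=1e-12)

    def test_matches_brute_force_with_censoring_and_ties(self, fp64):
        rng = np.random.default_rng(10)
        for _ in range(200):
            n = int(rng.integers(3, 51))
            h = rng.normal(size=n)
            e = rng.random(n) < 0.7
            t = rng.integers(1, max(2, n // 2), size=n).astype(float)  # ties
            a = float(coxph_loss(Tensor(h), e, t).data)
            b = coxph_loss_reference(h, e, t)
            assert a == pytest.approx(b, abs=1e-8)

    def test_shift_invariance(self, fp64):
        rng = np.random.default_rng(11)
        h = rng.normal(size=20)
        e = rng.random(20) < 0.6
        t = rng.exponential(100, 20) + 1
        a = float(coxph_loss(Tensor(h), e, t).data)
        b = float(coxph_loss(Tensor(h + 10.0), e, t).data)
        assert abs(a - b) < 1e-6

    def test_no_events_contributes_zero_without_gradient(self):
        loss = coxph_loss(Tensor(np.ones(4, dtype=np.float32)),
                          [0, 0, 0, 0], [1.0, 2.0, 3.0, 4.0])
        assert float(loss.data) == 0.0
        assert not loss.requires_grad

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            coxph_loss(Tensor(np.zeros(3)), [1, 1, 1], [-1.0, 2.0, 3.0])

    def test_gradient_matches_finite_differences(self, fp64):
        rng = np.random.default_rng(12)
        h = Tensor(rng.normal(size=8), requires_grad=True)
        e = np.array([1, 0, 1, 1, 0, 1, 0, 1])
        t = np.array([3.0, 5.0, 5.0, 9.0, 2.0, 7.0, 7.0, 1.0])
        coxph_loss(h, e, t).backward()
        numeric = finite_difference_grad(
            lambda: float(coxph_loss(Tensor(h.data), e, t).data), h.data)
        denom = np.maximum(1e-4, np.abs(h.grad) + np.abs(numeric))
        assert np.max(np.abs(h.grad - numeric) / denom) < 1e-4

    def test_optimum_agrees_with_established_fitter(self, fp64):
        """Minimizing the loss in a one-covariate model lands on the same
        coefficient as scikit-survival's Breslow-tie Cox fitter."""
        from scipy.optimize import minimize_scalar
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        rng = np.random.default_rng(13)
        for trial in range(5):
            n = 80
            x = rng.normal(size=n)
            t = rng.exponential(np.exp(-0.8 * x)) + 0.01
            t = np.round(t, 1) + 0.1  # introduce ties
            e = rng.random(n) < 0.75
            def nll(beta):
                return float(coxph_loss(Tensor(beta * x), e, t).data)
            ours = minimize_scalar(nll, bounds=(-5, 5), method="bounded").x
            y = np.array(list(zip(e, t)), dtype=[("e", bool), ("t", float)])
            ref = CoxPHSurvivalAnalysis(ties="breslow").fit(x[:, None], y)
            assert ours == pytest.approx(ref.coef_[0], abs=1e-3)


class TestMultilabelCox:
    @staticmethod
    def _labels(n, rng, n_cond=2):
        time = rng.exponential(100, size=(n, n_cond)) + 1
        event = (rng.random((n, n_cond)) < 0.6).astype(np.int8)
        return SurvivalLabelSet([f"p{i}" for i in range(n)],
                                [f"c{k}" for k in range(n_cond)], time, event)

    def test_sum_of_per_label_losses(self, fp64):
        rng = np.random.default_rng(14)
        lab = self._labels(12, rng)
        s = Tensor(rng.normal(size=(12, 2)))
        total = float(multilabel_coxph_loss(s, lab).data)
        parts = [float(coxph_loss(s[:, j], lab.event[:, j], lab.time[:, j]).data)
                 for j in range(2)]
        assert total == pytest.approx(sum(parts), abs=1e-9)

    def test_all_censored_label_contributes_zero(self, fp64):
        rng = np.random.default_rng(15)
        lab = self._labels(10, rng)
        lab.event[:, 1] = 0
        s = Tensor(rng.normal(size=(10, 2)))
        total = float(multilabel_coxph_loss(s, lab).data)
        only0 = float(coxph_loss(s[:, 0], lab.event[:, 0], lab.time[:, 0]).data)
        assert total == pytest.approx(only0, abs=1e-9)

    def test_single_batch_equals_full_cohort(self, fp64):
        rng = np.random.default_rng(16)
        lab = self._labels(20, rng)
        s = Tensor(rng.normal(size=(20, 2)))
        full = float(multilabel_coxph_loss(s, lab, batch_size=None).data)
        one = float(multilabel_coxph_loss(s, lab, batch_size=20).data)
        assert full == pytest.approx(one, abs=1e-9)

    def test_label_count_mismatch_rejected(self):
        rng = np.random.default_rng(17)
        lab = self._labels(6, rng)
        with pytest.raises(ValueError, match="conditions"):
            multilabel_coxph_loss(Tensor(np.zeros((6, 3), dtype=np.float32)), lab)


class TestFusionAndSequenceHead:
    def test_fusion_shapes_and_single_modality_identity(self, fp64):
        rng = np.random.default_rng(18)
        fusion = ModalityFusion(np.random.default_rng(19), ffn_width=64,
                                dropout=0.0)
        fusion.eval()
        emb = rng.normal(size=(4, 10, 128))
        patient = PatientTensor(embeddings=emb,
                                modality_mask=np.array([True, False, False, False]),
                                token_mask=np.ones(10, bool))
        out = fuse_modalities(fusion, patient)
        assert out.data.shape == (10, 128)
        solo = fusion(Tensor(emb.transpose(1, 0, 2)[:, :1]),
                      np.ones((10, 1), bool))
        assert np.allclose(out.data, solo.data, atol=1e-6)

    def test_modality_permutation_invariance(self, fp64):
        rng = np.random.default_rng(20)
        fusion = ModalityFusion(np.random.default_rng(21), ffn_width=64,
                                dropout=0.0)
        fusion.eval()
        x = rng.normal(size=(6, 4, 128))
        mask = np.ones((6, 4), bool)
        a = fusion(Tensor(x), mask).data
        perm = rng.permutation(4)
        b = fusion(Tensor(x[:, perm]), mask[:, perm]).data
        assert np.abs(a - b).max() < 1e-5

    def test_sequence_head_masked_mean_over_valid_prefix(self, fp64):
        rng = np.random.default_rng(22)
        head = SequenceHead(np.random.default_rng(23))
        head.eval()
        s_valid, s_total = 12, 16
        fused = rng.normal(size=(s_total, 128))
        mask = np.zeros(s_total, bool)
        mask[:s_valid] = True
        states, pooled = head(Tensor(fused), mask)
        assert states.data.shape == (s_total, 128)
        assert np.all(states.data[s_valid:] == 0.0)
        assert np.allclose(pooled.data, states.data[:s_valid].mean(axis=0),
                           atol=1e-6)
        # padded content cannot influence anything
        fused2 = fused.copy()
        fused2[s_valid:] = 1e3
        _, pooled2 = head(Tensor(fused2), mask)
        assert np.allclose(pooled.data, pooled2.data, atol=1e-9)

    def test_zero_valid_tokens_rejected(self):
        head = SequenceHead(np.random.default_rng(24))
        with pytest.raises(ValueError):
            head(Tensor(np.zeros((4, 128), dtype=np.float32)),
                 np.zeros(4, bool))


class TestTaskHeads:
    def test_survival_head_shapes_and_zero_weights(self, fp64):
        rng = np.random.default_rng(25)
        head = SurvivalHead(rng, n_conditions=1041)
        head.linear.weight.data[:] = 0.0
        head.linear.bias.data[:] = 0.0
        out = head(Tensor(np.random.default_rng(0).normal(size=(3, 128))),
                   np.zeros(3), np.zeros(3))
        assert out.data.shape == (3, 1041)
        assert np.all(out.data == 0.0)

    def test_no_demographics_variant_consumes_128(self):
        head = SurvivalHead(np.random.default_rng(26), 5, demographics=False)
        assert head.linear.weight.data.shape == (128, 5)

    def test_demographics_required_when_enabled(self):
        head = SurvivalHead(np.random.default_rng(27), 5)
        with pytest.raises(ValueError, match="age"):
            head(Tensor(np.zeros((2, 128), dtype=np.float32)))

    def test_staging_head_per_token_shape(self):
        head = StagingHead(np.random.default_rng(28))
        out = head(Tensor(np.zeros((6480, 128), dtype=np.float32)))
        assert out.data.shape == (6480, 5)

    def test_apnea_head_four_logits(self):
        head = PooledClassifierHead(np.random.default_rng(29), 4)
        assert head(Tensor(np.zeros(128, dtype=np.float32))).data.shape == (1, 4)

    def test_demographics_mlp_baseline_shape(self):
        mlp = DemographicsMLP(np.random.default_rng(30), 3)
        out = mlp(Tensor(np.zeros((5, 4), dtype=np.float32)))
        assert out.data.shape == (5, 3)


class TestParameterRecovery:
    def test_cox_head_recovers_simulation_coefficients(self):
        """A linear head trained with the multilabel CoxPH loss on the true
        latent risk recovers the simulation's beta within 2 SE of an
        established Cox fit, and its risk ranking matches the truth."""
        from lifelines import CoxPHFitter

        from somno.metrics import harrell_c_index
        from somno.synthetic import SimConfig, simulate_survival

        cfg = SimConfig(censor_rate=0.3, seed=3)
        z = np.random.default_rng(3).normal(size=(2000, 2))
        lab = simulate_survival(cfg, z)
        fit = fit_survival_head(z, lab, demographics=False, epochs=150,
                                lr=5e-2, batch_size=32, seed=0)
        w = fit.model.linear.weight.data  # (2, n_conditions)
        j = lab.conditions.index("coupled")
        t, e, _ = lab.column("coupled")
        df = pd.DataFrame({"z1": z[:, 0], "z2": z[:, 1], "t": t, "e": e})
        cph = CoxPHFitter().fit(df, "t", "e")
        for k, name in enumerate(("z1", "z2")):
            assert abs(w[k, j] - cph.params_[name]) < 2 * cph.standard_errors_[name]
        c_learned = harrell_c_index(z @ w[:, j], e, t)
        c_true = harrell_c_index(z @ np.array([1.0, 0.5]), e, t)
        assert abs(c_learned - c_true) < 0.02

    def test_staging_head_beats_majority_baseline(self, tiny_cohort,
                                                  tiny_token_arrays):
        """A briefly trained per-token staging classifier on simulated BAS
        band structure outperforms the majority-class macro F1."""
        from somno import _nn
        from somno.encoder import SleepEncoder, desk_config
        from somno.labels import expand_stage_labels
        from somno.metrics import classification_report

        enc = SleepEncoder(desk_config(dropout=0.0, seed=4))
        feats, targs = [], []
        for sim, ta in zip(tiny_cohort.recordings, tiny_token_arrays):
            emb = enc.embed_recording(ta)
            feats.append(emb.token_level["BAS"])
            targs.append(expand_stage_labels(sim.stage_labels,
                                             n_tokens=ta.n_tokens))
        x = np.concatenate(feats)
        y = np.concatenate(targs)
        n = len(x)
        tr = np.arange(n) % 2 == 0
        head = StagingHead(np.random.default_rng(5))
        opt = _nn.Adam(head.parameters(), lr=1e-2)
        for _ in range(60):
            loss = cross_entropy(head(Tensor(x[tr])), y[tr])
            opt.zero_grad()
            loss.backward()
            opt.step()
        with ag.no_grad():
            pred = head(Tensor(x[~tr])).data.argmax(axis=1)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = classification_report(y[~tr], pred, ["W", "N1", "N2", "N3", "R"])
            majority = classification_report(
                y[~tr], np.full((~tr).sum(), np.bincount(y[tr]).argmax()),
                ["W", "N1", "N2", "N3", "R"])
        assert rep["macro_f1"] > majority["macro_f1"]


class TestFrozenEncoderContract:
    def test_fine_tuning_never_mutates_encoder(self, tiny_cohort,
                                               tiny_token_arrays):
        from somno.encoder import SleepEncoder, desk_config

        enc = SleepEncoder(desk_config(seed=6))
        before = encoder_checksum(enc)
        feats = []
        for ta in tiny_token_arrays:
            emb = enc.embed_recording(ta)
            feats.append(np.concatenate([emb.pooled[m] for m in emb.modalities]))
        lab = tiny_cohort.survival
        fit = fit_survival_head(np.stack(feats), lab, demographics=False,
                                epochs=3, seed=0)
        predict_survival_scores(fit.model, np.stack(feats))
        assert encoder_checksum(enc) == before
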