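"""Resampling, standardization, grouping, tokenization and EDF round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somno.preprocess import (CHANNEL_CAPS, CONTEXT_TOKENS, Channel,
                              RawRecording, TARGET_RATE, TOKEN_LEN,
                              assign_modalities, group_modalities,
                              read_recording_edf, resample_to_common_rate,
                              segment_tokens, standardize, standardize_context,
                              tokenize_recording, write_recording_edf)


class TestResample:
    @pytest.mark.parametrize("rate", [64.0, 100.0, 128.0, 200.0, 256.0, 500.0])
    def test_constant_signal_stays_constant(self, rate):
        out = resample_to_common_rate(np.full(int(rate * 4), 3.25), rate)
        assert out.shape == (int(round(rate * 4 * 128 / rate)),)
        assert np.allclose(out, 3.25, atol=1e-6)

    def test_downsampled_sine_amplitude_and_phase(self):
        """A 10-Hz unit sine at 256 Hz must match the analytic sine on the
        new grid within 1% amplitude and no phase lag (zero-phase filter)."""
        rate, dur = 256.0, 4.0
        t = np.arange(int(rate * dur)) / rate
        out = resample_to_common_rate(np.sin(2 * np.pi * 10 * t), rate)
        t_new = np.arange(len(out)) / TARGET_RATE
        ref = np.sin(2 * np.pi * 10 * t_new)
        core = slice(64, -64)  # ignore filter edge transients
        assert np.abs(out[core] - ref[core]).max() < 0.01

    def test_upsampling_linear_interpolation_midpoint(self):
        out = resample_to_common_rate(np.array([0.0, 1.0] * 32), 64.0)
        # midpoints between 0 and 1 appear as 0.5
        assert np.any(np.isclose(out, 0.5))
        assert len(out) == 128

    def test_output_length_formula(self):
        for rate, n in [(200.0, 1000), (256.0, 2560), (64.0, 641)]:
            out = resample_to_common_rate(np.zeros(n), rate)
            assert len(out) == round(n * 128 / rate)

    def test_nonfinite_rejected_with_channel_identity(self):
        bad = np.ones(1000)
        bad[10] = np.nan
        with pytest.raises(ValueError, match="C3"):
            resample_to_common_rate(bad, 256.0, label="C3")

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            resample_to_common_rate(np.ones(100), 0.0)

    def test_too_short_for_filter_warmup(self):
        with pytest.raises(ValueError, match="warm-up"):
            resample_to_common_rate(np.ones(10), 256.0)


class TestStandardize:
    def test_three_point_example(self):
        out = standardize(np.array([1.0, 2.0, 3.0]))
        assert out.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.std() == pytest.approx(1.0, abs=1e-9)

    def test_constant_maps_to_zeros(self):
        assert np.all(standardize(np.full(100, 7.0)) == 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            standardize(np.array([]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent_and_unit_variance(self, seed):
        x = np.random.default_rng(seed).normal(2.0, 5.0, size=257)
        once = standardize(x)
        assert once.mean() == pytest.approx(0.0, abs=1e-6)
        assert once.std() == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(standardize(once), once, atol=1e-6)


def _recording(channel_specs, rate=128.0, n=TOKEN_LEN * 2):
    chans = [Channel(lab, np.random.default_rng(i).normal(size=n), rate)
             for i, lab in enumerate(channel_specs)]
    rec = RawRecording(chans, patient_id="T")
    return assign_modalities(rec)


class TestGroupModalities:
    def test_caps_enforced_with_canonical_order(self):
        labels = ["F3", "F4", "C3", "C4", "Cz", "O1", "O2", "Oz", "E1", "E2",
                  "F7", "F8"]  # 12 BAS channels
        rec = _recording(labels)
        groups = group_modalities(rec)
        assert len(groups["BAS"]) == CHANNEL_CAPS["BAS"] == 10
        # truncation keeps the earliest in canonical rank
        assert [c.label for c in groups["BAS"]][:4] == ["F3", "F4", "C3", "C4"]

    def test_missing_modality_flagged_not_fabricated(self):
        rec = _recording(["C3", "ECG", "THOR"])  # no EMG
        groups = group_modalities(rec)
        assert groups["EMG"] == []
        assert len(groups["BAS"]) == 1

    def test_one_channel_per_modality_all_retained(self):
        rec = _recording(["C3", "ECG", "CHIN1", "ABD"])
        groups = group_modalities(rec)
        assert all(len(groups[m]) == 1 for m in groups)

    def test_all_unknown_rejected(self):
        rec = _recording(["MYSTERY1", "MYSTERY2"])
        with pytest.raises(ValueError, match="known modality"):
            group_modalities(rec)


class TestSegmentTokens:
    def test_nine_hours_yields_6480_tokens(self):
        sig = np.zeros(int(9 * 3600 * TARGET_RATE))
        toks = segment_tokens(sig)
        assert toks.shape == (6480, 640)

    def test_five_minutes_yields_60_tokens(self):
        assert segment_tokens(np.zeros(300 * 128)).shape == (60, 640)

    def test_remainder_dropped(self):
        toks = segment_tokens(np.arange(645.0))
        assert toks.shape == (1, 640)

    def test_short_signal_warns_zero_tokens(self):
        with pytest.warns(UserWarning):
            assert segment_tokens(np.zeros(100)).shape == (0, 640)

    def test_token_count_formula_over_durations(self):
        for hours in (0.1, 0.5, 1.0, 2.5):
            n = int(3600 * hours * TARGET_RATE)
            assert segment_tokens(np.zeros(n)).shape[0] == n // TOKEN_LEN


class TestStandardizeContext:
    def _tokens(self, hours):
        rec = _recording(["C3", "ECG", "CHIN1", "ABD"],
                         n=int(hours * 3600 * TARGET_RATE))
        return tokenize_recording(rec)

    def test_long_recording_cropped_to_initial_segment(self):
        ta = self._tokens(10.0)
        out = standardize_context(ta)
        assert out.n_tokens == CONTEXT_TOKENS == 6480
        assert out.token_mask.all()
        assert np.array_equal(out.data["BAS"], ta.data["BAS"][:, :6480, :])

    def test_short_recording_zero_padded_with_mask(self):
        ta = self._tokens(8.0)
        out = standardize_context(ta)
        assert out.n_tokens == 6480
        assert out.token_mask.sum() == 5760  # 8 h x 720 tokens/h
        assert np.all(out.data["ECG"][:, 5760:, :] == 0.0)

    def test_exact_context_is_identity(self):
        ta = self._tokens(9.0)
        out = standardize_context(ta)
        assert np.array_equal(out.data["BAS"], ta.data["BAS"])
        assert out.token_mask.all()


class TestPipelineContracts:
    def test_pipeline_order_standardize_before_segment(self):
        """Standardizing per token instead of per recording changes the
        result; the pipeline must z-score over the whole recording first."""
        rng = np.random.default_rng(0)
        sig = np.concatenate([rng.normal(0, 0.1, TOKEN_LEN),
                              rng.normal(5, 3.0, TOKEN_LEN)])
        rec = RawRecording([Channel("C3", sig, 128.0)], "T")
        assign_modalities(rec)
        ta = tokenize_recording(rec)
        whole = ta.data["BAS"][0]
        per_token = np.stack([standardize(tok) for tok in
                              segment_tokens(sig)])
        # the pipeline keeps cross-token scale differences
        assert whole.reshape(-1).std() == pytest.approx(1.0, abs=1e-6)
        assert not np.allclose(whole, per_token, atol=1e-3)

    def test_edf_round_trip_matches_in_memory_path(self, tiny_cohort, tmp_path):
        sim = tiny_cohort.recordings[0]
        ta_mem = tokenize_recording(sim.recording)
        path = tmp_path / "p.edf"
        write_recording_edf(path, sim.recording)
        ta_disk = tokenize_recording(read_recording_edf(path))
        assert ta_mem.modalities == ta_disk.modalities
        for m in ta_mem.modalities:
            # identical up to 16-bit EDF quantization
            assert np.abs(ta_mem.data[m] - ta_disk.data[m]).max() < 5e-3

    def test_edf_reader_agrees_with_mne_on_uniform_rate_file(self, tmp_path):
        import mne

        rng = np.random.default_rng(1)
        chans = [Channel("C3", rng.normal(size=1280), 128.0),
                 Channel("ECG", rng.normal(size=1280), 128.0)]
        rec = RawRecording(chans, "U")
        path = tmp_path / "u.edf"
        write_recording_edf(path, rec)
        ours = read_recording_edf(path)
        theirs = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
        data = theirs.get_data()
        for i, ch in enumerate(ours.channels):
            scale = np.abs(ch.signal).max() / max(np.abs(data[i]).max(), 1e-30)
            assert np.allclose(ch.signal, data[i] * scale, atol=2e-3)
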