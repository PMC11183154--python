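"""Single-trial signal chain: load force, filtering, windowing, tensor shape."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

import lifttensor as lt
from lifttensor.preprocess import (
    CHANNEL_NAMES,
    DegenerateChannelError,
    LiftDetectionError,
    TensorAssemblyError,
)


class TestLoadForce:
    def test_static_weight(self):
        lf = lt.compute_load_force(0.2, np.zeros(5), np.zeros(5))
        np.testing.assert_allclose(lf, 0.2 * 9.81)

    def test_free_fall_is_zero(self):
        lf = lt.compute_load_force(0.2, np.full(5, -9.81), np.zeros(5))
        np.testing.assert_allclose(lf, 0.0, atol=1e-12)

    def test_hand_computed_value(self):
        # 0.2 * sqrt((1 + 9.81)^2 + 0.5^2) = 2.16432...
        lf = lt.compute_load_force(0.2, np.array([1.0]), np.array([0.5]))
        np.testing.assert_allclose(lf, 2.1643, atol=5e-5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            lt.compute_load_force(0.2, np.zeros(5), np.zeros(4))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_always_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        a_z, a_y = rng.normal(0, 30, (2, 50))
        assert lt.compute_load_force(0.3, a_z, a_y).min() >= 0


class TestLowpassFilter:
    def test_dc_gain_unity(self):
        x = np.full(400, 3.7)
        out = lt.lowpass_filter(x, 12.0, fs=200.0)
        np.testing.assert_allclose(out, 3.7, atol=1e-9)

    def test_attenuation_matches_analog_magnitude(self):
        # At fs=2000 the bilinear design is essentially the analog
        # prototype; closed-form |H(f)| = 1/sqrt(1 + (f/fc)^(2n)).
        fs, fc, f = 2000.0, 10.0, 50.0
        t = np.arange(int(4 * fs)) / fs
        y = lt.lowpass_filter(np.sin(2 * np.pi * f * t), fc, fs=fs,
                              zero_phase=False)
        measured = np.sqrt(2.0) * np.std(y[len(y) // 2:])  # phase-robust amp
        analytic = 1.0 / np.sqrt(1.0 + (f / fc) ** 8)
        assert abs(measured - analytic) / analytic < 0.10

    def test_attenuation_matches_designed_response_at_kinematic_rate(self):
        # At fs=200 frequency warping is large, so the oracle is the
        # filter's own frequency response rather than the analog formula.
        fs, fc, f = 200.0, 12.0, 50.0
        t = np.arange(int(20 * fs)) / fs
        y = lt.lowpass_filter(np.sin(2 * np.pi * f * t), fc, fs=fs,
                              zero_phase=False)
        measured = np.sqrt(2.0) * np.std(y[len(y) // 2:])
        sos = sps.butter(4, fc, btype="low", fs=fs, output="sos")
        _, h = sps.sosfreqz(sos, worN=[f], fs=fs)
        assert abs(measured - np.abs(h[0])) / np.abs(h[0]) < 0.10

    def test_zero_phase_preserves_peak_location(self):
        pulse = np.exp(-0.5 * ((np.arange(400) - 200) / 12.0) ** 2)
        out = lt.lowpass_filter(pulse, 12.0, fs=200.0, zero_phase=True)
        assert np.argmax(out) == 200

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            lt.lowpass_filter(np.zeros(100), 120.0, fs=200.0)


class TestRectifyDownsample:
    def test_rectify_definition(self):
        np.testing.assert_array_equal(
            lt.rectify_emg([-1.0, 2.0, -3.0]), [1.0, 2.0, 3.0])

    def test_rectify_identity_on_positives(self):
        x = np.array([0.5, 1.0, 2.0])
        np.testing.assert_array_equal(lt.rectify_emg(x), x)

    def test_downsample_counts_and_constants(self):
        assert lt.downsample(np.ones(1000), 2000, 200).shape == (100,)
        np.testing.assert_array_equal(
            lt.downsample(np.full(40, 2.5), 2000, 200), np.full(4, 2.5))

    def test_downsample_noninteger_ratio_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            lt.downsample(np.zeros(100), 2000, 300)


class TestLiftWindow:
    @staticmethod
    def _trial(contact=300, stable=900, fs=200.0, n=1200):
        gf = np.zeros(n)
        gf[contact:] = 5.0
        vel = np.zeros(n)
        vel[contact:stable] = 0.5  # peak inside the lift, zero after
        return gf, vel, fs

    def test_annotated_window(self):
        gf, vel, fs = self._trial()
        w = lt.detect_lift_window(gf, vel, fs)
        assert (w.first_contact_idx, w.stable_onset_idx) == (300, 900)
        assert (w.start, w.stop) == (280, 920)

    def test_no_contact_raises(self):
        gf = np.full(500, 0.05)
        vel = np.zeros(500)
        with pytest.raises(LiftDetectionError, match="never exceeded"):
            lt.detect_lift_window(gf, vel, 200.0)

    def test_pad_out_of_bounds_raises(self):
        gf, vel, fs = self._trial(contact=5, stable=200, n=400)
        with pytest.raises(LiftDetectionError, match="exceeds"):
            lt.detect_lift_window(gf, vel, fs)

    def test_matches_generator_annotations(self, raw_trial_batch):
        _, trials = raw_trial_batch
        for tr in trials:
            w = lt.detect_lift_window(
                np.maximum(tr.gf_r, tr.gf_l), tr.vel_z, tr.fs_kin)
            assert w.first_contact_idx == tr.annotations["true_first_contact"]
            assert w.stable_onset_idx == tr.annotations["true_stable_onset"]


class TestTimeNormalizeTrim:
    def test_constant_invariant(self):
        out = lt.time_normalize(np.full(700, 3.5), 500)
        assert out.shape == (500,)
        np.testing.assert_allclose(out, 3.5)

    def test_ramp_endpoints_preserved(self):
        out = lt.time_normalize(np.linspace(0, 1, 231), 500)
        assert out[0] == 0.0 and out[-1] == 1.0
        assert np.all(np.diff(out) >= 0)

    def test_trim_small_case(self):
        np.testing.assert_array_equal(
            lt.trim_edges(np.arange(10), 2), np.arange(2, 8))

    def test_trim_zero_is_identity(self):
        x = np.arange(10.0)
        np.testing.assert_array_equal(lt.trim_edges(x, 0), x)

    @given(st.integers(2, 2000))
    @settings(max_examples=30, deadline=None)
    def test_length_contract_460(self, n):
        """Any trial length maps to the canonical 460 samples."""
        x = np.random.default_rng(n).uniform(size=n)
        assert lt.trim_edges(lt.time_normalize(x, 500), 20).shape == (460,)

    def test_too_short_inputs_rejected(self):
        with pytest.raises(ValueError):
            lt.time_normalize(np.ones(1), 500)
        with pytest.raises(ValueError):
            lt.trim_edges(np.ones(30), 20)


class TestEmgNormalization:
    def test_per_channel_max_is_one(self, rng):
        trials = [rng.uniform(0, 5, (8, 100)) for _ in range(4)]
        out = lt.normalize_emg_per_participant(trials)
        maxima = np.stack(out).max(axis=(0, 2))
        np.testing.assert_allclose(maxima, 1.0)

    def test_scale_invariance_across_participants(self, rng):
        base = [rng.uniform(0, 1, (8, 50)) for _ in range(3)]
        scaled = [10.0 * t for t in base]
        out_a = lt.normalize_emg_per_participant(base)
        out_b = lt.normalize_emg_per_participant(scaled)
        for a, b in zip(out_a, out_b):
            np.testing.assert_allclose(a, b)

    def test_dead_channel_named(self, rng):
        trials = [rng.uniform(0, 1, (8, 50)) for _ in range(2)]
        for t in trials:
            t[3] = 0.0
        with pytest.raises(DegenerateChannelError, match=r"\[3\].*participant 9"):
            lt.normalize_emg_per_participant(trials, participant_id=9)


class TestAssembleBalance:
    @staticmethod
    def _cells(metas, n_trials=2, n_t=30, seed=0):
        rng = np.random.default_rng(seed)
        cells = {}
        for m in metas:
            for obj in ("heavy", "light"):
                for k in range(n_trials):
                    cells[(m.participant_id, obj, k)] = rng.uniform(
                        0, 1, (12, n_t))
        return cells

    def test_shape_and_age_order(self):
        metas = lt.generate_participants(2, 2, seed=1)
        mt = lt.assemble_tensor(self._cells(metas), metas)
        assert mt.X.shape == (12, 30, 2, 4, 2)
        ages = {m.participant_id: m.age for m in metas}
        assert list(mt.participant_ids) == sorted(
            mt.participant_ids, key=lambda p: ages[p])
        assert mt.channel_names == CHANNEL_NAMES

    def test_arrival_order_irrelevant(self):
        metas = lt.generate_participants(2, 2, seed=1)
        cells = self._cells(metas)
        shuffled = dict(reversed(list(cells.items())))
        np.testing.assert_array_equal(
            lt.assemble_tensor(cells, metas).X,
            lt.assemble_tensor(shuffled, metas).X)

    def test_missing_cell_named(self):
        metas = lt.generate_participants(2, 2, seed=1)
        cells = self._cells(metas)
        missing_key = (metas[0].participant_id, "light", 1)
        del cells[missing_key]
        with pytest.raises(TensorAssemblyError) as err:
            lt.assemble_tensor(cells, metas)
        assert missing_key in err.value.missing

    def test_balance_hand_computed_scale(self):
        X = np.ones((12, 10, 2, 3, 2))
        X[4:] = 2.0
        mt = lt.MotorTensor(X)
        out = lt.balance_modalities(mt)
        assert out.attrs["force_scale"] == pytest.approx(2.0)
        flat = out.X.reshape(12, -1)
        norms = np.linalg.norm(flat, axis=1)
        assert norms[:4].mean() == pytest.approx(norms[4:].mean(), rel=1e-12)

    def test_balance_idempotent_and_shape_preserving(self, small_noisy_tensor):
        mt, _ = small_noisy_tensor
        once = lt.balance_modalities(mt)
        twice = lt.balance_modalities(once)
        np.testing.assert_allclose(once.X, twice.X, rtol=1e-12)
        # relative strengths within the force group untouched
        norms_in = np.linalg.norm(mt.X.reshape(12, -1), axis=1)
        norms_out = np.linalg.norm(once.X.reshape(12, -1), axis=1)
        np.testing.assert_allclose(norms_out[:4] / norms_in[:4],
                                   np.full(4, norms_out[0] / norms_in[0]))


class TestOutlierFlag:
    def test_spike_channel_flagged(self, rng):
        channels = rng.normal(size=(12, 460))
        channels[5, 100] = 40.0
        assert 5 in lt.flag_amplitude_outliers(channels)

    def test_clean_channels_unflagged(self, rng):
        channels = rng.normal(size=(12, 460))
        assert lt.flag_amplitude_outliers(channels).size == 0


class TestFullChain:
    def test_failing_trial_named_in_error(self, raw_trial_batch):
        metas, trials = raw_trial_batch
        broken = [lt.TrialRecording(
            participant_id=t.participant_id, object_label=t.object_label,
            trial_index=t.trial_index, mass=t.mass,
            gf_r=np.zeros_like(t.gf_r), gf_l=np.zeros_like(t.gf_l),
            a_z=t.a_z, a_y=t.a_y, vel_z=t.vel_z, emg=t.emg,
            fs_kin=t.fs_kin, fs_emg=t.fs_emg) if i == 0 else t
            for i, t in enumerate(trials)]
        with pytest.raises(LiftDetectionError,
                           match=f"participant {trials[0].participant_id}"):
            lt.preprocess_dataset(broken, metas)

    def test_process_trial_shape_and_nonnegativity(self, raw_trial_batch):
        _, trials = raw_trial_batch
        mat = lt.process_trial(trials[0])
        assert mat.shape == (12, 460)
        assert mat.min() >= 0

    def test_preprocess_dataset_tensor(self, raw_trial_batch):
        metas, trials = raw_trial_batch
        mt = lt.preprocess_dataset(trials, metas)
        assert mt.X.shape == (12, 460, 2, 4, 2)
        assert mt.X.min() >= 0
        # EMG normalized per participant: per-channel max over each
        # participant's block is 1 before force balancing only; after
        # balancing the EMG block is untouched, so the max is still 1.
        for p in range(4):
            block = mt.X[4:, :, :, p, :]
            np.testing.assert_allclose(
                block.max(axis=(1, 2, 3)), 1.0, rtol=1e-9)
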