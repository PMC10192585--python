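import numpy as np
import pytest

from mirrorloop.containers import RawRecording
from mirrorloop.montage import standard_montage
from mirrorloop.preprocess import (FilterSpec, bandpass, baseline_correct,
                                   classify_components, extract_epochs,
                                   fit_ica, notch, reject_epochs,
                                   remove_components, rereference_average)
from mirrorloop.simulate import SourceSpec, gaussian_pattern, synthesize_recording


def _sine_raw(freq, montage, sfreq=500.0, dur=10.0, amp=1.0):
    t = np.arange(int(dur * sfreq)) / sfreq
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (len(montage), 1))
    return RawRecording(data, sfreq, montage), t


class TestFiltering:
    def test_passband_sinusoid_survives(self, montage):
        raw, t = _sine_raw(10.0, montage)
        out = bandpass(raw)
        mid = slice(1000, 4000)  # avoid filter edges
        ratio = out.data[0, mid].std() / raw.data[0, mid].std()
        assert ratio >= 0.94

    def test_dc_removed(self, montage):
        raw = RawRecording(np.full((48, 5000), 5.0), 500.0, montage)
        out = bandpass(raw)
        assert np.abs(out.data[:, 1000:4000]).max() < 1e-6

    def test_notch_attenuates_line_frequency(self, montage):
        raw, _ = _sine_raw(50.0, montage)
        out = notch(raw, 50.0)
        mid = slice(1000, 4000)
        assert out.data[0, mid].std() / raw.data[0, mid].std() < 0.1

    def test_band_edge_validation(self, montage):
        raw, _ = _sine_raw(10.0, montage)
        with pytest.raises(ValueError, match="outside"):
            bandpass(raw, FilterSpec(band=(1.0, 260.0)))

    def test_linearity(self, montage, rng):
        x = RawRecording(rng.standard_normal((48, 4000)), 500.0, montage)
        y = RawRecording(rng.standard_normal((48, 4000)), 500.0, montage)
        combo = RawRecording(2.0 * x.data + 3.0 * y.data, 500.0, montage)
        lhs = bandpass(combo).data
        rhs = 2.0 * bandpass(x).data + 3.0 * bandpass(y).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestRereference:
    def test_two_channel_example(self):
        m = standard_montage(["C3", "C4"])
        raw = RawRecording(np.array([[1.0], [3.0]]), 500.0, m)
        out = rereference_average(raw)
        np.testing.assert_allclose(out.data, [[-1.0], [1.0]])

    def test_idempotent_and_zero_mean(self, montage, rng):
        raw = RawRecording(rng.standard_normal((48, 100)), 500.0, montage)
        once = rereference_average(raw)
        np.testing.assert_allclose(once.data.mean(axis=0), 0.0, atol=1e-9)
        twice = rereference_average(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_single_channel_rejected(self):
        m = standard_montage(["Cz"])
        raw = RawRecording(np.zeros((1, 10)), 500.0, m)
        with pytest.raises(ValueError, match="at least 2"):
            rereference_average(raw)


class TestICA:
    def _mixed_sources(self, rng, n=20000):
        # two independent super-Gaussian (Laplacian) sources, 2x2 mixing
        s = rng.laplace(size=(2, n))
        A = np.array([[1.0, 0.4], [0.3, 1.0]])
        m = standard_montage(["C3", "C4"])
        return RawRecording(A @ s, 500.0, m), s

    def test_recovers_super_gaussian_sources(self, rng):
        raw, s = self._mixed_sources(rng)
        ica = fit_ica(raw, n_components=2, seed=0)
        rec = ica.get_sources(raw)
        corr = np.abs(np.corrcoef(np.vstack([rec, s]))[:2, 2:])
        # each recovered component matches one true source up to order/sign
        assert corr.max(axis=1).min() > 0.95

    def test_seeded_determinism(self, rng):
        raw, _ = self._mixed_sources(rng)
        a = fit_ica(raw, n_components=2, seed=1)
        b = fit_ica(raw, n_components=2, seed=1)
        np.testing.assert_array_equal(a.unmixing_, b.unmixing_)

    def test_rank_guard_reduces_components(self, rng, caplog):
        raw, _ = self._mixed_sources(rng)
        ica = fit_ica(raw, n_components=5, seed=0)
        assert ica.n_components_ == 2

    def test_unmixing_mixing_pseudoinverse(self, rng):
        raw, _ = self._mixed_sources(rng)
        ica = fit_ica(raw, n_components=2, seed=0)
        np.testing.assert_allclose(ica.unmixing_ @ ica.mixing_, np.eye(2),
                                   atol=1e-6)


class TestComponentClassification:
    @pytest.fixture(scope="class")
    def artifact_raw(self, montage):
        rng = np.random.default_rng(3)
        n = 60000
        sfreq = 500.0
        data = 2.0 * rng.standard_normal((48, n))
        # blink train at the frontopolar sites
        blink_pat = 0.5 * (gaussian_pattern(montage, "Fp1", 0.4)
                           + gaussian_pattern(montage, "Fp2", 0.4))
        bump = np.hanning(150)
        ts = np.zeros(n)
        for t0 in rng.uniform(0, n - 200, size=30).astype(int):
            ts[t0 : t0 + 150] += 60.0 * bump
        data += blink_pat[:, None] * ts[None, :]
        # bursty high-beta/gamma source at T7 (EMG is intermittent, hence
        # super-Gaussian and separable by ICA)
        from scipy import signal as sps
        sos = sps.butter(4, (25, 40), btype="bandpass", fs=sfreq, output="sos")
        musc = sps.sosfiltfilt(sos, rng.standard_normal(n))
        env = np.zeros(n)
        burst = np.hanning(500)
        for t0 in rng.uniform(0, n - 600, size=25).astype(int):
            env[t0 : t0 + 500] = np.maximum(env[t0 : t0 + 500], burst)
        data += gaussian_pattern(montage, "T7", 0.25)[:, None] * (12 * env * musc)[None, :]
        # central mu source
        sos = sps.butter(4, (9, 13), btype="bandpass", fs=sfreq, output="sos")
        mu = sps.sosfiltfilt(sos, rng.standard_normal(n))
        data += gaussian_pattern(montage, "C3", 0.5)[:, None] * (6 * mu)[None, :]
        return RawRecording(data, sfreq, montage)

    def test_planted_artifacts_labelled(self, artifact_raw, montage):
        ica = fit_ica(artifact_raw, n_components=8, seed=0, decim=2)
        labels = classify_components(ica, artifact_raw)
        assert "eog" in labels
        assert "muscle" in labels
        # the mu component is not flagged: find the component most correlated
        # with C3 and check its label
        srcs = ica.get_sources(artifact_raw)
        c3 = artifact_raw.data[montage.index("C3")]
        corr = [abs(np.corrcoef(s, c3)[0, 1]) for s in srcs]
        assert labels[int(np.argmax(corr))] == "brain"

    def test_blink_removal_drops_fp1_variance(self, artifact_raw, montage):
        ica = fit_ica(artifact_raw, n_components=8, seed=0, decim=2)
        classify_components(ica, artifact_raw)
        out = remove_components(artifact_raw, ica, ["eog"])
        i = montage.index("Fp1")
        assert out.data[i].var() < 0.2 * artifact_raw.data[i].var()

    def test_remove_nothing_is_identity(self, artifact_raw):
        ica = fit_ica(artifact_raw, n_components=8, seed=0, decim=2)
        out = remove_components(artifact_raw, ica, [])
        np.testing.assert_array_equal(out.data, artifact_raw.data)

    def test_missing_required_channel_rejected(self, rng):
        m = standard_montage(["C3", "C4", "Cz"])
        raw = RawRecording(rng.standard_normal((3, 5000)), 500.0, m)
        ica = fit_ica(raw, n_components=3, seed=0)
        with pytest.raises(ValueError, match="Fp1"):
            classify_components(ica, raw)


class TestEpoching:
    def test_epoch_counts_and_length(self, small_subject):
        raw = small_subject.recordings["passive"]
        sched = small_subject.schedules["passive"]
        ep = extract_epochs(raw, sched, "movement_onset", -1.0, 1.0)
        assert len(ep) == 16
        assert ep.data.shape == (16, 48, 1001)
        np.testing.assert_allclose(ep.times[0], -1.0)
        np.testing.assert_allclose(ep.times[-1], 1.0)

    def test_epoch_samples_are_exact_slices(self, small_subject):
        # no resampling anywhere: epoch content must equal the raw samples
        raw = small_subject.recordings["passive"]
        sched = small_subject.schedules["passive"]
        ep = extract_epochs(raw, sched, "movement_onset", -0.5, 0.5)
        onset = float(ep.metadata["onset_s"].iloc[0])
        c = int(round(onset * raw.sfreq))
        np.testing.assert_array_equal(
            ep.data[0], raw.data[:, c - 250 : c + 251])

    def test_out_of_bounds_events_dropped(self, montage, rng):
        from mirrorloop.containers import EventSchedule

        raw = RawRecording(rng.standard_normal((48, 2500)), 500.0, montage)
        sched = EventSchedule.from_records([
            dict(onset_s=0.2, kind="movement_onset", finger=None,
                 is_target=None, condition="AO", trial_index=0),
            dict(onset_s=2.5, kind="movement_onset", finger=None,
                 is_target=None, condition="AO", trial_index=1),
        ])
        ep = extract_epochs(raw, sched, "movement_onset", -1.0, 1.0)
        assert len(ep) == 1
        with pytest.raises(ValueError, match="no 'cue' events"):
            extract_epochs(raw, sched, "cue", -1.0, 1.0)

    def test_bci_rest_epochs_cut_before_feedback(self, small_subject):
        raw = small_subject.recordings["bci"]
        sched = small_subject.schedules["bci"]
        rest = extract_epochs(raw, sched, "feedback_onset", -4.0, -2.0)
        assert rest.data.shape[2] == 1001  # 2 s at 500 Hz
        assert len(rest) == 10


class TestBaseline:
    def test_constant_epoch_zeroed(self, montage):
        from mirrorloop.containers import Epochs
        import pandas as pd

        times = np.arange(-500, 501) / 500.0
        ep = Epochs(np.full((3, 48, 1001), 5.0), times, 500.0,
                    pd.DataFrame({"condition": ["AO"] * 3}))
        out = baseline_correct(ep)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_ramp_minus_interval_mean(self, montage):
        from mirrorloop.containers import Epochs
        import pandas as pd

        times = np.arange(-500, 501) / 500.0
        ramp = np.tile(times, (1, 48, 1)).astype(float)
        ep = Epochs(ramp, times, 500.0, pd.DataFrame({"condition": ["AO"]}))
        out = baseline_correct(ep, (-1.0, -0.2))
        expected = times - (-0.6)  # mean of the uniform interval
        np.testing.assert_allclose(out.data[0, 0], expected, atol=1e-9)
        sel = (times >= -1.0) & (times <= -0.2)
        np.testing.assert_allclose(out.data[..., sel].mean(), 0.0, atol=1e-9)

    def test_interval_outside_epoch_rejected(self):
        from mirrorloop.containers import Epochs
        import pandas as pd

        times = np.arange(0, 101) / 500.0
        ep = Epochs(np.zeros((1, 2, 101)), times, 500.0,
                    pd.DataFrame({"condition": ["AO"]}))
        with pytest.raises(ValueError, match="outside"):
            baseline_correct(ep, (-1.0, -0.5))


def test_amplitude_rejection(montage):
    from mirrorloop.containers import Epochs
    import pandas as pd

    times = np.arange(0, 101) / 500.0
    data = np.zeros((4, 2, 101))
    data[2, 0, 50] = 200.0
    ep = Epochs(data, times, 500.0, pd.DataFrame({"condition": ["AO"] * 4}))
    out = reject_epochs(ep, 120.0)
    assert len(out) == 3


def test_full_preprocess_preserves_band_content(montage):
    """A clean recording (no artifacts) loses < 5% RMS in 2-35 Hz."""
    from scipy import signal as sps
    from mirrorloop.simulate import SpellerConfig, build_speller_schedule
    from mirrorloop.preprocess import preprocess_raw

    rng = np.random.default_rng(9)
    sched, _ = build_speller_schedule(
        SpellerConfig(n_trials=3, n_forced_errors=1), rng)
    sources = [SourceSpec("C3", band=(9, 13), envelope_kind="constant",
                          amplitude=4.0),
               SourceSpec("Oz", band=(8, 12), envelope_kind="constant",
                          amplitude=4.0)]
    raw = synthesize_recording(sched, sources, montage, 5, duration=60.0,
                               sensor_noise_uv=6.0)
    ref = rereference_average(raw)  # the comparison baseline
    out = preprocess_raw(raw, run_ica=True, n_components=10, seed=0,
                         ica_decim=5)
    sos = sps.butter(4, (2.0, 35.0), btype="bandpass", fs=500.0, output="sos")
    a = sps.sosfiltfilt(sos, ref.data, axis=1)[:, 2000:-2000]
    b = sps.sosfiltfilt(sos, out.data, axis=1)[:, 2000:-2000]
    rel = np.sqrt(((a - b) ** 2).mean()) / np.sqrt((a ** 2).mean())
    assert rel < 0.05
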