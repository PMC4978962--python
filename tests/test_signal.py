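"""Filtering, segmentation, PLV estimation and FC ratios."""

import numpy as np
import pytest
import yaml
from hypothesis import given, settings, strategies as st

from plvmotif import io as pio
from plvmotif.signal import (
    AlignmentError,
    BandSpec,
    ConnectivityMatrix,
    DEFAULT_BANDS,
    InsufficientDataError,
    TrialSet,
    bandpass,
    plv_matrix,
    ratio_matrix,
    segment,
)

FS = 250.0


def tone(freq, fs=FS, duration=60.0, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)[None, :]


def fft_amplitude(x, freq, fs=FS):
    """FFT oracle: amplitude of the component nearest ``freq``."""
    spec = np.abs(np.fft.rfft(x[0])) * 2 / x.shape[-1]
    freqs = np.fft.rfftfreq(x.shape[-1], 1 / fs)
    return spec[np.argmin(np.abs(freqs - freq))]


class TestBandpass:
    def test_in_band_tone_preserved(self):
        x = tone(10.0)
        y = bandpass(x, DEFAULT_BANDS["alpha"], FS)
        ratio = fft_amplitude(y, 10.0) / fft_amplitude(x, 10.0)
        assert 0.95 <= ratio <= 1.05

    def test_out_of_band_tone_suppressed(self):
        x = tone(10.0)
        y = bandpass(x, DEFAULT_BANDS["delta"], FS)
        assert fft_amplitude(y, 10.0) / fft_amplitude(x, 10.0) < 0.01

    def test_zero_phase_response(self):
        x = tone(10.0)
        y = bandpass(x, DEFAULT_BANDS["alpha"], FS)
        # cross-correlation of filtered vs raw must peak at zero lag
        xc = np.correlate(y[0], x[0], mode="full")
        lag = np.argmax(xc) - (len(x[0]) - 1)
        assert lag == 0

    def test_zero_input_gives_zero_output(self):
        y = bandpass(np.zeros((2, 4000)), DEFAULT_BANDS["beta"], FS)
        assert np.allclose(y, 0.0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(tone(10.0), DEFAULT_BANDS["beta"], fs=50.0)

    def test_short_signal_rejected(self):
        with pytest.raises(InsufficientDataError):
            bandpass(np.zeros((1, 500)), DEFAULT_BANDS["alpha"], FS)


class TestSegment:
    def test_four_minutes_gives_sixty_trials(self):
        ts = segment(np.zeros((3, int(240 * FS))), FS)
        assert ts.n_trials == 60
        assert ts.data.shape == (60, 3, 1000)

    def test_remainder_dropped(self):
        ts = segment(np.zeros((1, int(64.5 * FS))), FS)
        assert ts.n_trials == 16

    def test_too_few_trials_rejected(self):
        with pytest.raises(InsufficientDataError):
            segment(np.zeros((1, int(59.9 * FS))), FS)

    def test_exactly_fifteen_trials_accepted(self):
        ts = segment(np.zeros((1, int(60 * FS))), FS)
        assert ts.n_trials == 15


def phase_trialset(phases, **kw):
    defaults = dict(subject_id="s", session="pre", band=DEFAULT_BANDS["theta"], fs=FS)
    defaults.update(kw)
    return TrialSet(data=phases, kind="phase", **defaults)


def brute_force_plv(phases):
    """Independent oracle: explicit per-pair, per-trial phasor sums."""
    n_trials, n_nodes, _ = phases.shape
    out = np.eye(n_nodes)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            per_trial = [
                abs(np.mean(np.exp(1j * (phases[k, i] - phases[k, j]))))
                for k in range(n_trials)
            ]
            out[i, j] = out[j, i] = np.mean(per_trial)
    return out


class TestPlvMatrix:
    def test_identical_series_give_unit_plv(self, rng):
        x = rng.normal(size=(2, 1, 1000))
        data = np.concatenate([x, x], axis=1)
        ts = TrialSet("s", "pre", DEFAULT_BANDS["alpha"], FS, data, kind="signal")
        assert plv_matrix(ts).plv[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_constant_phase_offset_gives_unit_plv(self, rng):
        ph = rng.uniform(0, 2 * np.pi, size=(3, 1, 500))
        data = np.concatenate([ph, ph + 1.234], axis=1)
        assert plv_matrix(phase_trialset(data)).plv[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            phases = rng.uniform(-np.pi, np.pi, size=(2, 3, 64))
            got = plv_matrix(phase_trialset(phases)).plv
            np.testing.assert_allclose(got, brute_force_plv(phases), atol=1e-10)

    def test_single_trial_rayleigh_floor(self, rng):
        t_eff = 1000
        phases = rng.uniform(-np.pi, np.pi, size=(1, 40, t_eff))
        plv = plv_matrix(phase_trialset(phases)).plv
        offdiag = plv[np.triu_indices(40, 1)]
        expected = np.sqrt(np.pi / (4 * t_eff))
        assert np.mean(offdiag) == pytest.approx(expected, rel=0.15)

    def test_global_phase_shift_invariance(self, rng):
        phases = rng.uniform(-np.pi, np.pi, size=(2, 4, 128))
        base = plv_matrix(phase_trialset(phases)).plv
        shifted = plv_matrix(phase_trialset(phases + 0.9)).plv
        np.testing.assert_allclose(base, shifted, atol=1e-12)

    def test_amplitude_rescale_invariance(self, rng):
        x = rng.normal(size=(2, 3, 800))
        scaled = x.copy()
        scaled[:, 1, :] *= 7.5
        a = plv_matrix(TrialSet("s", "pre", DEFAULT_BANDS["alpha"], FS, x))
        b = plv_matrix(TrialSet("s", "pre", DEFAULT_BANDS["alpha"], FS, scaled))
        np.testing.assert_allclose(a.plv, b.plv, atol=1e-10)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_plv_bounded_symmetric_unit_diagonal(self, seed):
        phases = np.random.default_rng(seed).uniform(-np.pi, np.pi, size=(2, 4, 50))
        plv = plv_matrix(phase_trialset(phases)).plv
        assert np.all((plv >= 0) & (plv <= 1))
        np.testing.assert_allclose(plv, plv.T)
        np.testing.assert_allclose(np.diag(plv), 1.0)

    def test_nonfinite_input_rejected(self):
        data = np.zeros((1, 2, 100))
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            TrialSet("s", "pre", DEFAULT_BANDS["alpha"], FS, data)


def conn(mat, sid="s", session="pre", band=DEFAULT_BANDS["theta"]):
    return ConnectivityMatrix(sid, session, band, mat)


class TestRatioMatrix:
    def test_identity_when_sessions_equal(self, rng):
        m = np.abs(rng.uniform(0.2, 0.9, size=(4, 4)))
        m = 0.5 * (m + m.T)
        r = ratio_matrix(conn(m, session="post"), conn(m))
        np.testing.assert_allclose(r.ratio, np.ones((4, 4)))

    def test_elementwise_quotient(self):
        pre = np.full((2, 2), 0.5)
        post = np.full((2, 2), 0.6)
        r = ratio_matrix(conn(post, session="post"), conn(pre))
        assert r.ratio[0, 1] == pytest.approx(1.2)

    def test_zero_pre_floored_with_warning(self):
        pre = np.array([[1.0, 0.0], [0.0, 1.0]])
        post = np.array([[1.0, 0.5], [0.5, 1.0]])
        with pytest.warns(RuntimeWarning, match="floored"):
            r = ratio_matrix(conn(post, session="post"), conn(pre))
        assert np.isfinite(r.ratio).all()
        assert r.ratio[0, 1] == pytest.approx(0.5 / 1e-6)

    def test_subject_mismatch_rejected(self):
        m = np.eye(2)
        with pytest.raises(AlignmentError):
            ratio_matrix(conn(m, sid="a", session="post"), conn(m, sid="b"))


class TestBandDefaults:
    def test_canonical_edges(self):
        assert DEFAULT_BANDS["delta"] == BandSpec("delta", 2.0, 3.9)
        assert DEFAULT_BANDS["theta"] == BandSpec("theta", 4.1, 7.9)
        assert DEFAULT_BANDS["alpha"] == BandSpec("alpha", 8.1, 11.9)
        assert DEFAULT_BANDS["beta"] == BandSpec("beta", 12.1, 29.9)

    def test_roundtrip_through_yaml_config(self):
        for band in DEFAULT_BANDS.values():
            payload = yaml.safe_load(yaml.safe_dump(pio.band_to_dict(band)))
            assert pio.band_from_dict(payload) == band
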