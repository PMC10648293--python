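"""Feature extraction: evoked detection, PSC area, TFA peaks, PCA, bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import oracle_polygon_area

from ssepml.features import (
    FEATURE_NAMES,
    EvokedWindows,
    all_feature_columns,
    assemble_feature_table,
    channel_columns,
    detect_evoked_response,
    nerve_columns,
    pca_scores,
    psc_area,
    tfa_features,
)
from ssepml.session import NERVE_MONTAGES, SSEPTrial


def _make_trial(samples, sample_rate=2000.0, nerve="left_ulnar", montage="CP4-Fpz"):
    return SSEPTrial(
        trial_id="t",
        nerve=nerve,
        montage=montage,
        timestamp=0.0,
        samples=np.asarray(samples, float),
        sample_rate=sample_rate,
    )


def _canonical_wave(sample_rate=2000.0, shift_ms=0.0, scale=1.0, n_ms=100.0):
    """N20/P30-like double bump used for equivariance checks."""
    t = np.arange(int(n_ms * sample_rate / 1000)) * 1000.0 / sample_rate
    wave = -2.0 * np.exp(-((t - 20 - shift_ms) ** 2) / (2 * 2.5**2))
    wave += 1.2 * np.exp(-((t - 30 - shift_ms) ** 2) / (2 * 3.0**2))
    return scale * wave


class TestDetectEvokedResponse:
    def test_canonical_latencies(self):
        trial = _make_trial(_canonical_wave())
        lat_p, amp_p, lat_v, amp_v = detect_evoked_response(trial)
        assert (lat_v, lat_p) == (20.0, 30.0)
        assert amp_v < 0 < amp_p

    def test_translation_equivariance(self):
        base = detect_evoked_response(_make_trial(_canonical_wave()))
        shifted = detect_evoked_response(_make_trial(_canonical_wave(shift_ms=2.0)))
        assert shifted[0] - base[0] == pytest.approx(2.0, abs=1e-9)
        assert shifted[2] - base[2] == pytest.approx(2.0, abs=1e-9)
        assert shifted[1] == pytest.approx(base[1], rel=1e-6)
        assert shifted[3] == pytest.approx(base[3], rel=1e-6)

    def test_amplitude_scale_equivariance(self):
        base = detect_evoked_response(_make_trial(_canonical_wave()))
        doubled = detect_evoked_response(_make_trial(_canonical_wave(scale=2.0)))
        assert doubled[1] == pytest.approx(2 * base[1])
        assert doubled[3] == pytest.approx(2 * base[3])
        assert (doubled[0], doubled[2]) == (base[0], base[2])

    def test_window_outside_sampled_range_rejected(self):
        trial = _make_trial(_canonical_wave(n_ms=30.0))  # ends before P30's window
        with pytest.raises(ValueError, match="window"):
            detect_evoked_response(trial)


class TestPscArea:
    def test_zero_waveform_has_zero_area(self):
        assert psc_area(_make_trial(np.zeros(200))) == 0.0

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        scale=st.floats(0.1, 10.0),
        seed=st.integers(0, 2**16),
    )
    def test_quadratic_scaling(self, scale, seed):
        wave = np.random.default_rng(seed).normal(size=120)
        a1 = psc_area(_make_trial(wave))
        a2 = psc_area(_make_trial(scale * wave))
        assert a2 == pytest.approx(scale**2 * a1, rel=1e-9)

    def test_sinusoid_quarter_period_delay_gives_circle_area(self):
        # 2 ms delay = quarter period of 125 Hz; one full period closes a circle
        fs, delay_ms, amp = 10000.0, 2.0, 1.7
        lag = int(delay_ms * fs / 1000)
        period = 4 * lag
        n = period + 2 * lag  # embedding consumes (dim-1)*lag samples
        t = np.arange(n) / fs
        wave = amp * np.sin(2 * np.pi * 125.0 * t)
        area = psc_area(_make_trial(wave, sample_rate=fs), delay_ms=delay_ms)
        assert area == pytest.approx(np.pi * amp**2, rel=5e-3)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**16), n=st.integers(12, 50))
    def test_matches_polygon_area_oracle(self, seed, n):
        """Shoelace area equals an independent triangle-fan polygon oracle."""
        wave = np.random.default_rng(seed).normal(size=n)
        lag = 2
        pts = np.column_stack([wave[: n - 2 * lag], wave[lag : n - lag]])
        expected = oracle_polygon_area(pts)
        got = psc_area(_make_trial(wave, sample_rate=2000.0), delay_ms=1.0)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_excessive_delay_rejected(self):
        with pytest.raises(ValueError, match="delay"):
            psc_area(_make_trial(np.zeros(50)), delay_ms=20.0)


class TestTfaFeatures:
    def test_pure_tone_peak_frequency(self):
        fs = 2000.0
        t = np.arange(200) / fs
        trial = _make_trial(np.sin(2 * np.pi * 100.0 * t), sample_rate=fs)
        freq, power, _ = tfa_features(trial)
        bin_width = fs / int(0.020 * fs)  # 20 ms Hann window
        assert abs(freq - 100.0) <= bin_width
        assert power > 0

    def test_burst_peak_time(self):
        fs = 5000.0
        t_ms = np.arange(500) * 1000.0 / fs
        burst = np.sin(2 * np.pi * 0.15 * t_ms) * np.exp(-((t_ms - 30) ** 2) / (2 * 4**2))
        _, _, peak_time = tfa_features(_make_trial(burst, sample_rate=fs))
        assert abs(peak_time - 30.0) <= 10.0  # one hop of the 20 ms / 50% STFT

    def test_zero_signal_degenerate_output(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="ssepml.features"):
            freq, power, t0 = tfa_features(_make_trial(np.zeros(200)))
        assert (freq, power, t0) == (10.0, 0.0, 0.0)
        assert any("all-zero" in r.message for r in caplog.records)

    def test_band_must_be_inside_nyquist(self):
        with pytest.raises(ValueError, match="band"):
            tfa_features(_make_trial(np.ones(200)), band_hz=(10.0, 5000.0))


class TestPcaScores:
    def test_identical_trials_degenerate(self):
        scores, cumvar = pca_scores(np.ones((6, 40)))
        assert np.all(scores == 0.0)
        assert np.isnan(cumvar)

    def test_rank_one_matrix_fully_explained_by_pc1(self, rng):
        v = rng.normal(size=50)
        coeffs = np.array([1.0, 2.0, -1.0, 0.5, 3.0])
        scores, cumvar = pca_scores(np.outer(coeffs, v))
        assert cumvar == pytest.approx(1.0)
        assert np.allclose(scores[:, 1:], 0.0, atol=1e-8)

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError, match="trials"):
            pca_scores(rng.normal(size=(3, 40)))

    def test_row_permutation_equivariance(self, rng):
        X = rng.normal(size=(10, 30)) @ np.diag(np.linspace(2, 0.1, 30))
        perm = rng.permutation(10)
        scores, _ = pca_scores(X)
        scores_p, _ = pca_scores(X[perm])
        assert np.allclose(scores_p, scores[perm], atol=1e-8)


class TestBookkeeping:
    def test_feature_count_conservation(self):
        assert len(FEATURE_NAMES) == 11
        for nerve, montages in NERVE_MONTAGES.items():
            for m in montages:
                assert len(channel_columns(nerve, m)) == 11
            assert len(nerve_columns(nerve)) == 33
        cols = all_feature_columns()
        assert len(cols) == 132
        assert len(set(cols)) == 132

    def test_assembled_table_counts(self, small_cfg, small_table):
        feature_cols = [
            c for c in small_table.columns
            if c not in ("patient_id", "nerve", "timestamp_s", "et_sevo_pct")
        ]
        assert len(feature_cols) == 132
        assert not small_table["et_sevo_pct"].isna().any()
        # each row carries its own nerve's 33 features, dense
        for nerve in NERVE_MONTAGES:
            sub = small_table[small_table["nerve"] == nerve]
            assert len(sub) == small_cfg.n_patients * small_cfg.trials_per_nerve
            assert not sub[nerve_columns(nerve)].isna().any().any()

    def test_latencies_inside_search_windows(self, small_table):
        windows = EvokedWindows().windows
        comp_of = {
            ("left_ulnar", "CP4-Fpz"): ("P30", "N20"),
            ("left_ulnar", "CS5-Fpz"): ("P14", "N13"),
            ("left_post_tibial", "CPz-Fpz"): ("P37", "N45"),
        }
        for (nerve, montage), (pos, neg) in comp_of.items():
            sub = small_table[small_table["nerve"] == nerve]
            lat_p = sub[f"{nerve}.{montage}.lat_peak"]
            lat_v = sub[f"{nerve}.{montage}.lat_valley"]
            assert lat_p.between(windows[pos].start_ms, windows[pos].end_ms).all()
            assert lat_v.between(windows[neg].start_ms, windows[neg].end_ms).all()
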