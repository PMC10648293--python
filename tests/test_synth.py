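"""Generator behaviour: profiles, dose effects, cohort structure, determinism."""

import dataclasses

import numpy as np
import pytest

from ssepml.features import detect_evoked_response, pca_scores
from ssepml.session import NERVE_MONTAGES, SchemaError, synchronize
from ssepml.synth import (
    ComponentTemplate,
    ConcentrationProfile,
    GeneratorConfig,
    generate_cohort,
    generate_concentration_profile,
    generate_patient,
    synthesize_trial,
)


class TestConcentrationProfile:
    def test_degenerate_profile_is_constant(self):
        cfg = GeneratorConfig(
            concentration_profile=ConcentrationProfile(
                induction_minutes=0.0,
                maintenance_mean=2.0,
                maintenance_sd=0.0,
                emergence_minutes=0.0,
            )
        )
        series = generate_concentration_profile(cfg, patient_seed=0)
        assert np.allclose(series.et_sevo, 2.0)

    def test_one_reading_per_minute(self):
        cfg = GeneratorConfig(session_minutes=120.0)
        series = generate_concentration_profile(cfg, patient_seed=0)
        assert len(series) == 120
        assert np.allclose(np.diff(series.timestamps), 60.0)

    def test_seed_determinism_and_distinctness(self):
        cfg = GeneratorConfig()
        a = generate_concentration_profile(cfg, patient_seed=1)
        b = generate_concentration_profile(cfg, patient_seed=1)
        c = generate_concentration_profile(cfg, patient_seed=2)
        assert np.array_equal(a.et_sevo, b.et_sevo)
        assert not np.array_equal(a.et_sevo, c.et_sevo)

    def test_phases_are_piecewise(self):
        cfg = GeneratorConfig(
            concentration_profile=ConcentrationProfile(maintenance_sd=0.0)
        )
        series = generate_concentration_profile(cfg, patient_seed=0)
        c = series.et_sevo
        assert np.all(c >= 0)
        # rising induction, plateau, decaying emergence
        assert np.all(np.diff(c[:10]) > 0)
        assert np.allclose(c[10:105], 2.0)
        assert np.all(np.diff(c[106:]) < 0)

    def test_short_session_rejected(self):
        with pytest.raises(ValueError, match="session_minutes"):
            generate_concentration_profile(
                GeneratorConfig(session_minutes=5.0), patient_seed=0
            )


class TestSynthesizeTrial:
    def test_component_latencies_per_channel_class(self, rng):
        cfg = GeneratorConfig().noiseless()
        t = synthesize_trial("left_ulnar", "CP4-Fpz", 0.0, cfg, rng)
        lat_p, _, lat_v, _ = detect_evoked_response(t)
        assert (lat_v, lat_p) == (20.0, 30.0)  # N20 / P30
        t = synthesize_trial("right_post_tibial", "CPz-Fpz", 0.0, cfg, rng)
        lat_p, _, lat_v, _ = detect_evoked_response(t)
        assert (lat_p, lat_v) == (37.0, 45.0)  # P37 / N45
        # raw extrema of the noiseless cortical waveform match the detections
        t = synthesize_trial("left_ulnar", "CP4-Fpz", 0.0, cfg, rng)
        assert t.times_ms[np.argmin(t.samples)] == 20.0
        assert t.times_ms[np.argmax(t.samples)] == 30.0

    def test_closed_form_dose_effect(self, rng):
        cfg = dataclasses.replace(
            GeneratorConfig().noiseless(), amp_atten_k=0.3, lat_shift_k=1.5
        )
        base = synthesize_trial("left_ulnar", "CP4-Fpz", 0.0, cfg, rng)
        dosed = synthesize_trial("left_ulnar", "CP4-Fpz", 2.0, cfg, rng)
        p0, a0, v0, av0 = detect_evoked_response(base)
        p2, a2, v2, av2 = detect_evoked_response(dosed)
        # amplitudes shrink by exp(-k_A * c) = exp(-0.6); latencies shift k_L*c = +3 ms
        assert a2 / a0 == pytest.approx(np.exp(-0.6), rel=1e-6)
        assert av2 / av0 == pytest.approx(np.exp(-0.6), rel=1e-6)
        assert p2 - p0 == pytest.approx(3.0, abs=1e-9)
        assert v2 - v0 == pytest.approx(3.0, abs=1e-9)

    def test_unknown_pairing_rejected(self, rng):
        with pytest.raises(SchemaError):
            synthesize_trial("left_ulnar", "CPz-Fpz", 0.0, GeneratorConfig(), rng)

    def test_negative_concentration_rejected(self, rng):
        with pytest.raises(ValueError):
            synthesize_trial("left_ulnar", "CP4-Fpz", -0.1, GeneratorConfig(), rng)

    @pytest.mark.parametrize(
        "nerve,montage",
        [("left_ulnar", "CP4-Fpz"), ("left_ulnar", "CS5-Fpz"), ("left_post_tibial", "CPz-Fpz")],
    )
    def test_dose_monotonicity_noiseless(self, nerve, montage, rng):
        """With noise off, detected amplitude magnitude strictly falls and
        latency strictly rises with concentration."""
        cfg = GeneratorConfig().noiseless()
        lats, amps = [], []
        for c in np.linspace(0.0, 3.0, 7):
            t = synthesize_trial(nerve, montage, float(c), cfg, rng)
            lat_p, amp_p, lat_v, amp_v = detect_evoked_response(t)
            lats.append((lat_p, lat_v))
            amps.append((abs(amp_p), abs(amp_v)))
        lats, amps = np.array(lats), np.array(amps)
        assert np.all(np.diff(lats, axis=0) > 0)
        assert np.all(np.diff(amps, axis=0) < 0)


class TestCohort:
    def test_cohort_structure(self, small_cfg, small_cohort):
        assert len(small_cohort) == small_cfg.n_patients
        for session in small_cohort:
            session.validate()
            streams = {(t.nerve, t.montage) for t in session.trials}
            assert len(streams) == 12  # 4 nerves x 3 montages
            for nerve, montages in NERVE_MONTAGES.items():
                for m in montages:
                    assert (
                        len(session.channel_trials(nerve, m))
                        == small_cfg.trials_per_nerve
                    )

    def test_cohort_determinism(self, small_cfg, small_cohort):
        again = generate_cohort(small_cfg)
        for a, b in zip(small_cohort, again):
            assert a.patient_id == b.patient_id
            assert np.array_equal(a.anesthesia.et_sevo, b.anesthesia.et_sevo)
            for ta, tb in zip(a.trials, b.trials):
                assert ta.trial_id == tb.trial_id
                assert np.array_equal(ta.samples, tb.samples)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="n_patients"):
            generate_cohort(GeneratorConfig(n_patients=2))

    def test_default_channel_trial_matrix_is_low_rank(self):
        """First three PCs of a default per-channel trial matrix carry >= 95%
        of the variance (the generator keeps noise small enough for this)."""
        patient = generate_patient(GeneratorConfig(seed=11), 0)
        synced = synchronize(patient)
        matrix = np.vstack(
            [
                st.trial.samples
                for st in synced
                if st.trial.nerve == "left_ulnar" and st.trial.montage == "CP4-Fpz"
            ]
        )
        _, cumvar = pca_scores(matrix, n_components=3)
        assert cumvar >= 0.95


class TestComponentTemplate:
    def test_polarity_must_match_name(self):
        with pytest.raises(ValueError, match="polarity"):
            ComponentTemplate("N20", +1, 20.0, 2.0, 2.5)
        with pytest.raises(ValueError, match="width"):
            ComponentTemplate("P30", +1, 30.0, 1.0, 0.0)
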