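from itertools import combinations

import numpy as np
import pytest

from qeegnorm.montage import preprocess, reconstruct_double_banana
from qeegnorm.normative import LOBE_CHANNELS
from qeegnorm.spectral import BAND_NAMES, band_areas, make_windows, power_spectrum
from qeegnorm.synchronization import band_coherence, coherence_spectrum
from qeegnorm.synthetic import (CohortSpec, SubjectSpec, default_band_power,
                                default_pdr, default_shared_fraction,
                                generate_cohort, generate_feature_cohort,
                                generate_subject, realize_spec, subject_traits,
                                twin_sessions, _measure_band_areas)


def shared_single_lobe(cval, side, lobe, age=30.0):
    base = {k: {b: 0.0 for b in v}
            for k, v in default_shared_fraction(age).items()}
    for b in base[(side, lobe)]:
        base[(side, lobe)][b] = cval
    return base


def lobe_band_coherence(rec, side, lobe):
    bip = reconstruct_double_banana(preprocess(rec))
    chs = list(dict.fromkeys(LOBE_CHANNELS[side][lobe]))
    cs = coherence_spectrum(make_windows(bip), pairs=list(combinations(chs, 2)))
    return band_coherence(cs)


class TestSubjectSpecDefaults:
    def test_defaults_follow_age_group_tables(self):
        spec = SubjectSpec(age=35.0)
        assert spec.band_power[("L", "PO")]["alpha"] == pytest.approx(10 ** 1.35)
        assert spec.shared_fraction[("L", "F")]["delta"] == pytest.approx(
            np.sqrt(0.2654))
        freq, amps = default_pdr(35.0)
        assert spec.pdr_freq == pytest.approx(freq)
        assert spec.pdr_amp == pytest.approx(amps)

    def test_invalid_specs_rejected(self):
        bad_power = default_band_power(30.0)
        bad_power[("L", "F")]["delta"] = -1.0
        with pytest.raises(ValueError, match="infeasible"):
            SubjectSpec(age=30.0, band_power=bad_power)
        bad_shared = default_shared_fraction(30.0)
        bad_shared[("L", "T")]["alpha"] = 1.5
        with pytest.raises(ValueError, match="shared_fraction"):
            SubjectSpec(age=30.0, shared_fraction=bad_shared)
        with pytest.raises(ValueError, match="pdr_freq"):
            SubjectSpec(age=30.0, pdr_freq=5.0)
        with pytest.raises(ValueError, match="pdr_amp"):
            SubjectSpec(age=30.0, pdr_amp=-2.0)


class TestGenerateSubject:
    def test_same_seed_bit_identical(self):
        a, _ = generate_subject(SubjectSpec(age=30.0, seed=9), duration=30.0)
        b, _ = generate_subject(SubjectSpec(age=30.0, seed=9), duration=30.0)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_different_seed_differs(self):
        a, _ = generate_subject(SubjectSpec(age=30.0, seed=9), duration=30.0)
        b, _ = generate_subject(SubjectSpec(age=30.0, seed=10), duration=30.0)
        assert not np.array_equal(a.samples, b.samples)

    def test_output_passes_recording_invariants(self, synth_subject):
        rec, truth = synth_subject
        assert rec.fs == 512.0
        assert rec.duration == pytest.approx(60.0)
        assert rec.subject_age == truth["age"]
        assert np.all(np.isfinite(rec.samples))  # also enforced in __post_init__

    def test_band_power_recovered_within_ten_percent(self):
        rec, truth = generate_subject(SubjectSpec(age=35.0, seed=42),
                                      duration=180.0)
        measured = _measure_band_areas(rec)
        rel = ((measured - truth["band_power"]).abs()
               / truth["band_power"]).max().max()
        assert rel < 0.10

    def test_alpha_only_spec_concentrates_posterior_power(self):
        power = {k: {b: (20.0 if b == "alpha" else 0.05) for b in v}
                 for k, v in default_band_power(30.0).items()}
        spec = SubjectSpec(age=30.0, seed=4, band_power=power, pdr_amp=15.0)
        rec, _ = generate_subject(spec, duration=60.0)
        areas = _measure_band_areas(rec)
        for ch in ("P3-O1", "P4-O2"):
            assert areas.loc[ch, "alpha"] / areas.loc[ch].sum() > 0.95

    def test_pdr_oscillator_measured_by_pipeline(self, synth_subject):
        rec, truth = synth_subject
        from qeegnorm.pipeline import analyze_recording

        feats = analyze_recording(rec)
        assert abs(feats.pdr.freq_left - truth["pdr_freq"]) <= 0.5
        assert abs(feats.pdr.freq_right - truth["pdr_freq"]) <= 0.5


class TestCoherenceControl:
    def test_fully_shared_lobe_is_fully_coherent(self):
        spec = SubjectSpec(age=30.0, seed=5,
                           shared_fraction=shared_single_lobe(1.0, "L", "PO"),
                           pdr_amp=0.01)
        rec, _ = generate_subject(spec, duration=60.0)
        bc = lobe_band_coherence(rec, "L", "PO")
        assert bc.min().min() > 0.9

    def test_band_coherence_monotone_in_shared_fraction(self):
        prev = -1.0
        for c in (0.0, 0.25, 0.5, 0.75, 1.0):
            spec = SubjectSpec(age=30.0, seed=5,
                               shared_fraction=shared_single_lobe(c, "L", "T"),
                               pdr_amp=0.01)
            rec, _ = generate_subject(spec, duration=60.0)
            m = float(lobe_band_coherence(rec, "L", "T")["alpha"].mean())
            assert m > prev
            prev = m


class TestCohorts:
    def test_traits_deterministic_and_ages_in_range(self):
        cs = CohortSpec(n=6, seed=3)
        t1 = subject_traits(cs)
        t2 = subject_traits(cs)
        assert [a["age"] for a in t1] == [a["age"] for a in t2]
        assert all(10 <= a["age"] <= 74 for a in t1)

    def test_twin_sessions_share_traits_but_not_noise(self):
        cs = CohortSpec(n=2, seed=1, duration=30.0)
        s1, s2 = twin_sessions(cs)
        for (r1, t1), (r2, t2) in zip(s1, s2):
            assert t1["age"] == t2["age"]
            assert t1["pdr_freq"] == t2["pdr_freq"]
            assert not np.array_equal(r1.samples, r2.samples)

    def test_session_specs_reproducible(self):
        cs = CohortSpec(n=2, seed=8)
        tr = subject_traits(cs)
        a = realize_spec(tr[0], cs, 0, 1)
        b = realize_spec(tr[0], cs, 0, 1)
        assert a.seed == b.seed and a.band_power == b.band_power

    def test_generate_cohort_reproducible(self):
        cs = CohortSpec(n=2, seed=13, duration=30.0)
        a = generate_cohort(cs)
        b = generate_cohort(cs)
        for (ra, _), (rb, _) in zip(a, b):
            np.testing.assert_array_equal(ra.samples, rb.samples)

    def test_explicit_ages_validated(self):
        with pytest.raises(ValueError, match="ages"):
            CohortSpec(n=2, ages=(20.0, 90.0))
        with pytest.raises(ValueError, match="len"):
            CohortSpec(n=3, ages=(20.0, 30.0))


class TestFeatureCohort:
    def test_shape_and_ranges(self):
        df = generate_feature_cohort(50, seed=1)
        assert len(df) == 50
        assert df["age"].between(10, 74).all()
        assert {"pdr_freq", "pdr_amp_left", "sse_L_F",
                "logps_L_PO_alpha", "coh_L_T_alpha"} <= set(df.columns)

    def test_pdr_centered_on_normative_cubic(self):
        from qeegnorm.normative import load_normative_bundle

        df = generate_feature_cohort(400, seed=2)
        eq = load_normative_bundle()["pdr_frequency"]
        resid = df["pdr_freq"] - eq.evaluate(df["age"].to_numpy())
        assert abs(resid.mean()) < 0.1
        assert resid.std() == pytest.approx(0.5, rel=0.25)
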