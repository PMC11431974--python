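import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pwavekit as pk
from pwavekit.params import LeadParameters, PatientFeatures


def triangle(dur_ms=120, amp=0.2, fs=1000.0):
    n = int(dur_ms * fs / 1000.0) + 1
    u = np.linspace(0, 1, n)
    return amp * (1 - np.abs(2 * u - 1))


def biphasic(a1=0.1, d1_ms=60, a2=-0.08, d2_ms=50, fs=1000.0):
    u1 = np.linspace(0, np.pi, int(d1_ms * fs / 1000.0))
    u2 = np.linspace(0, np.pi, int(d2_ms * fs / 1000.0))
    return np.concatenate([a1 * np.sin(u1), a2 * np.sin(u2)])


class TestDuration:
    @pytest.mark.parametrize("onset,offset,fs,expected", [
        (400, 520, 1000.0, 120.0),
        (0, 60, 500.0, 120.0),
    ])
    def test_pwd_arithmetic(self, onset, offset, fs, expected):
        assert pk.compute_pwd(onset, offset, fs) == pytest.approx(expected)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            pk.compute_pwd(100, 100, 1000.0)

    @pytest.mark.parametrize("pwd,hr,expected", [
        (120.0, 60.0, 120.0),   # identity at 60 bpm
        (120.0, 80.0, 155.0),
        (140.0, 40.0, 105.0),
    ])
    def test_hodges_correction(self, pwd, hr, expected):
        assert pk.correct_pwd_hodges(pwd, hr) == pytest.approx(expected)

    @given(st.floats(min_value=50.0, max_value=250.0))
    @settings(max_examples=50, derandomize=True)
    def test_hodges_identity_at_60(self, pwd):
        assert pk.correct_pwd_hodges(pwd, 60.0) == pytest.approx(pwd)

    def test_hodges_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            pk.correct_pwd_hodges(120.0, 0.0)


class TestVoltageAndArea:
    def test_pwv_triangle(self):
        assert pk.compute_pwv(triangle(amp=0.2)) == pytest.approx(0.2)

    def test_pwv_baseline_subtracted(self):
        assert pk.compute_pwv(triangle(amp=0.2) + 0.05,
                              baseline=0.05) == pytest.approx(0.2)

    def test_pwv_biphasic_magnitude_winner_is_signed(self):
        seg = biphasic(a1=0.1, a2=-0.15)
        assert pk.compute_pwv(seg) == pytest.approx(-0.15, abs=0.002)

    def test_pwv_empty_segment(self):
        with pytest.raises(ValueError):
            pk.compute_pwv(np.array([]))

    def test_pwa_triangle_formula(self):
        assert pk.compute_pwa(pwd_ms=140.0, pwv_mv=0.2,
                              method="triangle") == pytest.approx(14.0)

    def test_pwa_trapezoid_matches_closed_form_triangle(self):
        area = pk.compute_pwa(triangle(120, 0.2), method="trapezoid")
        assert area == pytest.approx(12.0, abs=0.15)

    def test_pwa_zero_segment(self):
        assert pk.compute_pwa(np.zeros(100)) == 0.0

    def test_pwa_unknown_method(self):
        with pytest.raises(ValueError):
            pk.compute_pwa(triangle(), method="simpson")

    @given(st.floats(min_value=0.1, max_value=5.0))
    @settings(max_examples=30, derandomize=True)
    def test_amplitude_scaling_property(self, c):
        seg = triangle(120, 0.2)
        assert pk.compute_pwv(c * seg) == pytest.approx(
            c * pk.compute_pwv(seg))
        assert pk.compute_pwa(c * seg) == pytest.approx(
            c * pk.compute_pwa(seg), rel=1e-9)


class TestDispersion:
    def test_max_minus_min(self):
        assert pk.compute_pwdisp([110, 120, 150]) == pytest.approx(40.0)

    def test_zero_on_constant(self):
        assert pk.compute_pwdisp([120] * 5) == 0.0

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            pk.compute_pwdisp([120])

    def test_within_lead_matches_brute_force(self):
        rng = np.random.default_rng(9)
        beats = 120.0 + rng.normal(0, 5, 20)
        assert pk.compute_pwdisp(beats, mode="within_lead_beats") == \
            pytest.approx(beats.max() - beats.min())

    @given(st.lists(st.floats(min_value=80, max_value=200),
                    min_size=2, max_size=12))
    @settings(max_examples=50, derandomize=True)
    def test_permutation_invariant_and_nonnegative(self, durs):
        d = pk.compute_pwdisp(durs)
        assert d >= 0
        rng = np.random.default_rng(0)
        assert pk.compute_pwdisp(rng.permutation(durs)) == pytest.approx(d)


class TestMorphology:
    def test_single_positive_hump(self):
        assert pk.classify_morphology(triangle()) == "mono_pos"

    def test_biphasic_positive_then_negative(self):
        assert pk.classify_morphology(biphasic(0.1, 60, -0.08, 50)) == \
            "biphasic_pm"

    def test_biphasic_negative_then_positive(self):
        assert pk.classify_morphology(biphasic(-0.08, 50, 0.1, 60)) == \
            "biphasic_mp"

    def test_short_sign_flicker_ignored(self):
        seg = triangle(120, 0.2)
        seg[5:10] = -0.05  # 5 ms flicker, below min_phase_ms
        assert pk.classify_morphology(seg) == "mono_pos"

    def test_flat_segment(self):
        assert pk.classify_morphology(np.zeros(100)) == "flat"


class TestTerminalForce:
    def test_boundary_value(self):
        # terminal negative phase: 0.05 mV deep, 60 ms long
        seg = biphasic(0.1, 60, -0.05, 60)
        assert pk.compute_ptfv1(seg) == pytest.approx(-0.03, abs=0.002)

    def test_monophasic_is_zero(self):
        assert pk.compute_ptfv1(triangle()) == 0.0

    def test_deep_terminal_phase(self):
        seg = biphasic(0.1, 60, -0.1, 80)
        assert pk.compute_ptfv1(seg) == pytest.approx(-0.08, abs=0.004)


def make_features(pwd_by_lead, biphasic_leads=(), hr=60.0):
    leads = {}
    for lead, pwd in pwd_by_lead.items():
        morph = "biphasic_pm" if lead in biphasic_leads else "mono_pos"
        leads[lead] = LeadParameters(
            lead=lead, pwd_ms=pwd,
            pwdc_ms=pk.correct_pwd_hodges(pwd, hr), pwv_mv=0.2,
            pwa_msmv=10.0, pwa_triangle_msmv=10.0,
            within_lead_dispersion_ms=2.0, morphology=morph,
            n_beats_used=20)
    return PatientFeatures(patient_id="p", heart_rate_bpm=hr, leads=leads)


class TestIAB:
    def test_long_pwd_with_one_biphasic_inferior_lead(self):
        f = make_features({"II": 125, "III": 118, "aVF": 117},
                          biphasic_leads=("aVF",))
        assert pk.classify_iab(f) is True

    def test_short_pwd_never_iab(self):
        f = make_features({"II": 110, "III": 110, "aVF": 110},
                          biphasic_leads=("II", "III", "aVF"))
        assert pk.classify_iab(f) is False

    def test_monophasic_never_iab(self):
        f = make_features({"II": 130, "III": 128, "aVF": 126})
        assert pk.classify_iab(f) is False

    def test_all_rule_is_stricter(self):
        f = make_features({"II": 130, "III": 128, "aVF": 126},
                          biphasic_leads=("II",))
        assert pk.classify_iab(f, lead_rule="any") is True
        assert pk.classify_iab(f, lead_rule="all") is False

    def test_missing_inferior_lead_is_error(self):
        f = make_features({"II": 130, "aVF": 126})
        with pytest.raises(ValueError, match="III"):
            pk.classify_iab(f)

    @given(st.floats(min_value=0, max_value=80))
    @settings(max_examples=40, derandomize=True)
    def test_monotone_in_pwd(self, bump):
        base = make_features({"II": 121, "III": 118, "aVF": 117},
                             biphasic_leads=("III",))
        assert pk.classify_iab(base) is True
        longer = make_features({"II": 121 + bump, "III": 118, "aVF": 117},
                               biphasic_leads=("III",))
        assert pk.classify_iab(longer) is True


class TestExtractFeatures:
    def beats_frame(self, pwds, lead="II"):
        rows = [{"lead": lead, "beat": i, "p_onset": 0, "p_peak": 1,
                 "p_offset": 2, "pwd_ms": p, "pwv_mv": 0.2,
                 "pwa_msmv": 12.0, "morphology": "mono_pos",
                 "ptf_mms": 0.0} for i, p in enumerate(pwds)]
        return pd.DataFrame(rows)

    def test_identical_beats_pass_through(self):
        f = pk.extract_features(self.beats_frame([120.0] * 20), 60.0)
        lp = f.leads["II"]
        assert lp.pwd_ms == 120.0 and lp.pwdc_ms == 120.0
        assert lp.n_beats_used == 20

    def test_alternating_beats_average(self):
        f = pk.extract_features(self.beats_frame([118.0, 122.0] * 10), 60.0)
        assert f.leads["II"].pwd_ms == pytest.approx(120.0)

    def test_empty_input_is_hard_error(self):
        with pytest.raises(ValueError):
            pk.extract_features(pd.DataFrame(), 60.0)

    def test_full_recording_recovery_within_2ms(self, clean_delineation):
        _, beats, truth = clean_delineation
        feats = pk.extract_features(beats, truth.heart_rate_bpm)
        for lead, lp in feats.leads.items():
            assert lp.pwd_ms == pytest.approx(
                truth.true_value(lead, "pwd_ms"), abs=2.5)
        assert np.isfinite(feats.pwdisp_global_ms)
        assert feats.ptfv1_mms < 0  # biphasic V1 with negative terminal phase
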