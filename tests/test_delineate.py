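import warnings

import numpy as np
import pytest

import pwavekit as pk
from pwavekit.delineate import (DelineationConfig, detect_p_offset,
                                detect_p_onset, detect_p_peak,
                                detect_r_peaks, detect_t_end,
                                estimate_heart_rate)
from pwavekit.synth import PWaveSpec
from conftest import fiducial_errors

FS = 1000.0


def triangle_p(onset_ms=100, dur_ms=120, amp=0.2, total_ms=300):
    """Baseline-0 signal with one triangular P hump."""
    t = np.arange(total_ms)
    x = np.zeros(total_ms)
    inside = (t >= onset_ms) & (t <= onset_ms + dur_ms)
    u = (t[inside] - onset_ms) / dur_ms
    x[inside] = amp * (1 - np.abs(2 * u - 1))
    return x


def brute_force_chord_onset(x, anchor, peak, mm_per_mv=10.0, ms_per_mm=40.0):
    """Independent oracle: smallest signed perpendicular distance to the
    chord, evaluated sample by sample, ties to the earliest index."""
    ta, ya = anchor / ms_per_mm, x[anchor] * mm_per_mv
    tb, yb = peak / ms_per_mm, x[peak] * mm_per_mv
    best, best_d = None, np.inf
    sgn = 1.0 if x[peak] >= 0 else -1.0
    for i in range(anchor + 1, peak):
        ti, yi = i / ms_per_mm, x[i] * mm_per_mv
        cross = (tb - ta) * (yi - ya) - (yb - ya) * (ti - ta)
        d = sgn * cross / np.hypot(tb - ta, yb - ya)
        if d < best_d - 1e-12:
            best_d, best = d, i
    return best


class TestRPeaks:
    def test_count_matches_ground_truth(self, clean_recording):
        rec, truth = clean_recording
        peaks = detect_r_peaks(rec.lead("II"), rec.fs)
        assert abs(len(peaks) - truth.n_beats) <= 1

    def test_positions_within_two_samples_of_truth(self, clean_recording):
        rec, truth = clean_recording
        peaks = detect_r_peaks(rec.lead("II"), rec.fs)
        tk = truth.annotations.by_key()
        true_peaks = sorted(s for (ld, b, k), s in tk.items()
                            if ld == "II" and k == "R_PEAK")
        for p in peaks:
            assert min(abs(p - t) for t in true_peaks) <= 2

    def test_flat_signal_yields_empty_with_warning(self):
        with pytest.warns(UserWarning, match="QRS"):
            peaks = detect_r_peaks(np.zeros(4000), FS)
        assert len(peaks) == 0

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            detect_r_peaks(np.zeros(500), FS)


class TestHeartRate:
    def test_uniform_rr(self):
        peaks = np.arange(0, 10000, 1000)
        assert estimate_heart_rate(peaks, FS) == pytest.approx(60.0)

    def test_median_robust_to_missed_beat(self):
        # RR = 750, 750, 1500 ms: median 750 -> 80 bpm
        peaks = np.array([0, 750, 1500, 3000])
        assert estimate_heart_rate(peaks, FS) == pytest.approx(80.0)

    def test_needs_two_peaks(self):
        with pytest.raises(ValueError):
            estimate_heart_rate(np.array([5]), FS)

    def test_jittered_recording_recovered_within_2bpm(self):
        spec = pk.default_spec(duration_s=30.0, heart_rate_bpm=75.0,
                               rr_jitter_ms=30.0, seed=4)
        rec, truth = pk.generate_recording(spec)
        peaks = detect_r_peaks(rec.lead("II"), rec.fs)
        assert estimate_heart_rate(peaks, rec.fs) == pytest.approx(
            truth.heart_rate_bpm, abs=2.0)


class TestTEnd:
    def test_tangent_within_5ms_of_support_end(self, clean_recording):
        rec, truth = clean_recording
        tk = truth.annotations.by_key()
        x = rec.lead("II")
        peaks = detect_r_peaks(x, rec.fs)
        errs = []
        for k in range(1, 6):
            te = detect_t_end(x, int(peaks[k]), rec.fs,
                              next_r=int(peaks[k + 1]))
            errs.append(te - tk[("II", k, "T_END")])
        assert np.abs(errs).mean() <= 5.0

    def test_flat_post_qrs_returns_none(self):
        x = np.zeros(3000)
        x[1000] = 1.0  # isolated spike, no T wave
        assert detect_t_end(x, 1000, FS) is None


class TestPPeak:
    def test_unique_triangular_apex_found_exactly(self):
        x = triangle_p()
        assert detect_p_peak(x, (0, 300), 0.0, fs=FS) == 160

    def test_narrow_noise_spike_ignored(self):
        x = triangle_p()
        x[140:145] += 0.3  # 5 ms spike taller than the P apex
        peak = detect_p_peak(x, (50, 280), 0.0, fs=FS)
        assert abs(peak - 160) <= 3

    def test_biphasic_larger_negative_phase_wins(self):
        t = np.arange(300, dtype=float)
        x = np.zeros(300)
        x[100:160] = 0.10 * np.sin(np.pi * (t[100:160] - 100) / 60)
        x[160:210] = -0.15 * np.sin(np.pi * (t[160:210] - 160) / 50)
        peak = detect_p_peak(x, (50, 260), 0.0, fs=FS)
        assert x[peak] == pytest.approx(-0.15, abs=0.01)

    def test_no_qualifying_candidate_returns_none(self):
        x = np.zeros(300)
        x[150:153] = 0.2  # 3 ms blip, below the 15 ms width rule
        assert detect_p_peak(x, (0, 300), 0.0, fs=FS) is None


class TestOnsetChord:
    def test_matches_brute_force_on_piecewise_linear_corner(self):
        # baseline to 100 ms, then linear rise to the apex at 160 ms
        t = np.arange(300, dtype=float)
        x = np.where(t <= 100, 0.0,
                     np.where(t <= 160, 0.2 * (t - 100) / 60, 0.0))
        oracle = brute_force_chord_onset(x, 0, 160)
        assert oracle == 100
        assert detect_p_onset(x, 0, 160, fs=FS) == oracle

    def test_straight_line_degenerates_to_earliest_interior_index(self):
        x = np.linspace(0.0, 0.2, 300)
        assert detect_p_onset(x, 0, 160, fs=FS) == 1

    def test_negative_p_mirrored_sign_convention(self):
        t = np.arange(300, dtype=float)
        x = np.where(t <= 100, 0.0,
                     np.where(t <= 160, -0.2 * (t - 100) / 60, 0.0))
        assert detect_p_onset(x, 0, 160, fs=FS, baseline=0.0) == 100

    def test_window_too_short_returns_none(self):
        assert detect_p_onset(np.zeros(10), 4, 6, fs=FS) is None


class TestOffset:
    def test_symmetric_triangle_offset_mirrors_onset(self):
        x = triangle_p()
        onset = detect_p_onset(x, 0, 160, fs=FS)
        offset = detect_p_offset(x, 160, 280, fs=FS)
        assert abs((offset - 160) - (160 - onset)) <= 1
        assert offset == pytest.approx(220, abs=1)

    def test_threshold_return_agrees_within_4ms(self):
        x = triangle_p()
        cfg = DelineationConfig(offset_method="threshold_return")
        alt = detect_p_offset(x, 160, 280, cfg, fs=FS)
        ref = detect_p_offset(x, 160, 280, fs=FS)
        assert abs(alt - ref) <= 4


class TestRecordingDelineation:
    def test_twenty_beats_averaged_per_lead(self):
        spec = pk.default_spec(duration_s=60.0, heart_rate_bpm=60.0, seed=2)
        rec, _ = pk.generate_recording(spec)
        ann, beats = pk.delineate_recording(rec)
        counts = beats.groupby("lead")["beat"].count()
        assert (counts == 20).all()

    def test_shortfall_uses_available_beats_with_warning(self, clean_recording):
        rec, truth = clean_recording  # 12 s -> ~10 usable beats
        with pytest.warns(UserWarning, match="clean beats"):
            _, beats = pk.delineate_recording(rec)
        assert 0 < beats.groupby("lead")["beat"].count().max() < 20

    def test_fiducial_ordering_invariant(self, clean_delineation):
        ann, beats, _ = clean_delineation
        keys = ann.by_key()
        for (lead, beat, kind) in list(keys):
            if kind == "P_ONSET":
                on = keys[(lead, beat, "P_ONSET")]
                peak = keys[(lead, beat, "P_PEAK")]
                off = keys[(lead, beat, "P_OFFSET")]
                te = keys[(lead, beat, "T_END")]
                assert te <= on < peak < off

    def test_clean_recovery_within_2ms(self, clean_delineation):
        ann, _, truth = clean_delineation
        for kind in ("P_ONSET", "P_OFFSET"):
            errs = fiducial_errors(ann, truth, kind)
            assert len(errs) > 50
            assert np.abs(errs).mean() <= 2.0

    def test_gaussian_p_onset_within_2ms(self):
        # smooth truncated-Gaussian onset; single-pass chord rule with a
        # realistic T-end-to-peak window (long, shallow chord)
        pw = PWaveSpec("gaussian", 120, 0.2)
        t = np.arange(700, dtype=float)
        x = pw.evaluate((t - 500) / 120.0)
        onset = detect_p_onset(x, 0, 560, fs=FS)
        assert abs(onset - 500) <= 2

    def test_translation_equivariance(self, clean_recording):
        rec, _ = clean_recording
        k = 37
        shifted = np.concatenate([np.zeros((rec.n_leads, k)),
                                  rec.samples[:, :-k]], axis=1)
        rec2 = pk.EcgRecording(shifted, fs=rec.fs,
                               lead_names=rec.lead_names)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a1, _ = pk.delineate_recording(rec)
            a2, _ = pk.delineate_recording(rec2)
        k1, k2 = a1.by_key(), a2.by_key()
        common = set(k1) & set(k2)
        assert len(common) >= 0.8 * len(k1)
        assert all(k2[key] == k1[key] + k for key in common)

    def test_truth_overrides_returned_verbatim(self, clean_recording):
        rec, truth = clean_recording
        ov = pk.AnnotationSet([r.__class__(r.lead, r.beat, r.kind, r.sample,
                                           "override")
                               for r in truth.annotations.records
                               if r.kind != "R_PEAK"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ann, _ = pk.delineate_recording(rec, overrides=ov)
        tk = truth.annotations.by_key()
        for (lead, beat, kind), s in ann.by_key().items():
            if kind in ("P_ONSET", "P_OFFSET", "P_PEAK", "T_END"):
                assert s == tk[(lead, beat, kind)]

    def test_override_shifts_pwd_by_index_delta(self, clean_recording):
        rec, _ = clean_recording
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, base = pk.delineate_recording(rec)
        row = base[base["lead"] == "II"].iloc[0]
        delta = 8
        ov = pk.AnnotationSet()
        ov.add("II", int(row["beat"]), "P_ONSET",
               int(row["p_onset"]) - delta, "override")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, shifted = pk.delineate_recording(rec, overrides=ov)
        row2 = shifted[(shifted["lead"] == "II")
                       & (shifted["beat"] == row["beat"])].iloc[0]
        assert row2["pwd_ms"] - row["pwd_ms"] == pytest.approx(
            delta / rec.fs * 1000.0)
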