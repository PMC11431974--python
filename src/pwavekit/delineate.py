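"""Per-beat fiducial detection: R peaks, T end, P peak, P onset/offset.

The P wave peak is the largest |deviation| from the isoelectric line
among local extrema whose width at half-prominence is at least 15 ms.
P onset is located with the chord rule: over the window from the anchor
(T end by default) to the P peak, the onset is the sample with the
extremal *signed* perpendicular distance to the chord joining the two
window endpoints — i.e. the point of maximal excursion below the chord
for an upright P (the classic chord/trapezium boundary detector, and the
first point of rise above the isoelectric line for piecewise-linear
signals).  The literal unsigned-minimum variant is available via
``extremum_rule='unsigned_max'`` for comparison; it is degenerate
(samples lying on the chord minimise it).  P offset mirrors the rule on
the chord from the P apex to the QRS onset, ties broken to the latest
index.

Perpendicular distance needs an amplitude-versus-time scale; the default
is the standard clinical paper grid, 25 mm/s and 10 mm/mV (40 ms per mm
horizontally).  The arg-extremum of the *signed* distance is invariant
under this axis scaling; only the reported distances change.

The isoelectric line is the median amplitude over the 20 ms window
ending at the candidate onset, with one refinement iteration (first pass
uses the median of the whole T-end→QRS-onset window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .io import AnnotationSet, EcgRecording
from . import params as _params

__all__ = [
    "DelineationConfig", "BeatFiducials",
    "detect_r_peaks", "estimate_heart_rate", "detect_t_end",
    "detect_p_peak", "detect_p_onset", "detect_p_offset",
    "delineate_recording",
]


@dataclass(frozen=True)
class DelineationConfig:
    p_peak_min_width_ms: float = 15.0
    n_beats_average: int = 20
    r_refractory_ms: float = 200.0
    t_end_method: str = "tangent"           # tangent | window
    onset_chord_anchor: str = "t_end"       # t_end | t_peak
    extremum_rule: str = "signed_min"       # signed_min | unsigned_max
    offset_method: str = "mirrored_chord"   # mirrored_chord | threshold_return
    edge_exclusion_s: float = 0.5
    mm_per_mv: float = 10.0
    ms_per_mm: float = 40.0
    baseline_window_ms: float = 20.0
    min_signal_mv: float = 0.05             # flat-signal floor
    chord_refine_ms: float = 40.0           # local re-anchoring pass; 0 = off
    smooth_ms: float = 9.0                  # detection-copy smoothing; 0 = off

    def __post_init__(self) -> None:
        if not self.p_peak_min_width_ms > 0:
            raise ValueError("p_peak_min_width_ms must be positive")
        if self.n_beats_average < 1:
            raise ValueError("n_beats_average must be >= 1")


@dataclass
class BeatFiducials:
    lead: str
    beat: int
    r_peak: int
    t_end: int | None = None
    p_peak: int | None = None
    p_onset: int | None = None
    p_offset: int | None = None
    flags: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.flags and None not in (
            self.t_end, self.p_peak, self.p_onset, self.p_offset)


# ---------------------------------------------------------------------------
# beat-level detectors


def detect_r_peaks(x: np.ndarray, fs: float,
                   cfg: DelineationConfig | None = None) -> np.ndarray:
    """R peak indices (strictly increasing, refractory-spaced).

    Threshold-based: peaks of |x − median| above half the global maximum
    deviation.  Returns an empty array (with a warning) on flat signals.
    """
    cfg = cfg or DelineationConfig()
    x = np.asarray(x, dtype=float)
    if len(x) < 2 * fs:
        raise ValueError("signal shorter than 2 s")
    dev = np.abs(x - np.median(x))
    top = dev.max()
    if top < cfg.min_signal_mv:
        warnings.warn("no QRS-sized deflections found; empty R peak set")
        return np.array([], dtype=int)
    dist = max(1, int(round(cfg.r_refractory_ms / 1000.0 * fs)))
    peaks, _ = _sig.find_peaks(dev, height=0.5 * top, distance=dist)
    return peaks.astype(int)


def estimate_heart_rate(r_peaks: np.ndarray, fs: float) -> float:
    """60000 / median RR in ms — robust to isolated missed beats."""
    r_peaks = np.asarray(r_peaks)
    if len(r_peaks) < 2:
        raise ValueError("need at least two R peaks to estimate heart rate")
    rr_ms = np.diff(r_peaks) / fs * 1000.0
    return 60000.0 / float(np.median(rr_ms))


def _t_search_window(r_peak: int, next_r: int, fs: float) -> tuple[int, int]:
    lo = r_peak + int(round(0.08 * fs))
    hi = min(r_peak + int(round(0.45 * fs)),
             r_peak + int(round(0.55 * (next_r - r_peak))))
    return lo, hi


def detect_t_end(x: np.ndarray, r_peak: int, fs: float,
                 cfg: DelineationConfig | None = None,
                 next_r: int | None = None,
                 baseline: float = 0.0) -> int | None:
    """T wave end after ``r_peak``; None when no T is detectable.

    ``tangent``: steepest point on the descending limb, extrapolated to
    the baseline crossing.  ``window``: first sample after the T apex
    where |deviation| falls below 5 % of the apex deviation.
    """
    cfg = cfg or DelineationConfig()
    x = np.asarray(x, dtype=float)
    if next_r is None:
        next_r = min(len(x) - 1, r_peak + int(round(1.2 * fs)))
    lo, hi = _t_search_window(r_peak, next_r, fs)
    if hi - lo < 3 or hi >= len(x):
        return None
    seg = x[lo:hi] - baseline
    apex = lo + int(np.argmax(np.abs(seg)))
    apex_dev = x[apex] - baseline
    if abs(apex_dev) < cfg.min_signal_mv:
        return None  # flat post-QRS segment

    # confine the limb to apex → first return below 10 % of apex deviation
    sgn = 1.0 if apex_dev >= 0 else -1.0
    limb_end = hi
    for i in range(apex, hi):
        if sgn * (x[i] - baseline) < 0.1 * abs(apex_dev):
            limb_end = i + 1
            break
    if limb_end - apex < 3:
        return None

    if cfg.t_end_method == "window":
        for i in range(apex, hi):
            if sgn * (x[i] - baseline) < 0.05 * abs(apex_dev):
                return i
        return None

    limb = x[apex:limb_end]
    slope = np.gradient(limb)
    j = int(np.argmax(np.abs(slope)))
    tangent_idx = apex + j
    s = slope[j]
    if sgn * s >= 0:  # not actually descending
        return None
    # extrapolate the tangent to the baseline crossing
    t_end = tangent_idx + (baseline - x[tangent_idx]) / s
    t_end = int(round(t_end))
    return int(np.clip(t_end, apex + 1, next_r - 1))


def _p_candidates(seg: np.ndarray, fs: float, cfg: DelineationConfig) -> np.ndarray:
    """Local extrema (both polarities) of a baseline-subtracted segment
    whose width at half-prominence is >= the configured minimum."""
    w = cfg.p_peak_min_width_ms / 1000.0 * fs
    cand = []
    for sign in (1.0, -1.0):
        peaks, _ = _sig.find_peaks(sign * seg, width=w, rel_height=0.5,
                                   prominence=1e-6)
        cand.extend(peaks.tolist())
    return np.array(sorted(set(cand)), dtype=int)


def detect_p_peak(x: np.ndarray, window: tuple[int, int], baseline: float,
                  cfg: DelineationConfig | None = None, fs: float = 1000.0,
                  return_candidates: bool = False):
    """P apex inside ``window``: the extremum of |signal − baseline| among
    candidate peaks at least 15 ms wide at half-prominence.  None when no
    candidate qualifies (beat flagged by the caller)."""
    cfg = cfg or DelineationConfig()
    i0, i1 = window
    if i1 - i0 < 3:
        return (None, np.array([], int)) if return_candidates else None
    seg = np.asarray(x[i0:i1], dtype=float) - baseline
    cand = _p_candidates(seg, fs, cfg)
    if cand.size == 0:
        return (None, cand) if return_candidates else None
    best = cand[int(np.argmax(np.abs(seg[cand])))]
    # drop residual-baseline wiggles: genuine P phases are within a
    # factor ~3 of the apex, above the morphology amplitude floor, and
    # adjacent to the apex (inside one plausible P-complex span)
    floor = max(0.3 * np.abs(seg[best]), 0.02)
    span = int(round(0.18 * fs))
    cand = cand[(np.abs(seg[cand]) >= floor)
                & (np.abs(cand - best) <= span)]
    peak = i0 + int(best)
    if return_candidates:
        return peak, i0 + cand
    return peak


def _signed_chord_distance(x: np.ndarray, i_a: int, i_b: int,
                           fs: float, cfg: DelineationConfig) -> np.ndarray:
    """Signed perpendicular distance (in paper-grid mm) of the samples in
    the open interval (i_a, i_b) to the chord from i_a to i_b."""
    idx = np.arange(i_a + 1, i_b)
    t_mm = idx * 1000.0 / fs / cfg.ms_per_mm
    y_mm = x[idx] * cfg.mm_per_mv
    t_a, y_a = i_a * 1000.0 / fs / cfg.ms_per_mm, x[i_a] * cfg.mm_per_mv
    t_b, y_b = i_b * 1000.0 / fs / cfg.ms_per_mm, x[i_b] * cfg.mm_per_mv
    dt, dy = t_b - t_a, y_b - y_a
    norm = np.hypot(dt, dy)
    if norm == 0:
        return np.zeros(len(idx))
    # positive = above the chord (left of the a→b direction)
    return (dt * (y_mm - y_a) - dy * (t_mm - t_a)) / norm


def detect_p_onset(x: np.ndarray, anchor_idx: int, p_peak_idx: int,
                   cfg: DelineationConfig | None = None, fs: float = 1000.0,
                   baseline: float = 0.0) -> int | None:
    """P onset by the chord rule over (anchor, peak); ties to the earliest
    index.  None when the window is shorter than 3 samples."""
    cfg = cfg or DelineationConfig()
    if p_peak_idx - anchor_idx < 3:
        return None
    x = np.asarray(x, dtype=float)
    sgn = 1.0 if x[p_peak_idx] - baseline >= 0 else -1.0
    s = _signed_chord_distance(x, anchor_idx, p_peak_idx, fs, cfg)
    vals = sgn * s if cfg.extremum_rule == "signed_min" else np.abs(s)
    # earliest index within a hair of the minimum (robust tie-break)
    j = int(np.flatnonzero(vals <= vals.min() + 1e-9)[0])
    return anchor_idx + 1 + j


def detect_p_offset(x: np.ndarray, p_peak_idx: int, qrs_onset_idx: int,
                    cfg: DelineationConfig | None = None, fs: float = 1000.0,
                    baseline: float = 0.0) -> int | None:
    """P offset: mirrored chord rule over (peak, QRS onset), ties to the
    latest index; or the threshold-return variant (first sample after the
    apex back within 5 % of the apex deviation)."""
    cfg = cfg or DelineationConfig()
    if qrs_onset_idx - p_peak_idx < 3:
        return None
    x = np.asarray(x, dtype=float)
    sgn = 1.0 if x[p_peak_idx] - baseline >= 0 else -1.0
    if cfg.offset_method == "threshold_return":
        apex_dev = abs(x[p_peak_idx] - baseline)
        for i in range(p_peak_idx + 1, qrs_onset_idx):
            if sgn * (x[i] - baseline) < 0.05 * apex_dev:
                return i
        return None
    s = _signed_chord_distance(x, p_peak_idx, qrs_onset_idx, fs, cfg)
    vals = sgn * s
    # latest index within a hair of the minimum (robust tie-break)
    j = int(np.flatnonzero(vals <= vals.min() + 1e-9)[-1])
    return p_peak_idx + 1 + j


def _refine_onset(x, anchor, peak, onset, cfg, fs, baseline):
    """Iterated local re-anchoring of the onset chord.  A chord spanning
    the whole quiet T-end→peak window is shallow, so its arg-minimum is
    dragged by noise extremes; re-running the rule from just outside the
    current estimate steepens the chord and pins the corner.  Exact on
    noise-free corners; on very smooth (Gaussian-tailed) onsets it moves
    the estimate into the tail, so it is configurable off."""
    if onset is None or cfg.chord_refine_ms <= 0:
        return onset
    margin = int(round(cfg.chord_refine_ms / 1000.0 * fs))
    for _ in range(5):
        a = max(anchor, onset - margin)
        if peak - a < 3:
            break
        new = detect_p_onset(x, a, peak, cfg, fs, baseline=baseline)
        if new is None or new == onset:
            break
        onset = new
    return onset


def _refine_offset(x, peak, qrs_onset, offset, cfg, fs, baseline):
    if offset is None or cfg.chord_refine_ms <= 0:
        return offset
    margin = int(round(cfg.chord_refine_ms / 1000.0 * fs))
    for _ in range(5):
        b = min(qrs_onset, offset + margin)
        if b - peak < 3:
            break
        new = detect_p_offset(x, peak, b, cfg, fs, baseline=baseline)
        if new is None or new == offset:
            break
        offset = new
    return offset


def _qrs_onset(x: np.ndarray, r_peak: int, fs: float, baseline: float) -> int:
    """QRS onset: end of the last sustained (≥8 ms) quiet run before the
    R peak, where quiet means |deviation| below 5 % of the R deviation.
    The sustained-run requirement skips the brief zero crossings between
    the Q and R deflections."""
    amp = abs(x[r_peak] - baseline)
    lo = max(0, r_peak - int(round(0.12 * fs)))
    thr = 0.05 * amp
    quiet = np.abs(x[lo:r_peak] - baseline) < thr
    min_run = max(1, int(round(0.008 * fs)))
    run_end, run_len, best_end = None, 0, None
    for i, q in enumerate(quiet):
        if q:
            run_len += 1
            run_end = i
            if run_len >= min_run:
                best_end = run_end
        else:
            run_len = 0
    if best_end is not None:
        return lo + int(best_end)
    return max(0, r_peak - int(round(0.06 * fs)))


# ---------------------------------------------------------------------------
# whole-recording delineation


def _beat_fiducials(x: np.ndarray, lead: str, k: int, r_k: int, r_next: int,
                    fs: float, cfg: DelineationConfig,
                    overrides: dict) -> BeatFiducials:
    def ov(kind):
        return overrides.get((lead, k, kind))

    flags: list[str] = []
    baseline = float(np.median(x[r_k:r_next]))

    t_end = ov("T_END")
    if t_end is None:
        t_end = detect_t_end(x, r_k, fs, cfg, next_r=r_next, baseline=baseline)
    if t_end is None:
        return BeatFiducials(lead, k, r_k, flags=("no_t_end",))

    q_on = _qrs_onset(x, r_next, fs, baseline)
    if q_on - t_end < 5:
        return BeatFiducials(lead, k, r_k, t_end=t_end, flags=("short_window",))

    def locate(base):
        p_peak = ov("P_PEAK")
        cand = None
        if p_peak is None:
            p_peak, cand = detect_p_peak(x, (t_end + 1, q_on), base, cfg, fs,
                                         return_candidates=True)
        if p_peak is None:
            return None, None, None, None
        if cand is None or cand.size == 0:
            cand = np.array([p_peak])
        onset_apex = int(cand[0])    # earliest qualifying apex
        offset_apex = int(cand[-1])  # terminal qualifying apex
        anchor = t_end
        if cfg.onset_chord_anchor == "t_peak":
            lo, hi = _t_search_window(r_k, r_next, fs)
            hi = min(hi, t_end + 1)
            if hi - lo > 1:
                anchor = lo + int(np.argmax(np.abs(x[lo:hi] - base)))
        p_on = ov("P_ONSET")
        if p_on is None:
            p_on = detect_p_onset(x, anchor, onset_apex, cfg, fs,
                                  baseline=base)
            p_on = _refine_onset(x, anchor, onset_apex, p_on, cfg, fs, base)
        p_off = ov("P_OFFSET")
        if p_off is None:
            p_off = detect_p_offset(x, offset_apex, q_on, cfg, fs,
                                    baseline=base)
            p_off = _refine_offset(x, offset_apex, q_on, p_off, cfg, fs,
                                   base)
        return p_peak, p_on, p_off, base

    p_peak, p_on, p_off, _ = locate(baseline)
    if p_on is not None:
        # one refinement iteration of the isoelectric line
        w = int(round(cfg.baseline_window_ms / 1000.0 * fs))
        lo = max(0, p_on - w)
        if p_on > lo:
            refined = float(np.median(x[lo:p_on]))
            p_peak, p_on, p_off, _ = locate(refined)
            baseline = refined

    if p_peak is None:
        flags.append("no_p_peak")
    elif p_on is None or p_off is None:
        flags.append("short_window")
    elif not (t_end <= p_on < p_peak < p_off < r_next):
        flags.append("ordering")
    fid = BeatFiducials(lead, k, r_k, t_end=t_end, p_peak=p_peak,
                        p_onset=p_on, p_offset=p_off, flags=tuple(flags))
    return fid


def delineate_recording(rec: EcgRecording,
                        cfg: DelineationConfig | None = None,
                        overrides: AnnotationSet | None = None
                        ) -> tuple[AnnotationSet, pd.DataFrame]:
    """Delineate every lead of a preprocessed recording.

    Returns the detected fiducials (override records passed through with
    their provenance) and a per-beat measurement table with columns
    ``lead, beat, p_onset, p_peak, p_offset, pwd_ms, pwv_mv, pwa_msmv,
    morphology, ptf_mms`` for the first ``n_beats_average`` clean beats
    per lead.  A shortfall is reported with a warning, not an error.
    """
    cfg = cfg or DelineationConfig()
    ov_map = overrides.by_key() if overrides is not None else {}
    ov_keys = set(ov_map)

    ann = AnnotationSet()
    rows = []
    edge = int(round(cfg.edge_exclusion_s * rec.fs))
    for lead in rec.lead_names:
        x = rec.lead(lead)
        xd = x
        if cfg.smooth_ms > 0:
            # fiducials are located on a lightly smoothed copy (zero-phase
            # moving average) so single-sample noise extremes cannot drag
            # the chord arg-minimum; amplitudes are measured on the
            # unsmoothed signal.  The smoothing is engaged only when it
            # actually removes something — on an already-smooth trace the
            # median |x − smoothed(x)| is at quantisation level and the
            # raw signal is used, avoiding corner-rounding bias.
            from scipy.ndimage import uniform_filter1d
            w = max(1, int(round(cfg.smooth_ms / 1000.0 * rec.fs)) | 1)
            xs = uniform_filter1d(x, size=w, mode="nearest")
            if np.median(np.abs(x - xs)) > 5e-4:
                xd = xs
        r_peaks = detect_r_peaks(xd, rec.fs, cfg)
        measured = 0
        for k in range(len(r_peaks) - 1):
            r_k, r_next = int(r_peaks[k]), int(r_peaks[k + 1])
            if r_k < edge or r_next > rec.n_samples - edge:
                continue
            if measured >= cfg.n_beats_average:
                break
            fid = _beat_fiducials(xd, lead, k, r_k, r_next, rec.fs, cfg,
                                  ov_map)
            ann.add(lead, k, "R_PEAK", r_k)
            if fid.t_end is not None:
                prov = ("override" if (lead, k, "T_END") in ov_keys
                        else "detected")
                ann.add(lead, k, "T_END", fid.t_end, prov)
            if not fid.ok:
                continue
            for kind, val in (("P_ONSET", fid.p_onset),
                              ("P_PEAK", fid.p_peak),
                              ("P_OFFSET", fid.p_offset)):
                prov = ("override" if (lead, k, kind) in ov_keys
                        else "detected")
                ann.add(lead, k, kind, val, prov)

            w = int(round(cfg.baseline_window_ms / 1000.0 * rec.fs))
            base = float(np.median(x[max(0, fid.p_onset - w):fid.p_onset])
                         ) if fid.p_onset > 0 else 0.0
            seg = x[fid.p_onset:fid.p_offset + 1]
            pwd = _params.compute_pwd(fid.p_onset, fid.p_offset, rec.fs)
            pwv = _params.compute_pwv(seg, base)
            pwa = _params.compute_pwa(seg, base, fs=rec.fs)
            morph = _params.classify_morphology(seg, base, rec.fs)
            ptf = _params.compute_ptfv1(seg, base, rec.fs)
            rows.append({"lead": lead, "beat": k,
                         "p_onset": fid.p_onset, "p_peak": fid.p_peak,
                         "p_offset": fid.p_offset, "pwd_ms": pwd,
                         "pwv_mv": pwv, "pwa_msmv": pwa,
                         "morphology": morph, "ptf_mms": ptf})
            measured += 1
        if measured < cfg.n_beats_average:
            warnings.warn(
                f"lead {lead}: only {measured} clean beats available "
                f"(wanted {cfg.n_beats_average})"
            )
    beats = pd.DataFrame(rows, columns=["lead", "beat", "p_onset", "p_peak",
                                        "p_offset", "pwd_ms", "pwv_mv",
                                        "pwa_msmv", "morphology", "ptf_mms"])
    return ann, beats
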