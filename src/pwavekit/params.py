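"""The six P wave parameters and inter-atrial block classification.

Definitions (all relative to the isoelectric line):

PWD
    onset→offset interval in ms;
PWDc
    PWD corrected for heart rate with the Hodges adjustment,
    ``PWD + 1.75 × (HR − 60)``;
PWV
    maximal vertical excursion of the P wave in mV, signed by the
    dominant phase;
PWA
    P wave area in ms·mV — trapezoidal integration of |deviation| as the
    primary estimate, with the triangle approximation 0.5·PWD·|PWV| also
    reported;
PWDisp
    max − min of a set of P wave durations (across-lead or within-lead
    beat-to-beat);
PTFV1
    terminal force in V1 — |terminal-phase extremum| × 10 mm/mV ×
    terminal-phase duration in s, stored signed (negative terminal phase
    ⇒ negative value, the convention under which values beyond 0.03 mm·s
    in magnitude are called abnormal);
IAB
    uncorrected PWD ≥ 120 ms with a biphasic P in at least one of the
    inferior leads (II, III, aVF) by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LeadParameters", "PatientFeatures",
    "compute_pwd", "correct_pwd_hodges", "compute_pwv", "compute_pwa",
    "compute_pwdisp", "classify_morphology", "compute_ptfv1",
    "classify_iab", "extract_features", "MORPHOLOGY_LABELS",
]

MORPHOLOGY_LABELS = ("mono_pos", "mono_neg", "biphasic_pm", "biphasic_mp",
                     "flat")

#: Clinical paper-grid scale used for PTFV1 (10 mm per mV).
MM_PER_MV = 10.0


def compute_pwd(p_onset: int, p_offset: int, fs: float) -> float:
    """P wave duration in ms from fiducial sample indices."""
    if p_offset <= p_onset:
        raise ValueError(
            f"P offset ({p_offset}) must come after onset ({p_onset})")
    return (p_offset - p_onset) / fs * 1000.0


def correct_pwd_hodges(pwd_ms: float, heart_rate_bpm: float) -> float:
    """Hodges rate correction: identity at 60 bpm, +1.75 ms per bpm."""
    if heart_rate_bpm <= 0:
        raise ValueError("heart rate must be positive")
    return pwd_ms + 1.75 * (heart_rate_bpm - 60.0)


def compute_pwv(segment: np.ndarray, baseline: float = 0.0) -> float:
    """Signed maximal excursion from the isoelectric line over the
    onset→offset segment."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("empty P wave segment")
    dev = segment - baseline
    return float(dev[np.argmax(np.abs(dev))])


def compute_pwa(segment: np.ndarray | None = None, baseline: float = 0.0,
                pwd_ms: float | None = None, pwv_mv: float | None = None,
                method: str = "trapezoid", fs: float = 1000.0) -> float:
    """P wave area in ms·mV.

    ``trapezoid``: numeric integral of |deviation| over the segment;
    ``triangle``: 0.5 × PWD × |PWV|.
    """
    if method == "trapezoid":
        if segment is None:
            raise ValueError("trapezoid method needs the signal segment")
        segment = np.asarray(segment, dtype=float)
        if segment.size == 0:
            raise ValueError("empty P wave segment")
        return float(np.trapezoid(np.abs(segment - baseline),
                                  dx=1000.0 / fs))
    if method == "triangle":
        if pwd_ms is None or pwv_mv is None:
            raise ValueError("triangle method needs pwd_ms and pwv_mv")
        return 0.5 * pwd_ms * abs(pwv_mv)
    raise ValueError(f"unknown PWA method {method!r}")


def compute_pwdisp(durations, mode: str = "across_leads") -> float:
    """Dispersion = max − min of the supplied durations (ms).  The mode
    label records whether the inputs are per-lead means or within-lead
    beat values; the arithmetic is identical."""
    if mode not in ("across_leads", "within_lead_beats"):
        raise ValueError(f"unknown dispersion mode {mode!r}")
    vals = np.asarray(list(durations), dtype=float)
    if vals.size < 2:
        raise ValueError("dispersion needs at least two durations")
    return float(vals.max() - vals.min())


def _phases(segment: np.ndarray, baseline: float, fs: float,
            min_phase_ms: float, min_phase_mv: float):
    """Maximal same-sign runs lasting >= min_phase_ms whose extremum is
    >= min_phase_mv in magnitude.  Returns (sign, start, length_samples,
    extremum) tuples in temporal order."""
    dev = np.asarray(segment, dtype=float) - baseline
    sign = np.sign(dev)
    min_len = max(1, int(round(min_phase_ms / 1000.0 * fs)))
    phases = []
    i = 0
    n = len(dev)
    while i < n:
        s = sign[i]
        j = i
        while j < n and sign[j] == s:
            j += 1
        if s != 0:
            ext = dev[i + int(np.argmax(np.abs(dev[i:j])))]
            if (j - i) >= min_len and abs(ext) >= min_phase_mv:
                phases.append((int(s), i, j - i, float(ext)))
        i = j
    return phases


def classify_morphology(segment: np.ndarray, baseline: float = 0.0,
                        fs: float = 1000.0, min_phase_ms: float = 20.0,
                        min_phase_mv: float = 0.025) -> str:
    """Morphology label from qualifying phases (noise flicker shorter than
    ``min_phase_ms`` or smaller than ``min_phase_mv`` is ignored)."""
    ph = _phases(segment, baseline, fs, min_phase_ms, min_phase_mv)
    if not ph:
        return "flat"
    if len(ph) == 1:
        return "mono_pos" if ph[0][0] > 0 else "mono_neg"
    first, last = ph[0], ph[-1]
    if first[0] != last[0]:
        return "biphasic_pm" if first[0] > 0 else "biphasic_mp"
    # >2 same-sign qualifying phases: dominant polarity wins
    ext = max(ph, key=lambda p: abs(p[3]))
    return "mono_pos" if ext[0] > 0 else "mono_neg"


def compute_ptfv1(segment: np.ndarray, baseline: float = 0.0,
                  fs: float = 1000.0, min_phase_ms: float = 20.0,
                  min_phase_mv: float = 0.025) -> float:
    """P wave terminal force of a V1 segment in mm·s.

    The terminal phase is the final opposite-sign phase of a biphasic P;
    the value is (|terminal extremum| × 10 mm/mV) × (terminal duration
    in s), negative when the terminal phase is negative.  Monophasic
    (or flat) segments yield 0.
    """
    ph = _phases(segment, baseline, fs, min_phase_ms, min_phase_mv)
    if len(ph) < 2 or ph[0][0] == ph[-1][0]:
        return 0.0
    sign, _, length, ext = ph[-1]
    force = abs(ext) * MM_PER_MV * (length / fs)
    return -force if sign < 0 else force


@dataclass
class LeadParameters:
    """20-beat-averaged P wave parameters of one lead."""

    lead: str
    pwd_ms: float
    pwdc_ms: float
    pwv_mv: float
    pwa_msmv: float
    pwa_triangle_msmv: float
    within_lead_dispersion_ms: float
    morphology: str
    n_beats_used: int

    def __post_init__(self) -> None:
        if self.morphology not in MORPHOLOGY_LABELS:
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if self.morphology != "flat" and not self.pwd_ms > 0:
            raise ValueError("non-flat lead must have positive PWD")


@dataclass
class PatientFeatures:
    """One patient's P wave feature row: 12 lead parameter sets plus the
    global quantities."""

    patient_id: str
    heart_rate_bpm: float
    leads: dict[str, LeadParameters] = field(default_factory=dict)
    pwdisp_global_ms: float = np.nan
    ptfv1_mms: float = np.nan
    iab: bool = False

    def to_row(self) -> dict:
        row: dict = {"patient_id": self.patient_id,
                     "hr_bpm": self.heart_rate_bpm}
        for lead, lp in self.leads.items():
            key = lead.lower().replace(" ", "")
            row[f"{key}_pwd_ms"] = lp.pwd_ms
            row[f"{key}_pwdc_ms"] = lp.pwdc_ms
            row[f"{key}_pwv_mv"] = lp.pwv_mv
            row[f"{key}_pwa_msmv"] = lp.pwa_msmv
            row[f"{key}_disp_ms"] = lp.within_lead_dispersion_ms
        row["pwdisp_global_ms"] = self.pwdisp_global_ms
        row["ptfv1_mms"] = self.ptfv1_mms
        row["iab"] = int(self.iab)
        return row


def classify_iab(features: PatientFeatures, pwd_threshold_ms: float = 120.0,
                 leads: tuple[str, ...] = ("II", "III", "aVF"),
                 lead_rule: str = "any", use_corrected: bool = False) -> bool:
    """Inter-atrial block: maximal per-lead PWD at/above the threshold AND
    biphasic morphology in the configured inferior leads (``any`` of them
    by default, ``all`` for the stricter convention).  Uncorrected PWD by
    default."""
    missing = [ld for ld in leads if ld not in features.leads]
    if missing:
        raise ValueError(f"inferior lead(s) {missing} not measured")
    attr = "pwdc_ms" if use_corrected else "pwd_ms"
    max_pwd = max(getattr(lp, attr) for lp in features.leads.values())
    if max_pwd < pwd_threshold_ms:
        return False
    biphasic = [features.leads[ld].morphology.startswith("biphasic")
                for ld in leads]
    return all(biphasic) if lead_rule == "all" else any(biphasic)


def extract_features(beats: pd.DataFrame, heart_rate_bpm: float,
                     patient_id: str = "", pwa_method: str = "trapezoid",
                     iab_threshold_ms: float = 120.0,
                     iab_lead_rule: str = "any",
                     iab_use_corrected: bool = False) -> PatientFeatures:
    """Aggregate per-beat measurements into one patient feature row.

    Per-lead values are arithmetic means over the measured beats; PWDc
    applies the Hodges correction to the lead-mean PWD using the
    recording-level heart rate; the global dispersion is max − min over
    the per-lead mean PWDs; PTFV1 is the mean per-beat terminal force in
    V1; the lead morphology label is the modal per-beat label.
    """
    if beats.empty:
        raise ValueError("no measurable beats in any lead")
    lead_params: dict[str, LeadParameters] = {}
    for lead, grp in beats.groupby("lead", sort=False):
        pwd = float(grp["pwd_ms"].mean())
        pwv = float(grp["pwv_mv"].mean())
        pwa_tri = compute_pwa(pwd_ms=pwd, pwv_mv=pwv, method="triangle")
        pwa_trap = float(grp["pwa_msmv"].mean())
        disp = (compute_pwdisp(grp["pwd_ms"], mode="within_lead_beats")
                if len(grp) >= 2 else 0.0)
        morph = grp["morphology"].mode().iloc[0]
        lead_params[str(lead)] = LeadParameters(
            lead=str(lead), pwd_ms=pwd,
            pwdc_ms=correct_pwd_hodges(pwd, heart_rate_bpm),
            pwv_mv=pwv,
            pwa_msmv=pwa_trap if pwa_method == "trapezoid" else pwa_tri,
            pwa_triangle_msmv=pwa_tri,
            within_lead_dispersion_ms=disp,
            morphology=str(morph), n_beats_used=len(grp))

    feats = PatientFeatures(patient_id=patient_id,
                            heart_rate_bpm=heart_rate_bpm,
                            leads=lead_params)
    mean_pwds = [lp.pwd_ms for lp in lead_params.values()]
    if len(mean_pwds) >= 2:
        feats.pwdisp_global_ms = compute_pwdisp(mean_pwds,
                                                mode="across_leads")
    v1 = next((ld for ld in lead_params if ld.lower() == "v1"), None)
    if v1 is not None:
        feats.ptfv1_mms = float(beats.loc[beats["lead"] == v1,
                                          "ptf_mms"].mean())
    try:
        feats.iab = classify_iab(feats, pwd_threshold_ms=iab_threshold_ms,
                                 lead_rule=iab_lead_rule,
                                 use_corrected=iab_use_corrected)
    except ValueError:
        feats.iab = False
    return feats
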