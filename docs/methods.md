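# Methods

`pwavekit` implements a P wave analysis pipeline for 12-lead ECG of the
kind used to relate pre-ablation atrial electrical properties to the
outcome of pulmonary vein isolation (PVI) in paroxysmal atrial
fibrillation: signal preprocessing, per-beat P wave delineation,
parameter extraction, and a cohort statistics layer. Because no patient
data accompany such studies, the package ships a first-class synthetic
ECG generator with exact ground truth, and every downstream stage is
validated against it.

## Synthetic ECG generation

Each beat is an analytic template: a balanced Q/R/S triangle triplet
around the R time, a triangular T wave after an ST segment, and a P
wave whose support ends one PR segment before the next QRS onset. All
components have literal finite supports, so the true P onset and offset
are support endpoints by construction and the clean signal equals the
baseline (0 mV) elsewhere — delineation accuracy can be measured without
circularity.

Design notes:

* **Balanced QRS.** The Q/R/S amplitudes (−0.15, 1, −0.8 relative to
  the R height, widths 0.2/0.4/0.4 of the QRS duration) integrate to
  near-zero net area. Real QRS complexes largely cancel in area; a
  monophasic spike of realistic height would drag a baseline sag of
  ~0.1 mV through any 1 Hz high-pass filter, which no delineator (and no
  clinical reader) would tolerate.
* **P shapes.** `triangular` (corner onsets, the default),
  `gaussian` (truncated at ±3σ and renormalised so the declared
  duration is the literal support), and `biphasic` (two opposite-signed
  sine half-lobes; the terminal phase occupies a configurable fraction
  of the duration).
* **Defaults as study conditions.** Recordings default to one minute of
  12 leads at 1 kHz, quantised to 16 bits over ±5 mV. Per-lead P
  durations (116–136 ms) and amplitudes (0.15–0.26 mV, negative in aVR,
  biphasic +0.09/−0.06 mV in V1) were fixed once to bracket the
  success-arm lead means reported for pre-ablation PAF cohorts; the
  sinus rate defaults to 60 bpm with optional Gaussian RR jitter.
* **Noise.** Additive i.i.d. white Gaussian noise, a pure mains
  sinusoid, and sinusoidal baseline wander, with one RNG stream per
  recording and sub-streams per lead so reproducibility is independent
  of lead evaluation order.

What the generator does *not* emulate: ectopy, atrial-fibrillation
rhythm, respiration-modulated morphology, electrode artefacts, or
inter-beat P morphology variation. Passing recovery tests on this
substrate therefore demonstrates correctness of the measurement
pipeline, not clinical-grade robustness on pathological recordings.

The cohort simulator draws a binary covariate X ~ Bernoulli(p) and
exponential event times with rate λ₀·HRᵡ censored at 12 months, with λ₀
solved so the expected event count matches the requested
success/failure split (154/57 by default). The realised split therefore
matches the target in expectation, which is the construction under
which a proportional-hazards fit recovers the designed hazard ratio.
Continuous covariates are drawn per realised outcome group from
user-specified (mean, SD) pairs.

## Preprocessing

The analysis chain is a 1–50 Hz Bessel band-pass plus a mains notch
(50 Hz, Q = 10; 60 Hz selectable). `order` in `FilterConfig` is the
order of the band-pass transfer function itself, so the default 2 is a
first-order high-pass section at 1 Hz and a first-order low-pass at
50 Hz — the gentlest DC-blocking behaviour, chosen because higher-order
1 Hz high-passing produces oscillatory baseline recovery around each
QRS-T complex that contaminates the PQ segment. Filtering is zero-phase
(forward–backward) by default so group delay cannot bias fiducial
timing; single-pass application is available. The first and last 0.5 s
are excluded from beat selection to avoid settling transients. The
band-pass is applied once in the pipeline.

## Delineation

Per lead: R peaks by thresholded peak-picking on |deviation from the
median| with a 200 ms refractory constraint; heart rate as
60000 / median RR (ms), robust to isolated missed beats; T end by the
tangent method (steepest point of the descending limb extrapolated to
the baseline crossing; a threshold-return variant is available).

**P peak.** Within the T-end→QRS-onset window, candidate peaks of both
polarities must be at least 15 ms wide at half prominence; the P apex is
the candidate with the largest |deviation| from the isoelectric line.
Candidates below 30 % of the apex deviation, below 0.02 mV, or more
than 180 ms from the apex are treated as residual baseline wiggles, not
P phases.

**P onset — chord rule.** Over the window from the anchor (T end by
default; T peak selectable) to the P apex, the onset is the sample with
the extremal *signed* perpendicular distance to the chord joining the
window endpoints, i.e. the point of maximal excursion below the chord
for an upright P. A "minimum perpendicular distance" read as unsigned
is degenerate — any sample lying on the chord attains zero — so the
signed reading, which reproduces the classic chord/trapezium boundary
detector and equals the first point of rise above the isoelectric line
on piecewise-linear signals, is the default; the literal unsigned
variant remains available (`extremum_rule="unsigned_max"`). Distances
are computed on the standard clinical paper grid (25 mm/s, 10 mm/mV);
the arg-extremum of the signed distance is invariant under this axis
scaling, so the grid only fixes the reported distance values. Ties go
to the earliest sample (latest for the offset).

**P offset** mirrors the rule on the chord from the P apex to the QRS
onset (end of the last sustained quiet run before the R peak). For
biphasic P waves the onset chord is anchored at the *first*-phase apex
and the offset chord at the *terminal*-phase apex, with the excursion
sign taken from that apex: a chord drawn from a positive apex across
the negative terminal lobe would otherwise select the negative trough
rather than the support end. For monophasic P waves all apex choices
coincide. A threshold-return offset variant (first return within 5 % of
the apex deviation) is provided for cross-checking.

**Robustness at the recording level.** Two measures, both active only
in `delineate_recording` (the primitive detectors implement the pure
single-pass rules):

1. *Conditional smoothing.* Fiducials are located on a zero-phase 9 ms
   moving-average copy, engaged only when the median |x − smoothed(x)|
   exceeds 0.5 µV (i.e. when there is actual noise to remove);
   amplitudes are always measured on the unsmoothed signal.
2. *Iterated chord re-anchoring.* The T-end→apex chord spans a long
   quiet baseline and is therefore shallow; its arg-minimum is an
   extreme-value statistic that noise drags tens of ms early. After the
   global pass, the chord is re-run from 40 ms outside the current
   estimate until a fixed point (≤5 iterations). This is exact on
   noise-free corners; on very smooth (Gaussian-tailed) onsets it moves
   the estimate into the tail by ~10 ms, so it can be disabled
   (`chord_refine_ms=0`). The same applies to the Gaussian offset,
   whose ±3σ tail makes any chord-based offset land inside the support;
   this is a property of the method, and the triangular default P
   shapes carry well-defined corners.

The isoelectric line is the median over the 20 ms window ending at the
candidate onset, with one refinement iteration (the first pass uses the
median of the whole search window). Measurements are per-beat; the
first 20 clean beats per lead enter the lead average (a shortfall
proceeds with the available beats and a warning). Manual corrections
are file-based override annotations that replace detected fiducials
with the same (lead, beat, kind) key before measurement.

Measured recovery on the generator defaults (12 s recordings, fs 1 kHz,
per-lead morphology and rate varied across seeds): noise-free mean
|onset| and |offset| errors ≈ 0.1 ms; at white-noise SD 0.02 mV through
the filter chain ≈ 6 ms and 4 ms.

## P wave parameters

With onset/offset indices and the isoelectric baseline:

* PWD = (offset − onset)/fs in ms; PWDc = PWD + 1.75·(HR − 60)
  (Hodges-type rate adjustment; identity at 60 bpm), applied to the
  lead-mean PWD using the recording-level median-RR heart rate.
* PWV = signed maximal |deviation| over the P segment (mV).
* PWA: trapezoidal integral of |deviation| (primary) and the triangle
  approximation 0.5·PWD·|PWV| (secondary); both are reported.
* PWDisp = max − min of a duration set, in both across-lead (global,
  from lead means) and within-lead (beat-to-beat) modes.
* Morphology: maximal same-sign runs lasting ≥20 ms with extremum
  ≥0.025 mV; one qualifying phase → mono_pos/mono_neg, two
  opposite-signed phases → biphasic_pm/biphasic_mp, none → flat.
* PTFV1: |terminal-phase extremum|·10 mm/mV × terminal-phase duration
  (s) for a biphasic V1 P, stored signed (negative terminal phase ⇒
  negative value; |PTFV1| > 0.03 mm·s is the conventional abnormality
  threshold); monophasic V1 → 0.
* IAB: maximal per-lead PWD ≥ 120 ms (uncorrected by default;
  switchable to PWDc) AND biphasic morphology in ≥1 of leads II, III,
  aVF (`any`; the stricter `all` convention is selectable).

## Cohort statistics

Continuous summaries are mean ± SEM (SD with n−1 denominator). The
two-sample test is Welch's t when both groups pass Shapiro–Wilk at
α = 0.05, otherwise Mann–Whitney U with the normal approximation and
tie correction; Welch rather than pooled-variance t because the two
outcome arms are markedly unequal in size. 2×2 tables use Fisher's
exact test when any expected cell is < 5, else Pearson's χ² without
continuity correction. Hazard ratios come from a single-covariate Cox
proportional-hazards model written against the Breslow partial
likelihood and fitted by Newton–Raphson (score/information in closed
form, Wald 95 % CI); monotone likelihoods (complete separation in the
risk sets) are flagged and reported without a CI. Continuous covariates
are z-standardised before the Cox fit so hazard ratios are per SD —
per-millisecond hazard ratios for duration-scale variables would be
indistinguishable from 1 — and the output marks the scale. Two-sided
p < 0.05 is flagged significant with no multiplicity adjustment across
rows; a Benjamini–Hochberg column is emitted additionally for
transparency.

Intraobserver variability for paired repeat measurements reports
mean |d|, SEM of |d|, and 100·mean |d| / mean of the pairwise means;
the paired-mean denominator is a documented choice since percentage
bases vary across the literature.

## Determinism and problem sizes

All stochastic procedures take explicit seeds; identical config + seed
reproduce byte-identical feature and report files (fixed float
formatting in CSV output). The validation suites use 12-s recordings
(≈10 beats/lead) for delineation recovery, 2000 replicates for null
calibration of the two-sample tests, and 200 simulated cohorts
(n = 154/57, true HR 2) for hazard-ratio recovery;
`scripts/acceptance.py` re-runs the same computations at somewhat
smaller replicate counts (12 recordings per noise condition, 100
cohorts, 600 null replicates).

## Known limitations

* The delineator assumes sinus rhythm with one P per RR interval; no
  AF-episode handling, no multi-lead fusion.
* Chord-based offsets are biased ~10–15 ms early on asymptotically
  smooth (Gaussian-tailed) P ends; onset/offset accuracy claims hold
  for waveforms with corner-type support endpoints.
* PWV/PWA are measured after the band-pass, which attenuates ~100 ms
  humps by roughly a third; truth comparisons for amplitudes are
  therefore made against filtered-domain expectations, and absolute
  amplitude calibration against an unfiltered standard is out of scope.
* The cohort simulator assigns outcome labels from realised event
  indicators; group sizes match the target split in expectation, not
  exactly.
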