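"""Extract the six P wave parameters from one recording: per-lead PWD,
PWDc, PWV and PWA, plus the global dispersion, PTFV1 and the
inter-atrial block flag."""

import warnings

import pwavekit as pk
from pwavekit.delineate import detect_r_peaks, estimate_heart_rate

spec = pk.default_spec(duration_s=60.0, heart_rate_bpm=72.0, seed=3)
rec, truth = pk.generate_recording(spec)
filtered = pk.apply_notch(pk.apply_bandpass(rec), pk.FilterConfig())

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    _, beats = pk.delineate_recording(filtered)
hr = estimate_heart_rate(detect_r_peaks(filtered.lead("II"), rec.fs),
                         rec.fs)
feats = pk.extract_features(beats, hr)

print(f"heart rate {hr:.1f} bpm "
      "(PWDc = PWD + 1.75 x (HR - 60), so PWDc > PWD here)")
print(f"{'lead':>5s} {'PWD ms':>8s} {'PWDc ms':>8s} {'PWV mV':>8s} "
      f"{'PWA ms*mV':>10s} {'morphology':>12s}")
for lead, lp in feats.leads.items():
    print(f"{lead:>5s} {lp.pwd_ms:8.1f} {lp.pwdc_ms:8.1f} "
          f"{lp.pwv_mv:8.3f} {lp.pwa_msmv:10.2f} {lp.morphology:>12s}")
print(f"global P wave dispersion: {feats.pwdisp_global_ms:.1f} ms "
      "(max - min of the per-lead durations)")
print(f"PTFV1: {feats.ptfv1_mms:.3f} mm*s "
      "(negative = negative terminal phase in V1)")
print(f"inter-atrial block: {feats.iab} "
      "(needs PWD >= 120 ms AND a biphasic inferior-lead P)")
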