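"""Generate a synthetic 12-lead ECG, run the filter chain and the
P wave delineator, and compare detected fiducials with the ground
truth baked into the recording."""

import warnings

import numpy as np

import pwavekit as pk

# one minute, 60 bpm, mild white noise + 50 Hz mains
spec = pk.default_spec(
    duration_s=60.0, heart_rate_bpm=60.0, seed=7,
    noise=pk.NoiseSpec(white_sd_mv=0.01, mains_amp_mv=0.05))
rec, truth = pk.generate_recording(spec)

filtered = pk.apply_notch(pk.apply_bandpass(rec), pk.FilterConfig())
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    ann, beats = pk.delineate_recording(filtered)

tk = truth.annotations.by_key()
errors = {"P_ONSET": [], "P_OFFSET": []}
for (lead, beat, kind), sample in ann.by_key().items():
    if kind in errors and (lead, beat, kind) in tk:
        errors[kind].append(sample - tk[(lead, beat, kind)])

print(f"{truth.n_beats} beats generated; "
      f"{len(beats)} P waves measured across 12 leads")
for kind, errs in errors.items():
    print(f"{kind:9s} mean |error| = {np.abs(errs).mean():.2f} ms "
          f"(bias {np.mean(errs):+.2f} ms, n = {len(errs)})")
print("Errors are detected-minus-true fiducial positions at fs = 1 kHz;"
      " values of a few ms reflect filter corner rounding plus noise.")
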