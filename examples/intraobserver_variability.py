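"""Repeat-measurement agreement: delineate the same recordings twice
under independent measurement noise and summarise the per-P-wave
duration differences as raw numbers and a percentage."""

import warnings

import numpy as np

import pwavekit as pk

pwd_day1, pwd_day2 = [], []
for i in range(4):  # 4 recordings x 12 leads x ~20 beats
    spec = pk.default_spec(duration_s=30.0, seed=100 + i)
    rec, _ = pk.generate_recording(spec)
    for day, noise_seed in ((pwd_day1, 1), (pwd_day2, 2)):
        noisy = pk.add_noise(rec, pk.NoiseSpec(white_sd_mv=0.015),
                             seed=1000 * noise_seed + i)
        filtered = pk.apply_notch(pk.apply_bandpass(noisy),
                                  pk.FilterConfig())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, beats = pk.delineate_recording(filtered)
        day.append(beats.set_index(["lead", "beat"])["pwd_ms"])

import pandas as pd

d1 = pd.concat(pwd_day1, keys=range(4))
d2 = pd.concat(pwd_day2, keys=range(4))
common = d1.index.intersection(d2.index)
mean_d, sem_d, pct = pk.intraobserver_variability(d1[common], d2[common])

print(f"{len(common)} paired P wave duration measurements")
print(f"mean |day1 - day2| = {mean_d:.2f} +/- {sem_d:.2f} ms "
      f"({pct:.1f}% of the paired mean)")
print("A few ms / a few percent indicates the delineation is stable"
      " against independent measurement noise.")
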