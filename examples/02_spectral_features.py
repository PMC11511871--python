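"""Turn epoched EEG into multitaper power / cross-power feature vectors.

One feature vector per (possibly overlapping) sub-window: for every 1-Hz
frequency from 1 to 55, the per-channel power (diagonal) and the cross-power
magnitude of every channel pair (upper triangle).
"""

import numpy as np

import eegrobust as er

# a 1-second, 3-channel toy epoch: 10-Hz alpha on ch0, shared 40-Hz gamma
# on ch1+ch2 (which induces cross-power), white noise everywhere
rng = np.random.default_rng(0)
t = np.arange(1000) / 1000.0
epoch = 0.3 * rng.standard_normal((1000, 3))
epoch[:, 0] += np.sin(2 * np.pi * 10 * t)
shared = np.sin(2 * np.pi * 40 * t + 0.3)
epoch[:, 1] += shared
epoch[:, 2] += shared

mt = er.MultitaperConfig()           # 5 Slepian tapers, 1-55 Hz
S = er.multitaper_cross_spectrum(epoch, mt, sample_rate=1000.0)
freqs = mt.frequencies
print(f"cross-spectral array: {S.shape} (channels x channels x frequencies)")
print(f"ch0 power peaks at {freqs[np.argmax(S[0, 0])]:.0f} Hz (alpha)")
print(f"ch1-ch2 cross-power peaks at {freqs[np.argmax(S[1, 2])]:.0f} Hz "
      "(the shared gamma oscillation)")

index = er.build_feature_index(("C3", "C4", "Cz"), mt)
x = er.vectorize(S, index)
print(f"vectorized: {len(x)} features "
      f"({index.n_pairs_per_frequency} per frequency x "
      f"{len(index.frequencies)} frequencies); all non-negative: "
      f"{bool(np.all(x >= 0))}")

# the full 19-channel 10-20 montage gives the standard feature count
full = er.build_feature_index(er.features.CHANNELS_1020, mt)
print(f"19-channel montage: {full.n_pairs_per_frequency} features/frequency, "
      f"{len(full)} total")

# augmentation: overlapping half-second sub-windows, denser for the
# negative class so an imbalanced cohort ends up window-balanced
aug = er.AugmentConfig(subwindow_length=0.5, overlap_fraction=0.5,
                       extra_windows_neg_class=6)
pos = er.augment_epoch(epoch, label=1, aug=aug, mt=mt, sample_rate=1000.0)
neg = er.augment_epoch(epoch, label=0, aug=aug, mt=mt, sample_rate=1000.0)
print(f"augmentation: positive-class epoch -> {len(pos)} windows, "
      f"negative-class epoch -> {len(neg)} windows")
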