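"""Multitaper power / cross-power feature extraction for epoched EEG.

Each epoch (or sub-window of an epoch) is reduced to a non-negative feature
vector holding, for every frequency on a 1-Hz grid, the per-channel multitaper
power (diagonal of the cross-spectral matrix) and the magnitude of the
cross-power for every unordered channel pair (upper triangle).  For an
L-channel montage and F frequencies this yields p = F * L * (L + 1) / 2
features — 10,450 for the 19-channel 10–20 montage at 1–55 Hz.

The cross-spectrum is evaluated on the exact 1-Hz grid by direct discrete
Fourier sums of the Slepian-tapered signal, so the grid is independent of the
window length (a 0.5-s window still yields estimates at every integer Hz,
at correspondingly coarser true resolution).
"""

from __future__ import annotations


from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal.windows import dpss

__all__ = [
    "MultitaperConfig",
    "AugmentConfig",
    "FeatureIndex",
    "SpectralSample",
    "multitaper_cross_spectrum",
    "build_feature_index",
    "vectorize",
    "unvectorize",
    "augment_epoch",
    "log_features",
]

#: Default 19-channel subset of the international 10–20 montage.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
)


@dataclass(frozen=True)
class MultitaperConfig:
    """Multitaper estimation settings.

    ``n_tapers`` Slepian tapers with time-half-bandwidth product
    ``time_half_bandwidth`` (NW).  The default NW = 3 is the smallest value for
    which the first five tapers all have spectral concentration above 0.9, so
    exactly K = 5 well-concentrated tapers are averaged.
    """

    n_tapers: int = 5
    freq_min: float = 1.0
    freq_max: float = 55.0
    freq_step: float = 1.0
    time_half_bandwidth: float = 3.0

    def __post_init__(self) -> None:
        if self.n_tapers < 1:
            raise ValueError("n_tapers must be >= 1")
        if self.freq_max < self.freq_min or self.freq_step <= 0:
            raise ValueError("frequency grid is empty")
        if self.n_tapers > 2 * self.time_half_bandwidth - 1 + 1e-9:
            raise ValueError(
                f"n_tapers={self.n_tapers} exceeds 2*NW-1="
                f"{2 * self.time_half_bandwidth - 1:g}; tapers beyond that "
                "limit are poorly concentrated"
            )

    @property
    def frequencies(self) -> np.ndarray:
        """The analysis grid in Hz (inclusive of both endpoints)."""
        n = int(round((self.freq_max - self.freq_min) / self.freq_step)) + 1
        return self.freq_min + self.freq_step * np.arange(n)


@dataclass(frozen=True)
class AugmentConfig:
    """Windowed data-augmentation settings.

    Every epoch is cut into shorter, partially overlapping sub-windows and each
    sub-window contributes one feature vector.  Negative-class (NT) epochs use
    a denser start grid — ``extra_windows_neg_class`` additional windows — to
    approximately balance the classes when the cohort is imbalanced.
    """

    subwindow_length: float = 0.5
    overlap_fraction: float = 0.5
    extra_windows_neg_class: int = 6

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.subwindow_length <= 0:
            raise ValueError("subwindow_length must be positive")
        if self.extra_windows_neg_class < 0:
            raise ValueError("extra_windows_neg_class must be >= 0")


@dataclass(frozen=True)
class FeatureIndex:
    """Ordered map from feature position to (channel_a, channel_b, frequency).

    Ordering is frequency-major; within a frequency, channel pairs are
    lexicographic over 0-based indices (a, b) with a <= b.  a == b entries are
    per-channel power, a < b entries are cross-power magnitude.
    """

    channel_labels: tuple
    frequencies: tuple

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def pairs(self) -> tuple:
        L = self.n_channels
        return tuple((a, b) for a in range(L) for b in range(a, L))

    @property
    def n_pairs_per_frequency(self) -> int:
        L = self.n_channels
        return L * (L + 1) // 2

    def __len__(self) -> int:
        return len(self.frequencies) * self.n_pairs_per_frequency

    def arrays(self) -> tuple:
        """(chan_a, chan_b, freq) int/float arrays, one entry per feature."""
        pa, pb = zip(*self.pairs)
        pa = np.asarray(pa)
        pb = np.asarray(pb)
        nf = len(self.frequencies)
        chan_a = np.tile(pa, nf)
        chan_b = np.tile(pb, nf)
        freq = np.repeat(np.asarray(self.frequencies, dtype=float),
                         self.n_pairs_per_frequency)
        return chan_a, chan_b, freq

    def position(self, channel_a: int, channel_b: int, frequency: float) -> int:
        """Flat position of feature (a, b, f); a and b may be given in either order."""
        a, b = sorted((channel_a, channel_b))
        L = self.n_channels
        if not 0 <= a <= b < L:
            raise ValueError(f"channel pair ({channel_a}, {channel_b}) outside montage")
        freqs = list(self.frequencies)
        try:
            fi = freqs.index(frequency)
        except ValueError:
            raise ValueError(f"frequency {frequency} not on the analysis grid") from None
        # pairs before (a, b) within one frequency block
        offset = a * L - a * (a - 1) // 2 + (b - a)
        return fi * self.n_pairs_per_frequency + offset


@dataclass
class SpectralSample:
    """One non-negative feature vector with its provenance."""

    x: np.ndarray
    subject_id: str
    window_id: str
    label: int

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if np.any(self.x < 0):
            raise ValueError("spectral features must be non-negative")


def build_feature_index(channel_labels: Sequence[str],
                        config: MultitaperConfig | None = None) -> FeatureIndex:
    """Deterministic feature index for a montage and frequency grid."""
    config = config or MultitaperConfig()
    labels = tuple(channel_labels)
    if len(set(labels)) != len(labels):
        raise ValueError("channel labels must be unique")
    return FeatureIndex(channel_labels=labels,
                        frequencies=tuple(config.frequencies))


def multitaper_cross_spectrum(epoch: np.ndarray,
                              config: MultitaperConfig | None = None,
                              sample_rate: float = 1000.0) -> np.ndarray:
    """Multitaper cross-spectral matrix of one epoch on the 1-Hz grid.

    Parameters
    ----------
    epoch : (T, L) array
        T samples by L channels.
    config : MultitaperConfig
        Taper count / bandwidth and frequency grid.
    sample_rate : float
        Sampling rate in Hz.

    Returns
    -------
    (L, L, F) array
        For each frequency f, a symmetric non-negative matrix: the diagonal is
        per-channel multitaper power, off-diagonals the magnitude of the
        taper-averaged cross-spectrum.
    """
    config = config or MultitaperConfig()
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2:
        raise ValueError("epoch must be a (T, L) array")
    T, L = epoch.shape
    if T < 2:
        raise ValueError("epoch must contain at least 2 samples")
    if not np.all(np.isfinite(epoch)):
        raise ValueError("epoch contains non-finite values")
    if T < 2 * config.n_tapers:
        raise ValueError(
            f"epoch of T={T} samples is too short for {config.n_tapers} "
            f"Slepian tapers (need T >= {2 * config.n_tapers})"
        )

    tapers = dpss(T, config.time_half_bandwidth, Kmax=config.n_tapers)  # (K, T)
    freqs = config.frequencies
    t = np.arange(T) / sample_rate
    # (F, T) complex exponentials evaluated on the exact analysis grid
    phase = np.exp(-2j * np.pi * freqs[:, None] * t[None, :])

    # eigenspectra: for each taper k, Z_k = phase @ (taper * epoch) -> (F, L)
    K = config.n_tapers
    acc = np.zeros((len(freqs), L, L), dtype=complex)
    for k in range(K):
        Zk = phase @ (tapers[k][:, None] * epoch)  # (F, L)
        acc += Zk[:, :, None] * np.conj(Zk[:, None, :])
    S = np.abs(acc) / K  # magnitude of the taper-averaged cross-spectrum
    return np.ascontiguousarray(np.moveaxis(S, 0, -1))  # (L, L, F)


def vectorize(cross_spectrum: np.ndarray, index: FeatureIndex) -> np.ndarray:
    """Flatten an (L, L, F) cross-spectral array in feature-index order."""
    S = np.asarray(cross_spectrum)
    L = index.n_channels
    F = len(index.frequencies)
    if S.shape != (L, L, F):
        raise ValueError(f"cross-spectrum shape {S.shape} does not match index "
                         f"({L}, {L}, {F})")
    ia, ib = np.triu_indices(L)
    # (F, n_pairs) then flatten frequency-major
    return np.ascontiguousarray(S[ia, ib, :].T).reshape(-1)


def unvectorize(x: np.ndarray, index: FeatureIndex) -> np.ndarray:
    """Inverse of :func:`vectorize`; fills both triangles symmetrically."""
    x = np.asarray(x, dtype=float)
    if x.shape != (len(index),):
        raise ValueError(f"vector of length {x.shape} does not match index "
                         f"of length {len(index)}")
    L = index.n_channels
    F = len(index.frequencies)
    S = np.zeros((L, L, F))
    ia, ib = np.triu_indices(L)
    vals = x.reshape(F, index.n_pairs_per_frequency).T  # (n_pairs, F)
    S[ia, ib, :] = vals
    S[ib, ia, :] = vals
    return S


def _window_starts(T: int, Tw: int, label: int, aug: AugmentConfig) -> np.ndarray:
    stride = max(1, int(round(Tw * (1.0 - aug.overlap_fraction))))
    pos_starts = np.arange(0, T - Tw + 1, stride)
    if label == 1 or aug.extra_windows_neg_class == 0:
        return pos_starts
    n = len(pos_starts) + aug.extra_windows_neg_class
    return np.unique(np.round(np.linspace(0, T - Tw, n)).astype(int))


def augment_epoch(epoch: np.ndarray,
                  label: int,
                  aug: AugmentConfig | None = None,
                  mt: MultitaperConfig | None = None,
                  sample_rate: float = 1000.0,
                  subject_id: str = "",
                  epoch_id: str = "0") -> list:
    """Feature vectors from overlapping sub-windows of one epoch.

    Negative-class epochs are cut on a denser start grid (see
    :class:`AugmentConfig`), so they yield at least as many windows as
    positive-class epochs under the same configuration.
    """
    aug = aug or AugmentConfig()
    mt = mt or MultitaperConfig()
    epoch = np.asarray(epoch, dtype=float)
    T = epoch.shape[0]
    Tw = int(round(aug.subwindow_length * sample_rate))
    if Tw > T:
        raise ValueError(
            f"sub-window of {Tw} samples does not fit in epoch of {T} samples")
    index = build_feature_index([f"ch{i}" for i in range(epoch.shape[1])], mt)
    samples = []
    for w, start in enumerate(_window_starts(T, Tw, label, aug)):
        S = multitaper_cross_spectrum(epoch[start:start + Tw], mt, sample_rate)
        samples.append(SpectralSample(
            x=vectorize(S, index),
            subject_id=subject_id,
            window_id=f"{epoch_id}w{w}",
            label=int(label),
        ))
    return samples


def log_features(x: np.ndarray, eps_floor: float = 1e-12) -> np.ndarray:
    """Natural log of non-negative features, floored to guard exact zeros."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("features must be non-negative")
    return np.log(x + eps_floor)
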