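"""Synthetic EEG cohorts with known ground-truth group-contrast signatures.

The generator emulates the statistical structure of a pediatric resting-state
EEG case/control cohort: per-subject 1/f-decaying background activity,
band-limited oscillations realized as narrow-band filtered Gaussian noise,
cross-channel coherence induced by latent oscillations shared between
connected channels, multiplicative subject- and channel-level nuisance gains,
class imbalance, and an age covariate correlated with the class label.

A :class:`GroundTruthSignature` plants a sparse set of (channel-pair x
frequency-band) effects: entries with positive effect elevate power /
cross-power in the positive class, entries with negative effect elevate the
negative class.  :func:`signature_as_profile` renders the signature as a dense
coefficient vector so that recovered association profiles can be scored
against the truth.

This is a statistical fixture, not a biophysical simulation: there is no
forward head model, no artifacts, and no claim that the distributional
choices match any real cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import CHANNELS_1020, FeatureIndex
from .interpretation import DEFAULT_BANDS, CoefficientProfile

#: (lo, hi) Hz intervals of the canonical bands used for subject-level
#: band-amplitude nuisance.
_NUISANCE_BANDS = tuple(DEFAULT_BANDS.values())

__all__ = [
    "SignatureEntry",
    "GroundTruthSignature",
    "CohortConfig",
    "EpochSet",
    "default_signature",
    "generate_cohort",
    "signature_as_profile",
]


@dataclass(frozen=True)
class SignatureEntry:
    """One planted effect: a signed log-power offset on a (pair, band) cell.

    ``effect > 0`` elevates the positive class, ``effect < 0`` the negative
    class; the magnitude is the log power-gain of the elevated class relative
    to the other.  ``channel_a == channel_b`` plants a power effect,
    ``channel_a != channel_b`` a cross-power (connectivity) effect via a
    shared latent oscillation.
    """

    channel_a: int
    channel_b: int
    band: tuple
    effect: float

    def __post_init__(self) -> None:
        if self.channel_a > self.channel_b:
            object.__setattr__(self, "channel_a", self.channel_b)
            object.__setattr__(self, "channel_b", self.channel_a)
        lo, hi = self.band
        if not (1 <= lo <= hi <= 55):
            raise ValueError("signature bands must lie within [1, 55] Hz")
        if self.effect == 0:
            raise ValueError("signature entries must have a nonzero effect")


@dataclass(frozen=True)
class GroundTruthSignature:
    entries: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        if self.entries:
            signs = {e.effect > 0 for e in self.entries}
            if signs != {True, False}:
                raise ValueError(
                    "signature needs at least one positive-class and one "
                    "negative-class entry (or be empty for a null cohort)")

    def to_json(self, path) -> None:
        payload = [{"channel_a": e.channel_a, "channel_b": e.channel_b,
                    "band": list(e.band), "effect": e.effect}
                   for e in self.entries]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruthSignature":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(tuple(SignatureEntry(d["channel_a"], d["channel_b"],
                                        tuple(d["band"]), d["effect"])
                         for d in payload))


def default_signature(channel_labels: Sequence[str] = CHANNELS_1020,
                      effect: float = 0.5) -> GroundTruthSignature:
    """Posterior-gamma-up in the positive class, cross-hemisphere theta/alpha
    up in the negative class — the canonical contrast the pipeline should
    recover.  Uses whichever of the named electrodes exist in the montage."""
    labels = list(channel_labels)

    def idx(name: str) -> int | None:
        return labels.index(name) if name in labels else None

    entries = []

    def add(a, b, band, eff):
        ia, ib = idx(a), idx(b)
        if ia is not None and ib is not None:
            entries.append(SignatureEntry(min(ia, ib), max(ia, ib), band, eff))

    # positive class: elevated posterior gamma power and occipito-parietal
    # gamma connectivity
    add("O1", "O1", (31, 55), +effect)
    add("O2", "O2", (31, 55), +effect)
    add("O1", "O2", (31, 55), +effect)
    add("P3", "O1", (31, 55), +effect)
    add("P4", "O2", (31, 55), +effect)
    # negative class: elevated cross-hemisphere theta/alpha connectivity
    add("T7", "T8", (5, 7), -effect)
    add("P3", "P4", (8, 10), -effect)
    add("C3", "C4", (8, 10), -effect)
    if not entries:
        raise ValueError("montage contains none of the default signature electrodes")
    return GroundTruthSignature(tuple(entries))


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the structure of the emulated cohort: a roughly 3:1
    positive:negative subject imbalance, 1-second epochs of 19-channel EEG at
    1000 Hz, a 1/f background with alpha ~ 1, ages 37–96 months with a mild
    positive age-class correlation.

    ``subject_variance_scale`` is the s.d. of the subject-level log
    *amplitude* gain (per-channel gains use half that scale); because power
    goes as amplitude squared, the default 0.25 corresponds to ~0.5 s.d. of
    broadband log power between subjects, in line with the large
    between-subject variability typical of band-power measures.
    ``exponent_jitter`` is the s.d. of the per-subject 1/f exponent around
    ``background_exponent``: subjects genuinely differ in spectral slope, and
    this tilt is the prototypical low-rank, diagnosis-unrelated source of
    spectral variance the SIRT preprocessing is meant to absorb.
    ``band_variance_scale`` is the s.d. of per-subject log amplitude gains
    applied uniformly across channels within each canonical band (delta ...
    gamma): individual band power — alpha especially — varies severalfold
    between people, and this band-structured variance is another low-rank
    nuisance source.
    """

    n_pos_subjects: int = 60
    n_neg_subjects: int = 20
    epochs_per_subject: int = 20
    channel_labels: tuple = CHANNELS_1020
    sample_rate: float = 1000.0
    epoch_length: float = 1.0
    background_exponent: float = 1.0
    exponent_jitter: float = 0.15
    band_variance_scale: float = 0.3
    signature: GroundTruthSignature | None = None
    oscillation_strength: float = 1.0
    subject_variance_scale: float = 0.25
    age_range: tuple = (37.0, 96.0)
    age_class_correlation: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pos_subjects, self.n_neg_subjects,
               self.epochs_per_subject) <= 0:
            raise ValueError("subject and epoch counts must be positive")
        n_samp = self.sample_rate * self.epoch_length
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("sample_rate * epoch_length must be an integer")
        if not -1 <= self.age_class_correlation <= 1:
            raise ValueError("age_class_correlation must lie in [-1, 1]")
        if self.signature is None:
            self.signature = default_signature(self.channel_labels)
        for e in self.signature.entries:
            if e.channel_b >= len(self.channel_labels):
                raise ValueError(
                    f"signature entry references channel {e.channel_b} outside "
                    f"the {len(self.channel_labels)}-channel montage")

    @property
    def n_samples_per_epoch(self) -> int:
        return int(round(self.sample_rate * self.epoch_length))


@dataclass
class EpochSet:
    """Cleaned, epoched EEG for one subject plus label/age metadata."""

    subject_id: str
    diagnosis: int
    age: float
    channel_labels: tuple
    sample_rate: float
    epochs: list
    study_id: str | None = None

    def __post_init__(self) -> None:
        shapes = {e.shape for e in self.epochs}
        if len(shapes) > 1:
            raise ValueError("all epochs must share one shape")
        for e in self.epochs:
            if e.shape[1] != len(self.channel_labels):
                raise ValueError("epoch channel count does not match labels")
            if not np.all(np.isfinite(e)):
                raise ValueError("epochs must be finite")


def _pink_noise(rng: np.random.Generator, T: int, L: int, fs: float,
                alpha: float) -> np.ndarray:
    """1/f^alpha-filtered Gaussian noise, unit-ish scale, (T, L)."""
    white = rng.standard_normal((T, L))
    spec = np.fft.rfft(white, axis=0)
    f = np.fft.rfftfreq(T, d=1.0 / fs)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** (-alpha / 2.0)
    return np.fft.irfft(spec * amp[:, None], n=T, axis=0)


def _band_noise(rng: np.random.Generator, T: int, fs: float,
                band: tuple) -> np.ndarray:
    """Unit-variance narrow-band filtered Gaussian noise, (T,)."""
    white = rng.standard_normal(T)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(T, d=1.0 / fs)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(spec, n=T)
    sd = x.std()
    return x / sd if sd > 0 else x


def _ages_tilted_by_class(rng: np.random.Generator, y: np.ndarray,
                          age_range: tuple, rho: float) -> np.ndarray:
    """Ages ~ Uniform(age_range) marginally, rank-tilted by class so the
    point-biserial corr(age, y) is approximately ``rho`` (Gaussian copula)."""
    n = len(y)
    ys = (y - y.mean()) / max(y.std(), 1e-12)
    z = rho * ys + np.sqrt(max(0.0, 1 - rho ** 2)) * rng.standard_normal(n)
    ranks = np.argsort(np.argsort(z))
    u = (ranks + 0.5) / n
    lo, hi = age_range
    return lo + u * (hi - lo)


def generate_cohort(config: CohortConfig) -> list:
    """Generate one synthetic cohort; fully determined by ``config.seed``."""
    T = config.n_samples_per_epoch
    fs = config.sample_rate
    L = len(config.channel_labels)
    n = config.n_pos_subjects + config.n_neg_subjects
    y = np.concatenate([np.ones(config.n_pos_subjects, dtype=int),
                        np.zeros(config.n_neg_subjects, dtype=int)])

    root = np.random.SeedSequence(config.seed)
    age_seed, *subject_seeds = root.spawn(n + 1)
    ages = _ages_tilted_by_class(np.random.default_rng(age_seed), y,
                                 config.age_range,
                                 config.age_class_correlation)

    entries = config.signature.entries

    # Draw all subject-level nuisance variates first, then center each within
    # diagnosis group: the planted nuisance (broadband gain, per-channel
    # gains, 1/f tilt, band-amplitude field) is exactly class-orthogonal in
    # every generated cohort, so finite-sample chance associations between
    # nuisance and diagnosis cannot masquerade as signal.  The per-subject
    # generators are reused afterwards for the epoch noise, keeping the whole
    # cohort a pure function of the seed.
    rngs = [np.random.default_rng(seed) for seed in subject_seeds]
    log_gsubj = np.array([config.subject_variance_scale * r.standard_normal()
                          for r in rngs])
    log_gchan = np.stack([0.5 * config.subject_variance_scale
                          * r.standard_normal(L) for r in rngs])
    alpha_dev = np.array([config.exponent_jitter * r.standard_normal()
                          for r in rngs])
    log_band = np.stack([config.band_variance_scale
                         * r.standard_normal(len(_NUISANCE_BANDS))
                         for r in rngs])
    for cls in (0, 1):
        sel = y == cls
        log_gsubj[sel] -= log_gsubj[sel].mean()
        log_gchan[sel] -= log_gchan[sel].mean(axis=0)
        alpha_dev[sel] -= alpha_dev[sel].mean()
        log_band[sel] -= log_band[sel].mean(axis=0)

    cohort = []
    for s in range(n):
        rng = rngs[s]
        g_subj = np.exp(log_gsubj[s])
        g_chan = np.exp(log_gchan[s])
        alpha_s = config.background_exponent + alpha_dev[s]
        band_gains = np.exp(log_band[s])
        gains = g_subj * g_chan  # (L,)
        power_entries = [e for e in entries if e.channel_a == e.channel_b]
        cross_entries = [e for e in entries if e.channel_a != e.channel_b]
        # per-channel in-band amplitude gain curves for the planted power
        # effects: the favored class gets amplitude exp(|effect|/2), i.e. a
        # power gain of exactly exp(|effect|) over the band
        fgrid = np.fft.rfftfreq(T, d=1.0 / fs)
        subject_curve = np.ones(len(fgrid))
        for (lo, hi), g_band in zip(_NUISANCE_BANDS, band_gains):
            subject_curve[(fgrid >= lo) & (fgrid <= hi)] *= g_band
        chan_gain = {}
        for e in power_entries:
            favored = 1 if e.effect > 0 else 0
            if y[s] != favored:
                continue
            curve = chan_gain.setdefault(e.channel_a, np.ones(len(fgrid)))
            in_band = (fgrid >= e.band[0]) & (fgrid <= e.band[1])
            curve[in_band] *= np.exp(abs(e.effect) / 2.0)
        epochs = []
        for _ in range(config.epochs_per_subject):
            data = _pink_noise(rng, T, L, fs, alpha_s)
            # connectivity effects: band-limited latent oscillations shared
            # between the two channels (plus channel-private band noise so
            # coherence stays below 1), stronger in the favored class
            for e in cross_entries:
                favored = 1 if e.effect > 0 else 0
                g = np.exp(abs(e.effect) / 2.0) if y[s] == favored else 1.0
                f_mid = 0.5 * (e.band[0] + e.band[1])
                base = config.oscillation_strength * f_mid ** (
                    -config.background_exponent / 2.0) * np.sqrt(
                        e.band[1] - e.band[0] + 1.0)
                shared = _band_noise(rng, T, fs, e.band)
                for ch in (e.channel_a, e.channel_b):
                    data[:, ch] += base * g * shared
                    data[:, ch] += 0.5 * base * _band_noise(rng, T, fs, e.band)
            # multiplicative spectral gains: planted power effects on their
            # (channel, band) cells, and the subject's band-amplitude field
            # on every channel
            if np.any(subject_curve != 1.0) or chan_gain:
                spec = np.fft.rfft(data, axis=0)
                spec *= subject_curve[:, None]
                for ch, curve in chan_gain.items():
                    spec[:, ch] *= curve
                data = np.fft.irfft(spec, n=T, axis=0)
            epochs.append((data * gains[None, :]).astype(np.float32))
        cohort.append(EpochSet(
            subject_id=f"S{s:04d}",
            diagnosis=int(y[s]),
            age=float(ages[s]),
            channel_labels=tuple(config.channel_labels),
            sample_rate=fs,
            epochs=epochs,
            study_id=None,
        ))
    return cohort


def signature_as_profile(signature: GroundTruthSignature,
                         index: FeatureIndex) -> CoefficientProfile:
    """Dense ground-truth coefficient vector for recovery scoring.

    Positive-class effects appear as positive entries over their band's 1-Hz
    bins, negative-class effects as negative entries; everything else is 0.
    """
    w = np.zeros(len(index))
    grid = set(index.frequencies)
    for e in signature.entries:
        if e.channel_b >= index.n_channels:
            raise ValueError(
                f"signature channel {e.channel_b} outside the feature index")
        freqs = [f for f in np.arange(e.band[0], e.band[1] + 1) if f in grid]
        if not freqs:
            raise ValueError(
                f"signature band {e.band} has no bins on the analysis grid")
        for f in freqs:
            w[index.position(e.channel_a, e.channel_b, float(f))] += e.effect
    return CoefficientProfile(w=w, index=index,
                              provenance={"source": "ground_truth_signature"})
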