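"""Interpretation of linear coefficient profiles over (channel-pair, frequency).

A trained classifier's coefficient vector, averaged over the repetitions of
the robustness evaluation, is the object of scientific interest: positive
entries are associated with the positive class, negative entries with the
negative class.  This module turns such a profile into the standard views —
per-frequency sums, canonical-band averages over channel pairs, top-fraction
masks, and plot-ready chord / brain-view tables — and correlates subject-level
prediction logits with clinical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureIndex

__all__ = [
    "CoefficientProfile",
    "CorrelationRow",
    "DEFAULT_BANDS",
    "average_profiles",
    "frequency_profile",
    "band_aggregate",
    "top_fraction_mask",
    "export_chord_data",
    "export_brainview_data",
    "montage_coordinates",
    "logit_covariate_correlations",
    "plot_frequency_profile",
    "plot_robustness_sweep",
]

#: Canonical EEG band definitions (Hz, inclusive); they partition 1–55 Hz.
DEFAULT_BANDS = {
    "delta": (1, 4),
    "theta": (5, 7),
    "alpha": (8, 10),
    "beta1": (11, 20),
    "beta2": (21, 30),
    "gamma": (31, 55),
}


@dataclass
class CoefficientProfile:
    """A linear coefficient vector indexed by (channel-pair, frequency)."""

    w: np.ndarray
    index: FeatureIndex
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (len(self.index),):
            raise ValueError(
                f"coefficient vector of length {self.w.size} does not match "
                f"feature index of length {len(self.index)}")


@dataclass
class CorrelationRow:
    """Pearson correlation of prediction logits with one covariate."""

    variable: str
    r: float
    p_raw: float
    p_corrected: float
    significant: bool
    n: int
    note: str = ""


def average_profiles(vectors, index: FeatureIndex,
                     provenance: dict | None = None) -> CoefficientProfile:
    """Elementwise mean of per-repetition coefficient vectors."""
    vectors = [np.asarray(v, dtype=float) for v in vectors]
    if not vectors:
        raise ValueError("need at least one coefficient vector")
    p = vectors[0].shape
    if any(v.shape != p for v in vectors):
        raise ValueError("coefficient vectors have mismatched lengths")
    prov = dict(provenance or {})
    prov.setdefault("n_models_averaged", len(vectors))
    return CoefficientProfile(w=np.mean(vectors, axis=0), index=index,
                              provenance=prov)


def frequency_profile(profile: CoefficientProfile) -> pd.Series:
    """Signed sum of coefficients over all channel pairs, per frequency."""
    _, _, freq = profile.index.arrays()
    s = pd.Series(profile.w).groupby(freq).sum()
    s.index.name = "frequency_hz"
    s.name = "coefficient_sum"
    return s


def band_aggregate(profile: CoefficientProfile,
                   bands: dict | None = None) -> pd.DataFrame:
    """Mean coefficient per (band, channel pair) over the band's 1-Hz bins."""
    bands = bands or DEFAULT_BANDS
    ca, cb, freq = profile.index.arrays()
    rows = []
    labels = profile.index.channel_labels
    for band, (lo, hi) in bands.items():
        in_band = (freq >= lo) & (freq <= hi)
        df = pd.DataFrame({
            "chan_a": ca[in_band], "chan_b": cb[in_band],
            "w": profile.w[in_band],
        })
        g = df.groupby(["chan_a", "chan_b"], sort=True)["w"].mean().reset_index()
        g.insert(0, "band", band)
        rows.append(g)
    out = pd.concat(rows, ignore_index=True)
    out["electrode_a"] = [labels[i] for i in out["chan_a"]]
    out["electrode_b"] = [labels[i] for i in out["chan_b"]]
    return out.rename(columns={"w": "mean_coefficient"})


def top_fraction_mask(values: np.ndarray, q: float = 0.05,
                      sign: str = "positive") -> np.ndarray:
    """Boolean mask over the top ``ceil(q * n)`` values.

    ``sign='positive'`` marks the largest values, ``sign='negative'`` the most
    negative ones.  Ties are broken deterministically by index order.
    """
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    values = np.asarray(values, dtype=float)
    n = values.size
    k = int(np.ceil(q * n))
    if sign == "positive":
        keyed = -values
    elif sign == "negative":
        keyed = values
    else:
        raise ValueError("sign must be 'positive' or 'negative'")
    order = np.argsort(keyed, kind="stable")
    mask = np.zeros(n, dtype=bool)
    mask[order[:k]] = True
    return mask


def export_chord_data(profile: CoefficientProfile,
                      mask: np.ndarray,
                      bands: dict | None = None) -> pd.DataFrame:
    """Plot-ready chord-diagram rows for the masked features.

    Self-pairs (a == b) are regional power (perimeter segments); cross-pairs
    are arcs between electrodes.
    """
    bands = bands or DEFAULT_BANDS
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (len(profile.index),):
        raise ValueError("mask length does not match feature index")
    ca, cb, freq = profile.index.arrays()
    labels = profile.index.channel_labels
    sel = np.flatnonzero(mask)

    def band_of(f: float) -> str:
        for name, (lo, hi) in bands.items():
            if lo <= f <= hi:
                return name
        return "other"

    rows = [{
        "electrode_a": labels[ca[i]],
        "electrode_b": labels[cb[i]],
        "frequency_hz": freq[i],
        "band": band_of(freq[i]),
        "weight": profile.w[i],
        "sign": "positive" if profile.w[i] >= 0 else "negative",
        "kind": "power" if ca[i] == cb[i] else "cross_power",
    } for i in sel]
    cols = ["electrode_a", "electrode_b", "frequency_hz", "band", "weight",
            "sign", "kind"]
    return pd.DataFrame(rows, columns=cols)


def montage_coordinates(channel_labels) -> pd.DataFrame:
    """3-D electrode coordinates (meters, head frame) from the standard 10–20 montage."""
    import mne

    try:
        montage = mne.channels.make_standard_montage("colin27_1020")
    except ValueError:  # older MNE releases use the previous montage name
        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    rows = []
    for lab in channel_labels:
        if lab not in pos:
            raise KeyError(f"no montage coordinate for channel label {lab!r}")
        x, y, z = pos[lab]
        rows.append({"electrode": lab, "x": x, "y": y, "z": z})
    return pd.DataFrame(rows).set_index("electrode")


# Orthographic projections: (horizontal, vertical) coordinate picks per view.
_VIEWS = {
    "axial": lambda c: (c["x"], c["y"]),           # drop vertical (z)
    "coronal": lambda c: (c["x"], c["z"]),
    "sagittal_left": lambda c: (-c["y"], c["z"]),  # viewed from the left
    "sagittal_right": lambda c: (c["y"], c["z"]),
}


def export_brainview_data(profile: CoefficientProfile,
                          mask: np.ndarray,
                          montage: pd.DataFrame | None = None,
                          bands: dict | None = None) -> pd.DataFrame:
    """Per-band brain-view rows for the masked features.

    Each row is one masked feature aggregated to its band: power features are
    points at their electrode, cross-power features lines between electrodes,
    with projected 2-D coordinates for axial, coronal and both sagittal views.
    """
    bands = bands or DEFAULT_BANDS
    if montage is None:
        montage = montage_coordinates(profile.index.channel_labels)
    for lab in profile.index.channel_labels:
        if lab not in montage.index:
            raise KeyError(f"no montage coordinate for channel label {lab!r}")
    chord = export_chord_data(profile, mask, bands)
    agg = (chord.groupby(["band", "electrode_a", "electrode_b", "kind"],
                         sort=False)["weight"].mean().reset_index())
    out = agg.copy()
    for view, proj in _VIEWS.items():
        h_a, v_a = proj(montage.loc[out["electrode_a"]])
        h_b, v_b = proj(montage.loc[out["electrode_b"]])
        out[f"{view}_ha"] = np.asarray(h_a)
        out[f"{view}_va"] = np.asarray(v_a)
        out[f"{view}_hb"] = np.asarray(h_b)
        out[f"{view}_vb"] = np.asarray(v_b)
    return out


def plot_frequency_profile(profile: CoefficientProfile, ax=None):
    """Reference plot: summed association per frequency, signed by class."""
    import matplotlib.pyplot as plt

    fp = frequency_profile(profile)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    pos = fp.clip(lower=0)
    neg = (-fp).clip(lower=0)
    ax.bar(fp.index, pos, color="tab:red", label="positive class")
    ax.bar(fp.index, neg, color="tab:blue", label="negative class")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("|summed coefficient|")
    ax.legend(frameon=False)
    return ax


def plot_robustness_sweep(summary: pd.DataFrame, ax=None):
    """Reference plot: P, S and R as a function of regularization strength."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    s = summary.sort_values("C_reg", ascending=False)
    x = -np.log10(s["C_reg"])
    for col, label in (("P_mean", "predictivity P"),
                       ("S_mean", "reproducibility S"),
                       ("R_mean", "robustness R")):
        se = s[col.replace("mean", "se")]
        ax.errorbar(x, s[col], yerr=se, label=label, marker="o", ms=3)
    ax.set_xlabel("-log10 C (regularization strength →)")
    ax.legend(frameon=False)
    return ax


def logit_covariate_correlations(logits, covariates: pd.DataFrame,
                                 alpha: float = 0.05) -> list:
    """Pearson correlation of subject logits with each covariate column.

    A Bonferroni correction over the number of covariates tested is applied;
    a correlation is flagged significant at the corrected ``alpha``.
    """
    logits = np.asarray(logits, dtype=float)
    if len(logits) != len(covariates):
        raise ValueError("logits and covariate table have different lengths")
    m = covariates.shape[1]
    rows = []
    for name in covariates.columns:
        vals = pd.to_numeric(covariates[name], errors="coerce").to_numpy()
        ok = np.isfinite(vals) & np.isfinite(logits)
        note = ""
        if ok.sum() < 3:
            rows.append(CorrelationRow(name, float("nan"), float("nan"),
                                       float("nan"), False, int(ok.sum()),
                                       "fewer than 3 complete observations"))
            continue
        v = vals[ok]
        if np.ptp(v) == 0:
            rows.append(CorrelationRow(name, float("nan"), float("nan"),
                                       float("nan"), False, int(ok.sum()),
                                       "constant covariate"))
            continue
        r, p = stats.pearsonr(logits[ok], v)
        p_corr = min(1.0, m * p)
        rows.append(CorrelationRow(name, float(r), float(p), float(p_corr),
                                   bool(p_corr < alpha), int(ok.sum()), note))
    return rows
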