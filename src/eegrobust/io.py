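"""File plumbing: HDF5 cohort/feature containers, CSV metadata, EDF reading.

Cohorts are stored one HDF5 group per subject (epochs + metadata attributes)
with a companion CSV metadata table; feature stores hold the window-level
matrix together with the feature index so a dataset round-trips exactly.
EDF recordings are read through MNE and cut into fixed-length epochs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import EpochSet
from .data import FeatureDataset
from .features import FeatureIndex

__all__ = [
    "save_cohort_hdf5",
    "load_cohort_hdf5",
    "cohort_metadata",
    "save_features_hdf5",
    "load_features_hdf5",
    "read_edf_epochs",
]


def save_cohort_hdf5(cohort, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for es in cohort:
            g = f.create_group(es.subject_id)
            g.create_dataset("epochs", data=np.stack(es.epochs),
                             compression="gzip", track_times=False)
            g.attrs["diagnosis"] = es.diagnosis
            g.attrs["age"] = es.age
            g.attrs["sample_rate"] = es.sample_rate
            g.attrs["channel_labels"] = list(es.channel_labels)
            if es.study_id is not None:
                g.attrs["study_id"] = es.study_id


def load_cohort_hdf5(path) -> list:
    import h5py

    cohort = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f.keys()):
            g = f[sid]
            epochs = list(np.asarray(g["epochs"]))
            cohort.append(EpochSet(
                subject_id=sid,
                diagnosis=int(g.attrs["diagnosis"]),
                age=float(g.attrs["age"]),
                channel_labels=tuple(str(c) for c in
                                     g.attrs["channel_labels"]),
                sample_rate=float(g.attrs["sample_rate"]),
                epochs=epochs,
                study_id=(str(g.attrs["study_id"])
                          if "study_id" in g.attrs else None)))
    return cohort


def cohort_metadata(cohort) -> pd.DataFrame:
    """Per-subject metadata table (subject_id, diagnosis, age, study_id)."""
    return pd.DataFrame([{
        "subject_id": es.subject_id,
        "diagnosis": es.diagnosis,
        "age": es.age,
        "study_id": es.study_id,
        "n_epochs": len(es.epochs),
    } for es in cohort])


def save_features_hdf5(dataset: FeatureDataset, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=dataset.X, compression="gzip",
                         track_times=False)
        f.create_dataset("y", data=dataset.y, track_times=False)
        f.create_dataset("subject_ids",
                         data=np.asarray(dataset.subject_ids, dtype="S"),
                         track_times=False)
        f.create_dataset("ages", data=dataset.ages, track_times=False)
        if dataset.groups is not None:
            f.create_dataset("groups",
                             data=np.asarray(dataset.groups, dtype="S"),
                             track_times=False)
        g = f.create_group("index")
        g.attrs["channel_labels"] = list(dataset.index.channel_labels)
        g.create_dataset("frequencies",
                         data=np.asarray(dataset.index.frequencies),
                         track_times=False)


def load_features_hdf5(path) -> FeatureDataset:
    import h5py

    with h5py.File(path, "r") as f:
        index = FeatureIndex(
            channel_labels=tuple(str(c) for c in
                                 f["index"].attrs["channel_labels"]),
            frequencies=tuple(float(v) for v in
                              np.asarray(f["index"]["frequencies"])))
        groups = (np.asarray(f["groups"]).astype(str)
                  if "groups" in f else None)
        return FeatureDataset(
            X=np.asarray(f["X"]),
            y=np.asarray(f["y"]),
            subject_ids=np.asarray(f["subject_ids"]).astype(str),
            ages=np.asarray(f["ages"]),
            index=index,
            groups=groups)


def read_edf_epochs(path, diagnosis: int, age: float,
                    subject_id: str | None = None,
                    study_id: str | None = None,
                    epoch_length: float = 1.0,
                    channel_labels=None) -> EpochSet:
    """Read an EDF recording and cut it into fixed-length epochs.

    ``channel_labels``, if given, selects (and orders) a channel subset by
    name; otherwise all channels are kept in file order.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channel_labels is not None:
        raw.pick([str(c) for c in channel_labels])
    data = raw.get_data().T  # (samples, channels)
    fs = float(raw.info["sfreq"])
    T = int(round(epoch_length * fs))
    n_epochs = data.shape[0] // T
    if n_epochs == 0:
        raise ValueError(f"recording shorter than one {epoch_length}-s epoch")
    epochs = [data[i * T:(i + 1) * T] for i in range(n_epochs)]
    return EpochSet(
        subject_id=subject_id or str(path),
        diagnosis=int(diagnosis), age=float(age),
        channel_labels=tuple(raw.ch_names), sample_rate=fs,
        epochs=epochs, study_id=study_id)
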