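"""Sample-level feature datasets and cohort -> feature extraction.

A :class:`FeatureDataset` holds the augmented window-level feature matrix
together with per-window subject provenance, so downstream code can always
split, train and evaluate at the subject level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import (AugmentConfig, FeatureIndex, MultitaperConfig,
                       augment_epoch, build_feature_index)

__all__ = ["FeatureDataset", "extract_features"]


@dataclass
class FeatureDataset:
    """Window-level features with subject provenance.

    X : (n_windows, p) non-negative feature matrix
    y : (n_windows,) binary labels
    subject_ids : (n_windows,) subject of each window
    ages : (n_windows,) subject age (months) repeated per window
    index : the FeatureIndex describing the columns of X
    groups : optional (n_windows,) grouping key (e.g. study id)
    """

    X: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray
    ages: np.ndarray
    index: FeatureIndex
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        for name in ("y", "subject_ids", "ages"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} does not align with X")
        if self.groups is not None and len(self.groups) != n:
            raise ValueError("groups does not align with X")
        if self.X.shape[1] != len(self.index):
            raise ValueError("X columns do not match the feature index")

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    def subject_table(self) -> pd.DataFrame:
        """One row per subject: subject_id, label, age, (group)."""
        d = {"subject_id": self.subject_ids, "label": self.y,
             "age": self.ages}
        if self.groups is not None:
            d["group"] = self.groups
        df = pd.DataFrame(d).drop_duplicates("subject_id")
        return df.reset_index(drop=True)

    def subset(self, subject_ids) -> "FeatureDataset":
        """Rows belonging to the given subjects (windows travel with subjects)."""
        wanted = set(subject_ids)
        sel = np.array([s in wanted for s in self.subject_ids])
        return FeatureDataset(
            X=self.X[sel], y=self.y[sel], subject_ids=self.subject_ids[sel],
            ages=self.ages[sel], index=self.index,
            groups=None if self.groups is None else self.groups[sel])


def extract_features(cohort,
                     mt: MultitaperConfig | None = None,
                     aug: AugmentConfig | None = None) -> FeatureDataset:
    """Augmented multitaper features for every epoch of every subject."""
    mt = mt or MultitaperConfig()
    aug = aug or AugmentConfig()
    if not cohort:
        raise ValueError("empty cohort")
    index = build_feature_index(cohort[0].channel_labels, mt)
    rows, labels, sids, ages, groups = [], [], [], [], []
    has_groups = any(es.study_id is not None for es in cohort)
    for es in cohort:
        for e_i, epoch in enumerate(es.epochs):
            samples = augment_epoch(np.asarray(epoch, dtype=float),
                                    es.diagnosis, aug, mt, es.sample_rate,
                                    subject_id=es.subject_id,
                                    epoch_id=f"e{e_i}")
            for s in samples:
                rows.append(s.x)
                labels.append(s.label)
                sids.append(es.subject_id)
                ages.append(es.age)
                if has_groups:
                    groups.append(es.study_id if es.study_id is not None
                                  else "")
    return FeatureDataset(
        X=np.asarray(rows), y=np.asarray(labels, dtype=int),
        subject_ids=np.asarray(sids), ages=np.asarray(ages, dtype=float),
        index=index,
        groups=np.asarray(groups) if has_groups else None)
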