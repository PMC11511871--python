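"""Disjoint-split model robustness: predictivity P, reproducibility S, R = P*S.

The evaluation partitions the subjects into two disjoint sets A and B, trains
the full pipeline twice — once on each side, testing on the other — and
records (i) the rescaled subject-level AUROC averaged over the two directions,
P = ((2*AUROC_A - 1) + (2*AUROC_B - 1)) / 2, and (ii) the Spearman rank
correlation S between the two learned coefficient vectors.  Robustness is
the mean over C repetitions of the per-repetition product:

    R = (1 / C) * sum_c  P_c * S_c .

Selecting the regularization strength by max R (rather than max P) trades a
small amount of predictive performance for coefficient profiles that
replicate across disjoint halves of the data.  A grouped-split mode replaces
the random halves with a split by an external key (e.g. study id) to probe
study-specific effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import ClassifierMetrics, evaluate, predict_subjects
from .data import FeatureDataset

__all__ = [
    "SplitPlan",
    "RepetitionResult",
    "RobustnessReport",
    "DEFAULT_C_GRID",
    "rescale_auroc",
    "disjoint_split",
    "coefficient_similarity",
    "evaluate_robustness",
    "grid_search",
    "select_model",
    "sweep_summary",
]

#: Default regularization sweep: eight inverse-strength decades.
DEFAULT_C_GRID = tuple(10.0 ** -k for k in range(5, 13))


@dataclass(frozen=True)
class SplitPlan:
    """How to build the disjoint subject splits."""

    repetitions: int = 10
    seed: int = 0
    mode: str = "random_halves"
    group_key: str | None = None

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.mode not in ("random_halves", "by_group"):
            raise ValueError("mode must be 'random_halves' or 'by_group'")
        if self.mode == "by_group" and self.group_key is None:
            raise ValueError("by_group mode requires a group_key")


@dataclass
class RepetitionResult:
    P_c: float
    S_c: float
    R_c: float
    w_A: np.ndarray
    w_B: np.ndarray
    metrics_A: ClassifierMetrics
    metrics_B: ClassifierMetrics
    subjects_A: tuple = ()
    subjects_B: tuple = ()


@dataclass
class RobustnessReport:
    """Per-repetition (P, S, R) triples and their aggregates."""

    per_repetition: list
    P_mean: float
    S_mean: float
    R_mean: float
    P_se: float
    S_se: float
    R_se: float
    hyperparameters: dict = field(default_factory=dict)

    @classmethod
    def from_repetitions(cls, reps, hyperparameters=None) -> "RobustnessReport":
        P = np.array([r.P_c for r in reps])
        S = np.array([r.S_c for r in reps])
        R = np.array([r.R_c for r in reps])

        def se(v):
            return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0

        return cls(per_repetition=list(reps),
                   P_mean=float(P.mean()), S_mean=float(S.mean()),
                   R_mean=float(R.mean()),
                   P_se=se(P), S_se=se(S), R_se=se(R),
                   hyperparameters=dict(hyperparameters or {}))

    def to_dict(self) -> dict:
        return {
            "P_mean": self.P_mean, "S_mean": self.S_mean,
            "R_mean": self.R_mean,
            "P_se": self.P_se, "S_se": self.S_se, "R_se": self.R_se,
            "per_repetition": [
                {"P_c": r.P_c, "S_c": r.S_c, "R_c": r.R_c,
                 "auroc_A": r.metrics_A.auroc, "auroc_B": r.metrics_B.auroc}
                for r in self.per_repetition],
            "hyperparameters": self.hyperparameters,
        }


def rescale_auroc(auroc: float) -> float:
    """Map AUROC in [0, 1] to P = 2*AUROC - 1 in [-1, 1] (0 = chance)."""
    if not 0.0 <= auroc <= 1.0:
        raise ValueError(f"AUROC {auroc} outside [0, 1]")
    return 2.0 * auroc - 1.0


def disjoint_split(subject_table: pd.DataFrame, plan: SplitPlan,
                   repetition: int) -> tuple:
    """Subject ids of the two disjoint sides for one repetition.

    random_halves: class-stratified equal halves (to within one subject per
    class), resampled independently per repetition with seed
    ``plan.seed + repetition``.  by_group: side A is the repetition-th group
    (sorted order), side B everything else.
    """
    if not 0 <= repetition:
        raise ValueError("repetition must be non-negative")
    ids = subject_table["subject_id"].to_numpy()
    labels = subject_table["label"].to_numpy()
    if plan.mode == "random_halves":
        for cls in np.unique(labels):
            if (labels == cls).sum() < 2:
                raise ValueError(
                    "random_halves needs at least 2 subjects per class")
        rng = np.random.default_rng(plan.seed + repetition)
        side_A, side_B = [], []
        extra_to_A = True  # alternate the odd subject so |A| == |B| (+/-1)
        for cls in np.unique(labels):
            members = ids[labels == cls]
            perm = rng.permutation(members)
            half = len(perm) // 2
            if len(perm) % 2 and extra_to_A:
                half += 1
            if len(perm) % 2:
                extra_to_A = not extra_to_A
            side_A.extend(perm[:half])
            side_B.extend(perm[half:])
        return tuple(side_A), tuple(side_B)

    if "group" not in subject_table.columns:
        raise ValueError("subject table has no 'group' column for by_group mode")
    groups = subject_table["group"].to_numpy()
    uniq = sorted(pd.unique(groups))
    if repetition >= len(uniq):
        raise ValueError(f"repetition {repetition} exceeds the "
                         f"{len(uniq)} available groups")
    g = uniq[repetition]
    in_A = groups == g
    side_A = tuple(ids[in_A])
    side_B = tuple(ids[~in_A])
    for name, sel in (("A", in_A), ("B", ~in_A)):
        if len(np.unique(labels[sel])) < 2:
            raise ValueError(
                f"by_group split leaves side {name} with a single class")
    return side_A, side_B


def coefficient_similarity(w_A: np.ndarray, w_B: np.ndarray) -> float:
    """Spearman rank correlation of two coefficient vectors (midranks)."""
    w_A = np.asarray(w_A, dtype=float)
    w_B = np.asarray(w_B, dtype=float)
    if w_A.shape != w_B.shape or w_A.size < 2:
        raise ValueError("coefficient vectors must share a length >= 2")
    if np.ptp(w_A) == 0 or np.ptp(w_B) == 0:
        warnings.warn("constant coefficient vector: similarity undefined, "
                      "returning 0", stacklevel=2)
        return 0.0
    rho = stats.spearmanr(w_A, w_B).statistic
    return float(rho)


def _derive_seed(base: int, repetition: int, side: int) -> int:
    return int(np.random.SeedSequence(
        (base, repetition, side)).generate_state(1)[0] % (2 ** 31))


def evaluate_robustness(pipeline_factory, dataset: FeatureDataset,
                        plan: SplitPlan, hyperparameters: dict | None = None,
                        audit: list | None = None) -> RobustnessReport:
    """Run the full repeated disjoint-split evaluation for one pipeline.

    ``pipeline_factory(seed)`` must return a fresh, untrained pipeline (a new
    SIRT model is trained for each side of each split).  All windows of a
    subject travel with the subject, so no subject contributes to both the
    training and the test side of any direction.  ``audit``, if given, is
    appended one record per repetition with the subject ids on each side.
    """
    table = dataset.subject_table()
    reps = []
    for c in range(plan.repetitions):
        ids_A, ids_B = disjoint_split(table, plan, c)
        if set(ids_A) & set(ids_B):
            raise AssertionError("split sides overlap")  # pragma: no cover
        if audit is not None:
            audit.append({"repetition": c, "side_A": tuple(ids_A),
                          "side_B": tuple(ids_B)})
        data = {"A": dataset.subset(ids_A), "B": dataset.subset(ids_B)}
        out = {}
        for side_i, (train_key, test_key) in enumerate((("A", "B"),
                                                        ("B", "A"))):
            tr, te = data[train_key], data[test_key]
            pipe = pipeline_factory(seed=_derive_seed(plan.seed, c, side_i))
            try:
                pipe.fit(tr.X, tr.y, tr.ages)
            except Exception as exc:
                raise RuntimeError(
                    f"training failed in repetition {c} "
                    f"(trained on side {train_key})") from exc
            probs = pipe.predict_proba(te.X)
            preds = predict_subjects(probs, te.subject_ids, te.y)
            out[train_key] = (np.asarray(pipe.coef_, dtype=float).copy(),
                              evaluate(preds))
        w_A, metrics_A = out["A"]
        w_B, metrics_B = out["B"]
        P_c = (rescale_auroc(metrics_A.auroc)
               + rescale_auroc(metrics_B.auroc)) / 2.0
        S_c = coefficient_similarity(w_A, w_B)
        reps.append(RepetitionResult(
            P_c=P_c, S_c=S_c, R_c=P_c * S_c, w_A=w_A, w_B=w_B,
            metrics_A=metrics_A, metrics_B=metrics_B,
            subjects_A=tuple(ids_A), subjects_B=tuple(ids_B)))
    return RobustnessReport.from_repetitions(reps, hyperparameters)


def grid_search(dataset: FeatureDataset, grid=None,
                plan: SplitPlan | None = None, sirt=None,
                pipeline_kwargs: dict | None = None) -> list:
    """One robustness report per regularization value.

    The identical split sequence (fixed by ``plan.seed``) is reused across
    grid values, making the reports a paired comparison; the SIRT stage,
    which does not depend on the classifier's regularization, is trained once
    per (repetition, side) and shared across the grid.
    """
    from .pipeline import make_pipeline_factory

    grid = list(grid if grid is not None else DEFAULT_C_GRID)
    if not grid:
        raise ValueError("regularization grid is empty")
    plan = plan or SplitPlan()
    sirt_cache: dict = {}
    reports = []
    for C_reg in grid:
        factory = make_pipeline_factory(C_reg, sirt=sirt,
                                        sirt_cache=sirt_cache,
                                        **(pipeline_kwargs or {}))
        reports.append(evaluate_robustness(
            factory, dataset, plan,
            hyperparameters={"C_reg": C_reg,
                             "sirt_enabled": sirt is not None}))
    return reports


def select_model(reports, criterion: str = "robustness") -> RobustnessReport:
    """Pick the report maximizing R_mean ('robustness') or P_mean
    ('predictivity'); exact ties go to the stronger regularization
    (smaller C_reg)."""
    if not reports:
        raise ValueError("no reports to select from")
    if criterion == "robustness":
        key = lambda r: r.R_mean
    elif criterion == "predictivity":
        key = lambda r: r.P_mean
    else:
        raise ValueError("criterion must be 'robustness' or 'predictivity'")
    best = reports[0]
    for r in reports[1:]:
        k, kb = key(r), key(best)
        if k > kb:
            best = r
        elif k == kb:
            c = r.hyperparameters.get("C_reg", np.inf)
            cb = best.hyperparameters.get("C_reg", np.inf)
            if c < cb:
                best = r
    return best


def sweep_summary(reports) -> pd.DataFrame:
    """Tidy sweep table (one row per grid value): C_reg, P/S/R means and SEs."""
    rows = [{
        "C_reg": r.hyperparameters.get("C_reg"),
        "sirt_enabled": r.hyperparameters.get("sirt_enabled"),
        "P_mean": r.P_mean, "P_se": r.P_se,
        "S_mean": r.S_mean, "S_se": r.S_se,
        "R_mean": r.R_mean, "R_se": r.R_se,
        "auroc_mean": (r.P_mean + 1) / 2.0,
    } for r in reports]
    return pd.DataFrame(rows)
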