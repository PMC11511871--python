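"""Configuration-driven end-to-end runs.

``run_pipeline`` binds the stages — simulate (or ingest) -> features ->
regularization sweep with robustness evaluation -> model selection (both
criteria, side by side) -> interpretation exports — into one reproducible
run: every artifact is traceable to the config and seed recorded in the run
manifest, and re-running the same config reproduces all deterministic
outputs bit-exactly.  The sweep and interpretation stages are standalone
helpers so the CLI can run them individually from a saved feature store.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (CohortConfig, GroundTruthSignature, SignatureEntry,
                     generate_cohort)
from .data import FeatureDataset, extract_features
from .features import AugmentConfig, MultitaperConfig
from .interpretation import (average_profiles, band_aggregate,
                             export_brainview_data, export_chord_data,
                             frequency_profile, logit_covariate_correlations,
                             top_fraction_mask)
from .io import (cohort_metadata, load_cohort_hdf5, load_features_hdf5,
                 save_cohort_hdf5, save_features_hdf5)
from .pipeline import make_pipeline_factory
from .robustness import (DEFAULT_C_GRID, RobustnessReport, SplitPlan,
                         disjoint_split, grid_search, select_model,
                         sweep_summary)
from .sirt import SIRTConfig

__all__ = ["RunConfig", "run_pipeline", "sweep_stage", "interpret_stage",
           "load_coefficients_hdf5"]

log = logging.getLogger("eegrobust")


@dataclass
class RunConfig:
    """Everything one run needs; nested configs use the module defaults."""

    output_dir: str = "eegrobust_run"
    seed: int = 0
    cohort: CohortConfig | None = None          # simulate when set
    cohort_h5: str | None = None                # ... or ingest from HDF5
    features_h5: str | None = None              # ... or start from features
    multitaper: MultitaperConfig = field(default_factory=MultitaperConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    sirt: SIRTConfig | None = field(default_factory=SIRTConfig)
    compare_without_sirt: bool = False
    grid: tuple = DEFAULT_C_GRID
    split: SplitPlan = field(default_factory=SplitPlan)
    top_fraction: float = 0.05
    covariates: tuple = ("age",)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw: dict = {}
        for key in ("output_dir", "seed", "cohort_h5", "features_h5",
                    "compare_without_sirt", "top_fraction"):
            if key in raw:
                kw[key] = raw[key]
        if "grid" in raw:
            kw["grid"] = tuple(float(c) for c in raw["grid"])
        if "covariates" in raw:
            kw["covariates"] = tuple(raw["covariates"])
        if "cohort" in raw and raw["cohort"] is not None:
            cd = dict(raw["cohort"])
            if "signature" in cd and isinstance(cd["signature"], list):
                cd["signature"] = GroundTruthSignature(tuple(
                    SignatureEntry(e["channel_a"], e["channel_b"],
                                   tuple(e["band"]), e["effect"])
                    for e in cd["signature"]))
            if "channel_labels" in cd:
                cd["channel_labels"] = tuple(cd["channel_labels"])
            if "age_range" in cd:
                cd["age_range"] = tuple(cd["age_range"])
            kw["cohort"] = CohortConfig(**cd)
        if "multitaper" in raw:
            kw["multitaper"] = MultitaperConfig(**raw["multitaper"])
        if "augment" in raw:
            kw["augment"] = AugmentConfig(**raw["augment"])
        if "sirt" in raw:
            sd = raw["sirt"]
            if sd is None or sd.get("enabled", True) is False:
                kw["sirt"] = None
            else:
                sd = {k: v for k, v in sd.items() if k != "enabled"}
                if "encoder_hidden_dims" in sd:
                    sd["encoder_hidden_dims"] = tuple(sd["encoder_hidden_dims"])
                kw["sirt"] = SIRTConfig(**sd)
        if "split" in raw:
            kw["split"] = SplitPlan(**raw["split"])
        return cls(**kw)

    def canonical(self) -> dict:
        """JSON-able view of the scientific configuration (the output path
        is excluded: it does not affect what gets computed)."""
        def conv(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: conv(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, (tuple, list)):
                return [conv(v) for v in o]
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return o
        d = conv(self)
        d.pop("output_dir", None)
        return d


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _save_coefficients_hdf5(report: RobustnessReport, path) -> None:
    """Per-repetition coefficient vectors (both sides) of one report."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["C_reg"] = report.hyperparameters.get("C_reg", float("nan"))
        f.attrs["sirt_enabled"] = bool(
            report.hyperparameters.get("sirt_enabled", False))
        for c, rep in enumerate(report.per_repetition):
            g = f.create_group(f"repetition{c:02d}")
            g.create_dataset("w_A", data=rep.w_A, track_times=False)
            g.create_dataset("w_B", data=rep.w_B, track_times=False)


def load_coefficients_hdf5(path) -> list:
    """Flat list of coefficient vectors saved by the sweep stage."""
    import h5py

    vectors = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            vectors.append(np.asarray(f[key]["w_A"]))
            vectors.append(np.asarray(f[key]["w_B"]))
    return vectors


def _collect_subject_logits(dataset: FeatureDataset, plan: SplitPlan,
                            repetition: int, factory) -> pd.DataFrame:
    """Test-fold subject predictions for one repetition (each subject
    appears exactly once as a test subject across the two directions)."""
    from .classifier import predict_subjects
    from .robustness import _derive_seed

    table = dataset.subject_table()
    ids_A, ids_B = disjoint_split(table, plan, repetition)
    rows = []
    for side_i, (tr_ids, te_ids) in enumerate(((ids_A, ids_B),
                                               (ids_B, ids_A))):
        tr, te = dataset.subset(tr_ids), dataset.subset(te_ids)
        pipe = factory(seed=_derive_seed(plan.seed, repetition, side_i))
        pipe.fit(tr.X, tr.y, tr.ages)
        preds = predict_subjects(pipe.predict_proba(te.X), te.subject_ids,
                                 te.y)
        rows.extend({"subject_id": p.subject_id,
                     "probability": p.probability,
                     "logit": p.logit, "label": p.label} for p in preds)
    return pd.DataFrame(rows)


def sweep_stage(dataset: FeatureDataset, config: RunConfig,
                out: Path) -> tuple:
    """Grid search + selection; writes sweep.csv, reports.json,
    selection.json and the selected model's coefficients.h5.
    Returns (chosen-by-criterion dict, artifacts dict)."""
    plan = config.split
    log.info("robustness sweep over %d regularization values "
             "(%d repetitions)", len(config.grid), plan.repetitions)
    artifacts: dict = {}
    sweeps = {"primary": grid_search(dataset, config.grid, plan,
                                     sirt=config.sirt)}
    if config.compare_without_sirt and config.sirt is not None:
        log.info("comparison sweep without SIRT")
        sweeps["no_sirt"] = grid_search(dataset, config.grid, plan, sirt=None)
    summary = pd.concat([sweep_summary(r) for r in sweeps.values()],
                        ignore_index=True)
    summary.to_csv(out / "sweep.csv", index=False)
    artifacts["sweep"] = "sweep.csv"
    with open(out / "reports.json", "w") as fh:
        json.dump({k: [r.to_dict() for r in v] for k, v in sweeps.items()},
                  fh, indent=2)
    artifacts["reports"] = "reports.json"

    chosen = {crit: select_model(sweeps["primary"], crit)
              for crit in ("robustness", "predictivity")}
    selection = {crit: {"C_reg": rep.hyperparameters.get("C_reg"),
                        "P_mean": rep.P_mean, "S_mean": rep.S_mean,
                        "R_mean": rep.R_mean}
                 for crit, rep in chosen.items()}
    with open(out / "selection.json", "w") as fh:
        json.dump(selection, fh, indent=2)
    artifacts["selection"] = "selection.json"
    _save_coefficients_hdf5(chosen["robustness"], out / "coefficients.h5")
    artifacts["coefficients"] = "coefficients.h5"
    return chosen, artifacts


def interpret_stage(dataset: FeatureDataset, vectors, hyperparameters: dict,
                    config: RunConfig, out: Path) -> dict:
    """Averaged-profile views and covariate correlations; returns artifacts."""
    artifacts: dict = {}
    profile = average_profiles(vectors, dataset.index,
                               {"criterion": "robustness",
                                **hyperparameters})
    frequency_profile(profile).to_csv(out / "frequency_profile.csv")
    artifacts["frequency_profile"] = "frequency_profile.csv"
    band_aggregate(profile).to_csv(out / "band_aggregate.csv", index=False)
    artifacts["band_aggregate"] = "band_aggregate.csv"
    for sign in ("positive", "negative"):
        mask = top_fraction_mask(profile.w, config.top_fraction, sign)
        export_chord_data(profile, mask).to_csv(
            out / f"chord_{sign}.csv", index=False)
        artifacts[f"chord_{sign}"] = f"chord_{sign}.csv"
        try:
            export_brainview_data(profile, mask).to_csv(
                out / f"brainview_{sign}.csv", index=False)
            artifacts[f"brainview_{sign}"] = f"brainview_{sign}.csv"
        except KeyError as exc:
            log.warning("skipping brain-view export: %s", exc)

    # subject predictions + logit-covariate correlations for one
    # seed-chosen repetition
    plan = config.split
    rep_idx = int(np.random.default_rng(config.seed).integers(
        plan.repetitions))
    factory = make_pipeline_factory(
        hyperparameters.get("C_reg", config.grid[0]), sirt=config.sirt)
    logits = _collect_subject_logits(dataset, plan, rep_idx, factory)
    logits.to_csv(out / "subject_predictions.csv", index=False)
    artifacts["subject_predictions"] = "subject_predictions.csv"
    table = dataset.subject_table().merge(
        logits[["subject_id", "logit"]], on="subject_id")
    cov_cols = [c for c in config.covariates if c in table.columns]
    if cov_cols:
        rows = logit_covariate_correlations(table["logit"].to_numpy(),
                                            table[cov_cols])
        pd.DataFrame([dataclasses.asdict(r) for r in rows]).to_csv(
            out / "correlations.csv", index=False)
        artifacts["correlations"] = "correlations.csv"
    return artifacts


def _load_or_build_dataset(config: RunConfig, out: Path,
                           artifacts: dict) -> FeatureDataset:
    if config.features_h5 is not None:
        p = Path(config.features_h5)
        if not p.exists():
            raise FileNotFoundError(f"features file not found: {p}")
        log.info("loading features from %s", p)
        return load_features_hdf5(p)
    if config.cohort_h5 is not None:
        p = Path(config.cohort_h5)
        if not p.exists():
            raise FileNotFoundError(f"cohort file not found: {p}")
        log.info("loading cohort from %s", p)
        cohort = load_cohort_hdf5(p)
    else:
        ccfg = config.cohort or CohortConfig(seed=config.seed)
        log.info("simulating cohort (%d+%d subjects)",
                 ccfg.n_pos_subjects, ccfg.n_neg_subjects)
        cohort = generate_cohort(ccfg)
        save_cohort_hdf5(cohort, out / "cohort.h5")
        cohort_metadata(cohort).to_csv(out / "metadata.csv", index=False)
        ccfg.signature.to_json(out / "signature.json")
        artifacts.update(cohort="cohort.h5", metadata="metadata.csv",
                         signature="signature.json")
    log.info("extracting multitaper features")
    dataset = extract_features(cohort, config.multitaper, config.augment)
    save_features_hdf5(dataset, out / "features.h5")
    artifacts["features"] = "features.h5"
    return dataset


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run; returns a manifest of the artifacts written."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    dataset = _load_or_build_dataset(config, out, artifacts)
    chosen, sweep_artifacts = sweep_stage(dataset, config, out)
    artifacts.update(sweep_artifacts)

    best = chosen["robustness"]
    vectors = [w for rep in best.per_repetition for w in (rep.w_A, rep.w_B)]
    artifacts.update(interpret_stage(
        dataset, vectors,
        {"C_reg": best.hyperparameters.get("C_reg")}, config, out))

    cfg_json = json.dumps(config.canonical(), sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "eegrobust_version": __version__,
        "artifacts": artifacts,
        "artifact_sha256": {
            name: _sha256_file(out / fname)
            for name, fname in artifacts.items()
            if fname.endswith((".csv", ".json"))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
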