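"""Disjoint-split robustness evaluation: P, S, R and model selection."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import eegrobust as er
from eegrobust.robustness import RepetitionResult, RobustnessReport


def _noise_dataset(n_subj=24, per=8, n_chan=5, n_freq=4, seed=0, signal=0.0):
    """Window-level gamma-feature dataset with optional 1-feature signal."""
    idx = er.FeatureIndex(
        channel_labels=tuple(f"c{i}" for i in range(n_chan)),
        frequencies=tuple(float(f) for f in range(1, n_freq + 1)))
    p = len(idx)
    rng = np.random.default_rng(seed)
    rows, y, sid, ages = [], [], [], []
    for s in range(n_subj):
        lab = s % 2
        for _ in range(per):
            x = rng.gamma(2.0, 1.0, p)
            if signal:
                x[0] *= np.exp(signal * (2 * lab - 1))
            rows.append(x)
            y.append(lab)
            sid.append(f"s{s}")
            ages.append(50.0 + s)
    return er.FeatureDataset(X=np.asarray(rows), y=np.asarray(y),
                             subject_ids=np.asarray(sid),
                             ages=np.asarray(ages), index=idx)


class TestRescaleAuroc:
    @pytest.mark.parametrize("auroc,expected", [
        (0.5, 0.0), (1.0, 1.0), (0.69, 0.38), (0.0, -1.0)])
    def test_linear_rescale(self, auroc, expected):
        assert er.rescale_auroc(auroc) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            er.rescale_auroc(1.2)


class TestDisjointSplit:
    @staticmethod
    def _table(n=10):
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "label": [i % 2 for i in range(n)]})

    def test_random_halves_partition(self):
        plan = er.SplitPlan(repetitions=3, seed=1)
        a, b = er.disjoint_split(self._table(10), plan, 0)
        assert len(a) == len(b) == 5
        assert not set(a) & set(b)
        assert set(a) | set(b) == set(self._table(10)["subject_id"])

    def test_halves_are_class_stratified(self):
        table = self._table(20)
        plan = er.SplitPlan(seed=3)
        a, _ = er.disjoint_split(table, plan, 2)
        labels = table.set_index("subject_id").loc[list(a), "label"]
        assert sorted(labels.value_counts()) == [5, 5]

    def test_deterministic_per_seed_and_repetition(self):
        plan = er.SplitPlan(seed=4)
        t = self._table(12)
        assert er.disjoint_split(t, plan, 1) == er.disjoint_split(t, plan, 1)
        assert er.disjoint_split(t, plan, 1) != er.disjoint_split(t, plan, 2)

    def test_by_group_selects_one_group(self):
        table = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(8)],
            "label": [0, 1] * 4,
            "group": ["g1", "g1", "g1", "g1", "g2", "g2", "g3", "g3"]})
        plan = er.SplitPlan(mode="by_group", group_key="group", seed=0)
        a, b = er.disjoint_split(table, plan, 0)
        assert set(a) == {"s0", "s1", "s2", "s3"}  # study g1 exactly
        assert set(b) == {"s4", "s5", "s6", "s7"}

    def test_by_group_single_class_side_rejected(self):
        table = pd.DataFrame({
            "subject_id": ["a", "b", "c", "d"],
            "label": [1, 1, 0, 1],
            "group": ["g1", "g1", "g2", "g2"]})
        plan = er.SplitPlan(mode="by_group", group_key="group")
        with pytest.raises(ValueError, match="single class"):
            er.disjoint_split(table, plan, 0)

    def test_too_few_subjects_rejected(self):
        plan = er.SplitPlan()
        with pytest.raises(ValueError):
            er.disjoint_split(self._table(3), plan, 0)


class TestCoefficientSimilarity:
    def test_identical_and_negated(self, rng):
        w = rng.standard_normal(40)
        assert er.coefficient_similarity(w, w) == pytest.approx(1.0)
        assert er.coefficient_similarity(w, -w) == pytest.approx(-1.0)

    def test_hand_checked_spearman(self):
        assert er.coefficient_similarity(
            [1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_matches_scipy_on_random_vectors(self, rng):
        a, b = rng.standard_normal(100), rng.standard_normal(100)
        assert er.coefficient_similarity(a, b) == pytest.approx(
            stats.spearmanr(a, b).statistic)

    def test_constant_vector_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert er.coefficient_similarity(np.ones(5),
                                             np.arange(5.0)) == 0.0


class TestReportArithmetic:
    @staticmethod
    def _rep(P, S):
        m = er.ClassifierMetrics(0.5, 0.5, 0.5, 0.5)
        return RepetitionResult(P_c=P, S_c=S, R_c=P * S,
                                w_A=np.zeros(2), w_B=np.zeros(2),
                                metrics_A=m, metrics_B=m)

    def test_two_repetition_mean(self):
        """(P, S) of (0.4, 0.5) and (0.6, 0.5) gives R_mean 0.25."""
        report = RobustnessReport.from_repetitions(
            [self._rep(0.4, 0.5), self._rep(0.6, 0.5)])
        assert report.R_mean == pytest.approx(0.25)
        assert report.P_mean == pytest.approx(0.5)
        assert report.S_mean == pytest.approx(0.5)

    def test_aggregates_match_direct_recomputation(self, rng):
        reps = [self._rep(p, s) for p, s in rng.uniform(-1, 1, (6, 2))]
        report = RobustnessReport.from_repetitions(reps)
        R = np.array([r.R_c for r in reps])
        assert report.R_mean == pytest.approx(R.mean())
        assert report.R_se == pytest.approx(R.std(ddof=1) / np.sqrt(len(R)))
        for r in reps:
            assert r.R_c == r.P_c * r.S_c


class TestEvaluateRobustness:
    def test_null_data_R_within_two_se_of_zero(self):
        """Random labels on pure noise features: R_mean compatible with 0."""
        dataset = _noise_dataset(signal=0.0, seed=5)
        plan = er.SplitPlan(repetitions=6, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = er.evaluate_robustness(
                er.make_pipeline_factory(1e-3), dataset, plan)
        assert abs(report.R_mean) <= 2 * max(report.R_se, 1e-3)

    def test_planted_signal_recovered(self):
        dataset = _noise_dataset(signal=1.5, seed=6, n_subj=30)
        plan = er.SplitPlan(repetitions=4, seed=2)
        report = er.evaluate_robustness(
            er.make_pipeline_factory(1e-2), dataset, plan)
        assert report.P_mean > 0.3
        # the signal feature dominates every fitted coefficient vector
        for rep in report.per_repetition:
            assert np.argmax(np.abs(rep.w_A)) == 0
            assert np.argmax(np.abs(rep.w_B)) == 0

    def test_subject_disjointness_audited(self):
        dataset = _noise_dataset(seed=7)
        plan = er.SplitPlan(repetitions=3, seed=1)
        audit = []
        er.evaluate_robustness(er.make_pipeline_factory(1e-3), dataset, plan,
                               audit=audit)
        assert len(audit) == 3
        for record in audit:
            assert not set(record["side_A"]) & set(record["side_B"])


class TestGridSearchAndSelection:
    def test_default_grid_has_eight_reports(self):
        dataset = _noise_dataset(seed=8, n_subj=12, per=4, n_chan=4, n_freq=3)
        plan = er.SplitPlan(repetitions=2, seed=0)
        reports = er.grid_search(dataset, plan=plan, sirt=None)
        assert len(reports) == 8
        assert [r.hyperparameters["C_reg"] for r in reports] == [
            10.0 ** -k for k in range(5, 13)]

    def test_single_value_grid(self):
        dataset = _noise_dataset(seed=8, n_subj=12, per=4, n_chan=4, n_freq=3)
        reports = er.grid_search(dataset, grid=[1e-6],
                                 plan=er.SplitPlan(repetitions=2, seed=0))
        assert len(reports) == 1
        assert reports[0].hyperparameters == {"C_reg": 1e-6,
                                              "sirt_enabled": False}

    @staticmethod
    def _fake_reports(triples):
        out = []
        for C, P, R in triples:
            rep = RobustnessReport(per_repetition=[], P_mean=P, S_mean=0.0,
                                   R_mean=R, P_se=0, S_se=0, R_se=0,
                                   hyperparameters={"C_reg": C})
            out.append(rep)
        return out

    def test_select_argmax_robustness(self):
        reports = self._fake_reports([(1e-5, 0.5, 0.1), (1e-6, 0.4, 0.3),
                                      (1e-7, 0.3, 0.2)])
        assert er.select_model(reports, "robustness") is reports[1]
        assert er.select_model(reports, "predictivity") is reports[0]

    def test_tie_breaks_toward_stronger_regularization(self):
        reports = self._fake_reports([(1e-5, 0.5, 0.3), (1e-8, 0.5, 0.3)])
        chosen = er.select_model(reports, "robustness")
        assert chosen.hyperparameters["C_reg"] == 1e-8

    def test_single_report_selected(self):
        reports = self._fake_reports([(1e-5, 0.1, 0.1)])
        assert er.select_model(reports) is reports[0]
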