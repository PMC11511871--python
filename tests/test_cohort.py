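"""Synthetic cohort generator: determinism, planted effects, null behavior."""

import numpy as np
import pytest
from scipy import stats

import eegrobust as er


def _mean_band_logpower(cohort, channels, band, mt=None):
    """Per-subject mean log power over a frequency band at given channels."""
    mt = mt or er.MultitaperConfig()
    freqs = mt.frequencies
    sel = (freqs >= band[0]) & (freqs <= band[1])
    out = {0: [], 1: []}
    for es in cohort:
        vals = []
        for ep in es.epochs:
            S = er.multitaper_cross_spectrum(np.asarray(ep, float), mt,
                                             es.sample_rate)
            vals.append(np.mean([np.log(S[c, c, sel]).mean()
                                 for c in channels]))
        out[es.diagnosis].append(np.mean(vals))
    return out


class TestDeterminismAndStructure:
    def test_same_seed_byte_identical(self, labels8):
        cfgs = [er.CohortConfig(n_pos_subjects=3, n_neg_subjects=2,
                                epochs_per_subject=2, channel_labels=labels8,
                                seed=7) for _ in range(2)]
        c1, c2 = er.generate_cohort(cfgs[0]), er.generate_cohort(cfgs[1])
        for a, b in zip(c1, c2):
            assert a.subject_id == b.subject_id
            assert a.diagnosis == b.diagnosis
            assert a.age == b.age
            np.testing.assert_array_equal(np.stack(a.epochs),
                                          np.stack(b.epochs))

    def test_counts_labels_and_finiteness(self, small_cohort):
        cfg, cohort = small_cohort
        assert len(cohort) == cfg.n_pos_subjects + cfg.n_neg_subjects
        assert sum(es.diagnosis for es in cohort) == cfg.n_pos_subjects
        for es in cohort:
            assert len(es.epochs) == cfg.epochs_per_subject
            assert all(np.all(np.isfinite(e)) for e in es.epochs)
            assert es.channel_labels == cfg.channel_labels

    def test_age_class_correlation_hits_target(self, labels8):
        cfg = er.CohortConfig(n_pos_subjects=150, n_neg_subjects=50,
                              epochs_per_subject=1, channel_labels=labels8,
                              age_class_correlation=0.3, seed=3)
        cohort = er.generate_cohort(cfg)
        ages = np.array([es.age for es in cohort])
        y = np.array([es.diagnosis for es in cohort])
        assert abs(np.corrcoef(ages, y)[0, 1] - 0.3) < 0.12
        lo, hi = cfg.age_range
        assert ages.min() >= lo and ages.max() <= hi

    def test_invalid_configs_rejected(self, labels8):
        with pytest.raises(ValueError):
            er.CohortConfig(n_pos_subjects=0, channel_labels=labels8)
        with pytest.raises(ValueError):
            er.CohortConfig(channel_labels=labels8, sample_rate=999.5,
                            epoch_length=1.0, n_pos_subjects=2,
                            n_neg_subjects=2)
        with pytest.raises(ValueError):
            er.CohortConfig(channel_labels=labels8,
                            age_class_correlation=1.5)


class TestSpectralShape:
    def test_null_cohort_power_decays_as_one_over_f(self, labels8):
        """Averaged log-log spectrum slope within +/-0.3 of -alpha for a
        signature-free cohort."""
        cfg = er.CohortConfig(n_pos_subjects=6, n_neg_subjects=6,
                              epochs_per_subject=6, channel_labels=labels8,
                              signature=er.GroundTruthSignature(()),
                              background_exponent=1.0, seed=2)
        mt = er.MultitaperConfig()
        freqs = mt.frequencies
        acc = np.zeros(len(freqs))
        for es in er.generate_cohort(cfg):
            for ep in es.epochs[:3]:
                S = er.multitaper_cross_spectrum(np.asarray(ep, float), mt,
                                                 es.sample_rate)
                acc += np.einsum("iif->f", S)
        slope = np.polyfit(np.log(freqs), np.log(acc), 1)[0]
        assert abs(slope - (-1.0)) < 0.3


class TestPlantedEffects:
    def test_null_signature_gives_no_group_difference(self, labels8):
        """Zero-effect signature: broadband two-sample test non-significant
        at alpha = 0.01."""
        cfg = er.CohortConfig(n_pos_subjects=30, n_neg_subjects=30,
                              epochs_per_subject=3, channel_labels=labels8,
                              signature=er.GroundTruthSignature(()), seed=11)
        vals = _mean_band_logpower(er.generate_cohort(cfg),
                                   range(len(labels8)), (1, 55))
        _, p = stats.ttest_ind(vals[1], vals[0], equal_var=False)
        assert p > 0.01

    def test_planted_gamma_offset_detected_by_welch(self, labels8):
        """+0.5 log-power gamma offset at two posterior channels, 40+40
        subjects: Welch test rejects at alpha = 0.001.  Interior band bins
        are used because the +/-3 Hz taper bandwidth dilutes the band edges;
        nuisance scales are set low so this checks the planted offset, not
        the nuisance model."""
        o1, o2 = labels8.index("O1"), labels8.index("O2")
        sig = er.GroundTruthSignature((
            er.SignatureEntry(o1, o1, (31, 55), +0.5),
            er.SignatureEntry(o2, o2, (31, 55), +0.5),
            er.SignatureEntry(2, 3, (5, 7), -0.5)))
        cfg = er.CohortConfig(n_pos_subjects=40, n_neg_subjects=40,
                              epochs_per_subject=8, channel_labels=labels8,
                              signature=sig, subject_variance_scale=0.15,
                              exponent_jitter=0.02, band_variance_scale=0.05,
                              seed=5)
        vals = _mean_band_logpower(er.generate_cohort(cfg), (o1, o2),
                                   (34, 52))
        t, p = stats.ttest_ind(vals[1], vals[0], equal_var=False)
        assert t > 0
        assert p < 1e-3

    def test_planted_cross_power_elevates_favored_class(self, labels8):
        """A negative-class theta connectivity entry raises that pair's
        cross-power in the negative class."""
        a, b = labels8.index("T7"), labels8.index("T8")
        sig = er.GroundTruthSignature((
            er.SignatureEntry(a, b, (5, 7), -0.8),
            er.SignatureEntry(0, 0, (31, 55), +0.3)))
        cfg = er.CohortConfig(n_pos_subjects=25, n_neg_subjects=25,
                              epochs_per_subject=4, channel_labels=labels8,
                              signature=sig, subject_variance_scale=0.1,
                              exponent_jitter=0.02, band_variance_scale=0.05,
                              seed=9)
        mt = er.MultitaperConfig()
        freqs = mt.frequencies
        sel = (freqs >= 5) & (freqs <= 7)
        out = {0: [], 1: []}
        for es in er.generate_cohort(cfg):
            vals = [np.log(er.multitaper_cross_spectrum(
                np.asarray(ep, float), mt, es.sample_rate)[a, b, sel]).mean()
                for ep in es.epochs]
            out[es.diagnosis].append(np.mean(vals))
        assert np.mean(out[0]) > np.mean(out[1])


class TestSignatureAsProfile:
    def test_empty_signature_is_all_zero(self, tiny_index):
        prof = er.signature_as_profile(er.GroundTruthSignature(()),
                                       tiny_index)
        assert not prof.w.any()

    def test_gamma_band_entry_covers_25_bins(self, labels8):
        idx = er.build_feature_index(labels8)
        sig = er.GroundTruthSignature((
            er.SignatureEntry(0, 1, (31, 55), +0.5),
            er.SignatureEntry(2, 3, (5, 7), -0.5)))
        prof = er.signature_as_profile(sig, idx)
        assert np.count_nonzero(prof.w > 0) == 25  # 1-Hz bins 31..55
        assert np.count_nonzero(prof.w < 0) == 3

    def test_disjoint_entries_union_support(self, labels8):
        idx = er.build_feature_index(labels8)
        e1 = er.SignatureEntry(0, 0, (10, 12), +1.0)
        e2 = er.SignatureEntry(1, 2, (20, 21), -1.0)
        both = er.signature_as_profile(
            er.GroundTruthSignature((e1, e2)), idx)
        assert np.count_nonzero(both.w) == 3 + 2

    def test_out_of_range_entry_rejected(self, tiny_index):
        sig = er.GroundTruthSignature((
            er.SignatureEntry(0, 5, (10, 10), +1.0),
            er.SignatureEntry(0, 1, (20, 20), -1.0)))
        with pytest.raises(ValueError):
            er.signature_as_profile(sig, tiny_index)


class TestSignatureSerialization:
    def test_json_roundtrip(self, tmp_path):
        sig = er.benchmarks.sparse_benchmark_signature(0.4)
        path = tmp_path / "sig.json"
        sig.to_json(path)
        assert er.GroundTruthSignature.from_json(path) == sig
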