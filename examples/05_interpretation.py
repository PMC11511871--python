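"""From averaged coefficients to interpretable association profiles.

Runs a quick sweep on a planted-signature cohort, averages the
robustness-selected coefficient vectors over all trained models, and derives
the standard views: per-frequency sums, band averages, the top-5% mask, and
plot-ready chord / brain-view tables.  Ends by checking how well the profile
recovers the planted truth.  Takes about a minute.
"""

import warnings

import numpy as np
from scipy import stats

import eegrobust as er

warnings.simplefilter("ignore")

config = er.CohortConfig(
    n_pos_subjects=20, n_neg_subjects=20, epochs_per_subject=4,
    channel_labels=er.benchmarks.BENCHMARK_CHANNELS,
    signature=er.benchmarks.dense_recovery_signature(effect=0.5),
    seed=2)
dataset = er.extract_features(
    er.generate_cohort(config),
    aug=er.AugmentConfig(extra_windows_neg_class=0))

reports = er.grid_search(dataset, plan=er.SplitPlan(repetitions=5, seed=3),
                         sirt=None)
best = er.select_model(reports, "robustness")
vectors = [w for rep in best.per_repetition for w in (rep.w_A, rep.w_B)]
profile = er.average_profiles(vectors, dataset.index,
                              {"criterion": "robustness"})
print(f"averaged {profile.provenance['n_models_averaged']} coefficient "
      f"vectors from the robustness-selected model "
      f"(C = {best.hyperparameters['C_reg']:g})")

fp = er.frequency_profile(profile)
print("\nstrongest per-frequency sums (positive = positive-class):")
print(fp.reindex(fp.abs().sort_values(ascending=False).index)
      .head(5).round(3).to_string())

mask_pos = er.top_fraction_mask(profile.w, 0.05, "positive")
chord = er.export_chord_data(profile, mask_pos)
print(f"\ntop-5% positive features: {mask_pos.sum()} "
      f"({(chord['kind'] == 'cross_power').sum()} cross-power arcs, "
      f"{(chord['kind'] == 'power').sum()} power segments)")
print("most frequent electrode pairs in the mask:")
print(chord.groupby(["electrode_a", "electrode_b"]).size()
      .sort_values(ascending=False).head(4).to_string())

brain = er.export_brainview_data(profile, mask_pos)
print(f"\nbrain-view rows (band-aggregated, 4 projections each): "
      f"{len(brain)}")

truth = er.signature_as_profile(config.signature, dataset.index)
rho = stats.spearmanr(profile.w, truth.w).statistic
overlap = int((mask_pos & (truth.w > 0)).sum())
print(f"\nrecovery vs planted truth: Spearman rho = {rho:.2f}; "
      f"{overlap}/{mask_pos.sum()} masked features lie on the planted "
      "positive support")
# High overlap means the chord/brain-view plots would be drawing the planted
# posterior-gamma contrast, not noise.
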