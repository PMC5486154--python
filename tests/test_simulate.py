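import numpy as np
import pytest
from scipy import stats

from ctleeg import (
    CohortSpec,
    extract_subject_features,
    generate_cohort,
    generate_subject,
    permute_cohort_labels,
    planted_truth,
    relieff_weights,
    similarity_profile,
)
from ctleeg.simulate import DEFAULT_ACTIVE, structured_cohort_spec, subject_patterns


class TestSpecValidation:
    def test_trial_count_must_balance_both_tasks(self):
        with pytest.raises(ValueError, match="multiple of 4"):
            CohortSpec(n_trials=10)

    def test_similarity_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="signature_similarity"):
            CohortSpec(signature_similarity=1.5)

    def test_negative_engagement_rejected(self):
        with pytest.raises(ValueError, match="engagement"):
            CohortSpec(engagement=-0.1)

    def test_active_pair_must_be_a_montage_pair(self):
        with pytest.raises(ValueError, match="not a montage symmetric pair"):
            CohortSpec(active_pairs_bands={"valence": ((("F3", "Cz"), "alpha"),)})

    def test_fs_below_gamma_nyquist_rejected(self):
        with pytest.raises(ValueError, match="fs"):
            CohortSpec(fs=80)


class TestGeneration:
    @pytest.fixture(scope="class")
    def small_spec(self):
        return CohortSpec(n_subjects=3, n_trials=8, fs=128, duration=8.0, seed=9)

    def test_same_seed_bit_identical(self, small_spec):
        a = generate_cohort(small_spec)
        b = generate_cohort(small_spec)
        for ta, tb in zip(a.trial_sets, b.trial_sets):
            np.testing.assert_array_equal(ta.signals, tb.signals)
            assert ta.labels.equals(tb.labels)

    def test_labels_exactly_balanced_per_task(self, small_spec):
        cohort = generate_cohort(small_spec)
        for ts in cohort.trial_sets:
            for task in ("valence", "arousal"):
                assert ts.labels[task].sum() == ts.n_trials // 2

    def test_shape_and_units(self, small_spec):
        ts = generate_cohort(small_spec).trial_sets[0]
        assert ts.signals.shape == (8, 30, 8 * 128)
        # microvolt-scale amplitudes, not volts
        assert 1.0 < ts.signals.std() < 1000.0

    def test_label_permutation_keeps_balance_and_signals(self, small_spec):
        cohort = generate_cohort(small_spec)
        permuted = permute_cohort_labels(cohort, np.random.default_rng(0))
        for a, b in zip(cohort.trial_sets, permuted.trial_sets):
            assert b.signals is a.signals or np.shares_memory(b.signals, a.signals)
            assert b.labels["valence"].sum() == 4


class TestPlantedTruth:
    def test_full_similarity_means_identical_patterns(self):
        spec = CohortSpec(n_subjects=3, signature_similarity=1.0, seed=3)
        truth = planted_truth(spec)
        corr = truth["pattern_correlation"]["valence"]
        assert np.allclose(corr.to_numpy(), 1.0)

    def test_zero_engagement_marked_poor(self):
        spec = CohortSpec(n_subjects=3, engagement=np.array([1.0, 0.0, 2.0]), seed=3)
        truth = planted_truth(spec)
        assert truth["transferability"] == {"S01": "good", "S02": "poor", "S03": "good"}

    def test_patterns_deterministic_and_unit_norm(self):
        spec = CohortSpec(n_subjects=4, signature_similarity=0.5, seed=8)
        p1 = subject_patterns(spec)
        p2 = subject_patterns(spec)
        for task in ("valence", "arousal"):
            np.testing.assert_array_equal(p1[task], p2[task])
            np.testing.assert_allclose(np.linalg.norm(p1[task], axis=1), 1.0)


class TestPlantedSignal:
    @pytest.fixture(scope="class")
    def class_conditional_dlat(self):
        """Mean DLAT per valence class over many trials of one subject."""
        spec = CohortSpec(
            n_subjects=1, n_trials=200, fs=128, duration=8.0,
            engagement=2.0, signature_similarity=1.0, seed=21,
        )
        ts = generate_subject(spec, 0)
        fm = extract_subject_features(ts, spec.montage, zscore=False)
        y = ts.task_labels("valence")
        mean_diff = fm.values[y == 1].mean(axis=0) - fm.values[y == 0].mean(axis=0)
        se = np.sqrt(
            fm.values[y == 1].var(axis=0) / (y == 1).sum()
            + fm.values[y == 0].var(axis=0) / (y == 0).sum()
        )
        return spec, fm, mean_diff, se

    def test_active_slots_carry_the_planted_sign(self, class_conditional_dlat):
        spec, fm, mean_diff, se = class_conditional_dlat
        patterns = subject_patterns(spec)["valence"][0]
        names = fm.feature_names
        for slot_idx, ((left, right), band) in enumerate(DEFAULT_ACTIVE["valence"]):
            col = names.index(f"{left}{right}_{band}")
            planted_sign = np.sign(patterns[slot_idx])
            assert np.sign(mean_diff[col]) == planted_sign
            assert abs(mean_diff[col]) > 3 * se[col]  # clearly nonzero

    def test_inactive_slots_have_zero_expectation(self, class_conditional_dlat):
        spec, fm, mean_diff, se = class_conditional_dlat
        active = {
            f"{l}{r}_{b}" for slots in DEFAULT_ACTIVE.values() for (l, r), b in slots
        }
        inactive = [i for i, n in enumerate(fm.feature_names) if n not in active]
        # class-conditional expectation is 0; allow 4 SE with a small slack
        z = np.abs(mean_diff[inactive]) / np.maximum(se[inactive], 1e-12)
        assert np.mean(z < 4) > 0.9
        assert np.max(np.abs(mean_diff[inactive])) < 0.5 * np.max(np.abs(mean_diff))


class TestSimilarityRecovery:
    def test_relieff_weight_similarity_tracks_planted_signatures(self):
        """In a high-SNR cohort the similarity ranking recovered from
        ReliefF weight correlations agrees with the planted signature
        overlap (Spearman >= 0.6 averaged over subjects and seeds).
        ReliefF weighting is blind to which hemisphere dominates, so the
        recoverable ordering is the magnitude overlap, not the signed
        pattern correlation."""
        rhos = []
        for seed in (0, 1, 2):
            spec = CohortSpec(
                n_subjects=6, n_trials=48, fs=128, duration=10.0, engagement=2.0,
                signature_similarity=np.array([1.0, 0.9, 0.7, 0.5, 0.2, 0.0]),
                seed=seed,
            )
            cohort = generate_cohort(spec)
            truth = planted_truth(spec)["signature_overlap"]["valence"]
            weights = {}
            for ts in cohort.trial_sets:
                fm = extract_subject_features(ts, spec.montage)
                weights[ts.subject_id] = relieff_weights(
                    fm.values, ts.task_labels("valence")
                ).weights
            for ts_id in cohort.subject_ids:
                prof = similarity_profile(
                    ts_id, weights[ts_id],
                    {s: w for s, w in weights.items() if s != ts_id},
                )
                others = [s for s in cohort.subject_ids if s != ts_id]
                recovered = [prof.source_r[s] for s in others]
                true = [truth.loc[ts_id, s] for s in others]
                rhos.append(stats.spearmanr(recovered, true).statistic)
        assert np.mean(rhos) >= 0.6


def test_structured_cohort_spec_realizes_planted_groups():
    spec = structured_cohort_spec(0)
    truth = planted_truth(spec)
    assert list(truth["transferability"].values()).count("poor") == 1
    corr = truth["pattern_correlation"]["valence"]
    # the engaged cluster S01-S03 shares one signature
    assert corr.loc["S01", "S02"] == pytest.approx(1.0)
    assert corr.loc["S02", "S03"] == pytest.approx(1.0)
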