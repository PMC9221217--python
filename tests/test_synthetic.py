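"""The synthetic generators: fGn correctness and planted-effect cohorts."""

import numpy as np
import pytest

from atlasfusion import (
    CohortSpec,
    FeatureTable,
    fgn_autocovariance,
    make_lattice_atlas,
    mrmr_rank,
    mutual_information,
    roi_reduce,
    rs_hurst_batch,
    simulate_cohort,
    simulate_feature_table,
    simulate_fgn,
)


def _lag1(series):
    x = series - series.mean()
    return (x[:-1] @ x[1:]) / (x @ x)


class TestFgn:
    def test_white_case_has_zero_lag1_autocovariance(self):
        draws = np.array([_lag1(simulate_fgn(0.5, 512, seed=s)) for s in range(200)])
        assert abs(draws.mean()) <= 0.02

    def test_persistent_case_matches_closed_form_lag1(self):
        # gamma(1) = 2^{2h-1} - 1 = 0.5157 at h = 0.8
        expected = fgn_autocovariance(0.8, np.array([1]))[0]
        draws = np.array([_lag1(simulate_fgn(0.8, 512, seed=s)) for s in range(200)])
        assert draws.mean() == pytest.approx(expected, abs=0.05)

    def test_fixed_seed_reproducible(self):
        a = simulate_fgn(0.7, 256, seed=9)
        b = simulate_fgn(0.7, 256, seed=9)
        assert np.array_equal(a, b)

    def test_mean_and_variance_match_the_model(self):
        h, n = 0.6, 1024
        means, variances = [], []
        for s in range(100):
            x = simulate_fgn(h, n, seed=s)
            means.append(x.mean())
            variances.append(x.var())
        means, variances = np.array(means), np.array(variances)
        assert abs(means.mean()) <= 3 * means.std() / 10  # 100 replicates
        # mean-adjusted sample variance of fGn has expectation 1 - n^{2h-2}
        # (the subtracted sample mean itself has variance exactly n^{2h-2})
        expected_var = 1.0 - n ** (2 * h - 2)
        assert abs(variances.mean() - expected_var) <= 3 * variances.std() / 10

    def test_invalid_h_rejected(self):
        for h in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                simulate_fgn(h, 64)


class TestCohort:
    def test_he_contrast_has_the_planted_sign(self):
        # patients persistent (h=0.7) vs controls (h=0.5) in region 8
        atlas = make_lattice_atlas((6, 6, 6), (2, 2, 2))
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            spec = CohortSpec(
                n_positive=8,
                n_negative=8,
                effect_regions={"HE": [8]},
                h_by_group=(0.7, 0.5),
                n_timepoints=512,
                seed=seed,
            )
            cohort = simulate_cohort(spec, atlas, modalities=("HE",))
            region_means = {1: [], 0: []}
            for series4d, label in zip(cohort.bold, cohort.labels):
                flat = series4d.reshape(-1, spec.n_timepoints)
                h, _, _ = rs_hurst_batch(flat)
                he_map = h.reshape(atlas.labels.shape)
                region_means[int(label)].append(roi_reduce(he_map, atlas, "mean")[-1])
            diff = np.mean(region_means[1]) - np.mean(region_means[0])
            hits += int(diff > 0)
        assert hits >= 9

    def test_gmv_atrophy_lowers_patient_volumes(self, toy_atlas):
        spec = CohortSpec(
            n_positive=10, n_negative=10, effect_regions={"GMV": [1, 2]},
            effect_size=3.0, seed=4,
        )
        cohort = simulate_cohort(spec, toy_atlas, modalities=("GMV",))
        patient = np.mean([m[toy_atlas.labels == 1].mean() for m, l in zip(cohort.gm_maps, cohort.labels) if l == 1])
        control = np.mean([m[toy_atlas.labels == 1].mean() for m, l in zip(cohort.gm_maps, cohort.labels) if l == 0])
        assert patient < control

    def test_unknown_effect_region_rejected(self, toy_atlas):
        spec = CohortSpec(effect_regions={"GMV": [99]})
        with pytest.raises(ValueError):
            simulate_cohort(spec, toy_atlas, modalities=("GMV",))

    def test_deterministic_under_seed(self, toy_atlas):
        spec = CohortSpec(n_positive=2, n_negative=2, n_timepoints=64, seed=3)
        a = simulate_cohort(spec, toy_atlas)
        b = simulate_cohort(spec, toy_atlas)
        assert np.array_equal(a.bold[0], b.bold[0])
        assert np.array_equal(a.gm_maps[-1], b.gm_maps[-1])


class TestFeatureTable:
    def test_null_tables_have_weak_relevance(self):
        worst = 0.0
        for seed in range(10):
            spec = CohortSpec(n_positive=50, n_negative=50, effect_size=0.0, seed=seed)
            table = simulate_feature_table(spec, n_features=10, n_informative=0)
            top = max(
                mutual_information(table.values[:, j], table.labels)
                for j in range(table.n_features)
            )
            worst = max(worst, top)
        assert worst <= 0.15

    def test_planted_features_reach_mrmr_top_ten(self):
        hits = 0
        for seed in range(10):
            spec = CohortSpec(n_positive=30, n_negative=30, effect_size=2.0, seed=seed)
            table = simulate_feature_table(spec, n_features=20, n_informative=3)
            top10 = set(mrmr_rank(table, k=10))
            hits += int({0, 1, 2} <= top10)
        assert hits >= 9

    def test_redundant_duplicate_is_penalized(self):
        # near-duplicate informative pair (rho = 0.95) plus an independent,
        # weaker feature: MRMR must interleave the weaker one before the twin
        spec = CohortSpec(
            n_positive=40, n_negative=40, effect_size=2.0,
            feature_correlation=0.95, seed=6,
        )
        table = simulate_feature_table(spec, n_features=2, n_informative=2)
        rng = np.random.default_rng(123)
        weak = table.labels + 2.0 * rng.standard_normal(table.n_subjects)
        values = np.column_stack([table.values, weak])
        augmented = FeatureTable(values=values, labels=table.labels)
        ranked = mrmr_rank(augmented, k=3)
        assert ranked.index(2) < 2  # weak independent beats the twin
        assert ranked[2] in (0, 1)

    def test_labels_match_group_sizes(self):
        spec = CohortSpec(n_positive=7, n_negative=5, seed=0)
        table = simulate_feature_table(spec, n_features=4, n_informative=1)
        assert int(table.labels.sum()) == 7
        assert table.n_subjects == 12
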