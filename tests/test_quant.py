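"""Detection filter, MinProb imputation, and the differential t-test stage."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pepwire import (AnalysisConfig, ValidationError, differential_test,
                     impute_minprob, log2_and_filter, summarize_counts)

from conftest import build_matrix


def _matrix_with_pattern(design, pattern):
    """12-sample rows where `pattern` maps condition -> number observed."""
    rows = []
    for detected in pattern:
        row = []
        for cond in design.conditions:
            n = detected[cond]
            row.extend([20.0] * n + [np.nan] * (design.replicates - n))
        rows.append(row)
    return build_matrix(rows, design)


class TestDetectionFilter:
    def test_feature_detected_fully_in_one_condition_is_retained(self, design,
                                                                 analysis):
        pattern = [{"control": 3, "imatinib": 0, "PP2": 0, "SP600125": 0}]
        out = log2_and_filter(_matrix_with_pattern(design, pattern), analysis)
        assert out.n_features == 1

    def test_feature_seen_once_everywhere_is_dropped(self, design, analysis):
        pattern = [{"control": 1, "imatinib": 1, "PP2": 1, "SP600125": 1}]
        out = log2_and_filter(_matrix_with_pattern(design, pattern), analysis)
        assert out.n_features == 0

    def test_matches_brute_force_predicate(self, design, analysis):
        rng = np.random.default_rng(7)
        values = rng.normal(25, 2, size=(300, 12))
        values[rng.random(values.shape) < 0.45] = np.nan
        matrix = build_matrix(values, design)
        kept = set(log2_and_filter(matrix, analysis).feature_ids)
        expected = set()
        for feature in matrix.feature_ids:
            row = matrix.data.loc[feature]
            for cond in design.conditions:
                observed = row[list(design.samples_for(cond))].notna().sum()
                if observed >= analysis.detection_min:
                    expected.add(feature)
                    break
        assert kept == expected

    def test_non_positive_raw_intensity_names_feature(self, design, analysis):
        values = np.full((2, 12), 100.0)
        values[1, 3] = -5.0
        matrix = build_matrix(values, design, scale="raw")
        with pytest.raises(ValidationError, match="F1"):
            log2_and_filter(matrix, analysis)

    def test_raw_values_are_log2_transformed(self, design, analysis):
        matrix = build_matrix(np.full((1, 12), 1024.0), design, scale="raw")
        out = log2_and_filter(matrix, analysis)
        assert np.allclose(out.data.to_numpy(), 10.0)


class TestImputation:
    def _missing_matrix(self, design, seed=0):
        rng = np.random.default_rng(seed)
        values = rng.normal(25, 2, size=(120, 12))
        values[rng.random(values.shape) < 0.15] = np.nan
        return build_matrix(values, design)

    def test_complete_matrix_returned_unchanged(self, design, analysis):
        matrix = build_matrix(np.full((5, 12), 20.0), design)
        assert impute_minprob(matrix, analysis) is matrix

    def test_observed_cells_bitwise_untouched(self, design, analysis):
        matrix = self._missing_matrix(design)
        out = impute_minprob(matrix, analysis, seed=5)
        observed = ~matrix.data.isna().to_numpy()
        assert np.array_equal(matrix.data.to_numpy()[observed],
                              out.data.to_numpy()[observed])
        assert out.n_missing() == 0

    def test_deterministic_under_seed(self, design, analysis):
        matrix = self._missing_matrix(design)
        a = impute_minprob(matrix, analysis, seed=5)
        b = impute_minprob(matrix, analysis, seed=5)
        c = impute_minprob(matrix, analysis, seed=6)
        pd.testing.assert_frame_equal(a.data, b.data, check_exact=True)
        missing = matrix.data.isna().to_numpy()
        assert not np.array_equal(a.data.to_numpy()[missing],
                                  c.data.to_numpy()[missing])

    def test_imputed_values_track_low_quantile(self, design, analysis):
        matrix = self._missing_matrix(design, seed=3)
        sample = design.sample_ids[0]
        observed = matrix.data[sample].dropna()
        mu = observed.quantile(analysis.imputation_q)
        sigma = analysis.imputation_sd_scale * observed.std(ddof=1)
        draws = []
        for seed in range(400):
            out = impute_minprob(matrix, analysis, seed=seed)
            draws.extend(out.data.loc[matrix.data[sample].isna(), sample])
        draws = np.asarray(draws)
        assert np.all(np.abs(draws - mu) < 6 * sigma)
        assert abs(draws.mean() - mu) < 3 * sigma / np.sqrt(len(draws))

    def test_sample_with_one_observed_value_errors(self, design, analysis):
        values = np.full((3, 12), 20.0)
        values[1:, 0] = np.nan  # sample control_1: one observed, two missing
        with pytest.raises(ValidationError, match="control_1"):
            impute_minprob(build_matrix(values, design), analysis)


class TestDifferentialTest:
    def test_closed_form_example(self, design, analysis):
        base = np.full((1, 12), 10.0)
        matrix_values = np.tile([10.0, 10.2, 9.8], (1, 4))
        matrix_values[0, 3:6] = [12.0, 12.2, 11.8]  # imatinib replicates
        matrix = build_matrix(matrix_values, design)
        results = differential_test(matrix, analysis)
        row = results[(results["treatment"] == "imatinib")].iloc[0]
        pooled_sd = 0.2
        expected_t = 2.0 / (pooled_sd * np.sqrt(2 / 3))
        assert row["log2FC"] == pytest.approx(2.0)
        assert row["t_statistic"] == pytest.approx(expected_t)
        assert row["p_value"] == pytest.approx(
            2 * stats.t.sf(expected_t, df=4), rel=1e-9)
        assert row["significant"] and row["direction"] == "up"

    def test_small_fold_change_never_significant(self, design, analysis):
        # tiny variance makes adj_p minuscule, but |log2FC| = 0.4 < 0.5
        rng = np.random.default_rng(0)
        values = np.tile(rng.normal(20, 1, size=(50, 1)), (1, 12))
        values += rng.normal(0, 1e-3, values.shape)
        values[0, 3:6] += 0.4
        results = differential_test(build_matrix(values, design), analysis)
        row = results[(results["treatment"] == "imatinib")].iloc[0]
        assert row["adj_p_value"] < 0.001
        assert abs(row["log2FC"]) == pytest.approx(0.4, abs=0.01)
        assert not row["significant"] and row["direction"] == "none"

    def test_identical_groups_have_zero_fc_and_no_direction(self, design,
                                                            analysis):
        matrix = build_matrix(np.tile([20.0, 20.5, 19.5], (4, 4)), design)
        results = differential_test(matrix, analysis)
        assert (results["log2FC"] == 0).all()
        assert (results["direction"] == "none").all()

    def test_zero_variance_degenerate_rows(self, design, analysis):
        values = np.full((2, 12), 20.0)
        values[0, 3:6] = 24.0  # shifted with zero variance
        results = differential_test(build_matrix(values, design), analysis)
        shifted = results[(results["feature_id"] == "F0") &
                          (results["treatment"] == "imatinib")].iloc[0]
        flat = results[(results["feature_id"] == "F1") &
                       (results["treatment"] == "imatinib")].iloc[0]
        assert shifted["p_value"] == 0.0 and shifted["significant"]
        assert flat["p_value"] == 1.0 and not flat["significant"]

    def test_missing_cells_rejected(self, design, analysis):
        values = np.full((2, 12), 20.0)
        values[0, 0] = np.nan
        with pytest.raises(ValidationError, match="missing"):
            differential_test(build_matrix(values, design), analysis)

    def test_effect_monotonicity_in_recovered_count(self, design, analysis):
        """Raising every planted effect magnitude never reduces the number of
        significant calls (paired seeds)."""
        rng = np.random.default_rng(21)
        base = rng.normal(25, 2, size=(400, 1))
        noise = rng.normal(0, 0.5, size=(400, 12))
        planted = rng.random(400) < 0.2
        signs = rng.choice([-1, 1], 400)
        counts = []
        for magnitude in (1.0, 2.0, 4.0):
            values = base + noise
            values[planted, 3:6] += (signs[planted] * magnitude)[:, None]
            results = differential_test(build_matrix(values, design), analysis)
            sig = results[(results["treatment"] == "imatinib") &
                          results["significant"]]
            counts.append(len(sig))
        assert counts[0] <= counts[1] <= counts[2]


class TestSummaries:
    def test_counts_partition_and_match_brute_force(self, design, analysis):
        rng = np.random.default_rng(3)
        values = rng.normal(25, 2, size=(200, 12))
        planted = rng.random(200) < 0.3
        values[planted, 3:6] += rng.choice([-4, 4], planted.sum())[:, None]
        results = differential_test(build_matrix(values, design), analysis)
        counts = summarize_counts(results)
        for _, row in counts.iterrows():
            subset = results[(results["layer"] == row["layer"]) &
                             (results["treatment"] == row["treatment"])]
            sig = subset[subset["significant"]]
            assert row["up"] == (sig["direction"] == "up").sum()
            assert row["down"] == (sig["direction"] == "down").sum()
            assert row["total_significant"] == row["up"] + row["down"]

    def test_no_significant_features_gives_zero_counts(self, design, analysis):
        rng = np.random.default_rng(4)
        values = rng.normal(25, 2, size=(50, 12))
        results = differential_test(build_matrix(values, design), analysis)
        results["significant"] = False
        results["direction"] = "none"
        counts = summarize_counts(results)
        assert (counts[["up", "down", "total_significant"]] == 0).all().all()
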