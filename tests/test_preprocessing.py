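import math

import numpy as np
import pandas as pd
import pytest

from aggremap.config import PipelineConfig
from aggremap.preprocess import (
    DegenerateDesignError,
    InsufficientDataError,
    PreprocessReport,
    apply_flag_filters,
    detect_outlier_samples,
    drop_pooled,
    filter_condition_missing,
    filter_global_observed,
    impute_downshifted_normal,
    median_normalize,
    preprocess_table,
    quantile_normalize,
    zeros_to_missing,
)
from aggremap.datatypes import make_design
from aggremap.synthetic import SyntheticConfig, generate_design, generate_tmt_experiment

from conftest import make_table, small_design


class TestFlagFilters:
    @pytest.mark.parametrize(
        "flags,n_pep,n_unique,kept",
        [
            ({"is_reverse": [True]}, 5, 2, False),     # decoy removed
            ({"is_contaminant": [True]}, 5, 2, False),
            ({"only_by_site": [True]}, 5, 2, False),
            ({}, 2, 1, True),                          # minimum acceptable evidence
            ({}, 1, 1, False),                         # "more than one peptide" boundary
            ({}, 5, 0, False),                         # no unique peptide
        ],
    )
    def test_protein_rules(self, flags, n_pep, n_unique, kept):
        design = small_design(2, pooled=False)
        table = make_table(np.ones((1, 4)), design, flags=flags, peptides=([n_pep], [n_unique]))
        out, report = apply_flag_filters(table)
        assert (out.n_features == 1) is kept
        assert report.n_removed() == (0 if kept else 1)

    def test_phospho_only_contaminant_rule(self):
        design = small_design(2, pooled=False)
        table = make_table(
            np.ones((3, 4)), design, kind="phosphosite",
            flags={"is_reverse": [True, False, False], "is_contaminant": [False, True, False]},
            peptides=([1, 1, 1], [1, 1, 1]),
        )
        out, _ = apply_flag_filters(table)
        # reverse flag and peptide counts are ignored for sites; contaminant removed
        assert out.n_features == 2
        assert "F001" not in out.meta.index


class TestDropPooled:
    def test_eleven_plex_to_ten(self):
        table = make_table(np.ones((2, 11)), small_design(5))
        out = drop_pooled(table)
        assert out.n_samples == 10 and not out.design["is_pooled"].any()

    def test_without_pooled_is_identity(self):
        table = make_table(np.ones((2, 10)), small_design(5, pooled=False))
        out = drop_pooled(table)
        assert list(out.design.index) == list(table.design.index)

    def test_degenerate_design_rejected(self):
        design = make_design(
            ["a", "b", "c"], ["PFF", "PBS", None], pooled=[False, False, True]
        )
        table = make_table(np.ones((2, 3)), design)
        with pytest.raises(DegenerateDesignError):
            drop_pooled(table)


def test_zeros_to_missing_counts():
    design = small_design(2, pooled=False)
    values = np.array([[0.0, 5, 5, 5], [5, 0.0, 5, 5], [5, 5, 5, 5]])
    out = zeros_to_missing(make_table(values, design))
    assert int(out.values.isna().sum().sum()) == 2
    assert out.values.iloc[2].notna().all()


class TestObservedFilters:
    def test_global_strict_majority(self):
        design = small_design(5, pooled=False)
        values = np.full((3, 10), 20.0)
        values[0, 6:] = np.nan   # 6/10 observed -> kept
        values[1, 5:] = np.nan   # 5/10 observed -> removed (strict >)
        values[2, :] = np.nan    # 0/10 -> removed
        out, report = filter_global_observed(make_table(values, design), 0.5)
        assert list(out.meta.index) == ["F000"]
        assert report.n_removed("global_observed") == 2

    def test_global_bad_fraction(self):
        design = small_design(2, pooled=False)
        with pytest.raises(ValueError):
            filter_global_observed(make_table(np.ones((1, 4)), design), 0.0)

    def test_condition_missing_per_group(self):
        design = small_design(5, pooled=False)
        values = np.full((3, 10), 20.0)
        values[0, 0:2] = np.nan          # 2/5 missing in PFF -> removed (0.4 > 0.2)
        values[1, 0] = np.nan            # 1/5 in each group -> kept (0.2 not > 0.2)
        values[1, 5] = np.nan
        out, report = filter_condition_missing(make_table(values, design), 0.2)
        assert list(out.meta.index) == ["F001", "F002"]
        assert report.n_removed("condition_missing") == 1


class TestMedianNormalize:
    def test_hand_example_two_samples(self):
        design = make_design(["a", "b"], ["PFF", "PBS"])
        # sample medians 20 and 22 -> both become 21
        values = np.array([[19.0, 21.0], [20.0, 22.0], [21.0, 23.0]])
        out, report = median_normalize(make_table(values, design))
        medians = out.values.median(axis=0)
        assert np.allclose(medians, 21.0)
        assert report.sample_offsets["a"] == pytest.approx(1.0)
        assert report.sample_offsets["b"] == pytest.approx(-1.0)

    def test_idempotent_and_order_preserving(self):
        rng = np.random.default_rng(0)
        design = small_design(3, pooled=False)
        table = make_table(rng.normal(25, 2, size=(50, 6)), design)
        once, _ = median_normalize(table)
        twice, _ = median_normalize(once)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy())
        for c in table.values.columns:
            assert (table.values[c].rank() == once.values[c].rank()).all()

    def test_all_missing_sample_named(self):
        design = small_design(2, pooled=False)
        values = np.ones((3, 4))
        values[:, 2] = np.nan
        with pytest.raises(ValueError, match="PBS_0"):
            median_normalize(make_table(values, design))


class TestQuantileNormalize:
    def test_identical_samples_unchanged(self):
        design = small_design(2, pooled=False)
        col = np.array([1.0, 2.0, 3.0, 4.0])
        table = make_table(np.column_stack([col] * 4), design)
        out = quantile_normalize(table)
        assert np.allclose(out.values.to_numpy(), table.values.to_numpy())

    def test_two_sample_hand_example(self):
        design = make_design(["a", "b"], ["PFF", "PBS"])
        values = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
        out = quantile_normalize(make_table(values, design))
        assert np.allclose(out.values["a"], [2.5, 3.5, 4.5])
        assert np.allclose(out.values["b"], [2.5, 3.5, 4.5])


class TestOutlierDetection:
    def test_identical_samples_clean(self):
        design = small_design(5, pooled=False)
        table = make_table(np.tile(np.arange(10.0, 20.0)[:, None], (1, 10)), design)
        assert detect_outlier_samples(table) == []

    def test_gross_shift_is_flagged(self):
        rng = np.random.default_rng(1)
        design = small_design(5, pooled=False)
        values = rng.normal(25, 0.3, size=(100, 10))
        values[:, 7] += 10.0  # one sample shifted by +10 log2 units
        flagged = detect_outlier_samples(make_table(values, design), z_threshold=4)
        assert flagged == [design.index[7]]

    def test_infinite_threshold_flags_nothing(self):
        rng = np.random.default_rng(1)
        design = small_design(5, pooled=False)
        values = rng.normal(25, 0.3, size=(100, 10))
        values[:, 7] += 10.0
        assert detect_outlier_samples(make_table(values, design), math.inf) == []

    def test_requires_complete_features(self):
        design = small_design(2, pooled=False)
        values = np.ones((5, 4))
        values[0:3, 0] = np.nan
        with pytest.raises(InsufficientDataError):
            detect_outlier_samples(make_table(values, design))


class TestImputation:
    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(2)
        design = small_design(2, pooled=False)
        table = make_table(rng.normal(25, 2, (20, 4)), design)
        out, report = impute_downshifted_normal(table, seed=1)
        assert np.array_equal(out.values.to_numpy(), table.values.to_numpy())
        assert report.imputed_cells == 0

    def test_observed_cells_bitwise_unchanged(self):
        rng = np.random.default_rng(2)
        design = small_design(2, pooled=False)
        values = rng.normal(25, 2, (50, 4))
        values[rng.random((50, 4)) < 0.2] = np.nan
        table = make_table(values, design)
        out, _ = impute_downshifted_normal(table, seed=1)
        obs = ~np.isnan(values)
        assert np.array_equal(out.values.to_numpy()[obs], values[obs])
        assert not np.isnan(out.values.to_numpy()).any()

    def test_degenerate_width_collapses_to_shifted_mean(self):
        design = small_design(2, pooled=False)
        values = np.tile(np.linspace(20, 30, 40)[:, None], (1, 4))
        values[0, 0] = np.nan
        table = make_table(values, design)
        out, _ = impute_downshifted_normal(table, width=1e-12, shift=0.0, seed=1)
        col = np.delete(values[:, 0], 0)
        assert out.values.iloc[0, 0] == pytest.approx(col.mean(), abs=1e-6)

    def test_too_few_observed_rejected(self):
        design = small_design(2, pooled=False)
        values = np.ones((3, 4))
        values[1:, 0] = np.nan
        with pytest.raises(ValueError):
            impute_downshifted_normal(make_table(values, design), seed=1)


class TestCascade:
    def test_clean_table_passes_through_unreduced(self):
        """Flag-free complete data loses nothing; normalization cancels in group differences."""
        rng = np.random.default_rng(13)
        design = small_design(5)
        values = rng.normal(25, 2, size=(300, 11))
        # equal sample medians: median normalization is then the identity,
        # so the whole cascade must leave group contrasts untouched
        values = values - np.median(values, axis=0, keepdims=True) + 25.0
        table = make_table(values, design)
        out, report = preprocess_table(table, PipelineConfig(seed=13))
        assert out.n_features == table.n_features
        assert report.n_removed() == 0 and report.imputed_cells == 0

        pff = [s for s in out.analytic_samples() if s.startswith("PFF")]
        pbs = [s for s in out.analytic_samples() if s.startswith("PBS")]
        before = table.values[pff].mean(axis=1) - table.values[pbs].mean(axis=1)
        after = out.values[pff].mean(axis=1) - out.values[pbs].mean(axis=1)
        assert np.allclose(before, after, atol=1e-9)

    def test_report_reconstructs_removals(self):
        cfg = SyntheticConfig(n_features=500, seed=17)
        table, _ = generate_tmt_experiment(cfg, generate_design(5, "day14"))
        out, report = preprocess_table(table, PipelineConfig(seed=17))
        assert report.n_removed() == table.n_features - out.n_features
        removed_ids = {fid for ids in report.removed.values() for fid in ids}
        assert removed_ids == set(table.meta.index) - set(out.meta.index)
        # deterministic given input + config + seed
        out2, report2 = preprocess_table(table, PipelineConfig(seed=17))
        pd.testing.assert_frame_equal(out.values, out2.values)
        assert report.removed == report2.removed
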