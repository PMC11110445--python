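import math

import numpy as np
import pandas as pd
import pytest

from aggremap.synthetic import (
    InvalidDesignError,
    SeparationError,
    SyntheticConfig,
    generate_design,
    generate_gene_sets,
    generate_insoluble_lfq,
    generate_phospho_experiment,
    generate_ppi_network,
    generate_tmt_experiment,
)


class TestDesign:
    def test_eleven_plex_with_pooled_channel(self):
        d = generate_design(5, "day14")
        assert len(d) == 11
        assert int(d["is_pooled"].sum()) == 1
        assert (d[~d["is_pooled"]]["treatment"].value_counts() == 5).all()

    def test_minimal_design(self):
        d = generate_design(2, "day7")
        assert len(d) == 5 and d.index.is_unique

    def test_single_replicate_rejected(self):
        with pytest.raises(InvalidDesignError):
            generate_design(1, "day7")


def _clean_config(**kw):
    base = dict(censor_quantile=0.0, mar_rate=0.0, flag_rates=(0.0, 0.0, 0.0))
    base.update(kw)
    return SyntheticConfig(**base)


class TestTmtExperiment:
    def test_null_de_fraction(self):
        cfg = _clean_config(n_features=100, de_fraction=0.0, seed=1)
        _, truth = generate_tmt_experiment(cfg, generate_design(3, "day7"))
        assert truth.is_de.sum() == 0

    def test_no_missingness_limit(self):
        cfg = _clean_config(n_features=100, seed=1)
        table, _ = generate_tmt_experiment(cfg, generate_design(3, "day7"))
        assert not table.values.isna().any().any()

    def test_seed_determinism(self):
        cfg = SyntheticConfig(n_features=200, seed=11)
        d = generate_design(5, "day14")
        t1, tr1 = generate_tmt_experiment(cfg, d)
        t2, tr2 = generate_tmt_experiment(cfg, d)
        pd.testing.assert_frame_equal(t1.values, t2.values)
        pd.testing.assert_frame_equal(t1.meta, t2.meta)
        pd.testing.assert_series_equal(tr1.true_log2fc, tr2.true_log2fc)

    def test_group_difference_matches_planted_lfc(self):
        # sample-mean oracle: mean (PFF - PBS) over planted up-features ~ +lfc
        cfg = _clean_config(
            n_features=2000, de_fraction=0.1, lfc_magnitude=1.0, noise_sd=0.25, seed=7
        )
        design = generate_design(5, "day14")
        table, truth = generate_tmt_experiment(cfg, design)
        pff = [s for s in table.analytic_samples() if s.startswith("PFF")]
        pbs = [s for s in table.analytic_samples() if s.startswith("PBS")]
        diff = table.values[pff].mean(axis=1) - table.values[pbs].mean(axis=1)
        for sign in (+1, -1):
            sel = truth.true_log2fc == sign * 1.0
            n = int(sel.sum())
            assert n > 50
            se = 0.25 * math.sqrt(2 / 5) / math.sqrt(n)
            assert abs(diff[sel].mean() - sign * 1.0) < 3 * se

    def test_truth_consistency_large_groups(self):
        cfg = _clean_config(
            n_features=500, n_per_group=50, de_fraction=0.2, lfc_magnitude=0.8,
            noise_sd=0.5, seed=21,
        )
        design = generate_design(50, "day14")
        table, truth = generate_tmt_experiment(cfg, design)
        pff = [s for s in table.analytic_samples() if s.startswith("PFF")]
        pbs = [s for s in table.analytic_samples() if s.startswith("PBS")]
        diff = table.values[pff].mean(axis=1) - table.values[pbs].mean(axis=1)
        up = truth.true_log2fc > 0
        se = 0.5 * math.sqrt(2 / 50) / math.sqrt(int(up.sum()))
        assert abs(diff[up].mean() - 0.8) < 3 * se

    def test_missing_fraction_within_specification(self):
        cfg = SyntheticConfig(
            n_features=2000, censor_quantile=0.05, mar_rate=0.01,
            flag_rates=(0.0, 0.0, 0.0), seed=5,
        )
        table, _ = generate_tmt_experiment(cfg, generate_design(5, "day14"))
        frac = float(table.values.isna().to_numpy().mean())
        expected = 0.05 + 0.95 * 0.01
        assert abs(frac - expected) < 0.012

    def test_pooled_channel_tracks_row_mean(self):
        cfg = _clean_config(n_features=300, noise_sd=0.25, seed=2)
        table, _ = generate_tmt_experiment(cfg, generate_design(5, "day14"))
        pooled = table.design.index[table.design["is_pooled"]][0]
        analytic = table.analytic_samples()
        resid = table.values[pooled] - table.values[analytic].mean(axis=1)
        assert abs(resid.mean()) < 3 * 0.25 / math.sqrt(300)
        assert resid.std() < 0.35

    def test_planted_de_never_on_artifact_rows(self):
        cfg = SyntheticConfig(n_features=1000, flag_rates=(0.1, 0.1, 0.1), seed=3)
        table, truth = generate_tmt_experiment(cfg, generate_design(3, "day7"))
        de = truth.de_features()
        flagged = table.meta[["is_reverse", "is_contaminant", "only_by_site"]].any(axis=1)
        assert not (flagged & table.meta.index.isin(de)).any()
        assert (table.meta.loc[sorted(de), "n_peptides"] > 1).all()


class TestPhosphoExperiment:
    def test_sites_share_leading_protein(self):
        cfg = _clean_config(n_features=30, seed=4)
        table, _ = generate_phospho_experiment(cfg, generate_design(3, "day7"), sites_per_protein=3)
        counts = table.meta["leading_protein"].value_counts()
        assert (counts == 3).all()
        assert table.meta["site_position"].notna().all()

    def test_de_restricted_to_candidate_subset(self):
        cfg = _clean_config(n_features=90, de_fraction=0.2, seed=4)
        table, truth = generate_phospho_experiment(cfg, generate_design(3, "day7"))
        subset = list(table.meta.index[:20])
        _, truth2 = generate_phospho_experiment(
            cfg, generate_design(3, "day7"), de_candidates=subset
        )
        assert truth2.de_features() <= set(subset)

    def test_determinism(self):
        cfg = SyntheticConfig(n_features=60, seed=8)
        d = generate_design(3, "day7")
        t1, _ = generate_phospho_experiment(cfg, d)
        t2, _ = generate_phospho_experiment(cfg, d)
        pd.testing.assert_frame_equal(t1.values, t2.values)


class TestInsolubleLfq:
    def test_unit_scales_match_tmt_generator(self, design_no_pool):
        cfg = _clean_config(n_features=80, seed=6)
        lfq, _ = generate_insoluble_lfq(cfg, design_no_pool, [1.0] * 10)
        tmt, _ = generate_tmt_experiment(cfg, design_no_pool)
        pd.testing.assert_frame_equal(
            lfq.values, tmt.values, check_exact=False, atol=1e-12
        )

    def test_loading_scale_shifts_median(self, design_no_pool):
        cfg = _clean_config(n_features=400, seed=6)
        scales = [1.0] * 10
        base, _ = generate_insoluble_lfq(cfg, design_no_pool, scales)
        scales[3] = 2.0
        shifted, _ = generate_insoluble_lfq(cfg, design_no_pool, scales)
        sid = design_no_pool.index[3]
        delta = shifted.values[sid].median() - base.values[sid].median()
        assert delta == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_scale_rejected(self, design_no_pool):
        cfg = _clean_config(n_features=10, seed=1)
        with pytest.raises(ValueError):
            generate_insoluble_lfq(cfg, design_no_pool, [1.0] * 9 + [0.0])


class TestPpiNetwork:
    def test_no_between_edges_when_p_between_zero(self):
        g, truth = generate_ppi_network(30, 3, 0.5, 0.0, 0.99, 0.5, seed=1)
        for a, b in g.edges:
            assert truth.module_id[a] == truth.module_id[b]

    def test_single_module_degenerate(self):
        g, truth = generate_ppi_network(20, 1, 0.3, 0.0, 0.9, 0.5, seed=2)
        assert truth.module_id.nunique() == 1
        assert g.number_of_nodes() == 20

    def test_edge_count_matches_expectation(self):
        # closed form: 3*C(20,2)*0.5 within + (C(60,2)-570)*0.02 between
        counts = []
        for seed in range(5):
            g, _ = generate_ppi_network(60, 3, 0.5, 0.02, 0.99, 0.5, seed=seed)
            counts.append(g.number_of_edges())
        expected = 570 * 0.5 + 1200 * 0.02
        sd = math.sqrt(570 * 0.25 + 1200 * 0.02 * 0.98)
        assert abs(np.mean(counts) - expected) < 4 * sd / math.sqrt(5)

    def test_separation_precondition(self):
        with pytest.raises(SeparationError):
            generate_ppi_network(30, 3, 0.1, 0.2, 0.9, 0.5, seed=1)

    def test_confidences_in_range_and_module_labels_cover_nodes(self):
        g, truth = generate_ppi_network(40, 4, 0.4, 0.05, 0.9995, 0.8, seed=3)
        assert set(truth.module_id.index) == set(g.nodes)
        confs = [d["confidence"] for _, _, d in g.edges(data=True)]
        assert all(0 <= c <= 1 for c in confs)


class TestGeneSets:
    def test_module_sets_equal_planted_membership(self):
        _, truth = generate_ppi_network(30, 3, 0.5, 0.02, 0.99, 0.5, seed=1)
        coll = generate_gene_sets(truth, n_extra_sets=2, seed=9)
        modules = truth.module_id
        for mid in modules.unique():
            assert coll[f"module_{mid:02d}"] == set(modules.index[modules == mid])

    def test_no_decoys_when_zero_extra(self):
        _, truth = generate_ppi_network(30, 3, 0.5, 0.02, 0.99, 0.5, seed=1)
        coll = generate_gene_sets(truth, n_extra_sets=0, seed=9)
        assert len(coll) == 3
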