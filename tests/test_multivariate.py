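"""Unsupervised views: clustering, PCA, volcano, box summaries."""

import numpy as np
import pandas as pd
import pytest

from serodiff import (
    SimulationConfig,
    build_folds,
    cluster_heatmap,
    normalize_chain,
    pca_scores,
    select_de,
    simulate_cohort,
    simulate_matrix,
    top_protein_boxes,
    volcano,
)

from conftest import make_matrix


@pytest.fixture(scope="module")
def strong_sim():
    cfg = SimulationConfig(
        seed=13, n_proteins=60, frac_de=1 / 6, effect_low=2.0, effect_high=2.0,
        sd_low=0.3, sd_high=0.3,
    )
    design = simulate_cohort(cfg)
    matrix, truth = simulate_matrix(cfg, design)
    norm = normalize_chain(matrix)
    plan = build_folds(design, seed=13)
    table = select_de(norm, design, plan)
    return design, norm, truth, table


class TestCluster:
    def test_strong_effects_separate_groups(self, strong_sim):
        design, norm, truth, table = strong_sim
        de = table.index[table["is_de"]].tolist()
        assert len(de) >= 2
        result = cluster_heatmap(norm.restrict(de), design)
        assert result.n_misassigned == 0

    def test_display_clipped_to_pm3(self, strong_sim):
        design, norm, _, table = strong_sim
        de = table.index[table["is_de"]].tolist()
        result = cluster_heatmap(norm.restrict(de), design)
        vals = result.display.to_numpy()
        assert np.nanmax(np.abs(vals)) <= 3.0

    def test_clipping_caps_extreme_z_scores(self, default_design):
        # one protein with a single extreme outlier sample
        vals = np.zeros((2, 36))
        vals[0] = np.concatenate([[50.0], np.random.default_rng(0).normal(size=35)])
        vals[1] = np.random.default_rng(1).normal(size=36)
        m = make_matrix(vals, samples=default_design["sample_id"].tolist())
        result = cluster_heatmap(m, default_design)
        assert result.display.iloc[0, 0] == 3.0

    def test_duplicate_samples_merge_at_zero_height(self, default_design):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(10, 36))
        vals[:, 1] = vals[:, 0]  # exact duplicate column
        m = make_matrix(vals, samples=default_design["sample_id"].tolist())
        result = cluster_heatmap(m, default_design)
        assert result.sample_linkage[0, 2] == pytest.approx(0.0)
        merged = set(result.sample_linkage[0, :2].astype(int))
        assert merged == {0, 1}

    def test_constant_rows_excluded_with_warning(self, default_design):
        vals = np.random.default_rng(3).normal(size=(3, 36))
        vals[1] = 1.0
        m = make_matrix(vals, samples=default_design["sample_id"].tolist())
        with pytest.warns(UserWarning, match="constant"):
            result = cluster_heatmap(m, default_design)
        assert result.display.shape[0] == 2

    def test_label_blind_to_sample_order(self, strong_sim):
        design, norm, _, table = strong_sim
        de = table.index[table["is_de"]].tolist()
        sub = norm.restrict(de)
        shuffled = sub.data.sample(frac=1.0, axis=1, random_state=5)
        from serodiff.matrix import IntensityMatrix

        result1 = cluster_heatmap(sub, design)
        result2 = cluster_heatmap(IntensityMatrix(shuffled, sub.stages), design)
        a = result1.sample_clusters
        b = result2.sample_clusters.reindex(a.index)
        agreement = (a == b).mean()
        assert agreement in (0.0, 1.0)  # identical up to cluster relabeling
        assert result1.n_misassigned == result2.n_misassigned


class TestPca:
    def test_strong_effects_separation_above_one(self, strong_sim):
        design, norm, _, table = strong_sim
        de = table.index[table["is_de"]].tolist()
        result = pca_scores(norm.restrict(de), design)
        assert result.separation > 1.0

    def test_explained_variance_sorted_and_bounded(self, strong_sim):
        design, norm, _, table = strong_sim
        de = table.index[table["is_de"]].tolist()
        result = pca_scores(norm.restrict(de), design)
        evr = result.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-9

    def test_scores_uncorrelated(self, strong_sim):
        design, norm, _, table = strong_sim
        de = table.index[table["is_de"]].tolist()
        scores = pca_scores(norm.restrict(de), design).scores.to_numpy()
        corr = np.corrcoef(scores.T)
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert np.allclose(off, 0.0, atol=1e-8)

    def test_translation_along_one_axis_dominates_pc1(self, default_design):
        # two identical point clouds translated apart along protein 0
        rng = np.random.default_rng(11)
        base = rng.normal(scale=0.01, size=(5, 36))
        vals = base.copy()
        is_cca = (default_design["group"] == "CCA").to_numpy()
        vals[0, is_cca] += 10.0
        m = make_matrix(vals, samples=default_design["sample_id"].tolist())
        result = pca_scores(m, default_design)
        assert result.explained_variance_ratio[0] > 0.99


class TestVolcano:
    def test_flags_reproduce_de_set(self, strong_sim):
        design, norm, _, table = strong_sim
        points = volcano(table, cutoff=0.01)
        assert set(points.index[points["is_de"]]) == set(table.index[table["is_de"]])

    def test_boundary_p_not_flagged(self):
        table = pd.DataFrame(
            {
                "quantifiable": [True, True],
                "mean_cca": [1.0, 1.0],
                "mean_bbtd": [0.0, 1.0],
                "max_fold_p": [0.01, 0.5],
                "is_de": [False, False],
            },
            index=pd.Index(["AT_CUTOFF", "NULL"], name="protein"),
        )
        points = volcano(table, cutoff=0.01)
        assert not points.loc["AT_CUTOFF", "is_de"]  # strict inequality

    def test_fold_change_is_mean_difference(self):
        table = pd.DataFrame(
            {
                "quantifiable": [True],
                "mean_cca": [0.98],
                "mean_bbtd": [-0.69],
                "max_fold_p": [1e-4],
                "is_de": [True],
            },
            index=pd.Index(["FAM19A5"], name="protein"),
        )
        points = volcano(table)
        assert points.loc["FAM19A5", "log2_fc"] == pytest.approx(1.67)
        assert points.loc["FAM19A5", "neg_log10_p"] == pytest.approx(4.0)


class TestBoxes:
    def test_five_number_summary_linear_quartiles(self, default_design):
        vals = np.tile(np.nan, (1, 36))
        m = make_matrix(vals, proteins=["P"], samples=default_design["sample_id"].tolist())
        cca_ids = default_design.loc[default_design["group"] == "CCA", "sample_id"]
        m.data.loc["P", cca_ids[:5]] = [1, 2, 3, 4, 5]
        bbtd_ids = default_design.loc[default_design["group"] == "BBTD", "sample_id"]
        m.data.loc["P", bbtd_ids[:4]] = [2, 2, 2, 2]
        boxes = top_protein_boxes(m, default_design, proteins=["P"]).set_index("group")
        cca = boxes.loc["CCA"]
        assert (cca["min"], cca["q1"], cca["median"], cca["q3"], cca["max"]) == (1, 2, 3, 4, 5)
        bbtd = boxes.loc["BBTD"]
        assert bbtd["min"] == bbtd["max"] == 2.0  # degenerate box

    def test_default_panel_is_top_by_fold_change(self, strong_sim):
        design, norm, _, table = strong_sim
        boxes = top_protein_boxes(norm, design, detable=table, n_top=5)
        assert boxes["protein"].nunique() == 5
        de = table[table["is_de"]]
        fc = (de["mean_cca"] - de["mean_bbtd"]).abs().sort_values(ascending=False)
        assert set(boxes["protein"]) == set(fc.index[:5])

    def test_group_medians_track_truth_effect(self, strong_sim):
        design, norm, truth, table = strong_sim
        tr = truth.set_index("protein")
        boxes = top_protein_boxes(norm, design, detable=table, n_top=3)
        for protein, grp in boxes.groupby("protein"):
            g = grp.set_index("group")
            diff = g.loc["CCA", "median"] - g.loc["BBTD", "median"]
            effect = tr.loc[protein, "effect"]
            assert diff == pytest.approx(effect, abs=0.5)

    def test_unknown_protein_listed(self, strong_sim):
        design, norm, _, _ = strong_sim
        with pytest.raises(KeyError, match="NOPE"):
            top_protein_boxes(norm, design, proteins=["NOPE"])


def test_null_data_cluster_agreement_near_chance():
    """Without true effects the 2-cluster cut recovers group labels no
    better than chance."""
    agreements = []
    for seed in range(40):
        cfg = SimulationConfig(seed=200 + seed, n_proteins=30, frac_de=0.0,
                               missing_rate=0.0)
        design = simulate_cohort(cfg)
        matrix, _ = simulate_matrix(cfg, design)
        norm = normalize_chain(matrix)
        result = cluster_heatmap(norm, design)
        agreements.append(1.0 - result.n_misassigned / 36.0)
    assert abs(np.mean(agreements) - 0.5) < 0.15
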