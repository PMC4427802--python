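"""Clinical comparisons and published-table audits."""

import numpy as np
import pandas as pd
import pytest

from serodiff import (
    SimulationConfig,
    audit_summary_table,
    compare_cohorts,
    reference_cohort_table,
    reference_summary_table,
    simulate_cohort,
    welch_test,
)
from serodiff.cohort import parse_printed_p


def brute_chi2(table):
    """Pearson chi-squared from first principles on a 2x2 count table."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def _design(cca_rows, bbtd_rows):
    rows = []
    for i, r in enumerate(cca_rows):
        rows.append({"sample_id": f"C{i}", "group": "CCA", **r})
    for i, r in enumerate(bbtd_rows):
        rows.append({"sample_id": f"B{i}", "group": "BBTD", **r})
    return pd.DataFrame(rows)[["sample_id", "group", "sex", "age", "cea", "ca19_9"]]


@pytest.fixture(scope="module")
def sim_design():
    return simulate_cohort(SimulationConfig(seed=42))


def test_variable_test_mapping(sim_design):
    comp = compare_cohorts(sim_design).set_index("variable")
    assert comp.loc["sex", "test"] == "Pearson chi-squared"
    assert comp.loc["age", "test"] == "Student t"
    assert comp.loc["cea", "test"] == "Mann-Whitney U"
    assert comp.loc["ca19_9", "test"] == "Mann-Whitney U"
    assert ((comp["p"] >= 0) & (comp["p"] <= 1)).all()


def test_constant_variable_reported_undefined(sim_design):
    d = sim_design.copy()
    d["age"] = 55.0
    comp = compare_cohorts(d).set_index("variable")
    assert np.isnan(comp.loc["age", "statistic"])
    assert np.isnan(comp.loc["age", "p"])


def test_equal_age_samples_t0():
    vals = [40, 50, 60, 70]
    cca = [{"sex": "male", "age": a, "cea": 1, "ca19_9": 1} for a in vals]
    bbtd = [{"sex": "male", "age": a, "cea": 1, "ca19_9": 1} for a in vals]
    comp = compare_cohorts(_design(cca, bbtd)).set_index("variable")
    assert comp.loc["age", "statistic"] == pytest.approx(0.0)
    assert comp.loc["age", "p"] == pytest.approx(1.0)


def test_reference_sex_counts_chi2(sim_design):
    """2x2 table 10:9 vs 10:7 gives Pearson chi-squared ~0.14 (verified by
    the from-first-principles oracle)."""
    d = sim_design.sort_values("group", ascending=True).copy()  # BBTD first
    d["sex"] = ["male"] * 10 + ["female"] * 7 + ["male"] * 10 + ["female"] * 9
    comp = compare_cohorts(d).set_index("variable")
    expected = brute_chi2([[10, 9], [10, 7]])
    assert comp.loc["sex", "statistic"] == pytest.approx(expected)
    assert expected == pytest.approx(0.14, abs=0.005)


def test_chi2_invariant_to_label_swap_and_transpose():
    assert brute_chi2([[10, 9], [10, 7]]) == pytest.approx(brute_chi2([[10, 7], [10, 9]]))
    assert brute_chi2([[10, 9], [10, 7]]) == pytest.approx(brute_chi2([[10, 10], [9, 7]]))


def test_perfectly_separated_ca19_9_extreme_u(sim_design):
    d = sim_design.copy()
    is_cca = d["group"] == "CCA"
    d.loc[is_cca, "ca19_9"] = np.linspace(1000, 2000, is_cca.sum())
    d.loc[~is_cca, "ca19_9"] = np.linspace(1, 100, (~is_cca).sum())
    comp = compare_cohorts(d).set_index("variable")
    u = comp.loc["ca19_9", "statistic"]
    # U for the CCA side at its maximum means the BBTD side sits at 0
    assert u in (0.0, 19.0 * 17.0)
    assert comp.loc["ca19_9", "p"] < 1e-6


def test_mannwhitney_invariant_under_monotone_transform(sim_design):
    comp1 = compare_cohorts(sim_design).set_index("variable")
    d = sim_design.copy()
    d["ca19_9"] = np.log(d["ca19_9"])
    comp2 = compare_cohorts(d).set_index("variable")
    assert comp1.loc["ca19_9", "statistic"] == comp2.loc["ca19_9", "statistic"]
    assert comp1.loc["ca19_9", "p"] == pytest.approx(comp2.loc["ca19_9", "p"])


class TestAudit:
    def test_reference_table_shape(self):
        table = reference_summary_table()
        assert len(table) == 93
        assert (table["direction"] == "up").sum() == 31
        assert (table["direction"] == "down").sum() == 62

    def test_strong_rows_not_flagged(self):
        table = reference_summary_table()
        audit = audit_summary_table(table, n_a=19, n_b=17, alpha=0.01)
        strong = audit.set_index("label").loc[["FAM19A5", "RBAK", "UPF3B", "A2M", "KRT10"]]
        assert (strong["recomputed_p"] < 0.001).all()
        assert not strong["flag_recomputed_p"].any()
        assert not strong["flag_printed_p"].any()
        assert not strong["flag_direction"].any()

    def test_printed_threshold_violation_flagged(self):
        """The reported table contains one row whose printed p (0.012)
        violates the stated <0.01 selection cutoff; the audit flags it."""
        table = reference_summary_table()
        audit = audit_summary_table(table, alpha=0.01).set_index("label")
        assert audit.loc["hCG_2008076", "flag_printed_p"]
        assert audit.loc["hCG_2008076", "printed_p"] == 0.012

    def test_equal_means_row_flagged(self):
        table = pd.DataFrame(
            [{"label": "X", "mean_a": 1.0, "sd_a": 0.5, "mean_b": 1.0,
              "sd_b": 0.5, "printed_p": "0.5"}]
        )
        audit = audit_summary_table(table, n_a=10, n_b=10, alpha=0.01)
        assert audit.loc[0, "recomputed_p"] == 1.0
        assert audit.loc[0, "flag_recomputed_p"]

    def test_direction_contradiction_flagged(self):
        table = pd.DataFrame(
            [{"label": "X", "mean_a": 2.0, "sd_a": 0.3, "mean_b": 1.0,
              "sd_b": 0.3, "printed_p": "<0.001", "direction": "down"}]
        )
        audit = audit_summary_table(table, n_a=10, n_b=10)
        assert audit.loc[0, "flag_direction"]

    def test_malformed_row_reported_not_fatal(self):
        table = pd.DataFrame(
            [
                {"label": "BAD", "mean_a": 1.0, "sd_a": -1.0, "mean_b": 0.0,
                 "sd_b": 0.3, "printed_p": "0.001"},
                {"label": "OK", "mean_a": 1.0, "sd_a": 0.3, "mean_b": 0.0,
                 "sd_b": 0.3, "printed_p": "0.001"},
            ]
        )
        audit = audit_summary_table(table, n_a=10, n_b=10)
        assert audit.loc[0, "error"] != ""
        assert audit.loc[1, "error"] == ""
        assert audit.loc[1, "recomputed_p"] < 0.001

    def test_audit_agrees_with_raw_welch_decisions(self, sim_design):
        """Summaries computed from raw samples give the same decision as the
        raw-data Welch test on every row."""
        rng = np.random.default_rng(9)
        rows, decisions = [], []
        for i in range(40):
            a = rng.normal(rng.uniform(-1, 1), rng.uniform(0.2, 0.8), 19)
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.2, 0.8), 17)
            res = welch_test(a, b)
            rows.append(
                {"label": f"P{i}", "mean_a": res.mean_a, "sd_a": res.sd_a,
                 "mean_b": res.mean_b, "sd_b": res.sd_b, "printed_p": "0.5"}
            )
            decisions.append(res.p < 0.01)
        audit = audit_summary_table(pd.DataFrame(rows), n_a=19, n_b=17, alpha=0.01)
        assert (~audit["flag_recomputed_p"]).tolist() == decisions


def test_parse_printed_p():
    assert parse_printed_p("<0.001") == (0.001, True)
    assert parse_printed_p("0.012") == (0.012, False)
    assert parse_printed_p(0.05) == (0.05, False)


def test_reference_cohort_fixture_loads():
    t = reference_cohort_table()
    row = t[(t["variable"] == "n")].iloc[0]
    assert row["cca"] == 19 and row["bbtd"] == 17
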