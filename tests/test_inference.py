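import numpy as np
import pandas as pd
import pytest

from dsbfold.disulfides import Category
from dsbfold.inference import (
    EnzymePools,
    InfeasibleConditionError,
    RATE_COLUMNS,
    correlate_with_growth_rate,
    enzyme_pools,
    evaluate_feasibility,
    infer_minimal_rates,
    load_published_rate_table,
    pseudo_first_order,
    pseudo_first_order_rate,
    summarize_rate_table,
)
from dsbfold.synthetic import SyntheticSpec, ground_truth_condition


class TestPseudoFirstOrder:
    def test_discussion_bracket(self):
        # 1e5 M^-1 s^-1 at 5 uM and 30 uM DsbA
        assert pseudo_first_order_rate(1e5, 5e-6) == pytest.approx(0.5)
        assert pseudo_first_order_rate(1e5, 30e-6) == pytest.approx(3.0)

    def test_zero_constant(self):
        assert pseudo_first_order_rate(0.0, 1e-6) == 0.0

    def test_bilinear(self):
        base = pseudo_first_order_rate(2.0, 3.0)
        assert pseudo_first_order_rate(4.0, 3.0) == pytest.approx(2 * base)
        assert pseudo_first_order_rate(2.0, 6.0) == pytest.approx(2 * base)

    def test_table_row_uses_partner_pools(self, gt_condition):
        row = pseudo_first_order(gt_condition.truth, gt_condition.pools)
        pools = gt_condition.pools
        truth = gt_condition.truth
        assert row["R3"] == pytest.approx(truth.k3 * pools.dsbb)
        assert row["R4_cat1"] == pytest.approx(truth.k45[Category.CAT1] * pools.dsba)
        assert row["R678_cat3"] == pytest.approx(
            truth.k678[Category.CAT3] * pools.dsbcg
        )
        assert row["R2"] == pytest.approx(truth.k2)
        assert set(row) == set(RATE_COLUMNS)


class TestSummaries:
    def test_published_medians_match_print(self):
        table = load_published_rate_table()
        summary = summarize_rate_table(table)
        assert summary.loc["median", "R2"] == pytest.approx(0.07, abs=0.005)
        assert summary.loc["median", "R3"] == pytest.approx(4.35, abs=0.005)
        assert summary.loc["median", "R4_cat1"] == pytest.approx(0.97, abs=0.005)
        assert summary.loc["median", "R45_cat2"] == pytest.approx(0.48, abs=0.005)

    def test_published_fold_ranges_match_print(self):
        summary = summarize_rate_table(load_published_rate_table())
        assert round(summary.loc["range_fold", "R3"], 1) == 2.7
        assert round(summary.loc["range_fold", "R678_cat3"], 1) == 8.2

    def test_constant_column_folds_are_one(self):
        table = pd.DataFrame({c: [2.0, 2.0, 2.0] for c in RATE_COLUMNS})
        summary = summarize_rate_table(table)
        assert (summary.loc["range_fold"] == 1.0).all()
        assert (summary.loc["iqr_fold"] == 1.0).all()
        assert (summary.loc["median"] == 2.0).all()

    def test_nonpositive_rates_rejected(self):
        table = pd.DataFrame({c: [1.0, 0.0] for c in RATE_COLUMNS})
        with pytest.raises(ValueError, match="non-positive"):
            summarize_rate_table(table)

    def test_sorted_list_oracle(self):
        rng = np.random.default_rng(9)
        values = rng.lognormal(0, 1, 21)
        table = pd.DataFrame({c: values for c in RATE_COLUMNS})
        summary = summarize_rate_table(table)
        ordered = np.sort(values)
        assert summary.loc["median", "R2"] == pytest.approx(ordered[10])
        assert summary.loc["range_fold", "R2"] == pytest.approx(ordered[-1] / ordered[0])
        q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation
        assert summary.loc["iqr_fold", "R2"] == pytest.approx(q3 / q1)


class TestCorrelation:
    def test_chemostat_growth_rate_correlation(self):
        table = load_published_rate_table()
        chemostat = table[table["group"] == "Chemostat"]
        r = correlate_with_growth_rate(chemostat, "R3")
        assert r >= 0.98

    def test_exact_linear_and_negated(self):
        table = pd.DataFrame({"growth_rate": [0.1, 0.2, 0.3], "R3": [1.0, 2.0, 3.0]})
        assert correlate_with_growth_rate(table, "R3") == pytest.approx(1.0)
        table["R3"] = -table["R3"]
        assert correlate_with_growth_rate(table, "R3") == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        table = pd.DataFrame({"growth_rate": [0.1, 0.2, 0.3], "R3": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            correlate_with_growth_rate(table, "R3")


class TestInference:
    def test_parameter_recovery(self, gt_condition):
        cond = gt_condition
        inferred = infer_minimal_rates(cond.demand, cond.pools, cond.mu)
        assert np.all(inferred.rate_vector() <= cond.truth.rate_vector())
        check = evaluate_feasibility(inferred, cond.pools, cond.mu)
        assert check.feasible
        assert max(check.accumulation.values()) <= 0.005
        assert check.doubling_time_min <= 1.05 * check.reported_doubling_min

    def test_more_enzyme_needs_lower_constants(self, gt_condition):
        cond = gt_condition
        base = infer_minimal_rates(cond.demand, cond.pools, cond.mu)
        doubled_pools = EnzymePools(
            2 * cond.pools.dsba, 2 * cond.pools.dsbb,
            2 * cond.pools.dsbcg, 2 * cond.pools.dsbd,
        )
        richer = infer_minimal_rates(cond.demand, doubled_pools, cond.mu)
        # association constants fall when the partner enzyme doubles
        assert np.all(richer.rate_vector() <= base.rate_vector() * 1.02)
        assert richer.k3 < base.k3
        assert richer.k45[Category.CAT1] < base.k45[Category.CAT1]

    def test_zero_dsba_is_infeasible(self, gt_condition):
        cond = gt_condition
        pools = EnzymePools(0.0, cond.pools.dsbb, cond.pools.dsbcg, cond.pools.dsbd)
        with pytest.raises(InfeasibleConditionError, match="accumulation"):
            infer_minimal_rates(cond.demand, pools, cond.mu)

    def test_deterministic_restart(self, gt_condition):
        cond = gt_condition
        a = infer_minimal_rates(cond.demand, cond.pools, cond.mu)
        b = infer_minimal_rates(cond.demand, cond.pools, cond.mu)
        np.testing.assert_array_equal(a.rate_vector(), b.rate_vector())


class TestEnzymePools:
    def test_missing_enzyme_rejected(self, small_proteome):
        from dsbfold.enzymes import extract_dsb_levels

        levels = extract_dsb_levels(small_proteome)  # no DsbB / DsbD
        with pytest.raises(ValueError, match="DsbB"):
            enzyme_pools(levels)

    def test_pooled_isomerases(self):
        from dsbfold.enzymes import DsbLevels, EnzymeLevel

        levels = DsbLevels(
            "c",
            {
                "DsbA": EnzymeLevel(1, 100.0),
                "DsbB": EnzymeLevel(1, 10.0),
                "DsbC": EnzymeLevel(1, 30.0),
                "DsbG": EnzymeLevel(1, 5.0),
                "DsbD": EnzymeLevel(1, 2.0),
            },
        )
        pools = enzyme_pools(levels)
        assert pools.dsbcg == pytest.approx(35.0)


def test_published_table_layout():
    table = load_published_rate_table()
    assert len(table) == 20
    assert set(RATE_COLUMNS) <= set(table.columns)
    chemostat_mu = table.loc[table["group"] == "Chemostat", "growth_rate"]
    assert sorted(chemostat_mu) == [0.12, 0.20, 0.35, 0.50]
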