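"""The four savings components and report assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wbvm.definitions import DISEASES, FACTORS
from wbvm.incidence import IncidenceDelta
from wbvm.monetization import (ValuationComponent, assemble_report,
                               net_disease_cost, relative_cost_table,
                               value_diseased, value_incidence,
                               value_newly_diseased, value_nondiseased)


def cohort_frame(rows: list[dict]) -> pd.DataFrame:
    """Wide year table with zero-filled factor/disease columns."""
    base = {f"factor_{f}": 0 for f in FACTORS}
    base.update({f"dis_{d}": 0 for d in DISEASES})
    base.update({f"new_{d}": 0 for d in DISEASES})
    base["pppy_cost"] = 0.0
    filled = [{**base, **r} for r in rows]
    df = pd.DataFrame(filled)
    df.index = [f"m{i}" for i in range(len(df))]
    return df


class TestRelativeCostTable:
    def test_equal_means_give_zero_excess(self):
        cohort = cohort_frame([
            {"pppy_cost": 100.0},
            {"pppy_cost": 100.0, "factor_strengths": 1},
        ])
        table = relative_cost_table(cohort)
        assert table.ratios["strengths"] == pytest.approx(0.0)

    def test_forty_four_percent_excess(self):
        cohort = cohort_frame(
            [{"pppy_cost": 100.0}] * 5
            + [{"pppy_cost": 144.0, "factor_current_health": 1}] * 5)
        table = relative_cost_table(cohort)
        assert table.ratios["current_health"] == pytest.approx(0.44)
        assert table.marginal_cost["current_health"] == pytest.approx(44.0)

    def test_four_member_toy_hand_arithmetic(self):
        cohort = cohort_frame([
            {"pppy_cost": 80.0}, {"pppy_cost": 120.0},          # ref mean 100
            {"pppy_cost": 130.0, "factor_mental_health": 1},
            {"pppy_cost": 190.0, "factor_mental_health": 1},    # mean 160
        ])
        table = relative_cost_table(cohort)
        assert table.reference_pppy == pytest.approx(100.0)
        assert table.ratios["mental_health"] == pytest.approx(0.60)

    def test_empty_reference_group_rejected(self):
        cohort = cohort_frame([{"pppy_cost": 10.0, "factor_strengths": 1}])
        with pytest.raises(ValueError, match="no risks and no disease"):
            relative_cost_table(cohort)


class TestValueNondiseased:
    def toy(self):
        cohort = cohort_frame(
            [{"pppy_cost": 100.0}] * 4
            + [{"pppy_cost": 150.0, "factor_current_health": 1}] * 3
            + [{"pppy_cost": 140.0, "factor_mental_health": 1}] * 3)
        return cohort, relative_cost_table(cohort)

    def test_equal_weights_total_is_sum_of_count_times_cost(self):
        cohort, costs = self.toy()
        avoided = {"current_health": 10.0, "mental_health": 4.0}
        comp = value_nondiseased(avoided, costs, cohort, cohort_n=10,
                                 weighting="equal")
        expected = (10.0 * costs.marginal_cost["current_health"]
                    + 4.0 * costs.marginal_cost["mental_health"])
        assert comp.total == pytest.approx(expected, abs=0.01)
        assert comp.pppy_savings == pytest.approx(comp.total / comp.n_applied,
                                                  abs=0.01)

    def test_single_risk_members_make_weighting_irrelevant(self):
        cohort, costs = self.toy()
        avoided = {"current_health": 10.0}
        equal = value_nondiseased(avoided, costs, cohort, 10, "equal")
        weighted = value_nondiseased(avoided, costs, cohort, 10,
                                     "inverse_risk_count")
        assert weighted.total == pytest.approx(equal.total, abs=0.01)

    def test_multi_risk_member_downweighted(self):
        cohort = cohort_frame(
            [{"pppy_cost": 100.0}] * 4
            + [{"pppy_cost": 180.0, "factor_current_health": 1,
                "factor_mental_health": 1}] * 4)
        costs = relative_cost_table(cohort)
        avoided = {"current_health": 5.0, "mental_health": 5.0}
        equal = value_nondiseased(avoided, costs, cohort, 8, "equal")
        weighted = value_nondiseased(avoided, costs, cohort, 8)
        assert weighted.total == pytest.approx(equal.total / 2, abs=0.01)

    def test_zero_avoided_gives_zero_component(self):
        cohort, costs = self.toy()
        comp = value_nondiseased({}, costs, cohort, 10)
        assert comp.total == 0.0 and comp.pppy_savings == 0.0

    def test_dissavings_sign_preserved(self):
        cohort, costs = self.toy()
        comp = value_nondiseased({"current_health": -3.0}, costs, cohort, 10)
        assert comp.total < 0

    def test_per_factor_detail_keeps_full_cohort_pppy(self):
        cohort, costs = self.toy()
        comp = value_nondiseased({"current_health": 10.0}, costs, cohort,
                                 cohort_n=10, weighting="equal")
        row = comp.detail.loc["current_health"]
        assert row["total_usd"] == pytest.approx(
            10.0 * costs.marginal_cost["current_health"])
        assert row["pppy_usd"] == pytest.approx(row["total_usd"] / 10)


class TestValueIncidence:
    def cohort(self):
        return cohort_frame(
            [{"pppy_cost": 6178.0, "dis_diabetes": 1}] * 4
            + [{"pppy_cost": 2002.0}] * 6)

    def test_net_cost_is_diseased_minus_nondiseased_mean(self):
        assert net_disease_cost(self.cohort(), "diabetes") \
            == pytest.approx(4176.0)

    def test_dollars_are_unrounded_avoided_times_net_cost(self):
        delta = IncidenceDelta("diabetes", 0.01, 0.012, 0.002, 1250, 2.5)
        comp = value_incidence([delta], self.cohort())
        assert comp.total == pytest.approx(2.5 * 4176.0, abs=0.01)
        assert comp.n_applied == 2  # rounded avoided count

    def test_zero_avoided_gives_zero_dollars(self):
        delta = IncidenceDelta("diabetes", 0.01, 0.01, 0.0, 1250, 0.0)
        comp = value_incidence([delta], self.cohort())
        assert comp.total == 0.0 and comp.pppy_savings == 0.0

    def test_disease_without_prevalent_members_skipped(self):
        delta = IncidenceDelta("copd", 0.0, 0.001, 0.001, 1000, 1.0)
        with pytest.warns(UserWarning, match="copd"):
            comp = value_incidence([delta], self.cohort())
        assert comp.total == 0.0

    def test_sub_unit_avoided_reports_total_only(self):
        delta = IncidenceDelta("diabetes", 0.01, 0.0101, 0.0001, 1000, 0.1)
        comp = value_incidence([delta], self.cohort())
        assert comp.total == pytest.approx(0.1 * 4176.0, abs=0.01)
        assert comp.n_applied == 0 and comp.pppy_savings == 0.0


class TestValueNewlyDiseased:
    def years(self, resolve: bool):
        y2_rows = (
            [{"pppy_cost": 3000.0, "dis_diabetes": 1, "new_diabetes": 1,
              "factor_current_health": 1}] * 5
            + [{"pppy_cost": 2000.0, "dis_diabetes": 1,
                "new_diabetes": 1}] * 5)
        y2 = cohort_frame(y2_rows)
        y1 = cohort_frame([{"factor_current_health": 1}] * 10)
        if not resolve:
            y1["factor_current_health"] = y2["factor_current_health"]
        return y1, y2

    def test_no_resolved_risk_gives_zero(self):
        y1, y2 = self.years(resolve=False)
        comp = value_newly_diseased(y1, y2)
        assert comp.total == 0.0
        assert comp.n_applied == 10

    def test_hand_set_cell_means_match_arithmetic(self):
        y1, y2 = self.years(resolve=True)
        comp = value_newly_diseased(y1, y2)
        # pct diff = 3000/2000 - 1 = 0.5; avg diseased PPPY = 2500;
        # 5 members resolved the risk
        assert comp.total == pytest.approx(5 * 0.5 * 2500.0, abs=0.01)
        assert comp.pppy_savings == pytest.approx(comp.total / 10, abs=0.01)

    def test_no_newly_diseased_warns_and_zeroes(self):
        y1 = cohort_frame([{}] * 4)
        y2 = cohort_frame([{}] * 4)
        with pytest.warns(UserWarning, match="no newly diseased"):
            comp = value_newly_diseased(y1, y2)
        assert comp.total == 0.0 and comp.n_applied == 0


class TestValueDiseased:
    def test_zero_engaged_gives_zero(self):
        comp = value_diseased(["a", "b"], {"a": False, "b": False})
        assert comp.total == 0.0

    def test_engaged_count_times_rate(self):
        members = [f"m{i}" for i in range(896)]
        engaged = {m: i < 190 for i, m in enumerate(members)}
        comp = value_diseased(members, engaged)
        assert comp.total == pytest.approx(55873.30, abs=0.01)
        assert comp.pppy_savings == pytest.approx(62.36, abs=0.01)
        assert comp.n_applied == 896

    def test_rate_override_is_linear(self):
        members = [f"m{i}" for i in range(100)]
        comp = value_diseased(members, {m: True for m in members},
                              annual_rate=12.0)
        assert comp.total == pytest.approx(1200.0)


def component(name, total, members=()):
    return ValuationComponent(name=name, n_applied=len(members),
                              pppy_savings=0.0,
                              total_cents=round(total * 100),
                              sd=0.0, members=frozenset(members))


class TestAssembleReport:
    def test_published_component_totals_reproduce_grand_total(self):
        report = assemble_report({
            "nondiseased": component("nondiseased", 134985),
            "incidence": component("incidence", 39897),
            "diseased": component("diseased", 55956),
            "newly_diseased": component("newly_diseased", 7289),
        }, cohort_n=6170)
        assert report.grand_total == pytest.approx(238127.0)
        assert report.grand_pppy == pytest.approx(38.59)

    def test_all_zero_components_give_zero_report(self):
        report = assemble_report(
            {n: component(n, 0.0) for n in
             ("nondiseased", "incidence", "diseased", "newly_diseased")},
            cohort_n=100)
        assert report.grand_total == 0.0 and report.grand_pppy == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(totals=st.lists(st.integers(-10 ** 7, 10 ** 7), min_size=4,
                           max_size=4))
    def test_grand_total_is_exact_cent_summation(self, totals):
        names = ("nondiseased", "incidence", "diseased", "newly_diseased")
        report = assemble_report(
            {n: component(n, t / 100) for n, t in zip(names, totals)},
            cohort_n=50)
        assert report.grand_total_cents == sum(totals)

    def test_overlapping_membership_rejected(self):
        with pytest.raises(ValueError, match="more than one"):
            assemble_report({
                "nondiseased": component("nondiseased", 1.0, ["m1"]),
                "incidence": component("incidence", 0.0),
                "diseased": component("diseased", 1.0, ["m1"]),
                "newly_diseased": component("newly_diseased", 0.0),
            }, cohort_n=10)

    def test_missing_component_rejected(self):
        with pytest.raises(ValueError, match="expected components"):
            assemble_report({"nondiseased": component("nondiseased", 0.0)},
                            cohort_n=10)


def test_scale_equivariance_of_dollar_outputs():
    """Multiplying all costs by k multiplies every dollar output by k."""
    k = 3.0
    rows = ([{"pppy_cost": 100.0}] * 4
            + [{"pppy_cost": 150.0, "factor_current_health": 1}] * 4
            + [{"pppy_cost": 900.0, "dis_diabetes": 1}] * 2)
    base = cohort_frame(rows)
    scaled = base.copy()
    scaled["pppy_cost"] *= k
    avoided = {"current_health": 7.0}
    c1 = value_nondiseased(avoided, relative_cost_table(base), base, 10)
    c2 = value_nondiseased(avoided, relative_cost_table(scaled), scaled, 10)
    assert c2.total == pytest.approx(k * c1.total, rel=1e-9)
    assert net_disease_cost(scaled, "diabetes") == pytest.approx(
        k * net_disease_cost(base, "diabetes"))
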