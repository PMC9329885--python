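"""Index-chemical dose balance, isoboles and response additivity."""

import numpy as np
import pytest

from toxmix import (balance_table, classify_point, dose_at_response,
                    equivalent_dose_balance, isobole,
                    observed_percent_response, percent_response,
                    response_additivity_table)
from toxmix.drmodels import LinearDRFit
from toxmix.reference import (FTS_COMPONENT_FIT, FTS_MIXTURE_FIT,
                              PFOS_COMPONENT_FIT, PFOS_MIXTURE_FIT)

GRID = [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]

#: measured binary-mixture regimen: (group, PFOS ug/L, 6:2 FTS ug/L)
MIX_REGIMEN = [("T1", 0.075, 1.3), ("T2", 0.63, 21.0), ("T3", 29.0, 683.0),
               ("T4", 241.0, 5825.0), ("T5", 1570.0, 15229.0)]


@pytest.fixture(scope="module")
def balance_rows():
    return {r.level: r for r in equivalent_dose_balance(
        PFOS_COMPONENT_FIT, PFOS_MIXTURE_FIT, FTS_MIXTURE_FIT, GRID)}


class TestEquivalentDoseBalance:
    def test_published_50_percent_row(self, balance_rows):
        row = balance_rows[0.5]
        assert row.flag == "ok"
        assert row.balance == pytest.approx(495, rel=0.02)
        assert row.rp_co_index == pytest.approx(37.8, rel=0.02)

    def test_low_levels_flagged_antagonistic(self, balance_rows):
        # mixture needs MORE index chemical than the component study here
        assert balance_rows[0.3].flag == "antagonistic"
        assert balance_rows[0.4].flag == "antagonistic"
        assert np.isnan(balance_rows[0.3].balance)

    def test_20_percent_below_intercept(self, balance_rows):
        assert balance_rows[0.2].flag == "below_intercept"
        assert balance_rows[0.2].dose_index_alone.status == "below_intercept"

    def test_degenerate_identical_fits_give_zero_balance(self):
        rows = equivalent_dose_balance(PFOS_COMPONENT_FIT, PFOS_COMPONENT_FIT,
                                       FTS_MIXTURE_FIT, [0.5, 0.8])
        for r in rows:
            # zero balance is reported as a (boundary) antagonistic flag,
            # never as a spurious potency ratio
            assert r.flag == "antagonistic"

    def test_decomposition_identity(self, balance_rows):
        for r in balance_rows.values():
            if r.flag == "ok":
                assert r.dose_index_mix.dose + r.balance == pytest.approx(
                    r.dose_index_alone.dose, rel=1e-12)
                assert r.rp_index_co * r.rp_co_index == pytest.approx(
                    1.0, abs=1e-12)

    def test_published_ratio_band_over_upper_levels(self, balance_rows):
        ratios = [balance_rows[lv].rp_co_index for lv in (0.5, 0.6, 0.7, 0.8, 0.9)]
        assert all(10 <= r <= 40 for r in ratios)

    def test_table_mirrors_rows(self, balance_rows):
        frame = balance_table(list(balance_rows.values()), "PFOS", "FTS")
        assert list(frame["flag"]) == [r.flag for r in balance_rows.values()]
        assert frame.shape[0] == len(GRID)


class TestIsobole:
    def test_endpoints_match_component_inversions(self):
        line = isobole(PFOS_COMPONENT_FIT, FTS_COMPONENT_FIT, 0.5)
        assert line.x_intercept == pytest.approx(2136, rel=0.01)
        assert line.y_intercept == pytest.approx(45193, rel=0.01)
        # shared definition with the relative-potency curve
        assert line.x_intercept == dose_at_response(PFOS_COMPONENT_FIT, 0.5).dose
        assert line.y_intercept == dose_at_response(FTS_COMPONENT_FIT, 0.5).dose

    def test_identical_fits_give_symmetric_line(self):
        line = isobole(PFOS_COMPONENT_FIT, PFOS_COMPONENT_FIT, 0.5)
        assert line.x_intercept == pytest.approx(line.y_intercept, rel=1e-12)

    def test_no_isobole_below_intercept(self):
        assert isobole(PFOS_COMPONENT_FIT, FTS_COMPONENT_FIT, 0.10) is None


class TestClassifyPoint:
    def test_point_on_additive_prediction_is_additive(self):
        d_i, d_c = 500.0, 5000.0
        pred = min(max(percent_response(PFOS_COMPONENT_FIT, d_i), 0)
                   + max(percent_response(FTS_COMPONENT_FIT, d_c), 0), 1.0)
        call = classify_point((d_i, d_c, pred), PFOS_COMPONENT_FIT,
                              FTS_COMPONENT_FIT)
        assert call.call == "additive" and call.deviation == pytest.approx(0.0)

    def test_shrinking_doses_of_online_point_flips_to_synergistic(self):
        d_i, d_c = 500.0, 5000.0
        pred = min(max(percent_response(PFOS_COMPONENT_FIT, d_i), 0)
                   + max(percent_response(FTS_COMPONENT_FIT, d_c), 0), 1.0)
        call = classify_point((0.2 * d_i, 0.2 * d_c, pred),
                              PFOS_COMPONENT_FIT, FTS_COMPONENT_FIT)
        assert call.call == "synergistic"

    def test_zero_doses_zero_response_additive_under_intercept_baseline(self):
        call = classify_point((0.0, 0.0, 0.0), PFOS_COMPONENT_FIT,
                              FTS_COMPONENT_FIT, baseline="intercept")
        assert call.call == "additive" and call.deviation == 0.0

    def test_top_mixture_group_call_depends_on_baseline_convention(self):
        """The observed top-dose mixture response (51% reduction) sits below
        the control-mean-baseline additive prediction (~44% + ~22%), an
        antagonistic deviation; only under the intercept baseline (~22% +
        ~16%) does it exceed the prediction and read as synergistic."""
        point = (1570.0, 15229.0, 0.51)
        ctrl = classify_point(point, PFOS_COMPONENT_FIT, FTS_COMPONENT_FIT)
        assert ctrl.predicted == pytest.approx(0.66, abs=0.01)
        assert ctrl.call == "antagonistic"
        intc = classify_point(point, PFOS_COMPONENT_FIT, FTS_COMPONENT_FIT,
                              baseline="intercept")
        assert intc.predicted == pytest.approx(0.38, abs=0.01)
        assert intc.deviation > 0
        assert intc.call == "synergistic"

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError, match="doses"):
            classify_point((-1.0, 0.0, 0.1), PFOS_COMPONENT_FIT,
                           FTS_COMPONENT_FIT)


class TestResponseAdditivity:
    def test_overprediction_flagged_except_top_group(self):
        observed = {"T1": 0.01, "T2": 0.02, "T3": 0.03, "T4": 0.08,
                    "T5": 0.51}
        frame = response_additivity_table(PFOS_COMPONENT_FIT,
                                          FTS_COMPONENT_FIT, MIX_REGIMEN,
                                          observed)
        flags = dict(zip(frame["group"], frame["overpredicted"]))
        assert all(flags[g] for g in ("T1", "T2", "T3", "T4"))

    def test_zero_concentrations_predict_baseline_response(self):
        frame = response_additivity_table(
            PFOS_COMPONENT_FIT, FTS_COMPONENT_FIT,
            [("T0", 0.0, 0.0)], {"T0": 0.0})
        assert frame["pred_index"].iloc[0] == pytest.approx(
            percent_response(PFOS_COMPONENT_FIT, 0.0))
        assert frame["pred_co"].iloc[0] == pytest.approx(
            percent_response(FTS_COMPONENT_FIT, 0.0))

    def test_predicted_sums_match_arithmetic_oracle(self):
        """Spreadsheet-style recomputation of each group's prediction."""
        observed = {g: 0.1 for g, _, _ in MIX_REGIMEN}
        frame = response_additivity_table(PFOS_COMPONENT_FIT,
                                          FTS_COMPONENT_FIT, MIX_REGIMEN,
                                          observed)
        for (g, ci, cc), (_, row) in zip(MIX_REGIMEN, frame.iterrows()):
            p_i = 1 - (PFOS_COMPONENT_FIT.a + PFOS_COMPONENT_FIT.b * ci) / PFOS_COMPONENT_FIT.R0
            p_c = 1 - (FTS_COMPONENT_FIT.a + FTS_COMPONENT_FIT.b * cc) / FTS_COMPONENT_FIT.R0
            expected = min(max(p_i, 0.0) + max(p_c, 0.0), 1.0)
            assert row["pred_sum"] == pytest.approx(expected, abs=1e-9)

    def test_missing_concentration_rejected(self):
        with pytest.raises(ValueError, match="missing a concentration"):
            response_additivity_table(PFOS_COMPONENT_FIT, FTS_COMPONENT_FIT,
                                      [("T1", None, 5.0)], {"T1": 0.1})


class TestObservedResponse:
    def test_group_means_versus_control(self, pfos_table):
        obs = observed_percent_response(pfos_table, "SBA_mm2")
        assert obs["T0"] == pytest.approx(0.0, abs=1e-12)
        alive = pfos_table[pfos_table["alive"]]
        means = alive.groupby("treatment")["SBA_mm2"].mean()
        assert obs["T4"] == pytest.approx(1 - means["T4"] / means["T0"])
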