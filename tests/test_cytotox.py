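"""Modified Z-score outliers, fold changes, treatment tests and grading."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pdmkit.cytotox import (
    FoldChangeTable,
    GradingError,
    PairingError,
    TreatmentTestResult,
    compute_fold_changes,
    grade_sensitivity,
    map_p_to_grade,
    modified_zscores,
)
from pdmkit.cytotox import TestingError as CytotoxTestingError
from pdmkit.cytotox import test_treatment_effects as run_treatment_tests
from tests.conftest import make_plate


class TestModifiedZScores:
    def test_hand_computed_single_outlier(self):
        scored = modified_zscores([1, 2, 3, 4, 100])
        # median 3, MAD 1: M for 100 is 0.6745 * 97
        assert scored[-1].mscore == pytest.approx(65.4265)
        assert [z.is_outlier for z in scored] == [False, False, False, False, True]

    def test_constant_vector_has_no_outliers(self):
        assert not any(z.is_outlier for z in modified_zscores([5, 5, 5, 5]))

    def test_mad_zero_falls_back_to_mean_absolute_deviation(self):
        scored = modified_zscores([5, 5, 5, 5, 100])
        # MAD = 0; meanAD = 19, so M = 95 / (1.253314 * 19) ~ 3.99
        assert scored[-1].mscore == pytest.approx(95 / (1.253314 * 19))
        assert scored[-1].is_outlier
        assert not any(z.is_outlier for z in scored[:-1])

    @given(
        st.lists(
            st.floats(min_value=-1e3, max_value=1e3).map(lambda v: round(v, 3)),
            min_size=3,
            max_size=12,
        ),
        st.floats(min_value=-1e3, max_value=1e3).map(lambda v: round(v, 3)),
    )
    def test_flags_invariant_under_location_shift(self, values, shift):
        base = [z.is_outlier for z in modified_zscores(values)]
        moved = [z.is_outlier for z in modified_zscores([v + shift for v in values])]
        assert base == moved

    @pytest.mark.parametrize("short", [[], [1.0], [1.0, 2.0]])
    def test_fewer_than_three_values_rejected(self, short):
        with pytest.raises(ValueError, match=">= 3"):
            modified_zscores(short)


class TestFoldChanges:
    def test_treated_identical_to_vehicle_gives_unit_fc(self):
        plate = make_plate(
            {(75.0, 72): [100, 110, 105]}, {72: [100, 110, 105]}
        )
        fct = compute_fold_changes(plate)
        assert fct.strata["fc"].iloc[0] == pytest.approx(1.0)

    def test_direct_arithmetic_on_stated_rule(self):
        plate = make_plate(
            {(75.0, 72): [200, 220, 210]}, {72: [100, 110, 105]}
        )
        fct = compute_fold_changes(plate)
        assert fct.strata["fc"].iloc[0] == pytest.approx(210 / 105)

    def test_scale_invariance_within_model_time_block(self):
        treated = {(75.0, 72): [180.0, 210.0, 195.0]}
        vehicle = {72: [90.0, 100.0, 95.0]}
        fc1 = compute_fold_changes(make_plate(treated, vehicle)).strata["fc"].iloc[0]
        scaled = make_plate(
            {k: [7.3 * v for v in vs] for k, vs in treated.items()},
            {k: [7.3 * v for v in vs] for k, vs in vehicle.items()},
        )
        fc2 = compute_fold_changes(scaled).strata["fc"].iloc[0]
        assert fc1 == pytest.approx(fc2)

    def test_planted_outlier_removed_before_averaging(self):
        clean = [100.0, 104.0, 96.0, 101.0, 99.0, 100.0]
        spiked = clean[:-1] + [clean[-1] * 5]
        fc_clean = compute_fold_changes(
            make_plate({(75.0, 72): clean}, {72: clean})
        ).strata["fc"].iloc[0]
        fct = compute_fold_changes(make_plate({(75.0, 72): spiked}, {72: clean}))
        assert len(fct.outliers) == 1
        assert fct.outliers["rfu"].iloc[0] == pytest.approx(500.0)
        assert fct.strata["fc"].iloc[0] == pytest.approx(fc_clean, rel=0.02)

    def test_unmatched_stratum_raises_pairing_error(self):
        plate = make_plate({(75.0, 48): [1, 2, 3]}, {72: [1, 2, 3]})
        with pytest.raises(PairingError, match="48"):
            compute_fold_changes(plate)


def _fct_from_cells(cells: dict, vehicle_sd: float = 0.05, n_veh: int = 6):
    """FoldChangeTable stub: cells maps (dose, time) -> replicate FC list."""
    rng = np.random.default_rng(0)
    rep = pd.DataFrame(
        [
            ("M1", "carboplatin", dose, t, fc)
            for (dose, t), fcs in cells.items()
            for fc in fcs
        ],
        columns=["model", "drug", "dose_uM", "time_h", "fc"],
    )
    times = sorted({t for _, t in cells})
    veh = pd.DataFrame(
        [
            ("M1", t, 1.0 + rng.normal(0, vehicle_sd))
            for t in times
            for _ in range(n_veh)
        ],
        columns=["model", "time_h", "fc"],
    )
    return FoldChangeTable(
        strata=pd.DataFrame(), replicate_fc=rep, vehicle_fc=veh,
        outliers=pd.DataFrame(),
    )


class TestTreatmentEffects:
    def test_planted_strong_effect_is_highly_significant(self):
        rng = np.random.default_rng(1)
        cells = {
            (d, t): list(1.0 + rng.normal(0, 0.1, 6))
            for d in (75.0, 150.0)
            for t in (24, 72)
        }
        cells[(150.0, 72)] = list(2.0 + rng.normal(0, 0.15, 6))
        res = run_treatment_tests(_fct_from_cells(cells), "M1", "carboplatin")
        hit = res.cells.query("dose_uM == 150.0 and time_h == 72")
        assert hit["p_adj"].iloc[0] < 0.001

    def test_single_replicate_per_cell_rejected(self):
        cells = {(d, t): [1.0] for d in (75.0, 150.0) for t in (24, 72)}
        with pytest.raises(CytotoxTestingError, match="insufficient replication"):
            run_treatment_tests(_fct_from_cells(cells), "M1", "carboplatin")

    def test_single_dose_rejected(self):
        cells = {(75.0, t): [1.0, 1.1, 0.9] for t in (24, 72)}
        with pytest.raises(CytotoxTestingError, match="2 doses"):
            run_treatment_tests(_fct_from_cells(cells), "M1", "carboplatin")


class TestGrading:
    @pytest.mark.parametrize(
        "p, grade", [(0.2, 0), (0.04, 1), (0.004, 2), (0.0004, 3), (0.05, 0)]
    )
    def test_significance_level_mapping(self, p, grade):
        assert map_p_to_grade(p) == grade

    def _result(self, cells):
        df = pd.DataFrame(
            [(d, t, 6, 1.0, p, p) for (d, t), p in cells.items()],
            columns=["dose_uM", "time_h", "n", "mean_fc", "p_raw", "p_adj"],
        )
        return TreatmentTestResult("M1", "carboplatin", df, pd.DataFrame())

    def test_grade_uses_minimum_p_across_doses_at_final_time(self):
        grade = grade_sensitivity(
            self._result({(75.0, 72): 0.2, (150.0, 72): 0.004, (75.0, 24): 1e-9})
        )
        assert grade.grade == 2 and grade.responder

    def test_decreasing_any_p_never_decreases_grade(self):
        base = {(75.0, 72): 0.03, (150.0, 72): 0.2}
        g0 = grade_sensitivity(self._result(base)).grade
        for key in base:
            lowered = dict(base)
            lowered[key] /= 100
            assert grade_sensitivity(self._result(lowered)).grade >= g0

    def test_missing_final_time_point_raises(self):
        with pytest.raises(GradingError, match="72"):
            grade_sensitivity(self._result({(75.0, 24): 0.001}))
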