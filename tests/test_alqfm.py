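import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mwfp import (
    FingerprintMatrix,
    GradeCriteria,
    MWFPError,
    assign_grade,
    evaluate_study,
    grade_discrimination,
    reference_fingerprint,
    similarity_parameters,
)

pos_vectors = st.lists(
    st.floats(0.01, 1e3, allow_nan=False, allow_infinity=False),
    min_size=2,
    max_size=20,
)


def _matrix(areas, channel="fused"):
    areas = np.asarray(areas, dtype=float)
    return FingerprintMatrix(
        sample_ids=[f"S{i+1}" for i in range(areas.shape[0])],
        peak_rts=np.arange(1.0, areas.shape[1] + 1),
        areas=areas,
        channel=channel,
    )


class TestReferenceFingerprint:
    def test_single_row_mean_is_that_row(self):
        m = _matrix([[1.0, 2.0, 3.0]])
        np.testing.assert_array_equal(
            reference_fingerprint(m).areas, [1.0, 2.0, 3.0]
        )

    def test_mean_of_two_rows(self):
        m = _matrix([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_array_equal(reference_fingerprint(m).areas, [2.0, 3.0])

    def test_mean_matches_brute_force_columns(self):
        rng = np.random.default_rng(0)
        areas = rng.uniform(0.5, 5.0, size=(32, 7))
        ref = reference_fingerprint(_matrix(areas))
        expected = np.array([areas[:, j].sum() / 32 for j in range(7)])
        np.testing.assert_allclose(ref.areas, expected, atol=1e-12)

    def test_sample_mode_and_unknown_id(self):
        m = _matrix([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_array_equal(
            reference_fingerprint(m, "sample:S2").areas, [3.0, 4.0]
        )
        with pytest.raises(MWFPError):
            reference_fingerprint(m, "sample:nope")


class TestSimilarityParameters:
    def test_identity_gives_perfect_scores(self):
        y = np.array([1.0, 5.0, 2.0])
        sm, pm, alpha = similarity_parameters(y, y)
        assert sm == pytest.approx(1.0)
        assert pm == pytest.approx(100.0)
        assert alpha == pytest.approx(0.0, abs=1e-12)

    def test_halved_sample_keeps_profile(self):
        y = np.array([1.0, 5.0, 2.0])
        sm, pm, alpha = similarity_parameters(0.5 * y, y)
        assert sm == pytest.approx(1.0)
        assert pm == pytest.approx(50.0)
        assert alpha == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_two_peak_case(self):
        # x=(1,0), y=(1,1): S_cos=1/sqrt(2), S_prof=0.5, ratios (1,0)
        sm, pm, alpha = similarity_parameters([1.0, 0.0], [1.0, 1.0])
        assert sm == pytest.approx((1 / np.sqrt(2) + 0.5) / 2, abs=1e-5)
        assert pm == pytest.approx(50.0)
        assert alpha == pytest.approx(np.sqrt(2) * 0.5 / 0.5, abs=1e-5)

    @settings(deadline=None, max_examples=60)
    @given(y=pos_vectors, c=st.floats(0.01, 100.0), data=st.data())
    def test_scale_invariance_of_sm_and_alpha(self, y, c, data):
        y = np.asarray(y)
        x = y * np.asarray(
            data.draw(
                st.lists(
                    st.floats(0.1, 10.0), min_size=len(y), max_size=len(y)
                )
            )
        )
        sm1, pm1, a1 = similarity_parameters(x, y)
        sm2, pm2, a2 = similarity_parameters(c * x, y)
        assert sm2 == pytest.approx(sm1, rel=1e-9)
        assert a2 == pytest.approx(a1, rel=1e-9, abs=1e-12)
        assert pm2 == pytest.approx(c * pm1, rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(MWFPError):
            similarity_parameters([1.0, 2.0], [1.0])
        with pytest.raises(MWFPError):
            similarity_parameters([1.0, 2.0], [1.0, 0.0])
        with pytest.raises(MWFPError):
            similarity_parameters([-1.0, 2.0], [1.0, 1.0])


class TestAssignGrade:
    @pytest.mark.parametrize(
        "sm,pm,alpha,expected",
        [
            (0.883, 94.3, 0.047, 3),  # printed fusion row S1
            (0.848, 59.4, 0.070, 7),  # printed fusion row S20
            (1.0, 100.0, 0.0, 1),
            (0.45, 100.0, 0.01, 8),  # Sm below the grade-7 floor
        ],
    )
    def test_reference_grades(self, sm, pm, alpha, expected):
        assert assign_grade(sm, pm, alpha) == expected

    @pytest.mark.parametrize(
        "sm,pm,alpha,expected",
        [
            (0.95, 100.0, 0.0, 1),  # Sm exactly on the grade-1 floor
            (1.0, 70.0, 0.0, 5),  # Pm exactly on the grade-5 band edge
            (1.0, 100.0, 0.05, 1),  # alpha exactly on the grade-1 cap
            (1.0, 105.0, 0.0, 1),
        ],
    )
    def test_band_boundaries_are_inclusive(self, sm, pm, alpha, expected):
        assert assign_grade(sm, pm, alpha) == expected

    @settings(deadline=None, max_examples=80)
    @given(
        sm=st.floats(0.0, 1.0),
        pm=st.floats(0.0, 200.0),
        alpha=st.floats(0.0, 1.0),
        d_sm=st.floats(0.0, 0.3),
        d_pm=st.floats(0.0, 40.0),
        d_alpha=st.floats(0.0, 0.3),
    )
    def test_grade_monotone_in_each_parameter(
        self, sm, pm, alpha, d_sm, d_pm, d_alpha
    ):
        base = assign_grade(sm, pm, alpha)
        worse_sm = assign_grade(max(sm - d_sm, 0.0), pm, alpha)
        away = pm + d_pm if pm >= 100 else max(pm - d_pm, 0.0)
        worse_pm = assign_grade(sm, away, alpha)
        worse_alpha = assign_grade(sm, pm, alpha + d_alpha)
        assert worse_sm >= base
        assert worse_pm >= base
        assert worse_alpha >= base

    def test_criteria_table_validation(self):
        with pytest.raises(MWFPError):
            GradeCriteria(sm_min=(0.95,) * 7)
        with pytest.raises(MWFPError):
            assign_grade(-0.1, 100.0, 0.0)


class TestEvaluateStudy:
    def test_identical_samples_all_grade_one(self):
        m = _matrix(np.tile([2.0, 4.0, 1.0], (5, 1)))
        res = evaluate_study({"fused": m})
        assert (res["grade"] == 1).all()

    def test_halved_sample_pm_follows_mean_reference(self):
        base = np.array([2.0, 4.0, 1.0])
        areas = np.tile(base, (4, 1)).astype(float)
        areas[0] = 0.5 * base
        res = evaluate_study({"fused": _matrix(areas)}).set_index("sample_id")
        # mean reference = (0.5 + 3) / 4 = 0.875 of base, so Pm = 50/0.875
        assert res.loc["S1", "pm"] == pytest.approx(100 * 0.5 / 0.875, rel=1e-9)
        assert res.loc["S2", "pm"] == pytest.approx(100 / 0.875, rel=1e-9)

    def test_one_result_per_sample_and_channel(self):
        rng = np.random.default_rng(1)
        mats = {
            ch: _matrix(rng.uniform(1, 5, (32, 6)), channel=ch)
            for ch in ("203", "270", "325", "fused")
        }
        res = evaluate_study(mats)
        assert len(res) == 32 * 4


class TestGradeDiscrimination:
    def test_perfect_separation(self):
        grades = {f"A{i}": 1 for i in range(5)} | {f"B{i}": 8 for i in range(5)}
        labels = {f"A{i}": "x" for i in range(5)} | {f"B{i}": "y" for i in range(5)}
        c = grade_discrimination(grades, labels, cutoff=4, similar_group="x")
        assert c.errors == 0

    def test_swapped_orientation_counts_complement(self):
        rng = np.random.default_rng(2)
        grades = {f"S{i}": int(g) for i, g in enumerate(rng.integers(1, 9, 32))}
        labels = {f"S{i}": ("a" if i < 15 else "b") for i in range(32)}
        e1 = grade_discrimination(grades, labels, similar_group="a").errors
        e2 = grade_discrimination(grades, labels, similar_group="b").errors
        assert e1 + e2 == 32

    def test_more_than_two_groups_rejected(self):
        grades = {"A": 1, "B": 2, "C": 3}
        labels = {"A": "x", "B": "y", "C": "z"}
        with pytest.raises(MWFPError):
            grade_discrimination(grades, labels)
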