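import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petkin import (
    DomainError,
    InsufficientDataError,
    TimeActivityCurve,
    UnitError,
    auc_trapezoid,
    fold_change,
    percent_id_per_g,
    summarize_groups,
    suv,
    welch_t_test,
)

from _oracles import permutation_test_greater, welch_by_hand


class TestNormalizations:
    def test_percent_id_per_g(self):
        assert percent_id_per_g(1.0, 100.0) == pytest.approx(1.0)
        assert percent_id_per_g(1.0, 200.0) == pytest.approx(0.5)  # doubling dose halves

    def test_suv_definitional_unity(self):
        dose, weight = 9.9, 25.0
        assert suv(dose / weight, dose, weight) == pytest.approx(1.0)

    def test_zero_dose_or_weight_rejected(self):
        with pytest.raises(DomainError):
            percent_id_per_g(1.0, 0.0)
        with pytest.raises(DomainError):
            suv(1.0, 9.9, 0.0)


class TestAuc:
    def test_constant_curve(self, schedule):
        tac = TimeActivityCurve(schedule=schedule, value=np.ones(25))
        assert auc_trapezoid(tac) == pytest.approx(7200.0, rel=0.01)

    def test_linear_ramp(self, schedule):
        mid_s = schedule.mid * 60.0
        tac = TimeActivityCurve(schedule=schedule, value=mid_s / 7200.0)
        assert auc_trapezoid(tac) == pytest.approx(3600.0, rel=0.01)

    def test_unit_enforced(self, schedule):
        tac = TimeActivityCurve(schedule=schedule, value=np.ones(25), unit="kBq/mL")
        with pytest.raises(UnitError):
            auc_trapezoid(tac)

    @given(st.floats(0.1, 50.0))
    @settings(deadline=None, max_examples=20)
    def test_homogeneity(self, schedule, c):
        rng = np.random.default_rng(1)
        v = rng.uniform(0.1, 3.0, 25)
        a1 = auc_trapezoid(TimeActivityCurve(schedule=schedule, value=v))
        a2 = auc_trapezoid(TimeActivityCurve(schedule=schedule, value=c * v))
        assert a2 == pytest.approx(c * a1, rel=1e-9)

    def test_additivity_over_curves_and_subintervals(self, schedule):
        rng = np.random.default_rng(2)
        v1 = rng.uniform(0.1, 3.0, 25)
        v2 = rng.uniform(0.1, 3.0, 25)
        t1 = TimeActivityCurve(schedule=schedule, value=v1)
        t2 = TimeActivityCurve(schedule=schedule, value=v2)
        both = TimeActivityCurve(schedule=schedule, value=v1 + v2)
        assert auc_trapezoid(both) == pytest.approx(auc_trapezoid(t1) + auc_trapezoid(t2), rel=1e-9)
        # splitting the node set at an interior node conserves the area
        mid_s = schedule.mid * 60.0
        nodes = np.concatenate([[0.0], mid_s, [schedule.end * 60.0]])
        vals = np.concatenate([[0.0], v1, [v1[-1]]])
        k = 13
        total = np.trapezoid(vals, nodes)
        split = np.trapezoid(vals[: k + 1], nodes[: k + 1]) + np.trapezoid(vals[k:], nodes[k:])
        assert split == pytest.approx(total, rel=1e-12)
        assert auc_trapezoid(t1) == pytest.approx(total, rel=1e-12)


class TestWelch:
    def test_identical_samples(self):
        r = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], sides="one")
        assert r.t_stat == pytest.approx(0.0)
        assert r.p_value == pytest.approx(0.5)

    def test_hand_computed_oracle(self):
        # a={1,2,3}, b={4,5,6}: t = 3/sqrt(2/3), df = 4 by the textbook formulas
        r = welch_t_test([1, 2, 3], [4, 5, 6], sides="two")
        t_hand, df_hand = welch_by_hand([1, 2, 3], [4, 5, 6])
        assert t_hand == pytest.approx(3.0 / np.sqrt(2.0 / 3.0))
        assert df_hand == pytest.approx(4.0)
        assert r.t_stat == pytest.approx(t_hand, rel=1e-12)
        assert r.df == pytest.approx(df_hand, rel=1e-12)
        assert r.p_value == pytest.approx(0.021311641128756713, rel=1e-9)

    def test_one_sided_is_half_two_sided_in_direction(self):
        one = welch_t_test([1, 2, 3], [4, 5, 6], sides="one")
        two = welch_t_test([1, 2, 3], [4, 5, 6], sides="two")
        assert one.p_value == pytest.approx(two.p_value / 2.0)

    def test_equal_variance_equal_n_df_matches_pooled(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 12)
        b = (b - b.mean()) / b.std(ddof=1) * a.std(ddof=1) + a.mean() + 0.5
        r = welch_t_test(a, b)
        assert r.df == pytest.approx(22.0, rel=1e-9)

    def test_agrees_with_permutation_direction(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(4.0, 1.0, 10)
        r = welch_t_test(a, b, sides="one")
        p_perm = permutation_test_greater(a, b)
        assert (r.p_value < 0.05) == (p_perm < 0.05)

    def test_small_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            welch_t_test([1.0], [2.0, 3.0])


class TestFoldChange:
    def test_densitometry_ratio(self):
        assert fold_change(0.93, 0.43) == 2.16

    def test_identity_and_doubling(self):
        assert fold_change(1.3, 1.3) == 1.0
        assert fold_change(1.0, 0.5) == 2.0

    def test_reciprocal_product_is_one(self):
        # to full precision (before the 2-decimal display rounding)
        a, b = 0.93, 0.43
        assert (a / b) * (b / a) == pytest.approx(1.0)

    def test_zero_denominator(self):
        with pytest.raises(DomainError):
            fold_change(1.0, 0.0)


class TestSummarizeGroups:
    @staticmethod
    def _fits(values):
        from petkin import KineticParameters, macroparameters
        from petkin.fitting import PARAM_NAMES, KineticFit

        fits = []
        for i, (k1, k2, ratio, kb) in enumerate(values):
            p = KineticParameters(K1=k1, k2=k2, k3=ratio * 0.05, k4=0.05, Kb=kb)
            fits.append(
                KineticFit(
                    params=p,
                    se={k: 0.0 for k in PARAM_NAMES},
                    percent_se={k: 1.0 for k in PARAM_NAMES},
                    wrss=0.0,
                    converged=True,
                    n_starts_used=1,
                    macro=macroparameters(p),
                    subject_id=f"s{i}",
                )
            )
        return fits

    def test_identical_groups_not_significant(self):
        vals = [(0.5, 0.3, 0.3, 0.5), (0.6, 0.35, 0.4, 0.55), (0.7, 0.4, 0.5, 0.6)]
        df = summarize_groups(self._fits(vals), self._fits(vals))
        assert (df["p_value"] >= 0.5).all()

    def test_table_layout(self):
        ctrl = self._fits([(0.5, 0.3, 0.3, 0.5), (0.6, 0.35, 0.4, 0.55)])
        lps = self._fits([(0.8, 0.3, 0.6, 0.6), (0.9, 0.4, 0.7, 0.7)])
        df = summarize_groups(ctrl, lps, auc_control=[7000, 7500], auc_lps=[11000, 12000])
        assert list(df["parameter"]) == ["K1", "k2", "k3/k4", "Kb", "VT", "AUC"]
        assert set(df.loc[df["parameter"] != "AUC", "sides"]) == {"one"}
        assert df.loc[df["parameter"] == "AUC", "sides"].item() == "two"

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            summarize_groups([], self._fits([(0.5, 0.3, 0.3, 0.5)]))
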