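"""Standard-curve fitting, NQ normalization, stability and transforms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtlcross import qpcr
from eqtlcross.types import ExpressionMatrix, ValidationError


def standards(slope, intercept=25.0, n=5):
    q = 4.0 ** -np.arange(n)
    return pd.DataFrame({"Cq": intercept + slope * np.log10(q), "standard_quantity": q})


class TestStandardCurve:
    def test_textbook_slope_gives_unit_efficiency(self):
        curve = qpcr.fit_standard_curve(standards(-3.3219), "a")
        assert curve.efficiency == pytest.approx(1.0, abs=5e-4)

    def test_slope_minus_three_and_half(self):
        # independent evaluation: 10**(1/3.5) - 1
        curve = qpcr.fit_standard_curve(standards(-3.5), "a")
        assert curve.efficiency == pytest.approx(10 ** (1 / 3.5) - 1, abs=1e-9)
        assert curve.efficiency == pytest.approx(0.9307, abs=5e-5)

    def test_collinear_points_r2_one(self):
        assert qpcr.fit_standard_curve(standards(-3.1), "a").r2 == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError, match=">=3"):
            qpcr.fit_standard_curve(standards(-3.3).iloc[:2], "a")

    def test_positive_slope_rejected(self):
        with pytest.raises(ValidationError):
            qpcr.fit_standard_curve(standards(3.3), "a")

    def test_quantify_inverts_curve_on_standards(self):
        std = standards(-3.41)
        curve = qpcr.fit_standard_curve(std, "a")
        back = qpcr.quantify(std["Cq"].to_numpy(), curve)
        rel = np.abs(back - std["standard_quantity"].to_numpy()) / std["standard_quantity"]
        assert rel.max() < 1e-9

    def test_one_slope_unit_divides_quantity_by_ten(self):
        curve = qpcr.fit_standard_curve(standards(-3.2), "a")
        q0 = qpcr.quantify(24.0, curve)
        q1 = qpcr.quantify(24.0 + abs(curve.slope), curve)
        assert q1 == pytest.approx(q0 / 10.0)

    def test_quantity_monotone_decreasing_in_cq(self):
        curve = qpcr.fit_standard_curve(standards(-3.2), "a")
        cqs = np.linspace(15, 35, 50)
        q = qpcr.quantify(cqs, curve)
        assert (np.diff(q) < 0).all()


class TestReferenceStability:
    def test_proportional_references_have_zero_m(self, rng):
        base = rng.lognormal(0.0, 0.5, 30)
        quantities = pd.DataFrame(
            {"r1": base, "r2": 3.0 * base}, index=[f"s{i}" for i in range(30)]
        ).T
        m = qpcr.reference_stability(quantities, ["r1", "r2"])
        assert m.max() == pytest.approx(0.0, abs=1e-12)

    def test_sample_permutation_invariance(self, rng):
        quantities = pd.DataFrame(
            rng.lognormal(0.0, 0.3, size=(3, 25)),
            index=["r1", "r2", "r3"],
            columns=[f"s{i}" for i in range(25)],
        )
        m1 = qpcr.reference_stability(quantities, ["r1", "r2", "r3"])
        perm = rng.permutation(quantities.columns)
        m2 = qpcr.reference_stability(quantities[perm], ["r1", "r2", "r3"])
        pd.testing.assert_series_equal(m1, m2)

    def test_single_candidate_rejected(self):
        with pytest.raises(ValidationError):
            qpcr.reference_stability(pd.DataFrame({"a": [1.0]}).T, ["a"])

    def test_unstable_reference_ranks_last(self):
        master = np.random.default_rng(99)
        last = 0
        for _ in range(200):
            n = 30
            base = master.lognormal(0.0, 0.4, n)
            quantities = pd.DataFrame(
                {
                    "stable1": base * master.lognormal(0.0, 0.05, n),
                    "stable2": base * master.lognormal(0.0, 0.05, n),
                    "drifty": base * master.lognormal(0.0, 0.5, n),
                }
            ).T
            m = qpcr.reference_stability(quantities, ["stable1", "stable2", "drifty"])
            last += m.index[-1] == "drifty"
        assert last >= 190  # >=95% of simulations


class TestNormalizeNq:
    def test_geometric_mean_of_two_references(self):
        targets = pd.DataFrame([[2.0]], index=["g"], columns=["s"])
        refs = pd.DataFrame([[1.0], [4.0]], index=["r1", "r2"], columns=["s"])
        nq = qpcr.normalize_nq(targets, refs)
        assert nq.values.loc["g", "s"] == pytest.approx(1.0)

    def test_unit_references_identity(self, rng):
        targets = pd.DataFrame(
            rng.lognormal(0, 0.5, size=(2, 6)), index=["g1", "g2"],
            columns=[f"s{i}" for i in range(6)],
        )
        refs = pd.DataFrame(1.0, index=["r1", "r2"], columns=targets.columns)
        nq = qpcr.normalize_nq(targets, refs)
        pd.testing.assert_frame_equal(nq.values, targets)

    def test_reference_scaling_homogeneity(self, rng):
        targets = pd.DataFrame(
            rng.lognormal(0, 0.5, size=(2, 6)), index=["g1", "g2"],
            columns=[f"s{i}" for i in range(6)],
        )
        refs = pd.DataFrame(
            rng.lognormal(0, 0.3, size=(2, 6)), index=["r1", "r2"],
            columns=targets.columns,
        )
        nq1 = qpcr.normalize_nq(targets, refs)
        nq2 = qpcr.normalize_nq(targets, 2.5 * refs)
        np.testing.assert_allclose(
            nq2.values.to_numpy(), nq1.values.to_numpy() / 2.5
        )

    def test_reference_relabeling_invariance(self, rng):
        targets = pd.DataFrame(
            rng.lognormal(0, 0.5, size=(1, 5)), index=["g"],
            columns=[f"s{i}" for i in range(5)],
        )
        refs = pd.DataFrame(
            rng.lognormal(0, 0.3, size=(2, 5)), index=["r1", "r2"],
            columns=targets.columns,
        )
        nq1 = qpcr.normalize_nq(targets, refs)
        nq2 = qpcr.normalize_nq(targets, refs.iloc[::-1])
        pd.testing.assert_frame_equal(nq1.values, nq2.values)

    def test_nonpositive_reference_rejected(self):
        targets = pd.DataFrame([[1.0]], index=["g"], columns=["s"])
        refs = pd.DataFrame([[0.0]], index=["r"], columns=["s"])
        with pytest.raises(ValidationError):
            qpcr.normalize_nq(targets, refs)


class TestNormalityTransform:
    def _expr(self, values):
        return ExpressionMatrix(
            pd.DataFrame([values], index=["g"], columns=[f"s{i}" for i in range(len(values))])
        )

    def test_normal_sample_left_untransformed(self):
        x = np.random.default_rng(7).normal(10.0, 1.0, 100)
        assert stats.shapiro(x).pvalue >= 0.05  # oracle check of the fixture itself
        out = qpcr.normality_transform(self._expr(x))
        assert out.log2["g"] is False
        np.testing.assert_array_equal(out.values.loc["g"].to_numpy(), x)

    def test_lognormal_sample_transformed(self):
        x = np.random.default_rng(8).lognormal(0.0, 1.0, 100)
        assert stats.shapiro(x).pvalue < 0.05
        out = qpcr.normality_transform(self._expr(x))
        assert out.log2["g"] is True
        np.testing.assert_allclose(out.values.loc["g"].to_numpy(), np.log2(x))

    def test_constant_gene_left_alone(self):
        out = qpcr.normality_transform(self._expr(np.full(10, 3.0)))
        assert out.log2["g"] is False

    def test_already_transformed_gene_untouched(self):
        x = np.random.default_rng(9).normal(0.0, 1.0, 50)  # includes negatives
        expr = ExpressionMatrix(
            pd.DataFrame([x], index=["g"], columns=[f"s{i}" for i in range(50)]),
            {"g": True},
        )
        out = qpcr.normality_transform(expr)
        np.testing.assert_array_equal(out.values.loc["g"].to_numpy(), x)
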