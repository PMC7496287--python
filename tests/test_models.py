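import math

import numpy as np
import pytest

import rbekit as rk
from rbekit import study
from rbekit.models import (
    jon_maxmin,
    load_coefficients,
    mcn_maxmin,
    rbe_from_maxmin,
    rmf_lq_params,
    ror_maxmin,
    zbar_f,
)
from rbekit.types import LQParameters, RBESource, RMFInputs, ValidationError

TISSUES = {
    # cell line: (alpha_x, beta_x, published (α/β)_x)
    "HaCat": (0.30, 0.02, 15.0),
    "FaDu": (0.30, 0.03, 10.0),
    "Du145": (0.14, 0.03, 4.7),
    "SKMel": (0.12, 0.04, 3.0),
}
#: Published model predictions at 2 Gy per cell line over the LET_d grid.
MCN_2GY = {
    "HaCat": [1.04, 1.05, 1.05, 1.06, 1.08, 1.08],
    "FaDu": [1.07, 1.07, 1.08, 1.08, 1.11, 1.12],
    "Du145": [1.11, 1.12, 1.13, 1.14, 1.19, 1.20],
    "SKMel": [1.14, 1.15, 1.17, 1.18, 1.23, 1.25],
}
ROR_2GY = {
    "HaCat": [1.06, 1.07, 1.09, 1.10, 1.14, 1.15],
    "FaDu": [1.09, 1.10, 1.11, 1.13, 1.18, 1.20],
    "Du145": [1.14, 1.15, 1.18, 1.20, 1.29, 1.31],
    "SKMel": [1.17, 1.18, 1.22, 1.24, 1.34, 1.37],
}
JON_2GY = {
    "HaCat": [1.23, 1.25, 1.31, 1.35, 1.51, 1.56],
    "FaDu": [1.21, 1.23, 1.28, 1.31, 1.46, 1.50],
    "Du145": [1.21, 1.23, 1.28, 1.32, 1.46, 1.50],
    "SKMel": [1.17, 1.19, 1.23, 1.26, 1.38, 1.42],
}


def _predict(model, cell, let, dp=2.0):
    ax, bx, ab = TISSUES[cell]
    return rk.predict_pheno(
        model, dp, let, alpha_x=ax, beta_x=bx, alpha_over_beta_x=ab
    )


class TestMcNamara:
    def test_zero_let_intercepts(self):
        pair = mcn_maxmin(10.0, 0.0)
        assert pair.rbe_max == pytest.approx(0.99064)
        assert pair.rbe_min == pytest.approx(1.1012)

    @pytest.mark.parametrize("cell", TISSUES)
    def test_published_2gy_predictions(self, cell):
        for let, expected in zip(study.LET_GRID, MCN_2GY[cell]):
            got = round(_predict(RBESource.MCN, cell, let), 2)
            assert abs(got - expected) <= 0.0101, (cell, let, got, expected)

    def test_negative_let_rejected(self):
        with pytest.raises(ValidationError):
            mcn_maxmin(10.0, -1.0)


class TestRorvik:
    def test_zero_let_is_identity_model(self):
        pair = ror_maxmin(10.0, 0.0)
        assert pair.rbe_max == 1.0 and pair.rbe_min == 1.0
        for dp in (0.5, 2.0, 6.0):
            assert rbe_from_maxmin(dp, 10.0, pair) == pytest.approx(1.0)

    @pytest.mark.parametrize("cell", TISSUES)
    def test_published_2gy_predictions(self, cell):
        for let, expected in zip(study.LET_GRID, ROR_2GY[cell]):
            got = round(_predict(RBESource.ROR, cell, let), 2)
            assert abs(got - expected) <= 0.0101, (cell, let, got, expected)


class TestJones:
    def test_tissue_dependence_beyond_the_ratio(self):
        """Equal (α/β)_x but different α_x must yield different pairs."""
        a = jon_maxmin(0.30, 0.03, 4.5)
        b = jon_maxmin(0.15, 0.015, 4.5)
        assert a.rbe_max != pytest.approx(b.rbe_max)

    @pytest.mark.parametrize("cell", TISSUES)
    def test_published_2gy_predictions(self, cell):
        for let, expected in zip(study.LET_GRID, JON_2GY[cell]):
            got = round(_predict(RBESource.JON, cell, let), 2)
            assert abs(got - expected) <= 0.0101, (cell, let, got, expected)

    def test_rbe_increases_with_let(self):
        for cell in TISSUES:
            vals = [_predict(RBESource.JON, cell, let) for let in study.LET_GRID]
            assert all(a < b for a, b in zip(vals, vals[1:]))


class TestSharedSkeleton:
    def test_unity_pair_is_exact_identity(self):
        pair = rk.MaxMinPair(rbe_max=1.0, rbe_min=1.0, model=RBESource.ROR)
        for dp in (0.1, 1.0, 2.0, 50.0):
            for ab in (1.0, 3.0, 15.0):
                assert rbe_from_maxmin(dp, ab, pair) == 1.0

    def test_equivalence_with_lq_parameter_formula(self, rng):
        """With α_p = RBE_max·α_x and β_p = RBE_min²·β_x the max/min dose
        response and the four-parameter RBE formula agree to 1e-10."""
        worst = 0.0
        for _ in range(1000):
            ax = rng.uniform(0.05, 0.5)
            bx = rng.uniform(0.005, 0.08)
            rmax = rng.uniform(0.9, 3.0)
            rmin = rng.uniform(0.7, 1.5)
            dp = rng.uniform(0.25, 8.0)
            pair = rk.MaxMinPair(rbe_max=rmax, rbe_min=rmin, model=RBESource.MCN)
            via_pair = rbe_from_maxmin(dp, ax / bx, pair)
            via_lq = rk.rbe_fixed_dose(ax, bx, rmax * ax, rmin**2 * bx, dp)
            worst = max(worst, abs(via_pair - via_lq))
        assert worst < 1e-10

    def test_dose_limits_approach_max_and_min(self):
        pair = mcn_maxmin(4.7, 4.5)
        assert rbe_from_maxmin(1e-3, 4.7, pair) == pytest.approx(
            pair.rbe_max, abs=1e-3
        )
        assert rbe_from_maxmin(1e3, 4.7, pair) == pytest.approx(
            pair.rbe_min, abs=1e-3
        )

    def test_limits_positive_and_ordered_over_study_range(self):
        """Both asymptotes stay positive everywhere; ROR and JON keep
        RBE_max ≥ RBE_min.  MCN legitimately crosses (RBE_min > RBE_max)
        at high (α/β)_x and low LET_d — there the model predicts RBE
        rising with dose, matching sub-unity low-dose RBE observations in
        radioresistant-ratio tissues — so only positivity is asserted."""
        for ab in (3.0, 4.7, 10.0, 15.0):
            for let in study.LET_GRID:
                mcn = mcn_maxmin(ab, let)
                assert mcn.rbe_max > 0 and mcn.rbe_min > 0
                ror = ror_maxmin(ab, let)
                assert ror.rbe_max >= ror.rbe_min > 0
        for ax, bx, _ in TISSUES.values():
            for let in study.LET_GRID:
                pair = jon_maxmin(ax, bx, let)
                assert pair.rbe_max >= pair.rbe_min > 0

    def test_ordering_in_let_and_ratio(self):
        """MCN and ROR 2 Gy predictions increase with LET_d and decrease
        with (α/β)_x across the study grid."""
        for model in (RBESource.MCN, RBESource.ROR):
            for ab in (3.0, 4.7, 10.0, 15.0):
                vals = [
                    rk.predict_pheno(model, 2.0, let, alpha_over_beta_x=ab)
                    for let in study.LET_GRID
                ]
                assert all(a < b for a, b in zip(vals, vals[1:]))
            for let in study.LET_GRID:
                vals = [
                    rk.predict_pheno(model, 2.0, let, alpha_over_beta_x=ab)
                    for ab in (3.0, 4.7, 10.0, 15.0)
                ]
                assert all(a > b for a, b in zip(vals, vals[1:]))


class TestSpecificEnergy:
    def test_doubling_diameter_quarters_zbar(self):
        assert zbar_f(4.5, 10.0) == pytest.approx(zbar_f(4.5, 5.0) / 4)

    def test_reference_value(self):
        assert zbar_f(4.5, 5.0) == pytest.approx(0.0367, abs=2e-4)

    def test_zero_let(self):
        assert zbar_f(0.0, 5.0) == 0.0


class TestRMF:
    def test_null_conversion_gives_unit_rbe(self):
        lx = LQParameters(alpha=0.30, beta=0.03)
        rmf = RMFInputs(rbe_dsb=1.0, zbar_f=0.0)
        lp = rmf_lq_params(lx, rmf, let_d=0.0, alpha_over_beta_x=10.0)
        assert lp.alpha == pytest.approx(lx.alpha)
        assert lp.beta == pytest.approx(lx.beta)
        assert rk.predict_rmf(2.0, lx, rmf, 0.0, 10.0) == pytest.approx(1.0)

    def test_low_dose_limit_and_beta_scaling(self):
        """With z̄_F → 0 the α ratio tends to RBE_DSB and β scales with
        RBE_DSB² exactly."""
        lx = LQParameters(alpha=0.30, beta=0.03)
        rmf = RMFInputs(rbe_dsb=1.1, zbar_f=1e-12)
        lp = rmf_lq_params(lx, rmf, let_d=2.0, alpha_over_beta_x=10.0)
        assert lp.alpha / lx.alpha == pytest.approx(1.1, rel=1e-9)
        assert lp.beta / lx.beta == pytest.approx(1.21)

    def test_predictions_bracket_published_range(self):
        """Any DSB-induction RBE in [1.0, 1.3] keeps the 2 Gy predictions of
        all four tissues inside [1.0, 1.4], bracketing the published
        mechanistic column (1.16–1.24)."""
        for cell, (ax, bx, ab) in TISSUES.items():
            lx = LQParameters(alpha=ax, beta=bx)
            for let in study.LET_GRID:
                for r in np.linspace(1.0, 1.3, 7):
                    value = rk.predict_rmf(2.0, lx, RMFInputs(rbe_dsb=r), let, ab)
                    assert 1.0 <= value <= 1.4, (cell, let, r, value)

    def test_zero_ratio_rejected(self):
        lx = LQParameters(alpha=0.30, beta=0.0)
        with pytest.raises(ValidationError):
            rmf_lq_params(lx, RMFInputs(rbe_dsb=1.1), let_d=2.0)


def test_coefficient_file_is_versioned():
    coeff = load_coefficients()
    assert coeff["version"] == 1
    assert len(rk.models.coefficients_hash()) == 64
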