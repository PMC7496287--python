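import numpy as np
import pytest

import rbekit as rk
from rbekit.lq import (
    compute_surviving_fractions,
    fit_lq,
    points_from_frame,
    propagate_ratio_error,
)
from rbekit.types import (
    LQParameters,
    Radiation,
    SurvivalPoint,
    SurvivalRecord,
    ValidationError,
)


def _record(dose, seeded, colonies, session="S1", well="W1"):
    return SurvivalRecord(
        cell_line="X",
        radiation=Radiation.XRAY_200KV,
        dose=dose,
        cells_seeded=seeded,
        colonies=colonies,
        session=session,
        well=well,
    )


def _points(alpha, beta, doses=(0.5, 1, 2, 4, 6), sd=0.01, n=18):
    return [
        SurvivalPoint(
            dose=d, sf_mean=float(np.exp(-alpha * d - beta * d * d)), sf_sd=sd, n_obs=n
        )
        for d in doses
    ]


class TestSurvivingFractions:
    def test_plating_efficiency_normalisation(self):
        """6 control wells at 75/250 give PE=0.30; a 2 Gy well with 60/500
        colonies then has SF = 0.12/0.30 = 0.40."""
        records = [_record(0.0, 250, 75, well=f"W{i}") for i in range(6)]
        records.append(_record(2.0, 500, 60))
        frame = compute_surviving_fractions(records)
        row = frame[frame["dose"] == 2.0].iloc[0]
        assert row["sf_mean"] == pytest.approx(0.40)
        assert frame[frame["dose"] == 0.0].iloc[0]["sf_mean"] == pytest.approx(1.0)

    def test_identical_counts_give_zero_sd(self):
        records = [_record(0.0, 250, 75, well=f"W{i}") for i in range(3)]
        records += [_record(2.0, 500, 60, well=f"W{i}") for i in range(3)]
        frame = compute_surviving_fractions(records)
        assert frame[frame["dose"] == 2.0].iloc[0]["sf_sd"] == 0.0

    def test_missing_control_rejected(self):
        with pytest.raises(ValidationError, match="no 0 Gy control"):
            compute_surviving_fractions([_record(2.0, 500, 60)])

    def test_zero_colony_control_names_session(self):
        records = [_record(0.0, 250, 0, session="S9")]
        with pytest.raises(ValidationError, match="S9"):
            compute_surviving_fractions(records)

    def test_generator_sf_matches_lq_truth(self):
        """Mean SF at 2 Gy is within 3 SE of exp(-2α-4β) for the generator."""
        arch = rk.study_archetypes()["Du145"]
        cond = rk.BeamCondition(rk.Radiation.PROTON, let_d=4.5)
        records = rk.simulate_assay(rk.AssayDesign(), arch, cond, rng=5)
        frame = compute_surviving_fractions(records)
        row = frame[frame["dose"] == 2.0].iloc[0]
        a, b = arch.proton_lq[4.5]
        truth = np.exp(-2 * a - 4 * b)
        se = row["sf_sd"] / np.sqrt(row["n_obs"])
        assert abs(row["sf_mean"] - truth) < 3 * max(se, 0.01)


class TestFitLQ:
    def test_noiseless_recovery_is_exact(self):
        fit = fit_lq(_points(0.30, 0.02))
        assert fit.alpha == pytest.approx(0.30, abs=1e-6)
        assert fit.beta == pytest.approx(0.02, abs=1e-6)

    def test_needs_three_distinct_doses(self):
        with pytest.raises(ValidationError, match="3 distinct"):
            fit_lq(_points(0.3, 0.02, doses=(1, 2)))

    def test_sigma_scale_invariance(self):
        """Multiplying all σ_i by a constant leaves (α, β) unchanged."""
        pts = _points(0.14, 0.03, sd=0.02)
        scaled = [
            SurvivalPoint(p.dose, p.sf_mean, 7.0 * p.sf_sd, p.n_obs) for p in pts
        ]
        f1, f2 = fit_lq(pts), fit_lq(scaled)
        assert f1.alpha == pytest.approx(f2.alpha, rel=1e-8)
        assert f1.beta == pytest.approx(f2.beta, rel=1e-8)

    def test_optimum_is_local_minimum(self, rng):
        """±1% parameter perturbations never lower the weighted chi-square."""
        pts = _points(0.2, 0.04)
        noisy = [
            SurvivalPoint(
                p.dose, p.sf_mean * (1 + rng.normal(0, 0.03)), 0.02, p.n_obs
            )
            for p in pts
        ]
        fit = fit_lq(noisy)
        doses = np.array([p.dose for p in noisy])
        sf = np.array([p.sf_mean for p in noisy])
        sd = np.array([max(p.sf_sd, 1e-4) for p in noisy])

        def chi2(a, b):
            return np.sum(((sf - np.exp(-a * doses - b * doses**2)) / sd) ** 2)

        best = chi2(fit.alpha, fit.beta)
        for fa in (0.99, 1.01):
            for fb in (0.99, 1.01):
                assert chi2(fit.alpha * fa, fit.beta * fb) >= best - 1e-12

    def test_noisy_recovery_is_unbiased(self, rng):
        """20 replicate fits with 5% multiplicative SF noise recover α=0.14
        within 2 SE of the replicate mean."""
        alphas = []
        for _ in range(20):
            pts = [
                SurvivalPoint(
                    p.dose, p.sf_mean * (1 + rng.normal(0, 0.05)), 0.05 * p.sf_mean, 18
                )
                for p in _points(0.14, 0.03)
            ]
            alphas.append(fit_lq(pts).alpha)
        alphas = np.array(alphas)
        sem = alphas.std(ddof=1) / np.sqrt(len(alphas))
        assert abs(alphas.mean() - 0.14) < 2 * sem

    def test_simulated_xray_fit_in_plausibility_band(self):
        """A HaCat-like x-ray assay recovers α ≈ 0.30, β ≈ 0.02."""
        arch = rk.study_archetypes()["HaCat"]
        records = rk.simulate_assay(
            rk.AssayDesign(), arch, rk.study.XRAY_CONDITION, rng=11
        )
        fit = fit_lq(points_from_frame(compute_surviving_fractions(records)))
        assert abs(fit.alpha - 0.30) < max(3 * fit.se_alpha, 0.06)
        assert abs(fit.beta - 0.02) < max(3 * fit.se_beta, 0.015)


class TestRatioError:
    def test_ratio_value(self):
        lq = LQParameters(alpha=0.39, beta=0.03)
        ratio, se = propagate_ratio_error(lq)
        assert ratio == pytest.approx(13.0)
        assert se == 0.0

    def test_beta_zero_is_undefined(self):
        with pytest.raises(ValidationError, match="undefined"):
            propagate_ratio_error(LQParameters(alpha=0.3, beta=0.0))

    @pytest.mark.parametrize(
        "alpha,beta,se_a,se_b,cov",
        [
            (0.30, 0.02, 0.015, 0.0015, -1e-5),
            (0.39, 0.03, 0.02, 0.002, -2e-5),
            (0.12, 0.04, 0.01, 0.003, 0.0),
        ],
    )
    def test_delta_method_matches_monte_carlo(self, alpha, beta, se_a, se_b, cov):
        """Delta-method SE agrees with a 10⁵-draw Monte-Carlo oracle to 5%
        (first-order propagation, so relative parameter errors ≲ 10%)."""
        lq = LQParameters(
            alpha=alpha, beta=beta, se_alpha=se_a, se_beta=se_b, cov_alpha_beta=cov
        )
        _, se = propagate_ratio_error(lq)
        draws = np.random.default_rng(99).multivariate_normal(
            [alpha, beta], lq.covariance, size=100_000
        )
        mc = np.std(draws[:, 0] / draws[:, 1])
        assert se == pytest.approx(mc, rel=0.05)
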