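"""Samplers: PERT, CI-calibrated normals, Gaussian copula, phase chains."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats

from orphanval.kernels import (
    BernoulliMarginal,
    CopulaSpec,
    NormalMarginal,
    PertMarginal,
    PertParams,
    Z95,
    copula_sample,
    gaussian_rank_correlation,
    normal_from_ci,
    pert_ppf,
    sample_pert,
    sample_phase_chain,
)
from orphanval.scenario import load_fixture


class TestPert:
    @pytest.mark.parametrize(
        "triple,mean",
        [((4, 6, 8), 6.0), ((9, 14, 40), 17.5), ((22, 35, 99), 43.5)],
    )
    def test_closed_form_mean_vs_numerical_integration(self, triple, mean):
        # independent oracle: integrate x f(x) over the scaled Beta density
        p = PertParams(*triple)
        a, b = p.shape()
        lo, hi = p.minimum, p.maximum
        num, _ = integrate.quad(
            lambda x: x * stats.beta.pdf((x - lo) / (hi - lo), a, b) / (hi - lo),
            lo,
            hi,
        )
        assert p.mean() == pytest.approx((lo + 4 * p.mode + hi) / 6)
        assert num == pytest.approx(mean, rel=1e-6)

    @pytest.mark.parametrize("triple", [(4, 6, 8), (9, 14, 40)])
    def test_sample_moments(self, triple, rng):
        p = PertParams(*triple)
        x = sample_pert(p, 200_000, rng)
        assert x.mean() == pytest.approx(p.mean(), rel=0.01)
        assert x.var() == pytest.approx(p.variance(), rel=0.05)
        assert x.min() >= p.minimum and x.max() <= p.maximum

    def test_degenerate_returns_constant(self, rng):
        assert (sample_pert(PertParams(5, 5, 5), 100, rng) == 5).all()

    def test_invalid_triple(self):
        with pytest.raises(ValueError):
            PertParams(3, 2, 4)

    def test_invalid_n(self, rng):
        with pytest.raises(ValueError):
            sample_pert(PertParams(1, 2, 3), 0, rng)

    @given(
        st.tuples(
            st.floats(0.1, 50), st.floats(0, 50), st.floats(0, 50)
        ).map(lambda t: (t[0], t[0] + t[1], t[0] + t[1] + t[2]))
    )
    def test_draws_within_bounds(self, triple):
        p = PertParams(*triple)
        x = sample_pert(p, 500, np.random.default_rng(0))
        assert ((x >= p.minimum - 1e-9) & (x <= p.maximum + 1e-9)).all()

    def test_reproducible(self):
        a = sample_pert(PertParams(1, 2, 4), 100, 42)
        b = sample_pert(PertParams(1, 2, 4), 100, 42)
        np.testing.assert_array_equal(a, b)


class TestNormalFromCI:
    def test_price_calibration(self):
        mean, sd = normal_from_ci(40_000, 30_000, 50_000)
        assert mean == 40_000
        assert sd == pytest.approx(10_000 / Z95)
        assert sd == pytest.approx(5102.1, abs=0.1)

    def test_adoption_calibration(self):
        _, sd = normal_from_ci(0.50, 0.35, 0.65)
        assert sd == pytest.approx(0.0765, abs=1e-4)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            normal_from_ci(1.0, 1.0, 1.0)

    def test_asymmetric_interval_rejected(self):
        with pytest.raises(ValueError, match="center"):
            normal_from_ci(10.0, 9.0, 14.0)

    @given(
        st.floats(-100, 100),
        st.floats(0.1, 50),
    )
    def test_round_trip(self, center, half):
        mean, sd = normal_from_ci(center, center - half, center + half)
        lo, hi = stats.norm.interval(0.95, loc=mean, scale=sd)
        assert lo == pytest.approx(center - half, rel=1e-4, abs=1e-6)
        assert hi == pytest.approx(center + half, rel=1e-4, abs=1e-6)


class TestCopula:
    def test_independent_pert_margins(self, rng):
        spec = CopulaSpec(
            np.eye(2),
            [PertMarginal(PertParams(1, 2, 3)), PertMarginal(PertParams(5, 6, 9))],
        )
        x = copula_sample(spec, 50_000, rng)
        assert abs(np.corrcoef(x.T)[0, 1]) < 0.02

    def test_gaussian_margins_exact_rho(self, rng):
        spec = CopulaSpec(
            np.array([[1, 0.5], [0.5, 1]]),
            [NormalMarginal(0, 1), NormalMarginal(0, 1)],
        )
        x = copula_sample(spec, 100_000, rng)
        assert np.corrcoef(x.T)[0, 1] == pytest.approx(0.5, abs=0.02)

    def test_rank_correlation_identity_for_pert_margins(self, rng):
        # Spearman rho of a Gaussian copula is (6/pi) arcsin(rho/2),
        # regardless of the margins
        spec = CopulaSpec(
            np.array([[1, 0.5], [0.5, 1]]),
            [
                PertMarginal(PertParams(1, 2, 3)),
                PertMarginal(PertParams(22, 35, 99)),
            ],
        )
        x = copula_sample(spec, 100_000, rng)
        target = gaussian_rank_correlation(0.5)
        assert target == pytest.approx(0.4826, abs=1e-4)
        got = stats.spearmanr(x[:, 0], x[:, 1]).statistic
        assert got == pytest.approx(target, abs=0.02)

    def test_marginal_preservation_under_correlation(self, rng):
        # each margin's empirical CDF matches its specification (KS test)
        p = PertParams(9, 14, 40)
        spec = CopulaSpec(
            np.array([[1, 0.5], [0.5, 1]]),
            [PertMarginal(p), NormalMarginal(3.0, 2.0)],
        )
        x = copula_sample(spec, 100_000, rng)
        a, b = p.shape()
        ks1 = stats.kstest(
            (x[:, 0] - p.minimum) / (p.maximum - p.minimum), stats.beta(a, b).cdf
        ).statistic
        ks2 = stats.kstest(x[:, 1], stats.norm(3.0, 2.0).cdf).statistic
        assert ks1 < 0.01 and ks2 < 0.01

    def test_bernoulli_margin_rate(self, rng):
        spec = CopulaSpec(
            np.array([[1, 0.5], [0.5, 1]]),
            [BernoulliMarginal(0.67), NormalMarginal(0, 1)],
        )
        x = copula_sample(spec, 100_000, rng)
        assert x[:, 0].mean() == pytest.approx(0.67, abs=0.01)

    def test_non_psd_matrix_reports_eigenvalue(self):
        corr = np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1]])
        with pytest.raises(ValueError, match="eigenvalue"):
            CopulaSpec(corr, [NormalMarginal(0, 1)] * 3)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            CopulaSpec(np.eye(2), [NormalMarginal(0, 1)])


class TestPhaseChain:
    def test_completion_rate_matches_cumulative_pos(self, base, rng):
        n = 100_000
        attempted, succeeded = sample_phase_chain(base.plan, n, rng)
        frac = succeeded[:, -1].mean()
        p = 0.67 * 0.53 * 0.69 * 0.94
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se

    def test_reach_phase3_rate(self, base, rng):
        n = 100_000
        attempted, _ = sample_phase_chain(base.plan, n, rng)
        p = 0.67 * 0.53
        se = np.sqrt(p * (1 - p) / n)
        assert abs(attempted[:, 2].mean() - p) < 3 * se

    def test_attempt_requires_prior_success(self, base, rng):
        attempted, succeeded = sample_phase_chain(base.plan, 5_000, rng)
        for j in range(1, attempted.shape[1]):
            assert (attempted[:, j] <= succeeded[:, j - 1]).all()

    def test_certain_plan_fully_successful(self, rng):
        s = load_fixture("rett_base").model_copy(deep=True)
        for ph in s.plan.phases:
            ph.pos = 1.0
        _, succeeded = sample_phase_chain(s.plan, 1_000, rng)
        assert succeeded.all()
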