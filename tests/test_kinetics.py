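"""The non-steady-state kinetic model, its ODE oracle, and rate fitting."""

import math

import numpy as np
import pytest

from turnoverkit import (
    EnrichmentCurve,
    KineticModelParams,
    PeptideTimeSeries,
    fit_k,
    fractional_synthesis,
    half_life,
    model_a0,
    ode_oracle,
    precursor_a0,
)
from turnoverkit.synth import generate_rates


class TestPrecursor:
    def test_no_label_limit(self, days):
        p = KineticModelParams(a=0.5, n_sites=10, enrichment=EnrichmentCurve(0.0, 2.0))
        assert np.allclose(precursor_a0(p, days), 0.5)

    def test_t_zero_is_a(self, params):
        assert precursor_a0(params, 0.0) == pytest.approx(params.a)

    def test_direct_formula_log_domain(self, params):
        """Direct evaluation agrees with log-domain computation at t=3."""
        t = 3.0
        p_t = 0.045 * (1 - math.exp(-2.0 * t))
        expected = math.exp(math.log(0.5) + 10 * math.log1p(-p_t))
        assert precursor_a0(params, t) == pytest.approx(expected, rel=1e-12)

    def test_decreasing_to_plateau(self, params):
        t = np.linspace(0, 60, 200)
        vals = precursor_a0(params, t)
        assert np.all(np.diff(vals) <= 0)  # flat only once numerically at plateau
        assert np.all(np.diff(vals[:20]) < 0)
        assert vals[-1] == pytest.approx(params.a0_plateau, rel=1e-6)


class TestModelA0:
    def test_initial_condition(self, params):
        for k in (0.01, 0.1, 1.0, 10.0):
            assert model_a0(k, params, 0.0) == pytest.approx(params.a, abs=1e-10)

    def test_stationary_limit(self, params):
        assert model_a0(0.5, params, 1e4) == pytest.approx(params.a0_plateau, abs=1e-10)

    def test_matches_ode_oracle_grid(self, enrichment, days):
        rng = np.random.default_rng(0)
        for _ in range(40):
            p = KineticModelParams(
                a=rng.uniform(0.1, 0.9),
                n_sites=rng.integers(1, 40),
                enrichment=EnrichmentCurve(rng.uniform(0.01, 0.2), rng.uniform(0.5, 5)),
            )
            k = 10 ** rng.uniform(-2, 1)
            assert np.max(np.abs(model_a0(k, p, days) - ode_oracle(k, p, days))) < 1e-8

    def test_degenerate_denominator_continuous(self, params):
        """k equal to i*k_p uses the limit term and stays continuous in k."""
        kp = params.enrichment.k_p
        t = np.array([0.5, 2.0, 7.0])
        exact = model_a0(kp, params, t)  # k = 1 * k_p exactly
        nearby = model_a0(kp * (1 + 1e-7), params, t)
        assert np.allclose(exact, nearby, atol=1e-6)
        assert np.max(np.abs(exact - ode_oracle(kp, params, t))) < 1e-8

    def test_monotone_non_increasing(self, params):
        t = np.linspace(0, 30, 300)
        for k in (0.01, 0.094, 0.5, 3.0):
            assert np.all(np.diff(model_a0(k, params, t)) <= 1e-15)

    def test_zero_sites_constant(self, enrichment):
        p = KineticModelParams(a=0.6, n_sites=0, enrichment=enrichment)
        t = np.linspace(0, 14, 20)
        assert np.allclose(model_a0(0.3, p, t), 0.6, atol=1e-12)
        assert np.allclose(ode_oracle(0.3, p, t), 0.6, atol=1e-10)

    def test_instant_enrichment_simple_exponential(self):
        """Very fast body-water equilibration reduces to the classic model.

        The deviation from the simple-exponential form scales as 1/k_p
        (the label deficit accrued during the equilibration transient).
        """
        p = KineticModelParams(a=0.5, n_sites=10, enrichment=EnrichmentCurve(0.045, 5e4))
        t = np.linspace(0.5, 14, 30)
        plateau = p.a0_plateau
        simple = plateau + (p.a - plateau) * np.exp(-0.2 * t)
        assert np.max(np.abs(ode_oracle(0.2, p, t) - simple)) < 1e-6

    def test_non_integer_sites_rounding_divergence_bounded(self, enrichment, days):
        """Rounding N shifts A0 by at most ~|dN| * |ln(1-p_ss)| * plateau.

        Rounding N to the nearest integer moves the plateau a(1-p_ss)^N by
        the factor (1-p_ss)^(-dN); the transient deviation stays below that
        plateau shift.  The ODE oracle handles real N exactly when needed.
        """
        for n_true in (10.5, 21.07, 7.49):
            p = KineticModelParams(a=0.5, n_sites=n_true, enrichment=enrichment)
            analytic = model_a0(0.094, p, days)  # rounds N internally
            exact = ode_oracle(0.094, p, days)  # real-valued N
            dn = abs(n_true - round(n_true))
            bound = 1.1 * dn * abs(np.log1p(-enrichment.p_ss)) * p.a0_plateau
            assert np.max(np.abs(analytic - exact)) <= max(bound, 1e-8)


class TestFitK:
    def test_noiseless_exact_recovery(self, params, days):
        series = PeptideTimeSeries("pep", days, model_a0(0.1, params, days))
        fit = fit_k(series, params)
        assert fit.k == pytest.approx(0.1, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.ss < 1e-12
        assert fit.converged and not fit.at_bound

    def test_optimizers_agree_on_noisy_series(self, params, days):
        rng = np.random.default_rng(7)
        for _ in range(50):
            k_true = float(generate_rates(1, rng=rng)[0])
            a0 = np.clip(model_a0(k_true, params, days) + rng.normal(0, 0.01, len(days)), 0, 1)
            series = PeptideTimeSeries("pep", days, a0)
            k_nm = fit_k(series, params, optimizer="nelder-mead").k
            k_qn = fit_k(series, params, optimizer="bfgs").k
            assert abs(k_nm - k_qn) / k_nm < 1e-4

    def test_flat_series_flagged(self, params, days):
        series = PeptideTimeSeries("pep", days, np.full(len(days), params.a))
        fit = fit_k(series, params)
        assert fit.at_bound
        assert fit.k == pytest.approx(1e-4, rel=1e-3)
        assert fit.r2 <= 0.0

    def test_local_optimality_audit(self, params, days):
        """SS at the fitted k is no worse than at 100 random probe values."""
        rng = np.random.default_rng(9)
        a0 = np.clip(model_a0(0.2, params, days) + rng.normal(0, 0.01, len(days)), 0, 1)
        series = PeptideTimeSeries("pep", days, a0)
        fit = fit_k(series, params)

        def ss(k):
            r = series.a0 - model_a0(k, params, series.t)
            return float(r @ r)

        probes = 10 ** rng.uniform(-4, np.log10(20), 100)
        assert all(fit.ss <= ss(k) + 1e-12 for k in probes)

    def test_dp_counts_distinct_times(self, params):
        t = np.array([0.0, 1.0, 1.0, 3.0, 5.0])
        series = PeptideTimeSeries("pep", t, np.full(5, 0.4))
        assert series.dp == 4


class TestHalfLife:
    def test_definition(self):
        assert half_life(math.log(2.0)) == pytest.approx(1.0)

    def test_fast_decile(self):
        assert half_life(0.30) == pytest.approx(2.31, abs=0.005)

    def test_median_rate(self):
        assert half_life(0.094) == pytest.approx(7.37, abs=0.005)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            half_life(0.0)


class TestFractionalSynthesis:
    def test_endpoints(self, params):
        assert fractional_synthesis(params.a, params) == pytest.approx(0.0)
        assert fractional_synthesis(params.a0_plateau, params) == pytest.approx(1.0)

    def test_undefined_without_labeling(self, enrichment):
        p0 = KineticModelParams(a=0.5, n_sites=0, enrichment=enrichment)
        with pytest.raises(ValueError, match="undefined"):
            fractional_synthesis(0.5, p0)

    def test_collapses_peptides_differing_in_a(self, enrichment):
        """14 peptides with one k and N but different a overlay exactly."""
        rng = np.random.default_rng(4)
        t = np.linspace(0, 14, 50)
        k_shared = 0.2
        curves = []
        for _ in range(14):
            p = KineticModelParams(
                a=rng.uniform(0.2, 0.9), n_sites=12, enrichment=enrichment
            )
            curves.append(fractional_synthesis(model_a0(k_shared, p, t), p))
        spread = np.max(np.ptp(np.vstack(curves), axis=0))
        assert spread < 1e-9

    def test_collapse_across_sites_in_instant_enrichment_limit(self):
        """With fast body-water equilibration FS is independent of N too.

        Under finite k_p the early transient retains a small N dependence;
        the overlay becomes exact as k_p grows.
        """
        fast = EnrichmentCurve(0.045, 200.0)
        t = np.linspace(0.2, 14, 40)
        curves = []
        for n_sites in (5, 12, 25, 40):
            p = KineticModelParams(a=0.5, n_sites=n_sites, enrichment=fast)
            curves.append(fractional_synthesis(ode_oracle(0.2, p, t), p))
        assert np.max(np.ptp(np.vstack(curves), axis=0)) < 1e-3
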