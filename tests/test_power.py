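"""Analytic and Monte-Carlo power, sample-size inversion, retrospective power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdxpower import (
    DesignSpec,
    ModelParams,
    analytic_power,
    make_schedule,
    required_sample_size,
    retrospective_power,
    retrospective_summary,
    simulate_power,
    slope_variance,
)


class TestAnalyticPower:
    @pytest.mark.parametrize(
        "beta, tau1, alpha, expected, tol",
        [
            (-0.044, 0.005, 0.05, 0.96, 0.01),
            (-0.02, 0.005, 0.05, 0.38, 0.01),
            (-0.02, 0.009, 0.05, 0.25, 0.01),
            (-0.010, 0.009, 0.05, 0.09, 0.01),
            (-0.02, 0.005, 0.20, 0.65, 0.01),
        ],
    )
    def test_canonical_1x1x1_cells(self, medians, design_4wk, beta, tau1, alpha, expected, tol):
        p = medians.with_(beta_effect=beta, tau1=tau1)
        d = DesignSpec(design_4wk.days, 1, alpha)
        assert analytic_power(p, d).power == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("alpha", [0.05, 0.2])
    def test_null_power_equals_alpha(self, medians, design_4wk, alpha):
        p = medians.with_(beta_effect=0.0)
        d = DesignSpec(design_4wk.days, 1, alpha)
        assert analytic_power(p, d).power == pytest.approx(alpha, abs=1e-12)

    def test_no_monte_carlo_fields(self, medians, design_4wk):
        res = analytic_power(medians, design_4wk)
        assert res.method == "analytic"
        assert res.n_sims is None and res.mc_stderr is None

    def test_degenerate_schedule_errors(self, medians):
        # Sxx = 0 cannot arise from a valid DesignSpec (distinct days are
        # enforced), so exercise the guard directly
        class Fake:
            def sxx(self):
                return 0.0

        with pytest.raises(ValueError, match="degenerate"):
            slope_variance(medians, Fake())

    @settings(derandomize=True, max_examples=30)
    @given(
        b1=st.floats(0.005, 0.08),
        b2=st.floats(0.005, 0.08),
        n=st.integers(1, 20),
    )
    def test_monotone_in_effect_magnitude(self, medians, design_4wk, b1, b2, n):
        lo, hi = sorted([b1, b2])
        d = DesignSpec(design_4wk.days, n, 0.05)
        p_lo = analytic_power(medians.with_(beta_effect=-lo), d).power
        p_hi = analytic_power(medians.with_(beta_effect=-hi), d).power
        assert p_hi >= p_lo

    def test_monotonicities(self, medians, design_4wk):
        d1 = DesignSpec(design_4wk.days, 1, 0.05)
        base = analytic_power(medians, d1).power
        # more mice
        assert analytic_power(medians, DesignSpec(design_4wk.days, 4, 0.05)).power > base
        # longer schedule (bigger Sxx)
        d8 = DesignSpec(tuple(make_schedule(8, 2)), 1, 0.05)
        assert analytic_power(medians, d8).power > base
        # more variation, more residual noise
        assert analytic_power(medians.with_(tau1=0.013), d1).power < base
        assert analytic_power(medians.with_(sigma=0.3), d1).power < base
        # stricter alpha
        assert analytic_power(medians, DesignSpec(design_4wk.days, 1, 0.01)).power < base

    def test_limit_power_to_one(self, medians):
        d = DesignSpec(tuple(make_schedule(52, 3)), 1, 0.05)
        p = medians.with_(tau1=1e-6, beta_effect=-0.01)
        assert analytic_power(p, d).power > 0.999


class TestSimulatedPower:
    def test_type_one_error_1x1x1(self, medians, design_4wk):
        p = medians.with_(beta_effect=0.0)
        res = simulate_power(p, design_4wk, n_sims=4000, seed=101)
        assert res.power == pytest.approx(0.05, abs=3 * max(res.mc_stderr, 1e-3))

    def test_agrees_with_analytic(self, medians, design_4wk):
        res = simulate_power(medians, design_4wk, n_sims=4000, seed=7)
        target = analytic_power(medians, design_4wk).power
        assert res.power == pytest.approx(target, abs=3 * res.mc_stderr)
        assert res.method == "simulation"
        assert res.n_nonconverged == 0

    def test_reproducible_given_seed(self, medians, design_4wk):
        a = simulate_power(medians, design_4wk, n_sims=500, seed=3)
        b = simulate_power(medians, design_4wk, n_sims=500, seed=3)
        assert a.power == b.power

    def test_monotone_in_effect(self, medians, design_4wk):
        pows = [
            simulate_power(medians.with_(beta_effect=b), design_4wk, n_sims=3000, seed=5).power
            for b in (-0.010, -0.02, -0.044)
        ]
        assert pows[0] < pows[1] < pows[2]

    def test_naive_ols_t_is_anticonservative_when_tau1_positive(self, medians, design_4wk):
        """The OLS t-test omits tau1 from its SE: with one mouse per arm it
        rejects a true population null far above nominal, which is why the
        1x1x1 power engine treats the variance components as known."""
        p = medians.with_(beta_effect=0.0)
        res = simulate_power(p, design_4wk, n_sims=2000, seed=11, test="ols-t")
        assert res.power > 0.10  # nominal would be 0.05

    def test_tau0_does_not_move_power(self, medians, design_4wk):
        """Intercept variance cancels in the slope contrast: simulation check
        of a property the analytic formula assumes."""
        lo = simulate_power(medians.with_(tau0=0.01), design_4wk, n_sims=3000, seed=19)
        hi = simulate_power(medians.with_(tau0=0.8), design_4wk, n_sims=3000, seed=19)
        band = 3 * np.hypot(lo.mc_stderr, hi.mc_stderr)
        assert lo.power == pytest.approx(hi.power, abs=band)

    def test_n_sims_floor(self, medians, design_4wk):
        with pytest.raises(ValueError):
            simulate_power(medians, design_4wk, n_sims=10, seed=0)


class TestSampleSize:
    @pytest.mark.parametrize(
        "beta, tau1, alpha, expected",
        [
            (-0.02, 0.009, 0.05, 5),  # headline: medium effect, average variation
            (-0.02, 0.005, 0.05, 3),
            (-0.010, 0.009, 0.20, 12),
            (-0.044, 0.005, 0.05, 1),
        ],
    )
    def test_printed_sample_sizes(self, medians, design_4wk, beta, tau1, alpha, expected):
        p = medians.with_(beta_effect=beta, tau1=tau1)
        d = DesignSpec(design_4wk.days, 1, alpha)
        assert required_sample_size(p, d).n_per_group == expected

    def test_small_effect_worst_case(self, medians, design_4wk):
        # closed form gives 20 (achieved power 0.801); the published 21 is
        # a conservative boundary call, so hold this cell to +-1
        p = medians.with_(beta_effect=-0.010, tau1=0.009)
        res = required_sample_size(p, design_4wk)
        assert abs(res.n_per_group - 21) <= 1
        assert res.achieved_power >= 0.80

    @settings(derandomize=True, max_examples=25)
    @given(
        beta=st.floats(-0.06, -0.005),
        tau1=st.floats(0.001, 0.015),
        alpha=st.sampled_from([0.05, 0.2]),
    )
    def test_minimality_definition(self, medians, design_4wk, beta, tau1, alpha):
        p = medians.with_(beta_effect=beta, tau1=tau1)
        d = DesignSpec(design_4wk.days, 1, alpha)
        res = required_sample_size(p, d)
        assert res.achieved_power >= 0.80
        if res.n_per_group > 1:
            below = analytic_power(p, DesignSpec(d.days, res.n_per_group - 1, alpha)).power
            assert below < 0.80

    def test_monotone_in_effect_and_variation(self, medians, design_4wk):
        d = DesignSpec(design_4wk.days, 1, 0.05)
        n_small = required_sample_size(medians.with_(beta_effect=-0.010), d).n_per_group
        n_large = required_sample_size(medians.with_(beta_effect=-0.044), d).n_per_group
        assert n_large <= n_small
        n_lovar = required_sample_size(medians.with_(tau1=0.005), d).n_per_group
        n_hivar = required_sample_size(medians.with_(tau1=0.013), d).n_per_group
        assert n_lovar <= n_hivar

    def test_zero_effect_errors(self, medians, design_4wk):
        with pytest.raises(ValueError, match="no finite"):
            required_sample_size(medians.with_(beta_effect=0.0), design_4wk)


class TestRetrospective:
    def test_consistency_with_analytic_at_medians(self, medians, design_4wk):
        table = pd.DataFrame(
            {"beta_effect": [-0.02], "tau1": [0.009], "sigma": [0.155]}
        )
        out = retrospective_power(table, days=design_4wk.days)
        expected = analytic_power(medians, design_4wk).power
        assert out.loc[0, "power_alpha_0.05"] == pytest.approx(expected, abs=1e-12)

    def test_null_rows_flagged_with_power_alpha(self, design_4wk):
        table = pd.DataFrame(
            {"beta_effect": [0.0, -0.044], "tau1": [0.009, 0.005], "sigma": [0.155, 0.155]}
        )
        out = retrospective_power(table, days=design_4wk.days)
        assert bool(out.loc[0, "no_effect"]) is True
        assert out.loc[0, "power_alpha_0.05"] == pytest.approx(0.05, abs=1e-12)
        assert out.loc[0, "power_alpha_0.2"] == pytest.approx(0.2, abs=1e-12)

    def test_summary_and_csv_input(self, design_4wk, tmp_path):
        rng = np.random.default_rng(0)
        # synthetic cohort: a spread of fitted coefficients
        table = pd.DataFrame(
            {
                "beta_effect": np.concatenate([[0.0], -rng.uniform(0.005, 0.05, 19)]),
                "tau1": rng.uniform(0.004, 0.014, 20),
                "sigma": rng.uniform(0.1, 0.25, 20),
            }
        )
        path = tmp_path / "coeffs.csv"
        table.to_csv(path, index=False)
        out = retrospective_power(path, days=design_4wk.days)
        summary = retrospective_summary(out)
        assert summary["0.05"]["n_experiments"] == 19  # null row excluded
        assert 0 <= summary["0.05"]["median_power"] <= 1
        assert summary["0.2"]["median_power"] >= summary["0.05"]["median_power"]

    def test_missing_columns_error(self, design_4wk):
        with pytest.raises(ValueError, match="missing columns"):
            retrospective_power(pd.DataFrame({"beta_effect": [-0.02]}), days=design_4wk.days)
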