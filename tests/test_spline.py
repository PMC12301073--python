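"""Penalized quasi-Poisson smoother tests: basis, PIRLS, REML, GAMM, metrics."""

import numpy as np
import pytest
from scipy.interpolate import BSpline

import bathrisk as br
from bathrisk import spline as sp
from .conftest import simulate_unit_counts


def newton_irls_oracle(y, X, offset, max_iter=200, tol=1e-12):
    """Independent unpenalized Poisson-IRLS oracle (lstsq-based Fisher scoring).

    Deliberately written without reusing the package's PIRLS internals.
    """
    y = np.asarray(y, float)
    offset = np.broadcast_to(np.asarray(offset, float), y.shape)
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(y.mean() + 0.1) - offset.mean()
    for _ in range(max_iter):
        eta = X @ beta + offset
        mu = np.exp(eta)
        z = (eta - offset) + (y - mu) / mu
        sw = np.sqrt(mu)
        beta_new, *_ = np.linalg.lstsq(sw[:, None] * X, sw * z, rcond=None)
        if np.max(np.abs(beta_new - beta)) < tol * (1 + np.max(np.abs(beta))):
            return beta_new
        beta = beta_new
    return beta


class TestBasis:
    def test_partition_of_unity(self):
        x = np.random.default_rng(0).uniform(0, 30, 300)
        _, _, spec = br.build_basis(x, k=10)
        B = BSpline.design_matrix(x, spec.knots, spec.degree).toarray()
        assert np.allclose(B.sum(axis=1), 1.0)

    def test_constraint_removes_one_column(self):
        x = np.random.default_rng(1).uniform(0, 30, 200)
        design, penalty, spec = br.build_basis(x, k=10)
        assert design.shape == (200, 9)
        assert penalty.shape == (9, 9)

    def test_penalty_vanishes_on_linear_functions(self):
        # coefficients of constants and of f(x)=x (Greville sites) are in the
        # second-order penalty null space
        x = np.random.default_rng(2).uniform(-5, 25, 400) ** 1.0
        _, _, spec = br.build_basis(x, k=10)
        S = sp._difference_penalty(spec.knots, spec.degree, 2)
        xi = sp._greville(spec.knots, spec.degree)
        scale = np.abs(S).max()
        assert np.ones(10) @ S @ np.ones(10) < 1e-10 * scale
        assert xi @ S @ xi < 1e-9 * scale * (xi @ xi)

    def test_penalty_positive_semidefinite_with_expected_nullity(self):
        x = np.random.default_rng(3).uniform(0, 30, 200)
        _, penalty, spec = br.build_basis(x, k=10)
        eig = np.linalg.eigvalsh(penalty)
        assert eig.min() > -1e-10 * eig.max()
        assert spec.null_dim == 1  # constraint absorbs the constant direction

    def test_too_few_distinct_values_raise(self):
        x = np.repeat([1.0, 2.0, 3.0], 20)
        with pytest.raises(ValueError, match="distinct"):
            br.build_basis(x, k=10)


class TestPirls:
    def test_matches_newton_oracle_unpenalized(self):
        """lambda=0 fits agree with an independent IRLS oracle to 1e-6."""
        rng = np.random.default_rng(12345)
        for _ in range(20):
            n = int(rng.integers(80, 500))
            k = int(rng.integers(4, 7))
            x = rng.uniform(0, 30, n)
            truth = 0.4 + 0.8 * np.sin(x / 6.0)
            off = rng.normal(0.0, 0.3, n)
            y = rng.poisson(np.exp(truth + off))
            if not y.any():
                continue
            fit = br.fit_pirls(y, x, off, lam=0.0, k=k)
            design = fit.basis.design(x)
            X = np.column_stack([np.ones(n), design])
            ref = newton_irls_oracle(y, X, off)
            ours = fit.coefficients
            assert np.allclose(ours, ref, rtol=1e-6, atol=1e-8)

    def test_intercept_only_reproduces_rate(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(2.0, 400)
        off = rng.normal(0.0, 0.5, 400)
        fit = br.fit_pirls(y, offset=off)
        assert np.exp(fit.intercept) == pytest.approx(
            y.sum() / np.exp(off).sum(), rel=1e-8
        )

    def test_dispersion_recovery_on_poisson_data(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 30, 50_000)
        y = rng.poisson(np.exp(0.3 + np.sin(x / 5.0)))
        fit = br.fit_pirls(y, x, lam=10.0)
        assert 0.95 <= fit.dispersion <= 1.05

    def test_dispersion_covers_one_across_replicates(self):
        rng = np.random.default_rng(9)
        disps = []
        for _ in range(20):
            x = rng.uniform(0, 30, 5000)
            y = rng.poisson(np.exp(0.5 + 0.5 * np.cos(x / 4.0)))
            disps.append(br.fit_pirls(y, x, lam=5.0).dispersion)
        mean = np.mean(disps)
        se = np.std(disps, ddof=1) / np.sqrt(len(disps))
        assert abs(mean - 1.0) < 3.0 * se + 0.01

    def test_all_zero_counts_raise(self):
        with pytest.raises(ValueError, match="zero"):
            br.fit_pirls(np.zeros(100, dtype=int), np.linspace(0, 30, 100))

    def test_negative_penalty_raises(self):
        y = np.random.default_rng(0).poisson(1.0, 50) + 1
        with pytest.raises(ValueError):
            br.fit_pirls(y, np.linspace(0, 30, 50), lam=-1.0)

    def test_offset_shift_invariance(self):
        temps, y, _, _ = simulate_unit_counts(21, years=2)
        x = temps["tmean"].to_numpy()
        fa = br.fit_pirls(y, x, 0.0, lam=5.0, tol=1e-12)
        fb = br.fit_pirls(y, x, 3.0, lam=5.0, tol=1e-12)
        mu_a = np.exp(fa.predict_log_rate(x))
        mu_b = np.exp(fb.predict_log_rate(x, offset=3.0))
        assert np.allclose(mu_a, mu_b, rtol=1e-8)

    def test_serialization_roundtrip(self, single_unit_fit):
        fit2 = sp.SmoothFit.from_json(single_unit_fit.to_json())
        grid = np.linspace(*single_unit_fit.exposure_percentiles, 50)
        assert np.allclose(fit2.smooth_values(grid), single_unit_fit.smooth_values(grid))
        assert fit2.dispersion == pytest.approx(single_unit_fit.dispersion)
        assert fit2.edf == pytest.approx(single_unit_fit.edf)


class TestRemlSelection:
    def test_linear_truth_is_smoothed_to_line(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 30, 20_000)
        y = rng.poisson(np.exp(0.1 + 0.05 * x))
        lam, fit = br.select_lambda_reml(y, x)
        assert fit.edf <= 2.5

    def test_edf_monotone_nonincreasing_in_lambda(self):
        temps, y, _, _ = simulate_unit_counts(31, years=3)
        x = temps["tmean"].to_numpy()
        edfs = [br.fit_pirls(y, x, lam=lam).edf for lam in 10.0 ** np.arange(-2, 7)]
        assert all(a >= b - 1e-6 for a, b in zip(edfs, edfs[1:]))
        assert all(1.0 - 1e-6 <= e <= 9.0 + 1e-6 for e in edfs)

    def test_edf_for_national_scale_curve(self):
        """A strongly nonlinear exposure-response at n~100k keeps a rich smooth."""
        rng = np.random.default_rng(18)
        frames = []
        for i in range(20):
            spec = br.UnitSpec(f"u{i}", 2e6, float(rng.uniform(9, 23)))
            t = br.simulate_temperature(spec, "1995-01-01", "2007-12-31", rng)
            yy = br.simulate_counts(
                t["tmean"].to_numpy(), br.make_true_curve(9.7, 1.8, 30.3), spec, 1.3, rng
            )
            frames.append((t["tmean"].to_numpy(), yy))
        x = np.concatenate([f[0] for f in frames])
        y = np.concatenate([f[1] for f in frames])
        assert len(y) >= 90_000  # 20 units x 13 years
        lam, fit = br.select_lambda_reml(y, x)
        assert 5.0 <= fit.edf <= 9.9


class TestGamm:
    def test_zero_variance_component_when_units_identical(self):
        rng = np.random.default_rng(40)
        xs, ys, us = [], [], []
        for i in range(15):
            spec = br.UnitSpec(f"u{i:02d}", 2e6, 15.0, random_intercept=0.0)
            t = br.simulate_temperature(spec, "2000-01-01", "2003-12-31", rng)
            yy = br.simulate_counts(
                t["tmean"].to_numpy(), br.make_true_curve(9.7, 1.8, 30.3), spec, 1.0, rng
            )
            xs.append(t["tmean"].to_numpy())
            ys.append(yy)
            us.append(np.full(len(yy), f"u{i:02d}"))
        fit = br.fit_gamm(
            np.concatenate(ys), np.concatenate(xs), np.log(2e6), np.concatenate(us)
        )
        assert fit.sigma2_u < 0.01

    def test_sigma_u_recovery(self):
        rng = np.random.default_rng(11)
        xs, ys, us = [], [], []
        for i in range(20):
            spec = br.UnitSpec(
                f"u{i:02d}", 1e6, 15.0, random_intercept=float(rng.normal(0, 0.5))
            )
            t = br.simulate_temperature(spec, "2000-01-01", "2002-12-31", rng)
            yy = br.simulate_counts(
                t["tmean"].to_numpy(), br.make_true_curve(9.7, 1.8, 30.3), spec, 1.3, rng
            )
            xs.append(t["tmean"].to_numpy())
            ys.append(yy)
            us.append(np.full(len(yy), f"u{i:02d}"))
        fit = br.fit_gamm(
            np.concatenate(ys), np.concatenate(xs), np.log(1e6), np.concatenate(us)
        )
        assert 0.3 <= np.sqrt(fit.sigma2_u) <= 0.7

    def test_unit_effect_additivity(self, small_cohort):
        p = small_cohort.panel
        fit = br.fit_gamm(
            p["deaths"].to_numpy(), p["tmean"].to_numpy(),
            np.log(p["population"].to_numpy()), p["unit_id"].to_numpy(),
        )
        uid = p["unit_id"].iloc[0]
        with_u = fit.predict_log_rate(10.0, unit_id=uid)
        without = fit.predict_log_rate(10.0)
        assert float(with_u - without) == pytest.approx(fit.random_intercepts[uid])

    def test_single_unit_raises(self):
        temps, y, _, _ = simulate_unit_counts(3, years=2)
        with pytest.raises(ValueError, match="fit_pirls"):
            br.fit_gamm(y, temps["tmean"].to_numpy(), 0.0, np.full(len(y), "u"))


class TestMetrics:
    def test_no_random_effects_marginal_equals_conditional(self, single_unit_fit):
        m = br.compute_metrics(single_unit_fit)
        assert m.marginal_r2 == pytest.approx(m.conditional_r2)
        assert 0.0 <= m.marginal_r2 <= 1.0

    def test_conditional_at_least_marginal_with_random_effects(self, small_cohort):
        p = small_cohort.panel
        fit = br.fit_gamm(
            p["deaths"].to_numpy(), p["tmean"].to_numpy(),
            np.log(p["population"].to_numpy()), p["unit_id"].to_numpy(),
        )
        m = br.compute_metrics(fit, p["deaths"].to_numpy())
        assert m.conditional_r2 >= m.marginal_r2
        assert m.p_value_smooth < 0.001

    def test_pure_noise_covariate_explains_nothing(self):
        rng = np.random.default_rng(23)
        x = rng.uniform(0, 30, 40_000)
        y = rng.poisson(1.0, 40_000)  # counts unrelated to x
        lam, fit = br.select_lambda_reml(y, x)
        m = br.compute_metrics(fit, y)
        assert m.marginal_r2 < 0.02

    def test_signal_beats_shuffled_covariate(self):
        temps, y, _, _ = simulate_unit_counts(29, years=4)
        x = temps["tmean"].to_numpy()
        rng = np.random.default_rng(0)
        xs = rng.permutation(x)
        _, fit = br.select_lambda_reml(y, x)
        _, fit_sh = br.select_lambda_reml(y, xs)
        m = br.compute_metrics(fit, y)
        m_sh = br.compute_metrics(fit_sh, y)
        assert m.marginal_r2 > m_sh.marginal_r2
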