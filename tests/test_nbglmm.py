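import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pahrank.errors import ModelError
from pahrank.exposure import FacilityAggregate
from pahrank.nbglmm import (
    NBMMSpec,
    _ModelData,
    _nb_log_pmf_core,
    backward_eliminate,
    fit,
    marginal_log_likelihood,
    nb_log_pmf,
    predict_facility_counts,
)


def simulate_units(rng, n_groups, per_group, beta, sigma_b, k, prevalence=(0.3, 0.5)):
    """Small NB2 mixed-model generator used as a self-contained test harness."""
    n = n_groups * per_group
    gids = np.repeat([f"G{i:03d}" for i in range(n_groups)], per_group)
    b = rng.normal(0, sigma_b, n_groups)
    X = np.column_stack([rng.binomial(1, p, n).astype(float) for p in prevalence])
    expo = rng.uniform(0.5, 2.0, n)
    eta = beta[0] + X @ np.asarray(beta[1:]) + np.log(expo) + np.repeat(b, per_group)
    mu = np.exp(eta)
    lam = rng.gamma(k, mu / k) if np.isfinite(k) else mu
    y = rng.poisson(lam)
    cols = {"facility_id": gids, "pah_count": y, "person_years": expo}
    for j in range(X.shape[1]):
        cols[f"x{j + 1}"] = X[:, j]
    return pd.DataFrame(cols)


class TestNbLogPmf:
    def test_poisson_limit_at_zero(self):
        # y=0, mu=1: Poisson log-pmf is exactly -1
        assert nb_log_pmf(0, 1.0, 1e12) == pytest.approx(-1.0, abs=1e-9)

    def test_matches_gamma_form_oracle(self):
        # independent route: scipy's nbinom with n=k, p=k/(k+mu)
        for y, mu, k in [(2, 2.0, 1.0), (0, 0.5, 3.0), (7, 4.2, 2.5), (100, 80.0, 5.0)]:
            expected = stats.nbinom.logpmf(y, k, k / (k + mu))
            assert nb_log_pmf(y, mu, k) == pytest.approx(expected, rel=1e-10)

    def test_geometric_case_direct_evaluation(self):
        # k=1: NB2 is geometric-type; direct Gamma-form arithmetic
        y, mu, k = 2, 2.0, 1.0
        direct = (math.lgamma(y + k) - math.lgamma(k) - math.lgamma(y + 1)
                  + k * math.log(k / (k + mu)) + y * math.log(mu / (k + mu)))
        assert nb_log_pmf(y, mu, k) == pytest.approx(direct, rel=1e-12)

    def test_normalizes_to_one(self):
        ys = np.arange(0, 400)
        total = np.exp(nb_log_pmf(ys, np.full_like(ys, 3.0, dtype=float), 1.5)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("mu,k", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
    def test_domain_errors(self, mu, k):
        with pytest.raises(ModelError):
            nb_log_pmf(1, mu, k)


class TestMarginalLogLikelihood:
    @pytest.fixture
    def small(self):
        rng = np.random.default_rng(5)
        df = simulate_units(rng, 3, 5, beta=(-0.5, 0.6, 0.3), sigma_b=0.4, k=2.0)
        spec = NBMMSpec(covariates=("x1", "x2"))
        return spec, df

    @staticmethod
    def brute_force(spec, beta, sigma_b, k, df, n_points=10001, half_width=10.0):
        md = _ModelData.from_frame(df, spec)
        eta0 = md.X @ np.asarray(beta) + md.offset
        total = 0.0
        bs = np.linspace(-half_width * sigma_b, half_width * sigma_b, n_points)
        for g in range(md.n_groups):
            sel = md.gidx == g
            vals = np.array([
                _nb_log_pmf_core(md.y[sel], np.exp(eta0[sel] + b), k).sum()
                - 0.5 * math.log(2 * math.pi * sigma_b**2) - b * b / (2 * sigma_b**2)
                for b in bs
            ])
            m = vals.max()
            total += m + math.log(np.trapezoid(np.exp(vals - m), bs))
        return total

    def test_sigma_zero_degenerates_to_independent_nb(self, small):
        spec, df = small
        beta = np.array([-0.5, 0.6, 0.3])
        ll = marginal_log_likelihood(spec, (beta, -math.inf, math.log(2.0)), df)
        md = _ModelData.from_frame(df, spec)
        direct = _nb_log_pmf_core(md.y, np.exp(md.X @ beta + md.offset), 2.0).sum()
        assert ll == pytest.approx(direct, rel=1e-12)

    def test_agrees_with_brute_force_quadrature(self, small):
        spec, df = small
        beta = np.array([-0.5, 0.6, 0.3])
        agq = marginal_log_likelihood(spec, (beta, math.log(0.4), math.log(2.0)), df)
        brute = self.brute_force(spec, beta, 0.4, 2.0, df)
        assert abs(agq - brute) / abs(brute) < 1e-6

    def test_more_nodes_move_monotonically_toward_brute_force(self, small):
        spec, df = small
        beta = np.array([-0.5, 0.6, 0.3])
        brute = self.brute_force(spec, beta, 0.4, 2.0, df)
        errs = []
        for q in (1, 3, 7, 15):
            sq = NBMMSpec(covariates=("x1", "x2"), quadrature_points=q)
            errs.append(abs(marginal_log_likelihood(
                sq, (beta, math.log(0.4), math.log(2.0)), df) - brute))
        for worse, better in zip(errs, errs[1:]):
            assert better <= worse + 1e-10

    def test_all_zero_covariate_with_zero_beta_is_invariant(self, small):
        spec, df = small
        beta = np.array([-0.5, 0.6, 0.3])
        base = marginal_log_likelihood(spec, (beta, math.log(0.4), math.log(2.0)), df)
        df2 = df.assign(xz=0.0)
        spec2 = NBMMSpec(covariates=("x1", "x2", "xz"))
        aug = marginal_log_likelihood(
            spec2, (np.append(beta, 0.0), math.log(0.4), math.log(2.0)), df2)
        assert aug == pytest.approx(base, rel=1e-12)

    def test_nonfinite_predictor_identifies_unit(self, small):
        spec, df = small
        df2 = df.copy()
        df2.loc[3, "x1"] = np.inf
        with pytest.raises(ModelError, match="non-finite linear predictor"):
            marginal_log_likelihood(
                spec, (np.array([-0.5, 0.6, 0.3]), math.log(0.4), math.log(2.0)), df2)


class TestFit:
    def test_poisson_limit_matches_irls_oracle(self):
        rng = np.random.default_rng(21)
        df = simulate_units(rng, 25, 40, beta=(-0.4, 0.7, 0.3), sigma_b=0.0, k=np.inf)
        spec = NBMMSpec(covariates=("x1", "x2"))
        model = fit(spec, df, fix_sigma_b=0.0, fix_k=1e8)
        oracle = _irls_poisson(df, ("x1", "x2"))
        assert np.max(np.abs(model.beta - oracle)) < 1e-4

    def test_recovers_parameters_at_moderate_scale(self):
        rng = np.random.default_rng(30)
        df = simulate_units(rng, 80, 40, beta=(-1.0, 0.8, 0.5), sigma_b=0.3, k=2.0)
        model = fit(NBMMSpec(covariates=("x1", "x2")), df)
        assert model.converged
        truth = np.array([-1.0, 0.8, 0.5])
        assert np.all(np.abs(model.beta - truth) < 3 * model.se)
        assert abs(model.sigma_b - 0.3) < 0.15
        assert 1.0 < model.dispersion_k < 4.0

    def test_constant_covariate_exercises_singular_path(self):
        rng = np.random.default_rng(8)
        df = simulate_units(rng, 10, 10, beta=(-0.5, 0.4), sigma_b=0.2, k=2.0,
                            prevalence=(0.5,))
        df["const"] = 1.0  # collinear with the intercept
        with pytest.warns(UserWarning, match="singular|converge"):
            model = fit(NBMMSpec(covariates=("x1", "const")), df)
        assert np.isnan(model.se).any() or not model.converged

    def test_fewer_than_two_facilities_rejected(self):
        df = pd.DataFrame({"facility_id": ["A"] * 5, "pah_count": [0, 1, 0, 2, 1],
                           "person_years": [1.0] * 5, "x1": [0, 1, 0, 1, 1.0]})
        with pytest.raises(ModelError, match="2 facilities"):
            fit(NBMMSpec(covariates=("x1",)), df)

    def test_zero_exposure_with_events_rejected(self):
        df = pd.DataFrame({"facility_id": ["A", "A", "B", "B"],
                           "pah_count": [1, 0, 0, 0],
                           "person_years": [0.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ModelError, match="zero exposure"):
            fit(NBMMSpec(), df)


class TestBackwardEliminate:
    def _df(self, seed=0, n_groups=60, per_group=30):
        rng = np.random.default_rng(seed)
        df = simulate_units(rng, n_groups, per_group,
                            beta=(-0.8, 0.7, 0.0), sigma_b=0.2, k=2.0)
        return df  # x1 true effect, x2 pure noise

    def test_noise_dropped_true_retained(self):
        spec = NBMMSpec(covariates=("x1", "x2"))
        model, trace = backward_eliminate(spec, self._df(seed=4), alpha=0.05)
        assert "x1" in model.names
        assert "x2" not in model.names
        assert [name for name, _ in trace] == ["x2"]

    def test_all_significant_is_fixed_point(self):
        rng = np.random.default_rng(9)
        df = simulate_units(rng, 60, 30, beta=(-0.8, 0.7, 0.5), sigma_b=0.2, k=2.0)
        model, trace = backward_eliminate(NBMMSpec(covariates=("x1", "x2")), df)
        assert trace == []
        assert set(model.names) == {"intercept", "x1", "x2"}

    def test_alpha_one_never_eliminates(self):
        spec = NBMMSpec(covariates=("x1", "x2"))
        model, trace = backward_eliminate(spec, self._df(seed=4), alpha=1.0)
        assert trace == []
        assert "x2" in model.names

    def test_retained_set_invariant_to_listed_order(self):
        df = self._df(seed=12)
        m1, _ = backward_eliminate(NBMMSpec(covariates=("x1", "x2")), df)
        m2, _ = backward_eliminate(NBMMSpec(covariates=("x2", "x1")), df)
        assert set(m1.names) == set(m2.names)

    def test_all_eliminated_returns_intercept_only(self):
        rng = np.random.default_rng(3)
        df = simulate_units(rng, 40, 20, beta=(-0.8, 0.0, 0.0), sigma_b=0.2, k=2.0)
        model, trace = backward_eliminate(NBMMSpec(covariates=("x1", "x2")), df,
                                          alpha=1e-6)
        assert model.names == ("intercept",)
        assert len(trace) == 2

    def test_intercept_never_removed(self):
        model, _ = backward_eliminate(NBMMSpec(covariates=("x1", "x2")),
                                      self._df(seed=4), alpha=1e-12)
        assert model.names[0] == "intercept"


class TestPredict:
    def _model(self, beta, names=("intercept",), offset_mode="log_person_time"):
        from pahrank.nbglmm import FittedNBMM

        p = len(beta)
        return FittedNBMM(
            names=tuple(names), beta=np.asarray(beta, dtype=float),
            sigma_b=0.2, dispersion_k=2.0, se=np.ones(p), p_values=np.ones(p),
            log_likelihood=0.0, converged=True, n_facilities=5, n_units=50,
            spec=NBMMSpec(covariates=tuple(names[1:]), offset_mode=offset_mode),
        )

    def _agg(self, fid="F1", py=100.0, **props):
        return FacilityAggregate(fid, 10, 0, py, dict(props), {}, n_beds=12, stratum="S")

    def test_intercept_only_rate_anchor(self):
        # rate 0.34 per person-year over 100 person-years -> 34 expected events
        model = self._model([math.log(0.34)])
        pred = predict_facility_counts(model, [self._agg(py=100.0)])
        assert pred.loc["F1"] == pytest.approx(34.0)

    def test_zero_exposure_zero_prediction(self):
        model = self._model([math.log(0.34)])
        pred = predict_facility_counts(model, [self._agg(py=0.0)])
        assert pred.loc["F1"] == 0.0

    def test_linear_in_exposure(self):
        model = self._model([0.1])
        p1 = predict_facility_counts(model, [self._agg(py=50.0)]).loc["F1"]
        p2 = predict_facility_counts(model, [self._agg(py=100.0)]).loc["F1"]
        assert p2 == pytest.approx(2 * p1)

    def test_missing_covariate_named(self):
        model = self._model([0.1, 0.5], names=("intercept", "gp_urgent_2wk"))
        agg = FacilityAggregate("F1", 10, 0, 10.0, {}, {})
        with pytest.raises(ModelError, match="gp_urgent_2wk"):
            predict_facility_counts(model, [agg])

    def test_covariates_shift_prediction(self):
        model = self._model([0.0, 1.0], names=("intercept", "gp_urgent_2wk"))
        lo = predict_facility_counts(model, [self._agg(gp_urgent_2wk=0.0)]).loc["F1"]
        hi = predict_facility_counts(model, [self._agg(gp_urgent_2wk=1.0)]).loc["F1"]
        assert hi == pytest.approx(lo * math.e)


def _irls_poisson(df, covariates, tol=1e-12, maxit=100):
    """Hand-rolled IRLS for a Poisson GLM with log link and offset."""
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in covariates])
    y = df["pah_count"].to_numpy(float)
    off = np.log(df["person_years"].to_numpy(float))
    beta = np.zeros(X.shape[1])
    for _ in range(maxit):
        mu = np.exp(X @ beta + off)
        z = X @ beta + (y - mu) / mu
        new = np.linalg.solve(X.T @ (mu[:, None] * X), X.T @ (mu * z))
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    return beta
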