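"""Mixed-effects estimator: likelihood oracles, conditional modes, and
full-fit behavior on controlled simulations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popsse.cohort import ScenarioSpec, VarianceSpec, simulate_dataset
from popsse.estimation import (EstimationSettings, build_design,
                               conditional_mode, fit, marginal_objective,
                               subject_neg2ll)
from popsse.pk_model import DoseEvent, PKParameters, Regimen, conc_profile

POP = PKParameters(CL=1.5, V1=24.2, V2=32.3, Q=11.2)
REG = Regimen.q_interval(1000.0, 1.0, 12.0, 4)


def toy_subject(eta, times, sigma=0.05, seed=0):
    """Observations for one subject with known random effects."""
    rng = np.random.default_rng(seed)
    params = PKParameters(*(POP.as_array() * np.exp(np.asarray(eta))))
    pred = conc_profile(params, REG, times)
    dv = pred * (1.0 + sigma * rng.normal(size=len(times)))
    return np.asarray(times, float), dv


class TestSubjectNeg2ll:
    def test_matches_direct_density_product(self):
        """-2 log of (product of proportional-error normal densities) times
        the eta prior, computed independently with scipy.stats."""
        times, dv = toy_subject([0.1, -0.2, 0.05, 0.15], [2.0, 10.0], seed=3)
        eta = np.array([0.05, -0.1, 0.2, 0.0])
        omega2 = np.array([0.09, 0.04, 0.09, 0.16])
        sigma = 0.1
        params = POP.as_array() * np.exp(eta)
        pred = conc_profile(PKParameters(*params), REG, times)
        loglik = stats.norm.logpdf(dv, loc=pred, scale=sigma * pred).sum()
        loglik += stats.multivariate_normal.logpdf(eta, mean=np.zeros(4),
                                                   cov=np.diag(omega2))
        expected = -2.0 * loglik
        got = subject_neg2ll(POP, omega2, sigma, eta, times, dv, REG)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_inactive_random_effect_drops_prior_term(self):
        times, dv = toy_subject([0.0] * 4, [2.0, 10.0])
        full = subject_neg2ll(POP, [0.09, 0.09, 0.09, 0.09], 0.1,
                              np.zeros(4), times, dv, REG)
        reduced = subject_neg2ll(POP, [0.09, 0.0, 0.0, 0.0], 0.1,
                                 np.zeros(4), times, dv, REG)
        # removing three active dimensions removes their log|2 pi omega^2|
        assert full - reduced == pytest.approx(3 * np.log(2 * np.pi * 0.09), rel=1e-10)
        with pytest.raises(ValueError, match="eta must be 0"):
            subject_neg2ll(POP, [0.09, 0.0, 0.0, 0.0], 0.1,
                           [0.0, 0.1, 0.0, 0.0], times, dv, REG)

    def test_zero_prediction_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            subject_neg2ll(POP, [0.09] * 4, 0.1, np.zeros(4),
                           [0.0, 2.0], [0.0, 20.0], REG)


class TestConditionalMode:
    def test_vanishing_bsv_pins_eta_at_zero(self):
        times, dv = toy_subject([0.3, 0.1, -0.2, 0.2], [1.0, 2.0, 4.0, 12.0])
        eta_hat, conv = conditional_mode(POP, [1e-8] * 4, 0.1, times, dv, REG)
        assert conv
        np.testing.assert_allclose(eta_hat, 0.0, atol=1e-4)

    def test_recovers_known_eta_at_tiny_noise(self):
        eta_true = np.array([0.25, -0.15, 0.1, -0.05])
        times = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 37.0, 40.0, 48.0])
        times, dv = toy_subject(eta_true, times, sigma=1e-4, seed=1)
        eta_hat, conv = conditional_mode(POP, [10.0] * 4, 1e-4, times, dv, REG)
        assert conv
        np.testing.assert_allclose(eta_hat, eta_true, atol=1e-3)

    def test_duplicate_subject_identical_mode(self):
        times, dv = toy_subject([0.2, 0.0, 0.0, -0.1], [1.0, 4.0, 12.0])
        a, _ = conditional_mode(POP, [0.09] * 4, 0.1, times, dv, REG)
        b, _ = conditional_mode(POP, [0.09] * 4, 0.1, times, dv, REG)
        np.testing.assert_array_equal(a, b)


def gauss_hermite_neg2ll(theta, omega2_cl, sigma, times, dv, regimen, nodes=41):
    """Adaptive Gauss-Hermite -2 log marginal likelihood for one subject
    with a single (clearance) random effect; independent oracle."""
    om = [omega2_cl, 0.0, 0.0, 0.0]

    def g(e):
        return subject_neg2ll(theta, om, sigma, [e, 0.0, 0.0, 0.0],
                              times, dv, regimen)

    mode, _ = conditional_mode(theta, om, sigma, times, dv, regimen)
    mu = mode[0]
    d = 1e-4
    half_hess = 0.5 * (g(mu + d) - 2 * g(mu) + g(mu - d)) / d ** 2
    scale = 1.0 / np.sqrt(half_hess)
    z, w = np.polynomial.hermite.hermgauss(nodes)
    vals = np.array([g(mu + np.sqrt(2) * scale * zi) for zi in z])
    ref = vals.min()
    integral = np.sqrt(2) * scale * np.sum(
        w * np.exp(z ** 2) * np.exp(-(vals - ref) / 2.0))
    return ref - 2.0 * np.log(integral)


@pytest.fixture(scope="module")
def small_dataset():
    return simulate_dataset(ScenarioSpec("PK1", 1.5, 1.0, 3), seed=[3, 0])


class TestMarginalObjective:
    def test_subject_permutation_invariance(self, small_dataset):
        ds = small_dataset
        shuffled = ds.records.copy()
        shuffled["ID"] = shuffled["ID"].map({1: 3, 2: 1, 3: 2})
        shuffled = shuffled.sort_values(["ID", "TIME", "EVID"],
                                        kind="stable", ignore_index=True)
        from popsse.cohort import PopDataset
        ds2 = PopDataset(records=shuffled)
        for method in ("foce-i", "laplace"):
            a = marginal_objective(POP, [0.09] * 4, 0.1, ds, method)
            b = marginal_objective(POP, [0.09] * 4, 0.1, ds2, method)
            assert a == pytest.approx(b, rel=1e-9)

    @staticmethod
    def _toy_instance(seed):
        """3 subjects, 2 observations each, single 1 h infusion, clearance
        random effect only."""
        reg = Regimen((DoseEvent(0.0, 1000.0, 1.0),))
        times = np.array([2.0, 10.0])
        rng = np.random.default_rng(seed)
        rows = []
        for sid in (1, 2, 3):
            eta = rng.normal(0.0, 0.3)
            p = PKParameters(*(POP.as_array() * np.exp([eta, 0, 0, 0])))
            pred = conc_profile(p, reg, times)
            dv = pred * (1.0 + 0.1 * rng.normal(size=2))
            rows.append(pd.DataFrame({
                "ID": sid, "TIME": [0.0, *times],
                "AMT": [1000.0, np.nan, np.nan],
                "RATE": [1000.0, np.nan, np.nan],
                "EVID": [1, 0, 0], "MDV": [1, 0, 0],
                "DV": [np.nan, *dv]}))
        from popsse.cohort import PopDataset
        return PopDataset(records=pd.concat(rows, ignore_index=True)), reg

    @pytest.mark.parametrize("seed", [100, 101, 102])
    @pytest.mark.parametrize("method", ["laplace", "foce-i"])
    def test_within_half_point_of_quadrature_oracle(self, method, seed):
        """On 3-subject, 2-observation toys with one active random effect,
        both conditional approximations sit within 0.5 of adaptive 41-node
        Gauss-Hermite quadrature on the -2LL scale."""
        ds, reg = self._toy_instance(seed)
        approx = marginal_objective(POP, [0.09, 0.0, 0.0, 0.0], 0.1, ds, method)
        grp = build_design(ds)[0]
        exact = sum(gauss_hermite_neg2ll(POP, 0.09, 0.1, grp.times, grp.dv[i], reg)
                    for i in range(grp.n_subjects))
        assert abs(approx - exact) <= 0.5

    def test_collapses_to_weighted_least_squares(self):
        """With no random effects the objective is the fixed-effects
        proportional-error -2 log likelihood, computed directly."""
        ds = simulate_dataset(ScenarioSpec("PK1", 1.5, 1.0, 4), seed=[5, 0])
        obj = marginal_objective(POP, [0.0] * 4, 0.1, ds, "foce-i")
        obs = ds.records[(ds.records["EVID"] == 0) & (ds.records["MDV"] == 0)]
        expected = 0.0
        for sid, sub in obs.groupby("ID"):
            pred = conc_profile(POP, REG, sub["TIME"].to_numpy())
            expected += -2.0 * stats.norm.logpdf(
                sub["DV"].to_numpy(), loc=pred, scale=0.1 * pred).sum()
        assert obj == pytest.approx(expected, rel=1e-10)

    def test_tiny_bsv_approaches_no_bsv_limit(self):
        ds = simulate_dataset(ScenarioSpec("PK1", 1.5, 1.0, 4), seed=[5, 0])
        fixed = marginal_objective(POP, [0.0] * 4, 0.1, ds, "laplace")
        tiny = marginal_objective(POP, [1e-10] * 4, 0.1, ds, "laplace")
        assert tiny == pytest.approx(fixed, abs=1e-3)


class TestFit:
    def test_noiseless_identifiability(self):
        """Simulated without BSV and with near-zero residual error, the
        fixed effects are recovered to 0.1% when BSV is held tiny."""
        sc = ScenarioSpec("PK3", 1.5, 1.0, 50)
        var = VarianceSpec(omega_sd=(0.0,) * 4, sigma_prop=1e-6)
        ds = simulate_dataset(sc, var, seed=[11, 0])
        settings = EstimationSettings(
            initial_theta=tuple(POP.as_array() * 1.05),
            initial_omega2=(1e-8,) * 4, initial_sigma=1e-6,
            fix_omega2=(1e-8,) * 4, fix_sigma=1e-6)
        res = fit(ds, settings)
        np.testing.assert_allclose(res.theta_hat.as_array(), POP.as_array(),
                                   rtol=1e-3)

    def test_refit_is_bit_reproducible(self):
        ds = simulate_dataset(ScenarioSpec("PK1", 4.5, 1.0, 12), seed=[2, 0])
        r1 = fit(ds)
        r2 = fit(ds)
        assert r1.objective == r2.objective
        np.testing.assert_array_equal(r1.theta_hat.as_array(),
                                      r2.theta_hat.as_array())
        np.testing.assert_array_equal(r1.omega2_hat, r2.omega2_hat)
        assert r1.sigma_hat == r2.sigma_hat

    def test_scale_equivariance(self):
        """Rescaling dose and concentration units together leaves the
        (dimensionless) proportional-error coefficient and all parameter
        estimates unchanged."""
        ds = simulate_dataset(ScenarioSpec("PK1", 4.5, 1.0, 12), seed=[8, 0])
        scaled = ds.records.copy()
        for col in ("AMT", "RATE", "DV"):
            scaled[col] = scaled[col] * 1000.0
        from popsse.cohort import PopDataset
        ds_scaled = PopDataset(records=scaled, scenario=ds.scenario)
        r = fit(ds)
        r_scaled = fit(ds_scaled)
        np.testing.assert_allclose(r_scaled.theta_hat.as_array(),
                                   r.theta_hat.as_array(), rtol=1e-5)
        assert r_scaled.sigma_hat == pytest.approx(r.sigma_hat, rel=1e-5)

    def test_requires_initial_values_without_provenance(self, tmp_path):
        from popsse.cohort import write_dataset, read_dataset
        ds = simulate_dataset(ScenarioSpec("PK1", 1.5, 1.0, 3), seed=[1, 0])
        write_dataset(ds, tmp_path / "d.csv")
        bare = read_dataset(tmp_path / "d.csv")
        with pytest.raises(ValueError, match="initial estimates"):
            fit(bare)

    def test_two_subject_minimum(self):
        ds = simulate_dataset(ScenarioSpec("PK1", 1.5, 1.0, 1), seed=[1, 0])
        with pytest.raises(ValueError, match="at least 2"):
            fit(ds)
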