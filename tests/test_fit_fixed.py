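"""Fixed-effects fitting: recovery, cross-checks, diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import coldtreat as ct
from coldtreat.bioassay import observations_to_frame

from conftest import simulate_boxes


class TestFitFixed:
    def test_recovers_known_probit_coefficients(self):
        # binomial data (rho=0), generous 3-SE recovery band
        df = simulate_boxes(alpha=-2.0, beta=0.5, rho=0.0, link="probit",
                            n_boxes=50, box_n=100, seed=3)
        fit = ct.fit_fixed(df, ct.ModelSpec(link="probit"))
        assert fit.converged
        a, b = fit.alpha("L3"), fit.beta("L3")
        se_a = np.sqrt(fit.ab_covariance("L3")[0, 0])
        se_b = np.sqrt(fit.ab_covariance("L3")[1, 1])
        assert abs(a - (-2.0)) < 3 * se_a
        assert abs(b - 0.5) < 3 * se_b

    @pytest.mark.parametrize("link", ["probit", "logit"])
    def test_agrees_with_irls_on_binomial_data(self, link):
        # independent oracle: statsmodels GLM with the same link on rho=0 data
        df = simulate_boxes(alpha=-1.5, beta=0.4, rho=0.0, link=link,
                            n_boxes=40, box_n=200, seed=5)
        fit = ct.fit_fixed(df, ct.ModelSpec(link=link, family="binomial"))
        d = observations_to_frame(df)
        dead = np.rint(d["treated_estimate"]).astype(int) - d["pupae_count"]
        X = sm.add_constant(d["duration_days"].to_numpy())
        fam = sm.families.Binomial(
            sm.families.links.Probit() if link == "probit" else sm.families.links.Logit()
        )
        glm = sm.GLM(np.column_stack([dead, d["pupae_count"]]), X, family=fam).fit()
        assert fit.alpha("L3") == pytest.approx(glm.params[0], abs=1e-4)
        assert fit.beta("L3") == pytest.approx(glm.params[1], abs=1e-4)

    def test_loglik_at_optimum_beats_truth(self):
        # MLE property: the fitted likelihood dominates the generating values
        for seed in range(5):
            df = simulate_boxes(alpha=-3.0, beta=0.8, rho=0.05, seed=seed)
            fit = ct.fit_fixed(df, ct.ModelSpec(link="logit"))
            prep_truth = np.sum(
                ct.betabinom_loglik(
                    np.rint(df.treated_estimate).astype(int) - df.pupae_count,
                    np.rint(df.treated_estimate).astype(int),
                    ct.link_inverse(-3.0 + 0.8 * df.duration_days.to_numpy(), "logit"),
                    0.05,
                )
            )
            assert fit.loglik >= prep_truth - 1e-6

    def test_predicted_mortality_monotone_for_positive_slope(self, sim_fit):
        assert sim_fit.beta("L3") > 0
        t = np.linspace(0, 25, 101)
        p = sim_fit.predict_mortality("L3", t)
        assert np.all(np.diff(p) >= 0)

    def test_single_duration_unidentifiable(self):
        df = simulate_boxes(seed=1, durations=(5,))
        with pytest.raises(ValueError, match="distinct durations"):
            ct.fit_fixed(df, ct.ModelSpec())

    def test_separation_flagged_not_silent(self):
        # all-or-nothing mortality across durations: no interior point
        rows = []
        for i, t in enumerate([0, 0, 1, 1, 9, 9, 10, 10]):
            dead = 0 if t < 5 else 100
            rows.append(dict(life_stage="L3", duration_days=float(t),
                             unit_id=str(i), pupae_count=100 - dead,
                             treated_estimate=100.0))
        fit = ct.fit_fixed(pd.DataFrame(rows), ct.ModelSpec(link="logit"))
        assert any("separation" in w for w in fit.warnings)

    def test_deterministic(self, sim_data):
        f1 = ct.fit_fixed(sim_data, ct.ModelSpec(link="logit"))
        f2 = ct.fit_fixed(sim_data, ct.ModelSpec(link="logit"))
        assert np.array_equal(f1.params, f2.params)
        assert f1.loglik == f2.loglik

    def test_covariance_symmetric_psd(self, sim_fit):
        c = sim_fit.covariance
        assert np.allclose(c, c.T)
        assert np.all(np.linalg.eigvalsh(c) > -1e-10)

    def test_serialization_round_trip(self, sim_fit, tmp_path):
        path = tmp_path / "fit.json"
        sim_fit.to_json(path)
        back = ct.ModelFit.from_json(path)
        assert back.param_names == sim_fit.param_names
        assert np.allclose(back.params, sim_fit.params)
        assert np.allclose(back.covariance, sim_fit.covariance)
        assert back.spec == sim_fit.spec

    def test_aic_link_selection_runs_both_links(self, sim_data):
        fit = ct.select_link(sim_data)
        other = "probit" if fit.spec.link == "logit" else "logit"
        alt = ct.fit_fixed(sim_data, ct.ModelSpec(link=other))
        assert fit.aic <= alt.aic


@pytest.fixture(scope="module")
def small_fit():
    df = simulate_boxes(n_boxes=30, box_n=60, rho=0.08, seed=21)
    return ct.fit_fixed(df, ct.ModelSpec(link="logit")), df


class TestDispersionCheck:

    def test_deterministic_given_seed(self, small_fit):
        fit, df = small_fit
        a = ct.dispersion_check(fit, df, n_sim=100, seed=9)
        b = ct.dispersion_check(fit, df, n_sim=100, seed=9)
        assert a == b

    def test_self_consistency_p_values_uniform(self, small_fit):
        # data simulated from the fitted model itself: p should be uniform
        from coldtreat.bioassay import _Prepared, betabinom_rvs
        from scipy import stats as sps

        fit, df = small_fit
        prep = _Prepared(observations_to_frame(df), fit.spec)
        mu, rho = prep.mu_rho(fit.params)
        rng = np.random.default_rng(2024)
        pvals = []
        for _ in range(200):
            sim = df.copy()
            dead = betabinom_rvs(prep.ntot, mu, rho, rng)
            sim["pupae_count"] = prep.ntot - dead
            res = ct.dispersion_check(fit, sim, n_sim=100,
                                      seed=int(rng.integers(2**31 - 1)))
            pvals.append(res.p_value)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_power_against_overdispersion(self):
        # a binomial model fit to strongly beta-binomial data must be flagged
        hits = 0
        for seed in range(20):
            df = simulate_boxes(rho=0.3, n_boxes=40, box_n=100, seed=100 + seed)
            fit = ct.fit_fixed(df, ct.ModelSpec(link="logit", family="binomial"))
            res = ct.dispersion_check(fit, df, n_sim=150, seed=seed)
            hits += res.dispersion_statistic > 1.0 and res.p_value < 0.05
        assert hits >= 16  # >= 80% of seeds

    def test_requires_converged_fit(self, small_fit):
        import dataclasses

        fit, df = small_fit
        broken = dataclasses.replace(fit, converged=False)
        with pytest.raises(ValueError):
            ct.dispersion_check(broken, df, n_sim=100, seed=0)
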