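"""Gamma-Poisson shrinker: marginal density, prior fit, posterior summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special, stats

from adrsignal import mgps
from adrsignal.mgps import PriorParams

PRIORS = [
    PriorParams(w=1 / 3, alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0),
    PriorParams(w=0.8, alpha1=1.5, beta1=0.8, alpha2=5.0, beta2=1.0),
    PriorParams(w=0.05, alpha1=0.3, beta1=0.3, alpha2=3.0, beta2=3.0),
]


def posterior_pdf_oracle(lam, n00, E, prior):
    """Unnormalised posterior density: Poisson(n00; λE) × mixture prior pdf."""
    pois = stats.poisson.pmf(n00, lam * E) if float(n00).is_integer() else np.exp(
        n00 * np.log(lam * E) - lam * E - special.gammaln(n00 + 1)
    )
    pri = prior.w * stats.gamma.pdf(lam, prior.alpha1, scale=1 / prior.beta1) + (
        1 - prior.w
    ) * stats.gamma.pdf(lam, prior.alpha2, scale=1 / prior.beta2)
    return pois * pri


def quadrature_posterior_moments(n00, E, prior):
    """Normalising constant, E[log2 λ] and a CDF callable, all by quadrature."""
    hi = 2 * max(
        stats.gamma.ppf(1 - 1e-13, prior.alpha1 + n00, scale=1 / (prior.beta1 + E)),
        stats.gamma.ppf(1 - 1e-13, prior.alpha2 + n00, scale=1 / (prior.beta2 + E)),
    )
    z, _ = integrate.quad(
        posterior_pdf_oracle, 0, hi, args=(n00, E, prior), limit=400, epsabs=0, epsrel=1e-11
    )
    mean_log2, _ = integrate.quad(
        lambda l: np.log2(l) * posterior_pdf_oracle(l, n00, E, prior) / z,
        0,
        hi,
        limit=400, epsabs=0, epsrel=1e-11,
    )

    def cdf(x):
        v, _ = integrate.quad(
            posterior_pdf_oracle, 0, x, args=(n00, E, prior), limit=400, epsabs=0, epsrel=1e-11
        )
        return v / z

    return z, mean_log2, cdf


class TestMarginalDensity:
    def test_closed_form_at_zero_count(self):
        # (1+1)^0 (1+1)^(-1) Γ(1)/Γ(1)0! = 0.5
        assert mgps.marginal_density(0, 1.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_normalizes_over_counts(self):
        n = np.arange(0, 501)
        total = mgps.marginal_density(n, 2.0, 1.5, 0.8).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_matches_poisson_gamma_quadrature(self):
        """The negative-binomial form equals ∫ Poisson(n; λE) Ga(λ; α, β) dλ."""
        alpha, beta, E, n00 = 1.5, 0.8, 2.0, 3

        def integrand(lam):
            return stats.poisson.pmf(n00, lam * E) * stats.gamma.pdf(
                lam, alpha, scale=1 / beta
            )

        oracle, _ = integrate.quad(integrand, 0, 200, limit=300, epsabs=0, epsrel=1e-11)
        assert mgps.marginal_density(n00, E, alpha, beta) == pytest.approx(
            oracle, abs=1e-8
        )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            mgps.marginal_density(-1, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            mgps.marginal_density(0, 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            mgps.marginal_density(0, np.inf, 1.0, 1.0)


class TestPosteriorWeight:
    def test_degenerate_mixture_weights(self):
        p1 = PriorParams(w=1.0, alpha1=1.0, beta1=1.0, alpha2=2.0, beta2=2.0)
        p0 = PriorParams(w=0.0, alpha1=1.0, beta1=1.0, alpha2=2.0, beta2=2.0)
        assert mgps.posterior_qn(3, 2.0, p1) == 1.0
        assert mgps.posterior_qn(3, 2.0, p0) == 0.0

    def test_identical_components_give_half(self):
        p = PriorParams(w=0.5, alpha1=1.3, beta1=0.7, alpha2=1.3, beta2=0.7)
        for n00, E in [(0, 0.5), (7, 3.0), (100, 40.0)]:
            assert mgps.posterior_qn(n00, E, p) == pytest.approx(0.5)

    def test_no_underflow_at_extreme_counts(self):
        p = PRIORS[0]
        qn = mgps.posterior_qn(5000, 1.0, p)
        assert np.isfinite(qn) and 0.0 <= qn <= 1.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        n00=st.integers(min_value=0, max_value=2000),
        E=st.floats(min_value=1e-3, max_value=1e4),
        w=st.floats(min_value=0.01, max_value=0.99),
    )
    def test_qn_always_a_probability(self, n00, E, w):
        p = PriorParams(w=w, alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0)
        qn = mgps.posterior_qn(n00, E, p)
        assert 0.0 <= qn <= 1.0


class TestPosteriorEblog2:
    def test_digamma_closed_form(self):
        # single component, n00=0, E=1: [ψ(1) − ln 2]/ln 2
        p = PriorParams(w=1.0, alpha1=1.0, beta1=1.0, alpha2=1.0, beta2=1.0)
        expected = (special.digamma(1.0) - np.log(2.0)) / np.log(2.0)
        got = mgps.posterior_eblog2(0, 1.0, p)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(-1.8327, abs=1e-4)

    def test_shrinkage_vanishes_at_large_counts(self):
        p = PriorParams(w=1.0, alpha1=1.0, beta1=1.0, alpha2=1.0, beta2=1.0)
        got = mgps.posterior_eblog2(10000, 1000.0, p)
        assert got == pytest.approx(np.log2(10000 / 1000), abs=0.01)

    def test_identical_components_reduce_to_single(self):
        mix = PriorParams(w=0.5, alpha1=1.5, beta1=0.8, alpha2=1.5, beta2=0.8)
        single = PriorParams(w=1.0, alpha1=1.5, beta1=0.8, alpha2=1.5, beta2=0.8)
        assert mgps.posterior_eblog2(4, 2.0, mix) == pytest.approx(
            mgps.posterior_eblog2(4, 2.0, single)
        )

    def test_matches_quadrature_mean(self):
        """Closed-form E[log2 λ] equals numerical integration of the posterior."""
        for prior in PRIORS[:2]:
            for n00, E in [(0, 0.5), (3, 2.0), (10, 2.0)]:
                _, mean_log2, _ = quadrature_posterior_moments(n00, E, prior)
                assert mgps.posterior_eblog2(n00, E, prior) == pytest.approx(
                    mean_log2, abs=1e-6
                )

    def test_variance_matches_quadrature(self):
        prior = PRIORS[1]
        n00, E = 3, 2.0
        z, mean_log2, _ = quadrature_posterior_moments(n00, E, prior)
        second, _ = integrate.quad(
            lambda l: np.log2(l) ** 2 * posterior_pdf_oracle(l, n00, E, prior) / z,
            0,
            200,
            limit=400, epsabs=0, epsrel=1e-11,
        )
        oracle_var = second - mean_log2**2
        assert mgps.posterior_log2_var(n00, E, prior) == pytest.approx(
            oracle_var, abs=1e-6
        )

    def test_monotone_in_count_for_single_component(self):
        p = PriorParams(w=1.0, alpha1=1.2, beta1=0.9, alpha2=1.2, beta2=0.9)
        vals = mgps.posterior_eblog2(np.arange(0, 30), 3.0, p)
        assert (np.diff(vals) > 0).all()


class TestPosteriorQuantile:
    def test_single_component_equals_gamma_ppf(self):
        p = PriorParams(w=1.0, alpha1=1.5, beta1=0.8, alpha2=1.5, beta2=0.8)
        n00, E = 4, 2.0
        oracle = stats.gamma.ppf(0.05, p.alpha1 + n00, scale=1 / (p.beta1 + E))
        assert mgps.posterior_quantile(n00, E, p, 0.05) == pytest.approx(oracle, rel=1e-9)

    def test_quantiles_increase_in_q(self):
        p = PRIORS[0]
        q05 = mgps.posterior_quantile(3, 2.0, p, 0.05)
        q50 = mgps.posterior_quantile(3, 2.0, p, 0.50)
        q95 = mgps.posterior_quantile(3, 2.0, p, 0.95)
        assert q05 < q50 < q95

    def test_cdf_round_trip(self):
        p = PRIORS[0]
        for n00, E in [(0, 0.5), (3, 2.0), (50, 20.0)]:
            x = mgps.posterior_quantile(n00, E, p, 0.05)
            qn = mgps.posterior_qn(n00, E, p)
            cdf = qn * stats.gamma.cdf(x, p.alpha1 + n00, scale=1 / (p.beta1 + E)) + (
                1 - qn
            ) * stats.gamma.cdf(x, p.alpha2 + n00, scale=1 / (p.beta2 + E))
            assert cdf == pytest.approx(0.05, abs=1e-6)

    def test_rejects_degenerate_q(self):
        with pytest.raises(ValueError):
            mgps.posterior_quantile(1, 1.0, PRIORS[0], 0.0)


def simulate_pairs(prior, n_pairs, seed):
    """Draw (n00, E) from the mixture model itself — the fit's own world."""
    rng = np.random.default_rng(seed)
    E = rng.uniform(0.5, 20.0, size=n_pairs)
    comp = rng.random(n_pairs) < prior.w
    lam = np.where(
        comp,
        rng.gamma(prior.alpha1, 1 / prior.beta1, size=n_pairs),
        rng.gamma(prior.alpha2, 1 / prior.beta2, size=n_pairs),
    )
    n00 = rng.poisson(lam * E)
    import pandas as pd

    return pd.DataFrame(
        {"drug_id": "d", "adr_id": [str(i) for i in range(n_pairs)], "n00": n00, "E": E}
    )


class TestFitPrior:
    def test_fixed_point_returns_immediately(self):
        true = PRIORS[0]
        df = simulate_pairs(true, 1500, seed=11)
        fitted = mgps.fit_prior(df)
        again = mgps.fit_prior(df, init=fitted)
        assert again.n_iter <= 2
        assert again.loglik == pytest.approx(fitted.loglik, abs=1e-6)

    def test_single_component_data_matches_single_gamma_fit(self):
        """On w=1 data the fitted mixture marginal tracks a plain single-gamma fit."""
        from scipy import optimize

        true = PriorParams(w=1.0, alpha1=1.2, beta1=0.6, alpha2=1.2, beta2=0.6)
        df = simulate_pairs(true, 20000, seed=3)
        n, e = df["n00"].to_numpy(float), df["E"].to_numpy(float)

        def neg_single(x):
            a, b = np.exp(x)
            return -mgps.log_marginal_density(n, e, a, b).sum()

        res = optimize.minimize(
            neg_single,
            np.log([1.0, 1.0]),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000},
        )
        a_hat, b_hat = np.exp(res.x)

        fitted = mgps.fit_prior(df)
        grid = np.arange(0, 21)
        e0 = 2.0
        single = mgps.marginal_density(grid, e0, a_hat, b_hat)
        mix = fitted.w * mgps.marginal_density(grid, e0, fitted.alpha1, fitted.beta1) + (
            1 - fitted.w
        ) * mgps.marginal_density(grid, e0, fitted.alpha2, fitted.beta2)
        assert np.max(np.abs(mix - single)) < 1e-3

    def test_degenerate_counts_flagged(self):
        import pandas as pd

        df = pd.DataFrame({"n00": [2.0] * 10, "E": np.linspace(1, 3, 10)})
        with pytest.warns(UserWarning, match="degenerate"):
            mgps.fit_prior(df)

    def test_requires_positive_expected_counts(self):
        import pandas as pd

        df = pd.DataFrame({"n00": [1, 2], "E": [1.0, 0.0]})
        with pytest.raises(ValueError):
            mgps.fit_prior(df)


class TestScoreAll:
    def test_identical_inputs_identical_scores(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "drug_id": ["a", "b", "c", "d"],
                "adr_id": ["x", "x", "y", "y"],
                "n00": [3.0, 3.0, 8.0, 1.0],
                "E": [1.5, 1.5, 2.0, 1.0],
            }
        )
        scores = mgps.score_all(df, PRIORS[0])
        assert scores.iloc[0]["ebgm"] == scores.iloc[1]["ebgm"]
        assert scores.iloc[0]["eb05"] == scores.iloc[1]["eb05"]

    def test_eb05_below_eb95(self):
        df = simulate_pairs(PRIORS[0], 300, seed=9)
        df["drug_id"] = [f"d{i}" for i in range(len(df))]
        scores = mgps.score_all(df, PRIORS[0])
        assert (scores["eb05"] <= scores["eb95"]).all()
        assert (scores["ebgm"] > 0).all()
        assert scores["qn"].between(0, 1).all()

    def test_planted_strong_pair_ranks_first(self):
        """A pair with tenfold reporting excess attains the maximum EBGM."""
        from adrsignal import reports as reports_mod, synthetic

        cfg = synthetic.SimConfig(
            n_reports=4000,
            n_drugs=40,
            n_adrs=12,
            n_causal_pairs=1,
            causal_rr=10.0,
            background_adr_rate=0.02,
            p_cluster=0.3,
            n_clusters=10,
            underreporting_prob=0.0,
            seed=21,
        )
        reps, truth = synthetic.generate_reports(cfg)
        ctab = reports_mod.build_contingency(reps)
        scores = mgps.score_all(ctab, compute_quantiles=False)
        top = scores.loc[scores["ebgm"].idxmax()]
        assert (top.drug_id, top.adr_id) in truth.causal_pairs

    def test_strict_margin_switch_changes_scores(self, small_dataset):
        from adrsignal import reports as reports_mod

        _, reports, _ = small_dataset
        default = reports_mod.build_contingency(reports)
        strict = reports_mod.build_contingency(reports, strict_margins=True)
        prior = mgps.fit_prior(default)
        s_default = mgps.score_all(default, prior, compute_quantiles=False)
        s_strict = mgps.score_all(strict, prior, compute_quantiles=False)
        assert not np.allclose(s_default["ebgm"], s_strict["ebgm"])


class TestPriorIO:
    def test_round_trip(self, tmp_path):
        p = PriorParams(
            w=0.4, alpha1=0.3, beta1=0.2, alpha2=2.5, beta2=3.5, loglik=-12.5,
            converged=True, n_iter=17,
        )
        path = tmp_path / "prior.ini"
        mgps.write_prior(p, path)
        back = mgps.read_prior(path)
        assert back == p
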