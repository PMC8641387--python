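"""The Gibbs-sampled mixed model against conjugate and symmetry oracles."""

import numpy as np
import pandas as pd
import pytest

from devwild import BayesianMixedRegression, fit_all, split_rhat, summarize
from devwild.model import posterior_table


def _conjugate_posterior(X, y, prior_var=1000.0, sigma2=1.0):
    """Closed-form posterior for Normal likelihood with known variance and
    independent N(0, prior_var) coefficient priors."""
    V = np.linalg.inv(X.T @ X / sigma2 + np.eye(X.shape[1]) / prior_var)
    m = V @ (X.T @ y / sigma2)
    return m, V


class TestGibbsCore:
    def test_matches_conjugate_closed_form(self):
        rng = np.random.default_rng(2)
        n = 100
        x = rng.normal(size=n)
        y = 0.4 * x + rng.normal(size=n)
        est = BayesianMixedRegression(
            fixed_resid_var=1.0, n_chains=2, n_iter=2500, n_burnin=500,
            center=False, random_state=0,
        ).fit(x[:, None], y)
        X = np.column_stack([np.ones(n), x])
        m, V = _conjugate_posterior(X, y)
        s = summarize(est.coefficient_draws(0))
        mcse = s["sd"] / np.sqrt(s["ess"])
        assert abs(s["mean"] - m[1]) < 3 * mcse
        assert abs(s["sd"] - np.sqrt(V[1, 1])) < 3 * s["sd"] / np.sqrt(2 * s["ess"])

    def test_null_response_concentrates_at_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=80)
        est = BayesianMixedRegression(
            n_chains=2, n_iter=1500, n_burnin=500, random_state=1
        ).fit(x[:, None], np.zeros(80))
        s = summarize(est.coefficient_draws(0))
        assert abs(s["mean"]) < 0.01
        assert s["ci_low"] <= 0 <= s["ci_high"]
        assert not s["support"]

    def test_posterior_sd_grows_toward_prior_as_data_shrink(self):
        """With uninformative data the coefficient posterior widens
        monotonically toward the prior scale (sd ~ sqrt(1000))."""
        rng = np.random.default_rng(4)
        sds = []
        for n in (40, 6, 2):
            x = rng.normal(size=n) * 1e-3  # nearly no signal in x
            y = rng.normal(size=n)
            est = BayesianMixedRegression(
                fixed_resid_var=1.0, n_chains=2, n_iter=2000, n_burnin=500,
                center=False, random_state=5,
            ).fit(x[:, None], y)
            sds.append(summarize(est.coefficient_draws(0))["sd"])
        assert sds[0] < sds[1] < sds[2]
        assert sds[2] == pytest.approx(np.sqrt(1000.0), rel=0.15)

    def test_sign_equivariance_within_mc_error(self):
        rng = np.random.default_rng(6)
        n = 120
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(scale=0.5, size=n)
        kw = dict(n_chains=2, n_iter=2000, n_burnin=500, random_state=7)
        a = BayesianMixedRegression(**kw).fit(x[:, None], y)
        b = BayesianMixedRegression(**kw).fit(-x[:, None], y)
        sa = summarize(a.coefficient_draws(0))
        sb = summarize(b.coefficient_draws(0))
        tol = 3 * np.hypot(sa["sd"] / np.sqrt(sa["ess"]), sb["sd"] / np.sqrt(sb["ess"]))
        assert abs(sa["mean"] + sb["mean"]) < tol

    def test_shifting_y_moves_only_the_intercept(self):
        rng = np.random.default_rng(8)
        n = 100
        x = rng.normal(size=n)
        y = 0.3 * x + rng.normal(scale=0.4, size=n)
        kw = dict(n_chains=2, n_iter=2000, n_burnin=500, random_state=9)
        a = BayesianMixedRegression(**kw).fit(x[:, None], y)
        b = BayesianMixedRegression(**kw).fit(x[:, None], y + 5.0)
        sa, sb = summarize(a.coefficient_draws(0)), summarize(b.coefficient_draws(0))
        tol = 3 * np.hypot(sa["sd"] / np.sqrt(sa["ess"]), sb["sd"] / np.sqrt(sb["ess"]))
        assert abs(sa["mean"] - sb["mean"]) < tol
        assert b.intercept_ - a.intercept_ == pytest.approx(5.0, abs=0.05)

    def test_random_intercepts_recovered_for_grouped_data(self):
        rng = np.random.default_rng(10)
        n_groups, per = 40, 8
        labels = np.repeat([f"g{i}" for i in range(n_groups)], per)
        u = rng.normal(scale=0.8, size=n_groups)
        x = rng.normal(size=n_groups * per)
        y = 0.5 * x + np.repeat(u, per) + rng.normal(scale=0.3, size=n_groups * per)
        est = BayesianMixedRegression(
            n_chains=2, n_iter=2000, n_burnin=500, random_state=11
        ).fit(x[:, None], y, groups={"species": labels})
        s = summarize(est.coefficient_draws(0))
        assert s["ci_low"] < 0.5 < s["ci_high"]
        sd_draws = est.group_sd_draws_[:, :, 0]
        assert abs(np.mean(sd_draws) - 0.8) < 0.2

    def test_single_level_factor_dropped_with_note(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=30)
        est = BayesianMixedRegression(
            n_chains=1, n_iter=600, n_burnin=100, random_state=13
        ).fit(x[:, None], x, groups={"region": ["only"] * 30})
        assert est.dropped_factors_ == ["region"]
        assert est.group_names_ == []

    def test_input_validation(self):
        est = BayesianMixedRegression()
        with pytest.raises(ValueError, match="non-finite"):
            est.fit(np.array([[1.0], [np.nan]]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="n_iter"):
            BayesianMixedRegression(n_iter=100, n_burnin=100).fit(
                np.ones((5, 1)), np.ones(5)
            )
        with pytest.raises(ValueError, match="mismatched"):
            est.fit(np.ones((5, 1)), np.ones(4))

    def test_sklearn_param_interface(self):
        est = BayesianMixedRegression(n_iter=123)
        assert est.get_params()["n_iter"] == 123
        est.set_params(n_chains=2)
        assert est.n_chains == 2


class TestSummarize:
    def test_degenerate_draws(self):
        s = summarize(np.full((1, 200), 3.0))
        assert s["ci_low"] == s["ci_high"] == 3.0
        assert s["support"]

    def test_symmetric_draws_centered_at_zero_lack_support(self):
        d = np.concatenate([np.linspace(-1, 1, 500)])[None, :]
        s = summarize(d)
        assert not s["support"]
        assert s["mean"] == pytest.approx(0.0, abs=1e-12)

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(14)
        s = summarize(rng.standard_normal((1, 10000)))
        assert s["ci_low"] == pytest.approx(-1.96, abs=0.1)
        assert s["ci_high"] == pytest.approx(1.96, abs=0.1)

    def test_too_few_draws_error(self):
        with pytest.raises(ValueError, match="at least 100"):
            summarize(np.ones((1, 50)))

    def test_split_rhat_flags_disagreeing_chains(self):
        rng = np.random.default_rng(15)
        good = rng.standard_normal((4, 500))
        bad = good + np.array([0.0, 0.0, 5.0, 5.0])[:, None]
        assert split_rhat(good) < 1.05
        assert split_rhat(bad) > 1.5


class TestFitAll:
    def _assembled(self, seed=0, n_countries=25, codes=("a", "b", "c")):
        rng = np.random.default_rng(seed)
        rows = []
        z = {c: rng.normal(size=n_countries) for c in codes}
        for i in range(n_countries):
            resp = 0.8 * z["b"][i] + rng.normal(scale=0.3)
            for code in codes:
                rows.append(
                    {
                        "population_id": f"p{i}",
                        "species": f"sp{i % 8}",
                        "order": f"aves_{i % 3 + 1}",
                        "region": f"region_{i % 4 + 1}",
                        "country": f"C{i}",
                        "taxon_class": "bird",
                        "response": resp,
                        "indicator_code": code,
                        "x": float(z[code][i]),
                        "log_land_area": 5.0 + rng.normal(scale=0.2),
                        "log_hpd_1996": 1.5 + rng.normal(scale=0.2),
                        "inverted": False,
                    }
                )
        return pd.DataFrame(rows)

    def test_one_summary_per_indicator_and_determinism(self):
        frame = self._assembled()
        kw = dict(seed=42, model_params={"n_chains": 2, "n_iter": 800, "n_burnin": 300})
        first, fail1 = fit_all(frame, **kw)
        second, _ = fit_all(frame, **kw)
        assert [s.indicator_code for s in first] == ["a", "b", "c"]
        assert len(fail1) == 0
        assert posterior_table(first).equals(posterior_table(second))

    def test_planted_effect_supported_and_null_not(self):
        frame = self._assembled(seed=1, n_countries=60)
        summaries, _ = fit_all(
            frame, seed=7, model_params={"n_chains": 2, "n_iter": 1200, "n_burnin": 400}
        )
        by_code = {s.indicator_code: s for s in summaries}
        assert by_code["b"].support
        assert not by_code["a"].support

    def test_failures_logged_not_raised(self):
        frame = self._assembled()
        summaries, failures = fit_all(
            frame,
            indicators=["a", "missing"],
            seed=0,
            model_params={"n_chains": 1, "n_iter": 400, "n_burnin": 100},
        )
        assert [s.indicator_code for s in summaries] == ["a"]
        assert list(failures["indicator_code"]) == ["missing"]

    def test_mixed_taxa_rejected(self):
        frame = self._assembled()
        frame.loc[frame.index[:3], "taxon_class"] = "mammal"
        with pytest.raises(ValueError, match="single taxon"):
            fit_all(frame, seed=0)
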