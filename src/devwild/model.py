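"""Bayesian linear mixed model with conjugate Gibbs sampling.

The regression stage asks, one indicator at a time, how wildlife trend
(log10 abundance units per year) covaries with the country's normalized
indicator trend, controlling for log country land area and log 1996 human
population density, with random intercepts for species, taxonomic order and
geographic region:

    y_i ~ Normal(x_i' beta + u_species[i] + u_order[i] + u_region[i], sigma^2)
    beta_j ~ Normal(0, 1000)          (all fixed effects, intercept included)
    u_g,k ~ Normal(0, sigma_g^2)      (independent per grouping factor g)
    1/sigma^2, 1/sigma_g^2 ~ Gamma(shape, rate)

The model is linear-Gaussian throughout, so every full conditional is
conjugate: a multivariate normal for the fixed-effect block, independent
normals for each random-intercept block, and gammas for the precisions.
The sampler draws from the exact posterior; approximate-inference engines
for the same model are approximations to this target.

The posterior is exactly invariant under jointly negating a design column
and its coefficient, which the per-indicator driver exploits to make
indicator orientation a pure relabeling of the reported effect (see
:func:`fit_all`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

GROUP_FACTORS = ("species", "order", "region")


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def split_rhat(draws: np.ndarray) -> float:
    """Split-R̂ (potential scale reduction) for draws shaped (chains, draws).

    Each chain is split in half, so the statistic is defined for a single
    chain as well.  Returns 1.0 for degenerate (zero-variance) draws.
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    half = draws.shape[1] // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain for split-R̂")
    segs = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    m, n = segs.shape
    chain_means = segs.mean(axis=1)
    within = segs.var(axis=1, ddof=1).mean()
    between = n * chain_means.var(ddof=1)
    if within == 0:
        return 1.0
    var_hat = (n - 1) / n * within + between / n
    return float(np.sqrt(var_hat / within))


def effective_sample_size(draws: np.ndarray) -> float:
    """Bulk effective sample size via arviz, on the (chains, draws) array."""
    import arviz as az

    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(draws))


def summarize(draws: np.ndarray, *, ci_level: float = 0.95, min_draws: int = 100) -> Dict[str, float]:
    """Equal-tailed posterior summary of one scalar parameter.

    ``draws`` is shaped (chains, draws); requires at least ``min_draws``
    post-burn-in draws in total.  ``support`` flags a credible interval that
    excludes zero.
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.size < min_draws:
        raise ValueError(f"need at least {min_draws} draws to summarize, got {draws.size}")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    flat = draws.ravel()
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(flat, [alpha, 1.0 - alpha])
    return {
        "mean": float(flat.mean()),
        "sd": float(flat.std(ddof=1)),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "support": bool(lo > 0 or hi < 0),
        "rhat": split_rhat(draws),
        "ess": effective_sample_size(draws),
    }


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class BayesianMixedRegression(BaseEstimator, RegressorMixin):
    """Gaussian linear regression with random intercepts, fitted by Gibbs.

    Parameters follow the model above.  ``fixed_resid_var`` pins the
    residual variance instead of sampling it (used by oracle tests against
    the conjugate closed form).  Columns of ``X`` are centered internally by
    default (a pure reparametrization of the intercept, improving mixing);
    slopes and their priors are unaffected.

    Attributes (after ``fit``)
    --------------------------
    coef_, intercept_ : posterior-mean slopes and intercept (original scale)
    coef_draws_ : ndarray (chains, draws, 1 + n_features), intercept first
    group_sd_draws_, resid_sd_draws_ : variance-component draws
    group_effects_ : posterior-mean random intercept per level and factor
    rhat_, ess_ : per-coefficient convergence diagnostics
    dropped_factors_ : grouping factors removed for having < 2 levels
    """

    def __init__(
        self,
        *,
        prior_mean: float = 0.0,
        prior_variance: float = 1000.0,
        re_prior_shape: float = 1.0,
        re_prior_rate: float = 5e-5,
        resid_prior_shape: float = 1.0,
        resid_prior_rate: float = 5e-5,
        fixed_resid_var: Optional[float] = None,
        n_chains: int = 4,
        n_iter: int = 5000,
        n_burnin: int = 1000,
        thin: int = 1,
        ci_level: float = 0.95,
        center: bool = True,
        random_state=None,
    ):
        self.prior_mean = prior_mean
        self.prior_variance = prior_variance
        self.re_prior_shape = re_prior_shape
        self.re_prior_rate = re_prior_rate
        self.resid_prior_shape = resid_prior_shape
        self.resid_prior_rate = resid_prior_rate
        self.fixed_resid_var = fixed_resid_var
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.n_burnin = n_burnin
        self.thin = thin
        self.ci_level = ci_level
        self.center = center
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _validate(self, X, y):
        if self.prior_variance <= 0:
            raise ValueError("prior_variance must be positive")
        if not (self.n_iter > self.n_burnin >= 0):
            raise ValueError("require n_iter > n_burnin >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have mismatched lengths")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in X or y")
        return X, y

    @staticmethod
    def _coerce_groups(groups, n: int):
        """Return list of (name, integer codes, levels array)."""
        if groups is None:
            return []
        if isinstance(groups, pd.DataFrame):
            items = [(str(c), groups[c].to_numpy()) for c in groups.columns]
        elif isinstance(groups, Mapping):
            items = [(str(k), np.asarray(v)) for k, v in groups.items()]
        else:
            arr = np.asarray(groups)
            if arr.ndim == 1:
                arr = arr[:, None]
            items = [(f"g{j}", arr[:, j]) for j in range(arr.shape[1])]
        out = []
        for name, labels in items:
            if len(labels) != n:
                raise ValueError(f"grouping factor {name} has wrong length")
            codes, levels = pd.factorize(labels, sort=True)
            out.append((name, codes.astype(np.intp), np.asarray(levels)))
        return out

    def _run_chain(self, y, X, factors, seed_seq):
        n, p = X.shape
        rng = np.random.default_rng(seed_seq)
        a_e, b_e = self.resid_prior_shape, self.resid_prior_rate
        a_g, b_g = self.re_prior_shape, self.re_prior_rate
        prior_prec = 1.0 / self.prior_variance
        prior_mean = self.prior_mean

        beta = np.zeros(p)
        us = [np.zeros(len(levels)) for _, _, levels in factors]
        counts = [np.bincount(codes, minlength=len(levels)) for _, codes, levels in factors]
        tau_g = np.ones(len(factors))
        if self.fixed_resid_var is not None:
            tau_e = 1.0 / self.fixed_resid_var
        else:
            tau_e = 1.0 / max(np.var(y), 1e-12)

        XtX = X.T @ X
        res = y - X @ beta
        for u, (_, codes, _) in zip(us, factors):
            res -= u[codes]

        n_keep = (self.n_iter - self.n_burnin + self.thin - 1) // self.thin
        beta_out = np.empty((n_keep, p))
        gsd_out = np.empty((n_keep, len(factors)))
        rsd_out = np.empty(n_keep)
        kept = 0

        for it in range(self.n_iter):
            # fixed-effect block: multivariate normal full conditional
            r = res + X @ beta
            prec = tau_e * XtX + prior_prec * np.eye(p)
            L = np.linalg.cholesky(prec)
            rhs = tau_e * (X.T @ r) + prior_prec * prior_mean
            mean = np.linalg.solve(prec, rhs)
            z = rng.standard_normal(p)
            beta = mean + np.linalg.solve(L.T, z)
            res = r - X @ beta

            # random-intercept blocks and their precisions
            for g, (name, codes, levels) in enumerate(factors):
                rg = res + us[g][codes]
                sums = np.bincount(codes, weights=rg, minlength=len(levels))
                prec_g = tau_e * counts[g] + tau_g[g]
                mean_g = tau_e * sums / prec_g
                us[g] = mean_g + rng.standard_normal(len(levels)) / np.sqrt(prec_g)
                res = rg - us[g][codes]
                tau_g[g] = rng.gamma(
                    a_g + 0.5 * len(levels), 1.0 / (b_g + 0.5 * float(us[g] @ us[g]))
                )

            if self.fixed_resid_var is None:
                tau_e = rng.gamma(a_e + 0.5 * n, 1.0 / (b_e + 0.5 * float(res @ res)))

            if it >= self.n_burnin and (it - self.n_burnin) % self.thin == 0:
                beta_out[kept] = beta
                gsd_out[kept] = 1.0 / np.sqrt(tau_g) if len(factors) else 0.0
                rsd_out[kept] = 1.0 / np.sqrt(tau_e)
                kept += 1

        if not np.all(np.isfinite(beta_out)):
            raise RuntimeError(
                "Gibbs sampler diverged: non-finite fixed-effect draws "
                f"(residual sd range {np.nanmin(rsd_out):.3g}..{np.nanmax(rsd_out):.3g})"
            )
        u_means = [u.copy() for u in us]  # last state as initializer fallback
        return beta_out, gsd_out, rsd_out, us

    # -- public API --------------------------------------------------------

    def fit(self, X, y, groups=None):
        X, y = self._validate(X, y)
        n, n_features = X.shape
        self.n_features_in_ = n_features

        factors = self._coerce_groups(groups, n)
        self.dropped_factors_ = [name for name, _, levels in factors if len(levels) < 2]
        factors = [f for f in factors if len(f[2]) >= 2]
        self.group_names_ = [name for name, _, _ in factors]
        self.group_levels_ = {name: levels for name, _, levels in factors}

        self._col_means = X.mean(axis=0) if self.center else np.zeros(n_features)
        Xc = X - self._col_means
        design = np.column_stack([np.ones(n), Xc])

        if isinstance(self.random_state, np.random.SeedSequence):
            root = self.random_state
        else:
            root = np.random.SeedSequence(self.random_state)
        seeds = root.spawn(self.n_chains)

        betas, gsds, rsds, u_sums = [], [], [], None
        for s in seeds:
            b, g, r, us = self._run_chain(y, design, factors, s)
            betas.append(b)
            gsds.append(g)
            rsds.append(r)
            if u_sums is None:
                u_sums = [u.copy() for u in us]
            else:
                for acc, u in zip(u_sums, us):
                    acc += u

        self.coef_draws_ = np.stack(betas)  # (chains, draws, 1 + n_features)
        self.group_sd_draws_ = np.stack(gsds)
        self.resid_sd_draws_ = np.stack(rsds)

        post_mean = self.coef_draws_.mean(axis=(0, 1))
        self.coef_ = post_mean[1:]
        # undo centering: y = a_c + sum b_j (x_j - m_j)
        self.intercept_ = float(post_mean[0] - self.coef_ @ self._col_means)
        self.group_effects_ = {
            name: dict(zip(self.group_levels_[name], acc / self.n_chains))
            for name, acc in zip(self.group_names_, u_sums or [])
        }
        self.rhat_ = np.array(
            [split_rhat(self.coef_draws_[:, :, j]) for j in range(1 + n_features)]
        )
        self.ess_ = np.array(
            [effective_sample_size(self.coef_draws_[:, :, j]) for j in range(1 + n_features)]
        )
        return self

    def coefficient_draws(self, index: int) -> np.ndarray:
        """Draws for one slope, shaped (chains, draws); index 0 is the first
        feature column (the intercept is not included)."""
        return self.coef_draws_[:, :, index + 1]

    def summary(self) -> pd.DataFrame:
        names = ["intercept"] + [
            str(c)
            for c in getattr(
                self, "feature_names_in_", [f"x{j}" for j in range(self.n_features_in_)]
            )
        ]
        rows = []
        for j, name in enumerate(names):
            s = summarize(self.coef_draws_[:, :, j], ci_level=self.ci_level)
            s["parameter"] = name
            rows.append(s)
        for g, name in enumerate(self.group_names_):
            s = summarize(self.group_sd_draws_[:, :, g], ci_level=self.ci_level)
            s["parameter"] = f"sd_{name}"
            rows.append(s)
        s = summarize(self.resid_sd_draws_, ci_level=self.ci_level)
        s["parameter"] = "sd_resid"
        rows.append(s)
        frame = pd.DataFrame(rows)
        return frame[["parameter", "mean", "sd", "ci_low", "ci_high", "support", "rhat", "ess"]]

    def predict(self, X, groups=None):
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        out = self.intercept_ + X @ self.coef_
        if groups is not None:
            factors = self._coerce_groups(groups, X.shape[0])
            for name, _, _ in factors:
                effects = self.group_effects_.get(name)
                if effects is None:
                    continue
                labels = (
                    groups[name] if isinstance(groups, (pd.DataFrame, Mapping)) else None
                )
                if labels is None:
                    continue
                out = out + np.array([effects.get(l, 0.0) for l in np.asarray(labels)])
        return out


# ---------------------------------------------------------------------------
# per-indicator driver
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    """Posterior of one indicator's coefficient for one taxon class.

    ``beta_*`` are in log10-abundance units per year per 1 SD of (oriented)
    indicator trend; ``prop_change_*`` is the companion 10**beta - 1 scale
    summarized over draws.  ``support`` requires convergence (R̂ <= 1.05)
    and a 95% credible interval excluding zero.
    """

    indicator_code: str
    taxon_class: str
    n_rows: int
    beta_mean: float
    beta_sd: float
    ci_low: float
    ci_high: float
    support: bool
    prop_change_mean: float
    prop_change_low: float
    prop_change_high: float
    rhat: float
    ess: float
    converged: bool
    inverted: bool
    variance_components: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "indicator_code": self.indicator_code,
            "taxon_class": self.taxon_class,
            "n_rows": self.n_rows,
            "beta_mean": self.beta_mean,
            "beta_sd": self.beta_sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "support": self.support,
            "prop_change_mean": self.prop_change_mean,
            "prop_change_low": self.prop_change_low,
            "prop_change_high": self.prop_change_high,
            "rhat": self.rhat,
            "ess": self.ess,
            "converged": self.converged,
            "inverted": self.inverted,
        }
        d.update({f"sigma_{k}": v for k, v in self.variance_components.items()})
        return d


def _orient_summary(s: Dict[str, float], sign: int) -> Dict[str, float]:
    """Map a posterior summary through beta -> sign * beta (exact)."""
    if sign == 1:
        return s
    out = dict(s)
    out["mean"] = -s["mean"]
    out["ci_low"], out["ci_high"] = -s["ci_high"], -s["ci_low"]
    return out


def fit_all(
    assembled: pd.DataFrame,
    *,
    seed: int = 0,
    rhat_max: float = 1.05,
    model_params: Optional[Mapping] = None,
    indicators: Optional[Sequence[str]] = None,
) -> Tuple[List[PosteriorSummary], pd.DataFrame]:
    """Fit one univariate mixed model per indicator on an assembled table.

    Every fit uses the identical covariate and random-effect structure; the
    per-fit seeds derive deterministically from ``seed`` and the sorted
    indicator order.  The sampler runs on the un-inverted indicator scale
    and the reported posterior is mapped through the exact sign
    reparametrization, so toggling an indicator's invert flag negates its
    reported coefficient exactly.  Per-fit failures are logged, never
    raised.
    """
    params = dict(model_params or {})
    taxa = assembled["taxon_class"].unique()
    if len(taxa) != 1:
        raise ValueError(f"fit_all expects a single taxon class, got {list(taxa)}")
    taxon = str(taxa[0])

    codes = sorted(indicators if indicators is not None else assembled["indicator_code"].unique())
    seeds = np.random.SeedSequence(seed).spawn(len(codes))
    summaries: List[PosteriorSummary] = []
    failures = []
    for code, child in zip(codes, seeds):
        sub = assembled[assembled["indicator_code"] == code]
        if sub.empty:
            failures.append({"indicator_code": code, "error": "no assembled rows"})
            continue
        inverted = bool(sub["inverted"].iloc[0]) if "inverted" in sub else False
        sign = -1 if inverted else 1
        try:
            X = pd.DataFrame(
                {
                    "x": sign * sub["x"].to_numpy(dtype=float),  # canonical orientation
                    "log_land_area": sub["log_land_area"].to_numpy(dtype=float),
                    "log_hpd_1996": sub["log_hpd_1996"].to_numpy(dtype=float),
                }
            )
            groups = sub[list(GROUP_FACTORS)]
            est = BayesianMixedRegression(random_state=child, **params)
            est.fit(X, sub["response"].to_numpy(dtype=float), groups=groups)
            ci = est.ci_level
            s = _orient_summary(summarize(est.coefficient_draws(0), ci_level=ci), sign)
            prop_draws = np.power(10.0, sign * est.coefficient_draws(0)) - 1.0
            p = _orient_summary(summarize(prop_draws, ci_level=ci), 1)
            converged = bool(s["rhat"] <= rhat_max)
            vc = {
                name: float(est.group_sd_draws_[:, :, g].mean())
                for g, name in enumerate(est.group_names_)
            }
            vc["resid"] = float(est.resid_sd_draws_.mean())
            summaries.append(
                PosteriorSummary(
                    indicator_code=code,
                    taxon_class=taxon,
                    n_rows=len(sub),
                    beta_mean=s["mean"],
                    beta_sd=s["sd"],
                    ci_low=s["ci_low"],
                    ci_high=s["ci_high"],
                    support=converged and s["support"],
                    prop_change_mean=p["mean"],
                    prop_change_low=p["ci_low"],
                    prop_change_high=p["ci_high"],
                    rhat=s["rhat"],
                    ess=s["ess"],
                    converged=converged,
                    inverted=inverted,
                    variance_components=vc,
                )
            )
        except Exception as err:  # per-fit failures are reported, not raised
            failures.append({"indicator_code": code, "error": str(err)})
    return summaries, pd.DataFrame(failures, columns=["indicator_code", "error"])


def posterior_table(summaries: Sequence[PosteriorSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])
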