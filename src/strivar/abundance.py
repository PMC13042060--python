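"""Compositional cell-type abundance analyses.

The workhorse is a maximum-likelihood beta-binomial regression with a logit
link on the mean fraction and a single overdispersion parameter
``rho in [0, 1)`` (the within-sample intraclass correlation; the classical
(a, b) parameterization is ``a = mu*(1-rho)/rho``, ``b = (1-mu)*(1-rho)/rho``).
Age enters in decades centred at 60; brain regions enter as fixed-effect
intercepts; variability in nuclei counts per sample is handled by the
binomial denominator itself.

Because the donors in these designs contribute one sample per region with a
shared donor-level propensity, standard errors default to a donor-clustered
sandwich; model-based Wald SEs badly undercover the age slope on pooled
multi-region fits.

Also here: Spearman cross-region correlations with an explicit BH family,
abundance residuals against the age-expected fraction, the lifespan decline
summary 1 - exp(beta * span), and the conservative median pairwise
fold-difference statistic derived from the shared (cross-region) component of
donor variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize
from scipy.special import betaln, digamma, expit, gammaln, logit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .stats import bh_adjust

__all__ = [
    "BetaBinomialRegression",
    "AbundanceFit",
    "beta_binomial_loglik",
    "fit_beta_binomial",
    "age_residuals",
    "cross_region_correlation",
    "decline_over_span",
    "pairwise_fold_difference",
    "FoldDifference",
]

# median of |X - Y| for independent X, Y ~ N(0, s^2) is MEDIAN_ABS_GAUSS * s
MEDIAN_ABS_GAUSS = float(np.sqrt(2.0) * sps.norm.ppf(0.75))  # 0.95387...


def beta_binomial_loglik(k, n, mu, rho) -> float:
    """Beta-binomial log-likelihood (including the binomial coefficient)."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), k.shape)
    rho = float(rho)
    lchoose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    if rho < 1e-12:
        with np.errstate(divide="ignore", invalid="ignore"):
            term = k * np.log(mu) + (n - k) * np.log1p(-mu)
            term = np.where(k == 0, (n - k) * np.log1p(-mu), term)
            term = np.where(k == n, k * np.log(mu), term)
        return float(np.sum(lchoose + term))
    r = (1.0 - rho) / rho
    a = mu * r
    b = (1.0 - mu) * r
    return float(np.sum(lchoose + betaln(k + a, n - k + b) - betaln(a, b)))


def _nll_grad(theta, X, k, n):
    beta, s = theta[:-1], theta[-1]
    rho = expit(s)
    r = (1.0 - rho) / rho
    p = expit(X @ beta)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    a = p * r
    b = (1.0 - p) * r
    ll = betaln(k + a, n - k + b) - betaln(a, b)
    dlda = digamma(k + a) - digamma(n + r) + digamma(r) - digamma(a)
    dldb = digamma(n - k + b) - digamma(n + r) + digamma(r) - digamma(b)
    w = (dlda - dldb) * r * p * (1.0 - p)
    gbeta = X.T @ w
    # chain rule for s = logit(rho): dr/ds = -r
    gs = float(np.sum(-r * (p * dlda + (1.0 - p) * dldb)))
    return -float(np.sum(ll)), -np.concatenate([gbeta, [gs]])


def _scores(theta, X, k, n):
    """Per-observation score vectors at theta (for the sandwich meat)."""
    beta, s = theta[:-1], theta[-1]
    rho = expit(s)
    r = (1.0 - rho) / rho
    p = np.clip(expit(X @ beta), 1e-12, 1 - 1e-12)
    a = p * r
    b = (1.0 - p) * r
    dlda = digamma(k + a) - digamma(n + r) + digamma(r) - digamma(a)
    dldb = digamma(n - k + b) - digamma(n + r) + digamma(r) - digamma(b)
    w = (dlda - dldb) * r * p * (1.0 - p)
    gs = -r * (p * dlda + (1.0 - p) * dldb)
    return np.column_stack([X * w[:, None], gs])


class BetaBinomialRegression(BaseEstimator):
    """Beta-binomial regression with logit link, sklearn-style.

    Parameters
    ----------
    max_iter : int
        L-BFGS-B iteration cap.
    tol : float
        Optimizer tolerance on the objective.
    rho_init : float
        Starting overdispersion.
    robust : bool
        Donor-clustered sandwich covariance when ``groups`` is passed to
        :meth:`fit`; falls back to the inverse observed information.

    Attributes
    ----------
    coef_ : (p,) coefficients on the logit scale.
    overdispersion_ : rho in [0, 1).
    se_ : Wald standard errors for coef_ (sandwich when clustered).
    cov_ : full covariance of (coef_, logit rho).
    loglik_ : maximized log-likelihood (binomial coefficient included).
    converged_ : optimizer status.
    """

    def __init__(self, max_iter: int = 500, tol: float = 1e-10,
                 rho_init: float = 0.05, robust: bool = True):
        self.max_iter = max_iter
        self.tol = tol
        self.rho_init = rho_init
        self.robust = robust

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must be (n, 2): successes k and trials N")
        k, n = y[:, 0], y[:, 1]
        if np.any(k > n) or np.any(k < 0) or np.any(n <= 0):
            raise ValueError("require 0 <= k <= N and N > 0")
        if X.shape[0] < X.shape[1] + 2:
            raise ValueError("need at least p + 2 observations")
        # warm start: weighted least squares on the empirical logit
        frac = (k + 0.5) / (n + 1.0)
        beta0, *_ = np.linalg.lstsq(X, logit(frac), rcond=None)
        theta0 = np.concatenate([beta0, [logit(self.rho_init)]])
        res = minimize(
            _nll_grad, theta0, args=(X, k, n), jac=True, method="L-BFGS-B",
            bounds=[(None, None)] * X.shape[1] + [(-20.0, 5.0)],
            options={"maxiter": self.max_iter, "ftol": self.tol},
        )
        grad_norm = float(np.max(np.abs(res.jac)))
        if not res.success and grad_norm > 1e-2 * (1.0 + abs(res.fun)) ** 0.5:
            raise RuntimeError(
                f"beta-binomial fit did not converge: {res.message}; "
                f"final max|gradient| {grad_norm:.3g}"
            )
        theta = res.x
        H = self._hessian(theta, X, k, n)
        try:
            hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError as err:
            raise RuntimeError(f"singular information matrix: {err}") from err
        if self.robust and groups is not None:
            groups = np.asarray(groups)
            S = _scores(theta, X, k, n)
            codes, _ = pd.factorize(groups)
            G = np.zeros((codes.max() + 1, S.shape[1]))
            np.add.at(G, codes, S)
            n_clusters = G.shape[0]
            # CR1 small-sample scaling
            cr1 = n_clusters / max(n_clusters - 1, 1)
            cov = cr1 * (hinv @ (G.T @ G) @ hinv)
            self.n_clusters_ = n_clusters
        else:
            cov = hinv
            self.n_clusters_ = None
        self.coef_ = theta[:-1]
        self.overdispersion_ = float(expit(theta[-1]))
        self.cov_ = cov
        self.se_ = np.sqrt(np.diag(cov)[:-1])
        self.loglik_ = beta_binomial_loglik(
            k, n, np.clip(expit(X @ self.coef_), 1e-12, 1 - 1e-12),
            self.overdispersion_,
        )
        self.converged_ = bool(res.success)
        self.n_iter_ = int(res.nit)
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _hessian(theta, X, k, n, eps: float = 1e-5):
        p = theta.size
        H = np.zeros((p, p))
        for j in range(p):
            step = np.zeros(p)
            step[j] = eps
            gp = _nll_grad(theta + step, X, k, n)[1]
            gm = _nll_grad(theta - step, X, k, n)[1]
            H[:, j] = (gp - gm) / (2 * eps)
        return 0.5 * (H + H.T)

    def predict(self, X):
        """Expected fraction at each row of X."""
        check_is_fitted(self, "coef_")
        return expit(np.asarray(X, dtype=float) @ self.coef_)


@dataclass
class AbundanceFit:
    """Fitted abundance model for one cell type."""

    cell_type: str
    denominator: str
    terms: list[str]
    coef: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    overdispersion: float
    loglik: float
    p_age: float
    p_sex: float | None
    converged: bool
    model: BetaBinomialRegression = field(repr=False)
    q_age: float | None = None
    q_sex: float | None = None

    @property
    def beta_age(self) -> float:
        return float(self.coef["age_decades"])

    @property
    def beta_sex(self) -> float | None:
        return float(self.coef["sex_male"]) if "sex_male" in self.coef else None


def _design(obs: pd.DataFrame, covariates: Sequence[str]):
    regions = sorted(obs["region"].unique())
    cols, names = [], []
    for r in regions:
        cols.append((obs["region"] == r).astype(float).to_numpy())
        names.append(f"region[{r}]")
    cols.append(((obs["age"].to_numpy() - 60.0) / 10.0))
    names.append("age_decades")
    sexes = set(obs["sex"].unique()) if "sex" in obs else set()
    has_sex = len(sexes) > 1
    if has_sex:
        cols.append((obs["sex"] == "M").astype(float).to_numpy())
        names.append("sex_male")
    for c in covariates:
        cols.append(obs[c].to_numpy(dtype=float))
        names.append(c)
    return np.column_stack(cols), names, has_sex


def fit_beta_binomial(
    obs: pd.DataFrame,
    cell_type: str = "",
    denominator: str = "all_nuclei",
    covariates: Sequence[str] = (),
    cluster: str | None = "donor_id",
    compute_lrt: bool = True,
    **estimator_kwargs,
) -> AbundanceFit:
    """Fit the abundance model to observations.

    ``obs`` columns: donor_id, region, k (target-type nuclei), N (denominator
    nuclei), age (years), sex ('M'/'F'; dropped when only one sex present),
    plus any declared covariate columns. Age is modelled in decades centred
    at 60; regions are fixed-effect intercepts.

    p-values for age (and sex) are likelihood-ratio by default; Wald 95% CIs
    come from the (clustered) sandwich covariance.
    """
    if len(obs) < 10:
        raise ValueError("need at least 10 observations")
    X, names, has_sex = _design(obs, covariates)
    y = obs[["k", "N"]].to_numpy(dtype=float)
    groups = obs[cluster].to_numpy() if cluster and cluster in obs else None
    est = BetaBinomialRegression(**estimator_kwargs).fit(X, y, groups=groups)
    coef = pd.Series(est.coef_, index=names)
    se = pd.Series(est.se_, index=names)
    # t critical value with G-1 df under clustering (normal otherwise)
    if getattr(est, "n_clusters_", None):
        zcrit = sps.t.ppf(0.975, df=max(est.n_clusters_ - 1, 2))
    else:
        zcrit = sps.norm.ppf(0.975)
    ci_low = coef - zcrit * se
    ci_high = coef + zcrit * se

    def _lrt(drop: str) -> float:
        keep = [i for i, nm in enumerate(names) if nm != drop]
        sub = BetaBinomialRegression(**estimator_kwargs).fit(
            X[:, keep], y, groups=groups
        )
        stat = 2.0 * (est.loglik_ - sub.loglik_)
        return float(sps.chi2.sf(max(stat, 0.0), df=1))

    def _wald(term: str) -> float:
        z = coef[term] / se[term]
        if getattr(est, "n_clusters_", None):
            return float(2 * sps.t.sf(abs(z), df=max(est.n_clusters_ - 1, 2)))
        return float(2 * sps.norm.sf(abs(z)))

    # the LRT assumes independent observations; with repeated regions per
    # donor the clustered Wald test is the calibrated one and is used as the
    # headline p whenever clustering is active
    p_age_wald = _wald("age_decades")
    p_sex_wald = _wald("sex_male") if has_sex else None
    if compute_lrt and groups is None:
        p_age = _lrt("age_decades")
        p_sex = _lrt("sex_male") if has_sex else None
    else:
        p_age, p_sex = p_age_wald, p_sex_wald
    return AbundanceFit(
        cell_type=cell_type,
        denominator=denominator,
        terms=names,
        coef=coef,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        overdispersion=est.overdispersion_,
        loglik=est.loglik_,
        p_age=p_age,
        p_sex=p_sex,
        converged=est.converged_,
        model=est,
    )


def adjust_fits(fits: Sequence[AbundanceFit], family_size: int | None = None) -> None:
    """BH-adjust age and sex p-values across a declared family, in place."""
    ps, keys = [], []
    for f in fits:
        ps.append(f.p_age)
        keys.append((f, "q_age"))
        if f.p_sex is not None:
            ps.append(f.p_sex)
            keys.append((f, "q_sex"))
    qs = bh_adjust(ps, family_size=family_size)
    for (fit, attr), q in zip(keys, qs):
        setattr(fit, attr, float(q))


def age_residuals(obs: pd.DataFrame, fit: AbundanceFit,
                  covariates: Sequence[str] = ()) -> np.ndarray:
    """Observed fraction minus the model-expected fraction per sample."""
    missing = set(obs["region"].unique()) - {
        t[len("region["):-1] for t in fit.terms if t.startswith("region[")
    }
    if missing:
        raise ValueError(f"regions absent from fit: {sorted(missing)}")
    X, names, _ = _design(obs, covariates)
    # rebuild in the fit's term order; sex column may be absent in new data
    Xfull = np.zeros((len(obs), len(fit.terms)))
    for j, t in enumerate(fit.terms):
        if t in names:
            Xfull[:, j] = X[:, names.index(t)]
    expected = expit(Xfull @ fit.coef.to_numpy())
    return obs["k"].to_numpy() / obs["N"].to_numpy() - expected


def cross_region_correlation(
    values: pd.DataFrame,
    family_size: int | None = None,
    value_col: str = "value",
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Spearman correlation of donor-level values between region pairs.

    ``values`` is long: donor_id, region, ``value_col`` (optionally
    cell_type, in which case correlations are computed within cell type and
    the BH family spans all rows). Pairs with fewer than ``min_pairs`` shared
    donors are reported with NA, never dropped.
    """
    if "cell_type" not in values:
        values = values.assign(cell_type="all")
    rows = []
    for ct, sub in values.groupby("cell_type", sort=True):
        wide = sub.pivot_table(index="donor_id", columns="region",
                               values=value_col, aggfunc="first")
        for r1, r2 in combinations(sorted(wide.columns), 2):
            paired = wide[[r1, r2]].dropna()
            if len(paired) < min_pairs:
                rows.append(
                    {"cell_type": ct, "region_a": r1, "region_b": r2,
                     "n_donors": len(paired), "rho": np.nan, "p": np.nan}
                )
                continue
            rho, p = sps.spearmanr(paired[r1], paired[r2])
            rows.append(
                {"cell_type": ct, "region_a": r1, "region_b": r2,
                 "n_donors": len(paired), "rho": float(rho), "p": float(p)}
            )
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested.to_numpy()] = bh_adjust(out.loc[tested, "p"], family_size=family_size)
    out["q"] = q
    out["family_size"] = family_size if family_size is not None else int(tested.sum())
    return out


def decline_over_span(beta_age: float, span_decades: float) -> float:
    """Fractional decline over a lifespan window: 1 - exp(beta * span).

    Exact on the odds scale; for rare cell types (odds ~ fraction) it is the
    fractional decline in abundance itself. A 5-decade window at
    beta = -0.096 gives 0.381 (the "about 40% between age 30 and 80" regime).
    """
    if span_decades <= 0:
        raise ValueError("span must be positive")
    return float(1.0 - np.exp(beta_age * span_decades))


def decline_over_span_exact(beta_age: float, span_decades: float,
                            baseline_logit: float) -> float:
    """Exact fraction-scale decline given the baseline logit at the window start."""
    p0 = expit(baseline_logit)
    p1 = expit(baseline_logit + beta_age * span_decades)
    return float(1.0 - p1 / p0)


@dataclass
class FoldDifference:
    fold: float
    ci_low: float
    ci_high: float
    shared_variance: float
    negative_covariance: bool = False


def pairwise_fold_difference(
    log_fracs_a,
    log_fracs_b,
    n_boot: int = 1000,
    seed: int = 0,
) -> FoldDifference:
    """Conservative median pairwise fold difference between two donors.

    The shared donor-level variance is estimated as the covariance of paired
    per-donor natural-log fractions from two regions (clipped at 0). If the
    shared components of two independent donors are X, Y ~ N(0, s2), the
    median fold difference exp(|X - Y|) is exp(0.9539 * s). A bootstrap over
    donors gives the CI.
    """
    a = np.asarray(log_fracs_a, dtype=float)
    b = np.asarray(log_fracs_b, dtype=float)
    if a.size != b.size or a.size < 10:
        raise ValueError("need >= 10 paired donors")

    def _fold(x, y):
        cov = np.cov(x, y)[0, 1]
        if cov <= 0:
            return 1.0, cov
        return float(np.exp(MEDIAN_ABS_GAUSS * np.sqrt(cov))), cov

    fold, cov = _fold(a, b)
    if cov < 0:
        warnings.warn("negative cross-region covariance; fold set to 1.0")
        return FoldDifference(1.0, 1.0, 1.0, 0.0, negative_covariance=True)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, a.size, a.size)
        boots[i] = _fold(a[idx], b[idx])[0]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return FoldDifference(fold, float(lo), float(hi), float(max(cov, 0.0)))
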