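"""Cell-type-specific transcriptional aging clocks.

An elastic-net regression predicts each donor's chronological age from the
standardized log2 expression of that cell type's age-associated genes.
Predictions are strictly out-of-sample (outer 10-fold CV; the inner 5-fold
CV selects the penalty on each training set; standardization is fit inside
each training fold). Because penalized predictions shrink toward the cohort
mean, raw residuals carry a shared age-dependent bias; the bias curve -- a
penalized cubic spline (GCV-selected smoothness) of predicted on
chronological age -- defines the corrected residual
``predicted - curve(chronological)``, the per-donor fast/slow-aging signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "AgingClock",
    "ClockModel",
    "train_clock",
    "BiasCurve",
    "fit_bias_curve",
    "residual_correlation",
    "gene_set_jaccard",
]


class AgingClock(BaseEstimator, RegressorMixin):
    """Elastic-net age predictor with internal penalty selection.

    Standardizes features and fits an elastic net; when ``lambda_`` is None
    the penalty is chosen by ``cv_inner``-fold cross-validation over
    ``lambda_grid`` (default 10^-3..10^2, 50 points). ``l1_ratio`` is the
    L1/L2 mixing (0.5 by default; 0 is pure ridge).
    """

    def __init__(
        self,
        l1_ratio: float = 0.5,
        lambda_grid=None,
        lambda_: float | None = None,
        cv_inner: int = 5,
        max_iter: int = 20000,
        tol: float = 1e-6,
        random_state: int = 0,
    ):
        self.l1_ratio = l1_ratio
        self.lambda_grid = lambda_grid
        self.lambda_ = lambda_
        self.cv_inner = cv_inner
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _grid(self):
        if self.lambda_grid is not None:
            return np.asarray(self.lambda_grid, dtype=float)
        return np.logspace(-3, 2, 50)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        sds = X.std(axis=0)
        keep = sds > 0
        if not np.all(keep):
            import warnings

            warnings.warn(f"dropping {np.sum(~keep)} constant features")
        self.keep_ = keep
        Xk = X[:, keep]
        scaler = StandardScaler().fit(Xk)
        Xs = scaler.transform(Xk)
        if self.lambda_ is not None:
            net = ElasticNet(
                alpha=self.lambda_, l1_ratio=self.l1_ratio,
                max_iter=self.max_iter, tol=self.tol,
            ).fit(Xs, y)
            self.selected_lambda_ = float(self.lambda_)
        else:
            cv = KFold(self.cv_inner, shuffle=True, random_state=self.random_state)
            net = ElasticNetCV(
                alphas=self._grid(), l1_ratio=self.l1_ratio, cv=cv,
                max_iter=self.max_iter, tol=self.tol,
            ).fit(Xs, y)
            self.selected_lambda_ = float(net.alpha_)
        self.scaler_ = scaler
        self.net_ = net
        self.coef_ = net.coef_
        self.intercept_ = float(net.intercept_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=float)[:, self.keep_]
        return self.net_.predict(self.scaler_.transform(X))


@dataclass
class ClockModel:
    """A trained cell-type clock and its cross-validation descriptor."""

    cell_type: str
    region: str
    genes: list[str]
    coefficients: pd.Series  # nonzero coefficients from the full-data refit
    intercept: float
    lambda_: float
    l1_ratio: float
    feature_means: pd.Series
    feature_sds: pd.Series
    cv_scheme: str
    mae: float
    mad: float

    @property
    def selected_genes(self) -> set[str]:
        return set(self.coefficients.index)


def train_clock(
    pb,
    de_results: pd.DataFrame,
    donors: pd.DataFrame,
    fdr: float = 0.05,
    n_outer: int = 10,
    n_repeats: int = 20,
    l1_ratio: float = 0.5,
    lambda_grid=None,
    cv_inner: int = 5,
    min_donors: int = 40,
    min_genes: int = 10,
    seed: int = 0,
) -> tuple[ClockModel, pd.DataFrame]:
    """Train one cell-type clock; return the model and per-donor predictions.

    Features are the cell type's age-associated genes (q_age < fdr in
    ``de_results`` for this cell type/region). Outer ``n_outer``-fold CV
    yields an out-of-sample prediction for every donor; the inner CV selects
    the penalty per training fold. The per-donor prediction SD comes from
    repeating the outer CV with ``n_repeats`` different fold shuffles.
    """
    meta = donors.set_index("donor_id").loc[pb.counts.index]
    if len(meta) < min_donors:
        raise ValueError(f"need >= {min_donors} donors")
    sub = de_results[
        (de_results["cell_type"] == pb.cell_type)
        & (de_results["region"] == pb.region)
        & (de_results["q_age"] < fdr)
    ]
    genes = [g for g in sub["gene"] if g in pb.counts.columns]
    if len(genes) < min_genes:
        raise ValueError(
            f"only {len(genes)} age-associated genes at q<{fdr}; need {min_genes}"
        )
    X = pb.log2cpm().loc[:, genes].to_numpy()
    y = meta["age"].to_numpy(dtype=float)

    def _oof(rep_seed: int) -> np.ndarray:
        preds = np.empty_like(y)
        kf = KFold(n_outer, shuffle=True, random_state=rep_seed)
        for tr, te in kf.split(X):
            clock = AgingClock(
                l1_ratio=l1_ratio, lambda_grid=lambda_grid, cv_inner=cv_inner,
                random_state=rep_seed,
            ).fit(X[tr], y[tr])
            preds[te] = clock.predict(X[te])
        return preds

    all_preds = np.column_stack([_oof(seed + r) for r in range(n_repeats)])
    predicted = all_preds[:, 0]
    pred_sd = all_preds.std(axis=1, ddof=1) if n_repeats > 1 else np.zeros_like(y)

    full = AgingClock(
        l1_ratio=l1_ratio, lambda_grid=lambda_grid, cv_inner=cv_inner,
        random_state=seed,
    ).fit(X, y)
    nonzero = np.flatnonzero(full.coef_)
    kept_genes = [g for g, k in zip(genes, full.keep_) if k]
    coefs = pd.Series(full.coef_[nonzero],
                      index=[kept_genes[i] for i in nonzero])
    resid = predicted - y
    model = ClockModel(
        cell_type=pb.cell_type,
        region=pb.region,
        genes=genes,
        coefficients=coefs,
        intercept=full.intercept_,
        lambda_=full.selected_lambda_,
        l1_ratio=l1_ratio,
        feature_means=pd.Series(full.scaler_.mean_, index=kept_genes),
        feature_sds=pd.Series(full.scaler_.scale_, index=kept_genes),
        cv_scheme=f"outer {n_outer}-fold (x{n_repeats} repeats), inner {cv_inner}-fold",
        mae=float(np.mean(np.abs(resid))),
        mad=float(np.median(np.abs(resid - np.median(resid)))),
    )
    preds = pd.DataFrame(
        {
            "donor_id": pb.counts.index,
            "cell_type": pb.cell_type,
            "region": pb.region,
            "age": y,
            "predicted_age": predicted,
            "prediction_sd": pred_sd,
            "raw_residual": resid,
        }
    )
    return model, preds


@dataclass
class BiasCurve:
    """Penalized cubic-spline fit of predicted on chronological age."""

    knots: np.ndarray
    coef: np.ndarray
    degree: int
    lambda_: float
    edf: float
    age_range: tuple[float, float]

    def predict(self, ages) -> np.ndarray:
        x = np.clip(np.asarray(ages, dtype=float), *self.age_range)
        return BSpline(self.knots, self.coef, self.degree)(x)


def _pspline_gcv(x, y, n_knots=12, degree=3, lambdas=None):
    lambdas = np.logspace(-4, 6, 41) if lambdas is None else lambdas
    lo, hi = float(x.min()), float(x.max())
    inner = np.linspace(lo, hi, n_knots)
    knots = np.r_[[lo] * degree, inner, [hi] * degree]
    B = BSpline.design_matrix(np.clip(x, lo, hi), knots, degree).toarray()
    D = np.diff(np.eye(B.shape[1]), 2, axis=0)
    P = D.T @ D  # second-difference penalty; linear trend unpenalized
    BtB = B.T @ B
    Bty = B.T @ y
    best = None
    for lam in lambdas:
        A = BtB + lam * P
        sol = np.linalg.solve(A, np.column_stack([Bty, BtB]))
        coef, Sdiag = sol[:, 0], sol[:, 1:]
        edf = float(np.trace(Sdiag))
        rss = float(np.sum((y - B @ coef) ** 2))
        gcv = len(y) * rss / (len(y) - edf) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, lam, coef, edf)
    _, lam, coef, edf = best
    return knots, coef, degree, lam, edf, (lo, hi)


def fit_bias_curve(
    predicted, chronological, n_knots: int = 12
) -> tuple[BiasCurve, np.ndarray]:
    """Fit the predicted-vs-chronological bias curve; return corrected residuals.

    Corrected residual = predicted - curve(chronological); by construction
    the corrected residuals are (Pearson-)uncorrelated with age to within
    numerical fitting error.
    """
    pred = np.asarray(predicted, dtype=float)
    age = np.asarray(chronological, dtype=float)
    if pred.size < 20:
        raise ValueError("need >= 20 predictions")
    if age.max() - age.min() < 30:
        raise ValueError("predictions must span >= 30 years of age")
    if np.unique(age).size < 4:
        raise ValueError("need >= 4 distinct ages")
    knots, coef, degree, lam, edf, rng = _pspline_gcv(age, pred, n_knots=n_knots)
    curve = BiasCurve(knots=knots, coef=coef, degree=degree, lambda_=float(lam),
                      edf=edf, age_range=rng)
    corrected = pred - curve.predict(age)
    return curve, corrected


def residual_correlation(
    preds: pd.DataFrame,
    value: str = "corrected_residual",
    method: str = "spearman",
    min_shared: int = 20,
) -> pd.DataFrame:
    """Pairwise correlation of corrected residuals across cell types.

    ``preds`` is tidy with donor_id, cell_type, and the residual column.
    Pairs with fewer than ``min_shared`` shared donors get NA.
    """
    wide = preds.pivot_table(index="donor_id", columns="cell_type", values=value,
                             aggfunc="first")
    cts = sorted(wide.columns)
    out = pd.DataFrame(np.eye(len(cts)), index=cts, columns=cts)
    for a, b in combinations(cts, 2):
        sub = wide[[a, b]].dropna()
        if len(sub) < min_shared:
            out.loc[a, b] = out.loc[b, a] = np.nan
            continue
        if method == "spearman":
            r = sps.spearmanr(sub[a], sub[b]).statistic
        else:
            r = sps.pearsonr(sub[a], sub[b]).statistic
        out.loc[a, b] = out.loc[b, a] = float(r)
    return out


def gene_set_jaccard(models: Mapping[str, "ClockModel | set"]) -> pd.DataFrame:
    """Pairwise Jaccard overlap of the clocks' selected gene sets."""
    sets = {
        k: (v.selected_genes if isinstance(v, ClockModel) else set(v))
        for k, v in models.items()
    }
    keys = sorted(sets)
    out = pd.DataFrame(np.eye(len(keys)), index=keys, columns=keys)
    for a, b in combinations(keys, 2):
        union = sets[a] | sets[b]
        if not union:
            raise ValueError(f"empty union for pair ({a}, {b})")
        j = len(sets[a] & sets[b]) / len(union)
        out.loc[a, b] = out.loc[b, a] = j
    return out
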