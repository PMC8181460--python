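"""Dimension reduction of the secondary traits by supervised learning.

The high-dimensional secondary phenotype Y_s is replaced by the single
derived trait S = h_hat(Y_s), where h_hat is a prediction of the focal
trait from the secondary traits fitted on the *training* genotypes only
(LASSO with internally cross-validated penalty, or a random-forest
regression).  Genomic prediction then proceeds with the bivariate GBLUP
using S as the secondary trait: LS-BLUP and RF-BLUP.

If the cross-validated LASSO selects the empty (intercept-only) model, the
reduction is flagged degenerate and the composed predictors fall back to
univariate GBLUP, so they can never do worse than GBLUP by construction in
that case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import GridSearchCV, KFold

from .kinship import KinshipPartition
from .predict import (
    PredictionResult,
    predict_multivariate_s1,
    predict_multivariate_s2,
    predict_univariate,
)
from .reml import BivariateGBLUP, UnivariateGBLUP

__all__ = ["ReducedTrait", "lasso_reduce", "rf_reduce", "ls_blup", "rf_blup"]


@dataclass
class ReducedTrait:
    """A one-dimensional reduction S of the secondary traits."""

    S_train: np.ndarray
    S_test: np.ndarray | None
    method: str
    degenerate: bool = False
    train_r2: float = float("nan")
    model: object = field(default=None, repr=False)
    meta: dict = field(default_factory=dict)


def _clean_columns(Ys_train, Ys_test):
    Ys_train = np.asarray(Ys_train, dtype=float)
    keep = np.ptp(Ys_train, axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {np.sum(~keep)} constant secondary trait(s)")
    if Ys_test is not None:
        Ys_test = np.asarray(Ys_test, dtype=float)[:, keep]
    return Ys_train[:, keep], Ys_test, keep


def lasso_reduce(
    y_fo,
    Ys_train,
    Ys_test=None,
    *,
    cv_folds: int = 10,
    penalty_rule: str = "1se",
    seed=None,
) -> ReducedTrait:
    """LASSO regression of the focal trait on the secondary traits.

    The penalty is chosen by ``cv_folds``-fold cross-validation within the
    training set.  ``penalty_rule='1se'`` (default, the cv.glmnet
    convention) picks the strongest penalty whose CV error is within one
    standard error of the minimum, which reliably returns the empty model
    on pure noise; ``'min'`` picks the error-minimizing penalty.
    Predictors are standardized internally; returned index values are on
    the focal-trait scale.
    """
    y = np.asarray(y_fo, dtype=float).ravel()
    if cv_folds < 2 or len(y) <= cv_folds:
        raise ValueError("need n_o > cv_folds >= 2")
    if penalty_rule not in ("min", "1se"):
        raise ValueError("penalty_rule must be 'min' or '1se'")
    Zs, Zt, keep = _clean_columns(Ys_train, Ys_test)
    if Zs.shape[1] == 0:
        return ReducedTrait(
            S_train=np.full_like(y, y.mean()),
            S_test=None,
            method="lasso",
            degenerate=True,
        )
    mu, sd = Zs.mean(axis=0), Zs.std(axis=0)
    Zs = (Zs - mu) / sd
    rng = np.random.default_rng(seed)
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=int(rng.integers(2**31)))
    path = LassoCV(cv=cv, alphas=100, max_iter=10_000, tol=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # occasional non-fatal convergence noise
        path.fit(Zs, y)
        if penalty_rule == "min":
            model, alpha = path, float(path.alpha_)
        else:
            mse = path.mse_path_  # (n_alphas, n_folds), alphas_ descending
            mean = mse.mean(axis=1)
            se = mse.std(axis=1, ddof=1) / np.sqrt(mse.shape[1])
            i_min = int(np.argmin(mean))
            thr = mean[i_min] + se[i_min]
            i_1se = int(np.argmax(mean <= thr))  # first (largest) such alpha
            alpha = float(path.alphas_[i_1se])
            model = Lasso(alpha=alpha, max_iter=10_000, tol=1e-4)
            model.fit(Zs, y)
    degenerate = not np.any(model.coef_ != 0.0)
    s_train = model.predict(Zs)
    s_test = model.predict((Zt - mu) / sd) if Zt is not None else None
    r2 = float(model.score(Zs, y))
    return ReducedTrait(
        S_train=s_train,
        S_test=s_test,
        method="lasso",
        degenerate=degenerate,
        train_r2=r2,
        model=model,
        meta={
            "alpha": alpha,
            "n_selected": int(np.sum(model.coef_ != 0.0)),
            "kept_columns": keep,
            "coef": model.coef_,
        },
    )


def rf_reduce(
    y_fo,
    Ys_train,
    Ys_test=None,
    *,
    n_trees: int = 500,
    mtry: int | None = None,
    tune: bool = False,
    cv_folds: int = 5,
    seed=None,
) -> ReducedTrait:
    """Random-forest regression of the focal trait on the secondary traits.

    Defaults follow the regression-forest convention: 500 trees and
    mtry = floor(p / 3) candidate variables per split.  With ``tune=True``
    mtry and the minimum node size are grid-searched by internal CV.
    """
    y = np.asarray(y_fo, dtype=float).ravel()
    Zs, Zt, keep = _clean_columns(Ys_train, Ys_test)
    p = Zs.shape[1]
    if p == 0:
        raise ValueError("no non-constant secondary traits")
    if mtry is None:
        mtry = max(1, p // 3)
    rng = np.random.default_rng(seed)
    rf_seed = int(rng.integers(2**31))
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=min(mtry, p),
        min_samples_leaf=5,
        oob_score=True,
        random_state=rf_seed,
        n_jobs=1,
    )
    tuned = None
    if tune:
        grid = {
            "max_features": sorted({max(1, p // 10), max(1, p // 3), max(1, p // 2), p}),
            "min_samples_leaf": [1, 5, 10],
        }
        search = GridSearchCV(
            RandomForestRegressor(
                n_estimators=n_trees, random_state=rf_seed, n_jobs=1
            ),
            grid,
            cv=KFold(cv_folds, shuffle=True, random_state=rf_seed),
            scoring="neg_mean_squared_error",
        )
        search.fit(Zs, y)
        rf = search.best_estimator_
        if not hasattr(rf, "oob_score_"):
            rf.set_params(oob_score=True)
            rf.fit(Zs, y)
        tuned = search.best_params_
    else:
        rf.fit(Zs, y)
    s_train = rf.predict(Zs)
    s_test = rf.predict(Zt) if Zt is not None else None
    return ReducedTrait(
        S_train=s_train,
        S_test=s_test,
        method="rf",
        degenerate=bool(np.ptp(s_train) == 0.0),
        train_r2=float(rf.score(Zs, y)),
        model=rf,
        meta={
            "oob_r2": float(getattr(rf, "oob_score_", np.nan)),
            "tuned": tuned,
            "kept_columns": keep,
        },
    )


def _reduced_blup(
    reducer,
    method_label: str,
    y_fo,
    Ys,
    kpart: KinshipPartition,
    scenario: int,
    *,
    diagonal_residual: bool = True,
    seed=None,
    X=None,
    **reduce_kwargs,
) -> PredictionResult:
    """Compose reduce -> bivariate REML -> Eq-4/Eq-5 prediction."""
    y_fo = np.asarray(y_fo, dtype=float).ravel()
    n_t, n_o = kpart.n_t, kpart.n_o
    if isinstance(Ys, pd.DataFrame):
        Ys = Ys.loc[kpart.ids if scenario == 2 else kpart.train_ids].to_numpy(
            dtype=float
        )
    Ys = np.asarray(Ys, dtype=float)
    if scenario == 2:
        if Ys.shape[0] != kpart.n:
            raise ValueError("scenario 2 requires secondary traits on all genotypes")
        Ys_train, Ys_test = Ys[n_t:], Ys[:n_t]
    else:
        if Ys.shape[0] not in (n_o, kpart.n):
            raise ValueError("secondary trait rows match neither train nor all")
        Ys_train = Ys[-n_o:] if Ys.shape[0] == kpart.n else Ys
        Ys_test = None

    red = reducer(y_fo, Ys_train, Ys_test, seed=seed, **reduce_kwargs)
    if red.degenerate:
        fit = UnivariateGBLUP(y_fo, eig=kpart.eigh_oo(), X=X).fit()
        out = predict_univariate(
            fit, y_fo, kpart, X=X, method=method_label, scenario=scenario
        )
        out.extras.update({"fallback": "univariate", "reduction": red})
        return out

    Y2 = np.column_stack([y_fo, red.S_train])
    fit = BivariateGBLUP(
        Y2,
        kpart.K_oo,
        X=X,
        diagonal_residual=diagonal_residual,
        eig=kpart.eigh_oo(),
    ).fit(trait_names=["focal", f"S_{red.method}"])
    if scenario == 1:
        out = predict_multivariate_s1(
            fit, Y2, kpart, X=X, method=method_label, scenario=1
        )
    else:
        S_all = np.concatenate([red.S_test, red.S_train])[:, None]
        out = predict_multivariate_s2(
            fit, y_fo, S_all, kpart, X=X, method=method_label, scenario=2
        )
    out.extras.update({"reduction": red, "fit": fit})
    return out


def ls_blup(
    y_fo, Ys, kpart, scenario=1, *, diagonal_residual=True, seed=None, cv_folds=10, X=None
) -> PredictionResult:
    """LS-BLUP: bivariate GBLUP with the LASSO reduction as secondary trait."""
    return _reduced_blup(
        lasso_reduce,
        "LS-BLUP",
        y_fo,
        Ys,
        kpart,
        scenario,
        diagonal_residual=diagonal_residual,
        seed=seed,
        X=X,
        cv_folds=cv_folds,
    )


def rf_blup(
    y_fo,
    Ys,
    kpart,
    scenario=1,
    *,
    diagonal_residual=True,
    seed=None,
    n_trees=500,
    tune=False,
    X=None,
) -> PredictionResult:
    """RF-BLUP: bivariate GBLUP with the random-forest reduction as
    secondary trait."""
    return _reduced_blup(
        rf_reduce,
        "RF-BLUP",
        y_fo,
        Ys,
        kpart,
        scenario,
        diagonal_residual=diagonal_residual,
        seed=seed,
        X=X,
        n_trees=n_trees,
        tune=tune,
    )
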