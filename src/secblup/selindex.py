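"""Penalized selection indices from replicated plot-level data.

The classical selection index S = sum_j gamma_j Y_s(j) weights the
secondary traits to best predict the focal genetic merit:
gamma = Sigma_s^{-1} Sigma_sf_u, where Sigma_s is the phenotypic covariance
of the secondary traits and Sigma_sf_u their genetic covariances with the
focal trait.  With hundreds of traits the classical index overfits, so a
ridge or LASSO penalty shrinks the coefficients; for the ridge penalty

    gamma(lambda) = (Sigma_s + lambda I)^{-1} Sigma_sf_u.

Sigma_sf_u is estimated by one-way MANOVA on the plot-level replicates
(between- minus within-genotype mean cross-products over the replicate
count); Sigma_s by the sample covariance of the genotype-mean secondary
traits.  No multi-trait mixed model is fitted for the index itself.

lambda is tuned by cross-validation over genotypes within the training
set, maximizing h(S) * rho_G(S, Y_f) estimated on the held-out plots.
The tuned index then enters the bivariate GBLUP as the single secondary
trait (SI-BLUP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import KinshipPartition
from .predict import (
    PredictionResult,
    predict_multivariate_s1,
    predict_multivariate_s2,
    predict_univariate,
)
from .reml import BivariateGBLUP, UnivariateGBLUP

__all__ = [
    "PlotLevelData",
    "SelectionIndexModel",
    "manova_genetic_cov",
    "penalized_si",
    "tune_si_lambda",
    "si_blup",
    "default_lambda_grid",
]


@dataclass
class PlotLevelData:
    """Balanced replicated records: one row per plot, focal + p secondary
    trait columns.  Column 0 of ``traits`` is the focal trait."""

    genotype: np.ndarray
    rep: np.ndarray
    traits: np.ndarray
    trait_names: list

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PlotLevelData":
        trait_cols = [c for c in df.columns if c not in ("genotype", "rep")]
        out = cls(
            genotype=df["genotype"].to_numpy(dtype=object),
            rep=df["rep"].to_numpy(),
            traits=df[trait_cols].to_numpy(dtype=float),
            trait_names=list(trait_cols),
        )
        out.validate()
        return out

    def validate(self) -> None:
        counts = pd.Series(self.genotype).value_counts()
        if counts.min() < 2:
            raise ValueError("replication required: every genotype needs >= 2 plots")
        if counts.nunique() != 1:
            raise ValueError(
                "unbalanced replicate counts are not supported; "
                f"found counts {sorted(counts.unique())}"
            )

    @property
    def n_genotypes(self) -> int:
        return len(set(self.genotype))

    @property
    def n_reps(self) -> int:
        return len(self.genotype) // self.n_genotypes

    @property
    def p(self) -> int:
        return self.traits.shape[1] - 1

    def genotype_means(self) -> pd.DataFrame:
        df = pd.DataFrame(self.traits, columns=self.trait_names)
        df["genotype"] = self.genotype
        return df.groupby("genotype", sort=False).mean()

    def subset(self, genotypes) -> "PlotLevelData":
        mask = np.isin(self.genotype, list(genotypes))
        return PlotLevelData(
            genotype=self.genotype[mask],
            rep=self.rep[mask],
            traits=self.traits[mask],
            trait_names=self.trait_names,
        )


@dataclass
class SelectionIndexModel:
    """Penalized selection index: coefficients and the tuning path."""

    gamma: np.ndarray
    lambda_pen: float
    penalty_type: str
    Sigma_s_hat: np.ndarray = field(repr=False, default=None)
    Sigma_sf_u_hat: np.ndarray = field(repr=False, default=None)
    criterion_path: pd.DataFrame | None = field(repr=False, default=None)
    trait_names: list = field(default_factory=list)

    def index_values(self, Ys: pd.DataFrame | np.ndarray) -> np.ndarray:
        """S = sum_j gamma_j (Y_s(j) - mean) on genotype-level data."""
        if isinstance(Ys, pd.DataFrame):
            Ys = Ys.to_numpy(dtype=float)
        Z = Ys - Ys.mean(axis=0)
        return Z @ self.gamma


def _manova_components(plots: PlotLevelData):
    """Between/within mean cross-product matrices of the one-way MANOVA."""
    df = pd.DataFrame(plots.traits)
    groups = pd.Series(plots.genotype)
    r = plots.n_reps
    g = plots.n_genotypes
    means = df.groupby(groups, sort=False).mean()
    grand = df.mean(axis=0).to_numpy()
    Mc = means.to_numpy() - grand
    B = r * (Mc.T @ Mc) / (g - 1)  # between-genotype mean cross-products
    resid = df.to_numpy() - means.loc[groups].to_numpy()
    W = (resid.T @ resid) / (g * (r - 1))  # within-genotype mean cross-products
    return B, W, r


def manova_genetic_cov(plots: PlotLevelData):
    """MANOVA moment estimates of genetic (co)variances from balanced plots.

    Returns ``(Sigma_sf_u_hat, genetic_variances)``: the p genetic
    covariances between focal and each secondary trait, and the genetic
    variance of every trait (focal first), each estimated as
    (between - within) / r.
    """
    B, W, r = _manova_components(plots)
    G = (B - W) / r
    return G[0, 1:], np.diag(G)


def manova_full_genetic_cov(plots: PlotLevelData) -> np.ndarray:
    """Full (p+1) x (p+1) MANOVA genetic covariance matrix."""
    B, W, r = _manova_components(plots)
    return (B - W) / r


def penalized_si(
    Sigma_s_hat,
    Sigma_sf_u_hat,
    lambda_pen: float,
    penalty_type: str = "ridge",
    *,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Solve for the penalized selection-index coefficients gamma.

    ridge: gamma = (Sigma_s + lambda I)^{-1} Sigma_sf_u, exactly.
    lasso: coordinate descent on the penalized quadratic
    gamma' Sigma_s gamma - 2 gamma' Sigma_sf + lambda |gamma|_1.
    """
    S = np.asarray(Sigma_s_hat, dtype=float)
    c = np.asarray(Sigma_sf_u_hat, dtype=float).ravel()
    p = c.size
    if lambda_pen < 0:
        raise ValueError("lambda_pen must be >= 0")
    if penalty_type == "ridge":
        A = S + lambda_pen * np.eye(p)
        try:
            return np.linalg.solve(A, c)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "Sigma_s is singular at lambda = 0; use a positive penalty"
            ) from exc
    if penalty_type != "lasso":
        raise ValueError("penalty_type must be 'ridge' or 'lasso'")
    if lambda_pen == 0.0 and np.linalg.matrix_rank(S) < p:
        raise ValueError("Sigma_s is singular at lambda = 0; use a positive penalty")
    gamma = np.zeros(p)
    d = np.diag(S).copy()
    if np.any(d <= 0):
        raise ValueError("Sigma_s has non-positive diagonal entries")
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            rho = c[j] - S[j] @ gamma + d[j] * gamma[j]
            new = np.sign(rho) * max(abs(rho) - lambda_pen / 2.0, 0.0) / d[j]
            delta = max(delta, abs(new - gamma[j]))
            gamma[j] = new
        if delta < tol:
            break
    else:
        warnings.warn("selection-index coordinate descent hit max_iter")
    return gamma


def default_lambda_grid(Sigma_s_hat, n_lambdas: int = 30) -> np.ndarray:
    """Log-spaced penalties spanning [1e-4, 1e2] x mean diag(Sigma_s)."""
    scale = float(np.mean(np.diag(Sigma_s_hat)))
    return scale * np.logspace(-4, 2, n_lambdas)


def _si_criterion(plots: PlotLevelData, gamma: np.ndarray) -> float:
    """h(S) * rho_G(S, Y_f) estimated from plot data via MANOVA."""
    Zs = plots.traits[:, 1:] - plots.traits[:, 1:].mean(axis=0)
    s_vals = Zs @ gamma
    pair = PlotLevelData(
        genotype=plots.genotype,
        rep=plots.rep,
        traits=np.column_stack([plots.traits[:, 0], s_vals]),
        trait_names=["focal", "S"],
    )
    B, W, r = _manova_components(pair)
    G = (B - W) / r
    var_g_s, var_g_f = G[1, 1], G[0, 0]
    var_w_s = W[1, 1]
    if var_g_s <= 0 or var_g_f <= 0 or var_g_s + var_w_s <= 0:
        raise FloatingPointError("criterion undefined: nonpositive variance")
    h2 = np.clip(var_g_s / (var_g_s + var_w_s), 0.0, 1.0)
    rho_g = np.clip(G[0, 1] / np.sqrt(var_g_s * var_g_f), -1.0, 1.0)
    return float(np.sqrt(h2) * rho_g)


def estimate_si_inputs(plots: PlotLevelData, *, structured: bool = False):
    """(Sigma_s_hat, Sigma_sf_u_hat) from plot-level data.

    Default: Sigma_s is the sample covariance of genotype-mean secondary
    traits.  ``structured=True`` instead uses the MANOVA decomposition
    k_bar * Sigma_ss_u + Sigma_ss_e (kinship-free, unit mean relatedness).
    """
    means = plots.genotype_means().to_numpy()
    Sigma_sf, _ = manova_genetic_cov(plots)
    if structured:
        B, W, r = _manova_components(plots)
        Gss = ((B - W) / r)[1:, 1:]
        Sigma_s = Gss + W[1:, 1:]
    else:
        Sigma_s = np.cov(means[:, 1:].T)
    return Sigma_s, Sigma_sf


def tune_si_lambda(
    plots: PlotLevelData,
    candidate_lambdas=None,
    *,
    penalty_type: str = "ridge",
    folds: int = 5,
    seed=None,
    structured: bool = False,
) -> SelectionIndexModel:
    """Choose the penalty by k-fold CV over genotypes, maximizing the
    held-out estimate of h(S) * rho_G(S, Y_f)."""
    if isinstance(plots, pd.DataFrame):
        plots = PlotLevelData.from_frame(plots)
    Sigma_s, Sigma_sf = estimate_si_inputs(plots, structured=structured)
    if candidate_lambdas is None:
        candidate_lambdas = default_lambda_grid(Sigma_s)
    lambdas = np.atleast_1d(np.asarray(candidate_lambdas, dtype=float))

    if lambdas.size == 1:
        gamma = penalized_si(Sigma_s, Sigma_sf, float(lambdas[0]), penalty_type)
        return SelectionIndexModel(
            gamma=gamma,
            lambda_pen=float(lambdas[0]),
            penalty_type=penalty_type,
            Sigma_s_hat=Sigma_s,
            Sigma_sf_u_hat=Sigma_sf,
            trait_names=plots.trait_names[1:],
        )

    rng = np.random.default_rng(seed)
    genos = np.array(sorted(set(plots.genotype)), dtype=object)
    perm = rng.permutation(len(genos))
    fold_of = np.empty(len(genos), dtype=int)
    fold_of[perm] = np.arange(len(genos)) % folds

    scores = np.zeros((lambdas.size, folds))
    valid = np.zeros((lambdas.size, folds), dtype=bool)
    for f in range(folds):
        infold = plots.subset(genos[fold_of != f])
        outfold = plots.subset(genos[fold_of == f])
        try:
            S_in, c_in = estimate_si_inputs(infold, structured=structured)
        except ValueError:
            continue
        for i, lam in enumerate(lambdas):
            try:
                gamma = penalized_si(S_in, c_in, float(lam), penalty_type)
                scores[i, f] = _si_criterion(outfold, gamma)
                valid[i, f] = True
            except (FloatingPointError, ValueError):
                warnings.warn(f"fold {f}: criterion undefined at lambda={lam:.3g}")
    mean_scores = np.where(
        valid.any(axis=1), np.nansum(scores * valid, axis=1) / valid.sum(axis=1).clip(1), -np.inf
    )
    best = int(np.argmax(mean_scores))
    gamma = penalized_si(Sigma_s, Sigma_sf, float(lambdas[best]), penalty_type)
    path = pd.DataFrame(
        {"lambda": lambdas, "criterion": mean_scores, "n_folds": valid.sum(axis=1)}
    )
    return SelectionIndexModel(
        gamma=gamma,
        lambda_pen=float(lambdas[best]),
        penalty_type=penalty_type,
        Sigma_s_hat=Sigma_s,
        Sigma_sf_u_hat=Sigma_sf,
        criterion_path=path,
        trait_names=plots.trait_names[1:],
    )


def si_blup(
    plots,
    y_fo,
    Ys_means,
    kpart: KinshipPartition,
    scenario: int = 1,
    *,
    candidate_lambdas=None,
    penalty_type: str = "ridge",
    folds: int = 5,
    diagonal_residual: bool = True,
    seed=None,
    si_model: SelectionIndexModel | None = None,
    X=None,
) -> PredictionResult:
    """SI-BLUP: bivariate GBLUP with the tuned selection index as the
    secondary trait.

    ``plots``: plot-level data on the training genotypes (required for the
    MANOVA genetic covariances).  ``Ys_means``: genotype-level secondary
    traits for the training set (scenario 1) or all genotypes (scenario 2),
    as a DataFrame indexed by genotype id.
    """
    if si_model is None:
        si_model = tune_si_lambda(
            plots,
            candidate_lambdas,
            penalty_type=penalty_type,
            folds=folds,
            seed=seed,
        )
    y_fo = np.asarray(y_fo, dtype=float).ravel()
    if not isinstance(Ys_means, pd.DataFrame):
        raise TypeError("Ys_means must be a genotype-indexed DataFrame")

    if np.allclose(si_model.gamma, 0.0):
        fit = UnivariateGBLUP(y_fo, eig=kpart.eigh_oo(), X=X).fit()
        out = predict_univariate(
            fit, y_fo, kpart, X=X, method="SI-BLUP", scenario=scenario
        )
        out.extras.update({"fallback": "univariate", "si_model": si_model})
        return out

    if scenario == 2:
        S_all = si_model.index_values(Ys_means.loc[kpart.ids])
        S_train = S_all[kpart.n_t :]
    else:
        S_train = si_model.index_values(Ys_means.loc[kpart.train_ids])

    Y2 = np.column_stack([y_fo, S_train])
    fit = BivariateGBLUP(
        Y2, kpart.K_oo, X=X, diagonal_residual=diagonal_residual, eig=kpart.eigh_oo()
    ).fit(trait_names=["focal", "S_index"])
    if scenario == 1:
        out = predict_multivariate_s1(
            fit, Y2, kpart, X=X, method="SI-BLUP", scenario=1
        )
    else:
        out = predict_multivariate_s2(
            fit, y_fo, S_all[:, None], kpart, X=X, method="SI-BLUP", scenario=2
        )
    out.extras.update({"si_model": si_model, "fit": fit})
    return out
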