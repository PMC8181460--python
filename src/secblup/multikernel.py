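"""Predictors built on a secondary-trait relatedness matrix M.

M is the linear kernel of the column-standardized secondary traits,
M = Z_s Z_s^T / p -- the direct analogue of a genomic relationship matrix
with traits in place of markers.  Equivalently the secondary-trait effect
V_f = Y_s b_s for i.i.d. random regression coefficients b_s with variance
sigma2_M / p, which is the form used to transfer the fitted effects to
other genotypes.

* Multi-BLUP (scenario 2 only): y = X beta + U_gen + V_sec + E with
  U_gen ~ N(0, s2_K K) and V_sec ~ N(0, s2_M M); the prediction is the sum
  of the two BLUPs, extended to the test set via K_to and M_to.  Partly a
  phenotypic prediction, since it uses the secondary trait *values* on the
  test set.
* GM-BLUP: replaces the secondary trait values by their per-trait genomic
  predictions, so it also works when secondary traits exist only on the
  training set.
* M-BLUP (scenario 2 only): drops the genomic kernel entirely and predicts
  from the secondary traits alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import KinshipPartition
from .predict import PredictionResult, predict_univariate
from .reml import MultiKernelModel, UnivariateGBLUP

__all__ = [
    "SecondaryKernel",
    "secondary_kernel",
    "multi_blup",
    "gm_blup",
    "m_blup",
]


@dataclass
class SecondaryKernel:
    """Linear relatedness kernel of column-standardized secondary traits."""

    M: np.ndarray
    Z: np.ndarray = field(repr=False, default=None)
    mu: np.ndarray = field(repr=False, default=None)
    sd: np.ndarray = field(repr=False, default=None)

    @property
    def p(self) -> int:
        return self.Z.shape[1]

    def standardize(self, Ys) -> np.ndarray:
        """Apply the stored column transforms to new secondary-trait rows."""
        return (np.asarray(Ys, dtype=float) - self.mu) / self.sd


def secondary_kernel(Ys) -> SecondaryKernel:
    """M = Z Z^T / p with Z the column-standardized secondary traits."""
    Ys = np.asarray(Ys, dtype=float)
    mu = Ys.mean(axis=0)
    sd = Ys.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {np.sum(~keep)} constant secondary trait(s)")
        Ys, mu, sd = Ys[:, keep], mu[keep], sd[keep]
    Z = (Ys - mu) / sd
    p = Z.shape[1]
    if p == 0:
        raise ValueError("no non-constant secondary traits")
    M = Z @ Z.T / p
    return SecondaryKernel(M=M, Z=Z, mu=mu, sd=sd)


def _centered(y, X, beta):
    y = np.asarray(y, dtype=float).ravel()
    return y - X @ np.asarray(beta, dtype=float).ravel()


def multi_blup(
    y_fo,
    Ys,
    kpart: KinshipPartition,
    *,
    seed=None,
    X=None,
) -> PredictionResult:
    """Multi-BLUP: two-kernel model, prediction = U_gen BLUP + V_sec BLUP.

    ``Ys`` must cover ALL genotypes (scenario 2), as a DataFrame indexed by
    genotype id or an array in test-first order.
    """
    y_fo = np.asarray(y_fo, dtype=float).ravel()
    n_t, n_o = kpart.n_t, kpart.n_o
    if isinstance(Ys, pd.DataFrame):
        missing = [g for g in kpart.ids if g not in Ys.index]
        if missing:
            raise ValueError(
                f"secondary traits missing on test genotypes ({missing[:5]}...); "
                "use gm_blup, which needs them on the training set only"
            )
        Ys = Ys.loc[kpart.ids].to_numpy(dtype=float)
    Ys = np.asarray(Ys, dtype=float)
    if Ys.shape[0] != kpart.n or np.isnan(Ys).any():
        raise ValueError(
            "Multi-BLUP is limited to scenario 2: secondary traits must be "
            "observed on every genotype; use gm_blup otherwise"
        )
    kern = secondary_kernel(Ys)
    M = kern.M
    M_oo = M[n_t:, n_t:]
    Xo = np.ones((n_o, 1)) if X is None else np.asarray(X, dtype=float)
    fit = MultiKernelModel(y_fo, kpart.K_oo, M_oo, X=Xo).fit()
    yc = _centered(y_fo, Xo, fit.beta)
    V = fit.sigma2_K * kpart.K_oo + fit.sigma2_M * M_oo + fit.sigma2_E * np.eye(n_o)
    a = np.linalg.solve(V, yc)
    u_gen = fit.sigma2_K * (kpart.K[:, n_t:] @ a)  # all genotypes
    v_sec = fit.sigma2_M * (M[:, n_t:] @ a)
    b_s = (fit.sigma2_M / kern.p) * (kern.Z[n_t:].T @ a)
    u = u_gen + v_sec
    return PredictionResult(
        u_test=pd.Series(u[:n_t], index=kpart.test_ids),
        u_train=pd.Series(u[n_t:], index=kpart.train_ids),
        method="Multi-BLUP",
        scenario=2,
        extras={
            "fit": fit,
            "b_s": b_s,
            "u_gen": u_gen,
            "v_sec": v_sec,
            "kernel": kern,
        },
    )


def gm_blup(
    y_fo,
    Ys_train,
    kpart: KinshipPartition,
    *,
    seed=None,
    X=None,
    scenario: int = 1,
) -> PredictionResult:
    """GM-BLUP: U_gen BLUP plus the *genomic predictions* of the secondary
    traits weighted by the Multi-BLUP regression coefficients.

    Works with secondary traits on the training set only; the per-trait
    univariate GBLUPs extend them to the test set.
    """
    y_fo = np.asarray(y_fo, dtype=float).ravel()
    n_t, n_o = kpart.n_t, kpart.n_o
    if isinstance(Ys_train, pd.DataFrame):
        Ys_train = Ys_train.loc[kpart.train_ids].to_numpy(dtype=float)
    Ys_train = np.asarray(Ys_train, dtype=float)
    if Ys_train.shape[0] == kpart.n:  # tolerate scenario-2 input; use train rows
        Ys_train = Ys_train[n_t:]
    if Ys_train.shape[0] != n_o:
        raise ValueError("Ys_train rows do not match the training set")

    kern = secondary_kernel(Ys_train)
    Xo = np.ones((n_o, 1)) if X is None else np.asarray(X, dtype=float)
    fit = MultiKernelModel(y_fo, kpart.K_oo, kern.M, X=Xo).fit()
    yc = _centered(y_fo, Xo, fit.beta)
    V = fit.sigma2_K * kpart.K_oo + fit.sigma2_M * kern.M + fit.sigma2_E * np.eye(n_o)
    a = np.linalg.solve(V, yc)
    u_gen = fit.sigma2_K * (kpart.K[:, n_t:] @ a)
    b_s = (fit.sigma2_M / kern.p) * (kern.Z.T @ a)

    # per-trait univariate GBLUP of each (standardized) secondary trait,
    # sharing one eigendecomposition of K_oo
    eig = kpart.eigh_oo()
    U_sec = np.zeros((kpart.n, kern.p))
    dropped = []
    for j in range(kern.p):
        try:
            fj = UnivariateGBLUP(kern.Z[:, j], eig=eig).fit()
            pj = predict_univariate(fj, kern.Z[:, j], kpart)
            U_sec[:n_t, j] = pj.u_test.to_numpy()
            U_sec[n_t:, j] = pj.u_train.to_numpy()
        except Exception as exc:  # noqa: BLE001 - per-trait failures are logged
            dropped.append((j, str(exc)))
    if dropped:
        warnings.warn(f"GM-BLUP: dropped {len(dropped)} secondary trait fits")
    u = u_gen + U_sec @ b_s
    return PredictionResult(
        u_test=pd.Series(u[:n_t], index=kpart.test_ids),
        u_train=pd.Series(u[n_t:], index=kpart.train_ids),
        method="GM-BLUP",
        scenario=scenario,
        extras={"fit": fit, "b_s": b_s, "u_gen": u_gen, "dropped": dropped},
    )


def m_blup(
    y_fo,
    Ys,
    kpart: KinshipPartition,
    *,
    X=None,
) -> PredictionResult:
    """M-BLUP: prediction from the secondary traits alone (no genomic
    kernel): U_hat = Y_s b_hat_s from y = X beta + Y_s b_s + E."""
    y_fo = np.asarray(y_fo, dtype=float).ravel()
    n_t, n_o = kpart.n_t, kpart.n_o
    if isinstance(Ys, pd.DataFrame):
        missing = [g for g in kpart.ids if g not in Ys.index]
        if missing:
            raise ValueError(
                f"secondary traits missing on test genotypes ({missing[:5]}...); "
                "M-BLUP requires scenario 2"
            )
        Ys = Ys.loc[kpart.ids].to_numpy(dtype=float)
    Ys = np.asarray(Ys, dtype=float)
    if Ys.shape[0] != kpart.n or np.isnan(Ys).any():
        raise ValueError("M-BLUP requires secondary traits on every genotype")
    kern = secondary_kernel(Ys)
    M_oo = kern.M[n_t:, n_t:]
    # one-kernel mixed model: reuse the univariate REML machinery with M as K
    Xo = np.ones((n_o, 1)) if X is None else np.asarray(X, dtype=float)
    fit = UnivariateGBLUP(y_fo, K=M_oo, X=Xo).fit()
    yc = _centered(y_fo, Xo, fit.beta)
    V = fit.sigma2_u * M_oo + fit.sigma2_e * np.eye(n_o)
    a = np.linalg.solve(V, yc)
    b_s = (fit.sigma2_u / kern.p) * (kern.Z[n_t:].T @ a)
    u = kern.Z @ b_s
    return PredictionResult(
        u_test=pd.Series(u[:n_t], index=kpart.test_ids),
        u_train=pd.Series(u[n_t:], index=kpart.train_ids),
        method="M-BLUP",
        scenario=2,
        extras={"fit": fit, "b_s": b_s},
    )
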