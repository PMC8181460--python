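"""REML estimation of variance components for the mixed models used in
secondary-phenotype genomic prediction.

Three model classes, each in the model / fit() / results idiom:

* :class:`UnivariateGBLUP` -- y ~ N(X beta, sigma2_u K + sigma2_e I).
  After one eigendecomposition of K the REML criterion is profiled down to a
  one-dimensional search over the heritability h = sigma2_u / (sigma2_u +
  sigma2_e).

* :class:`BivariateGBLUP` -- two traits with genetic covariance Sigma_u x K
  and residual covariance Sigma_e x I.  Balanced coverage (both traits on the
  same genotypes) uses the same eigendecomposition trick, giving an O(n)
  likelihood; unbalanced coverage (e.g., the secondary trait also observed on
  unphenotyped genotypes) is handled by marginalising the missing cells in a
  dense likelihood.  Covariance matrices are parameterised through their
  log-Cholesky factors, which keeps every iterate positive semidefinite.

* :class:`MultiKernelModel` -- y ~ N(X beta, s2_K K + s2_M M + s2_E I) with a
  second relatedness matrix M derived from secondary phenotypes.

Fixed effects default to an intercept.  Non-convergence is reported through
the ``converged`` flag, never raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "UnivariateFit",
    "CovarianceEstimate",
    "MultiKernelFit",
    "UnivariateGBLUP",
    "BivariateGBLUP",
    "MultiKernelModel",
    "fit_univariate_reml",
    "fit_bivariate_reml",
    "fit_multikernel_reml",
]

VARIANCE_FLOOR = 1e-8
LOG2PI = float(np.log(2.0 * np.pi))


def _as_design(X, n: int) -> np.ndarray:
    if X is None:
        return np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    if X.shape[0] != n:
        raise ValueError("design matrix rows do not match observations")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix X is rank deficient")
    return X


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class UnivariateFit:
    """Variance components and fixed effects of a univariate GBLUP model."""

    sigma2_u: float
    sigma2_e: float
    beta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int = 0

    @property
    def heritability(self) -> float:
        return self.sigma2_u / (self.sigma2_u + self.sigma2_e)

    def summary(self) -> str:
        lines = [
            "Univariate GBLUP (REML)",
            f"  n obs            : {self.n_obs}",
            f"  sigma2_u (genetic): {self.sigma2_u:.6g}",
            f"  sigma2_e (resid)  : {self.sigma2_e:.6g}",
            f"  heritability      : {self.heritability:.4f}",
            f"  beta              : {np.array2string(np.asarray(self.beta), precision=4)}",
            f"  REML loglik       : {self.loglik:.6f}",
            f"  converged         : {self.converged} ({self.n_iter} iterations)",
        ]
        return "\n".join(lines)


@dataclass
class CovarianceEstimate:
    """Genetic and residual covariance matrices of a multi-trait model.

    Trait 0 is the focal trait; the remaining traits are secondary.  The
    focal/secondary blocks Sigma_ff, Sigma_fs, Sigma_ss are exposed for both
    matrices.  Also used as a plain container for *known* (e.g., simulated)
    covariances, in which case ``loglik`` is NaN.
    """

    Sigma_u: np.ndarray
    Sigma_e: np.ndarray
    beta: np.ndarray  # (q, p) fixed effects per trait
    trait_names: list = field(default_factory=list)
    diagonal_residual: bool = False
    loglik: float = float("nan")
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.Sigma_u = np.asarray(self.Sigma_u, dtype=float)
        self.Sigma_e = np.asarray(self.Sigma_e, dtype=float)
        q = self.Sigma_u.shape[0]
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if self.beta.shape[0] != q:
            raise ValueError("beta must have one row per trait")
        if not self.trait_names:
            self.trait_names = [f"trait_{j}" for j in range(q)]

    @property
    def q(self) -> int:
        return self.Sigma_u.shape[0]

    # focal/secondary blocks
    @property
    def Sigma_ff_u(self) -> float:
        return float(self.Sigma_u[0, 0])

    @property
    def Sigma_fs_u(self) -> np.ndarray:
        return self.Sigma_u[0, 1:]

    @property
    def Sigma_ss_u(self) -> np.ndarray:
        return self.Sigma_u[1:, 1:]

    @property
    def Sigma_ff_e(self) -> float:
        return float(self.Sigma_e[0, 0])

    @property
    def Sigma_fs_e(self) -> np.ndarray:
        return self.Sigma_e[0, 1:]

    @property
    def Sigma_ss_e(self) -> np.ndarray:
        return self.Sigma_e[1:, 1:]

    def genetic_correlation(self, i: int = 0, j: int = 1) -> float:
        su = self.Sigma_u
        return float(su[i, j] / np.sqrt(su[i, i] * su[j, j]))

    def heritability(self, j: int = 0) -> float:
        return float(self.Sigma_u[j, j] / (self.Sigma_u[j, j] + self.Sigma_e[j, j]))

    def summary(self) -> str:
        with np.printoptions(precision=4, suppress=True):
            lines = [
                f"Multi-trait covariance estimate ({self.q} traits: "
                + ", ".join(map(str, self.trait_names)) + ")",
                f"  Sigma_u:\n{self.Sigma_u}",
                f"  Sigma_e{' (diagonal)' if self.diagonal_residual else ''}:\n{self.Sigma_e}",
                f"  heritabilities    : "
                + np.array2string(np.array([self.heritability(j) for j in range(self.q)])),
                f"  REML loglik       : {self.loglik:.6f}",
                f"  converged         : {self.converged} ({self.n_iter} iterations)",
            ]
        return "\n".join(lines)


@dataclass
class MultiKernelFit:
    """Variance components of the two-kernel (K + M) mixed model."""

    sigma2_K: float
    sigma2_M: float
    sigma2_E: float
    beta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int

    def summary(self) -> str:
        tot = self.sigma2_K + self.sigma2_M + self.sigma2_E
        return "\n".join(
            [
                "Two-kernel mixed model (REML)",
                f"  sigma2_K (genomic kernel)  : {self.sigma2_K:.6g} ({self.sigma2_K / tot:.1%})",
                f"  sigma2_M (secondary kernel): {self.sigma2_M:.6g} ({self.sigma2_M / tot:.1%})",
                f"  sigma2_E (residual)        : {self.sigma2_E:.6g} ({self.sigma2_E / tot:.1%})",
                f"  beta                       : {np.array2string(np.asarray(self.beta), precision=4)}",
                f"  REML loglik                : {self.loglik:.6f}",
                f"  converged                  : {self.converged} ({self.n_iter} iterations)",
            ]
        )


# ---------------------------------------------------------------------------
# univariate model
# ---------------------------------------------------------------------------


class UnivariateGBLUP:
    """Univariate animal model y ~ N(X beta, sigma2_u K + sigma2_e I).

    Parameters
    ----------
    y : (n,) trait values on the training genotypes.
    K : (n, n) relatedness matrix, or None if ``eig`` is given.
    X : fixed-effect design; defaults to an intercept.
    eig : optional precomputed ``(eigenvalues, eigenvectors)`` of K, e.g.
        from :meth:`KinshipPartition.eigh_oo`; avoids refactorising K when
        many traits share one kinship.
    """

    def __init__(self, y, K=None, X=None, *, eig=None):
        self.y = np.asarray(y, dtype=float).ravel()
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite trait values")
        n = self.y.size
        if n < 10:
            raise ValueError("need at least 10 observations for REML")
        if eig is None:
            if K is None:
                raise ValueError("provide K or a precomputed eigendecomposition")
            K = np.asarray(K, dtype=float)
            eig = np.linalg.eigh(0.5 * (K + K.T))
        self.eigval, self.eigvec = np.clip(eig[0], 0.0, None), eig[1]
        self.X = _as_design(X, n)
        self._yt = self.eigvec.T @ self.y
        self._Xt = self.eigvec.T @ self.X

    def profile_loglik(self, h: float) -> float:
        """REML log-likelihood profiled over beta and the total variance,
        as a function of the heritability h."""
        ll, *_ = self._profile(h)
        return ll

    def _profile(self, h: float):
        n, p = self._Xt.shape
        w = h * self.eigval + (1.0 - h)
        w = np.maximum(w, 1e-12)
        xw = self._Xt / w[:, None]
        xtwx = self._Xt.T @ xw
        beta = np.linalg.solve(xtwx, xw.T @ self._yt)
        r = self._yt - self._Xt @ beta
        nu = n - p
        s2 = float(r @ (r / w)) / nu
        s2 = max(s2, 1e-300)
        sign, logdet_xtwx = np.linalg.slogdet(xtwx)
        ll = -0.5 * (
            nu * np.log(s2)
            + np.log(w).sum()
            + logdet_xtwx
            + nu * (1.0 + LOG2PI)
        )
        return float(ll), beta, s2

    def fit(self, *, variance_floor: float = VARIANCE_FLOOR) -> UnivariateFit:
        lo, hi = 1e-9, 1.0 - 1e-9
        # coarse scan guards against flat/multimodal profiles
        grid = np.linspace(lo, hi, 21)
        vals = [self.profile_loglik(h) for h in grid]
        i = int(np.argmax(vals))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda h: -self.profile_loglik(h),
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-10},
        )
        h = float(res.x)
        ll, beta, s2 = self._profile(h)
        # the profile is continuous up to the boundary: snap if the edge wins
        for edge in (lo, hi):
            ll_edge = self.profile_loglik(edge)
            if ll_edge > ll:
                h, ll = edge, ll_edge
                _, beta, s2 = self._profile(edge)
        sigma2_u = max(h * s2, variance_floor)
        sigma2_e = max((1.0 - h) * s2, variance_floor)
        return UnivariateFit(
            sigma2_u=sigma2_u,
            sigma2_e=sigma2_e,
            beta=beta,
            loglik=ll,
            converged=bool(res.success),
            n_iter=int(res.nfev) + len(grid),
            n_obs=self.y.size,
        )


# ---------------------------------------------------------------------------
# covariance parameterisation helpers
# ---------------------------------------------------------------------------


def _chol_unpack(theta: np.ndarray, q: int) -> np.ndarray:
    """Lower-triangular L from a log-Cholesky parameter vector."""
    L = np.zeros((q, q))
    k = 0
    for i in range(q):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(theta[k])
            else:
                L[i, j] = theta[k]
            k += 1
    return L


def _chol_pack(S: np.ndarray) -> np.ndarray:
    q = S.shape[0]
    # PSD projection before factorising, so arbitrary start values work
    w, v = np.linalg.eigh(0.5 * (S + S.T))
    S = (v * np.maximum(w, 1e-6)) @ v.T
    L = np.linalg.cholesky(S)
    out = []
    for i in range(q):
        for j in range(i + 1):
            out.append(np.log(L[i, j]) if i == j else L[i, j])
    return np.array(out)


def _n_chol_params(q: int) -> int:
    return q * (q + 1) // 2


# ---------------------------------------------------------------------------
# bivariate model
# ---------------------------------------------------------------------------


class BivariateGBLUP:
    """Bivariate GBLUP with genetic covariance Sigma_u x K.

    ``Y`` is an (n, 2) array aligned with ``K``; missing cells are NaN.
    Column 0 is the focal trait.  When both columns are fully observed the
    fast eigendecomposition likelihood is used; otherwise the dense
    marginal likelihood over observed cells.

    ``diagonal_residual=True`` forces Sigma_e off-diagonals to exactly zero
    (traits measured on different plants).
    """

    def __init__(self, Y, K, X=None, *, diagonal_residual=False, eig=None):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[1] != 2:
            raise ValueError("Y must be n x 2 (focal, secondary)")
        self.Y = Y
        self.K = np.asarray(K, dtype=float)
        if self.K.shape != (Y.shape[0], Y.shape[0]):
            raise ValueError("K shape does not match Y rows")
        self.diagonal_residual = bool(diagonal_residual)
        self.obs = ~np.isnan(Y)
        for j in range(2):
            col = Y[self.obs[:, j], j]
            if col.size < 3:
                raise ValueError(f"trait {j} has fewer than 3 observations")
            if np.ptp(col) == 0.0:
                raise ValueError(f"trait {j} is constant")
        self.balanced = bool(self.obs.all())
        self.X = _as_design(X, Y.shape[0])
        self._eig = eig
        if self.balanced:
            if self._eig is None:
                self._eig = np.linalg.eigh(self.K)
            w, q = self._eig
            self._w = np.clip(w, 0.0, None)
            self._Yt = q.T @ Y
            self._Xt = q.T @ self.X
        else:
            self._setup_dense()

    # -- parameter vector layout ------------------------------------------
    def _unpack(self, theta):
        nu = _n_chol_params(2)
        Lu = _chol_unpack(theta[:nu], 2)
        Su = Lu @ Lu.T
        if self.diagonal_residual:
            Se = np.diag(np.exp(2.0 * theta[nu : nu + 2]))
        else:
            Le = _chol_unpack(theta[nu : nu + nu], 2)
            Se = Le @ Le.T
        # keep residual variances bounded away from zero so that downstream
        # V inversions stay well-posed
        Se = Se + VARIANCE_FLOOR * np.eye(2)
        return Su, Se

    def _pack_start(self):
        # half the phenotypic (co)variance on each side, per standard practice
        pairs = self.obs.all(axis=1)
        if pairs.sum() >= 3:
            C = np.cov(self.Y[pairs].T)
        else:
            v = [np.nanvar(self.Y[:, j]) for j in range(2)]
            C = np.diag(v)
        C = C + 1e-3 * np.eye(2)
        half = 0.5 * C
        theta = list(_chol_pack(half))
        if self.diagonal_residual:
            theta += list(0.5 * np.log(np.diag(half)))
        else:
            theta += list(_chol_pack(half))
        return np.array(theta)

    # -- balanced likelihood ----------------------------------------------
    def _negll_balanced(self, theta):
        Su, Se = self._unpack(theta)
        return self._negll_balanced_mats(Su, Se)

    def _negll_balanced_mats(self, Su, Se):
        n, p = self._Xt.shape
        C = self._w[:, None, None] * Su + Se  # (n, 2, 2)
        det = C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] ** 2
        if np.any(det <= 0) or np.any(C[:, 0, 0] <= 0):
            return 1e10
        Cinv = np.empty_like(C)
        Cinv[:, 0, 0] = C[:, 1, 1] / det
        Cinv[:, 1, 1] = C[:, 0, 0] / det
        Cinv[:, 0, 1] = Cinv[:, 1, 0] = -C[:, 0, 1] / det
        lhs = np.einsum("ijk,ia,ib->jakb", Cinv, self._Xt, self._Xt).reshape(
            2 * p, 2 * p
        )
        rhs = np.einsum("ijk,ik,ia->ja", Cinv, self._Yt, self._Xt).reshape(2 * p)
        try:
            beta = np.linalg.solve(lhs, rhs).reshape(2, p)
        except np.linalg.LinAlgError:
            return 1e10
        R = self._Yt - self._Xt @ beta.T
        quad = float(np.einsum("ijk,ij,ik->", Cinv, R, R))
        sign, logdet_lhs = np.linalg.slogdet(lhs)
        if sign <= 0:
            return 1e10
        ll = -0.5 * (
            np.log(det).sum() + quad + logdet_lhs + (2 * n - 2 * p) * LOG2PI
        )
        self._last_beta = beta
        return -ll

    # -- dense (unbalanced) likelihood ------------------------------------
    def _setup_dense(self):
        idx = [np.where(self.obs[:, j])[0] for j in range(2)]
        self._idx = idx
        self._yobs = np.concatenate([self.Y[idx[0], 0], self.Y[idx[1], 1]])
        n0, n1 = len(idx[0]), len(idx[1])
        Xd = np.zeros((n0 + n1, 2 * self.X.shape[1]))
        Xd[:n0, : self.X.shape[1]] = self.X[idx[0]]
        Xd[n0:, self.X.shape[1] :] = self.X[idx[1]]
        self._Xd = Xd
        # overlap indicator: same genotype observed for both traits
        self._J = (idx[0][:, None] == idx[1][None, :]).astype(float)

    def _negll_dense(self, theta):
        Su, Se = self._unpack(theta)
        return self._negll_dense_mats(Su, Se)

    def _negll_dense_mats(self, Su, Se):
        i0, i1 = self._idx
        n0, n1 = len(i0), len(i1)
        K = self.K
        V = np.empty((n0 + n1, n0 + n1))
        V[:n0, :n0] = Su[0, 0] * K[np.ix_(i0, i0)] + Se[0, 0] * np.eye(n0)
        V[n0:, n0:] = Su[1, 1] * K[np.ix_(i1, i1)] + Se[1, 1] * np.eye(n1)
        cross = Su[0, 1] * K[np.ix_(i0, i1)] + Se[0, 1] * self._J
        V[:n0, n0:] = cross
        V[n0:, :n0] = cross.T
        return _dense_reml_negll(self._yobs, self._Xd, V, self)

    # -- public API --------------------------------------------------------
    def negloglik(self, Sigma_u, Sigma_e) -> float:
        """Negative REML log-likelihood at given covariance matrices
        (evaluated exactly, without the optimizer's residual floor)."""
        Su = np.asarray(Sigma_u, dtype=float)
        Se = np.asarray(Sigma_e, dtype=float)
        f = self._negll_balanced_mats if self.balanced else self._negll_dense_mats
        return f(Su, Se)

    def fit(self, *, maxiter: int = 4000, trait_names=None) -> CovarianceEstimate:
        f = self._negll_balanced if self.balanced else self._negll_dense
        x0 = self._pack_start()
        res = optimize.minimize(
            f,
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": maxiter,
                "maxfev": maxiter,
                "xatol": 1e-6,
                "fatol": 1e-8,
                "adaptive": True,
            },
        )
        Su, Se = self._unpack(res.x)
        f(res.x)  # refresh cached beta at the optimum
        beta = np.asarray(self._last_beta).reshape(2, -1)
        if not res.success:
            warnings.warn("bivariate REML did not converge; result flagged")
        names = list(trait_names) if trait_names is not None else ["focal", "secondary"]
        return CovarianceEstimate(
            Sigma_u=Su,
            Sigma_e=Se,
            beta=beta,
            trait_names=names,
            diagonal_residual=self.diagonal_residual,
            loglik=-float(res.fun),
            converged=bool(res.success),
            n_iter=int(res.nit),
        )


def _dense_reml_negll(y, X, V, owner=None):
    """Dense REML criterion -ll for y ~ N(X beta, V); caches beta on owner."""
    try:
        c, low = (np.linalg.cholesky(V), True)
    except np.linalg.LinAlgError:
        return 1e10
    from scipy.linalg import cho_solve, solve_triangular

    logdet_v = 2.0 * np.log(np.diag(c)).sum()
    Vi_X = cho_solve((c, True), X)
    Vi_y = cho_solve((c, True), y)
    xtvix = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(xtvix)
    if sign <= 0:
        return 1e10
    beta = np.linalg.solve(xtvix, X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ cho_solve((c, True), r))
    nu = len(y) - X.shape[1]
    ll = -0.5 * (logdet_v + logdet_x + quad + nu * LOG2PI)
    if owner is not None:
        owner._last_beta = beta
    return -ll


# ---------------------------------------------------------------------------
# two-kernel model
# ---------------------------------------------------------------------------


class MultiKernelModel:
    """y ~ N(X beta, sigma2_K K + sigma2_M M + sigma2_E I).

    ``M`` is the relatedness matrix derived from secondary phenotypes.  Both
    kernels must be symmetric PSD on the training genotypes.
    """

    def __init__(self, y, K, M, X=None):
        self.y = np.asarray(y, dtype=float).ravel()
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite trait values")
        n = self.y.size
        self.K = np.asarray(K, dtype=float)
        self.M = np.asarray(M, dtype=float)
        if self.K.shape != (n, n) or self.M.shape != (n, n):
            raise ValueError("kernel shapes do not match y")
        if np.allclose(self.K, self.M, atol=1e-10):
            warnings.warn(
                "K and M are (nearly) identical: kernel variances are not "
                "separately identifiable; boundary solutions are possible"
            )
        self.X = _as_design(X, n)

    def negloglik(self, sigma2_K, sigma2_M, sigma2_E) -> float:
        V = (
            sigma2_K * self.K
            + sigma2_M * self.M
            + sigma2_E * np.eye(self.y.size)
        )
        return _dense_reml_negll(self.y, self.X, V, self)

    def fit(self, *, maxiter: int = 2000) -> MultiKernelFit:
        vp = float(np.var(self.y))
        x0 = np.log(np.full(3, max(vp, 1e-6) / 3.0))

        def f(theta):
            s = np.exp(np.clip(theta, -40.0, 40.0))
            return self.negloglik(s[0], s[1], s[2])

        res = optimize.minimize(
            f,
            x0,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "maxfev": maxiter, "xatol": 1e-9, "fatol": 1e-9},
        )
        s = np.exp(np.clip(res.x, -40.0, 40.0))
        s[2] = max(s[2], VARIANCE_FLOOR)
        # evaluate at the (floored) reported parameters so that loglik and
        # beta are exactly consistent with the returned components
        negll = self.negloglik(s[0], s[1], s[2])
        if not res.success:
            warnings.warn("two-kernel REML did not converge; result flagged")
        return MultiKernelFit(
            sigma2_K=float(s[0]),
            sigma2_M=float(s[1]),
            sigma2_E=float(s[2]),
            beta=np.asarray(self._last_beta).ravel(),
            loglik=-float(negll),
            converged=bool(res.success),
            n_iter=int(res.nit),
        )


# ---------------------------------------------------------------------------
# functional wrappers over the model classes
# ---------------------------------------------------------------------------


def fit_univariate_reml(y, X=None, K_oo=None, *, eig=None) -> UnivariateFit:
    return UnivariateGBLUP(y, K=K_oo, X=X, eig=eig).fit()


def fit_bivariate_reml(
    Y2, X=None, K=None, *, diagonal_residual=False, eig=None, trait_names=None
) -> CovarianceEstimate:
    return BivariateGBLUP(
        Y2, K, X=X, diagonal_residual=diagonal_residual, eig=eig
    ).fit(trait_names=trait_names)


def fit_multikernel_reml(y, X=None, K_oo=None, M_oo=None) -> MultiKernelFit:
    return MultiKernelModel(y, K_oo, M_oo, X=X).fit()
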