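"""Independent oracles used by the test suite.

These deliberately re-derive everything from first principles (dense joint
Gaussians, explicit REML criteria, naive coordinate descent) so they share
no code with the package's production paths.
"""

import numpy as np

LOG2PI = float(np.log(2.0 * np.pi))


def vanraden_oracle(dosages):
    """Literal VanRaden GRM: centered dosages, observed frequencies."""
    d = np.asarray(dosages, dtype=float)
    p = d.mean(axis=0) / 2.0
    zc = d - 2.0 * p
    return zc @ zc.T / (2.0 * np.sum(p * (1.0 - p)))


def conditional_mean(cov, idx_target, idx_obs, obs_values, mean=None):
    """E(target | observed) of a joint zero-mean Gaussian with matrix cov."""
    cov = np.asarray(cov, dtype=float)
    obs_values = np.asarray(obs_values, dtype=float)
    if mean is not None:
        obs_values = obs_values - np.asarray(mean)[idx_obs]
    c_to = cov[np.ix_(idx_target, idx_obs)]
    c_oo = cov[np.ix_(idx_obs, idx_obs)]
    return c_to @ np.linalg.solve(c_oo, obs_values)


def joint_cov_s1(Su, Se, K_oo):
    """Joint covariance of (U_f over all genotypes stacked first) is not
    needed; build cov of (Y_o stacked trait-major) under the multi-trait
    model on the training set."""
    return np.kron(Su, K_oo) + np.kron(Se, np.eye(K_oo.shape[0]))


def dense_s1_prediction(Su, Se, K, n_t, Y_o, beta=None):
    """Scenario-1 oracle: E(U_f | Y_o) via one big joint Gaussian.

    K is the full (test-first) kinship; Y_o the (n_o, q) trait values on
    the training rows.  Returns (u_test, u_train).
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    n_o = n - n_t
    q = Y_o.shape[1]
    Yc = Y_o - (0.0 if beta is None else np.asarray(beta))
    K_oo = K[n_t:, n_t:]
    V = np.kron(Su, K_oo) + np.kron(Se, np.eye(n_o))
    # cov(U_f over all genotypes, Y_o trait-major stack)
    C = np.hstack([Su[0, j] * K[:, n_t:] for j in range(q)])
    u = C @ np.linalg.solve(V, Yc.T.ravel())
    return u[:n_t], u[n_t:]


def dense_s2_prediction(Su, Se, K, n_t, y_fo, Ys, beta_f=0.0, beta_s=None):
    """Scenario-2 oracle: E(U_f | Y_f,o, Y_s on all genotypes), assembled
    as the explicit block system with zero residual covariance between the
    focal training records and the secondary test records."""
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    n_o = n - n_t
    Ys = np.atleast_2d(np.asarray(Ys, dtype=float))
    s = Ys.shape[1]
    yc = np.asarray(y_fo, dtype=float) - beta_f
    Ysc = Ys - (0.0 if beta_s is None else np.asarray(beta_s))

    K_oo = K[n_t:, n_t:]
    K_o_all = K[n_t:, :]
    Rsel = np.zeros((n_o, n))
    Rsel[np.arange(n_o), n_t + np.arange(n_o)] = 1.0

    A = Su[0, 0] * K_oo + Se[0, 0] * np.eye(n_o)
    B = np.hstack([Su[0, 1 + j] * K_o_all + Se[0, 1 + j] * Rsel for j in range(s)])
    D = np.kron(Su[1:, 1:], K) + np.kron(Se[1:, 1:], np.eye(n))
    V = np.block([[A, B], [B.T, D]])
    c = np.concatenate([yc, Ysc.T.ravel()])
    C_all = np.hstack(
        [Su[0, 0] * K[:, n_t:]]
        + [Su[0, 1 + j] * K for j in range(s)]
    )
    u = C_all @ np.linalg.solve(V, c)
    return u[:n_t], u[n_t:]


def dense_reml_loglik(y, X, V):
    """Textbook REML log-likelihood of y ~ N(X beta, V)."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    Vi_X = np.linalg.solve(V, X)
    Vi_y = np.linalg.solve(V, y)
    xtvix = X.T @ Vi_X
    beta = np.linalg.solve(xtvix, X.T @ Vi_y)
    r = y - X @ beta
    nu = y.size - X.shape[1]
    return -0.5 * (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(xtvix)[1]
        + r @ np.linalg.solve(V, r)
        + nu * LOG2PI
    )


def lasso_coordinate_descent(X, y, alpha, n_iter=5000, tol=1e-12):
    """Naive LASSO solver matching sklearn's objective
    (1/(2n)) ||y - Xb||^2 + alpha ||b||_1 on centered data."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    b = np.zeros(p)
    col_ss = (X**2).sum(axis=0)
    r = y - y.mean()
    Xc = X
    for _ in range(n_iter):
        b_old = b.copy()
        for j in range(p):
            rho = Xc[:, j] @ (r + Xc[:, j] * b[j])
            bj = np.sign(rho) * max(abs(rho) - n * alpha, 0.0) / col_ss[j]
            r += Xc[:, j] * (b[j] - bj)
            b[j] = bj
        if np.max(np.abs(b - b_old)) < tol:
            break
    return b


def manova_cross_products_oracle(genotype, y, z):
    """Hand sums-of-cross-products genetic covariance for two traits."""
    genotype = np.asarray(genotype)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    groups = sorted(set(genotype.tolist()))
    g = len(groups)
    r = len(y) // g
    ym = {k: y[genotype == k].mean() for k in groups}
    zm = {k: z[genotype == k].mean() for k in groups}
    gy, gz = y.mean(), z.mean()
    msb = r * sum((ym[k] - gy) * (zm[k] - gz) for k in groups) / (g - 1)
    msw = sum(
        ((y[genotype == k] - ym[k]) * (z[genotype == k] - zm[k])).sum()
        for k in groups
    ) / (g * (r - 1))
    return (msb - msw) / r
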