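"""Structural-equation simulation of a focal trait and p secondary traits.

The generating model for each genotype i is the recursion

    y_i = y_i Lambda + g_i + r_i          (y_i a 1 x (p+1) row vector)

where Lambda holds the causal coefficients (trait k -> trait l in entry
(k, l)), g_i are direct genetic effects with covariance Sigma_g and row
covariance K across genotypes, and r_i are direct residuals with covariance
Sigma_r.  Solving the recursion with Gamma = (I - Lambda)^{-1} gives trait
values Y = (G + R) Gamma whose joint distribution is the multi-trait GBLUP
model with implied covariances

    Sigma_u = Gamma^T Sigma_g Gamma,   Sigma_e = Gamma^T Sigma_r Gamma.

The focal trait is Y_1 = lambda (Y_2 + Y_3 + Y_4) + G_1 + R_1: traits 2-4
are causal for the target with common effect size lambda; the remaining
p - 3 secondary traits are independent noise traits.  Direct genetic
variances are 0.2 (focal) and 0.7 (secondary); direct residual variances
0.8 and 0.3, so at lambda = 0 the focal and secondary heritabilities are
exactly 0.2 and 0.7.  rho_G and rho_E set the correlations of the direct
genetic and residual effects between the focal trait and each causal trait.

Genotypes are synthetic unlinked biallelic SNPs: per-SNP allele frequency
uniform on [maf_min, 0.5], dosages Binomial(2, freq) per individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import KinshipPartition, MarkerMatrix, compute_grm, partition_kinship
from .predict import PredictionResult, predict_multivariate_s1, predict_multivariate_s2
from .reml import CovarianceEstimate

__all__ = [
    "StructuralModel",
    "SimulatedDataset",
    "build_structural_model",
    "simulate_genotypes",
    "simulate_dataset",
    "simulate_plot_data",
    "benchmark_predict",
    "secondary_usefulness",
    "LAMBDA_GRID",
    "RHO_GRID",
]

#: the causal-effect and correlation grids of the simulation study
LAMBDA_GRID = (-1.0, -0.5, 0.0, 0.5, 1.0)
RHO_GRID = (-0.5, 0.0, 0.5)

N_CAUSAL = 3  # traits 2..4 affect the focal trait

VAR_G_FOCAL, VAR_G_SEC = 0.2, 0.7
VAR_R_FOCAL, VAR_R_SEC = 0.8, 0.3


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class StructuralModel:
    """Causal coefficients and the implied trait covariances."""

    lambda_causal: float
    rho_G: float
    rho_E: float
    p: int
    Lambda: np.ndarray = field(repr=False, default=None)
    Gamma: np.ndarray = field(repr=False, default=None)
    Sigma_g: np.ndarray = field(repr=False, default=None)
    Sigma_r: np.ndarray = field(repr=False, default=None)
    Sigma_u: np.ndarray = field(repr=False, default=None)
    Sigma_e: np.ndarray = field(repr=False, default=None)

    @property
    def q(self) -> int:
        return self.p + 1

    def h2(self, j: int = 0) -> float:
        """Implied narrow-sense heritability of trait j (0 = focal)."""
        return float(self.Sigma_u[j, j] / (self.Sigma_u[j, j] + self.Sigma_e[j, j]))

    @property
    def covariance_4trait(self) -> CovarianceEstimate:
        """True implied covariances restricted to the focal + causal traits."""
        idx = np.arange(N_CAUSAL + 1)
        return CovarianceEstimate(
            Sigma_u=self.Sigma_u[np.ix_(idx, idx)],
            Sigma_e=self.Sigma_e[np.ix_(idx, idx)],
            beta=np.zeros((N_CAUSAL + 1, 1)),  # true means are zero
            trait_names=[f"Y{j + 1}" for j in idx],
        )


def build_structural_model(
    lambda_causal: float, rho_G: float, rho_E: float, p: int = 300
) -> StructuralModel:
    """Assemble Lambda, Gamma and the direct/implied covariance matrices."""
    if p < N_CAUSAL:
        raise ValueError(f"need at least {N_CAUSAL} secondary traits")
    for name, rho in (("rho_G", rho_G), ("rho_E", rho_E)):
        if abs(rho) >= 1:
            raise ValueError(f"|{name}| must be < 1")
    q = p + 1
    Lam = np.zeros((q, q))
    Lam[1 : N_CAUSAL + 1, 0] = lambda_causal  # traits 2..4 -> trait 1
    Gam = np.linalg.inv(np.eye(q) - Lam)

    Sg = np.diag(np.r_[VAR_G_FOCAL, np.full(p, VAR_G_SEC)])
    Sr = np.diag(np.r_[VAR_R_FOCAL, np.full(p, VAR_R_SEC)])
    cg = rho_G * np.sqrt(VAR_G_FOCAL * VAR_G_SEC)
    ce = rho_E * np.sqrt(VAR_R_FOCAL * VAR_R_SEC)
    for k in range(1, N_CAUSAL + 1):
        Sg[0, k] = Sg[k, 0] = cg
        Sr[0, k] = Sr[k, 0] = ce
    for S, name in ((Sg, "Sigma_g"), (Sr, "Sigma_r")):
        if np.linalg.eigvalsh(S[: N_CAUSAL + 1, : N_CAUSAL + 1]).min() < -1e-10:
            raise ValueError(f"{name} is not positive semidefinite")

    Su = Gam.T @ Sg @ Gam
    Se = Gam.T @ Sr @ Gam
    return StructuralModel(
        lambda_causal=lambda_causal,
        rho_G=rho_G,
        rho_E=rho_E,
        p=p,
        Lambda=Lam,
        Gamma=Gam,
        Sigma_g=Sg,
        Sigma_r=Sr,
        Sigma_u=Su,
        Sigma_e=Se,
    )


def secondary_usefulness(model: StructuralModel) -> float:
    """h2 of a causal secondary trait times its squared direct genetic
    correlation with the focal trait -- the classical single-secondary-trait
    criterion for when a bivariate model beats univariate GBLUP."""
    return model.h2(1) * model.rho_G**2


def simulate_genotypes(
    n: int = 500, m: int = 1500, maf_min: float = 0.3, seed=None
) -> MarkerMatrix:
    """Unlinked biallelic SNPs: freq ~ U[maf_min, 0.5], dosage ~ Bin(2, freq)."""
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 individuals and m >= 1 SNPs")
    if not 0.0 < maf_min < 0.5:
        raise ValueError("maf_min must be in (0, 0.5)")
    rng = _rng(seed)
    freq = rng.uniform(maf_min, 0.5, size=m)
    dosages = rng.binomial(2, freq, size=(n, m)).astype(float)
    ids = np.array([f"g{i:04d}" for i in range(n)], dtype=object)
    snps = np.array([f"snp{j:05d}" for j in range(m)], dtype=object)
    return MarkerMatrix(dosages=dosages, genotype_ids=ids, snp_ids=snps)


@dataclass
class SimulatedDataset:
    """One simulated dataset: genotypes, kinship partition, traits, truth.

    ``Y``, ``U_true``, ``g`` and ``r`` are (n, p+1) arrays in the
    partition's canonical test-first genotype order; trait 0 is focal.
    """

    markers: MarkerMatrix | None
    kpart: KinshipPartition
    Y: np.ndarray
    U_true: np.ndarray
    g: np.ndarray
    r: np.ndarray
    model: StructuralModel
    seed: object = None

    @property
    def y_focal_train(self) -> np.ndarray:
        return self.Y[self.kpart.n_t :, 0]

    @property
    def u_focal_test(self) -> np.ndarray:
        return self.U_true[: self.kpart.n_t, 0]

    def secondary_frame(self, n_traits: int | None = None) -> pd.DataFrame:
        """Secondary traits as a genotype-indexed DataFrame (all genotypes)."""
        p = self.model.p if n_traits is None else n_traits
        return pd.DataFrame(
            self.Y[:, 1 : p + 1],
            index=self.kpart.ids,
            columns=[f"Y{j + 2}" for j in range(p)],
        )

    def phenotype_frame(self) -> pd.DataFrame:
        cols = [f"Y{j + 1}" for j in range(self.model.q)]
        return pd.DataFrame(self.Y, index=self.kpart.ids, columns=cols)


def _draw_residuals(model, n, rng):
    """Fresh direct residual draws r ~ N(0, Sigma_r), (n, p+1)."""
    q = model.q
    b = N_CAUSAL + 1
    cr = np.linalg.cholesky(model.Sigma_r[:b, :b])
    r = np.empty((n, q))
    r[:, :b] = rng.standard_normal((n, b)) @ cr.T
    if q > b:
        r[:, b:] = rng.standard_normal((n, q - b)) * np.sqrt(VAR_R_SEC)
    return r


def _draw_effects(model, L_row, n, rng, full_draw):
    """Direct genetic (row-correlated) and residual draws, (n, p+1) each.

    Only the focal + causal block is correlated across traits; the other
    secondary traits are independent, so they are drawn separately unless
    ``full_draw`` forces the full (p+1)-dimensional factorisation.
    """
    q = model.q
    if full_draw:
        cg = np.linalg.cholesky(model.Sigma_g + 1e-12 * np.eye(q))
        cr = np.linalg.cholesky(model.Sigma_r + 1e-12 * np.eye(q))
        g = L_row @ rng.standard_normal((n, q)) @ cg.T
        r = rng.standard_normal((n, q)) @ cr.T
        return g, r
    b = N_CAUSAL + 1
    cg = np.linalg.cholesky(model.Sigma_g[:b, :b])
    cr = np.linalg.cholesky(model.Sigma_r[:b, :b])
    g = np.empty((n, q))
    r = np.empty((n, q))
    g[:, :b] = L_row @ rng.standard_normal((n, b)) @ cg.T
    r[:, :b] = rng.standard_normal((n, b)) @ cr.T
    if q > b:
        g[:, b:] = L_row @ rng.standard_normal((n, q - b)) * np.sqrt(VAR_G_SEC)
        r[:, b:] = rng.standard_normal((n, q - b)) * np.sqrt(VAR_R_SEC)
    return g, r


def simulate_dataset(
    model: StructuralModel,
    n: int = 500,
    n_test: int = 100,
    *,
    markers: MarkerMatrix | None = None,
    kinship: pd.DataFrame | None = None,
    m: int = 1500,
    maf_min: float = 0.3,
    seed=None,
    full_draw: bool = False,
) -> SimulatedDataset:
    """Simulate genotypes (unless given), kinship, and all trait values.

    Genetic effects are drawn from the kernel model N(0, Sigma_g x K), so
    the simulated data follow exactly the multi-trait GBLUP model that the
    predictors assume (with Sigma_u = Gamma^T Sigma_g Gamma).
    """
    rng = _rng(seed)
    if kinship is None:
        if markers is None:
            markers = simulate_genotypes(n, m, maf_min, seed=rng)
        kinship = compute_grm(markers)
    n = kinship.shape[0]
    if not 0 < n_test < n:
        raise ValueError("need 0 < n_test < n")
    test_ids = rng.choice(kinship.index.to_numpy(), size=n_test, replace=False)
    kpart = partition_kinship(kinship, test_ids)
    L = kpart.sqrt_full()
    g, r = _draw_effects(model, L, n, rng, full_draw)
    Y = (g + r) @ model.Gamma
    U = g @ model.Gamma
    return SimulatedDataset(
        markers=markers,
        kpart=kpart,
        Y=Y,
        U_true=U,
        g=g,
        r=r,
        model=model,
        seed=seed,
    )


def simulate_plot_data(
    dataset: SimulatedDataset,
    n_reps: int = 2,
    *,
    genotypes: str = "train",
    n_traits: int | None = None,
    seed=None,
) -> pd.DataFrame:
    """Plot-level replicated records: the genotype's direct genetic effects
    with fresh residual draws per replicate, propagated through Gamma.

    Returns columns: genotype, rep, Y1, Y2, ... (Y1 = focal).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = _rng(seed)
    model = dataset.model
    kp = dataset.kpart
    if genotypes == "train":
        rows = np.arange(kp.n_t, kp.n)
        ids = kp.train_ids
    elif genotypes == "all":
        rows = np.arange(kp.n)
        ids = kp.ids
    else:
        raise ValueError("genotypes must be 'train' or 'all'")
    q = model.q
    keep = q if n_traits is None else n_traits + 1
    frames = []
    for rep in range(n_reps):
        r_new = _draw_residuals(model, len(rows), rng)
        y_rep = (dataset.g[rows] + r_new) @ model.Gamma
        df = pd.DataFrame(
            y_rep[:, :keep], columns=[f"Y{j + 1}" for j in range(keep)]
        )
        df.insert(0, "rep", rep + 1)
        df.insert(0, "genotype", ids)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def benchmark_predict(dataset: SimulatedDataset, scenario: int) -> PredictionResult:
    """Oracle multivariate GBLUP on traits Y1-Y4 with the true (simulated)
    variance components -- no REML, true zero means."""
    cov = dataset.model.covariance_4trait
    kp = dataset.kpart
    if scenario == 1:
        Y_o = dataset.Y[kp.n_t :, : N_CAUSAL + 1]
        res = predict_multivariate_s1(cov, Y_o, kp, method="benchmark", scenario=1)
    elif scenario == 2:
        res = predict_multivariate_s2(
            cov,
            dataset.Y[kp.n_t :, 0],
            dataset.Y[:, 1 : N_CAUSAL + 1],
            kp,
            method="benchmark",
            scenario=2,
        )
    else:
        raise ValueError("scenario must be 1 or 2")
    return res
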