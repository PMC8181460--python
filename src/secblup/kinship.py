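"""Genomic relationship matrices and their train/test partition.

The central object is :class:`KinshipPartition`, which stores the n x n
relatedness matrix ``K`` in a canonical *test-first* genotype order and exposes
the blocks

    K = [[K_tt, K_to],
         [K_ot, K_oo]]

where ``o`` indexes the training genotypes (target trait observed) and ``t``
the test genotypes (to be predicted).  All downstream predictors index
genotypes by label, never by position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "KinshipPartition",
    "compute_grm",
    "partition_kinship",
    "ridge_repair",
]

#: tolerance below which a negative eigenvalue is treated as numerical noise
PSD_TOL = 1e-8


@dataclass
class MarkerMatrix:
    """Biallelic marker dosages (individuals x SNPs, values 0/1/2)."""

    dosages: np.ndarray
    genotype_ids: np.ndarray
    snp_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.genotype_ids = np.asarray(self.genotype_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        n, m = self.dosages.shape
        if len(self.genotype_ids) != n or len(self.snp_ids) != m:
            raise ValueError("id lengths do not match dosage matrix shape")
        if len(set(self.genotype_ids)) != n:
            raise ValueError("duplicate genotype ids")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP ids")
        if np.isnan(self.dosages).any():
            raise ValueError(
                "missing dosages are not supported; impute upstream before "
                "constructing a MarkerMatrix"
            )
        if not np.isin(self.dosages, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be coded 0/1/2")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Observed alternate-allele frequency per SNP."""
        return self.dosages.mean(axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        """Observed minor allele frequency per SNP."""
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages.astype(int), index=self.genotype_ids, columns=self.snp_ids
        )


def compute_grm(markers: MarkerMatrix) -> pd.DataFrame:
    """VanRaden genomic relationship matrix from 0/1/2 dosages.

    K = Z_c Z_c^T / (2 * sum_j p_j (1 - p_j)) with column-centered dosages
    Z_c and observed allele frequencies p_j.  Monomorphic SNPs contribute
    nothing to either numerator or denominator, so adding one leaves the
    matrix unchanged.
    """
    if markers.n < 2:
        raise ValueError("need at least 2 individuals")
    p = markers.allele_freq
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("zero denominator: all SNPs are monomorphic")
    zc = markers.dosages - 2.0 * p
    k = (zc @ zc.T) / denom
    k = 0.5 * (k + k.T)  # exact symmetry
    return pd.DataFrame(k, index=markers.genotype_ids, columns=markers.genotype_ids)


def ridge_repair(K: pd.DataFrame, epsilon: float = 1e-6) -> pd.DataFrame:
    """Add ``epsilon`` to the diagonal so that downstream solves are stable."""
    out = K.copy()
    out.values[np.diag_indices_from(out.values)] += epsilon
    return out


@dataclass
class KinshipPartition:
    """Relatedness matrix with a train/test block structure.

    ``K`` is stored in test-first order: rows/columns 0..n_t-1 are the test
    genotypes, the rest the training genotypes.  ``original_ids`` remembers
    the genotype order of the matrix the partition was built from, so the
    partition can be inverted exactly.
    """

    K: np.ndarray
    test_ids: np.ndarray
    train_ids: np.ndarray
    original_ids: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        self.test_ids = np.asarray(self.test_ids, dtype=object)
        self.train_ids = np.asarray(self.train_ids, dtype=object)
        n = len(self.test_ids) + len(self.train_ids)
        if self.K.shape != (n, n):
            raise ValueError("K shape does not match number of ids")
        if len(set(self.test_ids) | set(self.train_ids)) != n:
            raise ValueError("duplicate ids across test/train sets")
        asym = np.max(np.abs(self.K - self.K.T)) if n else 0.0
        if asym > PSD_TOL:
            raise ValueError(f"K is not symmetric (max |K - K^T| = {asym:.3g})")
        self.K = 0.5 * (self.K + self.K.T)
        if self.original_ids is None:
            self.original_ids = self.ids.copy()

    # -- basic geometry ---------------------------------------------------
    @property
    def n_t(self) -> int:
        return len(self.test_ids)

    @property
    def n_o(self) -> int:
        return len(self.train_ids)

    @property
    def n(self) -> int:
        return self.n_t + self.n_o

    @property
    def ids(self) -> np.ndarray:
        """All genotype ids in the canonical test-first order."""
        return np.concatenate([self.test_ids, self.train_ids])

    # -- blocks -----------------------------------------------------------
    @property
    def K_tt(self) -> np.ndarray:
        return self.K[: self.n_t, : self.n_t]

    @property
    def K_to(self) -> np.ndarray:
        return self.K[: self.n_t, self.n_t :]

    @property
    def K_ot(self) -> np.ndarray:
        return self.K[self.n_t :, : self.n_t]

    @property
    def K_oo(self) -> np.ndarray:
        return self.K[self.n_t :, self.n_t :]

    @property
    def K_t_all(self) -> np.ndarray:
        """K_t. = [K_tt K_to], relating test genotypes to everybody."""
        return self.K[: self.n_t, :]

    @property
    def K_o_all(self) -> np.ndarray:
        """K_o. = [K_ot K_oo]."""
        return self.K[self.n_t :, :]

    # -- spectral helpers (cached) ----------------------------------------
    def check_psd(self, tol: float = PSD_TOL) -> None:
        w = self.eigh_full()[0]
        if w.min() < -tol:
            raise ValueError(
                f"K is not positive semidefinite (min eigenvalue {w.min():.3g}); "
                "consider ridge_repair()"
            )

    def eigh_full(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigendecomposition of the full (test-first ordered) K."""
        if "eig_full" not in self._cache:
            self._cache["eig_full"] = np.linalg.eigh(self.K)
        return self._cache["eig_full"]

    def eigh_oo(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigendecomposition of the training block K_oo."""
        if "eig_oo" not in self._cache:
            self._cache["eig_oo"] = np.linalg.eigh(self.K_oo)
        return self._cache["eig_oo"]

    def sqrt_full(self) -> np.ndarray:
        """A matrix L with L L^T = K (eigenvalue square root, PSD-clipped)."""
        if "sqrt_full" not in self._cache:
            w, q = self.eigh_full()
            self._cache["sqrt_full"] = q * np.sqrt(np.clip(w, 0.0, None))
        return self._cache["sqrt_full"]

    # -- reassembly -------------------------------------------------------
    def to_frame(self, order: str = "original") -> pd.DataFrame:
        """Reassemble K as a labeled matrix, in 'original' or 'testfirst' order."""
        df = pd.DataFrame(self.K, index=self.ids, columns=self.ids)
        if order == "testfirst":
            return df
        if order == "original":
            return df.loc[self.original_ids, self.original_ids]
        raise ValueError(f"unknown order {order!r}")


def partition_kinship(
    K: pd.DataFrame,
    test_ids,
    *,
    check_psd: bool = False,
    repair: bool = False,
    epsilon: float = 1e-6,
) -> KinshipPartition:
    """Partition a labeled kinship matrix into train/test blocks.

    Parameters
    ----------
    K : square DataFrame with matching row/column labels.
    test_ids : labels of the genotypes to be predicted.  The remaining
        genotypes form the training set (must be nonempty).
    repair : if True, add ``epsilon`` to the diagonal before partitioning
        (downstream solvers require an invertible K_oo).
    """
    if not K.index.equals(K.columns):
        raise ValueError("kinship row and column labels differ")
    ids = list(K.index)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genotype ids in kinship")
    test_ids = list(test_ids)
    if len(set(test_ids)) != len(test_ids):
        raise ValueError(f"duplicate id in test set: {sorted(test_ids)}")
    unknown = [g for g in test_ids if g not in K.index]
    if unknown:
        raise ValueError(f"test ids absent from kinship: {unknown}")
    train_ids = [g for g in ids if g not in set(test_ids)]
    if not train_ids:
        raise ValueError("training set is empty")
    if repair:
        K = ridge_repair(K, epsilon)
    order = test_ids + train_ids
    part = KinshipPartition(
        K=K.loc[order, order].to_numpy(dtype=float),
        test_ids=np.array(test_ids, dtype=object),
        train_ids=np.array(train_ids, dtype=object),
        original_ids=np.array(ids, dtype=object),
    )
    if check_psd:
        part.check_psd()
    return part
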