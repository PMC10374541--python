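"""Henderson's mixed-model equations for the additive+dominance GBLUP model.

The model is ``y = 1 mu + g_A + g_D + e`` with ``g_A ~ N(0, sigma2_A K_A)``,
``g_D ~ N(0, sigma2_D K_D)`` and ``e ~ N(0, sigma2_e I)``.  With one record
per hybrid the BLUE of mu and the BLUPs of g_A, g_D solve the symmetric
(2n+1) x (2n+1) system

    [ n    1'            1'          ] [mu  ]   [1'y]
    [ 1    I + K_A^-1 lA  I          ] [g_A ] = [y  ]
    [ 1    I             I + K_D^-1 lD] [g_D ]   [y  ]

where ``lA = sigma2_e / sigma2_A`` and ``lD = sigma2_e / sigma2_D``.
Breeding-population BLUPs follow by projecting the training BLUPs through
the cross-relationship blocks, and the per-hybrid GEBV is
``mu + g_A^(bp) + g_D^(bp)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import DataError, NumericalError
from .kinship import KinshipSet
from .markers import DiallelFrame


@dataclass
class Phenotypes:
    """Trait values for the training hybrids, one record per hybrid."""

    hybrid_ids: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        if len(self.hybrid_ids) != self.y.size:
            raise DataError("phenotype ids and values differ in length")
        if self.y.size < 2:
            raise DataError("need at least 2 phenotyped hybrids")
        if len(set(self.hybrid_ids)) != len(self.hybrid_ids):
            raise DataError(
                "duplicate hybrid ids in phenotypes; pre-average repeated "
                "records to one value per hybrid"
            )
        if not np.isfinite(self.y).all():
            raise DataError("non-finite phenotype values")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def sample_mean(self) -> float:
        return float(self.y.mean())

    @property
    def sample_variance(self) -> float:
        return float(self.y.var(ddof=1))


@dataclass
class MMESystem:
    """Assembled coefficient matrix and right-hand side of Henderson's system."""

    C: np.ndarray
    gamma: np.ndarray
    n: int
    lambda_A: float
    lambda_D: float

    def block(self, i: int, j: int) -> np.ndarray:
        """Return block C_ij of the 3x3 partition (1-based, dims (1, n, n))."""
        edges = [0, 1, 1 + self.n, 1 + 2 * self.n]
        return self.C[edges[i - 1] : edges[i], edges[j - 1] : edges[j]]

    def gamma_block(self, i: int) -> np.ndarray:
        edges = [0, 1, 1 + self.n, 1 + 2 * self.n]
        return self.gamma[edges[i - 1] : edges[i]]


@dataclass
class MMESolution:
    """BLUE of the intercept and BLUPs of the genetic effects."""

    mu_hat: float
    g_A_hat: np.ndarray
    g_D_hat: np.ndarray

    def __post_init__(self) -> None:
        if not (
            np.isfinite(self.mu_hat)
            and np.isfinite(self.g_A_hat).all()
            and np.isfinite(self.g_D_hat).all()
        ):
            raise NumericalError("non-finite entries in MME solution")


def heritability(sigma2_A: float, sigma2_D: float, sigma2_e: float) -> float:
    """Genomic heritability (sigma2_A + sigma2_D) / (sigma2_A + sigma2_D + sigma2_e)."""
    if sigma2_A < 0 or sigma2_D < 0 or sigma2_e < 0:
        raise DataError("variance components must be nonnegative")
    total = sigma2_A + sigma2_D + sigma2_e
    if total <= 0:
        raise DataError("all variance components are zero")
    return (sigma2_A + sigma2_D) / total


@dataclass
class VarianceComponents:
    """Additive, dominance and residual variances with derived heritability."""

    sigma2_A: float
    sigma2_D: float
    sigma2_e: float

    def __post_init__(self) -> None:
        if self.sigma2_A < 0 or self.sigma2_D < 0 or self.sigma2_e < 0:
            raise DataError("variance components must be nonnegative")

    @property
    def h2(self) -> float:
        return heritability(self.sigma2_A, self.sigma2_D, self.sigma2_e)

    @property
    def lambda_A(self) -> float:
        if self.sigma2_A <= 0:
            raise DataError("sigma2_A must be positive to form lambda_A")
        return self.sigma2_e / self.sigma2_A

    @property
    def lambda_D(self) -> float:
        if self.sigma2_D <= 0:
            raise DataError("sigma2_D must be positive to form lambda_D")
        return self.sigma2_e / self.sigma2_D


def assemble_mme(
    pheno: Phenotypes,
    K_A_inv: np.ndarray,
    K_D_inv: np.ndarray,
    lambda_A: float,
    lambda_D: float,
) -> MMESystem:
    """Build the (2n+1) x (2n+1) Henderson system for given variance ratios."""
    n = pheno.n
    if lambda_A <= 0 or lambda_D <= 0:
        raise DataError("lambda_A and lambda_D must be positive")
    if K_A_inv.shape != (n, n) or K_D_inv.shape != (n, n):
        raise DataError(f"kinship inverses must be {n}x{n}")
    ones = np.ones((n, 1))
    eye = np.eye(n)
    C = np.block(
        [
            [np.array([[float(n)]]), ones.T, ones.T],
            [ones, eye + K_A_inv * lambda_A, eye],
            [ones, eye, eye + K_D_inv * lambda_D],
        ]
    )
    C = (C + C.T) / 2.0
    gamma = np.concatenate(([pheno.y.sum()], pheno.y, pheno.y))
    return MMESystem(C, gamma, n, float(lambda_A), float(lambda_D))


def solve_mme(system: MMESystem) -> MMESolution:
    """Solve the Henderson system by a symmetric factorization of C."""
    try:
        x = linalg.solve(system.C, system.gamma, assume_a="sym")
    except linalg.LinAlgError as exc:
        raise NumericalError(
            "singular mixed-model system; increase the kinship ridge"
        ) from exc
    if not np.isfinite(x).all():
        raise NumericalError(
            "non-finite mixed-model solution; increase the kinship ridge"
        )
    n = system.n
    return MMESolution(float(x[0]), x[1 : n + 1], x[n + 1 :])


@dataclass
class BreedingPrediction:
    """Predicted additive/dominance effects and GEBVs for a breeding population."""

    frame: DiallelFrame
    g_A_bp: np.ndarray
    g_D_bp: np.ndarray
    mu_hat: float
    gebv: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.g_A_bp.shape != (self.frame.N1,) or self.g_D_bp.shape != (
            self.frame.N1,
        ):
            raise DataError("predicted effect vectors must have length N1")
        self.gebv = self.mu_hat + self.g_A_bp + self.g_D_bp

    def to_frame(self) -> pd.DataFrame:
        names = self.frame.pair_names()
        return pd.DataFrame(
            {
                "hybrid_id": self.frame.hybrid_ids,
                "parent_i": [a for a, _ in names],
                "parent_j": [b for _, b in names],
                "gebv": self.gebv,
                "g_A": self.g_A_bp,
                "g_D": self.g_D_bp,
            }
        )


def predict_breeding(
    sol: MMESolution, kin: KinshipSet, frame: DiallelFrame
) -> BreedingPrediction:
    """Project training BLUPs onto the breeding population.

    ``g_A^(bp) = K_A^(bp) K_A^-1 g_A`` and likewise for dominance; the GEBV
    of each hybrid is ``mu + g_A^(bp) + g_D^(bp)``.
    """
    if kin.K_A_bp is None or kin.K_D_bp is None:
        raise DataError("kinship set lacks breeding-population cross blocks")
    if kin.K_A_bp.shape[0] != frame.N1:
        raise DataError(
            f"cross block has {kin.K_A_bp.shape[0]} rows but frame has {frame.N1} pairs"
        )
    g_A_bp = kin.K_A_bp @ (kin.K_A_inv @ sol.g_A_hat)
    g_D_bp = kin.K_D_bp @ (kin.K_D_inv @ sol.g_D_hat)
    return BreedingPrediction(frame, g_A_bp, g_D_bp, sol.mu_hat)
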