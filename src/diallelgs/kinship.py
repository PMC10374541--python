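"""Genomic relationship matrices (GRMs) and numerically safe inversion.

The additive GRM is ``K_A = (1/p) X_A X_A'`` over standardized additive
scores, and likewise ``K_D`` for dominance.  Rectangular cross-blocks
``K^(bp)`` relate a breeding population (e.g. all half-diallel hybrids) to
the training population and drive GEBV prediction for unphenotyped crosses.

Dominance GRMs built from few hybrids are frequently rank-deficient, so the
inverse required by the mixed-model equations and the Gibbs sampler is
computed through a Cholesky factorization with an escalating diagonal ridge
rather than a silent pseudo-inverse; the ridge actually applied is recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .errors import DataError, NumericalError
from .markers import CodedMarkers

logger = logging.getLogger(__name__)


def grm(X: np.ndarray) -> np.ndarray:
    """Genomic relationship matrix ``(1/p) X X'`` from a standardized score matrix."""
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if p == 0:
        raise DataError("cannot build a GRM from zero markers")
    K = (X @ X.T) / p
    return (K + K.T) / 2.0  # enforce exact symmetry


def cross_grm(X_bp: np.ndarray, X_train: np.ndarray) -> np.ndarray:
    """Rectangular relationship block ``(1/p) X_bp X_train'`` between populations."""
    X_bp = np.asarray(X_bp, dtype=float)
    X_train = np.asarray(X_train, dtype=float)
    if X_bp.shape[1] != X_train.shape[1]:
        raise DataError(
            f"marker count mismatch: {X_bp.shape[1]} vs {X_train.shape[1]}"
        )
    if X_train.shape[1] == 0:
        raise DataError("cannot build a GRM from zero markers")
    return (X_bp @ X_train.T) / X_train.shape[1]


def stabilized_inverse(
    K: np.ndarray, ridge_scale: float = 1e-6, max_attempts: int = 10
) -> tuple[np.ndarray, float]:
    """Invert a symmetric PSD matrix, adding a diagonal ridge only if needed.

    Tries a Cholesky-based inverse of ``K``; on failure adds
    ``ridge_scale * mean(diag(K))`` to the diagonal and retries, doubling the
    ridge up to ``max_attempts`` times.  Returns the inverse and the ridge
    actually applied (0.0 when none was needed).
    """
    K = np.asarray(K, dtype=float)
    if K.shape[0] != K.shape[1]:
        raise DataError("K must be square")
    if not np.allclose(K, K.T, atol=1e-8):
        raise DataError("K must be symmetric")
    base = ridge_scale * float(np.mean(np.diag(K)))
    if base <= 0:
        base = ridge_scale if ridge_scale > 0 else 1e-6
    ridge = 0.0
    eye = np.eye(K.shape[0])
    for attempt in range(max_attempts + 1):
        try:
            c, low = linalg.cho_factor(K + ridge * eye, lower=True)
            inv = linalg.cho_solve((c, low), eye)
            if ridge > 0:
                logger.info("GRM inverse required ridge %.3g", ridge)
            return (inv + inv.T) / 2.0, ridge
        except linalg.LinAlgError:
            ridge = base if ridge == 0.0 else 2.0 * ridge
    raise NumericalError(
        f"matrix still not positive definite after ridge {ridge:.3g}"
    )


@dataclass
class KinshipSet:
    """Additive and dominance GRMs for a training set, plus cross-blocks.

    ``K_A`` / ``K_D`` are the n x n training GRMs with cached stabilized
    inverses; ``K_A_bp`` / ``K_D_bp`` are the optional N1 x n blocks linking
    breeding-population hybrids to the training rows.
    """

    K_A: np.ndarray
    K_D: np.ndarray
    K_A_inv: np.ndarray
    K_D_inv: np.ndarray
    K_A_bp: np.ndarray | None = None
    K_D_bp: np.ndarray | None = None
    ridge_A: float = 0.0
    ridge_D: float = 0.0

    def __post_init__(self) -> None:
        n = self.K_A.shape[0]
        for name, M in (("K_A", self.K_A), ("K_D", self.K_D)):
            if M.shape != (n, n):
                raise DataError(f"{name} must be {n}x{n}")
            if not np.allclose(M, M.T, atol=1e-8):
                raise DataError(f"{name} is not symmetric")
        for name, M in (("K_A_bp", self.K_A_bp), ("K_D_bp", self.K_D_bp)):
            if M is not None and M.shape[1] != n:
                raise DataError(f"{name} must have {n} columns")

    @property
    def n_train(self) -> int:
        return self.K_A.shape[0]

    @property
    def ridge_used(self) -> float:
        return max(self.ridge_A, self.ridge_D)


def build_kinship(
    coded: CodedMarkers,
    train_rows: np.ndarray,
    bp_rows: np.ndarray | None = None,
    ridge_scale: float = 1e-6,
) -> KinshipSet:
    """Assemble the GRMs and inverses for a training/breeding row split.

    ``train_rows`` and ``bp_rows`` index rows of the shared coded matrices,
    which must have been standardized over one common reference set so the
    square and cross blocks live on the same scale.
    """
    XA_t, XD_t = coded.X_A[train_rows], coded.X_D[train_rows]
    K_A, K_D = grm(XA_t), grm(XD_t)
    K_A_inv, ridge_A = stabilized_inverse(K_A, ridge_scale)
    K_D_inv, ridge_D = stabilized_inverse(K_D, ridge_scale)
    # keep K and K^-1 an exact pair: work with the ridged matrix when needed
    if ridge_A > 0:
        K_A = K_A + ridge_A * np.eye(K_A.shape[0])
    if ridge_D > 0:
        K_D = K_D + ridge_D * np.eye(K_D.shape[0])
    K_A_bp = K_D_bp = None
    if bp_rows is not None:
        if np.array_equal(np.asarray(bp_rows), np.asarray(train_rows)):
            # breeding set == training set: reuse the (possibly ridged) square
            # GRMs so K^(bp) K^-1 is exactly the identity
            K_A_bp, K_D_bp = K_A.copy(), K_D.copy()
        else:
            K_A_bp = cross_grm(coded.X_A[bp_rows], XA_t)
            K_D_bp = cross_grm(coded.X_D[bp_rows], XD_t)
    return KinshipSet(
        K_A, K_D, K_A_inv, K_D_inv, K_A_bp, K_D_bp, ridge_A, ridge_D
    )
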