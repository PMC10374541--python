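"""Synthetic diallel data, the simulation-study harness, and cross-validation.

The generator emulates the data a half-diallel hybrid breeding program
produces: a panel of fully homozygous inbred parents with a uniform MAF
spectrum, F1 hybrid genotypes synthesized for every cross, and phenotypes
drawn from the additive+dominance GBLUP model
``y = 1 mu + g_A + g_D + e`` with the stated variance components.  On top of
it sit two protocol harnesses: a repeated-phenotype simulation study that
measures bias and dispersion of a variance-component estimator on a fixed
kinship, and a k-fold cross-validation of GEBV prediction accuracy in which
marker standardization and kinship are recomputed from the training rows of
each fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import DataError, NumericalError
from .kinship import KinshipSet, build_kinship
from .markers import (
    HYBRID,
    PARENTAL_INBRED,
    DiallelFrame,
    MarkerPanel,
    code_and_standardize,
    enumerate_half_diallel,
    synthesize_hybrids,
)
from .mme import Phenotypes, VarianceComponents

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


@dataclass
class SimSpec:
    """Conditions for one synthetic diallel scenario.

    ``vc`` and ``mu`` are the generating model parameters; ``maf_range``
    bounds the per-marker minor-allele frequencies of the parental panel.
    """

    N0: int
    p: int
    vc: VarianceComponents
    mu: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N0 < 3:
            raise DataError("need at least 3 parents")
        if self.p < 1:
            raise DataError("need at least 1 marker")
        low, high = self.maf_range
        if not (0 < low <= high <= 0.5):
            raise DataError("maf_range bounds must satisfy 0 < low <= high <= 0.5")
        if self.n_replicates < 1:
            raise DataError("n_replicates must be >= 1")


def simulate_parents(spec: SimSpec) -> MarkerPanel:
    """Draw a panel of inbred parental lines.

    Each marker gets a minor-allele frequency uniform in ``maf_range``; each
    parent is homozygous, carrying dosage 2 with probability equal to the
    major-allele frequency and dosage 0 otherwise, independently across
    parents and markers.  Columns that come out monomorphic are redrawn.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.N0, spec.p
    low, high = spec.maf_range
    dos = np.empty((n, p))
    todo = np.arange(p)
    while todo.size:
        maf = rng.uniform(low, high, todo.size)
        draw = np.where(rng.random((n, todo.size)) < (1.0 - maf), 2.0, 0.0)
        dos[:, todo] = draw
        mono = (draw == draw[0]).all(axis=0)
        todo = todo[mono]
    ids = [f"P{k + 1:03d}" for k in range(n)]
    markers = [f"snp{k + 1}" for k in range(p)]
    return MarkerPanel(ids, markers, dos, PARENTAL_INBRED)


def _psd_factor(K: np.ndarray, name: str) -> np.ndarray:
    """Square root of a PSD matrix via eigendecomposition with clipping."""
    s, U = linalg.eigh((K + K.T) / 2.0)
    tol = 1e-8 * max(float(np.trace(K)), 1.0)
    if s.min() < -tol:
        raise NumericalError(f"{name} is indefinite (min eigenvalue {s.min():.3g})")
    return U * np.sqrt(np.clip(s, 0.0, None))


def simulate_phenotypes(
    kin: KinshipSet,
    vc: VarianceComponents,
    mu: float,
    seed: int,
    hybrid_ids: list[str] | None = None,
) -> Phenotypes:
    """Draw phenotypes from the generating model on a fixed kinship.

    ``y = 1 mu + g_A + g_D + e`` with ``g_A ~ N(0, sigma2_A K_A)``,
    ``g_D ~ N(0, sigma2_D K_D)`` and iid residuals.
    """
    rng = np.random.default_rng(seed)
    n = kin.n_train
    y = np.full(n, float(mu))
    if vc.sigma2_A > 0:
        y += np.sqrt(vc.sigma2_A) * (_psd_factor(kin.K_A, "K_A") @ rng.standard_normal(n))
    if vc.sigma2_D > 0:
        y += np.sqrt(vc.sigma2_D) * (_psd_factor(kin.K_D, "K_D") @ rng.standard_normal(n))
    if vc.sigma2_e > 0:
        y += np.sqrt(vc.sigma2_e) * rng.standard_normal(n)
    ids = hybrid_ids if hybrid_ids is not None else [f"H{k + 1}" for k in range(n)]
    return Phenotypes(list(ids), y)


@dataclass
class DiallelDataset:
    """A fully synthesized diallel: parents, hybrids, coding and kinship."""

    parents: MarkerPanel
    frame: DiallelFrame
    hybrids: MarkerPanel
    kin: KinshipSet


def make_diallel_dataset(spec: SimSpec) -> DiallelDataset:
    """Parents -> all C(N0,2) hybrids -> coded markers -> kinship.

    All hybrids serve as the training set; coding and standardization use
    the full hybrid population as the reference.
    """
    parents = simulate_parents(spec)
    frame = enumerate_half_diallel(parents.individual_ids)
    hybrids = synthesize_hybrids(parents, frame)
    coded, _ = code_and_standardize(hybrids)
    train_rows = np.arange(frame.N1)
    kin = build_kinship(coded, train_rows, bp_rows=train_rows)
    return DiallelDataset(parents, frame, hybrids, kin)


def run_simulation_study(
    spec: SimSpec, estimator
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Repeated-phenotype study of a variance-component estimator.

    A single synthetic diallel fixes the kinship; ``n_replicates`` phenotype
    sets are drawn from the generating variance components and fed to
    ``estimator(pheno, kin, seed) -> (VarianceComponents, ...)``.  Returns
    the per-replicate estimates and, per component, bias (mean estimate
    minus generating value) and standard deviation.
    """
    data = make_diallel_dataset(spec)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for _ in range(spec.n_replicates):
        pheno_seed = int(rng.integers(_SEED_MOD))
        est_seed = int(rng.integers(_SEED_MOD))
        pheno = simulate_phenotypes(
            data.kin, spec.vc, spec.mu, pheno_seed, data.frame.hybrid_ids
        )
        vc_hat = estimator(pheno, data.kin, est_seed)[0]
        rows.append(
            {
                "sigma2_A": vc_hat.sigma2_A,
                "sigma2_D": vc_hat.sigma2_D,
                "sigma2_e": vc_hat.sigma2_e,
                "h2": vc_hat.h2,
            }
        )
    estimates = pd.DataFrame(rows)
    truth = {
        "sigma2_A": spec.vc.sigma2_A,
        "sigma2_D": spec.vc.sigma2_D,
        "sigma2_e": spec.vc.sigma2_e,
        "h2": spec.vc.h2,
    }
    summary = {
        name: {
            "truth": truth[name],
            "mean": float(estimates[name].mean()),
            "bias": float(estimates[name].mean() - truth[name]),
            "sd": float(estimates[name].std(ddof=1)) if len(estimates) > 1 else 0.0,
        }
        for name in truth
    }
    return estimates, summary


@dataclass
class CVResult:
    """Fold-wise GEBV prediction accuracies from repeated k-fold CV."""

    correlations: np.ndarray  # length n_folds * n_repeats; nan = undefined fold
    n_folds: int
    n_repeats: int

    @property
    def valid(self) -> np.ndarray:
        return self.correlations[~np.isnan(self.correlations)]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.correlations).sum())

    @property
    def mean_r(self) -> float:
        return float(self.valid.mean())

    @property
    def sd_r(self) -> float:
        return float(self.valid.std(ddof=1))


def cross_validate(
    pheno: Phenotypes,
    panel: MarkerPanel,
    estimator,
    n_folds: int = 10,
    n_repeats: int = 5,
    seed: int = 0,
) -> CVResult:
    """Repeated k-fold cross-validation of GEBV prediction accuracy.

    Per repeat, the hybrids are partitioned at random into ``n_folds``
    clusters of near-equal size (differing by at most one); each cluster
    serves once as the test set.  Within a fold, marker orientation,
    standardization and kinship are recomputed from the training rows only,
    the model is fitted by ``estimator(pheno_train, kin, seed)``, and the
    held-out GEBVs are obtained through the cross-relationship blocks.
    Pearson's r between predicted and observed test values is recorded per
    fold; a fold with zero variance on either side is recorded as missing.

    ``panel`` must hold the (imputed) hybrid genotypes in the same row
    order as ``pheno``.
    """
    if panel.ploidy_role != HYBRID:
        raise DataError("cross_validate expects a hybrid genotype panel")
    if panel.individual_ids != pheno.hybrid_ids:
        raise DataError("genotype and phenotype ids must match in order")
    n = pheno.n
    if n < n_folds:
        raise DataError(f"cannot split {n} hybrids into {n_folds} folds")
    rng = np.random.default_rng(seed)
    correlations = []
    for rep in range(n_repeats):
        order = rng.permutation(n)
        folds = np.array_split(order, n_folds)
        for fold_idx, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(order, test_idx)
            est_seed = int(rng.integers(_SEED_MOD))
            coded, _ = code_and_standardize(
                panel, reference_rows=train_idx, drop_zero_variance=True
            )
            kin = build_kinship(coded, train_idx, bp_rows=test_idx)
            pheno_train = Phenotypes(
                [pheno.hybrid_ids[k] for k in train_idx], pheno.y[train_idx]
            )
            vc_hat, sol = estimator(pheno_train, kin, est_seed)[:2]
            gebv = (
                sol.mu_hat
                + kin.K_A_bp @ (kin.K_A_inv @ sol.g_A_hat)
                + kin.K_D_bp @ (kin.K_D_inv @ sol.g_D_hat)
            )
            y_test = pheno.y[test_idx]
            if np.std(y_test) == 0 or np.std(gebv) == 0:
                warnings.warn(
                    f"repeat {rep + 1} fold {fold_idx + 1}: zero variance, "
                    "correlation undefined",
                    stacklevel=2,
                )
                correlations.append(np.nan)
            else:
                correlations.append(float(stats.pearsonr(gebv, y_test)[0]))
    result = CVResult(np.asarray(correlations), n_folds, n_repeats)
    if result.n_missing:
        logger.info("%d of %d folds had undefined correlations", result.n_missing,
                    len(correlations))
    return result
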