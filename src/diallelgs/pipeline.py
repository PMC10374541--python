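"""End-to-end workflow: QC -> coding -> kinship -> Gibbs fit -> diallel report.

Ties the library modules together for file-based runs: read inbred parental
genotypes and training-hybrid phenotypes, synthesize the genotypes of every
half-diallel hybrid, fit the additive+dominance GBLUP model by Gibbs
sampling on the phenotyped hybrids, predict GEBVs for the whole breeding
population, and derive the combining-ability and heterosis report tables.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import combining, io
from .errors import DataError
from .gibbs import GibbsConfig, run_bgs
from .kinship import KinshipSet, build_kinship
from .markers import (
    DiallelFrame,
    MarkerPanel,
    QCReport,
    code_and_standardize,
    enumerate_half_diallel,
    filter_markers,
    impute_major_allele,
    synthesize_hybrids,
)
from .mme import (
    BreedingPrediction,
    MMESolution,
    Phenotypes,
    VarianceComponents,
    predict_breeding,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """File paths and settings for a command-line run."""

    genotypes: str
    phenotypes: str
    output_dir: str = "."
    genotype_format: str | None = None
    max_missing_rate: float = 0.05
    min_maf: float = 0.05
    on_heterozygote: str = "error"
    ridge_scale: float = 1e-6
    top_k_hybrids: int = 25
    top_k_parents: int = 10
    decimals: int = 3
    seed: int = 0
    gibbs: GibbsConfig = field(default_factory=GibbsConfig)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        gibbs_raw = raw.pop("gibbs", {})
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        if gibbs_raw:
            cfg.gibbs = GibbsConfig(**gibbs_raw)
        cfg.gibbs = dataclasses.replace(cfg.gibbs, seed=cfg.seed)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    """Everything a full fit/predict/rank run produces."""

    qc_report: QCReport
    frame: DiallelFrame
    kin: KinshipSet
    pheno: Phenotypes
    vc: VarianceComponents
    sol: MMESolution
    prediction: BreedingPrediction
    evaluation: combining.HybridEvaluation


def prepare_inputs(
    config: RunConfig,
) -> tuple[MarkerPanel, QCReport, DiallelFrame, MarkerPanel, Phenotypes, np.ndarray]:
    """Load and QC the parents, synthesize all hybrids, align phenotypes.

    Returns (parents, qc_report, frame, hybrid_panel, phenotypes,
    training_row_indices) with hybrid rows ordered as the frame's pairs.
    """
    parents = io.read_genotypes(config.genotypes, config.genotype_format)
    parents, qc = filter_markers(parents, config.max_missing_rate, config.min_maf)
    parents = impute_major_allele(parents)
    frame = enumerate_half_diallel(parents.individual_ids)
    hybrids = synthesize_hybrids(parents, frame, config.on_heterozygote)
    pheno, pairs = io.read_phenotypes(config.phenotypes, parents.individual_ids)
    index = {pid: k for k, pid in enumerate(parents.individual_ids)}
    row_of_pair = {pair: row for row, pair in enumerate(frame.pairs)}
    train_rows = []
    for (a, b), hid in zip(pairs, pheno.hybrid_ids):
        i, j = sorted((index[a], index[b]))
        if i == j:
            raise DataError(f"phenotype record {hid!r} is a self-cross")
        train_rows.append(row_of_pair[(i, j)])
    train_rows = np.asarray(train_rows)
    if len(set(train_rows.tolist())) != len(train_rows):
        raise DataError("two phenotype records resolve to the same hybrid")
    logger.info(
        "QC: %d/%d markers retained; %d parents -> %d hybrids, %d phenotyped",
        qc.n_retained, qc.n_input_markers, frame.N0, frame.N1, pheno.n,
    )
    return parents, qc, frame, hybrids, pheno, train_rows


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full evaluation workflow for one configuration."""
    _, qc, frame, hybrids, pheno, train_rows = prepare_inputs(config)
    coded, n_zero_dom = code_and_standardize(hybrids)
    qc.n_removed_zero_dominance = n_zero_dom
    kin = build_kinship(
        coded,
        train_rows,
        bp_rows=np.arange(frame.N1),
        ridge_scale=config.ridge_scale,
    )
    if kin.ridge_used > 0:
        logger.info("kinship inversion used ridge %.3g", kin.ridge_used)
    vc, sol = run_bgs(pheno, kin, config.gibbs)
    prediction = predict_breeding(sol, kin, frame)
    evaluation = combining.evaluate_hybrids(
        prediction,
        top_k_hybrids=min(config.top_k_hybrids, frame.N1),
        top_k_parents=min(config.top_k_parents, frame.N0),
        decimals=config.decimals,
    )
    return PipelineResult(qc, frame, kin, pheno, vc, sol, prediction, evaluation)
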