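"""Genotype data model, marker QC, half-diallel hybrid synthesis and coding.

Genotypes are held as dosage matrices (individuals x markers) counting one of
the two alleles at each biallelic SNP, with values in {0, 1, 2} and ``nan``
for missing calls.  Inbred parental lines are fully homozygous, so their
dosages are restricted to {0, 2}.  A hybrid genotype is synthesized from two
inbred parents as the allele-dosage midpoint: identical homozygotes give the
same homozygote, opposite homozygotes give a heterozygote.

For model building, each marker is coded twice: an additive score (-1 minor
homozygote, 0 heterozygote, +1 major homozygote) and a dominance score
(1 heterozygote, 0 either homozygote).  Both score matrices are column
z-scored over a fixed reference set of rows so that training and breeding
populations live on one scale.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, QCError

logger = logging.getLogger(__name__)

PARENTAL_INBRED = "parental_inbred"
HYBRID = "hybrid"

_VALID_DOSAGES = (0.0, 1.0, 2.0)


@dataclass
class MarkerPanel:
    """A set of individuals genotyped at a shared panel of biallelic SNPs.

    Parameters
    ----------
    individual_ids
        Row labels, one per individual; must be unique.
    marker_ids
        Column labels, one per SNP; must be unique.
    dosages
        Float matrix of allele counts in {0, 1, 2}; ``nan`` marks missing.
    ploidy_role
        ``"parental_inbred"`` for homozygous lines, ``"hybrid"`` for F1s.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    ploidy_role: str = PARENTAL_INBRED

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise DataError("dosages must be a 2-D matrix")
        n, p = self.dosages.shape
        if n != len(self.individual_ids):
            raise DataError(
                f"{len(self.individual_ids)} individual ids but {n} dosage rows"
            )
        if p != len(self.marker_ids):
            raise DataError(f"{len(self.marker_ids)} marker ids but {p} dosage columns")
        if len(set(self.individual_ids)) != n:
            raise DataError("duplicate individual ids")
        if len(set(self.marker_ids)) != p:
            raise DataError("duplicate marker ids")
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, _VALID_DOSAGES).all():
            bad = observed[~np.isin(observed, _VALID_DOSAGES)]
            raise DataError(f"dosage values outside {{0,1,2,missing}}: {bad[:5]}")
        if self.ploidy_role not in (PARENTAL_INBRED, HYBRID):
            raise DataError(f"unknown ploidy_role {self.ploidy_role!r}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def missing_rate(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)

    def counted_allele_freq(self) -> np.ndarray:
        """Frequency of the allele counted by the dosage, from non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-nan columns
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency from non-missing calls."""
        f = self.counted_allele_freq()
        return np.minimum(f, 1.0 - f)

    def subset_markers(self, mask: np.ndarray) -> "MarkerPanel":
        ids = [m for m, keep in zip(self.marker_ids, mask) if keep]
        return MarkerPanel(
            list(self.individual_ids), ids, self.dosages[:, mask], self.ploidy_role
        )


@dataclass
class QCReport:
    """Tally of marker-filter removals; counts are by first-failing rule."""

    n_input_markers: int
    n_removed_missing: int = 0
    n_removed_maf: int = 0
    n_removed_zero_dominance: int = 0
    thresholds: tuple[float, float] = (np.nan, np.nan)

    @property
    def n_retained(self) -> int:
        return (
            self.n_input_markers
            - self.n_removed_missing
            - self.n_removed_maf
            - self.n_removed_zero_dominance
        )

    def to_dict(self) -> dict:
        return {
            "n_input_markers": self.n_input_markers,
            "n_removed_missing": self.n_removed_missing,
            "n_removed_maf": self.n_removed_maf,
            "n_removed_zero_dominance": self.n_removed_zero_dominance,
            "n_retained": self.n_retained,
            "max_missing_rate": self.thresholds[0],
            "min_maf": self.thresholds[1],
        }


@dataclass
class DiallelFrame:
    """All unordered parent pairs of a half diallel, stored with i < j."""

    parent_ids: list[str]
    pairs: list[tuple[int, int]]

    @property
    def N0(self) -> int:
        return len(self.parent_ids)

    @property
    def N1(self) -> int:
        return len(self.pairs)

    @property
    def hybrid_ids(self) -> list[str]:
        return [f"{self.parent_ids[i]}x{self.parent_ids[j]}" for i, j in self.pairs]

    def pair_names(self) -> list[tuple[str, str]]:
        return [(self.parent_ids[i], self.parent_ids[j]) for i, j in self.pairs]


def enumerate_half_diallel(parent_ids: list[str]) -> DiallelFrame:
    """Enumerate the C(N0, 2) unordered crosses of a half diallel.

    Pairs are returned in lexicographic-by-index order with i < j and no
    reciprocals or selfs.
    """
    parent_ids = list(parent_ids)
    if len(parent_ids) < 2:
        raise DataError("a half diallel needs at least 2 parents")
    if len(set(parent_ids)) != len(parent_ids):
        raise DataError("duplicate parent ids")
    pairs = list(itertools.combinations(range(len(parent_ids)), 2))
    return DiallelFrame(parent_ids, pairs)


def filter_markers(
    panel: MarkerPanel, max_missing_rate: float = 0.05, min_maf: float = 0.05
) -> tuple[MarkerPanel, QCReport]:
    """Drop markers by missing rate then by minor allele frequency.

    A marker is retained iff its missing rate is below ``max_missing_rate``
    and its MAF (computed from non-missing calls) is at least ``min_maf``.
    The missing-rate rule is applied first, so a marker failing both is
    tallied under the missing-rate removals.
    """
    if not 0 <= max_missing_rate <= 1 or not 0 <= min_maf <= 1:
        raise DataError("QC thresholds must lie in [0, 1]")
    if panel.n_markers == 0 or panel.n_individuals == 0:
        raise QCError("cannot filter an empty panel")
    mr = panel.missing_rate()
    fail_missing = mr >= max_missing_rate
    maf = panel.maf()
    with np.errstate(invalid="ignore"):
        fail_maf = ~fail_missing & ~(maf >= min_maf)  # nan MAF fails too
    keep = ~fail_missing & ~fail_maf
    report = QCReport(
        n_input_markers=panel.n_markers,
        n_removed_missing=int(fail_missing.sum()),
        n_removed_maf=int(fail_maf.sum()),
        thresholds=(max_missing_rate, min_maf),
    )
    if not keep.any():
        raise QCError(
            f"all {panel.n_markers} markers removed by QC "
            f"(max_missing_rate={max_missing_rate}, min_maf={min_maf})"
        )
    return panel.subset_markers(keep), report


def impute_major_allele(panel: MarkerPanel) -> MarkerPanel:
    """Replace missing calls by the homozygote of the major allele.

    At each marker the more frequent homozygote is substituted: dosage 0 when
    the counted-allele frequency is <= 0.5, dosage 2 otherwise.  An exact
    frequency tie resolves to dosage 0 with a warning.
    """
    dos = panel.dosages.copy()
    all_missing = np.isnan(dos).all(axis=0)
    if all_missing.any():
        bad = [m for m, b in zip(panel.marker_ids, all_missing) if b]
        raise DataError(f"markers with all calls missing: {bad}")
    f = panel.counted_allele_freq()
    ties = np.isnan(dos).any(axis=0) & (f == 0.5)
    if ties.any():
        tied = [m for m, t in zip(panel.marker_ids, ties) if t]
        warnings.warn(
            f"major-allele tie (freq exactly 0.5) at {tied}; imputing dosage 0",
            stacklevel=2,
        )
    fill = np.where(f <= 0.5, 0.0, 2.0)
    rows, cols = np.nonzero(np.isnan(dos))
    dos[rows, cols] = fill[cols]
    return MarkerPanel(
        list(panel.individual_ids), list(panel.marker_ids), dos, panel.ploidy_role
    )


def synthesize_hybrids(
    parents: MarkerPanel, frame: DiallelFrame, on_heterozygote: str = "error"
) -> MarkerPanel:
    """Derive F1 hybrid genotypes for every pair of a diallel frame.

    For inbred parents the hybrid dosage is the midpoint of the parental
    dosages: matching homozygotes reproduce themselves, opposite homozygotes
    give a heterozygote (dosage 1).

    Parameters
    ----------
    on_heterozygote
        ``"error"`` (default) rejects residual heterozygous parental calls;
        ``"missing"`` demotes them to missing with a warning and re-imputes
        the major-allele homozygote before crossing.
    """
    if parents.ploidy_role != PARENTAL_INBRED:
        raise DataError("synthesize_hybrids expects a parental_inbred panel")
    row_of = {pid: k for k, pid in enumerate(parents.individual_ids)}
    missing_parents = [p for p in frame.parent_ids if p not in row_of]
    if missing_parents:
        raise DataError(f"parents absent from genotype panel: {missing_parents}")
    dos = parents.dosages
    het = dos == 1.0
    if het.any():
        if on_heterozygote == "error":
            n_het = int(het.sum())
            raise DataError(
                f"{n_het} heterozygous calls in inbred parents; "
                "impute or rerun with on_heterozygote='missing'"
            )
        elif on_heterozygote == "missing":
            warnings.warn(
                f"{int(het.sum())} heterozygous parental calls set to missing "
                "and imputed with the major-allele homozygote",
                stacklevel=2,
            )
            dos = dos.copy()
            dos[het] = np.nan
            parents = MarkerPanel(
                list(parents.individual_ids),
                list(parents.marker_ids),
                dos,
                parents.ploidy_role,
            )
            parents = impute_major_allele(parents)
            dos = parents.dosages
        else:
            raise ValueError(f"on_heterozygote={on_heterozygote!r}")
    if np.isnan(dos).any():
        raise DataError("missing parental calls; run impute_major_allele first")
    rows_i = [row_of[frame.parent_ids[i]] for i, _ in frame.pairs]
    rows_j = [row_of[frame.parent_ids[j]] for _, j in frame.pairs]
    hyb = (dos[rows_i, :] + dos[rows_j, :]) / 2.0
    return MarkerPanel(frame.hybrid_ids, list(parents.marker_ids), hyb, HYBRID)


def code_markers(
    panel: MarkerPanel, orientation: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Produce raw additive and dominance score matrices.

    Additive: -1 for the minor-allele homozygote, 0 for the heterozygote,
    +1 for the major-allele homozygote.  Dominance: 1 for the heterozygote,
    0 for either homozygote.

    ``orientation`` (+1 / -1 per marker) fixes which dosage maps to +1; by
    default it is determined from the allele frequencies of ``panel`` itself.
    Passing the orientation of a reference set keeps a second panel on the
    same scale.

    Returns ``(additive, dominance, orientation)``.
    """
    dos = panel.dosages
    if np.isnan(dos).any():
        raise DataError("missing entries: impute before coding markers")
    if orientation is None:
        f = panel.counted_allele_freq()
        # counted allele minor (f <= 0.5): dosage 2 is the minor homozygote -> -1
        orientation = np.where(f <= 0.5, -1.0, 1.0)
    orientation = np.asarray(orientation, dtype=float)
    if orientation.shape != (panel.n_markers,):
        raise DataError("orientation length must match marker count")
    additive = orientation * (dos - 1.0)
    dominance = (dos == 1.0).astype(float)
    return additive, dominance, orientation


def drop_zero_dominance(
    additive: np.ndarray,
    dominance: np.ndarray,
    marker_ids: list[str],
    reference_rows: np.ndarray | slice | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    """Remove markers whose dominance column is all zero over the reference set.

    Such markers (no heterozygote anywhere) carry no dominance information
    and would break column standardization.  Returns the filtered additive
    and dominance matrices, the retained marker ids and the removal count.
    """
    ref = slice(None) if reference_rows is None else reference_rows
    keep = (dominance[ref] != 0).any(axis=0)
    n_removed = int((~keep).sum())
    if not keep.any():
        raise QCError("every marker has an all-zero dominance column")
    ids = [m for m, k in zip(marker_ids, keep) if k]
    return additive[:, keep], dominance[:, keep], ids, n_removed


@dataclass
class CodedMarkers:
    """Standardized additive (X_A) and dominance (X_D) score matrices.

    Columns are z-scored (mean 0, sd 1 with n-1 divisor) over the reference
    rows recorded in ``column_stats``; any further rows reuse the same stats
    so that cross-population relationship blocks stay on one scale.
    """

    X_A: np.ndarray
    X_D: np.ndarray
    marker_ids: list[str]
    column_stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.X_A.shape != self.X_D.shape:
            raise DataError("X_A and X_D must share a shape")
        if self.X_A.shape[1] != len(self.marker_ids):
            raise DataError("marker id count must match column count")

    @property
    def p(self) -> int:
        return self.X_A.shape[1]


def standardize(
    additive: np.ndarray,
    dominance: np.ndarray,
    marker_ids: list[str],
    reference_rows: np.ndarray | slice | None = None,
) -> CodedMarkers:
    """Column z-score raw marker scores over the reference rows.

    Each column is centered by its reference-row mean and divided by its
    reference-row standard deviation (n-1 divisor), separately for the
    additive and dominance matrices; the same statistics are applied to all
    rows.  A zero-variance column is an error — it should have been removed
    by the MAF or zero-dominance filters.
    """
    ref = slice(None) if reference_rows is None else reference_rows
    stats = {}
    out = []
    for name, raw in (("additive", additive), ("dominance", dominance)):
        mean = raw[ref].mean(axis=0)
        sd = raw[ref].std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            bad = [m for m, z in zip(marker_ids, zero) if z]
            raise QCError(
                f"zero-variance {name} column(s) over reference rows: {bad[:10]} "
                "(apply MAF / zero-dominance filters first)"
            )
        stats[f"{name}_mean"] = mean
        stats[f"{name}_sd"] = sd
        out.append((raw - mean) / sd)
    return CodedMarkers(out[0], out[1], list(marker_ids), stats)


def apply_standardization(
    coded: CodedMarkers, additive: np.ndarray, dominance: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize new raw scores with the column stats of an existing coding."""
    s = coded.column_stats
    X_A = (additive - s["additive_mean"]) / s["additive_sd"]
    X_D = (dominance - s["dominance_mean"]) / s["dominance_sd"]
    return X_A, X_D


def code_and_standardize(
    panel: MarkerPanel,
    reference_rows: np.ndarray | slice | None = None,
    drop_zero_variance: bool = False,
) -> tuple[CodedMarkers, int]:
    """Code, drop zero-dominance columns, and standardize in one pass.

    Allele orientation, the zero-dominance screen, and the column statistics
    are all taken over ``reference_rows`` (default: every row).  Returns the
    coded matrices and the number of markers removed.

    ``drop_zero_variance=True`` additionally removes any column whose
    additive or dominance scores are constant over the reference rows
    instead of raising; useful when the reference set is a training fold of
    a larger population.
    """
    ref = slice(None) if reference_rows is None else reference_rows
    ref_rows = np.arange(panel.n_individuals)[ref]
    ref_panel = MarkerPanel(
        [panel.individual_ids[k] for k in ref_rows],
        list(panel.marker_ids),
        panel.dosages[ref_rows],
        panel.ploidy_role,
    )
    _, _, orientation = code_markers(ref_panel)
    additive, dominance, _ = code_markers(panel, orientation=orientation)
    additive, dominance, ids, n_removed = drop_zero_dominance(
        additive, dominance, panel.marker_ids, reference_rows=ref_rows
    )
    if drop_zero_variance:
        keep = (additive[ref_rows].std(axis=0, ddof=1) > 0) & (
            dominance[ref_rows].std(axis=0, ddof=1) > 0
        )
        if not keep.any():
            raise QCError("no marker varies over the reference rows")
        n_removed += int((~keep).sum())
        additive, dominance = additive[:, keep], dominance[:, keep]
        ids = [m for m, k in zip(ids, keep) if k]
    if n_removed:
        logger.info("dropped %d uninformative markers before standardization",
                    n_removed)
    coded = standardize(additive, dominance, ids, reference_rows=ref_rows)
    return coded, n_removed
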