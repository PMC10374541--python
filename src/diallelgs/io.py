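"""Readers and writers for genotype matrices, phenotypes and report tables.

Genotype matrices travel as CSV/TSV with individuals in rows (first column
the individual id, header row the marker ids) and cells in {0, 1, 2} or
'.'/'NA' for missing.  Biallelic VCF is accepted read-only.  Phenotypes are
a two-column table (hybrid id or "parentA x parentB", trait value), one
record per hybrid.  All outputs are UTF-8 CSV with a provenance comment
line (package version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .markers import PARENTAL_INBRED, MarkerPanel
from .mme import Phenotypes

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {".", "NA", "NaN", "nan", ""}


def read_genotypes(path: str | Path, fmt: str | None = None,
                   ploidy_role: str = PARENTAL_INBRED) -> MarkerPanel:
    """Read a genotype panel from CSV, TSV or VCF (auto-detected by suffix)."""
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".vcf": "vcf"}.get(
            suffix, "csv"
        )
    if fmt == "vcf":
        return read_vcf(path, ploidy_role=ploidy_role)
    sep = "," if fmt == "csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, index_col=0)
    except pd.errors.ParserError as exc:
        raise DataError(f"{path}: malformed table ({exc})") from exc
    if df.shape[1] == 0:
        raise DataError(f"{path}: no marker columns found")
    individual_ids = [str(i) for i in df.index]
    if len(set(individual_ids)) != len(individual_ids):
        dup = pd.Index(individual_ids)
        dup = sorted(set(dup[dup.duplicated()]))
        raise DataError(f"{path}: duplicate individual id(s) {dup}")
    marker_ids = [str(c) for c in df.columns]
    values = df.to_numpy()
    dosages = np.full(values.shape, np.nan)
    for token, repl in (("0", 0.0), ("1", 1.0), ("2", 2.0)):
        dosages[values == token] = repl
    unparsed = ~np.isin(values, ("0", "1", "2")) & ~np.isin(
        values.astype(str), tuple(_MISSING_TOKENS)
    )
    unparsed &= ~pd.isna(values)
    if unparsed.any():
        r, c = np.argwhere(unparsed)[0]
        raise DataError(
            f"{path}: cell ({individual_ids[r]}, {marker_ids[c]}) = "
            f"{values[r, c]!r} is not a dosage in {{0,1,2}} or missing "
            f"(data line {r + 2})"
        )
    return MarkerPanel(individual_ids, marker_ids, dosages, ploidy_role)


def read_vcf(path: str | Path, ploidy_role: str = PARENTAL_INBRED) -> MarkerPanel:
    """Read biallelic SNPs from a VCF; GT becomes an ALT-allele dosage.

    Multi-allelic or non-SNP records are skipped with a warning; missing
    genotypes become missing dosages.
    """
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            n_skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = variant.gt_types
        dosage = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        rows.append(dosage)
        name = variant.ID or f"{variant.CHROM}:{variant.POS}"
        marker_ids.append(name)
    vcf.close()
    if n_skipped:
        warnings.warn(
            f"{path}: skipped {n_skipped} multi-allelic or non-SNP records",
            stacklevel=2,
        )
    if not rows:
        raise DataError(f"{path}: no biallelic SNPs found")
    return MarkerPanel(individual_ids, marker_ids, np.vstack(rows).T, ploidy_role)


def parse_cross_id(hybrid_id: str, parent_ids: list[str]) -> tuple[str, str]:
    """Resolve a phenotype-table hybrid id to an unordered parent pair.

    Accepts "A x B" (spaces around the x) or the canonical "AxB" form; the
    canonical form is matched against every split whose two sides are both
    known parents, so parent names containing the letter x stay unambiguous
    as long as only one split is valid.
    """
    known = set(parent_ids)
    if " x " in hybrid_id:
        a, b = (s.strip() for s in hybrid_id.split(" x ", 1))
        if a not in known or b not in known:
            raise DataError(f"hybrid id {hybrid_id!r} names unknown parent(s)")
        return (a, b)
    candidates = []
    for pos in range(1, len(hybrid_id)):
        if hybrid_id[pos] != "x":
            continue
        a, b = hybrid_id[:pos], hybrid_id[pos + 1 :]
        if a in known and b in known:
            candidates.append((a, b))
    if not candidates:
        raise DataError(
            f"hybrid id {hybrid_id!r} does not resolve to a known parent pair"
        )
    if len(candidates) > 1:
        raise DataError(f"hybrid id {hybrid_id!r} is ambiguous: {candidates}")
    return candidates[0]


def read_phenotypes(
    path: str | Path, parent_ids: list[str] | None = None
) -> tuple[Phenotypes, list[tuple[str, str]] | None]:
    """Read a two-column phenotype table (hybrid id, trait value).

    When ``parent_ids`` is given, each hybrid id is resolved to its parent
    pair and the list of pairs is returned alongside.  Repeated ids are an
    error: multiple records per hybrid must be pre-averaged upstream.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected columns (hybrid_id, value)")
    ids = [str(v) for v in df.iloc[:, 0]]
    dup = sorted({i for i in ids if ids.count(i) > 1})
    if dup:
        raise DataError(
            f"{path}: repeated phenotype records for {dup}; average repeated "
            "measurements to one value per hybrid before input"
        )
    try:
        y = df.iloc[:, 1].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise DataError(f"{path}: non-numeric trait values ({exc})") from exc
    pairs = None
    if parent_ids is not None:
        pairs = [parse_cross_id(i, parent_ids) for i in ids]
    return Phenotypes(ids, y), pairs


def write_genotypes(panel: MarkerPanel, path: str | Path) -> None:
    """Write a panel as CSV; missing dosages become '.'."""
    df = pd.DataFrame(panel.dosages, index=panel.individual_ids,
                      columns=panel.marker_ids)
    out = df.map(lambda v: "." if np.isnan(v) else str(int(v)))
    out.index.name = "id"
    out.to_csv(path)


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping, for output provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_line(seed: int | None, config: dict | None) -> str:
    from . import __version__

    chash = config_hash(config) if config else "none"
    return f"# diallelgs v{__version__} seed={seed} config_hash={chash}"


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> None:
    """Write a report table as CSV with a leading provenance comment."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(provenance_line(seed, config) + "\n")
        df.to_csv(fh, index=False)


def write_grm(K: np.ndarray, ids: list[str], path: str | Path) -> None:
    """Write a square GRM as CSV with an id header row and column."""
    df = pd.DataFrame(K, index=ids, columns=ids)
    df.index.name = "id"
    df.to_csv(path)


def read_grm(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index]
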