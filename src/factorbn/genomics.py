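"""Genotype handling and genomic relationship matrices.

Ingests SNP dosage data (CSV or PLINK-style text), applies minor-allele-
frequency filtering, builds the marker-standardized (VanRaden's second)
genomic relationship matrix G, and provides a Cholesky factorization of G
with an escalating ridge for numerically semi-definite kinships.  The
Cholesky factor L (G = LL') is what the downstream decorrelation step uses
to remove kinship-induced dependence from predicted breeding values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ridge ladder tried, in order, until the Cholesky factorization succeeds
RIDGE_LADDER = (0.0, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4)


class GenotypeParseError(ValueError):
    """Raised when a genotype file contains an unrecognized code."""


@dataclass
class GenotypeMatrix:
    """Accession-by-marker dosage matrix with per-marker allele frequencies.

    Dosages count copies of the coded allele (0, 1 or 2).  After mean
    imputation of missing cells, individual entries may be fractional; the
    allele frequency of marker i is always ``mean(dosage_i) / 2``.
    """

    accession_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray  # n x m, float
    coding: str = "counted-allele"

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.accession_ids) or m != len(self.marker_ids):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.accession_ids)} accessions x {len(self.marker_ids)} markers"
            )
        if len(set(self.accession_ids)) != n:
            raise ValueError("duplicate accession ids")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker ids")

    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def allele_freqs(self) -> np.ndarray:
        """Frequency of the coded allele, p_i = mean dosage / 2."""
        return self.dosages.mean(axis=0) / 2.0

    @property
    def minor_allele_freqs(self) -> np.ndarray:
        p = self.allele_freqs
        return np.minimum(p, 1.0 - p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.accession_ids, columns=self.marker_ids)


@dataclass
class GenomicRelationship:
    """Genomic relationship matrix with optional cached Cholesky factor."""

    matrix: np.ndarray  # n x n
    accession_ids: list[str]
    method_tag: str = "vanraden2"
    ridge: float = 0.0
    chol_lower: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("G must be square")
        if len(self.accession_ids) != n:
            raise ValueError("accession ids inconsistent with G dimension")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("G must be symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _validate_dosages(df: pd.DataFrame, source: str) -> np.ndarray:
    vals = df.to_numpy(dtype=float, na_value=np.nan)
    bad = np.isfinite(vals) & ~np.isin(vals, (0.0, 1.0, 2.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeParseError(
            f"{source}: unrecognized dosage code {vals[i, j]!r} at "
            f"accession {df.index[i]!r}, marker {df.columns[j]!r} (expected 0/1/2 or missing)"
        )
    return vals


def _impute_and_build(
    vals: np.ndarray, accession_ids: list[str], marker_ids: list[str]
) -> GenotypeMatrix:
    """Mean-impute missing cells per marker; drop all-missing markers."""
    n_obs = np.isfinite(vals).sum(axis=0)
    all_missing = n_obs == 0
    if all_missing.any():
        dropped = [m for m, d in zip(marker_ids, all_missing) if d]
        warnings.warn(f"dropping {len(dropped)} all-missing markers: {dropped[:5]}...")
        vals = vals[:, ~all_missing]
        marker_ids = [m for m, d in zip(marker_ids, all_missing) if not d]
    n_missing = int(np.isnan(vals).sum())
    if n_missing:
        col_means = np.nanmean(vals, axis=0)
        idx = np.where(np.isnan(vals))
        vals = vals.copy()
        vals[idx] = col_means[idx[1]]
        logger.info("mean-imputed %d missing genotype cells", n_missing)
    return GenotypeMatrix(list(accession_ids), list(marker_ids), vals)


def read_genotypes(path: str | Path, format_tag: str = "csv") -> GenotypeMatrix:
    """Read a genotype matrix from ``csv``, ``raw`` or ``ped`` text formats.

    csv
        accessions in rows (first column = id), markers in header; cells
        0/1/2 or empty/NA.
    raw
        PLINK additive export: FID IID PAT MAT SEX PHENOTYPE then one
        dosage column per marker, whitespace-separated, NA for missing.
    ped
        PLINK .ped with a sibling .map; two allele characters per marker,
        "0 0" missing.  Dosage counts the minor allele of each marker.

    Missing dosages are mean-imputed per marker (count logged); markers
    missing for every accession are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_tag == "csv":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        vals = _validate_dosages(df, str(path))
        return _impute_and_build(vals, list(df.index), [str(c) for c in df.columns])
    if format_tag == "raw":
        df = pd.read_csv(path, sep=r"\s+")
        meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        ids = df["IID"].astype(str).tolist()
        geno = df.drop(columns=[c for c in meta if c in df.columns])
        vals = _validate_dosages(geno.set_axis(ids, axis=0), str(path))
        return _impute_and_build(vals, ids, [str(c) for c in geno.columns])
    if format_tag == "ped":
        return _read_ped(path)
    raise ValueError(f"unknown genotype format {format_tag!r}")


def _read_ped(ped_path: Path) -> GenotypeMatrix:
    map_path = ped_path.with_suffix(".map")
    if not map_path.exists():
        raise FileNotFoundError(f"missing .map companion for {ped_path}")
    marker_ids = [line.split()[1] for line in map_path.read_text().splitlines() if line.strip()]
    m = len(marker_ids)
    ids: list[str] = []
    allele_rows: list[list[str]] = []
    for lineno, line in enumerate(ped_path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise GenotypeParseError(
                f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
            )
        ids.append(parts[1])
        allele_rows.append(parts[6:])
    # per marker: determine the minor allele, count its copies
    vals = np.full((len(ids), m), np.nan)
    for j in range(m):
        a1 = [row[2 * j] for row in allele_rows]
        a2 = [row[2 * j + 1] for row in allele_rows]
        alleles = [a for a in a1 + a2 if a != "0"]
        uniq = sorted(set(alleles))
        if len(uniq) > 2:
            raise GenotypeParseError(
                f"{ped_path}: marker {marker_ids[j]} has >2 alleles: {uniq}"
            )
        if not uniq:
            continue  # all missing, dropped later
        counts = {u: alleles.count(u) for u in uniq}
        minor = min(uniq, key=lambda u: (counts[u], u))
        for i in range(len(ids)):
            if a1[i] == "0" or a2[i] == "0":
                continue
            vals[i, j] = (a1[i] == minor) + (a2[i] == minor)
    return _impute_and_build(vals, ids, marker_ids)


def write_genotypes_csv(g: GenotypeMatrix, path: str | Path) -> None:
    g.to_frame().to_csv(path)


# ---------------------------------------------------------------------------
# QC and G matrix
# ---------------------------------------------------------------------------

def filter_maf(g: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Remove markers with minor allele frequency below ``threshold``.

    MAF is min(p, 1-p), so the filter is invariant to which allele the
    dosages count.  Survivor order is preserved; an empty result only
    warns.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    keep = g.minor_allele_freqs >= threshold
    if not keep.any():
        warnings.warn("MAF filter removed every marker")
    return GenotypeMatrix(
        list(g.accession_ids),
        [m for m, k in zip(g.marker_ids, keep) if k],
        g.dosages[:, keep],
        coding=g.coding,
    )


def compute_grm(g: GenotypeMatrix) -> GenomicRelationship:
    """Marker-standardized genomic relationship matrix.

    G = (1/m) * sum_i z_i z_i' / (2 p_i (1 - p_i)) with z_i the i-th
    centered dosage column.  Each marker is scaled by its own expected
    variance under Hardy-Weinberg, so the diagonal averages ~1 for an
    unstructured population.
    """
    if g.n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    p = g.allele_freqs
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        bad = [m for m, b in zip(g.marker_ids, mono) if b][:5]
        raise ValueError(
            f"monomorphic markers present (e.g. {bad}); run filter_maf first"
        )
    z = g.dosages - 2.0 * p
    w = z / np.sqrt(2.0 * p * (1.0 - p))
    G = (w @ w.T) / g.n_markers
    G = 0.5 * (G + G.T)
    return GenomicRelationship(G, list(g.accession_ids))


def cholesky_factor(
    grm: GenomicRelationship, ridge_ladder: tuple[float, ...] = RIDGE_LADDER
) -> GenomicRelationship:
    """Return a copy of ``grm`` with ``chol_lower`` set.

    Tries L L' = G + ridge * I for each ridge in the ladder (ascending,
    starting at 0) and keeps the first that succeeds; the ridge actually
    applied is recorded.  A matrix still indefinite at the largest ridge
    is a hard error naming its smallest eigenvalue.
    """
    G = grm.matrix
    for ridge in ridge_ladder:
        try:
            L = np.linalg.cholesky(G + ridge * np.eye(grm.n))
        except np.linalg.LinAlgError:
            continue
        if ridge > 0:
            logger.info("cholesky_factor applied ridge %g", ridge)
        return replace(grm, ridge=ridge, chol_lower=L)
    lam_min = float(np.linalg.eigvalsh(G).min())
    raise np.linalg.LinAlgError(
        f"G not positive definite at max ridge {ridge_ladder[-1]:g} "
        f"(smallest eigenvalue {lam_min:.3e})"
    )


def read_grm_csv(path: str | Path) -> GenomicRelationship:
    df = pd.read_csv(path, index_col=0)
    return GenomicRelationship(df.to_numpy(float), [str(i) for i in df.index])


def write_grm_csv(grm: GenomicRelationship, path: str | Path) -> None:
    pd.DataFrame(grm.matrix, index=grm.accession_ids, columns=grm.accession_ids).to_csv(path)
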