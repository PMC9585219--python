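"""SNP genotype matrices: reading, QC filtering, imputation, GRM and PCA.

Genotypes live in a :class:`MarkerMatrix` of additive codes {0, 1, 2}
(count of the minor allele, decided per marker) with NaN for missing
calls.  Supported on-disk dialects are HapMap text (tab-separated, 11
metadata columns), VCF (via cyvcf2, biallelic records only) and a plain
numeric CSV round-trip format.  Downstream quantities — the VanRaden-scaled
genomic relationship matrix and genotype principal components — are
invariant to which allele is counted, which the test suite asserts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "RelationshipMatrix",
    "GenotypePCs",
    "FilterReport",
    "read_genotypes",
    "write_hapmap",
    "write_numeric_csv",
    "filter_markers",
    "impute_missing",
    "compute_grm",
    "genotype_pca",
]

logger = logging.getLogger(__name__)

_HAPMAP_META = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


@dataclass
class MarkerMatrix:
    """Lines x markers additive genotype codes with per-marker metadata.

    ``codes`` is float with NaN marking missing calls; integer values are
    in {0, 1, 2}.  After marker-mean imputation codes are real-valued.
    """

    line_ids: np.ndarray
    marker_ids: np.ndarray
    codes: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    alleles: np.ndarray | None = None    # (p, 2): counted allele first

    def __post_init__(self):
        self.line_ids = np.asarray(self.line_ids)
        self.marker_ids = np.asarray(self.marker_ids)
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("codes shape does not match id lengths")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele per marker (observed calls)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.codes, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def het_rate(self) -> np.ndarray:
        obs = ~np.isnan(self.codes)
        het = (self.codes == 1.0) & obs
        denom = np.maximum(obs.sum(axis=0), 1)
        return het.sum(axis=0) / denom

    def marker_missing_rate(self) -> np.ndarray:
        return np.isnan(self.codes).mean(axis=0)

    def line_missing_rate(self) -> np.ndarray:
        return np.isnan(self.codes).mean(axis=1)

    def take_lines(self, mask) -> "MarkerMatrix":
        return replace(self, line_ids=self.line_ids[mask],
                       codes=self.codes[mask, :])

    def take_markers(self, mask) -> "MarkerMatrix":
        return replace(
            self,
            marker_ids=self.marker_ids[mask],
            codes=self.codes[:, mask],
            chrom=None if self.chrom is None else self.chrom[mask],
            pos=None if self.pos is None else self.pos[mask],
            alleles=None if self.alleles is None else self.alleles[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.line_ids,
                            columns=self.marker_ids)


@dataclass
class RelationshipMatrix:
    """Symmetric genomic relationship matrix (VanRaden scaling)."""

    line_ids: np.ndarray
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids,
                            columns=self.line_ids)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "RelationshipMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(line_ids=df.index.to_numpy(dtype=str),
                   values=df.to_numpy(dtype=float))


@dataclass
class GenotypePCs:
    """Principal-component scores of the centered genotype matrix."""

    line_ids: np.ndarray
    scores: np.ndarray
    explained_variance_fraction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.line_ids, columns=cols)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "GenotypePCs":
        df = pd.read_csv(path, index_col=0)
        return cls(line_ids=df.index.to_numpy(dtype=str),
                   scores=df.to_numpy(dtype=float),
                   explained_variance_fraction=np.full(df.shape[1], np.nan))


@dataclass
class FilterReport:
    n_lines_in: int
    n_lines_removed: int
    n_markers_in: int
    n_markers_removed_maf: int
    n_markers_removed_het: int
    n_markers_removed_missing: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# reading / writing

def read_genotypes(path, format: str = "hapmap") -> MarkerMatrix:
    """Read a genotype matrix in ``hapmap``, ``vcf`` or ``numeric-csv`` form.

    HapMap and VCF calls are encoded as counts of the per-marker minor
    allele (heterozygotes always 1); multi-allelic markers are dropped
    with a logged count.  The numeric CSV dialect stores codes verbatim
    and round-trips exactly.
    """
    if format == "hapmap":
        return _read_hapmap(path)
    if format == "vcf":
        return _read_vcf(path)
    if format in ("numeric-csv", "csv"):
        df = pd.read_csv(path, index_col=0)
        return MarkerMatrix(
            line_ids=df.index.to_numpy(dtype=str),
            marker_ids=df.columns.to_numpy(dtype=str),
            codes=df.to_numpy(dtype=float),
        )
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_hapmap(path) -> MarkerMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 12 or header[0] not in ("rs#", "rs"):
            raise ValueError(
                f"{path}: line 1: not a HapMap header (expected 'rs#' "
                "plus 11 metadata columns and at least one taxon)"
            )
        line_ids = np.array(header[11:])
        marker_ids, chroms, poss, allele_pairs, rows = [], [], [], [], []
        n_multi = 0
        for lineno, raw in enumerate(fh, start=2):
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != 11 + len(line_ids):
                raise ValueError(
                    f"{path}: line {lineno}: expected "
                    f"{11 + len(line_ids)} fields, got {len(parts)}"
                )
            alleles = parts[1].replace("/", "")
            uniq = [a for a in dict.fromkeys(alleles) if a in "ACGT"]
            if len(uniq) != 2:
                n_multi += 1
                continue
            a, b = uniq
            calls = parts[11:]
            row = np.full(len(calls), np.nan)
            for i, c in enumerate(calls):
                if c in ("NN", "N", "--", "NA", ""):
                    continue
                if len(c) != 2 or any(x not in (a, b) for x in c):
                    raise ValueError(
                        f"{path}: line {lineno}: unparseable call {c!r} "
                        f"for alleles {a}/{b}"
                    )
                row[i] = (c[0] == a) + (c[1] == a)
            marker_ids.append(parts[0])
            chroms.append(parts[2])
            poss.append(int(parts[3]))
            allele_pairs.append((a, b))
            rows.append(row)
    if n_multi:
        logger.info("dropped %d non-biallelic HapMap marker(s)", n_multi)
    codes = np.array(rows).T if rows else np.empty((len(line_ids), 0))
    m = MarkerMatrix(
        line_ids=line_ids,
        marker_ids=np.array(marker_ids),
        codes=codes,
        chrom=np.array(chroms),
        pos=np.array(poss),
        alleles=np.array(allele_pairs) if allele_pairs else None,
    )
    return _count_minor(m)


def _read_vcf(path) -> MarkerMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = np.array(vcf.samples)
    marker_ids, chroms, poss, allele_pairs, rows = [], [], [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gt = v.gt_types.astype(float)        # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        row = np.where(gt == 0, 0.0,
                       np.where(gt == 1, 1.0,
                                np.where(gt == 3, 2.0, np.nan)))
        marker_ids.append(v.ID or f"{v.CHROM}_{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        allele_pairs.append((v.ALT[0], v.REF))
        rows.append(row)
    if n_multi:
        logger.info("dropped %d multi-allelic VCF record(s)", n_multi)
    codes = np.array(rows).T if rows else np.empty((len(line_ids), 0))
    m = MarkerMatrix(
        line_ids=line_ids,
        marker_ids=np.array(marker_ids),
        codes=codes,
        chrom=np.array(chroms),
        pos=np.array(poss),
        alleles=np.array(allele_pairs) if allele_pairs else None,
    )
    return _count_minor(m)


def _count_minor(m: MarkerMatrix) -> MarkerMatrix:
    """Recode markers so the counted allele is the minor one."""
    p = m.allele_freq()
    flip = p > 0.5
    if flip.any():
        m.codes[:, flip] = 2.0 - m.codes[:, flip]
        if m.alleles is not None:
            m.alleles[flip] = m.alleles[flip][:, ::-1]
    return m


def write_numeric_csv(m: MarkerMatrix, path) -> None:
    m.to_frame().to_csv(path)


def write_hapmap(m: MarkerMatrix, path) -> None:
    """Write HapMap text; requires integer codes and allele letters."""
    if m.alleles is None:
        raise ValueError("MarkerMatrix has no allele letters to write")
    if np.nanmax(np.abs(m.codes - np.round(m.codes))) > 0:
        raise ValueError("cannot write imputed (non-integer) codes as HapMap")
    chrom = m.chrom if m.chrom is not None else np.full(m.n_markers, "0")
    pos = m.pos if m.pos is not None else np.arange(1, m.n_markers + 1)
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_META + list(m.line_ids)) + "\n")
        for j in range(m.n_markers):
            a, b = m.alleles[j]
            calls = []
            for x in m.codes[:, j]:
                if np.isnan(x):
                    calls.append("NN")
                elif x == 0:
                    calls.append(b + b)
                elif x == 1:
                    calls.append(a + b)
                else:
                    calls.append(a + a)
            fh.write("\t".join(
                [str(m.marker_ids[j]), f"{a}/{b}", str(chrom[j]),
                 str(pos[j]), "+", "NA", "NA", "NA", "NA", "NA", "NA"]
                + calls) + "\n")


# ---------------------------------------------------------------------------
# QC

def filter_markers(
    m: MarkerMatrix,
    maf_min: float = 0.05,
    het_max: float = 0.10,
    marker_missing_max: float = 0.20,
    line_missing_max: float = 0.85,
) -> tuple[MarkerMatrix, FilterReport]:
    """Standard SNP QC: drop bad lines first, then re-assess markers.

    Lines with missing rate above ``line_missing_max`` are removed; marker
    statistics are then recomputed on the retained lines and markers kept
    when MAF >= ``maf_min``, heterozygous proportion <= ``het_max`` and
    missing rate <= ``marker_missing_max``.
    """
    n_lines_in, n_markers_in = m.n_lines, m.n_markers
    line_keep = m.line_missing_rate() <= line_missing_max
    m2 = m.take_lines(line_keep)
    if m2.n_lines == 0:
        raise ValueError("all lines removed by missing-data filter")
    maf = m2.maf()
    het = m2.het_rate()
    miss = m2.marker_missing_rate()
    all_missing = np.isnan(maf)
    ok_maf = ~all_missing & (maf >= maf_min)
    ok_het = het <= het_max
    ok_miss = miss <= marker_missing_max
    keep = ok_maf & ok_het & ok_miss
    report = FilterReport(
        n_lines_in=n_lines_in,
        n_lines_removed=int((~line_keep).sum()),
        n_markers_in=n_markers_in,
        n_markers_removed_maf=int((~ok_maf).sum()),
        n_markers_removed_het=int((ok_maf & ~ok_het).sum()),
        n_markers_removed_missing=int((ok_maf & ok_het & ~ok_miss).sum()),
    )
    out = m2.take_markers(keep)
    if out.n_markers == 0:
        raise ValueError("no markers left after QC filtering")
    return out, report


def impute_missing(m: MarkerMatrix, method: str = "marker_mean") -> MarkerMatrix:
    """Fill missing calls with the per-marker mean of observed codes."""
    if method != "marker_mean":
        raise ValueError(f"unknown imputation method {method!r}")
    if np.isnan(m.codes).all(axis=0).any():
        raise ValueError("marker with no observed calls; run QC first")
    codes = m.codes.copy()
    means = np.nanmean(codes, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(codes))
    codes[nan_r, nan_c] = means[nan_c]
    return replace(m, codes=codes)


# ---------------------------------------------------------------------------
# relationship matrix and PCA

def compute_grm(m: MarkerMatrix) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix K = W W' / (sum 2 p q).

    W is the column-centered code matrix; the scaling makes the average
    diagonal approximately 1 in an unstructured panel.
    """
    if np.isnan(m.codes).any():
        raise ValueError("impute missing codes before computing the GRM")
    p = m.codes.mean(axis=0) / 2.0
    var = m.codes.var(axis=0)
    if (var == 0).any():
        raise ValueError(
            "zero-variance marker(s) present; apply filter_markers first"
        )
    W = m.codes - 2.0 * p
    c = float(np.sum(2.0 * p * (1.0 - p)))
    K = (W @ W.T) / c
    K = 0.5 * (K + K.T)
    return RelationshipMatrix(line_ids=m.line_ids.copy(), values=K)


def genotype_pca(m: MarkerMatrix, n_components: int = 100) -> GenotypePCs:
    """PCs of the centered genotype matrix via SVD.

    Scores are U * s; explained fractions are squared singular values over
    their total.
    """
    if np.isnan(m.codes).any():
        raise ValueError("impute missing codes before PCA")
    max_rank = min(m.n_lines - 1, m.n_markers)
    if n_components > max_rank:
        warnings.warn(
            f"n_components clipped from {n_components} to {max_rank}",
            UserWarning,
        )
        n_components = max_rank
    W = m.codes - m.codes.mean(axis=0)
    U, s, _ = np.linalg.svd(W, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        raise ValueError("genotype matrix is constant; PCA undefined")
    k = n_components
    return GenotypePCs(
        line_ids=m.line_ids.copy(),
        scores=U[:, :k] * s[:k],
        explained_variance_fraction=(s[:k] ** 2) / total,
    )
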