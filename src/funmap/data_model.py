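"""Data containers and sufficient-statistic construction.

All likelihood computation in the fine-mapping engine flows through the
quadruple (XᵀX, Xᵀy, yᵀy, n).  This module builds that quadruple either
from individual-level data (standardized genotypes X and phenotype y) or
from GWAS summary statistics (marginal z-scores plus an LD correlation
matrix R), using the identities

    XᵀX = n·R,   yᵀy = n,   xⱼᵀy = n·zⱼ / √(n + zⱼ²),

which hold exactly when every column of X and y is standardized with the
divide-by-n variance convention (so xⱼᵀxⱼ = n).

Inputs are assumed pre-harmonized: the z-score, LD and annotation files
must refer to the same SNPs in the same order and on the same allele
coding.  No allele flipping, liftover or reference-panel LD computation
is performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("funmap")

__all__ = [
    "GenotypePhenotype",
    "SummaryData",
    "SufficientStatistics",
    "AnnotationMatrix",
    "standardize_columns",
    "suffstats_from_individual",
    "z_from_individual",
    "suffstats_from_summary",
    "prepare_annotations",
    "read_zscores",
    "read_ld",
    "read_annotations",
    "read_genotypes",
    "read_phenotype",
]


def standardize_columns(M: np.ndarray) -> np.ndarray:
    """Standardize each column to mean 0 and variance 1 (denominator n).

    The population variance convention (divide by n, not n-1) is used so
    that a standardized column x satisfies xᵀx = n exactly, which is what
    the summary-statistics identities XᵀX = nR and yᵀy = n require.

    Raises
    ------
    ValueError
        If any column has zero variance (e.g. a monomorphic SNP).
    """
    M_in = np.asarray(M, dtype=float)
    one_d = M_in.ndim == 1
    M = M_in.reshape(-1, 1) if one_d else M_in
    mean = M.mean(axis=0)
    var = M.var(axis=0)  # ddof=0
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        raise ValueError(
            f"zero variance in column(s) {bad.tolist()}: cannot standardize"
        )
    out = (M - mean) / np.sqrt(var)
    return out.ravel() if one_d else out


def _standardize_vector(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    s2 = v.var()
    if s2 <= 0:
        raise ValueError("zero variance in phenotype: cannot standardize")
    return (v - v.mean()) / np.sqrt(s2)


@dataclass
class GenotypePhenotype:
    """Standardized genotype matrix, phenotype vector and SNP identifiers."""

    X: np.ndarray
    y: np.ndarray
    snp_ids: list[str]

    @classmethod
    def from_raw(cls, X_raw, y_raw, snp_ids=None) -> "GenotypePhenotype":
        """Standardize raw dosages/phenotype and validate invariants."""
        X = np.asarray(X_raw, dtype=float)
        y = np.asarray(y_raw, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n, p = X.shape
        if n != y.shape[0]:
            raise ValueError(
                f"dimension mismatch: X has {n} rows but y has {y.shape[0]}"
            )
        if n < 2 or p < 1:
            raise ValueError("need n >= 2 samples and p >= 1 SNPs")
        if snp_ids is None:
            snp_ids = [f"snp_{j}" for j in range(p)]
        return cls(standardize_columns(X), _standardize_vector(y), list(snp_ids))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class SummaryData:
    """Marginal z-scores, LD correlation matrix and GWAS sample size."""

    z: np.ndarray
    R: np.ndarray
    n: int
    snp_ids: list[str]

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float).ravel()
        self.R = np.asarray(self.R, dtype=float)
        p = self.z.shape[0]
        if self.R.shape != (p, p):
            raise ValueError(
                f"LD matrix is {self.R.shape} but {p} z-scores were given"
            )
        if len(self.snp_ids) != p:
            raise ValueError("snp_ids length does not match z-scores")
        if self.n <= 0:
            raise ValueError("sample size n must be positive")
        if not np.allclose(self.R, self.R.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal is not 1")
        evals = np.linalg.eigvalsh(self.R)
        if evals.min() < -1e-6:
            raise ValueError(
                f"LD matrix is far from positive semi-definite "
                f"(min eigenvalue {evals.min():.3g})"
            )
        if evals.min() < 0:
            # near-PSD: clip the slightly negative eigenvalues at zero
            w, V = np.linalg.eigh(self.R)
            self.R = (V * np.clip(w, 0, None)) @ V.T
            self.R = 0.5 * (self.R + self.R.T)

    @property
    def p(self) -> int:
        return self.z.shape[0]


@dataclass
class SufficientStatistics:
    """The quadruple (XᵀX, Xᵀy, yᵀy, n) through which the likelihood flows."""

    XtX: np.ndarray
    Xty: np.ndarray
    yty: float
    n: int
    snp_ids: list[str] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.Xty.shape[0]

    @property
    def R(self) -> np.ndarray:
        """In-scale LD correlation matrix XᵀX / n."""
        return self.XtX / self.n


def suffstats_from_individual(data: GenotypePhenotype) -> SufficientStatistics:
    """Exact matrix products of the standardized individual-level data."""
    X, y = data.X, data.y
    if X.shape[0] != y.shape[0]:
        raise ValueError("dimension mismatch between X and y")
    return SufficientStatistics(
        XtX=X.T @ X,
        Xty=X.T @ y,
        yty=float(y @ y),
        n=data.n,
        snp_ids=list(data.snp_ids),
    )


def z_from_individual(data: GenotypePhenotype) -> np.ndarray:
    """Marginal-regression z-scores zⱼ = β̂ⱼ/ŝⱼ.

    β̂ⱼ = (xⱼᵀxⱼ)⁻¹ xⱼᵀy and ŝⱼ² = ‖y − xⱼβ̂ⱼ‖² / (n · xⱼᵀxⱼ).
    """
    X, y = data.X, data.y
    n = data.n
    if n <= 2:
        raise ValueError("need n > 2 for marginal z-scores")
    xtx = np.einsum("ij,ij->j", X, X)
    xty = X.T @ y
    beta = xty / xtx
    rss = y @ y - beta * xty  # ||y - x beta||^2 per SNP
    if np.any(rss <= 0):
        j = int(np.argmin(rss))
        raise ValueError(
            f"perfect marginal fit for SNP index {j}: z-score is infinite"
        )
    s2 = rss / (n * xtx)
    return beta / np.sqrt(s2)


def suffstats_from_summary(summary: SummaryData) -> SufficientStatistics:
    """Map (z, R, n) to sufficient statistics.

    Inverts the marginal-regression definition of zⱼ under standardization:
    xⱼᵀy = n·zⱼ/√(n + zⱼ²), together with XᵀX = nR and yᵀy = n.
    """
    n, z = summary.n, summary.z
    Xty = n * z / np.sqrt(n + z**2)
    return SufficientStatistics(
        XtX=n * summary.R,
        Xty=Xty,
        yty=float(n),
        n=n,
        snp_ids=list(summary.snp_ids),
    )


@dataclass
class AnnotationMatrix:
    """p × m annotation matrix with per-column kind and standardization state.

    Continuous columns are standardized (mean 0, variance 1); binary columns
    are centered only, preserving their natural scale.  No intercept column
    is ever added: the softmax prior is invariant to a shared shift of all
    logits, so an intercept is unidentifiable.
    """

    A: np.ndarray
    annotation_names: list[str]
    column_kinds: list[str]
    standardized: bool = True

    @property
    def p(self) -> int:
        return self.A.shape[0]

    @property
    def m(self) -> int:
        return self.A.shape[1]


def prepare_annotations(
    A_raw, kinds=None, names=None, n_snps: int | None = None
) -> AnnotationMatrix:
    """Validate and preprocess a raw annotation matrix.

    Constant columns are dropped (with a warning), continuous columns are
    standardized, binary columns are centered.  ``kinds`` may give a kind
    ("continuous"/"binary") per column; unspecified columns are
    auto-detected as binary when they take at most 2 distinct values.
    """
    A = np.atleast_2d(np.asarray(A_raw, dtype=float))
    p, m = A.shape
    if n_snps is not None and p != n_snps:
        raise ValueError(
            f"annotation matrix has {p} rows but the SNP panel has {n_snps}"
        )
    if names is None:
        names = [f"annot_{k}" for k in range(m)]
    names = list(names)
    if kinds is None:
        kinds = [None] * m
    kinds = list(kinds)

    cols, out_names, out_kinds = [], [], []
    for k in range(m):
        col = A[:, k]
        if np.ptp(col) == 0:
            logger.warning("annotation %r is constant; dropped", names[k])
            continue
        kind = kinds[k]
        if kind is None:
            kind = "binary" if np.unique(col).size <= 2 else "continuous"
        if kind == "binary":
            col = col - col.mean()
        elif kind == "continuous":
            sd = col.std()
            col = (col - col.mean()) / sd
        else:
            raise ValueError(f"unknown annotation kind {kind!r}")
        cols.append(col)
        out_names.append(names[k])
        out_kinds.append(kind)

    A_out = np.column_stack(cols) if cols else np.empty((p, 0))
    return AnnotationMatrix(A_out, out_names, out_kinds, standardized=True)


# ---------------------------------------------------------------------------
# File readers (TSV / dense text matrices).  SNP alignment across files is
# by strict order + identifier equality, never by silent join.
# ---------------------------------------------------------------------------

def read_zscores(path) -> pd.DataFrame:
    """Read a z-score TSV with columns `snp_id`, `z` (extras passed through)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("snp_id", "z"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def read_ld(path, p: int | None = None) -> np.ndarray:
    """Read a dense whitespace-delimited p × p LD matrix."""
    R = np.loadtxt(path)
    R = np.atleast_2d(R)
    if R.shape[0] != R.shape[1]:
        raise ValueError(f"{path}: LD matrix is not square ({R.shape})")
    if p is not None and R.shape[0] != p:
        raise ValueError(
            f"{path}: LD matrix has {R.shape[0]} rows, expected {p}"
        )
    return R


def read_annotations(path, binary_columns=None) -> tuple[pd.DataFrame, list]:
    """Read an annotation TSV (first column `snp_id`, one column per annotation).

    Returns the frame and the per-column kinds (None = auto-detect), using
    ``binary_columns`` (a collection of column names) when given.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "snp_id":
        raise ValueError(f"{path}: first column must be `snp_id`")
    annot_cols = list(df.columns[1:])
    binary_columns = set(binary_columns or ())
    kinds = ["binary" if c in binary_columns else None for c in annot_cols]
    return df, kinds


def read_genotypes(path) -> np.ndarray:
    """Read a dense n × p genotype dosage matrix (whitespace-delimited)."""
    X = np.loadtxt(path)
    return np.atleast_2d(X)


def read_phenotype(path) -> pd.DataFrame:
    """Read a phenotype TSV with columns `sample_id`, `y`."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df
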