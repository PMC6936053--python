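"""Pairwise association measures: Pearson correlation and mutual information.

Two complementary gene-gene similarity measures drive network construction:

* Pearson correlation captures linear co-expression.  By default the
  magnitude |r| is kept, so positively and negatively co-regulated genes
  are treated alike and the matrix lives in [0, 1].
* Mutual information, MI(X, Y) = H(X) + H(Y) - H(X, Y), captures arbitrary
  (including non-monotone) dependence.  Expression profiles are first
  discretized gene-by-gene into B bins; entropies are plug-in estimates on
  the empirical code distributions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError, ZeroVarianceWarning
from .ingest import ExpressionMatrix

__all__ = [
    "AssociationMatrix",
    "DiscretizedMatrix",
    "pearson_matrix",
    "discretize",
    "entropy",
    "joint_entropy",
    "mutual_information_matrix",
]


@dataclass(frozen=True)
class AssociationMatrix:
    """A symmetric gene x gene association matrix tagged with its measure."""

    gene_ids: tuple[str, ...]
    values: np.ndarray
    measure: str  # "pcc" or "mi"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(self.gene_ids)
        if values.shape != (n, n):
            raise ValidationError(f"association matrix shape {values.shape} != ({n}, {n})")
        if not np.allclose(values, values.T, atol=1e-12, equal_nan=True):
            raise ValidationError("association matrix is not symmetric")
        if self.measure not in ("pcc", "mi"):
            raise ValidationError(f"unknown measure {self.measure!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class DiscretizedMatrix:
    """Integer bin codes (genes x samples), each row using codes in [0, n_bins)."""

    gene_ids: tuple[str, ...]
    codes: np.ndarray
    n_bins: int
    scheme: str

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if not np.issubdtype(codes.dtype, np.integer):
            raise ValidationError("codes must be integers")
        object.__setattr__(self, "codes", codes)
        if codes.ndim != 2 or codes.shape[0] != len(self.gene_ids):
            raise ValidationError("codes shape does not match gene_ids")
        if codes.size and (codes.min() < 0 or codes.max() >= self.n_bins):
            raise ValidationError(f"codes must lie in [0, {self.n_bins})")
        if self.scheme not in ("equal_width", "equal_frequency"):
            raise ValidationError(f"unknown scheme {self.scheme!r}")


def pearson_matrix(X: ExpressionMatrix, absolute: bool = True) -> AssociationMatrix:
    """All-pairs Pearson correlation of gene expression profiles.

    Entry (i, j) is r = cov(x_i, x_j) / (sd(x_i) sd(x_j)) across samples;
    with ``absolute`` (the default) the magnitude |r| is returned.
    Zero-variance genes yield 0 off-diagonal (their correlation is
    undefined); they are listed in ``params["zero_variance_genes"]`` and a
    warning is emitted.  The diagonal is forced to 1.
    """
    if X.n_samples < 2:
        raise ValidationError("Pearson correlation needs at least 2 samples")
    if X.has_missing:
        raise ValidationError("expression matrix contains missing values; integrate first")
    values = X.values
    sd = values.std(axis=1)
    flat = [g for g, s in zip(X.gene_ids, sd) if s == 0.0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.nan_to_num(corr, nan=0.0)
    if absolute:
        corr = np.abs(corr)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0  # exact symmetry
    if flat:
        warnings.warn(
            f"{len(flat)} zero-variance gene(s); correlations set to 0: {flat[:5]}",
            ZeroVarianceWarning,
            stacklevel=2,
        )
    return AssociationMatrix(
        gene_ids=X.gene_ids,
        values=corr,
        measure="pcc",
        params={"absolute": absolute, "zero_variance_genes": flat},
    )


def auto_bins(n_samples: int) -> int:
    """Default bin count B = ceil(sqrt(n)), the usual equal-width heuristic."""
    return int(math.ceil(math.sqrt(n_samples)))


def discretize(
    X: ExpressionMatrix,
    n_bins: int | str = "auto",
    scheme: str = "equal_width",
) -> DiscretizedMatrix:
    """Bin each gene's profile into integer codes for entropy estimation.

    ``"auto"`` sets B = ceil(sqrt(n_samples)).  ``equal_width`` splits
    [row min, row max] into B equal intervals (the max falls in the last
    bin); ``equal_frequency`` assigns code floor(rank * B / n) from the
    stable rank of each value, so ties are resolved by sample order and the
    bins are as balanced as the data allow.  A constant row maps to all
    zeros (warned under equal_frequency, where balanced bins are impossible).
    """
    if n_bins == "auto":
        bins = auto_bins(X.n_samples)
    else:
        bins = int(n_bins)
    if bins < 2:
        raise ValidationError("n_bins must be >= 2")
    if scheme not in ("equal_width", "equal_frequency"):
        raise ValidationError(f"unknown scheme {scheme!r}")
    if X.has_missing:
        raise ValidationError("expression matrix contains missing values; integrate first")

    values = X.values
    n = X.n_samples
    codes = np.zeros(values.shape, dtype=np.int64)
    constant = []
    for i in range(values.shape[0]):
        row = values[i]
        lo, hi = row.min(), row.max()
        if hi == lo:
            constant.append(X.gene_ids[i])
            continue
        if scheme == "equal_width":
            width = (hi - lo) / bins
            c = np.floor((row - lo) / width).astype(np.int64)
            codes[i] = np.minimum(c, bins - 1)
        else:
            ranks = np.argsort(np.argsort(row, kind="stable"), kind="stable")
            codes[i] = (ranks * bins) // n
    if constant and scheme == "equal_frequency":
        warnings.warn(
            f"{len(constant)} constant gene(s) placed in a single bin: {constant[:5]}",
            ZeroVarianceWarning,
            stacklevel=2,
        )
    return DiscretizedMatrix(X.gene_ids, codes, bins, scheme)


def entropy(codes: np.ndarray, log_base: float = math.e) -> float:
    """Plug-in Shannon entropy of an integer code vector (0 log 0 := 0)."""
    codes = np.asarray(codes)
    if codes.size == 0:
        raise ValidationError("entropy of an empty vector is undefined")
    _, counts = np.unique(codes, return_counts=True)
    p = counts / codes.size
    h = -np.sum(p * np.log(p))
    return float(h / math.log(log_base))


def joint_entropy(codes_x: np.ndarray, codes_y: np.ndarray, log_base: float = math.e) -> float:
    """Plug-in entropy of the empirical joint distribution of two code vectors."""
    codes_x = np.asarray(codes_x)
    codes_y = np.asarray(codes_y)
    if codes_x.shape != codes_y.shape or codes_x.size == 0:
        raise ValidationError("joint entropy needs two equal-length non-empty vectors")
    span = int(codes_y.max()) + 1
    counts = np.bincount(codes_x * span + codes_y)
    counts = counts[counts > 0]
    p = counts / codes_x.size
    h = -np.sum(p * np.log(p))
    return float(h / math.log(log_base))


def mutual_information_matrix(
    D: DiscretizedMatrix, log_base: float = math.e
) -> AssociationMatrix:
    """All-pairs mutual information MI(i, j) = H(i) + H(j) - H(i, j).

    Joint entropies come from the 2-D empirical histogram of code pairs.
    The diagonal equals the marginal entropy H(i), since MI(X, X) = H(X).
    """
    codes = D.codes
    p, n = codes.shape
    scale = 1.0 / math.log(log_base)
    marg = np.empty(p)
    for i in range(p):
        _, counts = np.unique(codes[i], return_counts=True)
        pr = counts / n
        marg[i] = -np.sum(pr * np.log(pr)) * scale

    mi = np.zeros((p, p))
    B = D.n_bins
    logn = math.log(n)
    for i in range(p):
        base_i = codes[i] * B
        for j in range(i + 1, p):
            counts = np.bincount(base_i + codes[j], minlength=1)
            counts = counts[counts > 0]
            h_joint = (logn - (counts * np.log(counts)).sum() / n) * scale
            val = marg[i] + marg[j] - h_joint
            mi[i, j] = mi[j, i] = max(val, 0.0)
    np.fill_diagonal(mi, marg)
    return AssociationMatrix(
        gene_ids=D.gene_ids,
        values=mi,
        measure="mi",
        params={"n_bins": B, "scheme": D.scheme, "log_base": log_base},
    )
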