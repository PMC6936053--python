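"""Adjacency-cutoff selection from the sorted association curve.

All off-diagonal association values are sorted in descending order; on real
co-expression data this curve shows a short head of strongly associated
pairs followed by an abrupt fall into the bulk of background pairs.  The
cutoff is placed at the inflection point that opens the curve's dominant
knee — where the plunge out of the head levels off into the bulk — so the
threshold always equals an actually observed association value, never an
interpolated one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import AssociationMatrix
from .errors import FallbackThresholdWarning, ValidationError

__all__ = ["ThresholdResult", "collect_offdiag", "select_threshold", "threshold_diagnostics"]


@dataclass(frozen=True)
class ThresholdResult:
    """A selected cutoff plus the diagnostic curve that produced it.

    ``threshold == sorted_values[inflection_rank]`` always holds;
    ``sorted_values`` is the (possibly head-truncated) descending sequence
    the selector actually examined, and ``smoothed`` its moving average
    (NaN where the centered window does not fit).  ``fallback_used`` marks
    runs where no inflection existed and a quantile fallback was taken.
    """

    threshold: float
    inflection_rank: int
    sorted_values: np.ndarray
    smoothed: np.ndarray
    smooth_window: int
    fallback_used: bool

    def __post_init__(self) -> None:
        if self.threshold != self.sorted_values[self.inflection_rank]:
            raise ValidationError("threshold must equal the value at inflection_rank")


def collect_offdiag(A: AssociationMatrix) -> np.ndarray:
    """Strict upper-triangle entries of a symmetric matrix, sorted descending."""
    if A.n_genes < 3:
        raise ValidationError("need at least 3 genes for a meaningful curve")
    iu = np.triu_indices(A.n_genes, k=1)
    values = A.values[iu]
    return np.sort(values)[::-1]


def select_threshold(
    values: np.ndarray,
    head_fraction: float = 0.02,
    smooth_window: int = 51,
    fallback_quantile: float = 0.99,
    curvature_tol: float = 0.05,
    snap_factor: float = 5.0,
) -> ThresholdResult:
    """Pick a cutoff at the first inflection point of the sorted curve.

    Procedure: (1) keep the top ``head_fraction`` of the descending values
    (at least ``3 * smooth_window`` of them); (2) smooth with a centered
    moving average of width ``smooth_window``; (3) take discrete second
    differences; (4) locate the dominant knee — the rank of the largest
    positive second difference, where the curve most sharply levels off out
    of its plunge into the bulk — and report the inflection that initiates
    it: the first rank of that convex run, i.e. the first significant
    positive second difference following the last significant negative one
    before the knee; (5) snap the rank back up through locally flat
    stretches to the foot of the nearest preceding steep drop (a raw
    one-rank step exceeding ``snap_factor`` times the mean step of the
    head), so the cutoff sits at the top of the bulk rather than inside it
    when the descent is abrupt at the scale of the smoothing window.

    Second differences smaller in magnitude than ``curvature_tol`` times
    the largest observed magnitude are treated as zero curvature, so
    float-level wiggles on straight stretches cannot masquerade as
    inflections.

    If the curve never changes curvature (e.g. a straight ramp), the
    threshold falls back to the observed value nearest the
    ``fallback_quantile`` upper quantile and a warning is emitted.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValidationError("values must be a 1-D sequence")
    if np.any(np.diff(values) > 0):
        raise ValidationError("values must be sorted in descending order")
    if smooth_window < 3 or smooth_window % 2 == 0:
        raise ValidationError("smooth_window must be an odd integer >= 3")
    if not 0 < head_fraction <= 1:
        raise ValidationError("head_fraction must be in (0, 1]")
    n = values.size
    need = 3 * smooth_window
    if n < need:
        raise ValidationError(f"need at least {need} values, got {n}")

    head_len = max(int(math.ceil(n * head_fraction)), need)
    head = values[:head_len]

    kernel = np.full(smooth_window, 1.0 / smooth_window)
    valid = np.convolve(head, kernel, mode="valid")
    half = smooth_window // 2
    smoothed = np.full(head_len, np.nan)
    smoothed[half : head_len - half] = valid

    d2 = np.diff(valid, 2)  # d2[k] is the curvature at head rank k + 1 + half
    mag = np.abs(d2).max() if d2.size else 0.0
    scale = max(abs(head[0]), abs(head[-1]), 1.0)
    tol = max(curvature_tol * mag, 1e-12 * scale)

    rank = _dominant_knee(d2, tol)
    if rank is not None:
        rank = rank + 1 + half
        rank = _snap_to_drop_foot(head, rank, smooth_window, snap_factor)
        return ThresholdResult(
            threshold=float(head[rank]),
            inflection_rank=int(rank),
            sorted_values=head,
            smoothed=smoothed,
            smooth_window=smooth_window,
            fallback_used=False,
        )

    fb_rank = min(int(math.floor((1.0 - fallback_quantile) * n)), head_len - 1)
    warnings.warn(
        "no inflection point found on the sorted curve; falling back to the "
        f"value at the {fallback_quantile:.2f} upper quantile (rank {fb_rank})",
        FallbackThresholdWarning,
        stacklevel=2,
    )
    return ThresholdResult(
        threshold=float(head[fb_rank]),
        inflection_rank=int(fb_rank),
        sorted_values=head,
        smoothed=smoothed,
        smooth_window=smooth_window,
        fallback_used=True,
    )


def _dominant_knee(d2: np.ndarray, tol: float) -> int | None:
    """Onset index of the convex run containing the largest curvature.

    The dominant knee is argmax(d2); the reported inflection is the first
    index of the contiguous run of significantly positive second
    differences that contains it — where the curve's sharpest leveling-off
    begins.  Returns None when the curve never bends upward significantly
    (no knee exists).
    """
    if d2.size == 0 or d2.max() <= tol:
        return None
    k = int(np.argmax(d2))
    while k > 0 and d2[k - 1] > tol:
        k -= 1
    return k


def _snap_to_drop_foot(
    head: np.ndarray, rank: int, smooth_window: int, snap_factor: float
) -> int:
    """Walk ``rank`` back up the curve to the foot of the last steep drop.

    Smoothing delays knee detection by up to half a window when the curve
    falls off a cliff; this realigns the rank with the raw curve.  A step
    is 'steep' when it exceeds ``snap_factor`` times the head's mean
    per-rank step.  If no steep step occurs within one window, the rank is
    kept as detected (the curve is genuinely smooth there).
    """
    if head.size < 2:
        return rank
    step_tol = snap_factor * (head[0] - head[-1]) / (head.size - 1)
    if step_tol <= 0:
        return rank
    lo = max(rank - smooth_window, 1)
    for j in range(rank, lo - 1, -1):
        if head[j - 1] - head[j] > step_tol:
            return j
    return rank


def threshold_diagnostics(result: ThresholdResult) -> pd.DataFrame:
    """Curve table for plotting: rank, raw value, smoothed value, chosen flag."""
    n = result.sorted_values.size
    frame = pd.DataFrame(
        {
            "rank": np.arange(n),
            "value": result.sorted_values,
            "smoothed": result.smoothed,
        }
    )
    frame["selected"] = frame["rank"] == result.inflection_rank
    return frame
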