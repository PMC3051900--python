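"""Within-array intensity normalization for two-channel arrays.

The observed methylation signal per probe is M = log2(Cy5/Cy3), the log
ratio of the test (red) over the common normal reference (green)
channel.  Intensity-dependent dye bias shows up as a smooth trend of M
against the average log intensity A = (log2 R + log2 G) / 2; it is
removed per array by subtracting a robust LOESS fit of M on A (local
linear, tricube weights).  Arrays are normalized independently — no
between-array step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

__all__ = ["TwoChannelArray", "compute_ma", "loess_normalize", "normalize_arrays"]

#: default LOESS span (fraction of points in each local window)
DEFAULT_SPAN = 0.3
#: robustness (bisquare reweighting) iterations
ROBUST_ITER = 3
#: below this many complete (M, A) pairs the smoother is unreliable
MIN_PAIRS = 20


@dataclass
class TwoChannelArray:
    """Raw per-probe intensities of one array (Cy5 = test, Cy3 = reference)."""

    sample_id: str
    red: np.ndarray
    green: np.ndarray

    def __post_init__(self):
        self.red = np.asarray(self.red, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        if self.red.shape != self.green.shape:
            raise ValueError(
                f"array {self.sample_id}: red and green lengths differ "
                f"({self.red.size} vs {self.green.size})"
            )


def compute_ma(array: TwoChannelArray) -> tuple[np.ndarray, np.ndarray]:
    """M/A transform: M = log2(red/green), A = (log2 red + log2 green)/2.

    Missing intensities (NaN in either channel) give missing M and A;
    non-positive intensities are an error (they have no log).
    """
    red, green = array.red, array.green
    present = ~(np.isnan(red) | np.isnan(green))
    bad = present & ((red <= 0) | (green <= 0))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"array {array.sample_id}: non-positive intensity at probe index {i} "
            f"(red={red[i]}, green={green[i]})"
        )
    with np.errstate(invalid="ignore"):
        lr = np.where(present, np.log2(np.where(present, red, 1.0)), np.nan)
        lg = np.where(present, np.log2(np.where(present, green, 1.0)), np.nan)
    return lr - lg, (lr + lg) / 2.0


def loess_normalize(M, A, span: float = DEFAULT_SPAN) -> np.ndarray:
    """Subtract the LOESS trend of M on A (per-array dye-bias correction).

    Local linear smoother with tricube weights and ``ROBUST_ITER``
    bisquare robustness iterations.  With fewer than ``MIN_PAIRS``
    complete pairs the input is returned unchanged with a warning.
    """
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    if M.shape != A.shape:
        raise ValueError("M and A must have the same length")
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must be in (0, 1], got {span}")
    present = ~(np.isnan(M) | np.isnan(A))
    n = int(present.sum())
    if n < MIN_PAIRS:
        warnings.warn(
            f"only {n} complete (M, A) pairs (< {MIN_PAIRS}); "
            "returning M without dye-bias correction",
            UserWarning,
            stacklevel=2,
        )
        logger.warning("loess_normalize skipped: %d complete pairs", n)
        return M.copy()
    trend = lowess(
        M[present],
        A[present],
        frac=span,
        it=ROBUST_ITER,
        return_sorted=False,
    )
    out = M.copy()
    out[present] = M[present] - trend
    return out


def normalize_arrays(arrays, span: float = DEFAULT_SPAN):
    """M/A transform + LOESS correction of a list of two-channel arrays.

    Returns ``(sample_ids, M_matrix)`` with M as probes x samples,
    missing-aware.  Each array is corrected independently.
    """
    sample_ids = []
    cols = []
    for arr in arrays:
        M, A = compute_ma(arr)
        cols.append(loess_normalize(M, A, span=span))
        sample_ids.append(arr.sample_id)
    return sample_ids, np.column_stack(cols)
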