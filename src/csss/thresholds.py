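"""Per-process amplitude cutoffs from the sorted-lambda ("sigmoid") curve.

A process counts as active in a cell only when the cell's amplitude falls in
a tail of the pooled amplitude distribution. Two cut rules are provided:

* ``quantile`` — symmetric empirical quantiles at ``tail_fraction`` and
  ``1 - tail_fraction``; fully deterministic and auditable.
* ``knee`` — on each half of the sorted amplitude curve, the point of
  maximum distance to the chord on the convex (bulk-corner) side, i.e. the
  elbow where the central bulk gives way to the tail. This mimics reading
  the tails off a sigmoid plot and adapts the cut to however many cells
  actually carry the process. Near-linear halves (no discernible elbow)
  fall back to the quantile cut with a warning.

Thresholds are always computed on the pooled population (all conditions
together) so that condition comparisons use a common ruler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .sa import Decomposition

__all__ = ["TailThresholder", "ThresholdSet", "compute_thresholds"]

#: max-distance below this (normalized units) means "no elbow": fall back
KNEE_DEGENERATE_TOL = 1e-3


def _knee_cut_upper(half: np.ndarray) -> tuple[float, float]:
    """Elbow of an ascending bulk-to-tail curve.

    Returns (cut_value, normalized max distance). The curve is normalized to
    the unit square; distance is measured below the chord y = x, where the
    corner between the flat central bulk and the rising tail lives. The
    max-distance point locates the bend; the cut is then placed at the point
    of maximum discrete curvature beyond it — the middle of the largest
    value gap in the tail segment — so that a genuinely separated carrier
    mode ends up wholly on the active side while the bulk's own smooth tail
    stays inactive.
    """
    m = half.size
    span = half[-1] - half[0]
    if m < 3 or span <= 0:
        return half[-1] if m else np.nan, 0.0
    x = np.linspace(0.0, 1.0, m)
    y = (half - half[0]) / span
    d = x - y                      # positive where the curve sags below the chord
    j = int(np.argmax(d))
    tail = half[j:]
    if tail.size >= 2:
        gaps = np.diff(tail)
        g = int(np.argmax(gaps))
        cut = float(0.5 * (tail[g] + tail[g + 1]))
    else:
        cut = float(half[j])
    return cut, float(d[j])


class TailThresholder(TransformerMixin, BaseEstimator):
    """Learn lower/upper amplitude cuts per process; transform to activity calls.

    Parameters
    ----------
    method : {"knee", "quantile"}, default "knee"
    tail_fraction : float in (0, 0.25], default 0.05
        Tail mass per side for the quantile method (also the fallback for
        degenerate knee halves).
    sides : {"both", "upper", "lower"}, default "both"
        Which tails mark a process active.

    Attributes
    ----------
    lower_cuts_, upper_cuts_ : ndarray, shape (n_processes,)
    active_fraction_ : realized fraction of cells active per process.
    method_used_ : list of per-process method actually applied.

    ``transform`` maps an amplitude matrix to a signed ternary activity
    matrix: +1 above the upper cut, -1 below the lower cut, 0 inside.
    """

    def __init__(self, method: str = "knee", tail_fraction: float = 0.05,
                 sides: str = "both"):
        self.method = method
        self.tail_fraction = tail_fraction
        self.sides = sides

    def fit(self, X, y=None):
        if self.method not in ("knee", "quantile"):
            raise ValueError(f"method must be 'knee' or 'quantile', got {self.method!r}")
        if not 0.0 < self.tail_fraction <= 0.25:
            raise ValueError(f"tail_fraction must be in (0, 0.25], got {self.tail_fraction}")
        if self.sides not in ("both", "upper", "lower"):
            raise ValueError(f"sides must be both/upper/lower, got {self.sides!r}")
        X = check_array(X, dtype=np.float64, ensure_min_features=1)
        n, k = X.shape
        lower = np.empty(k)
        upper = np.empty(k)
        used: list[str] = []
        for a in range(k):
            col = np.sort(X[:, a])
            q_lo = float(np.quantile(col, self.tail_fraction))
            q_hi = float(np.quantile(col, 1.0 - self.tail_fraction))
            if col[0] == col[-1]:           # constant column: nothing is ever active
                lower[a], upper[a] = col[0], col[0]
                used.append("constant")
                continue
            if self.method == "quantile":
                lower[a], upper[a] = q_lo, q_hi
                used.append("quantile")
                continue
            mid = n // 2
            up_cut, up_d = _knee_cut_upper(col[mid:])
            lo_half = -col[: mid + 1][::-1]     # mirror: ascending bulk -> tail
            lo_cut_m, lo_d = _knee_cut_upper(lo_half)
            lo_cut = -lo_cut_m
            how = "knee"
            if up_d <= KNEE_DEGENERATE_TOL:
                up_cut = q_hi
                how = "knee+quantile-fallback"
                warnings.warn(f"process {a + 1}: degenerate upper knee, using quantile cut",
                              RuntimeWarning, stacklevel=2)
            if lo_d <= KNEE_DEGENERATE_TOL:
                lo_cut = q_lo
                how = "knee+quantile-fallback"
                warnings.warn(f"process {a + 1}: degenerate lower knee, using quantile cut",
                              RuntimeWarning, stacklevel=2)
            # the central interval must keep the majority of cells
            inside = np.mean((X[:, a] >= lo_cut) & (X[:, a] <= up_cut))
            if inside < 0.5:
                warnings.warn(
                    f"process {a + 1}: knee cuts left only {inside:.0%} of cells in the "
                    "central interval; falling back to quantile cuts",
                    RuntimeWarning, stacklevel=2,
                )
                lo_cut, up_cut = q_lo, q_hi
                how = "quantile-fallback"
            lower[a], upper[a] = lo_cut, up_cut
            used.append(how)
        if self.sides == "upper":
            lower = np.array([np.min(X[:, a]) for a in range(k)])
        elif self.sides == "lower":
            upper = np.array([np.max(X[:, a]) for a in range(k)])
        self.lower_cuts_ = lower
        self.upper_cuts_ = upper
        self.method_used_ = used
        self.n_features_in_ = k
        act = self.transform(X)
        self.active_fraction_ = np.mean(act != 0, axis=0)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "lower_cuts_")
        X = check_array(X, dtype=np.float64)
        out = np.zeros(X.shape, dtype=np.int8)
        out[X > self.upper_cuts_] = 1
        out[X < self.lower_cuts_] = -1
        return out


@dataclass
class ThresholdSet:
    """Per-process amplitude cutoffs (processes indexed from 1)."""

    lower_cuts: np.ndarray
    upper_cuts: np.ndarray
    method: str
    params: dict
    method_used: list[str]
    active_fraction: np.ndarray

    @property
    def n_processes(self) -> int:
        return len(self.lower_cuts)

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(range(1, self.n_processes + 1), name="process")
        return pd.DataFrame(
            {
                "lower_cut": self.lower_cuts,
                "upper_cut": self.upper_cuts,
                "method": self.method_used,
                "params": [repr(self.params)] * self.n_processes,
                "active_fraction": self.active_fraction,
            },
            index=idx,
        )


def compute_thresholds(
    dec: Decomposition,
    method: str = "knee",
    tail_fraction: float = 0.05,
    sides: str = "both",
) -> ThresholdSet:
    """Cut the pooled amplitude distribution of every constraint process.

    Operates on the Decomposition's lambda columns 1..K (the reference
    amplitude is never thresholded).
    """
    if dec.n_processes < 1:
        raise ValueError("decomposition has no constraint processes to threshold")
    est = TailThresholder(method=method, tail_fraction=tail_fraction, sides=sides)
    est.fit(dec.Lambda[:, 1:])
    return ThresholdSet(
        lower_cuts=est.lower_cuts_.copy(),
        upper_cuts=est.upper_cuts_.copy(),
        method=method,
        params={"tail_fraction": tail_fraction, "sides": sides},
        method_used=list(est.method_used_),
        active_fraction=est.active_fraction_.copy(),
    )
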