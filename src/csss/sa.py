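"""Single-cell surprisal analysis: the covariance/SVD route.

The model treats each cell's measured protein levels ``X_i(cell)`` as a
reference (steady-state) level modulated by a small number of unbalanced
processes:

    ln X_i(cell) = G_i0 * lambda_0(cell) + sum_a G_ia * lambda_a(cell)

where the alpha = 0 term is the reference state, ``G_ia`` is the weight of
protein *i* in process *alpha* (columns of G are orthonormal), and
``lambda_a(cell)`` is the per-cell amplitude of the process. We store the
amplitudes so that reconstruction is a plain sum ``G @ lambda`` — i.e. the
conventional minus sign inside the exponential is absorbed into lambda —
and all downstream up/down-regulation logic is defined on the stored
product ``G_ia * lambda_a(cell)``.

Fitting runs the SVD through the small n_markers x n_markers second-moment
matrix ``C.T @ C`` of the log matrix ``C = ln(X + offset)``, never through
the n_cells x n_cells matrix, so memory and time scale linearly with the
number of cells. With m markers at most m - 1 constraint processes can be
resolved on top of the steady state (10 for an 11-marker panel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import ExpressionMatrix

__all__ = [
    "SurprisalAnalysis",
    "Decomposition",
    "fit_surprisal",
    "reference_state",
    "deviation_terms",
]

#: relative singular-value floor defining the numerical rank of the log matrix
RANK_RTOL = 1e-12


def _fix_signs(G: np.ndarray, Lam: np.ndarray) -> None:
    """Resolve SVD sign ambiguity in place: make each G column's
    largest-|entry| component positive, flipping lambda to match."""
    for a in range(G.shape[1]):
        j = int(np.argmax(np.abs(G[:, a])))
        if G[j, a] < 0:
            G[:, a] *= -1.0
            Lam[:, a] *= -1.0


class SurprisalAnalysis(TransformerMixin, BaseEstimator):
    """Surprisal-analysis decomposition of a cells x markers panel.

    Parameters
    ----------
    offset : float, default 1.0
        Positive constant added before the natural logarithm so zero
        intensities are admissible; logged in the fitted model for audit.
    n_processes : int or None, default None
        Cap on the number of constraint processes kept (besides the
        reference term). None keeps every process above the rank floor.

    Attributes
    ----------
    components_ : ndarray, shape (k_ + 1, n_features)
        Orthonormal weight patterns; row 0 is the reference-state pattern,
        rows 1..k_ the constraint processes in decreasing importance.
    singular_values_ : ndarray, shape (k_ + 1,)
        Nonincreasing importance values (singular values of the log matrix).
    k_ : int
        Number of constraint processes retained (excludes the reference).
    feature_names_in_ : marker names, when fitted from a DataFrame
        or :class:`~csss.io.ExpressionMatrix`.

    Notes
    -----
    ``transform`` returns the per-cell amplitude matrix ``lambda`` with
    column 0 the reference amplitude; ``inverse_transform`` maps amplitudes
    back to intensities.
    """

    def __init__(self, offset: float = 1.0, n_processes: int | None = None):
        self.offset = offset
        self.n_processes = n_processes

    def _log_matrix(self, X) -> np.ndarray:
        if isinstance(X, ExpressionMatrix):
            X = X.values
        X = check_array(X, dtype=np.float64, ensure_min_features=2)
        shifted = X + self.offset
        if np.any(shifted <= 0):
            raise ValueError(
                f"nonpositive value after adding offset={self.offset}; "
                "intensities must satisfy x + offset > 0"
            )
        return np.log(shifted)

    def fit(self, X, y=None):
        if self.offset <= 0:
            raise ValueError(f"offset must be > 0, got {self.offset}")
        names = None
        if isinstance(X, ExpressionMatrix):
            names = list(X.marker_names)
        elif isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
        C = self._log_matrix(X)
        n_cells, n_markers = C.shape
        if n_cells < n_markers:
            raise ValueError(f"need n_cells >= n_markers ({n_cells} < {n_markers})")

        # small symmetric second-moment matrix: m x m, independent of n_cells
        M = C.T @ C
        evals, evecs = eigh(M)          # ascending
        evals = evals[::-1]
        evecs = evecs[:, ::-1]
        svals = np.sqrt(np.clip(evals, 0.0, None))

        # the rank floor is applied to the eigenvalues of C.T C (the quantities
        # actually diagonalized): their absolute error scales with eps * trace,
        # so a relative floor on the singular values themselves would mistake
        # eigen-solver noise (~sqrt(eps) on the singular scale) for signal
        rank = int(np.sum(evals > RANK_RTOL * max(evals[0], np.finfo(float).tiny)))
        rank = max(rank, 1)
        if rank < n_markers:
            warnings.warn(
                f"log matrix is rank deficient (rank {rank} < {n_markers} markers); "
                f"keeping {rank - 1} constraint process(es)",
                RuntimeWarning,
                stacklevel=2,
            )
        k = rank - 1
        if self.n_processes is not None:
            k = min(k, int(self.n_processes))
        keep = k + 1

        G = evecs[:, :keep].copy()
        Lam = C @ G
        _fix_signs(G, Lam)

        self.components_ = G.T
        self.singular_values_ = svals[:keep]
        self.k_ = k
        self.rank_ = rank
        self.n_features_in_ = n_markers
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)
        self._fit_lambda_ = Lam
        return self

    def transform(self, X) -> np.ndarray:
        """Project cells onto the fitted processes: lambda = ln(X+offset) @ G."""
        check_is_fitted(self, "components_")
        C = self._log_matrix(X)
        return C @ self.components_.T

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return self._fit_lambda_

    def inverse_transform(self, Lam) -> np.ndarray:
        """Map amplitudes back to intensities: exp(lambda @ G) - offset."""
        check_is_fitted(self, "components_")
        Lam = np.asarray(Lam, dtype=np.float64)
        return np.clip(np.exp(Lam @ self.components_) - self.offset, 0.0, None)


@dataclass
class Decomposition:
    """Fitted surprisal-analysis factors for one cell population.

    ``G`` is n_markers x (K+1) with column 0 the reference pattern;
    ``Lambda`` is n_cells x (K+1); ``importance`` the nonincreasing singular
    values. Reconstruction: ``ln(X + offset) = Lambda @ G.T``.
    """

    G: np.ndarray
    Lambda: np.ndarray
    importance: np.ndarray
    offset: float
    marker_names: list[str]
    cell_ids: list[str]
    sample_labels: np.ndarray | None = None

    @property
    def n_processes(self) -> int:
        return self.G.shape[1] - 1

    @property
    def n_cells(self) -> int:
        return self.Lambda.shape[0]

    def g_frame(self) -> pd.DataFrame:
        cols = ["reference"] + [f"process_{a}" for a in range(1, self.G.shape[1])]
        return pd.DataFrame(self.G, index=pd.Index(self.marker_names, name="marker"), columns=cols)

    def lambda_frame(self) -> pd.DataFrame:
        cols = ["lambda_0"] + [f"lambda_{a}" for a in range(1, self.Lambda.shape[1])]
        df = pd.DataFrame(self.Lambda, index=pd.Index(self.cell_ids, name="cell_id"), columns=cols)
        if self.sample_labels is not None:
            df.insert(0, "sample", self.sample_labels)
        return df

    def importance_frame(self) -> pd.DataFrame:
        idx = pd.Index(range(len(self.importance)), name="process")
        return pd.DataFrame({"importance": self.importance}, index=idx)


def fit_surprisal(
    data: ExpressionMatrix,
    offset: float = 1.0,
    max_processes: int | None = None,
) -> Decomposition:
    """Fit the surprisal decomposition to an expression matrix.

    Thin functional wrapper over :class:`SurprisalAnalysis` that carries the
    marker/cell metadata through.
    """
    est = SurprisalAnalysis(offset=offset, n_processes=max_processes)
    Lam = est.fit_transform(data)
    return Decomposition(
        G=est.components_.T.copy(),
        Lambda=Lam,
        importance=est.singular_values_.copy(),
        offset=offset,
        marker_names=list(data.marker_names),
        cell_ids=list(data.cell_ids),
        sample_labels=None if data.sample_labels is None else data.sample_labels.copy(),
    )


def reference_state(dec: Decomposition) -> np.ndarray:
    """Reference-state intensities from the alpha = 0 term alone.

    Entrywise ``exp(G_i0 * lambda_0(cell)) - offset``, clipped at 0.
    """
    log_ref = np.outer(dec.Lambda[:, 0], dec.G[:, 0])
    return np.clip(np.exp(log_ref) - dec.offset, 0.0, None)


def deviation_terms(dec: Decomposition, alpha: int) -> np.ndarray:
    """Signed log-scale deviation attributable to process ``alpha``.

    Entry (cell, i) is ``G_i_alpha * lambda_alpha(cell)``; a positive product
    means protein *i* is upregulated in that cell by this process.
    """
    if not 1 <= alpha <= dec.n_processes:
        raise IndexError(f"alpha must be in 1..{dec.n_processes}, got {alpha}")
    return np.outer(dec.Lambda[:, alpha], dec.G[:, alpha])
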