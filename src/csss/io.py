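"""Reading and writing single-cell expression matrices and analysis tables.

The on-disk interchange format is delimited text (comma or tab, auto-detected
on read); FCS 3.0/3.1 files are supported read-only for raw cytometry input.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._fcs import read_fcs

logger = logging.getLogger(__name__)

__all__ = ["ExpressionMatrix", "read_expression", "write_expression", "concat_conditions"]


@dataclass
class ExpressionMatrix:
    """Cells x markers nonnegative intensity matrix with per-cell metadata.

    Attributes
    ----------
    values : ndarray, shape (n_cells, n_markers)
        Fluorescence intensities, arbitrary units, all finite and >= 0.
    marker_names : list of str
        Unique, ordered marker (protein) names.
    cell_ids : list of str
        Ordered cell identifiers.
    sample_labels : ndarray of str, shape (n_cells,)
        Condition / timepoint tag per cell (e.g. "control", "RT_d6").
    """

    values: np.ndarray
    marker_names: list[str]
    cell_ids: list[str] = field(default_factory=list)
    sample_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x markers matrix")
        n_cells, n_markers = self.values.shape
        if n_markers < 2:
            raise ValueError(f"need at least 2 markers, got {n_markers}")
        if n_cells < n_markers:
            raise ValueError(
                f"need n_cells >= n_markers for the covariance route "
                f"({n_cells} cells < {n_markers} markers)"
            )
        if len(self.marker_names) != n_markers:
            raise ValueError("marker_names length does not match values")
        if len(set(self.marker_names)) != n_markers:
            raise ValueError("marker_names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must all be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be nonnegative")
        if not self.cell_ids:
            self.cell_ids = [f"cell{j}" for j in range(n_cells)]
        elif len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match values")
        if self.sample_labels is None:
            self.sample_labels = np.full(n_cells, "sample", dtype=object)
        else:
            self.sample_labels = np.asarray(self.sample_labels, dtype=object)
            if self.sample_labels.shape != (n_cells,):
                raise ValueError("sample_labels length does not match values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.marker_names,
                          index=pd.Index(self.cell_ids, name="cell_id"))
        df.insert(0, "sample", self.sample_labels)
        return df

    def subset_markers(self, markers: Sequence[str]) -> "ExpressionMatrix":
        missing = [m for m in markers if m not in self.marker_names]
        if missing:
            raise KeyError(f"unknown marker(s): {missing}; available: {self.marker_names}")
        idx = [self.marker_names.index(m) for m in markers]
        return ExpressionMatrix(self.values[:, idx], list(markers),
                                list(self.cell_ids), self.sample_labels.copy())


def _read_delimited(path: Path, sample_label: str | None) -> ExpressionMatrix:
    # sniff delimiter from the header line
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    # round_trip: exact float64 recovery of %.17g-formatted values
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected >=2 columns, got {df.shape[1]}")

    cell_ids: list[str] | None = None
    labels: np.ndarray | None = None
    # optional leading non-numeric columns: cell id and/or sample label
    while df.shape[1] > 1:
        first = df.iloc[:, 0]
        if pd.api.types.is_numeric_dtype(first):
            break
        name = df.columns[0].strip().lower()
        if name in ("sample", "condition", "label", "sample_label"):
            labels = first.astype(str).to_numpy(dtype=object)
        elif cell_ids is None:
            cell_ids = first.astype(str).tolist()
        else:
            raise ValueError(f"{path}: multiple non-numeric leading columns ({df.columns[0]!r})")
        df = df.iloc[:, 1:]

    markers = [str(c).strip() for c in df.columns]
    values = np.empty(df.shape, dtype=np.float64)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=np.float64)
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(bad.isna().idxmax())
            raise ValueError(
                f"{path}: non-numeric entry {df[col].iloc[row]!r} at data row {row}, "
                f"column {markers[j]!r}"
            ) from None
    if labels is None and sample_label is not None:
        labels = np.full(values.shape[0], sample_label, dtype=object)
    return ExpressionMatrix(values, markers, cell_ids or [], labels)


def read_expression(
    path: str | Path,
    format: str | None = None,
    marker_subset: Sequence[str] | None = None,
    channel_map: Mapping[str, str] | None = None,
    sample_label: str | None = None,
) -> ExpressionMatrix:
    """Read a cells x markers expression matrix.

    Parameters
    ----------
    path : path to a delimited text file (one header row of marker names,
        optional leading cell-id and/or "sample" columns) or an FCS 3.0/3.1 file.
    format : "delimited" or "fcs"; inferred from the file suffix when None.
    marker_subset : restrict (and reorder) to these markers.
    channel_map : FCS only — mapping from instrument channel name to marker
        name; unmapped channels are dropped. Required to rename channels since
        panel naming is instrument specific.
    sample_label : condition tag applied to every cell (when the file itself
        carries no "sample" column).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "delimited"
    if format == "delimited":
        mat = _read_delimited(path, sample_label)
    elif format == "fcs":
        events, channels, _ = read_fcs(path)
        if channel_map:
            keep = [j for j, ch in enumerate(channels) if ch in channel_map]
            if not keep:
                raise KeyError(f"channel_map matches no channel of {channels}")
            events = events[:, keep]
            channels = [channel_map[channels[j]] for j in keep]
        n_clip = int(np.sum(events < 0))
        if n_clip:
            logger.warning("%s: clipped %d negative post-compensation values to 0", path, n_clip)
            events = np.clip(events, 0.0, None)
        labels = np.full(events.shape[0], sample_label, dtype=object) if sample_label else None
        mat = ExpressionMatrix(events, channels, [], labels)
    else:
        raise ValueError(f"unknown format {format!r}; use 'delimited' or 'fcs'")
    if marker_subset is not None:
        mat = mat.subset_markers(list(marker_subset))
    return mat


def write_expression(mat: ExpressionMatrix, path: str | Path, sep: str = ",") -> None:
    """Write an expression matrix as delimited text (round-trips with read)."""
    # %.17g guarantees float64 values survive a write -> read cycle exactly
    mat.to_frame().to_csv(path, sep=sep, index=True, float_format="%.17g")


def concat_conditions(matrices: Iterable[ExpressionMatrix]) -> ExpressionMatrix:
    """Row-stack matrices measured under different conditions.

    All inputs must share identical marker names in identical order; per-cell
    sample labels are preserved so downstream condition comparisons still see
    which cell came from which input.
    """
    mats = list(matrices)
    if not mats:
        raise ValueError("no matrices to concatenate")
    ref = mats[0].marker_names
    for m in mats[1:]:
        if m.marker_names != ref:
            raise ValueError(f"marker mismatch: {m.marker_names} != {ref}")
    values = np.vstack([m.values for m in mats])
    labels = np.concatenate([m.sample_labels for m in mats])
    ids = [cid for m in mats for cid in m.cell_ids]
    if len(set(ids)) != len(ids):
        ids = [f"{lab}:{cid}" for m in mats for lab, cid in zip(m.sample_labels, m.cell_ids)]
    return ExpressionMatrix(values, list(ref), ids, labels)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=index)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=index_col)
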