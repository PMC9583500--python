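"""CSSS barcodes: each cell's set of significantly active processes.

A cell's barcode is a length-K vector over {-1, 0, +1} (signed mode; the
default, since process direction carries the biology) or {0, 1} (binary
mode, which reproduces presentations that only distinguish active from
inactive). Cells sharing a barcode form a subpopulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sa import Decomposition
from .thresholds import TailThresholder, ThresholdSet

__all__ = [
    "BarcodeAssignment",
    "assign_barcodes",
    "barcode_to_string",
    "tabulate_subpopulations",
]

_CHR = {-1: "-", 0: "0", 1: "+"}


def barcode_to_string(code: np.ndarray) -> str:
    """Render a barcode vector as a compact +/-/0 string, e.g. '00+0-'."""
    return "".join(_CHR[int(v)] for v in code)


@dataclass
class BarcodeAssignment:
    """Per-cell barcodes over the K constraint processes."""

    codes: np.ndarray            # (n_cells, K) int8 in {-1,0,1} or {0,1}
    mode: str                    # "signed" | "binary"
    cell_ids: list[str]
    sample_labels: np.ndarray

    @property
    def n_processes(self) -> int:
        return self.codes.shape[1]

    @property
    def n_cells(self) -> int:
        return self.codes.shape[0]

    def strings(self) -> np.ndarray:
        return np.asarray([barcode_to_string(row) for row in self.codes], dtype=object)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"sample": self.sample_labels, "barcode": self.strings()},
            index=pd.Index(self.cell_ids, name="cell_id"),
        )
        for a in range(self.n_processes):
            df[f"process_{a + 1}"] = self.codes[:, a]
        return df


def assign_barcodes(
    dec: Decomposition,
    thr: ThresholdSet,
    mode: str = "signed",
) -> BarcodeAssignment:
    """Threshold each cell's amplitudes into its CSSS barcode.

    ``barcode[a] != 0`` iff the cell's lambda for process a lies outside the
    central interval [lower_cut, upper_cut]; the sign records whether the
    cell sits in the upper (+) or lower (-) tail.
    """
    if mode not in ("signed", "binary"):
        raise ValueError(f"mode must be 'signed' or 'binary', got {mode!r}")
    if thr.n_processes != dec.n_processes:
        raise ValueError(
            f"threshold set covers {thr.n_processes} processes but the decomposition "
            f"has {dec.n_processes}"
        )
    est = TailThresholder()
    est.lower_cuts_ = thr.lower_cuts
    est.upper_cuts_ = thr.upper_cuts
    est.n_features_in_ = thr.n_processes
    codes = est.transform(dec.Lambda[:, 1:])
    if mode == "binary":
        codes = np.abs(codes)
    labels = dec.sample_labels
    if labels is None:
        labels = np.full(dec.n_cells, "sample", dtype=object)
    return BarcodeAssignment(codes=codes, mode=mode,
                             cell_ids=list(dec.cell_ids), sample_labels=labels.copy())


def _letter_labels(n: int) -> list[str]:
    """a, b, ..., z, aa, ab, ... reproducible naming by abundance rank."""
    out = []
    for r in range(n):
        s, q = "", r
        while True:
            s = chr(ord("a") + q % 26) + s
            q = q // 26 - 1
            if q < 0:
                break
        out.append(s)
    return out


def tabulate_subpopulations(
    bars: BarcodeAssignment,
    abundance_floor: float = 0.01,
    floor_scope: str = "any_condition",
) -> pd.DataFrame:
    """Count and label barcode-defined subpopulations per condition.

    Returns a DataFrame indexed by barcode string with per-condition
    ``count_<cond>`` and ``frac_<cond>`` columns, a reproducible letter
    ``label`` (descending pooled abundance, ties broken by barcode string;
    the quiescent all-zero barcode is labelled "0"), and a ``dominant`` flag:
    fraction >= ``abundance_floor`` in at least one condition
    (``floor_scope="any_condition"``) or pooled (``"pooled"``). The all-zero
    barcode is never flagged dominant — it denotes cells with no active
    process, not a signature-bearing subpopulation. Rare barcodes are
    retained (never dropped), merely left unflagged.
    """
    if not 0.0 <= abundance_floor < 1.0:
        raise ValueError(f"abundance_floor must be in [0, 1), got {abundance_floor}")
    if floor_scope not in ("any_condition", "pooled"):
        raise ValueError(f"floor_scope must be 'any_condition' or 'pooled', got {floor_scope!r}")

    strings = bars.strings()
    conditions = list(pd.unique(bars.sample_labels))
    for cond in conditions:
        if not np.any(bars.sample_labels == cond):
            raise ValueError(f"condition {cond!r} has no cells")

    df = pd.DataFrame({"barcode": strings, "sample": bars.sample_labels})
    counts = df.groupby(["barcode", "sample"], sort=False).size().unstack(fill_value=0)
    counts = counts.reindex(columns=conditions, fill_value=0)

    n_per = counts.sum(axis=0)
    fracs = counts / n_per

    zero_code = "0" * bars.n_processes
    pooled = counts.sum(axis=1) / counts.values.sum()

    # order: descending pooled abundance, ties lexicographic by barcode
    order = sorted(counts.index, key=lambda b: (-pooled[b], b))
    counts = counts.loc[order]
    fracs = fracs.loc[order]
    pooled = pooled.loc[order]

    nonzero = [b for b in order if b != zero_code]
    labels = dict(zip(nonzero, _letter_labels(len(nonzero))))
    if zero_code in counts.index:
        labels[zero_code] = "0"

    if floor_scope == "any_condition":
        dominant = (fracs >= abundance_floor).any(axis=1)
    else:
        dominant = pooled >= abundance_floor
    dominant = dominant & (counts.index != zero_code)

    out = pd.DataFrame(index=counts.index)
    out.index.name = "barcode"
    out["label"] = [labels[b] for b in counts.index]
    for cond in conditions:
        out[f"count_{cond}"] = counts[cond].astype(int)
    for cond in conditions:
        out[f"frac_{cond}"] = fracs[cond]
    out["pooled_frac"] = pooled
    out["dominant"] = dominant
    out.attrs["conditions"] = conditions
    out.attrs["n_cells"] = {c: int(n_per[c]) for c in conditions}
    out.attrs["abundance_floor"] = abundance_floor
    out.attrs["floor_scope"] = floor_scope
    return out
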