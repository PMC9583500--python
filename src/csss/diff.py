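"""Differential subpopulation abundance between conditions.

Fold changes are computed on per-condition fractions. A subpopulation that
was undetectable in the control (zero observed cells, i.e. fraction below
the detection floor) is reported as *emergent* with a conservative lower
bound on the fold change, never as infinity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

__all__ = ["compare_conditions"]


def compare_conditions(
    tab: pd.DataFrame,
    control_label: str,
    treated_label: str,
    detection_floor: float | None = None,
    abundance_floor: float | None = None,
    replicate_fractions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Compare subpopulation fractions between two conditions.

    Parameters
    ----------
    tab : subpopulation table from :func:`csss.tabulate_subpopulations`.
    control_label, treated_label : condition names (must differ and exist).
    detection_floor : fractions below this count as undetectable; defaults
        to ``1 / n_cells(control)`` (one observed cell).
    abundance_floor : floor used for the emergent flag; defaults to the
        table's own flagging floor.
    replicate_fractions : optional long table with columns
        ``barcode, condition, replicate, fraction``. When given, a two-sample
        t-test on per-replicate fractions replaces the two-proportion z-test,
        matching designs with several independent flasks/experiments.

    Returns
    -------
    DataFrame indexed by barcode with fractions, ``fold_change``
    (``treated/control``; for emergent rows a lower bound
    ``treated_fraction / detection_floor``), ``fold_change_display`` (the
    bound rendered as ``\">= x\"``), ``delta_fraction``, ``emergent``,
    ``p_value`` and Benjamini-Hochberg ``q_value``.
    """
    if control_label == treated_label:
        raise ValueError("control and treated labels must differ")
    for lab in (control_label, treated_label):
        if f"count_{lab}" not in tab.columns:
            raise KeyError(f"condition {lab!r} not present in the subpopulation table")

    n_ctrl = int(tab[f"count_{control_label}"].sum())
    n_trt = int(tab[f"count_{treated_label}"].sum())
    if detection_floor is None:
        detection_floor = 1.0 / n_ctrl
    if abundance_floor is None:
        abundance_floor = float(tab.attrs.get("abundance_floor", 0.01))

    f_ctrl = tab[f"frac_{control_label}"].to_numpy(dtype=float)
    f_trt = tab[f"frac_{treated_label}"].to_numpy(dtype=float)
    c_ctrl = tab[f"count_{control_label}"].to_numpy(dtype=int)
    c_trt = tab[f"count_{treated_label}"].to_numpy(dtype=int)

    emergent = (f_ctrl < detection_floor) & (f_trt >= abundance_floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(f_ctrl >= detection_floor, f_trt / np.where(f_ctrl > 0, f_ctrl, np.nan),
                        f_trt / detection_floor)
    display = np.asarray(
        [f">= {f:.3g}" if em else f"{f:.3g}" for f, em in zip(fold, emergent)],
        dtype=object,
    )

    if replicate_fractions is not None:
        pvals = _replicate_ttest(tab.index, replicate_fractions, control_label, treated_label)
        test = "t-test (replicates)"
    else:
        pvals = np.empty(len(tab))
        for j in range(len(tab)):
            if c_ctrl[j] + c_trt[j] == 0:
                pvals[j] = 1.0
                continue
            _, p = proportions_ztest([c_ctrl[j], c_trt[j]], [n_ctrl, n_trt])
            pvals[j] = 1.0 if np.isnan(p) else p
        test = "two-proportion z"

    qvals = multipletests(pvals, method="fdr_bh")[1]

    out = pd.DataFrame(index=tab.index.copy())
    if "label" in tab.columns:
        out["label"] = tab["label"]
    out[f"frac_{control_label}"] = f_ctrl
    out[f"frac_{treated_label}"] = f_trt
    out["delta_fraction"] = f_trt - f_ctrl
    out["fold_change"] = fold
    out["fold_change_display"] = display
    out["emergent"] = emergent
    out["p_value"] = pvals
    out["q_value"] = qvals
    out.attrs["control"] = control_label
    out.attrs["treated"] = treated_label
    out.attrs["detection_floor"] = detection_floor
    out.attrs["test"] = test
    return out


def _replicate_ttest(barcodes, reps: pd.DataFrame, control: str, treated: str) -> np.ndarray:
    required = {"barcode", "condition", "replicate", "fraction"}
    if not required.issubset(reps.columns):
        raise ValueError(f"replicate_fractions needs columns {sorted(required)}")
    pvals = np.ones(len(barcodes))
    for j, bc in enumerate(barcodes):
        sub = reps[reps["barcode"] == bc]
        a = sub.loc[sub["condition"] == control, "fraction"].to_numpy(dtype=float)
        b = sub.loc[sub["condition"] == treated, "fraction"].to_numpy(dtype=float)
        if len(a) >= 2 and len(b) >= 2:
            res = stats.ttest_ind(a, b, equal_var=True)
            pvals[j] = res.pvalue if np.isfinite(res.pvalue) else 1.0
    return pvals
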