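"""Compositional analysis of cell-type fractions.

Cell-type fraction vectors live on the simplex, so Euclidean statistics are
applied after the centered log-ratio (clr) transform,
``clr(x)_i = ln(x_i / g(x))`` with ``g`` the geometric mean, which maps the
simplex isometrically (Aitchison geometry) into the zero-sum hyperplane.
Per-cell-type distribution differences between control and a condition are
assessed with two-sample Kolmogorov-Smirnov tests under Benjamini-Hochberg
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def clr_transform(fractions: pd.DataFrame, zero_impute: float = 1e-6) -> pd.DataFrame:
    """Centered log-ratio transform with additive zero imputation.

    Zero entries receive ``zero_impute`` additively, the row is renormalized
    to sum to 1, and the clr map is applied. Output rows sum to 0.
    """
    vals = fractions.to_numpy(dtype=float).copy()
    if (vals < 0).any():
        raise ValueError("fractions must be nonnegative")
    row_sums = vals.sum(axis=1)
    if (row_sums == 0).any():
        bad = fractions.index[row_sums == 0].tolist()
        raise ValueError(f"rows of all zeros cannot be clr-transformed: {bad}")
    vals[vals == 0] += zero_impute
    vals /= vals.sum(axis=1, keepdims=True)
    log_vals = np.log(vals)
    clr = log_vals - log_vals.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=fractions.index, columns=fractions.columns)


@dataclass
class CompositionTestResult:
    condition: str
    cell_type: str
    ks_statistic: float
    p_value: float
    q_value: float


def test_composition_shifts(
    clr_ctrl: pd.DataFrame, clr_cond: pd.DataFrame, condition: str
) -> pd.DataFrame:
    """KS-test each cell type's clr distribution, control vs one condition.

    BH correction is applied across the cell types of this one
    condition-vs-control family. Results are sorted by q value. scipy's
    two-sample KS switches between the exact and asymptotic null
    automatically at small n; that default is kept.
    """
    if list(clr_ctrl.columns) != list(clr_cond.columns):
        raise ValueError("control and condition matrices must share cell-type columns")
    if len(clr_ctrl) < 3 or len(clr_cond) < 3:
        raise ValueError("KS test needs at least 3 samples per group")
    rows = []
    for cell_type in clr_ctrl.columns:
        res = stats.ks_2samp(clr_ctrl[cell_type], clr_cond[cell_type])
        rows.append(
            dict(
                condition=condition,
                cell_type=cell_type,
                ks_statistic=float(res.statistic),
                p_value=float(res.pvalue),
            )
        )
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(out["p_value"], method="fdr_bh")
    out["q_value"] = q
    return out.sort_values("q_value", kind="stable").reset_index(drop=True)
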