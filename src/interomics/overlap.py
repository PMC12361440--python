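"""Random-simulation FDR for the between-sex overlap of GA-regulated analytes.

The null distribution is built by repeatedly reassigning all samples at random
to two pseudo-groups of the same sizes as the real fetal-sex groups, re-running
the full per-group procedure (family selection, GLM fits, BH correction), and
recording how many analytes are called GA-regulated in both pseudo-groups.
The empirical FDR for the observed between-sex overlap count is the fraction
of iterations whose null overlap is strictly smaller than the observed one
("fewer" is strict; ties contribute nothing). The same construction yields
FDRs for the two overlap proportions (shared / significant-in-group).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adjust import call_ga_regulated, design_matrix, fit_layer
from .datatypes import OmicsLayer, align_layers, qualify, validate_cohort

logger = logging.getLogger(__name__)


@dataclass
class OverlapNullResult:
    observed_shared: int
    observed_n_a: int
    observed_n_b: int
    observed_prop_a: float
    observed_prop_b: float
    null_shared: np.ndarray
    null_prop_a: np.ndarray
    null_prop_b: np.ndarray
    fdr_count: float
    fdr_prop_a: float
    fdr_prop_b: float
    n_iter: int

    def to_dict(self) -> dict:
        return {
            "observed_shared": self.observed_shared,
            "observed_n_a": self.observed_n_a,
            "observed_n_b": self.observed_n_b,
            "observed_prop_a": self.observed_prop_a,
            "observed_prop_b": self.observed_prop_b,
            "null_shared": self.null_shared.tolist(),
            "null_prop_a": self.null_prop_a.tolist(),
            "null_prop_b": self.null_prop_b.tolist(),
            "fdr_count": self.fdr_count,
            "fdr_prop_a": self.fdr_prop_a,
            "fdr_prop_b": self.fdr_prop_b,
            "n_iter": self.n_iter,
        }


def _significant_set(
    layers: list[OmicsLayer], cohort_rows: pd.DataFrame, q_threshold: float
) -> set[str]:
    """GA-regulated (layer-qualified) analytes for one sample group.

    Family selection is re-run per group, mirroring the per-sex procedure.
    """
    X = design_matrix(cohort_rows)
    fits = []
    for layer in layers:
        for fit in fit_layer(layer, X):
            fits.append((layer.name, fit))
    call_ga_regulated([f for _, f in fits], q_threshold)
    return {qualify(name, f.analyte_id) for name, f in fits if f.significant_ga}


def empirical_fdr(null: np.ndarray, observed: float) -> float:
    """Fraction of null draws strictly below the observed value."""
    null = np.asarray(null, dtype=float)
    return float(np.mean(null < observed))


def simulate_overlap_null(
    layers: list[OmicsLayer],
    cohort: pd.DataFrame,
    n_iter: int = 100,
    seed: int = 0,
    group_sizes: tuple[int, int] | None = None,
    q_threshold: float = 0.05,
    stratify_by_sex: bool = False,
) -> OverlapNullResult:
    """Overlap null simulation with per-iteration GLM refits.

    Parameters
    ----------
    layers
        Preprocessed (imputed, no-missing) layers.
    cohort
        Cohort table; the observed overlap uses the true fetal-sex split.
    n_iter
        Number of random relabelings (the study used 100).
    group_sizes
        Sizes of the two pseudo-groups; defaults to the real female/male
        counts.
    stratify_by_sex
        If True, shuffle within each sex instead of unrestricted relabeling
        (variant behind a flag; the default matches the printed procedure).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    validate_cohort(cohort)
    align_layers(layers)
    rng = np.random.default_rng(seed)

    female_idx = cohort.index[cohort["fetal_sex"] == "female"]
    male_idx = cohort.index[cohort["fetal_sex"] == "male"]
    if group_sizes is None:
        group_sizes = (len(female_idx), len(male_idx))
    n_a, n_b = group_sizes
    if n_a + n_b > len(cohort):
        raise ValueError("group sizes exceed the cohort size")

    sig_f = _significant_set(layers, cohort.loc[female_idx], q_threshold)
    sig_m = _significant_set(layers, cohort.loc[male_idx], q_threshold)
    observed_shared = len(sig_f & sig_m)
    observed_prop_a = len(sig_f & sig_m) / len(sig_f) if sig_f else 0.0
    observed_prop_b = len(sig_f & sig_m) / len(sig_m) if sig_m else 0.0

    null_shared = np.zeros(n_iter, dtype=int)
    null_prop_a = np.zeros(n_iter)
    null_prop_b = np.zeros(n_iter)
    all_ids = np.asarray(cohort.index)
    for it in range(n_iter):
        if stratify_by_sex:
            perm_f = rng.permutation(np.asarray(female_idx))
            perm_m = rng.permutation(np.asarray(male_idx))
            half_f, half_m = len(perm_f) // 2, len(perm_m) // 2
            group_a = np.concatenate([perm_f[:half_f], perm_m[:half_m]])
            group_b = np.concatenate([perm_f[half_f:], perm_m[half_m:]])
        else:
            perm = rng.permutation(all_ids)
            group_a, group_b = perm[:n_a], perm[n_a:n_a + n_b]
        sig_a = _significant_set(layers, cohort.loc[group_a], q_threshold)
        sig_b = _significant_set(layers, cohort.loc[group_b], q_threshold)
        shared = len(sig_a & sig_b)
        null_shared[it] = shared
        null_prop_a[it] = shared / len(sig_a) if sig_a else 0.0
        null_prop_b[it] = shared / len(sig_b) if sig_b else 0.0

    return OverlapNullResult(
        observed_shared=observed_shared,
        observed_n_a=len(sig_f),
        observed_n_b=len(sig_m),
        observed_prop_a=observed_prop_a,
        observed_prop_b=observed_prop_b,
        null_shared=null_shared,
        null_prop_a=null_prop_a,
        null_prop_b=null_prop_b,
        fdr_count=empirical_fdr(null_shared, observed_shared),
        fdr_prop_a=empirical_fdr(null_prop_a, observed_prop_a),
        fdr_prop_b=empirical_fdr(null_prop_b, observed_prop_b),
        n_iter=n_iter,
    )
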