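"""Shared containers and vocabulary for the placental interomics pipeline.

The pipeline operates on a cohort of placentas stratified into five obstetric
condition groups, with up to five sample-by-analyte data layers (metabolites,
proteins, miRNA counts, mRNA counts, histopathology features) and a cell-type
composition matrix on the simplex. Matrices are held as pandas DataFrames with
sample ids on the index; ``NaN`` marks a missing measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical condition labels: control term deliveries plus four obstetric
#: syndromes (severe fetal growth restriction, FGR with pregnancy-related
#: hypertension, severe preeclampsia, spontaneous preterm delivery).
CONDITIONS = ("Control", "FGR", "FGR+HDP", "PE", "PTD")

#: Study group sizes (number of placentas per condition).
DEFAULT_GROUP_SIZES = {"Control": 113, "FGR": 36, "FGR+HDP": 30, "PE": 71, "PTD": 71}

SEXES = ("female", "male")

LAYER_NAMES = ("metabolites", "proteins", "mirna", "mrna", "histopath")

#: Layers carrying molecular analytes (histopathology features are scored
#: separately and are excluded from the default cross-pair enumeration).
MOLECULAR_LAYERS = ("metabolites", "proteins", "mirna", "mrna")

LAYER_KINDS = ("abundance", "counts")

#: Columns every cohort table must carry.
COHORT_COLUMNS = (
    "condition",
    "fetal_sex",
    "ga_weeks",
    "bmi",
    "labor_init",
    "smoking",
    "drug_use",
)


def qualify(layer: str, analyte: str) -> str:
    """Layer-qualified node id, e.g. ``"mrna:FLT1"``.

    Gene symbols recur across the mRNA and protein layers, so network nodes
    always carry their layer prefix.
    """
    return f"{layer}:{analyte}"


def split_qualified(node: str) -> tuple[str, str]:
    layer, _, analyte = node.partition(":")
    return layer, analyte


@dataclass
class OmicsLayer:
    """One named sample-by-analyte matrix.

    Parameters
    ----------
    name
        Layer name (one of :data:`LAYER_NAMES` in the default study design,
        but arbitrary names are accepted).
    values
        DataFrame of shape (samples, analytes); ``NaN`` encodes missingness.
    kind
        ``"abundance"`` for continuous assay values (metabolites, proteins,
        histopathology scores) or ``"counts"`` for sequencing read counts.
    """

    name: str
    values: pd.DataFrame
    kind: str = "abundance"

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}; expected one of {LAYER_KINDS}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate analyte ids in layer {self.name!r}: {dups}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in layer {self.name!r}: {dups}")
        if self.kind == "counts":
            vals = self.values.to_numpy(dtype=float)
            observed = vals[~np.isnan(vals)]
            if observed.size and (observed < 0).any():
                raise ValueError(f"counts layer {self.name!r} contains negative values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.values.shape[1]

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def copy(self) -> "OmicsLayer":
        return OmicsLayer(self.name, self.values.copy(), self.kind)


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Check cohort-table invariants: unique ids, complete covariates, GA range."""
    missing_cols = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort table is missing columns {missing_cols}")
    if cohort.index.duplicated().any():
        raise ValueError("cohort sample ids are not unique")
    if cohort[list(COHORT_COLUMNS)].isna().any().any():
        raise ValueError("cohort covariates contain missing values")
    bad = set(cohort["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition labels {sorted(bad)}; expected {CONDITIONS}")
    bad_sex = set(cohort["fetal_sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown fetal_sex labels {sorted(bad_sex)}")
    ga = cohort["ga_weeks"].to_numpy(dtype=float)
    if (ga < 23).any() or (ga > 42).any():
        raise ValueError("ga_weeks outside the 23-42 week inclusion window")


def validate_fractions(fractions: pd.DataFrame, atol: float = 1e-9) -> None:
    """Check that a cell-fraction matrix lives on the simplex."""
    vals = fractions.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("cell-type fractions must be nonnegative")
    row_sums = vals.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=atol):
        worst = np.abs(row_sums - 1.0).max()
        raise ValueError(f"fraction rows must sum to 1 (worst deviation {worst:.3g})")


def align_layers(layers: list[OmicsLayer]) -> None:
    """Require all layers to share one sample index (same order)."""
    if not layers:
        raise ValueError("no layers supplied")
    ref = layers[0].values.index
    for layer in layers[1:]:
        if not layer.values.index.equals(ref):
            raise ValueError(
                f"layer {layer.name!r} sample index differs from {layers[0].name!r}"
            )
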