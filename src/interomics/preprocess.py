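"""Analyte filtering and imputation applied to each omics layer.

Stage order is fixed: missingness filter (with half-minimum imputation) ->
uniqueness filter -> count floor. All thresholds use strict inequalities:
analytes are kept with missing fraction strictly below 20% and a distinct-value
fraction strictly above 50%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import OmicsLayer

logger = logging.getLogger(__name__)

#: Minimum total read count per analyte, keyed by counts-layer name. Floors
#: are totals across all samples (a per-sample floor would eliminate nearly
#: every miRNA); applied as keep iff total >= floor.
DEFAULT_COUNT_FLOORS = {"mrna": 500, "mirna": 10}


@dataclass
class FilterReport:
    """Per-layer record of how many analytes survived each filtering stage."""

    layer_name: str
    n_input: int
    n_after_missingness: int
    n_after_uniqueness: int
    n_after_count_floor: int
    dropped_ids: dict[str, list[str]] = field(default_factory=dict)
    count_floor_scope: str = "total-across-samples"

    def __post_init__(self) -> None:
        counts = (
            self.n_input,
            self.n_after_missingness,
            self.n_after_uniqueness,
            self.n_after_count_floor,
        )
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError(f"filter counts must be nonincreasing, got {counts}")

    def to_dict(self) -> dict:
        return {
            "layer_name": self.layer_name,
            "n_input": self.n_input,
            "n_after_missingness": self.n_after_missingness,
            "n_after_uniqueness": self.n_after_uniqueness,
            "n_after_count_floor": self.n_after_count_floor,
            "dropped_ids": self.dropped_ids,
            "count_floor_scope": self.count_floor_scope,
        }


def filter_missingness(layer: OmicsLayer, max_missing_frac: float = 0.20) -> OmicsLayer:
    """Drop analytes at or above the missingness threshold; impute the rest.

    Surviving analytes have remaining missing entries imputed as half the
    analyte's observed minimum; in counts layers missing entries are set to
    zero instead (sequencing absence is a zero, not a missing measurement).
    """
    if not 0.0 <= max_missing_frac < 1.0:
        raise ValueError("max_missing_frac must be in [0, 1)")
    if layer.n_samples == 0:
        raise ValueError(f"layer {layer.name!r} has zero samples")
    values = layer.values
    miss_frac = values.isna().mean(axis=0)
    keep = miss_frac < max_missing_frac
    kept = values.loc[:, keep].copy()
    if layer.kind == "counts":
        kept = kept.fillna(0.0)
    else:
        kept = kept.fillna(0.5 * kept.min(axis=0))
    return OmicsLayer(layer.name, kept, layer.kind)


def filter_uniqueness(layer: OmicsLayer, min_unique_frac: float = 0.50) -> OmicsLayer:
    """Keep analytes whose distinct-value fraction strictly exceeds the threshold.

    Run after imputation, so there are no missing entries to count.
    """
    values = layer.values
    n = layer.n_samples
    if n == 0:
        raise ValueError(f"layer {layer.name!r} has zero samples")
    unique_frac = values.nunique(axis=0, dropna=False) / n
    keep = unique_frac > min_unique_frac
    return OmicsLayer(layer.name, values.loc[:, keep].copy(), layer.kind)


def filter_count_floor(
    layer: OmicsLayer, floors: dict[str, int] | None = None
) -> OmicsLayer:
    """Drop counts-layer analytes below their layer's total-count floor.

    Abundance layers pass through unchanged. The floor is taken from
    ``floors`` by layer name (default: mRNA 500, miRNA 10, others 0).
    """
    if layer.kind != "counts":
        return layer
    if floors is None:
        floors = DEFAULT_COUNT_FLOORS
    values = layer.values
    observed = values.fillna(0.0)
    if (observed.to_numpy() < 0).any():
        raise ValueError(f"counts layer {layer.name!r} contains negative values")
    floor = floors.get(layer.name, 0)
    totals = observed.sum(axis=0)
    keep = totals >= floor
    return OmicsLayer(layer.name, values.loc[:, keep].copy(), layer.kind)


def preprocess_layer(
    layer: OmicsLayer,
    max_missing_frac: float = 0.20,
    min_unique_frac: float = 0.50,
    count_floors: dict[str, int] | None = None,
) -> tuple[OmicsLayer, FilterReport]:
    """Run the full filter chain and report analyte counts per stage."""
    input_ids = set(layer.analyte_ids)
    after_miss = filter_missingness(layer, max_missing_frac)
    after_uniq = filter_uniqueness(after_miss, min_unique_frac)
    after_floor = filter_count_floor(after_uniq, count_floors)

    dropped = {
        "missingness": sorted(input_ids - set(after_miss.analyte_ids)),
        "uniqueness": sorted(set(after_miss.analyte_ids) - set(after_uniq.analyte_ids)),
        "count_floor": sorted(set(after_uniq.analyte_ids) - set(after_floor.analyte_ids)),
    }
    report = FilterReport(
        layer_name=layer.name,
        n_input=layer.n_analytes,
        n_after_missingness=after_miss.n_analytes,
        n_after_uniqueness=after_uniq.n_analytes,
        n_after_count_floor=after_floor.n_analytes,
        dropped_ids=dropped,
    )
    logger.info(
        "preprocess %s: %d -> %d (missingness) -> %d (uniqueness) -> %d (count floor)",
        layer.name,
        report.n_input,
        report.n_after_missingness,
        report.n_after_uniqueness,
        report.n_after_count_floor,
    )
    return after_floor, report
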