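"""Condition-specific cross-omics Spearman correlation networks.

Every analyte of one layer is correlated against every analyte of every other
layer (interomics only; within-layer pairs are never tested). Spearman's rho
is computed with average ranks (tie-corrected) as a Pearson correlation on
ranked columns, which lets a whole layer pair be evaluated as one matrix
product. Two-sided p-values use the t approximation on n - 2 degrees of
freedom. Edges are retained under Bonferroni control: p < alpha / m, where m
is the number of tests actually performed across all layer pairs.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import OmicsLayer, align_layers, qualify, validate_cohort

logger = logging.getLogger(__name__)


def count_cross_pairs(
    layer_sizes: Mapping[str, int], include: Iterable[str] | None = None
) -> int:
    """Number of cross-layer analyte pairs: sum of n_i * n_j over layer pairs."""
    if include is not None:
        include = set(include)
        layer_sizes = {k: v for k, v in layer_sizes.items() if k in include}
    if any(v < 0 for v in layer_sizes.values()):
        raise ValueError("layer sizes must be nonnegative")
    names = sorted(layer_sizes)
    return sum(layer_sizes[a] * layer_sizes[b] for a, b in combinations(names, 2))


def _rank_standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise average ranks, centered and scaled to unit norm.

    Returns (Z, valid) where Z.T @ Z gives tie-corrected Spearman
    correlations and ``valid`` marks non-constant columns (constant columns
    have undefined rho and are zeroed out).
    """
    ranks = stats.rankdata(values, axis=0)
    ranks = ranks - ranks.mean(axis=0, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=0))
    valid = norms > 0
    safe = np.where(valid, norms, 1.0)
    return ranks / safe, valid


def _t_pvalue(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation; |rho| = 1 maps to p = 0."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return np.where(np.abs(rho) >= 1.0 - 1e-12, 0.0, p)


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Spearman rho and its two-sided t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 4:
        raise ValueError("spearman needs at least 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("spearman requires finite values")
    zx, vx = _rank_standardize(x[:, None])
    zy, vy = _rank_standardize(y[:, None])
    if not (vx[0] and vy[0]):
        raise ValueError("spearman undefined for a constant vector")
    rho = float(zx[:, 0] @ zy[:, 0])
    return rho, float(_t_pvalue(np.array([rho]), len(x))[0])


def build_network(
    layers: list[OmicsLayer],
    condition: str | None = None,
    alpha: float = 0.05,
    sample_ids: pd.Index | None = None,
) -> nx.Graph:
    """All-cross-pairs Spearman network under Bonferroni control.

    ``m_tests`` counts the tests actually performed (constant analytes are
    skipped and logged); edges satisfy p < alpha / m_tests and nodes are the
    endpoints of retained edges. Graph attributes record condition, alpha,
    m_tests, the derived p threshold and the sample count.
    """
    if len(layers) < 2:
        raise ValueError("need at least 2 layers for an interomics network")
    align_layers(layers)
    if sample_ids is not None:
        layers = [OmicsLayer(l.name, l.values.loc[sample_ids], l.kind) for l in layers]
    n = layers[0].n_samples
    if n < 4:
        raise ValueError("need at least 4 samples")
    for layer in layers:
        if layer.values.isna().any().any():
            raise ValueError(f"layer {layer.name!r} contains missing values; preprocess first")

    ranked = {}
    n_constant = 0
    for layer in layers:
        Z, valid = _rank_standardize(layer.values.to_numpy(dtype=float))
        ranked[layer.name] = (Z, valid, list(layer.values.columns))
        n_constant += int((~valid).sum())
    if n_constant:
        logger.info("skipping %d constant analytes (undefined rho)", n_constant)

    # first pass: the Bonferroni denominator (tests actually performed)
    m_tests = 0
    for la, lb in combinations(layers, 2):
        m_tests += int(ranked[la.name][1].sum()) * int(ranked[lb.name][1].sum())

    G = nx.Graph()
    G.graph.update(
        condition=condition, alpha=float(alpha), m_tests=int(m_tests),
        n_samples=int(n),
        p_threshold=float(alpha / m_tests) if m_tests else 0.0,
    )
    if m_tests == 0 or alpha <= 0:
        return G
    threshold = alpha / m_tests

    for la, lb in combinations(layers, 2):
        Za, va, cols_a = ranked[la.name]
        Zb, vb, cols_b = ranked[lb.name]
        rho = Za.T @ Zb
        p = _t_pvalue(rho, n)
        hit = (p < threshold) & va[:, None] & vb[None, :]
        for i, j in np.argwhere(hit):
            node_a = qualify(la.name, cols_a[i])
            node_b = qualify(lb.name, cols_b[j])
            r = float(np.clip(rho[i, j], -1.0, 1.0))
            G.add_edge(node_a, node_b, rho=r, p=float(p[i, j]),
                       sign=1 if r >= 0 else -1)
    logger.info(
        "network %s: %d edges, %d nodes (m=%d, threshold %.3g)",
        condition, G.number_of_edges(), G.number_of_nodes(), m_tests, threshold,
    )
    return G


def condition_network(
    layers: list[OmicsLayer],
    cohort: pd.DataFrame,
    condition: str,
    alpha: float = 0.05,
) -> nx.Graph:
    """Network restricted to the samples of one condition."""
    validate_cohort(cohort)
    ids = cohort.index[cohort["condition"] == condition]
    if len(ids) == 0:
        raise ValueError(f"no samples with condition {condition!r}")
    return build_network(layers, condition=condition, alpha=alpha, sample_ids=ids)


def downsample_and_build(
    layers: list[OmicsLayer],
    cohort: pd.DataFrame,
    condition: str,
    n_target: int = 30,
    seed: int = 0,
    alpha: float = 0.05,
) -> nx.Graph:
    """Uniform subsample (without replacement) to ``n_target``, then build.

    Used to compare conditions at the power of the smallest group. A group
    already at ``n_target`` is used in full.
    """
    validate_cohort(cohort)
    ids = cohort.index[cohort["condition"] == condition]
    if len(ids) < n_target:
        raise ValueError(
            f"condition {condition!r} has {len(ids)} samples, fewer than n_target={n_target}"
        )
    rng = np.random.default_rng(seed)
    chosen = ids[np.sort(rng.choice(len(ids), size=n_target, replace=False))]
    G = build_network(layers, condition=condition, alpha=alpha, sample_ids=chosen)
    G.graph["downsampled_to"] = int(n_target)
    return G


def effect_size_histogram(
    G: nx.Graph, n_bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Counts of |rho| over fixed bins of [0, 1] for the retained edges."""
    abs_rho = [abs(d["rho"]) for _, _, d in G.edges(data=True)]
    return np.histogram(abs_rho, bins=n_bins, range=(0.0, 1.0))


def min_detectable_rho(n: int, p_threshold: float) -> float:
    """Smallest |rho| whose t-approximation p falls below ``p_threshold``."""
    if n <= 2:
        raise ValueError("need n > 2")
    t_crit = stats.t.isf(p_threshold / 2.0, n - 2)
    return float(t_crit / np.sqrt(t_crit**2 + n - 2))
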