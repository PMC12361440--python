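"""Community tracking, differential levels, signature selection and projection.

A reference community (found in the control network) is followed across the
condition-specific networks via closeness centrality. Pairwise differential
levels between conditions are computed as log2 fold-changes of group means on
positive-shifted adjusted values with pooled-variance two-tailed t-tests and
Benjamini-Hochberg correction per comparison; analytes must reach q < 0.05
with at least a 1.5-fold change in one comparison to enter signature
selection. Candidate analytes are hierarchically clustered (average linkage,
Euclidean) on their fold-change profiles; clusters are ranked by mean absolute
fold change over the comparisons involving the target condition, and the
highest-ranked cluster meeting the size floor becomes the signature. Group
separation is quantified by the silhouette of two-component PCA (unsupervised)
or PLS-DA (supervised) scores after per-analyte mean scaling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .communities import closeness
from .datatypes import CONDITIONS, OmicsLayer, align_layers, qualify

logger = logging.getLogger(__name__)

LOG2_FC_FLOOR = math.log2(1.5)


def stack_layers(layers: list[OmicsLayer]) -> pd.DataFrame:
    """Concatenate layers column-wise under layer-qualified analyte ids."""
    align_layers(layers)
    frames = []
    for layer in layers:
        df = layer.values.copy()
        df.columns = [qualify(layer.name, c) for c in df.columns]
        frames.append(df)
    return pd.concat(frames, axis=1)


# ---------------------------------------------------------------------------
# community tracking
# ---------------------------------------------------------------------------

def track_community(
    reference_nodes: set[str] | list[str],
    networks: dict[str, nx.Graph],
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Closeness of the reference community's nodes in every condition network.

    Nodes absent from a condition's network score 0 there. Returns the
    nodes-by-conditions centrality table and the most-connected node per
    condition (restricted to the reference set).
    """
    reference_nodes = sorted(set(reference_nodes))
    if not reference_nodes:
        raise ValueError("reference community is empty")
    table = pd.DataFrame(0.0, index=reference_nodes, columns=list(networks))
    hubs: dict[str, str] = {}
    for cond, G in networks.items():
        cc = closeness(G)
        for node in reference_nodes:
            table.loc[node, cond] = cc.get(node, 0.0)
        col = table[cond]
        hubs[cond] = col.index[np.argmax(col.to_numpy())]
    return table, hubs


# ---------------------------------------------------------------------------
# differential levels
# ---------------------------------------------------------------------------

def differential_levels(
    values: pd.DataFrame,
    cohort: pd.DataFrame,
    analytes: list[str] | None = None,
    conditions: tuple[str, ...] = CONDITIONS,
    q_threshold: float = 0.05,
    fc_floor: float = 1.5,
    equal_var: bool = True,
    fc_method: str = "log-mean",
) -> pd.DataFrame:
    """Pairwise log2 fold-changes with pooled-variance t-tests and BH.

    ``values`` is a stacked samples-by-analytes matrix of adjusted levels.
    Each analyte is shifted globally positive (|min| + 1e-6 when its minimum
    is nonpositive) before the log step; the t-test (on the unlogged values)
    is shift-invariant. ``fc_method`` selects the fold-change estimator:

    * ``"log-mean"`` (default) — difference of group means of per-sample
      log2 values; robust to the heavy tail of skewed abundance data.
    * ``"ratio-of-means"`` — log2 of the ratio of group means.

    BH runs across analytes within each comparison. The ``passes_fc_filter``
    flag is analyte-level: q < ``q_threshold`` and |log2FC| >=
    log2(``fc_floor``) in at least one comparison.
    """
    if fc_method not in ("log-mean", "ratio-of-means"):
        raise ValueError("fc_method must be 'log-mean' or 'ratio-of-means'")
    if analytes is not None:
        values = values[list(analytes)]
    conditions = [c for c in conditions if (cohort["condition"] == c).any()]
    groups = {
        c: values.loc[cohort.index[cohort["condition"] == c]].to_numpy(dtype=float)
        for c in conditions
    }
    for c, g in groups.items():
        if g.shape[0] < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 samples")

    mins = values.min(axis=0).to_numpy(dtype=float)
    shifts = np.where(mins <= 0, np.abs(mins) + 1e-6, 0.0)

    records = []
    for cond_a, cond_b in combinations(conditions, 2):
        ga, gb = groups[cond_a], groups[cond_b]
        if fc_method == "ratio-of-means":
            mean_a = ga.mean(axis=0) + shifts
            mean_b = gb.mean(axis=0) + shifts
            if (mean_a <= 0).any() or (mean_b <= 0).any():
                raise ValueError("nonpositive group mean after positive shift")
            lfc = np.log2(mean_a / mean_b)
        else:
            lfc = np.log2(ga + shifts).mean(axis=0) - np.log2(gb + shifts).mean(axis=0)
        _, p = stats.ttest_ind(ga, gb, axis=0, equal_var=equal_var)
        p = np.nan_to_num(p, nan=1.0)  # zero-variance-in-both degenerate case
        _, q, _, _ = multipletests(p, method="fdr_bh")
        for j, analyte in enumerate(values.columns):
            records.append(
                dict(
                    analyte_id=analyte,
                    comparison=f"{cond_a} vs {cond_b}",
                    cond_a=cond_a,
                    cond_b=cond_b,
                    log2fc=float(lfc[j]),
                    p_value=float(p[j]),
                    q_value=float(q[j]),
                )
            )
    out = pd.DataFrame(records)
    hit = (out["q_value"] < q_threshold) & (out["log2fc"].abs() >= math.log2(fc_floor))
    passing = set(out.loc[hit, "analyte_id"])
    out["passes_fc_filter"] = out["analyte_id"].isin(passing)
    return out


# ---------------------------------------------------------------------------
# signature selection
# ---------------------------------------------------------------------------

def select_signature(
    records: pd.DataFrame,
    target_condition: str,
    n_clusters: int = 6,
    min_cluster_size: int = 2,
) -> tuple[list[str], pd.DataFrame]:
    """Pick the most distinctive fold-change cluster involving the target.

    All candidate analytes are clustered (average linkage, Euclidean) on
    their log2FC profile across all comparisons; the non-differential
    background anchors the tree so a coherent fold-change block separates as
    its own cluster. The tree is cut into k clusters, where k (between 2 and
    ``n_clusters``) maximizes the gap between consecutive merge heights —
    the natural number of profile blocks, with ``n_clusters`` as an upper
    bound. Clusters are ranked by mean |log2FC| over comparisons involving
    ``target_condition``; the highest-ranked cluster retaining at least
    ``min_cluster_size`` members after intersecting with the fold-change
    filter (q < 0.05 and >= 1.5-fold in some comparison) is returned
    together with the full ranking table.
    """
    if not records["passes_fc_filter"].any():
        raise ValueError("no analyte passes the fold-change filter")
    passing_ids = set(records.loc[records["passes_fc_filter"], "analyte_id"])
    profile = records.pivot_table(index="analyte_id", columns="comparison", values="log2fc")
    if profile.isna().any().any():
        raise ValueError("incomplete fold-change profiles")
    X = profile.to_numpy(dtype=float)
    if np.allclose(X, X[0], atol=1e-12):
        raise ValueError("all analytes have identical fold-change profiles; no distinctive cluster")
    if len(profile) == 1:
        labels = np.array([1])
    else:
        Z = hierarchy.linkage(X, method="average", metric="euclidean")
        heights = Z[:, 2]
        k_max = min(n_clusters, len(profile))
        # cutting into k clusters removes the top k-1 merges; score each k by
        # the height gap it opens and keep the largest (ties -> fewest clusters)
        gaps = {
            k: heights[len(heights) - k + 1] - heights[len(heights) - k]
            for k in range(2, k_max + 1)
            if len(heights) - k >= 0
        }
        k = max(sorted(gaps), key=lambda kk: gaps[kk]) if gaps else k_max
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")

    target_cols = [
        c for c in profile.columns
        if target_condition in c.split(" vs ")
    ]
    if not target_cols:
        raise ValueError(f"no comparisons involve target condition {target_condition!r}")
    target_profile = profile[target_cols].abs()

    rows = []
    for lab in np.unique(labels):
        members = profile.index[labels == lab]
        selectable = [m for m in members if m in passing_ids]
        rows.append(
            dict(
                cluster=int(lab),
                size=len(members),
                n_passing=len(selectable),
                mean_abs_log2fc=float(target_profile.loc[members].to_numpy().mean()),
                members=list(members),
                passing_members=selectable,
            )
        )
    ranking = pd.DataFrame(rows).sort_values(
        "mean_abs_log2fc", ascending=False, kind="stable"
    ).reset_index(drop=True)
    eligible = ranking[ranking["n_passing"] >= min_cluster_size]
    if eligible.empty:
        raise ValueError(
            "no cluster meets the minimum size; ranking:\n"
            + ranking.drop(columns=["members", "passing_members"]).to_string()
        )
    selected = sorted(eligible.iloc[0]["passing_members"])
    logger.info(
        "selected %d-analyte signature (cluster %d of %d)",
        len(selected), int(eligible.iloc[0]["cluster"]), len(ranking),
    )
    return selected, ranking


# ---------------------------------------------------------------------------
# projection and separation
# ---------------------------------------------------------------------------

@dataclass
class ProjectionResult:
    method: str  # "pca" | "plsda"
    coords: pd.DataFrame  # samples x (comp1, comp2, condition)
    variance_explained: tuple[float, float]
    silhouette: float
    dropped_analytes: list[str] = field(default_factory=list)


def project_and_separate(
    values: pd.DataFrame,
    cohort: pd.DataFrame,
    analytes: list[str],
    condition_pair: tuple[str, str],
    supervised: bool = False,
) -> ProjectionResult:
    """Two-component projection of one condition pair with silhouette score.

    Each analyte is divided by its mean level (accounting for overall signal)
    and the matrix is mean-centered. Unsupervised projection is PCA with the
    variance explained by the first two components; supervised is
    two-component PLS-DA against the binary condition label (its variance
    share is the X variance captured by each score). Zero-mean analytes are
    undefined under mean scaling and are dropped with a warning.
    """
    cond_a, cond_b = condition_pair
    mask = cohort["condition"].isin(condition_pair)
    ids = cohort.index[mask]
    labels = cohort.loc[ids, "condition"]
    if (labels == cond_a).sum() < 3 or (labels == cond_b).sum() < 3:
        raise ValueError("need at least 3 samples per condition")
    if len(analytes) < 2:
        raise ValueError("need at least 2 analytes to project")
    M = values.loc[ids, list(analytes)].astype(float)
    means = M.mean(axis=0)
    # a mean at floating-point zero relative to the analyte's scale makes
    # mean-scaling blow up; treat it as undefined
    scale = M.abs().max(axis=0).clip(lower=1.0)
    dropped = means.index[(means.abs() / scale) < 1e-12].tolist()
    if dropped:
        logger.warning("dropping zero-mean analytes (scaling undefined): %s", dropped)
        M = M.drop(columns=dropped)
        means = means.drop(index=dropped)
    if M.shape[1] < 2:
        raise ValueError("fewer than 2 analytes remain after dropping zero-mean ones")
    X = (M / means).to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    total_var = float((X**2).sum())

    if supervised:
        y = (labels == cond_b).to_numpy(dtype=float) * 2.0 - 1.0
        pls = PLSRegression(n_components=2, scale=False)
        pls.fit(X, y)
        scores = pls.x_scores_
        # share of X variance carried by each PLS score direction
        loadings = pls.x_loadings_
        var = tuple(
            float((scores[:, k] ** 2).sum() * (loadings[:, k] ** 2).sum()) / total_var
            if total_var > 0 else 0.0
            for k in range(2)
        )
        method = "plsda"
    else:
        pca = PCA(n_components=2)
        scores = pca.fit_transform(X)
        var = tuple(float(v) for v in pca.explained_variance_ratio_[:2])
        method = "pca"

    sil = float(silhouette_score(scores, labels.to_numpy()))
    coords = pd.DataFrame(
        {"comp1": scores[:, 0], "comp2": scores[:, 1], "condition": labels},
        index=ids,
    )
    return ProjectionResult(method, coords, var, sil, dropped)
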