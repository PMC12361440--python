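"""End-to-end pipeline driver over a synthetic (or file-based) study.

Stage order follows the analysis design: simulate -> preprocess ->
composition testing -> sex-stratified covariate adjustment -> (optional)
overlap null -> per-condition interomics networks -> community statistics ->
community signature mining. Every stage writes its outputs under the run
directory, a structured line-delimited JSON log records per-stage counts, and
the resolved configuration is stored beside the outputs so a run is fully
reproducible from its directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition as comp
from . import io as pio
from .adjust import adjust_layers, screen_covariates
from .communities import (
    Partition,
    community_connectivity,
    closeness,
    jaccard_similarity,
    louvain_partition,
    partition_quality,
)
from .datatypes import CONDITIONS, DEFAULT_GROUP_SIZES, MOLECULAR_LAYERS, OmicsLayer
from .network import condition_network, count_cross_pairs, downsample_and_build, effect_size_histogram
from .overlap import simulate_overlap_null
from .preprocess import preprocess_layer
from .signature import (
    differential_levels,
    project_and_separate,
    select_signature,
    stack_layers,
    track_community,
)
from .simulate import (
    default_ground_truth,
    default_layer_specs,
    generate_cohort,
    generate_fractions,
    generate_layers,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, in one serializable place."""

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    sex_balance: float = 0.5
    layer_scale: float = 1.0  # proportional shrink of the default layer sizes
    noise_sd: float = 0.5
    seed: int = 0
    # preprocessing
    max_missing_frac: float = 0.20
    min_unique_frac: float = 0.50
    # adjustment
    q_threshold: float = 0.05
    # networks
    alpha: float = 0.05
    include_histopath: bool = False
    downsample_to: int | None = None
    # communities
    resolution: float = 0.45
    # signature
    target_condition: str = "FGR+HDP"
    reference_condition: str = "Control"
    fc_floor: float = 1.5
    n_clusters: int = 6
    min_cluster_size: int = 2
    # overlap null
    run_overlap: bool = False
    n_overlap_iter: int = 100

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        path.parent.mkdir(parents=True, exist_ok=True)
        self._fh = open(path, "a")

    def event(self, stage: str, **fields) -> None:
        rec = {"stage": stage, "t": time.time(), **fields}
        self._fh.write(json.dumps(rec, default=str) + "\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage on a synthetic study; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    log = _RunLog(out / "log.jsonl")
    summary: dict = {}
    try:
        # -- simulate ------------------------------------------------------
        cohort = generate_cohort(config.group_sizes, config.sex_balance, seed=config.seed)
        specs = default_layer_specs(config.layer_scale)
        truth = default_ground_truth(specs)
        layers, truth = generate_layers(
            cohort, truth, specs, noise_sd=config.noise_sd, seed=config.seed + 1
        )
        fractions = generate_fractions(
            cohort, shift=truth.composition_shift, seed=config.seed + 2
        )
        pio.write_cohort(cohort, out / "cohort.tsv")
        for layer in layers:
            pio.write_layer(layer, out / "layers" / f"{layer.name}.tsv")
        pio.write_matrix(fractions, out / "fractions.tsv")
        pio.write_json(truth.to_dict(), out / "ground_truth.json")
        log.event("simulate", n_samples=len(cohort),
                  layer_sizes={l.name: l.n_analytes for l in layers})

        # -- preprocess ----------------------------------------------------
        processed = []
        reports = {}
        for layer in layers:
            filtered, report = preprocess_layer(
                layer, config.max_missing_frac, config.min_unique_frac
            )
            processed.append(filtered)
            reports[layer.name] = report.to_dict()
            pio.write_layer(filtered, out / "preprocess" / f"{layer.name}.tsv")
        pio.write_json(reports, out / "preprocess" / "filter_report.json")
        log.event("preprocess", **{k: v["n_after_count_floor"] for k, v in reports.items()})

        # -- composition ---------------------------------------------------
        clr = comp.clr_transform(fractions)
        pio.write_matrix(clr, out / "composition" / "clr.tsv")
        ctrl_ids = cohort.index[cohort["condition"] == "Control"]
        comp_results = []
        for condition in CONDITIONS:
            if condition == "Control" or not (cohort["condition"] == condition).any():
                continue
            cond_ids = cohort.index[cohort["condition"] == condition]
            comp_results.append(
                comp.test_composition_shifts(clr.loc[ctrl_ids], clr.loc[cond_ids], condition)
            )
        comp_table = pd.concat(comp_results, ignore_index=True)
        comp_table.to_csv(out / "composition" / "ks_tests.tsv", sep="\t", index=False)
        log.event("composition", n_tests=len(comp_table),
                  n_significant=int((comp_table["q_value"] < 0.05).sum()))

        # -- covariate screening + adjustment ------------------------------
        corr, vif = screen_covariates(cohort)
        (out / "adjust").mkdir(exist_ok=True)
        (out / "composition").mkdir(exist_ok=True)
        (out / "signature").mkdir(exist_ok=True)
        corr.to_csv(out / "adjust" / "covariate_corr.tsv", sep="\t")
        vif.to_csv(out / "adjust" / "vif.tsv", sep="\t")
        adjusted, fits, ga_regulated = adjust_layers(
            processed, cohort, q_threshold=config.q_threshold
        )
        for layer in adjusted:
            pio.write_layer(layer, out / "adjust" / f"{layer.name}.tsv")
        fits.to_csv(out / "adjust" / "fits.tsv", sep="\t", index=False)
        summary["ga_regulated"] = {sex: len(ids) for sex, ids in ga_regulated.items()}
        summary["ga_regulated_shared"] = len(
            ga_regulated.get("female", set()) & ga_regulated.get("male", set())
        )
        log.event("adjust", **summary["ga_regulated"], shared=summary["ga_regulated_shared"])

        # -- overlap null (optional) ---------------------------------------
        if config.run_overlap:
            res = simulate_overlap_null(
                processed, cohort, n_iter=config.n_overlap_iter, seed=config.seed + 3,
                q_threshold=config.q_threshold,
            )
            pio.write_json(res.to_dict(), out / "overlap" / "overlap_null.json")
            pd.DataFrame(
                {"null_shared": res.null_shared, "null_prop_a": res.null_prop_a,
                 "null_prop_b": res.null_prop_b}
            ).to_csv(out / "overlap" / "null_distributions.tsv", sep="\t", index=False)
            summary["overlap_fdr_count"] = res.fdr_count
            log.event("overlap_null", fdr_count=res.fdr_count,
                      observed_shared=res.observed_shared)

        # -- networks ------------------------------------------------------
        net_layers = [
            l for l in adjusted
            if config.include_histopath or l.name != "histopath"
        ]
        summary["cross_pairs"] = count_cross_pairs(
            {l.name: l.n_analytes for l in net_layers}
        )
        networks = {}
        for condition in CONDITIONS:
            if not (cohort["condition"] == condition).any():
                continue
            if config.downsample_to is not None:
                G = downsample_and_build(
                    net_layers, cohort, condition, n_target=config.downsample_to,
                    seed=config.seed + 4, alpha=config.alpha,
                )
            else:
                G = condition_network(net_layers, cohort, condition, alpha=config.alpha)
            networks[condition] = G
            pio.write_network(G, out / "network" / condition.replace("+", "_"))
            counts, bin_edges = effect_size_histogram(G)
            pd.DataFrame({"bin_left": bin_edges[:-1], "bin_right": bin_edges[1:],
                          "count": counts}).to_csv(
                out / "network" / f"{condition.replace('+', '_')}.rho_hist.tsv",
                sep="\t", index=False)
            log.event("network", condition=condition, edges=G.number_of_edges(),
                      nodes=G.number_of_nodes(), m_tests=G.graph["m_tests"])

        # -- communities ---------------------------------------------------
        partitions: dict[str, Partition] = {}
        quality = {}
        for condition, G in networks.items():
            if G.number_of_nodes() == 0:
                log.event("communities", condition=condition, note="empty network")
                quality[condition] = None
                continue
            part = louvain_partition(G, resolution=config.resolution, seed=config.seed)
            partitions[condition] = part
            q = partition_quality(part, G)
            quality[condition] = q.to_dict()
            conn_table, conn_summary = community_connectivity(part, G)
            pio.write_partition(part, out / "communities" / f"{condition.replace('+', '_')}.tsv")
            conn_table.to_csv(
                out / "communities" / f"{condition.replace('+', '_')}.connectivity.tsv",
                sep="\t", index=False)
            cc = closeness(G)
            pd.Series(cc, name="closeness").rename_axis("node").to_csv(
                out / "communities" / f"{condition.replace('+', '_')}.closeness.tsv", sep="\t")
            log.event("communities", condition=condition, **q.to_dict(), **conn_summary)
        jaccard = {
            f"{a}|{b}": jaccard_similarity(set(networks[a].nodes), set(networks[b].nodes))
            for i, a in enumerate(networks) for b in list(networks)[i + 1:]
        }
        pio.write_json({"quality": quality, "jaccard_nodes": jaccard},
                       out / "communities" / "quality.json")
        summary["partition_quality"] = quality
        summary["jaccard_nodes"] = jaccard

        # -- signature -----------------------------------------------------
        ref_cond = config.reference_condition
        if ref_cond in partitions and networks[ref_cond].number_of_edges() > 0:
            ref_net = networks[ref_cond]
            cc = closeness(ref_net)
            hub_node = max(cc, key=cc.get)
            ref_comm = next(
                c for c in partitions[ref_cond].communities if hub_node in c
            )
            table, hubs = track_community(set(ref_comm), networks)
            table.to_csv(out / "signature" / "community_closeness.tsv", sep="\t")
            stacked = stack_layers(adjusted)
            records = differential_levels(
                stacked, cohort, analytes=sorted(ref_comm),
                q_threshold=config.q_threshold, fc_floor=config.fc_floor,
            )
            records.to_csv(out / "signature" / "differential.tsv", sep="\t", index=False)
            try:
                selected, ranking = select_signature(
                    records, config.target_condition,
                    n_clusters=config.n_clusters,
                    min_cluster_size=config.min_cluster_size,
                )
            except ValueError as exc:
                log.event("signature", error=str(exc))
                selected, ranking = [], pd.DataFrame()
            projections = {}
            if len(selected) >= 2:
                for condition in networks:
                    if condition == config.target_condition:
                        continue
                    for supervised in (False, True):
                        proj = project_and_separate(
                            stacked, cohort, selected,
                            (config.target_condition, condition), supervised=supervised,
                        )
                        key = f"{proj.method}:{config.target_condition} vs {condition}"
                        projections[key] = {
                            "variance_explained": list(proj.variance_explained),
                            "silhouette": proj.silhouette,
                        }
                        proj.coords.to_csv(
                            out / "signature" / f"{key.replace(' ', '_').replace(':', '_').replace('+', '_')}.tsv",
                            sep="\t")
            pio.write_json(
                {"reference_community": sorted(ref_comm), "hubs": hubs,
                 "selected": selected, "projections": projections},
                out / "signature" / "signature.json")
            summary["signature"] = {"n_selected": len(selected), "hubs": hubs,
                                    "projections": projections}
            log.event("signature", n_selected=len(selected))
        else:
            log.event("signature", note="reference network empty; stage skipped")

        pio.write_json(summary, out / "summary.json")
        log.event("done")
    except Exception as exc:
        log.event("failed", error=str(exc))
        raise
    finally:
        log.close()
    return out
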