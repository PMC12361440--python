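"""Readers and writers for the pipeline's delimited-text formats.

Matrices are TSV with a header row of analyte ids and a first column of
sample ids; empty cells encode missing values. Networks are serialized both
as an edge-list TSV and as GraphML (the archival form), with the Bonferroni
bookkeeping in a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import OmicsLayer


def _check_header(path: Path) -> None:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    body = header[1:]
    seen, dups = set(), []
    for col in body:
        if col in seen:
            dups.append(col)
        seen.add(col)
    if dups:
        raise ValueError(f"{path}: duplicated analyte column(s) {sorted(set(dups))}")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a samples-by-analytes TSV; empty cells become NaN (missing)."""
    path = Path(path)
    _check_header(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed rows ({exc})") from exc
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicated sample id(s) {dups}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep="")


def read_layer(path: str | Path, name: str, kind: str) -> OmicsLayer:
    return OmicsLayer(name, read_matrix(path), kind)


def write_layer(layer: OmicsLayer, path: str | Path) -> None:
    write_matrix(layer.values, path)


def read_cohort(path: str | Path) -> pd.DataFrame:
    cohort = pd.read_csv(path, sep="\t", index_col=0)
    return cohort


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, sep="\t")


def write_network(G: nx.Graph, stem: str | Path) -> None:
    """Write edge-list TSV, GraphML and a JSON sidecar next to ``stem``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        dict(node_a=a, node_b=b, rho=d["rho"], p=d["p"], sign=d["sign"])
        for a, b, d in G.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "rho", "p", "sign"]).to_csv(
        stem.with_suffix(".edges.tsv"), sep="\t", index=False
    )
    meta = {k: v for k, v in G.graph.items()}
    with open(stem.with_suffix(".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2)
    H = G.copy()
    H.graph.clear()  # GraphML cannot hold None-valued graph attributes
    nx.write_graphml(H, stem.with_suffix(".graphml"))


def read_network(stem: str | Path) -> nx.Graph:
    stem = Path(stem)
    G = nx.read_graphml(stem.with_suffix(".graphml"))
    with open(stem.with_suffix(".meta.json")) as fh:
        G.graph.update(json.load(fh))
    return G


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"cannot serialize {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)


def write_partition(partition, path: str | Path) -> None:
    rows = [
        dict(node=node, community=i)
        for i, comm in enumerate(partition.communities)
        for node in sorted(comm)
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["node", "community"]).to_csv(path, sep="\t", index=False)


def read_partition(path: str | Path, resolution: float = float("nan")):
    from .communities import Partition

    df = pd.read_csv(path, sep="\t")
    groups = df.groupby("community")["node"].apply(frozenset)
    return Partition(list(groups), resolution=resolution)
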