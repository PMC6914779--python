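"""Plain-text I/O: RFU TSVs, sample tables, edge lists, GraphML, GMT, JSON."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import RFUMatrix, SimGroundTruth


# -- RFU matrix (values TSV + analyte-metadata sidecar TSV) -----------------

def write_rfu(matrix: RFUMatrix, values_path, analytes_path) -> None:
    matrix.values.to_csv(values_path, sep="\t")
    matrix.analytes.to_csv(analytes_path, sep="\t")


def read_rfu(values_path, analytes_path) -> RFUMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    analytes = pd.read_csv(analytes_path, sep="\t", index_col=0)
    analytes["is_hyb_control"] = analytes["is_hyb_control"].astype(bool)
    analytes["uniprot"] = analytes["uniprot"].fillna("")
    return RFUMatrix(values, analytes)


# -- sample table -----------------------------------------------------------

def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t")


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# -- graphs -----------------------------------------------------------------

def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tsources\n")
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('sources', '')}\n")


def read_edge_list(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    g = nx.Graph()
    for _, row in df.iterrows():
        g.add_edge(row["source"], row["target"], sources=row.get("sources", ""))
    return g


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


# -- pathway sets (GMT: name <tab> description <tab> members...) ------------

def write_gmt(pathways: dict, path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sorted(pathways):
            members = "\t".join(sorted(pathways[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_gmt(path) -> dict:
    pathways = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pathways[parts[0]] = set(parts[2:])
    return pathways


# -- analyte -> node mapping table ------------------------------------------

def write_mapping(mapping: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("analyte\tnode\n")
        for analyte in sorted(mapping):
            for node in mapping[analyte]:
                fh.write(f"{analyte}\t{node}\n")


def read_mapping(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping = {}
    for _, row in df.iterrows():
        mapping.setdefault(row["analyte"], []).append(row["node"])
    return mapping


# -- ground truth / JSON ----------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def write_ground_truth(truth: SimGroundTruth, path) -> None:
    write_json(
        {
            "signal_analytes": truth.signal_analytes,
            "true_effects": truth.true_effects,
            "sample_biases": truth.sample_biases,
            "planted_communities": truth.planted_communities,
            "planted_pathways": truth.planted_pathways,
            "analyte_map": truth.analyte_map,
        },
        path,
    )


def read_ground_truth(path) -> SimGroundTruth:
    d = json.loads(Path(path).read_text())
    return SimGroundTruth(
        signal_analytes=set(d.get("signal_analytes", [])),
        true_effects=d.get("true_effects", {}),
        sample_biases=d.get("sample_biases", {}),
        planted_communities=d.get("planted_communities", {}),
        planted_pathways={k: set(v) for k, v in d.get("planted_pathways", {}).items()},
        analyte_map=d.get("analyte_map", {}),
    )
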