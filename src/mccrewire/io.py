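"""Readers and writers for the plain-text interchange formats.

All tabular outputs are TSV with headers; gene sets travel as GMT; network
provenance as JSON sidecars.  Writers format floats with ``%.10g`` so that
re-runs under identical configs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ExpressionMatrix
from .regnet import BipartiteNetwork
from .signature import GeneSignature

FLOAT_FMT = "%.10g"


# -- expression ------------------------------------------------------------

def write_expression(expr: ExpressionMatrix, values_path, meta_path) -> None:
    expr.values.to_csv(values_path, sep="\t", float_format=FLOAT_FMT,
                       index_label="gene")
    expr.meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_expression(values_path, meta_path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="gene")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample")
    return ExpressionMatrix(values, meta)


# -- GMT gene sets ---------------------------------------------------------

def write_gmt(sets: Mapping[str, Iterable[str]], path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sets:
            genes = "\t".join(sets[name])
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


# -- signatures ------------------------------------------------------------

def write_signature(signature: GeneSignature, gmt_path, scores_path) -> None:
    write_gmt({"UP": signature.up, "DOWN": signature.down}, gmt_path,
              description="signature-tail")
    table = signature.scores.copy()
    tail = pd.Series("none", index=table.index)
    tail[table.index.isin(signature.up)] = "up"
    tail[table.index.isin(signature.down)] = "down"
    table["tail"] = tail
    table.to_csv(scores_path, sep="\t", float_format=FLOAT_FMT,
                 index_label="gene")


def read_signature(gmt_path, scores_path) -> GeneSignature:
    sets = read_gmt(gmt_path)
    scores = pd.read_csv(scores_path, sep="\t", index_col="gene")
    return GeneSignature(up=sets["UP"], down=sets["DOWN"],
                         n_per_tail=len(sets["UP"]),
                         scores=scores[["score"]])


# -- perturbation profiles -------------------------------------------------

def write_profiles(profiles: Mapping[str, "object"], path) -> None:
    """One gene column plus one log2FC column per perturbagen."""
    frame = pd.DataFrame({name: p.log2fc for name, p in profiles.items()})
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene")


def read_profiles(path) -> dict[str, "object"]:
    from .reversal import PerturbationProfile
    frame = pd.read_csv(path, sep="\t", index_col="gene")
    return {name: PerturbationProfile(name, frame[name]) for name in frame.columns}


# -- networks --------------------------------------------------------------

def write_edge_list(frame: pd.DataFrame, path) -> None:
    """Dense TF x gene (or gene x gene) matrix as a (row, col, weight) TSV."""
    long = frame.stack().rename("weight").reset_index()
    long.columns = ["tf", "gene", "weight"]
    long.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_edge_list(path) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t")
    return long.pivot(index="tf", columns="gene", values="weight")


def write_network(net: BipartiteNetwork, edges_path, sidecar_path=None) -> None:
    write_edge_list(net.frame(), edges_path)
    if sidecar_path is not None:
        tag = {k: v for k, v in net.tag.items()
               if isinstance(v, (str, int, float, bool, type(None)))}
        Path(sidecar_path).write_text(json.dumps(tag, indent=1, sort_keys=True))


def read_network(edges_path, sidecar_path=None) -> BipartiteNetwork:
    frame = read_edge_list(edges_path)
    tag = {}
    if sidecar_path is not None and Path(sidecar_path).exists():
        tag = json.loads(Path(sidecar_path).read_text())
    return BipartiteNetwork(tfs=list(frame.index), genes=list(frame.columns),
                            weights=frame.to_numpy(), tag=tag)


def write_dense_matrix(frame: pd.DataFrame, path, index_label="gene") -> None:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label=index_label)


def read_dense_matrix(path, index_label="gene") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_label)


# -- communities, partitions, truth ---------------------------------------

def write_communities(result, path) -> None:
    rows = [{"node": name, "namespace": ns,
             "community": result.membership[(ns, name)],
             "contribution": result.diff_modularity[(ns, name)],
             "retained": int(result.membership[(ns, name)] in set(result.retained))}
            for (ns, name) in sorted(result.membership)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format=FLOAT_FMT)


def write_partition(labels: pd.Series, path) -> None:
    labels.rename("module").to_csv(path, sep="\t", index_label="gene")


def write_truth(truth, path) -> None:
    payload = {
        "planted_module_labels": truth.planted_module_labels,
        "planted_trends": truth.planted_trends,
        "planted_marker_assoc": truth.planted_marker_assoc,
        "planted_reverser": truth.planted_reverser,
        "planted_enriched_terms": truth.planted_enriched_terms,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path):
    from .data import SyntheticTruth
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(**payload)
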