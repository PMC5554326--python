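"""Reading and writing the pipeline's tabular formats.

Abundance tables are TSV with features as rows (first column the feature
id) and a header row of sample ids; metadata TSV has one row per sample
(first column the sample id, a ``ph`` column, remaining columns
environmental variables). Networks serialize as weighted edge-list TSV and
GraphML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import networkx as nx
import pandas as pd
import yaml

from .synth import AbundanceTable, SampleMetadata
from .network import CorrelationNetwork

__all__ = [
    "read_abundance_tsv",
    "write_abundance_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "write_network",
    "write_json",
    "load_yaml_config",
]


def read_abundance_tsv(path: str | Path, layer: str | None = None) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return AbundanceTable(layer=layer or Path(path).stem, data=df.astype(float))


def write_abundance_tsv(table: AbundanceTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="feature_id")


def read_metadata_tsv(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if "ph" not in df.columns:
        raise ValueError("metadata TSV must contain a 'ph' column")
    env = df.drop(columns=["ph"]).astype(float)
    return SampleMetadata(
        sample_ids=tuple(df.index.astype(str)),
        ph=df["ph"].astype(float),
        env=env,
    )


def write_metadata_tsv(metadata: SampleMetadata, path: str | Path) -> None:
    df = pd.concat([metadata.ph, metadata.env], axis=1)
    df.to_csv(path, sep="\t", index_label="sample_id")


def write_network(net: CorrelationNetwork, prefix: str | Path) -> None:
    """Write one network as edge-list TSV and GraphML (``prefix`` + ext)."""
    prefix = Path(prefix)
    rows = [
        {"node_a": a, "node_b": b, "r": data["weight"]}
        for a, b, data in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "r"]).to_csv(
        prefix.with_suffix(".tsv"), sep="\t", index=False
    )
    nx.write_graphml(net.graph, prefix.with_suffix(".graphml"))


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg
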