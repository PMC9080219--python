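"""Plain-text file formats: count tables (TSV), environment (CSV),
planted-truth JSON, association tables (TSV) and networks (GraphML +
edge-list/node-table TSV)."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from planktonet.prep import CountTable
from planktonet.synth import SynthTruth


def _parse_months(columns, context: str) -> pd.PeriodIndex:
    try:
        return pd.PeriodIndex([pd.Period(c, freq="M") for c in columns])
    except Exception as exc:
        raise ValueError(f"{context}: column headers must be ISO year-month stamps: {exc}")


def write_count_table(table: CountTable, path) -> None:
    out = table.counts.copy()
    out.columns = [str(c) for c in out.columns]
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t")


def read_count_table(path, domain: str, size_fraction: str) -> CountTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    months = _parse_months(df.columns, str(path))
    if months.duplicated().any():
        dupes = months[months.duplicated()].astype(str).tolist()
        raise ValueError(f"{path}: duplicate sample dates {dupes}")
    arr = df.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise ValueError(
            f"{path}: non-integer count at OTU {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"{path}: negative count at OTU {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    df = df.astype(int)
    df.columns = months
    df.index.name = None
    return CountTable(counts=df, domain=domain, size_fraction=size_fraction)


def read_tables(metadata_path) -> list[CountTable]:
    """Load count tables listed in a metadata TSV with columns
    ``file``, ``domain``, ``size_fraction`` (paths relative to the
    metadata file)."""
    metadata_path = Path(metadata_path)
    meta = pd.read_csv(metadata_path, sep="\t")
    required = {"file", "domain", "size_fraction"}
    if not required <= set(meta.columns):
        raise ValueError(
            f"{metadata_path}: metadata needs columns {sorted(required)}, "
            f"found {list(meta.columns)}"
        )
    tables = []
    for i, row in meta.iterrows():
        fpath = metadata_path.parent / row["file"]
        if not fpath.exists():
            raise ValueError(f"{metadata_path} line {i + 2}: missing table file {fpath}")
        tables.append(read_count_table(fpath, row["domain"], row["size_fraction"]))
    return tables


def write_env(env: pd.DataFrame, path) -> None:
    out = env.copy()
    out.index = out.index.astype(str)
    out.index.name = "month"
    out.to_csv(path)


def read_env(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    months = _parse_months(df.index, str(path))
    expected = pd.period_range(months.min(), months.max(), freq="M")
    missing = expected.difference(months)
    if len(missing):
        raise ValueError(f"{path}: missing months {missing.astype(str).tolist()}")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"{path}: missing values in variables {bad}")
    df.index = months
    return df


def write_truth(truth: SynthTruth, path) -> None:
    payload = {
        "direct_pairs": [[sorted(p)[0], sorted(p)[1], s] for p, s in truth.direct_pairs.items()],
        "env_driven_pairs": [
            [sorted(p)[0], sorted(p)[1], v] for p, v in truth.env_driven_pairs.items()
        ],
        "niche_labels": truth.niche_labels,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path) -> SynthTruth:
    payload = json.loads(Path(path).read_text())
    return SynthTruth(
        direct_pairs={frozenset((a, b)): int(s) for a, b, s in payload["direct_pairs"]},
        env_driven_pairs={
            frozenset((a, b)): v for a, b, v in payload["env_driven_pairs"]
        },
        niche_labels=dict(payload["niche_labels"]),
    )


def write_associations(associations: pd.DataFrame, path) -> None:
    associations.to_csv(path, sep="\t", index=False)


def read_associations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.attrs["n_tests"] = len(df)
    return df


def write_network(net: nx.Graph, prefix, fmt: str = "tsv") -> list[Path]:
    """Write a network as GraphML or as an edge-list + node-table TSV pair.

    The TSV pair is a lossless attribute round trip; GraphML is loadable
    by standard graph tools.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    if fmt == "graphml":
        path = prefix.with_suffix(".graphml")
        nx.write_graphml(net, path)
        written.append(path)
    elif fmt == "tsv":
        edge_rows = [
            {"node_a": str(u), "node_b": str(v), **data} for u, v, data in net.edges(data=True)
        ]
        node_rows = [{"node": str(u), **data} for u, data in net.nodes(data=True)]
        epath = prefix.with_name(prefix.name + "_edges.tsv")
        npath = prefix.with_name(prefix.name + "_nodes.tsv")
        edge_df = pd.DataFrame(edge_rows) if edge_rows else pd.DataFrame(columns=["node_a", "node_b"])
        node_df = pd.DataFrame(node_rows) if node_rows else pd.DataFrame(columns=["node"])
        edge_df.to_csv(epath, sep="\t", index=False)
        node_df.to_csv(npath, sep="\t", index=False)
        written.extend([epath, npath])
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return written


def read_network_tsv(prefix) -> nx.Graph:
    prefix = Path(prefix)
    epath = prefix.with_name(prefix.name + "_edges.tsv")
    npath = prefix.with_name(prefix.name + "_nodes.tsv")
    g = nx.Graph()
    nodes = pd.read_csv(npath, sep="\t")
    for _, row in nodes.iterrows():
        attrs = {k: row[k] for k in nodes.columns if k != "node" and pd.notna(row[k])}
        g.add_node(str(row["node"]), **attrs)
    if epath.exists():
        edges = pd.read_csv(epath, sep="\t")
        for _, row in edges.iterrows():
            attrs = {
                k: row[k]
                for k in edges.columns
                if k not in ("node_a", "node_b") and pd.notna(row[k])
            }
            g.add_edge(str(row["node_a"]), str(row["node_b"]), **attrs)
    return g
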