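"""Readers and writers for every on-disk artifact.

Tabular formats are TSV (QIIME-classic dialect: first header cell
``#OTU ID``, tab-separated, UTF-8, no quoting). Abundance tables can also be
read/written as dense BIOM 1.0 JSON. Trees are newick (via scikit-bio),
networks are GraphML (via networkx) or a flat edge TSV.

All readers validate and reject malformed input (duplicate ids, negative
entries) rather than silently coercing it.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

from .datatypes import (
    TAXONOMY_RANKS,
    AbundanceTable,
    FunctionTable,
    GenomeContentTable,
    TaxonomyTable,
)

__all__ = [
    "read_abundance",
    "write_abundance",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "read_genome_content",
    "write_genome_content",
    "read_ko_pathway_map",
    "write_ko_pathway_map",
    "read_function_table",
    "write_function_table",
    "read_tree",
    "write_tree",
    "write_network",
    "read_edge_tsv",
]

_OTU_HEADER = "#OTU ID"
_SSU_COLUMN = "16S_copies"
_FLOAT_FMT = "%.12g"


def _read_id_matrix(path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.index.name = None
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} id(s) in {path}: {dup}")
    if pd.Index(df.columns).has_duplicates:
        raise ValueError(f"duplicate column id(s) in {path}")
    return df


def _check_non_negative(df: pd.DataFrame, path) -> None:
    values = df.to_numpy()
    if values.size and values.min() < 0:
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative entry in {path} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )


# ---------------------------------------------------------------------------
# abundance tables


def read_abundance(
    path,
    dialect: str = "tsv",
    metadata: pd.DataFrame | None = None,
    is_relative: bool = False,
) -> AbundanceTable:
    """Read an ASV-by-sample table from TSV or BIOM 1.0 JSON."""
    if dialect == "tsv":
        df = _read_id_matrix(path, "ASV").astype(float)
        _check_non_negative(df, path)
        return AbundanceTable(df, metadata=metadata, is_relative=is_relative)
    if dialect == "biom-json":
        return _read_biom_json(path, is_relative=is_relative)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'biom-json')")


def write_abundance(table: AbundanceTable, path, dialect: str = "tsv") -> None:
    if dialect == "tsv":
        _write_matrix_tsv(table.data, path, header=_OTU_HEADER)
    elif dialect == "biom-json":
        _write_biom_json(table, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_matrix_tsv(df: pd.DataFrame, path, header: str) -> None:
    out = df.copy()
    out.index.name = header
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def _read_biom_json(path, is_relative: bool = False) -> AbundanceTable:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("matrix_type") != "dense":
        raise ValueError("only dense BIOM 1.0 JSON is supported")
    asv_ids = [row["id"] for row in doc["rows"]]
    sample_ids = [col["id"] for col in doc["columns"]]
    data = pd.DataFrame(doc["data"], index=asv_ids, columns=sample_ids, dtype=float)
    metadata = None
    col_meta = [col.get("metadata") for col in doc["columns"]]
    if any(m for m in col_meta):
        metadata = pd.DataFrame(
            [m or {} for m in col_meta], index=pd.Index(sample_ids)
        )
    _check_non_negative(data, path)
    if data.index.has_duplicates:
        dup = data.index[data.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate ASV id(s) in {path}: {dup}")
    return AbundanceTable(data, metadata=metadata, is_relative=is_relative)


def _write_biom_json(table: AbundanceTable, path) -> None:
    meta = table.metadata
    columns = []
    for s in table.sample_ids:
        m = None
        if meta is not None:
            m = {k: v for k, v in meta.loc[s].items()}
        columns.append({"id": s, "metadata": m})
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "dualcore",
        "date": "",
        "matrix_type": "dense",
        "matrix_element_type": "float",
        "shape": [table.n_asvs, table.n_samples],
        "rows": [{"id": a, "metadata": None} for a in table.asv_ids],
        "columns": columns,
        "data": table.data.to_numpy().tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# sample metadata


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = None
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id(s) in {path}: {dup}")
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = "#SampleID"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# taxonomy


def read_taxonomy(path) -> TaxonomyTable:
    df = _read_id_matrix(path, "ASV")
    missing = [r for r in TAXONOMY_RANKS if r not in df.columns]
    if missing:
        raise ValueError(f"taxonomy file {path} missing rank column(s): {missing}")
    return TaxonomyTable(df[list(TAXONOMY_RANKS)].astype(str))


def write_taxonomy(taxonomy: TaxonomyTable, path) -> None:
    _write_matrix_tsv(taxonomy.data, path, header="#ASV ID")


# ---------------------------------------------------------------------------
# genome content (per-ASV KO copy numbers + 16S copies)


def read_genome_content(path) -> GenomeContentTable:
    df = _read_id_matrix(path, "ASV")
    if _SSU_COLUMN not in df.columns:
        raise ValueError(f"genome content file {path} missing {_SSU_COLUMN!r} column")
    ssu = df[_SSU_COLUMN].astype(int).rename(None)
    kos = df.drop(columns=[_SSU_COLUMN]).astype(int)
    _check_non_negative(kos, path)
    return GenomeContentTable(ko_copies=kos, ssu_copies=ssu)


def write_genome_content(gc: GenomeContentTable, path) -> None:
    out = gc.ko_copies.copy()
    out.insert(0, _SSU_COLUMN, gc.ssu_copies.loc[out.index])
    _write_matrix_tsv(out, path, header="#ASV ID")


# ---------------------------------------------------------------------------
# KO -> pathway map


def read_ko_pathway_map(path) -> dict[str, frozenset[str]]:
    mapping: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: expected '#KO ID' header line")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            ko = parts[0]
            if ko in mapping:
                raise ValueError(f"duplicate KO id {ko!r} at {path}:{lineno}")
            pwys = parts[1] if len(parts) > 1 else ""
            pathway_ids = frozenset(p for p in pwys.split(";") if p)
            mapping[ko] = pathway_ids
    return mapping


def write_ko_pathway_map(mapping: dict[str, frozenset[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("#KO ID\tpathways\n")
        for ko in sorted(mapping):
            fh.write(f"{ko}\t{';'.join(sorted(mapping[ko]))}\n")


# ---------------------------------------------------------------------------
# function tables


def read_function_table(path, level: str) -> FunctionTable:
    df = _read_id_matrix(path, level)
    _check_non_negative(df, path)
    return FunctionTable(level=level, data=df.astype(float))


def write_function_table(table: FunctionTable, path) -> None:
    header = "#KO ID" if table.level == "KO" else "#Pathway ID"
    _write_matrix_tsv(table.data, path, header=header)


# ---------------------------------------------------------------------------
# trees


def read_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    n_missing = sum(1 for n in tree.traverse(include_self=False) if n.length is None)
    if n_missing:
        warnings.warn(
            f"{path}: {n_missing} branch(es) without length, treated as 0",
            stacklevel=2,
        )
        for node in tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
    return tree


def write_tree(tree: TreeNode, path) -> None:
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError("branch lengths are mandatory on write")
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# networks

_NODE_ATTRS = ("core_label", "degree", "closeness", "betweenness", "is_hub")
_EDGE_ATTRS = ("mic", "pearson_r", "nonlinearity", "nonlinear", "p_raw", "q_value")


def write_network(network, path, format: str = "graphml") -> None:
    """Write a :class:`~dualcore.network_mic.Network` as GraphML or edge TSV."""
    graph = network.graph
    if format == "graphml":
        g = nx.Graph()
        for node, attrs in graph.nodes(data=True):
            g.add_node(node, **{k: attrs[k] for k in _NODE_ATTRS if k in attrs})
        for u, v, attrs in graph.edges(data=True):
            g.add_edge(u, v, **{k: attrs[k] for k in _EDGE_ATTRS if k in attrs})
        nx.write_graphml(g, path)
    elif format == "edge_tsv":
        rows = []
        for u, v, attrs in sorted(graph.edges(data=True)):
            row = {"source": u, "target": v}
            row.update({k: attrs.get(k) for k in _EDGE_ATTRS})
            rows.append(row)
        df = pd.DataFrame(rows, columns=["source", "target", *_EDGE_ATTRS])
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_edge_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=0)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
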