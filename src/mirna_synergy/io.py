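"""Readers and writers for the tool's plain-text formats.

All tabular formats are TSV.  Expression matrices have a header row of sample
ids and entity ids in the first column; empty cells or ``NA`` mark missing
values.  Network edgelists canonicalise each pair with lexicographic endpoint
ordering so that outputs are deterministic and diffable.
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import BindingNetwork, ExpressionMatrix, GeneList, SurvivalTable

_MISSING = {"", "NA", "NaN", "nan"}


def read_expression(path: str | Path, class_label: str) -> ExpressionMatrix:
    """Read an entities-x-samples TSV; ``class_label`` tags every row."""
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for lineno, rec in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if lineno > 1 and rows and len(rec) != len(rows[0]):
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(rec)} fields, expected {len(rows[0])})")
            rows.append(rec)
    if not rows:
        raise ValueError(f"{path}: empty file")
    sample_ids = rows[0][1:]
    entity_ids = [r[0] for r in rows[1:]]
    seen: set[str] = set()
    for eid in entity_ids:
        if eid in seen:
            raise ValueError(f"{path}: duplicate entity id {eid!r}")
        seen.add(eid)
    data = np.full((len(entity_ids), len(sample_ids)), np.nan)
    for i, rec in enumerate(rows[1:]):
        for j, cell in enumerate(rec[1:]):
            if cell.strip() not in _MISSING:
                data[i, j] = float(cell)
    df = pd.DataFrame(data, index=entity_ids, columns=sample_ids)
    return ExpressionMatrix(df, pd.Series(class_label, index=entity_ids))


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", na_rep="NA", index_label="id")


def concat_expression(a: ExpressionMatrix, b: ExpressionMatrix) -> ExpressionMatrix:
    """Stack two matrices sharing the same samples (e.g. miRNA + mRNA blocks)."""
    if list(a.sample_ids) != list(b.sample_ids):
        raise ValueError("sample ids differ between matrices")
    return ExpressionMatrix(pd.concat([a.values, b.values]),
                            pd.concat([a.entity_class, b.entity_class]))


def read_survival(path: str | Path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df.columns = [c.lower() for c in df.columns]
    df = df.set_index(df.columns[0])
    return SurvivalTable(df[["time", "event"]].astype(float))


def write_survival(s: SurvivalTable, path: str | Path) -> None:
    s.table.to_csv(path, sep="\t", index_label="sample_id")


def read_interactions(path: str | Path) -> BindingNetwork:
    """Read a two-column (miRNA, mRNA) TSV, optional header, deduplicated."""
    edges: set[tuple[str, str]] = set()
    with open(path, newline="") as fh:
        for lineno, rec in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue
            if len(rec) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            u, v = rec[0].strip(), rec[1].strip()
            if lineno == 1 and u.lower() in {"mirna", "mir", "regulator"}:
                continue
            edges.add((u, v))
    return BindingNetwork(edges)   # bipartiteness validated by the type


def write_interactions(net: BindingNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("miRNA\tmRNA\n")
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Plain text, one identifier per line; '#' comments ignored."""
    members = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                members.add(line)
    return GeneList(name or Path(path).stem, members)


def read_gmt(path: str | Path) -> list[GeneList]:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out.append(GeneList(parts[0], set(p for p in parts[2:] if p)))
    return out


def write_network(net, path: str | Path, fmt: str = "edgelist") -> None:
    """Write a synergy network; ``fmt`` is ``edgelist`` (TSV) or ``graphml``.

    Edgelist rows are ``miRNA_A  miRNA_B  supporting_mRNAs`` with A < B
    lexicographically and deterministic row order.
    """
    if fmt == "edgelist":
        with open(path, "w") as fh:
            fh.write("miRNA_A\tmiRNA_B\tsupporting_mRNAs\n")
            for (a, b), support in sorted(net.edges.items()):
                fh.write(f"{a}\t{b}\t{';'.join(sorted(support))}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        g.add_nodes_from(sorted(net.nodes))
        for (a, b), support in sorted(net.edges.items()):
            g.add_edge(a, b, supporting_mRNAs=";".join(sorted(support)))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network_edgelist(path: str | Path):
    """Inverse of :func:`write_network` for the edgelist dialect."""
    from .synergy import SynergyNetwork
    edges: dict[tuple[str, str], set[str]] = {}
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            a, b = parts[0], parts[1]
            support = set(parts[2].split(";")) if len(parts) > 2 and parts[2] else set()
            edges[tuple(sorted((a, b)))] = support
    nodes = {n for pair in edges for n in pair}
    return SynergyNetwork(nodes=nodes, edges=edges)
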