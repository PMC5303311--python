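"""Readers and writers for expression matrices, prior-score tables and
networks, plus the JSON run manifest used by the command-line interface.

Prior tables follow the STRING export convention: one row per gene pair
with a combined confidence score. Scores on the 0-1000 scale are
auto-detected and divided by 1000 so that all weights live in [0, 1].
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .solvers import GeneNetwork

__all__ = [
    "read_expression",
    "read_prior_table",
    "build_weight_matrix",
    "write_network",
    "read_network_tsv",
    "write_manifest",
]

logger = logging.getLogger(__name__)


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path, orientation: str = "samples×genes"):
    """Read an expression matrix with a header row and an index column.

    Returns (matrix, gene_ids, sample_ids) with samples in rows. Accepts
    TSV (default) or CSV by extension. ``orientation`` is
    "samples×genes" (alias "samples x genes") or "genes×samples".
    """
    orientation = orientation.replace(" x ", "×").replace("x", "×") if "×" not in orientation else orientation
    if orientation not in ("samples×genes", "genes×samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        axis = "gene" if orientation == "samples×genes" else "sample"
        raise ValueError(f"duplicate {axis} IDs: {dupes[:10]}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "genes×samples":
        df = df.T
    if df.isna().any().any():
        rr, cc = np.where(df.isna().to_numpy())
        cells = [
            f"(row {df.index[r]!r}, column {df.columns[c]!r})" for r, c in zip(rr, cc)
        ][:10]
        raise ValueError(f"missing values in expression matrix at {', '.join(cells)}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate gene IDs: {dupes[:10]}")
    try:
        mat = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric values in expression matrix: {exc}") from exc
    return mat, [str(c) for c in df.columns], [str(i) for i in df.index]


def read_prior_table(path, scale_mode: str = "auto") -> pd.DataFrame:
    """Read a (gene_a, gene_b, score) table of prior interaction scores.

    ``scale_mode``: "unit" (scores already in [0, 1]), "string1000"
    (divide by 1000, the STRING combined-score convention), or "auto"
    (use string1000 iff any score exceeds 1). Duplicate pairs keep the
    maximum score; self-pairs are dropped.
    """
    df = pd.read_csv(path, sep=_sep_for(path), header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError("prior table needs 3 columns: gene_a, gene_b, score")
    first = df.iloc[0]
    try:
        float(first[df.columns[2]])
    except ValueError:
        df = df.iloc[1:]  # header row
    out = pd.DataFrame(
        {
            "gene_a": df.iloc[:, 0].astype(str),
            "gene_b": df.iloc[:, 1].astype(str),
            "score": df.iloc[:, 2].astype(float),
        }
    )
    if scale_mode == "auto":
        scale_mode = "string1000" if (out["score"] > 1).any() else "unit"
        if scale_mode == "string1000":
            logger.info("prior scores exceed 1: assuming the 0-1000 STRING scale")
    if scale_mode == "string1000":
        out["score"] = out["score"] / 1000.0
    elif scale_mode != "unit":
        raise ValueError(f"unknown scale_mode {scale_mode!r}")
    if ((out["score"] < 0) | (out["score"] > 1)).any():
        raise ValueError("prior scores outside [0, 1] after scaling")
    return out


def build_weight_matrix(prior: pd.DataFrame, gene_ids: list[str]) -> np.ndarray:
    """Symmetric weight matrix aligned to ``gene_ids``.

    Pairs absent from the prior get weight 0 (no supporting evidence);
    self-pairs are 0; prior rows naming unknown genes are ignored with a
    logged count; duplicate pairs keep the maximum score.
    """
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("gene_ids must be unique")
    idx = {g: i for i, g in enumerate(gene_ids)}
    p = len(gene_ids)
    w = np.zeros((p, p))
    skipped = 0
    for a, b, s in prior[["gene_a", "gene_b", "score"]].itertuples(index=False):
        if not (0 <= s <= 1):
            raise ValueError(f"score {s} for pair ({a}, {b}) outside [0, 1]")
        ia, ib = idx.get(a), idx.get(b)
        if ia is None or ib is None:
            skipped += 1
            continue
        if ia == ib:
            continue
        if s > w[ia, ib]:
            w[ia, ib] = s
            w[ib, ia] = s
    if skipped:
        logger.info("%d prior record(s) referenced genes outside the expression matrix", skipped)
    return w


def _sorted_edges(net: GeneNetwork):
    return sorted(net.edges)


def write_network(net: GeneNetwork, fmt: str, path) -> None:
    """Write a network as 'tsv' (edge list), 'sif' or 'graphml'.

    Output ordering is deterministic (lexicographic by gene pair); the
    TSV round-trips through :func:`read_network_tsv`.
    """
    path = Path(path)
    if fmt == "tsv":
        df = pd.DataFrame(_sorted_edges(net), columns=["gene_a", "gene_b"])
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for a, b in _sorted_edges(net):
                fh.write(f"{a}\tpp\t{b}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        g.add_nodes_from(net.nodes)
        g.add_edges_from(_sorted_edges(net))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network_tsv(path, nodes: list[str] | None = None) -> GeneNetwork:
    """Read an edge-list TSV written by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    edges = list(df.itertuples(index=False, name=None))
    if nodes is None:
        nodes = sorted({g for e in edges for g in e})
    return GeneNetwork.from_edges(nodes, edges)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, params: dict, input_files: list | None = None) -> None:
    """JSON manifest of parameters, seeds and input checksums for a run."""
    manifest = {"parameters": params, "inputs": {}}
    for f in input_files or []:
        if f is not None and Path(f).exists():
            manifest["inputs"][str(f)] = _sha256(f)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
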