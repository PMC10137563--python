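"""Reading and writing weighted networks.

Supported read formats: TSV weighted edge list, GML, Pajek .net, and
dense CSV adjacency.  Write formats: TSV edge list and dense CSV.
All readers return a :class:`~ndfawm.samplers.WeightedNetwork` with a
deterministic node ordering (sorted ids, numerically where possible) so
the same file always yields the same index mapping.  Unweighted edges
get weight 1; negative weights (signed networks) are preserved.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

from .samplers import WeightedNetwork

__all__ = ["read_network", "write_network", "network_from_graph", "karate_club"]

READ_FORMATS = ("tsv_edgelist", "gml", "pajek_net", "csv_adjacency")
WRITE_FORMATS = ("tsv_edgelist", "csv_adjacency")

_EXT_TO_FORMAT = {
    ".tsv": "tsv_edgelist", ".edges": "tsv_edgelist", ".txt": "tsv_edgelist",
    ".gml": "gml", ".net": "pajek_net", ".csv": "csv_adjacency",
}


class NetworkFormatError(ValueError):
    """The file cannot be interpreted in the requested format."""


def _sort_key(node):
    try:
        return (0, float(node), "")
    except (TypeError, ValueError):
        return (1, 0.0, str(node))


def _edges_to_network(edges, nodes=None) -> WeightedNetwork:
    """Assemble a symmetric adjacency from (u, v, w) records.

    Both orientations of a pair may appear if their weights agree
    exactly; conflicting duplicates are an error (silent averaging would
    hide data problems).
    """
    seen: dict[tuple, float] = {}
    node_set = set(nodes) if nodes is not None else set()
    for u, v, w in edges:
        w = float(w)
        if not np.isfinite(w):
            raise NetworkFormatError(f"non-finite weight on edge ({u}, {v})")
        node_set.update((u, v))
        key = (u, v) if _sort_key(u) <= _sort_key(v) else (v, u)
        if key in seen and seen[key] != w:
            raise NetworkFormatError(
                f"conflicting weights for pair {key}: {seen[key]} vs {w}")
        seen[key] = w
    ids = sorted(node_set, key=_sort_key)
    index = {node: i for i, node in enumerate(ids)}
    A = np.zeros((len(ids), len(ids)))
    for (u, v), w in seen.items():
        i, j = index[u], index[v]
        A[i, j] = w
        A[j, i] = w
    return WeightedNetwork(A=A, node_ids=ids)


def network_from_graph(G: "nx.Graph", weight: str = "weight",
                       default_weight: float = 1.0) -> WeightedNetwork:
    """Convert a networkx graph (directed graphs are checked for
    symmetric weights first; multigraph parallel edges must agree)."""
    if G.is_directed():
        edges = [(u, v, d.get(weight, default_weight)) for u, v, d in G.edges(data=True)]
        return _edges_to_network(edges, nodes=G.nodes())
    if G.is_multigraph():
        edges = [(u, v, d.get(weight, default_weight)) for u, v, d in G.edges(data=True)]
        return _edges_to_network(edges, nodes=G.nodes())
    edges = [(u, v, d.get(weight, default_weight)) for u, v, d in G.edges(data=True)]
    return _edges_to_network(edges, nodes=G.nodes())


def _read_tsv_edgelist(path: Path) -> WeightedNetwork:
    edges = []
    nodes: set = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and parts and not _is_number(parts[-1]) and len(parts) >= 2:
                continue  # header row
            if len(parts) == 2:
                u, v, w = parts[0], parts[1], 1.0
            elif len(parts) >= 3:
                u, v, w = parts[0], parts[1], float(parts[2])
            else:
                raise NetworkFormatError(f"{path}:{lineno}: expected 2 or 3 columns")
            u = int(u) if _is_int(u) else u
            v = int(v) if _is_int(v) else v
            edges.append((u, v, w))
            nodes.update((u, v))
    return _edges_to_network(edges, nodes=nodes)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _is_int(s) -> bool:
    try:
        int(s)
        return True
    except (TypeError, ValueError):
        return False


def _read_csv_adjacency(path: Path) -> WeightedNetwork:
    A = np.loadtxt(path, delimiter=",", ndmin=2)
    if A.shape[0] != A.shape[1]:
        raise NetworkFormatError(f"adjacency in {path} is {A.shape}, not square")
    if not np.allclose(A, A.T, rtol=0.0, atol=0.0):
        if np.allclose(A, A.T, rtol=1e-12, atol=0.0):
            A = (A + A.T) / 2.0
        else:
            raise NetworkFormatError(f"adjacency in {path} is not symmetric")
    return WeightedNetwork(A=A)


def read_network(path: str | Path, format: str | None = None) -> WeightedNetwork:
    """Read a weighted network; format inferred from the extension if omitted."""
    path = Path(path)
    if format is None:
        format = _EXT_TO_FORMAT.get(path.suffix.lower())
        if format is None:
            raise NetworkFormatError(
                f"cannot infer format from {path.suffix!r}; pass format=")
    if format == "tsv_edgelist":
        return _read_tsv_edgelist(path)
    if format == "gml":
        G = nx.read_gml(path, label="label")
        return network_from_graph(G)
    if format == "pajek_net":
        G = nx.read_pajek(path)
        return network_from_graph(G)
    if format == "csv_adjacency":
        return _read_csv_adjacency(path)
    raise NetworkFormatError(f"unknown format {format!r}; known: {READ_FORMATS}")


def write_network(net: WeightedNetwork, path: str | Path,
                  format: str | None = None) -> None:
    """Write a network losslessly (weights at full double precision).

    TSV edge lists carry one row per unordered pair with nonzero weight
    (i < j, 1-based positional ids); CSV writes the dense matrix.
    """
    path = Path(path)
    if format is None:
        format = _EXT_TO_FORMAT.get(path.suffix.lower())
    if format == "tsv_edgelist":
        lines = ["source\ttarget\tweight"]
        A = net.A
        iu, ju = np.nonzero(np.triu(A, k=0))
        for i, j in zip(iu, ju):
            lines.append(f"{i + 1}\t{j + 1}\t{float(A[i, j])!r}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "csv_adjacency":
        np.savetxt(path, net.A, delimiter=",", fmt="%.17g")
    else:
        raise NetworkFormatError(f"unknown write format {format!r}; known: {WRITE_FORMATS}")


def karate_club(weighted: bool = False) -> WeightedNetwork:
    """Zachary's Karate club network (34 nodes, 2 factions).

    networkx ships the original interaction counts as edge weights;
    ``weighted=False`` gives the classical binary version.
    """
    G = nx.karate_club_graph()
    if weighted:
        return network_from_graph(G, weight="weight")
    H = nx.Graph()
    H.add_nodes_from(G.nodes())
    H.add_edges_from(G.edges())
    return network_from_graph(H)
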