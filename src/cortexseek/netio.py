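"""Network serialization: GraphML (lossless) and SIF (edge-type relation token)."""

from __future__ import annotations

from pathlib import Path

import networkx as nx

NETWORK_FORMATS = ("graphml", "sif")


def write_network(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> Path:
    """Write an undirected gene graph.

    Nodes may carry a ``role`` attribute ({query, associated}) and edges a
    ``type`` and ``weight``; GraphML preserves all attributes, SIF writes one
    ``source <type> target`` line per edge (isolated nodes are emitted as
    bare single-token lines, the conventional SIF escape).
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
        return path
    if fmt == "sif":
        lines = []
        for u, v, data in sorted(graph.edges(data=True)):
            lines.append(f"{u}\t{data.get('type', 'association')}\t{v}")
        for node in sorted(graph.nodes):
            if graph.degree(node) == 0:
                lines.append(str(node))
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
        return path
    raise ValueError(f"unsupported network format {fmt!r}; choose from {NETWORK_FORMATS}")


def read_network(path: str | Path, fmt: str | None = None) -> nx.Graph:
    path = Path(path)
    if fmt is None:
        fmt = "sif" if path.suffix == ".sif" else "graphml"
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "sif":
        graph = nx.Graph()
        for raw in path.read_text(encoding="utf-8").splitlines():
            if not raw.strip():
                continue
            parts = raw.split("\t")
            if len(parts) == 1:
                graph.add_node(parts[0])
            elif len(parts) == 3:
                graph.add_edge(parts[0], parts[2], type=parts[1])
            else:
                raise ValueError(f"{path}: malformed SIF line {raw!r}")
        return graph
    raise ValueError(f"unsupported network format {fmt!r}")
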