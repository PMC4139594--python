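"""Query-list extension over a compendium of typed association networks.

The evidence channels (co-expression, co-localization, physical interaction,
predicted interaction, shared protein domains) are combined into one
weighted graph as a convex combination of their adjacency matrices (uniform
weights by default), query membership is propagated over the composite with
a Gaussian-field label-propagation scorer

    s = (I - alpha * S)^{-1} y,

where ``S`` is the symmetric degree-normalized adjacency and ``y`` puts
1/|query| on each query gene, and the top-``k`` non-query genes by score are
reported as the associated tier.  The output network is the induced subgraph
of query + associated nodes over all evidence channels, with roles and
scores attached.  This is a declared simplification of service-style
query-adaptive network weighting: the contract is "k associated genes from
evidence networks", not parity with any particular service.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .config import PipelineConfig
from .symbols import GeneList

log = logging.getLogger(__name__)


@dataclass
class ExtendedNetwork:
    """Query + associated genes with evidence edges and propagation scores."""

    graph: nx.Graph
    query: list[str]
    associated: list[str]
    scores: dict[str, float] = field(default_factory=dict)
    network_weights: dict[str, float] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def combine_networks(networks: dict[str, nx.Graph],
                     weights: dict[str, float] | None = None) -> nx.Graph:
    """Convex combination of evidence networks into one weighted graph.

    Edge weight = sum_i w_i * W_i(u, v) with the w_i normalized to sum to 1;
    uniform weights by default.
    """
    if not networks:
        raise ValueError("need at least one network")
    if weights is None:
        weights = {name: 1.0 for name in networks}
    missing = set(networks) - set(weights)
    if missing:
        raise ValueError(f"no weight for networks {sorted(missing)}")
    total = sum(weights[name] for name in networks)
    if total <= 0 or any(weights[name] < 0 for name in networks):
        raise ValueError("network weights must be non-negative with positive sum")

    composite = nx.Graph()
    for name, graph in networks.items():
        w = weights[name] / total
        composite.add_nodes_from(graph.nodes)
        if w == 0:
            continue
        for u, v, data in graph.edges(data=True):
            increment = w * float(data.get("weight", 1.0))
            if composite.has_edge(u, v):
                composite[u][v]["weight"] += increment
            else:
                composite.add_edge(u, v, weight=increment)
    return composite


def propagate(composite: nx.Graph, query: GeneList | list[str],
              alpha: float = 0.85) -> dict[str, float]:
    """Gaussian-field label propagation scores for every node.

    Solves (I - alpha*S) s = y with S = D^{-1/2} W D^{-1/2} and y uniform
    over the query genes present in the graph.  Isolated non-query nodes
    score exactly 0.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    nodes = sorted(composite.nodes)
    query_members = list(query)
    query_keys = {g.casefold() for g in query_members}
    query_idx = [i for i, node in enumerate(nodes) if str(node).casefold() in query_keys]
    if not query_idx:
        raise ValueError("no query gene is present in the composite graph")

    W = nx.to_numpy_array(composite, nodelist=nodes, weight="weight")
    deg = W.sum(axis=1)
    inv_sqrt = np.divide(1.0, np.sqrt(deg), out=np.zeros_like(deg), where=deg > 0)
    S = inv_sqrt[:, None] * W * inv_sqrt[None, :]
    y = np.zeros(len(nodes))
    y[query_idx] = 1.0 / len(query_idx)
    s = np.linalg.solve(np.eye(len(nodes)) - alpha * S, y)
    s = np.where(np.abs(s) < 1e-15, 0.0, s)  # clean solver noise on unreachable nodes
    return {node: float(score) for node, score in zip(nodes, s)}


def extend_list(networks: dict[str, nx.Graph], query: GeneList,
                config: PipelineConfig | None = None, *,
                network_weights: dict[str, float] | None = None,
                exclude_evidence: list[str] | None = None) -> ExtendedNetwork:
    """Extend a query gene list by the top-k propagation-ranked associates.

    Ties are broken lexicographically by symbol so the output is
    reproducible.  If fewer than ``config.k_extend`` non-query genes score
    above zero, all positive scorers are returned with a warning.
    ``exclude_evidence`` drops whole channels (e.g. ``["predicted"]``).
    """
    config = config or PipelineConfig()
    if exclude_evidence:
        networks = {name: g for name, g in networks.items() if name not in set(exclude_evidence)}
        if not networks:
            raise ValueError("all evidence networks were excluded")
    weights = network_weights or {name: 1.0 for name in networks}
    composite = combine_networks(networks, weights)
    scores = propagate(composite, query, alpha=config.propagation_alpha)

    query_keys = {g.casefold() for g in query}
    query_nodes = sorted(n for n in composite.nodes if str(n).casefold() in query_keys)
    candidates = [(node, s) for node, s in scores.items()
                  if str(node).casefold() not in query_keys and s > 0]
    candidates.sort(key=lambda item: (-item[1], str(item[0])))
    if len(candidates) < config.k_extend:
        log.warning("only %d scorable non-query genes available (k_extend=%d)",
                    len(candidates), config.k_extend)
    associated = [node for node, _ in candidates[:config.k_extend]]

    keep = set(query_nodes) | set(associated)
    out = nx.Graph()
    for node in sorted(keep):
        out.add_node(node, role="query" if str(node).casefold() in query_keys else "associated",
                     score=scores.get(node, 0.0))
    for name, graph in networks.items():
        for u, v, data in graph.edges(data=True):
            if u in keep and v in keep:
                out.add_edge(u, v, type=name, weight=float(data.get("weight", 1.0)))

    total = sum(weights[name] for name in networks)
    return ExtendedNetwork(graph=out, query=query_nodes, associated=associated,
                           scores={n: scores[n] for n in out.nodes},
                           network_weights={name: weights[name] / total for name in networks})
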