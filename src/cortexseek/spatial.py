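"""Spatial co-expression network construction (the neocortex VZ network).

Genes are prefiltered to those expressed in the included samples and
fold-enriched in a target zone, pairwise Pearson correlations of their
spatial profiles are computed, edges above a strict correlation threshold
are kept, and the reported network is (by default) the connected component
containing the most zone-enriched gene.  Running the same machinery with an
inverted mask yields the complementary "non-VZ" network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .config import PipelineConfig
from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

SEED_RULES = ("top-enriched-component", "all-components", "seed-gene")


class ConstantProfileError(ValueError):
    """Correlation is undefined for a constant expression profile."""


@dataclass
class ZoneMask:
    """Sample selection for zone-enrichment analysis.

    ``included_samples`` defines the spatial domain (e.g. all structures at
    E15.5); ``target_samples`` is the zone of interest within it (e.g. VZ at
    E15.5).  Enrichment compares target samples with the remaining included
    samples.
    """

    included_samples: list[str]
    target_samples: list[str]

    def __post_init__(self) -> None:
        included = set(self.included_samples)
        target = set(self.target_samples)
        if not included or not target:
            raise ValueError("mask sample sets must be non-empty")
        if not target <= included:
            raise ValueError("target samples must be a subset of included samples")
        if target == included:
            raise ValueError("target must leave a non-empty complement for comparison")

    @property
    def complement(self) -> list[str]:
        target = set(self.target_samples)
        return [s for s in self.included_samples if s not in target]

    def inverted(self) -> "ZoneMask":
        """Swap target and complement (the non-VZ analogue)."""
        return ZoneMask(list(self.included_samples), self.complement)


def mask_for(matrix: ExpressionMatrix, target_structures, target_ages=None,
             included_ages=None, invert: bool = False) -> ZoneMask:
    """Build a mask from sample-sheet structure/age annotations.

    ``included_ages`` defaults to ``target_ages`` (correlation within the
    target age only); pass ``included_ages=matrix.samples['age'].unique()``
    or an explicit list for cross-age profiles.
    """
    if isinstance(target_structures, str):
        target_structures = [target_structures]
    if isinstance(target_ages, str):
        target_ages = [target_ages]
    if included_ages is None:
        included_ages = target_ages
    conditions = {} if included_ages is None else {"age": tuple(included_ages)}
    included = matrix.sample_ids_where(**conditions)
    t_conditions: dict[str, object] = {"structure": tuple(target_structures)}
    if target_ages is not None:
        t_conditions["age"] = tuple(target_ages)
    target = [s for s in matrix.sample_ids_where(**t_conditions) if s in set(included)]
    mask = ZoneMask(included, target)
    return mask.inverted() if invert else mask


@dataclass
class CorrelationNetwork:
    """Thresholded Pearson co-expression graph plus its provenance."""

    graph: nx.Graph
    r_threshold: float
    seed_rule: str
    enrichment: dict[str, float] = field(default_factory=dict)
    dropped_constant: int = 0
    prefiltered_genes: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantProfileError("correlation undefined for a constant vector")
    return float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))


def zone_enrichment(matrix: ExpressionMatrix, mask: ZoneMask, gene: str,
                    eps: float = 1e-9) -> float:
    """Mean expression in the target zone over mean in the rest of the domain."""
    values = _zone_enrichment_all(matrix.subset(genes=[gene]), mask, eps)
    return float(values[0])


def _zone_enrichment_all(matrix: ExpressionMatrix, mask: ZoneMask, eps: float = 1e-9) -> np.ndarray:
    complement = mask.complement
    if not complement:
        raise ValueError("mask complement is empty")
    target_mean = matrix.values[mask.target_samples].mean(axis=1).to_numpy()
    rest_mean = matrix.values[complement].mean(axis=1).to_numpy()
    return (target_mean + eps) / (rest_mean + eps)


def build_vz_network(matrix: ExpressionMatrix, mask: ZoneMask,
                     config: PipelineConfig | None = None, *,
                     seed_rule: str = "top-enriched-component",
                     seed_gene: str | None = None,
                     floor_quantile: float = 0.2,
                     prefilter_fold: float | None = None) -> CorrelationNetwork:
    """Construct the zone co-expression network.

    Prefilters: mean expression over the included samples at or above the
    ``floor_quantile`` quantile of all gene means ("expressed in the
    domain"), and zone enrichment of at least ``prefilter_fold`` (default:
    ``config.fold_min``, "highly expressed in the zone").  Pairwise Pearson
    correlations are computed on the included-sample profiles and edges with
    ``r > config.r_threshold`` (strictly) are kept.
    """
    config = config or PipelineConfig()
    if seed_rule not in SEED_RULES:
        raise ValueError(f"seed_rule must be one of {SEED_RULES}")
    if prefilter_fold is None:
        prefilter_fold = config.fold_min

    sub = matrix.subset(sample_ids=list(mask.included_samples))
    means = sub.values.mean(axis=1).to_numpy()
    floor = float(np.quantile(means, floor_quantile))
    enrich = _zone_enrichment_all(sub, mask)
    passing = (means >= floor) & (enrich >= prefilter_fold)

    profiles = sub.values.to_numpy()
    constant = np.ptp(profiles, axis=1) == 0
    dropped_constant = int((passing & constant).sum())
    if dropped_constant:
        log.info("dropped %d constant-profile genes before correlation", dropped_constant)
    passing &= ~constant

    candidates = [g for g, ok in zip(sub.genes, passing) if ok]
    if len(candidates) < 2:
        raise ValueError(
            "fewer than 2 genes pass the prefilters "
            f"(floor={floor:.3g}, fold>={prefilter_fold}); nothing to correlate")
    enrich_map = {g: float(e) for g, e, ok in zip(sub.genes, enrich, passing) if ok}

    corr = np.corrcoef(profiles[passing])
    graph = nx.Graph()
    graph.add_nodes_from(candidates)
    idx_i, idx_j = np.nonzero(np.triu(corr > config.r_threshold, k=1))
    for i, j in zip(idx_i, idx_j):
        graph.add_edge(candidates[i], candidates[j], weight=float(corr[i, j]))

    if seed_rule == "top-enriched-component":
        seed = max(enrich_map, key=enrich_map.get)
        keep = nx.node_connected_component(graph, seed)
        graph = graph.subgraph(keep).copy()
    elif seed_rule == "seed-gene":
        if seed_gene is None or seed_gene not in graph:
            raise ValueError("seed_rule='seed-gene' requires a seed_gene present in the graph")
        keep = nx.node_connected_component(graph, seed_gene)
        graph = graph.subgraph(keep).copy()

    log.info("zone network: %d candidates -> %d nodes, %d edges (r > %g)",
             len(candidates), graph.number_of_nodes(), graph.number_of_edges(),
             config.r_threshold)
    return CorrelationNetwork(graph=graph, r_threshold=config.r_threshold,
                              seed_rule=seed_rule, enrichment=enrich_map,
                              dropped_constant=dropped_constant,
                              prefiltered_genes=candidates)
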