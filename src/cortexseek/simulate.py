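"""Synthetic developmental expression atlases, association networks and annotations.

The generators emulate the statistical structure the discovery pipeline
assumes, with known ground truth:

* a mouse structure-by-age ISH-like atlas (2104 genes, 7 stages) with a
  planted module of VZ-specific genes sharing a spatial template at E15.5;
* a human spatial panel (structures at 15-21 pcw, VZ/SVZ target) and a human
  temporal panel (stage bins from 8 pcw to adulthood, earliest bin target),
  both with planted modules whose cross-panel overlap mirrors the published
  screen overlaps (407-gene core, 7 of which are mouse-module orthologs);
* a five-evidence-channel association-network compendium wired so that a
  designated "associated" tier is preferentially linked to the query module;
* flat GMT annotation sets, some enriched in the planted genes.

All expression values are non-negative: every gene has a log-normal baseline,
planted genes multiply a shared spatial/temporal template (``planted_fold``
in the target samples, 1 elsewhere), and measurement noise is multiplicative
log-normal with standard deviation ``sigma`` on the log scale, split into a
module-shared and a gene-specific component so that planted genes co-vary
(``within_module_correlation``).  Every generator is deterministic given its
parameters and seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats

from . import published
from .genesets import GeneSet
from .matrix import ExpressionMatrix, SampleAnnotation, matrix_from_arrays
from .symbols import GeneList, HUMAN, MOUSE, OrthologTable, canonicalize

#: Evidence channels of the association compendium.
EVIDENCE_TYPES = ("coexpression", "colocalization", "physical", "predicted", "shared_domain")

# rng substream labels so panels simulated from one master seed do not share
# noise realizations
_STREAM = {"mouse": 11, "human_spatial": 12, "human_temporal": 13,
           "networks": 14, "annotations": 15}

MOUSE_STRUCTURES = ["VZ", "SVZ", "IZ", "CP", "MZ", "SP", "GE", "HIP", "TH", "HY", "MB", "HB"]
MOUSE_AGES = ["E11.5", "E13.5", "E15.5", "E18.5", "P4", "P14", "P56"]

HUMAN_STRUCTURES = ["VZ", "SVZ", "IZ", "SP", "CP", "MZ", "AMY", "THM", "Tg", "HIP",
                    "STR", "CB", "OB", "INS", "OCC", "PAR", "TEM", "FRO", "HY", "MD"]
HUMAN_SPATIAL_AGES = [f"{w}pcw" for w in range(15, 22)]           # 15..21 pcw weekly
HUMAN_TEMPORAL_STAGES = ["8-9pcw", "10-12pcw", "13-15pcw", "16-18pcw", "19-24pcw",
                         "25-38pcw", "0-1y", "2-11y", "12-19y", "20-40y"]
HUMAN_TEMPORAL_REGIONS = ["NCX", "HIP", "AMY", "STR", "THM", "CB",
                          "OFC", "DFC", "MFC", "ITC", "STC", "V1C"]


class ParameterError(ValueError):
    """Simulation parameters are inconsistent."""


@dataclass
class SimulationParams:
    """Parameters of one simulated expression panel."""

    n_genes: int = 2104
    structures: Sequence[str] = field(default_factory=lambda: list(MOUSE_STRUCTURES))
    ages: Sequence[str] = field(default_factory=lambda: list(MOUSE_AGES))
    species: str = MOUSE
    target_structures: Sequence[str] | None = field(default_factory=lambda: ["VZ"])
    target_ages: Sequence[str] | None = field(default_factory=lambda: ["E15.5"])
    planted_module_size: int = 13
    planted_genes: Sequence[str] | None = None
    gene_names: Sequence[str] | None = None
    planted_fold: float = 10.0
    within_module_correlation: float = 0.9
    sigma: float = 0.3                 # log-sd of multiplicative measurement noise
    baseline_scale: float = 50.0       # median baseline expression
    baseline_sigma: float = 0.5        # log-sd of gene baselines
    decoy_profile_sigma: float = 0.25  # log-sd of decoy structure/age variation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_genes is not None:
            self.planted_genes = [canonicalize(g, self.species) for g in self.planted_genes]
            self.planted_module_size = len(self.planted_genes)
        if self.planted_module_size >= self.n_genes:
            raise ParameterError("planted_module_size must be smaller than n_genes")
        if self.planted_module_size <= 0 or self.n_genes <= 0:
            raise ParameterError("counts must be positive")
        if self.planted_fold <= 1.0:
            raise ParameterError("planted_fold must exceed 1")
        if not 0.0 <= self.within_module_correlation <= 1.0:
            raise ParameterError("within_module_correlation must lie in [0, 1]")
        if self.sigma < 0 or self.decoy_profile_sigma < 0:
            raise ParameterError("noise parameters must be non-negative")

    @classmethod
    def mouse_atlas(cls, **overrides) -> "SimulationParams":
        return cls(**overrides)

    @classmethod
    def human_spatial(cls, **overrides) -> "SimulationParams":
        base = dict(
            n_genes=3000, structures=list(HUMAN_STRUCTURES), ages=list(HUMAN_SPATIAL_AGES),
            species=HUMAN, target_structures=["VZ", "SVZ"], target_ages=None,
            planted_module_size=407,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def human_temporal(cls, **overrides) -> "SimulationParams":
        base = dict(
            n_genes=3000, structures=list(HUMAN_TEMPORAL_REGIONS),
            ages=list(HUMAN_TEMPORAL_STAGES), species=HUMAN,
            target_structures=None, target_ages=["8-9pcw"],
            planted_module_size=407,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class GroundTruth:
    """What the generator planted, for recovery testing."""

    planted_genes: GeneList
    planted_annotations: list[str] = field(default_factory=list)
    ortholog_map: OrthologTable = field(default_factory=OrthologTable)


def _default_gene_names(params: SimulationParams) -> tuple[list[str], list[str]]:
    """Planted + decoy symbol lists for a panel."""
    m = params.planted_module_size
    if params.planted_genes is not None:
        planted = list(params.planted_genes)
    elif params.species == MOUSE and m == len(published.MOUSE_VZ_13):
        planted = list(published.MOUSE_VZ_13)
    else:
        tag = "HVZ" if params.species == HUMAN else "Vzp"
        planted = [canonicalize(f"{tag}{i:04d}", params.species) for i in range(m)]
    n_decoys = params.n_genes - m
    if params.gene_names is not None:
        planted_keys = {g.casefold() for g in planted}
        decoys = [g for g in params.gene_names if g.casefold() not in planted_keys]
        if len(decoys) != n_decoys:
            raise ParameterError("gene_names inconsistent with n_genes and planted module")
    else:
        tag = "HBG" if params.species == HUMAN else "Mbg"
        decoys = [canonicalize(f"{tag}{i:05d}", params.species) for i in range(n_decoys)]
    return planted, decoys


def _simulate_panel(params: SimulationParams, stream: int) -> tuple[ExpressionMatrix, GroundTruth]:
    rng = np.random.default_rng([params.seed, stream])
    planted, decoys = _default_gene_names(params)
    genes = planted + decoys
    m, n_dec = len(planted), len(decoys)

    annotations = []
    is_target = []
    for structure, age in itertools.product(params.structures, params.ages):
        target = ((params.target_structures is None or structure in params.target_structures)
                  and (params.target_ages is None or age in params.target_ages))
        annotations.append(SampleAnnotation(
            sample_id=f"{structure}_{age}", structure=structure, age=age,
            species=params.species, zone="target" if target else ""))
        is_target.append(target)
    is_target = np.asarray(is_target)
    if not is_target.any():
        raise ParameterError("no sample matches the target structures/ages")
    if is_target.all():
        raise ParameterError("target must not cover every sample")
    n_samples = len(annotations)

    # gene baselines; planted genes are drawn from the expressed part of the
    # baseline distribution (left-truncated at -0.5 sd): a silent gene could
    # not have been a detected module member in the data being emulated
    z_planted = stats.truncnorm.rvs(-0.5, np.inf, size=m, random_state=rng)
    z_decoy = rng.standard_normal(n_dec)
    baseline = params.baseline_scale * np.exp(
        params.baseline_sigma * np.concatenate([z_planted, z_decoy]))

    template = np.where(is_target, params.planted_fold, 1.0)

    rho = params.within_module_correlation
    shared = rng.standard_normal(n_samples)
    own = rng.standard_normal((m, n_samples))
    planted_noise = params.sigma * (np.sqrt(rho) * shared[None, :] + np.sqrt(1.0 - rho) * own)
    planted_vals = baseline[:m, None] * template[None, :] * np.exp(planted_noise)

    decoy_profile = params.decoy_profile_sigma * rng.standard_normal((n_dec, n_samples))
    decoy_noise = params.sigma * rng.standard_normal((n_dec, n_samples))
    decoy_vals = baseline[m:, None] * np.exp(decoy_profile + decoy_noise)

    values = np.vstack([planted_vals, decoy_vals])
    matrix = matrix_from_arrays(genes, annotations, values, species=params.species)

    orthologs = OrthologTable(
        [(g, g.upper()) for g in planted] if params.species == MOUSE
        else [(canonicalize(g, MOUSE), g) for g in planted])
    truth = GroundTruth(
        planted_genes=GeneList("planted", planted, species=params.species,
                               provenance="synthetic planted module"),
        ortholog_map=orthologs,
    )
    return matrix, truth


def simulate_mouse_atlas(params: SimulationParams | None = None, **overrides):
    """Mouse ISH-like atlas with a VZ@E15.5-specific planted module."""
    params = replace(params, **overrides) if params else SimulationParams.mouse_atlas(**overrides)
    return _simulate_panel(params, _STREAM["mouse"])


def simulate_human_spatial(params: SimulationParams | None = None, **overrides):
    """Human structure panel (15-21 pcw) with a VZ/SVZ-specific planted module."""
    params = replace(params, **overrides) if params else SimulationParams.human_spatial(**overrides)
    return _simulate_panel(params, _STREAM["human_spatial"])


def simulate_human_temporal(params: SimulationParams | None = None, **overrides):
    """Human temporal panel with a module elevated in the earliest stage bin."""
    params = replace(params, **overrides) if params else SimulationParams.human_temporal(**overrides)
    if len(set(params.ages)) < 2:
        raise ParameterError("temporal panel needs at least 2 stage bins")
    return _simulate_panel(params, _STREAM["human_temporal"])


@dataclass
class HumanDesign:
    """Coordinated gene lists for the two human panels.

    ``core`` is the designed intersection of the two planted modules (the
    407-gene analogue); ``spatial_planted``/``temporal_planted`` additionally
    contain the mouse-ortholog members unique to each screen, so that the
    spatial module shares 10 symbols with the 13-gene mouse module, the
    temporal module 8, and the core exactly 7.
    """

    universe: list[str]
    spatial_planted: list[str]
    temporal_planted: list[str]
    core: list[str]


def design_human_panels(n_genes: int = 3000, n_core_human_only: int = 400,
                        spatial_mouse_members: Sequence[str] | None = None,
                        temporal_mouse_members: Sequence[str] | None = None) -> HumanDesign:
    spatial_mouse = list(spatial_mouse_members if spatial_mouse_members is not None
                         else published.HUMAN_SPATIAL_10)
    temporal_mouse = list(temporal_mouse_members if temporal_mouse_members is not None
                          else published.HUMAN_TEMPORAL_8)
    spatial_keys = {g.casefold() for g in spatial_mouse}
    core_mouse = [g for g in spatial_mouse if g.casefold() in {x.casefold() for x in temporal_mouse}]
    human_only = [f"HVZ{i:04d}" for i in range(n_core_human_only)]
    core = core_mouse + human_only
    spatial_planted = spatial_mouse + human_only
    temporal_planted = core_mouse + [g for g in temporal_mouse
                                     if g.casefold() not in spatial_keys] + human_only
    all_planted = list(dict.fromkeys(spatial_planted + temporal_planted))
    n_decoys = n_genes - len(all_planted)
    if n_decoys < 0:
        raise ParameterError("n_genes too small for the designed planted modules")
    decoys = [f"HBG{i:05d}" for i in range(n_decoys)]
    return HumanDesign(universe=all_planted + decoys, spatial_planted=spatial_planted,
                       temporal_planted=temporal_planted, core=core)


def simulate_human_panels(n_genes: int = 3000, seed: int = 0, sigma: float = 0.3,
                          planted_fold: float = 10.0, n_core_human_only: int = 400):
    """Both human panels over one shared gene universe.

    Returns ``(spatial_matrix, spatial_truth, temporal_matrix,
    temporal_truth, design)``.
    """
    design = design_human_panels(n_genes=n_genes, n_core_human_only=n_core_human_only)
    spatial_params = SimulationParams.human_spatial(
        n_genes=n_genes, planted_genes=design.spatial_planted,
        gene_names=design.universe, seed=seed, sigma=sigma, planted_fold=planted_fold)
    temporal_params = SimulationParams.human_temporal(
        n_genes=n_genes, planted_genes=design.temporal_planted,
        gene_names=design.universe, seed=seed, sigma=sigma, planted_fold=planted_fold)
    sp_mat, sp_truth = simulate_human_spatial(spatial_params)
    tm_mat, tm_truth = simulate_human_temporal(temporal_params)
    return sp_mat, sp_truth, tm_mat, tm_truth, design


def simulate_association_compendium(
        genes: Sequence[str], query_genes: Sequence[str], *,
        associated_genes: Sequence[str] | None = None, n_associated: int = 50,
        evidence_types: Sequence[str] = EVIDENCE_TYPES,
        p_within_query: float = 0.6, p_query_associated: float = 0.35,
        p_within_associated: float = 0.2, p_background: float = 0.02,
        seed: int = 0) -> tuple[dict[str, nx.Graph], list[str]]:
    """Typed evidence networks with a wired-in associated tier.

    Every evidence channel is an independent undirected weighted graph on
    ``genes``.  Edge probability is elevated inside the query module, between
    query and associated-tier genes, and (more weakly) inside the associated
    tier; all other pairs connect at the background rate with low weights.
    Returns ``(networks, associated_tier)``.
    """
    rng = np.random.default_rng([seed, _STREAM["networks"]])
    genes = list(dict.fromkeys(genes))
    query_keys = {g.casefold() for g in query_genes}
    query = [g for g in genes if g.casefold() in query_keys]
    if not query:
        raise ParameterError("no query gene present in the gene universe")
    non_query = [g for g in genes if g.casefold() not in query_keys]
    if associated_genes is None:
        if len(non_query) < n_associated:
            raise ParameterError(
                f"need at least {n_associated} non-query genes, have {len(non_query)}")
        associated = non_query[:n_associated]
    else:
        associated = [g for g in non_query
                      if g.casefold() in {a.casefold() for a in associated_genes}]
    if len(non_query) < len(associated) + 1:
        raise ParameterError("too few decoy genes outside the associated tier")

    tier = np.zeros(len(genes), dtype=int)      # 0 decoy, 1 associated, 2 query
    assoc_keys = {g.casefold() for g in associated}
    for i, g in enumerate(genes):
        if g.casefold() in query_keys:
            tier[i] = 2
        elif g.casefold() in assoc_keys:
            tier[i] = 1

    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    ti, tj = tier[iu], tier[ju]
    prob = np.full(iu.shape, p_background)
    prob[(ti == 2) & (tj == 2)] = p_within_query
    prob[((ti == 2) & (tj == 1)) | ((ti == 1) & (tj == 2))] = p_query_associated
    prob[(ti == 1) & (tj == 1)] = p_within_associated
    elevated = prob > p_background

    networks: dict[str, nx.Graph] = {}
    for etype in evidence_types:
        draw = rng.random(iu.shape) < prob
        weights = np.where(elevated, 0.5 + 0.5 * rng.random(iu.shape),
                           0.05 + 0.15 * rng.random(iu.shape))
        graph = nx.Graph(evidence_type=etype)
        graph.add_nodes_from(genes)
        for k in np.flatnonzero(draw):
            graph.add_edge(genes[iu[k]], genes[ju[k]],
                           weight=float(weights[k]), type=etype)
        networks[etype] = graph
    return networks, associated


def simulate_annotations(genes: Sequence[str], planted: Sequence[str], *,
                         enriched_sizes: Sequence[int] | None = None,
                         enriched_names: Sequence[str] | None = None,
                         enriched_fraction: float = 0.3, n_background: int = 20,
                         background_size_range: tuple[int, int] = (50, 350),
                         species: str = HUMAN, seed: int = 0) -> dict[str, GeneSet]:
    """Flat GMT-style annotation sets over a gene universe.

    The enriched sets draw ``enriched_fraction`` of their members from the
    planted genes (default sizes and names echo the published top-10 pathway
    table); background sets are uniform draws from the whole universe.
    """
    rng = np.random.default_rng([seed, _STREAM["annotations"]])
    genes = list(dict.fromkeys(genes))
    planted_keys = {g.casefold() for g in planted}
    planted_in = [g for g in genes if g.casefold() in planted_keys]
    others = [g for g in genes if g.casefold() not in planted_keys]
    if enriched_sizes is None:
        enriched_sizes = list(published.PATHWAY_SET_SIZES)
    if enriched_names is None:
        enriched_names = ([row[0] for row in published.PATHWAY_TABLE]
                          if len(enriched_sizes) == len(published.PATHWAY_TABLE)
                          else [f"EnrichedSet{i + 1:02d}" for i in range(len(enriched_sizes))])

    sets: dict[str, GeneSet] = {}
    for name, size in zip(enriched_names, enriched_sizes):
        if size > len(genes):
            raise ParameterError(f"set size {size} exceeds gene universe {len(genes)}")
        n_planted = min(int(round(enriched_fraction * size)), len(planted_in))
        chosen = list(rng.choice(planted_in, size=n_planted, replace=False))
        n_rest = size - n_planted
        if n_rest > len(others):
            raise ParameterError(f"set size {size} too large for the decoy pool")
        chosen += list(rng.choice(others, size=n_rest, replace=False))
        sets[name] = GeneSet(name, "synthetic enriched set", sorted(chosen))

    lo, hi = background_size_range
    for i in range(n_background):
        size = int(rng.integers(lo, min(hi, len(genes)) + 1))
        chosen = sorted(rng.choice(genes, size=size, replace=False))
        name = f"BackgroundSet{i + 1:02d}"
        sets[name] = GeneSet(name, "synthetic background set", list(chosen))
    return sets
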