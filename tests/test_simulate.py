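"""Generator contracts: determinism, noise-free limits, planted-signal strength."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cortexseek import published
from cortexseek.simulate import (ParameterError, SimulationParams,
                                 design_human_panels, simulate_annotations,
                                 simulate_association_compendium,
                                 simulate_human_panels, simulate_human_spatial,
                                 simulate_human_temporal, simulate_mouse_atlas)


def small_mouse(**over):
    over.setdefault("n_genes", 200)
    return SimulationParams.mouse_atlas(**over)


class TestMouseAtlas:
    def test_deterministic_given_seed(self):
        m1, _ = simulate_mouse_atlas(small_mouse(seed=1))
        m2, _ = simulate_mouse_atlas(small_mouse(seed=1))
        pd.testing.assert_frame_equal(m1.values, m2.values)
        m3, _ = simulate_mouse_atlas(small_mouse(seed=2))
        assert not m1.values.equals(m3.values)

    def test_noise_free_planted_profiles_are_template_multiples(self):
        matrix, truth = simulate_mouse_atlas(small_mouse(sigma=0.0, seed=3))
        planted = matrix.values.loc[truth.planted_genes.members].to_numpy()
        ratios = planted / planted[0]
        assert np.allclose(ratios, ratios[:, :1])  # scalar multiples of row 0
        r = np.corrcoef(planted)
        assert np.allclose(r, 1.0)

    def test_planted_fold_visible_in_target_samples(self):
        params = small_mouse(sigma=0.0, seed=4)
        matrix, truth = simulate_mouse_atlas(params)
        target = matrix.sample_ids_where(structure="VZ", age="E15.5")
        rest = [s for s in matrix.sample_ids if s not in target]
        row = matrix.values.loc[truth.planted_genes.members[0]]
        assert row[target].mean() / row[rest].mean() == pytest.approx(params.planted_fold)

    def test_planted_enrichment_exceeds_filter_in_most_replicates(self):
        # planted fold 10 vs the 6-fold filter with sigma=0.3 measurement
        # noise on one target sample: the per-gene filter should hold in the
        # vast majority of (replicate, gene) draws
        hits = total = 0
        for seed in range(60):
            matrix, truth = simulate_mouse_atlas(small_mouse(seed=seed))
            target = matrix.sample_ids_where(structure="VZ", age="E15.5")
            rest = [s for s in matrix.sample_ids if s not in target]
            planted = matrix.values.loc[truth.planted_genes.members]
            ratio = planted[target].mean(axis=1) / planted[rest].mean(axis=1)
            hits += int((ratio >= 6).sum())
            total += len(ratio)
        assert hits / total >= 0.90

    def test_module_too_large_rejected(self):
        with pytest.raises(ParameterError):
            SimulationParams.mouse_atlas(n_genes=10, planted_module_size=10)

    def test_fold_monotonicity(self):
        # raising planted_fold never loses 6-fold passers at matched seeds
        for seed in (0, 1, 2):
            passed = []
            for fold in (6.5, 10.0, 20.0):
                matrix, truth = simulate_mouse_atlas(small_mouse(seed=seed, planted_fold=fold))
                target = matrix.sample_ids_where(structure="VZ", age="E15.5")
                rest = [s for s in matrix.sample_ids if s not in target]
                planted = matrix.values.loc[truth.planted_genes.members]
                ratio = planted[target].mean(axis=1) / planted[rest].mean(axis=1)
                passed.append((ratio >= 6).sum())
            assert passed == sorted(passed)


class TestHumanPanels:
    def test_designed_overlaps(self):
        design = design_human_panels(n_genes=1000)
        spatial = {g.casefold() for g in design.spatial_planted}
        temporal = {g.casefold() for g in design.temporal_planted}
        core = spatial & temporal
        assert core == {g.casefold() for g in design.core}
        mouse = {g.upper().casefold() for g in published.MOUSE_VZ_13}
        assert len(spatial & mouse) == 10
        assert len(temporal & mouse) == 8
        assert len(core & mouse) == 7

    def test_overlap_parameter_controls_core(self):
        design = design_human_panels(
            n_genes=600, n_core_human_only=0,
            spatial_mouse_members=[g.upper() for g in published.MOUSE_VZ_13][:10],
            temporal_mouse_members=[g.upper() for g in published.MOUSE_VZ_13][3:])
        assert len(design.core) == 7

    def test_noise_free_six_fold_filter_separates_planted(self):
        params = SimulationParams.human_spatial(n_genes=300, planted_module_size=40,
                                                sigma=0.0, seed=5)
        matrix, truth = simulate_human_spatial(params)
        target = matrix.sample_ids_where(structure=("VZ", "SVZ"))
        rest = [s for s in matrix.sample_ids if s not in target]
        ratio = matrix.values[target].mean(axis=1) / matrix.values[rest].mean(axis=1)
        planted = set(truth.planted_genes.members)
        assert set(ratio.index[ratio >= 6]) == planted

    def test_temporal_needs_two_stages(self):
        with pytest.raises(ParameterError):
            simulate_human_temporal(SimulationParams.human_temporal(
                n_genes=100, planted_module_size=5, ages=["8-9pcw"]))

    def test_temporal_planted_fold_median(self):
        folds = []
        for seed in range(20):
            params = SimulationParams.human_temporal(n_genes=150, planted_module_size=10,
                                                     seed=seed)
            matrix, truth = simulate_human_temporal(params)
            target = matrix.sample_ids_where(age="8-9pcw")
            rest = [s for s in matrix.sample_ids if s not in target]
            planted = matrix.values.loc[truth.planted_genes.members]
            folds.extend(planted[target].mean(axis=1) / planted[rest].mean(axis=1))
        assert np.median(folds) >= 10.0 / 1.5

    def test_shared_universe(self):
        sp, _, tm, _, design = simulate_human_panels(n_genes=800, n_core_human_only=50, seed=1)
        assert sp.genes != [] and set(sp.genes) == set(tm.genes) == set(design.universe)


class TestAssociationCompendium:
    def test_clique_when_intra_probability_one(self):
        query = [f"Q{i}" for i in range(5)]
        nets, _ = simulate_association_compendium(
            query + [f"D{i}" for i in range(60)], query, n_associated=10,
            p_within_query=1.0, p_query_associated=0.0, p_within_associated=0.0,
            p_background=0.0, seed=1)
        for graph in nets.values():
            sub = graph.subgraph(query)
            assert sub.number_of_edges() == 5 * 4 // 2

    def test_deterministic(self):
        genes = [f"Q{i}" for i in range(5)] + [f"D{i}" for i in range(60)]
        n1, _ = simulate_association_compendium(genes, genes[:5], n_associated=10, seed=9)
        n2, _ = simulate_association_compendium(genes, genes[:5], n_associated=10, seed=9)
        for name in n1:
            assert sorted(n1[name].edges) == sorted(n2[name].edges)

    def test_associated_tier_better_connected_than_decoys(self):
        genes = [f"Q{i}" for i in range(13)] + [f"D{i}" for i in range(150)]
        deg_assoc, deg_decoy = [], []
        for seed in range(10):
            nets, assoc = simulate_association_compendium(genes, genes[:13], seed=seed)
            assoc = set(assoc)
            for graph in nets.values():
                for node in graph:
                    if node.startswith("D"):
                        (deg_assoc if node in assoc else deg_decoy).append(graph.degree(node))
        assert np.mean(deg_assoc) > np.mean(deg_decoy)

    def test_too_few_decoys_rejected(self):
        with pytest.raises(ParameterError):
            simulate_association_compendium(["Q1", "Q2", "D1"], ["Q1", "Q2"],
                                            n_associated=5, seed=0)


class TestAnnotations:
    def test_default_sizes_match_reference_pathway_table(self):
        genes = [f"HVZ{i:04d}" for i in range(500)] + [f"HBG{i:05d}" for i in range(2500)]
        sets = simulate_annotations(genes, genes[:407], seed=2)
        sizes = [len(sets[row[0]]) for row in published.PATHWAY_TABLE]
        assert sizes == published.PATHWAY_SET_SIZES

    def test_full_enrichment_gives_subset_of_planted(self):
        genes = [f"G{i}" for i in range(100)]
        sets = simulate_annotations(genes, genes[:20], enriched_sizes=[20],
                                    enriched_names=["S"], enriched_fraction=1.0,
                                    n_background=0, seed=3)
        assert set(sets["S"].members) <= {g.upper() for g in genes[:20]}

    def test_oversized_set_rejected(self):
        with pytest.raises(ParameterError):
            simulate_annotations(["A", "B"], ["A"], enriched_sizes=[5],
                                 enriched_names=["S"], seed=0)

    def test_background_sets_null_uniform_pvalues(self):
        # hypergeometric rawP of background sets should be (super-)uniform
        from cortexseek.enrichment import hypergeom_tail
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(400)]
        pvals = []
        for seed in range(40):
            sets = simulate_annotations(genes, genes[:50], enriched_sizes=[],
                                        enriched_names=[], n_background=5,
                                        background_size_range=(40, 80), seed=seed)
            query = set(g.upper() for g in rng.choice(genes, size=60, replace=False))
            for gs in sets.values():
                O = len(set(gs.members) & query)
                pvals.append(hypergeom_tail(400, len(gs), 60, O))
        # discrete test statistic: check no excess of small p-values
        pvals = np.asarray(pvals)
        for threshold in (0.05, 0.1, 0.25):
            assert (pvals <= threshold).mean() <= threshold + 3 * np.sqrt(
                threshold * (1 - threshold) / len(pvals))
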