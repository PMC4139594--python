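"""Fold changes, Welch tests, Holm-Bonferroni control, and full screens."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cortexseek.config import PipelineConfig
from cortexseek.enrichment import bh_fdr
from cortexseek.screen import (Contrast, collapse_probes, contrast_for,
                               fold_change, holm_bonferroni, pass_list,
                               run_screen, welch_p)
from cortexseek.simulate import SimulationParams, simulate_human_spatial

from conftest import make_matrix


def holm_oracle(pvals):
    """Literal step-down Holm: sort, multiply by (m-i), cummax, cap."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adj[idx] = running
    return adj


def bh_oracle(pvals):
    """Literal step-up BH: sort, p*m/i, cumulative min from the right, cap."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


class TestFoldChange:
    def test_arithmetic(self):
        matrix = make_matrix([[12, 12, 2, 2], [5, 5, 5, 5]], ["VZ", "SVZ", "CP", "GE"])
        contrast = Contrast("c", ["s0", "s1"], ["s2", "s3"])
        assert fold_change(matrix, "G0", contrast) == pytest.approx(6.0, rel=1e-6)
        assert fold_change(matrix, "G1", contrast) == pytest.approx(1.0, rel=1e-6)

    def test_scale_invariance(self):
        vals = np.array([[12, 11, 2, 3], [5, 6, 5, 4.0]])
        contrast = Contrast("c", ["s0", "s1"], ["s2", "s3"])
        f1 = fold_change(make_matrix(vals, ["VZ", "SVZ", "CP", "GE"]), "G0", contrast)
        f2 = fold_change(make_matrix(vals * 10, ["VZ", "SVZ", "CP", "GE"]), "G0", contrast)
        assert f1 == pytest.approx(f2, rel=1e-6)


class TestWelch:
    def test_identical_groups_p_one(self):
        matrix = make_matrix([[3, 4, 3, 4.0]], ["VZ", "VZ", "CP", "CP"])
        contrast = Contrast("c", ["s0", "s1"], ["s2", "s3"])
        assert welch_p(matrix, "G0", contrast) == pytest.approx(1.0)

    def test_matches_from_definition_computation(self):
        a_raw = np.array([10.0, 11.0, 12.0])
        b_raw = np.array([1.0, 1.2, 0.9])
        matrix = make_matrix([np.concatenate([a_raw, b_raw])],
                             ["VZ", "VZ", "VZ", "CP", "CP", "CP"])
        contrast = Contrast("c", ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        a, b = np.log2(a_raw + 1), np.log2(b_raw + 1)
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / 2 + vb ** 2 / 2)
        expected = 2 * stats.t.sf(abs(t), df)
        assert welch_p(matrix, "G0", contrast) == pytest.approx(expected, rel=1e-12)

    def test_two_sided_symmetry(self):
        matrix = make_matrix([[10, 11, 1, 2.0]], ["VZ", "VZ", "CP", "CP"])
        ab = Contrast("c", ["s0", "s1"], ["s2", "s3"])
        ba = Contrast("c", ["s2", "s3"], ["s0", "s1"])
        assert welch_p(matrix, "G0", ab) == pytest.approx(welch_p(matrix, "G0", ba))

    def test_zero_variance_conventions(self):
        matrix = make_matrix([[5, 5, 5, 5], [9, 9, 2, 2.0]],
                             ["VZ", "VZ", "CP", "CP"])
        contrast = Contrast("c", ["s0", "s1"], ["s2", "s3"])
        assert welch_p(matrix, "G0", contrast) == 1.0
        assert 0 < welch_p(matrix, "G1", contrast) < 1e-300


class TestHolm:
    def test_single_p_identity(self):
        adj, reject = holm_bonferroni([0.03], alpha=0.05)
        assert adj[0] == pytest.approx(0.03) and reject[0]

    def test_hand_stepdown(self):
        adj, reject = holm_bonferroni([1e-12, 1e-10, 0.5], alpha=1e-9)
        assert adj == pytest.approx([3e-12, 2e-10, 0.5])
        assert list(reject) == [True, True, False]

    def test_all_ones_no_rejections(self):
        _, reject = holm_bonferroni([1.0] * 5, alpha=0.05)
        assert not reject.any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.5])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200))
    def test_matches_from_definition_oracle(self, pvals):
        adj, _ = holm_bonferroni(pvals)
        assert np.allclose(adj, holm_oracle(pvals))

    def test_oracle_agreement_large_vector(self):
        rng = np.random.default_rng(1)
        p = rng.random(10_000) ** 3
        adj, _ = holm_bonferroni(p)
        assert np.allclose(adj, holm_oracle(p))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=60),
           st.floats(min_value=1e-6, max_value=0.2))
    def test_rejection_ordering_bonferroni_holm_bh(self, pvals, alpha):
        p = np.asarray(pvals)
        bonf = set(np.flatnonzero(np.minimum(p * len(p), 1.0) < alpha))
        _, holm_rej = holm_bonferroni(p, alpha=alpha)
        holm = set(np.flatnonzero(holm_rej))
        bh = set(np.flatnonzero(bh_fdr(p) < alpha))
        assert bonf <= holm <= bh


class TestRunScreen:
    def human_matrix(self, **over):
        over.setdefault("n_genes", 200)
        over.setdefault("planted_module_size", 20)
        return simulate_human_spatial(SimulationParams.human_spatial(**over))

    def test_noise_free_pass_set_is_exactly_planted(self):
        matrix, truth = self.human_matrix(sigma=0.0, seed=21)
        contrast = contrast_for(matrix, "c", target_structures=("VZ", "SVZ"))
        table = run_screen(matrix, contrast)
        assert set(pass_list(table)) == set(truth.planted_genes.members)

    def test_alpha_zero_passes_nothing(self):
        matrix, _ = self.human_matrix(seed=22)
        contrast = contrast_for(matrix, "c", target_structures=("VZ", "SVZ"))
        table = run_screen(matrix, contrast, PipelineConfig(alpha=np.nextafter(0, 1)))
        assert not table["passed"].any()

    def test_noisy_recovery_and_false_positive_control(self):
        recovered, spurious, planted_total = 0, 0, 0
        for seed in range(15):
            matrix, truth = self.human_matrix(seed=seed)
            contrast = contrast_for(matrix, "c", target_structures=("VZ", "SVZ"))
            passed = set(pass_list(table := run_screen(matrix, contrast)))
            planted = set(truth.planted_genes.members)
            recovered += len(passed & planted)
            spurious += len(passed - planted)
            planted_total += len(planted)
        assert recovered / planted_total >= 0.95
        assert spurious == 0

    def test_pass_set_invariant_under_global_scaling(self):
        matrix, _ = self.human_matrix(seed=23)
        contrast = contrast_for(matrix, "c", target_structures=("VZ", "SVZ"))
        base = set(pass_list(run_screen(matrix, contrast)))
        scaled = matrix.subset()
        scaled.values *= 50.0
        assert set(pass_list(run_screen(scaled, contrast))) == base

    def test_holm_family_is_fold_passing_set(self):
        matrix, _ = self.human_matrix(seed=24)
        contrast = contrast_for(matrix, "c", target_structures=("VZ", "SVZ"))
        table = run_screen(matrix, contrast)
        family = table["fold"] >= 6.0
        assert table.loc[family, "adj_p"].notna().all()
        assert table.loc[~family, "adj_p"].isna().all()
        assert int(table["family_size"].iloc[0]) == int(family.sum())
        fam = table[family]
        assert (fam["adj_p"] >= fam["raw_p"] - 1e-15).all()

    def test_null_screen_passes_nothing(self):
        # pure-null matrices: expected passes at alpha=1e-9 is ~0
        total = 0
        for seed in range(100):
            matrix, _ = simulate_human_spatial(SimulationParams.human_spatial(
                n_genes=30, planted_module_size=1, planted_fold=1.0001, seed=seed))
            contrast = contrast_for(matrix, "c", target_structures=("VZ", "SVZ"))
            total += len(pass_list(run_screen(matrix, contrast)))
        assert total == 0

    def test_empty_contrast_rejected(self):
        matrix, _ = self.human_matrix(seed=25)
        with pytest.raises(ValueError):
            contrast_for(matrix, "c", target_structures="NOPE")


class TestProbeCollapse:
    def test_best_p_per_gene(self):
        matrix = make_matrix([[60, 66, 2, 2.2], [50, 45, 2, 2.1], [5, 6, 5, 6.0]],
                             ["VZ", "SVZ", "CP", "GE"],
                             genes=["probe1", "probe2", "probe3"])
        contrast = Contrast("c", ["s0", "s1"], ["s2", "s3"])
        table = run_screen(matrix, contrast, PipelineConfig(alpha=0.5, fold_min=1.0))
        collapsed = collapse_probes(table, {"probe1": "GENE_A", "probe2": "GENE_A",
                                            "probe3": "GENE_B"})
        assert sorted(collapsed["gene"]) == ["GENE_A", "GENE_B"]
        row_a = collapsed.set_index("gene").loc["GENE_A"]
        best = table.set_index("gene").loc[["probe1", "probe2"], "raw_p"].min()
        assert row_a["raw_p"] == pytest.approx(best)
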