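"""Differential-expression screens with fold filter and Holm-Bonferroni control.

A screen contrasts a target sample group (VZ+SVZ structures, or the earliest
developmental stage bin) against the remaining samples: per-gene linear fold
change, a two-sided Welch t-test on log2(x+1), a minimum-fold filter (>= 6
by default), and step-down Holm-Bonferroni adjustment of the fold-passing
family at a stringent alpha (1e-9 by default).

The hypothesis test is Welch's unequal-variance t by default (declared in
the output) with a Wilcoxon rank-sum alternative; the fold filter is applied
before correction, so the Holm family is the fold-passing set and its size
is recorded per row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

TINY_P = float(np.nextafter(0, 1))


@dataclass
class Contrast:
    """Two disjoint sample groups: target (a) vs reference (b)."""

    name: str
    group_a: list[str]
    group_b: list[str]

    def __post_init__(self) -> None:
        a, b = set(self.group_a), set(self.group_b)
        if a & b:
            raise ValueError(f"contrast {self.name!r}: groups overlap")
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"contrast {self.name!r}: both groups need >= 2 samples")


def contrast_for(matrix: ExpressionMatrix, name: str, *, target_structures=None,
                 target_ages=None) -> Contrast:
    """Target = samples matching the given structures/ages; reference = rest."""
    conditions: dict[str, object] = {}
    if target_structures is not None:
        conditions["structure"] = tuple(np.atleast_1d(target_structures))
    if target_ages is not None:
        conditions["age"] = tuple(np.atleast_1d(target_ages))
    if not conditions:
        raise ValueError("specify target_structures and/or target_ages")
    group_a = matrix.sample_ids_where(**conditions)
    in_a = set(group_a)
    group_b = [s for s in matrix.sample_ids if s not in in_a]
    if not group_a or not group_b:
        raise ValueError(f"contrast {name!r}: a group is empty after matching")
    return Contrast(name, group_a, group_b)


def fold_change(matrix: ExpressionMatrix, gene: str, contrast: Contrast,
                eps: float = 1e-9) -> float:
    """(mean_a + eps) / (mean_b + eps) on the linear scale."""
    row = matrix.values.loc[gene]
    return float((row[contrast.group_a].mean() + eps) / (row[contrast.group_b].mean() + eps))


def _welch_p_vector(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Welch p-values per row of log2-transformed groups."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    if degenerate.any():
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p = np.where(degenerate & equal_means, 1.0, p)
        n_sent = int((degenerate & ~equal_means).sum())
        if n_sent:
            log.info("%d genes with zero variance and unequal means: p set to "
                     "smallest representable value", n_sent)
        p = np.where(degenerate & ~equal_means, TINY_P, p)
    return np.clip(p, TINY_P, 1.0)


def welch_p(matrix: ExpressionMatrix, gene: str, contrast: Contrast) -> float:
    """Two-sided Welch unequal-variance t-test on log2(value + 1)."""
    row = matrix.values.loc[gene]
    a = np.log2(row[contrast.group_a].to_numpy(dtype=float) + 1.0)[None, :]
    b = np.log2(row[contrast.group_b].to_numpy(dtype=float) + 1.0)[None, :]
    return float(_welch_p_vector(a, b)[0])


def holm_bonferroni(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm adjustment; reject where adjusted p < alpha (strict)."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.isnan(p).any() or p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    adjusted = multipletests(p, alpha=alpha, method="holm")[1]
    return adjusted, adjusted < alpha


def run_screen(matrix: ExpressionMatrix, contrast: Contrast,
               config: PipelineConfig | None = None, *,
               test: str = "welch") -> pd.DataFrame:
    """Per-gene screen table.

    Columns: gene, fold, raw_p, adj_p, passed, family_size.  ``adj_p`` is NaN
    for genes outside the Holm family (those failing the fold filter);
    ``passed`` requires fold >= fold_min and adj_p < alpha.  Rows are sorted
    by adj_p then fold descending.
    """
    config = config or PipelineConfig()
    vals = matrix.values
    missing = [s for s in contrast.group_a + contrast.group_b if s not in vals.columns]
    if missing:
        raise ValueError(f"contrast sample {missing[0]!r} absent from matrix")

    eps = 1e-9
    mean_a = vals[contrast.group_a].mean(axis=1).to_numpy()
    mean_b = vals[contrast.group_b].mean(axis=1).to_numpy()
    fold = (mean_a + eps) / (mean_b + eps)

    log_a = np.log2(vals[contrast.group_a].to_numpy(dtype=float) + 1.0)
    log_b = np.log2(vals[contrast.group_b].to_numpy(dtype=float) + 1.0)
    if test == "welch":
        raw_p = _welch_p_vector(log_a, log_b)
    elif test == "wilcoxon":
        raw_p = np.array([
            stats.mannwhitneyu(ra, rb, alternative="two-sided").pvalue
            if (np.ptp(ra) or np.ptp(rb) or not np.isclose(ra.mean(), rb.mean())) else 1.0
            for ra, rb in zip(log_a, log_b)])
        raw_p = np.clip(raw_p, TINY_P, 1.0)
    else:
        raise ValueError(f"unknown test {test!r}")

    in_family = fold >= config.fold_min
    family_size = int(in_family.sum())
    adj_p = np.full(fold.shape, np.nan)
    passed = np.zeros(fold.shape, dtype=bool)
    if family_size:
        adj, reject = holm_bonferroni(raw_p[in_family], alpha=config.alpha)
        adj_p[in_family] = adj
        passed[in_family] = reject

    table = pd.DataFrame({
        "gene": vals.index,
        "fold": fold,
        "raw_p": raw_p,
        "adj_p": adj_p,
        "passed": passed,
        "family_size": family_size,
    })
    table.attrs["test"] = test
    table.attrs["contrast"] = contrast.name
    log.info("screen %s (%s): %d genes, %d in fold family (>= %g), %d passed "
             "at alpha=%g", contrast.name, test, len(table), family_size,
             config.fold_min, int(passed.sum()), config.alpha)
    return table.sort_values(["adj_p", "fold"], ascending=[True, False],
                             na_position="last", kind="mergesort").reset_index(drop=True)


def collapse_probes(table: pd.DataFrame, probe_to_gene: dict[str, str]) -> pd.DataFrame:
    """Collapse probe-level screen rows to gene level.

    Keeps, for each gene, the probe row with the smallest raw p-value (the
    declared collapse rule when several probes report the same gene).
    """
    out = table.copy()
    out["gene"] = [probe_to_gene.get(p, p) for p in out["gene"]]
    out = out.sort_values("raw_p", kind="mergesort").drop_duplicates("gene", keep="first")
    return out.sort_values(["adj_p", "fold"], ascending=[True, False],
                           na_position="last", kind="mergesort").reset_index(drop=True)


def pass_list(table: pd.DataFrame) -> list[str]:
    """Genes flagged as passing, in table order."""
    return table.loc[table["passed"], "gene"].tolist()
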