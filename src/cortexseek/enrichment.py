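"""Gene-set over-representation: hypergeometric upper tail with BH FDR.

For each annotation set the test asks whether the query list overlaps the
set more than expected under uniform sampling from a reference universe of
N genes: with C annotated genes, a query of n genes and an observed overlap
O, rawP = P(X >= O) for X ~ Hypergeometric(N, C, n), E = n*C/N and
R = O/E.  Benjamini-Hochberg step-up adjustment is applied across all
tested sets.

The reference universe defaults to the genes carrying at least one
annotation in the GMT; an explicit reference list (e.g. a genome-wide one)
may be supplied instead, and the choice is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet
from .symbols import GeneList, unique_preserving_order

log = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["set_name", "C", "O", "E", "R", "rawP", "adjP"]


def hypergeom_tail(N: int, C: int, n: int, O: int) -> float:
    """Upper-tail P(X >= O) for X ~ Hypergeometric(N, C, n)."""
    if not (0 <= C <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= C, n <= N (got N={N}, C={C}, n={n})")
    if not 0 <= O <= min(C, n):
        raise ValueError(f"require 0 <= O <= min(C, n) (got O={O})")
    if O == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(O - 1, N, C, n)))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.isnan(p).any() or p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentContext:
    """Query, reference universe and annotation sets for one analysis."""

    query: GeneList
    sets: dict[str, GeneSet]
    reference: GeneList | None = None   # None -> all annotated genes
    fdr_threshold: float = 0.05
    universe_label: str = field(init=False, default="")

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("need at least one gene set")
        if self.reference is None:
            members: list[str] = []
            for gs in self.sets.values():
                members.extend(gs.members)
            members = unique_preserving_order(members)
            self.reference = GeneList("annotated_universe", members,
                                      species=self.query.species,
                                      provenance="all genes with >= 1 annotation")
            self.universe_label = "annotated"
        else:
            self.universe_label = "explicit"
        log.info("enrichment universe: %s (N=%d)", self.universe_label, len(self.reference))

    @property
    def N(self) -> int:
        return len(self.reference)

    @property
    def n(self) -> int:
        return len(self.query.keys() & self.reference.keys())


def enrich(context: EnrichmentContext) -> pd.DataFrame:
    """Over-representation table with columns set_name, C, O, E, R, rawP, adjP.

    Rows sorted by adjP ascending; a boolean ``significant`` column flags
    adjP below the context's FDR threshold.
    """
    ref_keys = context.reference.keys()
    query_keys = context.query.keys() & ref_keys
    N, n = context.N, len(query_keys)
    if n == 0:
        raise ValueError("query has no gene in the reference universe")

    rows = []
    for name, gs in context.sets.items():
        set_keys = {m.casefold() for m in gs.members} & ref_keys
        C = len(set_keys)
        O = len(set_keys & query_keys)
        E = n * C / N
        rows.append({
            "set_name": name, "C": C, "O": O, "E": E,
            "R": (O / E) if E > 0 else np.nan,
            "rawP": hypergeom_tail(N, C, n, O),
        })
    table = pd.DataFrame(rows)
    table["adjP"] = bh_fdr(table["rawP"].to_numpy())
    table["significant"] = table["adjP"] < context.fdr_threshold
    table.attrs["N"] = N
    table.attrs["n"] = n
    table.attrs["universe"] = context.universe_label
    return table.sort_values(["adjP", "rawP", "set_name"], kind="mergesort").reset_index(drop=True)
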