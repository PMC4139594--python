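"""Cross-species gene-list operations: intersection, ortholog mapping, overlaps."""

from __future__ import annotations

import logging

import pandas as pd

from .symbols import GeneList, HUMAN, MOUSE, OrthologTable, canonicalize

log = logging.getLogger(__name__)

DIRECTIONS = ("mouse_to_human", "human_to_mouse")


def intersect_lists(a: GeneList, b: GeneList, name: str | None = None) -> GeneList:
    """Case-insensitive intersection, ordered as in ``a``."""
    b_keys = b.keys()
    members = [m for m in a.members if m.casefold() in b_keys]
    return GeneList(name or f"{a.name}&{b.name}", members, species=a.species,
                    provenance=f"intersection of {a.name} and {b.name}")


def map_orthologs(gene_list: GeneList, table: OrthologTable | None,
                  direction: str = "mouse_to_human") -> GeneList:
    """Map a gene list across species via an ortholog table.

    Symbols without a table entry fall back to case-restyling for the target
    species (mouse ``Cdon`` -> human ``CDON``); the fallback count is logged
    so a real ortholog table can replace it.  Many-to-many entries expand and
    duplicates collapse.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    target_species = HUMAN if direction == "mouse_to_human" else MOUSE
    table = table or OrthologTable()
    mapped: list[str] = []
    fallbacks = 0
    for symbol in gene_list.members:
        targets = table.targets(symbol, direction)
        if not targets:
            targets = [canonicalize(symbol, target_species)]
            fallbacks += 1
        mapped.extend(targets)
    if fallbacks:
        log.info("map_orthologs(%s): %d/%d symbols mapped by case-restyle fallback",
                 gene_list.name, fallbacks, len(gene_list))
    out = GeneList(f"{gene_list.name}_{target_species}", mapped, species=target_species,
                   provenance=f"{direction} mapping of {gene_list.name} "
                              f"({fallbacks} fallback restylings)")
    out.fallback_count = fallbacks  # type: ignore[attr-defined]
    return out


def overlap_report(lists: dict[str, GeneList]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise overlap counts and a per-gene membership indicator table."""
    if len(lists) < 2:
        raise ValueError("need at least two lists")
    names = list(lists)
    counts = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, ni in enumerate(names):
        ki = lists[ni].keys()
        for nj in names[i:]:
            n_common = len(ki & lists[nj].keys())
            counts.loc[ni, nj] = counts.loc[nj, ni] = n_common
    all_keys: dict[str, str] = {}
    for gl in lists.values():
        for member in gl.members:
            all_keys.setdefault(member.casefold(), member)
    membership = pd.DataFrame(
        {name: [key in lists[name].keys() for key in all_keys] for name in names},
        index=pd.Index(all_keys.values(), name="gene"),
    )
    return counts, membership
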