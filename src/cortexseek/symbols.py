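"""Gene symbols, gene lists, and ortholog tables.

Symbols are matched case-insensitively everywhere in the pipeline (the same
gene is written ``Cdon`` in mouse and ``CDON`` in human), but each species has
a canonical display style: mouse symbols are written with an initial capital
followed by lowercase, human symbols all-uppercase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

log = logging.getLogger(__name__)

MOUSE = "mouse"
HUMAN = "human"
SPECIES = (MOUSE, HUMAN)


class FormatError(ValueError):
    """A file did not conform to one of the declared plain-text formats."""


def canonicalize(symbol: str, species: str) -> str:
    """Return the species-styled canonical form of a gene symbol.

    Mouse: ``CDON`` -> ``Cdon``; human: ``Cdon`` -> ``CDON``.  Idempotent.
    Raises ``ValueError`` for empty symbols or symbols containing whitespace.
    """
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}")
    token = str(symbol).strip()
    if not token:
        raise ValueError("empty gene symbol")
    if any(ch.isspace() for ch in token):
        raise FormatError(f"gene symbol contains whitespace: {symbol!r}")
    if species == HUMAN:
        return token.upper()
    return token[:1].upper() + token[1:].lower()


def symbols_equal(a: str, b: str) -> bool:
    """Case-insensitive symbol comparison (cross-species safe)."""
    return a.strip().casefold() == b.strip().casefold()


@dataclass
class GeneList:
    """An ordered, duplicate-free list of gene symbols of one species."""

    name: str
    members: list[str]
    species: str = MOUSE
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        canon: list[str] = []
        for raw in self.members:
            sym = canonicalize(raw, self.species)
            key = sym.casefold()
            if key in seen:
                log.warning("duplicate symbol %s dropped from list %s", raw, self.name)
                continue
            seen[key] = sym
            canon.append(sym)
        self.members = canon

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)

    def __contains__(self, symbol: str) -> bool:
        return str(symbol).casefold() in {m.casefold() for m in self.members}

    def keys(self) -> set[str]:
        """Casefolded membership keys, for order-free comparison."""
        return {m.casefold() for m in self.members}


def write_gene_list(gene_list: GeneList, path: str | Path) -> Path:
    """Write one symbol per line with a '#' comment header."""
    path = Path(path)
    lines = [f"# name: {gene_list.name}", f"# species: {gene_list.species}"]
    if gene_list.provenance:
        lines.append(f"# provenance: {gene_list.provenance}")
    lines.extend(gene_list.members)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_gene_list(path: str | Path, species: str | None = None, name: str | None = None) -> GeneList:
    """Read a one-symbol-per-line gene list.

    '#' lines are comments; ``# name:``/``# species:``/``# provenance:``
    headers are recognized.  An empty file yields an empty list with a
    warning, not an error.
    """
    path = Path(path)
    meta = {"name": name or path.stem, "species": species or MOUSE, "provenance": ""}
    members: list[str] = []
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            for key in ("name", "species", "provenance"):
                prefix = f"{key}:"
                if body.lower().startswith(prefix):
                    value = body[len(prefix):].strip()
                    if key == "species" and species is not None:
                        continue  # caller override wins
                    if key == "name" and name is not None:
                        continue
                    meta[key] = value
            continue
        members.append(line)
    if not members:
        log.warning("gene list file %s is empty", path)
    return GeneList(meta["name"], members, species=meta["species"], provenance=meta["provenance"])


@dataclass
class OrthologTable:
    """Many-to-many mouse<->human symbol pairs."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        canon: list[tuple[str, str]] = []
        for mouse_sym, human_sym in self.pairs:
            pair = (canonicalize(mouse_sym, MOUSE), canonicalize(human_sym, HUMAN))
            key = (pair[0].casefold(), pair[1].casefold())
            if key in seen:
                continue
            seen.add(key)
            canon.append(pair)
        self.pairs = canon

    def targets(self, symbol: str, direction: str) -> list[str]:
        """Mapped symbols for one query symbol; empty if unmapped."""
        key = symbol.casefold()
        if direction == "mouse_to_human":
            return [h for m, h in self.pairs if m.casefold() == key]
        if direction == "human_to_mouse":
            return [m for m, h in self.pairs if h.casefold() == key]
        raise ValueError(f"unknown direction {direction!r}")


def write_ortholog_table(table: OrthologTable, path: str | Path) -> Path:
    frame = pd.DataFrame(table.pairs, columns=["mouse", "human"])
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_ortholog_table(path: str | Path) -> OrthologTable:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("mouse", "human"):
        if col not in frame.columns:
            raise FormatError(f"ortholog table {path} lacks column {col!r}")
    return OrthologTable(list(zip(frame["mouse"], frame["human"])))


def unique_preserving_order(symbols: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for sym in symbols:
        key = sym.casefold()
        if key not in seen:
            seen.add(key)
            out.append(sym)
    return out
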