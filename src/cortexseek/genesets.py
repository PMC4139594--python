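"""GMT gene-set files (name, description, tab-separated member symbols)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .symbols import FormatError, canonicalize, unique_preserving_order


@dataclass
class GeneSet:
    name: str
    description: str
    members: list[str]

    def __len__(self) -> int:
        return len(self.members)


def read_gene_sets(path: str | Path, species: str = "human") -> dict[str, GeneSet]:
    """Parse a GMT file into a name -> GeneSet mapping.

    Members are canonicalized for ``species``; duplicate set names and lines
    with fewer than three fields are format errors.
    """
    sets: dict[str, GeneSet] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
        name, description, *members = fields
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        canon = unique_preserving_order(canonicalize(m, species) for m in members if m.strip())
        sets[name] = GeneSet(name, description, canon)
    return sets


def write_gene_sets(sets: dict[str, GeneSet], path: str | Path) -> Path:
    path = Path(path)
    lines = ["\t".join([s.name, s.description, *s.members]) for s in sets.values()]
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    return path
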