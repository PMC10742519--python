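"""Pathway gene sets in GMT format.

A GMT line is ``name <TAB> source_id/description <TAB> gene1 <TAB> ...``.
Genes may belong to several sets; the union of distinct symbols across a
collection counts each symbol once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = ["PathwaySet", "load_gmt", "write_gmt", "distinct_genes"]


@dataclass(frozen=True)
class PathwaySet:
    """A named gene set (e.g. a KEGG functional pathway)."""

    name: str
    source_id: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"pathway {self.name!r} has no genes")

    def quantified(self, available: Iterable[str]) -> tuple[str, ...]:
        """Subset of the pathway actually present in an analysis."""
        avail = set(available)
        return tuple(g for g in self.genes if g in avail)


def load_gmt(path: str | Path) -> list[PathwaySet]:
    """Read pathway sets from a GMT file.

    Duplicate genes within one set are collapsed (first occurrence kept)
    with a warning; a set with zero genes is an error.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, id, and >=1 gene")
            name, source_id, *genes = fields
            genes = [g for g in genes if g]
            seen: dict[str, None] = {}
            for g in genes:
                if g in seen:
                    warnings.warn(f"pathway {name!r}: duplicate gene {g!r} collapsed")
                seen[g] = None
            sets.append(PathwaySet(name=name, source_id=source_id, genes=tuple(seen)))
    return sets


def write_gmt(sets: Sequence[PathwaySet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ps in sets:
            fh.write("\t".join([ps.name, ps.source_id, *ps.genes]) + "\n")


def distinct_genes(sets: Sequence[PathwaySet]) -> set[str]:
    """Union of gene symbols across overlapping sets, each counted once."""
    out: set[str] = set()
    for ps in sets:
        out.update(ps.genes)
    return out
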