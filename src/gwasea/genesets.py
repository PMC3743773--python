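"""Gene set collections in GMT format and the set-size filter.

GMT is the MSigDB tab-separated container: one set per line, fields are
``name<TAB>description<TAB>gene1<TAB>gene2...``.  Collections used for
enrichment are conventionally restricted to sets of 5-250 annotated genes so
that terms are neither trivially narrow nor uninformatively broad.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.sets:
            raise ValueError(f"duplicate gene set name: {gene_set.name!r}")
        if not gene_set.genes:
            raise ValueError(f"gene set {gene_set.name!r} has no members")
        self.sets[gene_set.name] = gene_set

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def sizes(self) -> dict[str, int]:
        return {s.name: s.size for s in self}

    def mean_size(self) -> float:
        if not self.sets:
            raise ValueError("empty collection")
        return sum(s.size for s in self) / len(self)


def _dedup(genes: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for g in genes:
        if g and g not in seen:
            seen[g] = None
    return list(seen)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file; duplicate genes within a line are collapsed."""
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: GMT needs >= 3 tab-separated fields")
            name, description = fields[0], fields[1]
            genes = _dedup(fields[2:])
            if not genes:
                raise ValueError(f"line {lineno}: gene set {name!r} has no genes")
            collection.add(GeneSet(name, description, genes))
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def filter_by_size(
    collection: GeneSetCollection, min_genes: int = 5, max_genes: int = 250
) -> GeneSetCollection:
    """Keep sets whose annotated size is within [min_genes, max_genes].

    Sizes are measured on the annotated membership as given, not on the
    subset of genes covered by genotyped SNPs; coverage is accounted for
    downstream when gene statistics are joined in.
    """
    if min_genes < 1 or max_genes < min_genes:
        raise ValueError("need 1 <= min_genes <= max_genes")
    out = GeneSetCollection()
    for s in collection:
        if min_genes <= s.size <= max_genes:
            out.add(GeneSet(s.name, s.description, list(s.genes)))
    return out
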