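"""Signed circular gene orders, breakpoint distance, synapomorphies.

A gene order is a signed circular permutation of gene labels (sign = strand).
Reading the circle from the opposite strand yields the same physical genome,
so canonicalization reorients (reverse + sign flip) whenever the anchor gene
carries "-", then rotates the anchor to the front; the anchor is cox1, with
the lexicographically smallest label as fallback.  Adjacencies are identified
under (a, b) ~ (-b, -a) for the same reason; a genuinely reflected
arrangement that keeps strand annotations is still a distinct order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome import MitoGenome

__all__ = ["SignedGene", "GeneOrder", "extract_order", "adjacency_set",
           "breakpoint_distance", "synapomorphic_adjacencies"]

SignedGene = tuple[str, int]            # (label, +1/-1)
Adjacency = tuple[SignedGene, SignedGene]

SCOPES = {
    "pcg-rrna": ("PCG", "rRNA"),
    "all": ("PCG", "ORF", "rRNA", "tRNA"),
}


@dataclass(frozen=True)
class GeneOrder:
    identifier: str
    genes: tuple[SignedGene, ...]
    scope: str = "pcg-rrna"

    def __post_init__(self):
        labels = [g for g, _ in self.genes]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate labels in order: {dupes}")

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.genes)

    def canonical(self, anchor: str = "cox1") -> "GeneOrder":
        genes = list(self.genes)
        labels = [g for g, _ in genes]
        if anchor not in labels:
            anchor = min(labels)
        idx = labels.index(anchor)
        if genes[idx][1] == -1:
            genes = [(g, -s) for g, s in reversed(genes)]
            idx = [g for g, _ in genes].index(anchor)
        return GeneOrder(self.identifier,
                         tuple(genes[idx:] + genes[:idx]), self.scope)

    def __str__(self) -> str:
        return ";".join(f"{g},{'+' if s > 0 else '-'}" for g, s in self.genes)


def extract_order(genome: MitoGenome, scope: str = "pcg-rrna") -> GeneOrder:
    """Signed gene order around the circle, canonicalized to start at cox1."""
    kinds = SCOPES[scope]
    genes = tuple((f.label, f.strand) for f in genome.features if f.kind in kinds)
    if not genes:
        raise ValueError(f"{genome.identifier}: no features in scope {scope!r}")
    return GeneOrder(genome.identifier, genes, scope).canonical()


def _canonical_adjacency(a: SignedGene, b: SignedGene) -> Adjacency:
    flipped = ((b[0], -b[1]), (a[0], -a[1]))
    return min((a, b), flipped)


def adjacency_set(order: GeneOrder) -> frozenset[Adjacency]:
    """The order's circular signed adjacencies, |adjacencies| = |genes|."""
    g = order.genes
    n = len(g)
    return frozenset(_canonical_adjacency(g[i], g[(i + 1) % n]) for i in range(n))


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Adjacencies of ``a`` not conserved in ``b`` (symmetric for equal
    label sets)."""
    if a.labels != b.labels:
        only_a = sorted(a.labels - b.labels)
        only_b = sorted(b.labels - a.labels)
        raise ValueError(f"label sets differ: only in a={only_a}, only in b={only_b}")
    return len(adjacency_set(a) - adjacency_set(b))


def synapomorphic_adjacencies(orders: Sequence[GeneOrder],
                              group: Iterable[str]) -> frozenset[Adjacency]:
    """Adjacencies present in every group member and absent from every
    non-member — candidate clade-diagnostic rearrangement characters."""
    group = set(group)
    inside = [o for o in orders if o.identifier in group]
    outside = [o for o in orders if o.identifier not in group]
    if not inside or not outside:
        raise ValueError("group and its complement must both be non-empty")
    shared = frozenset.intersection(*(adjacency_set(o) for o in inside))
    others = frozenset.union(*(adjacency_set(o) for o in outside))
    return shared - others
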