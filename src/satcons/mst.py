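"""Minimum spanning trees of monomer variants and shared-variant reports.

Each node is an exact monomer haplotype; edge weights are Hamming distances,
so an edge of weight d represents d mutational steps.  Kruskal's algorithm
with an explicit tie-break (distance ascending, combined endpoint abundance
descending, then lexicographic endpoint ids) makes the tree deterministic
under input permutation, imitating the founder-preference of classical
haplotype-network tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .monomers import VariantPool

__all__ = [
    "hamming_matrix",
    "build_mst",
    "shared_variants",
    "SpanningTree",
    "SharedVariant",
]


def hamming_matrix(variants: Sequence[str]) -> np.ndarray:
    """Symmetric integer Hamming distance matrix over unique sequences."""
    if len(set(variants)) != len(variants):
        raise ValueError("variant sequences must be unique")
    lengths = {len(v) for v in variants}
    if len(lengths) > 1:
        raise ValueError(f"mixed sequence lengths: {sorted(lengths)}")
    X = np.array([list(v.encode()) for v in variants], dtype=np.uint8)
    return (X[:, None, :] != X[None, :, :]).sum(axis=2).astype(int)


@dataclass
class SpanningTree:
    """An MST with per-node abundance annotations."""

    nodes: list[str]
    edges: list[tuple[str, str, int]]
    abundances: dict[str, int] = field(default_factory=dict)

    @property
    def total_weight(self) -> int:
        return sum(d for _, _, d in self.edges)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[ri] = rj
        return True


def build_mst(
    distances: np.ndarray,
    ids: Optional[Sequence[str]] = None,
    abundances: Optional[Mapping[str, int]] = None,
) -> SpanningTree:
    """Kruskal MST over a symmetric distance matrix.

    Edges are processed sorted by (distance asc, combined endpoint abundance
    desc, lexicographic endpoint ids), which fixes the tree among equal-weight
    alternatives and prefers founding high-abundance nodes.
    """
    D = np.asarray(distances)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need >= 2 variants for a spanning tree")
    if D.shape != (n, n) or not np.array_equal(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    names = list(ids) if ids is not None else [f"v{i}" for i in range(n)]
    if len(set(names)) != n:
        raise ValueError("node ids must be unique")
    ab = {name: (abundances or {}).get(name, 1) for name in names}
    candidates = []
    for i in range(n):
        for j in range(i + 1, n):
            u, v, a, b = names[i], names[j], i, j
            if v < u:
                u, v, a, b = v, u, j, i
            candidates.append((int(D[i, j]), -(ab[u] + ab[v]), u, v, a, b))
    candidates.sort()
    uf = _UnionFind(n)
    edges: list[tuple[str, str, int]] = []
    for d, _, u, v, a, b in candidates:
        if uf.union(a, b):
            edges.append((u, v, d))
            if len(edges) == n - 1:
                break
    return SpanningTree(names, edges, ab)


@dataclass(frozen=True)
class SharedVariant:
    """A monomer haplotype carried by several species, with per-species counts."""

    sequence: str
    species_counts: tuple[tuple[str, int], ...]

    @property
    def n_species(self) -> int:
        return len(self.species_counts)


def shared_variants(pools: VariantPool, min_species: int = 2) -> list[SharedVariant]:
    """Exact-sequence intersection of variant pools across species.

    Returns variants present (count >= 1) in at least ``min_species`` pools,
    sorted by species count descending then by sequence.
    """
    carriers: dict[str, list[tuple[str, int]]] = {}
    for sp in pools.species():
        for seq, count in sorted(pools.counts(sp).items()):
            carriers.setdefault(seq, []).append((sp, count))
    out = [
        SharedVariant(seq, tuple(specs))
        for seq, specs in carriers.items()
        if len(specs) >= min_species
    ]
    out.sort(key=lambda v: (-v.n_species, v.sequence))
    return out
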