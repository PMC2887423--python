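"""Directed regulatory networks and the positive/unlabeled edge partition.

A gene regulatory network is a directed graph whose nodes are genes and
whose edge ``(a, b)`` means "gene *a* regulates gene *b*".  Edges are
ordered throughout: ``(a, b)`` and ``(b, a)`` are distinct hypotheses.
Self-regulation is excluded from every edge set and every pair universe.

The supervised inference problem partitions the ordered non-self gene
pairs into

* ``P`` — regulations known from the literature (labeled positives),
* ``Q`` — true regulations not yet known (hidden positives),
* ``N`` — pairs that genuinely do not interact (true negatives),

and the PSEUDO-RANDOM heuristic implemented here selects candidate
negative training pairs from the transitive closure of the known network
and its transpose, exploiting the near-acyclic, tree-like topology of
prokaryotic transcriptional networks: in a tree, any pair connected by a
path of length two or more, and any reversed pair, is not itself an edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx
import numpy as np

Edge = tuple[str, str]

__all__ = [
    "GeneNetwork",
    "LabelPartition",
    "transitive_closure",
    "transpose",
    "pseudo_random_negatives",
    "partition_edges",
    "all_ordered_pairs",
]


def all_ordered_pairs(genes: Iterable[str]) -> Iterator[Edge]:
    """Yield every ordered non-self pair over ``genes`` in lexicographic order."""
    ordered = sorted(genes)
    for a in ordered:
        for b in ordered:
            if a != b:
                yield (a, b)


@dataclass(frozen=True)
class GeneNetwork:
    """A directed regulatory graph with an explicit gene universe.

    Parameters
    ----------
    genes
        Ordered collection of gene identifiers (opaque strings).
    edges
        Set of ordered ``(regulator, target)`` pairs.  Self-loops are
        rejected, as are edges whose endpoints are not in ``genes``.
    """

    genes: tuple[str, ...]
    edges: frozenset[Edge] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        gene_set = set(self.genes)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-regulatory edge ({a!r}, {b!r}) not allowed")
            if a not in gene_set or b not in gene_set:
                raise ValueError(f"edge ({a!r}, {b!r}) has endpoint outside gene set")

    @classmethod
    def from_edges(cls, edges: Iterable[Edge], genes: Iterable[str] | None = None) -> "GeneNetwork":
        """Build a network from an edge list; genes default to edge endpoints."""
        edges = frozenset(tuple(e) for e in edges)
        if genes is None:
            genes = sorted({g for e in edges for g in e})
        return cls(tuple(genes), edges)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def ordered_pairs(self) -> Iterator[Edge]:
        """All candidate ordered non-self pairs over this network's genes."""
        return all_ordered_pairs(self.genes)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class LabelPartition:
    """The (P, Q, N) split of all ordered non-self gene pairs.

    ``P`` are known positives, ``Q`` hidden positives, ``N`` true
    negatives; together they cover the full ordered-pair universe over
    ``genes`` and are pairwise disjoint.
    """

    genes: tuple[str, ...]
    P: frozenset[Edge]
    Q: frozenset[Edge]
    N: frozenset[Edge]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        for name in ("P", "Q", "N"):
            object.__setattr__(self, name, frozenset(getattr(self, name)))
        if (self.P & self.Q) or (self.P & self.N) or (self.Q & self.N):
            raise ValueError("P, Q, N must be pairwise disjoint")

    def validate_universe(self) -> None:
        """Check that P ∪ Q ∪ N covers every ordered non-self pair exactly."""
        universe = set(all_ordered_pairs(self.genes))
        covered = self.P | self.Q | self.N
        if covered != universe:
            raise ValueError("P ∪ Q ∪ N does not cover the ordered-pair universe")

    @property
    def true_edges(self) -> frozenset[Edge]:
        """The gold-standard edge set P ∪ Q."""
        return self.P | self.Q


def transitive_closure(network: GeneNetwork) -> GeneNetwork:
    """Transitive closure: edge (i, j) wherever a directed path i → j exists.

    Self-pairs are excluded even when a cycle makes a node reachable from
    itself, because self-regulation is outside the pair universe.
    """
    closed = nx.transitive_closure(network.to_digraph(), reflexive=None)
    return GeneNetwork(network.genes, frozenset(closed.edges()))


def transpose(network: GeneNetwork) -> GeneNetwork:
    """The same graph with every edge reversed."""
    return GeneNetwork(network.genes, frozenset((b, a) for a, b in network.edges))


def pseudo_random_negatives(
    known: GeneNetwork,
    universe_genes: Iterable[str],
    random_fraction: float = 0.1,
    seed: int = 0,
) -> frozenset[Edge]:
    """Candidate negative pairs via the transitive-closure heuristic.

    The heuristic set is ``(TC(P) ∪ Transpose(TC(P))) \\ P`` where ``P``
    is the known network: pairs linked by longer paths, and reversals of
    such pairs, are unlikely to be regulations when the network is nearly
    a tree.  The set is then extended with
    ``ceil(random_fraction * |heuristic set|)`` distinct pairs drawn
    uniformly (seeded) from the remaining unlabeled ordered pairs over
    ``universe_genes``.

    Known edges are never returned: they are labeled positives and cannot
    serve as negatives.

    Raises
    ------
    ValueError
        If the requested random extension exceeds the number of available
        unlabeled pairs.
    """
    if random_fraction < 0:
        raise ValueError("random_fraction must be nonnegative")
    universe = tuple(sorted(universe_genes))
    if not set(known.genes) <= set(universe):
        raise ValueError("known network genes must be a subset of universe_genes")

    tc = transitive_closure(known)
    heuristic = (tc.edges | transpose(tc).edges) - known.edges

    n_extra = math.ceil(random_fraction * len(heuristic))
    if n_extra == 0:
        return frozenset(heuristic)

    pool = [
        pair
        for pair in all_ordered_pairs(universe)
        if pair not in known.edges and pair not in heuristic
    ]
    if n_extra > len(pool):
        raise ValueError(
            f"random extension of {n_extra} pairs exceeds {len(pool)} available unlabeled pairs"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n_extra, replace=False)
    return frozenset(heuristic | {pool[i] for i in idx})


def partition_edges(gold: GeneNetwork, known_fraction: float, seed: int = 0) -> LabelPartition:
    """Split a gold-standard network into known/hidden positives and negatives.

    A seeded uniform sample of ``round(known_fraction * |edges|)`` edges
    (at least one) becomes ``P``; the remaining true edges are ``Q``; all
    other ordered non-self pairs are ``N``.
    """
    if not 0 < known_fraction <= 1:
        raise ValueError("known_fraction must be in (0, 1]")
    if not gold.edges:
        raise ValueError("gold network has no edges to partition")
    edges = sorted(gold.edges)
    n_known = max(1, round(known_fraction * len(edges)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(edges), size=n_known, replace=False)
    P = frozenset(edges[i] for i in idx)
    Q = gold.edges - P
    N = frozenset(all_ordered_pairs(gold.genes)) - gold.edges
    return LabelPartition(gold.genes, P, Q, N)
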