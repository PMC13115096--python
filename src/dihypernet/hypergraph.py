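"""Directed hypergraph data model.

A directed hyperedge joins two disjoint, non-empty node sets: a *tail*
(the source side of the follow relation) and a *head* (the followed
side).  Two edge kinds exist:

* ``ONE_WAY`` — tail members follow head members.  Information travels
  against the follow direction, i.e. from the head to the tail.
* ``MUTUAL`` — both sides follow each other; information travels in
  both directions across the tail/head partition.

Node identifiers are dense 0-based integers so that growth models can
append nodes sequentially; external labels should be mapped through a
symbol table by the caller.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

__all__ = [
    "EdgeKind",
    "Hyperedge",
    "DirectedHypergraph",
    "IncidenceMatrices",
    "HypergraphError",
]


class HypergraphError(ValueError):
    """Raised for malformed hyperedges or unknown node/edge ids."""


class EdgeKind(Enum):
    ONE_WAY = "one_way"
    MUTUAL = "mutual"


@dataclass(frozen=True)
class Hyperedge:
    """A directed hyperedge with disjoint, non-empty tail and head sets."""

    id: int
    kind: EdgeKind
    tail: frozenset[int]
    head: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tail", frozenset(self.tail))
        object.__setattr__(self, "head", frozenset(self.head))
        if not self.tail or not self.head:
            raise HypergraphError(
                f"edge {self.id}: tail and head must both be non-empty"
            )
        if self.tail & self.head:
            raise HypergraphError(
                f"edge {self.id}: tail and head overlap on {sorted(self.tail & self.head)}"
            )

    @property
    def members(self) -> frozenset[int]:
        return self.tail | self.head

    def degree(self) -> int:
        """Number of vertices in the edge, |tail| + |head|."""
        return len(self.tail) + len(self.head)


@dataclass
class IncidenceMatrices:
    """Sparse tail/head incidence matrices of shape (n_nodes, n_edges).

    ``H_tail[v, e] = 1`` iff node v belongs to tail(e), and likewise for
    ``H_head``.  Disjointness of tail and head makes the element-wise
    product of the two matrices identically zero.
    """

    H_tail: sp.csr_matrix
    H_head: sp.csr_matrix

    def dense(self) -> tuple[np.ndarray, np.ndarray]:
        return self.H_tail.toarray(), self.H_head.toarray()

    def to_edges(self, kinds: Iterable[EdgeKind]) -> list[Hyperedge]:
        """Rebuild the hyperedge list (round-trip check helper)."""
        tail_cols = self.H_tail.tocsc()
        head_cols = self.H_head.tocsc()
        edges = []
        for e, kind in enumerate(kinds):
            tail = frozenset(tail_cols.indices[tail_cols.indptr[e]:tail_cols.indptr[e + 1]].tolist())
            head = frozenset(head_cols.indices[head_cols.indptr[e]:head_cols.indptr[e + 1]].tolist())
            edges.append(Hyperedge(e, kind, tail, head))
        return edges


class DirectedHypergraph:
    """A set of ``n_nodes`` dense-integer nodes plus an ordered edge list.

    Edge ids equal their position in the list.  Neighborhood queries are
    cached and invalidated whenever the structure changes.
    """

    def __init__(self, n_nodes: int, edges: Iterable[Hyperedge] = ()) -> None:
        if n_nodes < 1:
            raise HypergraphError("a hypergraph needs at least one node")
        self.n_nodes = int(n_nodes)
        self.edges: list[Hyperedge] = []
        self._in_nbrs: list[set[int]] | None = None
        self._followers: list[set[int]] | None = None
        for e in edges:
            self.add_edge(e.kind, e.tail, e.head)

    # -- construction -------------------------------------------------

    def add_node(self) -> int:
        self.n_nodes += 1
        self._invalidate()
        return self.n_nodes - 1

    def add_edge(self, kind: EdgeKind, tail: Iterable[int], head: Iterable[int]) -> Hyperedge:
        edge = Hyperedge(len(self.edges), kind, frozenset(tail), frozenset(head))
        for v in edge.members:
            if not (0 <= v < self.n_nodes):
                raise HypergraphError(f"edge {edge.id}: node {v} outside [0, {self.n_nodes})")
        self.edges.append(edge)
        self._invalidate()
        return edge

    def set_kind(self, edge_id: int, kind: EdgeKind) -> None:
        e = self._edge(edge_id)
        self.edges[edge_id] = Hyperedge(e.id, kind, e.tail, e.head)
        self._invalidate()

    def _invalidate(self) -> None:
        self._in_nbrs = None
        self._followers = None

    def _edge(self, edge_id: int) -> Hyperedge:
        if not (0 <= edge_id < len(self.edges)):
            raise HypergraphError(f"unknown edge id {edge_id}")
        return self.edges[edge_id]

    def _check_node(self, v: int) -> None:
        if not (0 <= v < self.n_nodes):
            raise HypergraphError(f"unknown node id {v}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    # -- incidence and degrees ----------------------------------------

    def incidence_matrices(self) -> IncidenceMatrices:
        rows_t, cols_t, rows_h, cols_h = [], [], [], []
        for e in self.edges:
            rows_t.extend(e.tail)
            cols_t.extend([e.id] * len(e.tail))
            rows_h.extend(e.head)
            cols_h.extend([e.id] * len(e.head))
        shape = (self.n_nodes, self.n_edges)
        H_tail = sp.csr_matrix(
            (np.ones(len(rows_t), dtype=np.int8), (rows_t, cols_t)), shape=shape
        )
        H_head = sp.csr_matrix(
            (np.ones(len(rows_h), dtype=np.int8), (rows_h, cols_h)), shape=shape
        )
        return IncidenceMatrices(H_tail, H_head)

    def edge_degree(self, edge_id: int) -> int:
        """|tail(e)| + |head(e)|."""
        return self._edge(edge_id).degree()

    def node_degree(self, v: int) -> int:
        """Number of hyperedges containing v (the node's hyperdegree)."""
        self._check_node(v)
        return sum(1 for e in self.edges if v in e.tail or v in e.head)

    def hyperdegrees(self) -> np.ndarray:
        """Hyperdegree of every node as an int array of length n_nodes."""
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for e in self.edges:
            for v in e.members:
                deg[v] += 1
        return deg

    def hyperdegree_distribution(self) -> dict[int, float]:
        """P(k) = (number of nodes with hyperdegree k) / n_nodes."""
        counts = Counter(self.hyperdegrees().tolist())
        return {k: c / self.n_nodes for k, c in sorted(counts.items())}

    # -- neighborhoods ------------------------------------------------

    def _build_neighborhoods(self) -> None:
        in_nbrs: list[set[int]] = [set() for _ in range(self.n_nodes)]
        followers: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for e in self.edges:
            if e.kind is EdgeKind.ONE_WAY:
                # tail follows head; information flows head -> tail
                for v in e.tail:
                    in_nbrs[v].update(e.head)
                for u in e.head:
                    followers[u].update(e.tail)
            else:
                for v in e.tail:
                    in_nbrs[v].update(e.head)
                    followers[v].update(e.head)
                for u in e.head:
                    in_nbrs[u].update(e.tail)
                    followers[u].update(e.tail)
        for v in range(self.n_nodes):
            in_nbrs[v].discard(v)
            followers[v].discard(v)
        self._in_nbrs = in_nbrs
        self._followers = followers

    def in_neighbors(self, v: int) -> set[int]:
        """Nodes whose information can reach v directly (the nodes v follows)."""
        self._check_node(v)
        if self._in_nbrs is None:
            self._build_neighborhoods()
        return set(self._in_nbrs[v])

    def in_neighbor_sets(self) -> list[set[int]]:
        if self._in_nbrs is None:
            self._build_neighborhoods()
        return [set(s) for s in self._in_nbrs]

    def follow_counts(self, v: int) -> tuple[int, int]:
        """(followers, followings) of node v as distinct-node counts."""
        self._check_node(v)
        if self._in_nbrs is None or self._followers is None:
            self._build_neighborhoods()
        return len(self._followers[v]), len(self._in_nbrs[v])

    def follower_counts(self) -> np.ndarray:
        if self._followers is None:
            self._build_neighborhoods()
        return np.array([len(s) for s in self._followers], dtype=np.int64)

    def following_counts(self) -> np.ndarray:
        if self._in_nbrs is None:
            self._build_neighborhoods()
        return np.array([len(s) for s in self._in_nbrs], dtype=np.int64)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DirectedHypergraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def distribution_from_mapping(p: Mapping[int, float]) -> dict[int, float]:
    """Validate and normalize-check a hyperdegree distribution mapping."""
    total = sum(p.values())
    if abs(total - 1.0) > 1e-9:
        raise HypergraphError(f"hyperdegree distribution sums to {total}, not 1")
    return dict(sorted(p.items()))
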