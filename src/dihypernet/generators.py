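"""Growth models for directed social hypernetworks and comparison substrates.

The main generator grows a scale-free *directed* social hypernetwork by
preferential attachment on follower/following counts: at every time step
``n1`` new users join and each follows ``n2`` existing users, chosen with
probability proportional to ``eps * followers + (1 - eps) * followings + 1``.
Targets shared by several of the step's newcomers are grouped into one
joint one-way follow hyperedge (head = the shared target, tail = the
sharing newcomers); each newcomer's remaining targets form a single
one-way hyperedge (head = those targets, tail = the newcomer).  Each
one-way hyperedge created in a step is followed back — converted to a
mutual hyperedge — with probability ``p_mutual`` within the same step.

Comparison substrates: a BA-style scale-free hypernetwork and an NW
small-world hypernetwork, both emitted with mutual hyperedges because
those classical models are undirected, plus an undirected projection of
any directed hypernetwork and a homogeneous random group-mixing network
used for mean-field consistency checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hypergraph import DirectedHypergraph, EdgeKind, HypergraphError

__all__ = [
    "ConfigError",
    "GrowthConfig",
    "BAConfig",
    "NWConfig",
    "attachment_weights",
    "grow_directed_social",
    "generate_ba_hypernetwork",
    "generate_nw_hypernetwork",
    "generate_homogeneous_mixing",
    "to_undirected",
]


class ConfigError(ValueError):
    """Raised for invalid generator or contagion configurations."""


@dataclass
class GrowthConfig:
    """Parameters of the directed social hypernetwork growth model.

    N        target number of nodes
    n0       initial (seed) node count, >= 2
    n1       new nodes per time step
    n2       follow targets per new node
    eps      in/out-degree weight in [0, 1] (1 = followers only)
    p_mutual probability that a step's one-way hyperedge is followed back
    seed     RNG seed (used when no generator is passed explicitly)
    """

    N: int = 5000
    n0: int = 6
    n1: int = 2
    n2: int = 5
    eps: float = 0.8
    p_mutual: float = 0.1
    seed: int | None = None

    def validate(self) -> None:
        if self.n0 < 2:
            raise ConfigError("n0 must be >= 2")
        if self.N < self.n0:
            raise ConfigError("N must be >= n0")
        if self.n1 < 1 or self.n2 < 1:
            raise ConfigError("n1 and n2 must be >= 1")
        if not 0.0 <= self.eps <= 1.0:
            raise ConfigError("eps must lie in [0, 1]")
        if not 0.0 <= self.p_mutual <= 1.0:
            raise ConfigError("p_mutual must lie in [0, 1]")


@dataclass
class BAConfig:
    """Scale-free (growth + hyperdegree-preferential-attachment) hypernetwork."""

    N: int = 5000
    n0: int = 6
    n2: int = 5
    seed: int | None = None

    def validate(self) -> None:
        if self.n0 < 2:
            raise ConfigError("n0 must be >= 2")
        if self.N < self.n0:
            raise ConfigError("N must be >= n0")
        if not 1 <= self.n2 <= self.n0:
            raise ConfigError("n2 must lie in [1, n0]")


@dataclass
class NWConfig:
    """Small-world hypernetwork: ring-lattice hyperedges plus random shortcuts."""

    N: int = 5000
    K: int = 14
    f: float = 0.01
    seed: int | None = None

    def validate(self) -> None:
        if self.K >= self.N:
            raise ConfigError("K must be smaller than N")
        if self.K < 2:
            raise ConfigError("K must be >= 2")
        if not 0.0 <= self.f <= 1.0:
            raise ConfigError("f must lie in [0, 1]")


def attachment_weights(H: DirectedHypergraph, eps: float) -> np.ndarray:
    """Normalized preferential-attachment weights over the nodes of ``H``.

    weight(i) ∝ eps * followers(i) + (1 - eps) * followings(i) + 1; the
    additive 1 keeps degree-0 nodes reachable.
    """
    if not 0.0 <= eps <= 1.0:
        raise ConfigError("eps must lie in [0, 1]")
    w = eps * H.follower_counts() + (1.0 - eps) * H.following_counts() + 1.0
    return w / w.sum()


def _seed_network(n0: int) -> DirectedHypergraph:
    """Initial follow pattern: nodes 1..n0-2 jointly follow node 0 (one-way)
    and nodes 1 and n0-1 follow each other (mutual)."""
    H = DirectedHypergraph(n0)
    if n0 == 2:
        H.add_edge(EdgeKind.MUTUAL, {0}, {1})
        return H
    H.add_edge(EdgeKind.ONE_WAY, set(range(1, n0 - 1)), {0})
    H.add_edge(EdgeKind.MUTUAL, {1}, {n0 - 1})
    return H


def grow_directed_social(
    config: GrowthConfig, rng: np.random.Generator | None = None
) -> DirectedHypergraph:
    """Grow a directed social hypernetwork to ``config.N`` nodes.

    The generator is deterministic given (config, seed): identical inputs
    reproduce a byte-identical hyperedge list.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    H = _seed_network(config.n0)
    # incremental follower/following bookkeeping (distinct-node counts)
    followings: list[set[int]] = [set() for _ in range(config.N)]
    followers = np.zeros(config.N, dtype=np.float64)

    def record_follow(u: int, w: int) -> None:
        if w not in followings[u] and u != w:
            followings[u].add(w)
            followers[w] += 1.0

    for e in H.edges:
        for u in e.tail:
            for w in e.head:
                record_follow(u, w)
        if e.kind is EdgeKind.MUTUAL:
            for w in e.head:
                for u in e.tail:
                    record_follow(w, u)

    while H.n_nodes < config.N:
        existing = H.n_nodes
        if config.n2 > existing:
            raise ConfigError(
                f"n2={config.n2} exceeds current network size {existing}"
            )
        n_new = min(config.n1, config.N - existing)
        new_ids = [H.add_node() for _ in range(n_new)]

        following_counts = np.fromiter(
            (len(followings[v]) for v in range(existing)), dtype=np.float64, count=existing
        )
        w = config.eps * followers[:existing] + (1.0 - config.eps) * following_counts + 1.0
        w /= w.sum()

        choices: dict[int, np.ndarray] = {
            v: np.sort(rng.choice(existing, size=config.n2, replace=False, p=w))
            for v in new_ids
        }

        # group shared targets into joint one-way hyperedges
        target_owners: dict[int, list[int]] = {}
        for v in new_ids:
            for tgt in choices[v]:
                target_owners.setdefault(int(tgt), []).append(v)
        step_edges = []
        shared = {t for t, owners in target_owners.items() if len(owners) >= 2}
        for tgt in sorted(shared):
            step_edges.append(
                H.add_edge(EdgeKind.ONE_WAY, set(target_owners[tgt]), {tgt})
            )
        for v in new_ids:
            residual = {int(t) for t in choices[v] if int(t) not in shared}
            if residual:
                step_edges.append(H.add_edge(EdgeKind.ONE_WAY, {v}, residual))

        for edge in step_edges:
            for u in edge.tail:
                for t in edge.head:
                    record_follow(u, t)
        # follow-back: convert this step's one-way edges with prob p_mutual
        for edge in step_edges:
            if rng.random() < config.p_mutual:
                H.set_kind(edge.id, EdgeKind.MUTUAL)
                for t in edge.head:
                    for u in edge.tail:
                        record_follow(t, u)

    return H


def generate_ba_hypernetwork(
    config: BAConfig, rng: np.random.Generator | None = None
) -> DirectedHypergraph:
    """Scale-free hypernetwork: each step one new node joins ``n2`` existing
    nodes, chosen preferentially by hyperdegree, in a single mutual hyperedge."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    H = DirectedHypergraph(config.n0)
    H.add_edge(EdgeKind.MUTUAL, {0}, set(range(1, config.n0)))
    deg = np.zeros(config.N, dtype=np.float64)
    deg[: config.n0] = 1.0

    while H.n_nodes < config.N:
        existing = H.n_nodes
        p = deg[:existing] / deg[:existing].sum()
        targets = rng.choice(existing, size=config.n2, replace=False, p=p)
        v = H.add_node()
        H.add_edge(EdgeKind.MUTUAL, {v}, {int(t) for t in targets})
        deg[v] += 1.0
        deg[targets] += 1.0
    return H


def generate_nw_hypernetwork(
    config: NWConfig, rng: np.random.Generator | None = None
) -> DirectedHypergraph:
    """Small-world hypernetwork.

    One lattice hyperedge per node groups it with its K nearest ring
    neighbors (⌊K/2⌋ per side); with probability ``f`` each lattice
    hyperedge additionally spawns a shortcut hyperedge of the same size
    over uniformly random distinct nodes.  All hyperedges are mutual.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    N, per_side = config.N, config.K // 2
    H = DirectedHypergraph(N)
    for i in range(N):
        nbrs = {(i + d) % N for d in range(1, per_side + 1)}
        nbrs |= {(i - d) % N for d in range(1, per_side + 1)}
        nbrs.discard(i)
        H.add_edge(EdgeKind.MUTUAL, {i}, nbrs)
    size = 2 * per_side + 1
    for i in range(N):
        if rng.random() < config.f:
            members = rng.choice(N, size=size, replace=False)
            H.add_edge(
                EdgeKind.MUTUAL, {int(members[0])}, {int(m) for m in members[1:]}
            )
    return H


def generate_homogeneous_mixing(
    n_nodes: int,
    group_size: int,
    rounds: int,
    rng: np.random.Generator | None = None,
) -> DirectedHypergraph:
    """Dense homogeneous mutual hypernetwork for mean-field comparisons.

    Each round randomly partitions the nodes into groups of ``group_size``
    and turns every group into one mutual hyperedge, giving every node
    exactly ``rounds`` memberships and ≈ rounds*(group_size-1) in-neighbors
    with negligible clustering.
    """
    if n_nodes % group_size != 0:
        raise ConfigError("group_size must divide n_nodes")
    if rng is None:
        rng = np.random.default_rng()
    H = DirectedHypergraph(n_nodes)
    for _ in range(rounds):
        perm = rng.permutation(n_nodes)
        for g in range(0, n_nodes, group_size):
            grp = perm[g : g + group_size]
            H.add_edge(EdgeKind.MUTUAL, {int(grp[0])}, {int(m) for m in grp[1:]})
    return H


def to_undirected(H: DirectedHypergraph) -> DirectedHypergraph:
    """Undirected projection: same nodes and edges, every kind set to mutual."""
    out = DirectedHypergraph(H.n_nodes)
    for e in H.edges:
        out.add_edge(EdgeKind.MUTUAL, e.tail, e.head)
    return out
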