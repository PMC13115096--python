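"""Independent brute-force oracles used by the test suite.

Everything here is written directly from the model rules, by literal
enumeration over edge lists and node loops — deliberately sharing no
code with the package's vectorized implementation.
"""

from __future__ import annotations

import numpy as np

from dihypernet.hypergraph import DirectedHypergraph, EdgeKind

S, E, I, R = 0, 1, 2, 3


def brute_in_neighbors(H: DirectedHypergraph) -> list[set[int]]:
    """In-neighbor sets from the edge list, rule by rule."""
    out = [set() for _ in range(H.n_nodes)]
    for e in H.edges:
        for v in e.tail:
            for u in e.head:
                if u != v:
                    out[v].add(u)
                    if e.kind is EdgeKind.MUTUAL:
                        out[u].add(v)
    return out


def brute_xi(H: DirectedHypergraph, alpha: float) -> dict[tuple[int, int], float]:
    """Capped intimacy per ordered propagation pair (source j, receiver i)."""
    nbrs = brute_in_neighbors(H)
    raised = {}
    for i in range(H.n_nodes):
        for j in nbrs[i]:
            n_common = len(nbrs[i] & nbrs[j])
            raised[(j, i)] = (n_common + 1) ** alpha
    mean = sum(raised.values()) / len(raised)
    return {pair: min(v / mean, 1.0) for pair, v in raised.items()}


def brute_step(
    states: np.ndarray,
    H: DirectedHypergraph,
    draws: list[float],
    t: int,
    *,
    mode: str,
    C: np.ndarray,
    lam: float = 0.0,
    alpha: float = 1.0,
    xi: float | None = None,
    beta: float | None = None,
    eta: float | None = None,
    gamma: float | None = None,
) -> np.ndarray:
    """One synchronous update, consuming ``draws`` in the documented order:
    active transmission pairs (receiver-major, sources ascending), then
    exposed-node draws (threshold mode: dropout draws for the nodes that
    fail their threshold; fixed mode: all beta draws, then eta draws for
    the beta-failures), then recovery draws for infected nodes."""
    nbrs = brute_in_neighbors(H)
    xi_pairs = None if xi is not None else brute_xi(H, alpha)
    new = states.copy()
    queue = list(draws)
    pop = lambda: queue.pop(0)

    # transmission: S node exposed if any infected in-neighbor succeeds
    for i in range(H.n_nodes):
        if states[i] != S:
            continue
        exposed = False
        for j in sorted(nbrs[i]):
            if states[j] != I:
                continue
            p = xi if xi is not None else xi_pairs[(j, i)]
            if pop() < p:
                exposed = True
        if exposed:
            new[i] = E

    # exposed transitions
    e_nodes = [i for i in range(H.n_nodes) if states[i] == E]
    if mode == "threshold":
        for i in e_nodes:
            K = len(nbrs[i])
            m = sum(1 for j in nbrs[i] if states[j] == I)
            if K > 0 and m >= C[i] * K:
                new[i] = I
            else:
                eta_i = eta if eta is not None else min(C[i], 1.0)
                if pop() < eta_i:
                    new[i] = R
    else:
        survivors = []
        for i in e_nodes:
            if pop() < beta:
                new[i] = I
            else:
                survivors.append(i)
        for i in survivors:
            if pop() < eta:
                new[i] = R

    # recovery
    g = gamma if gamma is not None else 1.0 - np.exp(-lam * t)
    for i in range(H.n_nodes):
        if states[i] == I and pop() < g:
            new[i] = R
    return new


def threshold_closure(
    H: DirectedHypergraph, seeds: set[int], theta: np.ndarray
) -> tuple[set[int], dict[int, int]]:
    """Monotone closure of the in-neighbor threshold update.

    Starting from ``seeds`` active, repeatedly activate every node whose
    active in-neighbor count m reaches theta*K (K = in-neighbor count;
    K = 0 never activates).  Returns the fixed point and the round at
    which each node activated (seeds at round 0).
    """
    nbrs = brute_in_neighbors(H)
    active = set(seeds)
    round_of = {v: 0 for v in active}
    r = 0
    while True:
        r += 1
        newly = set()
        for i in range(H.n_nodes):
            if i in active:
                continue
            K = len(nbrs[i])
            if K == 0:
                continue
            m = len(nbrs[i] & active)
            if m >= theta[i] * K:
                newly.add(i)
        if not newly:
            return active, round_of
        for v in newly:
            round_of[v] = r
        active |= newly


def random_hypergraph(rng: np.random.Generator, max_nodes: int = 6) -> DirectedHypergraph:
    """Small random directed hypergraph with at least one edge."""
    n = int(rng.integers(2, max_nodes + 1))
    H = DirectedHypergraph(n)
    n_edges = int(rng.integers(1, 5))
    for _ in range(n_edges):
        nodes = rng.permutation(n)
        cut = int(rng.integers(1, len(nodes)))
        size = int(rng.integers(cut + 1, len(nodes) + 1))
        tail = {int(v) for v in nodes[:cut]}
        head = {int(v) for v in nodes[cut:size]}
        kind = EdgeKind.MUTUAL if rng.random() < 0.4 else EdgeKind.ONE_WAY
        H.add_edge(kind, tail, head)
    return H
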