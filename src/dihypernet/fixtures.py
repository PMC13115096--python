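"""Deterministic toy networks and a scripted-randomness harness.

These encode, node for node, the small worked examples used throughout
the package's tests: the two-seed-edge growth vignette (``fig4_network``,
nine users over three time steps), a nine-vertex three-edge incidence
example (``fig2_network``), and the propagation vignette
(``fig6_network``) whose narrated state sequence — seed spreader v10,
exposure of v5/v12/v13, activation of v12, dropout of v5 and v13 — is
forced by scripted draws and scripted confidences.

Node labels v1..vn map to ids 0..n-1.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Sequence

import numpy as np

from .contagion import NodeAttributes
from .hypergraph import DirectedHypergraph, EdgeKind

__all__ = [
    "ScriptedRng",
    "fig2_network",
    "fig4_network",
    "fig6_network",
    "fig6_attributes",
    "fig6_draws",
]


class ScriptedRng:
    """Replays preordained uniform draws and selection outcomes.

    Duck-types the slice of ``numpy.random.Generator`` the simulator and
    generators use (``random`` and ``choice``).  Raises RuntimeError
    when a queue is exhausted and records total consumption so tests can
    assert the draw-order contract.
    """

    def __init__(
        self,
        uniforms: Iterable[float] = (),
        selections: Iterable[Sequence[int]] = (),
    ) -> None:
        self._uniforms = deque(float(u) for u in uniforms)
        self._selections = deque(np.asarray(s, dtype=np.int64) for s in selections)
        self.uniforms_consumed = 0
        self.selections_consumed = 0

    def random(self, size: int | None = None):
        if size is None:
            return self._next_uniform()
        out = np.array([self._next_uniform() for _ in range(int(size))])
        return out

    def _next_uniform(self) -> float:
        if not self._uniforms:
            raise RuntimeError("ScriptedRng: uniform queue exhausted")
        self.uniforms_consumed += 1
        return self._uniforms.popleft()

    def choice(self, n, size=None, replace=True, p=None):
        if not self._selections:
            raise RuntimeError("ScriptedRng: selection queue exhausted")
        sel = self._selections.popleft()
        self.selections_consumed += 1
        if size is not None and len(sel) != size:
            raise RuntimeError(
                f"ScriptedRng: scripted selection has {len(sel)} items, caller wants {size}"
            )
        return sel.copy()


def fig2_network() -> DirectedHypergraph:
    """Nine vertices, three directed hyperedges covering all of them.

    The published drawing fixes only the vertex and edge counts, so the
    memberships here are a synthetic stand-in chosen to exercise
    many-to-one, one-to-many and many-to-many shapes; tests only rely on
    counts and incidence-column sums.
    """
    H = DirectedHypergraph(9)
    H.add_edge(EdgeKind.ONE_WAY, {1, 2}, {0})        # many-to-one
    H.add_edge(EdgeKind.ONE_WAY, {3}, {4, 5, 6})     # one-to-many
    H.add_edge(EdgeKind.ONE_WAY, {6, 7}, {8, 0})     # many-to-many
    return H


_FIG4_STAGES = ("t0", "t1", "t2a", "t2b")


def fig4_network(stage: str = "t2b") -> DirectedHypergraph:
    """Growth vignette at one of its four stages: t0, t1, t2a, t2b.

    t0: v2,v3,v4 jointly follow v1 (one-way e1); v2 and v5 follow each
    other (mutual e2).  t1: newcomers v6 (follows v1,v3; e3) and v7
    (follows v2,v4; e4).  t2a: newcomers v8,v9 jointly follow v1 (e5),
    v9 follows v4 (e6), v8 follows v7 (e7).  t2b: v7 follows v8 back and
    e7 becomes mutual.
    """
    if stage not in _FIG4_STAGES:
        raise ValueError(f"stage must be one of {_FIG4_STAGES}")
    n = {"t0": 5, "t1": 7, "t2a": 9, "t2b": 9}[stage]
    H = DirectedHypergraph(n)
    H.add_edge(EdgeKind.ONE_WAY, {1, 2, 3}, {0})     # e1
    H.add_edge(EdgeKind.MUTUAL, {1}, {4})            # e2
    if stage == "t0":
        return H
    H.add_edge(EdgeKind.ONE_WAY, {5}, {0, 2})        # e3
    H.add_edge(EdgeKind.ONE_WAY, {6}, {1, 3})        # e4
    if stage == "t1":
        return H
    H.add_edge(EdgeKind.ONE_WAY, {7, 8}, {0})        # e5
    H.add_edge(EdgeKind.ONE_WAY, {8}, {3})           # e6
    e7_kind = EdgeKind.MUTUAL if stage == "t2b" else EdgeKind.ONE_WAY
    H.add_edge(e7_kind, {7}, {6})                    # e7
    return H


def fig6_network() -> tuple[DirectedHypergraph, list[int]]:
    """Propagation vignette fragment plus its seed spreader list ([v10]).

    Narrated structure: mutual hyperedge e3 joins v5,v6 with v10; one-way
    hyperedge e5 has tail {v12, v13} and head containing v10 (here
    {v10, v11}).  Two filler follows are added so the narrated outcome is
    forced rather than accidental:

    * v5 follows v4 — gives v5 a second influence source, so with a
      scripted confidence above 1/2 its threshold fails and the dropout
      draw can retire it (narrative: v5 exits to R, it never spreads);
    * v12 follows v5 — creates one pair with a common in-neighbor, so
      intimacy is heterogeneous and pairs with no common neighbors get
      ξ < 1, letting v6's transmission draw fail (narrative: v6 stays S).
    """
    H = DirectedHypergraph(13)
    H.add_edge(EdgeKind.MUTUAL, {4, 5}, {9})         # e3: v5,v6 <-> v10
    H.add_edge(EdgeKind.ONE_WAY, {11, 12}, {9, 10})  # e5: v12,v13 -> v10,v11
    H.add_edge(EdgeKind.ONE_WAY, {4}, {3})           # filler: v5 -> v4
    H.add_edge(EdgeKind.ONE_WAY, {11}, {4})          # filler: v12 -> v5
    return H, [9]


def fig6_attributes(n_nodes: int = 13) -> NodeAttributes:
    """Scripted confidences forcing the narrated thresholds.

    v12 low confidence (activates on one source of three), v13 and v5
    high confidence (thresholds fail with a single infected source).
    """
    C = np.full(n_nodes, 0.5)
    C[11] = 0.3   # v12: theta*K = 0.9 <= 1 infected source -> activates
    C[12] = 0.8   # v13: theta*K = 1.6 > 1 -> fails, dropout draw applies
    C[4] = 0.7    # v5:  theta*K = 1.4 > 1 -> fails, dropout draw applies
    w = -np.log1p(-C)
    return NodeAttributes(w=w, C=C, K=None)


def fig6_draws() -> list[float]:
    """Uniform draws replaying the narrated two steps (see tests).

    Step 1: transmission draws for (v5, v6, v12, v13) from v10 — v6's
    fails against ξ<1 — then v10's recovery draw (γ=0 at t=0).
    Step 2: v6's transmission draw fails again; dropout draws retire v5
    and v13; v12 activates without a draw; v10's recovery draw fails.
    """
    return [
        0.5, 0.9, 0.5, 0.5,   # step 1 transmission: v5 ok, v6 fails, v12 ok, v13 ok
        0.5,                  # step 1 recovery draw for v10 (gamma = 0)
        0.9,                  # step 2 transmission to v6 fails again
        0.0, 0.5,             # step 2 dropout: v5 -> R (eta=0.7), v13 -> R (eta=0.8)
        0.9,                  # step 2 recovery draw for v10 (gamma = 1-e^{-0.1})
    ]
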