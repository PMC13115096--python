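"""Plain-text directed hyperedge-list format (.dhl).

Layout::

    %dihyper v1 nodes=<N>
    # optional comments
    <edge_id>\t<kind>\ttail:v1,v2\thead:v3

one edge per line, ``kind`` in {one_way, mutual}, node ids 0-based.
The writer emits edges in list order with sorted member ids, so output
is byte-stable for a fixed hypergraph.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import TextIO

from .hypergraph import DirectedHypergraph, EdgeKind, HypergraphError

__all__ = ["read_dhl", "write_dhl", "dumps_dhl", "loads_dhl"]

_HEADER_PREFIX = "%dihyper v1 nodes="


def write_dhl(H: DirectedHypergraph, path: str | Path | TextIO) -> None:
    if hasattr(path, "write"):
        path.write(dumps_dhl(H))
    else:
        Path(path).write_text(dumps_dhl(H))


def dumps_dhl(H: DirectedHypergraph) -> str:
    lines = [f"{_HEADER_PREFIX}{H.n_nodes}"]
    for e in H.edges:
        tail = ",".join(str(v) for v in sorted(e.tail))
        head = ",".join(str(v) for v in sorted(e.head))
        lines.append(f"{e.id}\t{e.kind.value}\ttail:{tail}\thead:{head}")
    return "\n".join(lines) + "\n"


def read_dhl(path: str | Path | TextIO) -> DirectedHypergraph:
    if hasattr(path, "read"):
        return loads_dhl(path.read())
    return loads_dhl(Path(path).read_text())


def loads_dhl(text: str) -> DirectedHypergraph:
    lines = [ln.strip() for ln in _io.StringIO(text)]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines or not lines[0].startswith(_HEADER_PREFIX):
        raise HypergraphError(f"missing header line '{_HEADER_PREFIX}<N>'")
    n_nodes = int(lines[0][len(_HEADER_PREFIX):])
    H = DirectedHypergraph(n_nodes)
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != 4:
            raise HypergraphError(f"malformed edge line: {ln!r}")
        edge_id, kind_s, tail_s, head_s = parts
        if not tail_s.startswith("tail:") or not head_s.startswith("head:"):
            raise HypergraphError(f"malformed edge line: {ln!r}")
        try:
            kind = EdgeKind(kind_s)
        except ValueError as exc:
            raise HypergraphError(f"unknown edge kind {kind_s!r}") from exc
        tail = {int(v) for v in tail_s[5:].split(",") if v != ""}
        head = {int(v) for v in head_s[5:].split(",") if v != ""}
        edge = H.add_edge(kind, tail, head)
        if edge.id != int(edge_id):
            raise HypergraphError(
                f"edge id {edge_id} out of order (expected {edge.id})"
            )
    return H
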