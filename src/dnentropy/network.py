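"""Directed regulatory-network container with edge provenance.

Edges carry a status — ``confirmed`` (present in the prior literature
network), ``unconfirmed`` (inferred only), or ``candidate-added`` (accepted
by the entropy screen) — and the set of plateau-interval indices that
contributed them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

__all__ = ["RegNetwork", "EDGE_STATUSES"]

EDGE_STATUSES = ("confirmed", "unconfirmed", "candidate-added")


@dataclass
class RegNetwork:
    """Directed graph over genes; per-interval subgraphs are acyclic."""

    nodes: list[str]
    edges: dict[tuple[str, str], str] = field(default_factory=dict)
    provenance: dict[tuple[str, str], frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = [str(n) for n in self.nodes]
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate nodes")
        for (u, v), status in self.edges.items():
            if u == v:
                raise ValueError(f"self-loop {u}->{v}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge {u}->{v} references unknown gene")
            if status not in EDGE_STATUSES:
                raise ValueError(f"bad status {status!r} on {u}->{v}")
        self.provenance = {
            e: frozenset(self.provenance.get(e, frozenset())) for e in self.edges
        }

    # -- construction --------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        nodes: Sequence[str],
        edges: Iterable[tuple[str, str]],
        status: str = "unconfirmed",
    ) -> "RegNetwork":
        return cls(list(nodes), {tuple(e): status for e in edges})

    def copy(self) -> "RegNetwork":
        return RegNetwork(list(self.nodes), dict(self.edges), dict(self.provenance))

    def with_edge(self, u: str, v: str, status: str = "unconfirmed") -> "RegNetwork":
        out = self.copy()
        out.edges[(u, v)] = status
        out.provenance[(u, v)] = self.provenance.get((u, v), frozenset())
        return out

    def without_node(self, node: str) -> "RegNetwork":
        if node not in self.nodes:
            raise KeyError(f"unknown gene {node!r}")
        edges = {e: s for e, s in self.edges.items() if node not in e}
        prov = {e: self.provenance[e] for e in edges}
        return RegNetwork([n for n in self.nodes if n != node], edges, prov)

    # -- views ---------------------------------------------------------
    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edges_with_status(self, status: str) -> list[tuple[str, str]]:
        return [e for e, s in self.edges.items() if s == status]

    def neighbors(self, node: str) -> list[str]:
        """Undirected neighborhood: in- plus out-edges, order of self.nodes."""
        if node not in self.nodes:
            raise KeyError(f"unknown gene {node!r}")
        nbrs = {v for (u, v) in self.edges if u == node}
        nbrs |= {u for (u, v) in self.edges if v == node}
        return [n for n in self.nodes if n in nbrs]

    def parents(self, node: str) -> list[str]:
        return [u for (u, v) in self.edges if v == node]

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (u, v), s in self.edges.items():
            g.add_edge(u, v, status=s, intervals=sorted(self.provenance.get((u, v), ())))
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_digraph())

    # -- TSV edge-list dialect ------------------------------------------
    def write_tsv(self, path: str | Path) -> None:
        lines = ["source\ttarget\tstatus\tintervals"]
        for (u, v), s in sorted(self.edges.items()):
            ivals = ",".join(str(i) for i in sorted(self.provenance.get((u, v), ())))
            lines.append(f"{u}\t{v}\t{s}\t{ivals}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path, nodes: Sequence[str] | None = None) -> "RegNetwork":
        edges: dict[tuple[str, str], str] = {}
        prov: dict[tuple[str, str], frozenset[int]] = {}
        seen: list[str] = []
        for line in Path(path).read_text().splitlines()[1:]:
            if not line.strip():
                continue
            parts = line.split("\t")
            u, v, status = parts[0], parts[1], parts[2] if len(parts) > 2 else "unconfirmed"
            ivals = parts[3] if len(parts) > 3 else ""
            edges[(u, v)] = status
            prov[(u, v)] = frozenset(int(x) for x in ivals.split(",") if x)
            for n in (u, v):
                if n not in seen:
                    seen.append(n)
        return cls(list(nodes) if nodes is not None else seen, edges, prov)
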