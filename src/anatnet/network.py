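"""Data model for anatomical networks.

An anatomical network represents an anatomical system (a head, a forelimb,
a hindlimb, ...) as an unweighted, undirected, simple graph: bones and
muscles are nodes, and a link joins two nodes whenever the corresponding
structures are in physical contact.  Nodes carry two categorical
attributes: the tissue type (bone, muscle, or other) and the body side
(left, right, midline, or unspecified), inferred from naming conventions
such as ``Temporal.Right``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "Tissue",
    "Side",
    "AnatomicalNode",
    "AnatomicalNetwork",
    "subset_by_tissue",
]


class Tissue(str, Enum):
    """Tissue type of an anatomical structure."""

    BONE = "bone"
    MUSCLE = "muscle"
    OTHER = "other"


class Side(str, Enum):
    """Body side of an anatomical structure."""

    LEFT = "left"
    RIGHT = "right"
    MIDLINE = "midline"
    UNSPECIFIED = "unspecified"


def _coerce_tissue(value: "Tissue | str") -> Tissue:
    if isinstance(value, Tissue):
        return value
    try:
        return Tissue(str(value).lower())
    except ValueError as exc:
        raise ValueError(
            f"invalid tissue {value!r}; expected one of "
            f"{[t.value for t in Tissue]}"
        ) from exc


def _coerce_side(value: "Side | str") -> Side:
    if isinstance(value, Side):
        return value
    try:
        return Side(str(value).lower())
    except ValueError as exc:
        raise ValueError(
            f"invalid side {value!r}; expected one of "
            f"{[s.value for s in Side]}"
        ) from exc


@dataclass(frozen=True)
class AnatomicalNode:
    """A single anatomical structure.

    Parameters
    ----------
    label : str
        Unique (case-sensitive), non-empty anatomical name,
        e.g. ``"Masseter.Left"``.
    tissue : Tissue or str
        Tissue type; defaults to ``other``.
    side : Side or str
        Body side; defaults to ``unspecified``.
    """

    label: str
    tissue: Tissue = Tissue.OTHER
    side: Side = Side.UNSPECIFIED

    def __post_init__(self) -> None:
        if not isinstance(self.label, str) or not self.label:
            raise ValueError("node label must be a non-empty string")
        object.__setattr__(self, "tissue", _coerce_tissue(self.tissue))
        object.__setattr__(self, "side", _coerce_side(self.side))


class AnatomicalNetwork:
    """Undirected simple graph of tissue-typed anatomical structures.

    Nodes are kept in insertion order; that order is the canonical node
    order used by deterministic downstream algorithms.  Self-loops and
    duplicate edges are rejected/ignored so the simple-graph invariant
    always holds.

    Parameters
    ----------
    nodes : iterable of AnatomicalNode or str
        Node declarations.  Bare strings become ``other``/``unspecified``
        nodes.
    edges : iterable of (str, str)
        Unordered label pairs; every endpoint must be a declared node.
    """

    def __init__(
        self,
        nodes: Iterable["AnatomicalNode | str"] = (),
        edges: Iterable[tuple[str, str]] = (),
    ) -> None:
        self._g = nx.Graph()
        for node in nodes:
            self.add_node(node)
        for u, v in edges:
            self.add_edge(u, v)

    # -- construction -------------------------------------------------

    def add_node(self, node: "AnatomicalNode | str") -> None:
        if isinstance(node, str):
            node = AnatomicalNode(node)
        if node.label in self._g:
            raise ValueError(f"duplicate node label {node.label!r}")
        self._g.add_node(node.label, tissue=node.tissue, side=node.side)

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError(f"self-loop on node {u!r} is not allowed")
        for endpoint in (u, v):
            if endpoint not in self._g:
                raise KeyError(f"edge endpoint {endpoint!r} is not a declared node")
        self._g.add_edge(u, v)

    @classmethod
    def from_networkx(cls, graph: nx.Graph) -> "AnatomicalNetwork":
        """Build a network from a networkx graph with optional
        ``tissue``/``side`` node attributes."""
        net = cls()
        for label, data in graph.nodes(data=True):
            net.add_node(
                AnatomicalNode(
                    str(label),
                    data.get("tissue", Tissue.OTHER),
                    data.get("side", Side.UNSPECIFIED),
                )
            )
        for u, v in graph.edges():
            if u == v:
                continue
            net.add_edge(str(u), str(v))
        return net

    # -- inspection ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        """Number of nodes N (anatomical structures, isolates included)."""
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        """Number of links K (physical contacts)."""
        return self._g.number_of_edges()

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self._g.nodes)

    @property
    def nodes(self) -> tuple[AnatomicalNode, ...]:
        return tuple(
            AnatomicalNode(lbl, d["tissue"], d["side"])
            for lbl, d in self._g.nodes(data=True)
        )

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self._g.edges()}

    def node(self, label: str) -> AnatomicalNode:
        d = self._g.nodes[label]
        return AnatomicalNode(label, d["tissue"], d["side"])

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def degree(self, label: str) -> int:
        return self._g.degree[label]

    def degrees(self) -> dict[str, int]:
        return dict(self._g.degree())

    def neighbors(self, label: str) -> Iterator[str]:
        return iter(self._g[label])

    def to_networkx(self) -> nx.Graph:
        """Return a copy as a networkx graph (string-valued attributes)."""
        g = nx.Graph()
        for lbl, d in self._g.nodes(data=True):
            g.add_node(lbl, tissue=d["tissue"].value, side=d["side"].value)
        g.add_edges_from(self._g.edges())
        return g

    def copy(self) -> "AnatomicalNetwork":
        return AnatomicalNetwork(self.nodes, [tuple(e) for e in self.edges])

    def relabel(self, mapping: Mapping[str, str]) -> "AnatomicalNetwork":
        """Return a copy with node labels replaced per ``mapping``
        (labels absent from the mapping are kept)."""
        new = AnatomicalNetwork()
        for node in self.nodes:
            new.add_node(
                AnatomicalNode(mapping.get(node.label, node.label), node.tissue, node.side)
            )
        for u, v in self._g.edges():
            new.add_edge(mapping.get(u, u), mapping.get(v, v))
        return new

    def subgraph(self, keep_labels: Iterable[str]) -> "AnatomicalNetwork":
        """Induced subgraph on ``keep_labels`` (input node order preserved)."""
        keep = set(keep_labels)
        unknown = keep - set(self._g.nodes)
        if unknown:
            raise KeyError(f"unknown node labels: {sorted(unknown)}")
        new = AnatomicalNetwork()
        for node in self.nodes:
            if node.label in keep:
                new.add_node(node)
        for u, v in self._g.edges():
            if u in keep and v in keep:
                new.add_edge(u, v)
        return new

    def __contains__(self, label: str) -> bool:
        return label in self._g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnatomicalNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"AnatomicalNetwork(N={self.n_nodes}, K={self.n_edges})"


def subset_by_tissue(
    network: AnatomicalNetwork, keep: Iterable["Tissue | str"]
) -> AnatomicalNetwork:
    """Induced subgraph on nodes whose tissue is in ``keep``.

    The skeletal view keeps ``{bone}``, the muscular view ``{muscle}``,
    and the full musculoskeletal view keeps everything.

    Raises
    ------
    ValueError
        If ``keep`` is empty.
    """
    keep_set = {_coerce_tissue(t) for t in keep}
    if not keep_set:
        raise ValueError("keep set must contain at least one tissue type")
    return network.subgraph(
        node.label for node in network.nodes if node.tissue in keep_set
    )
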