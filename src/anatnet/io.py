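"""Readers and writers for anatomical networks.

Supported formats:

``adjacency_csv``
    A labeled square binary matrix: first row and first column hold the
    node labels (same strings, same order), cells are 0/1 presence of
    contact, diagonal is zero, matrix is symmetric.  This is the
    spreadsheet-export dialect in which anatomical contact matrices are
    typically distributed.  A sidecar ``<stem>.types.csv`` manifest
    (``label,tissue,side``) carries node attributes; when absent, tissue
    falls back to a user mapping and side to a label-suffix rule.

``edgelist``
    A single self-contained CSV with a ``[nodes]`` manifest section
    (``label,tissue,side``) followed by an ``[edges]`` section
    (``source,target``).  Isolated nodes survive round trips because the
    manifest lists every node.

``graphml``
    Standard GraphML with node attributes ``tissue`` and ``side``.

Validation is strict: a non-square matrix, mismatched labels, non-binary
or blank cells, an asymmetric cell pair, or a nonzero diagonal all raise
:class:`AdjacencyMatrixError` — such defects are data-entry bugs and are
never silently repaired.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .network import AnatomicalNetwork, AnatomicalNode, Side, Tissue, _coerce_tissue

__all__ = [
    "AdjacencyMatrixError",
    "SideRule",
    "read_adjacency",
    "read_graph",
    "write_graph",
    "load_config",
]

FORMATS = ("graphml", "edgelist", "adjacency_csv")


class AdjacencyMatrixError(ValueError):
    """A labeled binary contact matrix violated its format contract."""


@dataclass(frozen=True)
class SideRule:
    """Label-suffix rule used to infer the body side of a structure.

    The defaults match the common naming convention for bilateral
    structures (``Temporal.Right``, ``Masseter.Left``).  Matching is a
    case-sensitive substring test; labels matching neither token are
    ``unspecified``.
    """

    left_token: str = ".Left"
    right_token: str = ".Right"

    def side_of(self, label: str) -> Side:
        if self.left_token and self.left_token in label:
            return Side.LEFT
        if self.right_token and self.right_token in label:
            return Side.RIGHT
        return Side.UNSPECIFIED

    def strip(self, label: str) -> str:
        """Remove the side token so homonymous left/right structures map
        to the same normalized name."""
        return label.replace(self.left_token, "").replace(self.right_token, "")


DEFAULT_SIDE_RULE = SideRule()


def _types_sidecar(path: Path) -> Path:
    return path.with_suffix(".types.csv")


def _read_manifest_rows(rows) -> list[AnatomicalNode]:
    nodes = []
    for row in rows:
        if not row or not row[0]:
            continue
        label = row[0]
        tissue = row[1] if len(row) > 1 and row[1] else "other"
        side = row[2] if len(row) > 2 and row[2] else "unspecified"
        nodes.append(AnatomicalNode(label, tissue, side))
    return nodes


def read_adjacency(
    path,
    tissue_map: Mapping[str, "Tissue | str"] | None = None,
    side_rule: SideRule | None = None,
) -> AnatomicalNetwork:
    """Read a labeled square binary contact matrix into a network.

    Parameters
    ----------
    path : path-like
        CSV file; first row and first column are node labels.
    tissue_map : mapping, optional
        label -> tissue for nodes; unlisted labels become ``other``.
        When omitted and a ``<stem>.types.csv`` sidecar exists next to
        ``path``, the sidecar supplies tissues and sides instead.
    side_rule : SideRule, optional
        Suffix rule for inferring sides; defaults to ``.Left``/``.Right``
        substring matching.

    Returns
    -------
    AnatomicalNetwork
        The edge set is exactly the upper-triangle 1-cells; isolated
        nodes (all-zero rows) are retained, so N equals the label count.
    """
    path = Path(path)
    side_rule = side_rule or DEFAULT_SIDE_RULE
    try:
        frame = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - re-raise with format context
        raise AdjacencyMatrixError(f"{path}: cannot parse as labeled CSV matrix: {exc}")

    labels = [str(x) for x in frame.index]
    col_labels = [str(x) for x in frame.columns]
    if len(labels) != len(col_labels):
        raise AdjacencyMatrixError(
            f"{path}: matrix is not square ({len(labels)} rows, {len(col_labels)} columns)"
        )
    if labels != col_labels:
        bad = next(
            (i for i, (r, c) in enumerate(zip(labels, col_labels)) if r != c), None
        )
        raise AdjacencyMatrixError(
            f"{path}: row/column labels differ (first mismatch at position {bad}: "
            f"{labels[bad]!r} vs {col_labels[bad]!r})"
        )
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise AdjacencyMatrixError(f"{path}: duplicate labels {dupes}")

    raw = frame.to_numpy()
    cells = np.empty(raw.shape, dtype=int)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            value = str(raw[i, j]).strip().strip('"').strip("'")
            if value not in ("0", "1"):
                raise AdjacencyMatrixError(
                    f"{path}: non-binary cell at ({labels[i]!r}, {labels[j]!r}): "
                    f"{raw[i, j]!r}"
                )
            cells[i, j] = int(value)

    if np.any(np.diag(cells) != 0):
        k = int(np.flatnonzero(np.diag(cells))[0])
        raise AdjacencyMatrixError(f"{path}: nonzero diagonal at {labels[k]!r}")
    asym = np.argwhere(cells != cells.T)
    if asym.size:
        i, j = asym[0]
        raise AdjacencyMatrixError(
            f"{path}: asymmetric cell pair ({labels[i]!r}, {labels[j]!r}): "
            f"cell ({i},{j})={cells[i, j]} but ({j},{i})={cells[j, i]}"
        )

    # node attributes: explicit map > sidecar manifest > suffix rule
    sidecar = _types_sidecar(path)
    manifest: dict[str, AnatomicalNode] = {}
    if tissue_map is None and sidecar.exists():
        with open(sidecar, newline="") as fh:
            rows = list(csv.reader(fh))
        if rows and rows[0][:1] == ["label"]:
            rows = rows[1:]
        manifest = {n.label: n for n in _read_manifest_rows(rows)}

    net = AnatomicalNetwork()
    for label in labels:
        if label in manifest:
            net.add_node(manifest[label])
        else:
            tissue = Tissue.OTHER
            if tissue_map is not None and label in tissue_map:
                tissue = _coerce_tissue(tissue_map[label])
            net.add_node(AnatomicalNode(label, tissue, side_rule.side_of(label)))
    for i, j in zip(*np.triu_indices(len(labels), k=1)):
        if cells[i, j]:
            net.add_edge(labels[i], labels[j])
    return net


def _write_adjacency(network: AnatomicalNetwork, path: Path) -> None:
    labels = network.labels
    n = len(labels)
    cells = np.zeros((n, n), dtype=int)
    index = {lbl: i for i, lbl in enumerate(labels)}
    for e in network.edges:
        u, v = tuple(e)
        cells[index[u], index[v]] = cells[index[v], index[u]] = 1
    pd.DataFrame(cells, index=labels, columns=labels).to_csv(path)
    with open(_types_sidecar(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "tissue", "side"])
        for node in network.nodes:
            writer.writerow([node.label, node.tissue.value, node.side.value])


def _write_edgelist(network: AnatomicalNetwork, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["[nodes]"])
        writer.writerow(["label", "tissue", "side"])
        for node in network.nodes:
            writer.writerow([node.label, node.tissue.value, node.side.value])
        writer.writerow(["[edges]"])
        writer.writerow(["source", "target"])
        for u, v in sorted(tuple(sorted(e)) for e in network.edges):
            writer.writerow([u, v])


def _read_edgelist(path: Path) -> AnatomicalNetwork:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    try:
        nodes_at = next(i for i, r in enumerate(rows) if r[:1] == ["[nodes]"])
        edges_at = next(i for i, r in enumerate(rows) if r[:1] == ["[edges]"])
    except StopIteration:
        raise AdjacencyMatrixError(
            f"{path}: edge list must contain [nodes] and [edges] sections"
        )
    node_rows = [r for r in rows[nodes_at + 1 : edges_at] if r and r[0] != "label"]
    edge_rows = [r for r in rows[edges_at + 1 :] if r and r[0] != "source"]
    net = AnatomicalNetwork(_read_manifest_rows(node_rows))
    for row in edge_rows:
        net.add_edge(row[0], row[1])
    return net


def write_graph(network: AnatomicalNetwork, path, format: str) -> Path:
    """Write a network to ``path`` in one of :data:`FORMATS`.

    Round-trip guarantee: ``read_graph(write_graph(x, ...))`` reproduces
    node labels, tissues, sides, and the edge set exactly.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network.to_networkx(), path)
    elif format == "edgelist":
        _write_edgelist(network, path)
    elif format == "adjacency_csv":
        _write_adjacency(network, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    return path


def read_graph(path, format: str, **kwargs) -> AnatomicalNetwork:
    """Read a network written by :func:`write_graph` (or any compatible
    file in one of the supported formats)."""
    path = Path(path)
    if format == "graphml":
        return AnatomicalNetwork.from_networkx(nx.read_graphml(path))
    if format == "edgelist":
        return _read_edgelist(path)
    if format == "adjacency_csv":
        return read_adjacency(path, **kwargs)
    raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


def load_config(path) -> dict:
    """Load a YAML/JSON key-value config file.

    Recognized keys: ``tissue_map`` (label -> tissue), ``side_rule``
    (``left_token``/``right_token``), ``steps``, ``seed``.
    """
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    if "side_rule" in config:
        rule = config["side_rule"]
        config["side_rule"] = SideRule(
            left_token=rule.get("left_token", ".Left"),
            right_token=rule.get("right_token", ".Right"),
        )
    return config
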