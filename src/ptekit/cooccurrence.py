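"""The weighted quote co-occurrence network.

Every pair of quotes that at least one sorter placed in the same pile is
joined by an edge.  The canonical stored quantity is the co-sort count
``c_ij`` (number of sorters who co-piled the pair); the inverse weight
``w_ij = 1/c_ij`` attached to each edge is derived on demand so that
``w_ij * c_ij == 1`` holds exactly.  With two of nine sorters co-piling a
pair, the edge weight is exactly 1/2.

Downstream consumers choose how to read the edges:

* *similarity* mode exposes ``A_ij = c_ij`` — edge strength, used by
  modularity and greedy merging;
* *distance* mode exposes ``w_ij = 1/c_ij`` — edge length, used for
  shortest paths, so strongly co-sorted quotes are close.
"""

from __future__ import annotations

import json
from itertools import combinations
from pathlib import Path
from typing import IO, Optional, Union

import networkx as nx

from .errors import InputError, ValidationError
from .pilesort_data import SortingStudy, sorter_partition

__all__ = [
    "CooccurrenceNetwork",
    "cooccurrence_count",
    "build_network",
    "export_network",
    "read_network",
    "FORMATS",
]

FORMATS = ("graphml", "edgelist", "json")


class CooccurrenceNetwork:
    """Undirected quote network with integer co-sort counts on edges.

    Parameters
    ----------
    graph
        Undirected simple graph whose edges carry an integer ``count``
        attribute with ``1 <= count <= n_sorters``.  Nodes without edges
        (quotes never co-sorted with anything) are legal and kept.
    n_sorters
        Size S of the sorter panel the network was built from; the upper
        bound on any count.
    """

    def __init__(self, graph: nx.Graph, n_sorters: int):
        if n_sorters < 1:
            raise ValidationError("n_sorters must be >= 1")
        for u, v, data in graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            c = data.get("count")
            if not isinstance(c, int) or isinstance(c, bool):
                raise ValidationError(f"edge ({u!r},{v!r}) has non-integer count {c!r}")
            if not 1 <= c <= n_sorters:
                raise ValidationError(
                    f"edge ({u!r},{v!r}) count {c} outside [1, {n_sorters}]"
                )
        self._graph = graph
        self.n_sorters = n_sorters

    # -- views -------------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return sorted(self._graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, int]]:
        """Sorted (i, j, count) triples with i < j."""
        out = []
        for u, v, data in self._graph.edges(data=True):
            i, j = sorted((u, v))
            out.append((i, j, data["count"]))
        return sorted(out)

    def has_edge(self, i: str, j: str) -> bool:
        return self._graph.has_edge(i, j)

    def count(self, i: str, j: str) -> int:
        """Co-sort count c_ij; 0 when no edge."""
        if self._graph.has_edge(i, j):
            return self._graph[i][j]["count"]
        if i not in self._graph or j not in self._graph:
            raise ValidationError(f"unknown node in pair ({i!r}, {j!r})")
        return 0

    def weight(self, i: str, j: str) -> float:
        """Inverse-count edge weight w_ij = 1/c_ij (edge must exist)."""
        if not self._graph.has_edge(i, j):
            raise ValidationError(f"no edge between {i!r} and {j!r}")
        return 1.0 / self._graph[i][j]["count"]

    def similarity_graph(self) -> nx.Graph:
        """Copy with edge attribute ``weight = c_ij`` (strength A_ij)."""
        g = nx.Graph()
        g.add_nodes_from(self._graph.nodes)
        for u, v, data in self._graph.edges(data=True):
            g.add_edge(u, v, weight=data["count"], count=data["count"])
        return g

    def distance_graph(self) -> nx.Graph:
        """Copy with edge attribute ``weight = 1/c_ij`` (length w_ij)."""
        g = nx.Graph()
        g.add_nodes_from(self._graph.nodes)
        for u, v, data in self._graph.edges(data=True):
            g.add_edge(u, v, weight=1.0 / data["count"], count=data["count"])
        return g

    def __eq__(self, other) -> bool:
        if not isinstance(other, CooccurrenceNetwork):
            return NotImplemented
        return (
            self.n_sorters == other.n_sorters
            and set(self.nodes) == set(other.nodes)
            and self.edges() == other.edges()
        )

    def __repr__(self) -> str:
        return (
            f"CooccurrenceNetwork({self.n_nodes} nodes, {self.n_edges} edges, "
            f"S={self.n_sorters})"
        )


# ---------------------------------------------------------------------------
# Construction


def cooccurrence_count(study: SortingStudy, i: str, j: str) -> int:
    """Number of sorters whose piles place quotes *i* and *j* together.

    Symmetric in (i, j); self-pairs are undefined.
    """
    if i == j:
        raise ValidationError("co-occurrence of a quote with itself is undefined")
    known = set(study.quotes)
    for q in (i, j):
        if q not in known:
            raise ValidationError(f"unknown quote id {q!r}")
    n = 0
    for s in study.sorters:
        pi = study.pile_of(s, i)
        if pi is not None and pi == study.pile_of(s, j):
            n += 1
    return n


def build_network(study: SortingStudy) -> CooccurrenceNetwork:
    """Build the co-occurrence network of a study.

    One node per quote (quotes never co-sorted stay as isolated nodes); one
    edge per pair with ``c_ij >= 1``.  Deterministic.
    """
    if study.n_quotes < 2:
        raise ValidationError("a network needs at least 2 quotes")
    if study.n_sorters < 1:
        raise ValidationError("a network needs at least 1 sorter")
    counts: dict[tuple[str, str], int] = {}
    for s in study.sorters:
        part = sorter_partition(study, s)
        for members in part.groups.values():
            for i, j in combinations(sorted(members), 2):
                counts[(i, j)] = counts.get((i, j), 0) + 1
    g = nx.Graph()
    g.add_nodes_from(study.quote_ids)
    for (i, j), c in counts.items():
        g.add_edge(i, j, count=c)
    return CooccurrenceNetwork(g, n_sorters=study.n_sorters)


# ---------------------------------------------------------------------------
# Serialisation

_HEADER_PREFIX = "# ptekit-network n_sorters="


def export_network(
    net: CooccurrenceNetwork,
    dest: Union[str, Path, IO[str]],
    format: str = "graphml",
) -> None:
    """Write a network to ``dest`` in one of :data:`FORMATS`.

    Every format carries node ids and, per edge, both the count ``c_ij`` and
    the weight ``w_ij`` as named attributes; re-import reproduces the network
    exactly (weights are recomputed from counts on read).
    """
    if format not in FORMATS:
        raise InputError(f"unknown network format {format!r}; choose from {FORMATS}")

    if format == "graphml":
        g = nx.Graph(n_sorters=net.n_sorters)
        g.add_nodes_from(net.nodes)
        for i, j, c in net.edges():
            g.add_edge(i, j, count=c, weight=1.0 / c)
        if hasattr(dest, "write"):
            nx.write_graphml(g, dest)
        else:
            nx.write_graphml(g, str(dest))
        return

    if format == "edgelist":
        lines = [f"{_HEADER_PREFIX}{net.n_sorters}", "source,target,count,weight"]
        covered: set[str] = set()
        for i, j, c in net.edges():
            lines.append(f"{i},{j},{c},{1.0 / c!r}")
            covered.update((i, j))
        for node in net.nodes:
            if node not in covered:
                lines.append(f"{node},,,")
        text = "\n".join(lines) + "\n"
    else:  # json
        payload = {
            "n_sorters": net.n_sorters,
            "nodes": [{"id": n} for n in net.nodes],
            "links": [
                {"source": i, "target": j, "count": c, "weight": 1.0 / c}
                for i, j, c in net.edges()
            ],
        }
        text = json.dumps(payload, indent=1, sort_keys=True) + "\n"

    if hasattr(dest, "write"):
        dest.write(text)  # type: ignore[union-attr]
    else:
        Path(dest).write_text(text, encoding="utf-8")  # type: ignore[arg-type]


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".graphml":
        return "graphml"
    if suffix == ".json":
        return "json"
    if suffix in (".csv", ".edgelist", ".txt"):
        return "edgelist"
    raise InputError(f"cannot infer network format from {path.name!r}")


def read_network(
    source: Union[str, Path], format: Optional[str] = None
) -> CooccurrenceNetwork:
    """Read a network previously written by :func:`export_network`."""
    path = Path(source)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if format is None:
        format = _infer_format(path)
    if format not in FORMATS:
        raise InputError(f"unknown network format {format!r}; choose from {FORMATS}")

    if format == "graphml":
        g_in = nx.read_graphml(str(path))
        n_sorters = int(g_in.graph.get("n_sorters", 0)) or None
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in g_in.nodes)
        max_c = 1
        for u, v, data in g_in.edges(data=True):
            c = int(data["count"])
            max_c = max(max_c, c)
            g.add_edge(str(u), str(v), count=c)
        return CooccurrenceNetwork(g, n_sorters=n_sorters or max_c)

    if format == "edgelist":
        lines = path.read_text(encoding="utf-8").splitlines()
        if not lines or not lines[0].startswith(_HEADER_PREFIX):
            raise InputError(f"{path.name}: missing ptekit network header line")
        n_sorters = int(lines[0][len(_HEADER_PREFIX):])
        if len(lines) < 2 or lines[1] != "source,target,count,weight":
            raise InputError(f"{path.name}: unexpected edge-list columns")
        g = nx.Graph()
        for line in lines[2:]:
            if not line.strip():
                continue
            src, tgt, c, _w = line.split(",")
            if tgt == "":
                g.add_node(src)
            else:
                g.add_nodes_from((src, tgt))
                g.add_edge(src, tgt, count=int(c))
        return CooccurrenceNetwork(g, n_sorters=n_sorters)

    payload = json.loads(path.read_text(encoding="utf-8"))
    g = nx.Graph()
    g.add_nodes_from(n["id"] for n in payload["nodes"])
    for link in payload["links"]:
        g.add_edge(link["source"], link["target"], count=int(link["count"]))
    return CooccurrenceNetwork(g, n_sorters=int(payload["n_sorters"]))
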