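"""Plain-text I/O for PPI networks, module sets and annotation tables.

Networks are simple undirected graphs over opaque, case-sensitive protein
identifiers.  On read, self-loops are dropped and duplicate edges (in either
orientation) are collapsed, so every stored network satisfies the simple-graph
invariants by construction.  Module files follow the MIPS-complex convention
of one tab-separated module per line; annotation tables are two-column
(protein, term) TSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "PPINetwork",
    "ModuleSet",
    "AnnotationTable",
    "ReadReport",
    "ParseError",
    "read_edge_list",
    "read_module_set",
    "write_module_set",
    "read_annotations",
]


class ParseError(ValueError):
    """A text input line could not be interpreted."""


@dataclass
class ReadReport:
    """Counts of lines dropped or normalized while parsing an edge list."""

    data_lines: int = 0
    self_loops: int = 0
    duplicate_edges: int = 0
    comment_lines: int = 0
    blank_lines: int = 0


def _canonical(u: str, v: str) -> tuple[str, str]:
    """Lexicographically ordered pair, the canonical edge representation."""
    return (u, v) if u <= v else (v, u)


class PPINetwork:
    """Simple undirected protein-protein interaction network.

    Thin wrapper around :class:`networkx.Graph` that guarantees the graph is
    simple (no self-loops, no parallel edges) and exposes the quantities the
    density-modularity formulas need: the node set, canonical edge set, the
    total edge count ``L`` and per-node degrees.
    """

    def __init__(self, graph: nx.Graph | None = None,
                 report: ReadReport | None = None):
        g = nx.Graph() if graph is None else graph
        loops = list(nx.selfloop_edges(g))
        if loops:
            raise ValueError(f"network contains self-loops: {loops[:3]}")
        self._graph = g
        self.report = report

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]],
                   nodes: Iterable[str] = ()) -> "PPINetwork":
        """Build a network from raw pairs, dropping loops and duplicates."""
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v in edges:
            g.add_node(u)
            g.add_node(v)
            if u != v:
                g.add_edge(*_canonical(u, v))
        return cls(g)

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {_canonical(u, v) for u, v in self._graph.edges}

    @property
    def L(self) -> int:
        """Total number of edges in the network."""
        return self._graph.number_of_edges()

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    def degree(self, node: str) -> int:
        return self._graph.degree[node]

    def neighbors(self, node: str) -> Iterator[str]:
        return self._graph.neighbors(node)

    def __contains__(self, node: str) -> bool:
        return node in self._graph

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PPINetwork(n_nodes={self.n_nodes}, L={self.L})"


@dataclass(frozen=True)
class ModuleSet:
    """Ordered collection of labelled protein sets.

    Used both for predicted functional modules (pairwise disjoint) and for
    reference complexes (which may share proteins).  Labels are unique and
    every module is non-empty.
    """

    modules: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self):
        labels = [lab for lab, _ in self.modules]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate module labels")
        for lab, members in self.modules:
            if not members:
                raise ValueError(f"module {lab!r} is empty")

    @classmethod
    def from_sets(cls, sets: Iterable[Iterable[str]],
                  prefix: str = "m") -> "ModuleSet":
        mods = tuple((f"{prefix}{i + 1}", frozenset(s))
                     for i, s in enumerate(sets))
        return cls(mods)

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.modules]

    def sets(self) -> list[frozenset[str]]:
        return [members for _, members in self.modules]

    def sizes(self) -> list[int]:
        return [len(members) for _, members in self.modules]

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)


@dataclass(frozen=True)
class AnnotationTable:
    """Function term -> protein set mapping over a genome background of size N."""

    entries: Mapping[str, frozenset[str]]
    genome_size: int

    def __post_init__(self):
        if self.genome_size < 1:
            raise ValueError("genome_size must be positive")
        for term, prots in self.entries.items():
            if not prots:
                raise ValueError(f"term {term!r} has an empty protein set")
            if len(prots) > self.genome_size:
                raise ValueError(
                    f"term {term!r} annotates {len(prots)} proteins, more "
                    f"than genome_size={self.genome_size}")

    def __len__(self) -> int:
        return len(self.entries)


def read_edge_list(path: str | Path, format: str = "tsv") -> PPINetwork:
    """Read an interaction network from a TSV edge list or a SIF file.

    Preprocessing mirrors the published protocol: self-loops and redundant
    (duplicate or reverse-duplicate) edges are removed.  Nodes named only in
    dropped lines are retained as isolated nodes.  Lines starting with ``#``
    are comments.  A :class:`ReadReport` of dropped-line counts is attached to
    the returned network as ``.report``.

    Parameters
    ----------
    path
        Input file path.
    format
        ``"tsv"`` (two or more whitespace/tab-separated columns, one
        interaction per line; extra columns ignored with a warning) or
        ``"sif"`` (``node  relation  node [node ...]``).
    """
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format {format!r}")
    report = ReadReport()
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    warned_extra = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                report.blank_lines += 1
                continue
            if line.startswith("#"):
                report.comment_lines += 1
                continue
            fields = line.split()
            report.data_lines += 1
            if format == "tsv":
                if len(fields) < 2:
                    raise ParseError(
                        f"{path}: line {lineno}: expected at least 2 "
                        f"fields, got {len(fields)}")
                if len(fields) > 2 and not warned_extra:
                    warnings.warn(
                        f"{path}: extra columns beyond the first two are "
                        "ignored (the method is unweighted)", stacklevel=2)
                    warned_extra = True
                pairs = [(fields[0], fields[1])]
            else:  # sif
                if len(fields) < 3:
                    raise ParseError(
                        f"{path}: line {lineno}: SIF line needs "
                        f"'node relation node...', got {len(fields)} fields")
                pairs = [(fields[0], t) for t in fields[2:]]
            for u, v in pairs:
                nodes.update((u, v))
                if u == v:
                    report.self_loops += 1
                    continue
                key = _canonical(u, v)
                if key in edges:
                    report.duplicate_edges += 1
                else:
                    edges.add(key)
    net = PPINetwork.from_edges(edges, nodes=nodes)
    net.report = report
    return net


def read_module_set(path: str | Path, labels: bool = True) -> ModuleSet:
    """Read one module per line; duplicate protein IDs within a line collapse.

    With ``labels=True`` the first field of each line is the module label;
    otherwise labels ``m1, m2, ...`` are generated in file order.  Blank
    module lines are skipped with a warning; duplicate labels are an error.
    """
    modules: list[tuple[str, frozenset[str]]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if line.startswith("#"):
                continue
            fields = line.split()
            if labels and fields:
                label, members = fields[0], fields[1:]
            else:
                label, members = f"m{len(modules) + 1}", fields
            if not members:
                warnings.warn(f"{path}: line {lineno}: blank module line "
                              "skipped", stacklevel=2)
                continue
            if label in seen:
                raise ValueError(
                    f"{path}: line {lineno}: duplicate module label {label!r}")
            seen.add(label)
            modules.append((label, frozenset(members)))
    return ModuleSet(tuple(modules))


def write_module_set(modules: ModuleSet, path: str | Path) -> None:
    """Write one module per line: label, then tab-separated sorted IDs.

    Output is byte-deterministic for a given :class:`ModuleSet`.
    """
    with open(path, "w") as fh:
        for label, members in modules:
            fh.write(label + "\t" + "\t".join(sorted(members)) + "\n")


def read_annotations(path: str | Path, genome_size: int) -> AnnotationTable:
    """Read a two-column (protein, term) TSV into an annotation table."""
    entries: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 'protein<TAB>term'")
            protein, term = fields[0], fields[1]
            entries.setdefault(term, set()).add(protein)
    frozen = {term: frozenset(prots) for term, prots in entries.items()}
    return AnnotationTable(frozen, genome_size)
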