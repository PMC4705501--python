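"""Density-modularity mathematics over an incrementally maintained partition.

The partition-quality score is the density modularity

    D = sum_i [ l_i^2 / (n_i^2 L)  -  d_i^4 / (n_i^2 L^3) ]

where, for module i, ``l_i`` is the intra-module edge count, ``n_i`` the node
count, ``d_i`` the sum of node degrees, and ``L`` the total number of edges
in the network.  The first term rewards internal edge density; the second
penalizes modules by total degree.  Note that on small graphs the degree
penalty dominates and D is negative; D is meaningful as a *relative* score
between candidate partitions of the same network.

Node-move decisions use the "closely associated degree": the increment in
(the dominant, size-normalized part of) D obtained by merging a node into a
module.  Internal CAD scores the node against its host module; external CAD
scores it against each neighboring module and keeps the best.  Decision
comparisons deliberately omit the 1/L factor and the degree bracket, which
are constant or negligible for a single-node move; full D is used only to
score and rank whole partitions.

All scores are ratios of small integers evaluated in double precision;
comparisons are strict, with no epsilon, so genuine ties behave as ties.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from .graph_io import PPINetwork

__all__ = [
    "Partition",
    "CadResult",
    "NO_MOVE",
    "partition_density",
    "partition_phi",
    "merge_gain",
    "internal_cad",
    "external_cad",
]

#: Sentinel score for a node with no external neighbor module (cannot move).
NO_MOVE = float("-inf")

CAD_FORMS = ("consistent", "eq5_as_printed")


@dataclass(frozen=True)
class CadResult:
    """A closely-associated-degree score.

    ``target`` is the module the score refers to (the arg-max neighbor module
    for external scores); it is ``None`` for internal scores and for the
    no-move sentinel.
    """

    value: float
    target: int | None = None


def _ekey(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


class Partition:
    """Assignment of every network node to exactly one module.

    Maintains per-module statistics (``l`` intra-module edges, ``n`` nodes,
    ``d`` degree sum), the member sets, and inter-module edge counts
    ``e[(i, j)]`` incrementally under single-node moves and pairwise merges,
    so that sweep decisions are O(degree) rather than O(network).
    """

    def __init__(self, network: PPINetwork,
                 membership: Mapping[str, int]):
        if set(membership) != network.nodes:
            raise ValueError("membership must cover exactly the network nodes")
        self.network = network
        self.membership: dict[str, int] = dict(membership)
        self._rebuild()

    @classmethod
    def singletons(cls, network: PPINetwork) -> "Partition":
        """One module per node; module ids follow sorted node order."""
        if network.n_nodes == 0:
            raise ValueError("cannot partition an empty network")
        return cls(network, {v: i for i, v in enumerate(sorted(network.nodes))})

    def _rebuild(self) -> None:
        members: dict[int, set[str]] = defaultdict(set)
        for v, m in self.membership.items():
            members[m].add(v)
        self.members = dict(members)
        self.n = {m: len(s) for m, s in self.members.items()}
        self.d = {m: sum(self.network.degree(v) for v in s)
                  for m, s in self.members.items()}
        self.l = {m: 0 for m in self.members}
        self.e: dict[tuple[int, int], int] = {}
        for u, v in self.network.edges:
            a, b = self.membership[u], self.membership[v]
            if a == b:
                self.l[a] += 1
            else:
                k = _ekey(a, b)
                self.e[k] = self.e.get(k, 0) + 1

    # -- queries ---------------------------------------------------------

    @property
    def L(self) -> int:
        return self.network.L

    @property
    def n_modules(self) -> int:
        return len(self.n)

    def module_ids(self) -> list[int]:
        return sorted(self.n)

    def edges_between(self, a: int, b: int) -> int:
        return self.e.get(_ekey(a, b), 0)

    def node_module_edges(self, node: str) -> Counter:
        """Edge counts from ``node`` into each module (by module id)."""
        return Counter(self.membership[w] for w in self.network.neighbors(node))

    def blocks(self) -> set[frozenset[str]]:
        """The partition as a set of frozen member sets (id-free view)."""
        return {frozenset(s) for s in self.members.values()}

    def copy(self) -> "Partition":
        new = object.__new__(Partition)
        new.network = self.network
        new.membership = dict(self.membership)
        new.members = {m: set(s) for m, s in self.members.items()}
        new.n = dict(self.n)
        new.d = dict(self.d)
        new.l = dict(self.l)
        new.e = dict(self.e)
        return new

    def check_consistency(self) -> None:
        """Audit: recompute every cache from scratch and compare.

        Raises ``AssertionError`` on any mismatch.  Intended for tests.
        """
        fresh = Partition(self.network, self.membership)
        assert self.members == fresh.members, "member sets diverged"
        assert self.n == fresh.n, "node counts diverged"
        assert self.l == fresh.l, "intra-edge counts diverged"
        assert self.d == fresh.d, "degree sums diverged"
        assert self.e == fresh.e, "inter-edge counts diverged"
        total = sum(self.l.values()) + sum(self.e.values())
        assert total == self.L, "edge bookkeeping does not sum to L"

    # -- updates ---------------------------------------------------------

    def _e_add(self, a: int, b: int, delta: int) -> None:
        k = _ekey(a, b)
        new = self.e.get(k, 0) + delta
        if new < 0:
            raise AssertionError(f"negative inter-module count for {k}")
        if new:
            self.e[k] = new
        else:
            self.e.pop(k, None)

    def move(self, node: str, target: int) -> None:
        """Relocate ``node`` into module ``target``, updating all caches.

        The source module is retired if it becomes empty.
        """
        s = self.membership[node]
        if target == s:
            return
        if target not in self.n:
            raise KeyError(f"unknown or retired module id {target}")
        cnt = self.node_module_edges(node)
        deg = self.network.degree(node)
        self.l[s] -= cnt.get(s, 0)
        self.l[target] += cnt.get(target, 0)
        for m, c in cnt.items():
            if m == s:
                self._e_add(s, target, c)
            elif m == target:
                self._e_add(s, target, -c)
            else:
                self._e_add(s, m, -c)
                self._e_add(target, m, c)
        self.n[s] -= 1
        self.n[target] += 1
        self.d[s] -= deg
        self.d[target] += deg
        self.members[s].discard(node)
        self.members[target].add(node)
        self.membership[node] = target
        if self.n[s] == 0:
            del self.n[s], self.d[s], self.l[s], self.members[s]
            # all of s's edges moved with its last node
            stale = [k for k in self.e if s in k]
            if stale:
                raise AssertionError(f"retired module {s} still has edges")

    def merge(self, a: int, b: int) -> int:
        """Merge modules ``a`` and ``b``; the smaller id survives."""
        if a == b:
            raise ValueError("cannot merge a module with itself")
        for m in (a, b):
            if m not in self.n:
                raise KeyError(f"unknown or retired module id {m}")
        keep, drop = (a, b) if a < b else (b, a)
        self.l[keep] = self.l[a] + self.l[b] + self.e.pop(_ekey(a, b), 0)
        self.n[keep] = self.n[a] + self.n[b]
        self.d[keep] = self.d[a] + self.d[b]
        for v in self.members[drop]:
            self.membership[v] = keep
        self.members[keep] |= self.members.pop(drop)
        for k in [k for k in self.e if drop in k]:
            other = k[0] if k[1] == drop else k[1]
            self._e_add(keep, other, self.e.pop(k))
        del self.n[drop], self.d[drop], self.l[drop]
        return keep


# -- scores --------------------------------------------------------------


def partition_density(partition: Partition) -> float:
    """Density modularity D of the whole partition (the printed formula)."""
    L = partition.L
    if L == 0:
        raise ValueError("density modularity is undefined for L = 0")
    D = 0.0
    for m in partition.n:
        l, n, d = partition.l[m], partition.n[m], partition.d[m]
        D += l * l / (n * n * L) - d ** 4 / (n * n * L ** 3)
    return D


def partition_phi(partition: Partition) -> float:
    """The proportional surrogate objective  Phi = sum_i l_i^2 / n_i^2.

    Phi drives node-move decisions under the consistent CAD form: a move is
    accepted exactly when it strictly increases Phi, which guarantees sweep
    termination (Phi takes finitely many values on a finite graph).
    """
    return sum(partition.l[m] ** 2 / partition.n[m] ** 2 for m in partition.n)


def merge_gain(partition: Partition, module_a: int, module_b: int,
               mode: str = "proportional") -> float:
    """Change in density modularity from merging two modules.

    ``proportional`` returns the dominant, L-free expression

        (l1 + l2 + e12)^2 / (n1 + n2)^2  -  l1^2/n1^2  -  l2^2/n2^2

    used to rank candidate merges.  ``full`` returns the complete delta-D,
    including the 1/L factor and the degree bracket, and equals
    ``partition_density(after) - partition_density(before)`` exactly.
    """
    if module_a == module_b:
        raise ValueError("merge_gain requires two distinct modules")
    for m in (module_a, module_b):
        if m not in partition.n:
            raise KeyError(f"unknown or retired module id {m}")
    l1, n1, d1 = (partition.l[module_a], partition.n[module_a],
                  partition.d[module_a])
    l2, n2, d2 = (partition.l[module_b], partition.n[module_b],
                  partition.d[module_b])
    e12 = partition.edges_between(module_a, module_b)
    prop = ((l1 + l2 + e12) ** 2 / (n1 + n2) ** 2
            - l1 ** 2 / n1 ** 2 - l2 ** 2 / n2 ** 2)
    if mode == "proportional":
        return prop
    if mode == "full":
        L = partition.L
        bracket = (d1 ** 4 / n1 ** 2 + d2 ** 4 / n2 ** 2
                   - (d1 + d2) ** 4 / (n1 + n2) ** 2)
        return prop / L + bracket / L ** 3
    raise ValueError(f"unknown merge_gain mode {mode!r}")


def internal_cad(partition: Partition, node: str,
                 form: str = "consistent") -> CadResult:
    """Internal closely associated degree R_in of a node toward its host.

    The node is treated as a singleton and its host module *without* the
    node supplies (l2, n2); ``e_in`` counts edges from the node into the
    host.  The default ``consistent`` form is

        (l2 + e_in)^2 / (1 + n2)^2  -  l2^2 / n2^2 ,

    the same functional form used for the external score, so that the
    R_in vs R_out comparison is like-for-like.  ``eq5_as_printed`` instead
    returns (e_in^2 + 2 l2 e_in) / (1 + n2)^2, the published final
    simplification, which silently drops the -l2^2/n2^2 term.  A node that
    is already a singleton module scores 0 under both forms.
    """
    if form not in CAD_FORMS:
        raise ValueError(f"unknown CAD form {form!r}")
    host = partition.membership.get(node)
    if host is None:
        raise KeyError(f"unknown node {node!r}")
    if partition.n[host] == 1:
        return CadResult(0.0)
    e_in = sum(1 for w in partition.network.neighbors(node)
               if partition.membership[w] == host)
    n2 = partition.n[host] - 1
    l2 = partition.l[host] - e_in
    if form == "consistent":
        value = (l2 + e_in) ** 2 / (1 + n2) ** 2 - l2 ** 2 / n2 ** 2
    else:
        value = (e_in ** 2 + 2 * l2 * e_in) / (1 + n2) ** 2
    return CadResult(value)


def external_cad(partition: Partition, node: str) -> CadResult:
    """External closely associated degree R_out: best neighboring module.

    Scores every module (other than the host) containing at least one
    neighbor of ``node`` with (l2 + e_out)^2/(1 + n2)^2 - l2^2/n2^2, where
    (l2, n2) are the candidate's statistics and ``e_out`` the edge count
    from the node into it, and returns the maximum with its module id.
    Ties resolve to the smallest module id.  If no such module exists the
    no-move sentinel (``-inf`` value, ``target=None``) is returned.
    """
    if node not in partition.membership:
        raise KeyError(f"unknown node {node!r}")
    host = partition.membership[node]
    cnt = partition.node_module_edges(node)
    best_value = NO_MOVE
    best_target: int | None = None
    for t in sorted(m for m in cnt if m != host):
        l2, n2 = partition.l[t], partition.n[t]
        e_out = cnt[t]
        value = (l2 + e_out) ** 2 / (1 + n2) ** 2 - l2 ** 2 / n2 ** 2
        if value > best_value:
            best_value = value
            best_target = t
    return CadResult(best_value, best_target)
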