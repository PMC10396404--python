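"""Missingness DAGs: data model, structural validation, d-separation.

An m-DAG is a causal directed acyclic graph over the analysis variables,
augmented with one binary *missingness indicator* node per incomplete
variable (or per collapsed group of incomplete variables, e.g. "any of the
confounders is missing").  Arrows into an indicator encode assumed causes of
missingness; the graph as a whole is the analyst's assumption object, from
which recoverability of the target estimand is read off graphically.

Three structural conventions are enforced or checked here:

* node kinds are ``substantive`` (analysis variables), ``latent`` (unmeasured
  common causes) and ``missingness`` (indicators);
* a missingness indicator never causes anything — no arrows out of
  indicators, including arrows between indicators;
* a latent variable may not be a common cause of a substantive variable and
  an indicator (that would put the graph outside the scope of the canonical
  recoverability catalogue).

d-separation is answered by the linear-time reachability ("Bayes-ball")
algorithm; the test suite checks it against an exhaustive path-enumeration
oracle and against networkx.
"""

from __future__ import annotations

import json
import re
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .errors import CyclicGraphError, GraphFormatError, UnknownNodeError

NODE_KINDS = ("substantive", "latent", "missingness")
NODE_ROLES = ("exposure", "outcome", "confounder", "auxiliary", "none")

_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")


@dataclass(frozen=True)
class Node:
    """A single m-DAG node.

    ``indicator_of`` names the substantive node (or collapsed node group)
    whose missingness this indicator marks; it is required exactly when
    ``kind == "missingness"``.  ``group_members`` optionally lists the
    individual variables a collapsed node stands for; the collapsed node is
    treated as atomic by every graph algorithm.
    """

    name: str
    kind: str = "substantive"
    role: str = "none"
    indicator_of: str | None = None
    group_members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not _NAME_RE.match(self.name):
            raise GraphFormatError(f"invalid node name {self.name!r}")
        if self.kind not in NODE_KINDS:
            raise GraphFormatError(f"node {self.name!r}: unknown kind {self.kind!r}")
        if self.role not in NODE_ROLES:
            raise GraphFormatError(f"node {self.name!r}: unknown role {self.role!r}")
        if self.kind != "substantive" and self.role != "none":
            raise GraphFormatError(
                f"node {self.name!r}: role {self.role!r} only allowed on substantive nodes"
            )
        if (self.kind == "missingness") != bool(self.indicator_of):
            raise GraphFormatError(
                f"node {self.name!r}: indicator_of must be set iff kind is 'missingness'"
            )
        if self.group_members and self.kind == "latent":
            raise GraphFormatError(
                f"node {self.name!r}: group_members not allowed on latent nodes"
            )
        object.__setattr__(self, "group_members", tuple(self.group_members))


class MDag:
    """Immutable directed acyclic graph over :class:`Node` objects.

    Nodes and edges are stored sorted by name so serialization is byte-stable
    across runs and platforms.
    """

    def __init__(self, nodes: Iterable[Node], edges: Iterable[tuple[str, str]]):
        node_list = sorted(nodes, key=lambda n: n.name)
        names = [n.name for n in node_list]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise GraphFormatError(f"duplicate node names: {sorted(dupes)}")
        self._nodes: dict[str, Node] = {n.name: n for n in node_list}

        edge_set = set()
        for e in edges:
            u, v = e
            if u not in self._nodes or v not in self._nodes:
                missing = u if u not in self._nodes else v
                raise GraphFormatError(f"edge ({u!r}, {v!r}) references unknown node {missing!r}")
            if u == v:
                raise GraphFormatError(f"self-loop on node {u!r}")
            edge_set.add((u, v))
        self._edges: tuple[tuple[str, str], ...] = tuple(sorted(edge_set))

        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self._edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = [u for u, _ in nx.find_cycle(g)]
            raise CyclicGraphError(cycle)
        self._nx = g

    # -- basic accessors -------------------------------------------------

    @property
    def nodes(self) -> tuple[Node, ...]:
        return tuple(self._nodes.values())

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(self._nodes)

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return self._edges

    def node(self, name: str) -> Node:
        try:
            return self._nodes[name]
        except KeyError:
            raise UnknownNodeError(f"unknown node {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._nodes

    def __iter__(self) -> Iterator[Node]:
        return iter(self._nodes.values())

    def __len__(self) -> int:
        return len(self._nodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MDag):
            return NotImplemented
        return self.nodes == other.nodes and self._edges == other._edges

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"MDag({len(self)} nodes, {len(self._edges)} edges)"

    def parents(self, name: str) -> tuple[str, ...]:
        self.node(name)
        return tuple(sorted(self._nx.predecessors(name)))

    def children(self, name: str) -> tuple[str, ...]:
        self.node(name)
        return tuple(sorted(self._nx.successors(name)))

    def ancestors(self, name: str) -> frozenset[str]:
        self.node(name)
        return frozenset(nx.ancestors(self._nx, name))

    def descendants(self, name: str) -> frozenset[str]:
        self.node(name)
        return frozenset(nx.descendants(self._nx, name))

    def topological_order(self) -> tuple[str, ...]:
        """Topological order with lexicographic tie-break (deterministic)."""
        return tuple(nx.lexicographical_topological_sort(self._nx))

    def nodes_of_kind(self, kind: str) -> tuple[Node, ...]:
        return tuple(n for n in self if n.kind == kind)

    @property
    def substantive_nodes(self) -> tuple[Node, ...]:
        return self.nodes_of_kind("substantive")

    @property
    def latent_nodes(self) -> tuple[Node, ...]:
        return self.nodes_of_kind("latent")

    @property
    def missingness_nodes(self) -> tuple[Node, ...]:
        return self.nodes_of_kind("missingness")

    def to_networkx(self) -> nx.DiGraph:
        return self._nx.copy()

    def with_extra_edges(self, extra: Iterable[tuple[str, str]]) -> "MDag":
        """A new MDag with additional edges (used e.g. to add outcome→indicator
        arrows to form an alternative, more pessimistic m-DAG)."""
        return MDag(self.nodes, list(self._edges) + list(extra))

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        nodes = []
        for n in self.nodes:  # already sorted by name
            d: dict = {"name": n.name, "kind": n.kind}
            if n.role != "none":
                d["role"] = n.role
            if n.indicator_of:
                d["indicator_of"] = n.indicator_of
            if n.group_members:
                d["group_members"] = list(n.group_members)
            nodes.append(d)
        return {"nodes": nodes, "edges": [list(e) for e in self._edges]}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_dict(cls, doc: Mapping) -> "MDag":
        return _mdag_from_document(doc)


def _mdag_from_document(doc: Mapping) -> MDag:
    if not isinstance(doc, Mapping):
        raise GraphFormatError("graph document must be a JSON object")
    for key in ("nodes", "edges"):
        if key not in doc:
            raise GraphFormatError(f"graph document missing top-level key {key!r}")
    nodes = []
    for i, nd in enumerate(doc["nodes"]):
        if isinstance(nd, str):
            nd = {"name": nd}
        if not isinstance(nd, Mapping):
            raise GraphFormatError(f"nodes[{i}]: expected object, got {type(nd).__name__}")
        if "name" not in nd:
            raise GraphFormatError(f"nodes[{i}]: missing field 'name'")
        unknown = set(nd) - {"name", "kind", "role", "indicator_of", "group_members"}
        if unknown:
            raise GraphFormatError(f"nodes[{i}] ({nd['name']!r}): unknown fields {sorted(unknown)}")
        try:
            nodes.append(
                Node(
                    name=nd["name"],
                    kind=nd.get("kind", "substantive"),
                    role=nd.get("role", "none"),
                    indicator_of=nd.get("indicator_of"),
                    group_members=tuple(nd.get("group_members") or ()),
                )
            )
        except GraphFormatError as exc:
            raise GraphFormatError(f"nodes[{i}]: {exc}") from None
    edges = []
    for i, ed in enumerate(doc["edges"]):
        if not (isinstance(ed, (list, tuple)) and len(ed) == 2):
            raise GraphFormatError(f"edges[{i}]: expected a two-element [from, to] list")
        edges.append((ed[0], ed[1]))
    return MDag(nodes, edges)


def parse_mdag(text: str) -> MDag:
    """Parse a graph document (JSON) into an :class:`MDag`.

    The format has two top-level keys: ``nodes`` — a list of objects with
    fields ``name`` (required), ``kind``, ``role``, ``indicator_of``,
    ``group_members`` — and ``edges`` — a list of two-element
    ``[from, to]`` lists.  Serialization via :meth:`MDag.to_json` emits nodes
    and edges in lexicographic order, so parse → serialize round-trips are
    byte-identical on serialized output.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise GraphFormatError(f"invalid JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}") from None
    return _mdag_from_document(doc)


# -- structural validation ----------------------------------------------


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_mdag`.

    ``violations`` are structural problems that put the graph outside the
    scope of the canonical recoverability results; ``warnings`` record
    assumptions that cannot be machine-checked and remain user attestations.
    """

    violations: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_mdag(g: MDag) -> ValidationReport:
    """Check the overarching structural assumptions behind the canonical catalogue.

    Violations:

    * ``ASSUMPTION_III`` — an arrow out of a missingness indicator (to a
      variable or to another indicator).
    * ``ASSUMPTION_I`` — a latent node that is a common cause of a
      substantive variable and a missingness indicator (an *unmeasured*
      common cause of a variable and an indicator).

    Warnings:

    * ``ASSUMPTION_II`` — "no measured common causes of a variable and an
      indicator are omitted from the graph" cannot be machine-checked; the
      user must attest to it.  Always emitted.
    """
    report = ValidationReport()
    for u, v in g.edges:
        if g.node(u).kind == "missingness":
            report.violations.append(
                (
                    "ASSUMPTION_III",
                    f"edge {u}->{v}: missingness indicators must not cause "
                    "other variables or indicators",
                )
            )
    for latent in g.latent_nodes:
        kinds = {g.node(c).kind for c in g.children(latent.name)}
        if "missingness" in kinds and kinds & {"substantive", "latent"}:
            report.violations.append(
                (
                    "ASSUMPTION_I",
                    f"latent node {latent.name!r} is an unmeasured common cause of a "
                    "variable and a missingness indicator",
                )
            )
    report.warnings.append(
        (
            "ASSUMPTION_II",
            "cannot machine-check that no measured common cause of a variable and "
            "a missingness indicator has been omitted from the m-DAG; this remains "
            "a user attestation",
        )
    )
    return report


# -- d-separation --------------------------------------------------------


def _as_name_set(g: MDag, names, arg: str) -> frozenset[str]:
    if isinstance(names, str):
        names = {names}
    s = frozenset(names)
    for n in s:
        if n not in g:
            raise UnknownNodeError(f"{arg}: unknown node {n!r}")
    return s


def d_separated(g: MDag, a, b, z=()) -> bool:
    """True iff every path between ``a`` and ``b`` is blocked given ``z``.

    Standard d-separation: a chain or fork is blocked when its middle node is
    conditioned on; a collider is blocked unless the collider or one of its
    descendants is conditioned on.  Computed by reachability over
    (node, travel-direction) states, linear in the size of the graph.
    Collapsed group nodes are atomic.

    ``a``, ``b``, ``z`` may be node names or iterables of names and must be
    pairwise disjoint.
    """
    A = _as_name_set(g, a, "a")
    B = _as_name_set(g, b, "b")
    Z = _as_name_set(g, z, "z")
    if A & B or A & Z or B & Z:
        raise ValueError("a, b and z must be pairwise disjoint")
    if not A or not B:
        return True

    # nodes with a descendant in Z (inclusive): these open colliders
    an_z: set[str] = set(Z)
    for zn in Z:
        an_z.update(g.ancestors(zn))

    # states: (node, dir); dir "up" = arrived from a child (or a start node),
    # dir "down" = arrived from a parent
    queue: deque[tuple[str, str]] = deque((n, "up") for n in A)
    visited: set[tuple[str, str]] = set()
    while queue:
        x, d = queue.popleft()
        if (x, d) in visited:
            continue
        visited.add((x, d))
        if x in B:
            return False
        if d == "up":
            if x not in Z:
                for p in g.parents(x):
                    queue.append((p, "up"))
                for c in g.children(x):
                    queue.append((c, "down"))
        else:  # arrived from a parent
            if x not in Z:
                for c in g.children(x):
                    queue.append((c, "down"))
            if x in an_z:  # collider at x is open
                for p in g.parents(x):
                    queue.append((p, "up"))
    return True
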