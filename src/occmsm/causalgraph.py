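"""Causal DAG machinery: d-separation, backdoor adjustment, treatment-confounder feedback.

The analysis rests on a directed acyclic graph over daily hospital variables:
capacity utilization (the exposure, ``CU1``, ``CU2``), patient turnover and
patient clinical complexity (time-varying confounders, ``PT*``, ``PCCL*``),
daily mortality (``M1``, ``M2``), baseline patient covariates (``C``) and an
unmeasured staffing-like process (``U``).  The graph exhibits
treatment-confounder feedback (TCF): day-one utilization affects day-two
turnover, which confounds day-two utilization, while ``U`` opens a backdoor
from turnover to mortality.  No adjustment set of measured nodes blocks every
backdoor path, which is why the analysis uses a marginal structural model
rather than covariate adjustment.

d-separation is decided by a reachability ("Bayes-ball") traversal over the
moral-free graph; an exhaustive path-enumeration oracle lives in the test
suite only.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

__all__ = [
    "Dag",
    "default_two_day_dag",
    "d_separated",
    "backdoor_valid",
    "detect_tcf",
    "load_dag",
    "dump_dag",
]


class GraphError(ValueError):
    """Raised for malformed graphs, unknown nodes, or missing role declarations."""


@dataclass
class Dag:
    """A labelled DAG with measured/unmeasured marking and analysis roles.

    Roles are optional for plain d-separation queries but required by
    :func:`detect_tcf`:

    * ``exposures`` -- time-indexed exposure nodes, e.g. ``{1: "CU1", 2: "CU2"}``
    * ``confounders`` -- time-indexed lists of time-varying confounders
    * ``outcome`` -- the terminal outcome node
    * ``baseline`` -- baseline covariate nodes
    * ``unmeasured`` -- nodes not observed in the data
    """

    graph: nx.DiGraph
    unmeasured: frozenset[str] = frozenset()
    exposures: dict[int, str] = field(default_factory=dict)
    confounders: dict[int, list[str]] = field(default_factory=dict)
    outcome: str | None = None
    baseline: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise GraphError("graph contains a directed cycle")
        self.unmeasured = frozenset(self.unmeasured)
        for role_node in self._role_nodes():
            if role_node not in self.graph:
                raise GraphError(f"role refers to unknown node {role_node!r}")

    def _role_nodes(self) -> Iterable[str]:
        yield from self.unmeasured
        yield from self.exposures.values()
        for nodes in self.confounders.values():
            yield from nodes
        if self.outcome is not None:
            yield self.outcome
        yield from self.baseline

    @property
    def measured(self) -> frozenset[str]:
        return frozenset(self.graph.nodes) - self.unmeasured

    def check_nodes(self, nodes: Iterable[str]) -> set[str]:
        nodes = set(nodes)
        missing = nodes - set(self.graph.nodes)
        if missing:
            raise GraphError(f"unknown node(s): {sorted(missing)}")
        return nodes


def default_two_day_dag() -> Dag:
    """The two-day hospital DAG used throughout the analysis.

    Edges: baseline covariates drive exposure and mortality on both days;
    turnover and complexity drive same-day utilization; day-one utilization
    feeds day-two turnover (the TCF arrow) and the next day's utilization;
    the unmeasured staffing process drives turnover on both days and day-two
    mortality.
    """
    g = nx.DiGraph()
    g.add_edges_from(
        [
            ("C", "CU1"), ("C", "CU2"), ("C", "M1"), ("C", "M2"),
            ("PT1", "CU1"), ("PCCL1", "CU1"),
            ("CU1", "M1"), ("CU1", "CU2"), ("CU1", "PT2"),
            ("PT2", "CU2"), ("PCCL2", "CU2"),
            ("CU2", "M2"),
            ("U", "PT1"), ("U", "PT2"), ("U", "M2"),
            ("PCCL1", "PCCL2"),
        ]
    )
    return Dag(
        graph=g,
        unmeasured=frozenset({"U"}),
        exposures={1: "CU1", 2: "CU2"},
        confounders={1: ["PT1", "PCCL1"], 2: ["PT2", "PCCL2"]},
        outcome="M2",
        baseline=["C"],
    )


def _ancestors_of(graph: nx.DiGraph, nodes: set[str]) -> set[str]:
    out = set(nodes)
    for n in nodes:
        out |= nx.ancestors(graph, n)
    return out


def d_separated(dag: Dag, x: Iterable[str], y: Iterable[str], z: Iterable[str] = ()) -> bool:
    """Decide whether every path between ``x`` and ``y`` is blocked given ``z``.

    Chains and forks are blocked when their middle node is in ``z``; colliders
    are open exactly when the collider or one of its descendants is in ``z``.
    Implemented as a breadth-first reachability over (node, direction) states:
    from ``x`` the ball travels along edges in both orientations, passing
    through a node according to the standard opening rules, and ``x`` and
    ``y`` are d-separated iff no ``y`` node is reached.
    """
    xs, ys, zs = (dag.check_nodes(s) for s in (x, y, z))
    if xs & ys or xs & zs or ys & zs:
        raise GraphError("x, y and z must be pairwise disjoint")
    g = dag.graph
    # collider (or descendant-of-collider) opening test
    z_anc = _ancestors_of(g, zs)

    # states: (node, arrived_via) with arrived_via in {"child", "parent"};
    # "child" means we entered the node along an edge pointing INTO it.
    start = deque(("start", s) for s in xs)
    seen: set[tuple[str, str]] = set()
    queue = deque()
    for _, s in start:
        for p in g.predecessors(s):
            queue.append((p, "up"))  # moving against an edge: we leave via a parent
        for c in g.successors(s):
            queue.append((c, "down"))
    # "up" state: we arrived at node by traversing an edge tail-first (node is a
    # parent of where we came from); "down": node is a child of where we came from.
    while queue:
        node, direction = queue.popleft()
        if (node, direction) in seen:
            continue
        seen.add((node, direction))
        if node in ys:
            return False
        if direction == "up":
            # arrived against an arrow; pass through unless conditioned on
            if node not in zs:
                for p in g.predecessors(node):
                    queue.append((p, "up"))
                for c in g.successors(node):
                    queue.append((c, "down"))
        else:  # arrived along an arrow: node may act as chain middle or collider
            if node not in zs:
                for c in g.successors(node):
                    queue.append((c, "down"))
            if node in z_anc:
                # collider open: bounce back to parents
                for p in g.predecessors(node):
                    queue.append((p, "up"))
    return True


def backdoor_valid(dag: Dag, x: Iterable[str], y: str, z: Iterable[str] = ()) -> bool:
    """Check the backdoor criterion for adjustment set ``z``.

    ``z`` must contain no descendant of any exposure node and must d-separate
    the exposures from the outcome once the exposures' outgoing edges are
    removed.  Only measured nodes are eligible.
    """
    xs = dag.check_nodes(x)
    zs = dag.check_nodes(z)
    dag.check_nodes([y])
    if zs - dag.measured:
        raise GraphError("adjustment set contains unmeasured nodes")
    for ex in xs:
        if zs & nx.descendants(dag.graph, ex):
            return False
    g_cut = dag.graph.copy()
    g_cut.remove_edges_from(list(g_cut.out_edges(xs)))
    cut = Dag(graph=g_cut, unmeasured=dag.unmeasured)
    return d_separated(cut, xs, [y], zs)


def all_backdoor_sets(dag: Dag, x: Iterable[str], y: str) -> list[frozenset[str]]:
    """Exhaustively enumerate valid measured backdoor adjustment sets.

    Intended for small graphs (the search is over all subsets of measured
    nodes excluding exposures and outcome).  On the shipped two-day DAG the
    result is empty: the unmeasured staffing path cannot be blocked, which is
    the formal motivation for weighting instead of adjustment.
    """
    from itertools import chain, combinations

    xs = dag.check_nodes(x)
    candidates = sorted(dag.measured - xs - {y})
    valid = []
    for r in range(len(candidates) + 1):
        for combo in combinations(candidates, r):
            if backdoor_valid(dag, xs, y, combo):
                valid.append(frozenset(combo))
    return valid


def detect_tcf(dag: Dag) -> tuple[bool, list[dict]]:
    """Detect treatment-confounder feedback and return witness structures.

    A time-``t`` confounder ``L`` witnesses TCF when it is (i) a descendant of
    an earlier exposure, (ii) an ancestor of a later exposure, and (iii)
    associated with the outcome through a directed path or a common unmeasured
    cause.  Returns ``(flag, witnesses)`` where each witness records the
    confounder, the feeding exposure, the downstream exposure and how the
    outcome link arises.
    """
    if not dag.exposures or dag.outcome is None or not dag.confounders:
        raise GraphError("detect_tcf requires exposure, confounder and outcome roles")
    g = dag.graph
    witnesses: list[dict] = []
    for t, conf_nodes in dag.confounders.items():
        earlier = [a for s, a in dag.exposures.items() if s < t]
        later = [a for s, a in dag.exposures.items() if s >= t]
        for L in conf_nodes:
            fed_by = [a for a in earlier if L in nx.descendants(g, a)]
            feeds = [a for a in later if a in nx.descendants(g, L)]
            if not fed_by or not feeds:
                continue
            # the outcome association must not run through the exposures
            # themselves (that is the treatment path, not confounding)
            g_no_exp = g.copy()
            g_no_exp.remove_nodes_from(set(dag.exposures.values()) - {L})
            outcome_link = None
            if dag.outcome in g_no_exp and L in g_no_exp and dag.outcome in nx.descendants(g_no_exp, L):
                outcome_link = {"kind": "directed", "via": L}
            else:
                common = [
                    u for u in dag.unmeasured
                    if L in nx.descendants(g, u) and dag.outcome in nx.descendants(g, u)
                ]
                if common:
                    outcome_link = {"kind": "unmeasured_common_cause", "via": common[0]}
            if outcome_link is not None:
                witnesses.append(
                    {
                        "confounder": L,
                        "fed_by_exposure": fed_by[0],
                        "feeds_exposure": feeds[0],
                        "outcome_link": outcome_link,
                    }
                )
    return bool(witnesses), witnesses


# ---------------------------------------------------------------------------
# text round-trip: one "src -> dst" per line plus role declarations

def dump_dag(dag: Dag) -> str:
    lines = [f"{u} -> {v}" for u, v in sorted(dag.graph.edges)]
    for n in sorted(dag.unmeasured):
        lines.append(f"unmeasured: {n}")
    for t in sorted(dag.exposures):
        lines.append(f"exposure[{t}]: {dag.exposures[t]}")
    for t in sorted(dag.confounders):
        lines.append(f"confounders[{t}]: {', '.join(dag.confounders[t])}")
    if dag.outcome is not None:
        lines.append(f"outcome: {dag.outcome}")
    if dag.baseline:
        lines.append(f"baseline: {', '.join(dag.baseline)}")
    return "\n".join(lines) + "\n"


def load_dag(text: str) -> Dag:
    g = nx.DiGraph()
    unmeasured: set[str] = set()
    exposures: dict[int, str] = {}
    confounders: dict[int, list[str]] = {}
    outcome: str | None = None
    baseline: list[str] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "->" in line:
            u, v = (part.strip() for part in line.split("->", 1))
            if not u or not v:
                raise GraphError(f"malformed edge line: {raw!r}")
            g.add_edge(u, v)
        elif ":" in line:
            key, val = (part.strip() for part in line.split(":", 1))
            if key == "unmeasured":
                unmeasured.add(val)
            elif key.startswith("exposure["):
                exposures[int(key[len("exposure["):-1])] = val
            elif key.startswith("confounders["):
                t = int(key[len("confounders["):-1])
                confounders[t] = [s.strip() for s in val.split(",") if s.strip()]
            elif key == "outcome":
                outcome = val
            elif key == "baseline":
                baseline = [s.strip() for s in val.split(",") if s.strip()]
            else:
                raise GraphError(f"unknown declaration {key!r}")
        else:
            raise GraphError(f"unparseable line: {raw!r}")
    g.add_nodes_from(unmeasured)
    return Dag(
        graph=g,
        unmeasured=frozenset(unmeasured),
        exposures=exposures,
        confounders=confounders,
        outcome=outcome,
        baseline=baseline,
    )
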