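"""Indirect-path consistency of separating sets.

Structure learning is repeated while only accepting contributors consistent
with the graph of the previous iteration, until the sequence of graphs enters
a limit cycle; the edge-union of the cycle members is returned.

Two levels:

* ``skeleton``: every separating-set node must lie on some simple path
  between the extremities of the removed edge (orientation-blind);
* ``orientation``: additionally, the node must be adjacent to one of the
  extremities and must not be a descendant (through head-marked directed
  edges) of the extremity it neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .core import HEAD, DataTable, MixedGraph, pair_key
from .info import InfoEngine
from .orientation import orient_graph
from .skeleton import learn_skeleton


@dataclass
class ConsistencyConfig:
    level: str = "none"  # none | skeleton | orientation
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if self.level not in ("none", "skeleton", "orientation"):
            raise ValueError(f"unknown consistency level {self.level!r}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def _skeleton_nx(graph: MixedGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(graph.names)
    for e in graph.present_edges():
        g.add_edge(e.x, e.y)
    return g


def _directed_nx(graph: MixedGraph) -> nx.DiGraph:
    """Directed view over head-marked edges only (one head, other end not a
    head); undirected and bidirected edges create no descent."""
    d = nx.DiGraph()
    d.add_nodes_from(graph.names)
    for e in graph.present_edges():
        hx = e.end_x.mark == HEAD
        hy = e.end_y.mark == HEAD
        if hy and not hx:
            d.add_edge(e.x, e.y)
        elif hx and not hy:
            d.add_edge(e.y, e.x)
    return d


def nodes_on_simple_paths(g: nx.Graph, x: str, y: str) -> set:
    """All nodes lying on at least one simple path between x and y, via the
    block-cut (biconnected-component) decomposition."""
    if x not in g or y not in g:
        return set()
    # build the block-cut tree restricted to the component containing x
    comp_nodes = None
    for comp in nx.connected_components(g):
        if x in comp:
            comp_nodes = comp
            break
    if comp_nodes is None or y not in comp_nodes:
        return set()
    sub = g.subgraph(comp_nodes)
    blocks = [frozenset(b) for b in nx.biconnected_components(sub)]
    bct = nx.Graph()
    for b in blocks:
        bct.add_node(("B", b))
        for v in b:
            bct.add_node(("N", v))
            bct.add_edge(("B", b), ("N", v))
    try:
        path = nx.shortest_path(bct, ("N", x), ("N", y))
    except nx.NetworkXNoPath:
        return set()
    out: set = set()
    for node in path:
        if node[0] == "B":
            out |= set(node[1])
        else:
            out.add(node[1])
    return out


def sepset_is_consistent(graph: MixedGraph, record, level: str) -> bool:
    """Does every contributor of a removed pair remain interpretable as an
    indirect path through the given graph?"""
    if level == "none" or not record.contributors:
        return True
    x, y = record.pair
    g = _skeleton_nx(graph)
    on_path = nodes_on_simple_paths(g, x, y)
    if not set(record.contributors) <= on_path:
        return False
    if level == "skeleton":
        return True
    d = _directed_nx(graph)
    desc_x = nx.descendants(d, x) if x in d else set()
    desc_y = nx.descendants(d, y) if y in d else set()
    for a in record.contributors:
        ok = (g.has_edge(a, x) and a not in desc_x) or (
            g.has_edge(a, y) and a not in desc_y
        )
        if not ok:
            return False
    return True


def _candidate_filter(graph: MixedGraph, level: str):
    """Per-candidate eligibility predicate for the next learning pass."""
    g = _skeleton_nx(graph)
    d = _directed_nx(graph) if level == "orientation" else None
    path_cache: dict[tuple[str, str], set] = {}
    desc_cache: dict[str, set] = {}

    def desc(v):
        if v not in desc_cache:
            desc_cache[v] = nx.descendants(d, v) if v in d else set()
        return desc_cache[v]

    def ok(x: str, y: str, a: str) -> bool:
        key = pair_key(x, y)
        if key not in path_cache:
            path_cache[key] = nodes_on_simple_paths(g, x, y)
        if a not in path_cache[key]:
            return False
        if level == "skeleton":
            return True
        return (g.has_edge(a, x) and a not in desc(x)) or (
            g.has_edge(a, y) and a not in desc(y)
        )

    return ok


def _merge_endpoint(target, source):
    if source.mark == "undefined":
        return
    if target.mark == "undefined":
        target.mark = source.mark
        target.p_head = source.p_head
        target.p_tail = source.p_tail
        target.score = source.score
    elif target.mark != source.mark:
        conf_t = max(target.p_head, target.p_tail)
        conf_s = max(source.p_head, source.p_tail)
        if conf_s > conf_t:
            target.mark = source.mark
            target.p_head = source.p_head
            target.p_tail = source.p_tail
            target.score = source.score
        elif conf_s == conf_t:
            # irreconcilable equal-confidence conflict
            target.mark = "undefined"
            target.p_head = target.p_tail = 0.5
            target.score = 0.0
    else:
        if max(source.p_head, source.p_tail) > max(target.p_head, target.p_tail):
            target.p_head = source.p_head
            target.p_tail = source.p_tail
            target.score = source.score


def union_graph(graphs: list[MixedGraph], beta: float = 0.5) -> MixedGraph:
    """Edge-union of limit-cycle members; endpoint marks merged by keeping
    the highest-probability mark (equal-confidence conflicts -> undefined)."""
    from copy import deepcopy

    from .orientation import classify_edge

    out = deepcopy(graphs[0])
    for g in graphs[1:]:
        for key, e in g.edges.items():
            t = out.edges[key]
            if e.present and not t.present:
                t.present = True
                t.sepset = None
                t.status = e.status
                t.info_reg = e.info_reg
                t.residual_info = e.residual_info
                t.sign = e.sign
                t.end_x = deepcopy(e.end_x)
                t.end_y = deepcopy(e.end_y)
            elif e.present and t.present:
                _merge_endpoint(t.end_x, e.end_x)
                _merge_endpoint(t.end_y, e.end_y)
    for e in out.present_edges():
        e.status = classify_edge(e.end_x, e.end_y, beta)
    return out


@dataclass
class ConsistentResult:
    graph: MixedGraph
    records: dict
    contributions: object | None = None
    n_iterations: int = 1
    cycle_length: int = 1
    converged: bool = True
    inconsistent_records: list = field(default_factory=list)


def learn_consistent(
    data: DataTable,
    config: ConsistencyConfig | None = None,
    beta: float = 0.5,
    propagate: bool = False,
    max_cond: int = 20,
    engine_opts: dict | None = None,
) -> ConsistentResult:
    """Full pipeline: skeleton + orientation, iterated to a limit cycle when
    a consistency level is configured."""
    config = config or ConsistencyConfig()
    engine_opts = engine_opts or {}

    def one_pass(filt):
        engine = InfoEngine(data, **engine_opts)
        graph, records = learn_skeleton(
            data, max_cond=max_cond, consistency_filter=filt, engine=engine
        )
        orient_graph(graph, records, data, beta=beta, propagate=propagate,
                     engine=engine)
        return graph, records

    graph, records = one_pass(None)
    if config.level == "none":
        return ConsistentResult(graph=graph, records=records)

    seen = {graph.canonical_signature(): 0}
    history = [(graph, records)]
    converged = False
    for it in range(1, config.max_iterations):
        filt = _candidate_filter(graph, config.level)
        graph, records = one_pass(filt)
        sig = graph.canonical_signature()
        if sig in seen:
            start = seen[sig]
            cycle = history[start:]
            converged = True
            break
        seen[sig] = it
        history.append((graph, records))
    else:
        cycle = history[-2:] if len(history) >= 2 else history
        it = config.max_iterations

    graphs = [g for g, _ in cycle]
    final = union_graph(graphs, beta=beta) if len(graphs) > 1 else graphs[0]
    final_records = cycle[-1][1]
    bad = [
        rec
        for rec in final_records.values()
        if rec.removed and not sepset_is_consistent(final, rec, config.level)
    ]
    return ConsistentResult(
        graph=final,
        records=final_records,
        n_iterations=it + 1,
        cycle_length=len(graphs),
        converged=converged,
        inconsistent_records=bad,
    )
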