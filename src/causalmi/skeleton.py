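"""Skeleton learning by iterative collection of information contributors.

Starting from the complete graph, every pair whose regularized mutual
information rectifies to zero is dropped immediately (marginal independence,
empty separating set).  For the surviving edges the algorithm repeatedly
picks the edge whose residual I'(X;Y|{Ai}) looks most confidently reducible
(rank = residual minus its best next contribution), collects that top
contributor, and removes the edge the moment the rectified residual reaches
exactly zero, recording the ordered contributor list as the separating set.
Contributors are only ever collected when their information contribution
I'(X;Y;Ak|{Ai}_{k-1}) is strictly positive, which is what makes the recorded
contributions interpretable as indirect-path contributions downstream.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

from .core import DataTable, MixedGraph, edge_sign
from .info import InfoEngine


@dataclass
class SepSetRecord:
    """Ordered contributors collected for one pair, with their contributions
    and the final rectified residual (0 for removed pairs)."""

    pair: tuple[str, str]
    contributors: list[str] = field(default_factory=list)
    contributions: list[float] = field(default_factory=list)
    residual: float = 0.0
    info0: float = 0.0  # marginal I'(X;Y), rectified
    removed: bool = False


def find_top_contributor(x: str, y: str, collected, candidates,
                         engine: InfoEngine, residual: float):
    """Best next contributor for the pair (x, y): the candidate maximizing the
    positive contribution I'(X;Y;A|{collected}); None when no candidate
    contributes strictly positively.  Ties break toward the smaller name."""
    best = None
    best_contrib = 0.0
    for a in sorted(candidates):
        if a in collected or a in (x, y):
            continue
        res = engine.info(x, y, tuple(collected) + (a,), quality="scan")
        contrib = residual - res.reg_info_rect
        if contrib > best_contrib + 1e-12:
            best = a
            best_contrib = contrib
    if best is None:
        return None
    return best, best_contrib


def learn_skeleton(
    data: DataTable,
    max_cond: int = 20,
    consistency_filter=None,
    engine: InfoEngine | None = None,
    compute_signs: bool = True,
) -> tuple[MixedGraph, dict[tuple[str, str], SepSetRecord]]:
    """Learn the undirected skeleton; returns the graph plus one
    SepSetRecord per pair that had positive marginal information.

    ``consistency_filter(x, y, a)`` (optional) vetoes contributor candidates
    that are inconsistent with a previously inferred graph.
    """
    if engine is None:
        engine = InfoEngine(data)
    graph = MixedGraph(nodes=list(data.specs))
    names = graph.names
    adj: dict[str, set[str]] = {n: set() for n in names}
    records: dict[tuple[str, str], SepSetRecord] = {}

    # marginal pass
    survivors = []
    for key in sorted(graph.edges):
        x, y = key
        res = engine.info(x, y, quality="full")
        e = graph.edges[key]
        if res.reg_info_rect <= 0.0:
            e.present = False
            e.sepset = []
            e.residual_info = 0.0
            records[key] = SepSetRecord(pair=key, residual=0.0, info0=0.0,
                                        removed=True)
            continue
        e.present = True
        e.sepset = None
        e.info_reg = res.reg_info_rect
        e.residual_info = res.reg_info_rect
        adj[x].add(y)
        adj[y].add(x)
        records[key] = SepSetRecord(pair=key, residual=res.reg_info_rect,
                                    info0=res.reg_info_rect)
        survivors.append(key)

    state = {key: records[key] for key in survivors}
    finalized: set[tuple[str, str]] = set()

    def candidates_for(key):
        x, y = key
        cands = (adj[x] | adj[y]) - {x, y}
        rec = state[key]
        cands -= set(rec.contributors)
        if consistency_filter is not None:
            cands = {a for a in cands if consistency_filter(x, y, a)}
        return cands

    def top_for(key):
        x, y = key
        rec = state[key]
        return find_top_contributor(x, y, rec.contributors,
                                    candidates_for(key), engine, rec.residual)

    heap: list[tuple[float, tuple[str, str]]] = []
    for key in survivors:
        found = top_for(key)
        if found is None:
            finalized.add(key)
            continue
        _, contrib = found
        heapq.heappush(heap, (state[key].residual - contrib, key))

    while heap:
        _, key = heapq.heappop(heap)
        if key in finalized or not graph.edges[key].present:
            continue
        # recompute against the current neighborhoods (lazy heap)
        found = top_for(key)
        if found is None:
            finalized.add(key)
            continue
        a, contrib = found
        rec = state[key]
        rec.contributors.append(a)
        rec.contributions.append(contrib)
        x, y = key
        # memoized: identical to the estimate used to pick the contributor,
        # so contribution_k == residual_{k-1} - residual_k holds exactly
        res = engine.info(x, y, tuple(rec.contributors), quality="scan")
        rec.residual = res.reg_info_rect
        e = graph.edges[key]
        if rec.residual <= 0.0:
            rec.residual = 0.0
            rec.removed = True
            e.present = False
            e.sepset = list(rec.contributors)
            e.residual_info = 0.0
            adj[x].discard(y)
            adj[y].discard(x)
            continue
        e.residual_info = rec.residual
        if len(rec.contributors) >= max_cond:
            finalized.add(key)  # conditioning budget reached; edge retained
            continue
        nxt = top_for(key)
        if nxt is None:
            finalized.add(key)
            continue
        _, ncontrib = nxt
        heapq.heappush(heap, (rec.residual - ncontrib, key))

    if compute_signs:
        for e in graph.present_edges():
            e.sign = edge_sign(data, e.x, e.y)
    return graph, records
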