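"""Orientation of the learned skeleton.

V-structures X*->Z<-*Y are read off negative conditional 3-point information
computed over unshielded triples; their head probability is

    P = (1 + exp(N*I3)) / (1 + 3*exp(N*I3))  in [1/2, 1)

which for numerical ranking at large N is carried as an equivalent score

    score_v = -N*I3 + log1p(exp(N*I3)) - ln 2,   P = 1 / (1 + exp(-score_v)).

Orientations are applied strictly in decreasing score order.  An existing
arrowhead into Z induces, for each unshielded triple through Z, a mark on the
opposite edge at the Z end (head when the 3-point term is negative, tail when
positive) with a rectified induced score

    score_i = max(0, m - log1p(e^{m-M} + e^{-M})),
    m = min(N*|I3|, score_src),  M = max(N*|I3|, score_src),

which can never exceed the score of the arrowhead it derives from.  With
propagation enabled, an induced tail at Z on edge X-Z is propagated as a head
at the X end when that end is still undefined.  Contextual variables carry a
permanent tail (p_tail = 1) and never receive an arrowhead.

After orientation every present edge is classified against a confidence
threshold beta: genuine (head one side and tail the other both significant),
putative (one significant head), bidirected (two significant heads, i.e. an
unobserved common cause), otherwise undirected.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

from .core import (
    BIDIRECTED,
    GENUINE,
    HEAD,
    PUTATIVE,
    TAIL,
    UNDEFINED,
    UNDIRECTED,
    DataTable,
    EndpointMark,
    MixedGraph,
    pair_key,
)
from .info import InfoEngine


def v_structure_probability(n_i3: float) -> float:
    """Head probability of a v-structure from N*I3 < 0."""
    if not n_i3 < 0:
        raise ValueError("v-structure requires negative 3-point information")
    e = math.exp(n_i3)
    return (1.0 + e) / (1.0 + 3.0 * e)


def v_structure_score(n_i3: float) -> float:
    """Score equivalent of the v-structure probability, stable for large N."""
    if not n_i3 < 0:
        raise ValueError("v-structure requires negative 3-point information")
    return -n_i3 + math.log1p(math.exp(n_i3)) - math.log(2.0)


def induced_score(n_i3_abs: float, score_v: float) -> tuple[float, float]:
    """Rectified induced score and its probability.

    ``n_i3_abs`` is N*|I3| of the triple carrying the induced mark and
    ``score_v`` the score of the arrowhead it originates from.
    """
    if n_i3_abs < 0 or score_v < 0:
        raise ValueError("inputs must be non-negative")
    m = min(n_i3_abs, score_v)
    M = max(n_i3_abs, score_v)
    s = m - math.log1p(math.exp(m - M) + math.exp(-M))
    s = max(0.0, s)
    return s, _sigmoid(s)


def _sigmoid(s: float) -> float:
    return 1.0 / (1.0 + math.exp(-s))


def classify_edge(end_x: EndpointMark, end_y: EndpointMark, beta: float) -> str:
    """Causal status of a present edge from its endpoint probabilities."""
    if not (0.5 <= beta < 1.0):
        raise ValueError("beta must lie in [0.5, 1)")
    hx = end_x.significant_head(beta)
    hy = end_y.significant_head(beta)
    if hx and hy:
        return BIDIRECTED
    if hy and end_x.significant_tail(beta):
        return GENUINE
    if hx and end_y.significant_tail(beta):
        return GENUINE
    if hx or hy:
        return PUTATIVE
    return UNDIRECTED


@dataclass
class TripleScore:
    """One unshielded triple x - z - y (x, y non-adjacent)."""

    x: str
    z: str
    y: str
    n_i3: float
    score_v: float | None
    kind: str  # "v_structure" or "non_v"


def enumerate_unshielded_triples(graph: MixedGraph):
    """(x, z, y) with x-z and z-y present, x < y, x and y non-adjacent."""
    out = []
    for z in sorted(graph.names):
        nbrs = graph.neighbors(z)
        for i, x in enumerate(nbrs):
            for y in nbrs[i + 1:]:
                if not graph.adjacent(x, y):
                    out.append((x, z, y))
    return out


def score_triples(graph: MixedGraph, sepsets, engine: InfoEngine):
    triples = {}
    for x, z, y in enumerate_unshielded_triples(graph):
        rec = sepsets.get(pair_key(x, y))
        cond = tuple(rec.contributors) if rec is not None else ()
        i3, n = engine.three_point(x, y, z, cond)
        n_i3 = n * i3
        if n_i3 < 0:
            triples[(x, z, y)] = TripleScore(
                x, z, y, n_i3, v_structure_score(n_i3), "v_structure"
            )
        else:
            triples[(x, z, y)] = TripleScore(x, z, y, n_i3, None, "non_v")
    return triples


def orient_graph(
    skeleton: MixedGraph,
    sepsets,
    data: DataTable,
    beta: float = 0.5,
    propagate: bool = False,
    contextual_priors: bool = True,
    engine: InfoEngine | None = None,
) -> MixedGraph:
    """Orient a learned skeleton in place (and return it)."""
    if engine is None:
        engine = InfoEngine(data)
    graph = skeleton
    contextual = {s.name for s in graph.nodes if s.is_contextual}

    if contextual_priors:
        for e in graph.present_edges():
            for node, end in ((e.x, e.end_x), (e.y, e.end_y)):
                if node in contextual:
                    end.mark = TAIL
                    end.p_tail = 1.0
                    end.p_head = 0.0
                    end.score = math.inf

    triples = score_triples(graph, sepsets, engine)
    # triples indexed by center for induced-orientation lookup
    by_center: dict[str, list[tuple[str, str, str]]] = {}
    for (x, z, y) in triples:
        by_center.setdefault(z, []).append((x, z, y))

    # event heap: (-score, tie_break, seq, kind, payload)
    heap: list = []
    seq = 0

    def push(score, tie, kind, payload):
        nonlocal seq
        heapq.heappush(heap, (-score, tie, seq, kind, payload))
        seq += 1

    for t in sorted(triples):
        ts = triples[t]
        if ts.kind == "v_structure":
            push(ts.score_v, t, "v", t)

    def endpoint(edge_key, node):
        return graph.edges[edge_key].endpoint(node)

    def try_place(edge_key, node, mark, score):
        """Place a mark unless a higher-score mark already sits there.
        Returns True only when the mark was newly placed (prevents event
        cascades from re-firing on already-marked endpoints)."""
        if mark == HEAD and contextual_priors and node in contextual:
            return False
        end = endpoint(edge_key, node)
        if end.mark != UNDEFINED and end.score >= score:
            return False
        end.mark = mark
        end.score = score
        p = _sigmoid(score)
        if mark == HEAD:
            end.p_head, end.p_tail = p, 1.0 - p
        else:
            end.p_head, end.p_tail = 1.0 - p, p
        return True

    def on_head(z, other, score):
        """A head landed at z on edge (z, other): spawn induced marks at the
        z end of every other unshielded triple edge through z."""
        for t in by_center.get(z, ()):  # t = (a, z, b)
            a, _, b = t
            if other not in (a, b):
                continue
            far = b if other == a else a
            edge_key = pair_key(far, z)
            if not graph.edges[edge_key].present:
                continue
            ts = triples[t]
            s_i, _ = induced_score(abs(ts.n_i3), score)
            mark = HEAD if ts.n_i3 < 0 else TAIL
            push(s_i, t, "induced", (edge_key, z, mark, far))

    while heap:
        neg_score, tie, _, kind, payload = heapq.heappop(heap)
        score = -neg_score
        if kind == "v":
            x, z, y = payload
            kx = pair_key(x, z)
            ky = pair_key(y, z)
            if not (graph.edges[kx].present and graph.edges[ky].present):
                continue
            if try_place(kx, z, HEAD, score):
                on_head(z, x, score)
            if try_place(ky, z, HEAD, score):
                on_head(z, y, score)
        else:
            edge_key, z, mark, far = payload
            if not graph.edges[edge_key].present:
                continue
            if try_place(edge_key, z, mark, score):
                if mark == HEAD:
                    on_head(z, far, score)
                elif propagate:
                    # induced tail at z propagated as head to the far end
                    far_end = endpoint(edge_key, far)
                    if far_end.mark == UNDEFINED:
                        if try_place(edge_key, far, HEAD, score):
                            on_head(far, z, score)

    for e in graph.present_edges():
        e.status = classify_edge(e.end_x, e.end_y, beta)
    return graph
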