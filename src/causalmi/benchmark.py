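"""Synthetic benchmark generation and graph-scoring harness.

The generator emulates registry-style mixed-type health data: a random
skeleton with a right-skewed degree distribution (preset: 51 nodes, mean
degree ~11, i.e. ~280 edges), oriented into a DAG by a random node ordering,
populated by a mixed-type structural equation model with a configurable
proportion of categorical variables (2-6 levels, skewed marginals) and
bimodal continuous roots.  Each parent contributes a standardized effect of
0.3-1.0 noise SDs, so individual links range from weak to strong.

Scoring follows three levels: skeleton (edge presence only), CPDAG (an edge
with the wrong orientation status counts as a false positive), and the
oriented-edge subgraph (precision/recall/F restricted to edges oriented in
the true CPDAG versus edges oriented in the inferred graph; genuine and
putative causes both count as oriented, a bidirected edge matches a truth
arrowhead into either of its two heads).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .consistency import ConsistencyConfig, learn_consistent
from .core import (
    CATEGORICAL,
    CONTINUOUS,
    HEAD,
    DataTable,
    MixedGraph,
    VariableSpec,
    pair_key,
)

# ---------------------------------------------------------------------------
# graph generation
# ---------------------------------------------------------------------------

def _draw_degrees(p: int, mean_degree: float, rng) -> np.ndarray:
    """Right-skewed degree draw with the requested mean."""
    sigma = 0.5
    mu = np.log(mean_degree) - sigma**2 / 2.0
    d = np.round(rng.lognormal(mu, sigma, size=p)).astype(int)
    return np.clip(d, 1, p - 1)


def generate_skeleton(
    p: int,
    degree_sequence=None,
    jitter: int = 2,
    seed: int = 0,
    mean_degree: float = 11.0,
) -> nx.Graph:
    """Random simple graph with (jittered) target degrees via Havel-Hakimi
    construction followed by edge-swap Monte Carlo randomization."""
    rng = np.random.default_rng(seed)
    explicit = degree_sequence is not None
    base = (
        np.asarray(degree_sequence, dtype=int)
        if explicit
        else _draw_degrees(p, mean_degree, rng)
    )
    if base.size != p:
        raise ValueError("degree sequence length must equal p")
    for _ in range(100):
        seq = base + rng.integers(-jitter, jitter + 1, size=p)
        # drawn sequences are coerced into the simple-graph range; an
        # explicitly supplied sequence must stand on its own
        seq = np.clip(seq, 1, None if explicit else p - 1)
        if seq.sum() % 2 == 1:
            i = int(rng.integers(p))
            seq[i] += 1 if seq[i] < p - 1 else -1
        if nx.is_graphical(seq.tolist()):
            break
    else:
        raise ValueError("no feasible degree sequence after 100 jitter redraws")
    g = nx.havel_hakimi_graph(seq.tolist())
    g = nx.relabel_nodes(g, {i: _node_name(i, p) for i in range(p)})
    n_edges = g.number_of_edges()
    if n_edges > 1 and p >= 4:
        try:
            nx.double_edge_swap(
                g, nswap=4 * n_edges, max_tries=100 * n_edges,
                seed=int(rng.integers(2**31 - 1)),
            )
        except nx.NetworkXException:
            pass  # swap-saturated (dense or tiny graphs); sequence still holds
    return g


def _node_name(i: int, p: int) -> str:
    width = len(str(p))
    return f"V{i + 1:0{width}d}"


def orient_to_dag(skeleton: nx.Graph, seed: int = 0) -> nx.DiGraph:
    """Orient every edge from earlier to later in a uniform random node
    ordering; the result is acyclic by construction."""
    rng = np.random.default_rng(seed)
    nodes = sorted(skeleton.nodes)
    order = {n: r for r, n in zip(rng.permutation(len(nodes)), nodes)}
    dag = nx.DiGraph()
    dag.add_nodes_from(nodes)
    for u, v in skeleton.edges:
        if order[u] < order[v]:
            dag.add_edge(u, v)
        else:
            dag.add_edge(v, u)
    return dag


def assign_specs(nodes, discrete_prop: float, seed: int = 0) -> list[VariableSpec]:
    """Mark a fraction ``discrete_prop`` of nodes categorical (2-6 levels)."""
    rng = np.random.default_rng(seed)
    nodes = sorted(nodes)
    n_cat = int(round(discrete_prop * len(nodes)))
    cat_idx = set(rng.choice(len(nodes), size=n_cat, replace=False).tolist())
    specs = []
    for i, n in enumerate(nodes):
        if i in cat_idx:
            levels = int(rng.integers(2, 7))
            specs.append(
                VariableSpec(n, CATEGORICAL,
                             levels=tuple(f"l{j}" for j in range(levels)))
            )
        else:
            specs.append(VariableSpec(n, CONTINUOUS))
    return specs


# ---------------------------------------------------------------------------
# structural equation model
# ---------------------------------------------------------------------------

def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd <= 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def _skewed_probs(levels: int, rng) -> np.ndarray:
    dominant = rng.uniform(0.4, 0.7)
    rest = rng.dirichlet(np.ones(levels - 1)) * (1.0 - dominant)
    probs = np.concatenate([[dominant], rest])
    rng.shuffle(probs)
    return probs


def _sample_multinomial(probs: np.ndarray, n: int, rng) -> np.ndarray:
    if probs.ndim == 1:
        cdf = np.cumsum(probs)
        return np.searchsorted(cdf, rng.random(n)).astype(np.int64)
    cdf = np.cumsum(probs, axis=1)
    u = rng.random(n)[:, None]
    return (u > cdf).sum(axis=1).astype(np.int64)


def simulate_sem(dag: nx.DiGraph, specs: list[VariableSpec], n: int,
                 seed: int = 0,
                 effect_range: tuple[float, float] = (0.3, 1.0)) -> DataTable:
    """Sample n rows from a mixed-type SEM on the DAG (topological order).

    Roots: bimodal location-mixture for continuous nodes, skewed multinomial
    for categorical ones.  A parent contributes a z-scored effect scaled to a
    standardized magnitude drawn in [0.3, 1.0] (random sign for continuous
    children); continuous children add unit Gaussian noise, categorical
    children sample from a multinomial logit over the same parent effects.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    spec_by = {s.name: s for s in specs}
    values: dict[str, np.ndarray] = {}

    def parent_effect(parent: str, rng) -> np.ndarray:
        s = spec_by[parent]
        if s.vtype == CONTINUOUS:
            return _zscore(values[parent])
        eff = rng.normal(size=len(s.levels))
        return _zscore(eff[values[parent]])

    for node in nx.topological_sort(dag):
        s = spec_by[node]
        parents = sorted(dag.predecessors(node))
        if not parents:
            if s.vtype == CONTINUOUS:
                w = rng.uniform(0.3, 0.7)
                delta = rng.uniform(1.0, 3.0)
                comp = rng.random(n) < w
                values[node] = rng.normal(0.0, 1.0, size=n) + np.where(
                    comp, delta / 2.0, -delta / 2.0
                )
            else:
                probs = _skewed_probs(len(s.levels), rng)
                values[node] = _sample_multinomial(probs, n, rng)
            continue
        if s.vtype == CONTINUOUS:
            eff = np.zeros(n)
            for parent in parents:
                scale = rng.uniform(*effect_range)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                eff += sign * scale * parent_effect(parent, rng)
            values[node] = eff + rng.normal(0.0, 1.0, size=n)
        else:
            levels = len(s.levels)
            logits = np.zeros((n, levels))
            for parent in parents:
                scale = rng.uniform(*effect_range)
                ps = spec_by[parent]
                if ps.vtype == CONTINUOUS:
                    coef = rng.normal(size=levels)
                    contrib = np.outer(_zscore(values[parent]), coef)
                else:
                    emat = rng.normal(size=(len(ps.levels), levels))
                    contrib = emat[values[parent]]
                sd = contrib.std()
                if sd > 0:
                    contrib = contrib / sd * scale
                logits += contrib
            logits -= logits.max(axis=1, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            values[node] = _sample_multinomial(probs, n, rng)

    columns = {}
    for s in specs:
        if s.vtype == CONTINUOUS:
            columns[s.name] = values[s.name].astype(float)
        else:
            columns[s.name] = values[s.name].astype(np.int64)
    return DataTable(specs=[VariableSpec(s.name, s.vtype, s.is_contextual,
                                         s.levels) for s in specs],
                     columns=columns, n_samples=n)


# ---------------------------------------------------------------------------
# CPDAG
# ---------------------------------------------------------------------------

@dataclass
class CPDAG:
    """Markov-equivalence class of a DAG: compelled edges directed,
    reversible edges undirected."""

    nodes: list
    oriented: dict  # pair_key -> (tail, head)
    undirected: set  # pair_key set

    @property
    def skeleton_pairs(self) -> set:
        return set(self.oriented) | self.undirected


def dag_to_cpdag(dag: nx.DiGraph) -> CPDAG:
    """Compelled-edge closure: v-structures, then the standard orientation
    rules applied to a fixed point."""
    adj: dict = {n: set() for n in dag.nodes}
    for u, v in dag.edges:
        adj[u].add(v)
        adj[v].add(u)
    oriented: dict = {}
    undirected = {pair_key(u, v) for u, v in dag.edges}

    def orient(u, v):  # u -> v
        key = pair_key(u, v)
        if key in undirected:
            undirected.discard(key)
            oriented[key] = (u, v)
            return True
        return False

    for z in dag.nodes:
        parents = sorted(dag.predecessors(z))
        for u, v in itertools.combinations(parents, 2):
            if v not in adj[u]:
                orient(u, z)
                orient(v, z)

    changed = True
    while changed:
        changed = False
        for key in sorted(undirected):
            a, b = key
            for x, y in ((a, b), (b, a)):
                # R1: w -> x, x - y, w and y non-adjacent  =>  x -> y
                for w in adj[x]:
                    o = oriented.get(pair_key(w, x))
                    if o == (w, x) and y not in adj[w] and w != y:
                        if orient(x, y):
                            changed = True
                        break
                if pair_key(x, y) in oriented:
                    break
                # R2: x -> w -> y with x - y  =>  x -> y
                for w in adj[x] & adj[y]:
                    if oriented.get(pair_key(x, w)) == (x, w) and oriented.get(
                        pair_key(w, y)
                    ) == (w, y):
                        if orient(x, y):
                            changed = True
                        break
                if pair_key(x, y) in oriented:
                    break
                # R3: x - w1 -> y, x - w2 -> y, w1,w2 non-adjacent, x - y
                ws = [
                    w
                    for w in adj[x] & adj[y]
                    if pair_key(x, w) in undirected
                    and oriented.get(pair_key(w, y)) == (w, y)
                ]
                done = False
                for w1, w2 in itertools.combinations(sorted(ws), 2):
                    if w2 not in adj[w1]:
                        if orient(x, y):
                            changed = True
                        done = True
                        break
                if done:
                    break
    return CPDAG(nodes=sorted(dag.nodes), oriented=oriented,
                 undirected=undirected)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass
class LevelScore:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f_score(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class ScoreReport:
    skeleton: LevelScore
    cpdag: LevelScore
    oriented: LevelScore


def inferred_orientation(graph: MixedGraph, beta: float = 0.5):
    """pair -> ('bi', None) | ('dir', head_node) | ('undir', None)."""
    out = {}
    for e in graph.present_edges():
        hx = e.end_x.mark == HEAD and e.end_x.p_head > beta
        hy = e.end_y.mark == HEAD and e.end_y.p_head > beta
        if hx and hy:
            out[pair_key(e.x, e.y)] = ("bi", None)
        elif hx:
            out[pair_key(e.x, e.y)] = ("dir", e.x)
        elif hy:
            out[pair_key(e.x, e.y)] = ("dir", e.y)
        else:
            out[pair_key(e.x, e.y)] = ("undir", None)
    return out


def score_graphs(truth: CPDAG, inferred: MixedGraph,
                 beta: float = 0.5) -> ScoreReport:
    if set(truth.nodes) != set(inferred.names):
        raise ValueError("truth and inferred graphs have different node sets")
    inf = inferred_orientation(inferred, beta)
    s_t = truth.skeleton_pairs
    s_i = set(inf)

    common = s_t & s_i
    skel = LevelScore(len(common), len(s_i - s_t), len(s_t - s_i))

    # CPDAG: mark-mismatched common edges become false positives
    match = 0
    for key in common:
        kind, head = inf[key]
        if key in truth.undirected:
            ok = kind == "undir"
        else:
            ok = kind == "dir" and head == truth.oriented[key][1]
        if ok:
            match += 1
    cpdag = LevelScore(match, len(s_i - s_t) + (len(common) - match),
                       len(s_t - s_i))

    t_o = set(truth.oriented)
    i_o = {k for k, (kind, _) in inf.items() if kind in ("dir", "bi")}
    tp = 0
    for key in t_o & i_o:
        kind, head = inf[key]
        if kind == "bi" or head == truth.oriented[key][1]:
            tp += 1
    oriented = LevelScore(tp, len(i_o) - tp, len(t_o) - tp)
    return ScoreReport(skeleton=skel, cpdag=cpdag, oriented=oriented)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkInstance:
    dag: nx.DiGraph
    specs: list[VariableSpec]
    cpdag: CPDAG
    sample: DataTable
    seed: int


def generate_instance(
    n: int,
    discrete_prop: float = 0.8,
    p: int = 51,
    mean_degree: float = 11.0,
    seed: int = 0,
    effect_range: tuple[float, float] = (0.3, 1.0),
) -> BenchmarkInstance:
    """One benchmark network + sampled table (all stages seeded from one
    root seed)."""
    rng = np.random.default_rng(seed)
    s1, s2, s3, s4 = rng.integers(2**31 - 1, size=4)
    skel = generate_skeleton(p, seed=int(s1), mean_degree=mean_degree)
    dag = orient_to_dag(skel, seed=int(s2))
    specs = assign_specs(dag.nodes, discrete_prop, seed=int(s3))
    sample = simulate_sem(dag, specs, n, seed=int(s4), effect_range=effect_range)
    return BenchmarkInstance(dag=dag, specs=specs, cpdag=dag_to_cpdag(dag),
                             sample=sample, seed=seed)


def run_benchmark(
    n_networks: int = 10,
    n_samples: int = 500,
    discrete_prop: float = 0.8,
    p: int = 51,
    mean_degree: float = 11.0,
    seed: int = 1,
    beta: float = 0.5,
    propagate: bool = True,
    consistency: str = "none",
    max_cond: int = 20,
    engine_opts: dict | None = None,
) -> pd.DataFrame:
    """Generate -> simulate -> learn -> orient -> score over ``n_networks``
    instances (seeds seed..seed+n_networks-1); returns per-network rows plus
    a mean row."""
    rows = []
    for i in range(n_networks):
        inst = generate_instance(
            n_samples, discrete_prop=discrete_prop, p=p,
            mean_degree=mean_degree, seed=seed + i,
        )
        result = learn_consistent(
            inst.sample,
            ConsistencyConfig(level=consistency),
            beta=beta,
            propagate=propagate,
            max_cond=max_cond,
            engine_opts=engine_opts,
        )
        rep = score_graphs(inst.cpdag, result.graph, beta=beta)
        row = {"network": seed + i, "n": n_samples,
               "discrete_prop": discrete_prop}
        for level in ("skeleton", "cpdag", "oriented"):
            ls = getattr(rep, level)
            row[f"{level}_precision"] = ls.precision
            row[f"{level}_recall"] = ls.recall
            row[f"{level}_f"] = ls.f_score
        rows.append(row)
    df = pd.DataFrame(rows)
    mean = df.mean(numeric_only=True)
    mean["network"] = -1
    df = pd.concat([df, mean.to_frame().T], ignore_index=True)
    return df
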