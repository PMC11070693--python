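"""Benchmark generator, CPDAG computation and the scoring harness."""

import itertools

import networkx as nx
import numpy as np
import pytest

from causalmi.benchmark import (
    LevelScore,
    dag_to_cpdag,
    generate_instance,
    generate_skeleton,
    orient_to_dag,
    run_benchmark,
    score_graphs,
    simulate_sem,
)
from causalmi.core import MixedGraph, VariableSpec, pair_key
from causalmi.skeleton import learn_skeleton


class TestGenerateSkeleton:
    def test_triangle_from_degrees_222(self):
        g = generate_skeleton(3, degree_sequence=[2, 2, 2], jitter=0, seed=0)
        assert g.number_of_edges() == 3

    def test_deterministic(self):
        a = generate_skeleton(20, seed=5)
        b = generate_skeleton(20, seed=5)
        assert set(a.edges) == set(b.edges)

    def test_preset_mean_edges_near_280(self):
        counts = [generate_skeleton(51, seed=s).number_of_edges()
                  for s in range(50)]
        assert abs(np.mean(counts) - 280) < 28

    def test_infeasible_sequence_raises(self):
        with pytest.raises(ValueError):
            generate_skeleton(3, degree_sequence=[5, 5, 5], jitter=0, seed=0)


class TestOrientToDag:
    @pytest.mark.parametrize("seed", range(10))
    def test_always_acyclic(self, seed):
        skel = generate_skeleton(15, seed=seed, mean_degree=4)
        dag = orient_to_dag(skel, seed=seed)
        assert nx.is_directed_acyclic_graph(dag)
        assert dag.number_of_edges() == skel.number_of_edges()

    def test_triangle_has_three_shapes(self):
        skel = generate_skeleton(3, degree_sequence=[2, 2, 2], jitter=0, seed=0)
        shapes = {frozenset(orient_to_dag(skel, seed=s).edges)
                  for s in range(60)}
        # 6 orderings of 3 nodes collapse onto at most 6 edge sets; the
        # triangle admits exactly 6 acyclic orientations
        assert 3 <= len(shapes) <= 6
        assert all(
            nx.is_directed_acyclic_graph(nx.DiGraph(list(s))) for s in shapes
        )

    def test_deterministic(self):
        skel = generate_skeleton(10, seed=1, mean_degree=3)
        assert set(orient_to_dag(skel, 7).edges) == set(orient_to_dag(skel, 7).edges)


class TestSimulateSem:
    def test_seeded_reproducibility(self):
        inst1 = generate_instance(200, discrete_prop=0.5, p=10,
                                  mean_degree=3, seed=4)
        inst2 = generate_instance(200, discrete_prop=0.5, p=10,
                                  mean_degree=3, seed=4)
        for name in inst1.sample.names:
            assert np.array_equal(inst1.sample.columns[name],
                                  inst2.sample.columns[name], equal_nan=True)

    def test_n_must_be_positive(self):
        dag = nx.DiGraph()
        dag.add_edge("A", "B")
        specs = [VariableSpec("A"), VariableSpec("B")]
        with pytest.raises(ValueError):
            simulate_sem(dag, specs, 0)

    def test_zero_effects_give_independence(self):
        """With all parent effects forced to zero every pair is independent
        by construction and the estimators report exact zeros."""
        hits = 0
        for seed in range(10):
            inst = generate_instance(2000, discrete_prop=0.5, p=6,
                                     mean_degree=2, seed=seed,
                                     effect_range=(0.0, 0.0))
            g, _ = learn_skeleton(inst.sample)
            if not g.present_edges():
                hits += 1
        assert hits >= 9

    def test_two_node_edge_recovered_with_consistent_sign(self):
        dag = nx.DiGraph()
        dag.add_edge("A", "B")
        specs = [VariableSpec("A"), VariableSpec("B")]
        data = simulate_sem(dag, specs, 1500, seed=3, effect_range=(0.9, 1.0))
        g, _ = learn_skeleton(data)
        e = g.edge("A", "B")
        assert e.present
        from scipy.stats import spearmanr

        rho = spearmanr(data.columns["A"], data.columns["B"]).statistic
        assert e.sign == ("positive" if rho > 0 else "negative")

    def test_discrete_proportion_respected(self):
        inst = generate_instance(50, discrete_prop=0.8, p=20, mean_degree=3,
                                 seed=0)
        n_cat = sum(1 for s in inst.specs if s.vtype == "categorical")
        assert n_cat == 16


def brute_force_cpdag(dag: nx.DiGraph):
    """Compelled edges by enumerating every acyclic orientation of the
    skeleton with the same v-structures."""
    nodes = sorted(dag.nodes)
    edges = [pair_key(u, v) for u, v in dag.edges]
    adjacent = set(edges)

    def vstructs(orient):
        parents = {}
        for (u, v) in orient.values():
            parents.setdefault(v, set()).add(u)
        out = set()
        for z, ps in parents.items():
            for a, b in itertools.combinations(sorted(ps), 2):
                if pair_key(a, b) not in adjacent:
                    out.add((a, z, b))
        return out

    base = {pair_key(u, v): (u, v) for u, v in dag.edges}
    target = vstructs(base)
    dirs_seen = {key: set() for key in edges}
    for bits in itertools.product([0, 1], repeat=len(edges)):
        orient = {}
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for key, b in zip(edges, bits):
            u, v = key if b == 0 else (key[1], key[0])
            orient[key] = (u, v)
            g.add_edge(u, v)
        if not nx.is_directed_acyclic_graph(g):
            continue
        if vstructs(orient) != target:
            continue
        for key, d in orient.items():
            dirs_seen[key].add(d)
    oriented = {k: next(iter(d)) for k, d in dirs_seen.items() if len(d) == 1}
    undirected = {k for k, d in dirs_seen.items() if len(d) > 1}
    return oriented, undirected


class TestDagToCpdag:
    def test_chain_fully_undirected(self):
        c = dag_to_cpdag(nx.DiGraph([("A", "B"), ("B", "C")]))
        assert c.oriented == {} and len(c.undirected) == 2

    def test_collider_kept(self):
        c = dag_to_cpdag(nx.DiGraph([("A", "B"), ("C", "B")]))
        assert c.undirected == set()
        assert c.oriented == {("A", "B"): ("A", "B"), ("B", "C"): ("C", "B")}

    @pytest.mark.parametrize("p", [3, 4])
    def test_matches_exhaustive_oracle_small(self, p):
        rng = np.random.default_rng(0)
        nodes = [f"n{i}" for i in range(p)]
        pairs = list(itertools.combinations(nodes, 2))
        for mask in range(2 ** len(pairs)):
            present = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
            perm = {n: i for i, n in enumerate(rng.permutation(nodes))}
            dag = nx.DiGraph()
            dag.add_nodes_from(nodes)
            for u, v in present:
                dag.add_edge(*((u, v) if perm[u] < perm[v] else (v, u)))
            c = dag_to_cpdag(dag)
            o, u_ = brute_force_cpdag(dag)
            assert c.oriented == o and c.undirected == u_


class TestScoreGraphs:
    def test_perfect_recovery_scores_one(self):
        inst = generate_instance(50, discrete_prop=0.5, p=8, mean_degree=2,
                                 seed=2)
        g = MixedGraph(nodes=[VariableSpec(n) for n in inst.cpdag.nodes])
        for key in inst.cpdag.skeleton_pairs:
            e = g.edges[key]
            e.present = True
            e.sepset = None
            if key in inst.cpdag.oriented:
                _, head = inst.cpdag.oriented[key]
                end = e.endpoint(head)
                end.mark = "head"
                end.p_head = 0.95
        rep = score_graphs(inst.cpdag, g)
        for level in (rep.skeleton, rep.cpdag, rep.oriented):
            assert level.precision == level.recall == level.f_score == 1.0

    def test_closed_form_identities(self):
        s = LevelScore(tp=9, fp=1, fn=3)
        assert s.precision == pytest.approx(0.9)
        assert s.recall == pytest.approx(0.75)
        assert s.f_score == pytest.approx(2 * 0.9 * 0.75 / 1.65)

    def test_empty_inferred_graph_conventions(self):
        inst = generate_instance(50, discrete_prop=0.5, p=6, mean_degree=2,
                                 seed=3)
        g = MixedGraph(nodes=[VariableSpec(n) for n in inst.cpdag.nodes])
        for e in g.edges.values():
            e.sepset = []
        rep = score_graphs(inst.cpdag, g)
        assert rep.skeleton.recall == 0.0 and rep.skeleton.precision == 0.0

    def test_node_mismatch_rejected(self):
        inst = generate_instance(50, discrete_prop=0.5, p=6, mean_degree=2,
                                 seed=3)
        g = MixedGraph(nodes=[VariableSpec("other")] + [
            VariableSpec(n) for n in inst.cpdag.nodes[:-1]])
        with pytest.raises(ValueError):
            score_graphs(inst.cpdag, g)


class TestRunBenchmark:
    def test_small_sweep_shape_and_determinism(self):
        kw = dict(n_networks=2, n_samples=250, discrete_prop=0.5, p=10,
                  mean_degree=3, seed=11)
        df1 = run_benchmark(**kw)
        df2 = run_benchmark(**kw)
        assert len(df1) == 3  # 2 networks + mean row
        assert df1.equals(df2)
        mean_row = df1.iloc[-1]
        col = "oriented_precision"
        assert df1[col][:2].min() - 1e-12 <= mean_row[col] <= df1[col][:2].max() + 1e-12
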