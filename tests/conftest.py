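"""Shared simulators and fixtures.

All test data is generated programmatically with seeded generators; the
structures below are the canonical 3-5 node motifs (collider, chain, fork,
hidden confounder) whose d-separation properties are known in closed form.
"""

from __future__ import annotations

import numpy as np
import pytest

from causalmi.core import (
    CATEGORICAL,
    CONTINUOUS,
    DataTable,
    EndpointMark,
    MixedGraph,
    VariableSpec,
)


def cat_table(columns: dict[str, np.ndarray], n_levels: int = 2,
              contextual=()) -> DataTable:
    specs = [
        VariableSpec(k, CATEGORICAL, is_contextual=k in contextual,
                     levels=tuple(str(i) for i in range(n_levels)))
        for k in columns
    ]
    n = len(next(iter(columns.values())))
    return DataTable(specs=specs,
                     columns={k: v.astype(np.int64) for k, v in columns.items()},
                     n_samples=n)


def cont_table(columns: dict[str, np.ndarray], contextual=()) -> DataTable:
    specs = [VariableSpec(k, CONTINUOUS, is_contextual=k in contextual)
             for k in columns]
    n = len(next(iter(columns.values())))
    return DataTable(specs=specs,
                     columns={k: v.astype(float) for k, v in columns.items()},
                     n_samples=n)


def binary_motif(kind: str, n: int = 2000, seed: int = 0,
                 strength: float = 2.0, contextual=()) -> DataTable:
    """Binary-variable collider / chain / fork / independent triple.

    Children follow a logistic response to the sum of their parents, so all
    pairwise margins are dependent (unlike XOR-style colliders).
    """
    rng = np.random.default_rng(seed)

    def child(*parents):
        drive = sum(parents)
        p = 1.0 / (1.0 + np.exp(-strength * (drive - len(parents) / 2.0)))
        return (rng.random(n) < p).astype(np.int64)

    if kind == "collider":
        x = rng.integers(0, 2, n)
        y = rng.integers(0, 2, n)
        z = child(x, y)
    elif kind == "chain":
        x = rng.integers(0, 2, n)
        z = child(x)
        y = child(z)
    elif kind == "fork":
        z = rng.integers(0, 2, n)
        x = child(z)
        y = child(z)
    elif kind == "independent":
        x, z, y = (rng.integers(0, 2, n) for _ in range(3))
    else:
        raise ValueError(kind)
    return cat_table({"X": x, "Z": z, "Y": y}, contextual=contextual)


def gaussian_motif(kind: str, n: int = 2000, seed: int = 0,
                   b: float = 0.8) -> DataTable:
    rng = np.random.default_rng(seed)
    e = lambda: rng.normal(size=n)
    if kind == "collider":
        x, y = e(), e()
        z = b * x + b * y + e()
    elif kind == "chain":
        x = e()
        z = b * x + e()
        y = b * z + e()
    elif kind == "fork":
        z = e()
        x = b * z + e()
        y = b * z + e()
    elif kind == "independent":
        x, z, y = e(), e(), e()
    else:
        raise ValueError(kind)
    return cont_table({"X": x, "Z": z, "Y": y})


def hidden_confounder(n: int = 5000, seed: int = 0, flip: float = 0.1) -> DataTable:
    """W -> X <- L -> Z <- V with the common cause L unobserved.

    X and Z are 3-level sums of their binary parents (with label noise), so
    all retained margins are dependent and the two v-structures around the
    hidden variable force a bidirected X-Z edge.
    """
    rng = np.random.default_rng(seed)

    def noisy3(v):
        out = v.copy()
        m = rng.random(n) < flip
        out[m] = rng.integers(0, 3, m.sum())
        return out

    w = rng.integers(0, 2, n)
    v = rng.integers(0, 2, n)
    latent = rng.integers(0, 2, n)
    x = noisy3(w + latent)
    z = noisy3(latent + v)
    return cat_table({"W": w, "X": x, "Z": z, "V": v}, n_levels=3)


def random_mixed_graph(seed: int, p: int = 5) -> MixedGraph:
    """Random fully-specified MixedGraph for writer round-trip tests."""
    rng = np.random.default_rng(seed)
    specs = [
        VariableSpec(
            f"n{i}",
            CATEGORICAL if rng.random() < 0.5 else CONTINUOUS,
            is_contextual=bool(rng.random() < 0.2),
            levels=("a", "b") if rng.random() < 0.5 else None,
        )
        for i in range(p)
    ]
    for s in specs:
        if s.vtype == CONTINUOUS:
            s.levels = None
        elif s.levels is None:
            s.levels = ("a", "b")
    g = MixedGraph(nodes=specs)
    for e in g.edges.values():
        if rng.random() < 0.5:
            e.sepset = sorted(
                rng.choice([s.name for s in specs], size=rng.integers(0, 2),
                           replace=False).tolist()
            )
            continue
        e.present = True
        e.sepset = None
        e.info_reg = float(np.round(rng.random(), 6))
        e.sign = ["positive", "negative", "na"][rng.integers(3)]
        kind = rng.integers(4)
        if kind == 0:
            e.end_x, e.end_y = EndpointMark(), EndpointMark()
            e.status = "undirected"
        elif kind == 1:
            e.end_y = EndpointMark("head", 0.9, 0.1, 2.2)
            e.status = "putative"
        elif kind == 2:
            e.end_y = EndpointMark("head", 0.9, 0.1, 2.2)
            e.end_x = EndpointMark("tail", 0.2, 0.8, 1.4)
            e.status = "genuine"
        else:
            e.end_x = EndpointMark("head", 0.8, 0.2, 1.4)
            e.end_y = EndpointMark("head", 0.7, 0.3, 0.9)
            e.status = "bidirected"
    return g


def graphs_equal(a: MixedGraph, b: MixedGraph, marks_only: bool = False) -> bool:
    if sorted(a.names) != sorted(b.names):
        return False
    for key, ea in a.edges.items():
        eb = b.edges[key]
        if ea.present != eb.present:
            return False
        if marks_only:
            if ea.present and (ea.end_x.mark != eb.end_x.mark
                               or ea.end_y.mark != eb.end_y.mark):
                return False
            continue
        if (ea.status != eb.status or ea.sign != eb.sign
                or ea.sepset != eb.sepset
                or abs(ea.info_reg - eb.info_reg) > 1e-12):
            return False
        for ma, mb in ((ea.end_x, eb.end_x), (ea.end_y, eb.end_y)):
            if ma.mark != mb.mark:
                return False
            if abs(ma.p_head - mb.p_head) > 1e-12 or abs(ma.p_tail - mb.p_tail) > 1e-12:
                return False
    return True


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
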