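"""Core domain types and readers/writers.

The package works on rectangular sample-by-variable tables mixing continuous
and categorical variables, with optional missing values.  Graphs are *mixed
graphs*: every unordered pair of variables carries an edge state whose two
endpoints each hold a mark (head / tail / undefined) together with separate
head and tail probabilities.  This endpoint-level bookkeeping is what allows
the method to distinguish genuine causes (head one side, tail the other),
putative causes (a single significant head), latent common causes (two heads,
drawn as a bidirected edge) and plain undirected edges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = "NA"

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

HEAD = "head"
TAIL = "tail"
UNDEFINED = "undefined"

GENUINE = "genuine"
PUTATIVE = "putative"
BIDIRECTED = "bidirected"
UNDIRECTED = "undirected"
ABSENT = "absent"


class DataError(ValueError):
    """Raised on malformed tables or variable specifications."""


@dataclass
class VariableSpec:
    """Declaration of one column: its name, type and contextual flag.

    Contextual variables (e.g. sex, year of birth) are externally fixed:
    they cannot be the consequence of any observed or unobserved variable,
    which the orientation step encodes as a permanent tail (p_tail = 1) at
    every one of their edge endpoints.
    """

    name: str
    vtype: str = CONTINUOUS
    is_contextual: bool = False
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.vtype not in (CONTINUOUS, CATEGORICAL):
            raise DataError(f"unknown vtype {self.vtype!r} for {self.name!r}")
        if self.levels is not None:
            self.levels = tuple(self.levels)


@dataclass
class DataTable:
    """Validated samples-by-variables table.

    Continuous columns are stored as float arrays (NaN = missing) and
    categorical columns as integer level codes (-1 = missing), which is the
    representation the information estimators consume directly.
    """

    specs: list[VariableSpec]
    columns: dict[str, np.ndarray]
    n_samples: int

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise DataError("duplicate variable names")
        if len(names) < 2:
            raise DataError("need at least 2 variables")
        if self.n_samples < 2:
            raise DataError("need at least 2 samples")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, specs: list[VariableSpec]) -> "DataTable":
        spec_names = [s.name for s in specs]
        for name in spec_names:
            if name not in df.columns:
                raise DataError(f"spec lists column {name!r} absent from the table")
        columns: dict[str, np.ndarray] = {}
        out_specs: list[VariableSpec] = []
        for s in specs:
            raw = df[s.name]
            missing = raw.isna() | (raw.astype(str).str.strip().isin(["", MISSING]))
            if s.vtype == CONTINUOUS:
                vals = np.full(len(df), np.nan)
                ok = ~missing
                try:
                    vals[ok.to_numpy()] = pd.to_numeric(
                        raw[ok], errors="raise"
                    ).to_numpy(dtype=float)
                except (ValueError, TypeError):
                    conv = pd.to_numeric(raw[ok], errors="coerce")
                    bad = conv.index[conv.isna()][0]
                    raise DataError(
                        f"non-numeric cell in continuous column {s.name!r} at row {bad}"
                    ) from None
                columns[s.name] = vals
                out_specs.append(replace(s, levels=None))
            else:
                labels = raw.astype(str).str.strip().where(~missing, other=None)
                observed = sorted({v for v in labels.dropna().unique()})
                levels = tuple(s.levels) if s.levels else tuple(observed)
                unknown = set(observed) - set(levels)
                if unknown:
                    raise DataError(
                        f"column {s.name!r} has labels {sorted(unknown)} outside its levels"
                    )
                if len(observed) < 2:
                    raise DataError(
                        f"categorical column {s.name!r} has fewer than 2 observed levels"
                    )
                lookup = {lv: i for i, lv in enumerate(levels)}
                codes = np.array(
                    [-1 if v is None else lookup[v] for v in labels], dtype=np.int64
                )
                columns[s.name] = codes
                out_specs.append(replace(s, levels=levels))
        return cls(specs=out_specs, columns=columns, n_samples=len(df))

    def to_dataframe(self) -> pd.DataFrame:
        data = {}
        for s in self.specs:
            col = self.columns[s.name]
            if s.vtype == CONTINUOUS:
                data[s.name] = col
            else:
                labels = np.array(list(s.levels) + [None], dtype=object)
                data[s.name] = labels[col]
        return pd.DataFrame(data)


@dataclass
class EndpointMark:
    """Mark and separate head/tail probabilities at one edge extremity."""

    mark: str = UNDEFINED
    p_head: float = 0.5
    p_tail: float = 0.5
    score: float = 0.0  # orientation score that placed the mark (internal)

    def significant_head(self, beta: float) -> bool:
        return self.p_head > beta

    def significant_tail(self, beta: float) -> bool:
        return self.p_tail > beta


@dataclass
class EdgeState:
    """Full state of one unordered variable pair."""

    x: str
    y: str
    present: bool = False
    end_x: EndpointMark = field(default_factory=EndpointMark)
    end_y: EndpointMark = field(default_factory=EndpointMark)
    status: str = ABSENT
    info_reg: float = 0.0
    sign: str = "na"
    sepset: list[str] | None = None
    residual_info: float = 0.0

    def endpoint(self, node: str) -> EndpointMark:
        if node == self.x:
            return self.end_x
        if node == self.y:
            return self.end_y
        raise KeyError(node)

    def other(self, node: str) -> str:
        return self.y if node == self.x else self.x


def pair_key(x: str, y: str) -> tuple[str, str]:
    return (x, y) if x < y else (y, x)


@dataclass
class MixedGraph:
    """Nodes plus one EdgeState per unordered pair (total map)."""

    nodes: list[VariableSpec]
    edges: dict[tuple[str, str], EdgeState] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.nodes]
        for x, y in itertools.combinations(sorted(names), 2):
            self.edges.setdefault((x, y), EdgeState(x=x, y=y))

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.nodes]

    def edge(self, x: str, y: str) -> EdgeState:
        return self.edges[pair_key(x, y)]

    def present_edges(self) -> list[EdgeState]:
        return [e for e in self.edges.values() if e.present]

    def neighbors(self, node: str) -> list[str]:
        out = []
        for e in self.edges.values():
            if e.present and node in (e.x, e.y):
                out.append(e.other(node))
        return sorted(out)

    def adjacent(self, x: str, y: str) -> bool:
        return self.edges[pair_key(x, y)].present

    def spec(self, name: str) -> VariableSpec:
        for s in self.nodes:
            if s.name == name:
                return s
        raise KeyError(name)

    def canonical_signature(self) -> tuple:
        """Hashable serialization of (edge set, mark set); used for limit-cycle
        detection during the consistency iteration."""
        items = []
        for key in sorted(self.edges):
            e = self.edges[key]
            if e.present:
                items.append((key, e.end_x.mark, e.end_y.mark))
        return tuple(items)


# ---------------------------------------------------------------------------
# table / spec readers
# ---------------------------------------------------------------------------

def read_variable_specs(path) -> list[VariableSpec]:
    """Read a TSV/CSV spec file with columns: name, vtype, contextual."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    for need in ("name", "vtype"):
        if need not in cols:
            raise DataError(f"spec file lacks required column {need!r}")
    specs = []
    for _, row in df.iterrows():
        ctx = False
        if "contextual" in cols:
            ctx = str(row[cols["contextual"]]).strip().lower() in (
                "1", "true", "yes", "y",
            )
        specs.append(
            VariableSpec(
                name=str(row[cols["name"]]).strip(),
                vtype=str(row[cols["vtype"]]).strip().lower(),
                is_contextual=ctx,
            )
        )
    return specs


def write_variable_specs(specs: list[VariableSpec], path) -> None:
    df = pd.DataFrame(
        {
            "name": [s.name for s in specs],
            "vtype": [s.vtype for s in specs],
            "contextual": [int(s.is_contextual) for s in specs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_table(path, spec_path) -> DataTable:
    """Read a CSV/TSV data table with its variable-spec file.

    The delimiter is auto-detected; empty cells and the literal ``NA`` are
    treated as missing.
    """
    specs = read_variable_specs(spec_path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ("," if "," in header else
                                       (";" if ";" in header else "\t"))
    df = pd.read_csv(path, sep=sep, dtype=str,
                     keep_default_na=False, na_values=[])
    return DataTable.from_dataframe(df, specs)


# ---------------------------------------------------------------------------
# graph writers / readers
# ---------------------------------------------------------------------------

_ADJ_ABSENT = 0
_ADJ_UNDIRECTED = 1
_ADJ_HEAD = 2       # arrowhead into the column variable
_ADJ_TAIL = -2
_ADJ_BIDIRECTED = 6


def _fmt(v: float) -> str:
    return repr(float(v))


def write_edge_summary(graph: MixedGraph, contributions, path) -> None:
    """Write one TSV row per unordered variable pair (deterministic order).

    ``contributions`` is a ContributionTable (or None); its rows are folded
    into a ``contributor:percentage`` list column.
    """
    contrib_map: dict[tuple[str, str], str] = {}
    if contributions is not None:
        contrib_map = contributions.summary_column()
    rows = []
    for key in sorted(graph.edges):
        e = graph.edges[key]
        rows.append(
            {
                "x": e.x,
                "y": e.y,
                "status": e.status,
                "info_reg": _fmt(e.info_reg),
                "sign": e.sign,
                "p_head_x": _fmt(e.end_x.p_head),
                "p_tail_x": _fmt(e.end_x.p_tail),
                "p_head_y": _fmt(e.end_y.p_head),
                "p_tail_y": _fmt(e.end_y.p_tail),
                "sepset": ";".join(e.sepset) if e.sepset is not None else "",
                "contributions": contrib_map.get(key, ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_edge_summary(path, node_names=None) -> MixedGraph:
    """Rebuild a MixedGraph from an edge-summary TSV (marks inferred from the
    stored head/tail probabilities)."""
    df = pd.read_csv(path, sep="\t", dtype={"x": str, "y": str},
                     keep_default_na=False)
    names = sorted(set(df["x"]) | set(df["y"]) | set(node_names or ()))
    g = MixedGraph(nodes=[VariableSpec(n) for n in names])
    for _, row in df.iterrows():
        key = pair_key(str(row["x"]), str(row["y"]))
        e = g.edges[key]
        e.info_reg = float(row["info_reg"])
        e.sign = str(row["sign"])
        if row["status"] == ABSENT:
            sep = str(row["sepset"])
            e.sepset = sep.split(";") if sep else []
            continue
        e.present = True
        e.sepset = None
        e.status = str(row["status"])
        for end, suffix in ((e.end_x, "x"), (e.end_y, "y")):
            ph = float(row[f"p_head_{suffix}"])
            pt = float(row[f"p_tail_{suffix}"])
            end.p_head, end.p_tail = ph, pt
            end.mark = HEAD if ph > 0.5 else (TAIL if pt > 0.5 else UNDEFINED)
    return g


def _mark_from_probs(p_head: float, p_tail: float) -> str:
    if p_head >= 0.5 and p_head >= p_tail and p_head > 0.5:
        return HEAD
    if p_tail > 0.5:
        return TAIL
    return UNDEFINED


def write_graph(graph: MixedGraph, path, format: str = "adjacency_tsv") -> None:
    if format == "adjacency_tsv":
        _write_adjacency(graph, path)
    elif format == "graphml":
        _write_graphml(graph, path)
    elif format == "dot":
        _write_dot(graph, path)
    else:
        raise ValueError(f"unknown graph format {format!r}")


def read_graph(path, format: str, specs: list[VariableSpec] | None = None) -> MixedGraph:
    if format == "adjacency_tsv":
        return _read_adjacency(path, specs)
    if format == "graphml":
        return _read_graphml(path)
    if format == "dot":
        return _read_dot(path)
    raise ValueError(f"unknown graph format {format!r}")


def _adj_codes(e: EdgeState) -> tuple[int, int]:
    """Codes at (row=x looking toward y) and (row=y looking toward x)."""
    if not e.present:
        return _ADJ_ABSENT, _ADJ_ABSENT
    hx = e.end_x.mark == HEAD
    hy = e.end_y.mark == HEAD
    if hx and hy:
        return _ADJ_BIDIRECTED, _ADJ_BIDIRECTED
    if hy:  # arrow into y
        return _ADJ_HEAD, _ADJ_TAIL if e.end_x.mark == TAIL else _ADJ_UNDIRECTED
    if hx:
        return _ADJ_TAIL if e.end_y.mark == TAIL else _ADJ_UNDIRECTED, _ADJ_HEAD
    return _ADJ_UNDIRECTED, _ADJ_UNDIRECTED


def _write_adjacency(graph: MixedGraph, path) -> None:
    names = sorted(graph.names)
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for e in graph.present_edges():
        toward_y, toward_x = _adj_codes(e)
        mat.loc[e.x, e.y] = toward_y
        mat.loc[e.y, e.x] = toward_x
    mat.to_csv(path, sep="\t", index_label="")


def _read_adjacency(path, specs) -> MixedGraph:
    mat = pd.read_csv(path, sep="\t", index_col=0)
    names = [str(c) for c in mat.columns]
    if specs is None:
        specs = [VariableSpec(name=n, vtype=CONTINUOUS) for n in names]
    g = MixedGraph(nodes=specs)
    for x, y in itertools.combinations(sorted(names), 2):
        cxy = int(mat.loc[x, y])
        cyx = int(mat.loc[y, x])
        e = g.edges[(x, y)]
        if cxy == _ADJ_ABSENT:
            e.sepset = []
            continue
        e.present = True
        e.sepset = None
        if cxy == _ADJ_BIDIRECTED:
            e.end_x.mark = e.end_y.mark = HEAD
            e.status = BIDIRECTED
        elif cxy == _ADJ_HEAD:
            e.end_y.mark = HEAD
            e.end_x.mark = TAIL if cyx == _ADJ_TAIL else UNDEFINED
            e.status = PUTATIVE
        elif cyx == _ADJ_HEAD:
            e.end_x.mark = HEAD
            e.end_y.mark = TAIL if cxy == _ADJ_TAIL else UNDEFINED
            e.status = PUTATIVE
        else:
            e.status = UNDIRECTED
    return g


def _edge_attrs(e: EdgeState) -> dict:
    return {
        "present": int(e.present),
        "status": e.status,
        "info_reg": float(e.info_reg),
        "sign": e.sign,
        "residual_info": float(e.residual_info),
        "mark_x": e.end_x.mark,
        "p_head_x": float(e.end_x.p_head),
        "p_tail_x": float(e.end_x.p_tail),
        "score_x": float(e.end_x.score),
        "mark_y": e.end_y.mark,
        "p_head_y": float(e.end_y.p_head),
        "p_tail_y": float(e.end_y.p_tail),
        "score_y": float(e.end_y.score),
        "sepset": ";".join(e.sepset) if e.sepset is not None else "",
        "sepset_defined": int(e.sepset is not None),
    }


def _edge_from_attrs(x: str, y: str, a: dict) -> EdgeState:
    sep = str(a.get("sepset", ""))
    defined = bool(int(a.get("sepset_defined", 0)))
    return EdgeState(
        x=x, y=y,
        present=bool(int(a["present"])),
        status=a["status"],
        info_reg=float(a["info_reg"]),
        sign=a["sign"],
        residual_info=float(a["residual_info"]),
        end_x=EndpointMark(a["mark_x"], float(a["p_head_x"]),
                           float(a["p_tail_x"]), float(a["score_x"])),
        end_y=EndpointMark(a["mark_y"], float(a["p_head_y"]),
                           float(a["p_tail_y"]), float(a["score_y"])),
        sepset=(sep.split(";") if sep else []) if defined else None,
    )


def _write_graphml(graph: MixedGraph, path) -> None:
    import networkx as nx

    g = nx.Graph()
    for s in graph.nodes:
        g.add_node(s.name, vtype=s.vtype, contextual=int(s.is_contextual))
    for key in sorted(graph.edges):
        e = graph.edges[key]
        g.add_edge(e.x, e.y, **_edge_attrs(e))
    nx.write_graphml(g, path)


def _read_graphml(path) -> MixedGraph:
    import networkx as nx

    g = nx.read_graphml(path)
    specs = [
        VariableSpec(name=str(n), vtype=d.get("vtype", CONTINUOUS),
                     is_contextual=bool(int(d.get("contextual", 0))))
        for n, d in sorted(g.nodes(data=True))
    ]
    out = MixedGraph(nodes=specs)
    for u, v, d in g.edges(data=True):
        x, y = pair_key(str(u), str(v))
        out.edges[(x, y)] = _edge_from_attrs(x, y, d)
    return out


def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def _write_dot(graph: MixedGraph, path) -> None:
    # DOT emitted in a regular one-line-per-element form; _read_dot parses
    # exactly this subset.
    lines = ["graph causal {"]
    for s in graph.nodes:
        lines.append(
            f'  "{_dot_escape(s.name)}" [vtype="{s.vtype}", contextual="{int(s.is_contextual)}"];'
        )
    for key in sorted(graph.edges):
        e = graph.edges[key]
        attrs = _edge_attrs(e)
        attr_s = ", ".join(f'{k}="{_dot_escape(str(v))}"' for k, v in attrs.items())
        lines.append(f'  "{_dot_escape(e.x)}" -- "{_dot_escape(e.y)}" [{attr_s}];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_dot(path) -> MixedGraph:
    import re

    node_re = re.compile(r'^\s*"(.*?)" \[vtype="(\w+)", contextual="(\d)"\];$')
    edge_re = re.compile(r'^\s*"(.*?)" -- "(.*?)" \[(.*)\];$')
    attr_re = re.compile(r'(\w+)="((?:[^"\\]|\\.)*)"')
    specs: list[VariableSpec] = []
    edges: dict[tuple[str, str], EdgeState] = {}

    def unescape(s: str) -> str:
        return s.replace('\\"', '"').replace("\\\\", "\\")

    with open(path) as fh:
        for line in fh:
            m = node_re.match(line)
            if m:
                specs.append(
                    VariableSpec(name=unescape(m.group(1)), vtype=m.group(2),
                                 is_contextual=bool(int(m.group(3))))
                )
                continue
            m = edge_re.match(line)
            if m:
                x, y = unescape(m.group(1)), unescape(m.group(2))
                attrs = {k: unescape(v) for k, v in attr_re.findall(m.group(3))}
                edges[pair_key(x, y)] = _edge_from_attrs(*pair_key(x, y), attrs)
    out = MixedGraph(nodes=specs)
    out.edges.update(edges)
    return out


# ---------------------------------------------------------------------------
# edge sign
# ---------------------------------------------------------------------------

def edge_sign(data: DataTable, x: str, y: str) -> str:
    """Association sign for a retained edge.

    Spearman correlation when either variable is continuous; log-odds sign for
    binary-binary pairs; ``na`` otherwise (no canonical ordering of levels).
    """
    from scipy import stats

    sx, sy = data.spec(x), data.spec(y)
    cx, cy = data.columns[x], data.columns[y]
    if sx.vtype == CONTINUOUS or sy.vtype == CONTINUOUS:
        vx = cx.astype(float) if sx.vtype == CATEGORICAL else cx
        vy = cy.astype(float) if sy.vtype == CATEGORICAL else cy
        if sx.vtype == CATEGORICAL:
            vx = np.where(cx < 0, np.nan, vx)
        if sy.vtype == CATEGORICAL:
            vy = np.where(cy < 0, np.nan, vy)
        ok = ~(np.isnan(vx) | np.isnan(vy))
        if ok.sum() < 3:
            return "na"
        rho = stats.spearmanr(vx[ok], vy[ok]).statistic
        if not np.isfinite(rho) or rho == 0:
            return "na"
        return "positive" if rho > 0 else "negative"
    if len(sx.levels) == 2 and len(sy.levels) == 2:
        ok = (cx >= 0) & (cy >= 0)
        tab = np.zeros((2, 2))
        np.add.at(tab, (cx[ok], cy[ok]), 1.0)
        det = tab[0, 0] * tab[1, 1] - tab[0, 1] * tab[1, 0]
        if det == 0:
            return "na"
        return "positive" if det > 0 else "negative"
    return "na"
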