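"""Regularized (conditional) mutual information for mixed-type variables.

Conventions
-----------
``raw_info`` is the plug-in (conditional) mutual information in nats per
sample.  ``complexity`` is the finite-size penalty k(N) in *total* nats, so
the regularized information is ``reg_info = raw_info - complexity / n`` and
``n * reg_info`` is the quantity consumed by the orientation scores.

Negative regularized values signal (conditional) independence and are
rectified to exactly zero (``reg_info_rect``); every estimate the package
hands downstream is rectified, so independence is an exact zero, never an
epsilon test.

Estimators
----------
* categorical-categorical (conditioning categorical): plug-in MI from the
  stratified contingency table; complexity is either the NML two-part
  codelength difference (default) or a BIC term.
* any continuous member: the variable's samples are partitioned by a dynamic
  program over equal-frequency candidate cutpoints maximizing the regularized
  (conditional) mutual information; partitions of two continuous variables
  are optimized alternately until the objective stops improving.  Continuous
  conditioning variables are collapsed to an equal-frequency-binned joint
  factor.  The penalty for a DP estimate is the MDL cutpoint-coding scheme
  0.5*(Bx-1)*(By-1)*ru*ln n plus ln(C) per cutpoint (C candidate positions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, xlogy

from ._kernels import _build_gains, _dp_partition
from .core import CATEGORICAL, CONTINUOUS, DataTable

__all__ = [
    "Partition",
    "InfoResult",
    "InfoEngine",
    "discrete_mi",
    "complexity_term",
    "rectify",
    "optimal_discretization_mi",
    "conditional_mi_reg",
    "three_point_info",
]

DEFAULT_MAX_BINS = 50

# estimator-level zero snap: regularized values below this (per-sample nats)
# are indistinguishable from the floating-point residue of the plug-in sums
# and are treated as exact independence
REG_TOL = 1e-8


def rectify(v: float) -> float:
    """Non-negativity rectification: negative regularized information means
    (conditional) independence and is mapped to exactly 0."""
    return v if v > 0.0 else 0.0


@dataclass
class Partition:
    variable: str
    cutpoints: np.ndarray  # sorted thresholds; empty = single bin
    n_bins: int

    def __post_init__(self) -> None:
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        if self.n_bins < 1:
            raise ValueError("partition needs at least one bin")
        if np.any(np.diff(self.cutpoints) <= 0):
            raise ValueError("cutpoints must be strictly increasing")


@dataclass
class InfoResult:
    raw_info: float
    complexity: float
    reg_info: float
    reg_info_rect: float
    n: int
    partitions: dict[str, Partition] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.reg_info_rect >= 0.0


# ---------------------------------------------------------------------------
# NML parametric complexity
# ---------------------------------------------------------------------------

class _NMLCache:
    """Multinomial parametric complexity log C_r(n), cached as arrays over n.

    C_1 = 1; C_2(n) computed exactly (by summation) for moderate n and by the
    sqrt(pi n / 2) asymptotic beyond; C_r via the linear recurrence
    C_r(n) = C_{r-1}(n) + n/(r-2) * C_{r-2}(n).
    """

    _EXACT_LIMIT = 4096

    def __init__(self, n_max: int):
        self.n_max = n_max
        ns = np.arange(n_max + 1)
        self._tables: dict[int, np.ndarray] = {1: np.zeros(n_max + 1)}
        logc2 = np.empty(n_max + 1)
        logc2[0] = 0.0
        for n in range(1, min(n_max, self._EXACT_LIMIT) + 1):
            k = np.arange(n + 1, dtype=float)
            ll = (
                _log_binom(n, k)
                + xlogy(k, k / n)
                + xlogy(n - k, (n - k) / n)
            )
            logc2[n] = logsumexp(ll)
        if n_max > self._EXACT_LIMIT:
            big = ns[self._EXACT_LIMIT + 1:]
            logc2[self._EXACT_LIMIT + 1:] = 0.5 * np.log(np.pi * big / 2.0) + (
                np.sqrt(2.0 / (np.pi * big)) * 2.0 / 3.0
            )
        self._tables[2] = logc2
        self._ln_n = np.where(ns > 0, np.log(np.maximum(ns, 1)), -np.inf)

    # exact tables are stored up to this support; beyond it the Rissanen
    # asymptotic log C_r(n) ~ ((r-1)/2) log(n/2) + log(sqrt(pi)/Gamma(r/2))
    # is used (relative error < 1% in the penalty at the sizes involved)
    _EXACT_R = 64

    def table(self, r: int) -> np.ndarray:
        if r < 1:
            raise ValueError("cardinality must be >= 1")
        if r > self._EXACT_R:
            return self._asymptotic(r)
        if r not in self._tables:
            top = max(k for k in self._tables if isinstance(k, int))
            for rr in range(top + 1, r + 1):
                with np.errstate(divide="ignore"):
                    self._tables[rr] = np.logaddexp(
                        self._tables[rr - 1],
                        self._ln_n - math.log(rr - 2) + self._tables[rr - 2],
                    )
        return self._tables[r]

    def _asymptotic(self, r: int) -> np.ndarray:
        from scipy.special import gammaln

        key = ("a", r)
        if key not in self._tables:
            ns = np.arange(self.n_max + 1, dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                val = (
                    0.5 * (r - 1) * np.log(np.maximum(ns, 1.0) / 2.0)
                    + 0.5 * math.log(math.pi)
                    - gammaln(r / 2.0)
                )
            self._tables[key] = np.maximum(val, 0.0)
        return self._tables[key]

    def k_pair(self, rx: int, ry: int, n_u: np.ndarray) -> float:
        """NML complexity of an independence test of an rx-by-ry table,
        summed over conditioning strata of sizes n_u (total nats)."""
        t_joint = self.table(rx * ry)
        t_x = self.table(rx)
        t_y = self.table(ry)
        return float((t_joint[n_u] - t_x[n_u] - t_y[n_u]).sum())


def _log_binom(n, k):
    from scipy.special import gammaln

    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


_GLOBAL_NML: dict[int, _NMLCache] = {}


def _nml_cache(n_max: int) -> _NMLCache:
    key = 1 << max(8, int(np.ceil(np.log2(max(n_max, 1) + 1))))
    if key not in _GLOBAL_NML:
        _GLOBAL_NML[key] = _NMLCache(key)
    return _GLOBAL_NML[key]


def complexity_term(card_x: int, card_y: int, card_cond: int, n: int,
                    mode: str = "nml") -> float:
    """Finite-size penalty k(N) in total nats for an independence decision
    between variables of the given cardinalities.

    ``bic``: 0.5 * (card_x-1) * (card_y-1) * card_cond * ln n.
    ``nml``: NML codelength difference summed over conditioning strata; with
    only cardinalities available the n samples are split as evenly as
    possible across the card_cond strata.
    """
    if min(card_x, card_y, card_cond) < 1 or n < 1:
        raise ValueError("cardinalities and n must be >= 1")
    if card_x == 1 or card_y == 1:
        return 0.0
    if mode == "bic":
        return 0.5 * (card_x - 1) * (card_y - 1) * card_cond * math.log(n)
    if mode != "nml":
        raise ValueError(f"unknown complexity mode {mode!r}")
    base, extra = divmod(n, card_cond)
    sizes = np.array([base + (1 if i < extra else 0) for i in range(card_cond)])
    return _nml_cache(n).k_pair(card_x, card_y, sizes)


# ---------------------------------------------------------------------------
# plug-in discrete MI
# ---------------------------------------------------------------------------

def _factorize(values) -> tuple[np.ndarray, int]:
    arr = np.asarray(values)
    _, codes = np.unique(arr, return_inverse=True)
    return codes.astype(np.int64), int(codes.max()) + 1


def discrete_mi(x, y) -> float:
    """Plug-in mutual information (nats) of two equal-length complete-case
    categorical samples."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d samples")
    n = x.size
    if n == 0:
        raise ValueError("zero usable rows")
    xc, rx = _factorize(x)
    yc, ry = _factorize(y)
    cnt = np.bincount(xc * ry + yc, minlength=rx * ry).reshape(rx, ry).astype(float)
    return _table_mi_total(cnt[None, :, :]) / n


def _table_mi_total(cnt: np.ndarray) -> float:
    """Total (not per-sample) conditional MI sum from a (ru, rx, ry) count
    cube: sum c ln(c n_u / (n_ux n_uy))."""
    n_u = cnt.sum(axis=(1, 2))
    n_ux = cnt.sum(axis=2)
    n_uy = cnt.sum(axis=1)
    return float(
        xlogy(cnt, cnt).sum()
        + xlogy(n_u, n_u).sum()
        - xlogy(n_ux, n_ux).sum()
        - xlogy(n_uy, n_uy).sum()
    )


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

@dataclass
class _Var:
    name: str
    is_cat: bool
    codes: np.ndarray | None  # categorical level codes (-1 missing)
    card: int  # categorical cardinality
    values: np.ndarray | None  # continuous values (nan missing)
    ok: np.ndarray = None  # non-missing mask
    cand_full: tuple[np.ndarray, np.ndarray] | None = None  # (cuts, codes)
    cand_scan: tuple[np.ndarray, np.ndarray] | None = None
    cond_codes: np.ndarray | None = None  # equal-frequency factor for conditioning
    cond_card: int = 1


def _equal_freq_cuts(values: np.ndarray, ok: np.ndarray, n_cuts: int):
    """Candidate cutpoints at equal-frequency boundaries of the unique values
    (ties broken toward the lower value); returns (cuts, codes)."""
    uniq = np.unique(values[ok])
    if uniq.size < 2 or n_cuts < 1:
        return np.empty(0), np.zeros(values.shape, dtype=np.int64)
    max_cuts = uniq.size - 1
    if n_cuts >= max_cuts:
        cuts = uniq[:-1]
    else:
        # boundaries at equal-frequency quantiles; method "lower" lands on
        # actual sample values, i.e. ties break toward the lower value
        qs = np.quantile(values[ok], np.linspace(0, 1, n_cuts + 2)[1:-1],
                         method="lower")
        cuts = np.unique(qs)
        if cuts.size and cuts[-1] >= uniq[-1]:
            cuts = cuts[:-1]
    codes = np.zeros(values.shape, dtype=np.int64)
    codes[ok] = np.searchsorted(cuts, values[ok], side="left")
    return cuts, codes


class InfoEngine:
    """Per-dataset estimator with caches for codes, candidate grids, NML
    tables and memoized conditional estimates."""

    def __init__(
        self,
        data: DataTable,
        max_bins: int = DEFAULT_MAX_BINS,
        complexity: str = "nml",
        cond_bins: int = 5,
        cand_full: int | None = None,
        cand_scan: int = 16,
        max_rounds: int = 20,
        scan_rounds: int = 4,
    ):
        if complexity not in ("nml", "bic"):
            raise ValueError(f"unknown complexity mode {complexity!r}")
        self.data = data
        self.n_total = data.n_samples
        self.max_bins = max_bins
        self.mode = complexity
        self.cond_bins = cond_bins
        self.cand_full = cand_full if cand_full is not None else max(2 * max_bins, 32)
        self.cand_scan = cand_scan
        self.max_rounds = max_rounds
        self.scan_rounds = scan_rounds
        self.nml = _nml_cache(self.n_total)
        self.vars: dict[str, _Var] = {}
        for s in data.specs:
            col = data.columns[s.name]
            if s.vtype == CATEGORICAL:
                ok = col >= 0
                card = len(s.levels)
                v = _Var(s.name, True, col, card, None, ok)
                v.cond_codes, v.cond_card = col, card
            else:
                ok = ~np.isnan(col)
                v = _Var(s.name, False, None, 0, col, ok)
                v.cand_full = _equal_freq_cuts(col, ok, self.cand_full)
                v.cand_scan = _equal_freq_cuts(col, ok, self.cand_scan)
                ncond = min(self.cond_bins, max(1, int(ok.sum()) // 10))
                cuts, codes = _equal_freq_cuts(col, ok, max(ncond - 1, 0))
                v.cond_codes = np.where(ok, codes, -1)
                v.cond_card = int(codes[ok].max()) + 1 if ok.any() else 1
            self.vars[s.name] = v
        self._all_ok = np.logical_and.reduce(
            [v.ok for v in self.vars.values()]
        ) if self.vars else None
        self._no_missing = bool(self._all_ok.all()) if self.vars else True
        self._memo: dict[tuple, InfoResult] = {}

    # -- helpers ------------------------------------------------------------

    def _mask(self, names: tuple[str, ...]) -> np.ndarray | None:
        if self._no_missing:
            return None
        m = self.vars[names[0]].ok
        for nm in names[1:]:
            m = m & self.vars[nm].ok
        return m

    def _take(self, arr: np.ndarray, mask) -> np.ndarray:
        return arr if mask is None else arr[mask]

    def _cond_factor(self, cond: tuple[str, ...], mask) -> tuple[np.ndarray, int]:
        """Joint conditioning factor: categorical conditioners by level,
        continuous ones by their equal-frequency bins; compressed to observed
        strata."""
        if not cond:
            n = self.n_total if mask is None else int(mask.sum())
            return np.zeros(n, dtype=np.int64), 1
        code = None
        for nm in cond:
            v = self.vars[nm]
            c = self._take(v.cond_codes, mask)
            code = c if code is None else code * v.cond_card + c
        _, inv = np.unique(code, return_inverse=True)
        return inv.astype(np.int64), int(inv.max()) + 1

    # -- categorical path ---------------------------------------------------

    def _cat_result(self, xc, rx, yc, ry, uc, ru, n) -> InfoResult:
        cnt = (
            np.bincount((uc * rx + xc) * ry + yc, minlength=ru * rx * ry)
            .reshape(ru, rx, ry)
            .astype(float)
        )
        n_u = cnt.sum(axis=(1, 2)).astype(np.int64)
        raw_total = _table_mi_total(cnt)
        if self.mode == "nml":
            # fNML convention: each stratum pays only for its observed
            # support, not for levels that never occur in it
            rx_u = (cnt.sum(axis=2) > 0).sum(axis=1)
            ry_u = (cnt.sum(axis=1) > 0).sum(axis=1)
            k = self._nml_strata(rx_u, ry_u, n_u)
        else:
            k = 0.5 * (rx - 1) * (ry - 1) * ru * math.log(n)
        raw = raw_total / n
        reg = raw - k / n
        rect = reg if reg > REG_TOL else 0.0
        return InfoResult(raw, k, reg, rect, n)

    def _nml_strata(self, rx_u, ry_u, n_u) -> float:
        """Sum of per-stratum NML codelength differences, vectorized over the
        few distinct observed-support cardinalities."""
        act = (rx_u > 1) & (ry_u > 1)
        if not act.any():
            return 0.0
        rx_u, ry_u, n_u = rx_u[act], ry_u[act], n_u[act]
        k = 0.0
        for r in np.unique(rx_u * ry_u):
            k += float(self.nml.table(int(r))[n_u[rx_u * ry_u == r]].sum())
        for arr, sgn in ((rx_u, -1.0), (ry_u, -1.0)):
            for r in np.unique(arr):
                k += sgn * float(self.nml.table(int(r))[n_u[arr == r]].sum())
        return k

    def _nml_split_cost(self, partner_card: int, n_u: np.ndarray) -> float:
        """Approximate NML cost of one additional bin of the focal variable:
        the exact 1 -> 2 bin codelength increment against the partner."""
        if partner_card < 2:
            return 0.0
        t = (
            self.nml.table(2 * partner_card)[n_u]
            - self.nml.table(2)[n_u]
            - self.nml.table(partner_card)[n_u]
        )
        return float(t.sum())

    # -- DP path ------------------------------------------------------------

    def _dp_side(self, cand_codes, n_cand_cuts, partner_codes, partner_card,
                 uc, ru, lam):
        """One DP: merge candidate intervals of the focal variable against
        the fixed partner/stratum factor.  Returns (value, cuts_idx)."""
        C = n_cand_cuts  # number of candidate boundaries
        m = partner_card * ru
        cell = (cand_codes * ru + uc) * partner_card + partner_codes
        M = np.bincount(cell, minlength=(C + 1) * m).reshape(C + 1, m).astype(float)
        P = np.vstack([np.zeros((1, m)), np.cumsum(M, axis=0)])
        MU = M.reshape(C + 1, ru, partner_card).sum(axis=2)
        PU = np.vstack([np.zeros((1, ru)), np.cumsum(MU, axis=0)])
        H = _build_gains(np.ascontiguousarray(P), np.ascontiguousarray(PU))
        return _dp_partition(H, lam, self.max_bins)

    def _dp_lambda(self, partner_card: int, ru: int, n_u, ln_n: float,
                   n_cand: int) -> float:
        """Per-extra-bin search penalty for the DP: NML 1->2-bin increment
        (default) or the BIC term, plus the cutpoint coding cost."""
        code = math.log(n_cand) if n_cand > 1 else 0.0
        if self.mode == "nml":
            return self._nml_split_cost(partner_card, n_u) + code
        return 0.5 * max(partner_card - 1, 0) * ru * ln_n + code

    def _eval_partition(self, xb, bx, partner, pcard, uc, ru, n,
                        coding: float) -> tuple[float, float, float]:
        """(raw_total, k_total, reg_total) of a chosen partition pair; the
        complexity is the same per-stratum NML (or BIC) as for categorical
        data, plus the cutpoint coding cost."""
        res = self._cat_result(xb, bx, partner, pcard, uc, ru, n)
        raw_total = res.raw_info * n
        k = res.complexity + coding
        return raw_total, k, raw_total - k

    def _info_with_continuous(self, x: str, y: str, cond: tuple[str, ...],
                              mask, quality: str) -> InfoResult:
        vx, vy = self.vars[x], self.vars[y]
        n = self.n_total if mask is None else int(mask.sum())
        if n < 3:
            raise ValueError("fewer than 3 complete rows")
        uc, ru = self._cond_factor(cond, mask)
        n_u = np.bincount(uc, minlength=ru)
        ln_n = math.log(n)

        def cand(v: _Var):
            # candidate intervals with zero mass (possible after complete-case
            # filtering) are harmless: the DP never profits from cutting them
            cuts, codes = v.cand_full if quality == "full" else v.cand_scan
            return cuts, self._take(codes, mask), cuts.size

        rounds = self.max_rounds if quality == "full" else self.scan_rounds

        if vx.is_cat or vy.is_cat:
            # exactly one continuous side: a single DP suffices
            if vx.is_cat:
                vcat, vcont, cont_name = vx, vy, y
            else:
                vcat, vcont, cont_name = vy, vx, x
            cat_codes = self._take(vcat.codes, mask)
            cuts, codes, C = cand(vcont)
            lam = self._dp_lambda(vcat.card, ru, n_u, ln_n, C)
            _, cut_idx = self._dp_side(codes, C, cat_codes, vcat.card, uc, ru, lam)
            b = len(cut_idx) + 1
            xb = np.searchsorted(cut_idx, codes, side="right")
            coding = (b - 1) * (math.log(C) if C > 1 else 0.0)
            raw_total, k, reg_total = self._eval_partition(
                xb, b, cat_codes, vcat.card, uc, ru, n, coding
            )
            reg = reg_total / n
            if reg <= REG_TOL:
                parts = {cont_name: Partition(cont_name, np.empty(0), 1)}
                return InfoResult(0.0, 0.0, min(reg, 0.0), 0.0, n, parts)
            parts = {cont_name: Partition(cont_name, cuts[cut_idx - 1], b)}
            return InfoResult(raw_total / n, k, reg, reg, n, parts)

        # both continuous: alternating optimization
        cuts_x, codes_x, Cx = cand(vx)
        cuts_y, codes_y, Cy = cand(vy)
        code_x = math.log(Cx) if Cx > 1 else 0.0
        code_y = math.log(Cy) if Cy > 1 else 0.0

        def run(by_init: int):
            if by_init >= Cy + 1:
                yb = codes_y.copy()
                y_cuts_idx = np.arange(1, Cy + 1)
            else:
                edges = np.linspace(0, Cy + 1, by_init + 1)[1:-1]
                y_cuts_idx = np.unique(np.clip(np.round(edges).astype(np.int64),
                                               1, Cy))
                yb = np.searchsorted(y_cuts_idx, codes_y, side="right")
            x_cuts_idx = np.empty(0, dtype=np.int64)
            best = -np.inf
            state = None

            def evaluate(xi, yi):
                nonlocal best, state
                bx, by = len(xi) + 1, len(yi) + 1
                xbv = np.searchsorted(xi, codes_x, side="right")
                ybv = np.searchsorted(yi, codes_y, side="right")
                coding = (bx - 1) * code_x + (by - 1) * code_y
                raw_total, k, reg_total = self._eval_partition(
                    xbv, bx, ybv, by, uc, ru, n, coding
                )
                if reg_total > best + 1e-9:
                    best = reg_total
                    state = (raw_total, k, xi.copy(), yi.copy())
                    return True
                return False

            for _ in range(rounds):
                by = len(y_cuts_idx) + 1
                lam_x = self._dp_lambda(by, ru, n_u, ln_n, Cx)
                _, x_cuts_idx = self._dp_side(codes_x, Cx, yb, by, uc, ru, lam_x)
                imp_x = evaluate(x_cuts_idx, y_cuts_idx)
                xb = np.searchsorted(x_cuts_idx, codes_x, side="right")
                bx = len(x_cuts_idx) + 1
                lam_y = self._dp_lambda(bx, ru, n_u, ln_n, Cy)
                _, y_cuts_idx = self._dp_side(codes_y, Cy, xb, bx, uc, ru, lam_y)
                yb = np.searchsorted(y_cuts_idx, codes_y, side="right")
                imp_y = evaluate(x_cuts_idx, y_cuts_idx)
                if not (imp_x or imp_y):
                    break
                if state is not None and not imp_y:
                    y_cuts_idx = state[3]
                    yb = np.searchsorted(y_cuts_idx, codes_y, side="right")
            return best, state

        by0 = min(self.max_bins, max(2, int(round(n ** (1.0 / 3.0)))))
        best, state = run(by0)
        if (state is None or best <= 0.0) and by0 != 2:
            best2, state2 = run(2)
            if state2 is not None and best2 > best:
                best, state = best2, state2
        if state is None or best <= REG_TOL * n:
            parts = {
                x: Partition(x, np.empty(0), 1),
                y: Partition(y, np.empty(0), 1),
            }
            reg = min(best / n if np.isfinite(best) else 0.0, 0.0)
            return InfoResult(0.0, 0.0, reg, 0.0, n, parts)
        raw_total, k, xi, yi = state
        parts = {
            x: Partition(x, cuts_x[xi - 1] if xi.size else np.empty(0), len(xi) + 1),
            y: Partition(y, cuts_y[yi - 1] if yi.size else np.empty(0), len(yi) + 1),
        }
        reg = (raw_total - k) / n
        return InfoResult(raw_total / n, k, reg, rectify(reg), n, parts)

    def _cond_mi_total(self, cand_codes, cut_idx, partner_codes, partner_card,
                       uc, ru) -> float:
        xb = np.searchsorted(cut_idx, cand_codes, side="right")
        bx = len(cut_idx) + 1
        cnt = (
            np.bincount((uc * bx + xb) * partner_card + partner_codes,
                        minlength=ru * bx * partner_card)
            .reshape(ru, bx, partner_card)
            .astype(float)
        )
        return _table_mi_total(cnt)

    # -- public estimates ---------------------------------------------------

    def info(self, x: str, y: str, cond=(), require=(),
             quality: str | None = None) -> InfoResult:
        """Regularized conditional mutual information I'(X;Y|cond).

        ``require`` lists extra variables whose missingness restricts the
        complete-case sample without entering the estimate (used so that the
        two terms of a 3-point information share one sample).
        """
        cond = tuple(cond)
        require = tuple(require)
        if x in cond or y in cond or x == y:
            raise ValueError("x, y and cond must be distinct")
        if quality is None:
            quality = "full" if not cond else "scan"
        key = (x, y, tuple(sorted(cond)), tuple(sorted(require)), quality)
        alt = (y, x, key[2], key[3], quality)
        if key in self._memo:
            return self._memo[key]
        if alt in self._memo:
            return self._memo[alt]
        names = (x, y) + cond + require
        mask = self._mask(names)
        vx, vy = self.vars[x], self.vars[y]
        if vx.is_cat and vy.is_cat:
            n = self.n_total if mask is None else int(mask.sum())
            if n < 1:
                raise ValueError("empty complete-case intersection")
            uc, ru = self._cond_factor(cond, mask)
            res = self._cat_result(
                self._take(vx.codes, mask), vx.card,
                self._take(vy.codes, mask), vy.card,
                uc, ru, n,
            )
        else:
            res = self._info_with_continuous(x, y, cond, mask, quality)
        self._memo[key] = res
        return res

    def three_point(self, x: str, y: str, z: str, cond=()) -> tuple[float, int]:
        """Conditional 3-point information I'(X;Y;Z|cond) (per-sample nats,
        may be negative) and the shared complete-case count.

        Both terms are rectified, so if each signals independence the
        difference is exactly zero.
        """
        cond = tuple(c for c in cond if c != z)
        t1 = self.info(x, y, cond, require=(z,), quality="scan")
        t2 = self.info(x, y, cond + (z,), quality="scan")
        return t1.reg_info_rect - t2.reg_info_rect, t2.n


# ---------------------------------------------------------------------------
# spec-level convenience wrappers
# ---------------------------------------------------------------------------

def _table_from_arrays(arrs: dict[str, np.ndarray], vtypes: dict[str, str]) -> DataTable:
    import pandas as pd

    from .core import VariableSpec

    df = pd.DataFrame({k: np.asarray(v) for k, v in arrs.items()})
    specs = [VariableSpec(name=k, vtype=vtypes[k]) for k in arrs]
    for k, vt in vtypes.items():
        if vt == CATEGORICAL:
            df[k] = df[k].astype(str)
    return DataTable.from_dataframe(df, specs)


def optimal_discretization_mi(x, y, max_bins: int = DEFAULT_MAX_BINS,
                              y_categorical: bool = False) -> InfoResult:
    """Regularized MI of two samples, at least one continuous, via the
    cutpoint DP (alternating when both are continuous)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("fewer than 3 complete rows")
    vt = {"x": CONTINUOUS, "y": CATEGORICAL if y_categorical else CONTINUOUS}
    data = _table_from_arrays({"x": x, "y": np.asarray(y)}, vt)
    eng = InfoEngine(data, max_bins=max_bins)
    return eng.info("x", "y", quality="full")


def conditional_mi_reg(x: str, y: str, cond, data: DataTable,
                       max_bins: int = DEFAULT_MAX_BINS,
                       complexity: str = "nml") -> InfoResult:
    eng = InfoEngine(data, max_bins=max_bins, complexity=complexity)
    return eng.info(x, y, tuple(cond))


def three_point_info(x: str, y: str, z: str, cond, data: DataTable,
                     max_bins: int = DEFAULT_MAX_BINS) -> float:
    eng = InfoEngine(data, max_bins=max_bins)
    i3, _ = eng.three_point(x, y, z, tuple(cond))
    return i3
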