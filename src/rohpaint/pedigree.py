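"""Pedigree metrics: equivalent generations, completeness, inbreeding,
the F_ROH-on-generation regression and Ne from the inbreeding rate.

Equivalent generations g = sum over all known ancestors of (1/2)^n, n the
generation distance, measures realized pedigree depth. The pedigree
completeness index (PCI) is the harmonic mean of the two parents' ancestor-
knowledge proportions over d ascending generations. Inbreeding F is
Wright's coefficient computed by recursive coancestry (founders taken
unrelated and non-inbred). The rate of inbreeding per generation, the slope
of F_ROH regressed on g, gives the effective population size Ne = 1/(2·ΔF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UNKNOWN = "0"


class Pedigree:
    """id/sire/dam records; "0", "" or NaN denote an unknown parent.

    Construction validates acyclicity and establishes a topological order
    with parents before offspring.
    """

    def __init__(self, records: pd.DataFrame):
        tab = records.copy()
        for col in ("id", "sire", "dam"):
            if col not in tab.columns:
                raise ValueError(f"pedigree is missing column {col!r}")
            tab[col] = tab[col].fillna(UNKNOWN).astype(str).replace("", UNKNOWN)
        if tab["id"].duplicated().any():
            dup = tab.loc[tab["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate pedigree id {dup!r}")
        self.table = tab.reset_index(drop=True)
        self._parents = {r.id: (r.sire if r.sire != UNKNOWN else None,
                                r.dam if r.dam != UNKNOWN else None)
                         for r in tab.itertuples()}
        # a parent named but never listed as an id is a founder record
        for s, d in list(self._parents.values()):
            for p in (s, d):
                if p is not None and p not in self._parents:
                    self._parents[p] = (None, None)
        self.order = self._toposort()

    def parents(self, ident: str):
        """(sire, dam) of an animal, None for unknown."""
        return self._parents.get(str(ident), (None, None))

    def _toposort(self) -> list:
        state: dict = {}
        order: list = []
        for start in self._parents:
            if state.get(start) == 2:
                continue
            stack = [(start, iter([p for p in self._parents[start] if p]))]
            state[start] = 1
            while stack:
                node, it = stack[-1]
                advanced = False
                for parent in it:
                    st = state.get(parent)
                    if st == 1:
                        raise ValueError(f"pedigree cycle involving {parent!r}")
                    if st is None:
                        state[parent] = 1
                        stack.append(
                            (parent,
                             iter([p for p in self._parents[parent] if p])))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 2
                    order.append(node)
                    stack.pop()
        return order

    @property
    def ids(self) -> list:
        return list(self.table["id"])


def read_pedigree(path: str) -> Pedigree:
    return Pedigree(pd.read_csv(path, sep="\t", dtype=str))


# ---------------------------------------------------------------------------
# equivalent generations
# ---------------------------------------------------------------------------

def equivalent_generations(ped: Pedigree, ident: str | None = None):
    """g = Σ (1/2)^n over all known-ancestor paths; recursion
    g(x) = Σ_parents (1/2)(1 + g(parent)). Returns a float for one id or a
    Series over all ids."""
    memo: dict = {}

    def g(x):
        if x is None or x not in ped._parents:
            return 0.0
        if x in memo:
            return memo[x]
        s, d = ped._parents[x]
        val = sum(0.5 * (1.0 + g(p)) for p in (s, d) if p is not None)
        memo[x] = val
        return val

    for x in ped.order:  # fill memo bottom-up, avoids deep recursion
        g(x)
    if ident is not None:
        return g(str(ident))
    return pd.Series({i: g(i) for i in ped.ids}, name="equiv_generations")


# ---------------------------------------------------------------------------
# pedigree completeness
# ---------------------------------------------------------------------------

def _known_slots(ped: Pedigree, ident, depth: int) -> list:
    """Number of known ancestor slots of ``ident`` at generations 1..depth
    (generation 1 = parents; a full generation k has 2^k slots)."""
    counts = [0] * depth
    level = {str(ident): 1}
    for k in range(depth):
        nxt: dict = {}
        for x, mult in level.items():
            s, d = ped._parents.get(x, (None, None))
            for p in (s, d):
                if p is not None:
                    counts[k] += mult
                    nxt[p] = nxt.get(p, 0) + mult
        level = nxt
    return counts


def pedigree_completeness(ped: Pedigree, ident: str, depth: int = 5) -> float:
    """PCI: harmonic mean 2·Cs·Cd/(Cs+Cd) of the parents' completeness
    C = (1/d)·Σ_{k=1..d} known_k / 2^k; zero if either parent is unknown."""
    if depth < 1:
        raise ValueError("depth must be at least 1")
    s, d = ped._parents.get(str(ident), (None, None))
    if s is None or d is None:
        return 0.0

    def c(parent):
        counts = _known_slots(ped, parent, depth)
        return sum(counts[k] / 2 ** (k + 1) for k in range(depth)) / depth

    cs, cd = c(s), c(d)
    if cs + cd == 0:
        return 0.0
    return 2.0 * cs * cd / (cs + cd)


# ---------------------------------------------------------------------------
# inbreeding
# ---------------------------------------------------------------------------

def inbreeding(ped: Pedigree) -> pd.Series:
    """Wright's inbreeding coefficient per animal via recursive coancestry
    (kinship): F(x) = f(sire, dam), with f(x,x) = (1 + F(x))/2 and
    f(x,y) = (f(sire_y, x) + f(dam_y, x))/2 taking y as the younger animal.
    Founders (unknown or unlisted parents) are unrelated and non-inbred.
    """
    rank = {x: k for k, x in enumerate(ped.order)}
    fmemo: dict = {}
    kmemo: dict = {}

    def kin(x, y):
        if x is None or y is None:
            return 0.0
        if x == y:
            return 0.5 * (1.0 + F(x))
        if rank[x] > rank[y]:  # decompose the younger animal
            x, y = y, x
        key = (x, y)
        if key in kmemo:
            return kmemo[key]
        s, d = ped._parents[y]
        val = 0.5 * (kin(s, x) + kin(d, x))
        kmemo[key] = val
        return val

    def F(x):
        if x in fmemo:
            return fmemo[x]
        s, d = ped._parents[x]
        val = kin(s, d) if (s is not None and d is not None) else 0.0
        fmemo[x] = val
        return val

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(ped.order) + 1000))
    try:
        for x in ped.order:
            F(x)
    finally:
        sys.setrecursionlimit(old)
    return pd.Series({i: fmemo.get(i, 0.0) for i in ped.ids}, name="F")


# ---------------------------------------------------------------------------
# F_ROH regression and Ne
# ---------------------------------------------------------------------------

@dataclass
class NeEstimate:
    delta_f: float
    ne: float


@dataclass
class FrohRegression:
    intercept: float
    slope: float
    r2_adj: float
    p_value: float
    ne: NeEstimate


def ne_from_delta_f(delta_f: float) -> NeEstimate:
    """Effective population size from the per-generation inbreeding rate:
    Ne = 1 / (2·ΔF)."""
    if delta_f <= 0:
        return NeEstimate(delta_f, float("inf"))
    return NeEstimate(delta_f, 1.0 / (2.0 * delta_f))


def froh_regression(f_roh: np.ndarray, generations: np.ndarray) -> FrohRegression:
    """OLS of per-animal F_ROH on equivalent generations; the slope is the
    realized inbreeding rate per generation and yields Ne = 1/(2·slope)."""
    import statsmodels.api as sm

    y = np.asarray(f_roh, dtype=float)
    x = np.asarray(generations, dtype=float)
    if y.size < 3:
        raise ValueError("need at least three animals")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in generation numbers")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(fit.params[1])
    return FrohRegression(float(fit.params[0]), slope, float(fit.rsquared_adj),
                          float(fit.pvalues[1]), ne_from_delta_f(slope))
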