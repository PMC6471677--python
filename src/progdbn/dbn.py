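"""Two-slice dynamic Bayesian network learning on discrete cohorts.

The transition model is learned from one training instance per consecutive
visit pair (stationarity: a single transition distribution is shared across
all slice pairs), plus one terminal instance per deceased patient in which
the absorbing death indicator fires.  Structure search is the max-min
hill-climbing hybrid: a constraint-based skeleton from MMPC (G² conditional
independence tests), then greedy BIC-scored hill climbing whose edge
additions are restricted to the skeleton and to the layered edge mask.
Parameters are maximum-a-posteriori estimates under a symmetric Dirichlet
prior.

BIC is the natural-log decomposable score

    score(G : D) = l(theta_G : D) - (log M / 2) * Dim[G],
    Dim[G] = sum_i (R_i - 1) * Q_i,

with M the number of training instances, R_i the cardinality of node i and
Q_i its number of parent configurations.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import chdtrc

from .cohort import DAY, PID, DiscreteCohort
from .specs import (
    DEATH_NODE,
    MISSING,
    TSO_NODE,
    LayerMask,
    NodeDef,
    Role,
    VariableSpec,
    cur_name,
    prev_name,
    unroll_nodes,
)

# ---------------------------------------------------------------------------
# data container


@dataclass
class DiscreteData:
    """Fully categorical learning table: int64 codes, -1 = missing."""

    df: pd.DataFrame
    cards: dict[str, int]

    def __post_init__(self) -> None:
        self._arr = {c: self.df[c].to_numpy(dtype=np.int64) for c in self.df.columns}
        self._obs = {c: a != MISSING for c, a in self._arr.items()}

    @property
    def m(self) -> int:
        return len(self.df)

    def col(self, name: str) -> np.ndarray:
        return self._arr[name]

    def observed(self, name: str) -> np.ndarray:
        return self._obs[name]

    def card(self, name: str) -> int:
        return self.cards[name]


# ---------------------------------------------------------------------------
# structures


@dataclass
class DbnStructure:
    """DAG over the unrolled node set with per-node ordered parent lists."""

    nodes: tuple[NodeDef, ...]
    parents: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        names = {n.name for n in self.nodes}
        for child, ps in self.parents.items():
            if child not in names:
                raise ValueError(f"unknown child {child}")
            for p in ps:
                if p not in names:
                    raise ValueError(f"unknown parent {p} of {child}")
        for n in self.nodes:
            self.parents.setdefault(n.name, ())
        if not self.is_acyclic():
            raise ValueError("structure contains a directed cycle")

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def node(self, name: str) -> NodeDef:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def edges(self) -> list[tuple[str, str]]:
        return [(p, c) for c, ps in sorted(self.parents.items()) for p in ps]

    def n_edges(self) -> int:
        return sum(len(ps) for ps in self.parents.values())

    def skeleton_edges(self) -> set[frozenset]:
        return {frozenset((p, c)) for p, c in self.edges()}

    def is_acyclic(self) -> bool:
        children: dict[str, list[str]] = {n.name: [] for n in self.nodes}
        indeg = {n.name: 0 for n in self.nodes}
        for child, ps in self.parents.items():
            for p in ps:
                children[p].append(child)
                indeg[child] += 1
        queue = [n for n, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            u = queue.pop()
            seen += 1
            for v in children[u]:
                indeg[v] -= 1
                if indeg[v] == 0:
                    queue.append(v)
        return seen == len(self.nodes)

    def validate_mask(self, mask: LayerMask) -> None:
        for p, c in self.edges():
            if not mask.allowed(p, c):
                raise ValueError(f"edge {p} -> {c} violates the layer mask")

    def topo_order(self, names: Iterable[str] | None = None) -> list[str]:
        """Deterministic topological order of ``names`` (default: all nodes),
        considering only edges whose endpoints both lie in the subset."""
        pool = set(self.node_names if names is None else names)
        indeg = {n: sum(1 for p in self.parents[n] if p in pool) for n in pool}
        ready = sorted(n for n in pool if indeg[n] == 0)
        order: list[str] = []
        while ready:
            u = ready.pop(0)
            order.append(u)
            changed = False
            for v in pool:
                if u in self.parents[v] and indeg[v] > 0:
                    indeg[v] -= 1
                    if indeg[v] == 0:
                        ready.append(v)
                        changed = True
            if changed:
                ready.sort()
        if len(order) != len(pool):
            raise ValueError("cycle among requested nodes")
        return order


def parent_config_count(structure: DbnStructure, child: str) -> int:
    q = 1
    for p in structure.parents[child]:
        q *= structure.node(p).cardinality
    return q


def dim_g(structure: DbnStructure, cards: Mapping[str, int] | None = None) -> int:
    """Number of independent parameters: sum over nodes of (R_i - 1) * Q_i."""
    total = 0
    for n in structure.nodes:
        r = cards[n.name] if cards is not None else n.cardinality
        q = 1
        for p in structure.parents[n.name]:
            q *= cards[p] if cards is not None else structure.node(p).cardinality
        total += (r - 1) * q
    return total


@dataclass
class CpdSet:
    """One conditional probability table per node.

    ``tables[node]`` has shape ``(Q_i, R_i)``; the row index is the
    mixed-radix encoding of the parent codes in declared parent order,
    most-significant first.  Every row is a proper distribution.
    """

    tables: dict[str, np.ndarray]
    parents: dict[str, tuple[str, ...]]
    cards: dict[str, int]
    alpha: float = 2.0

    def __post_init__(self) -> None:
        for node, tab in self.tables.items():
            if tab.ndim != 2 or tab.shape[1] != self.cards[node]:
                raise ValueError(f"{node}: CPT shape {tab.shape} inconsistent")
            q = 1
            for p in self.parents[node]:
                q *= self.cards[p]
            if tab.shape[0] != q:
                raise ValueError(f"{node}: expected {q} parent configurations")
            if (tab < 0).any() or np.abs(tab.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError(f"{node}: rows must be distributions")

    def row_strides(self, node: str) -> np.ndarray:
        ps = self.parents[node]
        strides = np.ones(len(ps), dtype=np.int64)
        for i in range(len(ps) - 2, -1, -1):
            strides[i] = strides[i + 1] * self.cards[ps[i + 1]]
        return strides


# ---------------------------------------------------------------------------
# score ledger


@dataclass
class ScoreLedger:
    """Audit trail of the hill-climbing search."""

    m: int
    entries: list[dict] = field(default_factory=list)

    def record(self, move: str, parent: str, child: str, bic: float, accepted: bool) -> None:
        self.entries.append(
            {"move": move, "parent": parent, "child": child, "bic": bic, "accepted": accepted}
        )

    def accepted_bics(self) -> list[float]:
        return [e["bic"] for e in self.entries if e["accepted"]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)


# ---------------------------------------------------------------------------
# conditional independence (G^2)


def ci_test(
    data: DiscreteData,
    x: str,
    y: str,
    conditioning_set: Sequence[str] = (),
    alpha: float = 0.05,
    min_avg_cell: float = 5.0,
) -> tuple[float, float, bool]:
    """G² likelihood-ratio test of X ⟂ Y | S on available cases.

    Returns ``(statistic, p_value, dependent)`` with ``dependent = p < alpha``.
    When the contingency table is too sparse (average expected cell count
    below ``min_avg_cell``) the test is skipped and independence is returned,
    mirroring the usual reliability heuristic for G² tests.  When x or y
    shows no variation in the available cases (which happens when the
    conditioning set is never jointly observed with an outcome level, e.g.
    slice-t variables on terminal death instances) the test is uninformative:
    the p-value is NaN and must not be read as evidence of independence.
    """
    if x == y:
        raise ValueError("x and y must differ")
    cond = tuple(conditioning_set)
    if x in cond or y in cond:
        raise ValueError("x/y cannot appear in the conditioning set")

    cols = (x, y) + cond
    arrs = [data.col(c) for c in cols]
    ok = data.observed(x) & data.observed(y)
    for c in cond:
        ok &= data.observed(c)
    n = int(ok.sum())
    rx, ry = data.card(x), data.card(y)
    qs = 1
    for c in cond:
        qs *= data.card(c)
    n_cells = rx * ry * qs
    if n == 0 or n / n_cells < min_avg_cell:
        return 0.0, 1.0, False

    # joint index: strata-major, then y, then x
    idx = np.zeros(n, dtype=np.int64)
    for c, a in zip(cond, arrs[2:]):
        idx = idx * data.card(c) + a[ok]
    idx = (idx * ry + arrs[1][ok]) * rx + arrs[0][ok]
    counts = np.bincount(idx, minlength=n_cells).reshape(qs, ry, rx).astype(float)

    if (counts.sum(axis=(0, 1)) > 0).sum() < 2 or (counts.sum(axis=(0, 2)) > 0).sum() < 2:
        return 0.0, float("nan"), False  # uninformative: no variation left

    n_s = counts.sum(axis=(1, 2), keepdims=True)
    n_sx = counts.sum(axis=1, keepdims=True)
    n_sy = counts.sum(axis=2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = n_sx * n_sy / n_s
        ratio = np.where(counts > 0, counts / expected, 1.0)
        g2 = 2.0 * float(np.sum(counts * np.log(ratio)))
    dof = (rx - 1) * (ry - 1) * qs
    p = float(chdtrc(dof, max(g2, 0.0))) if dof > 0 else 1.0
    return g2, p, p < alpha


# ---------------------------------------------------------------------------
# MMPC skeleton


def _subsets(pool: Sequence[str], max_size: int, must_include: str | None = None):
    pool = [p for p in pool if p != must_include]
    base = (must_include,) if must_include else ()
    lo = 0 if must_include else 0
    for k in range(lo, max_size + 1 - len(base)):
        for comb in itertools.combinations(pool, k):
            yield base + comb


def mmpc(
    data: DiscreteData,
    mask: LayerMask,
    alpha_ci: float = 0.05,
    max_cond: int = 3,
    min_avg_cell: float = 5.0,
) -> dict[str, set[str]]:
    """Max-min parents-and-children skeleton under the layer mask.

    For each target the forward phase greedily admits the candidate with the
    strongest minimum association (smallest maximum p-value over subsets of
    the current candidate set, capped at ``max_cond``); the backward phase
    removes candidates independent of the target given some subset.  An edge
    survives only if each endpoint selects the other (symmetry), and pairs
    forbidden by the mask in both orientations are never tested.
    """
    names = [n.name for n in mask.nodes]
    cpc: dict[str, set[str]] = {}

    for t in names:
        cands = [x for x in names if x != t and mask.undirected_allowed(x, t)]
        # p_max[x]: largest p-value observed so far over tested subsets
        p_max: dict[str, float] = {}
        alive: list[str] = []
        for xc in cands:
            _, p, dep = ci_test(data, xc, t, (), alpha_ci, min_avg_cell)
            if math.isnan(p) or p >= alpha_ci:
                continue
            p_max[xc] = p
            alive.append(xc)
        selected: list[str] = []
        while alive:
            # max-min heuristic: admit the candidate with smallest p_max
            best = min(alive, key=lambda v: (p_max[v], v))
            selected.append(best)
            alive.remove(best)
            if not alive:
                break
            survivors = []
            for xc in alive:
                rejected = False
                for s in _subsets(selected, max_cond, must_include=best):
                    _, p, _ = ci_test(data, xc, t, s, alpha_ci, min_avg_cell)
                    if math.isnan(p):
                        continue  # uninformative test: no evidence either way
                    p_max[xc] = max(p_max[xc], p)
                    if p_max[xc] >= alpha_ci:
                        rejected = True
                        break
                if not rejected:
                    survivors.append(xc)
            alive = survivors
        # backward pruning
        final = []
        for xc in selected:
            others = [v for v in selected if v != xc]
            independent = False
            for s in _subsets(others, max_cond):
                if not s:
                    continue
                _, p, _ = ci_test(data, xc, t, s, alpha_ci, min_avg_cell)
                if not math.isnan(p) and p >= alpha_ci:
                    independent = True
                    break
            if not independent:
                final.append(xc)
        cpc[t] = set(final)

    return {t: {x for x in s if t in cpc.get(x, set())} for t, s in cpc.items()}


def skeleton_edge_set(cpc: Mapping[str, set[str]]) -> set[frozenset]:
    return {frozenset((a, b)) for a, bs in cpc.items() for b in bs}


def full_skeleton(mask: LayerMask) -> dict[str, set[str]]:
    """All mask-admissible adjacencies (used to run unconstrained searches)."""
    names = [n.name for n in mask.nodes]
    return {
        t: {x for x in names if x != t and mask.undirected_allowed(x, t)} for t in names
    }


# ---------------------------------------------------------------------------
# BIC scoring


def _family_counts(
    data: DiscreteData, child: str, parents: Sequence[str]
) -> tuple[np.ndarray, int]:
    """Available-case joint counts, shape (Q, R)."""
    cols = [child] + list(parents)
    arrs = [data.col(c) for c in cols]
    ok = data.observed(child).copy()
    for c in parents:
        ok &= data.observed(c)
    r = data.card(child)
    q = 1
    for p in parents:
        q *= data.card(p)
    idx = np.zeros(int(ok.sum()), dtype=np.int64)
    for p, a in zip(parents, arrs[1:]):
        idx = idx * data.card(p) + a[ok]
    idx = idx * r + arrs[0][ok]
    counts = np.bincount(idx, minlength=q * r).reshape(q, r).astype(float)
    return counts, q


def family_loglik(data: DiscreteData, child: str, parents: Sequence[str]) -> float:
    """Maximum-likelihood log-likelihood of one family; empty cells add 0."""
    counts, _ = _family_counts(data, child, parents)
    n_j = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(counts > 0, counts * np.log(counts / n_j), 0.0)
    return float(terms.sum())


class FamilyScoreCache:
    """Memoized per-family BIC contributions: ll - (ln M / 2)(R-1)Q."""

    def __init__(self, data: DiscreteData):
        if data.m == 0:
            raise ValueError("cannot score an empty dataset")
        self.data = data
        self.half_log_m = 0.5 * math.log(data.m)
        self._cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def family_score(self, child: str, parents: tuple[str, ...]) -> float:
        key = (child, tuple(parents))
        if key not in self._cache:
            q = 1
            for p in parents:
                q *= self.data.card(p)
            ll = family_loglik(self.data, child, parents)
            penalty = self.half_log_m * (self.data.card(child) - 1) * q
            self._cache[key] = ll - penalty
        return self._cache[key]

    def total(self, structure: DbnStructure) -> float:
        return sum(
            self.family_score(n.name, tuple(structure.parents[n.name]))
            for n in structure.nodes
        )


def bic_score(structure: DbnStructure, data: DiscreteData) -> float:
    """BIC of a structure: l(theta_hat : D) - (log M / 2) Dim[G] (natural log)."""
    return FamilyScoreCache(data).total(structure)


# ---------------------------------------------------------------------------
# hill climbing


def _reaches(children: Mapping[str, set[str]], src: str, dst: str) -> bool:
    stack, seen = [src], {src}
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        for v in children.get(u, ()):
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


_MOVE_ORDER = {"add": 0, "delete": 1, "reverse": 2}


def hill_climb(
    skeleton: Mapping[str, set[str]],
    data: DiscreteData,
    mask: LayerMask,
    max_iter: int = 15,
    cache: FamilyScoreCache | None = None,
    start: DbnStructure | None = None,
) -> tuple[DbnStructure, ScoreLedger]:
    """Greedy BIC search constrained to the MMPC skeleton and layer mask.

    Starting from the empty graph, the search repeatedly evaluates every
    legal add / delete / reverse move and applies the one with the largest
    score increase (ties broken lexicographically on (child, parent, move
    type)).  ``max_iter`` caps the number of search iterations, each of
    which may accept up to one move per node, so the default cap of 15
    iterations can still assemble networks with hundreds of edges.

    Two-node reversals are exactly score-neutral (BIC is likelihood
    equivalent), so a greedy search can stall in the wrong orientation of a
    collider.  At a local optimum the search therefore attempts plateau
    escapes: a score-neutral reversal is accepted only when it immediately
    enables a strictly improving move.  Ledger BICs are consequently
    non-decreasing, strictly increasing except at those neutral reversals.

    Additions are restricted to skeleton adjacencies in mask-allowed
    orientations; acyclicity is enforced throughout.
    """
    eps = 1e-9
    cache = cache or FamilyScoreCache(data)
    nodes = mask.nodes
    parents: dict[str, tuple[str, ...]] = (
        {n.name: tuple(start.parents[n.name]) for n in nodes}
        if start is not None
        else {n.name: () for n in nodes}
    )
    children: dict[str, set[str]] = {n.name: set() for n in nodes}
    for c, ps in parents.items():
        for p in ps:
            children[p].add(c)
    ledger = ScoreLedger(m=data.m)
    current = sum(cache.family_score(c, ps) for c, ps in parents.items())

    def best_move_for_child(c: str, best):
        ps = parents[c]
        base = cache.family_score(c, ps)
        for p in sorted(skeleton.get(c, ())):
            if p in ps or not mask.allowed(p, c):
                continue
            if _reaches(children, c, p):
                continue  # would close a cycle
            cand = (cache.family_score(c, ps + (p,)) - base, c, p, "add")
            if _better(cand, best):
                best = cand
        for p in ps:
            reduced = tuple(v for v in ps if v != p)
            cand = (cache.family_score(c, reduced) - base, c, p, "delete")
            if _better(cand, best):
                best = cand
        for p in ps:  # reversal: p -> c becomes c -> p
            if not mask.allowed(c, p):
                continue
            children[p].discard(c)
            closes = _reaches(children, p, c)
            children[p].add(c)
            if closes:
                continue
            delta = (
                cache.family_score(c, tuple(v for v in ps if v != p))
                - base
                + cache.family_score(p, parents[p] + (c,))
                - cache.family_score(p, parents[p])
            )
            cand = (delta, c, p, "reverse")
            if _better(cand, best):
                best = cand
        return best

    def best_global_move():
        best = None
        for c in sorted(parents):
            best = best_move_for_child(c, best)
        return best

    def apply_move(c: str, p: str, move: str) -> None:
        if move == "add":
            parents[c] = parents[c] + (p,)
            children[p].add(c)
        elif move == "delete":
            parents[c] = tuple(v for v in parents[c] if v != p)
            children[p].discard(c)
        else:  # reverse
            parents[c] = tuple(v for v in parents[c] if v != p)
            children[p].discard(c)
            parents[p] = parents[p] + (c,)
            children[c].add(p)

    def _neutral_reversals():
        out = []
        for c in sorted(parents):
            for p in sorted(parents[c]):
                if not mask.allowed(c, p):
                    continue
                children[p].discard(c)
                closes = _reaches(children, p, c)
                children[p].add(c)
                if closes:
                    continue
                delta = (
                    cache.family_score(c, tuple(v for v in parents[c] if v != p))
                    - cache.family_score(c, parents[c])
                    + cache.family_score(p, parents[p] + (c,))
                    - cache.family_score(p, parents[p])
                )
                if abs(delta) <= eps:
                    out.append((c, p))
        return out

    def plateau_escape(max_depth: int = 3) -> bool:
        """Walk score-neutral reversals until an improving move appears.

        BIC cannot distinguish structures in the same likelihood-equivalence
        class, so a greedy search can converge to the wrong orientation of
        an equivalence class; chains of covered-edge reversals move within
        the class.  A chain is committed only when it ends in a position
        with a strictly improving move; otherwise everything is reverted.
        """
        nonlocal current

        def _signature():
            return frozenset((p, c) for c, ps in parents.items() for p in ps)

        visited = {_signature()}

        def rec(depth: int, path: list) -> bool:
            for c, p in _neutral_reversals():
                apply_move(c, p, "reverse")
                sig = _signature()
                if sig in visited:
                    apply_move(p, c, "reverse")
                    continue
                visited.add(sig)
                path.append((c, p))
                follow = best_global_move()
                if follow is not None and follow[0] > eps:
                    return True
                if depth > 1 and rec(depth - 1, path):
                    return True
                path.pop()
                apply_move(p, c, "reverse")
            return False

        path: list = []
        if rec(max_depth, path):
            for c, p in path:
                ledger.record("reverse", p, c, current, accepted=True)
            return True
        return False

    budget = max_iter * len(nodes)
    while budget > 0:
        best = best_global_move()
        if best is None or best[0] <= eps:
            if not plateau_escape():
                break
            budget -= 1
            continue
        delta, c, p, move = best
        apply_move(c, p, move)
        current += delta
        ledger.record(move, p, c, current, accepted=True)
        budget -= 1

    structure = DbnStructure(nodes=tuple(nodes), parents=parents)
    structure.validate_mask(mask)
    return structure, ledger


def _better(cand, best) -> bool:
    if cand[0] <= 1e-9:
        return False
    if best is None:
        return True
    if cand[0] != best[0]:
        return cand[0] > best[0]
    key = (cand[1], cand[2], _MOVE_ORDER[cand[3]])
    bkey = (best[1], best[2], _MOVE_ORDER[best[3]])
    return key < bkey


# ---------------------------------------------------------------------------
# parameters


def learn_parameters(
    structure: DbnStructure, data: DiscreteData, alpha: float = 2.0
) -> CpdSet:
    """MAP conditional probability tables under a Dirichlet(alpha) prior.

    Each row is ``(n_k + alpha - 1) / (n + R_i (alpha - 1))``; with the
    default alpha = 2 this is add-one smoothing, so no entry is ever zero.
    In the limit alpha -> 1 the estimate reduces to maximum likelihood
    (unseen parent configurations fall back to uniform rows).
    """
    if alpha < 1:
        raise ValueError("Dirichlet pseudo-count alpha must be >= 1")
    cards = {n.name: n.cardinality for n in structure.nodes}
    tables: dict[str, np.ndarray] = {}
    for n in structure.nodes:
        ps = structure.parents[n.name]
        q = 1
        for p in ps:
            q *= cards[p]
        if q > 1_000_000:
            raise ValueError(
                f"{n.name}: {q} parent configurations; use a coarser quantization"
            )
        counts, _ = _family_counts(data, n.name, ps)
        r = cards[n.name]
        num = counts + (alpha - 1.0)
        denom = counts.sum(axis=1, keepdims=True) + r * (alpha - 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            tab = np.where(denom > 0, num / denom, 1.0 / r)
        tables[n.name] = tab
    return CpdSet(tables=tables, parents=dict(structure.parents), cards=cards, alpha=alpha)


# ---------------------------------------------------------------------------
# transition table and full fit


def build_transition_table(dc: DiscreteCohort) -> tuple[DiscreteData, list[NodeDef], LayerMask]:
    """Unroll a discrete cohort into two-slice training instances.

    One row per consecutive visit pair (death = 0) and, for each deceased
    patient, one terminal row in which the previous slice is the last visit,
    the current slice is unobserved and death = 1.  TSO is taken at the
    current visit (at the last visit for terminal rows).
    """
    dyn = dc.dynamic_variables()
    specs = [s for s in dc.specs]
    dyn_specs = []
    for v in dyn:
        try:
            dyn_specs.append(dc.spec_by_name(v))
        except KeyError:
            # MITOS domains carry no explicit spec; binary by construction
            dyn_specs.append(
                VariableSpec(v, "dynamic", 5, _binary_quantization(), units="flag")
            )
    static_cols = list(dc.statics.columns)
    static_specs = [dc.spec_by_name(c) for c in static_cols]

    nodes = unroll_nodes(static_specs + dyn_specs, tso_cardinality=3)
    mask = LayerMask(nodes)

    rows: list[np.ndarray] = []
    colnames = (
        static_cols
        + [prev_name(v) for v in dyn]
        + [cur_name(v) for v in dyn]
        + [TSO_NODE, DEATH_NODE]
    )
    stat_arr = dc.statics[static_cols].to_numpy(dtype=np.int64)
    pid_to_row = {pid: i for i, pid in enumerate(dc.statics.index)}
    died = dc.death_day.notna()

    vis = dc.visits.sort_values([PID, DAY])
    for pid, grp in vis.groupby(PID, sort=True):
        codes = grp[dyn].to_numpy(dtype=np.int64)
        tso = grp["tso"].to_numpy(dtype=np.int64)
        st = stat_arr[pid_to_row[pid]]
        k = len(grp)
        for i in range(1, k):
            rows.append(
                np.concatenate([st, codes[i - 1], codes[i], [tso[i], 0]])
            )
        if bool(died.get(pid, False)):
            rows.append(
                np.concatenate(
                    [st, codes[k - 1], np.full(len(dyn), MISSING, dtype=np.int64), [tso[k - 1], 1]]
                )
            )
    if not rows:
        raise ValueError("no transition instances: patients need >= 2 visits")
    df = pd.DataFrame(np.vstack(rows), columns=colnames)
    cards = {n.name: n.cardinality for n in nodes}
    return DiscreteData(df=df, cards=cards), nodes, mask


def _binary_quantization():
    from .specs import Categorical

    return Categorical(("0", "1"))


@dataclass
class LearnConfig:
    alpha_ci: float = 0.05
    alpha: float = 2.0
    max_iter: int = 15
    max_cond: int = 3
    min_avg_cell: float = 5.0
    seed: int = 0


@dataclass
class DbnModel:
    """A structure + CPD pair bound to the variable schema that produced it."""

    structure: DbnStructure
    cpds: CpdSet
    specs: list[VariableSpec]
    tso_cuts: tuple[float, float]

    def model_hash(self) -> str:
        payload = {
            "parents": {c: list(ps) for c, ps in sorted(self.structure.parents.items())},
            "tables": {
                k: np.round(v, 12).tolist() for k, v in sorted(self.cpds.tables.items())
            },
            "tso_cuts": list(self.tso_cuts),
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()

    def dynamic_bases(self) -> list[str]:
        seen = []
        for n in self.structure.nodes:
            if n.role == Role.CUR:
                seen.append(n.base)
        return seen


@dataclass
class FittedDbn(DbnModel):
    """A learned model with its search ledger and provenance."""

    ledger: ScoreLedger | None = None
    config: LearnConfig | None = None
    skeleton: dict[str, set[str]] | None = None

    def provenance(self) -> dict:
        cfg = self.config or LearnConfig()
        return {
            "alpha_ci": cfg.alpha_ci,
            "alpha": cfg.alpha,
            "max_iter": cfg.max_iter,
            "max_cond": cfg.max_cond,
            "seed": cfg.seed,
            "m": self.ledger.m if self.ledger else None,
            "model_hash": self.model_hash(),
        }


def fit_dbn(train: DiscreteCohort, config: LearnConfig | None = None) -> FittedDbn:
    """Full learning pass: unroll, MMPC skeleton, hill climbing, MAP CPDs."""
    config = config or LearnConfig()
    data, nodes, mask = build_transition_table(train)
    skeleton = mmpc(data, mask, config.alpha_ci, config.max_cond, config.min_avg_cell)
    structure, ledger = hill_climb(skeleton, data, mask, config.max_iter)
    cpds = learn_parameters(structure, data, config.alpha)
    dyn_specs = []
    for v in train.dynamic_variables():
        try:
            dyn_specs.append(train.spec_by_name(v))
        except KeyError:
            dyn_specs.append(VariableSpec(v, "dynamic", 5, _binary_quantization(), units="flag"))
    static_specs = [train.spec_by_name(c) for c in train.statics.columns]
    return FittedDbn(
        structure=structure,
        cpds=cpds,
        specs=static_specs + dyn_specs,
        tso_cuts=train.tso_cuts,
        ledger=ledger,
        config=config,
        skeleton=skeleton,
    )
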