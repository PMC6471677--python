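"""Independent oracles and small builders shared by the test suite.

Everything here deliberately avoids the library's own search/sampling code
paths: DAG scoring oracles enumerate structures exhaustively, AU-ROC is
computed by explicit pair counting, and slice marginals are propagated
exactly over the full joint state space.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from progdbn.dbn import (
    CpdSet,
    DbnModel,
    DbnStructure,
    DiscreteData,
    FamilyScoreCache,
)
from progdbn.specs import DEATH_NODE, TSO_NODE, LayerMask, NodeDef, Role, cur_name, prev_name


def build_data(columns: dict[str, np.ndarray], cards: dict[str, int]) -> DiscreteData:
    return DiscreteData(df=pd.DataFrame(columns), cards=dict(cards))


def cur_mask(cards: dict[str, int]) -> LayerMask:
    """Mask over intra-slice nodes only: any acyclic orientation is allowed."""
    return LayerMask([NodeDef(n, Role.CUR, c, base=n) for n, c in cards.items()])


def enumerate_dags(names: list[str]):
    """Yield every DAG over the nodes as a parents dict (exhaustive)."""
    pairs = list(itertools.combinations(names, 2))
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        parents = {n: [] for n in names}
        for (a, b), s in zip(pairs, states):
            if s == 1:
                parents[b].append(a)
            elif s == 2:
                parents[a].append(b)
        if _acyclic(parents, names):
            yield {n: tuple(ps) for n, ps in parents.items()}


def _acyclic(parents, names) -> bool:
    indeg = {n: len(parents[n]) for n in names}
    ready = [n for n in names if indeg[n] == 0]
    seen = 0
    while ready:
        u = ready.pop()
        seen += 1
        for v in names:
            if u in parents[v]:
                indeg[v] -= 1
                if indeg[v] == 0:
                    ready.append(v)
    return seen == len(names)


def best_bic_exhaustive(data: DiscreteData, mask: LayerMask) -> float:
    """Highest BIC over every mask-valid DAG (enumeration oracle)."""
    names = [n.name for n in mask.nodes]
    cache = FamilyScoreCache(data)
    best = -np.inf
    for parents in enumerate_dags(names):
        if any(not mask.allowed(p, c) for c, ps in parents.items() for p in ps):
            continue
        score = sum(cache.family_score(c, ps) for c, ps in parents.items())
        best = max(best, score)
    return best


def pairwise_auroc_oracle(risks: np.ndarray, labels: np.ndarray) -> float:
    """AU-ROC by exhaustive pair enumeration; ties count one half."""
    pos = risks[labels == 1]
    neg = risks[labels == 0]
    total = 0.0
    for r_e in pos:
        for r_n in neg:
            if r_e > r_n:
                total += 1.0
            elif r_e == r_n:
                total += 0.5
    return total / (len(pos) * len(neg))


def make_chain_model(
    n_vars: int = 6,
    persist: float = 0.85,
    death_hazard: float = 0.0,
    seed: int = 0,
) -> DbnModel:
    """Small all-binary two-slice model with x_i[t] | x_i[t-1], x_{i-1}[t]."""
    from progdbn.specs import Categorical, VariableSpec, unroll_nodes

    rng = np.random.default_rng(seed)
    specs = [
        VariableSpec(f"x{i}", "dynamic", 5, Categorical(("0", "1"))) for i in range(n_vars)
    ]
    nodes = unroll_nodes(specs, tso_cardinality=3)
    parents = {}
    tables = {}
    for i in range(n_vars):
        ps = [prev_name(f"x{i}")]
        if i > 0:
            ps.append(cur_name(f"x{i-1}"))
        parents[cur_name(f"x{i}")] = tuple(ps)
        q = 2 ** len(ps)
        tab = np.empty((q, 2))
        for row in range(q):
            prev_state = row >> (len(ps) - 1)  # most-significant parent = own past
            base = persist if prev_state == 1 else 1 - persist
            jitter = rng.uniform(-0.1, 0.1)
            p1 = min(max(base + jitter, 0.02), 0.98)
            tab[row] = [1 - p1, p1]
        tables[cur_name(f"x{i}")] = tab
    parents[DEATH_NODE] = ()
    tables[DEATH_NODE] = np.array([[1 - death_hazard, death_hazard]])
    tables[TSO_NODE] = np.full((1, 3), 1 / 3)
    structure = DbnStructure(nodes=tuple(nodes), parents=parents)
    cards = {n.name: n.cardinality for n in nodes}
    cpds = CpdSet(tables=tables, parents=dict(structure.parents), cards=cards, alpha=0.0)
    return DbnModel(structure=structure, cpds=cpds, specs=specs, tso_cuts=(300.0, 550.0))


def exact_slice_marginals(model: DbnModel, initial: dict[str, int], n_slices: int):
    """Exact per-variable marginals per slice by full joint propagation.

    Only valid for models whose sampled nodes are the slice-t variables (no
    death, statics or TSO dependence).  Returns {var: array (n_slices+1, 2)}.
    """
    s = model.structure
    cur_nodes = [n.name for n in s.nodes if n.role == Role.CUR]
    order = s.topo_order(cur_nodes)
    bases = [s.node(c).base for c in order]
    k = len(bases)
    n_cfg = 2**k
    pos = {b: i for i, b in enumerate(bases)}

    # transition matrix over joint configurations
    T = np.zeros((n_cfg, n_cfg))
    for prev_cfg in range(n_cfg):
        prev_bits = [(prev_cfg >> (k - 1 - i)) & 1 for i in range(k)]
        for cur_cfg in range(n_cfg):
            cur_bits = [(cur_cfg >> (k - 1 - i)) & 1 for i in range(k)]
            p = 1.0
            for node in order:
                base = s.node(node).base
                row = 0
                for par in model.cpds.parents[node]:
                    nd = s.node(par)
                    val = prev_bits[pos[nd.base]] if nd.role == Role.PREV else cur_bits[pos[nd.base]]
                    row = row * 2 + val
                p *= model.cpds.tables[node][row, cur_bits[pos[base]]]
            T[prev_cfg, cur_cfg] = p

    joint = np.zeros(n_cfg)
    cfg0 = 0
    for b in bases:
        cfg0 = cfg0 * 2 + int(initial[b])
    joint[cfg0] = 1.0

    out = {b: np.zeros((n_slices + 1, 2)) for b in bases}
    for t in range(n_slices + 1):
        for b in bases:
            i = pos[b]
            mask1 = np.array([(c >> (k - 1 - i)) & 1 for c in range(n_cfg)], dtype=bool)
            out[b][t, 1] = joint[mask1].sum()
            out[b][t, 0] = 1.0 - out[b][t, 1]
        if t < n_slices:
            joint = joint @ T
    return out
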