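"""Synthetic longitudinal ALS-like cohorts from a known ground-truth DBN.

The generator emulates the structure of pooled ALS clinical-trial data:
static covariates (sex, age at onset, onset site, onset delta, Riluzole,
placebo/treatment), dynamic labs/vitals on an irregular visit grid
(44 ± 20 days between visits, minimum 7), ALSFRS-R items consistent with
four monotone MITOS loss-of-autonomy domains, an absorbing death event,
administrative censoring (549-day study window) and both entry-level and
whole-variable (block) missingness.  Because the ground truth — structure,
conditional probability tables, emission intervals — is known, every other
module can be validated by recovery experiments without any external data.

Two presets ship:

* ``small8`` — eight variables (sex, onset delta, treatment, FVC, weight,
  MITOS movement, TSO, death) with strong effects, for fast oracle tests;
* ``als_like`` — nineteen variables across all six layers, including seven
  labs/vitals, all four MITOS domains and a treatment effect on the death
  hazard.

Continuous values are emitted uniformly from per-code intervals that leave a
margin around each quantization cut point, so re-quantizing the emitted
values recovers the generating codes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import ALSFRSR_ITEMS, DAY, MITOS_DOMAINS, PID, Cohort, DiscreteCohort
from .dbn import (
    CpdSet,
    DbnModel,
    DbnStructure,
    DiscreteData,
    LearnConfig,
    build_transition_table,
    fit_dbn,
    learn_parameters,
)
from .preprocessing import DEFAULT_MITOS_RULE, quantize
from .simulation import CompiledModel
from .specs import (
    DEATH_NODE,
    MISSING,
    TSO_NODE,
    Categorical,
    ClinicalThresholds,
    LayerMask,
    Tertiles,
    VariableSpec,
    cur_name,
    prev_name,
    unroll_nodes,
)

Interval = tuple[float, float]


@dataclass
class GroundTruth:
    """A generating model plus everything needed to emit raw cohort tables."""

    model: DbnModel
    initial: dict[str, np.ndarray]  # slice-0 distribution per dynamic variable
    emission: dict[str, list[Interval]]  # per-code continuous intervals
    visit_gap_mean: float = 44.0
    visit_gap_sd: float = 20.0
    visit_gap_min: float = 7.0
    study_length_days: float = 549.0
    study_length_sd: float = 244.0
    study_length_min: float = 90.0
    mcar_rate: float = 0.05
    dropout_rate: float = 0.05
    emit_alsfrsr: bool = False
    preset: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        self.model.structure.validate_mask(LayerMask(self.model.structure.nodes))
        for v, p in self.initial.items():
            if abs(float(np.sum(p)) - 1.0) > 1e-9:
                raise ValueError(f"initial distribution of {v} does not sum to 1")
        for r in (self.mcar_rate, self.dropout_rate):
            if not 0 <= r <= 1:
                raise ValueError("missingness rates must be in [0, 1]")

    def variable_specs(self) -> list[VariableSpec]:
        """Schema for the preprocessing pipeline: tertile cuts left unfitted."""
        out = []
        for s in self.model.specs:
            if s.name in MITOS_DOMAINS:
                continue
            if isinstance(s.quantization, Tertiles):
                out.append(replace(s, quantization=Tertiles(None)))
            else:
                out.append(s)
        return out


# ---------------------------------------------------------------------------
# CPT construction helpers


def _table(parent_cards: Sequence[int], card: int, fn: Callable[..., Sequence[float]]) -> np.ndarray:
    """Build a CPT with mixed-radix row order (most-significant parent first)."""
    q = int(np.prod(parent_cards)) if parent_cards else 1
    tab = np.zeros((q, card))
    if parent_cards:
        for i, cfg in enumerate(itertools.product(*(range(c) for c in parent_cards))):
            tab[i] = fn(*cfg)
    else:
        tab[0] = fn()
    if (tab < 0).any() or np.abs(tab.sum(axis=1) - 1).max() > 1e-9:
        raise ValueError("invalid CPT rows")
    return tab


def _decline_row(card: int, state: int, p_down: float, p_up: float) -> np.ndarray:
    """Random walk biased downward; mass at the edges folds into staying."""
    row = np.zeros(card)
    if state > 0:
        row[state - 1] = p_down
    if state < card - 1:
        row[state + 1] = p_up
    row[state] = 1.0 - row.sum()
    return row


def _hazard_row(h: float) -> np.ndarray:
    h = min(max(h, 0.0), 0.95)
    return np.array([1.0 - h, h])


def _mitos_row(prev: int, h: float) -> np.ndarray:
    if prev == 1:
        return np.array([0.0, 1.0])  # irreversible
    return np.array([1.0 - h, h])


def _margin_intervals(cuts: Sequence[float], lo: float, hi: float, margin: float) -> list[Interval]:
    """Per-code emission intervals leaving ``margin`` clear around each cut."""
    edges = [lo] + list(cuts) + [hi]
    out = []
    for i in range(len(edges) - 1):
        a = edges[i] + (margin if i > 0 else 0.0)
        b = edges[i + 1] - (margin if i + 1 < len(edges) - 1 else 0.0)
        out.append((a, b))
    return out


# ---------------------------------------------------------------------------
# presets


def make_ground_truth(preset: str, seed: int = 0) -> GroundTruth:
    """Construct a named ground-truth model (reproducible from the seed)."""
    if preset == "small8":
        return _small8(seed)
    if preset == "als_like":
        return _als_like(seed)
    raise ValueError(f"unknown preset {preset!r}; available: small8, als_like")


def _small8(seed: int) -> GroundTruth:
    specs = [
        VariableSpec("sex", "static", 1, Categorical(("F", "M"))),
        VariableSpec("onset_delta", "static", 2, Tertiles((200.0, 400.0)), units="days"),
        VariableSpec("treatment", "static", 3, Categorical(("placebo", "active"))),
        VariableSpec("fvc", "dynamic", 5, ClinicalThresholds((50.0, 80.0)), units="% predicted"),
        VariableSpec("weight", "dynamic", 5, ClinicalThresholds((60.0, 80.0)), units="kg"),
        VariableSpec("mitos_movement", "dynamic", 5, Categorical(("0", "1"))),
    ]
    nodes = unroll_nodes(specs, tso_cardinality=3)
    parents = {
        cur_name("fvc"): (prev_name("fvc"), "treatment"),
        cur_name("weight"): (prev_name("weight"),),
        cur_name("mitos_movement"): (prev_name("mitos_movement"), prev_name("fvc")),
        DEATH_NODE: (prev_name("fvc"), prev_name("mitos_movement"), "treatment", "sex"),
    }
    structure = DbnStructure(nodes=tuple(nodes), parents=parents)
    cards = {n.name: n.cardinality for n in nodes}

    tables = {
        "sex": _table((), 2, lambda: [0.45, 0.55]),
        "onset_delta": _table((), 3, lambda: [1 / 3, 1 / 3, 1 / 3]),
        "treatment": _table((), 2, lambda: [0.5, 0.5]),
        prev_name("fvc"): _table((), 3, lambda: [0.10, 0.30, 0.60]),
        prev_name("weight"): _table((), 3, lambda: [0.20, 0.50, 0.30]),
        prev_name("mitos_movement"): _table((), 2, lambda: [0.92, 0.08]),
        TSO_NODE: _table((), 3, lambda: [1 / 3, 1 / 3, 1 / 3]),
        cur_name("fvc"): _table(
            (3, 2), 3, lambda f, tr: _decline_row(3, f, p_down=0.10 if tr else 0.28, p_up=0.02)
        ),
        cur_name("weight"): _table((3,), 3, lambda w: _decline_row(3, w, 0.15, 0.02)),
        cur_name("mitos_movement"): _table(
            (2, 3), 2, lambda m, f: _mitos_row(m, h=[0.30, 0.12, 0.04][f])
        ),
        DEATH_NODE: _table(
            (3, 2, 2, 2),
            2,
            lambda f, m, tr, sx: _hazard_row(
                0.005 * [4.0, 2.0, 1.0][f] * (3.0 if m else 1.0) * (0.5 if tr else 1.0) * (1.8 if sx else 1.0)
            ),
        ),
    }
    cpds = CpdSet(tables=tables, parents=dict(structure.parents), cards=cards, alpha=0.0)
    model = DbnModel(structure=structure, cpds=cpds, specs=specs, tso_cuts=(300.0, 550.0))
    emission = {
        "onset_delta": _margin_intervals((200, 400), 60, 720, 8.0),
        "fvc": _margin_intervals((50, 80), 25, 115, 0.6),
        "weight": _margin_intervals((60, 80), 42, 110, 0.6),
    }
    initial = {
        "fvc": np.array([0.10, 0.30, 0.60]),
        "weight": np.array([0.20, 0.50, 0.30]),
        "mitos_movement": np.array([0.92, 0.08]),
    }
    return GroundTruth(
        model=model, initial=initial, emission=emission, preset="small8", seed=seed
    )


def _als_like(seed: int) -> GroundTruth:
    lab_cuts = {
        "fvc": ((50.0, 80.0), 25, 115, "% predicted"),
        "weight": ((60.0, 80.0), 42, 110, "kg"),
        "creatinine": ((0.7, 1.0), 0.35, 1.6, "mg/dL"),
        "phosphorus": ((2.5, 4.5), 1.5, 6.5, "mg/dL"),
        "calcium": ((8.5, 10.5), 7.2, 11.8, "mg/dL"),
        "bicarbonate": ((22.0, 29.0), 15, 36, "mmol/L"),
        "chloride": ((98.0, 107.0), 90, 115, "mmol/L"),
    }
    specs = [
        VariableSpec("sex", "static", 1, Categorical(("F", "M"))),
        VariableSpec("age_onset", "static", 1, Tertiles((51.0, 61.0)), units="years"),
        VariableSpec("onset_site", "static", 2, Categorical(("limb", "bulbar"))),
        VariableSpec("onset_delta", "static", 2, Tertiles((200.0, 400.0)), units="days"),
        VariableSpec("riluzole", "static", 3, Categorical(("no", "yes"))),
        VariableSpec("treatment", "static", 3, Categorical(("placebo", "active"))),
    ]
    for name, (cuts, lo, hi, units) in lab_cuts.items():
        specs.append(VariableSpec(name, "dynamic", 5, ClinicalThresholds(cuts), units=units))
    for dom in MITOS_DOMAINS:
        specs.append(VariableSpec(dom, "dynamic", 5, Categorical(("0", "1"))))

    nodes = unroll_nodes(specs, tso_cardinality=3)
    parents = {
        "onset_site": ("sex",),
        cur_name("fvc"): (prev_name("fvc"), "treatment"),
        cur_name("weight"): (prev_name("weight"),),
        cur_name("creatinine"): (prev_name("creatinine"), prev_name("phosphorus")),
        cur_name("phosphorus"): (prev_name("phosphorus"), prev_name("creatinine")),
        cur_name("calcium"): (prev_name("calcium"),),
        cur_name("bicarbonate"): (prev_name("bicarbonate"),),
        cur_name("chloride"): (prev_name("chloride"), prev_name("mitos_breathing")),
        cur_name("mitos_movement"): (prev_name("mitos_movement"), prev_name("creatinine")),
        cur_name("mitos_communication"): (prev_name("mitos_communication"), "onset_site"),
        cur_name("mitos_swallowing"): (prev_name("mitos_swallowing"), "onset_site"),
        cur_name("mitos_breathing"): (prev_name("mitos_breathing"), prev_name("fvc")),
        DEATH_NODE: (prev_name("mitos_breathing"), prev_name("fvc"), "treatment", "age_onset"),
    }
    structure = DbnStructure(nodes=tuple(nodes), parents=parents)
    cards = {n.name: n.cardinality for n in nodes}

    uniform3 = lambda: [1 / 3, 1 / 3, 1 / 3]
    tables: dict[str, np.ndarray] = {
        "sex": _table((), 2, lambda: [0.40, 0.60]),
        "age_onset": _table((), 3, uniform3),
        "onset_site": _table((2,), 2, lambda sx: [0.55, 0.45] if sx == 0 else [0.75, 0.25]),
        "onset_delta": _table((), 3, uniform3),
        "riluzole": _table((), 2, lambda: [0.30, 0.70]),
        "treatment": _table((), 2, lambda: [0.5, 0.5]),
        TSO_NODE: _table((), 3, uniform3),
        cur_name("fvc"): _table(
            (3, 2), 3, lambda f, tr: _decline_row(3, f, 0.05 if tr else 0.13, 0.01)
        ),
        cur_name("weight"): _table((3,), 3, lambda w: _decline_row(3, w, 0.10, 0.02)),
        cur_name("creatinine"): _table(
            (3, 3), 3, lambda c, p: _decline_row(3, c, 0.25 if p == 0 else 0.08, 0.03)
        ),
        cur_name("phosphorus"): _table(
            (3, 3), 3, lambda p, c: _decline_row(3, p, 0.22 if c == 0 else 0.07, 0.04)
        ),
        cur_name("calcium"): _table((3,), 3, lambda c: _decline_row(3, c, 0.08, 0.08)),
        cur_name("bicarbonate"): _table((3,), 3, lambda b: _decline_row(3, b, 0.10, 0.06)),
        cur_name("chloride"): _table(
            (3, 2), 3, lambda c, br: _decline_row(3, c, 0.30 if br else 0.08, 0.04)
        ),
        cur_name("mitos_movement"): _table(
            (2, 3), 2, lambda m, c: _mitos_row(m, h=[0.15, 0.06, 0.02][c])
        ),
        cur_name("mitos_communication"): _table(
            (2, 2), 2, lambda m, site: _mitos_row(m, h=0.14 if site else 0.03)
        ),
        cur_name("mitos_swallowing"): _table(
            (2, 2), 2, lambda m, site: _mitos_row(m, h=0.16 if site else 0.04)
        ),
        cur_name("mitos_breathing"): _table(
            (2, 3), 2, lambda m, f: _mitos_row(m, h=[0.08, 0.025, 0.004][f])
        ),
        DEATH_NODE: _table(
            (2, 3, 2, 3),
            2,
            lambda br, f, tr, age: _hazard_row(
                0.0004
                * (35.0 if br else 1.0)
                * [18.0, 5.0, 1.0][f]
                * (0.35 if tr else 1.0)
                * [1.0, 2.2, 5.0][age]
            ),
        ),
    }
    # slice-0 marginals: trial entry spans the whole spectrum of disease
    # stages, so the baseline state is strongly prognostic
    initial = {
        "fvc": np.array([0.30, 0.30, 0.40]),
        "weight": np.array([0.25, 0.50, 0.25]),
        "creatinine": np.array([0.30, 0.40, 0.30]),
        "phosphorus": np.array([0.25, 0.50, 0.25]),
        "calcium": np.array([0.20, 0.60, 0.20]),
        "bicarbonate": np.array([0.20, 0.60, 0.20]),
        "chloride": np.array([0.20, 0.60, 0.20]),
        "mitos_movement": np.array([0.70, 0.30]),
        "mitos_communication": np.array([0.90, 0.10]),
        "mitos_swallowing": np.array([0.88, 0.12]),
        "mitos_breathing": np.array([0.80, 0.20]),
    }
    emission: dict[str, list[Interval]] = {
        "age_onset": _margin_intervals((51, 61), 40, 79, 1.0),
        "onset_delta": _margin_intervals((200, 400), 60, 720, 8.0),
    }
    for name, (cuts, lo, hi, _) in lab_cuts.items():
        margin = 0.02 * (hi - lo) / 3
        emission[name] = _margin_intervals(cuts, lo, hi, margin)

    cpds = CpdSet(tables=tables, parents=dict(structure.parents), cards=cards, alpha=0.0)
    model = DbnModel(structure=structure, cpds=cpds, specs=specs, tso_cuts=(300.0, 550.0))
    return GroundTruth(
        model=model,
        initial=initial,
        emission=emission,
        emit_alsfrsr=True,
        preset="als_like",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cohort generation


def _sample_categorical(p: np.ndarray, rng: np.random.Generator, n: int) -> np.ndarray:
    u = rng.random(n)
    return (np.cumsum(p) > u[:, None]).argmax(axis=1).astype(np.int64)


def generate_cohort(
    truth: GroundTruth,
    n_patients: int,
    seed: int = 0,
    return_latent: bool = False,
):
    """Sample a raw cohort from the ground truth.

    Per patient: statics sampled root-down from the truth CPDs; an irregular
    visit grid (clipped normal gaps); the dynamic state unrolled one visit at
    a time with the absorbing death indicator sampled per transition; raw
    continuous values emitted from per-code intervals; ALSFRS-R items derived
    consistently with the generating MITOS flags (``als_like``); missingness
    applied last.  With ``return_latent=True`` the generating codes are also
    returned, enabling round-trip checks.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng([seed, 101])
    compiled = CompiledModel(truth.model)
    n = n_patients
    pids = np.array([f"P{i:05d}" for i in range(n)])

    # statics (codes), root-down in topological order
    statics: dict[str, np.ndarray] = {}
    ctx = {"static": statics, "prev": {}, "cur": {}, "tso": {}}
    for name in compiled.static_order:
        statics[name] = compiled.samplers[name].sample(ctx, n, rng)

    onset_iv = truth.emission["onset_delta"]
    onset_raw = np.array(
        [rng.uniform(*onset_iv[c]) for c in statics["onset_delta"]]
    )

    # initial dynamic state
    state = {v: _sample_categorical(p, rng, n) for v, p in truth.initial.items()}

    day = np.zeros(n)
    alive = np.ones(n, dtype=bool)
    active = np.ones(n, dtype=bool)
    death_day = np.full(n, np.nan)
    # per-patient observation window (non-uniform follow-up across trials)
    window = np.clip(
        rng.normal(truth.study_length_days, truth.study_length_sd, n),
        truth.study_length_min,
        None,
    )

    visit_rows: list[tuple] = []  # (pid_idx, day, {var: code})
    bases = compiled.bases
    max_visits = int(window.max() / truth.visit_gap_min) + 2

    for _ in range(max_visits):
        idx = np.where(active)[0]
        if idx.size == 0:
            break
        for i in idx:
            visit_rows.append((i, float(day[i]), {v: int(state[v][i]) for v in bases}))

        gaps = np.clip(
            rng.normal(truth.visit_gap_mean, truth.visit_gap_sd, n), truth.visit_gap_min, None
        )
        next_day = day + gaps
        tso_days = onset_raw + next_day
        tso_code = compiled.tso_code(tso_days)
        ctx = {"static": statics, "prev": state, "cur": {}, "tso": {TSO_NODE: tso_code}}

        dies = compiled.samplers[DEATH_NODE].sample(ctx, n, rng).astype(bool)
        newly = active & dies
        death_day[newly] = next_day[newly]
        alive &= ~(active & dies)
        active &= alive & (next_day <= window)

        cur: dict[str, np.ndarray] = {}
        ctx["cur"] = cur
        for node in compiled.cur_order:
            base = truth.model.structure.node(node).base
            sampled = compiled.samplers[node].sample(ctx, n, rng)
            if base in compiled.monotone:
                sampled = np.maximum(sampled, state[base])
            cur[base] = sampled
        for b in bases:
            state[b] = np.where(active, cur[b], state[b])
        day = next_day

    # assemble tables -------------------------------------------------------
    vis_records = {
        PID: [pids[i] for i, _, _ in visit_rows],
        DAY: [int(round(d)) for _, d, _ in visit_rows],
    }
    for b in bases:
        vis_records[b] = [codes[b] for _, _, codes in visit_rows]
    codes_df = pd.DataFrame(vis_records)

    statics_raw = pd.DataFrame(index=pd.Index(pids, name=PID))
    spec_by = {s.name: s for s in truth.model.specs}
    for name in compiled.static_order:
        spec = spec_by[name]
        if isinstance(spec.quantization, Categorical):
            statics_raw[name] = [spec.quantization.labels[c] for c in statics[name]]
        else:
            iv = truth.emission[name]
            statics_raw[name] = [
                onset_raw[i] if name == "onset_delta" else rng.uniform(*iv[statics[name][i]])
                for i in range(n)
            ]

    visits_raw = codes_df[[PID, DAY]].copy()
    for b in bases:
        if b in MITOS_DOMAINS:
            if not truth.emit_alsfrsr:
                visits_raw[b] = codes_df[b].astype(float)
            continue
        spec = spec_by[b]
        if isinstance(spec.quantization, Categorical):
            visits_raw[b] = [spec.quantization.labels[c] for c in codes_df[b]]
        else:
            iv = truth.emission[b]
            lo = np.array([iv[c][0] for c in codes_df[b]])
            hi = np.array([iv[c][1] for c in codes_df[b]])
            visits_raw[b] = lo + rng.random(len(codes_df)) * (hi - lo)

    alsfrsr = None
    if truth.emit_alsfrsr:
        alsfrsr = _emit_alsfrsr(codes_df, rng)

    # missingness: entry-level MCAR plus per-subject whole-variable dropout
    labs = [b for b in bases if b not in MITOS_DOMAINS]
    for b in labs:
        col = visits_raw[b].to_numpy(dtype=float)
        if truth.mcar_rate > 0:
            col = np.where(rng.random(len(col)) < truth.mcar_rate, np.nan, col)
        if truth.dropout_rate > 0:
            dropped = set(pids[rng.random(n) < truth.dropout_rate])
            col = np.where(visits_raw[PID].isin(dropped), np.nan, col)
        visits_raw[b] = col

    cohort = Cohort(
        statics=statics_raw,
        visits=visits_raw,
        death_day=pd.Series(death_day, index=statics_raw.index),
        alsfrsr=alsfrsr,
    )
    if not return_latent:
        return cohort
    latent = {"visits": codes_df, "statics": pd.DataFrame(statics, index=statics_raw.index)}
    return cohort, latent


def _emit_alsfrsr(codes_df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """ALSFRS-R items consistent with the generating MITOS flags.

    For a lost domain, one defining item is pinned at/below its cut; for a
    preserved domain every defining item is sampled above its cut.
    Non-defining items are uninformative (uniform 1-4).
    """
    m = len(codes_df)
    out = codes_df[[PID, DAY]].copy()
    items: dict[str, np.ndarray] = {
        it: rng.integers(1, 5, size=m) for it in ALSFRSR_ITEMS
    }
    for dom, rule in DEFAULT_MITOS_RULE.items():
        flags = codes_df[dom].to_numpy()
        primary_item, primary_cut = rule[0]
        for item, cut in rule:
            hi = rng.integers(cut + 1, 5, size=m)
            items[item] = np.where(flags == 1, items[item], hi)
        low = rng.integers(0, primary_cut + 1, size=m)
        other = rng.integers(primary_cut + 1, 5, size=m)
        items[primary_item] = np.where(flags == 1, low, other)
        for item, cut in rule[1:]:
            items[item] = np.where(flags == 1, rng.integers(cut + 1, 5, size=m), items[item])
    for it in ALSFRSR_ITEMS:
        out[it] = items[it]
    return out


# ---------------------------------------------------------------------------
# recovery experiments


def skeleton_metrics(truth: DbnStructure, fitted: DbnStructure) -> dict[str, float]:
    """Precision/recall/F1 of the fitted skeleton against the truth skeleton."""
    t = truth.skeleton_edges()
    f = fitted.skeleton_edges()
    tp = len(t & f)
    precision = tp / len(f) if f else (1.0 if not t else 0.0)
    recall = tp / len(t) if t else 1.0
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return {"precision": precision, "recall": recall, "f1": f1, "tp": tp, "n_truth": len(t), "n_fitted": len(f)}


def cpd_recovery_error(
    truth: GroundTruth,
    data: DiscreteData,
    alpha: float = 2.0,
    min_row_count: int = 100,
) -> float:
    """Max absolute CPT error, truth structure fixed, over well-observed rows.

    Only transition families are compared — slice-t variables and the death
    indicator — because those are the tables the simulation consumes.  Root
    marginals of slice t-1 nodes are evidence summaries pooled over the whole
    visit history, not parameters of the generating process.
    """
    from .dbn import _family_counts
    from .specs import Role

    est = learn_parameters(truth.model.structure, data, alpha=alpha)
    roles = {n.name: n.role for n in truth.model.structure.nodes}
    worst = 0.0
    for node, truth_tab in truth.model.cpds.tables.items():
        if roles[node] not in (Role.CUR, Role.DEATH):
            continue
        counts, _ = _family_counts(data, node, truth.model.structure.parents[node])
        rows = counts.sum(axis=1) >= min_row_count
        if rows.any():
            err = np.abs(est.tables[node][rows] - truth_tab[rows]).max()
            worst = max(worst, float(err))
    return worst


def discretize_generated(
    truth: GroundTruth, cohort: Cohort, seed: int = 0
) -> DiscreteCohort:
    """Quantize a generated cohort with its own schema (tertiles fit on it)."""
    return quantize(cohort, truth.variable_specs())


def recovery_experiment(
    preset: str,
    n_grid: Sequence[int],
    seeds: Sequence[int],
    learn_config: LearnConfig | None = None,
) -> pd.DataFrame:
    """Structure/parameter recovery across cohort sizes and seeds.

    For each (n, seed): generate a cohort, preprocess it, fit the network and
    report skeleton precision/recall/F1 against the truth plus the max CPT
    error with the structure fixed to truth.
    """
    learn_config = learn_config or LearnConfig()
    truth = make_ground_truth(preset)
    rows = []
    for n in n_grid:
        for seed in seeds:
            cohort = generate_cohort(truth, n, seed=seed)
            dc = discretize_generated(truth, cohort, seed=seed)
            fitted = fit_dbn(dc, learn_config)
            met = skeleton_metrics(truth.model.structure, fitted.structure)
            data, _, _ = build_transition_table(dc)
            met.update(
                {
                    "preset": preset,
                    "n": n,
                    "seed": seed,
                    "cpd_max_error": cpd_recovery_error(truth, data, learn_config.alpha),
                }
            )
            rows.append(met)
    return pd.DataFrame(rows)
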