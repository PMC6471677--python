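"""Forward simulation of in-silico patient trajectories from a fitted DBN.

Starting from a patient's first observed (discretized) visit, the engine
repeatedly samples one time slice at a time: cumulative time since onset is
advanced deterministically by the slice duration and re-quantized with the
training tertile cuts, the absorbing death indicator is sampled from its
conditional table given the previous slice, statics and TSO, and — if the
in-silico patient survives — the slice-t variables are sampled in topological
order of the intra-slice edges.  MITOS loss-of-autonomy flags are clamped to
be non-decreasing.  Replicates are vectorized, so a patient's 400 replicate
trajectories are produced in a handful of NumPy operations per slice.

Months are 30-day months throughout, so with the default 30-day slice the
slice index coincides with the month.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import DAY, MITOS_DOMAINS, PID, DiscreteCohort
from .dbn import DbnModel
from .specs import DEATH_NODE, MISSING, TSO_NODE, Role, cur_name

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.0


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation settings: horizon, replicate count, slice length, seed."""

    n_slices: int = 30
    n_reps: int = 400
    slice_duration: float = 30.0  # days
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1 or self.n_reps < 1 or self.slice_duration <= 0:
            raise ValueError("invalid simulation configuration")


# ---------------------------------------------------------------------------
# compiled sampler


class _NodeSampler:
    """Precompiled CPT lookup for one node: parent sources and strides."""

    def __init__(self, model: DbnModel, node: str):
        self.table = model.cpds.tables[node]
        self.card = model.cpds.cards[node]
        parents = model.cpds.parents[node]
        strides = model.cpds.row_strides(node)
        self.parents: list[tuple[str, str, int]] = []
        roles = {n.name: n for n in model.structure.nodes}
        for p, s in zip(parents, strides):
            nd = roles[p]
            if nd.role == Role.PREV:
                self.parents.append(("prev", nd.base, int(s)))
            elif nd.role == Role.CUR:
                self.parents.append(("cur", nd.base, int(s)))
            elif nd.role == Role.TSO:
                self.parents.append(("tso", TSO_NODE, int(s)))
            else:
                self.parents.append(("static", p, int(s)))

    def row_index(self, ctx: Mapping[str, Mapping[str, np.ndarray]], n: int) -> np.ndarray:
        idx = np.zeros(n, dtype=np.int64)
        for kind, key, stride in self.parents:
            idx += stride * ctx[kind][key]
        return idx

    def sample(self, ctx, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.table[self.row_index(ctx, n)]
        u = rng.random(n)
        return (p.cumsum(axis=1) > u[:, None]).argmax(axis=1)


class CompiledModel:
    """Model compiled into per-node samplers and a slice-sampling order."""

    def __init__(self, model: DbnModel):
        self.model = model
        s = model.structure
        self.static_names = [
            n.name for n in s.nodes if n.role in (Role.L1, Role.L2, Role.L3)
        ]
        self.static_order = s.topo_order(self.static_names)
        cur_nodes = [n.name for n in s.nodes if n.role == Role.CUR]
        self.cur_order = s.topo_order(cur_nodes)
        self.bases = [s.node(c).base for c in self.cur_order]
        self.monotone = [b for b in self.bases if b in MITOS_DOMAINS]
        # only nodes that are ever sampled need tables (t-1 nodes are evidence)
        sampled = self.static_names + cur_nodes + [DEATH_NODE]
        self.samplers = {name: _NodeSampler(model, name) for name in sampled}
        self.tso_cuts = np.asarray(model.tso_cuts, dtype=float)

    def tso_code(self, days: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.tso_cuts, days, side="right").astype(np.int64)

    def tso_representative_days(self, code: int) -> float:
        lo, hi = self.tso_cuts
        return {0: 0.5 * lo, 1: 0.5 * (lo + hi), 2: 1.25 * hi}[int(code)]


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class PatientTrajectories:
    """All replicate trajectories simulated for one starting patient."""

    patient_id: object
    death_slice: np.ndarray  # (n_reps,), -1 when no in-silico death by horizon
    event_slice: dict[str, np.ndarray]  # outcome -> (n_reps,), -1 = never
    config: SimulationConfig
    states: dict[str, np.ndarray] | None = None  # var -> (n_reps, n_slices+1)

    @property
    def n_reps(self) -> int:
        return len(self.death_slice)


@dataclass
class TrajectorySet:
    """Simulated replicate trajectories for a set of starting patients."""

    patients: dict[object, PatientTrajectories]
    config: SimulationConfig
    model_hash: str

    @property
    def n_trajectories(self) -> int:
        return sum(t.n_reps for t in self.patients.values())

    @property
    def patient_ids(self) -> list:
        return list(self.patients.keys())

    def outcomes(self) -> list[str]:
        first = next(iter(self.patients.values()))
        return list(first.event_slice.keys())

    def event_matrix(self, outcome: str) -> np.ndarray:
        """(n_patients, n_reps) matrix of event slices (-1 = never)."""
        return np.vstack([t.event_slice[outcome] for t in self.patients.values()])


OUTCOMES = MITOS_DOMAINS + ("death",)


def _initial_statics(
    compiled: CompiledModel,
    initial_state: Mapping[str, int],
    n: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    ctx = {"static": out, "prev": {}, "cur": {}, "tso": {}}
    for name in compiled.static_order:
        v = initial_state.get(name, MISSING)
        if v is None or int(v) == MISSING:
            logger.info("static %s missing at baseline: sampled from model", name)
            out[name] = compiled.samplers[name].sample(ctx, n, rng)
        else:
            out[name] = np.full(n, int(v), dtype=np.int64)
    return out


def _initial_dynamic(
    compiled: CompiledModel,
    initial_state: Mapping[str, int],
    n: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for base in compiled.bases:
        v = initial_state.get(base, MISSING)
        if v is None or int(v) == MISSING:
            # marginalize the slice-t table uniformly over parent configs
            logger.info("dynamic %s missing at baseline: sampled from model marginal", base)
            p = compiled.samplers[cur_name(base)].table.mean(axis=0)
            u = rng.random(n)
            out[base] = (p.cumsum() > u[:, None]).argmax(axis=1).astype(np.int64)
        else:
            out[base] = np.full(n, int(v), dtype=np.int64)
    return out


def simulate_patient(
    model: DbnModel,
    initial_state: Mapping[str, float],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    keep_states: bool = True,
    compiled: CompiledModel | None = None,
) -> PatientTrajectories:
    """Simulate ``config.n_reps`` replicate trajectories for one patient.

    ``initial_state`` maps variable names to baseline codes (statics plus
    first-visit dynamic values; missing entries are sampled from the model)
    and should carry ``tso_days``, the raw cumulative days since onset at
    the first visit (falls back to a representative value of the supplied
    ``tso`` code).
    """
    compiled = compiled or CompiledModel(model)
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_reps
    horizon = config.n_slices

    for base in compiled.bases:
        v = initial_state.get(base)
        if v is not None and int(v) != MISSING and not 0 <= int(v) < model.cpds.cards[cur_name(base)]:
            raise ValueError(f"state code {v} outside cardinality of {base}")

    statics = _initial_statics(compiled, initial_state, n, rng)
    prev = _initial_dynamic(compiled, initial_state, n, rng)

    if "tso_days" in initial_state and initial_state["tso_days"] is not None and np.isfinite(
        initial_state["tso_days"]
    ):
        tso0 = float(initial_state["tso_days"])
    elif "tso" in initial_state and initial_state["tso"] is not None:
        tso0 = compiled.tso_representative_days(int(initial_state["tso"]))
    else:
        raise ValueError("initial state needs tso_days or a tso code")

    death_slice = np.full(n, -1, dtype=np.int64)
    event = {d: np.full(n, -1, dtype=np.int64) for d in OUTCOMES}
    for d in compiled.monotone:
        event[d] = np.where(prev[d] == 1, 0, -1).astype(np.int64)

    states = None
    if keep_states:
        states = {
            b: np.full((n, horizon + 1), MISSING, dtype=np.int16) for b in compiled.bases
        }
        for b in compiled.bases:
            states[b][:, 0] = prev[b]

    alive = np.ones(n, dtype=bool)
    for t in range(1, horizon + 1):
        if not alive.any():
            break
        tso_days = tso0 + t * config.slice_duration
        tso_code = np.full(n, 0, dtype=np.int64)
        tso_code[:] = compiled.tso_code(np.full(n, tso_days))
        ctx = {"static": statics, "prev": prev, "cur": {}, "tso": {TSO_NODE: tso_code}}

        # death first: it is conditioned on the previous slice only
        dies = compiled.samplers[DEATH_NODE].sample(ctx, n, rng).astype(bool)
        newly_dead = alive & dies
        death_slice[newly_dead] = t
        event["death"][newly_dead] = t
        alive = alive & ~dies

        cur: dict[str, np.ndarray] = {}
        ctx["cur"] = cur
        for node in compiled.cur_order:
            base = compiled.model.structure.node(node).base
            sampled = compiled.samplers[node].sample(ctx, n, rng)
            if base in compiled.monotone:
                sampled = np.maximum(sampled, prev[base])
            cur[base] = sampled
        for d in compiled.monotone:
            hit = alive & (cur[d] == 1) & (event[d] < 0)
            event[d][hit] = t
        if keep_states:
            for b in compiled.bases:
                states[b][alive, t] = cur[b][alive]
        # frozen state for the dead keeps vector ops simple; never recorded
        for b in compiled.bases:
            prev[b] = np.where(alive, cur[b], prev[b])

    return PatientTrajectories(
        patient_id=initial_state.get("patient_id", None),
        death_slice=death_slice,
        event_slice=event,
        config=config,
        states=states,
    )


def initial_states_from_cohort(cohort: DiscreteCohort) -> dict[object, dict]:
    """Baseline (first visit) state per patient, with raw TSO days if stored."""
    out: dict[object, dict] = {}
    first = cohort.visits.sort_values([PID, DAY]).groupby(PID, sort=True).head(1)
    for _, row in first.iterrows():
        pid = row[PID]
        st = {c: int(cohort.statics.loc[pid, c]) for c in cohort.statics.columns}
        for v in cohort.dynamic_variables():
            st[v] = int(row[v])
        st["tso"] = int(row["tso"])
        if "tso_raw" in cohort.visits.columns and np.isfinite(row["tso_raw"]):
            st["tso_days"] = float(row["tso_raw"])
        st["patient_id"] = pid
        out[pid] = st
    return out


def simulate_cohort(
    model: DbnModel,
    cohort: DiscreteCohort,
    config: SimulationConfig,
    keep_states: bool = False,
) -> TrajectorySet:
    """Simulate every cohort patient from their first visit (seed-reproducible)."""
    compiled = CompiledModel(model)
    model_bases = set(compiled.bases)
    cohort_vars = set(cohort.dynamic_variables())
    if not model_bases <= cohort_vars | {TSO_NODE}:
        missing = sorted(model_bases - cohort_vars)
        raise ValueError(f"cohort lacks model variables: {missing}")

    states = initial_states_from_cohort(cohort)
    patients: dict[object, PatientTrajectories] = {}
    for idx, pid in enumerate(sorted(states.keys(), key=str)):
        rng = np.random.default_rng([config.seed, idx])
        patients[pid] = simulate_patient(
            model, states[pid], config, rng=rng, keep_states=keep_states, compiled=compiled
        )
    return TrajectorySet(patients=patients, config=config, model_hash=model.model_hash())


# ---------------------------------------------------------------------------
# population curves


def _event_by_month(trajset: TrajectorySet, outcome: str, month: float) -> np.ndarray:
    """(n_patients, n_reps) boolean: event occurred by the given month."""
    ev = trajset.event_matrix(outcome)
    days = ev * trajset.config.slice_duration
    return (ev >= 0) & (days <= month * DAYS_PER_MONTH + 1e-9)


def survival_curve(trajset: TrajectorySet, grid_months: Sequence[float]) -> pd.DataFrame:
    """Probability of death by each grid month: mean and replicate spread.

    For each month the fraction of in-silico patients dead by that time is
    computed within every replicate; the curve reports the across-replicate
    mean and standard deviation.
    """
    return _outcome_curve(trajset, "death", grid_months)


def impairment_curves(
    trajset: TrajectorySet, grid_months: Sequence[float]
) -> pd.DataFrame:
    """Per-MITOS-domain probability of impairment by each grid month."""
    frames = [_outcome_curve(trajset, d, grid_months) for d in MITOS_DOMAINS]
    return pd.concat(frames, ignore_index=True)


def _outcome_curve(trajset, outcome, grid_months) -> pd.DataFrame:
    if not trajset.patients:
        raise ValueError("empty trajectory set")
    rows = []
    for m in grid_months:
        frac = _event_by_month(trajset, outcome, m).mean(axis=0)  # per replicate
        rows.append((outcome, float(m), float(frac.mean()), float(frac.std(ddof=0))))
    return pd.DataFrame(rows, columns=["outcome", "month", "mean", "sd"])


def patient_density(
    model: DbnModel,
    initial_state: Mapping[str, float],
    config: SimulationConfig,
    variables: Sequence[str],
) -> dict[str, np.ndarray]:
    """Per-variable, per-slice empirical state distribution for one patient.

    Rows (slices) are normalized over the replicates still alive at that
    slice; rows with no surviving replicate are NaN.
    """
    compiled = CompiledModel(model)
    for v in variables:
        if v not in compiled.bases:
            raise ValueError(f"unknown dynamic variable {v!r}")
    traj = simulate_patient(
        model,
        initial_state,
        config,
        rng=np.random.default_rng(config.seed),
        keep_states=True,
        compiled=compiled,
    )
    out: dict[str, np.ndarray] = {}
    for v in variables:
        card = model.cpds.cards[cur_name(v)]
        st = traj.states[v]
        dens = np.full((config.n_slices + 1, card), np.nan)
        for t in range(config.n_slices + 1):
            col = st[:, t]
            obs = col[col != MISSING]
            if obs.size:
                dens[t] = np.bincount(obs, minlength=card) / obs.size
        out[v] = dens
    return out


# ---------------------------------------------------------------------------
# stratification


def stratify_compare(
    model: DbnModel,
    cohort: DiscreteCohort,
    arms: Mapping[str, Mapping[str, int]],
    config: SimulationConfig,
    grid_months: Sequence[float] | None = None,
) -> dict:
    """Simulate intervention arms over a cloned base population.

    Each arm overrides static (or baseline dynamic) variables in every
    patient's initial state; arms share random-number streams so the
    contrast between them is estimated with reduced Monte-Carlo variance.
    Returns per-arm survival/impairment curves and the difference in median
    in-silico survival time (in months) between the arms.
    """
    compiled = CompiledModel(model)
    static_set = set(compiled.static_names)
    dynamic_set = set(compiled.bases)
    for arm, override in arms.items():
        for var in override:
            if var in (DEATH_NODE, TSO_NODE):
                raise ValueError(f"cannot intervene on {var}")
            if var not in static_set | dynamic_set:
                raise ValueError(f"unknown intervention variable {var!r} in arm {arm}")
    grid = list(grid_months) if grid_months is not None else list(range(0, config.n_slices + 1, 3))

    base_states = initial_states_from_cohort(cohort)
    result: dict = {"arms": {}, "config": config}
    medians: dict[str, float] = {}
    for arm, override in arms.items():
        patients = {}
        for idx, pid in enumerate(sorted(base_states.keys(), key=str)):
            st = dict(base_states[pid])
            st.update({k: int(v) for k, v in override.items()})
            rng = np.random.default_rng([config.seed, idx])  # common random numbers
            patients[pid] = simulate_patient(
                model, st, config, rng=rng, keep_states=False, compiled=compiled
            )
        ts = TrajectorySet(patients=patients, config=config, model_hash=model.model_hash())
        surv = survival_curve(ts, grid)
        imp = impairment_curves(ts, grid)
        medians[arm] = _median_event_month(ts, "death")
        result["arms"][arm] = {"survival": surv, "impairment": imp, "median_death_month": medians[arm]}
    arm_names = list(arms.keys())
    if len(arm_names) == 2:
        a, b = arm_names
        result["median_difference_months"] = _diff(medians[a], medians[b])
    return result


def _median_event_month(trajset: TrajectorySet, outcome: str) -> float:
    ev = trajset.event_matrix(outcome).ravel().astype(float)
    months = np.where(ev >= 0, ev * trajset.config.slice_duration / DAYS_PER_MONTH, np.inf)
    med = float(np.median(months))
    return med


def _diff(a: float, b: float) -> float:
    if np.isinf(a) and np.isinf(b):
        return 0.0
    return float(a - b)
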