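"""Model assessment: simulation error, fixed-horizon AU-ROC, cross-validation.

Fidelity and discrimination are quantified per outcome (death plus the four
MITOS loss-of-autonomy domains) at fixed horizons, by default months 12, 24,
36 and 42:

* simulation error — the absolute difference, in percentage points, between
  the share of real patients with the event by the horizon and the share of
  simulated replicates with the event by the same horizon;
* AU-ROC — how well the per-patient simulated risk (fraction of replicates
  with the event by the horizon) ranks the patients who actually experience
  the event; computed with the Mann-Whitney convention (ties count 1/2);
* k-fold cross-validation — the model is refit on k-1 folds and evaluated on
  the held-out fold, aggregating AU-ROCs as mean ± sample SD over folds.

Patients censored before a horizon without the event have unknown status at
that horizon and are excluded from both the real percentage and the AU-ROC
labels (the standard fixed-horizon binary reduction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .cohort import DAY, MITOS_DOMAINS, PID, DiscreteCohort
from .dbn import LearnConfig, fit_dbn
from .simulation import (
    DAYS_PER_MONTH,
    OUTCOMES,
    SimulationConfig,
    TrajectorySet,
    simulate_cohort,
)

logger = logging.getLogger(__name__)

DEFAULT_TIMEPOINTS = (12.0, 24.0, 36.0, 42.0)


@dataclass
class OutcomeEvents:
    """Per-patient time-to-event records for the five outcomes.

    ``tables[outcome]`` is a DataFrame indexed by patient id with columns
    ``event`` (bool: the event was observed) and ``time`` (months: event time
    when observed, otherwise censoring time).
    """

    tables: dict[str, pd.DataFrame]

    @classmethod
    def from_cohort(cls, cohort: DiscreteCohort) -> "OutcomeEvents":
        vis = cohort.visits.sort_values([PID, DAY])
        last_day = vis.groupby(PID)[DAY].max()
        tables: dict[str, pd.DataFrame] = {}

        death = cohort.death_day
        t_death = np.where(death.notna(), death, last_day.reindex(death.index))
        tables["death"] = pd.DataFrame(
            {"event": death.notna().to_numpy(), "time": t_death / DAYS_PER_MONTH},
            index=death.index,
        )

        for dom in MITOS_DOMAINS:
            if dom not in vis.columns:
                continue
            hits = vis[vis[dom] == 1].groupby(PID)[DAY].min()
            first_hit = hits.reindex(cohort.patient_ids)
            event = first_hit.notna()
            # follow-up for impairment ends at the first loss or the last visit
            time = np.where(event, first_hit, last_day.reindex(cohort.patient_ids))
            tables[dom] = pd.DataFrame(
                {"event": event.to_numpy(), "time": time / DAYS_PER_MONTH},
                index=cohort.patient_ids,
            )
        return cls(tables=tables)

    def outcomes(self) -> list[str]:
        return list(self.tables.keys())

    def labels_at(self, outcome: str, horizon: float) -> pd.Series:
        """Event-by-horizon labels; NaN where status at the horizon is unknown."""
        tab = self.tables[outcome]
        lab = pd.Series(np.nan, index=tab.index)
        lab[tab["event"] & (tab["time"] <= horizon)] = 1.0
        lab[tab["time"] > horizon] = 0.0
        lab[(~tab["event"]) & np.isclose(tab["time"], horizon)] = 0.0
        return lab


# ---------------------------------------------------------------------------
# simulation error


def simulation_error(
    real: OutcomeEvents,
    trajset: TrajectorySet,
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
) -> pd.DataFrame:
    """|% real − % simulated| with the event by each horizon, per outcome.

    Percentages are computed among patients whose status at the horizon is
    known; horizons where no patient is observable yield NaN (undefined).
    """
    rows = {}
    sim_ids = trajset.patient_ids
    for outcome in real.outcomes():
        vals = []
        for m in timepoints:
            labels = real.labels_at(outcome, m).reindex(sim_ids)
            obs = labels.dropna()
            if len(obs) == 0:
                logger.warning("no observable patients for %s at month %s", outcome, m)
                vals.append(np.nan)
                continue
            pct_real = 100.0 * obs.mean()
            ev = trajset.event_matrix(outcome)
            by = _sim_event_by(trajset, outcome, m)
            keep = np.isin(np.asarray(sim_ids, dtype=object), obs.index.to_numpy())
            pct_sim = 100.0 * by[keep].mean()
            vals.append(abs(pct_real - pct_sim))
        rows[outcome] = vals
    return pd.DataFrame(rows, index=list(timepoints)).T


def _sim_event_by(trajset: TrajectorySet, outcome: str, month: float) -> np.ndarray:
    ev = trajset.event_matrix(outcome)
    days = ev * trajset.config.slice_duration
    return (ev >= 0) & (days <= month * DAYS_PER_MONTH + 1e-9)


# ---------------------------------------------------------------------------
# risk and AU-ROC


def risk_score(trajset: TrajectorySet, outcome: str, horizon: float) -> pd.Series:
    """Per-patient risk: fraction of replicates with the event by the horizon."""
    span_months = trajset.config.n_slices * trajset.config.slice_duration / DAYS_PER_MONTH
    if horizon > span_months + 1e-9:
        raise ValueError(f"horizon {horizon} months beyond simulated span {span_months}")
    by = _sim_event_by(trajset, outcome, horizon)
    return pd.Series(by.mean(axis=1), index=trajset.patient_ids)


def auroc(
    real: OutcomeEvents, risks: pd.Series, outcome: str, horizon: float
) -> float:
    """Probability a random event patient outranks a random non-event patient.

    Ties count one half (Mann-Whitney U normalization).  Returns NaN when
    either class is empty at the horizon.
    """
    labels = real.labels_at(outcome, horizon).reindex(risks.index).dropna()
    if labels.nunique() < 2:
        logger.warning("AU-ROC undefined for %s at month %s (one class empty)", outcome, horizon)
        return float("nan")
    return float(roc_auc_score(labels.astype(int), risks.reindex(labels.index)))


@dataclass
class AssessmentReport:
    """Tables of simulation error (pp) and AU-ROC per outcome × horizon."""

    simulation_error: pd.DataFrame
    auroc: pd.DataFrame
    cv: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "simulation_error_pct": self.simulation_error.to_dict(),
            "auroc": self.auroc.to_dict(),
        }
        if self.cv is not None:
            out["cross_validation"] = self.cv.to_dict(orient="records")
        return out


def assess(
    real: OutcomeEvents,
    trajset: TrajectorySet,
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
) -> AssessmentReport:
    """Simulation error and AU-ROC for every outcome at every horizon."""
    err = simulation_error(real, trajset, timepoints)
    auc_rows = {}
    for outcome in real.outcomes():
        vals = []
        for m in timepoints:
            risks = risk_score(trajset, outcome, m)
            vals.append(auroc(real, risks, outcome, m))
        auc_rows[outcome] = vals
    auc = pd.DataFrame(auc_rows, index=list(timepoints)).T
    return AssessmentReport(simulation_error=err, auroc=auc)


# ---------------------------------------------------------------------------
# cross-validation


def cross_validate(
    full_cohort: DiscreteCohort,
    k: int = 10,
    learn_config: LearnConfig | None = None,
    sim_config: SimulationConfig | None = None,
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    seed: int = 0,
    stratify_by_deaths: bool = True,
) -> pd.DataFrame:
    """Death-stratified k-fold CV of the full pipeline.

    Each fold refits the network on k−1 folds and simulates the held-out
    patients from their first visit; AU-ROCs are aggregated as mean ± sample
    (n−1) standard deviation over the folds in which they are defined.
    Set ``stratify_by_deaths=False`` for plain shuffled folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    learn_config = learn_config or LearnConfig()
    sim_config = sim_config or SimulationConfig()
    ids = np.asarray(full_cohort.patient_ids, dtype=object)
    died = full_cohort.death_indicator().reindex(ids).to_numpy()

    if stratify_by_deaths and 0 < died.sum() < len(died):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(ids, died)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(ids)

    records = []
    fold_members: dict[int, list] = {}
    for fold_idx, (tr, va) in enumerate(folds):
        train = full_cohort.subset(ids[tr])
        valid = full_cohort.subset(ids[va])
        fold_members[fold_idx] = list(ids[va])
        model = fit_dbn(train, learn_config)
        fold_sim = SimulationConfig(
            n_slices=sim_config.n_slices,
            n_reps=sim_config.n_reps,
            slice_duration=sim_config.slice_duration,
            seed=sim_config.seed + fold_idx,
        )
        trajset = simulate_cohort(model, valid, fold_sim)
        real = OutcomeEvents.from_cohort(valid)
        for outcome in real.outcomes():
            for m in timepoints:
                risks = risk_score(trajset, outcome, m)
                records.append(
                    {
                        "fold": fold_idx,
                        "outcome": outcome,
                        "month": float(m),
                        "auroc": auroc(real, risks, outcome, m),
                    }
                )
        logger.info("cross_validate: fold %d/%d done", fold_idx + 1, k)

    per_fold = pd.DataFrame(records)
    agg = (
        per_fold.groupby(["outcome", "month"])["auroc"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n_folds="count")
        .reset_index()
    )
    agg.attrs["per_fold"] = per_fold
    agg.attrs["fold_ids"] = fold_members
    return agg
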