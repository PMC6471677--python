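"""Cohort preprocessing: missingness filtering, quantization, MITOS staging.

The pipeline turns a raw longitudinal cohort into the discrete, layered,
monotone-MITOS dataset the network learner consumes:

1. drop variables missing for more than half of the subjects;
2. split patients into training and validation parts, stratified by deaths;
3. convert ALSFRS-R item scores to the four MITOS loss-of-autonomy domains
   and enforce their irreversibility over visits;
4. quantize continuous measurements — clinical cut points for labs/vitals,
   training-set tertiles for age at onset, onset delta and cumulative time
   since onset (TSO).

Tertile cuts are always estimated on the training part and frozen for the
validation part and for simulation, so no information leaks across the split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .cohort import ALSFRSR_ITEMS, DAY, MITOS_DOMAINS, PID, Cohort, DiscreteCohort
from .specs import (
    MISSING,
    Categorical,
    ClinicalThresholds,
    Quantization,
    Tertiles,
    VariableSpec,
)

logger = logging.getLogger(__name__)

#: Default MITOS conversion rule: a domain's independence is lost when any of
#: its defining ALSFRS-R items falls at or below the configured cut score.
#: Items: 1 speech, 3 swallowing, 4 handwriting, 6 dressing/hygiene,
#: 8 walking, 10 dyspnea, 12 respiratory insufficiency.  The table is data,
#: not code: pass a custom mapping to override any rule.
DEFAULT_MITOS_RULE: dict[str, tuple[tuple[str, int], ...]] = {
    "mitos_movement": (("item8", 1), ("item6", 1)),
    "mitos_swallowing": (("item3", 1),),
    "mitos_communication": (("item1", 1), ("item4", 1)),
    "mitos_breathing": (("item10", 1), ("item12", 2)),
}


# ---------------------------------------------------------------------------
# variable-level missingness filter


def filter_variables(cohort: Cohort, max_missing_frac: float = 0.5) -> Cohort:
    """Drop variables missing for more than ``max_missing_frac`` of subjects.

    A dynamic variable is missing for a subject when it is absent at every
    one of their visits; a static variable when its value is NaN.  The rule
    is strictly "more than": a variable missing for exactly the threshold
    fraction is retained.
    """
    if not 0 < max_missing_frac <= 1:
        raise ValueError(f"max_missing_frac must be in (0, 1], got {max_missing_frac}")
    if cohort.n_patients == 0:
        raise ValueError("empty cohort")

    n = cohort.n_patients
    keep_static, keep_dynamic, dropped = [], [], []
    for col in cohort.static_variables():
        frac = float(cohort.statics[col].isna().mean())
        (keep_static if frac <= max_missing_frac else dropped).append(col)
    observed = cohort.visits.groupby(PID)[cohort.dynamic_variables()].count() if cohort.dynamic_variables() else None
    for col in cohort.dynamic_variables():
        n_with = int((observed[col] > 0).sum())
        frac = 1.0 - n_with / n
        (keep_dynamic if frac <= max_missing_frac else dropped).append(col)

    if not keep_static and not keep_dynamic:
        raise ValueError(
            f"all variables exceed the missingness threshold {max_missing_frac:.2f}"
        )
    for col in dropped:
        logger.info("filter_variables: dropping %s (> %.0f%% subjects missing)", col, 100 * max_missing_frac)
    logger.info("filter_variables: retained %s", keep_static + keep_dynamic)
    return Cohort(
        statics=cohort.statics[keep_static].copy(),
        visits=cohort.visits[[PID, DAY] + keep_dynamic].copy(),
        death_day=cohort.death_day.copy(),
        alsfrsr=None if cohort.alsfrsr is None else cohort.alsfrsr.copy(),
    )


# ---------------------------------------------------------------------------
# MITOS conversion and monotone enforcement


def alsfrsr_to_mitos(
    items: Mapping[str, float] | Sequence[float],
    rule: Mapping[str, tuple[tuple[str, int], ...]] | None = None,
) -> tuple[int, int, int, int]:
    """Convert one visit's 12 ALSFRS-R item scores to MITOS domain flags.

    Returns loss-of-autonomy flags ``(movement, communication, swallowing,
    breathing)``; 1 means independence is lost in that domain, -1 that the
    flag cannot be determined because a defining item is missing.
    """
    rule = dict(DEFAULT_MITOS_RULE if rule is None else rule)
    if not isinstance(items, Mapping):
        if len(items) != 12:
            raise ValueError("expected 12 ALSFRS-R items")
        items = dict(zip(ALSFRSR_ITEMS, items))
    for name, v in items.items():
        if v is not None and np.isfinite(v) and not 0 <= v <= 4:
            raise ValueError(f"ALSFRS-R {name}={v} outside 0-4")
    flags = []
    for domain in MITOS_DOMAINS:
        lost, missing = 0, False
        for item, cut in rule[domain]:
            v = items.get(item)
            if v is None or not np.isfinite(v):
                missing = True
            elif v <= cut:
                lost = 1
        # a missing defining item can hide a loss, but an observed loss stands
        flags.append(MISSING if (missing and not lost) else lost)
    return tuple(flags)


def enforce_monotone(series: Sequence[int]) -> np.ndarray:
    """Make a per-visit binary impairment series irreversible.

    Takes the running maximum over observed values: once a domain is lost it
    stays lost.  A missing entry is filled with the current running maximum
    only when a later observed value equals that maximum (so the fill is
    forced); otherwise it stays missing — the onset time of an impairment is
    never moved earlier than observed.  Idempotent.
    """
    x = np.asarray(series, dtype=np.int64)
    out = x.copy()
    run = 0
    for i in range(len(x)):
        if x[i] == MISSING:
            if run == 1:
                out[i] = 1
            else:
                later = x[i + 1:]
                later_obs = later[later != MISSING]
                out[i] = 0 if later_obs.size and later_obs[0] == 0 else MISSING
        else:
            run = max(run, int(x[i]))
            out[i] = run
    return out


# ---------------------------------------------------------------------------
# TSO


def compute_raw_tso(cohort: Cohort) -> pd.Series:
    """Cumulative days since symptom onset per visit: onset_delta + day_offset."""
    if "onset_delta" not in cohort.statics.columns:
        raise ValueError("cohort statics lack onset_delta; cannot derive TSO")
    onset = cohort.statics["onset_delta"].reindex(cohort.visits[PID]).to_numpy(dtype=float)
    return pd.Series(onset + cohort.visits[DAY].to_numpy(dtype=float), index=cohort.visits.index)


def drop_patients_without_onset(cohort: Cohort) -> Cohort:
    """Exclude patients whose time of onset is unavailable (logged)."""
    if "onset_delta" not in cohort.statics.columns:
        raise ValueError("cohort statics lack onset_delta")
    bad = cohort.statics.index[cohort.statics["onset_delta"].isna()]
    for pid in bad:
        logger.info("excluding patient %s: onset time unavailable", pid)
    if len(bad) == cohort.n_patients:
        raise ValueError("no patient has a known onset time")
    return cohort.subset([p for p in cohort.patient_ids if p not in set(bad)])


# ---------------------------------------------------------------------------
# quantization


def _encode_numeric(spec: VariableSpec, values: np.ndarray) -> np.ndarray:
    vals = np.asarray(values, dtype=float)
    if np.isinf(vals).any():
        warnings.warn(f"{spec.name}: non-finite values treated as missing")
        vals = np.where(np.isinf(vals), np.nan, vals)
    return spec.quantization.encode(vals)


def fit_tertile_specs(cohort: Cohort, specs: Sequence[VariableSpec]) -> list[VariableSpec]:
    """Freeze tertile cut points from this (training) cohort's raw values."""
    fitted = []
    for s in specs:
        if isinstance(s.quantization, Tertiles) and s.quantization.cuts is None:
            if s.kind == "static":
                vals = cohort.statics[s.name].to_numpy(dtype=float)
            else:
                vals = cohort.visits[s.name].to_numpy(dtype=float)
            fitted.append(replace(s, quantization=s.quantization.fit(vals)))
        else:
            fitted.append(s)
    return fitted


def quantize(
    cohort: Cohort,
    specs: Sequence[VariableSpec],
    tso_cuts: tuple[float, float] | None = None,
    mitos_rule: Mapping | None = None,
) -> DiscreteCohort:
    """Quantize a raw cohort into categorical codes per its variable specs.

    ``specs`` must have concrete cut points for every tertile variable (use
    :func:`fit_tertile_specs` on the training part first); likewise
    ``tso_cuts`` are the training tertiles of raw TSO.  When ``tso_cuts`` is
    None the cuts are fitted here — only do that on training data.

    MITOS domains are derived from the ALSFRS-R table when present (or taken
    from ``mitos_*`` visit columns) and made monotone per patient.
    """
    cohort = drop_patients_without_onset(cohort)
    specs = fit_tertile_specs(cohort, specs)
    by_name = {s.name: s for s in specs}

    for name in cohort.static_variables() + cohort.dynamic_variables():
        if name not in by_name and not name.startswith("mitos_"):
            raise ValueError(f"no VariableSpec for retained variable {name!r}")

    statics = pd.DataFrame(index=cohort.statics.index)
    for col in cohort.static_variables():
        s = by_name[col]
        if isinstance(s.quantization, Categorical):
            statics[col] = s.quantization.encode(cohort.statics[col].tolist())
        else:
            statics[col] = _encode_numeric(s, cohort.statics[col].to_numpy())

    visits = cohort.visits[[PID, DAY]].copy()
    for col in cohort.dynamic_variables():
        if col.startswith("mitos_"):
            raw = cohort.visits[col].to_numpy(dtype=float)
            visits[col] = np.where(np.isfinite(raw), raw, MISSING).astype(np.int64)
            continue
        s = by_name[col]
        if isinstance(s.quantization, Categorical):
            visits[col] = s.quantization.encode(cohort.visits[col].tolist())
        else:
            visits[col] = _encode_numeric(s, cohort.visits[col].to_numpy())

    # MITOS from ALSFRS-R (aligned on patient & day); overrides absent columns
    if cohort.alsfrsr is not None:
        rule = dict(DEFAULT_MITOS_RULE if mitos_rule is None else mitos_rule)
        fr = cohort.alsfrsr.set_index([PID, DAY])
        key = pd.MultiIndex.from_frame(visits[[PID, DAY]])
        aligned = fr.reindex(key)
        items = {it: aligned[it].to_numpy(dtype=float) for it in ALSFRSR_ITEMS}
        for it, v in items.items():
            if np.nanmax(v, initial=0) > 4 or np.nanmin(v, initial=0) < 0:
                raise ValueError(f"ALSFRS-R {it} outside 0-4")
        for dom in MITOS_DOMAINS:
            lost = np.zeros(len(visits), dtype=bool)
            miss = np.zeros(len(visits), dtype=bool)
            for item, cut in rule[dom]:
                v = items[item]
                lost |= v <= cut
                miss |= ~np.isfinite(v)
            visits[dom] = np.where(lost, 1, np.where(miss, MISSING, 0)).astype(np.int64)

    for dom in MITOS_DOMAINS:
        if dom in visits.columns:
            visits[dom] = (
                visits.groupby(PID, sort=False)[dom]
                .transform(lambda s: enforce_monotone(s.to_numpy()))
                .astype(np.int64)
            )

    raw_tso = compute_raw_tso(cohort).to_numpy()
    tso_q = Tertiles(tso_cuts) if tso_cuts is not None else Tertiles().fit(raw_tso)
    visits["tso"] = tso_q.encode(raw_tso)
    visits["tso_raw"] = raw_tso  # kept so simulation can advance real time

    return DiscreteCohort(
        statics=statics,
        visits=visits,
        death_day=cohort.death_day.copy(),
        specs=list(specs),
        tso_cuts=tso_q.cuts,
    )


# ---------------------------------------------------------------------------
# train/validation split


def split_train_validation(cohort, validation_frac: float = 0.25, seed: int = 0):
    """Partition patients into train/validation parts, stratified by deaths.

    Works on either a raw or a discrete cohort (anything with ``patient_ids``,
    ``death_day`` and ``subset``).  Reproducible from ``seed``.
    """
    if not 0 < validation_frac < 1:
        raise ValueError(f"validation_frac must be in (0, 1), got {validation_frac}")
    ids = np.asarray(cohort.patient_ids)
    died = cohort.death_day.reindex(ids).notna().to_numpy().astype(int)
    stratify = died
    if died.sum() == 0 or died.sum() == len(died):
        warnings.warn("cohort has no death-status variation; plain random split")
        stratify = None
    train_ids, valid_ids = train_test_split(
        ids, test_size=validation_frac, random_state=seed, stratify=stratify
    )
    return cohort.subset(train_ids), cohort.subset(valid_ids)


def split_manifest(train, validation, seed: int) -> dict:
    return {
        "seed": seed,
        "train": {
            "patient_ids": [str(p) for p in train.patient_ids],
            "n": train.n_patients,
            "deaths": int(train.death_day.notna().sum()),
        },
        "validation": {
            "patient_ids": [str(p) for p in validation.patient_ids],
            "n": validation.n_patients,
            "deaths": int(validation.death_day.notna().sum()),
        },
    }


# ---------------------------------------------------------------------------
# end-to-end convenience


def preprocess(
    cohort: Cohort,
    specs: Sequence[VariableSpec],
    max_missing_frac: float = 0.5,
    validation_frac: float = 0.25,
    seed: int = 0,
    mitos_rule: Mapping | None = None,
) -> tuple[DiscreteCohort, DiscreteCohort]:
    """Filter, split, fit tertiles on train, and quantize both parts."""
    cohort = filter_variables(cohort, max_missing_frac)
    cohort = drop_patients_without_onset(cohort)
    train_raw, valid_raw = split_train_validation(cohort, validation_frac, seed)
    train = quantize(train_raw, specs, mitos_rule=mitos_rule)
    valid = quantize(valid_raw, train.specs, tso_cuts=train.tso_cuts, mitos_rule=mitos_rule)
    return train, valid
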