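"""In-memory containers for longitudinal clinical cohorts.

A :class:`Cohort` holds raw (possibly continuous) measurements: one row of
static covariates per patient, an ordered visit table with day offsets, an
optional table of ALSFRS-R item scores per visit, and a death/censoring day
per patient.  A :class:`DiscreteCohort` is the quantized counterpart the
network learner consumes: every measurement is a categorical code, the four
MITOS loss-of-autonomy domains are attached per visit, and the cumulative
time since onset (TSO) is derived and quantized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .specs import MISSING, VariableSpec

PID = "patient_id"
DAY = "day_offset"

MITOS_DOMAINS = ("mitos_movement", "mitos_communication", "mitos_swallowing", "mitos_breathing")
ALSFRSR_ITEMS = tuple(f"item{i}" for i in range(1, 13))


@dataclass
class Cohort:
    """Raw longitudinal cohort.

    Attributes
    ----------
    statics
        One row per patient, indexed by patient id; columns are static
        variables (``onset_delta`` in days is required for TSO derivation).
    visits
        One row per visit: ``patient_id``, ``day_offset`` plus one column
        per dynamic variable.  Within a patient, day offsets are strictly
        increasing.
    death_day
        Per-patient day of death, NaN when the patient is censored (at the
        last visit).
    alsfrsr
        Optional per-visit ALSFRS-R item table (``patient_id``,
        ``day_offset``, ``item1`` .. ``item12``).
    """

    statics: pd.DataFrame
    visits: pd.DataFrame
    death_day: pd.Series
    alsfrsr: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.statics) == 0:
            raise ValueError("empty cohort: no patients")
        self.statics = self.statics.sort_index()
        self.visits = self.visits.sort_values([PID, DAY]).reset_index(drop=True)
        if (self.visits[DAY] < 0).any():
            raise ValueError("negative day_offset in visits")
        dup = self.visits.duplicated([PID, DAY])
        if dup.any():
            raise ValueError("duplicate (patient, day) visit rows")
        self.death_day = self.death_day.reindex(self.statics.index)
        if self.alsfrsr is not None:
            self.alsfrsr = self.alsfrsr.sort_values([PID, DAY]).reset_index(drop=True)

    @property
    def patient_ids(self) -> list:
        return list(self.statics.index)

    @property
    def n_patients(self) -> int:
        return len(self.statics)

    def dynamic_variables(self) -> list[str]:
        return [c for c in self.visits.columns if c not in (PID, DAY)]

    def static_variables(self) -> list[str]:
        return list(self.statics.columns)

    def subset(self, patient_ids: Sequence) -> "Cohort":
        ids = set(patient_ids)
        return Cohort(
            statics=self.statics.loc[self.statics.index.isin(ids)].copy(),
            visits=self.visits[self.visits[PID].isin(ids)].copy(),
            death_day=self.death_day[self.death_day.index.isin(ids)].copy(),
            alsfrsr=None
            if self.alsfrsr is None
            else self.alsfrsr[self.alsfrsr[PID].isin(ids)].copy(),
        )


@dataclass
class DiscreteCohort:
    """Quantized cohort ready for network learning and simulation.

    ``statics`` and ``visits`` mirror :class:`Cohort` but hold integer codes
    (missing = -1).  ``visits`` additionally carries the four MITOS domain
    flags (monotone within patient) and the quantized ``tso`` column.
    ``specs`` records the schema (with fitted tertile cuts) used to produce
    the codes, so that the same cuts can be reused on validation data and
    during simulation.
    """

    statics: pd.DataFrame
    visits: pd.DataFrame
    death_day: pd.Series
    specs: list[VariableSpec]
    tso_cuts: tuple[float, float]

    def __post_init__(self) -> None:
        self.statics = self.statics.sort_index()
        self.visits = self.visits.sort_values([PID, DAY]).reset_index(drop=True)
        self.death_day = self.death_day.reindex(self.statics.index)
        by_name = {s.name: s for s in self.specs}
        for col in self.code_columns():
            if col == "tso_raw":
                continue
            card = 2 if col in MITOS_DOMAINS else (3 if col == "tso" else None)
            if card is None:
                card = by_name[col].cardinality if col in by_name else None
            if card is not None:
                vals = self.visits[col] if col in self.visits.columns else self.statics[col]
                bad = (np.asarray(vals) >= card) & (np.asarray(vals) != MISSING)
                if bad.any():
                    raise ValueError(f"codes out of range for {col}")

    def code_columns(self) -> list[str]:
        cols = [c for c in self.statics.columns]
        cols += [c for c in self.visits.columns if c not in (PID, DAY)]
        return cols

    @property
    def patient_ids(self) -> list:
        return list(self.statics.index)

    @property
    def n_patients(self) -> int:
        return len(self.statics)

    def dynamic_variables(self) -> list[str]:
        """Dynamic code columns in visit order (MITOS included, tso excluded)."""
        return [c for c in self.visits.columns if c not in (PID, DAY, "tso", "tso_raw")]

    def spec_by_name(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def death_indicator(self) -> pd.Series:
        """1 where a death day is recorded, else 0 (censored)."""
        return self.death_day.notna().astype(int)

    def subset(self, patient_ids: Sequence) -> "DiscreteCohort":
        ids = set(patient_ids)
        return DiscreteCohort(
            statics=self.statics.loc[self.statics.index.isin(ids)].copy(),
            visits=self.visits[self.visits[PID].isin(ids)].copy(),
            death_day=self.death_day[self.death_day.index.isin(ids)].copy(),
            specs=list(self.specs),
            tso_cuts=self.tso_cuts,
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format export: patient_id, slice_index, variable, code."""
        rows = []
        for pid, grp in self.visits.groupby(PID, sort=True):
            grp = grp.sort_values(DAY)
            for slice_index, (_, row) in enumerate(grp.iterrows()):
                for col in grp.columns:
                    if col in (PID, DAY, "tso_raw"):
                        continue
                    rows.append((pid, slice_index, col, int(row[col])))
        stat = [
            (pid, -1, col, int(self.statics.loc[pid, col]))
            for pid in self.patient_ids
            for col in self.statics.columns
        ]
        return pd.DataFrame(stat + rows, columns=[PID, "slice_index", "variable", "code"])
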