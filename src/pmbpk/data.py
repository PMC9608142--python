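"""Event-record data model and I/O for longitudinal dosing/concentration data.

The canonical in-memory form is an :class:`EventTable`: one
:class:`SubjectRecord` per subject, each holding zero-order infusion
:class:`DoseEvent` s, plasma-concentration :class:`Observation` s and a
per-subject covariate map.  On disk the same information lives in a single
NONMEM-flavoured CSV (``ID, TIME, AMT, DUR`` or ``RATE``, ``DV, EVID, MDV``
plus covariate columns); :func:`read_event_table` and
:func:`write_event_table` convert between the two.

Internal units are fixed: mg for amounts, hours for time, mg/L for
concentrations.  Serum creatinine is accepted in µmol/L and converted to
mg/dl (factor 88.4) inside :func:`cockcroft_gault`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseEvent",
    "Observation",
    "SubjectRecord",
    "EventTable",
    "EventTableError",
    "read_event_table",
    "write_event_table",
    "cockcroft_gault",
    "LOQ_MG_PER_L",
]

#: Lower limit of quantification of the plasma assay (mg/L).
LOQ_MG_PER_L = 0.1

#: µmol/L of creatinine per mg/dl.
_SCR_UMOL_PER_MGDL = 88.4


class EventTableError(ValueError):
    """Raised when an event table violates a structural invariant."""


@dataclass(frozen=True)
class DoseEvent:
    """A zero-order intravenous infusion.

    ``time`` is hours since the subject's first dose; ``amount`` is mg;
    ``infusion_duration`` is hours (> 0).  The infusion rate is
    ``amount / infusion_duration``.
    """

    time: float
    amount: float
    infusion_duration: float = 1.0

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise EventTableError(f"dose amount must be > 0, got {self.amount}")
        if not self.infusion_duration > 0:
            raise EventTableError(
                f"infusion duration must be > 0, got {self.infusion_duration}"
            )
        if self.time < 0:
            raise EventTableError(f"dose time must be >= 0, got {self.time}")

    @property
    def rate(self) -> float:
        """Infusion rate in mg/h."""
        return self.amount / self.infusion_duration


@dataclass(frozen=True)
class Observation:
    """A measured plasma concentration (the DV), in mg/L.

    Concentrations below the assay LOQ (0.1 mg/L) must carry
    ``below_loq=True``; flagged observations are kept but excluded from
    likelihood computations.
    """

    time: float
    concentration: float
    below_loq: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise EventTableError(f"observation time must be >= 0, got {self.time}")
        if not self.below_loq:
            if not self.concentration > 0:
                raise EventTableError(
                    f"concentration must be > 0 unless flagged below LOQ, "
                    f"got {self.concentration}"
                )
            if self.concentration < LOQ_MG_PER_L:
                raise EventTableError(
                    f"concentration {self.concentration} mg/L is below the "
                    f"LOQ ({LOQ_MG_PER_L} mg/L) but is not flagged below_loq"
                )


@dataclass(frozen=True)
class SubjectRecord:
    """All dose and observation events for one subject, plus covariates."""

    id: str
    doses: tuple[DoseEvent, ...]
    observations: tuple[Observation, ...]
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(self.doses))
        object.__setattr__(self, "observations", tuple(self.observations))
        object.__setattr__(self, "covariates", dict(self.covariates))
        if len(self.doses) == 0:
            raise EventTableError(f"subject {self.id}: at least one dose required")
        if len(self.observations) == 0:
            raise EventTableError(
                f"subject {self.id}: at least one observation required"
            )
        dose_times = [d.time for d in self.doses]
        if any(b < a for a, b in zip(dose_times, dose_times[1:])):
            raise EventTableError(
                f"subject {self.id}: dose times must be non-decreasing"
            )
        first = dose_times[0]
        for obs in self.observations:
            if obs.time < first:
                raise EventTableError(
                    f"subject {self.id}: observation at t={obs.time} precedes "
                    f"the first dose at t={first}"
                )

    @property
    def n_quantified(self) -> int:
        """Number of observations above the LOQ (usable for fitting)."""
        return sum(not o.below_loq for o in self.observations)


@dataclass(frozen=True)
class EventTable:
    """A study dataset: the collection of subject records."""

    subjects: tuple[SubjectRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise EventTableError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        names: set[str] = set()
        for s in self.subjects:
            names.update(s.covariates)
        return tuple(sorted(names))

    def covariate_frame(self) -> pd.DataFrame:
        """One row per subject, one column per covariate (indexed by id)."""
        rows = {s.id: dict(s.covariates) for s in self.subjects}
        return pd.DataFrame.from_dict(rows, orient="index").loc[
            [s.id for s in self.subjects]
        ]

    def require_covariates(self, names: Sequence[str]) -> None:
        for s in self.subjects:
            missing = [n for n in names if n not in s.covariates]
            if missing:
                raise EventTableError(
                    f"subject {s.id} is missing covariate(s) {missing}"
                )

    def subset(self, indices: Sequence[int], relabel: bool = True) -> "EventTable":
        """A new table from subject positions (bootstrap resampling helper).

        With ``relabel`` (default) each selected record gets a fresh unique
        id so a subject drawn twice yields two independent records.
        """
        subs = []
        for k, i in enumerate(indices):
            s = self.subjects[i]
            new_id = f"{s.id}#{k}" if relabel else s.id
            subs.append(
                SubjectRecord(new_id, s.doses, s.observations, s.covariates)
            )
        return EventTable(tuple(subs))


_MANDATORY = ("id", "time", "amt", "dv", "evid")
_DEFAULT_COLUMNS = {
    "id": "ID",
    "time": "TIME",
    "amt": "AMT",
    "dur": "DUR",
    "rate": "RATE",
    "dv": "DV",
    "evid": "EVID",
    "mdv": "MDV",
    "blq": "BLQ",
}


def read_event_table(
    path, column_map: Mapping[str, str] | None = None
) -> EventTable:
    """Read a NONMEM-flavoured event-record CSV into an :class:`EventTable`.

    One row per event.  ``EVID`` 1 marks a dose (``AMT`` mg infused over
    ``DUR`` hours, or at ``RATE`` mg/h); ``EVID`` 0 marks an observation
    (``DV`` mg/L).  Any column not named in the mapping is treated as a
    covariate, which must be constant within a subject.  Times are
    normalised to hours since each subject's first dose.

    Parameters
    ----------
    path : str or file-like
        CSV source.
    column_map : mapping, optional
        Overrides for the logical-to-physical column names; logical keys are
        ``id, time, amt, dur, rate, dv, evid, mdv, blq``.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path)

    for key in _MANDATORY:
        if cols[key] not in df.columns:
            raise EventTableError(f"missing mandatory column {cols[key]!r}")
    has_dur = cols["dur"] in df.columns
    has_rate = cols["rate"] in df.columns
    if not (has_dur or has_rate):
        raise EventTableError(
            f"need an infusion column: {cols['dur']!r} or {cols['rate']!r}"
        )
    known = {cols[k] for k in cols}
    cov_cols = [c for c in df.columns if c not in known]

    key_cols = [cols["id"], cols["time"], cols["evid"]]
    if df.duplicated(subset=key_cols).any():
        dupes = df[df.duplicated(subset=key_cols, keep=False)][key_cols]
        raise EventTableError(
            f"duplicate (id, time, event-type) rows:\n{dupes.to_string(index=False)}"
        )

    subjects = []
    for sid, grp in df.groupby(cols["id"], sort=False):
        grp = grp.sort_values(cols["time"], kind="stable")
        dose_rows = grp[grp[cols["evid"]] == 1]
        obs_rows = grp[grp[cols["evid"]] == 0]
        if dose_rows.empty:
            raise EventTableError(f"subject {sid}: no dose records")
        t0 = float(dose_rows[cols["time"]].iloc[0])

        doses = []
        for _, row in dose_rows.iterrows():
            amt = float(row[cols["amt"]])
            if has_dur and not pd.isna(row.get(cols["dur"], np.nan)):
                dur = float(row[cols["dur"]])
            elif has_rate and not pd.isna(row.get(cols["rate"], np.nan)):
                rate = float(row[cols["rate"]])
                if rate <= 0:
                    raise EventTableError(f"subject {sid}: non-positive RATE")
                dur = amt / rate
            else:
                raise EventTableError(
                    f"subject {sid}: dose at t={row[cols['time']]} has neither "
                    f"duration nor rate"
                )
            doses.append(DoseEvent(float(row[cols["time"]]) - t0, amt, dur))

        observations = []
        for _, row in obs_rows.iterrows():
            if cols["mdv"] in df.columns and int(row[cols["mdv"]]) == 1:
                continue
            blq = bool(int(row[cols["blq"]])) if cols["blq"] in df.columns else False
            if float(row[cols["time"]]) < t0:
                raise EventTableError(
                    f"subject {sid}: observation at t={row[cols['time']]} "
                    f"precedes the first dose at t={t0}"
                )
            observations.append(
                Observation(
                    float(row[cols["time"]]) - t0,
                    float(row[cols["dv"]]),
                    below_loq=blq,
                )
            )

        covs: dict[str, float] = {}
        for c in cov_cols:
            vals = grp[c].dropna().unique()
            if len(vals) > 1:
                raise EventTableError(
                    f"subject {sid}: covariate {c!r} is not constant"
                )
            if len(vals) == 1:
                covs[c.lower()] = float(vals[0])
        subjects.append(SubjectRecord(str(sid), tuple(doses), tuple(observations), covs))
    return EventTable(tuple(subjects))


def write_event_table(table: EventTable, path) -> None:
    """Write an :class:`EventTable` as a NONMEM-flavoured CSV.

    Inverse of :func:`read_event_table` under the default column map.
    """
    rows = []
    for s in table.subjects:
        covs = {k.upper(): v for k, v in s.covariates.items()}
        for d in s.doses:
            rows.append(
                {
                    "ID": s.id,
                    "TIME": d.time,
                    "AMT": d.amount,
                    "DUR": d.infusion_duration,
                    "DV": np.nan,
                    "EVID": 1,
                    "MDV": 1,
                    "BLQ": 0,
                    **covs,
                }
            )
        for o in s.observations:
            rows.append(
                {
                    "ID": s.id,
                    "TIME": o.time,
                    "AMT": np.nan,
                    "DUR": np.nan,
                    "DV": o.concentration,
                    "EVID": 0,
                    "MDV": 0,
                    "BLQ": int(o.below_loq),
                    **covs,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def cockcroft_gault(
    age_years: float, weight_kg: float, scr_umol_per_l: float, sex: str
) -> float:
    """Estimated creatinine clearance (ml/min) by Cockcroft–Gault.

    ``CrCL = (140 - age) * weight / (72 * Scr[mg/dl])``, multiplied by 0.85
    for females.  Serum creatinine is given in µmol/L and converted with
    1 mg/dl = 88.4 µmol/L.

    ``sex`` accepts ``"M"/"F"`` or ``"male"/"female"`` (case-insensitive).
    """
    if age_years <= 0 or weight_kg <= 0 or scr_umol_per_l <= 0:
        raise ValueError("age, weight and serum creatinine must be positive")
    if age_years >= 140:
        raise ValueError("age >= 140 years gives a non-positive clearance")
    s = str(sex).strip().lower()
    if s in ("m", "male", "0"):
        factor = 1.0
    elif s in ("f", "female", "1"):
        factor = 0.85
    else:
        raise ValueError(f"unrecognised sex {sex!r}")
    scr_mgdl = scr_umol_per_l / _SCR_UMOL_PER_MGDL
    return (140.0 - age_years) * weight_kg / (72.0 * scr_mgdl) * factor
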