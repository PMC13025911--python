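"""Cohort selection, planned-readmission merging, and outcome labeling.

The analysis cohort keeps adult stays (age >= 18) lasting at least 24 h
whose patient survived the ICU and was discharged to a general ward.
Planned surgical returns to the ICU are not deterioration events: they are
merged with the parent stay into one continuous interval before labeling.
The endpoint is deterioration — an unplanned ICU readmission or death —
within 7 days (closed right endpoint) of the ICU-to-ward transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .synthetic import GENERAL_WARD, Readmission, StayRecord

__all__ = ["CohortAudit", "select_cohort", "merge_planned_readmissions",
           "label_outcome", "prepare_cohort"]

# exclusion reasons, applied in this order (first matching reason counts)
REASONS = ("missing_metadata", "age_lt_18", "los_lt_24h", "icu_death",
           "not_ward_discharge")


@dataclass
class CohortAudit:
    """Counts of removed stays by reason; partitions the removals."""

    counts: dict[str, int] = field(default_factory=lambda: {r: 0 for r in REASONS})
    errors: list[str] = field(default_factory=list)

    @property
    def total_removed(self) -> int:
        return sum(self.counts.values())


def select_cohort(stays: list[StayRecord]) -> tuple[list[StayRecord], CohortAudit]:
    """Apply the cohort filters; removals are audited, never silently dropped.

    A stay is kept iff age >= 18 at ICU admission, ICU length of stay
    >= 24 h, no death during the stay, and discharge destination is a
    general ward.
    """
    kept: list[StayRecord] = []
    audit = CohortAudit()
    for s in stays:
        if s.icu_in is None or s.icu_out is None or s.icu_out <= s.icu_in:
            audit.counts["missing_metadata"] += 1
            audit.errors.append(f"{s.stay_id}: invalid or missing icu_in/icu_out")
        elif s.age < 18:
            audit.counts["age_lt_18"] += 1
        elif s.los_days < 1.0:
            audit.counts["los_lt_24h"] += 1
        elif s.death_time is not None and s.death_time <= s.icu_out:
            audit.counts["icu_death"] += 1
        elif s.discharge_destination != GENERAL_WARD:
            audit.counts["not_ward_discharge"] += 1
        else:
            kept.append(s)
    return kept, audit


def merge_planned_readmissions(stays: list[StayRecord]) -> list[StayRecord]:
    """Concatenate each planned return interval with its parent stay.

    The merged stay keeps its id, spans the union time range (length of
    stay recomputed), and absorbs the return interval's events.  Unplanned
    readmissions are untouched — they are outcome events for labeling.
    Records are not mutated; merged copies are returned.
    """
    out: list[StayRecord] = []
    for s in stays:
        planned = [r for r in s.readmissions if r.planned]
        if not planned:
            out.append(s)
            continue
        merged_out = s.icu_out
        merged_events = list(s.events)
        remaining: list[Readmission] = [r for r in s.readmissions if not r.planned]
        for r in sorted(planned, key=lambda r: r.time_in):
            if r.time_out is None:
                raise ValueError(f"{s.stay_id}: planned readmission lacks an interval end")
            if r.time_in < merged_out:
                raise ValueError(f"{s.stay_id}: planned readmission interval overlaps the stay")
            merged_events.extend(r.events)
            merged_out = r.time_out
        merged_events.sort(key=lambda e: e[1])
        out.append(StayRecord(
            stay_id=s.stay_id, age=s.age, sex=s.sex,
            admission_source=s.admission_source,
            icu_in=s.icu_in, icu_out=merged_out, events=merged_events,
            discharge_destination=s.discharge_destination,
            death_time=s.death_time, readmissions=remaining,
            latent_severity=s.latent_severity, sim_category=s.sim_category))
    return out


def label_outcome(stay: StayRecord, window_days: float = 7.0) -> int:
    """1 iff an unplanned ICU readmission or death occurs in
    ``(icu_out, icu_out + window_days]`` (closed right endpoint)."""
    out = stay.icu_out
    if stay.death_time is not None:
        if stay.death_time <= out:
            raise ValueError(f"{stay.stay_id}: death during the ICU stay should have "
                             "been excluded before labeling")
        if stay.death_time <= out + window_days:
            return 1
    for r in stay.readmissions:
        if not r.planned and out < r.time_in <= out + window_days:
            return 1
    return 0


def prepare_cohort(stays: list[StayRecord], window_days: float = 7.0,
                   ) -> tuple[list[StayRecord], list[int], CohortAudit]:
    """Full cohort pipeline: merge planned returns, apply the filters,
    label the endpoint.  Returns (kept stays, labels, audit)."""
    merged = merge_planned_readmissions(stays)
    kept, audit = select_cohort(merged)
    labels = [label_outcome(s, window_days) for s in kept]
    return kept, labels, audit
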