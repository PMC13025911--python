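"""SWIFT — the Stability and Workload Index for Transfer.

A five-component integer score for post-ICU-discharge deterioration risk:
original admission source, total ICU length of stay, last GCS before
discharge, most recent PaO2/FiO2 ratio, and most recent PaCO2.  The point
table ships as versioned configuration transcribed from the original 2008
derivation (range 0-64); tests that need exact scores pin the packaged
version, and ``--table`` lets a deployment override it.

Missing-data conventions: each component forward-fills the most recent
observation at or before discharge (flagged ``carried-forward`` when not
from the final day); when no arterial blood gas exists the SpO2/FiO2 ratio
substitutes for oxygenation (flagged ``proxy``, with its own bin set in the
packaged table); FiO2 defaults to room air (0.21) when no value is
recorded; components with no value at all score the lowest-risk bin so no
stay is excluded, and the breakdown records the degradation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .synthetic import StayRecord

__all__ = ["SwiftInputs", "SwiftTable", "DEFAULT_TABLE", "ROOM_AIR_FIO2",
           "extract_swift_inputs", "compute_swift", "score_cohort",
           "swift_auroc"]

ROOM_AIR_FIO2 = 0.21

MEASURED, CARRIED, PROXY, UNAVAILABLE = ("measured", "carried-forward",
                                         "proxy", "unavailable")


@dataclass
class SwiftInputs:
    """The five components at discharge, with per-component provenance."""

    admission_source: str
    icu_los: float                  # cumulative days at prediction time
    last_gcs: float | None
    pao2_fio2: float | None
    spo2_fio2: float | None
    paco2: float | None
    provenance: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class BinSet:
    """Ordered (upper_edge, points) pairs over a component's domain.

    A value v scores the points of the first bin with v < upper_edge
    (None = +inf).  Bins must be listed in increasing-edge order.
    """
    edges: tuple[tuple[float | None, int], ...]

    def points(self, value: float) -> int:
        for edge, pts in self.edges:
            if edge is None or value < edge:
                return pts
        raise ValueError(f"value {value} outside the table domain")

    def min_points(self) -> int:
        return min(p for _, p in self.edges)

    def max_points(self) -> int:
        return max(p for _, p in self.edges)


@dataclass(frozen=True)
class SwiftTable:
    """Cut-points and integer point values for the five components."""

    version: str
    admission_source: dict[str, int]
    los: BinSet
    gcs: BinSet
    pf_ratio: BinSet
    sf_ratio: BinSet       # proxy-specific oxygenation bins
    paco2: BinSet

    def score_range(self) -> tuple[int, int]:
        lo = (min(self.admission_source.values()) + self.los.min_points()
              + self.gcs.min_points() + self.pf_ratio.min_points()
              + self.paco2.min_points())
        hi = (max(self.admission_source.values()) + self.los.max_points()
              + self.gcs.max_points()
              + max(self.pf_ratio.max_points(), self.sf_ratio.max_points())
              + self.paco2.max_points())
        return lo, hi


# Packaged default, transcribed from the original derivation (version tag
# pins it for exact-score tests).  Higher clinical risk never maps to fewer
# points within a component.  The SpO2/FiO2 bins translate the PaO2/FiO2
# cut-points through the standard linear pulse-oximetry correspondence
# (S/F ~ 64 + 0.84 * P/F).
DEFAULT_TABLE = SwiftTable(
    version="gajic-2008",
    admission_source={"emergency": 0, "operating-room": 0,
                      "ward": 8, "other-hospital": 8},
    los=BinSet(((2, 0), (10, 1), (None, 14))),           # days
    gcs=BinSet(((8, 24), (11, 14), (15, 6), (None, 0))),  # last GCS, 3-15
    pf_ratio=BinSet(((100, 13), (150, 10), (400, 5), (None, 0))),
    sf_ratio=BinSet(((148, 13), (190, 10), (400, 5), (None, 0))),
    paco2=BinSet(((45, 0), (None, 5))),                   # mmHg
)


def _last_value(events: Sequence[tuple[str, float, float]], channel: str,
                before: float) -> tuple[float, float] | None:
    best = None
    for ch, t, v in events:
        if ch == channel and t <= before and (best is None or t > best[1]):
            best = (v, t)
    return best


def extract_swift_inputs(stay: StayRecord,
                         events: Sequence[tuple[str, float, float]] | None = None,
                         ) -> SwiftInputs:
    """Pull the five components from a stay's event stream at discharge.

    Oxygenation prefers PaO2/FiO2 whenever any arterial gas exists, else
    falls back to SpO2/FiO2 with a ``proxy`` flag; FiO2 defaults to room
    air when never recorded.
    """
    events = stay.events if events is None else events
    out = stay.icu_out
    final_day_start = out - 1.0
    prov: dict[str, str] = {}

    def flagged(channel: str) -> float | None:
        got = _last_value(events, channel, out)
        if got is None:
            prov[channel] = UNAVAILABLE
            return None
        v, t = got
        prov[channel] = MEASURED if t >= final_day_start else CARRIED
        return v

    gcs = flagged("gcs")
    pao2 = _last_value(events, "pao2", out)
    paco2 = flagged("paco2")
    fio2 = _last_value(events, "fio2", out)
    spo2 = _last_value(events, "spo2", out)

    fio2_v = fio2[0] if fio2 is not None else ROOM_AIR_FIO2
    pf = sf = None
    if pao2 is not None:
        pf = pao2[0] / fio2_v
        prov["oxygenation"] = (MEASURED if pao2[1] >= final_day_start else CARRIED)
    elif spo2 is not None:
        sf = spo2[0] / fio2_v
        prov["oxygenation"] = PROXY
    else:
        prov["oxygenation"] = UNAVAILABLE
    if fio2 is None and (pf is not None or sf is not None):
        prov["fio2"] = "room-air-default"

    prov["admission_source"] = MEASURED
    prov["icu_los"] = MEASURED
    return SwiftInputs(admission_source=stay.admission_source,
                       icu_los=stay.los_days, last_gcs=gcs,
                       pao2_fio2=pf, spo2_fio2=sf, paco2=paco2,
                       provenance=prov)


def compute_swift(inputs: SwiftInputs,
                  table: SwiftTable = DEFAULT_TABLE) -> tuple[int, dict[str, int]]:
    """Score = sum of the five component points; unavailable components
    score their lowest-risk bin (recorded in the breakdown keys)."""
    breakdown: dict[str, int] = {}
    try:
        breakdown["admission_source"] = table.admission_source[inputs.admission_source]
    except KeyError:
        raise ValueError(f"admission_source {inputs.admission_source!r} "
                         "outside the table domain") from None
    breakdown["icu_los"] = table.los.points(inputs.icu_los)
    if inputs.last_gcs is None:
        breakdown["gcs (unavailable)"] = table.gcs.min_points()
    else:
        if not 3 <= inputs.last_gcs <= 15:
            raise ValueError(f"gcs {inputs.last_gcs} outside the table domain")
        breakdown["gcs"] = table.gcs.points(inputs.last_gcs)
    if inputs.pao2_fio2 is not None:
        breakdown["oxygenation"] = table.pf_ratio.points(inputs.pao2_fio2)
    elif inputs.spo2_fio2 is not None:
        breakdown["oxygenation (proxy)"] = table.sf_ratio.points(inputs.spo2_fio2)
    else:
        breakdown["oxygenation (unavailable)"] = table.pf_ratio.min_points()
    if inputs.paco2 is None:
        breakdown["paco2 (unavailable)"] = table.paco2.min_points()
    else:
        breakdown["paco2"] = table.paco2.points(inputs.paco2)
    return sum(breakdown.values()), breakdown


def score_cohort(stays: Sequence[StayRecord],
                 table: SwiftTable = DEFAULT_TABLE) -> np.ndarray:
    """Integer SWIFT score per stay."""
    return np.array([compute_swift(extract_swift_inputs(s), table)[0]
                     for s in stays], dtype=float)


def swift_auroc(stays: Sequence[StayRecord], labels: Sequence[int],
                table: SwiftTable = DEFAULT_TABLE) -> dict:
    """AUROC/AUPR of the raw integer scores against the labels."""
    from .evaluation import auroc, aupr
    scores = score_cohort(stays, table)
    y = np.asarray(labels)
    return {"model": "swift", "auroc": auroc(scores, y), "aupr": aupr(scores, y),
            "scores": scores}
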