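"""Thermoregulation parameters and the accuracy-of-thermoregulation index.

``summarize`` computes, per annotated trace: mean skin temperature over
the whole test, means of upper and lower set-points, the thermal
passivity range (TPR = mean upper − mean lower), the global maximum,
the percentage of test time spent thermoregulating, the shuttle count,
and the accuracy index db — the mean deviation of all samples from a
reference set-point range (zero inside the range, distance to the
nearest bound outside).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trace_model import AnnotatedTrace, ThermoregulationSummary

__all__ = [
    "ReferenceRange",
    "compute_db",
    "summarize",
    "derive_reference_range",
]


@dataclass(frozen=True)
class ReferenceRange:
    """A reference set-point range (°C), ``lower <= upper``."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.upper < self.lower:
            raise ValueError("upper must be >= lower")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


def compute_db(temps, ref: ReferenceRange, *, from_midpoint: bool = False) -> float:
    """Mean deviation of temperatures from the reference range (°C).

    Samples inside ``[ref.lower, ref.upper]`` contribute zero; samples
    outside contribute their distance to the nearest bound.  With
    ``from_midpoint=True`` the (non-default) scalar reading is used
    instead: mean absolute deviation from the range midpoint.
    """
    temps = np.asarray(temps, dtype=float)
    if temps.size == 0:
        raise ValueError("compute_db requires at least one sample")
    if from_midpoint:
        return float(np.mean(np.abs(temps - ref.midpoint)))
    dev = np.maximum(ref.lower - temps, 0.0) + np.maximum(temps - ref.upper, 0.0)
    return float(dev.mean())


def summarize(
    at: AnnotatedTrace,
    ref: ReferenceRange,
    plausibility_ceiling: float = 41.0,
    *,
    db_from_midpoint: bool = False,
) -> ThermoregulationSummary:
    """Compute the seven parameters plus db for one annotated trace.

    ``mean_tsk`` and ``t_max`` cover every sample (thermoregulating or
    not); set-point means are over confirmed events of each kind and are
    absent (``None``) when no such event exists.  A trace whose maximum
    reaches ``plausibility_ceiling`` is flagged (battery-drift style
    artefact), never dropped — exclusion is the caller's decision.
    """
    temps = at.trace.temp
    uppers = [ev.temp for ev in at.events_of_kind("upper")]
    lowers = [ev.temp for ev in at.events_of_kind("lower")]
    mean_upper = float(np.mean(uppers)) if uppers else None
    mean_lower = float(np.mean(lowers)) if lowers else None
    tpr = (
        mean_upper - mean_lower
        if mean_upper is not None and mean_lower is not None
        else None
    )
    t_max = float(temps.max())
    return ThermoregulationSummary(
        mean_tsk=float(temps.mean()),
        mean_upper=mean_upper,
        mean_lower=mean_lower,
        tpr=tpr,
        t_max=t_max,
        pct_time_thermoregulating=100.0 * float(at.thermoregulating.sum()) / at.trace.n,
        n_shuttles=at.n_shuttles,
        db=compute_db(temps, ref, from_midpoint=db_from_midpoint),
        is_thermoregulator=at.is_thermoregulator,
        n_bouts=at.n_bouts,
        plausibility_warning=bool(t_max >= plausibility_ceiling),
        animal_id=at.trace.animal_id,
        treatment=at.trace.treatment,
    )


def derive_reference_range(
    summaries: Sequence[ThermoregulationSummary],
) -> ReferenceRange:
    """Reference range from a baseline cohort of summaries.

    Averages the per-trace mean lower and mean upper set-points over
    thermoregulators that have both set-point means; everything else is
    excluded.  Raises if no summary is eligible.
    """
    eligible = [
        s
        for s in summaries
        if s.is_thermoregulator and s.mean_upper is not None and s.mean_lower is not None
    ]
    if not eligible:
        raise ValueError(
            "no eligible summaries: need >=1 thermoregulator with both set-point means"
        )
    return ReferenceRange(
        lower=float(np.mean([s.mean_lower for s in eligible])),
        upper=float(np.mean([s.mean_upper for s in eligible])),
    )
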