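"""Trace annotation: section labelling, hysteresis set-point detection,
bout segmentation and thermoregulator classification.

The detector is a single forward pass over each thermoregulating bout.
It keeps a direction state (unknown / warming / cooling) and the running
extremum of the current segment.  A direction change is confirmed only
once the temperature has reversed by at least the hysteresis sensitivity
(default 2 °C) from the running extremum; the event is placed at the
sample where the extremum was first attained.  Detector state resets at
every bout boundary, so the exit-cooling ramp toward ambient air cannot
manufacture events outside the heated zone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .trace_model import AnnotatedTrace, SetPointEvent, Trace

__all__ = [
    "AnnotatorConfig",
    "label_sections",
    "detect_setpoints",
    "classify",
    "annotate",
]


@dataclass(frozen=True)
class AnnotatorConfig:
    """Annotation parameters.

    hysteresis
        Minimum reversal (°C) before a direction change is confirmed.
    section_threshold
        Temperature (°C) strictly above which a sample counts as
        thermoregulating; ``None`` means use the trace's ``ta_ref``.
    min_section_samples
        Thermoregulating runs shorter than this are relabelled
        non-thermoregulating (1 = no smoothing).
    """

    hysteresis: float = 2.0
    section_threshold: Optional[float] = None
    min_section_samples: int = 1

    def __post_init__(self) -> None:
        if not (self.hysteresis > 0):
            raise ValueError("hysteresis must be > 0")
        if self.min_section_samples < 1:
            raise ValueError("min_section_samples must be >= 1")

    def threshold_for(self, trace: Trace) -> float:
        return self.section_threshold if self.section_threshold is not None else trace.ta_ref


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) ranges of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]


def label_sections(
    trace: Trace, cfg: AnnotatorConfig | None = None
) -> tuple[np.ndarray, tuple[tuple[int, int], ...]]:
    """Label each sample and return the boolean mask plus bout list.

    A sample is thermoregulating iff its temperature is strictly above
    the section threshold.  Thermoregulating runs shorter than
    ``min_section_samples`` are suppressed; the reverse smoothing is not
    applied.  Bouts are the remaining maximal runs, time-ordered.
    """
    cfg = cfg or AnnotatorConfig()
    mask = trace.temp > cfg.threshold_for(trace)
    if cfg.min_section_samples > 1:
        for s, e in _true_runs(mask):
            if e - s < cfg.min_section_samples:
                mask[s:e] = False
    return mask, tuple(_true_runs(mask))


_UNKNOWN, _WARMING, _COOLING = 0, 1, -1


def detect_setpoints(
    trace: Trace, bout: tuple[int, int], cfg: AnnotatorConfig | None = None
) -> tuple[list[SetPointEvent], int]:
    """Detect confirmed set-point events within one bout.

    Single forward pass.  From the unknown state the direction becomes
    warming once the temperature is ``>= running_min + hysteresis`` and
    cooling once ``<= running_max - hysteresis`` (this initial
    determination is not counted as a direction change).  While warming,
    a drop to ``<= running_max - hysteresis`` confirms an upper set-point
    at the first sample that attained the running maximum, flips the
    state to cooling and restarts the running minimum at the current
    sample (and symmetrically while cooling).  A trailing rise or fall
    with no reversal of at least the hysteresis inside the bout yields no
    event.  Returns the (time-ordered) events with global sample indices
    and the number of confirmed direction changes (== number of events).
    """
    cfg = cfg or AnnotatorConfig()
    h = cfg.hysteresis
    start, end = bout
    temp = trace.temp
    events: list[SetPointEvent] = []

    state = _UNKNOWN
    run_max = run_min = float(temp[start])
    argmax = argmin = start

    for i in range(start, end):
        x = float(temp[i])
        if state == _UNKNOWN:
            if x > run_max:
                run_max, argmax = x, i
            if x < run_min:
                run_min, argmin = x, i
            if x >= run_min + h:
                state = _WARMING
                run_max, argmax = x, i  # warming segment starts at the minimum
            elif x <= run_max - h:
                state = _COOLING
                run_min, argmin = x, i
        elif state == _WARMING:
            if x > run_max:
                run_max, argmax = x, i
            elif x <= run_max - h:
                events.append(SetPointEvent(index=argmax, kind="upper", temp=run_max))
                state = _COOLING
                run_min, argmin = x, i
        else:  # _COOLING
            if x < run_min:
                run_min, argmin = x, i
            elif x >= run_min + h:
                events.append(SetPointEvent(index=argmin, kind="lower", temp=run_min))
                state = _WARMING
                run_max, argmax = x, i
    return events, len(events)


def classify(n_direction_changes_total: int) -> bool:
    """More than two confirmed direction changes => thermoregulator."""
    return n_direction_changes_total > 2


def annotate(trace: Trace, cfg: AnnotatorConfig | None = None) -> AnnotatedTrace:
    """Label sections, detect set-points per bout and assemble the result.

    Detector state does not carry across bouts; events are concatenated
    in time order.
    """
    cfg = cfg or AnnotatorConfig()
    mask, bouts = label_sections(trace, cfg)
    events: list[SetPointEvent] = []
    for bout in bouts:
        ev, _ = detect_setpoints(trace, bout, cfg)
        events.extend(ev)
    return AnnotatedTrace(
        trace=trace, thermoregulating=mask, events=tuple(events), bouts=bouts
    )
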