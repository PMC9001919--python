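"""Independent brute-force reference for set-point detection.

Deliberately quadratic and structurally different from the production
single-pass state machine: every reversal test recomputes the segment
extremum from scratch over a growing slice.  Used only as a test oracle.
"""

from __future__ import annotations


def reference_setpoints(temps, hysteresis: float) -> list[tuple[str, int, float]]:
    """Return [(kind, index, temp), ...] for one bout, by exhaustive rescanning."""
    temps = [float(x) for x in temps]
    h = float(hysteresis)
    n = len(temps)
    events: list[tuple[str, int, float]] = []

    # establish the initial direction (not an event)
    direction = 0
    pos = -1
    for i in range(n):
        window = temps[: i + 1]
        if temps[i] >= min(window) + h:
            direction, pos = +1, i
            break
        if temps[i] <= max(window) - h:
            direction, pos = -1, i
            break
    if direction == 0:
        return events

    seg_start = pos  # the current segment's extremum is searched from here
    while True:
        rev = None
        if direction == +1:
            for j in range(seg_start, n):
                if temps[j] <= max(temps[seg_start : j + 1]) - h:
                    rev = j
                    break
            if rev is None:
                break
            seg = temps[seg_start : rev + 1]
            m = max(seg)
            events.append(("upper", seg_start + seg.index(m), m))
        else:
            for j in range(seg_start, n):
                if temps[j] >= min(temps[seg_start : j + 1]) + h:
                    rev = j
                    break
            if rev is None:
                break
            seg = temps[seg_start : rev + 1]
            m = min(seg)
            events.append(("lower", seg_start + seg.index(m), m))
        direction = -direction
        seg_start = rev
    return events
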