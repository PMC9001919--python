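"""Domain types and file I/O for skin-temperature traces.

A :class:`Trace` is a uniformly sampled skin-temperature time series with
the metadata needed downstream (sampling interval, logger quantization
step, ambient reference temperature, animal id and treatment label).
An :class:`AnnotatedTrace` adds per-sample section labels, the list of
confirmed set-point events and the bout structure.

File conventions
----------------
* Trace CSV: columns ``time_s,temp_c`` (header row, UTF-8, comma
  separated).  Metadata travels in a JSON sidecar ``<stem>.meta.json``
  next to the CSV so the sample table stays clean.
* Annotated CSV: columns ``time_s,temp_c,label,event`` plus a JSON
  sidecar ``<stem>.annot.json`` holding the event list, bout ranges and
  trace metadata.
* Summaries: one row per trace in a plain CSV.

All sample indices are 0-based; bout ranges are half-open
``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "SetPointEvent",
    "AnnotatedTrace",
    "ThermoregulationSummary",
    "LABEL_THERMOREGULATING",
    "LABEL_NON_THERMOREGULATING",
    "read_trace",
    "write_trace",
    "read_annotated",
    "write_annotated",
    "read_summaries",
    "write_summaries",
]

LABEL_THERMOREGULATING = "thermoregulating"
LABEL_NON_THERMOREGULATING = "non_thermoregulating"

_TIME_COL = "time_s"
_TEMP_COL = "temp_c"

#: tolerance (seconds) for checking uniform sampling
_DT_TOL = 1e-9


class TraceError(ValueError):
    """Raised for malformed trace files or inconsistent metadata."""


def _meta_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def _annot_path(path: Path) -> Path:
    return path.with_name(path.stem + ".annot.json")


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled skin-temperature series plus metadata.

    Parameters
    ----------
    t : ndarray
        Sample times in seconds from test start, strictly increasing with
        constant spacing ``dt``.
    temp : ndarray
        Skin temperature in °C, one value per sample; all finite.
    dt : float
        Sampling interval in seconds.
    resolution : float
        Logger quantization step in °C.
    ta_ref : float
        Ambient reference temperature in °C (section threshold default).
    animal_id : str
        Identifier of the animal.
    treatment : float or None
        Treatment label (wind speed in m/s) if known.
    calibration_offset : float or None
        Additive correction already applied to ``temp``, if any.
    """

    t: np.ndarray
    temp: np.ndarray
    dt: float = 2.0
    resolution: float = 0.0625
    ta_ref: float = 18.0
    animal_id: str = ""
    treatment: Optional[float] = None
    calibration_offset: Optional[float] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        temp = np.asarray(self.temp, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "temp", temp)
        if t.ndim != 1 or temp.ndim != 1:
            raise TraceError("t and temp must be 1-D arrays")
        if len(t) != len(temp):
            raise TraceError("t and temp must have equal length")
        if len(t) < 2:
            raise TraceError("a trace needs at least 2 samples")
        if not np.all(np.isfinite(temp)):
            bad = int(np.flatnonzero(~np.isfinite(temp))[0])
            raise TraceError(f"non-finite temperature at sample {bad}")
        if not (self.resolution > 0):
            raise TraceError("resolution must be > 0")
        if not (self.dt > 0):
            raise TraceError("dt must be > 0")
        diffs = np.diff(t)
        off = np.flatnonzero(np.abs(diffs - self.dt) > _DT_TOL)
        if off.size:
            i = int(off[0])
            raise TraceError(
                f"non-uniform sampling: interval between samples {i} and "
                f"{i + 1} is {diffs[i]!r} s, expected {self.dt!r} s"
            )

    @property
    def n(self) -> int:
        return len(self.temp)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def metadata(self) -> dict:
        """Metadata dict as stored in the JSON sidecar."""
        return {
            "animal_id": self.animal_id,
            "treatment": self.treatment,
            "dt": self.dt,
            "resolution": self.resolution,
            "ta_ref": self.ta_ref,
            "calibration_offset": self.calibration_offset,
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trace):
            return NotImplemented
        return (
            np.array_equal(self.t, other.t)
            and np.array_equal(self.temp, other.temp)
            and self.dt == other.dt
            and self.resolution == other.resolution
            and self.ta_ref == other.ta_ref
            and self.animal_id == other.animal_id
            and self.treatment == other.treatment
            and self.calibration_offset == other.calibration_offset
        )


@dataclass(frozen=True, order=True)
class SetPointEvent:
    """One confirmed direction-change extremum.

    ``kind`` is ``"upper"`` (warming -> cooling) or ``"lower"``
    (cooling -> warming); ``index`` is the 0-based sample index of the
    extremum, ``temp`` the temperature there.
    """

    index: int
    kind: str
    temp: float

    def __post_init__(self) -> None:
        if self.kind not in ("upper", "lower"):
            raise ValueError(f"invalid event kind {self.kind!r}")


@dataclass(frozen=True)
class AnnotatedTrace:
    """A trace plus section labels, set-point events and bouts.

    ``thermoregulating`` is a boolean mask (True = thermoregulating
    section); ``bouts`` are half-open index ranges of its maximal True
    runs; ``events`` are time-ordered and alternate in kind within each
    bout.
    """

    trace: Trace
    thermoregulating: np.ndarray
    events: tuple[SetPointEvent, ...]
    bouts: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        mask = np.asarray(self.thermoregulating, dtype=bool)
        object.__setattr__(self, "thermoregulating", mask)
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(
            self, "bouts", tuple((int(s), int(e)) for s, e in self.bouts)
        )
        if len(mask) != self.trace.n:
            raise ValueError("label mask length must match trace length")
        idx = [ev.index for ev in self.events]
        if idx != sorted(idx):
            raise ValueError("events must be sorted by index")
        for ev in self.events:
            if not any(s <= ev.index < e for s, e in self.bouts):
                raise ValueError(f"event at {ev.index} lies outside all bouts")
        for s, e in self.bouts:
            kinds = [ev.kind for ev in self.events if s <= ev.index < e]
            for a, b in zip(kinds, kinds[1:]):
                if a == b:
                    raise ValueError(f"event kinds do not alternate in bout [{s},{e})")

    @property
    def labels(self) -> np.ndarray:
        """Per-sample string labels."""
        return np.where(
            self.thermoregulating, LABEL_THERMOREGULATING, LABEL_NON_THERMOREGULATING
        )

    @property
    def n_shuttles(self) -> int:
        return len(self.events)

    @property
    def n_bouts(self) -> int:
        return len(self.bouts)

    @property
    def is_thermoregulator(self) -> bool:
        from .annotator import classify

        return classify(self.n_shuttles)

    def events_of_kind(self, kind: str) -> tuple[SetPointEvent, ...]:
        return tuple(ev for ev in self.events if ev.kind == kind)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedTrace):
            return NotImplemented
        return (
            self.trace == other.trace
            and np.array_equal(self.thermoregulating, other.thermoregulating)
            and self.events == other.events
            and self.bouts == other.bouts
        )


@dataclass(frozen=True)
class ThermoregulationSummary:
    """Per-trace thermoregulation parameters.

    The seven descriptive parameters plus the accuracy index ``db`` and
    the classification.  Set-point means (and hence ``tpr``) are ``None``
    when no event of that kind was confirmed — never 0 or a sentinel.
    """

    mean_tsk: float
    mean_upper: Optional[float]
    mean_lower: Optional[float]
    tpr: Optional[float]
    t_max: float
    pct_time_thermoregulating: float
    n_shuttles: int
    db: float
    is_thermoregulator: bool
    n_bouts: int
    plausibility_warning: bool = False
    animal_id: str = ""
    treatment: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_time_thermoregulating <= 100.0):
            raise ValueError("pct_time_thermoregulating must be in [0, 100]")
        if self.t_max < self.mean_tsk - 1e-12:
            raise ValueError("t_max cannot be below mean_tsk")
        if (
            self.mean_upper is not None
            and self.mean_lower is not None
            and self.mean_upper < self.mean_lower
        ):
            raise ValueError("mean_upper must be >= mean_lower")
        if self.n_shuttles < 0:
            raise ValueError("n_shuttles must be >= 0")

    def to_record(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# trace I/O
# ---------------------------------------------------------------------------

def _read_table(path: Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in required:
        if col not in df.columns:
            raise TraceError(f"{path}: missing required column {col!r}")
    for col in required:
        if col in (_TIME_COL, _TEMP_COL):
            try:
                df[col] = pd.to_numeric(df[col], errors="raise")
            except (ValueError, TypeError) as exc:
                raise TraceError(f"{path}: non-numeric value in column {col!r}: {exc}")
    return df


def _load_metadata(path: Path) -> dict:
    mp = _meta_path(path)
    if mp.exists():
        with open(mp) as fh:
            return json.load(fh)
    return {}


def read_trace(path, **overrides) -> Trace:
    """Read a trace CSV (columns ``time_s,temp_c``) and its sidecar.

    Metadata is resolved, in order of precedence: keyword ``overrides``,
    the ``<stem>.meta.json`` sidecar, then documented defaults.  The
    sampling interval is always inferred from the time column and must
    agree with any declared ``dt`` (non-uniform sampling is rejected,
    naming the first offending row).
    """
    path = Path(path)
    df = _read_table(path, (_TIME_COL, _TEMP_COL))
    if len(df) < 2:
        raise TraceError(f"{path}: a trace needs at least 2 samples")
    t = df[_TIME_COL].to_numpy(dtype=float)
    temp = df[_TEMP_COL].to_numpy(dtype=float)

    meta = _load_metadata(path)
    meta.update({k: v for k, v in overrides.items() if v is not None})

    dt_inferred = float(t[1] - t[0])
    dt_meta = meta.get("dt")
    if dt_meta is not None and abs(float(dt_meta) - dt_inferred) > _DT_TOL:
        raise TraceError(
            f"{path}: declared dt={dt_meta} disagrees with inferred "
            f"dt={dt_inferred} from the time column"
        )
    kwargs = dict(
        dt=dt_inferred,
        resolution=float(meta.get("resolution", 0.0625)),
        ta_ref=float(meta.get("ta_ref", 18.0)),
        animal_id=str(meta.get("animal_id", path.stem)),
        treatment=meta.get("treatment"),
        calibration_offset=meta.get("calibration_offset"),
    )
    if kwargs["treatment"] is not None:
        kwargs["treatment"] = float(kwargs["treatment"])
    return Trace(t=t, temp=temp, **kwargs)


def write_trace(trace: Trace, path) -> None:
    """Write a trace CSV and its metadata sidecar."""
    path = Path(path)
    pd.DataFrame({_TIME_COL: trace.t, _TEMP_COL: trace.temp}).to_csv(path, index=False)
    with open(_meta_path(path), "w") as fh:
        json.dump(trace.metadata(), fh, indent=1)


# ---------------------------------------------------------------------------
# annotated-trace I/O
# ---------------------------------------------------------------------------

def write_annotated(at: AnnotatedTrace, path) -> None:
    """Write the per-sample table plus a structured sidecar.

    The CSV carries one row per sample (``time_s,temp_c,label,event``,
    event blank except at set-point samples); the sidecar carries the
    event list, bouts and trace metadata so that
    ``read_annotated(write_annotated(x)) == x``.
    """
    path = Path(path)
    event_col = np.full(at.trace.n, "", dtype=object)
    for ev in at.events:
        event_col[ev.index] = ev.kind
    pd.DataFrame(
        {
            _TIME_COL: at.trace.t,
            _TEMP_COL: at.trace.temp,
            "label": at.labels,
            "event": event_col,
        }
    ).to_csv(path, index=False)
    sidecar = {
        "meta": at.trace.metadata(),
        "events": [
            {"kind": ev.kind, "index": ev.index, "temp": ev.temp} for ev in at.events
        ],
        "bouts": [list(b) for b in at.bouts],
    }
    with open(_annot_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_annotated(path) -> AnnotatedTrace:
    """Read an annotated trace written by :func:`write_annotated`."""
    path = Path(path)
    df = _read_table(path, (_TIME_COL, _TEMP_COL, "label", "event"))
    ap = _annot_path(path)
    if not ap.exists():
        raise TraceError(f"{path}: missing annotation sidecar {ap.name}")
    with open(ap) as fh:
        sidecar = json.load(fh)
    meta = sidecar.get("meta", {})
    trace = Trace(
        t=df[_TIME_COL].to_numpy(dtype=float),
        temp=df[_TEMP_COL].to_numpy(dtype=float),
        dt=float(meta.get("dt", 2.0)),
        resolution=float(meta.get("resolution", 0.0625)),
        ta_ref=float(meta.get("ta_ref", 18.0)),
        animal_id=str(meta.get("animal_id", path.stem)),
        treatment=(
            float(meta["treatment"]) if meta.get("treatment") is not None else None
        ),
        calibration_offset=meta.get("calibration_offset"),
    )
    mask = df["label"].to_numpy() == LABEL_THERMOREGULATING
    events = tuple(
        SetPointEvent(index=int(e["index"]), kind=str(e["kind"]), temp=float(e["temp"]))
        for e in sidecar.get("events", [])
    )
    bouts = tuple((int(s), int(e)) for s, e in sidecar.get("bouts", []))
    return AnnotatedTrace(trace=trace, thermoregulating=mask, events=events, bouts=bouts)


# ---------------------------------------------------------------------------
# summary I/O
# ---------------------------------------------------------------------------

_SUMMARY_COLS = [
    "animal_id",
    "treatment",
    "mean_tsk",
    "mean_upper",
    "mean_lower",
    "tpr",
    "t_max",
    "pct_time_thermoregulating",
    "n_shuttles",
    "db",
    "is_thermoregulator",
    "n_bouts",
    "plausibility_warning",
]


def write_summaries(summaries: Sequence[ThermoregulationSummary], path) -> None:
    """Write one-row-per-trace summary CSV."""
    rows = [s.to_record() for s in summaries]
    pd.DataFrame(rows, columns=_SUMMARY_COLS).to_csv(path, index=False)


def read_summaries(path) -> list[ThermoregulationSummary]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        def opt(name):
            v = row[name]
            return None if pd.isna(v) else float(v)

        out.append(
            ThermoregulationSummary(
                mean_tsk=float(row["mean_tsk"]),
                mean_upper=opt("mean_upper"),
                mean_lower=opt("mean_lower"),
                tpr=opt("tpr"),
                t_max=float(row["t_max"]),
                pct_time_thermoregulating=float(row["pct_time_thermoregulating"]),
                n_shuttles=int(row["n_shuttles"]),
                db=float(row["db"]),
                is_thermoregulator=bool(row["is_thermoregulator"]),
                n_bouts=int(row["n_bouts"]),
                plausibility_warning=bool(row["plausibility_warning"]),
                animal_id=str(row["animal_id"]) if not pd.isna(row["animal_id"]) else "",
                treatment=opt("treatment"),
            )
        )
    return out
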