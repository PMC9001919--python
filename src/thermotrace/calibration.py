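"""Bio-logger to cloacal temperature calibration.

The correction is a single additive offset (mean cloacal − logger
difference); no regression slope is fitted.  Applying the fit is off by
default in the pipeline — annotation thresholds are never auto-shifted.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .trace_model import Trace

__all__ = ["CalibrationFit", "fit_offset", "apply_offset"]


@dataclass(frozen=True)
class CalibrationFit:
    """Summary of a paired logger/cloacal comparison."""

    n_pairs: int
    mean_offset: float  # cloacal − logger, °C
    se_offset: float
    pearson_r: float

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("need at least 2 pairs")
        if not -1.0 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("pearson_r must lie in [-1, 1]")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationFit":
        with open(path) as fh:
            return cls(**json.load(fh))


def fit_offset(pairs) -> CalibrationFit:
    """Fit the additive logger->cloacal correction from paired readings.

    ``pairs`` is a sequence of (logger °C, cloacal °C).  Returns the mean
    difference, its standard error and the Pearson correlation of the two
    columns.  Raises for fewer than 2 pairs, non-finite values, or zero
    variance in either column (correlation undefined).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (logger, cloacal)")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    if not np.all(np.isfinite(arr)):
        raise ValueError("pairs must be finite")
    logger, cloacal = arr[:, 0], arr[:, 1]
    for name, col in (("logger", logger), ("cloacal", cloacal)):
        if np.ptp(col) == 0.0:
            raise ValueError(f"zero variance in {name} column: correlation undefined")
    diff = cloacal - logger
    n = len(diff)
    se = float(np.std(diff, ddof=1) / math.sqrt(n))
    r = float(stats.pearsonr(logger, cloacal).statistic)
    return CalibrationFit(
        n_pairs=n, mean_offset=float(diff.mean()), se_offset=se, pearson_r=r
    )


def apply_offset(trace: Trace, fit: CalibrationFit) -> Trace:
    """Shift every temperature by ``+fit.mean_offset``.

    The correction is recorded in the trace metadata; section thresholds
    and ``ta_ref`` are deliberately left untouched.
    """
    prior = trace.calibration_offset or 0.0
    return replace(
        trace,
        temp=trace.temp + fit.mean_offset,
        calibration_offset=prior + fit.mean_offset,
    )
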