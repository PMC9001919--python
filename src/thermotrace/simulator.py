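"""Seedable synthetic-trace generator for shuttling ectotherms.

The latent (noise-free) skin temperature relaxes toward a
behaviour-dependent equilibrium with first-order Newtonian kinetics,

    T'[i+1] = T_env + (T'[i] - T_env) * exp(-k * dt),

where the behavioural controller picks ``T_env`` and ``k``:

* ``bask``  — under the lamp: ``T_env = t_hot``, rate ``k_warm``;
* ``cool``  — at the cool end of the tunnel: ``T_env = ta``, rate
  ``k_cool``;
* ``rest``  — out of the tunnel on the ambient substrate: ``T_env = ta``
  at the faster conductive rate ``k_exit_multiplier * k_cool``.

A thermoregulator switches bask->cool when the latent temperature
reaches the upper set-point and cool->bask at the lower set-point; on
reaching the lower set-point it may instead leave the tunnel with
probability ``p_exit`` and rest for ``rest_s`` seconds before
re-entering (a new bout).  A non-thermoregulator basks until it reaches
the upper set-point once (or ``exit_after_s`` elapses) and then leaves
for good.  The controller acts on the latent temperature; the observed
trace is the latent series plus Gaussian measurement noise, quantized to
the logger resolution.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .trace_model import Trace, write_trace

__all__ = [
    "SimulationConfig",
    "TreatmentEffect",
    "CohortConfig",
    "GroundTruth",
    "simulate_trace",
    "simulate_cohort",
    "overshoot_bounds",
    "write_cohort",
    "DEFAULT_TREATMENTS",
]

_BASK, _COOL, _REST, _GONE = 0, 1, 2, 3


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one trace."""

    duration_s: float = 5400.0
    dt_s: float = 2.0
    resolution: float = 0.0625
    ta: float = 18.0
    t_hot: float = 35.0
    true_upper: float = 34.7
    true_lower: float = 29.1
    k_warm: float = 0.015
    k_cool: float = 0.005
    noise_sd: float = 0.1
    mode: str = "thermoregulator"
    exit_after_s: float = 1800.0
    p_exit: float = 0.0
    rest_s: float = 900.0
    k_exit_multiplier: float = 3.0
    setpoint_jitter_sd: float = 0.0
    seed: int = 0
    animal_id: str = "sim"
    treatment: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.true_lower < self.true_upper <= self.t_hot):
            raise ValueError("need true_lower < true_upper <= t_hot")
        if not (self.ta < self.true_lower):
            raise ValueError("need ta < true_lower")
        if self.k_warm <= 0 or self.k_cool <= 0:
            raise ValueError("rate constants must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mode not in ("thermoregulator", "non_thermoregulator"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 <= self.p_exit <= 1.0):
            raise ValueError("p_exit must be in [0, 1]")
        if self.duration_s < self.dt_s or self.dt_s <= 0:
            raise ValueError("invalid duration/dt")


@dataclass(frozen=True)
class GroundTruth:
    """What the controller actually did, for validating the pipeline."""

    mode: str
    true_upper: float
    true_lower: float
    n_switches: int  # confirmed bask<->cool reversals inside the tunnel
    switch_indices: tuple[int, ...]
    n_exits: int  # tunnel exits (rest periods and the permanent exit)
    is_thermoregulator: bool

    def to_record(self) -> dict:
        d = dataclasses.asdict(self)
        d["switch_indices"] = list(self.switch_indices)
        return d


def overshoot_bounds(cfg: SimulationConfig) -> tuple[float, float]:
    """Worst-case one-step overshoot past (upper, lower) set-points."""
    up = (cfg.t_hot - cfg.true_upper) * (1.0 - math.exp(-cfg.k_warm * cfg.dt_s))
    lo = (cfg.true_lower - cfg.ta) * (1.0 - math.exp(-cfg.k_cool * cfg.dt_s))
    return up, lo


def _quantize(x: np.ndarray, resolution: float) -> np.ndarray:
    return np.round(x / resolution) * resolution


def simulate_trace(cfg: SimulationConfig) -> tuple[Trace, GroundTruth]:
    """Simulate one trace; returns the observed Trace and the ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s / cfg.dt_s)) + 1
    dt = cfg.dt_s
    k_exit = cfg.k_exit_multiplier * cfg.k_cool

    def draw_setpoint(base: float, low_clamp: float, high_clamp: float) -> float:
        if cfg.setpoint_jitter_sd <= 0:
            return base
        return float(np.clip(rng.normal(base, cfg.setpoint_jitter_sd), low_clamp, high_clamp))

    latent = np.empty(n)
    latent[0] = cfg.ta
    state = _BASK
    cur_upper = draw_setpoint(cfg.true_upper, cfg.true_lower + 0.1, cfg.t_hot - 0.05)
    cur_lower = draw_setpoint(cfg.true_lower, cfg.ta + 0.5, cfg.true_upper - 0.1)
    switches: list[int] = []
    n_exits = 0
    rest_until = -1.0

    for i in range(1, n):
        if state == _BASK:
            t_env, k = cfg.t_hot, cfg.k_warm
        elif state == _COOL:
            t_env, k = cfg.ta, cfg.k_cool
        else:  # _REST or _GONE
            t_env, k = cfg.ta, k_exit
        latent[i] = t_env + (latent[i - 1] - t_env) * math.exp(-k * dt)
        t_now = i * dt

        if state == _BASK:
            if latent[i] >= cur_upper:
                if cfg.mode == "non_thermoregulator":
                    state = _GONE
                    n_exits += 1
                else:
                    state = _COOL
                    switches.append(i)
                    cur_lower = draw_setpoint(
                        cfg.true_lower, cfg.ta + 0.5, cfg.true_upper - 0.1
                    )
            elif cfg.mode == "non_thermoregulator" and t_now >= cfg.exit_after_s:
                state = _GONE
                n_exits += 1
        elif state == _COOL:
            if latent[i] <= cur_lower:
                if cfg.p_exit > 0 and rng.random() < cfg.p_exit:
                    state = _REST
                    n_exits += 1
                    rest_until = t_now + cfg.rest_s
                else:
                    state = _BASK
                    switches.append(i)
                cur_upper = draw_setpoint(
                    cfg.true_upper, cfg.true_lower + 0.1, cfg.t_hot - 0.05
                )
        elif state == _REST:
            if t_now >= rest_until:
                state = _BASK

    observed = latent
    if cfg.noise_sd > 0:
        observed = observed + rng.normal(0.0, cfg.noise_sd, size=n)
    observed = _quantize(observed, cfg.resolution)

    trace = Trace(
        t=np.arange(n) * dt,
        temp=observed,
        dt=dt,
        resolution=cfg.resolution,
        ta_ref=cfg.ta,
        animal_id=cfg.animal_id,
        treatment=cfg.treatment,
    )
    truth = GroundTruth(
        mode=cfg.mode,
        true_upper=cfg.true_upper,
        true_lower=cfg.true_lower,
        n_switches=len(switches),
        switch_indices=tuple(switches),
        n_exits=n_exits,
        is_thermoregulator=cfg.mode == "thermoregulator",
    )
    return trace, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreatmentEffect:
    """Per-treatment modifiers applied to the base simulation config."""

    delta_upper: float = 0.0
    delta_lower: float = 0.0
    p_thermoregulate: float = 17.0 / 28.0
    k_cool_multiplier: float = 1.0
    p_exit: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_thermoregulate <= 1.0):
            raise ValueError("p_thermoregulate must be in [0, 1]")
        if self.k_cool_multiplier <= 0:
            raise ValueError("k_cool_multiplier must be > 0")


#: treatment structure mirroring a still / moderate / strong airflow design:
#: set-points shift down and convective cooling speeds up with wind, and
#: animals take fewer breaks from the heat source.
DEFAULT_TREATMENTS: Mapping[float, TreatmentEffect] = {
    0.0: TreatmentEffect(0.0, 0.0, 17.0 / 28.0, 1.0, 0.15),
    2.0: TreatmentEffect(-1.0, -1.0, 23.0 / 28.0, 1.6, 0.05),
    6.0: TreatmentEffect(-2.0, -2.0, 23.0 / 28.0, 2.5, 0.01),
}


@dataclass(frozen=True)
class CohortConfig:
    """A repeated-measures cohort: each animal is tested in every treatment."""

    n_per_treatment: int = 28
    treatments: Mapping[float, TreatmentEffect] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENTS)
    )
    base: SimulationConfig = field(default_factory=SimulationConfig)
    animal_effect_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_treatment < 1:
            raise ValueError("n_per_treatment must be >= 1")
        if not self.treatments:
            raise ValueError("need at least one treatment")


def simulate_cohort(
    cfg: CohortConfig,
) -> tuple[list[tuple[Trace, GroundTruth]], dict]:
    """Simulate every animal under every treatment.

    Animal identities repeat across treatments (repeated measures); each
    animal carries a persistent random offset on both set-points.  Child
    seeds are spawned deterministically from the cohort seed.  Returns
    the (trace, ground-truth) list and a manifest dict describing each
    trace.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    treatments = sorted(cfg.treatments)
    n_traces = cfg.n_per_treatment * len(treatments)
    child_seeds = [int(c.generate_state(1, np.uint64)[0]) for c in ss.spawn(n_traces)]

    animal_ids = [f"an{i + 1:02d}" for i in range(cfg.n_per_treatment)]
    offsets = {
        a: (float(rng.normal(0.0, cfg.animal_effect_sd)) if cfg.animal_effect_sd > 0 else 0.0)
        for a in animal_ids
    }

    results: list[tuple[Trace, GroundTruth]] = []
    manifest_rows: list[dict] = []
    idx = 0
    for treatment in treatments:
        eff = cfg.treatments[treatment]
        for animal in animal_ids:
            is_thermo = bool(rng.random() < eff.p_thermoregulate)
            # keep shifted set-points inside the physical envelope
            upper = min(
                cfg.base.true_upper + eff.delta_upper + offsets[animal],
                cfg.base.t_hot - 0.1,
            )
            lower = max(
                cfg.base.true_lower + eff.delta_lower + offsets[animal],
                cfg.base.ta + 1.0,
            )
            lower = min(lower, upper - 0.5)
            sim = replace(
                cfg.base,
                true_upper=upper,
                true_lower=lower,
                k_cool=cfg.base.k_cool * eff.k_cool_multiplier,
                p_exit=eff.p_exit,
                mode="thermoregulator" if is_thermo else "non_thermoregulator",
                seed=child_seeds[idx],
                animal_id=animal,
                treatment=float(treatment),
            )
            trace, truth = simulate_trace(sim)
            results.append((trace, truth))
            manifest_rows.append(
                {
                    "trace_id": f"{animal}_w{treatment:g}",
                    "animal_id": animal,
                    "treatment": float(treatment),
                    **truth.to_record(),
                }
            )
            idx += 1
    manifest = {
        "seed": cfg.seed,
        "n_per_treatment": cfg.n_per_treatment,
        "treatments": [float(x) for x in treatments],
        "traces": manifest_rows,
    }
    return results, manifest


def write_cohort(
    results: Sequence[tuple[Trace, GroundTruth]], manifest: dict, outdir
) -> None:
    """Write each trace (CSV + meta sidecar), its ground truth and the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (trace, truth), row in zip(results, manifest["traces"]):
        stem = row["trace_id"]
        write_trace(trace, outdir / f"{stem}.csv")
        with open(outdir / f"{stem}.truth.json", "w") as fh:
            json.dump(truth.to_record(), fh, indent=1)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
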