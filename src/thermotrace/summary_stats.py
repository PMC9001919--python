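"""Cohort-level descriptive tables and seedable permutation comparisons.

This layer deliberately does not fit mixed models: it produces a tidy
per-trace table suitable for model fitting elsewhere, descriptive
per-treatment means/SEs, and permutation tests (pairwise difference of
group means plus an overall among-group variance statistic).  When the
cohort is repeated-measures — the same animals appear in more than one
treatment — labels are permuted within each animal by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trace_model import ThermoregulationSummary

__all__ = [
    "RESPONSE_VARS",
    "summaries_frame",
    "summarize_cohort",
    "PermutationResult",
    "permutation_test",
]

#: the eight per-trace response variables reported per treatment
RESPONSE_VARS = (
    "mean_tsk",
    "mean_upper",
    "mean_lower",
    "tpr",
    "t_max",
    "pct_time_thermoregulating",
    "n_shuttles",
    "db",
)


def summaries_frame(summaries: Sequence[ThermoregulationSummary]) -> pd.DataFrame:
    """Tidy one-row-per-trace table from summaries."""
    return pd.DataFrame([s.to_record() for s in summaries])


def summarize_cohort(
    summaries: Sequence[ThermoregulationSummary],
    treatments: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Per-treatment counts and response means/SEs.

    Classification counts cover every trace; the response means and
    standard errors are computed over thermoregulators only.  If
    ``treatments`` is given, an unknown treatment label in the input is
    an error.  The result is order-invariant in the input and indexed by
    treatment.
    """
    if not summaries:
        raise ValueError("no summaries given")
    df = summaries_frame(summaries)
    if df["treatment"].isna().any():
        raise ValueError("every summary needs a treatment label")
    if treatments is not None:
        allowed = {float(t) for t in treatments}
        unknown = set(df["treatment"].unique()) - allowed
        if unknown:
            raise ValueError(f"unknown treatment label(s): {sorted(unknown)}")
    rows = []
    for treatment, grp in df.groupby("treatment", sort=True):
        thermo = grp[grp["is_thermoregulator"]]
        row: dict = {
            "treatment": treatment,
            "n_thermoregulators": int(grp["is_thermoregulator"].sum()),
            "n_non_thermoregulators": int((~grp["is_thermoregulator"]).sum()),
        }
        for var in RESPONSE_VARS:
            # sort so the table is exactly invariant to input order
            vals = np.sort(thermo[var].dropna().to_numpy(dtype=float))
            row[f"{var}_mean"] = float(vals.mean()) if vals.size else np.nan
            row[f"{var}_se"] = (
                float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("treatment")


@dataclass(frozen=True)
class PermutationResult:
    """p-values from a permutation comparison across treatment groups."""

    overall_p: float
    pairwise_p: dict
    pairwise_p_holm: dict
    n_perm: int
    within_animal: bool


def _holm(pvals: dict) -> dict:
    """Holm step-down adjustment; never decreases a p-value."""
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted: dict = {}
    running = 0.0
    for rank, (key, p) in enumerate(items):
        running = max(running, min(1.0, (m - rank) * p))
        adjusted[key] = running
    return adjusted


def _perm_label_matrix(
    codes: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    blocks: Optional[np.ndarray],
) -> np.ndarray:
    """n_perm independently permuted copies of ``codes`` (optionally within blocks)."""
    mat = np.tile(codes, (n_perm, 1))
    if blocks is None:
        return rng.permuted(mat, axis=1)
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        if idx.size > 1:
            mat[:, idx] = rng.permuted(mat[:, idx], axis=1)
    return mat


def permutation_test(
    values,
    groups,
    n_perm: int = 10000,
    seed: Optional[int] = None,
    animals=None,
    within_animal: Optional[bool] = None,
) -> PermutationResult:
    """Permutation comparison of a per-trace statistic across groups.

    Pairwise contrasts use the absolute difference of group means; the
    overall test uses the variance of the group means.  p-values are
    ``(1 + #{permuted >= observed}) / (1 + n_perm)`` and the pairwise set
    is Holm-adjusted.  If ``animals`` is given and any animal appears in
    more than one group, labels are permuted within animals by default
    (set ``within_animal`` explicitly to override).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape or values.ndim != 1:
        raise ValueError("values and groups must be 1-D and aligned")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    for g in labels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")

    animals = None if animals is None else np.asarray(animals)
    if within_animal is None:
        within_animal = bool(
            animals is not None
            and pd.DataFrame({"a": animals, "g": groups})
            .groupby("a")["g"]
            .nunique()
            .max()
            > 1
        )
    if within_animal and animals is None:
        raise ValueError("within_animal permutation requires animal ids")

    rng = np.random.default_rng(seed)
    codes = np.searchsorted(labels, groups)

    def pval(perm_stats: np.ndarray, observed: float) -> float:
        hits = int(np.sum(perm_stats >= observed - 1e-12))
        return (1.0 + hits) / (1.0 + len(perm_stats))

    # overall: variance of group means under full (or within-animal) relabelling
    perm = _perm_label_matrix(codes, n_perm, rng, animals if within_animal else None)
    means = np.empty((labels.size, n_perm))
    obs_means = np.empty(labels.size)
    for gi in range(labels.size):
        mask = perm == gi
        means[gi] = (mask @ values) / mask.sum(axis=1)
        obs_means[gi] = values[codes == gi].mean()
    overall_obs = float(np.var(obs_means))
    overall_p = pval(np.var(means, axis=0), overall_obs)

    pairwise_p: dict = {}
    for ai in range(labels.size):
        for bi in range(ai + 1, labels.size):
            sel = (codes == ai) | (codes == bi)
            v = values[sel]
            c = codes[sel]
            blk = animals[sel] if within_animal else None
            pm = _perm_label_matrix(c, n_perm, rng, blk)
            is_a = pm == ai
            na = is_a.sum(axis=1).astype(float)
            nb = (~is_a).sum(axis=1).astype(float)
            diffs = np.abs((is_a @ v) / na - ((~is_a) @ v) / nb)
            obs = abs(v[c == ai].mean() - v[c == bi].mean())
            key = (labels[ai].item() if hasattr(labels[ai], "item") else labels[ai],
                   labels[bi].item() if hasattr(labels[bi], "item") else labels[bi])
            pairwise_p[key] = pval(diffs, obs)

    return PermutationResult(
        overall_p=overall_p,
        pairwise_p=pairwise_p,
        pairwise_p_holm=_holm(pairwise_p),
        n_perm=n_perm,
        within_animal=within_animal,
    )
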