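"""Cohort-level aggregation, group comparison and out-of-distribution flagging.

Per-subject masked uncertainty aggregates C are collected into a tidy table
(one row per subject), summarized per group as mean and interquartile
range, and compared across named cohort contrasts with Welch's
unequal-variance t-test, jointly corrected with the Benjamini–Hochberg
false-discovery-rate step-up.

Two QC heuristics flag prospective subjects against a reference cohort:
Tukey IQR fences on the aggregate value, and the Kullback–Leibler
divergence D(new || reference) between histogram estimates of the two
uncertainty distributions (Jensen–Shannon available as the symmetric
variant).  Both are screening statistics, not calibrated tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SubjectRecord",
    "CohortTable",
    "summarize_groups",
    "welch_t",
    "bh_fdr",
    "iqr_flags",
    "kl_divergence",
    "compare_cohorts",
]


@dataclass
class SubjectRecord:
    """One subject's labels, per-metric aggregate C values, and volume."""

    subject_id: str
    diagnosis: str
    cohort: str
    site: str
    age_group: str
    uncertainty: dict[str, float]
    volume_mm3: float = float("nan")
    dice: float = float("nan")
    age: float | None = None

    def __post_init__(self) -> None:
        if self.age_group not in ("adult", "child"):
            raise ValueError("age_group must be 'adult' or 'child'")
        if self.age is not None:
            expected = "adult" if self.age >= 18 else "child"
            if self.age_group != expected:
                raise ValueError(
                    f"age_group {self.age_group!r} inconsistent with age {self.age}"
                )


@dataclass
class CohortTable:
    """A list of subject records plus run provenance (scheme, version, seeds)."""

    records: list[SubjectRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("subject_ids must be unique")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "subject_id": r.subject_id,
                "diagnosis": r.diagnosis,
                "cohort": r.cohort,
                "site": r.site,
                "age_group": r.age_group,
                "volume_mm3": r.volume_mm3,
                "dice": r.dice,
            }
            for metric, value in r.uncertainty.items():
                row[f"c_{metric}"] = value
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: dict | None = None) -> "CohortTable":
        metric_cols = [c for c in df.columns if c.startswith("c_")]
        records = [
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                diagnosis=str(row["diagnosis"]),
                cohort=str(row["cohort"]),
                site=str(row["site"]),
                age_group=str(row["age_group"]),
                uncertainty={c[2:]: float(row[c]) for c in metric_cols},
                volume_mm3=float(row.get("volume_mm3", float("nan"))),
                dice=float(row.get("dice", float("nan"))),
            )
            for _, row in df.iterrows()
        ]
        return cls(records=records, provenance=provenance or {})


def summarize_groups(
    table: pd.DataFrame, group_by: str, value: str
) -> pd.DataFrame:
    """Mean, Q1, Q3 (linear-interpolation quantiles) and n per group.

    Rows are ordered by group label for deterministic output.
    """
    if group_by not in table.columns:
        raise KeyError(f"unknown grouping column {group_by!r}")
    if value not in table.columns:
        raise KeyError(f"unknown value column {value!r}")
    rows = []
    for label, sub in table.groupby(group_by, sort=True):
        vals = sub[value].to_numpy(dtype=float)
        if len(vals) < 1:
            continue
        rows.append(
            {
                group_by: label,
                "mean": float(np.mean(vals)),
                "q1": float(np.quantile(vals, 0.25)),
                "q3": float(np.quantile(vals, 0.75)),
                "n": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)


def welch_t(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, Welch–Satterthwaite df, p).

    An identical pair of groups gives t = 0, p = 1 by convention (zero
    pooled standard error is treated as exact equality).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float("inf"), float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_fdr(pvalues: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up; returns (adjusted p, reject flags at level q)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def iqr_flags(
    reference_values: Sequence[float],
    new_values: Sequence[float],
    fence_multiplier: float = 1.5,
) -> np.ndarray:
    """Flag new values outside [Q1 - f*IQR, Q3 + f*IQR] of the reference.

    ``fence_multiplier = 0`` reduces to the literal "outside the
    interquartile range" rule (which flags ~half of in-distribution
    subjects); the default 1.5 is the standard Tukey fence.
    """
    ref = np.asarray(reference_values, dtype=float)
    if len(ref) < 4:
        raise ValueError("reference needs n >= 4 for stable quartiles")
    if fence_multiplier < 0:
        raise ValueError("fence_multiplier must be >= 0")
    q1, q3 = np.quantile(ref, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - fence_multiplier * iqr, q3 + fence_multiplier * iqr
    new = np.asarray(new_values, dtype=float)
    return (new < lo) | (new > hi)


def kl_divergence(
    reference_values: Sequence[float],
    new_values: Sequence[float],
    bins: int = 32,
    smoothing: float = 1e-6,
    symmetric: bool = False,
) -> float:
    """Histogram KL divergence D(new || reference), in nats.

    Both samples are binned on a shared equal-width grid spanning the pooled
    range; ``smoothing`` is added to every bin of both histograms before
    normalization so the divergence stays finite.  ``symmetric=True``
    returns the Jensen–Shannon divergence instead.
    """
    ref = np.asarray(reference_values, dtype=float)
    new = np.asarray(new_values, dtype=float)
    if len(ref) < 10 or len(new) < 10:
        raise ValueError("both samples need n >= 10")
    pooled = np.concatenate([ref, new])
    lo, hi = pooled.min(), pooled.max()
    if lo == hi:
        raise ValueError("degenerate input: all pooled values identical")
    edges = np.linspace(lo, hi, bins + 1)
    q_ref, _ = np.histogram(ref, bins=edges)
    q_new, _ = np.histogram(new, bins=edges)
    p = q_new.astype(float) + smoothing
    q = q_ref.astype(float) + smoothing
    p /= p.sum()
    q /= q.sum()
    if symmetric:
        m = 0.5 * (p + q)
        return float(0.5 * np.sum(p * np.log(p / m)) + 0.5 * np.sum(q * np.log(q / m)))
    return float(np.sum(p * np.log(p / q)))


def compare_cohorts(
    table: pd.DataFrame,
    metric: str,
    contrasts: Sequence[tuple[str, str]],
    group_col: str = "cohort",
    q: float = 0.05,
) -> pd.DataFrame:
    """Welch tests over named cohort contrasts, jointly FDR-corrected.

    ``metric`` is a column of the cohort table (e.g. ``c_mi``); each
    contrast is a (group A, group B) pair of labels in ``group_col``.
    Output includes group means and IQRs alongside t, df, p, adjusted p and
    the rejection flag at level ``q``.
    """
    if metric not in table.columns:
        raise KeyError(f"unknown metric column {metric!r}")
    groups = {label: sub[metric].to_numpy(dtype=float) for label, sub in table.groupby(group_col)}
    rows = []
    for ga, gb in contrasts:
        for g in (ga, gb):
            if g not in groups:
                raise ValueError(f"contrast group {g!r} not present in table")
        a, b = groups[ga], groups[gb]
        t, df, p = welch_t(a, b)
        qa = np.quantile(a, [0.25, 0.75])
        qb = np.quantile(b, [0.25, 0.75])
        rows.append(
            {
                "contrast": f"{ga} vs {gb}",
                "metric": metric,
                "mean_a": float(a.mean()),
                "iqr_a": f"[{qa[0]:.4g}, {qa[1]:.4g}]",
                "mean_b": float(b.mean()),
                "iqr_b": f"[{qb[0]:.4g}, {qb[1]:.4g}]",
                "t": t,
                "df": df,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    p_adj, reject = bh_fdr(out["p"].to_numpy(), q=q)
    out["p_adj"] = p_adj
    out["reject"] = reject
    return out
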