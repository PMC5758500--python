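"""Test-retest reliability via the intraclass correlation ICC(A,k).

Two-way mixed-model ICC for absolute agreement of averaged measurements:
from the two-way ANOVA decomposition without replication (rows = subjects,
columns = sessions),

    ICC(A,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n)

Negative values are reported as computed (not clipped); the qualitative
bands are poor (<= 0.20), fair (<= 0.40), moderate (<= 0.60), strong
(<= 0.80), almost perfect (> 0.80).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["IccResult", "icc_a_k", "interpret_icc", "reliability_profile"]


@dataclass(frozen=True)
class IccResult:
    icc: float
    ms_r: float
    ms_c: float
    ms_e: float
    n: int
    k: int
    label: str


def icc_a_k(measurements: "np.ndarray | pd.DataFrame") -> IccResult:
    """ICC(A,k) of an n-subjects x k-sessions table with no missing cells."""
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2:
        raise ValueError("measurements must be a 2-D n x k table")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need n >= 2 subjects and k >= 2 sessions, got {n} x {k}")
    if not np.all(np.isfinite(x)):
        raise ValueError("measurements contain missing or non-finite cells")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_r = k * np.sum((row_means - grand) ** 2)
    ss_c = n * np.sum((col_means - grand) ** 2)
    ss_t = np.sum((x - grand) ** 2)
    ss_e = ss_t - ss_r - ss_c
    ms_r = ss_r / (n - 1)
    ms_c = ss_c / (k - 1)
    ms_e = max(ss_e / ((n - 1) * (k - 1)), 0.0)
    denom = ms_r + (ms_c - ms_e) / n
    if denom == 0.0:
        if ss_t == 0.0:
            warnings.warn(
                "all measurements identical; ICC defined as 1 (zero variance)",
                stacklevel=2,
            )
            icc = 1.0
        else:
            icc = np.nan
    else:
        icc = float((ms_r - ms_e) / denom)
    # a negative denominator (MS_R < (MS_E - MS_C)/n, agreement far worse
    # than chance) can push the ratio above 1; such values are labeled
    # undefined rather than banded
    label = interpret_icc(icc) if not np.isfinite(icc) or icc <= 1.0 else "undefined"
    return IccResult(
        icc=icc, ms_r=float(ms_r), ms_c=float(ms_c), ms_e=float(ms_e),
        n=n, k=k, label=label,
    )


def interpret_icc(value: float) -> str:
    """Map an ICC value into the five qualitative agreement bands."""
    if not np.isfinite(value):
        return "undefined"
    if value > 1.0:
        raise ValueError(f"ICC cannot exceed 1, got {value}")
    if value <= 0.20:
        return "poor"
    if value <= 0.40:
        return "fair"
    if value <= 0.60:
        return "moderate"
    if value <= 0.80:
        return "strong"
    return "almost perfect"


def reliability_profile(
    metric_table: pd.DataFrame,
    metrics: "tuple[str, ...]" = ("Q", "Eglob", "Eloc_mean"),
    groupings: "tuple[str, ...]" = ("all", "per-group"),
) -> pd.DataFrame:
    """ICC(A,k=2) per metric per density threshold (and the
    threshold-averaged 'mean' rows), for the pooled sample and each group.

    ``metric_table`` is the tidy per-subject x session x density table from
    :func:`restnet.metrics.compute_metric_tables`; every subject must have
    both sessions.
    """
    rows = []
    sessions = sorted(metric_table["session"].unique())
    if len(sessions) != 2:
        raise ValueError(f"need exactly 2 sessions, found {sessions}")
    scopes: list[tuple[str, pd.DataFrame]] = []
    if "all" in groupings:
        scopes.append(("all", metric_table))
    if "per-group" in groupings:
        for g, sub in metric_table.groupby("group"):
            scopes.append((str(g), sub))
    for scope, table in scopes:
        for density, dsub in table.groupby("density"):
            for metric in metrics:
                wide = dsub.pivot(index="subject_id", columns="session", values=metric)
                if wide.isna().any().any():
                    missing = wide[wide.isna().any(axis=1)].index.tolist()
                    raise ValueError(f"missing sessions for subjects: {missing}")
                res = icc_a_k(wide.to_numpy())
                rows.append(
                    dict(
                        grouping=scope,
                        density=density,
                        metric=metric,
                        icc=res.icc,
                        ms_r=res.ms_r,
                        ms_c=res.ms_c,
                        ms_e=res.ms_e,
                        label=res.label,
                    )
                )
    return pd.DataFrame(rows)
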