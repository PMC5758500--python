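"""Group-difference and brain-behavior inference.

Permutation tests on group mean differences, the max-statistic family-wise
error correction across a family of modules, Spearman and motion-partialled
Spearman correlations, per-subject piecewise-linear (spline) learning-curve
fits with a knot at the second training session, and the association of
baseline network metrics with early learning rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PermTestResult",
    "LearningSlopes",
    "AssociationResult",
    "permutation_group_test",
    "max_stat_fwe",
    "spearman",
    "partial_spearman",
    "fit_learning_slopes",
    "associate_metrics_learning",
]


@dataclass(frozen=True)
class PermTestResult:
    statistic: float
    null_distribution: np.ndarray
    p_value: float
    p_fwe: "float | None"
    n_permutations: int
    seed: "int | None" = None


@dataclass(frozen=True)
class LearningSlopes:
    subject_id: str
    early_slope: float
    late_slope: float
    residual_rms: float


@dataclass(frozen=True)
class AssociationResult:
    metric: str
    group: str
    session: int
    rho: float
    p_value: float
    rho_partial: float
    p_partial: float
    per_threshold: "dict[float, float]" = field(default_factory=dict)


def _group_masks(group_labels) -> tuple[np.ndarray, np.ndarray]:
    groups = np.asarray(group_labels)
    uniq = np.unique(groups)
    if uniq.size != 2:
        raise ValueError(f"exactly two groups required, found {uniq.tolist()}")
    g1 = groups == uniq[0]
    if g1.sum() < 2 or (~g1).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    return g1, ~g1


def permutation_group_test(
    values,
    group_labels,
    n_perm: int = 5000,
    seed: "int | None" = None,
) -> PermTestResult:
    """Two-sided permutation test on the difference of group means,
    shuffling group labels while retaining group sizes; p-values carry the
    finite-sample +1 correction."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x = np.asarray(values, dtype=float)
    g1, g2 = _group_masks(group_labels)
    observed = float(x[g1].mean() - x[g2].mean())
    rng = np.random.default_rng(seed)
    n1 = int(g1.sum())
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(x.shape[0])
        null[b] = x[perm[:n1]].mean() - x[perm[n1:]].mean()
    p = (1 + int(np.sum(np.abs(null) >= abs(observed)))) / (n_perm + 1)
    return PermTestResult(
        statistic=observed, null_distribution=null, p_value=p,
        p_fwe=None, n_permutations=n_perm, seed=seed,
    )


def max_stat_fwe(
    values_by_module: "dict | pd.DataFrame",
    group_labels,
    n_perm: int = 5000,
    seed: "int | None" = None,
) -> "dict[str, PermTestResult]":
    """Family-wise error-corrected group tests across a family of modules
    using the max-statistic method: one shared permutation stream records,
    per permutation, the maximum absolute mean difference over modules;
    each module's p_fwe compares its observed statistic to that null."""
    if isinstance(values_by_module, pd.DataFrame):
        values_by_module = {c: values_by_module[c].to_numpy() for c in values_by_module}
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    names = list(values_by_module)
    mat = np.stack([np.asarray(values_by_module[m], dtype=float) for m in names])
    g1, g2 = _group_masks(group_labels)
    n1 = int(g1.sum())
    observed = mat[:, g1].mean(axis=1) - mat[:, g2].mean(axis=1)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(names)))
    for b in range(n_perm):
        perm = rng.permutation(mat.shape[1])
        null[b] = mat[:, perm[:n1]].mean(axis=1) - mat[:, perm[n1:]].mean(axis=1)
    max_null = np.abs(null).max(axis=1)
    out: dict[str, PermTestResult] = {}
    for i, name in enumerate(names):
        p_unc = (1 + int(np.sum(np.abs(null[:, i]) >= abs(observed[i])))) / (n_perm + 1)
        p_fwe = (1 + int(np.sum(max_null >= abs(observed[i])))) / (n_perm + 1)
        out[name] = PermTestResult(
            statistic=float(observed[i]),
            null_distribution=null[:, i],
            p_value=p_unc,
            p_fwe=max(p_fwe, p_unc),
            n_permutations=n_perm,
            seed=seed,
        )
    return out


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties; t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.shape[0] < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector has no rank correlation")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def partial_spearman(x, y, covariate) -> tuple[float, float]:
    """Spearman correlation of x and y controlling for a covariate:
    rank-transform all three, residualize the x- and y-ranks on the
    covariate ranks by least squares, and correlate the residuals. A
    constant covariate falls back to the plain Spearman with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if not (x.shape == y.shape == c.shape) or x.ndim != 1:
        raise ValueError("x, y and covariate must be equal-length 1-D vectors")
    n = x.shape[0]
    if n < 5:
        raise ValueError("need at least 5 observations")
    if np.all(c == c[0]):
        warnings.warn(
            "constant covariate; falling back to plain Spearman", stacklevel=2
        )
        return spearman(x, y)
    rx, ry, rc = (stats.rankdata(v) for v in (x, y, c))
    design = np.column_stack([np.ones(n), rc])
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    # a variable fully explained by the covariate leaves only numerical
    # noise in its residual; the partial correlation is 0 by definition
    scale = np.sqrt(n)
    if res_x.std() < 1e-9 * scale or res_y.std() < 1e-9 * scale:
        return 0.0, 1.0
    rho = float(np.corrcoef(res_x, res_y)[0, 1])
    # t-approximation with one covariate partialled out
    df = n - 3
    t = rho * np.sqrt(df / max(1e-300, 1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p


def fit_learning_slopes(
    scores,
    sessions=None,
    knot: int = 2,
    subject_id: str = "",
) -> LearningSlopes:
    """Per-subject least-squares fit of score ~ 1 + s + (s - knot)_+.

    ``early_slope`` is the coefficient on s (the session-1 -> knot rate);
    ``late_slope`` is the sum of the two slope coefficients (the rate after
    the knot).
    """
    y = np.asarray(scores, dtype=float)
    if y.ndim != 1 or y.shape[0] < 3:
        raise ValueError("need at least 3 training sessions")
    if not np.all(np.isfinite(y)):
        raise ValueError("scores contain non-finite values")
    s = (
        np.arange(1, y.shape[0] + 1, dtype=float)
        if sessions is None
        else np.asarray(sessions, dtype=float)
    )
    if s.shape != y.shape:
        raise ValueError("sessions and scores must align")
    if not s.min() <= knot <= s.max():
        raise ValueError(f"knot {knot} outside session range [{s.min()}, {s.max()}]")
    design = np.column_stack([np.ones_like(s), s, np.maximum(s - knot, 0.0)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return LearningSlopes(
        subject_id=subject_id,
        early_slope=float(coef[1]),
        late_slope=float(coef[1] + coef[2]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def slopes_from_curves(learning: pd.DataFrame, knot: int = 2) -> pd.DataFrame:
    """Fit learning slopes for every subject in a tidy curve table with
    columns subject_id, session, score."""
    rows = []
    for sid, sub in learning.groupby("subject_id"):
        sub = sub.sort_values("session")
        fit = fit_learning_slopes(
            sub["score"].to_numpy(), sub["session"].to_numpy(), knot=knot,
            subject_id=str(sid),
        )
        rows.append(
            dict(
                subject_id=fit.subject_id,
                early_slope=fit.early_slope,
                late_slope=fit.late_slope,
                residual_rms=fit.residual_rms,
            )
        )
    return pd.DataFrame(rows)


def associate_metrics_learning(
    metric_table: pd.DataFrame,
    slopes: pd.DataFrame,
    motion: pd.DataFrame,
    metrics: "tuple[str, ...]" = ("Q", "Eglob", "Eloc_mean"),
) -> "list[AssociationResult]":
    """Spearman association of threshold-averaged brain-wide metrics with
    early learning slopes, separately per group and session, with
    per-threshold rho curves and motion-partialled rho.

    ``metric_table`` is the tidy table from ``compute_metric_tables``;
    ``slopes`` has columns subject_id, early_slope; ``motion`` has columns
    subject_id, motion. Raises when subject sets do not match.
    """
    slope_map = dict(zip(slopes["subject_id"], slopes["early_slope"]))
    motion_map = dict(zip(motion["subject_id"], motion["motion"]))
    results: list[AssociationResult] = []
    for (group, session), sub in metric_table.groupby(["group", "session"]):
        subjects = sorted(sub["subject_id"].unique())
        missing = [s for s in subjects if s not in slope_map or s not in motion_map]
        if missing:
            raise ValueError(f"subjects missing slopes or motion: {missing}")
        y = np.array([slope_map[s] for s in subjects])
        cov = np.array([motion_map[s] for s in subjects])
        mean_rows = sub[sub["density"] == "mean"].set_index("subject_id")
        for metric in metrics:
            x = mean_rows.loc[subjects, metric].to_numpy(dtype=float)
            rho, p = spearman(x, y)
            rho_p, p_p = partial_spearman(x, y, cov)
            per_thr: dict[float, float] = {}
            for d, dsub in sub[sub["density"] != "mean"].groupby("density"):
                xd = dsub.set_index("subject_id").loc[subjects, metric].to_numpy(dtype=float)
                per_thr[float(d)] = spearman(xd, y)[0]
            results.append(
                AssociationResult(
                    metric=metric,
                    group=str(group),
                    session=int(session),
                    rho=rho,
                    p_value=p,
                    rho_partial=rho_p,
                    p_partial=p_p,
                    per_threshold=per_thr,
                )
            )
    return results
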