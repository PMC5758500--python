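"""Synthetic two-group, two-session resting-state cohort generator.

Emulates the statistical structure the downstream analysis assumes: modular
(block) correlation structure among ROIs, a planted group difference (the
"older" group has weaker within-module and stronger between-module coupling),
subject-level jitter on coupling, tunable session-to-session reliability, a
per-subject head-motion scalar, and multi-session training learning curves
whose early gain is coupled to each subject's planted network coupling.

Time series are sampled i.i.d. over time from a zero-mean multivariate
normal; temporal autocorrelation and scanner artifacts are deliberately not
modelled — only the correlation structure matters downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "CohortData",
    "build_block_covariance",
    "sample_cohort",
    "default_config",
    "reduced_config",
]

GROUP_LABELS = ("young", "older")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a two-group, two-session cohort.

    Correlations are Pearson r on the raw scale. ``r_within_by_group`` /
    ``r_between_by_group`` are ordered as :data:`GROUP_LABELS` (young, older).
    ``session_reliability`` in [0, 1] sets the fraction of a subject's
    coupling jitter that is shared between the two sessions (1 = identical
    generative covariance in both sessions). ``learning_coupling`` is the
    early learning gain (set-size units) per standard deviation of a
    subject's planted within-module coupling jitter.
    """

    n_nodes: int = 234
    module_sizes: tuple[int, ...] = (60, 50, 45, 40, 39)
    n_subjects_per_group: int = 20
    n_timepoints: int = 235
    r_within_by_group: tuple[float, float] = (0.45, 0.22)
    r_between_by_group: tuple[float, float] = (0.05, 0.13)
    subject_sd: float = 0.05
    session_reliability: float = 0.8
    motion_mean_by_group: tuple[float, float] = (0.10, 0.14)
    motion_sd: float = 0.03
    learning_coupling: float = 0.5
    learning_noise_sd: float = 0.2
    n_training_sessions: int = 10
    seed: int = 0
    # learning-curve shape: linear rise to the knot, slower rise afterwards
    learning_baseline: float = 3.0
    learning_base_gain: float = 1.5
    learning_late_rate: float = 0.2

    def __post_init__(self) -> None:
        if sum(self.module_sizes) != self.n_nodes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)}, "
                f"expected n_nodes={self.n_nodes}"
            )
        for r in (*self.r_within_by_group, *self.r_between_by_group):
            if not -1.0 < r < 1.0:
                raise ValueError(f"correlation {r} outside (-1, 1)")
        for rw, rb in zip(self.r_within_by_group, self.r_between_by_group):
            if rw <= rb:
                raise ValueError(
                    f"planted structure requires r_within > r_between, got {rw} <= {rb}"
                )
        if not 0.0 <= self.session_reliability <= 1.0:
            raise ValueError("session_reliability must lie in [0, 1]")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.n_training_sessions < 3:
            raise ValueError("n_training_sessions must be >= 3 for spline fitting")


@dataclass
class CohortData:
    """In-memory cohort: manifest, per-(subject, session) time series,
    learning curves, and the planted-truth table of generative parameters."""

    manifest: pd.DataFrame
    timeseries: dict[tuple[str, int], np.ndarray]
    learning: pd.DataFrame
    truth: pd.DataFrame
    node_ids: list[str]


def build_block_covariance(
    module_sizes: "list[int] | tuple[int, ...]",
    r_within: float,
    r_between: float,
) -> np.ndarray:
    """Block-structured correlation matrix: unit diagonal, ``r_within`` for
    same-module pairs, ``r_between`` otherwise.

    Raises ``ValueError`` (naming the smallest eigenvalue) if the requested
    parameters do not yield a positive semi-definite matrix.
    """
    sizes = np.asarray(module_sizes, dtype=int)
    if sizes.ndim != 1 or len(sizes) == 0 or np.any(sizes <= 0):
        raise ValueError("module_sizes must be a non-empty list of positive counts")
    n = int(sizes.sum())
    labels = np.repeat(np.arange(len(sizes)), sizes)
    same = labels[:, None] == labels[None, :]
    cov = np.where(same, r_within, r_between).astype(float)
    np.fill_diagonal(cov, 1.0)
    min_eig = float(np.linalg.eigvalsh(cov)[0])
    if min_eig < -1e-10:
        raise ValueError(
            f"covariance not positive semi-definite for r_within={r_within}, "
            f"r_between={r_between}: smallest eigenvalue {min_eig:.6g}"
        )
    return cov


def _module_labels(config: SimulationConfig) -> np.ndarray:
    return np.repeat(np.arange(len(config.module_sizes)), config.module_sizes)


def _sample_session_timeseries(
    rng: np.random.Generator, cov: np.ndarray, n_timepoints: int
) -> np.ndarray:
    # cholesky with a tiny jitter guards against exactly-singular PSD inputs
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(cov)))
    z = rng.standard_normal((n_timepoints, len(cov)))
    return z @ chol.T


def sample_cohort(config: SimulationConfig, out_dir: "Path | str | None" = None) -> CohortData:
    """Draw a full synthetic cohort; optionally write it to ``out_dir``.

    Each subject's two sessions share the subject-level coupling jitter in
    proportion ``sqrt(session_reliability)`` and receive independent
    session-level jitter in proportion ``sqrt(1 - session_reliability)``, so
    reliability 1 gives identical generative covariances across sessions.
    The learning curve rises by ``base_gain + coupling * z + noise`` from
    training session 1 to 2 and by ``late_rate`` per session thereafter,
    where z is the subject's standardized coupling jitter.

    Returns a :class:`CohortData`; when ``out_dir`` is given, also writes
    TSV time series, ``manifest.csv``, ``learning_curves.csv`` and
    ``planted_truth.csv`` and fills ``timeseries_path`` in the manifest.
    """
    rng = np.random.default_rng(config.seed)
    node_ids = [f"roi{j:03d}" for j in range(config.n_nodes)]

    out_path: Path | None = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)

    rho = config.session_reliability
    w_shared, w_sess = np.sqrt(rho), np.sqrt(1.0 - rho)

    manifest_rows, truth_rows, learning_rows = [], [], []
    timeseries: dict[tuple[str, int], np.ndarray] = {}

    for g_idx, group in enumerate(GROUP_LABELS):
        r_w = config.r_within_by_group[g_idx]
        r_b = config.r_between_by_group[g_idx]
        for s_idx in range(config.n_subjects_per_group):
            sid = f"{group[0]}{s_idx + 1:02d}"
            z_subj = float(rng.standard_normal())
            motion = float(
                abs(rng.normal(config.motion_mean_by_group[g_idx], config.motion_sd))
            )
            r_sessions = []
            for session in (1, 2):
                z_sess = float(rng.standard_normal())
                jitter = config.subject_sd * (w_shared * z_subj + w_sess * z_sess)
                r_ws = float(np.clip(r_w + jitter, r_b + 0.01, 0.97))
                r_sessions.append(r_ws)
                cov = build_block_covariance(config.module_sizes, r_ws, r_b)
                ts = _sample_session_timeseries(rng, cov, config.n_timepoints)
                timeseries[(sid, session)] = ts
                ts_path = ""
                if out_path is not None:
                    ts_file = out_path / f"{sid}_ses{session}.tsv"
                    pd.DataFrame(ts, columns=node_ids).to_csv(
                        ts_file, sep="\t", index=False, float_format="%.6f"
                    )
                    ts_path = str(ts_file)
                manifest_rows.append(
                    dict(
                        subject_id=sid,
                        group=group,
                        session=session,
                        timeseries_path=ts_path,
                        motion=motion,
                    )
                )

            early_gain = (
                config.learning_base_gain
                + config.learning_coupling * z_subj
                + float(rng.normal(0.0, config.learning_noise_sd))
            )
            sessions = np.arange(1, config.n_training_sessions + 1)
            scores = (
                config.learning_baseline
                + early_gain * (np.minimum(sessions, 2) - 1)
                + config.learning_late_rate * np.maximum(sessions - 2, 0)
            )
            for s, score in zip(sessions, scores):
                learning_rows.append(
                    dict(subject_id=sid, session=int(s), score=float(score))
                )
            truth_rows.append(
                dict(
                    subject_id=sid,
                    group=group,
                    z_subject=z_subj,
                    r_within_target=r_w,
                    r_between=r_b,
                    r_within_session1=r_sessions[0],
                    r_within_session2=r_sessions[1],
                    motion=motion,
                    early_gain=early_gain,
                    late_rate=config.learning_late_rate,
                )
            )

    manifest = pd.DataFrame(manifest_rows)
    learning = pd.DataFrame(learning_rows)
    truth = pd.DataFrame(truth_rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
        learning.to_csv(out_path / "learning_curves.csv", index=False)
        truth.to_csv(out_path / "planted_truth.csv", index=False)
    return CohortData(
        manifest=manifest,
        timeseries=timeseries,
        learning=learning,
        truth=truth,
        node_ids=node_ids,
    )


def planted_module_labels(config: SimulationConfig) -> np.ndarray:
    """Ground-truth node -> module labels implied by ``module_sizes``."""
    return _module_labels(config)


def default_config(**overrides) -> SimulationConfig:
    """Study-scale defaults: 234 ROIs in 5 modules, 20 subjects/group,
    235 time points per session."""
    return dataclasses.replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


def reduced_config(**overrides) -> SimulationConfig:
    """Desk-scale profile for tests and quick runs: 60 ROIs in 5 modules of
    12, 10 subjects/group, 200 time points."""
    base = SimulationConfig(
        n_nodes=60,
        module_sizes=(12, 12, 12, 12, 12),
        n_subjects_per_group=10,
        n_timepoints=200,
    )
    return dataclasses.replace(base, **overrides) if overrides else base
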