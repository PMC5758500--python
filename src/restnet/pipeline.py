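"""End-to-end orchestration: cohort -> connectivity -> consensus partitions
-> metrics -> similarity -> reliability -> learning associations.

``run_pipeline`` executes every stage in dependency order on an in-memory
cohort (or one loaded from a manifest), derives every stage seed from one
master seed, and returns a machine-readable summary (also written to
``summary.json``, stamped with a hash of the analysis-relevant config).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, connectivity, inference, metrics, reliability, similarity
from .community import ConsensusParams, Partition
from .synthetic import CohortData

logger = logging.getLogger("restnet")

__all__ = [
    "PipelineConfig",
    "paper_profile",
    "reduced_profile",
    "config_hash",
    "validate_inputs",
    "load_cohort",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis parameters.

    Defaults follow the full-scale analysis: density grid 2-10% in 1%
    steps, Louvain resolution gamma = 1.25, agreement threshold tau = 0.5,
    500 Louvain repetitions per consensus stage, 5,000 permutations, and
    edge FDR at q < 0.05.
    """

    thresholds: tuple[float, ...] = metrics.DEFAULT_THRESHOLDS
    gamma: float = 1.25
    tau: float = 0.5
    runs: int = 500
    n_perm: int = 5000
    fdr_q: float = 0.05
    knot: int = 2
    seed: int = 0
    out_dir: "str | None" = None

    def __post_init__(self) -> None:
        if not all(0.0 < d < 1.0 for d in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1)")
        if min(self.runs, self.n_perm) < 1:
            raise ValueError("runs and n_perm must be positive")


def paper_profile(**overrides) -> PipelineConfig:
    """Full-fidelity parameters (500 runs, 5,000 permutations)."""
    return dataclasses.replace(PipelineConfig(), **overrides)


def reduced_profile(**overrides) -> PipelineConfig:
    """Desk-scale profile for tests and demos: 20 Louvain runs per stage and
    200 permutations; all scientific defaults unchanged."""
    base = PipelineConfig(runs=20, n_perm=200)
    return dataclasses.replace(base, **overrides)


def load_config(path: "str | Path") -> PipelineConfig:
    """Read a :class:`PipelineConfig` from a YAML or JSON file; unknown
    keys are rejected, absent keys keep their defaults."""
    import yaml

    payload = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(payload, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(payload) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "thresholds" in payload:
        payload["thresholds"] = tuple(payload["thresholds"])
    return PipelineConfig(**payload)


_HASH_EXCLUDE = {"out_dir"}


def config_hash(config: PipelineConfig) -> str:
    """Stable hash over the analysis-relevant configuration fields."""
    payload = {
        k: v
        for k, v in dataclasses.asdict(config).items()
        if k not in _HASH_EXCLUDE
    }
    blob = json.dumps(payload, sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_inputs(
    manifest: pd.DataFrame,
    timeseries: "dict[tuple[str, int], np.ndarray]",
    learning: "pd.DataFrame | None" = None,
) -> "list[dict]":
    """Structural checks on a cohort; returns a list of issue records
    (never raises)."""
    issues: list[dict] = []
    required = {"subject_id", "group", "session", "motion"}
    missing_cols = required - set(manifest.columns)
    if missing_cols:
        issues.append(dict(kind="manifest", detail=f"missing columns {sorted(missing_cols)}"))
        return issues
    dup = manifest.duplicated(["subject_id", "session"])
    if dup.any():
        issues.append(
            dict(kind="duplicate", detail=f"duplicated subject-session rows: "
                 f"{manifest.loc[dup, 'subject_id'].tolist()}")
        )
    shapes = {k: v.shape for k, v in timeseries.items()}
    expected_n = None
    for key, shape in shapes.items():
        if len(shape) != 2 or shape[0] < 2:
            issues.append(dict(kind="dimension", detail=f"{key}: bad shape {shape}"))
            continue
        if expected_n is None:
            expected_n = shape[1]
        elif shape[1] != expected_n:
            issues.append(
                dict(kind="dimension",
                     detail=f"{key}: {shape[1]} nodes, expected {expected_n}")
            )
    for key, arr in timeseries.items():
        if not np.all(np.isfinite(arr)):
            issues.append(dict(kind="finiteness", detail=f"{key}: non-finite values"))
    for sid, sub in manifest.groupby("subject_id"):
        sessions = set(sub["session"])
        if sessions != {1, 2}:
            issues.append(
                dict(kind="completeness", detail=f"{sid}: sessions {sorted(sessions)}")
            )
        for _, row in sub.iterrows():
            if (row["subject_id"], row["session"]) not in timeseries:
                issues.append(
                    dict(kind="missing-data",
                         detail=f"{sid} session {row['session']}: no time series")
                )
    if learning is not None:
        manifest_subjects = set(manifest["subject_id"])
        learning_subjects = set(learning["subject_id"])
        unmatched = manifest_subjects ^ learning_subjects
        if unmatched:
            issues.append(
                dict(kind="subject-match",
                     detail=f"subjects not in both manifest and learning: {sorted(unmatched)}")
            )
    return issues


def load_cohort(manifest_path: "str | Path", learning_path: "str | Path | None" = None) -> CohortData:
    """Load a cohort from a manifest CSV whose ``timeseries_path`` entries
    point to TSV time-series files."""
    manifest = pd.read_csv(manifest_path)
    timeseries = {}
    node_ids: list[str] = []
    for _, row in manifest.iterrows():
        df = connectivity.read_timeseries(row["timeseries_path"])
        node_ids = [str(c) for c in df.columns]
        timeseries[(row["subject_id"], int(row["session"]))] = df.to_numpy(dtype=float)
    learning = pd.read_csv(learning_path) if learning_path else pd.DataFrame(
        columns=["subject_id", "session", "score"]
    )
    return CohortData(
        manifest=manifest, timeseries=timeseries, learning=learning,
        truth=pd.DataFrame(), node_ids=node_ids,
    )


def _per_threshold_best_partitions(
    C, thresholds, gamma, runs, seed_seq
) -> "list[Partition]":
    parts = []
    for d, child in zip(thresholds, seed_seq.spawn(len(thresholds))):
        G = connectivity.threshold_density(C, float(d))
        part, _ = community.best_partition(
            np.asarray(G.adjacency, dtype=float), gamma, runs, child
        )
        parts.append(part)
    return parts


def run_pipeline(config: PipelineConfig, cohort: CohortData) -> dict:
    """Run the full analysis and return the result bundle.

    Stages: connectivity -> subject/group consensus -> canonical module
    assignment -> brain-wide and per-module metric tables -> partition-
    similarity permutation tests -> ICC reliability -> group-difference
    tests -> learning-slope associations. Any stage failure raises with the
    stage name attached.
    """
    master = np.random.SeedSequence(config.seed)
    (s_subject, s_group, s_metrics, s_parts, s_sim, s_infer) = master.spawn(6)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    manifest = cohort.manifest.sort_values(["group", "subject_id", "session"])
    subjects = manifest[["subject_id", "group"]].drop_duplicates()
    groups = dict(zip(subjects["subject_id"], subjects["group"]))
    group_names = sorted(set(groups.values()))
    if len(group_names) != 2:
        raise RuntimeError(f"stage connectivity: expected 2 groups, found {group_names}")
    stage = "connectivity"
    try:
        conn: dict[tuple[str, int], connectivity.ConnectivityMatrix] = {}
        for key, ts in cohort.timeseries.items():
            conn[key] = connectivity.correlation_matrix(ts, node_ids=cohort.node_ids)
        logger.info("connectivity: %d matrices", len(conn))

        stage = "subject consensus"
        keys = sorted(conn)
        subj_parts: dict[tuple[str, int], Partition] = {}
        for key, child in zip(keys, s_subject.spawn(len(keys))):
            params = ConsensusParams(
                gamma=config.gamma, tau=config.tau, runs=config.runs,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            subj_parts[key] = community.subject_consensus(conn[key], params)
        logger.info("subject consensus partitions: %d", len(subj_parts))

        stage = "group consensus"
        group_parts: dict[str, Partition] = {}
        for (g, ses), child in zip(
            [(g, s) for g in group_names for s in (1, 2)], s_group.spawn(4)
        ):
            members = [
                subj_parts[(sid, ses)] for sid in groups if groups[sid] == g
            ]
            params = ConsensusParams(
                gamma=config.gamma, tau=config.tau, runs=config.runs,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            group_parts[f"{g}|{ses}"] = community.group_consensus(members, params)
        assignment = metrics.consistent_nodes(group_parts)
        logger.info(
            "canonical assignment: %d consistent nodes, %d modules",
            int(assignment.consistent.sum()), assignment.modules.size,
        )

        stage = "per-threshold partitions"
        thresh_parts: dict[tuple[str, int], list[Partition]] = {}
        for key, child in zip(keys, s_parts.spawn(len(keys))):
            thresh_parts[key] = _per_threshold_best_partitions(
                conn[key], config.thresholds, config.gamma, config.runs, child
            )

        stage = "metrics"
        fdr_graphs = {
            key: {
                sign: connectivity.threshold_fdr(conn[key], config.fdr_q, sign)
                for sign in ("positive", "negative")
            }
            for key in keys
        }
        metric_table, module_table, conn_table = metrics.compute_metric_tables(
            conn, groups, assignment=assignment, thresholds=config.thresholds,
            gamma=config.gamma, runs=config.runs,
            seed=int(s_metrics.generate_state(1)[0] % (2**31)),
            fdr_graphs=fdr_graphs,
        )

        stage = "similarity"
        sim_seeds = s_sim.spawn(6)
        sim_results: dict[str, dict] = {}
        sid_by_group = {
            g: sorted(s for s, gg in groups.items() if gg == g) for g in group_names
        }
        for i, ses in enumerate((1, 2)):
            parts1 = [thresh_parts[(sid, ses)] for sid in sid_by_group[group_names[0]]]
            parts2 = [thresh_parts[(sid, ses)] for sid in sid_by_group[group_names[1]]]
            bg = similarity.between_group_test(
                parts1, parts2, config.n_perm,
                seed=int(sim_seeds[i].generate_state(1)[0] % (2**31)),
            )
            wg = similarity.within_group_similarity_test(
                parts1, parts2, config.n_perm,
                seed=int(sim_seeds[2 + i].generate_state(1)[0] % (2**31)),
            )
            sim_results[f"session{ses}"] = dict(
                between=dict(observed=bg.observed, p=bg.p_value,
                             significant_low=bool(bg.significant_low)),
                within={
                    g: dict(observed=wg[k].observed, p_two_sided=wg[k].p_two_sided)
                    for g, k in zip(group_names, ("group1", "group2"))
                },
            )
        all_sids = sorted(groups)
        over_time, per_subject_nmi = similarity.within_subject_over_time_test(
            [thresh_parts[(sid, 1)] for sid in all_sids],
            [thresh_parts[(sid, 2)] for sid in all_sids],
            [groups[sid] for sid in all_sids],
            config.n_perm,
            seed=int(sim_seeds[4].generate_state(1)[0] % (2**31)),
        )

        stage = "reliability"
        icc_table = reliability.reliability_profile(metric_table)

        stage = "group differences"
        infer_seeds = s_infer.spawn(8)
        mean_rows = metric_table[metric_table["density"] == "mean"]
        group_tests: dict[str, dict] = {}
        for i, ses in enumerate((1, 2)):
            sub = mean_rows[mean_rows["session"] == ses].sort_values("subject_id")
            labels = sub["group"].to_numpy()
            per_metric = {}
            for j, m in enumerate(("Q", "Eglob", "Eloc_mean")):
                res = inference.permutation_group_test(
                    sub[m].to_numpy(), labels, config.n_perm,
                    seed=int(infer_seeds[i].generate_state(1)[0] % (2**31)) + j,
                )
                per_metric[m] = dict(difference=res.statistic, p=res.p_value)
            group_tests[f"session{ses}"] = per_metric
        module_tests: dict[str, dict] = {}
        if module_table is not None:
            for i, ses in enumerate((1, 2)):
                sub = module_table[
                    (module_table["session"] == ses)
                    & (module_table["density"] == "mean")
                ]
                for k, m in enumerate(("participation", "local_efficiency")):
                    wide = sub.pivot(index="subject_id", columns="module", values=m)
                    order = wide.index.to_numpy()
                    fam = inference.max_stat_fwe(
                        {str(c): wide[c].to_numpy() for c in wide.columns},
                        [groups[s] for s in order],
                        config.n_perm,
                        seed=int(infer_seeds[2 + i].generate_state(1)[0] % (2**31)) + k,
                    )
                    module_tests[f"session{ses}|{m}"] = {
                        mod: dict(difference=r.statistic, p=r.p_value, p_fwe=r.p_fwe)
                        for mod, r in fam.items()
                    }

        connectivity_tests: dict[str, dict] = {}
        if conn_table is not None:
            for i, ses in enumerate((1, 2)):
                for j, sign in enumerate(("positive", "negative")):
                    sub = conn_table[
                        (conn_table["session"] == ses) & (conn_table["sign"] == sign)
                    ]
                    for k, kind in enumerate(("within", "between")):
                        part = sub[sub["kind"] == kind].copy()
                        if part.empty:
                            continue
                        part["pair"] = (
                            part["module_a"].astype(str) + "-" + part["module_b"].astype(str)
                        )
                        wide = part.pivot(
                            index="subject_id", columns="pair", values="value"
                        ).dropna(axis=1)
                        if wide.shape[1] == 0:
                            continue
                        order = wide.index.to_numpy()
                        fam = inference.max_stat_fwe(
                            {str(c): wide[c].to_numpy() for c in wide.columns},
                            [groups[s] for s in order],
                            config.n_perm,
                            seed=int(infer_seeds[4 + i].generate_state(1)[0] % (2**31))
                            + 2 * j + k,
                        )
                        connectivity_tests[f"session{ses}|{sign}|{kind}"] = {
                            pair: dict(difference=r.statistic, p=r.p_value, p_fwe=r.p_fwe)
                            for pair, r in fam.items()
                        }

        stage = "learning associations"
        associations: list = []
        slopes = pd.DataFrame()
        if len(cohort.learning):
            slopes = inference.slopes_from_curves(cohort.learning, knot=config.knot)
            motion = manifest[["subject_id", "motion"]].drop_duplicates("subject_id")
            associations = inference.associate_metrics_learning(
                metric_table[metric_table["subject_id"].isin(slopes["subject_id"])],
                slopes, motion,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    summary = dict(
        config_hash=config_hash(config),
        seed=config.seed,
        n_subjects={g: len(sid_by_group[g]) for g in group_names},
        consistent_nodes=int(assignment.consistent.sum()),
        n_modules=int(assignment.modules.size),
        group_means={
            g: {
                m: float(mean_rows[mean_rows["group"] == g][m].mean())
                for m in ("Q", "Eglob", "Eloc_mean")
            }
            for g in group_names
        },
        similarity=sim_results,
        over_time=dict(
            statistic=over_time.statistic, p=over_time.p_value,
            per_group_mean_nmi={
                g: float(np.mean([per_subject_nmi[i] for i, sid in enumerate(all_sids)
                                  if groups[sid] == g]))
                for g in group_names
            },
        ),
        icc={
            f"{r.grouping}|{r.metric}": round(float(r.icc), 10)
            for r in icc_table[icc_table["density"] == "mean"].itertuples()
        },
        group_tests=group_tests,
        module_tests=module_tests,
        module_connectivity_tests=connectivity_tests,
        associations=[
            dict(metric=a.metric, group=a.group, session=a.session,
                 rho=a.rho, p=a.p_value, rho_partial=a.rho_partial,
                 p_partial=a.p_partial)
            for a in associations
        ],
    )

    results = dict(
        summary=summary,
        metric_table=metric_table,
        module_table=module_table,
        connectivity_table=conn_table,
        icc_table=icc_table,
        group_partitions=group_parts,
        assignment=assignment,
        subject_partitions=subj_parts,
        slopes=slopes,
    )
    if out_dir:
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        metric_table.to_csv(out_dir / "metric_table.csv", index=False)
        if module_table is not None:
            module_table.to_csv(out_dir / "module_metric_table.csv", index=False)
        if conn_table is not None:
            conn_table.to_csv(out_dir / "module_connectivity.csv", index=False)
        icc_table.to_csv(out_dir / "icc_table.csv", index=False)
        parts_df = pd.DataFrame(
            {cell: part.labels for cell, part in group_parts.items()}
        )
        parts_df.insert(0, "node_id", cohort.node_ids)
        parts_df.to_csv(out_dir / "group_partitions.csv", index=False)
        if len(slopes):
            slopes.to_csv(out_dir / "learning_slopes.csv", index=False)
    return results
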