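# restnet

Graph-theoretic analysis of resting-state functional brain networks for
aging studies: from ROI time series to consensus community structure,
brain-wide and per-module network metrics, their test-retest reliability,
and their association with subsequent learning during cognitive training.

## The problem

Healthy aging reorganizes the brain's large-scale functional networks:
within-module coupling weakens and between-module coupling strengthens
("dedifferentiation"), which shows up topologically as lower modularity and
local efficiency. Quantifying this requires a long pipeline — connectivity
estimation, degeneracy-aware community detection, density-matched graph
metrics, permutation inference, reliability analysis — in which every step
has knobs that matter. `restnet` packages that pipeline for a two-group
(young / older), two-session cohort design, together with a synthetic
cohort generator that plants known group differences, session reliability
and brain-behavior coupling, so every stage is testable against ground
truth without access to human data.

## The model

Per subject and session, an N×N connectivity matrix holds Fisher-z
transformed Pearson correlations between ROI time courses. Graphs are built
two ways: binarized at matched connection densities d ∈ {2%, …, 10%} (the
top K = round(d·N(N−1)/2) connections), and FDR-thresholded (Benjamini–
Hochberg, q < 0.05, positive and negative edges separately) keeping signed
weights.

Community structure comes from Louvain maximization of modularity

    Q = (1/2m) Σ_ij [W_ij − γ·s_i s_j/2m] δ(m_i, m_j)

at resolution γ = 1.25, stabilized by iterative fine-tuning and two-level
consensus clustering (subject ensembles → agreement matrix thresholded at
τ = 0.5 → re-partition until unanimity; then the same across subjects per
group). Brain-wide metrics are the modularity score (mean best Q over R
Louvain runs), global efficiency E_glob = ⟨1/L_ij⟩, and mean local
efficiency (efficiency of each node's neighbor subgraph). Module-level
metrics (participation coefficient P(i) = 1 − Σ_m (k_i(m)/k_i)², local
efficiency, FDR-weighted within/between-module connectivity) are computed
over nodes consistently assigned to the same module across all four
group-session partitions.

Inference is permutation-based throughout: partition similarity by NMI with
group-label shuffling, metric group differences by mean-difference
shuffling, module families corrected by the max-statistic method.
Reliability across sessions is ICC(A,k); learning curves are fit per
subject with a linear spline (knot at training session 2) whose early slope
is correlated (Spearman, optionally motion-partialled) with baseline
metrics.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

Generate a desk-scale synthetic cohort (60 ROIs in 5 modules, 10 subjects
per group, 2 sessions) and run the full pipeline:

```python
from restnet import synthetic, pipeline

cohort = synthetic.sample_cohort(synthetic.reduced_config(seed=42))
config = pipeline.reduced_profile(seed=1, out_dir="out")
results = pipeline.run_pipeline(config, cohort)

s = results["summary"]
print("threshold-averaged Q:",
      {g: round(m["Q"], 3) for g, m in s["group_means"].items()})
print("Q group test (t1):", s["group_tests"]["session1"]["Q"])
print("between-group NMI p (t1):", s["similarity"]["session1"]["between"]["p"])
print("ICC(Q), all subjects:", s["icc"]["all|Q"])
```

prints

```
threshold-averaged Q: {'older': 0.555, 'young': 0.677}
Q group test (t1): {'difference': -0.09782098622113988, 'p': 0.03482587064676617}
between-group NMI p (t1): 0.08955223880597014
ICC(Q), all subjects: 0.8494657074
```

The older group's planted dedifferentiation (weaker within-module, stronger
between-module coupling) is recovered as a lower modularity score
(0.56 vs 0.68, permutation p ≈ 0.035), and the modularity score is reliable
across the two sessions (ICC ≈ 0.85, "almost perfect" band). The
between-group NMI test lands at p ≈ 0.09 for this particular cohort draw —
with 10 subjects per group and 200 permutations its power is modest, and
across cohort seeds it fluctuates around the 5% level (the acceptance run
below, at a different seed, detects it at p ≈ 0.005). The same run yields
per-module metric tables,
within/between-module connectivity, learning-slope associations
(`results["summary"]["associations"]`), and writes tidy CSVs plus
`summary.json` to `out/`.

The same stages are scriptable from the shell:

```bash
restnet simulate --out cohort --seed 42 --profile reduced
restnet all cohort/manifest.csv cohort/learning_curves.csv --out results_dir --seed 1
```

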