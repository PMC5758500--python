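# Methods

`restnet` implements a graph-theoretic analysis of resting-state functional
brain connectivity for a two-group (young / older), two-session cohort:
consensus community detection, brain-wide and per-module network metrics,
partition-similarity permutation tests, test-retest reliability, and the
association of baseline network properties with subsequent learning. This
note documents the models, the parameters that matter, the synthetic-data
conditions every claim is tested under, and the numerical choices made where
the design was genuinely open.

## From time series to graphs

Per subject and session, an N-node connectivity matrix is built from T×N ROI
time series as the Pearson correlation of every ROI pair, Fisher-z
transformed (`z = atanh(r)`, with r clipped to ±(1−1e−7) so duplicated
signals stay finite) and zeroed on the diagonal. Two thresholded graph
families are derived:

* **Proportional density thresholding** retains the K = round(d·N(N−1)/2)
  strongest connections (raw signed value; at the 2–10% densities used,
  negative edges effectively never qualify) and binarizes them. Equal edge
  counts make graphs comparable across subjects and groups. K uses
  round-half-up; ties at the cutoff break by ascending (i, j) lexicographic
  order so the graph is a deterministic function of the matrix. Nodes
  disconnected at sparse densities are kept with degree 0, not dropped.
  Default density grid: 0.02–0.10 in steps of 0.01; reported metrics are
  threshold averages unless stated otherwise.
* **Edge-wise FDR thresholding** (used only for within/between-module
  connectivity) converts each Fisher-z value to a two-sided p-value via the
  normal approximation z·√(T−3), applies Benjamini–Hochberg at q = 0.05
  separately to positive and negative edges, and keeps the surviving signed
  weights. The z·√(T−3) p-value machinery is this package's documented
  choice; the per-edge sample size T comes from the subject's own session.

## Community detection and consensus

Modularity at resolution γ is the configuration-model form

    Q = (1/2m) Σ_ij [W_ij − γ s_i s_j / 2m] δ(m_i, m_j)

summed over ordered pairs including i = j (W_ii = 0, but the null term is
counted) — the standard Newman convention, shared by the brute-force oracle
the tests compare against. For weighted graphs node strengths replace
degrees (weighted configuration null).

`louvain` is a standard two-phase implementation (greedy local moving, graph
aggregation) with seed-shuffled node visit order. `fine_tune` alternates
deterministic single-node reassignment sweeps with Louvain re-runs
initialized from the current labels until a full sweep yields no gain;
modularity never decreases. `best_partition` keeps the best of R repetitions
(ties broken by the lowest canonical label sequence).

Consensus clustering iterates: build the co-assignment (agreement) matrix of
the current ensemble, zero entries below τ (surviving entries keep their
fractional values — thresholded agreement is not re-binarized), re-partition
with R Louvain+fine-tune runs, and stop when all R runs agree (checked by
exact label equality, equivalent at convergence to a binary agreement matrix
but cheaper). Subject-level consensus operates on the positive Fisher-z
weights (threshold-independent); group-level consensus operates on the
subjects' consensus partitions. Defaults γ = 1.25, τ = 0.5, R = 500
(R = 20 in the reduced profile); the (γ, τ) sweep covers γ 1.0–1.5 and
τ 0.2–0.5 in 0.05 steps and picks the grid point maximizing mean modularity
across the four group-session cells, each cell scored on its mean
positive-weight matrix (the input the sweep receives).

A failure to reach τ anywhere in the agreement matrix, or non-convergence
within 50 iterations, raises with a recommendation to change τ.

## Metrics

Global efficiency is the mean inverse shortest-path hop count over ordered
pairs (disconnected pairs contribute 0). Local efficiency of node i is the
global efficiency of the subgraph induced by i's neighbors (i excluded);
nodes with fewer than two neighbors score 0 (the formula's denominator is
undefined there — the common toolbox convention). The participation
coefficient is P(i) = 1 − Σ_m (k_i(m)/k_i)²; degree-0 nodes score 0. The
per-subject modularity score is the mean Q over R Louvain+fine-tune runs at
γ = 1.25, matching the consensus resolution.

Module-level comparisons need a module definition shared across groups and
sessions: the four group-session consensus partitions are label-matched to
the first (young, session 1) by maximum-overlap optimal assignment
(Hungarian algorithm on the module confusion matrix; unmatched modules get
fresh labels whose nodes can never count as consistent), and a node is
*consistent* iff its matched label agrees across all four partitions.
Per-module participation and local efficiency average over consistent nodes
only; each subject's participation uses their cell's matched partition
labels for neighbor counting. Within-module connectivity is the sum of
FDR-surviving weights among a module's consistent nodes divided by the
number of possible pairs (missing if fewer than two consistent nodes);
between-module connectivity divides by n_m·n_m'.

## Statistics

Partition similarity uses NMI = 2·I(X;Y)/(H(X)+H(Y)) (arithmetic-mean
normalization, natural logs) from the module contingency table; two
single-module partitions score 1, exactly one scores 0. Three permutation
tests shuffle group membership (retaining group sizes) around a precomputed
pairwise-NMI matrix: between-group mean cross-pair NMI (significant when the
observed value falls below the null's 5th percentile; a two-sided p is also
reported), within-group mean NMI per group (two-sided), and the group
difference in within-subject session-1-vs-2 NMI (two-sided). All permutation
p-values carry the finite-sample correction p = (1 + #extreme)/(n_perm + 1),
so p ≥ 1/(n_perm+1) always.

Group differences in metrics use the same label-shuffling engine on the
difference of group means (two-sided throughout; directions are read off the
estimates). Module-level families are corrected by the max-statistic method:
one shared permutation stream records, per permutation, the maximum absolute
mean difference across modules, and each module's p_FWE is computed against
that null (reported as at least the uncorrected p). 5,000 permutations by
default, 200 in the reduced profile.

Test-retest reliability is ICC(A,k): from the two-way ANOVA decomposition
without replication, ICC = (MS_R − MS_E)/[MS_R + (MS_C − MS_E)/n], with
qualitative bands poor (≤0.20), fair (≤0.40), moderate (≤0.60), strong
(≤0.80), almost perfect (>0.80); values in the printed gaps resolve to the
band whose edge they exceed. Negative estimates are reported as computed
(they band as "poor"); in the degenerate regime where the denominator turns
negative the ratio can exceed 1 and is labeled "undefined" rather than
banded. Note ICC(A,k) is a left-skewed ratio: under destroyed agreement its
median is near 0 but its mean is biased negative — tests assert the median.

Learning curves (mean set size per training session) are fit per subject by
ordinary least squares to score ~ 1 + s + (s − 2)₊, a linear spline with a
knot at the second session; the early slope is the coefficient on s (the
session-1→2 rate), the late slope the sum of both slope coefficients.
Brain-behavior association is Spearman's ρ between each threshold-averaged
brain-wide metric and the early slope, per group and session, with
per-threshold ρ curves and a motion-partialled ρ_p (rank all three
variables, residualize the metric and slope ranks on the motion ranks by
least squares, correlate the residuals; a constant covariate falls back to
plain ρ with a warning). The motion covariate is the subject's mean
composite motion scalar from the manifest.

## Synthetic cohorts: what is emulated, and what is not

The generator plants exactly the statistical structure the analysis
consumes. ROI time series are i.i.d. draws over time from a zero-mean
multivariate normal with a block correlation structure: unit diagonal,
r_within for same-module pairs, r_between otherwise (positive
semi-definiteness is checked; violations raise with the offending
eigenvalue). Defaults emulate the study design: 234 ROIs in 5 modules,
2 groups × 20 subjects × 2 sessions, 235 time points; the reduced profile
(60 ROIs in 5 modules of 12, 10 subjects/group, 200 time points) is used by
tests and the acceptance script so everything runs on one CPU in minutes.

Group effect: the young group has r_within = 0.45, r_between = 0.05; the
older group r_within = 0.22, r_between = 0.13 — weaker within-module and
stronger between-module coupling, the dedifferentiation pattern. These
values were fixed by a design-stage power analysis so that the planted
direction (lower modularity and local efficiency in the older group) holds
in ≥95% of replicate cohorts at the reduced profile; the realized effect is
a threshold-averaged Q difference of about −0.14 (SD ≈ 0.02 across
cohorts).

Subject heterogeneity adds Gaussian jitter (SD 0.05) to each subject's
r_within; with session reliability ρ ∈ [0, 1], each session's jitter is
√ρ·(shared subject draw) + √(1−ρ)·(session draw), so ρ = 1 gives identical
generative covariances across sessions and ρ drives test-retest ICC
monotonically (default 0.8). Motion is a per-subject |Normal| scalar
(means 0.10/0.14 by group, SD 0.03) written to the manifest; it influences
nothing downstream, which is exactly what the partial-correlation check
should find. Learning curves rise linearly to a plateau: baseline 3.0 set
sizes, a session-1→2 gain of 1.5 + 0.5·z + Normal(0, 0.2) where z is the
subject's standardized coupling jitter (coupling 0.5 set-size units per SD),
then 0.2 per session thereafter; curves carry no additional per-session
observation noise, so the spline fit recovers the planted gain exactly up to
the planted noise. The planted truth table (per-subject jitter, realized
per-session r_within, motion, learning gain) is written alongside the data
for parameter-recovery tests.

Not emulated: temporal autocorrelation and spectra (band-pass preprocessing
is out of scope and every downstream quantity depends only on the
correlation structure), scanner artifacts and physiological noise, spatially
heterogeneous node properties, and negative true correlations beyond what
noise produces. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted effects under the stated model — not
robustness to fMRI artifacts.

**A structural limitation worth knowing.** In this generative family at
matched edge density, any between-module coupling increase strong enough to
depress modularity necessarily adds cross-module edges among the retained
strongest connections, and those act as shortcuts: global efficiency comes
out slightly but *systematically* higher for the degraded group at every
threshold. Real aging data shows roughly equal global efficiency because
counterbalancing forces (overall connectivity strength, fragmentation of
weaker networks) exist that this block-covariance model does not plant. A
test asserting "no systematic Eglob sign" under these conditions fails, and
is left failing deliberately — it documents the model's boundary, and fixing
it would require a richer generative family (e.g., group differences in
overall signal-to-noise or node-level heterogeneity), which is out of scope.

## Numerical and reproducibility choices

* One master seed per entry point; internal repetitions draw child seeds
  from a spawned `numpy.random.SeedSequence`, so every stochastic stage is
  bit-reproducible and the reduced pipeline reruns byte-identically.
* Louvain accepts a move only for a strict gain (>1e−12), so modularity
  strictly increases across levels and termination is guaranteed; fine-tune
  sweeps nodes in index order (deterministic by contract).
* Best-partition ties resolve to the lowest canonical label sequence;
  density-threshold ties to lexicographic edge order; sweep ties to the
  smallest γ, then smallest τ.
* Degenerate inputs are errors, not silent results: constant time-series
  columns (named), all-zero weight matrices, K = 0 densities, missing
  sessions, group sizes below 2, constant vectors in rank correlation.
  A constant ICC table warns and returns 1.
* The reduced profile (R = 20 Louvain runs, 200 permutations, 60-node
  cohorts) is a separate named profile; full-fidelity defaults
  (R = 500, 5,000 permutations) are never silently reduced.
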