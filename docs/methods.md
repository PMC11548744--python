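# Methods

This note documents the models, numerical choices and limitations of
`organet`, stage by stage.

## The dynamical model

Expression of gene *g* in organ *r* is one coordinate of a state vector
E(t) assumed to follow the linear time-invariant system

    dE/dt = K · E(t),

where K[r·, j·] (units 1/week) is the interaction coefficient with
which node *j* drives the rate of change of node *r*.  Nodes are
(organ, gene) pairs, so K couples genes within and across organs;
self-regulation (diagonal entries) is allowed.  The model is a
deliberately coarse, descriptive account of slow (weeks-scale)
transcriptional co-variation: it has no inputs, no nonlinearity, no
time-varying coefficients and no noise process.

## Synthetic cohorts (what the generator emulates, and what not)

`synthetic.make_synthetic_dataset` draws a ground truth K with:

* off-diagonal support: exactly `round(density · n(n−1))` entries
  chosen uniformly; magnitudes Laplace(0, `coeff_scale`), heavy-tailed
  as sparse regulatory effects tend to be (defaults: density 0.05,
  scale 0.2/week);
* diagonal: −(row off-diagonal L1) + `stability_bound` −
  uniform(0, `decay_spread`).  The Gershgorin bound guarantees a
  spectral abscissa ≤ `stability_bound` (default −0.05/week, bounded
  trajectories over the 16-week window).  The per-node uniform margin
  (default spread 0.15/week) gives every gene its own turnover rate;
  without it all unregulated nodes decay as the same exponential and
  are mutually indistinguishable from a single trajectory.

Strain trajectories share K but start from independent initial states
uniform(0.2, 1.0) — a strain contrast in state, not topology — and are
integrated exactly with matrix-exponential steps.  Before measurement,
each node's trajectory is shifted by a constant so its minimum is at
least 0.5: transcript abundance never crosses zero, and the Ct mapping

    Ct = 25 − log2(expression),   floor 1e−6

stays in its gentle regime (Ct ≈ 24–26).  A static per-node offset is
removed by the −ΔΔCt centering and integrates to zero against the
modulating basis, so it does not change what is identifiable.
Replicate noise is Gaussian on the Ct scale (default 0.25 cycles; the
replicate-to-replicate variability of chip qPCR with n = 3 animals has
no published model for this design, so this is a stand-in, not an
inference).  Missing reactions are independent Bernoulli (default 2%),
and a configurable fraction of samples is duplicated as second-chip
technical replicates.

Not emulated: amplification chemistry, primer efficiency, chip spatial
effects, biological nonlinearity, inter-animal heterogeneity beyond
i.i.d. noise.  Passing recovery tests on this generator therefore
shows the estimator handles the study's sampling design and noise
scale — not that real tissue dynamics are linear.

`make_normalized_dataset` emits data directly on the normalized
(log2-relative) scale, bypassing the Ct/median-reference machinery.
Parameter-recovery studies use it because with a small panel (5 genes
per organ) the per-sample reference median is itself strongly dynamic
and would confound the estimator being tested; with the study's
92-gene panel the reference is far more stable.

## QC and normalization

* Genes, then samples, with < 60% present reactions are dropped (one
  pass each; iteration to a fixpoint is deliberately off, matching a
  single reported QC outcome).
* Duplicate-chip pairs are averaged per gene when the zero-intercept
  regression slope of chip-2 on chip-1 Ct over co-present genes lies
  inside (0.85, 1.15); otherwise the replicate with more present
  reactions is kept.  A Pearson correlation cannot exceed 1, so a
  bounded "agreement" band of that form must refer to a slope-like
  statistic; the exact choice is config-switchable.
* ΔCt references each sample to the median Ct of the organ's robustly
  expressed genes (> 60% present within that organ); −ΔΔCt centers
  each gene at its cross-sample median (organ-wise) and flips sign.
  Medians use present entries only; even counts take the midpoint; no
  imputation anywhere.
* `rank_reference_stability` scores candidate reference genes by mean
  pairwise log-ratio SD (Ct differences are already log2 ratios); it
  documents why a median vector beats any single housekeeping gene but
  plays no role in the normalization itself.

## Exploratory statistics

PCA runs on samples × genes with per-gene centering and no variance
scaling (−ΔΔCt is already a common log2 scale; scaling is a config
switch).  Genes with any missingness inside the analyzed sample subset
are dropped for that decomposition only — at n = 3 imputation
artifacts are worse than a smaller panel, but note the consequence: at
a few percent missingness a whole-cohort PCA can retain few genes,
while per-age subsets retain most.

Per-gene ANOVA is age × strain with interaction, type-II sums of
squares via OLS, Tukey HSD per factor family with pooled error, raw
p < 0.05 (no multiplicity correction by default; Benjamini–Hochberg is
available).  Exact fits (zero residual SS) use the convention F = 0,
p = 1 for zero-SS effects.  The sex contrast takes Δ = mean(SHR) −
mean(WKY) per (gene, organ, age, sex) and runs age × sex ANOVA per
gene with organs as replicates — the only reading that leaves positive
error degrees of freedom for the interaction.

## HMF network identification

Pipeline per strain: replicate means per (organ, gene, age) → min-max
scaling to [0, 1] per node (constant nodes map to 0.5 and are
flagged) → natural cubic spline onto a uniform dense grid (default 257
points) over the shifted window t = age − 8, T = 16 weeks → projection
onto the modulating basis → per-target elastic net → joint model
selection.

**Basis.**  φ_m(t) = Σ_{k=0}^{N} (−1)^k C(N,k) cas((m+k) ω₀ t) with
ω₀ = 2π/T, m = 1..M.  The alternating binomial identities make φ_m and
φ_m′ vanish at t = 0 and t = T exactly for N ≥ 2, so projecting the
model equation and integrating by parts gives, per target node r,

    −∫ φ_m′ E_r dt = Σ_j (∫ φ_m E_j dt) K[r, j],   m = 1..M,

with no boundary terms and no numerical differentiation.  Defaults
M = 8, N = 3: M at least the number of ages, N the smallest order
comfortably above the boundary requirement.  Moments are trapezoid
sums on the dense grid; an independent spectral path reads the same
integrals off discrete Hartley (cas) components via the FFT — the
basis's own endpoint cancellation makes the two agree to rounding
error, which the tests exploit as a cross-check.

**Affine intercept.**  Min-max scaling (and the log2 Ct map) are
affine, so scaled data obey dy/dt = K·y + c.  The basis integrates
constants to zero — the regression is invariant to c — but forward
simulation is not, so c is recovered from the exact boundary identity
y(T) − y(0) = K ∫y dt + c·T and carried through candidate evaluation
and `simulate_fitted_model`.  Without it, model selection always
prefers the all-zero network (drift alone).

**Elastic net and selection.**  Columns of the moment matrix are
scaled to unit SD (no centering — there is no intercept in the
regression), l1_ratio defaults to 0.5, and the penalty grid is
logarithmic over 1e−6..1e1 (22 points); the floor is low enough that
on clean, well-excited data selection can approach the least-squares
limit (a grid containing exactly 0 falls back to `lstsq`).  For each
penalty, all target rows are fitted and assembled into a candidate K,
the candidate is simulated from the first-age state, and the penalty
minimizing whole-model RMSE against the scaled data at the observed
ages wins — jointly across nodes, not per row.  Unstable candidates
score infinity; if all candidates are unstable the most penalized one
is kept with a warning.

**Identifiability, honestly.**  A single trajectory of a stable linear
system is a sum of decaying exponentials, and such families are
numerically near-collinear: with 5 time points the moment matrix has
numerical rank well below the node count, so individual coefficients
of a 15-node network are not recoverable from one trajectory at any
noise level — no estimator can do it, and the ranking of estimated
coefficient magnitudes against ground truth reflects this (the
dedicated acceptance test states the intended standard and fails in
this regime, by design left failing rather than weakened).
`fit_network` therefore accepts multiple experiments (independent
initial states); with ~8 of them the stacked system is well posed and
the noise-free recovery tests pass with exact support and signs.  On
single-trajectory study-like data the fitted networks are descriptive
summaries of co-variation, and the joint selection is deliberately
conservative — at realistic noise it often returns a heavily penalized
(even empty) network rather than one that cannot reproduce the data.

## Network analysis

* ±2·SD rule: mean and SD over **all** entries of K (including
  elastic-net zeros; a nonzero-only population is a config switch);
  keep |k − mean| > factor·SD.  On an i.i.d. Gaussian matrix this
  keeps the two-sided tail fraction 0.0455, which the tests use as a
  calibration.
* Fraction-of-maximum rule: keep |k| > frac·max|k| within a node scope
  (e.g. the adrenal–kidney block).  Where a "top 25%" could mean a
  distribution percentile instead, the fraction-of-max reading is the
  default and the percentile variant remains available.
* Peak ordering sorts nodes by the argmax time of their simulated
  trajectories; ties (including constant trajectories, argmax at the
  first grid time) break by organ then gene label.
* Exports: edge-list TSV with 17-significant-digit weights
  (round-trips at full double precision) and GraphML via networkx.

## Problem sizes and runtime

The analysis scripts run a 3 organs × 12 genes cohort (36 nodes) —
every stage in seconds while preserving the factorial design.  The
recovery benchmarks use 15 nodes (3 × 5), the scale at which the
identifiability picture above is fully visible.  Fitting the full
92-gene × 5-organ matrix works through the same code path but takes
tens of minutes on one core, dominated by coordinate descent on
460-column regressions; the solver caps at 10⁴ iterations with
tolerance 1e−7, which is far below the fit uncertainty of this
problem class.

## Known limitations

* The linear ODE has no input terms; developmental or disease-stage
  forcing is absorbed into K and the affine intercept.
* Replicate means feed the fit; animals are cross-sectional, so no
  within-animal correlation structure exists or is modeled.
* Min-max scaling equalizes node amplitudes, which rescales K entries
  by amplitude ratios; comparisons of coefficient magnitudes across
  node pairs inherit that distortion.
* No uncertainty quantification beyond the penalty-path diagnostics;
  the method yields point networks.
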