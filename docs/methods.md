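# Methods

## Setting

The pipeline analyses a probes × samples matrix of continuous, normalized,
log-like expression values with each sample assigned to one of two groups.
Group 1 is the reference ("nulliparous") and group 2 the contrast
("parous"); every delta, direction flag and ratio is contrast relative to
reference.  The default design is 42 reference and 71 contrast samples,
the sample shape of the parity study that motivates the package.

## Synthetic data

`simulate.generate_dataset` draws background probes i.i.d. from
N(μ₀, σ₀²) (defaults μ₀ = 8, σ₀ = 1, a typical normalized log₂-intensity
scale) identically in both groups, then overwrites designated rows with
planted blocks.  One global seed feeds an independent substream per block
(`default_rng([seed, block_index])`), so adding or resizing one block never
changes the values of another; the background is drawn for the full matrix
first for the same reason.

- **Mean shifts** move the contrast-group mean by `effect_size` baseline
  SDs (default 1.0).  `fraction_up` = 0.685 gives the ~2.2 : 1
  up/down-regulation mix typical of the parity contrast.
- **Shape shifts** keep the mean and multiply the contrast-group variance
  by `variance_ratio` (default 9, i.e. the SD triples).  A tripled SD is
  the regime where rank/KS tests detect the change reliably at n ≈ 40–70
  (measured KS sensitivity ≈ 0.94) while a merely tripled *variance*
  (SD × 1.73) leaves KS power near 0.24 and would make the block
  undetectable by design.
- **Entropy shifts** keep the mean and draw the contrast group uniformly
  over μ₀ ± √3·`dispersion_ratio`·σ₀ (default ratio 3), so the values
  spread over many grid bins and discretized entropy rises while the mean
  does not.
- **Modules** use a shared latent factor per module per group:
  x = μ₀ + σ₀(a·z + e)/√(a² + 1) with loading a = √(ρ/(1−ρ)), which gives
  expected pairwise within-module correlation exactly ρ (ρ = a²/(a²+1)).
  The default plants modules at ρ = 0.9 in the contrast group only.
- **Quadruplets** satisfy
  p₁ = μ₀ + [w(p₂−μ₀) + (p₃−μ₀) + (p₄−μ₀) + ε]/√(w²+2) with lead weight
  w = 3 and per-group noise SD.  Expected R² is
  (w²+2)σ₀²/((w²+2)σ₀² + σ_ε²); the defaults give ≈ 0.95 (contrast) and
  ≈ 0.05 (reference).  The lead weight makes corr(p₁, p₂) ≈ 0.88 in the
  low-noise group: an equally weighted sum caps that correlation at
  1/√3 ≈ 0.58, below the |ρ| > 0.8 seed-pair threshold, so no planted
  relation could ever surface in the screen — up-weighting the seed
  regressor is what makes the planted relations discoverable by the same
  route the screen uses on real data.

What the generator does **not** emulate: probe-level microarray artifacts,
batch effects, heteroscedastic intensity-dependent noise, missing values,
or correlated background probes.  Passing recovery tests therefore shows
the pipeline detects the planted statistical structures at these sample
sizes, not that real microarray preprocessing issues are handled.

## Gene-by-gene criteria

**ME.** Welch t (two-sided, unequal variances) per probe;
Benjamini–Hochberg step-up adjustment across probes (via statsmodels).
Probes with zero variance in both groups are flagged and excluded from
testing.

**CD.** The empirical CDF is integrated exactly over a support common to
both groups (the probe's pooled min/max): for in-bounds data
∫F = upper − mean, so the CD *difference* is the negated mean difference —
the criterion's added value over ME lies in the non-parametric tests
attached to it, not in the area itself.  KS uses the exact two-sample
distribution at these sample sizes; Wilcoxon uses midranks with the normal
approximation.  Raw and BH-adjusted p-values are both reported because FDR
calibration for these statistics is less settled.

**SE.** Each probe is discretized on an equal-width grid spanning the
pooled min/max of both groups; the bin count (default 10) is exposed
because entropies depend on it and no canonical value exists for 40–70
observations.  Entropy is −Σf log₂ f with 0·log 0 = 0, so
0 ≤ SE ≤ log₂(bins).  Significance offers two rules:

- `collection` (default): Welch t-test between the two collections of
  `n_boot` own-group bootstrap entropies.  This is the most direct reading
  of "resample each group 1,000 times and t-test the entropies", and it is
  what reproduces the characteristically extreme significance counts of
  that procedure — but it treats every resample as an independent
  observation, so its effective n is `n_boot`, not the group size.  Under
  independent same-distribution groups it rejects ~94% of probes at
  α = 0.05.  Use it only to mirror the original procedure.
- `null_bootstrap`: a calibrated bootstrap hypothesis test.  Both groups
  are resampled with replacement from the *pooled* sample (imposing the
  null), the grid is rebuilt from each resample exactly as for the
  observed statistic, and the observed entropy difference is referred to
  the resampled difference distribution,
  p = (1 + #{|d\*| ≥ |d|})/(n_boot + 1).  Measured null rejection at
  α = 0.05, n = 42/71, 10 bins: 0.056 (3,000 replicates).  The smallest
  attainable p is 1/(n_boot+1).

  Simpler calibrated candidates were evaluated and rejected: a z-test on
  per-group bootstrap SEs is anti-conservative (≈ 0.07) because the
  plug-in bootstrap underestimates the entropy estimator's variance at
  these n, and neither bootstrap bias correction nor Miller–Madow repairs
  it.

**Criterion correlations and profiles.** Cross-criterion Pearson
correlations and the ordered relative-change curves use per-probe
contrast/reference ratios; probes with zero reference values are excluded
with a warning.  Clustering support is complete-linkage agglomeration on
Euclidean row distances, with optional row z-scoring (zero-variance rows
skipped and flagged).

## Power calibration

Welch power uses the noncentral t with Welch–Satterthwaite df (scipy's
noncentral-t tail underflow is clamped).  The detectable-correlation
operation inverts the Fisher-z power function,
ρ\* = tanh((z_α + z_power)/√(n−3)); a √n denominator variant is provided
because the two differ only in the third decimal and the rounding path of
published values is not always recoverable.  One-sided α is the default
for this operation: it is the convention that reproduces the commonly
quoted 0.29 (n = 71) and ~0.37 (n = 42) pair at α = 0.05, power 0.8.
Wilcoxon power is estimated by vectorized Monte-Carlo with the rank-sum
normal approximation; the normality screen is per-probe, per-group
Shapiro–Wilk with constant series excluded and counted.

## Co-expression networks

Correlations are product-moment Pearson (Spearman behind a flag);
zero-variance probes are excluded with a report.  The all-pairs
computation is guarded at 5,000 probes by default — a full 18,653-probe
run (≈ 1.74 × 10⁸ pairs) is supported by raising the guard explicitly.

The nine bins partition [−1, 1]: positive bins left-open/right-closed,
the central [−0.2, 0.2] closed, negative bins left-closed/right-open, so
every value including ±1 falls in exactly one bin; |ρ| > 0.8 defines the
two high-correlation networks.  Networks contain only probes with at
least one in-bin edge (the bins count edges, not probes).  The middle
bins of a large study hold millions of edges; `bin_networks(build=...)`
controls which graphs are materialized, while the count table is always
complete.

Graph summaries: characteristic path length and diameter use unweighted
breadth-first shortest paths on the largest connected component (flagged
when the graph is disconnected); clustering is the unweighted local
coefficient averaged over all nodes; modularity is the quality of a
Blondel-style greedy (Louvain) partition on absolute edge weights, seeded,
with restarts (16 for graphs ≤ 200 nodes, where single greedy passes are
cheap and most variable; 4 otherwise) and the best-Q partition kept and
reported alongside Q; eigenvector centrality is the mean over nodes of
the max-normalized leading eigenvector of |A|, computed by power
iteration on |A| + I (the identity shift makes the dominant eigenvalue
unique in magnitude, so bipartite graphs converge).  Reporting a single
number per network requires an aggregation convention; the mean of the
max-normalized vector is this package's, stated rather than inherited.

Subsampling inference draws `reps` induced subgraphs on ⌈fraction·|V|⌉
uniformly sampled nodes per network and compares the metric distributions
by Student's t-test.  Integration metrics and the raw link count are not
eligible (path lengths on subsampled graphs are expensive and the link
count is a census, not an estimate).

Differential edges use z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))
with two-sided normal p-values; pairs with |r| = 1 (infinite atanh) are
excluded and counted.  Significant-edge networks carry Louvain community
labels and degree-proportional size attributes for external layout tools.
The changed-correlation/stable-mean count pairs a Fisher-z rejection with
Welch-t non-rejections (p ≥ α) for both probes, on a seeded probe
subsample, scaled up by the pair-count ratio.

## Differential multiple-regression screen

Seed pairs need |ρ| > 0.8 in one group *and* |Δρ| > 0.4 (both filters
conjunctive — the printed class inequalities alone are neither equivalent
to the global filter nor mutually exclusive for extreme sign flips; ties
are resolved in the order A, B, C, D and affect only pathological pairs).
For sampled pairs and sampled third probes the fourth regressor sweeps all
remaining probes; R² for the sweep is computed by QR-projection of the
base design and rank-one updates, with collinear candidates flagged NaN.

Selection requires all four criteria:

1. R² transitions between groups from [0.8, 1) to [0, 0.4] (boundaries
   as stated; 1.0 excluded as exact collinearity).
2. At least one of the four probes is mean-stable (not BH-significant
   under ME).
3. The four probes are *not* all in one connected component of the
   |ρ| > 0.8 network of the group where R² is high ("the same correlation
   network" is read as that network, consistent with how networks are
   defined elsewhere in the pipeline).
4. The six pairwise correlation changes are *not* homogeneous, where
   homogeneous means all sharing one sign with |Δρ| > 0.4 (the screen's
   own change threshold).  The predicate is pluggable since "homogeneously
   modify" admits other formalizations.

Counts are extrapolated by found × total/examined with the sampling
fraction reported.  On data with planted contrast-only modules the
module seed pairs alone explain most selections (any fourth regressor
keeps the pair-driven R² high); the per-class selection fractions are
therefore only meaningful relative to the data's planted structure.

## Numerical and design notes

- All randomness descends from explicit integer seeds; the pipeline
  derives independent per-stage substreams from one root seed, and two
  runs with the same configuration are byte-identical.
- BH adjustment is statsmodels' `fdr_bh`; degenerate (NaN) p-values are
  excluded from adjustment and carried through as NaN.
- Correlation matrices are symmetrized and clipped to [−1, 1] after
  `np.corrcoef` to absorb floating-point drift; unit diagonal enforced.
- Degenerate inputs (constant probes, rank-deficient designs, empty seed
  classes, empty networks) are flagged and excluded rather than fatal,
  except where a computation is meaningless (empty graph summaries).
- Problem sizes used by the shipped analysis and tests: 2,000-probe
  simulated studies for recovery and calibration, ≤ 60-node graphs for
  exact oracle comparisons, ≤ 12-node graphs for exhaustive-partition
  modularity, 10,000 simulated pairs for Fisher-z size, 500 replicates
  for BH false-discovery proportion.  These sizes give Monte-Carlo
  standard errors small enough for the stated bands while keeping a full
  run in minutes on one core.

## Limitations

- The KS exact test is discretely supported, hence mildly conservative at
  these sample sizes (null rate ≈ 0.044 at α = 0.05).
- The calibrated entropy test's granularity is 1/(n_boot+1); with BH
  across many probes this bounds attainable adjusted significance.
- Louvain modularity is a greedy optimum: restarts stabilize it but do not
  guarantee the global maximum on large graphs.
- Eigenvector centrality on disconnected graphs reflects the dominant
  component; other components receive near-zero scores by construction.
- Upstream microarray preprocessing (background correction, batch removal,
  normalization), annotation enrichment, and force-directed layout are out
  of scope; networks are exported for external tools instead.
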