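# Methods

This note documents the statistical models behind `dielnet`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer should know about.

## Study design assumed

The pipeline targets a diel time course sampled every 4 h over 48 h
starting one hour after lights-on (ZT1, ZT5, …, ZT45), under two
conditions — well-watered (WW) and droughted (D) — with two biological
replicates per condition and time point (24 columns per condition).
Physiology (A, g_s, Fv'/Fm', NSC) is measured on the same grid with ≥ 8
replicates per time point. Expression values are FPKM; network
construction uses log2(FPKM + 1).

## Network stage

**Adjacency.** Signed soft-threshold adjacency
`a_ij = ((1 + cor(x_i, x_j)) / 2) ^ β` with Pearson correlation over all
24 columns of one condition (replicates are kept as separate columns; more
columns stabilize the correlations). Default β = 16, the value appropriate
for signed networks of this sample size. Anti-phased genes get adjacency
near 0, so morning- and evening-peaked transcripts separate into distinct
modules — essential for phase-resolved diel analysis.

**Topological overlap.** Signed TOM
`TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`, computed
by matrix multiplication and verified in the tests against a literal
triple-loop oracle at 1e-12.

**Module detection.** Average-linkage clustering of 1 − TOM followed by a
top-down adaptive branch decomposition: cut the dendrogram at the 0.99
quantile of its merge heights, recursively re-cluster and re-cut branches
that still contain an internal join above 0.5 × the cut, release branch
members whose mean TOM to the branch is below 0.5 × the branch median
("loose-member pruning"), and accept a branch as a module only if its
median internal TOM exceeds twice its median TOM to the rest of the
network. The pruning step exists because average linkage sweeps weakly
connected noise genes into module branches near the cut height (on the
default synthetic data this moves the adjusted Rand index from ~0.6 to
~0.99); the contrast gate exists so that structureless input (uniform
random TOM) yields no modules rather than one arbitrary branch. Modules
smaller than 30 genes are left unassigned (label 0). All thresholds are
keyword arguments; a fixed-height cut (`static_height`) is available as a
fallback. Detection quality is assessed by planted-module recovery, not by
bit-equivalence with any particular dendrogram-cutting implementation —
different reasonable cut rules give the same modules on well-separated
structure and differ only on marginal genes.

**Eigengenes and merging.** The module eigengene is the leading right-
singular vector over samples of the z-scored member profiles, unit norm,
oriented to correlate non-negatively with the module's mean standardized
profile (degenerate orientation falls back to a non-negative loading on
the lexicographically first member gene, making the sign reproducible).
Modules whose eigengene dissimilarity 1 − cor falls below 0.25 are merged
iteratively, recomputing eigengenes each round until stable. Module
membership MM_gm = cor(x_g, ME_m) with the usual Student-t p-value
(t = r√(n−2)/√(1−r²)).

## Cross-condition comparison

Overlap between two module assignments is counted on the intersection of
their gene universes; unassigned genes stay in the universe N but
contribute to no cell. Each cell gets the one-sided hypergeometric
(Fisher) over-representation tail P(X ≥ k), displayed as −log10(p) capped
at 50. Consensus modules are detected on the element-wise minimum of the
two TOMs; by default the second TOM is first rescaled so its 95th
percentile matches the first's, preventing a globally weaker network from
dominating the minimum (disable with `scale_quantile=None`). When both
expression matrices are supplied, consensus-module merging uses the
worst-case (maximum over conditions) eigengene dissimilarity.

## Trait association

Trait per-ZT means are expanded onto the expression sample axis — both
replicates of a ZT receive that ZT's trait mean — preserving the full
n = 24 alignment; this matches correlating eigengenes with "mean values at
each time point". Averaging expression down to 12 time points instead is
a caller-side choice (pass averaged matrices). A trait missing a sampled
ZT (NSC is typically not assayed at ZT9) raises by default, naming the ZT;
`interpolate_missing=True` enables linear interpolation. Per-timepoint
condition contrasts use the unpaired equal-variance Student t-test,
one-tailed in a direction the caller must supply — the biological
direction of each trait's drought response is an input, never a silent
default. Gene significance is |cor(x_g, expanded trait means)|; the GS vs
|MM| correlation within a module tests whether hubs carry the trait signal.

## Rhythm detection

The cycling test compares each gene's 24 values against cosine references
`cos(2π(t − φ)/24)` at every phase offset on the 4 h sampling grid
(6 references; φ anchored at the first sampled ZT). The statistic is
Kendall's S (concordant minus discordant pairs). Reference values tie
heavily by construction — replicates share the reference value, the two
days repeat it, and cosine symmetry pairs phases — giving a tie pattern of
group sizes (4, 8, 8, 4) on the default design. Under the null
(exchangeable data), S is distributed as a Jonckheere–Terpstra-type
statistic whose exact pmf follows from the generating polynomial of
cross-group inversion counts, a product of Gaussian binomial coefficients
computed by integer dynamic programming (exact up to 26 points; beyond
that a variance-matched normal approximation with continuity correction is
used and flagged). The tests verify the DP against full permutation
enumeration at n = 7 (5040 permutations) and for a tied 3×2 pattern.

Per reference, the two-sided exact p is Bonferroni-multiplied by the
number of distinct reference *shapes* (antiphase pairs are one shape up to
sign, so 3 for the default grid); the per-gene p is the minimum over
references, LAG is the phase of the best (most concordant) reference, and
q-values are Benjamini–Hochberg within each condition's gene universe.
The test runs on FPKM values: being rank-based, its p-values are invariant
to any monotone transform (asserted in the tests), while the amplitude —
and the amplitude-difference selection threshold of 10 — is interpreted in
FPKM units, where a threshold of 10 is meaningful (on log2 scale it would
be implausible). The null assumes untied data; exact ties in the data
(e.g. clipped zeros) only make the test conservative.

**Amplitude** is the fixed-period least-squares cosinor
`y = m + a·cos(2πt/24) + b·sin(2πt/24)`, AMP = √(a² + b²) — half the
peak-to-trough swing, unbiased under the generator's model and verified by
Monte-Carlo calibration (500 simulations, planted AMP 30, noise sd 5:
mean estimate within ±2).

**Selection.** Within the caller-supplied modules of interest (in the
intended workflow: drought-network modules correlated with g_s and
Fv'/Fm' at p < 0.01), candidates are genes that either gained rhythm
(q_WW ≥ 0.01 and q_D < 0.01) or are rhythmic in both conditions with
|AMP_D − AMP_WW| > 10 (the signed difference is recorded; the criterion is
absolute because both gains and losses of amplitude are of interest).
Candidates are ranked within modules by |MM|, ties broken by gene id.

## Probe-count QC

Normalization is multiplicative and geometric-mean based (counts are a
multiplicative process): the CodeSet step scales each sample set so its
pooled-RNA reference column matches the across-set geometric mean; the
Content step scales each sample by (mean of housekeeping geometric means
across samples) / (own housekeeping geometric mean), and is idempotent.
Samples with a zero housekeeping count are rejected by name. The modified
Z-score `M = 0.6745 (x − median) / MAD` is computed per probe across all
(normalized) samples; cells with |M| > 3 are masked individually —
spurious counts are single-cell events, so whole-probe removal would
discard good data (MAD = 0 falls back to the mean-absolute-deviation
variant with constant 0.7979, flagged). For technical-replicate pairs the
member with the lower maximum |M| is kept, ties broken by sample id.
Note one statistical reality: at cut 3, roughly 0.3% of perfectly clean
Gaussian-tailed cells exceed the threshold by chance, so "no false masks
ever" is not achievable; the guarantee tested is ≤ 1% false masking
(observed ~0.02–0.04%) with 100% of planted spikes caught.

The over-representation test for candidate sets is the one-sided
hypergeometric tail with BH adjustment across terms; terms with fewer than
5 members in the universe are skipped.

## Synthetic-data generator

`simulate_experiment` plants: module-structured cosine rhythms
(FPKM(g, t) = max(0, B_g (1 + A_rel cos(2π(t − φ_m)/24)) + ε),
ε ~ N(0, 0.1·B_g)), lognormal baselines (median 100 FPKM, log-sd 0.25),
relative amplitude 0.5, module phases spread uniformly over the day, and a
drought condition that scales one module's amplitude ×1.6, shifts another's
phase by 4 h, converts 30% of a third module to gained rhythm (flat in WW)
and 30% of a fourth to lost rhythm (flat in D). Traits are cosine
waveforms sharing their coupled module's phase (sign-flipped for negative
coupling such as Fv'/Fm'), 8 replicates per time point, with
condition-level shifts in the mild-drought direction (g_s down 40%, NSC up
30%, etc.) so the one-tailed t-tests have something to find. Negative
values are clipped to zero (FPKM is non-negative; negligible bias at these
noise levels). Multiplicative (relative) noise makes high- and
low-expressed genes equally detectable after the log transform, coarsely
matching RNA-seq mean–variance behaviour. Identical config and seed give
bit-identical outputs.

`simulate_probe_counts` builds a 36-probe panel (33 endogenous + 3 flat
housekeeping probes at low/medium/high levels) × (2 conditions × 12 ZT ×
5 biological replicates) with Poisson counts around scaled noise-free
profiles, per-set and per-sample depth factors for the normalization steps
to remove, ~1% of endogenous cells multiplied ×10 (the spurious-count
model; the mask is returned as ground truth), and technical-replicate
pairs. Panel probes are drawn from genes rhythmic in both conditions with
relative amplitude ≤ 0.6: a ×10 spike on a trough cell is separable from
the probe's own across-sample diel spread only when
spike_factor × (1 − A) exceeds the peak (1 + A); beyond A ≈ 0.8 no
across-sample modified-Z filter can detect it, so such probes are not a
valid test of the filter.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: library-size and compositional normalization
effects, count-level mean–variance structure (negative binomial
dispersion), non-sinusoidal waveforms (sharp dawn peaks, day-asymmetric
light/dark responses), gradual drought progression across the two days
(effects are planted as constant within a condition), correlated noise
between co-regulated genes beyond the planted module structure, and any
sequence- or mapping-level artefacts. Recovery rates reported by the
acceptance script are therefore upper bounds on what identical settings
would achieve on real data.

## Problem sizes and determinism

Default analyses run at 750 genes × 24 samples per condition (network
stage seconds, full acceptance sweep well under a minute); the trait-
recovery check repeats the whole pipeline over 20 seeds, and the
false-positive check uses 2000 pure-noise genes. These sizes were chosen
to make planted-structure recovery statistically meaningful while keeping
the default test run fast. All randomness flows from
`numpy.random.default_rng` seeds carried in the configs; the acceptance
script derives every stage seed from its single `--seed` argument.

## Known limitations

- The adaptive branch cut is one member of the family of dynamic
  dendrogram-cutting algorithms; marginal genes near module boundaries can
  be assigned differently than by other implementations.
- The rhythm test scans a single 24 h period with single-harmonic cosine
  references; multi-component waveforms and period estimation are out of
  scope.
- Trait–expression association is contemporaneous Pearson correlation;
  lagged relationships shorter than the 4 h sampling interval are
  invisible, and longer lags are not modelled.
- The consensus construction (quantile scaling then element-wise minimum)
  is one standard choice among several; it is configurable but not
  benchmarked against alternatives here.
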