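# Methods

This note documents the statistical procedures implemented in
`inflamsig`, the design choices made where several readings were
defensible, and what the synthetic data generator does and does not
emulate.

## Cohort regression with permutation inference

Measurements are standard-score normalized within each cohort (sample
mean 0, sample SD 1 per feature, ddof = 1). Features with zero variance
inside a cohort are flagged and excluded from regression rather than
propagating NaN. Each feature is then fit by ordinary least squares on an
intercept plus age, sex (F = 0, M = 1), CMV, HIV and HCV status;
covariates constant within a cohort (e.g. HIV outside the HIV cohort) are
dropped for that cohort rather than estimated as zero. Age is
standardized within cohort by default so that its coefficient shares the
per-SD scale of the response; this rescaling leaves permutation p-values
unchanged.

Coefficient significance uses a permutation scheme: the covariate of
interest is permuted across subjects B = 1000 times, the full model
refit, and p = #{|β*| ≥ |β̂|}/B (two-sided by absolute value; ties count
as exceedances, so a coefficient of exactly zero gets p = 1). The refit
uses the Frisch–Waugh–Lovell identity — the full-model coefficient of a
column equals (Mx)'y/(Mx)'(Mx) with M the projector orthogonal to the
other columns — which is algebraically exact and reduces each permutation
to one projection. Permutation streams are derived from
(seed, cohort, covariate, feature) by SHA-256, so p-values are invariant
to feature order and to adding stages. The plain ratio p = b/B is
reported (so p = 0 is possible, as a printed rule); the add-one-smoothed
(b+1)/(B+1) value is always reported alongside and is the right choice
for uniformity diagnostics. A Freedman–Lane residual-permutation scheme
(permute reduced-model residuals of y instead of x) is available via
`scheme="freedman-lane"`.

q-values follow Storey–Tibshirani: π₀ estimated from the p-value
histogram on a λ-grid (0.05…0.90, step 0.05) with a cubic polynomial
smoother evaluated at the largest λ, clipped to [1/m, 1]; for fewer than
50 p-values π₀ is fixed to 1, which reduces the transform exactly to
Benjamini–Hochberg. Selection is q < 0.2 by default.

**Known limitation — dependence.** Features sharing a latent correlation
block have dependent test statistics; the realized false-discovery
proportion in any single dataset can exceed the nominal level even though
the procedure controls FDR in expectation (in one default-seed run, a
chance correlation between a block factor and age produced a cluster of
correlated false positives). This is a property of FDR methodology under
dependence, not of the implementation.

**Known limitation — small-cohort power.** With the default design the
HCV cohort has 25 subjects (14 vs 11). A 1-SD planted effect on a binary
indicator there has a coefficient standard error of ≈ 0.40, so
per-feature power at q < 0.2 is roughly 45–60%. End-to-end recovery of
1-SD effects is therefore high (> 0.8) for the aging (n = 89) and HIV
(n = 69) cohorts but partial for HCV; the tests assert exactly that.

## Functional domains and overlap

Domain assignment is a total, deterministic function of the feature
descriptor: memory/naïve T-subset frequencies → "T cell memory skewing";
baseline signaling in lineage X → "Baseline signaling in X"; responses to
stimulus C in lineage X → "Sensitivity to C in X"; serum analyte A →
"Systemic A"; CD28⁺ subsets → "CD28+ T cell frequency"; remaining subsets
→ "\<subset\> frequency". The three per-driver significant-domain sets are
partitioned into the seven exclusive Venn regions; the regions are
disjoint by construction and their counts sum to the number of unique
domains (property-tested over random set triples).

## Hierarchical clustering and the gap statistic

Default clustering is agglomerative with average linkage on Euclidean
distances over z-scored features (ward and complete are available); the
merge order for tied distances follows the deterministic nearest-neighbor
chain, so results are reproducible for a fixed row order. The gap
statistic uses W_k = Σ_r D_r/(2 n_r) (equivalently the pooled
within-cluster sum of squares), B = 100 reference datasets drawn
uniformly over each feature's observed range (a PCA-frame variant is
available), s_k = sd·√(1+1/B), and chooses the smallest k with
Gap(k) ≥ Gap(k+1) − s_{k+1}. Cluster composition is scored with the exact
upper-tail hypergeometric probability (no normal approximation); the
implementation is verified against brute-force enumeration to 1e-12.

## Paired SAM

For each feature the paired difference post − pre is summarized by
d = mean/(se + s₀); s₀ is chosen by the Tusher coefficient-of-variation
criterion over the 0, 5, …, 100 percentiles of the per-feature standard
errors (spread of d measured by scaled MAD within se-quantile windows),
with `s0_mode="median"` as a simple fallback. The null flips the sign of
each subject's whole difference vector, preserving the inter-feature
correlation structure. Calling uses the Tusher order-statistic rule with
asymmetric cutoffs: sorted observed d is compared with the
permutation-expected order statistics, and the cutoffs at a given Δ are
the extreme observed values whose deviation reaches Δ. A symmetric
|d| ≥ Δ mode is provided for cross-checking.

FDR(Δ) = π₀ × (false-call summary over permutations)/(observed calls),
with π₀ estimated as the fraction of observed d inside the interquartile
band of the permuted d, capped at 1. The classic summary is the *median*
permuted false-call count; at call counts of one or two it is granular —
whenever the observed extreme exceeds its permutation median, the median
false count is 0 and FDR collapses to 0, producing spurious calls on
pure-null data in roughly half of datasets. The default summary is
therefore the *mean* false-call count (the expected number of false
positives), which is calibrated in that regime: on null data (500
features, 14 pairs) the call set at FDR < 0.01 is empty in ≥ 95% of
seeds, while recovery of the 13 planted 1.5-SD improvements remains
complete with ≤ 1 false call. Both summaries are computed and written to
the FDR table; `false_summary="median"` restores the classic behavior.
The reported FDR curve is additionally monotonized (running minimum in
Δ), which only matters where the raw curve jitters at boundary Δ values.

## Signaling networks

Spearman correlations use average ranks for ties; constant node features
get missing correlations and end up isolated. An undirected edge joins
nodes with |ρ| ≥ 0.5 ("at least", not strictly greater); the signed ρ is
the edge attribute and |ρ| the weight. Betweenness is computed on the
unweighted thresholded graph (fractional credit across tied shortest
paths; unordered pairs), eccentricity within each connected component,
and both are verified against exhaustive path-enumeration oracles on all
random graphs up to 8 nodes. Isolated nodes get betweenness and
eccentricity 0. Hubs are the top ⌈0.2·N⌉ nodes by degree and bottlenecks
the top ⌈0.2·N⌉ by betweenness, boundary ties included; when a metric is
constant across nodes it is uninformative and classifies nobody. Roles
cross-classify as H-B, H-NB, NH-B, NH-NB.

Communities come from Louvain modularity maximization on |ρ| weights
(signed-weight modularity is undefined in the classical formulation; the
count of negative edges is available from the edge table), best Q over 10
seeded restarts, labels ordered by decreasing community size. Weighted
shortest-path (1 − |ρ|) betweenness is not the default because no
weight-to-distance mapping is given for the original analysis.

The cross-timepoint robustness test summarizes each node v at timepoint t
by m_t(v), the median of its correlations with all other nodes, and
compares Δo(v) = |m_t1(v) − m_t2(v)| against a null built by permuting
the node→median assignment independently within each timepoint (10,000
draws); p(v) is the fraction of null differences at least as large.
Identical inputs give p = 1 for every node by construction. An
alternative null that shuffles each feature's values across subjects and
recomputes the correlation matrix per draw is available
(`null="subjects"`); it is O(n_perm) correlation matrices, so use far
fewer permutations with it.

## Response kinetics

Responses are arcsinh(x/5)-transformed stimulated minus unstimulated
intensities (the mass-cytometry convention; a raw-ratio mode exists). The
synthetic generator emits response-scale values directly, so the
transform choice never blocks testing. Trajectories are mean ± SEM per
(cell type, timepoint) with optional z-scoring against a young-control
reference; 95% CI columns are mean ± 1.96·SEM. Group comparisons use
Kruskal–Wallis across independent groups and the Wilcoxon matched-pairs
signed-rank test for pre vs post (zero differences dropped; exact null
distribution when n ≤ 25 and no tied |differences|; a degenerate all-zero
comparison is reported as p = 1 and flagged).

## Synthetic data generator

The generator emulates the three-cohort design: aging 60 cases (61–90 y)
vs 29 young controls (22–33 y); HIV 24 vs 45; HCV 14 vs 11 with the HCV
cases observed at pre, wk1, wk2, wk4, wk8, wk12 and a ~9.5-month post
timepoint. The default panel has 357 features: the 12 × 7 baseline
signaling grid (84), IFN-α and IFN-γ response grids (168), 62 serum
analytes and 43 cell-subset frequencies. Pathway labels map pCREB/pAkt/pS6
→ P/S/D, IκBα/pIRF7 → PS/AV, pERK1/2/pMAPKAPK2/pp38 → MAPK, pSTAT1/3/4/5
→ STAT.

Values follow a linear factor model: planted driver effects (β in
within-cohort SD units; age enters z-scored, HIV/HCV as indicators), a
latent block factor per pathway with loading λ = 0.8 over the baseline
grid (within-block Pearson correlation λ², Spearman ≈ λ² via the
bivariate-normal rank relation), and Gaussian noise. Longitudinal data
add a subject random intercept (variance share 0.5) so repeated measures
are properly paired; viral load decays as VL(t) = 10⁶·e^(−2t) copies/mL
per week, floored at a detection limit of 15; DC IFN-α responses get a
+1 SD pulse at wk2 only; and 13 features (pSTAT1–IFN-α response in all
seven lineages, monocyte IκBα, DC IFN-γ response, PAI-1, EGF, IP-10,
Resistin) shift by +1.5 SD at post. These magnitudes were chosen as
realistic standardized immunology effect sizes and are configurable.

What the generator does **not** emulate: missing data (an optional
dropout rate exists but is off), batch effects, non-Gaussian marginals,
age-dependent covariance, raw cytometry event data (generation starts at
per-cell-type summary statistics), or cross-timepoint rewiring of the
block structure. Passing tests therefore demonstrate correctness of the
statistical machinery under the declared generating model, not robustness
to those real-data complications.

## Determinism and seeds

All randomness flows from one master seed through SHA-256-based
derivation keyed by stage and entity names, so adding a stage, reordering
features or changing one stage's parameters never perturbs another
stage's stream; `run-all` with a fixed seed is byte-identical across
runs.

## Problem sizes used by the tests and the acceptance script

Calibration checks use 1000 features × 100 subjects × 1000 permutations
(regression), 100 seeds of 60-point blob datasets with B = 20 references
(gap statistic), 100 (tests) / 50 (script) null SAM datasets of 500
features × 14 pairs at 300 sign flips plus 50/25 power replicates at the
full default study, 20/10 seeds of the n = 100 planted four-block panel
(communities), and 10,000 permutations for the robustness test. The
determinism check runs the full pipeline twice at reduced permutation
counts (50/100/300), which exercises identical code paths since
determinism does not depend on the number of permutations.
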