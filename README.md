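# inflamsig

Systems-immunology analysis of chronic-inflammation signatures across
cohorts, packaged as a tested, reusable pipeline.

Chronic inflammation — whether driven by aging ("inflammaging"), by
treated HIV infection, or by active HCV infection — remodels the immune
system: memory T cells accumulate, baseline phospho-signaling rises, and
sensitivity to cytokine stimulation falls. When a direct-acting antiviral
eliminates HCV viremia within weeks, it creates a rare natural experiment:
which of these alterations revert once the inflammatory trigger is gone?
`inflamsig` implements the full analytical toolchain such a study needs,
for immunologists and computational biologists working with
subject-by-feature immune measurement tables (mass/flow cytometry summary
statistics plus serum proteomics):

1. **Permutation-based regression feature selection.** Each standard-score
   normalized feature is modeled per cohort as

   *Y<sub>ij</sub>* = β<sub>j0</sub> + β<sub>jAge</sub>·Age<sub>i</sub> +
   β<sub>jSex</sub>·Sex<sub>i</sub> + β<sub>jCMV</sub>·CMV<sub>i</sub> +
   β<sub>jHIV</sub>·HIV<sub>i</sub> + β<sub>jHCV</sub>·HCV<sub>i</sub> +
   ε<sub>ij</sub>,

   with coefficient p-values from 1,000 covariate permutations
   (p = #{|β*| ≥ |β̂|}/B) and Storey q-values; features are selected at
   FDR < 0.2.
2. **Functional domains.** Significant features are binned by
   deterministic rules ("T cell memory skewing", "Baseline signaling in
   X", "Sensitivity to C in X", "Systemic A") and the per-driver domain
   sets are intersected into a three-set Venn partition.
3. **Clustering.** Hierarchical clustering with the gap statistic of
   Tibshirani–Walther–Hastie for the number of clusters and exact
   hypergeometric enrichment of labels within clusters.
4. **Paired SAM.** Two-class paired significance analysis of microarrays:
   d = mean(diff)/(se + s₀) with subject-level sign-flip permutations,
   asymmetric order-statistic cutoffs, and a permutation FDR curve
   (calls at FDR Q < 0.01).
5. **Signaling-network topology.** Per-timepoint Spearman correlation
   networks over the 84 nodes (12 signaling parameters × 7 PBMC
   lineages), edges at |ρ| ≥ 0.5; degree, strength, betweenness,
   eccentricity; hub/bottleneck roles (top 20% by degree/betweenness);
   Louvain modularity communities; and a 10,000-permutation robustness
   test of per-node median-correlation changes between timepoints.
6. **Response kinetics.** arcsinh-scale stimulation responses, mean ± SEM
   trajectories (optionally referenced to young controls), Kruskal–Wallis
   and Wilcoxon matched-pairs tests.

A synthetic-data module generates the full three-cohort study — aging
(60 cases 61–90 y, 29 young controls), HIV (24/45), HCV (14/11 with
pre/during/post-treatment timepoints, exponentially decaying viral load, a
transient DC pSTAT1 pulse and 13 planted post-treatment improvements) —
with planted linear driver effects and a planted four-pathway correlation
block structure, so every stage is testable end to end with known ground
truth.

## Worked example

Did any features improve after viral clearance? Simulate the default HCV
cohort and run the paired SAM stage:

```python
from inflamsig import simulate as sim
from inflamsig.sam import PairedSAM, paired_differences

subjects = sim.generate_subjects(seed=1)
panel = sim.generate_panel()                      # 357 features
longitudinal = sim.simulate_longitudinal_hcv(subjects, panel, seed=1)
paired = paired_differences(longitudinal, pre="pre", post="post")
result = PairedSAM(paired).fit(n_perm=1000, seed=1, fdr_threshold=0.01)
print(result.summary())
```

```
Two-class paired SAM
  features:        357
  s0:              0.4508
  pi0:             1.000
  permutations:    1000
  FDR threshold:   0.01
  chosen delta:    0.2225
  features called: 13
```

The 13 called features are exactly the planted improvements: the pSTAT1
response to IFN-α in all seven lineages (`resp_IFNa_pSTAT1_*`), IκBα in
monocytes, the DC IFN-γ response, and four serum analytes. `result.frame`
holds per-feature d statistics, `result.fdr_table` the Δ → FDR curve, and
`result.plot()` the classic SAM observed-vs-expected plot.

The whole pipeline (simulate → regress → domains → cluster → sam →
network → kinetics) runs from one command and one seed:

```bash
inflamsig run-all --seed 1 --outdir results/
```

writing TSV tables (regression results, domain overlap, gap curve, SAM
calls, per-timepoint GraphML networks, robustness report, trajectories)
plus a run manifest; re-running with the same seed reproduces every table
byte for byte.

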