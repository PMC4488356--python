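# chemores

Personalized chemoresistance analysis for expression cohorts.

Bulk expression cohorts of heterogeneous tumors (the motivating case is
basal-like / triple-negative breast cancer treated with anthracyclines)
contain patients who respond to chemotherapy (CR) and patients who do not
(NOCR) — and the *resistant* patients are themselves heterogeneous: a gene
can drive resistance in one molecular subgroup while staying perfectly
normal in another. Conventional two-group tests (t-test, SAM, …) average
over that substructure and miss subgroup-restricted resistance genes.
`chemores` implements a pipeline designed for exactly this situation:

1. **Deviation-score differential expression.** Per gene, the sensitive
   group defines a *normal range* `[μ₁ − σ₁, μ₁ + σ₁]`. Each resistant
   sample contributes its clamped excursion beyond the range, and the gene
   score is the cumulative sum

   `score(g) = Σᵢ (X₂ᵢ − X′)`, with `X′ = X_max` if `X₂ᵢ > X_max`,
   `X′ = X_min` if `X₂ᵢ < X_min`, and `X′ = X₂ᵢ` otherwise,

   so only out-of-range expression counts. Significance comes from
   permuting the CR/NOCR labels (10,000 permutations by default,
   empirical p with add-one correction, calls at p < 0.05). A gene shifted
   in only a *subset* of resistant patients still accumulates score from
   exactly those patients — which is what makes the statistic sensitive to
   personalized resistance genes.
2. **Subgrouping.** The significant-gene submatrix is median-centered
   (genes, then samples), samples are compared by centered Pearson
   correlation distance `1 − r`, and average-linkage (UPGMA) clustering
   splits the cohort into molecular subgroups; each subgroup is summarized
   by its CR/NOCR composition and flagged resistant on an NOCR majority.
3. **Subgroup gene allocation.** A significant gene is *specific* to a
   resistant subgroup when its subgroup mean falls outside the sensitive
   group's fluctuation range (mean ± sd), and symmetrically for sensitive
   subgroups against the resistant range; intersecting the per-subgroup
   lists yields the *common* resistance genes.
4. **Pathway analysis.** Subgroup gene sets are tested for enrichment
   against a GMT pathway collection with the upper-tail hypergeometric
   probability and Benjamini–Hochberg FDR, and every enriched pathway P is
   scored per subgroup with the deviation score
   `A(P) = log₁₀( (1/N) Σᵢ (X̄ᵢ − Ȳᵢ)² )` over its N differentially
   expressed genes (subgroup mean X̄ᵢ vs sensitive mean Ȳᵢ).
5. **Hub biomarkers.** A protein-interaction edge list is restricted to
   the candidate (pathway) and common resistance genes; node degrees are
   converted with log₂ and genes with `log₂(degree) > 4.7` (≈ ≥26
   neighbors) are selected as hub biomarkers.
6. **Validation classifier.** Expression of the biomarkers is discretized
   per cohort by the μ ± s rule into {−1, 0, 1}, a seeded decision tree is
   trained on the discovery cohort and evaluated on a validation cohort
   (labels from the response column, or from disease-specific survival
   dichotomized at 3 years), reporting per-label precision/recall/F1/support.

A seeded synthetic-cohort generator (`chemores.synthetic_data`) plants all
of this structure — common and subgroup-specific shifted genes, latent
sensitive subgroups, enriched pathways, network hubs — so every stage is
testable against a known ground truth without any downloads.

## Worked example

Run the full pipeline on the default synthetic cohort (500 genes,
24 CR / 22 NOCR, two planted subgroups on each side, 2-sd shifts):

```
$ chemores run-all --seed 17 --out results/demo
{
  "biomarkers": 3,
  "classifier_features": 3,
  "common_resistant_genes": 62,
  "enrichment_sets": 3,
  "genes": 500,
  "network_nodes": 91,
  "samples": 46,
  "significant_degs": 172,
  "significant_pathways": 2,
  "subgroups": 4
}
```

172 of 500 genes are called significant (the cohort plants 60 common +
2×40 subgroup-specific shifted genes; ~5% of the null genes are expected
false positives at α = 0.05). Cutting the dendrogram at k = 4 cleanly
separates the cohort (`subgroup_summary.tsv`):

```
subgroup  size  n_cr  n_nocr  dominant_response  resistant
       1    13    13       0                 CR      False
       2    11    11       0                 CR      False
       3    11     0      11               NOCR       True
       4    11     0      11               NOCR       True
```

Allocation finds 62 common resistance genes; both planted pathways are
significantly enriched, and each scores highest in its own resistant
subgroup in `pathway_deviation.tsv` (e.g. `PW_R1_1` scores 0.37 in its
planted subgroup versus −1.7 to −0.9 elsewhere). The degree stage selects
the three planted hubs (`biomarker_degrees.tsv`, degrees 31–33, log₂
4.95–5.04 > 4.7), and the decision tree trained on their discretized
expression reaches 71.7% accuracy on the simulated validation cohort
(`classification_report.json`). Every stage output is a plain TSV/JSON in
the output directory, and rerunning with the same seed reproduces them
byte for byte.

The same stages are available individually (`chemores simulate`,
`detect-degs`, `subgroup`, `allocate`, `enrich`, `biomarkers`,
`classify`), or as library functions.

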