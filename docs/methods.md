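# Methods

This note documents the statistical model behind `chemores`, the defaults
and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical conventions used throughout.

## Deviation-score test

For gene *g*, let the sensitive group (CR, size n₁) have mean μ₁ and
sample standard deviation σ₁ (n − 1 denominator, as everywhere in this
package). The *normal range* is [μ₁ − σ₁, μ₁ + σ₁]. Each resistant sample
value X₂ᵢ contributes its clamped excursion beyond the range
(X₂ᵢ − X_max if above, X₂ᵢ − X_min if below, 0 inside), and the **raw
score** is the signed sum of the n₂ contributions. The signed sum is the
statistic as classically printed; because upward and downward excursions
cancel, the package also computes an **absolute score** (sum of
|contribution|) and exposes `statistic="absolute"` as a robust
alternative. The default is the signed score, tested two-sided on its
magnitude.

Significance: B label permutations (default 10,000) re-draw which n₁
samples play the sensitive role, preserving group sizes; each permutation
rebuilds the normal range and rescores. The empirical p-value uses the
add-one correction p = (#{|s_b| ≥ |s_obs|} + 1)/(B + 1), so p ∈ [1/(B+1), 1]
and p = 1 for degenerate genes (e.g. constant rows). One shared, seeded
sequence of shuffles is reused across genes — this is what makes the
gene-by-gene computation vectorizable and the run exactly reproducible;
per-gene independent streams would change nothing statistically for
marginal p-values. Calls are made at raw p < α (default 0.05) with no
multiplicity correction, matching the procedure the pipeline reproduces;
a Benjamini–Hochberg q-value column is emitted for reference only.

Properties the tests verify: translation invariance, positive
homogeneity (scores scale with the data, p unchanged), |raw| ≤ abs,
agreement of the Monte-Carlo p with exhaustive enumeration over all
C(n, n₁) label assignments on small cohorts, and type-I error ≈ α on null
cohorts.

## Subgrouping

Clustering operates on the significant-gene submatrix only. Following the
Cluster 3.0 conventions: one pass of median centering over genes, then
one pass over samples (not iterated — a single pass is not a fixed point
in general, and the iterated version changes results only marginally);
centered Pearson correlation between sample columns, converted to the
distance 1 − r; UPGMA (average linkage) agglomeration. Linkage is
delegated to scipy's nearest-neighbor-chain implementation, which is
deterministic for a fixed input; its tie-breaking order can differ from
naive smallest-index merging on exactly tied distances, which never
affects the cut assignments tested here.

**Choice of k.** `cut_clusters` accepts an explicit k or selects it by
maximal mean silhouette on the correlation distance (k = 2…10). The
silhouette default is honest but has a measurable failure mode on
*nested* structure: when a dominant axis (CR vs NOCR) separates two
blocks that each contain weaker subgroups, the global silhouette (0.43 at
k = 2 vs 0.27 at k = 4 on default synthetic cohorts) always prefers the
top-level split, as do Calinski–Harabasz and Davies–Bouldin. The
dendrogram itself is correct — cutting at k = 4 recovers the planted 2+2
subgroups with ARI 0.94–1.0 — so the pipeline's default configuration
fixes k = 4, the four-subgroup design of the basal-like cohort it models,
and leaves `k: null` (silhouette selection) available for exploratory
use. Subgroups are flagged resistant by strict NOCR majority; a tie is
flagged sensitive with a warning.

## Gene allocation

The *fluctuation range* of a reference group is read as mean ± sd over
that group's samples — the same construction as the normal range, which
keeps the two stages internally consistent. The alternative reading (the
span of the opposite group's per-subgroup means) is implemented behind
`mode="span"`. A significant gene is specific to resistant subgroup *j*
iff its mean over subgroup *j* lies strictly outside the sensitive
(all-CR) range; sensitive subgroups are treated symmetrically against the
pooled resistant range. Genes may be specific to several subgroups; the
intersection across resistant subgroups (`common_resistant`) and across
all subgroups (`common_all`) are both reported, because published counts
of this procedure require overlapping per-subgroup lists. Allocation is a
deterministic rule, not a second hypothesis test.

## Pathway analysis

Enrichment uses the exact hypergeometric upper tail P(X ≥ k) with the
universe = expression genes ∩ pathway-annotated genes (the universe is
configurable; there is no canonical choice when the annotation source is
external), and BH q-values across the tested pathways; significance is
called at raw p < 0.05, with q-values reported. The pathway deviation
score is A(P) = log₁₀((1/N) Σ (X̄ᵢ − Ȳᵢ)²) over the pathway's N
differentially expressed genes, with Ȳᵢ always the mean over *all*
sensitive samples — including when scoring sensitive subgroups, whose
scores are therefore small but not identical. The variant without the
1/N factor (log of the cumulative sum) differs by exactly log₁₀ N and is
available behind `variant="sum"`; the mean form is the default because it
is the displayed formula of the procedure being reproduced. A pathway
whose mean squared deviation is exactly zero has an undefined score and
is reported as NA (never −∞, to keep TSV round-trips clean). Every
pathway enriched for any subgroup gene set is scored in every subgroup,
using the same gene set (pathway ∩ significant genes) in each column so
the columns are comparable.

## Network biomarkers

The interaction network is the induced simple subgraph on the candidate
genes (significant genes inside enriched pathways) plus the common
resistance genes; edges are unweighted and any confidence scores in the
input are ignored. Degrees are counted within this restricted node set
(a flag-free design choice: the procedure's own description counts
interactions "with" candidate and common genes). Selection is strict:
log₂(degree) > 4.7, i.e. degree ≥ 26; note the slight mismatch with the
verbal "at least 25 neighbors" (log₂ 25 ≈ 4.64) — the logarithmic
threshold is taken as operative since it is the one used to produce the
published gene list. Isolated nodes have undefined log-degree and are
never selected.

## Validation classifier

Discretization maps each gene row to {−1, 0, 1} by value > μ + s → 1,
value < μ − s → −1, else 0, with μ, s computed per cohort — so the code is
invariant to strictly increasing affine transforms of a gene row, which
is the property that lets discovery and validation cohorts from different
platforms share a feature space. Boundary values map to 0 (strict
inequalities as printed). The decision tree uses Gini impurity, no depth
limit, minimum leaf size 1, and a fixed seed; all are exposed. The
classification report computes per-label precision, recall, F1 and
support from raw confusion counts (cross-checked against scikit-learn in
the tests) and reports *both* macro and support-weighted averages,
because the published "avg / total" row matches neither convention
exactly; this package reports the standard ones and does not attempt to
replicate that row. Validation labels come from a `dss_years`
(disease-specific survival) column dichotomized at 3 years when present
— below 3 years ⇒ chemoresistant — else from the `response` column.

## Synthetic cohorts

`SyntheticConfig` defaults are the study conditions all calibration and
recovery numbers refer to: 500 genes; 24 sensitive / 22 resistant samples
(the basal-like cohort sizes); 2 resistant + 2 sensitive latent
subgroups; 60 common-DE genes and 40 specific-DE genes per resistant
subgroup (≈1:6 scale-down of the ~3,000 DEGs / 819 common genes of the
motivating dataset, keeping their proportions); 40 marker genes per
sensitive subgroup shifted only within that subgroup's CR samples, so the
clustering stage can split the sensitive side as well; shifts of
2 noise-sd with per-gene random sign (both up- and downregulation occur);
unit Gaussian noise, a reasonable idealization of RMA-normalized,
z-scored log expression. Pathways: 20 sets of 20 genes, one planted per
resistant subgroup with ≥80% of members from that subgroup's specific
genes, background sets drawn from unshifted genes. Network: 3 hubs of
degree 32 whose neighbors are drawn from the common-DE and
planted-pathway genes (the candidate-and-common neighborhood the
biomarker stage restricts to; without this the induced subgraph would
truncate hub degrees below the selection threshold by construction),
background edges with probability 0.01. A paired validation cohort
reuses the same gene roles and shift signs with fresh noise and carries
`dss_years` consistent with its response labels.

What the generator does **not** emulate: probe-level artifacts, batch and
platform effects, RMA preprocessing, correlated gene-gene noise,
non-Gaussian heavy tails, label noise in the survival dichotomization,
or literature-biased interaction networks. Passing recovery tests
therefore demonstrate that the algorithms are implemented correctly and
behave as designed under their own model assumptions — not that the
biological findings of any particular dataset are correct or that the
pipeline is robust to real-world confounding.

## Numerical conventions and degenerate inputs

Standard deviations use the n − 1 denominator everywhere. Zero-variance
genes: dropped at z-scoring (counted and logged); degenerate normal range
(x_min = x_max) allowed with a warning; discretized to all zeros with a
warning. Missing expression entries cause the whole gene row to be
dropped at load (counted); duplicate gene rows are collapsed by mean.
Empirical p-values can never be 0 (add-one correction). Correlation
distances are symmetrized and clipped at 0 against floating-point noise;
constant sample columns are an error naming the sample. Undefined
pathway scores and log-degrees are NA. All randomness flows from
explicit integer seeds; pipeline reruns with the same config are
byte-identical, and problem sizes throughout (500-gene cohorts, B = 1,000
permutations in tests and summary scripts, B = 10,000 in the pipeline
default) were chosen so a full run takes seconds on one CPU while keeping
every Monte-Carlo estimate's standard error well inside the asserted
tolerances.
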