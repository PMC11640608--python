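# Methods

## The pathway-activity model

Each signal-transduction pathway is scored by a naive-Bayes ("two-layer")
network. The latent node *T* is the binary state of the pathway's terminal
transcription factor; its children are the pathway's direct target genes,
each binary (up-expressed or not). Because the gene nodes are conditionally
independent given *T*, the posterior odds of activity factorize into one
likelihood ratio per gene, which keeps inference exact and O(#genes).

Two modeling layers had to be fixed where only the qualitative design is
public:

* **Observation layer.** Log2 intensities are turned into soft evidence
  `e_g = σ(slope · (x_g − t_g))` with the per-gene threshold `t_g` defaulting
  to the cohort median. The median is scale-robust across platforms and
  makes a zero-variance gene exactly uninformative (e = 0.5 ⇒ LR = 1).
  `slope` (default 1.0 per log2 unit) controls how sharply expression is
  dichotomized; explicit per-gene thresholds can be supplied instead, e.g.
  from a reference cohort.
* **Conditional probability tables.** `P(up | T=active) = 0.5 + κ·w`,
  `P(up | T=inactive) = 0.5 − κ·w` for an up-regulated target of evidence
  weight `w ∈ (0, 1]` (roles swapped for down-regulated targets). κ = 0.45
  bounds every CPT entry inside (0.05, 0.95), so no single gene can produce
  an infinite likelihood ratio; weights scale a gene's maximal influence,
  mirroring literature-evidence weighting. Both κ and the prior
  P(active) = 0.5 are configurable.

A gene listed in a pathway but absent from the matrix contributes LR = 1
(with a warning) rather than erroring: cross-platform gene coverage varies
and neutrality is the correct marginalization of an unobserved leaf.

## Score normalization

Scores are the linear map of log2-odds onto [0, 100] between two calibration
anchors, clipped outside. In the default "extremes" mode the anchors are the
minimal and maximal attainable log2-odds: the active anchor sets every
up-target to e = 1 and every down-target to e = 0, the inactive anchor the
mirror image. Defining the active extreme direction-aware (rather than
e = 1 for all genes regardless of direction) is deliberate: with
down-regulated targets present, an all-genes-up profile is *not* maximal
evidence of activity, and anchoring there could invert the scale. With
extremes anchors the clip is a no-op and 0/100 retain their semantics of
"odds of a fully inactive/active pathway". Explicit anchors (e.g. from
reference samples) may be supplied per pathway instead. Scores of different
pathways are not directly comparable: each pathway occupies its own
empirical sub-range of the scale, which the package reports per cohort
rather than hard-coding.

## Cohort handling

Eligibility filtering removes treated, contaminated and non-ovarian samples
(flags in the metadata sidecar; a missing flag means false). The per-rule
exclusion counts are logged; a sample failing several rules is counted under
each, so the counts can exceed the removed total but never undershoot it.
Replicates are averaged **on scores**, not on expression, within each
(entity, dataset) pair; the same cell line measured in different datasets
keeps one row per dataset, which is what enables cross-laboratory
comparisons of the same line. The growth-factor pathways MAPK, PI3K and
JAK-STAT3 default to excluded from cell-line analyses because their activity
tracks culture conditions (serum growth factors) rather than tumor biology.

## Clustering and characterization

Clustering is agglomerative on the pathway-score vectors, Ward linkage on
Euclidean distance by default (compact, variance-minimizing clusters on
commensurate 0–100 columns); both are config keys since no single choice is
canonical. k = 7 is the default cut. The dendrogram is exported as Newick
with branch lengths equal to merge-height differences.

Groups (clusters or histological subtypes) are characterized per pathway by
a Kruskal–Wallis omnibus and pairwise two-sided Mann–Whitney tests, all at
α = 0.05 with stars at 0.05/0.01/0.001/0.0001. A group is labeled High
(Low) on a pathway only when it differs significantly from at least three
other groups and every significant difference points the same way;
significant but fewer-than-three or mixed-direction patterns give "CNBD"
(cannot be determined). Single-member groups are untestable: comparisons
against them are flagged CNBD and they earn no labels. Pairwise p-values are
uncorrected by default — the labeling rule itself already demands replicated
significance — with Holm adjustment available as a config switch.

## Matching and ranking

Each tumor is assigned to the cell line minimizing the summed squared score
difference over a pathway subset (default: AR, ER, HH, Notch, TGF-β — the
hormonal and developmental pathways; the full seven-pathway set is used for
clustering). Exact ties break lexicographically on cell-line id and are
flagged; the subset used is recorded in every result. Composition summaries
report integer percentages (round half up). The recommendation ranking uses
a two-tier rule: cell lines whose matched samples are mostly (> 50%) of the
target histology, by matched count descending, then the remaining matched
cell lines; the rule identifier is emitted with the output because a
recommendation order is inherently a modeling choice, not a statistic.

## Synthetic data

The generator emulates multi-laboratory microarray cohorts: per-gene
baselines ~ N(8, 1) on the log2 scale, and for a sample with latent activity
`a ∈ [0, 1]` on a pathway, each up-target is shifted by `a · effect · w`
(down-targets mirrored) with `effect = 3.0` log2 units — roughly an
eight-fold expression swing for a fully active pathway at full weight — plus
Gaussian noise. Seven default archetypes (hormonal-high, hormonal-low,
HH-driven, Wnt/HH, …) assign levels 0.9/0.1/0.5 per pathway; synthetic
pathway definitions carry 25–35 targets, weights U(0.3, 1) and ~20%
down-regulated genes. Replicates share their entity's latent state. Noise is
drawn as `noise_sd × standard_normal` from the seeded stream, so cohorts at
different noise levels under one seed share the same noise realization up to
scale — this makes "recovery degrades monotonically with noise" a
well-posed, reproducible check.

What the generator does **not** emulate: probe-level artifacts, batch
effects between series, correlated noise across genes, pathway cross-talk,
or clonal drift of cell lines. Recovery results on synthetic data therefore
demonstrate the correctness of the inference/clustering/matching machinery,
not expected performance on real cohorts, where effect sizes are smaller and
structure messier.

Two default archetypes (HH-driven vs Wnt/HH) differ only through NF-κB and
Wnt, which lie outside the default 5-pathway matching subset, so archetype
recovery through matching is measured on the full analysis pathway set;
on the 5-pathway projection those archetypes are indistinguishable by
construction and same-archetype accuracy has a ceiling around 0.86.

## Problem sizes and numerics

Test and acceptance runs use desk-scale cohorts (4 cell lines and 6 tumors
per archetype, 7 pathways ≈ 200 genes; 1000 repeats for the type-I-error
simulation) — large enough for stable statistics, small enough to run
anywhere in minutes. Exactness choices: inference is validated against
exhaustive joint enumeration to 1e−9 on the log2 scale for ≤ 8 targets;
normalization divides before scaling so the anchors map to exactly 0
and 100; clustering and rank tests inherit scipy's deterministic tie
handling, and every stochastic path takes an explicit integer seed.

## Known limitations

* The CPT parameterization and logistic observation layer are principled
  reconstructions of a commercial model family whose trained parameters are
  not public; absolute score values are therefore not comparable to any
  published clinical scores, only to scores from this package.
* Real target-gene lists are not bundled; users must supply pathway
  definitions (JSON) built from literature or use the synthetic generator.
* The Kruskal–Wallis p-value uses the chi-square approximation (as is
  standard), which is anticonservative for very small groups; groups of
  size 1 are excluded from inference altogether rather than approximated.
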