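# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices, and the limitations of `ovorigin`.

## The model

The package answers one question: given bulk RNA-seq of four sample groups —
normal fallopian-tube epithelium (N-FT), normal ovarian-surface epithelium
(N-O), and tumors derived from each (T-FT, T-O) — construct gene signatures
that distinguish the two tumor types, and score arbitrary expression
profiles for fallopian-tube-like versus ovarian-surface-like character.

### Normalization and differential expression

Size factors are median-of-ratios: for sample *i*,
`s_i = median_g (c_gi / geomean_g)` over genes with positive counts in every
sample, then rescaled to geometric mean 1. The median is taken on the ratio
scale (for even gene counts this averages the two central ratios rather than
their logs). If no gene is positive everywhere the estimator refuses and
suggests a pseudo-reference; we deliberately do not silently fall back.

Each gene is tested between two groups with a negative-binomial Wald test:

- Dispersion `φ_g` (variance `μ + φμ²`) is estimated by method of moments on
  size-factor-normalized counts: the within-group pooled variance solved for
  `φ`, floored at 1e-8. Per-gene estimates at n of 3–6 are noisy, so they are
  shrunk halfway toward a monotone trend `φ̃(μ) = a₁/μ + a₀` fit by
  non-negative least squares over all genes. The 50/50 shrink is a fixed
  design choice: enough pooling to stabilize small-sample estimates, enough
  per-gene freedom to keep genuinely overdispersed genes conservative.
- Group means are the NB maximum-likelihood solutions of the score equation
  `Σ_i (c_i − s_i m)/(1 + φ s_i m) = 0`, solved by vectorized Newton
  iteration (30 iterations, halving steps that would go non-positive).
- A pseudo-mean of 0.5 (the logCPM prior, on the normalized-count scale) is
  added to both group means before forming `β = ln(m_B) − ln(m_A)`, so fold
  changes remain finite when one group is all zero. Applying it to both
  groups, always, keeps the statistic continuous in the data; at typical
  baselines (mean ≈ 100) the shrinkage is < 1%.
- The Wald statistic is `z = β/SE` with `SE² = 1/ΣwA + 1/ΣwB`,
  `w_i = μ_i/(1 + φμ_i)` (the Fisher information of the two-group log-link
  GLM), and the two-sided p comes from the standard normal. Genes with zero
  counts everywhere report missing p-values and `log2fc = 0`.

This is a desk-scale test in the DESeq2 family; bit-level agreement with any
particular implementation is not a goal. Correctness is defined by the
calibration suite: on a null simulation (2000 genes, 6 vs 6, φ = 0.1) the
type-I error at nominal 0.05 must lie in [0.02, 0.08] (measured ≈ 0.055),
and planted four-fold genes at baseline 100 with 5 vs 5 replication must be
detected at ≥ 95 % after FDR control (measured 100 %). Independent filtering,
fold-change shrinkage, outlier handling, and covariates are intentionally
not implemented. Benjamini–Hochberg runs within each comparison separately,
with missing p-values excluded from *m*.

Orientation convention: a table "B vs A" reports `log2fc` of B relative to
A, so tissue markers of the fallopian tube come out negative in
"N-O vs N-FT". The six pairwise tables are stored under a canonical
"later vs earlier" orientation of (N-FT, N-O, T-FT, T-O) and flipping an
orientation negates `log2fc` while preserving p-values.

### logCPM

`logCPM_gi = log2((c_gi + p)/(L_i + 2p) × 1e6)` with library size `L_i` and
prior `p = 0.5`. The prior is a fixed pseudo-count, not scaled with depth;
consequently doubling all counts shifts logCPM by first-order
`p/(2c·ln 2)` (< 0.004 log₂ units at counts ≥ 100) rather than being
exactly invariant. The closed form and its behavior are pinned by tests.

### Minimax-p signatures

For target group T with others X, Y, Z: a gene is *eligible* when
`log2fc > 0` in all of "T vs X", "T vs Y", "T vs Z" — upregulation with no
significance floor. Its selection p is `max` of the three *raw* pairwise
p-values (adjusted values would tie heavily; significance enters only
through the ranking). Genes are ranked ascending on selection p; ties break
by larger minimum |log2fc| across the three comparisons, then
lexicographically by gene id, making construction invariant to input order.
The top *k* genes form the signature; requesting more than the eligible
count returns all eligible genes with a truncation flag. Signatures at
sizes 50/100/250/500 are prefixes of one another by construction.

The gene universe is restricted, when an orthology table is supplied, to
protein-coding genes with a human ortholog supported by at least one of the
14 databases of an HCOP-style resource. One-to-many mouse→human mappings
resolve to the symbol with the most supporting databases (ties by symbol
name); symbol collisions keep the better-ranked signature gene; a signature
more than half unmappable is an error rather than a silent attrition.

### Scores

Within each dataset independently (never pooled across datasets), each
gene's log-expression is z-scored across samples with the n−1 denominator.
Constant genes get z = 0 and a flag instead of being dropped, so signature
coverage does not vary between samples. A signature score is the arithmetic
mean z over the signature genes present in the matrix (absent genes lower
the recorded coverage); the combined cell-of-origin score is
`FT−O = ft_score − o_score`, positive meaning greater FTE character.
Genome-wide z-scoring and z-scoring restricted to signature genes are
identical per gene, so the implementation z-scores genome-wide.

### Cohort analysis

- **Subtype contrasts.** The FT−O score is compared between subtype groups
  by Mann–Whitney U. For pooled sizes ≤ 12 without ties the exact null is
  enumerated; otherwise the normal approximation with midranks, tie
  correction, and continuity correction is used. The exact path is verified
  equal to a brute-force enumeration over all `C(n+m, n)` assignments; the
  asymptotic path is verified within 0.02 of enumeration at the smallest
  sizes it serves (n+m = 13–14, balanced splits). All-identical pooled data
  returns p = 1.
- **IPL ranking.** Each pathway-activity feature is correlated (Pearson)
  with the FT−O score over shared samples; features are ranked by |r|
  descending with signed r reported, ties broken by feature name, constant
  features excluded with a note. The default report keeps the top 50.
- **Clustering.** Euclidean distances between samples over all genes,
  complete-linkage agglomeration by default (average linkage available) —
  complete linkage is deterministic and compact, and the group-segregation
  behavior on planted data is linkage-robust. Output includes the distance
  matrix, the linkage, the deterministic leaf order, and a Newick tree.

## The synthetic-data generator

`simulate_mouse_experiment` emulates the four-group design: 5 T-FT, 3 T-O,
3 N-FT, 3 N-O samples (the study sizes), 2000 genes, log-normal baselines
(median 100, sd of ln = 1), per-sample size factors uniform in [0.7, 1.3],
NB counts with shared φ = 0.1. Five disjoint programs are planted with
|log2FC| = 2: FT markers (100 genes, high in N-FT and T-FT), O markers
(100, high in N-O and T-O), shared tumor genes (50, high in both tumors),
and FT- and O-tumor-specific genes (50 each, high in one tumor group only).
Tissue-marker programs are larger than tumor programs so tissue identity
dominates the transcriptome — that is what makes the four groups segregate
with a tissue-level split at the dendrogram root, the qualitative structure
the pipeline is meant to detect.

`generate_orthology_table` assigns each gene a biotype and a human symbol
with 1–14 supporting databases; configurable fractions of background genes
are non-coding or orphaned to exercise the universe filter. Planted program
genes are always protein-coding with an ortholog: the ground truth is
in-universe by design, so recovery metrics measure the pipeline rather than
random dropout of the truth. Filter behavior on orphans is tested separately
with no planted genes, where exclusion counts are exactly binomial.

`simulate_cohort` draws a latent origin coefficient α ~ Uniform[0, 1] per
sample (Beta or degenerate options available) and sets log-scale expression
to `α·(T-FT profile) + (1−α)·(T-O profile)` on the human-symbol namespace,
plus Gaussian noise (sd 0.5). The cohort is generated directly on the log
scale — external cohorts arrive normalized, and the scoring stage must not
assume raw counts. Subtype labels are "mesenchymal-like" above the upper
30 % α-quantile, "proliferative-like" below the lower 30 %, "other" between
(quantile cut-offs give separated groups without degenerate sizes). Of 200
pathway features, 10 informative ones equal `α + N(0, 0.2)`; the rest are
standard normal noise.

What the generator does **not** emulate: gene-length/GC bias, batch
effects, per-gene dispersion trends, correlated gene programs, realistic
subtype heterogeneity, or any specific normalization of real tumor
compendia. Passing tests therefore demonstrate that the pipeline recovers
planted structure under its own model assumptions — not that it would
reproduce any particular published cohort analysis.

## Seeding and determinism

Every stochastic stage derives its generator from one master seed via
`SeedSequence([seed, stage])` with stage ids 0 (mouse counts), 1
(orthology), 2 (cohort), so partial reruns reproduce exactly. Pipeline
outputs are byte-identical across runs of the same configuration; the run
manifest records the seed and a hash of the full configuration.

## Problem sizes

The default study (2000 genes, 14 mouse samples, 100 cohort samples) runs
the full pipeline in about a second; the test suite and the acceptance
script each complete in well under a minute. These sizes were chosen so the
planted effects are comfortably identifiable at the study's replication
levels while keeping simulation-based calibration (thousands of genes,
hundreds of label shuffles) cheap to repeat.

## Known limitations

- The NB test uses a normal reference for the Wald statistic with no
  small-sample degrees-of-freedom correction; calibration is verified at
  n ≥ 5 per group and degrades below that.
- Selection p-values are reused descriptively in signatures; they are not
  corrected for the selection step and should not be read as inference.
- The moment/trend dispersion estimator assumes a shared mean–dispersion
  relationship; strongly bimodal dispersion structure would be over-shrunk.
- `venn_summary` percentages are integer-rounded, matching how such overlaps
  are reported.
- The exact rank-sum path requires tie-free data; tied small samples fall
  back to the tie-corrected normal approximation.
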