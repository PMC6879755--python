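# ovorigin

Cell-of-origin transcriptomic scoring for high-grade serous ovarian
carcinoma (HGSOC).

HGSOC can arise from two candidate tissues: the fallopian tube epithelium
(FTE) and the ovarian surface epithelium (OSE). Given RNA-seq counts from a
four-group design — normal FTE (N-FT), normal OSE (N-O), and tumors derived
from each (T-FT, T-O) — `ovorigin` builds tumor signatures specific to each
cell of origin and scores any expression dataset for FTE-like versus
OSE-like character. It is aimed at computational biologists who want to ask,
for a tumor cohort, *which cell of origin does each sample resemble?*

## Method

1. **Differential expression.** Counts are normalized with median-of-ratios
   size factors and every pair of the four groups is compared with a
   negative-binomial Wald test (log-link GLM with a group indicator;
   method-of-moments dispersion `φ̂_g` shrunk halfway toward a monotone
   mean–dispersion trend; `var = μ + φμ²`). Benjamini–Hochberg adjustment is
   applied within each comparison.
2. **Minimax-p signatures.** The universe is restricted to protein-coding
   genes with a human ortholog. For a target group (T-FT or T-O), a gene is
   eligible if upregulated (`log2FC > 0`) versus *all three* other groups.
   Each eligible gene has three pairwise p-values; its *selection p* is the
   largest (least significant) of the three. Genes are ranked ascending on
   selection p and the top *k* ∈ {50, 100, 250, 500} form the signature.
3. **Scoring.** log₂ counts-per-million (pseudo-count 0.5) are z-scored per
   gene within each dataset; a signature score is the mean z over its genes,
   and the combined cell-of-origin score is

   `FT−O = mean z(T-FT signature) − mean z(T-O signature)`

   so positive values mean greater FTE character.
4. **Cohort application.** Signatures are mapped to human symbols (best
   supporting-database count wins), the cohort matrix is z-scored within
   itself, subtype groups are compared with Wilcoxon rank-sum tests, and
   pathway-activity (PARADIGM IPL) features are ranked by |Pearson r| with
   the combined score. Sample structure is summarized by Euclidean-distance
   hierarchical clustering.

A synthetic-data module generates the whole study with known ground truth
(planted tissue-marker and tumor programs, a latent origin coefficient
α ∈ [0, 1] mixing the two tumor profiles in the cohort), so every stage is
testable without external data.

## Worked example

```python
from ovorigin import (SimulationConfig, simulate_mouse_experiment,
                      generate_orthology_table, simulate_cohort,
                      CellOfOriginModel)

cfg = SimulationConfig(seed=1)
matrix, truth = simulate_mouse_experiment(cfg)
orthology = generate_orthology_table(cfg, truth)
cohort, truth = simulate_cohort(cfg, truth, orthology)

results = CellOfOriginModel(matrix, orthology=orthology).fit()
print(results.summary())
applied = results.apply_to_cohort(cohort, k=50)
print(applied.summary())
```

prints (abridged):

```
Cell-of-origin model fit
============================================================
genes: 2000   samples: 14
gene universe: 1833 (ortholog/biotype filtered)
adjusted-p threshold: 0.05

comparison           DEGs (padj < alpha)
N-O vs N-FT                          203
...
T-O vs T-FT                          317

signature               size     max selection p
T-FT_top50                50             0.00756
...

Cohort application (signature size k=50)
============================================================
samples scored: 100
subtype contrasts (rank sum on FT-O score):
  mesenchymal-like > proliferative-like: U=900.0, p=3.02e-11 (n=30/30)
top IPL features by |Pearson r| with the FT-O score:
    1. IPL_0006  r=+0.830
...
```

Reading this: the six pairwise comparisons find a few hundred DEGs each
(the simulation plants 350 regulated genes among 2000); the size-50 T-FT
signature's weakest member still clears selection p ≈ 0.008; and on the
synthetic cohort the mesenchymal-like subtype (high latent FTE coefficient)
scores decisively higher on FT−O than the proliferative-like subtype, with
the planted informative pathway features at the top of the correlation
ranking — the qualitative behavior expected of the score by construction.

The same pipeline is available from the shell:

```sh
ovorigin simulate --seed 1 --out-dir sim/
ovorigin de --counts sim/counts.tsv --annotation sim/annotation.tsv --all-pairs --out-dir de/
ovorigin all --seed 1 --out-dir run/      # simulate + fit + cohort, one shot
```

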