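# toxdescent

Comparative "toxicity by descent" analysis: how far across the animal
phylogeny are human disease genes, pathways and biomarker gene sets
conserved, and what does that imply for using invertebrate test species in
chemical hazard assessment?

The package is aimed at comparative genomicists and computational
toxicologists.  It takes a rooted species tree, a gene-family-by-species
copy-number matrix (with disease / non-disease / mixed class labels derived
from a morbid-gene list), per-pathway conserved gene and reaction counts,
and gene sets in GMT format, and runs four linked analyses:

1. **Family conservation and origins.**  Copy profiles are binarized and
   each family's evolutionary origin is reconstructed by Dollo parsimony: a
   family is gained exactly once (at the most recent common ancestor of the
   species carrying it) and can only be lost.  On a rooted tree the
   minimum-loss solution is unique — losses sit on the root edges of the
   maximal all-absent subtrees inside the gain clade.  Branch-wise gain and
   loss counts for the disease class are compared against a null built from
   repeated random subsamples (without replacement, default 1000 replicates)
   of the non-disease class, reporting per-branch
   `z = (obs − mean)/sd`, `se = sd/√n`, and the one-sided normal 99% upper
   limit `mean + 2.326·se`.

2. **Pathway gene vs reaction conservation.**  Per-pathway conservation
   percentages (conserved / human count, for genes and for reactions),
   vertebrate and invertebrate group averages, and a GLM
   `invert ~ vert + n_genes + vert:n_genes` (binomial family, logit link,
   pathway size as variance weights) predicting invertebrate conservation
   from vertebrate conservation and human network size.

3. **Pure-loss network evolution.**  A phylogenetic maximum-likelihood model
   of pathway content: a pathway enters the root with `N ~ Poisson(λ)`
   elements and each element survives branch `b` independently with
   probability `s_b` (no gains or duplications).  Likelihoods use a
   postorder dynamic program with `Binomial(k, s_b)` branch transitions and
   a truncated Poisson root prior; an inside–outside pass yields exact
   ancestral count posteriors, expected per-branch whole-network losses
   (parent ≥ 1 → child 0) and contractions (parent ≥ 2 → child 1), and a
   rate tree with branch lengths `−ln s_b`.

4. **Shannon ranking and ortholog-set enrichment.**  Families are ranked by
   the Shannon index `H′ = −Σ p_i ln p_i` of their per-species copy
   proportions (high H′ = evenly spread, deeply conserved).  Gene sets are
   mapped to unique ortholog-family IDs and scored against the ranking with
   the weighted Kolmogorov–Smirnov running sum (preranked GSEA, gene-set
   permutation null, NES/FDR by the standard empirical procedure),
   including a biomarker-panel experiment comparing random panel subsets to
   random genome subsets.

A synthetic-data generator (`toxdescent.simulate`) produces all inputs with
the structure these analyses assume — single-origin profiles with
branch-specific loss and duplication, disease origins biased toward the
root, reactions that survive whenever any member gene survives, and
conservation-biased gene sets — together with truth logs, so the whole
pipeline is testable end to end without any database access.

## Worked example

```
python analysis/01_simulate_inputs.py
python analysis/02_family_conservation.py
```

prints, for the default desk-scale synthetic dataset (seed 42):

```
160 disease vs 745 non-disease families
disease families gaining at the root: 73%
subsampled non-disease root gains:    59%
root-gain z-score (disease vs null):  3.92
```

i.e. the disease class originates disproportionately at the bilaterian root
(73% vs 59% for size-matched non-disease subsamples), and the excess is
about 3.9 null standard deviations — the same qualitative signature the
pipeline is designed to detect in curated ortholog-database exports.  The
remaining drivers (`03`–`05`) write the pathway-conservation GLM, the
pure-loss fits (e.g. the reaction-loss tree comes out 19–49% shorter than
the gene-loss tree, reactions outlasting their member genes), and the
enrichment tables (66% of synthetic sets score positively; the
conservation-biased panel reaches p < 0.05 for 100% of random subsets vs 8%
for genome-wide subsets) under `results/`.

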