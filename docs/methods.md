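# Methods

This note records the models, conventions and parameter choices behind the
package, including the decisions taken where the problem admitted more than
one reasonable formalization.

## Species trees and input conventions

All stages share one rooted, internally labeled phylogeny (polytomies
allowed).  Two reference topologies ship with the package: a 12-species
suite spanning mammals (*Homo*, *Mus*), a frog, two fish, three insects,
three crustaceans and a nematode, rooted at Bilateria with Vertebrata and
Ecdysozoa as the two root clades; and an 8-species suite (five non-human
vertebrates plus *Drosophila* and *Caenorhabditis*) used for pathway-level
analyses.  Unlabeled internal nodes are auto-named `N<preorder-index>` so
event tables are stable across runs.  Species matching is exact-string,
with a small alias table (common shorthand → canonical underscored
binomial).

Every analysis is anchored on humans: the profile matrix validator requires
a positive *Homo sapiens* count for each family (disable with
`anchor=None`).  Families are classified from a morbid-gene list: `disease`
if *all* of the family's human genes are disease-linked, `non_disease` if
none, `mixed` otherwise.  Mixed families are kept in totals but excluded
from disease/non-disease contrasts.

Percentages quoted in summary tables are rounded half-up at the printed
number of decimals; this convention reproduces reference-table cells that
banker's rounding does not.

## Dollo parsimony

For a binary presence profile with at least one present leaf, the
minimum-loss single-gain reconstruction on a rooted tree is unique: the
gain is the MRCA of the present leaves and the losses are the root edges of
the maximal all-absent subtrees inside the gain clade.  (Moving the gain
above the MRCA adds an unavoidable loss and removes none; any loss edge
with a present descendant is contradictory; one loss per maximal absent
subtree is both necessary and sufficient.)  No tie-breaking is therefore
needed.  Gains at terminal branches (species-private families) are
permitted even though curated inputs typically exclude them.  Branch tables
list internal branches before terminal branches, in preorder.

## Subsampling null and z-scores

The observed class's branch statistics are compared against `n_reps`
(default 1000) random subsamples of the reference class, each of the
observed class's size, drawn **without replacement within a replicate and
independently across replicates** (subsamples may repeat across replicates;
the data do not dictate the alternative and this is the natural reading of
repeated random subsampling).  Per statistic we report the replicate mean,
sd (n−1 denominator — below printed precision at n = 1000 but fixed for
reproducibility), `se = sd/√n_reps`, the **one-sided** 99% normal upper
limit `mean + 2.326·se` (the two-sided 2.576 does not reproduce the
reference arithmetic), and `z = (obs − mean)/sd`.  A degenerate null
(sd = 0) yields z = 0 when the observation matches the mean and a signed
infinity sentinel (with a warning) otherwise.  Seeds are mandatory and
recorded in the output metadata.  No multiple-testing correction is applied
across branches; raw z-scores are reported.

Implementation note: per-family gains and losses are precomputed once, so a
replicate's branch tally is a column sum over the sampled rows — verified
in tests to equal rerunning the full event table on the subsample.

## Pure-loss likelihood model

Pathway content evolves by loss only: root size `N ~ Poisson(λ)`, each
element survives branch `b` independently with probability `s_b ∈ (0, 1]`.
Branches are parameterized by `s_b` directly — the trees carry no time
calibration, so a rate × time factorization would be unidentifiable.  One
shared `s_b` per branch is fitted across all pathways of a class (rates are
lineage properties, the standard usage for gene-content models); the
alternative of pathway-specific rates is noted as out of scope.

*Likelihood.*  Conditional on a node holding `k` elements, the child count
across a branch with survival `s` is `Binomial(k, s)`; a postorder pass
over count vectors `0..n_max` gives `P(leaf counts)`, with the Poisson root
prior truncated at `n_max` chosen so the tail mass is below 1e−12 (default
`max(observed) + ~6√λ`, raised adaptively; the optimizer's λ upper bound is
tied to the same tail condition).  The pass is vectorized across pathways
(one matrix product per branch) and rescaled per profile to avoid
underflow.

*Posteriors and tallies.*  An inside–outside pass yields exact conditional
count distributions at every node, and joint parent–child distributions per
branch.  A pathway is counted **lost** on a branch when the parent holds
≥ 1 element and the child none, and **contracted** when the parent holds
≥ 2 and the child exactly 1; expected tallies are sums of these joint
posterior probabilities over pathways, with cumulative root-to-leaf
percentages.  This formalization of "lost or contracted to a single
element" is recorded here because the verbal definition admits variants.

*Fitting.*  `logit(s_b)` and `log λ` are optimized jointly by bounded
L-BFGS-B with finite-difference gradients and 5 multi-starts (start seeds
logged): the first start uses moment-based initial values (λ from the
largest leaf mean, survivals from leaf-mean ratios along root paths),
subsequent starts jitter them.  Non-convergence of every start raises an
error carrying the best model found.  Genes and reactions are fitted as two
independent runs over the same tree.  The reported "rate tree" uses branch
lengths `−ln s_b` (expected per-element loss intensity).

## Pathway conservation and the GLM

Size filtering keeps terminal pathways with 3–1227 human genes (elements
are genes with identifiers; reactions never enter the size filter), and the
filter log is exact: input = retained + removed_small + removed_large +
removed_non_terminal.  Conservation percent is `100·conserved/human`;
group averages are unweighted over species; the invertebrate response is
the unweighted mean of the *Drosophila* and *Caenorhabditis* percents.  A
pathway counts as "conserved" for the shaded-fraction summary when its
group average exceeds 75% (configurable).

The GLM regresses the invertebrate conserved proportion on the vertebrate
proportion, the human gene count and their interaction.  Since only "GLM"
is specified upstream, the default is a binomial family with logit link and
pathway gene counts as variance weights (the response is a proportion with
size-dependent precision); a gaussian-identity mode is provided for
sensitivity analysis.  Surface predictions outside the fitted predictor
range are emitted with an extrapolation warning.

## Shannon ranking and enrichment

`H′ = −Σ p_i ln p_i` uses natural logs (so the 12-species uniform maximum
is ln 12 ≈ 2.485, consistent with the reference scale) and is computed on
**copy counts**, not presence — the index measures the distribution of
genes, and correlates with (but does not equal) species breadth.  Massive
ties (e.g. all uniformly distributed single-copy families share ln 12) are
broken by ascending family ID for determinism; within-tie order is
biologically arbitrary and can shift ES slightly for small sets.

Gene sets are converted to ortholog sets by mapping gene IDs to family IDs
and deduplicating; sets outside [3, 500] unique families are excluded, and
sets with no mappable gene dropped with a warning.  The enrichment score is
the signed extremum of the weighted Kolmogorov–Smirnov running sum
(increment `|score|^p / Σ_set|score|^p` at hits, default `p = 1`; decrement
`1/(N − k)` at misses); an exact tie between the positive and negative
extremes resolves to the positive one.  Significance uses the only null
available to a preranked analysis — random same-size family sets — with
NES = ES / mean(|null ES| of the same sign), nominal p as the same-sign
exceedance fraction, and FDR q by the standard NES-based empirical ratio,
clipped to [0, 1].  The panel experiment draws `n_sets` random gene subsets
(default 100 of size 100; the size is not externally fixed and is
configurable) from a biomarker panel and from the whole gene universe and
compares the fractions of subsets with p < 0.05.

## Synthetic-data generator

The generator emulates curated ortholog-database exports at desk scale
(defaults are ~10× smaller than the reference magnitudes):

* 1044 families (160 disease / 745 non-disease / 139 mixed, the 10,441 =
  1597 + 7446 + 1398 split scaled down); gain nodes drawn per class from a
  distribution over the anchor's ancestors, with 71% of disease and 59% of
  non-disease families at the root and mammal-specific families mostly
  non-disease;
* per-branch loss probabilities highest on the nematode and insect
  branches; duplication adds geometric extra copies with probability 0.05
  per surviving branch (chosen so ~40% of families remain single-copy, the
  reference fraction) — duplication is additive-geometric rather than a
  full birth–death process, enough to give H′ variation;
* families absent from the anchor are redrawn (the process is conditioned
  on anchoring), and a truth log records each family's gain node and loss
  branches;
* pathways draw genes from the simulated families (log-normal sizes, mean
  ≈ 29 genes and ≈ 11 reactions; disease pathways smaller on average,
  matching the reported size gap), and a reaction is conserved in a species
  iff ≥ 1 member gene's family is present — the mechanism that makes
  reactions systematically more conserved than genes (under the default
  settings the fitted reaction-loss tree is roughly a third shorter than
  the gene-loss tree);
* gene sets sample from top-quartile H′ families ("conserved"),
  bottom-quartile ("recent") or uniformly ("neutral"), with truth labels
  for calibration and power checks.

What passing tests on this generator do **not** show: real ortholog
databases have annotation noise, lineage-specific gene birth, correlated
loss across related families, and non-independent pathway membership, none
of which are modeled.  Synthetic results validate the inference machinery,
not the biological conclusions.

## Problem sizes and numerical tolerances

Exhaustive oracle checks cover every rooted binary topology with ≤ 6 leaves
for Dollo (state-assignment enumeration; the optimum is verified unique)
and every ≤ 3-leaf instance with counts ≤ 3 over a survival/λ grid for the
pure-loss model (per-element pattern enumeration; absolute error < 1e−9).
Parameter recovery uses 2000 simulated pathways on the 8-species tree
(survivals 0.55–0.97, λ = 25); calibration checks use 20 datasets of 1100
families with 200 subsampling replicates, and 200 neutral + 200 biased gene
sets at 250 permutations.  These sizes were chosen to keep the default
suite at desk scale while leaving the statistical assertions comfortably
powered.  Root-prior truncation error is held below 1e−12 and likelihood
rescaling guards against underflow on deep trees; posterior vectors are
normalized and verified to sum to 1 within 1e−9.

## Known limitations

* No gain or duplication rates in the pure-loss model, and no model
  selection among birth–death variants (deliberate: the model encodes
  irreversible loss).
* No analytic (non-resampling) subsampling null.
* No phenotype-labeled two-class GSEA and no leading-edge reporting.
* Identifier handling beyond the alias table (no database normalization),
  and no network access of any kind.
* Near-degenerate survival probabilities (s → 0 with positive observed
  counts) drive log-likelihoods to −∞; the optimizer's logit bounds keep it
  away from the boundary, at the cost of capping fitted survivals at
  ~0.9997 rather than exactly 1.
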