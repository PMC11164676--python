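# Methods

This note documents the statistical models, parameter defaults, and
numerical choices behind `crosspath`, along with what the synthetic-study
generator does and does not emulate.

## Data model and normalization

Expression is held gene-major (genes × cells) as dense float arrays; counts
must be non-negative. All analyses operate on library-size-normalized data:
counts per 10,000 per cell followed by log1p
(`normalize_log1p_cp10k`). Normalizing twice is rejected, because a second
pass would silently distort fold changes. Cross-species comparison goes
exclusively through one-to-one orthologs; any gene with more than one
partner in the other species is dropped from the mapping (a conservative
choice that avoids arbitrary many-to-many resolutions, at the cost of losing
some genes).

## Differential expression

Old vs young cells are compared per gene with the two-sided Wilcoxon
rank-sum (Mann–Whitney U) test. The exact distribution is enumerated when
the pooled sample has ≤ 16 cells and no ties; otherwise the tie-corrected
normal approximation with continuity correction is used (both via
`scipy.stats.mannwhitneyu`). The cutoff 16 keeps exact enumeration cheap
while covering the regime where the normal approximation is least reliable.
Genes expressed in neither age group are removed *before* multiple-testing
correction, so the Bonferroni factor counts only tests actually performed.
The fold change is log2((mean_old + 1)/(mean_young + 1)); the pseudocount of
1 stabilizes ratios for lowly expressed genes. A gene is a DEG when
|log2FC| ≥ 0.1 and Bonferroni-adjusted p ≤ 0.05. The permissive fold-change
threshold reflects that aging effects in single-cell data are typically
subtle; significance carries the main burden.

## Pre-ranked GSEA

Genes are ranked by log2FC (or signed −log10 p), descending, ties broken
lexicographically for determinism. The enrichment score is the signed
maximum deviation of the weighted Kolmogorov–Smirnov running sum (hit
increment |r|^p normalized by the sum over hits with p = 1; miss decrement
1/(N − n_hits)). If all member statistics are zero the score falls back to
the unweighted statistic. Significance uses gene-label permutations: member
labels are redrawn uniformly, independently for every gene set — sharing one
permutation pool across same-size sets would correlate their p-values and
break null calibration (verified empirically). NES divides ES by the mean
|ES| of same-sign permutation scores; the nominal p is the add-one
permutation p. Defaults: 1000 permutations (minimum 10), set size bounds
5–500. Skipped sets carry an explicit reason rather than silent NaNs.

## Concordance labels

A gene is SM when it is a DEG in every species and all fold-change signs
agree and are nonzero; DE when it is a DEG everywhere but signs disagree;
otherwise not shared. Pathways are labeled the same way from NES signs.
Model recommendation for a pathway returns the species whose NES sign
matches the reference species; mismatching species are flagged for caution
rather than hidden.

## Cell–cell communication

Group activity of a gene is the Tukey trimean ½Q₂ + ¼(Q₁ + Q₃) of its
normalized expression over the group's cells (robust to outliers, stricter
than the mean: a gene must be expressed in ≥ 25% of cells to get a nonzero
trimean). Multi-subunit ligands/receptors use the geometric mean of subunit
activities, so one absent subunit zeroes the complex. Co-stimulatory
receptor partners multiply receptor activity by (1 + mean RA); co-inhibitory
by 1/(1 + mean RI). The interaction probability between sender i and
receiver j is a Hill response with K_h = 0.5 on the ligand–receptor product,
an agonist gain term (1 + AG/(K_h + AG)) per agonist, an antagonist
attenuation K_h/(K_h + AN) per antagonist, and a n_i·n_j/n² group-abundance
weight. Networks are assembled per age group and differenced old − young;
significance is assessed by shuffling cell-type labels within the age group
(add-one p, ≥ 10 permutations). Groups with fewer than 3 cells are flagged
low-confidence.

## Betweenness centrality and hubs

Betweenness is computed with Brandes' algorithm via
`networkx.betweenness_centrality`, reported both as the raw unordered-pair
count and the 2/((n−1)(n−2))-normalized value. Hubs within a gene subset are
ranked on the induced subgraph by betweenness, then degree, then gene id —
fully deterministic.

## Regulon inference

For each target, expression is regressed on a TF panel with gradient-boosted
depth-1 regression stumps under squared loss: 50 rounds, shrinkage 0.1,
optional subsampling. Each stump's split is found by prefix-sum SSE
minimization over sorted unique values of one TF. A TF's importance is its
summed training-loss reduction; with learning rate in (0, 2) each round is a
damped projection, so training loss is provably non-increasing. Regulons
take the top-10 targets per TF (ties broken by gene id); a TF never appears
in its own regulon. At least 20 cells are required — stumps on fewer cells
overfit noise.

## Synthetic studies

The generator plants ground truth into negative-binomial counts
(log-link mean, dispersion θ = 2, so p = θ/(θ+μ); log-normal(0, 1)
baselines):

- **Pathway effects**: a δ = 0.5 shift on old-group log-means of member
  genes, sign alternating across pathways; DE pathways flip sign in one
  designated discordant species (default monkey).
- **Regulons**: TF counts are drawn first; targets add β · centered
  log1p(TF) to their log-mean (β = 1).
- **Ligand–receptor pairs**: ligand and receptor log-means are raised in old
  cells by `lr_effect` (default 1).
- **PPI**: dense edges within planted pathways (p = 0.25) over a sparse
  background (p = 0.002).
- **Orthologs**: shared symbols across all species pairs, plus deliberate
  many-to-many decoys among private genes to exercise the 1:1 filter.

Defaults — 3 species, 2400 genes each (80% shared), 4 cell types × 50 cells
per age group, 10 SM + 10 DE pathways of 50 genes — were chosen as the
smallest sizes at which all stages have comfortable statistical power while
the full pipeline runs in seconds. The simulator does *not* emulate dropout
beyond NB sampling, batch effects, compositional shifts between ages, or
doublets; conclusions about those phenomena cannot be tested against it.
Each random stage draws from its own named stream
(`SeedSequence(seed, spawn_key=crc32(name))`), so adding one stage never
perturbs another and whole studies are byte-identical across runs for a
fixed seed.

## Numerical choices

- Permutation ES values are computed by a vectorized piecewise-linear
  extremum search over hit boundaries only, matching the naive running sum
  to 1e-12.
- Large-group Wilcoxon tests run vectorized across genes
  (`mannwhitneyu(axis=1)`).
- All permutation p-values use the add-one estimator (k+1)/(n+1), which is
  never exactly zero.
- Quantiles use numpy's default linear interpolation (type 7) throughout.

## Limitations

- Bonferroni is deliberately conservative; with thousands of genes, weak
  true effects will be missed (the cost of strict family-wise control).
- The communication model is steady-state and ignores spatial proximity and
  secreted-ligand diffusion.
- Stump-based importance captures marginal, not conditional, TF effects;
  strongly correlated TFs share credit unpredictably.
- SM/DE labels are binary by design; borderline pathways with near-zero NES
  in one species land in "not shared" rather than receiving a graded score.
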