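# Methods

## Problem

Given two species' transcriptome atlases — gene × sample read-count matrices
spanning organs, stages and conditions, with biological replicates — decide
for any interspecific gene pair whether the two genes' expression profiles
resemble those of orthologous genes or those of unrelated genes. Classical
distance measures (Euclidean distance, Pearson correlation) need a one-to-one
correspondence between the samples of the two atlases, which does not exist
when the species differ in morphology or developmental rate. The approach
implemented here sidesteps sample matching: a supervised classifier learns,
from known 1-to-1 orthologs (orthopairs) versus random pairs, whatever
cross-sample structure distinguishes them.

## Expression Score

The classifier is gradient boosting of decision trees (XGBoost) with a binary
logistic objective. The input for a pair (gene *a* of species A, gene *b* of
species B) is the concatenation of the two raw count vectors, species A
first, each replicate column its own feature; no normalization is applied in
this path (boosted trees are invariant to monotone per-feature rescaling, and
split thresholds adapt to each column's scale). The output in [0, 1] is the
Expression Score (ES): ES > 0.5 means more orthopair-like, ES < 0.5 more
random-pair-like, and ES = 0.5 is undecided (treated as below threshold
everywhere a hard decision is needed).

Booster configuration: no row or column subsampling
(`subsample = colsample_bytree = colsample_bylevel = 1`), default
regularisation (alpha 0, lambda 1, gamma 0), class weight 1 (training sets
are balanced by construction), and no depth cap (`max_depth = 0`, realised
via histogram growth with a loss-guided policy). Two numerical choices are
ours: 64 histogram bins (counts span orders of magnitude; 64 quantile bins
measurably change nothing but halve single-thread training time) and the
round-selection rule — the "automatic" number of trees is implemented as
early stopping on a stratified 20% split of the training pairs, stopping
after 15 rounds without AUC improvement, capped at 500 rounds. Loss-guided
growth is additionally capped at 64 leaves per tree: without a cap each tree
simply memorizes the ~3000 training pairs, which costs several-fold more
single-thread time and measurably changes nothing on held-out AUC. All of
these knobs are estimator parameters. Training sets too small to
split (under ~10 pairs) fall back to a fixed 50 rounds.

## Training sets and out-of-fold re-classification

Positives are the orthopairs; negatives are an equal number of random
interspecific pairs drawn uniformly without replacement from the gene cross
product minus the positive set. Training members cannot be scored by a model
that saw them, so they are re-classified out of fold: positives and negatives
are split into k = 10 stratified folds (sizes differ by at most one per
class), one model is trained per held-out fold, and each training pair is
scored exactly once, by the model that excluded it. Every pair outside the
training sets — the remaining interspecific pairs inside orthogroups — is
scored by a model trained on the complete training sets.

The negative set unavoidably contains some co-expressed (orthopair-like)
pairs. The whole procedure is therefore iterated (100 times by default; 10 in
the `--fast` profile and in this repository's tests) with a fresh negative
set and fold split per iteration, seeded `base_seed + i`; the final ES of a
pair is the median of its per-iteration scores (median of the two central
values for even counts). Per-iteration scores are retained so the median can
be audited. Note that a sampled negative pair typically appears in only a
subset of iterations; its final ES is the median over the iterations that
scored it.

## Fractionation into expresso-groups

Each orthogroup becomes a complete bipartite graph: species-A genes on one
side, species-B genes on the other, the ES of every interspecific pair as the
edge weight (within-species edges do not exist). Edges with weight ≤ 0.5 are
removed — a score exactly at the threshold counts as negative, consistent
with the ES > 0.5 decision rule — and the connected components of what
remains are the expresso-groups (components are found with networkx;
an independent union-find oracle cross-checks them in the tests). Genes left
without partners become singleton groups; a singleton means the gene has no
cross-species partner in its orthogroup with ES above the threshold.
Components may contain several genes of either species and are reported
as-is. Summaries cover the component-size histogram, the global singleton
count/fraction, and — for 1×2 and 1×3 orthogroups — how many co-orthologs
remain connected to their single partner.

## Pseudo-Euclidean baseline

The comparison method: counts are normalized by DESeq-style median-of-ratios
size factors (genes with any zero count are excluded from the median),
incremented by 1, and each gene row is divided by its median over exactly the
samples entering the comparison. Samples of the two species are either
matched directly or grouped where one-to-one matching is impossible. Per
evaluation repeat, one biological replicate per sample label is drawn at
random; each direct match contributes a squared residual and each group match
the square of the *minimal absolute* residual over its cross-species label
combinations (minimizing the signed residual would reward large negative
differences); the distance is the square root of the sum. 100 repeats expose
the replicate variance. For ROC comparisons the baseline scores a pair by its
negated mean distance. The per-gene median is computed after normalization
and before replicate selection, over the comparison samples.

## Evaluation

AUC follows the Mann–Whitney formulation (ties count one half — sklearn's
`roc_auc_score`). Sensitivity is TP/(TP+FN) and specificity TN/(TN+FP) with a
pair predicted positive only when its score is strictly above the threshold.
The pipeline-level summary `out_of_fold_auc` computes AUC on the final
(median) ES of out-of-fold-scored training pairs.

Expression breadth of a profile is the fraction of samples with counts at or
above 10% of the profile's maximum (both the 10% and the broad/narrow split —
default: median breadth — are configurable; this fraction-above-threshold
definition is our choice, made for interpretability). All-zero profiles are
unclassifiable (NaN).

Sample downsampling reproduces the robustness protocol: samples are clustered
hierarchically under the distance 1 − Pearson correlation of their count
profiles, the tree is cut at a given height, and one uniformly random sample
per flat cluster is retained. Average linkage is used (a common default for
correlation distances; configurable). A constant sample column has undefined
correlation; its distance to everything is set to 1. An explicit exclusion
list supports removing named sample labels (e.g. a tissue with an extreme
expression profile) before clustering.

Sequence identity uses Biopython's global pairwise aligner with BLOSUM62,
gap open −11 (first gap residue) and gap extend −1, end gaps penalized.
Identity = identical aligned columns / alignment length, gapped columns in
the denominator (the alternative, dividing by the shorter sequence length, is
recorded as a design choice not taken; the denominator is stated in the
output metadata).

## Synthetic data

The generator emulates two bulk atlases over a latent "organ axis" in [0, 1].
A pool of archetypes — smooth positive curves, 1–3 Gaussian bumps over the
axis plus a low baseline, normalized to mean 1 — stands for the organism's
distinct expression programs. Each species samples the axis at its own
equally spaced label positions (40 vs 30 by default, two replicates each), so
the species' sample sets are deliberately unmatched. A gene is an archetype
plus a magnitude; counts are negative binomial with variance
mu + dispersion·mu² around gene intensity × per-column library factor.

Default conditions (frozen as the package's study conditions): 2000 genes
per species; dispersion 0.1; 80% of the smaller gene set placed into
orthogroups with shape mix 70% 1×1, 15% 1×2, 10% 1×3, 5% 2×2; conservation
rate 0.8. In each orthogroup the first species-A gene anchors the ancestral
archetype and every other member retains it with the conservation rate, so
1×1 pairs are conserved with exactly that rate. Diverged orthologs draw an
independent archetype but keep a correlated magnitude (log-sd 0.15 jitter
around the ancestral magnitude) — orthologs tend to retain expression level
even when the pattern moves. Unassigned species-B genes copy a random free
species-A gene's archetype with probability 0.05 (planted co-expressed
background, the negative-set noise that motivates the iterated training);
further coincidental archetype sharing occurs at ~1/n_archetypes.

Calibrated free parameters, chosen to land the generator in the regimes the
pipeline targets while staying in the range of real atlases: 120 archetypes
(a smaller pool leaves so much accidental co-expression among random pairs
that even the self-comparison ceiling drops below its real-data value);
magnitudes log-normal with median 30 and log-sd 2.0, floored at 3 (real
atlas analyses are restricted to expressed genes; an un-floored tail of
silent genes is pure noise for every method), library size 10⁶ expected
counts per sample (sequencing depth comparable to real atlases after scaling
to 2000 genes); per-column library-factor log-sd 0.1.

What the generator does not model: batch structure beyond a per-column
factor, circadian/field-condition effects, mappability or annotation errors,
correlated noise between replicates, and partial (as opposed to all-or-none)
expression divergence. Passing tests therefore show that the pipeline's
machinery is sound under a realistic noise model, not that real-data AUCs
will match.

The generator also emits the axis-derived sample matching for the baseline:
the organ axis is divided into coarse bins (⌊min(m_A, m_B)/3⌋), labels of
both species falling in one bin form a group match (or a direct match when
both sides have exactly one label there).

A self-comparison variant renders one gene set into two datasets with
different label counts and independent noise; positives pair each gene with
itself. This is the known-truth ceiling test: every positive is functionally
identical by construction.

## Problem sizes used in tests and the acceptance script

The full published protocol uses 100 iterations; the repository's end-to-end
runs use the `--fast` profile (10 iterations) and the default 2000-gene
simulations, which reproduce all of the qualitative regimes: null training
AUC ≈ 0.5 (mean over 10 generator seeds), self-comparison AUC ≥ 0.99,
signal-regime AUC ≥ 0.90 with the distance baseline strictly between chance
and the classifier. The downsampling-stability check runs on 600-gene,
16/12-label simulations with 4 iterations over 5 seeds and cut heights
0.1–0.9.

## Known limitations

* ES is dataset-dependent: it measures similarity relative to the sampled
  organs/conditions, so atlases must cover the processes of interest.
* The classifier consumes raw counts; severe depth imbalance between
  species' libraries is handled only implicitly by tree thresholds.
* Negative sets are random pairs, so a fraction of negatives is genuinely
  co-expressed; the median over iterations damps but does not remove this.
* With very small training sets (tens of pairs) early stopping degenerates
  to a fixed round count and scores become less calibrated.
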