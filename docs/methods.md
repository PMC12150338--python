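# Methods

## Model and procedure

The selector treats biomarker-candidate discovery as a feature-subset
search wrapped around a supervised classifier. The base learner is an
XGBoost gradient-boosted decision-tree classifier (histogram tree growth,
single thread, log-loss objective). Trees are used deliberately: missing
abundances follow the learned default split direction instead of being
imputed, and monotone feature rescalings do not change the model, so
neither imputation artefacts nor normalisation choices can masquerade as
phenotype signal.

### Elimination passes

Stage 1 is organised as repeated *elimination passes*. A single pass:

1. cross-validates the classifier on the training samples (stratified,
   replicate-group-atomic k-fold; k = 5 by default, reduced with a warning
   when the smallest class has fewer replicate groups than k);
2. sums each feature's total split gain over the k fold models;
3. removes the `ceil(0.10 × n)` lowest-gain features — gains are compared
   after rounding to an absolute tolerance of 1e-12, kept features whose
   gain exactly ties the best removed gain are recorded and re-ranked in
   the next round rather than silently lost, and remaining gain ties break
   by the current column order (which the per-simulation column shuffle
   randomises — a fixed alphabetical tie-break would bias removal against
   lexicographically early feature names and make the shuffle a no-op);
4. repeats from step 1 until a single feature remains, recording the CV
   ROC AUC (one-vs-one weighted) at every subset size. This curve is the
   pass's scalability plot.

The pass returns its best-performing subset: highest mean CV AUC, ties
resolved to the smaller subset (parsimony — the tool's purpose is the
shortest reliable candidate list; preferring the larger tied subset can
stall the pass loop on plateaued data). The next pass restarts from that
subset. Passes repeat until one shows a *significant loss*: its best CV
AUC falls below the previous pass's by more than `0.1 × current` (a
relative rule; an absolute-drop variant is available behind
`--absolute-drop`). The feature list in force before the losing pass is
the simulation's optimal set. Termination is structural: each pass starts
from a strictly smaller set, so either the loss fires or one feature
remains.

Stage 2, when enabled, continues the same elimination from the optimal set
with the stopping rule disabled until at most `stage2_cap` (default 30)
features remain, never removing more than needed to reach the cap in the
final round.

### Monte-Carlo structure and the final model

The final test set is split off once (default 30% of replicate groups per
class, rounded half away from zero, clamped so each side keeps at least
one group per class). Each simulation `i` then uses seed `master_seed+1+i`
to shuffle the feature columns, draw its own train / internal-test split
(default 30% of the remainder) and CV folds. A random-grid search (20
draws from a fixed grid over depth, learning rate, tree count, row/column
subsampling and minimum child weight) fits the "Grid2" model on the
simulation's selected features and scores it on the internal test set.

The golden features are the union of the per-simulation selections. The
final model is a second random-grid search on the golden features using
repeated (2 × 5-fold) group-atomic CV over all non-final-test samples,
refitted on those samples, and evaluated exactly once on the final test
set. Decision thresholds for confusion matrices are tuned per class on
out-of-fold CV predictions only (the ROC point nearest (0, 1); distance
ties resolve to the lower false-positive rate) and applied frozen to test
predictions; samples for which no class clears its threshold fall back to
argmax. ROC AUCs are reported under two averages everywhere: micro
(pooled indicator/score pairs; headline test metric, robust to imbalance)
and one-vs-one prevalence-weighted (tracked during elimination).

### Bootstrap augmentation

When enabled, every CV fold fit first estimates a per-(class, feature)
Gaussian noise model — mean and ML (ddof = 0) standard deviation of the
observed values — *from the fold-train samples only*, then appends
`n_replicates` (default 2) synthetic copies of each training sample with
cell-wise noise `N(0, (noise_scale × sd)²)`. Missing cells stay missing;
cells whose class has fewer than two observations get sd 0 (plain copies);
synthetic identifiers carry a `::boot` tag and are barred from every
evaluation path. Noise is not truncated at zero, so synthetic abundances
can be negative on linear-scale data; on log-scale inputs (the
recommended representation) this is harmless. The "bootstrap" flag adds
the copies; the "noisy" flag perturbs them; bootstrap without noisy is a
pure resampling-weight effect.

## Leakage control

All splits operate on replicate groups (a group = all files sharing a
SampleID; unannotated files are singletons; a group spanning two classes
is rejected). Groups are atomic across final-test / train / internal-test
and across CV folds, stratification counts groups per class, and a class
with a single group is refused rather than silently leaked. The selection
result carries an audit set of every sample id that entered any model
fit, noise model, or threshold choice; tests assert it is disjoint from
the final test set.

## Input conventions

Expression tables are CSV with `files` first, `class` last; empty, `NA`
and `NaN` cells are missing (written back as empty fields — never 0).
Long-format search reports (`file`, `protein`, `peptide`, `intensity`)
are pivoted at peptide or protein level; the protein rollup is the sum of
observed peptide intensities (the common label-free convention; the
aggregation is parameterisable). The `log2(x + 1)` transform is an
explicit flag, not an implicit step, because the tree model itself does
not need it; it merely symmetrises abundance distributions.

## Statistics layer

* Kendall tau-b with tie correction (pairwise-complete observations;
  exact p at small n, normal approximation otherwise). Chosen over
  Pearson because it assumes no distributional form and tolerates ties.
* Benjamini-Hochberg step-up FDR adjustment; the golden-feature
  correlation family is all golden × other pairs at once, and retained
  rows need adjusted p < 0.05 (flag).
* Volcano tables: per-feature observed-minimum imputation (a conservative
  below-detection-limit reading; a global-minimum variant is available),
  effect = difference of class means of the (log-scale) values, two-sided
  Mann-Whitney U p, BH within the table. One table per class one-vs-rest;
  a two-class run emits a single contrast since the pair would mirror.
* Attributions: the booster's exact tree-path Shapley decomposition
  (additivity to the prediction margin is asserted to 1e-6; multiclass
  attributions are taken toward each sample's predicted class).
* Embeddings: PCA (deterministic up to sign) is the tested contract; UMAP
  is optional and seeded. Constant matrices are rejected for PCA.
* Feature clustering: average linkage on correlation distance
  (1 − Pearson r) over minimum-imputed values.

## The synthetic benchmark

The generator emulates the hard shape of omics selection: a nonlinear
two-feature signal (interleaving half-circles, 40 samples per class,
scatter 0.2 — chosen so a two-feature model alone exceeds 0.9 test AUC)
buried in 5000 i.i.d. standard-normal noise features. It does *not*
emulate missing values, feature correlation blocks, batch effects, or
heavy-tailed abundance distributions — passing benchmark tests therefore
demonstrates signal recovery under high-dimensional noise, not robustness
to those real-data pathologies (the io/augmentation/splitting layers are
tested on fixtures with missingness and replicate structure instead).

Comparisons use one stratified 70/30 split per seed shared by all
methods. The cross-validated-RFE comparators default to the textbook one
feature-per-iteration step; the benchmark harness and the acceptance
script run them at 10% of remaining features per iteration, which keeps
the five-way comparison tractable (one-at-a-time elimination over 5002
features costs thousands of boosted-tree fits per fold) at the price of a
coarser elimination path. Augmentation is off in the benchmark.

Problem sizes used by the shipped checks (package choices): the five-way
comparison runs the full 80 × 5002 setting over 5 seeds; the recovery
check uses 500 noise features over 5 seeds; the null control runs 20
seeds of a 60-sample × 40-feature label-free noise matrix; the
demo-scale end-to-end run uses 24 samples × 12 features.

## Known limitations

* With very small cohorts the CV AUC of a pass is noisy (five folds of a
  few validation samples each); the pass-best subset inherits that noise,
  which is exactly why the Monte-Carlo union exists.
* The stopping rule compares consecutive passes; data whose AUC/feature
  curve declines gently can eliminate informative features late in a pass
  without triggering the loss.
* Hyperparameter search is a fixed 20-draw random grid, not nested
  optimisation; reported internal-test scores are mildly optimistic for
  the grid winner, while the final-test score is not (single evaluation).
* GPU training is not implemented; the `--gpu` flag is accepted and
  ignored for interface compatibility.
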