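# Methods

This note records the modelling choices behind `lorenzgini`: what each
stage assumes, which knobs matter, where the design was genuinely open
and what was decided, and what the synthetic validation does and does not
demonstrate.

## Problem setting

Input: a continuous genes × samples expression matrix (thousands to tens
of thousands of genes, a few hundred samples) with one class label per
sample, typically multi-class and strongly unbalanced (the motivating
setting is tumour sub-typing: adenocarcinoma / squamous / carcinoid /
normal at roughly 139/21/20/17).  Output: a small gene panel and a
fitted probabilistic classifier.  The pipeline is
discretize → rank → wrapper-select → evaluate.

## Discretization

Each gene is modelled independently as a one-dimensional Gaussian
mixture fitted by EM.

* **Initialization** — component means at the k interior quantiles,
  common variance equal to the sample variance, uniform weights.
  Deterministic; a seeded jitter is applied only when quantile means
  collide (heavily tied data).  The per-gene seed is derived from the
  stage seed and the gene's row index, so results do not depend on how
  many genes precede it.
* **Variance floor** — 10⁻⁶ × the gene's sample variance (absolute floor
  10⁻¹²), preventing singular components on duplicated values.
* **Convergence** — stop when the relative log-likelihood change is
  below `tol` (default 10⁻⁶) or after `max_iter` (default 500)
  iterations.  The log-likelihood is non-decreasing by construction and
  asserted so in the tests.  `discretize_matrix` runs the identical
  update equations batched across genes; the tests verify the batched
  and the per-gene paths agree.
* **Component count** — candidates k ∈ {1, 2, 3, 4} per gene.  Inside
  the discretization the count is chosen by **AIC**, not BIC: the target
  here is downstream class separation, not parsimonious density
  estimation, and BIC's 3·ln(n) ≈ 16 penalty (n ≈ 200) refuses to split
  genuinely multimodal class-ladder genes whose log-likelihood gain is
  6–12.  The standalone `choose_components` keeps BIC, the conventional
  criterion for mixture order selection, for users who want a density
  model.  Including k = 1 matters: a unimodal (uninformative) gene then
  stays single-range, and a single-range gene has splitting status 0 and
  ranking score 0 by convention.
* **Range boundaries** — posterior crossing points between adjacent
  ascending-mean components (root of the weighted log-density
  difference; midpoint fallback if one component dominates throughout).
  Codes are assigned by cut-point lookup, which makes them monotone in
  the expression value by construction.
* **Minimum range occupancy** — ranges holding fewer than
  `min_range_fraction` (default 2.5%) of the samples are merged into
  their smaller neighbour.  Rationale: a near-empty range carries no
  class evidence, but it drives the splitting-status denominator of the
  gini ratio towards zero and would hand uninformative genes unbounded
  scores.  The default stays below the 3%-occupancy ranges of the
  motivating reference tables, which therefore survive unmerged.

## The ranking statistic

For a gene with m ranges over n classes (contingency counts |C_ij|, row
sums |R_i|, column sums |C_j|, total d):

    gini(R_i)  = 1 − Σ_j (|C_ij|/|R_i|)²
    gini(D)    = 1 − Σ_j (|C_j|/d)²
    split_A(D) = 1 − Σ_i (|R_i|/d)²
    LorenzGini = (gini(D) − gini_A(D)) / split_A(D)

where `gini_A(D)` is the weighted index described below.  A single-range
gene scores 0 (it never splits the data).  All quantities are linear in
the table size, so ranking a genome costs the same order as the plain
Gini index.

### α: class-order weights

All Lorenz curves use one dataset-level class order (ascending |C_j|,
stable ties).  The equality polygon is the whole dataset's cumulative
class-share curve; each range's curve uses its own counts on the same
grid x = 0, 1/n, …, 1.  Areas are trapezoid integrals, and the range's
Gini coefficient is g_i = (∫L(R_i) − ∫Eq)/∫Eq — signed, kept in
`GeneScore` for diagnostics.  Two ranges whose count vectors are class
permutations of each other trace different curves, which is exactly the
information the plain impurity discards.

The weight normalization was an open design point.  The naive choice
α_i ∝ |g_i| is degenerate: a range whose class profile matches the
dataset profile has |g_i| ≈ 0, and that is precisely the typical
majority range of a *noise* gene — weighting by |g_i| silently deletes
most of such a gene's impurity and manufactures an impurity "reduction"
of nearly gini(D) over a small split, swamping genuinely informative
genes (observed score inflation of 10–70×).  The package therefore uses
the bounded form

    α_i = m · (1 + |g_i|) / Σ_j (1 + |g_j|),

which still separates permuted rows, reduces exactly to uniform weights
when all coefficients are equal (including the all-zero case), and
keeps every weight near 1.

### δ: range-order weights

δ(i) is the mean closeness of range i to its existing neighbours, with
closeness = 1 − (L1 distance between class-proportion vectors)/2 (the
division normalizes by the L1 diameter of the simplex), so δ ∈ [0, 1]
and larger means the class profile varies smoothly along the expression
axis.  Boundary ranges have one neighbour, interior ranges two; a
single-range gene gets δ = (1).  The "closeness" form is used because
an emphasis weight must grow when a range resembles its neighbours; a
raw sum of distances would do the opposite.

### Combining the weights

α and δ multiply into one per-range weight w_i = α_i·δ_i, and the
combined weights are rescaled to unit row-mass-weighted mean
(Σ_i (|R_i|/d)·w_i = 1) before forming

    gini_A(D) = Σ_i w_i · (|R_i|/d) · gini(R_i).

The rescaling makes `gini_A(D)` a weighted *average* of range impurities,
directly comparable with gini(D): a common shrinkage of all weights (for
example δ ≈ 0.8 everywhere on a lopsided split of a noise gene) can no
longer masquerade as impurity reduction, and the score is invariant to
any common rescaling of α or δ — so no arbitrary normalization constant
leaks into the gene ranking.  With uniform weights the index equals the
classical one exactly (asserted to 10⁻¹² on random tables).  If the
combined weights vanish everywhere (possible only when every δ is 0),
uniform weights are substituted; every impurity is then zero anyway in
the cases that produce it.

Known consequence, accepted: for tables whose ranges are all pure
(every gini(R_i) = 0) the weighted index is 0 regardless of the weights,
so two such genes tie at the score level even though their δ vectors
differ.  δ and the signed g_i are exposed in `GeneScore` as tie-breaking
diagnostics rather than folded into the score in some unprincipled way.

Ranking sorts by descending score with an alphabetical gene-id
tie-break and keeps the top 250 by default.

## Bayesian-network classifier

Discrete network over the class node (always a root and a parent of
every gene) and the marker genes.  CPTs use pseudo-count smoothing
(default 0.5, a standard choice that keeps every posterior strictly
positive); unobserved parent combinations become uniform rows.  The
score is AIC = −log-likelihood + number of free parameters, with the
standard count Σ_nodes (arity−1)·Π(parent arities); lower is better.
Structure search processes genes in a fixed order (default: the ranking
order), considering gene-parents only among earlier genes — acyclicity
by construction — adding at most `max_parents` (default 1, optionally 2)
per gene, one at a time, each kept only on a strict AIC improvement.
The AIC decomposes over families, so only the affected family is
rescored.  Prediction multiplies the class prior by each gene's CPT
entry and normalizes; ties go to the earlier class in `class_set`.

## Wrapper subset search

Goodness of a subset = mean accuracy of the classifier under a fixed
small CV protocol (5-fold, 3 repeats, fixed internal seed), cached by
subset, so goodness is a deterministic function of the subset and no
subset is ever evaluated twice.  The heavyweight k = 5…9 × 50-seed
protocol is reserved for the final report; running it inside the search
loop would multiply the cost by ~80 for no ranking benefit.

* **Greedy** — repeated best-child replacement (add one gene forward,
  remove one backward) until no child strictly improves.
* **Best-first** — open list of scored frontier subsets, always expand
  the best unexpanded one, stop after `stale_limit` (default 5)
  consecutive expansions without a new global best.  With no limit the
  search provably exhausts the lattice, which the tests exploit as an
  exhaustive-enumeration oracle on pools of ≤ 12 genes.

Ties between equal-goodness subsets prefer the smaller subset, then
earlier ranking positions — small panels are the stated goal.  The
pipeline default runs both strategies forward; backward elimination from
a 250-gene pool costs O(pool²) cross-validated fits and is available by
configuration rather than by default.

## Evaluation harness

Folds are stratified by default: each class's shuffled samples are dealt
onto the folds by one global round-robin pointer, so total fold sizes
*and* per-fold class counts differ by at most one.  With a 17-sample
class and k up to 9, plain random folds can lack a class entirely;
stratification keeps every fold testable (plain mode is available, and a
class smaller than k triggers a warning).  Every sample is tested
exactly once per (k, seed) run; per-run accuracy is pooled correct/total,
and the report keeps all per-run accuracies, their mean/SD, a pooled
confusion matrix and per-class sensitivity/specificity.

By default the discretization fitted once on the full matrix is reused
across folds, mirroring a preparation step that precedes model building;
`strict=True` refits the discretization on each training fold and maps
held-out samples through the training boundaries.  The residual
train/test coupling of the default is mild (discretization never sees
labels) but measurable in principle; fold-wise *re-ranking* of genes is
not implemented — the prefilter, like the preparation step, is treated
as upstream of the evaluation protocol, and this is a known limitation.

ROC curves are empirical with tie-grouping; the trapezoid AUC equals the
Mann-Whitney statistic (asserted against a pair-counting oracle), the
standard error is Hanley & McNeil's formula (the conventional choice
when none is specified), and the 95% CI is auc ± 1.96·SE clipped to
[0, 1].

## Synthetic data

`SyntheticSpec` emulates the target regime: few informative genes among
thousands of class-independent Gaussian noise genes, unbalanced classes,
optional correlated blocks.  An informative gene's class means are
`effect_size · within_sd` times a centred random permutation of the
class levels — a multi-class "ladder" whose adjacent classes sit
`effect_size` within-SDs apart.  Correlated blocks share both the
class-mean pattern and a latent noise factor at the requested
correlation, emulating the redundant co-ranked genes that defeat
filter-only selection (the tests assert that a wrapper-selected subset
beats the equal-sized top-of-ranking subset on such data).  A log-normal
option exponentiates the Gaussian draws.

What this generator does *not* model: probe-level artifacts, batch
effects, heavy-tailed or zero-inflated counts, gene-gene correlation
among noise genes, label noise.  Passing recovery benchmarks here shows
the machinery is sound under its own assumptions, not that the method's
accuracy transfers to any particular real cohort.

The validation problem sizes are deliberate package choices: the
recovery benchmark uses 4 classes (60/60/50/30), 1000 genes with 20
planted at effect 2.0 and a wrapper pool of the 50 top-ranked genes;
the ranking itself is computed over all 1000 genes with the default
top-250 table.  Recovery (all 20 planted genes inside the ranking's top
50; cross-validated accuracy ≥ 0.95 from ≤ 22 selected markers) holds
across generator seeds, and runs in about a minute on one CPU.

The nine-marker worked-example network is a synthetic reconstruction:
the "normal"-class factors and prior are the published ones, the
remaining prior mass is split by the study's class sizes, and the other
classes' factors are chosen (uniform per gene) to reproduce the
published per-class joints on the all-zero profile.

## Null behaviour of the harness

Cross-validating any learner on label-independent data sits slightly
*below* chance (training-fold class fluctuations anti-correlate with the
held-out fold); with 200 balanced samples the observed offset is about
1–2%.  The right uncertainty scale for "consistent with chance" is the
binomial SE of an accuracy estimated from n samples (0.5/√n ≈ 0.035 at
n = 200), not the across-run SD (≈ 0.003): all runs re-test the same
cohort, so the across-run spread measures partition noise only.  The
tests assert the null mean lies within 3 binomial SEs of 0.5.

## Reproducibility

One master seed (`PipelineConfig.seed`) derives the per-stage seeds
(discretization, search goodness, final evaluation) through a fixed
spawn order of `numpy.random.SeedSequence`; the run manifest records the
config, stage seeds, every search's result and the full goodness audit
log, and re-running from the same manifest reproduces marker lists and
accuracy tables exactly.  Model files are versioned JSON with
repr-precision floats, so serialization round-trips are bit-exact.

## Limitations

* The score-level tie for all-pure-range genes (above).
* AIC-based range selection can over-split heavy-tailed genes; the
  minimum-occupancy merge bounds, but does not eliminate, the resulting
  noise in the ranking tail.
* Structure search conditions on a gene ordering; different orderings
  can give different (equally scoring) networks.
* Wrapper goodness uses a fixed internal CV seed; marker panels are
  reproducible but carry that protocol's selection noise.
* No multiple-testing control is applied to the ranking — the wrapper
  stage, not a significance threshold, is what controls the final panel.
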