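# Methods

## Model

`cogem` implements *cognitive encoding models* (CEMs): region-wise linear
mappings from an ontological description of a task to the activation it
evokes across a cortical parcellation. A task is described by a feature
vector `f ∈ [0, 1]^K` whose entries annotate the psychological functions the
task engages — mostly binary presence/absence indicators, plus a few
parametric features (e.g. number of response alternatives) recoded as dense
rank indices scaled to [0, 1] (ties share a code; order is preserved). For
each region `r`, weights `w_r` and an intercept `b_r` are estimated by ridge
regression over the session-level design (each task contributes one
identical row per imaging session, 2 or 4 of them):

    minimize  ‖y_r − X w_r − b_r‖² + α ‖w_r‖²

The intercept is unpenalized: design columns and responses are centered, the
penalized normal equations are solved for all regions jointly, and the
intercepts recovered. Features stay on their native [0, 1] annotation scale;
no further standardization is applied, so coefficients remain interpretable
as activation change per unit annotation.

The model assumes (a) activation is a linear, interaction-free combination
of feature engagements, (b) all subjects perform a task with the same
feature mixture (individuality lives entirely in the region-wise weights),
and (c) session maps are exchangeable draws around a task's true map.

## Generalization to unseen tasks

Leave-two-out cross-validation over tasks: every unordered task pair is held
out once (C(n, 2) splits; 946 for a 44-task battery), models are trained on
the session rows of the remaining tasks, and each held-out task's map is
predicted from its feature vector alone. Per split and held-out task:

- **Session-averaged map r** — mean over that task's sessions of the
  Pearson correlation between predicted and observed region maps. Over a
  full 44-task run this yields 2 × 946 = 1892 values per subject.
- **R²** — coefficient of determination about each observed session map's
  mean, averaged over sessions. This choice (rather than squared
  correlation) can go negative and is what makes the null model's
  mean-prediction bias visible as low-but-positive R².
- **Two-way classification** — each predicted map is *independently*
  assigned to whichever held-out task gives the larger session-averaged
  correlation; a split is correct only if both maps go to their own task.
  Independence is essential: it yields the 25% chance level, and it allows
  both maps to be assigned to the same task, in which case the split can
  never be correct. Exact ties are broken toward the pair's first task and
  flagged; they have measure zero for continuous data.

The regularization strength is chosen per outer split by an inner k-fold
cross-validation (default k = 10) over the grid
{0.001, 0.01, 0.1, 1, 2, …, 10}. Inner folds partition *tasks*, not rows,
so a task's sessions never straddle the inner train/validation boundary.
The score is the mean over validation rows of the Pearson correlation
between predicted and observed maps; rows with undefined correlations are
skipped, and exact ties (e.g. constant responses) resolve to the smallest
alpha. One alpha is shared by all regions within a split, matching the
map-wise (region-pooling) scoring. Fold assignment is seeded.

## Noise ceiling

The explainable-variance bound for each (subject, task) is the square root
of the between-session reliability of its maps, estimated within scanning
timepoints: each within-timepoint session pair contributes one Pearson r;
four-session tasks (two timepoints) average their two √r estimates.
Non-positive reliabilities make the square root undefined; they are
excluded from averages (not clipped to zero) and counted in the output
table.

## Task-shuffled null

Each null iteration draws a uniform bijective remapping of tasks (the
global identity excluded; individual fixed points allowed, with a
derangement option) and replaces every task's feature vector by its
donor's before re-running the *entire* nested-CV pipeline. Because all 2–4
session rows of a task receive the donor's vector, task blocks are
preserved while column densities are not. Twenty iterations are averaged
per subject, and each iteration's permutation is reconstructible from
(seed, iteration). With activation maps sharing a strong common mean
component, shuffled-feature models shrink toward that mean, the two
predicted maps of a split collapse together, and accuracy falls *below*
25% — the same mechanism that leaves null R² modestly positive.

## Cognitive-space structure

Classification decisions are pooled across subjects and splits into a task
confusion matrix (two decisions per split; each row sums to the row task's
appearance count). Rows are normalized to probabilities before projecting
into feature space (`conf @ features`) so tasks contribute equally
regardless of appearance counts; the normalization is a keyword and can be
switched off. Feature dissimilarity is 1 − Pearson r between projected
feature profiles (symmetrized against float noise; constant columns yield
NaN pairs with a warning), and the RDM is clustered with UPGMA
(average-linkage agglomeration, via `scipy.cluster.hierarchy.linkage`);
merge heights are monotone non-decreasing and ties resolve by SciPy's
deterministic condensed-order rule. Trees export as linkage tables and
Newick strings.

## Between-subject transfer

Each source subject's models are fit once on all of their tasks (alpha by
the same inner CV on the full task set) and evaluated on every target
subject: all task maps are predicted, and two-way classification runs for
every task pair against the target's observed sessions. The source × target
accuracy matrix's diagonal (self-transfer) is computed identically to the
off-diagonal cells — no cross-validation — so it upper-bounds cross-subject
transfer whenever subjects genuinely differ.

## Network profiles

Feature importances per resting-state network aggregate coefficients in a
fixed order: average across subjects per (feature, region) first, then
across the regions of each network. Functional specialization is tested by
correlating every region pair's subject-averaged coefficient vectors and
comparing the mean within-network to the mean between-network correlation;
the null permutes region → network labels (default 100 iterations), and the
p-value includes the observed statistic in the denominator,
p = (1 + #{perm ≥ obs}) / (1 + n_perm), so p is never smaller than
1/(n_perm + 1). Word-cloud exports keep only strictly positive
coefficients, scaled so size is proportional to magnitude. Region-level
clustering reuses the UPGMA machinery on the region × region 1 − r matrix
of subject-averaged coefficients.

## Synthetic data generator

The generator emulates the structure of a dense-sampling task battery:
44 tasks × 36 features (24 Cognitive / 12 Perceptual-Motor, 3 parametric),
1000 regions in 7 balanced networks, 23 subjects, 14 four-session tasks
(timepoints 0,0,1,1) and the rest two-session. Session maps follow

    z = f(task) · W_subject + μ + ε,   ε ~ N(0, noise_sd²)

with `W_subject = W_group + N(0, subject_weight_sd²)` and a per-region mean
map `μ ~ N(0, mean_map_sd²)` shared by all tasks. Group weights are an
unstructured N(0, baseline_weight_sd²) background plus planted structure:
each network elevates 3–6 randomly chosen *signature* features by
`signature_shift` across its regions. Binary annotation columns are
Bernoulli(0.25), redrawn if constant (constant columns are unidentifiable);
parametric columns draw from small magnitude pools and are rank-recoded;
task rows are redrawn until pairwise distinct, erroring after a bounded
number of attempts for degenerate configurations. All randomness flows
through one explicitly passed generator; equal seeds give bit-identical
data.

Default scales — `baseline_weight_sd = 0.1`, `signature_shift = 1.0`,
`subject_weight_sd = 0.1`, `mean_map_sd = 1.0`, `noise_sd = 1.0` (z-score
units) — were calibrated once so that at the default noise level the
full-scale two-way accuracy lands strictly between chance and 1 and the
mean noise ceiling (~0.80) sits in the range typical of session-level task
z-maps. What the generator does *not* emulate: hemodynamics and GLM
estimation (maps are drawn directly at the z level), spatially correlated
noise, inter-regional correlation beyond network signatures, annotation
error, and meta-task condition families. Passing tests therefore certify
the pipeline's correctness and its qualitative behavior (null below chance,
self-transfer above cross-transfer, within-network coherence), not
quantitative performance on real data.

## Numerical choices and degenerate inputs

- Zero-variance maps make Pearson r undefined: metric functions raise an
  explicit error; inner-CV scoring skips such rows instead so alpha search
  survives constant validation maps.
- Identifiability at small scale: with t tasks and K features, noiseless
  leave-two-out predictions are exact only if every feature remains
  non-constant and the centered design keeps rank K in every (t−2)-task
  training subset. The noiseless-recovery tests assert this property of the
  annotation draw as an explicit precondition.
- Repeated-measures ANOVA sums of squares at float-cancellation scale
  (≤ 1e−12 of the total) are treated as exact zeros, so identical accuracy
  vectors give F = 0 rather than 0/0; zero-variance paired differences are
  flagged degenerate with an infinite (or undefined) t.
- Ridge solves use `numpy.linalg.solve` on K × K normal equations; with
  K ≤ 36 and α > 0 conditioning is unproblematic.
- The null's map-level correlation exceeds-model comparisons are only
  meaningful where feature-activation coupling dominates the shared mean
  map; with a large `mean_map_sd`, model and null map r converge even
  though accuracies separate sharply.

## Problem sizes

Tests and the acceptance script run the pipeline at desk scale — typically
8–20 tasks, 4–12 features, 50–154 regions, 1–3 subjects, inner k of 3–5 —
chosen so the complete suite finishes in well under a minute per analysis
while leaving every combinatorial structure (session blocks, two-or-four
session tasks, seven networks, three parametric features) intact. The
full-scale default configuration (44 tasks, 1000 regions, 23 subjects,
inner k = 10) runs the identical code path; one subject's 946-split nested
CV takes on the order of two minutes.

## Known limitations

- Region-wise univariate fits; no joint multivariate model of the map.
- No feature interactions or nonlinearities.
- The annotation matrix of a real study must be supplied as a TSV (tasks ×
  features with class and parametric header rows); the package does not
  ship ontology annotations.
- The classifier's tie-breaking convention (toward the pair's first task)
  is deterministic but arbitrary; ties are flagged and essentially never
  occur with continuous data.
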