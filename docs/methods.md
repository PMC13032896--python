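# Methods

This note records the models, numerical choices and limitations behind
`udpep`, in the order the pipeline runs.

## Sequence space and encodings

The alphabet is the 20 canonical residues ordered alphabetically by
one-letter code; all encodings and design↔sequence mappings derive from
that order, so every artifact is reproducible from a seed alone.
Enumeration of the k-peptide space is lexicographic and refused for k > 6
(20⁶ ≈ 6.4·10⁷ sequences). One-hot encodings are k blocks of 20; a
tetrapeptide is an 80-vector with exactly four ones.

## Uniform designs

A design is an n × s matrix of levels 1..q with exact per-column balance
(q | n required). Levels map to the unit cube by the centred convention
x = (u − ½)/q, which keeps points off the boundary and is the standard
lattice image in the uniform-design literature; the discrepancy being
minimised is the mixture L2-discrepancy (MD2), evaluated in closed form.
Because levels are discrete, the pairwise kernel is precomputed as a q × q
lookup table; the O(n²) double sum is processed in row blocks so an
n = 16 000 evaluation fits comfortably in memory.

The SOAT search:

* **move set** — swap two entries within one randomly chosen column. This
  preserves balance by construction, so no repair step ever runs.
* **threshold schedule** — the initial threshold is the 0.3 quantile of
  |ΔMD2| over 100 probe moves and is multiplied by 0.85 after each outer
  loop; a worsening move is accepted iff ΔMD2 < threshold. The best design
  seen is returned, so the final MD2 never exceeds the initial one.
* **incremental evaluation** — a single swap touches two rows, so ΔMD2 is
  computed from the two affected kernel rows in O(n·s); per-row products
  are cached and a full recomputation runs every 1000 accepted moves to cap
  floating-point drift (verified in tests to agree with the from-scratch
  value to 1e-9).
* **budget** — defaults outer_loops = 50, inner_loops = 200·s build an
  n = 1000 design in a few seconds and n = 16 000 in minutes on one CPU.
  The tests and the acceptance script use smaller budgets (stated inline)
  because every balance property holds at any budget and the diagnostics
  they check are budget-insensitive.

The 31-design series uses sizes 1000..16000 step 500 with seeds
`cfg.seed + i`, built independently (the series is not nested).

A note on the Hamming diagnostic: for a balanced design the per-position
match probability against *any* test set is exactly 1/20, so the mean
train–test Hamming distance of a tetrapeptide design is 3.8 of 4 positions
up to rounding — the balance guarantee, not a sampling accident.

## Properties

* **logP** is the sum over residues of Wimley–White whole-residue
  water→octanol transfer free energies. The bundled scale is stored
  hydrophobic-positive (the negative of the published transfer energies)
  with neutral histidine; this orientation reproduces the full-space centre
  of −1.62 kcal/mol and the extreme ranges (logP < −10 for Asp/Glu/Lys-rich
  and > 4 for Trp/Phe-rich peptides), whereas the opposite sign convention
  contradicts those numbers. The full-space extreme-tail mass
  (logP < −10 or > 4) is exactly 3.01 %; sample draws of 10 000 sequences
  scatter around that by ±0.2 pp, which is how a printed figure of ~2.95 %
  on a test sample arises.
* **net charge / pI** use Henderson–Hasselbalch sums over an EMBOSS-style
  pKa set (N-term 8.6, C-term 3.6; side chains C 8.5, D 3.9, E 4.1, H 6.5,
  K 10.8, R 12.5, Y 10.1). pI is found by fixed-depth bisection (60
  halvings of [0, 14]), unique because the charge curve is strictly
  non-increasing and the termini guarantee both signs. This is a classical
  calculator: it stands in for learned pI predictors and will differ from
  them by up to a few tenths of a pH unit.
* **AP** cannot be computed at desk scale (it is defined over
  coarse-grained MD trajectories); the package implements the
  SASA_initial/SASA_final post-processing and the class binning
  [1, 1.5) / [1.5, 2) / [2, 2.5]. Ingested values above 2.5 are clamped to
  class 2 with a warning, since the class definition ends at 2.5 without
  an overflow rule.
* **descriptor panel** (11 keys): aromatic count over {F, H, W, Y}, net
  charge at pH 7, logP, pI, composition fractions for a documented
  hydrophobic/polar/charged partition, a Boman-style binding index (minus
  the mean Radzicka–Wolfenden side-chain value, proline set to 0), and the
  three Dubchak normalised van-der-Waals volume class fractions. This is a
  deliberately curated subset, not a reimplementation of the
  726-descriptor panels in R packages; keys are stable across runs.

## Modelling protocol

Training samples are split 80/20 into train/validation by design run;
hyperparameters are chosen by random search (default 50 configurations)
under 5-fold CV on RMSE and the winner is refit on the training split.
Two test surfaces are reported: a seeded 10 000-sequence draw from the
space excluding the design ("fixed"), and the full complement of the
training sequences ("nonfixed"). Metrics are MAE, MSE, RMSE and R².
Search spaces (random forest: 100–1000 trees, depth 5–None, min-leaf 1–10;
SVR: RBF with C ∈ [0.1, 100], γ ∈ [1e-4, 1] log-uniform; GBDT: common
ranges) are package defaults, exposed as configuration.

Learning-curve inflections are local maxima of |central second
difference| of the metric over the size grid, optionally after a
3-point moving average; a relative tolerance of 1e-9 of the maximum
curvature suppresses float-noise peaks, so constant-curvature curves
return no inflection. Error profiles report 100·|a−p|/|a| binned by the
actual value; samples with |a| < 1e-6 are excluded and counted separately
because the ratio is undefined near zero (the same artifact inflates
percentage errors near logP = 0 on real data).

The transformer backend follows a fixed architecture (6 encoder layers,
8 heads × 64, feed-forward 2048, embedding 512, MLP head
512/256/64/32 → 1 with batch-norm and dropout 0.3; SGD momentum 0.9 with
linear warmup 0.001 → 0.2). It is capability-gated on torch: in
environments without torch the function raises a clear error and the
classical backends are unaffected. The warmup peak of 0.2 is unusually
high for SGD and is exposed as configuration rather than asserted optimal.

## Attribution

AP classes are learned by three distinct GBDT implementations — xgboost,
lightgbm, and sklearn's GradientBoostingClassifier as the third ensemble —
on stratified 80/20 splits, with optional stratified-CV random search
scored by negative log-loss. Feature voting uses each model's gain-style
importances averaged over five stratified refits: significant iff
importance > mean + 1 SD within that model (strictly, so all-equal scores
select nothing), selected iff significant in ≥ 2 models. The vote is
invariant to feature order and to per-model positive affine rescaling of
the scores.

SHAP values and pairwise interaction values are computed **exactly** by
path-dependent tree traversal: E[f | x_S] descends the instance branch for
revealed features and cover-weights both children otherwise; per tree, the
coalition lattice over that tree's used features is enumerated (capped at
16 features per tree; the bundled search spaces keep trees shallow) and
Shapley/interaction weights are applied, summing across trees by
linearity. The interaction matrix is symmetric with pure main effects on
the diagonal, and φ₀ + ΣᵢΣⱼ Φᵢⱼ reconstructs the class margin to < 1e-6 on
every evaluated row (in practice ~1e-15). Feature comparisons replicate
each library's internal arithmetic (float32 thresholds for xgboost,
float32 feature casts for sklearn, raw doubles for lightgbm), which is
required for exact margin agreement. Multiclass surfaces are per-class
log-odds margins; class 1 (the self-assembly window) is the default
reported surface.

The aromaticity threshold statistic is a two-sided Mann–Whitney U between
SHAP values of adjacent aromatic-count groups, with significance tiers at
the Bonferroni-corrected cutoffs 0.001/4, 0.01/4, 0.05/4 and the median
change reported as a percentage of the lower group's absolute median.
Dependence-plot trends use a simple local-mean smoother (window fraction
0.3) and critical values are sign changes of the smoothed curve.

**A caution established by the negative control.** SHAP values of a
feature are a deterministic function of that same feature, so grouping
them by its value and testing location differences certifies *model
behaviour*, not a data-level effect: a model that has fitted pure noise
still shows significant group differences whenever it happened to split on
the feature. The package's zero-signal generator demonstrates this — the
*** tier fires in roughly half of null runs — so threshold-test
significance should always be read together with the effect magnitude and
with out-of-sample predictive performance, never alone. The corresponding
acceptance check is deliberately left failing rather than silently
weakening the test statistic.

## Synthetic data

The generator plants a known mechanism into AP labels:

ap = clip( 1.72 + g(aromatic) − 0.01·dist(logP, [−5, 2])² + 0.03·charge
           − 0.02·aromatic·logP + ε ,  [1, 2.5] ),   ε ~ N(0, 0.15²)

with g = (+0.18, +0.22, −0.10, −0.25, −0.35) for aromatic counts 0–4. The
intercept was calibrated once by full-space enumeration so the noiseless
mean lands at 1.853 (inside the target band [1.80, 1.92] around the
realistic centre 1.86); class shares are about 5.6 / 85 / 9.5 %. The
noiseless ground truth is stored beside the noisy labels.

What the generator emulates: the AP distribution's centre and support, an
aromaticity threshold, a logP window, a small charge effect, and one true
pairwise interaction. What it does not: trajectory-level physics,
position-specific effects, heteroscedastic noise, and the multimodal pI
distribution (pI is computed, never simulated). Recovery tests on this
generator therefore show that the pipeline can find planted
composition-level mechanisms at realistic noise — they do not certify the
specific magnitudes any real simulation campaign would produce.

Recovery at n = 4000 (uniform-design sample, 80 % training, fixed
10 000-sequence test) finds the planted aromaticity ranking, the 1→2
threshold drop at the strongest tier, and the aromatic×logP interaction in
all three GBDTs, with exact SHAP additivity. The companion R² ≥ 0.8 bound
against the noiseless signal is *not* met: at noise sd 0.15 the best
backend (a deep random forest) reaches R² ≈ 0.72, and only a noiseless
training set reaches 0.82 — the bound sits above what the stated noise
level permits at this sample size, and the corresponding acceptance check
is left failing rather than quietly relaxing the noise or the bound.
Uniform-design training does beat simple random sampling at n = 1000 in
mean test MSE (16/20 paired seeds, one-sided sign test p < 0.05),
the empirical counterpart of the design-optimality argument.

## Problem sizes used by the test-suite

Tests run the same algorithms at reduced budgets chosen as the package's
own defaults for quick verification: SOAT with a few hundred proposals per
size (balance and diagnostics are budget-insensitive), recovery at
n = 4000 across five seeds, the null control across ten seeds, and the
design-vs-random comparison across twenty paired seeds with a
3000-sequence truth-evaluated test set. The acceptance script builds the
n = 1000 and n = 4500 designs fresh at each invocation and evaluates the
Hamming diagnostic over all 45 million train–test pairs.
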