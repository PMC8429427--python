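# Methods

`fcbrainage` implements a resting-state functional-connectome brain-age
pipeline and exercises it end to end on synthetic cohorts with a planted
accelerated-aging group. This note documents the models, the choices
made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Pipeline

1. **Motion scrubbing.** Frames with framewise displacement (FD) above
   0.5 mm are censored together with 1 frame before and 2 after; removal
   windows from multiple spikes are unioned. Subjects retaining less
   than 40% of their frames are discarded — *exactly* 40% passes, since
   the discard rule is "less than 40%".
2. **Connectivity.** Pairwise Pearson correlation over retained frames,
   Fisher z-transformed with |r| clipped at 1 − 1e-7 so degenerate
   inputs stay finite. The diagonal is stored as 0 and ignored by all
   consumers.
3. **Mean-regression (MR) denoising.** For every edge, an OLS fit of the
   edge value on the subject-mean connectivity (mean of the Fisher-z
   upper triangle) is estimated across training subjects only; each
   subject's edge is replaced by its residual. The predictor is the
   *z-scale* subject mean: MR is described operationally after the
   z-transform, and using z keeps the regression on one scale
   throughout. The model is frozen after fitting — applying it never
   updates coefficients, and applying it twice is an error.
4. **Graph metrics.** A 26-entry catalog (21 metrics of the weighted
   signed matrix, 5 of a binary graph obtained by proportional
   thresholding at 5% link density — exactly round(0.05·E) strongest
   edges, ties broken lexicographically). Nodal metrics are summarized
   by mean, median, or median of log (subgraph centrality, whose
   distribution is heavy-tailed). Weighted metrics that need
   non-negative weights use |z|; signed quantities (assortativity,
   positive-edge summaries) read the raw residuals. Small-worldness,
   resilience, rich-club and coreness are degenerate on complete
   weighted graphs and therefore operate on the 5%-thresholded graph
   derived from the weighted matrix.
   * Small-worldness is the ratio of ratios
     SW = (C/C_rand)/(E_rand/E) with C, E the average clustering and
     global efficiency and the null means taken over 20 seeded
     Erdős–Rényi graphs with the same node and edge count (matching the
     "same node-edge count random network" reference, not
     degree-preserving rewiring).
   * Resilience is the OLS slope of log(density) vs log(bin center)
     over 10 logarithmic degree bins (density = count/bin width, so the
     slope estimates the exponent of a power-law degree distribution);
     fewer than 3 occupied bins is an error, not a value.
   * Community structure uses Louvain (igraph multilevel, C
     implementation), best Q of 10 seeded runs, first occurrence wins
     ties. Coreness is summarized by its **mean**: at 5% density the
     median k-core index is the same small integer for every subject,
     which would violate the sd > 0 invariants of the outlier rule and
     standardization.
   * Any non-finite metric raises with the metric and subject named.
5. **Outlier exclusion.** A subject is dropped when any metric is more
   than 5 training-set standard deviations from the training mean; the
   rule is fitted on training subjects only and applied frozen to all
   splits.
6. **Feature ranking.** Linear support-vector regression (standardized
   features, penalty chosen over a 13-point log grid 1e-4…1e2 by 5-fold
   CV stratified by age quintile) scored by normalized |coefficient|,
   and a tree ensemble (bagging/gradient boosting over a small seeded
   search: cycles {50, 100, 200}, learning rates {0.05, 0.1, 0.3}) on
   unstandardized features, scored by the sum of MSE reductions over
   splits per predictor divided by the total branch-node count. Final
   order = average of the two ranks; ties break by margin rank, then
   catalog order. The deterministic grids replace black-box Bayesian
   optimization; at 26 features they cover the same range.
7. **Brain-age networks.** Fully connected nets with tanh hidden layers
   (1–2 layers, units in {2, 5, 7, 10}, second ≤ first: 14 shapes) over
   5–25 top-ranked inputs. Training minimizes MSE + λ·Σw² (weight decay
   λ = 0.01, biases unpenalized) on internally z-scored targets, by
   L-BFGS with analytic gradients to gradient norm < 1e-6 or 2000
   iterations from seeded Glorot-uniform initialization — fixed weight
   decay plays the shrinkage role of Bayesian-regularized
   backpropagation while staying deterministic. Target z-scoring is
   purely numerical: without it the output bias must travel ~50 years
   from zero and the optimizer can stall in a constant-predictor basin.
   Each grid cell is trained 3 times (seeds s, s+1, s+2); the cell with
   the lowest mean validation rmse wins, ties broken by fewer
   parameters, then fewer inputs. An optional null repeats the grid
   with a randomly permuted feature order. The frozen model keeps the
   best-validation iteration of the selected cell; `model.json` is
   written before any test file is opened, and prediction never refits.
   No age-bias correction is applied to predictions; age enters the
   inference stage as a covariate instead.
8. **PAD inference.** PAD = predicted − chronological age. Group
   contrasts are OLS GLMs of PAD on a group indicator plus chronological
   age (F test on the group term, df (1, n − 3); optional one-tailed).
   Continuous associations are partial Pearson correlations with age
   residualized from both sides (df = n − 3). The Mann–Whitney fallback
   enumerates group assignments exhaustively (with ties counted 1/2)
   when C(n_a+n_b, n_a) ≤ 1e5, uses the exact no-tie distribution for
   n_a·n_b ≤ 400, and the tie-corrected normal approximation otherwise —
   full enumeration with ties at e.g. 20 × 20 (C(40,20) ≈ 1.4e11) is
   infeasible. EYO = chronological age − parental onset age (negative
   before expected onset). No multiple-testing correction; contrasts are
   reported individually.

## Synthetic cohorts

The generator emulates the statistical skeleton of multi-site lifespan
rs-fMRI cohorts. Per subject it builds a block-modular correlation
target at the subject's *effective* age (chronological + group delta +
N(0, 2 yr) jitter), perturbs it in Fisher-z space, projects to the
nearest positive-semidefinite correlation matrix (eigenvalue clipping at
1e-8, diagonal renormalized) and samples Gaussian time series, plus an
FD trace with baseline |N(0.15 mm, 0.05)| and spike frames (prob 0.02)
at 0.8 mm with added high-variance noise.

Aging acts through four channels, all linear in effective age:

* module structure: within-module r falls (−0.002/yr from 0.45),
  between-module r rises (+0.001/yr from 0.05);
* per-edge aging-rate jitter (sd 0.002 z/yr) around the class trend;
* region-level aging rates (sd 0.003 z/yr), edges inheriting the mean
  of their endpoints' rates, so fast-aging hubs reorganize degree
  structure;
* **dedifferentiation**: the per-subject idiosyncratic edge field
  (sd 0.18 z at mid-cohort) shrinks by 1.2%/yr of effective age.

The last channel matters most and its design is deliberate. MR
residualization centers every edge across the cohort, so *any*
deterministic (cohort-fixed) age pattern leaves residuals that cross
zero near mid-cohort age — |residual|-based global metrics then see a
V-shape that aliases young against old. An age-dependent amplitude of
the *random per-subject* field survives centering (its per-edge mean is
already zero) and moves magnitude-based metrics monotonically, mirroring
the empirical decline of connectome distinctiveness with age. With the
defaults, the latent amplitude factor correlates with age at r ≈ −0.87
through the full pipeline, and a network trained on 300 subjects reaches
out-of-sample R² ≈ 0.67 with a prediction-vs-age slope ≈ 0.8.

Site effects are additive per-site Fisher-z edge offsets (sd 0.02);
a per-subject global offset (sd 0.05) emulates the motion-driven global
component that MR is designed to remove — without it the subject-mean
predictor would be an almost deterministic function of age and MR would
strip the entire linear age signal. Motion is independent of age by
default (the joint distribution is not characterized in real cohorts).
Amyloid load tracks the planted brain-age offset (+0.03 SUVR-like units
per accelerated year, noise sd 0.08, positivity at ≥ 1.31) so the
PAD–amyloid partial correlation has recoverable signal; parental onset
age for carriers is chronological age + N(10, 5) yr.

What the generator does **not** model: raw 4-D volumes, hemodynamics,
scanner physics, realistic sex/education confounds, nonlinear aging
trajectories, or motion–age dependence. Passing tests therefore show
that the pipeline recovers planted effects through the full metric and
model stack under Gaussian assumptions, not that it would achieve the
same accuracy on real cohorts.

## Study design and problem sizes

The planted accelerated-aging experiment (`accelerated_aging_study`)
uses 480 controls over ages 18–90 (three site draws feeding
training/test, one held-out validation site) and 30 carriers with
Δ = 8 yr over ages 25–65; splits give ≈ 240 training, ≈ 120 validation
and ≈ 120 + 30 test subjects at 60 regions, 300 frames, TR 2 s. The
carrier band is mid-range because any regression-based age predictor
flattens near the edges of its training range (regression to the mean),
which would attenuate the recovered group difference for very old
carriers. The default reduced grid for this study is inputs
{5, 10, 15, 20} × architectures {(5), (5,2), (10,5)}; the full 70-cell
grid is available via `full_grid=True`.

Replicate counts in the test suite (5 end-to-end recovery replicates,
10 ranking-recovery and ranked-vs-null replicates, 200 inference-only
type-I replicates) and the 60-region default (238 supported) are the
package's chosen problem sizes; proportional pass thresholds (≥ 80%,
≥ 90%) follow the corresponding property statements.

## Numerical notes and limitations

* Determinism: every stochastic step (cohort sampling, Louvain runs,
  null graphs, CV folds, net initialization, null ordering) is seeded;
  a full run is a pure function of its configuration, and repeated runs
  produce byte-identical reports.
* Proportional thresholding uses banker's rounding (`round`), and ties
  at the cutoff are broken by (i, j) order — relabeling invariance holds
  only up to these tie-breaks.
* Binary assortativity is undefined (NaN) when all endpoint degrees are
  equal; the metric layer raises rather than imputing. At 5% density on
  60+ regions this does not occur in practice.
* The catalog is configurable via YAML; the binarized/weighted split of
  the default catalog (21/5) reflects the convention that only a
  minority of whole-brain metrics require equal-density binary graphs.
  One published account of the retained binarized metric calls it a
  "weighted modularity coefficient", which is internally contradictory;
  the catalog carries both weighted and binary modularity.
* The EYO sign convention (negative before onset) follows the reported
  cohort tables; the alternative sign is a trivial negation.
* Collinearity among the 26 metrics is not corrected (no stability
  selection or recursive elimination); the ranking stage inherits the
  usual instability of importance measures under correlated features.
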