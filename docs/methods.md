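# Methods

`dynfc` classifies subjects of a resting-state fMRI cohort from the *dynamics*
of functional connectivity between independent brain networks. This note
documents the model at each stage, the defaults and why they were chosen, what
the synthetic cohorts do and do not emulate, and the numerical decisions that
an auditor of the results would want to know.

## Pipeline

### Group spatial ICA

Subject series `X_i (T x V)` are reduced in two PCA stages: per subject to the
smallest dimension explaining >= 95% of variance (capped at 30, preventing the
variance criterion from exploding the dimension on noisy data), then the
temporally concatenated reduced data are reduced to exactly `n_components`
(default 20) directions. The group matrix is unmixed by natural-gradient
Infomax with a logistic nonlinearity — the maximum-likelihood gradient for
super-Gaussian sources, which spatial network maps are. Defaults: learning
rate 3e-3, block size 128, rate annealed by 0.9 on oscillation (successive
update angle > 60 deg) and, once the per-pass update norm falls below 1e-3, on
every pass, so the tolerance of 1e-7 on the weight change is actually reached;
at most 500 passes, after which the best iterate is returned with a warning.
Non-extended Infomax is used deliberately: sub-Gaussian sources are not
expected.

Stability (ICASSO): the decomposition is re-run `icasso_runs` (default 10)
times from random initializations; components are pooled across runs,
similarity = |Pearson r| between maps, average-linkage clustering into
`n_components` clusters, quality index `Iq` = mean intra-cluster minus mean
extra-cluster similarity. The consensus map of a cluster is its centrotype
(member with the largest total intra-cluster similarity). Clusters are ordered
by decreasing `Iq`, so a keep-list of `range(15)` retains the 15 most stable
components — the analogue of discarding noise components. Note that `Iq`
equals 1 only up to the cross-component similarity floor: even bit-identical
runs leave a small extra-cluster term, so "identical runs give Iq = 1" is
asserted at intra-similarity exactly 1 and Iq > 0.9.

Subject-level maps and time courses are recovered by dual regression (two
least-squares stages with intercept: maps -> time courses, time courses ->
maps). Group-information-guided constrained ICA would be a drop-in
alternative; dual regression was chosen because it is deterministic, standard,
and fully specified. Group maps are always estimated on training folds only
and applied frozen to test subjects.

Component sign is fixed by making each source's largest-magnitude sample
positive, and sources have unit variance; both conventions exist to make runs
comparable inside ICASSO and across folds.

### Connectivity features

Component (or atlas-ROI-mean) time courses are optionally post-processed
(linear detrend, optional nuisance regression, zero-phase 2nd-order
Butterworth band-pass 0.01-0.08 Hz). A rectangular sliding window (width 50
TR, step 1 TR; no taper, because none is part of the design) yields
`w = floor((T - width)/step) + 1` windows; each window's K x K Pearson matrix
keeps the sign of r (no Fisher transform) with a unit diagonal, and its strict
upper triangle in row-major order is the feature vector — d = K(K-1)/2, i.e.
105 for K = 15 and 6670 for the 116-region AAL parcellation. A window segment
with zero variance would make r undefined; such entries are set to 0 with a
warning rather than dropping the window, preserving sequence alignment across
subjects. Static features are the same vector computed once from the whole
time course.

### Sequence classifier

A single unidirectional LSTM layer with H = 30 hidden cells consumes the
d x w sequence column by column; the final hidden state feeds two fully
connected layers (30 -> 16 -> classes) with a ReLU between them and a softmax
output. The gate equations are the standard coupling in which the output gate
multiplies the tanh of the updated cell state. Training: cross-entropy, Adam
(1e-3), mini-batches of 16 with end-padding and a mask (the cell state is
carried unchanged through padded steps, so the readout is the last *valid*
state), at most 200 epochs. All of this is implemented in NumPy float64 with
hand-written backpropagation through time; the analytic gradient is verified
against central finite differences to < 1e-4 relative error in the test
suite, and a same-seed fit is bit-reproducible.

Regularization deserves a paragraph, because the failure mode it addresses is
intrinsic to windowed-correlation features. With step 1 and width 50,
consecutive windows share 98% of their samples, so every feature is a slowly
varying curve around a subject-specific mean whose sampling error (about
1/sqrt(width) ~ 0.14 in r units) does not average away within a subject. A
cohort therefore presents the classifier with ~d near-constant "signature"
features per subject, and with n in the tens, hidden-state trajectories can
memorize training subjects instead of the group effect. Three conventional
measures counter this: Gaussian input jitter (sd 2.0 on standardized
features) during training, a stratified 20% validation holdout that drives
early stopping (patience 20) with best-epoch weight restore, and decoupled
weight decay (1e-2) on the weight matrices. The forget-gate bias is
initialized to +1 (standard practice for gradient flow over ~80 steps); other
weights are Glorot-uniform.

Static-feature baselines are a standardized linear SVM and a 100-tree random
forest.

### Evaluation

Stratified 10-fold cross-validation. Per fold, *everything* trainable — the
PCA bases, ICA maps, feature standardization statistics (per-feature z-scores
pooled over training subjects and windows), and classifier weights — is a pure
function of the training subjects; the test suite asserts bit-identical fold
artifacts when test-subject data are replaced by noise. Metrics: accuracy,
sensitivity, specificity, precision, F1 (one-vs-rest macro-averaged in the
multiclass case), Cohen's kappa with the marginal-product chance term,
macro-averaged Jaccard, and trapezoidal ROC AUC. Ratios with zero denominators
are reported as NaN and excluded from fold averages instead of being
zero-filled, which would bias small folds. Both the mean-over-folds and the
pooled-confusion aggregates are reported; for accuracy they agree to within
one subject per fold by construction. The positive class is explicit in the
configuration (default: the lexicographically last label).

## Synthetic cohorts

The generator produces exactly the data model the pipeline assumes: K
non-negative Gaussian-blob spatial maps with distinct centers (pairwise
spatial |r| < 0.3, placed by best-candidate sampling), component time courses
drawn at each time point from a zero-mean multivariate normal whose
correlation matrix depends on a hidden Markov state (uniform off-diagonal
transitions, stay probability 1 - 1/mean_dwell), and voxel data =
timecourses x maps + white Gaussian noise scaled to a target signal/noise sd
ratio. Group "B" differs from group "A" only in that designated component
pairs have their correlation shifted by delta — in every state by default, or
per-state (e.g. +delta/-delta) to build effects that vanish from whole-course
correlation.

Defaults describe a mid-sized aging-cohort scan: K = 15 networks, T = 130
time points, 2 states with mean dwell 40 TR, a 15 x 15 x 10 voxel grid
(V = 2250), snr 2, n = 40 + 40 subjects. The default planted effect shifts
three disjoint pairs together, emulating a distributed disconnection
phenotype rather than a single edge; disjointness keeps every shifted
correlation matrix positive-definite for any |delta| < 1 at zero baseline,
and components carrying the effect receive no background correlation, so at
delta = 0 the groups are exchangeable by construction. Background state
structure correlates a different set of the remaining pairs (r = 0.5) in each
state, making the states identifiable from windowed connectivity.

What the generator does *not* emulate: hemodynamic convolution (the pipeline
only consumes second-order temporal statistics), scanner drift and motion,
physiological noise spectra, spatial autocorrelation of noise, site effects,
and between-subject anatomical variability of the maps. Passing tests
therefore certify the statistical machinery — recovery, windowing,
leakage-free evaluation, sensitivity to dynamic vs. static effects — not
performance on real scans.

## Problem sizes used in the checks

The end-to-end checks run at deliberately desk-scale sizes: source-recovery
on 3-source mixtures of 5000 samples and on 12-subject cohorts with K = 5 on
a 12 x 12 x 8 grid; stability on a 4-source, 2048-voxel mixture; the
strong-effect benchmark at the full default scale (80 subjects, V = 2250,
10-fold, ICASSO 10); the null (delta = 0) and dynamic-vs-static comparisons
on component time courses directly, since they probe the feature/classifier
stages rather than ICA.

The dynamic-vs-static comparison deserves care, because with a Markov state
process the fraction of the scan spent in each state varies widely across
subjects, and a state-confined correlation effect then *leaks into the
whole-course correlation* through that occupancy fraction — static
classifiers score well for reasons that have nothing to do with temporal
modeling. To isolate a purely dynamic effect the comparison cohort uses a
balanced two-state sequence (`sample_balanced_state_sequence`: exactly T/2
time points per state in randomly cut alternating blocks) and an
opposite-sign pair effect (+0.7 in one state, -0.7 in the other, three
disjoint pairs, n = 20 + 20, five cohort seeds). Whole-course correlations
are then uninformative by construction, while 30-TR windows swing by +/-0.7;
the LSTM is run with the mean-over-time readout, which suits a signal
expressed in the distribution of window values rather than in a terminal
trend.

## Known limitations

- Infomax may report non-convergence on very small sample counts (hundreds of
  voxels); the returned iterate is still usable and flagged.
- ICASSO uses random-restart resampling only (no bootstrap).
- The kappa chance term uses the standard marginal products; a variant that
  ties chance agreement to the diagonal is not implemented because it is not
  a proper chance correction.
- Multiclass AUC is not defined (binary only); multiclass reports use
  macro-averaged one-vs-rest rates.
- The LSTM is a faithful but small implementation; it is not intended for
  GPU-scale work, attention variants, or bidirectional processing.
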