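# dynfc

Dynamic functional connectivity of independent brain networks, with an LSTM
sequence classifier — a complete pipeline for classifying subjects of a
resting-state fMRI cohort (e.g. patients vs. controls) from how the coupling
between brain networks *changes over a scan*, rather than from its
whole-scan average.

## What it does

Given preprocessed 4D rs-fMRI volumes (or the built-in synthetic cohorts):

1. **Group spatial ICA** — two-stage PCA reduction (per-subject 95% variance,
   then exactly 20 group components), natural-gradient Infomax unmixing,
   ICASSO stability analysis (10 restarts, components clustered across runs
   by |r|, quality index Iq = intra − extra cluster similarity), and subject
   back-reconstruction by dual regression.
2. **Sliding-window connectivity** — for the K retained networks, each window
   of 50 TR (step 1 TR) yields a K×K Pearson matrix R with diagonal 1; the
   feature vector is its strict upper triangle, `d = K(K−1)/2` (105 for
   K = 15; 6670 for the 116-region AAL baseline), giving a `d × w` sequence
   per subject with `w = ⌊(T − width)/step⌋ + 1`.
3. **LSTM classification** — a single 30-cell LSTM layer

       f(t) = σ(ω_f·[h(t−1), X(t)] + b_f)
       i(t) = σ(ω_i·[h(t−1), X(t)] + b_i)
       C̃(t) = tanh(ω_c·[h(t−1), X(t)] + b_c)
       C(t) = f(t)⊙C(t−1) + i(t)⊙C̃(t)
       h(t) = σ(ω_o·[h(t−1), X(t)] + b_o) ⊙ tanh C(t)

   read out at the last window into two fully connected layers
   (30 → 16 → classes) with ReLU and softmax, trained by Adam/BPTT in NumPy.
   Static-feature baselines (linear SVM, random forest) quantify what the
   temporal dynamics add.
4. **Evaluation** — stratified 10-fold cross-validation with the ICA maps,
   feature standardization and classifier all fitted per fold on training
   subjects only; accuracy, sensitivity, specificity, F1, Cohen's kappa,
   macro Jaccard and ROC AUC, reported per fold and as mean ± sd.

A synthetic-cohort generator with full ground truth (spatial maps,
state-switching inter-network covariance via a hidden Markov process, planted
group differences at chosen correlation shifts and SNR) backs the test suite
and lets every stage be validated against known answers.

## Worked example

```python
import numpy as np
from dynfc import make_cohort, run_experiment

# 80 subjects, 15 networks, T=130; group B has three network couplings
# shifted by +0.6, mixed into 2250 voxels at SNR 2
cohort = make_cohort(n_per_group=(40, 40), delta=0.6, snr=2.0, seed=1)

report = run_experiment(
    cohort.voxel_series, cohort.group_labels,
    level="ica", mode="dynamic",          # group ICA -> windowed FC -> LSTM
    n_components=20, keep_list=list(range(15)),
    k=10, seed=0)
print(report.summary())
```

prints (metric: mean ± sd over the 10 folds):

```
ACC: 0.9750 +/- 0.0750
AUC: 0.9875 +/- 0.0375
F1: 0.9750 +/- 0.0750
Jaccard: 0.9600 +/- 0.1200
Kappa: 0.9500 +/- 0.1500
SEN: 0.9750 +/- 0.0750
SPE: 0.9750 +/- 0.0750
precision: 0.9750 +/- 0.0750
recall: 0.9750 +/- 0.0750
```

i.e. the planted 0.6 correlation shift is recovered almost perfectly through
the full ICA → windowed-connectivity → LSTM chain, while the same experiment
with `delta=0.0` stays at chance (the test suite asserts both, as well as the
gap between this dynamic pipeline and the static SVM/RF baselines when the
group effect is visible only in state-dependent covariance).

The same pipeline is scriptable from a shell:

```bash
dynfc simulate --out cohort/ --n-per-group 40,40 --delta 0.6 --seed 1
dynfc run-all --data cohort/ --out results/ --seed 0
```

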