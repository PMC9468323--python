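"""Cross-validated experiment harness.

For every stratified fold the pipeline is fitted strictly on the training
subjects — group ICA maps, feature-standardization statistics and classifier
weights never see test data — and the held-out fold is pushed through the
fitted stages (back-reconstruction against the frozen group maps, fixed
standardization, fixed classifier).  Per-fold scores and their mean +/- sd
across folds are reported, alongside the pooled confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import LSTMSequenceClassifier, train_rf_baseline, train_svm_baseline
from .connectivity import (dfc_sequence, postprocess_timecourses,
                           roi_mean_timecourses, static_fc)
from .ica import GroupICA
from .metrics import (binary_metrics, cohen_kappa, confusion_counts,
                      confusion_matrix, jaccard_score, roc_auc,
                      stratified_kfold)

__all__ = ["ExperimentConfig", "FoldArtifacts", "ExperimentReport",
           "SequenceStandardizer", "fit_fold", "run_experiment"]


@dataclass
class ExperimentConfig:
    """Everything a cross-validated run depends on.

    level: "ica" (voxel data, group ICA per fold — the full protocol),
    "roi" (voxel data averaged within atlas regions, no ICA), or
    "timecourse" (component signals supplied directly, ICA skipped).
    mode: "dynamic" (windowed feature sequences + LSTM) or "static"
    (whole-course vectors + SVM/RF).
    """
    level: str = "ica"
    mode: str = "dynamic"
    classifier: str = "lstm"            # lstm | svm | rf
    n_components: int = 20
    variance_threshold: float = 0.95
    subject_pca_max: int = 30
    icasso_runs: int = 10
    keep_list: list = None
    width: int = 50
    step: int = 1
    band: tuple = (0.01, 0.08)
    tr: float = 3.0
    postprocess: bool = False
    k: int = 10
    seed: int = 0
    positive_class: object = None
    hidden_size: int = 30
    fc_size: int = 16
    learning_rate: float = 1e-3
    max_epochs: int = 200
    batch_size: int = 16
    patience: int = 20
    readout: str = "last"

    def __post_init__(self):
        if self.level not in ("ica", "roi", "timecourse"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.mode not in ("dynamic", "static"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.classifier not in ("lstm", "svm", "rf"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.mode == "dynamic" and self.classifier != "lstm":
            raise ValueError("dynamic feature sequences require the LSTM")
        if self.mode == "static" and self.classifier == "lstm":
            raise ValueError("the LSTM consumes dynamic sequences; use "
                             "svm or rf for static vectors")


class SequenceStandardizer:
    """Per-feature z-scoring of (d, w) sequences with training-set statistics.

    The mean and sd of each of the d features are pooled over all training
    subjects and windows; transform applies the frozen statistics.
    """

    def fit(self, sequences):
        cat = np.concatenate([np.asarray(s, dtype=float) for s in sequences],
                             axis=1)
        self.mean_ = cat.mean(axis=1)
        sd = cat.std(axis=1)
        self.scale_ = np.where(sd == 0, 1.0, sd)
        return self

    def transform(self, sequences):
        return [(np.asarray(s, dtype=float) - self.mean_[:, None])
                / self.scale_[:, None] for s in sequences]


@dataclass
class FoldArtifacts:
    """Training-fold state exposed for the leakage audit."""
    group_maps: np.ndarray
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    classifier: object


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    per_fold: list                       # list of dicts of metric -> value
    mean: dict
    sd: dict
    pooled_confusion: np.ndarray
    classes: np.ndarray
    pooled_metrics: dict
    y_true: np.ndarray
    y_pred: np.ndarray
    fold_artifacts: list = field(default_factory=list)

    def summary(self):
        lines = [f"{k}: {self.mean[k]:.4f} +/- {self.sd[k]:.4f}"
                 for k in sorted(self.mean)]
        return "\n".join(lines)


def _timecourses_for(data, idx, cfg, atlas_labels, ica=None):
    """Component/ROI time courses for the subjects in ``idx``."""
    if cfg.level == "timecourse":
        tcs = [np.asarray(data[i], dtype=float) for i in idx]
    elif cfg.level == "roi":
        tcs = [roi_mean_timecourses(data[i], atlas_labels)[0] for i in idx]
    else:
        comps = ica.transform([data[i] for i in idx])
        tcs = [c.timecourses for c in comps]
    if cfg.postprocess:
        tcs = [postprocess_timecourses(tc, tr=cfg.tr, band=cfg.band)
               for tc in tcs]
    return tcs


def _features_for(tcs, cfg):
    if cfg.mode == "dynamic":
        return [dfc_sequence(tc, width=cfg.width, step=cfg.step)
                for tc in tcs]
    return [static_fc(tc) for tc in tcs]


def fit_fold(data, labels, train_idx, cfg, atlas_labels=None, fold_seed=0):
    """Fit every trainable stage of one fold on the training subjects only.

    Returns (artifacts, ica) so the caller can evaluate held-out subjects;
    a pure function of the training subjects, which the leakage audit
    exploits by perturbing test subjects and asserting bit-identical output.
    """
    labels = np.asarray(labels)
    ica = None
    if cfg.level == "ica":
        ica = GroupICA(
            n_components=cfg.n_components,
            variance_threshold=cfg.variance_threshold,
            subject_pca_max=cfg.subject_pca_max,
            icasso_runs=cfg.icasso_runs,
            keep_list=cfg.keep_list,
            random_state=fold_seed,
        ).fit([data[i] for i in train_idx])
    tcs = _timecourses_for(data, train_idx, cfg, atlas_labels, ica)
    feats = _features_for(tcs, cfg)

    if cfg.mode == "dynamic":
        scaler = SequenceStandardizer().fit(feats)
        Xtr = scaler.transform(feats)
        clf = LSTMSequenceClassifier(
            hidden_size=cfg.hidden_size, fc_size=cfg.fc_size,
            learning_rate=cfg.learning_rate, max_epochs=cfg.max_epochs,
            batch_size=cfg.batch_size, patience=cfg.patience,
            readout=cfg.readout, random_state=fold_seed).fit(Xtr, labels[train_idx])
        scaler_mean, scaler_scale = scaler.mean_, scaler.scale_
    else:
        Xtr = np.asarray(feats)
        y = labels[train_idx]
        if cfg.classifier == "svm":
            clf = train_svm_baseline(Xtr, y, seed=fold_seed)
        else:
            clf = train_rf_baseline(Xtr, y, seed=fold_seed)
        scaler = None
        scaler_mean = scaler_scale = np.zeros(0)

    artifacts = FoldArtifacts(
        group_maps=(ica.group_maps_.copy() if ica is not None else None),
        scaler_mean=np.array(scaler_mean, copy=True),
        scaler_scale=np.array(scaler_scale, copy=True),
        classifier=clf)
    return artifacts, ica, scaler


def _predict_fold(data, test_idx, cfg, atlas_labels, ica, scaler, clf,
                  classes):
    tcs = _timecourses_for(data, test_idx, cfg, atlas_labels, ica)
    feats = _features_for(tcs, cfg)
    if cfg.mode == "dynamic":
        Xte = scaler.transform(feats)
        probs = clf.predict_proba(Xte)
        pred = clf.predict(Xte)
        score_pos = probs[:, -1] if classes.size == 2 else None
    else:
        Xte = np.asarray(feats)
        pred = clf.predict(Xte)
        if classes.size == 2:
            if hasattr(clf, "predict_proba") and cfg.classifier == "rf":
                score_pos = clf.predict_proba(Xte)[:, -1]
            else:
                score_pos = clf.decision_function(Xte)
        else:
            score_pos = None
    return pred, score_pos


def _fold_metrics(y_true, y_pred, scores, classes, positive):
    out = {}
    M, _ = confusion_matrix(y_true, y_pred, classes)
    if classes.size == 2:
        counts = confusion_counts(y_true, y_pred, positive)
        out.update(binary_metrics(counts))
        if scores is not None:
            try:
                out["AUC"] = roc_auc(y_true, scores, positive=positive)
            except ValueError:
                out["AUC"] = float("nan")
    else:
        out["ACC"] = float(np.trace(M) / M.sum())
        per = [binary_metrics(confusion_counts(y_true, y_pred, c))
               for c in classes]
        for key in ("SEN", "precision", "F1"):
            out[key] = float(np.nanmean([p[key] for p in per]))
    out["Kappa"] = cohen_kappa(M)
    out["Jaccard"] = jaccard_score(y_true, y_pred)
    return out


def run_experiment(data, labels, config=None, atlas_labels=None,
                   keep_artifacts=False, **config_kwargs):
    """Stratified k-fold evaluation of the configured pipeline.

    Parameters
    ----------
    data : list of per-subject arrays
        (T, V) voxel series for level "ica"/"roi", (T, K) time courses for
        level "timecourse".
    labels : array of group labels, one per subject.
    config : ExperimentConfig, or keyword overrides of its defaults.
    atlas_labels : (V,) int array, required for level "roi".
    keep_artifacts : bool
        Retain per-fold group maps / scaler stats / classifiers in the
        report (used by the leakage audit).
    """
    cfg = config if config is not None else ExperimentConfig(**config_kwargs)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    positive = cfg.positive_class if cfg.positive_class is not None \
        else classes[-1]
    if cfg.level == "roi" and atlas_labels is None:
        raise ValueError("level 'roi' requires atlas_labels")

    folds = stratified_kfold(labels, k=cfg.k, seed=cfg.seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in np.random.SeedSequence(cfg.seed).spawn(len(folds))]

    per_fold, artifacts_list = [], []
    y_true_all, y_pred_all = [], []
    for f, (tr, te) in enumerate(folds):
        artifacts, ica, scaler = fit_fold(
            data, labels, tr, cfg, atlas_labels, fold_seed=fold_seeds[f])
        pred, scores = _predict_fold(
            data, te, cfg, atlas_labels, ica, scaler, artifacts.classifier,
            classes)
        m = _fold_metrics(labels[te], pred, scores, classes, positive)
        m["fold"] = f
        per_fold.append(m)
        y_true_all.append(labels[te])
        y_pred_all.append(pred)
        if keep_artifacts:
            artifacts_list.append(artifacts)

    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    keys = [k for k in per_fold[0] if k != "fold"]
    mean = {k: float(np.nanmean([m[k] for m in per_fold])) for k in keys}
    sd = {k: float(np.nanstd([m[k] for m in per_fold])) for k in keys}
    pooled_M, _ = confusion_matrix(y_true, y_pred, classes)
    pooled = {"ACC": float(np.trace(pooled_M) / pooled_M.sum()),
              "Kappa": cohen_kappa(pooled_M),
              "Jaccard": jaccard_score(y_true, y_pred)}
    return ExperimentReport(
        config=cfg, per_fold=per_fold, mean=mean, sd=sd,
        pooled_confusion=pooled_M, classes=classes, pooled_metrics=pooled,
        y_true=y_true, y_pred=y_pred, fold_artifacts=artifacts_list)
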