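"""Downstream classification: does adding synthesized pairs to the training
set help a conventional radiomics-style classifier?

Pipeline: per-image feature extraction (pluggable; a deterministic
non-learned fallback extractor is built in so no pretrained weights are
needed), recursive feature elimination with fivefold cross-validated linear
rankings down to 30 features, kernel SVM classification, and
Acc/Sen/Spe/AUC.  Synthetic samples may only ever enter training sets; the
experiment driver enforces that structurally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize as _resize
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .phantoms import PairedSample


@dataclass
class FeatureTable:
    """Samples x named real-valued features, with binary labels and a
    real/synthetic provenance tag per row."""

    X: np.ndarray
    labels: np.ndarray          # 0/1, positive class analogous to HGG
    feature_names: list
    provenance: np.ndarray      # "real" | "synthetic"
    positive_label: str | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if np.isnan(self.X).any():
            raise ValueError("feature table contains missing values")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature name count != column count")
        if not np.isin(np.unique(self.labels), (0, 1)).all():
            raise ValueError("labels must be binary 0/1")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select(self, names) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(self.X[:, idx], self.labels, list(names),
                            self.provenance, self.positive_label)


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        for k in ("TP", "TN", "FP", "FN"):
            if getattr(self, k) < 0:
                raise ValueError(f"{k} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


# ---------------------------------------------------------------------------
# feature extraction


def fallback_extractor(image: np.ndarray) -> np.ndarray:
    """Deterministic non-learned features: downsampled intensities, grayscale
    histogram, super-threshold area fractions (sensitive to lesion size),
    marginal profiles, and gradient statistics.  >= 500 values."""
    img = np.asarray(image, dtype=np.float64)
    small = _resize(img, (16, 16), order=1, preserve_range=True,
                    anti_aliasing=True).ravel()                       # 256
    hist = np.histogram(img, bins=128, range=(0.0, 1.0))[0] / img.size  # 128
    thresholds = np.linspace(0.05, 0.95, 64)
    areas = np.array([(img > t).mean() for t in thresholds])           # 64
    prof = _resize(img, (32, 32), order=1, preserve_range=True,
                   anti_aliasing=True)
    row_means = prof.mean(axis=1)                                      # 32
    col_means = prof.mean(axis=0)                                      # 32
    gy, gx = np.gradient(img)
    gmag = np.hypot(gx, gy)
    grad_stats = np.array([
        gmag.mean(), gmag.std(), np.percentile(gmag, 90),
        img.mean(), img.std(), np.percentile(img, 10),
        np.percentile(img, 50), np.percentile(img, 90),
        img.min(), img.max(),
    ])                                                                 # 10
    return np.concatenate([small, hist, areas, row_means, col_means,
                           grad_stats])


def extract_features(samples, extractor=None, n_features: int = 500,
                     positive_label: str | None = None,
                     provenance: str = "real") -> FeatureTable:
    """Apply the extractor to each sample image and keep its first
    ``n_features`` output entries, in extractor order."""
    if extractor is None:
        extractor = fallback_extractor
    if not samples:
        raise ValueError("no samples")
    feats = []
    labels = []
    for s in samples:
        v = np.asarray(extractor(s.image), dtype=np.float64).ravel()
        if v.size < n_features:
            raise ValueError(
                f"extractor produced {v.size} values; {n_features} required")
        feats.append(v[:n_features])
        labels.append(s.group_label)
    classes = sorted({l for l in labels if l is not None})
    if positive_label is None:
        positive_label = classes[0] if classes else None
    y = np.array([1 if l == positive_label else 0 for l in labels])
    names = [f"f{i:04d}" for i in range(n_features)]
    return FeatureTable(np.asarray(feats), y, names,
                        np.array([provenance] * len(samples)),
                        positive_label)


def concat_tables(*tables: FeatureTable) -> FeatureTable:
    first = tables[0]
    for t in tables[1:]:
        if t.feature_names != first.feature_names:
            raise ValueError("feature tables have different columns")
    return FeatureTable(
        np.vstack([t.X for t in tables]),
        np.concatenate([t.labels for t in tables]),
        first.feature_names,
        np.concatenate([t.provenance for t in tables]),
        first.positive_label,
    )


# ---------------------------------------------------------------------------
# feature selection / classification


def rfe_select(table: FeatureTable, n_keep: int = 30, folds: int = 5,
               seed: int = 0):
    """Recursive feature elimination with cross-validated rankings.

    At each iteration a linear SVM is fitted on each of ``folds`` stratified
    training folds (features standardized per fold); the |coefficient|
    rankings are averaged over folds and the lowest-ranked 10% of the
    remaining features (at least one) are dropped, until exactly ``n_keep``
    remain.  Deterministic under ``seed``.
    """
    if n_keep > table.n_features:
        raise ValueError("n_keep exceeds feature count")
    counts = np.bincount(table.labels, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"each class needs >= {folds} members for {folds}-fold CV")
    remaining = np.arange(table.n_features)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(table.X, table.labels))
    while len(remaining) > n_keep:
        scores = np.zeros(len(remaining))
        for tr_idx, _ in splits:
            Xtr = table.X[np.ix_(tr_idx, remaining)]
            sc = StandardScaler().fit(Xtr)
            Xs = sc.transform(Xtr)
            sd = sc.scale_
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(Xs, table.labels[tr_idx])
            scores += np.abs(np.asarray(clf.coef_).ravel())
        n_drop = min(max(1, int(0.1 * len(remaining))),
                     len(remaining) - n_keep)
        order = np.argsort(scores, kind="stable")
        remaining = np.sort(remaining[order[n_drop:]])
    selected = [table.feature_names[i] for i in remaining]
    return table.select(selected), selected


def svm_classify(train: FeatureTable, test: FeatureTable,
                 kernel: str = "rbf", C: float = 1.0, gamma="scale",
                 seed: int = 0):
    """Fit a kernel SVM (standardized features) on train, predict test.
    Returns (ConfusionCounts, decision scores, predictions)."""
    if train.feature_names != test.feature_names:
        raise ValueError("train and test tables have different columns")
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training set must contain both classes")
    clf = make_pipeline(StandardScaler(),
                        SVC(kernel=kernel, C=C, gamma=gamma,
                            random_state=seed))
    clf.fit(train.X, train.labels)
    pred = clf.predict(test.X)
    scores = clf.decision_function(test.X)
    y = test.labels
    counts = ConfusionCounts(
        TP=int(np.sum((pred == 1) & (y == 1))),
        TN=int(np.sum((pred == 0) & (y == 0))),
        FP=int(np.sum((pred == 1) & (y == 0))),
        FN=int(np.sum((pred == 0) & (y == 1))),
    )
    return counts, scores, pred


def auc_score(labels, scores) -> float:
    """Area under the ROC curve by trapezoidal integration."""
    fpr, tpr = roc_points(labels, scores)
    return float(np.trapezoid(tpr, fpr))


def roc_points(labels, scores):
    """ROC curve points (fpr, tpr) for export and plotting."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr


def classification_metrics(counts: ConfusionCounts, scores=None,
                           labels=None) -> dict:
    """Acc = (TP+TN)/total, Sen = TP/(TP+FN), Spe = TN/(FP+TN); AUC from the
    ROC curve when scores and labels are given."""
    if counts.total == 0:
        raise ValueError("Acc undefined: no evaluated samples")
    if counts.TP + counts.FN == 0:
        raise ValueError("Sen undefined: no positive samples (TP+FN=0)")
    if counts.FP + counts.TN == 0:
        raise ValueError("Spe undefined: no negative samples (FP+TN=0)")
    out = {
        "acc": (counts.TP + counts.TN) / counts.total,
        "sen": counts.TP / (counts.TP + counts.FN),
        "spe": counts.TN / (counts.FP + counts.TN),
    }
    if scores is not None and labels is not None:
        out["auc"] = auc_score(labels, scores)
    return out


# ---------------------------------------------------------------------------
# the augmentation-benefit experiment


def augmentation_experiment(real_train, synthetic_sets: dict, test,
                            extractor=None, n_features: int = 500,
                            n_keep: int = 30, folds: int = 5,
                            seed: int = 0,
                            positive_label: str | None = None,
                            return_roc: bool = False):
    """One classification arm per training condition: baseline (real only)
    and real + each synthetic set; all arms share the same test set, which
    must contain no synthetic sample.  With ``return_roc=True`` also returns
    a per-arm DataFrame of ROC curve points."""
    test_ids = {id(s) for s in test} | {s.sample_id for s in test}
    for name, syn in synthetic_sets.items():
        for s in syn:
            if id(s) in test_ids or s.sample_id in test_ids:
                raise ValueError(
                    f"synthetic sample {s.sample_id!r} from arm {name!r} "
                    "appears in the test set")
    base_train = extract_features(real_train, extractor, n_features,
                                  positive_label, provenance="real")
    test_table = extract_features(test, extractor, n_features,
                                  base_train.positive_label,
                                  provenance="real")
    rows = []
    arms = [("baseline", base_train)]
    for name, syn in synthetic_sets.items():
        if not syn:  # an empty augmentation arm is exactly the baseline
            arms.append((name, base_train))
            continue
        syn_table = extract_features(syn, extractor, n_features,
                                     base_train.positive_label,
                                     provenance="synthetic")
        arms.append((name, concat_tables(base_train, syn_table)))
    roc_rows = []
    for name, train_table in arms:
        reduced, selected = rfe_select(train_table, n_keep, folds, seed)
        counts, scores, _ = svm_classify(reduced, test_table.select(selected),
                                         seed=seed)
        m = classification_metrics(counts, scores, test_table.labels)
        rows.append({"arm": name, "n_train": len(train_table.labels),
                     **m})
        if return_roc:
            fpr, tpr = roc_points(test_table.labels, scores)
            roc_rows.append(pd.DataFrame({"arm": name, "fpr": fpr,
                                          "tpr": tpr}))
    table = pd.DataFrame(rows)
    if return_roc:
        return table, pd.concat(roc_rows, ignore_index=True)
    return table
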