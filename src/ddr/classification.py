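"""Tier-feature classifiers for single-sample, cross-platform prediction.

Biomarker tiers are small ordinal integers with the same meaning on every
platform, so a classifier trained on tiers from one dataset can score a
single sample from another platform once the same reference genes have been
re-anchored there. The classifier is an RBF-kernel support vector machine
with C = 1 (gamma = 'scale'), wrapped in one-vs-one or one-vs-rest for
multi-class problems. Performance is estimated by Monte Carlo cross
validation: repeated stratified 90/10 train/test splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.multiclass import OneVsOneClassifier, OneVsRestClassifier
from sklearn.svm import SVC

from .io import DDRError, SampleMetadata
from .tiering import TierMatrix

SCHEMES = ("binary", "one_vs_one", "one_vs_rest")


@dataclass(frozen=True)
class FeatureTable:
    """Samples x biomarkers integer tier features, optionally labelled."""

    features: pd.DataFrame  # int tiers, columns ordered by the signature
    labels: pd.Series | None = None  # condition per sample, aligned to rows

    @property
    def sample_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def biomarkers(self) -> list[str]:
        return list(self.features.columns)


@dataclass(frozen=True)
class SignatureModel:
    """A trained signature: biomarkers + references + fitted classifier."""

    biomarkers: list[str]
    reference_ids: list[str]
    n_refs: int
    labels: list[str]
    scheme: str
    classifier_spec: dict
    estimator: object

    def check_schema(self, features: FeatureTable) -> None:
        if list(features.biomarkers) != list(self.biomarkers):
            raise DDRError(
                "feature table columns do not match the model's biomarkers: "
                f"expected {self.biomarkers}, got {features.biomarkers}"
            )
        arr = features.features.to_numpy()
        if arr.size and (arr.min() < 0 or arr.max() > self.n_refs):
            raise DDRError(f"tier features outside [0, {self.n_refs}]")


def build_feature_table(
    tiers: TierMatrix,
    biomarkers: list[str],
    metadata: SampleMetadata | None = None,
) -> FeatureTable:
    """Extract the biomarker tier rows as a samples x genes feature table.

    Column order follows the biomarker list, not the tier matrix order.
    """
    missing = [g for g in biomarkers if g not in tiers.tiers.index]
    if missing:
        raise DDRError(f"biomarker(s) absent from tier matrix: {missing}")
    feats = tiers.tiers.loc[biomarkers].T.copy()
    labels = None
    if metadata is not None:
        meta = metadata.aligned_to(list(feats.index))
        labels = meta.table.reindex(feats.index)
    return FeatureTable(features=feats, labels=labels)


def _make_estimator(scheme: str, c: float, seed: int | None):
    svc = SVC(kernel="rbf", C=c, gamma="scale", random_state=seed)
    if scheme == "binary":
        return svc
    if scheme == "one_vs_one":
        return OneVsOneClassifier(svc)
    if scheme == "one_vs_rest":
        return OneVsRestClassifier(svc)
    raise DDRError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")


def train(
    features: FeatureTable,
    scheme: str = "binary",
    c: float = 1.0,
    seed: int = 0,
    reference_ids: list[str] | None = None,
    n_refs: int | None = None,
) -> SignatureModel:
    """Fit the SVM on ordinal tier features (no scaling or one-hot encoding)."""
    if features.labels is None:
        raise DDRError("training requires a labelled feature table")
    y = features.labels.astype(str)
    classes = list(dict.fromkeys(y))
    if len(classes) < 2:
        raise DDRError("training requires at least 2 classes")
    for cls in classes:
        if (y == cls).sum() < 2:
            raise DDRError(f"class {cls!r} has fewer than 2 samples")
    est = _make_estimator(scheme, c, seed)
    est.fit(features.features.to_numpy(dtype=np.float64), y.to_numpy())
    inferred_n_refs = n_refs if n_refs is not None else int(features.features.to_numpy().max())
    return SignatureModel(
        biomarkers=features.biomarkers,
        reference_ids=list(reference_ids or []),
        n_refs=inferred_n_refs,
        labels=classes,
        scheme=scheme,
        classifier_spec={"kernel": "rbf", "C": c, "gamma": "scale", "seed": seed},
        estimator=est,
    )


def predict(model: SignatureModel, features: FeatureTable) -> list[str]:
    """Predicted condition per sample; works on a single-row table."""
    model.check_schema(features)
    if features.features.shape[0] == 0:
        return []
    return list(model.estimator.predict(features.features.to_numpy(dtype=np.float64)))


@dataclass(frozen=True)
class EvalReport:
    """Mean MCCV metrics plus the confusion matrix pooled over iterations."""

    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    per_class: pd.DataFrame  # precision/recall/f1 per class (mean over iters)
    confusion: pd.DataFrame  # pooled counts, rows = true class
    n_iterations: int
    accuracy_per_iteration: np.ndarray = field(repr=False, default=None)
    pooled_accuracy: float = float("nan")


def _stratified_split(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split with at least one test sample per class."""
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            raise DDRError(f"class {cls!r} too small to stratify")
        n_test = max(1, int(round(idx.size * (1 - train_fraction))))
        if n_test >= idx.size:
            n_test = idx.size - 1
        perm = rng.permutation(idx)
        test_idx.append(perm[:n_test])
        train_idx.append(perm[n_test:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def mccv_evaluate(
    features: FeatureTable,
    scheme: str = "binary",
    iterations: int = 1000,
    train_fraction: float = 0.9,
    c: float = 1.0,
    seed: int = 0,
) -> EvalReport:
    """Monte Carlo cross-validation with stratified train/test splits.

    Reports the mean of per-iteration accuracy and macro precision/recall/F1,
    per-class means, and the confusion matrix pooled over all iterations
    (from which a pooled accuracy is also derived).
    """
    if features.labels is None:
        raise DDRError("evaluation requires a labelled feature table")
    # canonical sample order so the report is invariant to input row order
    order = np.argsort(np.asarray(features.sample_ids))
    x = features.features.to_numpy(dtype=np.float64)[order]
    y = features.labels.astype(str).to_numpy()[order]
    classes = sorted(np.unique(y))
    rng = np.random.default_rng(seed)
    accs = np.empty(iterations)
    pr = np.zeros((iterations, len(classes)))
    rc = np.zeros((iterations, len(classes)))
    f1 = np.zeros((iterations, len(classes)))
    pooled = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for it in range(iterations):
        tr, te = _stratified_split(y, train_fraction, rng)
        est = _make_estimator(scheme, c, seed)
        est.fit(x[tr], y[tr])
        pred = est.predict(x[te])
        accs[it] = float(np.mean(pred == y[te]))
        p, r, f, _ = precision_recall_fscore_support(
            y[te], pred, labels=classes, zero_division=0
        )
        pr[it], rc[it], f1[it] = p, r, f
        pooled += confusion_matrix(y[te], pred, labels=classes)
    per_class = pd.DataFrame(
        {"precision": pr.mean(axis=0), "recall": rc.mean(axis=0), "f1": f1.mean(axis=0)},
        index=classes,
    )
    return EvalReport(
        accuracy=float(accs.mean()),
        precision_macro=float(pr.mean()),
        recall_macro=float(rc.mean()),
        f1_macro=float(f1.mean()),
        per_class=per_class,
        confusion=pd.DataFrame(pooled, index=classes, columns=classes),
        n_iterations=iterations,
        accuracy_per_iteration=accs,
        pooled_accuracy=float(np.trace(pooled) / pooled.sum()),
    )
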