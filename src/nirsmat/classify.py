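"""From-scratch Gaussian discriminant classification and evaluation.

LDA and QDA are implemented directly from the Gaussian class model:
class c is N(μ_c, Σ_c) with prior π_c, and a point is assigned to the
class maximising the log-discriminant

    δ_c(x) = −½ log|Σ_c| − ½ (x−μ_c)ᵀ Σ_c⁻¹ (x−μ_c) + log π_c,

with Σ_c the pooled within-class covariance for LDA and the per-class
covariance for QDA.  Covariances use 1/n_c (population) weighting, the
pooled LDA covariance is the class-size-weighted average, and every
covariance is regularized as Σ + shrinkage·(trace(Σ)/p)·I so that
two-feature fits on classes as small as six subjects stay invertible.
Ties go to the earlier class in declaration order (HC < CM < MOH).

Two classification schemes mirror the clinical question:

* direct: one three-class QDA on a named feature pair;
* stepwise: QDA separating HC from migraineurs (CM ∪ MOH) first, then a
  second QDA separating CM from MOH among predicted migraineurs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureTable, canonical_feature_name

DEFAULT_SHRINKAGE = 1e-6
CLASS_ORDER = ("HC", "CM", "MOH")

# Feature pairs used by the two schemes (chosen by exhaustive pair
# search on the original cohort; see search_feature_pairs).
DIRECT_FEATURES = ("HbT_recovery_rest_mean_d (ch3)", "COE_recovery_skewness (ch3)")
STAGE1_FEATURES = ("HbT_task_recovery_mean_d (ch3)", "HbT_task_rest_mean_d (01, ch3)")
STAGE2_FEATURE_SETS = {
    "set1": ("HbO_task_std (ch3)", "COE_TB_slope (01, ch2)"),
    "set2": ("HbT_task_std (ch3)", "COE_TB_slope (01, ch2)"),
}


class ClassifyError(ValueError):
    """Raised for invalid classification input."""


def _order_classes(labels) -> list[str]:
    present = list(dict.fromkeys(labels))
    known = [c for c in CLASS_ORDER if c in present]
    extra = sorted(c for c in present if c not in CLASS_ORDER)
    return known + extra


@dataclass
class DiscriminantModel:
    """Fitted Gaussian discriminant (LDA or QDA) on a feature subset."""

    kind: str
    classes: list[str]
    priors: np.ndarray
    means: np.ndarray  # (n_classes, p)
    covariances: np.ndarray  # (1, p, p) pooled for LDA; (n_classes, p, p) for QDA
    shrinkage: float
    feature_subset: list[str] = field(default_factory=list)

    def covariance_for(self, class_index: int) -> np.ndarray:
        return self.covariances[0] if self.kind == "LDA" else self.covariances[class_index]


def _regularize(cov: np.ndarray, shrinkage: float) -> np.ndarray:
    p = cov.shape[0]
    return cov + shrinkage * (np.trace(cov) / p) * np.eye(p)


def _fit_arrays(
    X: np.ndarray,
    y: np.ndarray,
    classes: list[str],
    kind: str,
    shrinkage: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lean fitting path shared by fit_discriminant and the pair search."""
    n, p = X.shape
    k = len(classes)
    priors = np.empty(k)
    means = np.empty((k, p))
    covs = np.empty((k, p, p))
    for i, c in enumerate(classes):
        Xc = X[y == c]
        nc = len(Xc)
        if nc < 2:
            raise ClassifyError(f"class {c!r} has {nc} sample(s); need at least 2")
        priors[i] = nc / n
        means[i] = Xc.mean(axis=0)
        d = Xc - means[i]
        covs[i] = d.T @ d / nc
    if kind == "LDA":
        pooled = np.tensordot(priors, covs, axes=1)  # size-weighted average
        covs = _regularize(pooled, shrinkage)[None, :, :]
    else:
        covs = np.stack([_regularize(c, shrinkage) for c in covs])
    return priors, means, covs


def fit_discriminant(
    X: np.ndarray,
    y,
    kind: str = "QDA",
    shrinkage: float = DEFAULT_SHRINKAGE,
    feature_subset: list[str] | None = None,
) -> DiscriminantModel:
    """Fit an LDA or QDA model by class-wise Gaussian moment estimation."""
    if kind not in ("LDA", "QDA"):
        raise ClassifyError(f"kind must be 'LDA' or 'QDA', got {kind!r}")
    if shrinkage < 0:
        raise ClassifyError("shrinkage must be >= 0")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ClassifyError("X must be a 2-D feature matrix")
    if not np.all(np.isfinite(X)):
        raise ClassifyError("X contains non-finite values")
    y = np.asarray(y)
    if len(y) != len(X):
        raise ClassifyError("X and y lengths differ")
    classes = _order_classes(y)
    if len(classes) < 2:
        raise ClassifyError("need at least 2 classes")
    priors, means, covs = _fit_arrays(X, y, classes, kind, shrinkage)
    for i in range(covs.shape[0]):
        sign, logdet = np.linalg.slogdet(covs[i])
        if sign <= 0 or not np.isfinite(logdet):
            raise ClassifyError(
                "singular covariance matrix; increase shrinkage"
            )
    return DiscriminantModel(
        kind=kind,
        classes=classes,
        priors=priors,
        means=means,
        covariances=covs,
        shrinkage=shrinkage,
        feature_subset=list(feature_subset or []),
    )


def _scores_arrays(
    X: np.ndarray,
    kind: str,
    priors: np.ndarray,
    means: np.ndarray,
    covs: np.ndarray,
) -> np.ndarray:
    """Log-discriminant scores, shape (n, n_classes)."""
    n = X.shape[0]
    k = means.shape[0]
    scores = np.empty((n, k))
    for i in range(k):
        cov = covs[0] if kind == "LDA" else covs[i]
        sign, logdet = np.linalg.slogdet(cov)
        diff = X - means[i]
        sol = np.linalg.solve(cov, diff.T).T
        maha = np.einsum("ij,ij->i", diff, sol)
        scores[:, i] = -0.5 * logdet - 0.5 * maha + np.log(priors[i])
    return scores


def predict(
    model: DiscriminantModel, X: np.ndarray, return_scores: bool = False
):
    """Assign each row of X to the class with the largest discriminant.

    Ties break to the earlier class in ``model.classes``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    p = model.means.shape[1]
    if X.shape[1] != p:
        raise ClassifyError(
            f"X has {X.shape[1]} features but the model expects {p}"
        )
    scores = _scores_arrays(
        X, model.kind, model.priors, model.means, model.covariances
    )
    labels = np.array([model.classes[i] for i in np.argmax(scores, axis=1)])
    return (labels, scores) if return_scores else labels


def stratified_split(
    table: FeatureTable, train_fraction: float = 2.0 / 3.0, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Per-class random 2:1 split with round-half-up train counts.

    Reproduces the cohort splits 34 → 23/11 (13, 9, 12 per class) and
    21 → 14/7 (9, 12).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ClassifyError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    labels = table.labels
    train_mask = np.zeros(len(table), dtype=bool)
    for c in _order_classes(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            raise ClassifyError(f"class {c!r} has fewer than 2 members")
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))  # round half up
        chosen = rng.choice(idx, size=n_train, replace=False)
        train_mask[chosen] = True
    return table.subset(train_mask), table.subset(~train_mask)


def _loocv_arrays(
    X: np.ndarray, y: np.ndarray, kind: str, shrinkage: float
) -> np.ndarray:
    """Leave-one-out predictions; fold i never sees row i."""
    n = len(X)
    preds = np.empty(n, dtype=object)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        y_tr = y[mask]
        classes = _order_classes(y_tr)
        counts = {c: int(np.sum(y_tr == c)) for c in classes}
        classes = [c for c in classes if counts[c] >= 2]
        if len(classes) < 2:
            raise ClassifyError(
                "leave-one-out fold leaves fewer than 2 trainable classes"
            )
        keep = np.isin(y_tr, classes)
        priors, means, covs = _fit_arrays(
            X[mask][keep], y_tr[keep], classes, kind, shrinkage
        )
        scores = _scores_arrays(X[i : i + 1], kind, priors, means, covs)
        preds[i] = classes[int(np.argmax(scores[0]))]
    return preds.astype(str)


def loocv(
    table: FeatureTable,
    kind: str,
    feature_subset,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> float:
    """Leave-one-out cross-validated accuracy on a feature subset."""
    if len(table) < 3:
        raise ClassifyError("LOOCV needs at least 3 subjects")
    X = table.matrix(list(feature_subset))
    y = table.labels.astype(str)
    preds = _loocv_arrays(X, y, kind, shrinkage)
    return float(np.mean(preds == y))


def search_feature_pairs(
    table: FeatureTable,
    kind: str = "QDA",
    candidate_features: list[str] | None = None,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> list[tuple[tuple[str, str], float]]:
    """Exhaustive wrapper search over all feature pairs by LOOCV accuracy.

    Ranks every unordered pair (all C(144,2) = 10,296 by default) by
    leave-one-out accuracy, ties broken lexicographically by pair name.
    LOOCV is deterministic, so the ranking is too.
    """
    from .features import FEATURE_NAMES

    feats = [
        canonical_feature_name(f)
        for f in (candidate_features or list(FEATURE_NAMES))
    ]
    X_all = table.matrix(feats)
    y = table.labels.astype(str)
    results = []
    for i, j in itertools.combinations(range(len(feats)), 2):
        preds = _loocv_arrays(X_all[:, [i, j]], y, kind, shrinkage)
        acc = float(np.mean(preds == y))
        results.append(((feats[i], feats[j]), acc))
    results.sort(key=lambda r: (-r[1], r[0]))
    return results


@dataclass
class EvaluationReport:
    """Confusion matrix and summary statistics for one evaluation."""

    classes: list[str]
    confusion_matrix: np.ndarray  # rows: true class, cols: predicted
    accuracy: float
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    split_info: dict = field(default_factory=dict)
    train_accuracy: float | None = None
    test_accuracy: float | None = None
    loocv_accuracy: float | None = None
    extras: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [f"classes: {', '.join(self.classes)}"]
        lines.append("confusion matrix (rows true, cols predicted):")
        header = "        " + "".join(f"{c:>8}" for c in self.classes)
        lines.append(header)
        for i, c in enumerate(self.classes):
            row = "".join(f"{int(v):>8}" for v in self.confusion_matrix[i])
            lines.append(f"{c:>8}{row}")
        lines.append(f"accuracy: {self.accuracy:.3f}")
        for c in self.classes:
            lines.append(
                f"{c}: sensitivity {self.sensitivity[c]:.3f}, "
                f"specificity {self.specificity[c]:.3f}"
            )
        for name, value in (
            ("train accuracy", self.train_accuracy),
            ("test accuracy", self.test_accuracy),
            ("LOOCV accuracy", self.loocv_accuracy),
        ):
            if value is not None:
                lines.append(f"{name}: {value:.3f}")
        return "\n".join(lines)


def evaluate(y_true, y_pred, classes: list[str] | None = None) -> EvaluationReport:
    """Confusion matrix with one-vs-rest sensitivity/specificity per class."""
    y_true = np.asarray(y_true, dtype=str)
    y_pred = np.asarray(y_pred, dtype=str)
    if len(y_true) != len(y_pred):
        raise ClassifyError("y_true and y_pred lengths differ")
    classes = classes or _order_classes(y_true)
    index = {c: i for i, c in enumerate(classes)}
    unknown = set(y_true) | set(y_pred)
    unknown -= set(classes)
    if unknown:
        raise ClassifyError(f"labels {sorted(unknown)} not in classes {classes}")
    k = len(classes)
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    n = cm.sum()
    accuracy = float(np.trace(cm) / n) if n else float("nan")
    sensitivity, specificity = {}, {}
    for c, i in index.items():
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = n - tp - fn - fp
        sensitivity[c] = float(tp / (tp + fn)) if tp + fn else float("nan")
        specificity[c] = float(tn / (tn + fp)) if tn + fp else float("nan")
    return EvaluationReport(
        classes=list(classes),
        confusion_matrix=cm,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
    )


def _split_accuracies(
    table: FeatureTable,
    features: tuple[str, str],
    kind: str,
    seed: int,
    shrinkage: float,
) -> tuple[float, float, EvaluationReport, dict]:
    train, test = stratified_split(table, seed=seed)
    feats = [canonical_feature_name(f) for f in features]
    model = fit_discriminant(
        train.matrix(feats), train.labels, kind, shrinkage, feature_subset=feats
    )
    train_acc = float(np.mean(predict(model, train.matrix(feats)) == train.labels))
    test_pred = predict(model, test.matrix(feats))
    test_report = evaluate(test.labels, test_pred, model.classes)
    split_info = {
        "train_per_class": {
            c: int(np.sum(train.labels == c)) for c in model.classes
        },
        "test_per_class": {c: int(np.sum(test.labels == c)) for c in model.classes},
    }
    return train_acc, test_report.accuracy, test_report, split_info


def direct_classify(
    table: FeatureTable,
    seed: int = 0,
    features: tuple[str, str] = DIRECT_FEATURES,
    kind: str = "QDA",
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> EvaluationReport:
    """Direct three-class QDA on the named feature pair.

    Reports accuracy on a 2:1 stratified split (train and test), the
    leave-one-out accuracy on the full cohort, and the test confusion
    matrix.
    """
    feats = [canonical_feature_name(f) for f in features]
    train_acc, test_acc, test_report, split_info = _split_accuracies(
        table, features, kind, seed, shrinkage
    )
    report = test_report
    report.train_accuracy = train_acc
    report.test_accuracy = test_acc
    report.loocv_accuracy = loocv(table, kind, feats, shrinkage)
    report.split_info = split_info
    report.extras = {"features": feats, "kind": kind}
    return report


def _binary_labels(labels: np.ndarray) -> np.ndarray:
    return np.where(labels == "HC", "HC", "Migraine")


def stepwise_classify(
    table: FeatureTable,
    seed: int = 0,
    cm_moh_feature_set: str = "set1",
    kind: str = "QDA",
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> EvaluationReport:
    """Two-stage classification: HC vs migraine, then CM vs MOH.

    Stage 1 is a binary QDA (HC vs CM∪MOH) on right-PFC blood-volume
    features; subjects predicted migrainous pass to stage 2, a binary
    QDA (CM vs MOH) trained on migraine subjects only.  The headline
    3×3 confusion matrix composes leave-one-out predictions with
    predicted-label routing (what a deployed stepwise classifier does);
    true-label routing is reported alongside in ``extras``.  Stage-wise
    2:1-split train/test accuracies and LOOCV accuracies are included.
    """
    if cm_moh_feature_set not in STAGE2_FEATURE_SETS:
        raise ClassifyError(
            f"cm_moh_feature_set must be one of {sorted(STAGE2_FEATURE_SETS)}"
        )
    s1_feats = [canonical_feature_name(f) for f in STAGE1_FEATURES]
    s2_feats = [
        canonical_feature_name(f) for f in STAGE2_FEATURE_SETS[cm_moh_feature_set]
    ]
    labels = table.labels.astype(str)
    binary = _binary_labels(labels)
    migraine_mask = binary == "Migraine"
    migraine_table = table.subset(migraine_mask)

    # stage-wise split evaluation (paper-style 34->23/11 and 21->14/7)
    bin_df = table.df.copy()
    bin_df["group"] = binary
    # FeatureTable validates groups via the df; binary labels are fine
    bin_table = FeatureTable(bin_df)
    s1_train_acc, s1_test_acc, _, s1_split = _split_accuracies(
        bin_table, tuple(s1_feats), kind, seed, shrinkage
    )
    s2_train_acc, s2_test_acc, _, s2_split = _split_accuracies(
        migraine_table, tuple(s2_feats), kind, seed, shrinkage
    )
    s1_loocv = loocv(bin_table, kind, s1_feats, shrinkage)
    s2_loocv = loocv(migraine_table, kind, s2_feats, shrinkage)

    # composed three-class predictions, leave-one-out, predicted routing
    X1 = table.matrix(s1_feats)
    X2 = table.matrix(s2_feats)
    n = len(table)
    idx = np.arange(n)
    composed = np.empty(n, dtype=object)
    for i in range(n):
        rest = idx != i
        p1, m1, c1 = _fit_arrays(
            X1[rest], binary[rest], _order_classes(binary[rest]), kind, shrinkage
        )
        classes1 = _order_classes(binary[rest])
        s = _scores_arrays(X1[i : i + 1], kind, p1, m1, c1)
        stage1_pred = classes1[int(np.argmax(s[0]))]
        if stage1_pred == "HC":
            composed[i] = "HC"
            continue
        rest2 = rest & migraine_mask
        classes2 = _order_classes(labels[rest2])
        p2, m2, c2 = _fit_arrays(
            X2[rest2], labels[rest2], classes2, kind, shrinkage
        )
        s2 = _scores_arrays(X2[i : i + 1], kind, p2, m2, c2)
        composed[i] = classes2[int(np.argmax(s2[0]))]
    composed = composed.astype(str)
    report = evaluate(labels, composed, _order_classes(labels))

    # true-label routing: stage 2 applied only to true migraineurs
    routed_true = np.full(n, "HC", dtype=object)
    if migraine_mask.sum() >= 3:
        routed_true[migraine_mask] = _loocv_arrays(
            X2[migraine_mask], labels[migraine_mask], kind, shrinkage
        )
    else:
        routed_true[migraine_mask] = labels[migraine_mask]
    routed_true = routed_true.astype(str)

    report.train_accuracy = s1_train_acc
    report.test_accuracy = s1_test_acc
    report.loocv_accuracy = float(np.mean(composed == labels))
    report.split_info = {"stage1": s1_split, "stage2": s2_split}
    report.extras = {
        "kind": kind,
        "stage1_features": s1_feats,
        "stage2_features": s2_feats,
        "stage1": {
            "train_accuracy": s1_train_acc,
            "test_accuracy": s1_test_acc,
            "loocv_accuracy": s1_loocv,
        },
        "stage2": {
            "train_accuracy": s2_train_acc,
            "test_accuracy": s2_test_acc,
            "loocv_accuracy": s2_loocv,
        },
        "true_label_routing": evaluate(
            labels, routed_true, _order_classes(labels)
        ),
    }
    return report
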