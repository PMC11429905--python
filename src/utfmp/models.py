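"""PLS-DA and the four-classifier evaluation suite.

Protocol: stratified 70:30 split of control-vs-malignant samples; repeated
stratified 10-fold cross-validation on the training partition for metric
distributions; a final refit on the whole training partition evaluated on
the held-out 30%. Features are standardized with statistics from the
training side of every fit, so no information leaks across folds.

Models and hyperparameters: random forest (150 trees, depth 10), RBF-kernel
SVM (C=1), logistic regression (1000-iteration cap), SGD with logistic loss
(alpha 1e-4, 'optimal' schedule), and 2-component PLS-DA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .stats import roc_analysis

POSITIVE_GROUP = "malignant"
NEGATIVE_GROUP = "control"

MODEL_NAMES = ("RF", "LR", "SVM", "SGD")

METRIC_NAMES = (
    "sensitivity", "specificity", "ppv", "npv", "plr", "nlr", "accuracy", "auc",
)


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7
    test_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train_fraction + self.test_fraction - 1.0) > 1e-9:
            raise ValueError("train and test fractions must sum to 1")


@dataclass(frozen=True)
class ModelSpec:
    model: str  # one of MODEL_NAMES or "PLSDA"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class CvSpec:
    n_folds: int = 10
    n_repetitions: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2 or self.n_repetitions < 1:
            raise ValueError("need >= 2 folds and >= 1 repetition")


def default_model_specs() -> list[ModelSpec]:
    return [
        ModelSpec("RF", {"n_estimators": 150, "max_depth": 10}),
        ModelSpec("LR", {"max_iter": 1000}),
        ModelSpec("SVM", {"C": 1.0}),
        ModelSpec("SGD", {"loss": "log_loss", "alpha": 1e-4, "learning_rate": "optimal"}),
    ]


def make_estimator(spec: ModelSpec, seed: int) -> Pipeline:
    """Scaler + classifier pipeline for one model spec."""
    hp = dict(spec.hyperparameters)
    if spec.model == "RF":
        clf = RandomForestClassifier(
            n_estimators=int(hp.get("n_estimators", 150)),
            max_depth=int(hp.get("max_depth", 10)),
            random_state=seed,
        )
    elif spec.model == "LR":
        clf = LogisticRegression(max_iter=int(hp.get("max_iter", 1000)))
    elif spec.model == "SVM":
        clf = SVC(C=float(hp.get("C", 1.0)), kernel="rbf", gamma="scale", random_state=seed)
    elif spec.model == "SGD":
        clf = SGDClassifier(
            loss=str(hp.get("loss", "log_loss")),
            alpha=float(hp.get("alpha", 1e-4)),
            learning_rate=str(hp.get("learning_rate", "optimal")),
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown model {spec.model!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _scores_from(estimator: Pipeline, X: np.ndarray) -> np.ndarray:
    """Continuous positive-class scores: probability if available, else
    signed decision value."""
    if hasattr(estimator, "predict_proba"):
        try:
            return estimator.predict_proba(X)[:, 1]
        except AttributeError:  # pragma: no cover
            pass
    return estimator.decision_function(X)


def stratified_split(table: pd.DataFrame, spec: SplitSpec = SplitSpec()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic stratified 70:30 split on the ``group`` column."""
    counts = table["group"].value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups too small to stratify: {small}")
    train_idx, test_idx = train_test_split(
        table.index,
        test_size=spec.test_fraction,
        stratify=table["group"],
        random_state=spec.seed,
    )
    return table.loc[sorted(train_idx)], table.loc[sorted(test_idx)]


def metrics_from_confusion(
    tp: int, fp: int, tn: int, fn: int,
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> dict[str, float]:
    """Closed-form metric panel; undefined ratios are NaN, never 0."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion matrix")

    def _ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            return float("nan")
        return num / den

    sens = _ratio(tp, tp + fn, "sensitivity")
    spec = _ratio(tn, tn + fp, "specificity")
    out = {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": _ratio(tp, tp + fp, "ppv"),
        "npv": _ratio(tn, tn + fn, "npv"),
        "plr": _ratio(sens, 1.0 - spec, "plr") if not np.isnan(sens) and not np.isnan(spec) else float("nan"),
        "nlr": _ratio(1.0 - sens, spec, "nlr") if not np.isnan(sens) and not np.isnan(spec) else float("nan"),
        "accuracy": (tp + tn) / total,
    }
    if scores is not None and labels is not None and len(np.unique(labels)) == 2:
        out["auc"] = roc_analysis(scores, labels).auc
    else:
        out["auc"] = float("nan")
    return out


@dataclass
class PlsdaResult:
    n_components: int
    r2: float
    q2: float
    accuracy: float
    auc: float
    report: dict[str, dict[str, float]]  # per-class precision/recall/f1/support
    macro_avg: dict[str, float]
    weighted_avg: dict[str, float]
    scores_train: np.ndarray  # latent components, train
    scores_test: np.ndarray


def _xy(table: pd.DataFrame, positive_group: str) -> tuple[np.ndarray, np.ndarray]:
    X = table.drop(columns="group").to_numpy(dtype=float)
    y = (table["group"] == positive_group).to_numpy(dtype=int)
    return X, y


def fit_plsda(
    train: pd.DataFrame,
    test: pd.DataFrame,
    n_components: int = 2,
    positive_group: str = POSITIVE_GROUP,
    cv_folds: int = 10,
    seed: int = 0,
) -> PlsdaResult:
    """Two-class PLS-DA with a 0/1-coded response.

    R2 is the explained response variance on the training partition; Q2 the
    cross-validated counterpart (pooled press over ``cv_folds`` folds).
    Class 1 is predicted when the regressed response is >= 0.5.
    """
    X_train, y_train = _xy(train, positive_group)
    X_test, y_test = _xy(test, positive_group)
    if len(np.unique(y_train)) < 2:
        raise ValueError("degenerate response: training partition has one class")
    if n_components > min(X_train.shape):
        raise ValueError("n_components exceeds the rank of the training matrix")

    scaler = StandardScaler().fit(X_train)
    Xs_train = scaler.transform(X_train)
    Xs_test = scaler.transform(X_test)
    pls = PLSRegression(n_components=n_components, scale=False).fit(Xs_train, y_train.astype(float))

    y_hat_train = pls.predict(Xs_train).ravel()
    ss_tot = float(np.sum((y_train - y_train.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y_train - y_hat_train) ** 2)) / ss_tot

    # Q2: leave-fold-out predicted residual sum of squares on the training set;
    # folds cannot exceed the minority-class count
    n_splits = min(cv_folds, int(np.bincount(y_train).min()))
    if n_splits < 2:
        raise ValueError("too few samples per class for cross-validated Q2")
    press = 0.0
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for fit_idx, held_idx in skf.split(Xs_train, y_train):
        sc = StandardScaler().fit(X_train[fit_idx])
        sub = PLSRegression(n_components=n_components, scale=False).fit(
            sc.transform(X_train[fit_idx]), y_train[fit_idx].astype(float)
        )
        pred = sub.predict(sc.transform(X_train[held_idx])).ravel()
        press += float(np.sum((y_train[held_idx] - pred) ** 2))
    q2 = 1.0 - press / ss_tot

    y_score = pls.predict(Xs_test).ravel()
    y_pred = (y_score >= 0.5).astype(int)
    report: dict[str, dict[str, float]] = {}
    supports, precisions, recalls, f1s = [], [], [], []
    for cls, name in ((0, "negative"), (1, "positive")):
        tp_c = int(np.sum((y_pred == cls) & (y_test == cls)))
        prec = tp_c / max(int(np.sum(y_pred == cls)), 1) if np.sum(y_pred == cls) else 0.0
        rec = tp_c / max(int(np.sum(y_test == cls)), 1)
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        support = int(np.sum(y_test == cls))
        report[name] = {"precision": prec, "recall": rec, "f1": f1, "support": support}
        supports.append(support)
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
    weights = np.asarray(supports) / sum(supports)
    auc = roc_analysis(y_score, y_test).auc if len(np.unique(y_test)) == 2 else float("nan")
    return PlsdaResult(
        n_components=n_components,
        r2=r2,
        q2=q2,
        accuracy=float(np.mean(y_pred == y_test)),
        auc=auc,
        report=report,
        macro_avg={"precision": float(np.mean(precisions)), "recall": float(np.mean(recalls)), "f1": float(np.mean(f1s))},
        weighted_avg={
            "precision": float(np.dot(weights, precisions)),
            "recall": float(np.dot(weights, recalls)),
            "f1": float(np.dot(weights, f1s)),
        },
        scores_train=pls.transform(Xs_train),
        scores_test=pls.transform(Xs_test),
    )


@dataclass
class SuiteReport:
    """Cross-validation and held-out-test results for one model on one
    feature representation."""

    model: str
    representation: str
    fold_metrics: pd.DataFrame  # columns: repetition, fold, + METRIC_NAMES
    cv_mean: dict[str, float]  # mean over folds then over repetitions
    cv_sd: dict[str, float]
    cv_pooled_confusion: dict[str, int]  # TP/FP/TN/FN summed over CV predictions
    cv_pooled_metrics: dict[str, float]  # panel recomputed from pooled counts
    test_metrics: dict[str, float]  # final refit, held-out 30%
    test_confusion: dict[str, int]
    roc_points: pd.DataFrame  # held-out ROC sweep


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, int]:
    return {
        "tp": int(np.sum((y_pred == 1) & (y_true == 1))),
        "fp": int(np.sum((y_pred == 1) & (y_true == 0))),
        "tn": int(np.sum((y_pred == 0) & (y_true == 0))),
        "fn": int(np.sum((y_pred == 0) & (y_true == 1))),
    }


def run_suite(
    table: pd.DataFrame,
    models: Sequence[ModelSpec] | None = None,
    cv: CvSpec = CvSpec(),
    split: SplitSpec = SplitSpec(),
    representation: str = "zones",
) -> list[SuiteReport]:
    """Repeated stratified CV plus held-out evaluation for every model.

    Only control and malignant rows enter the suite; benign samples, if
    present in ``table``, are dropped. Repetition ``r`` shuffles folds with
    seed ``cv.seed + r``, so the whole suite is reproducible from the base
    seed.
    """
    models = list(models) if models is not None else default_model_specs()
    known = set(MODEL_NAMES)
    for m in models:
        if m.model not in known:
            raise ValueError(f"unknown model {m.model!r}; expected one of {sorted(known)}")
    two_class = table[table["group"].isin([NEGATIVE_GROUP, POSITIVE_GROUP])]
    train, test = stratified_split(two_class, split)
    X_train, y_train = _xy(train, POSITIVE_GROUP)
    X_test, y_test = _xy(test, POSITIVE_GROUP)

    reports = []
    for m in models:
        rows = []
        pooled = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        pooled_scores: list[np.ndarray] = []
        pooled_labels: list[np.ndarray] = []
        for rep in range(cv.n_repetitions):
            skf = StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=cv.seed + rep)
            for fold, (fit_idx, val_idx) in enumerate(skf.split(X_train, y_train)):
                if len(np.unique(y_train[val_idx])) < 2:
                    raise ValueError(f"fold {fold} lacks both classes")
                est = make_estimator(m, seed=cv.seed + rep)
                est.fit(X_train[fit_idx], y_train[fit_idx])
                y_pred = est.predict(X_train[val_idx])
                y_score = _scores_from(est, X_train[val_idx])
                conf = _confusion(y_train[val_idx], y_pred)
                panel = metrics_from_confusion(**conf, scores=y_score, labels=y_train[val_idx])
                rows.append({"repetition": rep, "fold": fold, **panel})
                for k in pooled:
                    pooled[k] += conf[k]
                pooled_scores.append(y_score)
                pooled_labels.append(y_train[val_idx])
        fold_metrics = pd.DataFrame(rows)
        # mean over folds within a repetition, then over repetitions
        per_rep = fold_metrics.drop(columns="fold").groupby("repetition").mean()
        cv_mean = {k: float(per_rep[k].mean()) for k in METRIC_NAMES}
        cv_sd = {k: float(fold_metrics[k].std(ddof=1)) for k in METRIC_NAMES}
        cv_pooled_metrics = metrics_from_confusion(
            **pooled,
            scores=np.concatenate(pooled_scores),
            labels=np.concatenate(pooled_labels),
        )

        final = make_estimator(m, seed=cv.seed)
        final.fit(X_train, y_train)
        test_pred = final.predict(X_test)
        test_score = _scores_from(final, X_test)
        test_conf = _confusion(y_test, test_pred)
        test_metrics = metrics_from_confusion(**test_conf, scores=test_score, labels=y_test)
        roc = roc_analysis(test_score, y_test)
        reports.append(
            SuiteReport(
                model=m.model,
                representation=representation,
                fold_metrics=fold_metrics,
                cv_mean=cv_mean,
                cv_sd=cv_sd,
                cv_pooled_confusion=pooled,
                cv_pooled_metrics=cv_pooled_metrics,
                test_metrics=test_metrics,
                test_confusion=test_conf,
                roc_points=roc.to_frame(),
            )
        )
    return reports


def suite_summary(reports: Sequence[SuiteReport]) -> pd.DataFrame:
    """Long-format metric table: model, representation, metric, mean, sd,
    pooled-count value, and held-out-test value."""
    rows = []
    for r in reports:
        for metric in METRIC_NAMES:
            rows.append(
                {
                    "model": r.model,
                    "representation": r.representation,
                    "metric": metric,
                    "cv_mean": r.cv_mean[metric],
                    "cv_sd": r.cv_sd[metric],
                    "cv_pooled": r.cv_pooled_metrics[metric],
                    "test": r.test_metrics[metric],
                }
            )
    return pd.DataFrame(rows)
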