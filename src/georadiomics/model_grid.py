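"""Feature-selection x classifier evaluation grid with stratified CV.

For every ROI/ensemble feature table: z-score scaling, a 70/30 stratified
train/test split, 5-fold cross-validation on the training set (scaler and
feature selection refit inside each fold — no leakage), a final model on the
full training set, and test-set AUC / precision / recall / F1.

Variance thresholding runs on the *pre-scaled* features (after z-scoring all
variances are 1 and a 0.8 threshold would be vacuous); every other selector
sees z-scored features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA, FastICA
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier, RandomForestClassifier
from sklearn.feature_selection import RFECV, SelectorMixin, VarianceThreshold
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .feature_table import FeatureTable

__all__ = [
    "FSKind",
    "FSMethodSpec",
    "ClassifierSpec",
    "GridCell",
    "GridResult",
    "default_fs_specs",
    "default_classifier_specs",
    "zscore_fit_apply",
    "stratified_split",
    "select_features",
    "train_eval",
    "run_grid",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# scaling and splitting


def zscore_fit_apply(train: np.ndarray, test: np.ndarray | None = None):
    """Z-score features using training statistics only.

    Returns (scaled_train, scaled_test, params) where params holds the
    training mean, population SD and a mask of constant (SD = 0) columns,
    which are mapped to 0.
    """
    train = np.asarray(train, dtype=float)
    mu = train.mean(axis=0)
    sd = train.std(axis=0)  # population SD
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant feature(s) mapped to 0 after scaling", constant.sum())
    safe = np.where(constant, 1.0, sd)
    scaled_train = (train - mu) / safe
    scaled_test = None if test is None else (np.asarray(test, dtype=float) - mu) / safe
    return scaled_train, scaled_test, {"mean": mu, "sd": sd, "constant": constant}


def stratified_split(
    table: FeatureTable,
    test_fraction: float = 0.3,
    seed: int = 0,
    group_by_patient: bool = False,
) -> tuple[FeatureTable, FeatureTable]:
    """Random stratified split preserving the BM/HB ratio within one sample.

    With ``group_by_patient`` all points of a patient land on the same side
    (multiple points per patient can otherwise leak patient identity across
    the split); stratification is then only approximate.
    """
    y = table.binary_labels()
    if len(np.unique(y)) < 2:
        raise ValueError("cannot stratify a single-class table")
    idx = np.arange(table.n_samples)
    if group_by_patient:
        from sklearn.model_selection import GroupShuffleSplit

        groups = table.data["patient_id"].to_numpy()
        splitter = GroupShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed)
        train_idx, test_idx = next(splitter.split(idx, y, groups))
    else:
        train_idx, test_idx = train_test_split(
            idx, test_size=test_fraction, stratify=y, random_state=seed
        )
    return table.select_rows(np.sort(train_idx)), table.select_rows(np.sort(test_idx))


# ---------------------------------------------------------------------------
# feature-selection specs


class FSKind(str, Enum):
    NONE = "NONE"
    PCA = "PCA"
    FASTICA = "FastICA"
    VT = "VT"
    LASSO = "LASSO"
    RFECV = "RFECV"
    TREE = "TREE"


@dataclass(frozen=True)
class FSMethodSpec:
    kind: FSKind
    n_components: int | None = None  # PCA / FastICA
    variance_threshold: float | None = None  # VT
    alpha: float | None = None  # LASSO L1 penalty

    @property
    def name(self) -> str:
        if self.kind == FSKind.PCA or self.kind == FSKind.FASTICA:
            return f"{self.kind.value}_{self.n_components}"
        if self.kind == FSKind.VT:
            v = self.variance_threshold
            return f"VT_{int(v) if float(v).is_integer() else v}"
        if self.kind == FSKind.LASSO:
            return f"LASSO_{self.alpha}"
        return self.kind.value


def default_fs_specs() -> list[FSMethodSpec]:
    """The 14 feature-selection settings: 13 methods plus the no-FS baseline."""
    specs = [FSMethodSpec(FSKind.NONE)]
    specs += [FSMethodSpec(FSKind.VT, variance_threshold=v) for v in (0.0, 0.8)]
    specs += [FSMethodSpec(FSKind.PCA, n_components=n) for n in (20, 24, 30)]
    specs += [FSMethodSpec(FSKind.FASTICA, n_components=n) for n in (20, 24, 30)]
    specs += [FSMethodSpec(FSKind.LASSO, alpha=a) for a in (0.1, 0.5, 1.0)]
    specs += [FSMethodSpec(FSKind.RFECV), FSMethodSpec(FSKind.TREE)]
    return specs


class L1LogisticSelector(SelectorMixin, BaseEstimator):
    """Keep features with nonzero coefficients of an L1 logistic fit.

    ``alpha`` is the L1 penalty (sklearn's C = 1/alpha).  If the penalty
    kills every coefficient the single largest-|coefficient| feature is kept
    and the fallback is logged.
    """

    def __init__(self, alpha: float = 0.5, seed: int = 0):
        self.alpha = alpha
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X)
        model = LogisticRegression(
            penalty="l1",
            C=1.0 / self.alpha,
            solver="liblinear",
            random_state=self.seed,
            max_iter=1000,
        ).fit(X, y)
        coef = np.abs(model.coef_[0])
        support = coef > 1e-10
        if not support.any():
            logger.warning(
                "LASSO alpha=%s selected 0 features; keeping the largest-|coef| one",
                self.alpha,
            )
            support = np.zeros_like(support)
            support[np.argmax(coef)] = True
        self.support_ = support
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        return self.support_


def select_features(spec: FSMethodSpec, seed: int = 0):
    """Build the (unfitted) transformer for one FS setting; None for no FS."""
    if spec.kind == FSKind.NONE:
        return None
    if spec.kind == FSKind.PCA:
        return PCA(n_components=spec.n_components, random_state=seed)
    if spec.kind == FSKind.FASTICA:
        return FastICA(
            n_components=spec.n_components, random_state=seed, max_iter=1000, tol=1e-3
        )
    if spec.kind == FSKind.VT:
        return VarianceThreshold(threshold=spec.variance_threshold)
    if spec.kind == FSKind.LASSO:
        return L1LogisticSelector(alpha=spec.alpha, seed=seed)
    if spec.kind == FSKind.RFECV:
        return RFECV(
            estimator=SVC(kernel="linear", random_state=seed),
            step=0.1,
            cv=3,
            scoring="roc_auc",
            min_features_to_select=1,
        )
    if spec.kind == FSKind.TREE:
        from sklearn.feature_selection import SelectFromModel

        return SelectFromModel(
            DecisionTreeClassifier(random_state=seed), threshold="mean"
        )
    raise ValueError(f"unknown FS kind {spec.kind}")


def make_preprocessor(spec: FSMethodSpec, seed: int = 0) -> Pipeline:
    """Scaling + FS pipeline; VT is applied before scaling (see module doc)."""
    steps = []
    if spec.kind == FSKind.VT:
        steps.append(("vt", VarianceThreshold(threshold=spec.variance_threshold)))
        steps.append(("scale", StandardScaler()))
    else:
        steps.append(("scale", StandardScaler()))
        fs = select_features(spec, seed)
        if fs is not None:
            steps.append(("fs", fs))
    return Pipeline(steps)


def _n_selected(prep: Pipeline, n_input: int) -> int:
    last = prep.steps[-1][1]
    if isinstance(last, StandardScaler):
        vt = dict(prep.steps).get("vt")
        return int(vt.get_support().sum()) if vt is not None else n_input
    if hasattr(last, "get_support"):
        return int(last.get_support().sum())
    if hasattr(last, "n_components_"):
        return int(last.n_components_)
    if hasattr(last, "n_components"):
        return int(last.n_components)
    return n_input


# ---------------------------------------------------------------------------
# classifiers


@dataclass(frozen=True)
class ClassifierSpec:
    name: str
    builder: str  # key into _CLASSIFIER_BUILDERS


_CLASSIFIER_BUILDERS = {
    "L-SVM": lambda seed: SVC(kernel="linear", random_state=seed),
    "SVM": lambda seed: SVC(kernel="rbf", random_state=seed),
    "NB": lambda seed: GaussianNB(),
    "kNN": lambda seed: KNeighborsClassifier(n_neighbors=5),
    "QDA": lambda seed: QuadraticDiscriminantAnalysis(),
    "GPR": lambda seed: GaussianProcessClassifier(kernel=1.0 * RBF(1.0), random_state=seed),
    "DT": lambda seed: DecisionTreeClassifier(random_state=seed),
    "RF": lambda seed: RandomForestClassifier(n_estimators=100, random_state=seed),
    "Bagging": lambda seed: BaggingClassifier(random_state=seed),
    "AdaBoost": lambda seed: AdaBoostClassifier(random_state=seed),
    "NNet-SGD": lambda seed: MLPClassifier(
        hidden_layer_sizes=(100,), activation="relu", solver="sgd",
        max_iter=2000, random_state=seed,
    ),
    "NNet-LBFGS": lambda seed: MLPClassifier(
        hidden_layer_sizes=(100,), activation="relu", solver="lbfgs",
        max_iter=2000, random_state=seed,
    ),
}


def default_classifier_specs() -> list[ClassifierSpec]:
    """The 12 supervised classifiers (both neural nets use ReLU activation)."""
    return [ClassifierSpec(name, name) for name in _CLASSIFIER_BUILDERS]


def build_classifier(spec: ClassifierSpec, seed: int = 0):
    return _CLASSIFIER_BUILDERS[spec.builder](seed)


def _scores(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        cols = np.flatnonzero(np.asarray(model.classes_) == 1)
        # degenerate single-class fit: constant score
        return proba[:, cols[0]] if len(cols) else np.zeros(len(X))
    return model.decision_function(X)


# ---------------------------------------------------------------------------
# grid cells


@dataclass
class GridCell:
    roi: str
    fs: str
    classifier: str
    test_auc: float = float("nan")
    precision: float = float("nan")
    recall: float = float("nan")
    f1: float = float("nan")
    cv_auc_mean: float = float("nan")
    cv_auc_sd: float = float("nan")
    n_selected: int = 0
    confusion: list = field(default_factory=list)
    failed: bool = False
    reason: str = ""


@dataclass
class GridResult:
    cells: list[GridCell]
    provenance: dict

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.cells])

    def best_cell(self, metric: str = "test_auc") -> GridCell:
        ok = [c for c in self.cells if not c.failed]
        if not ok:
            raise ValueError("every grid cell failed; see cell reasons")
        return max(ok, key=lambda c: getattr(c, metric))


def _fold_transforms(Xtr, ytr, fs_spec, folds, seed):
    """Fit the preprocessor inside each CV fold; shared across classifiers."""
    out = []
    for tr_idx, va_idx in folds:
        prep = make_preprocessor(fs_spec, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prep.fit(Xtr[tr_idx], ytr[tr_idx])
            out.append(
                (prep.transform(Xtr[tr_idx]), ytr[tr_idx],
                 prep.transform(Xtr[va_idx]), ytr[va_idx])
            )
    return out


def train_eval(
    train: FeatureTable,
    test: FeatureTable,
    fs: FSMethodSpec,
    clf: ClassifierSpec,
    cv_folds: int = 5,
    seed: int = 0,
    roi_name: str = "",
) -> GridCell:
    """Evaluate one (FS, classifier) cell on a prepared split."""
    Xtr, ytr = train.feature_matrix(), train.binary_labels()
    Xte, yte = test.feature_matrix(), test.binary_labels()
    folds = list(
        StratifiedKFold(cv_folds, shuffle=True, random_state=seed).split(Xtr, ytr)
    )
    fold_data = _fold_transforms(Xtr, ytr, fs, folds, seed)
    prep = make_preprocessor(fs, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prep.fit(Xtr, ytr)
    return _eval_cell(
        roi_name, fs, clf, fold_data, prep, Xtr, ytr, Xte, yte, seed
    )


def _eval_cell(roi_name, fs_spec, clf_spec, fold_data, prep, Xtr, ytr, Xte, yte, seed):
    cell = GridCell(roi=roi_name, fs=fs_spec.name, classifier=clf_spec.name)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv_aucs = []
            for Ztr, yf, Zva, yva in fold_data:
                model = build_classifier(clf_spec, seed).fit(Ztr, yf)
                cv_aucs.append(roc_auc_score(yva, _scores(model, Zva)))
            Ztr_full = prep.transform(Xtr)
            Zte = prep.transform(Xte)
            final = build_classifier(clf_spec, seed).fit(Ztr_full, ytr)
            y_pred = final.predict(Zte)
            cell.test_auc = float(roc_auc_score(yte, _scores(final, Zte)))
            cell.precision = float(precision_score(yte, y_pred, zero_division=0))
            cell.recall = float(recall_score(yte, y_pred, zero_division=0))
            cell.f1 = float(f1_score(yte, y_pred, zero_division=0))
            cell.cv_auc_mean = float(np.mean(cv_aucs))
            cell.cv_auc_sd = float(np.std(cv_aucs))
            cell.n_selected = _n_selected(prep, Xtr.shape[1])
            cell.confusion = confusion_matrix(yte, y_pred).tolist()
    except Exception as exc:  # a failed cell must not halt the grid
        logger.warning("cell (%s, %s, %s) failed: %s", roi_name, fs_spec.name, clf_spec.name, exc)
        cell.failed = True
        cell.reason = f"{type(exc).__name__}: {exc}"
    return cell


def run_grid(
    feature_tables: dict[str, FeatureTable],
    fs_list: list[FSMethodSpec] | None = None,
    clf_list: list[ClassifierSpec] | None = None,
    test_fraction: float = 0.3,
    cv_folds: int = 5,
    seed: int = 0,
    group_by_patient: bool = False,
) -> GridResult:
    """Run the full (ROI x FS x classifier) grid.

    Preprocessors (scaler + FS) are fit once per (table, FS, fold) and shared
    across classifiers; the evaluation is identical to fitting a fresh
    pipeline per cell.
    """
    fs_list = default_fs_specs() if fs_list is None else fs_list
    clf_list = default_classifier_specs() if clf_list is None else clf_list
    for name, table in feature_tables.items():
        if table.n_samples == 0:
            raise ValueError(f"feature table {name!r} is empty")

    cells: list[GridCell] = []
    for roi_name, table in feature_tables.items():
        train, test = stratified_split(table, test_fraction, seed, group_by_patient)
        Xtr, ytr = train.feature_matrix(), train.binary_labels()
        Xte, yte = test.feature_matrix(), test.binary_labels()
        folds = list(
            StratifiedKFold(cv_folds, shuffle=True, random_state=seed).split(Xtr, ytr)
        )
        for fs_spec in fs_list:
            try:
                fold_data = _fold_transforms(Xtr, ytr, fs_spec, folds, seed)
                prep = make_preprocessor(fs_spec, seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    prep.fit(Xtr, ytr)
            except Exception as exc:
                for clf_spec in clf_list:
                    cells.append(
                        GridCell(
                            roi=roi_name, fs=fs_spec.name, classifier=clf_spec.name,
                            failed=True, reason=f"FS failed: {exc}",
                        )
                    )
                continue
            for clf_spec in clf_list:
                cells.append(
                    _eval_cell(
                        roi_name, fs_spec, clf_spec, fold_data, prep,
                        Xtr, ytr, Xte, yte, seed,
                    )
                )
        logger.info("grid: finished table %s (%d cells so far)", roi_name, len(cells))
    provenance = {
        "seed": seed,
        "test_fraction": test_fraction,
        "cv_folds": cv_folds,
        "group_by_patient": group_by_patient,
        "tables": list(feature_tables),
        "fs": [s.name for s in fs_list],
        "classifiers": [s.name for s in clf_list],
    }
    return GridResult(cells=cells, provenance=provenance)
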