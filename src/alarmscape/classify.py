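"""Critical-illness classification from alarm-pattern features.

Per-patient feature vectors are assembled from the modal alarm patterns
(one slot per signal-bound group: modal value, modal duration, alarm count,
presence flag), the cohort is optionally balanced (the event-free class
subsampled to the event count), split 70/30 *by patient* so no patient
contributes to both partitions, and classified with a random forest
(200 trees, Gini impurity, unlimited depth), an RBF-kernel support vector
machine (C = 1, gamma = "scale", probability outputs) or a decision tree
(Gini, unlimited depth). Reports carry per-class precision/recall/F1 for
the death/CPR/PICU and sepsis classes, overall accuracy, one-vs-rest AUC
per class plus a micro average, and the confusion matrix.

A statsmodels-style facade wraps the steps: build an
:class:`AlarmPatternModel` from a feature table and manifest, call
``fit()``, and read the :class:`AlarmPatternResults` (``summary()`` prints
the classification report).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

LABELS = ("none", "death_cpr_picu", "sepsis")
REPORTED_CLASSES = ("death_cpr_picu", "sepsis")

#: fixed (signal, bound) slots of the feature vector
FEATURE_GROUPS = (
    ("ECGRR", "upper"),
    ("ECGRR", "lower"),
    ("ECGHR", "upper"),
    ("ECGHR", "lower"),
    ("SPO2", "lower"),
)

MODEL_FAMILIES = ("random_forest", "svm", "decision_tree")

_DEFAULT_HYPERPARAMETERS = {
    "random_forest": {"n_estimators": 200, "criterion": "gini", "max_depth": None},
    "svm": {"kernel": "rbf", "C": 1.0, "gamma": "scale", "probability": True},
    "decision_tree": {"criterion": "gini", "max_depth": None},
}


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family with its hyperparameters and seed."""

    family: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; valid: {MODEL_FAMILIES}"
            )

    def resolved_hyperparameters(self) -> dict:
        params = dict(_DEFAULT_HYPERPARAMETERS[self.family])
        params.update(self.hyperparameters)
        return params


def build_estimator(spec: ModelSpec):
    """Instantiate the sklearn estimator for a spec. SVM features are
    standardized inside a pipeline (parameters learned on train only);
    tree models take raw features."""
    params = spec.resolved_hyperparameters()
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, **params)
    if spec.family == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed, **params)
    svc = SVC(random_state=spec.seed, **params)
    return Pipeline([("scale", StandardScaler()), ("svc", svc)])


def feature_column_names() -> list[str]:
    cols = []
    for signal, bound in FEATURE_GROUPS:
        stem = f"{signal.lower()}_{bound}"
        cols += [
            f"{stem}_modal_value",
            f"{stem}_modal_duration",
            f"{stem}_n_alarms",
            f"{stem}_present",
        ]
    return cols


def assemble_dataset(
    features: pd.DataFrame,
    manifest: pd.DataFrame,
    balance: bool = True,
    seed: int = 42,
) -> pd.DataFrame:
    """One fixed-width feature vector per patient, labeled from the manifest.

    Missing (signal, bound) slots — the patient had no alarms in that group
    — are filled with 0 and flagged by a ``*_present`` indicator of 0.
    With ``balance=True`` the event-free class is randomly subsampled
    (seeded) to the event-patient count. Patients with neither features nor
    a manifest row are excluded.
    """
    cols = feature_column_names()
    rows = {}
    labels = manifest.set_index("patient_id")["cie_type"]
    for pid in manifest["patient_id"].astype(str):
        rows[pid] = dict.fromkeys(cols, 0.0)
    for _, row in features.iterrows():
        pid = str(row["patient_id"])
        if pid not in rows:
            warnings.warn(f"feature row for unknown patient {pid}; skipped")
            continue
        stem = f"{row['signal'].lower()}_{row['bound']}"
        if f"{stem}_present" not in rows[pid]:
            continue  # group outside the fixed slot set
        rows[pid][f"{stem}_modal_value"] = float(row["modal_value"])
        rows[pid][f"{stem}_modal_duration"] = float(row["modal_duration"])
        rows[pid][f"{stem}_n_alarms"] = float(row["n_alarms"])
        rows[pid][f"{stem}_present"] = 1.0
    dataset = pd.DataFrame.from_dict(rows, orient="index")
    dataset.index.name = "patient_id"
    dataset["label"] = labels.reindex(dataset.index).fillna("none").astype(str)
    if balance:
        rng = np.random.default_rng(seed)
        cie_idx = dataset.index[dataset["label"] != "none"]
        none_idx = dataset.index[dataset["label"] == "none"]
        n_keep = min(len(cie_idx), len(none_idx))
        keep_none = rng.choice(none_idx.to_numpy(), size=n_keep, replace=False)
        dataset = dataset.loc[dataset.index.isin(set(keep_none) | set(cie_idx))]
    return dataset


def patient_grouped_split(
    dataset: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 42,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified 70/30 split by patient id.

    Each label class is shuffled and split separately so both partitions see
    every class with at least two members; a single-member class goes to
    train with a warning. The train and test patient sets are disjoint by
    construction (the index is one row per patient).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    for label in sorted(dataset["label"].unique()):
        ids = dataset.index[dataset["label"] == label].to_numpy()
        rng.shuffle(ids)
        if len(ids) == 1:
            warnings.warn(f"class {label!r} has a single member; placed in train")
            train_ids += list(ids)
            continue
        n_train = int(round(train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train_ids += list(ids[:n_train])
        test_ids += list(ids[n_train:])
    return dataset.loc[train_ids], dataset.loc[test_ids]


@dataclass
class ClassMetrics:
    precision: float | None
    recall: float | None
    f1: float | None
    support: int
    note: str | None = None  # reason when undefined (class absent from test)


@dataclass
class EvaluationReport:
    """Per-class metrics, accuracy, AUC and confusion matrix on the test set."""

    model_family: str
    per_class: dict[str, ClassMetrics]
    accuracy: float
    auc: dict[str, float | None]  # one-vs-rest per class + "micro"
    confusion: pd.DataFrame  # rows true, columns predicted
    n_train: int
    n_test: int

    def summary(self) -> str:
        lines = [
            f"Classification report — {self.model_family} "
            f"(train n={self.n_train}, test n={self.n_test})",
            f"{'class':>16} {'precision':>9} {'recall':>9} {'f1':>9} {'support':>9}",
        ]
        for name, m in self.per_class.items():
            if m.precision is None:
                lines.append(f"{name:>16} {'—':>9} {'—':>9} {'—':>9} {m.support:>9} ({m.note})")
            else:
                lines.append(
                    f"{name:>16} {m.precision:>9.2f} {m.recall:>9.2f} "
                    f"{m.f1:>9.2f} {m.support:>9}"
                )
        lines.append(f"{'accuracy':>16} {self.accuracy:>9.2f}")
        for name, value in self.auc.items():
            shown = "—" if value is None else f"{value:.2f}"
            lines.append(f"{'AUC ' + name:>16} {shown:>9}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model_family": self.model_family,
            "per_class": {
                k: {
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                    "support": m.support,
                    "note": m.note,
                }
                for k, m in self.per_class.items()
            },
            "accuracy": self.accuracy,
            "auc": self.auc,
            "confusion_matrix": {
                "labels": list(self.confusion.index),
                "counts": self.confusion.to_numpy().tolist(),
            },
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


def _split_xy(frame: pd.DataFrame):
    x = frame.drop(columns="label").to_numpy(dtype=float)
    y = frame["label"].to_numpy(dtype=object)
    return x, y


def train_and_evaluate(
    spec: ModelSpec,
    train: pd.DataFrame,
    test: pd.DataFrame,
) -> tuple[EvaluationReport, object]:
    """Fit one family on the train partition and score the test partition.

    Returns the report and the fitted estimator. Raises if the partitions
    share a patient — metrics are only ever computed on held-out patients.
    """
    if len(train) == 0 or len(test) == 0:
        raise ValueError("train and test must be non-empty")
    shared = set(train.index) & set(test.index)
    if shared:
        raise ValueError(f"patients appear in both partitions: {sorted(shared)[:5]}")
    estimator = build_estimator(spec)
    x_train, y_train = _split_xy(train)
    x_test, y_test = _split_xy(test)
    estimator.fit(x_train, y_train)
    y_pred = estimator.predict(x_test)
    fitted_classes = list(estimator.classes_)
    present = set(y_test)

    labels_order = [l for l in LABELS if l in set(y_train) | present]
    prec, rec, f1, support = precision_recall_fscore_support(
        y_test, y_pred, labels=labels_order, zero_division=0
    )
    per_class: dict[str, ClassMetrics] = {}
    for name in REPORTED_CLASSES:
        if name not in labels_order or name not in present:
            per_class[name] = ClassMetrics(
                precision=None,
                recall=None,
                f1=None,
                support=0,
                note="class absent from test partition",
            )
            continue
        i = labels_order.index(name)
        per_class[name] = ClassMetrics(
            precision=float(prec[i]),
            recall=float(rec[i]),
            f1=float(f1[i]),
            support=int(support[i]),
        )
    conf = confusion_matrix(y_test, y_pred, labels=labels_order)
    confusion = pd.DataFrame(conf, index=labels_order, columns=labels_order)
    accuracy = float(np.trace(conf) / conf.sum())

    proba = estimator.predict_proba(x_test)
    auc: dict[str, float | None] = {}
    for name in REPORTED_CLASSES:
        if name not in fitted_classes or name not in present or len(present) < 2:
            auc[name] = None
            continue
        col = fitted_classes.index(name)
        y_bin = (y_test == name).astype(int)
        auc[name] = float(roc_auc_score(y_bin, proba[:, col]))
    try:
        y_bin_all = np.column_stack(
            [(y_test == c).astype(int) for c in fitted_classes]
        )
        auc["micro"] = float(
            roc_auc_score(y_bin_all, proba, average="micro")
        )
    except ValueError:
        auc["micro"] = None

    report = EvaluationReport(
        model_family=spec.family,
        per_class=per_class,
        accuracy=accuracy,
        auc=auc,
        confusion=confusion,
        n_train=len(train),
        n_test=len(test),
    )
    return report, estimator


def roc_points(estimator, test: pd.DataFrame) -> pd.DataFrame:
    """One-vs-rest ROC coordinates per reported class, for plotting."""
    from sklearn.metrics import roc_curve

    x_test, y_test = _split_xy(test)
    proba = estimator.predict_proba(x_test)
    classes = list(estimator.classes_)
    pieces = []
    for name in REPORTED_CLASSES:
        if name not in classes:
            continue
        y_bin = (y_test == name).astype(int)
        if y_bin.sum() in (0, len(y_bin)):
            continue
        fpr, tpr, thr = roc_curve(y_bin, proba[:, classes.index(name)])
        pieces.append(
            pd.DataFrame({"class": name, "fpr": fpr, "tpr": tpr, "threshold": thr})
        )
    if not pieces:
        return pd.DataFrame(columns=["class", "fpr", "tpr", "threshold"])
    return pd.concat(pieces, ignore_index=True)


def compare_models(
    specs: list[ModelSpec],
    dataset: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 42,
) -> tuple[pd.DataFrame, dict[str, EvaluationReport]]:
    """Fit every spec on the same patient-grouped split and tabulate metrics.

    Returns a one-row-per-spec table (accuracy, micro AUC, per-class
    precision/recall/F1) and the full reports; tree-family rows include
    feature importances in the report objects' estimators via
    :class:`AlarmPatternModel` when used through the facade.
    """
    train, test = patient_grouped_split(dataset, train_fraction, seed)
    rows = []
    reports: dict[str, EvaluationReport] = {}
    for spec in specs:
        report, _ = train_and_evaluate(spec, train, test)
        reports[spec.family] = report
        row = {
            "family": spec.family,
            "accuracy": report.accuracy,
            "auc_micro": report.auc.get("micro"),
        }
        for name in REPORTED_CLASSES:
            m = report.per_class[name]
            row[f"{name}_precision"] = m.precision
            row[f"{name}_recall"] = m.recall
            row[f"{name}_f1"] = m.f1
        rows.append(row)
    return pd.DataFrame(rows), reports


class AlarmPatternModel:
    """Classifier over per-patient alarm-pattern features.

    Parameters
    ----------
    dataset : DataFrame
        Output of :func:`assemble_dataset` (feature columns + ``label``,
        indexed by patient).
    spec : ModelSpec, optional
        Family and hyperparameters; defaults to the random forest.
    train_fraction : float
        Patient-grouped train share (default 0.7).
    seed : int
        Split seed (the estimator's own seed lives in ``spec``).

    Examples
    --------
    >>> model = AlarmPatternModel.from_features(features, manifest)
    >>> results = model.fit()
    >>> print(results.summary())
    """

    def __init__(
        self,
        dataset: pd.DataFrame,
        spec: ModelSpec | None = None,
        train_fraction: float = 0.7,
        seed: int = 42,
    ) -> None:
        if "label" not in dataset.columns:
            raise ValueError("dataset must carry a 'label' column")
        self.dataset = dataset
        self.spec = spec or ModelSpec()
        self.train_fraction = train_fraction
        self.seed = seed

    @classmethod
    def from_features(
        cls,
        features: pd.DataFrame,
        manifest: pd.DataFrame,
        balance: bool = True,
        spec: ModelSpec | None = None,
        train_fraction: float = 0.7,
        seed: int = 42,
    ) -> "AlarmPatternModel":
        dataset = assemble_dataset(features, manifest, balance=balance, seed=seed)
        return cls(dataset, spec=spec, train_fraction=train_fraction, seed=seed)

    def fit(self) -> "AlarmPatternResults":
        train, test = patient_grouped_split(
            self.dataset, self.train_fraction, self.seed
        )
        report, estimator = train_and_evaluate(self.spec, train, test)
        return AlarmPatternResults(self, estimator, report, train, test)


class AlarmPatternResults:
    """Fitted classifier plus its held-out evaluation.

    Attributes
    ----------
    report : EvaluationReport
    estimator : fitted sklearn estimator
    train, test : the patient-grouped partitions
    """

    def __init__(self, model, estimator, report, train, test) -> None:
        self.model = model
        self.estimator = estimator
        self.report = report
        self.train = train
        self.test = test

    @property
    def accuracy(self) -> float:
        return self.report.accuracy

    @property
    def auc(self) -> dict:
        return self.report.auc

    @property
    def feature_importances(self) -> pd.Series | None:
        """Impurity-based importances for tree families; None for the SVM."""
        est = self.estimator
        if hasattr(est, "feature_importances_"):
            cols = [c for c in self.model.dataset.columns if c != "label"]
            return pd.Series(est.feature_importances_, index=cols)
        return None

    def roc_points(self) -> pd.DataFrame:
        return roc_points(self.estimator, self.test)

    def summary(self) -> str:
        return self.report.summary()

    def plot_roc(self, ax=None):
        """Plot one-vs-rest ROC curves (requires matplotlib)."""
        import matplotlib.pyplot as plt

        pts = self.roc_points()
        if ax is None:
            _, ax = plt.subplots()
        for name, sub in pts.groupby("class"):
            label = f"{name} (AUC {self.report.auc.get(name):.2f})"
            ax.plot(sub["fpr"], sub["tpr"], label=label)
        ax.plot([0, 1], [0, 1], linestyle="--", color="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax
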