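"""Per-subject 7-class decoding over (feature family x band x classifier) cells.

Protocol: stratified 10-fold cross-validation over all of a subject's
epochs; features are standardized (zero mean, unit variance) per column
using training-fold statistics only; accuracy is the mean over held-out
folds and the confusion matrix accumulates over them.  An 80/20 stratified
holdout is available as ``protocol="holdout"``.  Aggregation across
subjects (mean +/- SD, ddof=1) produces the familiar accuracy matrix of
family x band rows by classifier.

Classifiers: back-propagation MLP (one hidden layer of 64 units), KNN with
k=5, random forest with 500 trees, and a linear-kernel SVM (C=1, native
one-vs-one multiclass).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from eegscape.errors import ConfigurationError
from eegscape.features import FeatureTensor

N_CLASSES = 7
CLASSIFIER_KINDS = ("bp", "knn", "rf", "svm")


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier kind plus its hyperparameters.

    Defaults: knn k=5, rf 500 trees, svm linear kernel with C=1, bp a single
    64-unit hidden layer trained with early stopping (max 500 iterations).
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise ConfigurationError(f"unknown classifier kind {self.kind!r}")

    def build(self, seed: int):
        p = dict(self.params)
        if self.kind == "knn":
            clf = KNeighborsClassifier(n_neighbors=p.pop("k", 5), **p)
        elif self.kind == "rf":
            clf = RandomForestClassifier(n_estimators=p.pop("trees", 500),
                                         random_state=seed, n_jobs=1, **p)
        elif self.kind == "svm":
            clf = SVC(kernel=p.pop("kernel", "linear"), C=p.pop("C", 1.0),
                      random_state=seed, **p)
        else:  # bp
            clf = MLPClassifier(hidden_layer_sizes=p.pop("hidden", (64,)),
                                max_iter=p.pop("max_iter", 500),
                                early_stopping=True, validation_fraction=0.1,
                                n_iter_no_change=10, random_state=seed, **p)
        return make_pipeline(StandardScaler(), clf)


def default_specs() -> list[ClassifierSpec]:
    return [ClassifierSpec(k) for k in CLASSIFIER_KINDS]


@dataclass
class EvalCell:
    """Decoding result of one (subject, family, band, classifier) cell."""

    subject_id: int
    family: str
    band: str
    classifier: str
    fold_accuracies: np.ndarray
    confusion: np.ndarray  # 7 x 7, rows = true class

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(self.fold_accuracies) > 1 else float("nan")

    @property
    def sensitivity(self) -> np.ndarray:
        """Per-class recall diag_k / row-sum_k; NaN for classes absent from the test sets."""
        row = self.confusion.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, np.diag(self.confusion) / row, np.nan)


def _cell_seed(global_seed: int, subject_id: int) -> int:
    """Stable per-subject seed below 2**31 so subjects are independent but reproducible."""
    return int(np.random.SeedSequence([int(global_seed), int(subject_id)]).generate_state(1)[0] % (2**31))


def evaluate_subject(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec,
                     protocol: str = "cv10", seed: int = 0,
                     subject_id: int = 0, family: str = "", band: str = "") -> EvalCell:
    """Decode one design matrix with one classifier under the stated protocol."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.arange(1, N_CLASSES + 1)
    counts = pd.Series(y).value_counts()
    cell_seed = _cell_seed(seed, subject_id)

    if protocol == "cv10":
        n_folds = 10
        short = counts[counts < n_folds]
        if len(short):
            raise ConfigurationError(
                f"class(es) {sorted(short.index.tolist())} have fewer than {n_folds} examples")
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cell_seed)
        splits = cv.split(X, y)
    elif protocol == "holdout":
        short = counts[counts < 2]
        if len(short):
            raise ConfigurationError(
                f"class(es) {sorted(short.index.tolist())} have fewer than 2 examples")
        tr, te = train_test_split(np.arange(len(y)), test_size=0.2,
                                  stratify=y, random_state=cell_seed)
        splits = [(tr, te)]
    else:
        raise ConfigurationError(f"unknown protocol {protocol!r}")

    accs = []
    conf = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for tr, te in splits:
        model = spec.build(cell_seed)
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        accs.append(float(np.mean(pred == y[te])))
        conf += confusion_matrix(y[te], pred, labels=classes)
    return EvalCell(subject_id=subject_id, family=family, band=band,
                    classifier=spec.kind, fold_accuracies=np.array(accs), confusion=conf)


def make_design(tensor: FeatureTensor, family: str, band: str) -> tuple[np.ndarray, np.ndarray]:
    """Epochs x dim design matrix and class labels for one (family, band) slice."""
    return tensor.slice(family, band)


@dataclass
class EvaluationGrid:
    """All cells plus across-subject aggregates (mean +/- SD, ddof=1)."""

    cells: list[EvalCell]

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "subject_id": c.subject_id, "family": c.family, "band": c.band,
            "classifier": c.classifier, "accuracy": c.mean_accuracy,
            "fold_sd": c.sd_accuracy,
            **{f"sens_{k + 1}": s for k, s in enumerate(c.sensitivity)},
        } for c in self.cells]
        return pd.DataFrame(rows)

    def aggregate(self) -> pd.DataFrame:
        """Mean +/- SD accuracy across subjects per (family, band, classifier)."""
        df = self.to_frame()
        g = df.groupby(["family", "band", "classifier"], sort=False)["accuracy"]
        out = g.agg(mean_accuracy="mean",
                    sd_accuracy=lambda s: s.std(ddof=1) if len(s) > 1 else np.nan,
                    n_subjects="count").reset_index()
        return out

    def fold_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            for i, a in enumerate(c.fold_accuracies):
                rows.append({"subject_id": c.subject_id, "family": c.family,
                             "band": c.band, "classifier": c.classifier,
                             "fold": i, "accuracy": a})
        return pd.DataFrame(rows)


def evaluate_grid(tensors: list[FeatureTensor], specs: list[ClassifierSpec] | None = None,
                  families=None, bands=None, protocol: str = "cv10",
                  seed: int = 0) -> EvaluationGrid:
    """Evaluate every (subject, family, band, classifier) cell.

    ``families``/``bands`` default to all six families and the five bands
    plus "total"; restrict them to keep small studies cheap.
    """
    if not tensors:
        raise ConfigurationError("no subjects to evaluate")
    specs = specs or default_specs()
    first = tensors[0]
    all_fams = sorted({f for f, _ in first.values}, key=str)
    all_bands = list(dict.fromkeys(b for _, b in first.values))
    families = list(families) if families is not None else all_fams
    bands = list(bands) if bands is not None else all_bands

    cells = []
    for tensor in tensors:
        for fam in families:
            for band in bands:
                X, y = tensor.slice(fam, band)
                for spec in specs:
                    cells.append(evaluate_subject(
                        X, y, spec, protocol=protocol, seed=seed,
                        subject_id=tensor.subject_id, family=fam, band=band))
    return EvaluationGrid(cells)


def best_per_subject(grid: EvaluationGrid, by: str = "classifier") -> pd.DataFrame:
    """Per subject, the maximum accuracy over the named axis with its argmax cell(s).

    Ties are all reported, ordered by (band, family, classifier).
    """
    if by not in ("classifier", "family"):
        raise ConfigurationError("by must be 'classifier' or 'family'")
    df = grid.to_frame()
    if df.empty:
        raise ConfigurationError("empty grid")
    rows = []
    for (subj, key), sub in df.groupby(["subject_id", by]):
        m = sub["accuracy"].max()
        winners = sub[sub["accuracy"] == m].sort_values(["band", "family", "classifier"])
        for _, r in winners.iterrows():
            rows.append({"subject_id": subj, by: key, "best_accuracy": m,
                         "family": r["family"], "band": r["band"],
                         "classifier": r["classifier"]})
    return pd.DataFrame(rows)
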