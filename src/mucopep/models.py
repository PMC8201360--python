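"""Per-property kNN and random-forest classifiers.

The training protocol for each bioactive-property category is:

1. balance the positive/negative classes by random oversampling of the
   minority class (duplication with replacement);
2. stratified 70%:30% train/test split;
3. fit a k-nearest-neighbour model (k = 2, Euclidean distance; the seven
   scalar descriptors are z-score standardized so that mass in Daltons
   cannot dominate, while the 400 dipeptide frequencies stay in their
   natural, already commensurable [0, 1] scale — per-feature unit variance
   on the sparse dipeptide block would amplify rare-pair noise until it
   swamps the class signal) and a random forest (1000 trees, Gini
   criterion, per-split feature subset of floor(sqrt(407)) = 20);
4. evaluate both on the held-out 30% with the confusion-matrix panel:
   accuracy, sensitivity, specificity, exact (Clopper-Pearson) 95% CI on
   accuracy, no-information rate, and the one-sided exact binomial p-value
   of accuracy against the no-information rate.

Balancing happens *before* splitting, so duplicated minority examples can
land on both sides of the split; this ordering is kept deliberately (it is
the documented protocol this package reproduces) and its optimistic bias is
discussed in docs/methods.md.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors

from mucopep.features import FEATURE_NAMES, featurize_all
from mucopep.io import LabeledPeptideSet, Peptide

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    """Hyperparameters of the per-property training protocol."""

    k_neighbors: int = 2
    n_trees: int = 1000
    train_fraction: float = 0.70
    seed: int = 1
    standardize: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.k_neighbors < 1 or self.n_trees < 1:
            raise ValueError("k_neighbors and n_trees must be >= 1")


@dataclass
class PerformanceReport:
    """Held-out confusion-matrix panel for one classifier."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ci95: tuple[float, float]
    nir: float
    p_value: float

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["ci95"] = list(self.ci95)
        return d


@dataclass
class KnnModel:
    """k-NN on the standardized training matrix with an explicit tie rule.

    Prediction is positive iff the positive fraction among the k nearest
    neighbours exceeds 1/2; at exactly 1/2 the nearest neighbour's class
    wins, and an exact distance tie between opposite-class nearest
    neighbours resolves to positive.
    """

    k: int
    mean_: np.ndarray = field(repr=False)
    scale_: np.ndarray = field(repr=False)
    X_: np.ndarray = field(repr=False)  # standardized training matrix
    y_: np.ndarray = field(repr=False)
    _nn: NearestNeighbors | None = field(default=None, repr=False, compare=False)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (X - self.mean_) / self.scale_
        # zero-variance features carry no information: standardized value 0
        Z[:, self.scale_ == 0] = 0.0
        return Z

    def _neighbors(self, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self._nn is None:
            self._nn = NearestNeighbors(n_neighbors=self.k).fit(self.X_)
        return self._nn.kneighbors(Z, n_neighbors=self.k)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = self._standardize(np.asarray(X, dtype=float))
        dist, idx = self._neighbors(Z)
        out = np.empty(len(Z), dtype=int)
        for i in range(len(Z)):
            labels = self.y_[idx[i]]
            frac_pos = labels.mean()
            if frac_pos > 0.5:
                out[i] = 1
            elif frac_pos < 0.5:
                out[i] = 0
            else:
                d = dist[i]
                # neighbours are distance-sorted; equal-distance, opposite-class
                # nearest pair is an exact tie -> positive
                nearest_tied = (d == d[0]) & (self.y_[idx[i]] != labels[0])
                out[i] = 1 if nearest_tied.any() else labels[0]
        return out


@dataclass
class ClassifierPair:
    """A trained kNN + RF pair for one bioactive property."""

    property_name: str
    knn_model: KnnModel
    rf_model: RandomForestClassifier
    feature_names: tuple[str, ...]
    knn_report: PerformanceReport | None = None
    rf_report: PerformanceReport | None = None

    def save(self, directory: str | Path) -> None:
        """Serialize as JSON metadata + array payloads in ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "property_name": self.property_name,
            "feature_names": list(self.feature_names),
            "k": self.knn_model.k,
            "knn_report": self.knn_report.to_dict() if self.knn_report else None,
            "rf_report": self.rf_report.to_dict() if self.rf_report else None,
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
        np.savez(
            directory / "knn.npz",
            mean=self.knn_model.mean_,
            scale=self.knn_model.scale_,
            X=self.knn_model.X_,
            y=self.knn_model.y_,
        )
        joblib.dump(self.rf_model, directory / "rf.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "ClassifierPair":
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        arr = np.load(directory / "knn.npz")
        knn = KnnModel(meta["k"], arr["mean"], arr["scale"], arr["X"], arr["y"])
        rf = joblib.load(directory / "rf.joblib")

        def _report(d: dict | None) -> PerformanceReport | None:
            if d is None:
                return None
            d = dict(d)
            d["ci95"] = tuple(d["ci95"])
            return PerformanceReport(**d)

        return cls(
            meta["property_name"], knn, rf, tuple(meta["feature_names"]),
            _report(meta["knn_report"]), _report(meta["rf_report"]),
        )


def oversample_balance(s: LabeledPeptideSet, seed: int) -> LabeledPeptideSet:
    """Equalize class counts by duplicating minority examples with replacement.

    The majority class (and every original example) is untouched; an already
    balanced set is returned unchanged.
    """
    n_pos, n_neg = s.n_positive, s.n_negative
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"{s.property_name}: both classes must be non-empty "
            f"(got {n_pos} positive, {n_neg} negative)"
        )
    if n_pos == n_neg:
        return s
    minority = 1 if n_pos < n_neg else 0
    deficit = abs(n_pos - n_neg)
    rng = np.random.default_rng(seed)
    pool = np.flatnonzero(s.labels == minority)
    extra = rng.choice(pool, size=deficit, replace=True)
    idx = np.concatenate([np.arange(len(s)), extra])
    return s.subset(idx)


def stratified_split(
    s: LabeledPeptideSet, cfg: TrainingConfig
) -> tuple[LabeledPeptideSet, LabeledPeptideSet]:
    """Seeded stratified partition into train and test sets.

    Per-class train counts are ``round(train_fraction * n_class)``; the
    partition is exhaustive and disjoint.
    """
    rng = np.random.default_rng(cfg.seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in (0, 1):
        members = np.flatnonzero(s.labels == cls)
        if len(members) < 2:
            raise ValueError(
                f"{s.property_name}: class {cls} has {len(members)} member(s); "
                "need >= 2 to split"
            )
        members = rng.permutation(members)
        n_train = int(round(cfg.train_fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)  # both sides non-empty
        train_idx.append(members[:n_train])
        test_idx.append(members[n_train:])
    return (
        s.subset(np.sort(np.concatenate(train_idx))),
        s.subset(np.sort(np.concatenate(test_idx))),
    )


def _design_matrix(s: LabeledPeptideSet) -> tuple[np.ndarray, np.ndarray]:
    X = featurize_all(s.peptides).to_numpy()
    return X, s.labels.copy()


#: Number of leading scalar descriptors subject to z-score standardization;
#: the trailing dipeptide-frequency block is left in its natural scale.
N_SCALAR_FEATURES = 7


def train_knn(train: LabeledPeptideSet, cfg: TrainingConfig) -> KnnModel:
    """Fit the kNN model: store standardization parameters and training data.

    With ``standardize`` on, the scalar descriptor block is z-scored
    feature-wise (a zero-variance scalar maps to 0); dipeptide frequencies
    are used as-is.
    """
    X, y = _design_matrix(train)
    mean = np.zeros(X.shape[1])
    scale = np.ones(X.shape[1])
    if cfg.standardize:
        ns = N_SCALAR_FEATURES
        mean[:ns] = X[:, :ns].mean(axis=0)
        scale[:ns] = X[:, :ns].std(axis=0, ddof=0)
    model = KnnModel(cfg.k_neighbors, mean, scale, np.empty(0), y)
    model.X_ = model._standardize(X)
    return model


def train_rf(train: LabeledPeptideSet, cfg: TrainingConfig) -> RandomForestClassifier:
    """Fit the random forest: bootstrap CART trees, Gini splits, mtry = sqrt."""
    X, y = _design_matrix(train)
    rf = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        criterion="gini",
        max_features="sqrt",
        bootstrap=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    return rf


def _rf_predict(rf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Majority tree vote with exact ties resolved to positive."""
    if len(rf.classes_) == 1:
        return np.full(len(X), int(rf.classes_[0]))
    pos_col = int(np.flatnonzero(rf.classes_ == 1)[0])
    proba = rf.predict_proba(X)[:, pos_col]
    return (proba >= 0.5).astype(int)


def _clopper_pearson(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion."""
    alpha = 1.0 - conf
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def evaluate(model, test: LabeledPeptideSet) -> PerformanceReport:
    """Confusion-matrix panel of ``model`` on a held-out labeled set.

    ``nir`` is the majority-class prevalence of the test set and the p-value
    is the one-sided exact binomial tail P(X >= tp + tn | n, p = nir). If
    the test set contains a single class, the undefined one of
    sensitivity/specificity is NaN (with a warning).
    """
    if len(test) == 0:
        raise ValueError("test set is empty")
    X, y = _design_matrix(test)
    y_hat = model.predict(X)
    tp = int(((y == 1) & (y_hat == 1)).sum())
    tn = int(((y == 0) & (y_hat == 0)).sum())
    fp = int(((y == 0) & (y_hat == 1)).sum())
    fn = int(((y == 1) & (y_hat == 0)).sum())
    n = tp + tn + fp + fn
    correct = tp + tn
    accuracy = correct / n
    if tp + fn == 0:
        warnings.warn("test set has no positives; sensitivity undefined (NaN)")
        sensitivity = float("nan")
    else:
        sensitivity = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("test set has no negatives; specificity undefined (NaN)")
        specificity = float("nan")
    else:
        specificity = tn / (tn + fp)
    prev_pos = (tp + fn) / n
    nir = max(prev_pos, 1 - prev_pos)
    p_value = float(stats.binom.sf(correct - 1, n, nir))
    return PerformanceReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        ci95=_clopper_pearson(correct, n), nir=nir, p_value=p_value,
    )


def train_classifier_pair(
    s: LabeledPeptideSet, cfg: TrainingConfig | None = None
) -> ClassifierPair:
    """Full protocol: balance, split, fit both models, evaluate on held-out."""
    cfg = cfg or TrainingConfig()
    balanced = oversample_balance(s, cfg.seed)
    train, test = stratified_split(balanced, cfg)
    knn = train_knn(train, cfg)
    rf = train_rf(train, cfg)
    pair = ClassifierPair(
        s.property_name, knn, rf, FEATURE_NAMES,
        knn_report=evaluate(knn, test), rf_report=evaluate(rf, test),
    )
    logger.info(
        "%s: kNN acc %.3f, RF acc %.3f (held-out n=%d)",
        s.property_name, pair.knn_report.accuracy, pair.rf_report.accuracy, len(test),
    )
    return pair


def predict(pair: ClassifierPair, peptides: list[Peptide]) -> "pd.DataFrame":
    """Binary kNN and RF calls for new peptides."""
    import pandas as pd

    X = featurize_all(peptides).to_numpy()
    return pd.DataFrame(
        {
            "knn_call": pair.knn_model.predict(X),
            "rf_call": _rf_predict(pair.rf_model, X),
        },
        index=pd.Index([p.id for p in peptides], name="peptide_id"),
    )
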