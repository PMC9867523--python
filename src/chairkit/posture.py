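"""Posture classifiers on center-of-mass features.

Four model families are supported: k-NN (brute force, inverse-distance
vote), nearest centroid, SVM, and a per-class Gaussian mixture whose
components are mapped to classes by majority training label.  Evaluation
reports macro (unweighted per-label mean) precision/recall/F1 with their
across-label SD, overall accuracy, and the full confusion matrix.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.svm import SVC

from chairkit.chairio import ChairGeometry
from chairkit.loadcell import compute_cm_series, smooth_downsample

logger = logging.getLogger(__name__)

FIVE_CLASSES = ("P1", "P2", "P3", "P5", "P6")
SEVEN_CLASSES = ("P1", "P2", "P3", "P5", "P6", "P7", "P8")


@dataclass
class CMDataset:
    """Labeled (CMx, CMy) feature vectors.

    ``X`` has shape (n, 2); ``y`` holds string class labels drawn from
    ``class_set``.  P4 is never a valid training class (it forms no cluster
    in the seat plane).
    """

    X: np.ndarray
    y: np.ndarray
    class_set: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        if self.X.ndim != 2 or self.X.shape[1] != 2:
            raise ValueError(f"X must be (n, 2), got {self.X.shape}")
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        self.class_set = tuple(self.class_set)
        if "P4" in self.class_set:
            raise ValueError("P4 is excluded from every training class set")
        extra = set(self.y) - set(self.class_set)
        if extra:
            raise ValueError(f"labels outside class_set: {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.y)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, class_set: Sequence[str]) -> "CMDataset":
        sub = frame[frame["label"].isin(class_set)]
        return cls(sub[["CMx", "CMy"]].to_numpy(), sub["label"].to_numpy(), tuple(class_set))


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus its hyperparameters.

    family: 'knn' | 'nc' | 'svm' | 'gmm'.
    knn: k (neighbor count; inverse-distance weighted, brute-force search).
    nc: metric ('euclidean' | 'cityblock').
    svm: kernel ('linear' | 'rbf'), C, gamma.
    gmm: covariance ('tied' | 'full' | 'diagonal' | 'spherical').
    """

    family: str
    params: tuple[tuple[str, Any], ...] = ()

    @classmethod
    def make(cls, family: str, **params: Any) -> "ModelSpec":
        if family not in ("knn", "nc", "svm", "gmm"):
            raise ValueError(f"unknown family {family!r}")
        return cls(family, tuple(sorted(params.items())))

    @property
    def kwargs(self) -> dict[str, Any]:
        return dict(self.params)


class GMMClassifier:
    """Per-class mixture components mapped to labels by majority vote.

    One Gaussian component per class is fitted by EM (initialized at the
    labeled class means); each component is then assigned the majority true
    label of the training points it claims.  If some class captures no
    component the model keeps the gap (it will simply never predict that
    class), reporting its own failure through the evaluation metrics.
    """

    def __init__(self, covariance: str = "tied", random_state: int = 0):
        self.covariance = covariance
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GMMClassifier":
        classes = sorted(set(y))
        means = np.array([X[y == c].mean(axis=0) for c in classes])
        for c in classes:
            if (y == c).sum() < 2 and self.covariance == "full":
                raise ValueError(
                    f"class {c} has a single point: full covariance is degenerate "
                    "(add points or use tied/spherical covariance)"
                )
        self.gmm_ = GaussianMixture(
            n_components=len(classes),
            covariance_type=self.covariance,
            means_init=means,
            random_state=self.random_state,
        ).fit(X)
        comp = self.gmm_.predict(X)
        self.component_label_ = {}
        for k in range(len(classes)):
            claimed = y[comp == k]
            if claimed.size:
                vals, counts = np.unique(claimed, return_counts=True)
                self.component_label_[k] = vals[np.argmax(counts)]
            else:
                self.component_label_[k] = classes[k]  # unclaimed: keep init order
        unmapped = set(classes) - set(self.component_label_.values())
        if unmapped:
            logger.warning("GMM left classes unmapped (never predicted): %s", sorted(unmapped))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        comp = self.gmm_.predict(np.asarray(X, dtype=float))
        return np.array([self.component_label_[k] for k in comp], dtype=object)


def train(dataset: CMDataset, spec: ModelSpec, random_state: int = 0):
    """Fit a classifier (a total function over the seat plane) per ``spec``."""
    X, y = dataset.X, dataset.y
    classes = set(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    kw = spec.kwargs
    if spec.family == "knn":
        k = kw.get("k", 1000)
        if k > len(X):
            raise ValueError(f"k={k} exceeds training-set size {len(X)}")
        model = KNeighborsClassifier(n_neighbors=k, weights="distance", algorithm="brute")
    elif spec.family == "nc":
        metric = kw.get("metric", "euclidean")
        model = NearestCentroid(metric={"cityblock": "manhattan"}.get(metric, metric))
    elif spec.family == "svm":
        model = SVC(
            kernel=kw.get("kernel", "linear"),
            C=kw.get("C", 1.0),
            gamma=kw.get("gamma", "scale"),
            random_state=random_state,
        )
    elif spec.family == "gmm":
        model = GMMClassifier(covariance=kw.get("covariance", "tied"), random_state=random_state)
    else:
        raise ValueError(f"unknown family {spec.family!r}")
    model.fit(X, y)
    logger.info("trained %s on %d points / %d classes", spec.family, len(X), len(classes))
    return model


def default_grid(family: str, grids: Mapping[str, Any] | None = None) -> list[ModelSpec]:
    """Expand the per-family hyperparameter grid into specs (grid order)."""
    g = grids or {}
    if family == "nc":
        return [ModelSpec.make("nc", metric=m) for m in g.get("nc", {}).get("metric", ["euclidean", "cityblock"])]
    if family == "svm":
        svm = g.get("svm", {})
        kernels = svm.get("kernel", ["linear", "rbf"])
        Cs = svm.get("C", [1e-3, 1e-2, 1e-1, 1.0, 10.0])
        gammas = svm.get("gamma", [0.05, 0.1, 0.5, 1.0])
        specs = []
        for kern, C in itertools.product(kernels, Cs):
            if kern == "linear":
                specs.append(ModelSpec.make("svm", kernel=kern, C=C))
            else:
                specs.extend(ModelSpec.make("svm", kernel=kern, C=C, gamma=gm) for gm in gammas)
        return specs
    if family == "gmm":
        covs = g.get("gmm", {}).get("covariance", ["tied", "full", "diagonal", "spherical"])
        return [ModelSpec.make("gmm", covariance=c) for c in covs]
    raise ValueError(f"no tunable grid for family {family!r} (k-NN's k is fixed manually)")


def tune(
    dataset: CMDataset,
    grid: Iterable[ModelSpec],
    folds: int = 5,
    random_state: int = 0,
) -> tuple[ModelSpec, float]:
    """Exhaustive grid search with stratified k-fold CV on accuracy.

    Every grid point is evaluated; ties break to the first point in grid
    order.  Note that the k-NN neighbor count is deliberately not part of any
    grid — it is selected manually.
    """
    X, y = dataset.X, dataset.y
    vals, counts = np.unique(y, return_counts=True)
    for v, c in zip(vals, counts):
        if c < folds:
            raise ValueError(f"class {v} has {c} points, fewer than {folds} folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=False)
    splits = list(skf.split(X, y))
    best_spec, best_acc = None, -1.0
    for spec in grid:
        accs = []
        for tr, va in splits:
            sub = CMDataset(X[tr], y[tr], dataset.class_set)
            model = train(sub, spec, random_state=random_state)
            accs.append(float(np.mean(model.predict(X[va]) == y[va])))
        acc = float(np.mean(accs))
        logger.info("tune: %s -> CV accuracy %.4f", spec, acc)
        if acc > best_acc:
            best_spec, best_acc = spec, acc
    if best_spec is None:
        raise ValueError("empty grid")
    return best_spec, best_acc


@dataclass
class EvaluationReport:
    """Confusion matrix plus macro-averaged classification metrics."""

    label_set: tuple[str, ...]
    confusion: np.ndarray  # rows: true, cols: predicted
    per_label: pd.DataFrame = field(repr=False)  # columns precision/recall/f1 per label
    precision: float = 0.0
    precision_sd: float = 0.0
    recall: float = 0.0
    recall_sd: float = 0.0
    f1: float = 0.0
    f1_sd: float = 0.0
    accuracy: float = 0.0

    def to_dict(self) -> dict[str, Any]:
        return {
            "label_set": list(self.label_set),
            "confusion": self.confusion.tolist(),
            "per_label": {m: self.per_label[m].tolist() for m in ("precision", "recall", "f1")},
            "precision": self.precision,
            "precision_sd": self.precision_sd,
            "recall": self.recall,
            "recall_sd": self.recall_sd,
            "f1": self.f1,
            "f1_sd": self.f1_sd,
            "accuracy": self.accuracy,
        }


def evaluate(classifier, testset: CMDataset) -> EvaluationReport:
    """Evaluate a fitted classifier: macro precision/recall/F1 (± across-label
    SD), accuracy, and the confusion matrix over ``testset.class_set``."""
    if len(testset) == 0:
        raise ValueError("empty test set")
    labels = testset.class_set
    y = testset.y
    yhat = np.asarray(classifier.predict(testset.X), dtype=object)
    idx = {c: i for i, c in enumerate(labels)}
    n = len(labels)
    confusion = np.zeros((n, n), dtype=int)
    for t, p in zip(y, yhat):
        confusion[idx[t], idx[str(p)]] += 1

    tp = np.diag(confusion).astype(float)
    pred_tot = confusion.sum(axis=0).astype(float)
    true_tot = confusion.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        rec = np.where(true_tot > 0, tp / true_tot, 0.0)
        denom = prec + rec
        f1 = np.where(denom > 0, 2 * prec * rec / np.where(denom > 0, denom, 1.0), 0.0)
    per_label = pd.DataFrame({"precision": prec, "recall": rec, "f1": f1}, index=list(labels))
    return EvaluationReport(
        label_set=labels,
        confusion=confusion,
        per_label=per_label,
        precision=float(prec.mean()),
        precision_sd=float(prec.std()),
        recall=float(rec.mean()),
        recall_sd=float(rec.std()),
        f1=float(f1.mean()),
        f1_sd=float(f1.std()),
        accuracy=float(tp.sum() / confusion.sum()),
    )


def decision_map(
    classifier, g: ChairGeometry, step: float = 0.1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predicted class over an inclusive grid covering the seat plane.

    Returns ``(xs, ys, labels)`` with ``labels[i, j]`` the prediction at
    ``(xs[j], ys[i])``; the grid spans [0, dRL] x [0, dBF] at ``step`` cm.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    nx = int(np.floor(g.dRL / step + 1e-9)) + 1
    ny = int(np.floor(g.dBF / step + 1e-9)) + 1
    xs = np.arange(nx) * step
    ys = np.arange(ny) * step
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    labels = np.asarray(classifier.predict(pts), dtype=object).reshape(ny, nx)
    return xs, ys, labels


def decision_map_frame(xs: np.ndarray, ys: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    gx, gy = np.meshgrid(xs, ys)
    return pd.DataFrame({"CMx": gx.ravel(), "CMy": gy.ravel(), "label": labels.ravel()})


def transition_frequencies(
    classifier,
    stream,
    g: ChairGeometry,
    bouts: list[tuple[int, int, str]],
    class_set: Sequence[str],
) -> pd.DataFrame:
    """Relative frequency (%) of predicted labels in each transition period.

    One row per consecutive bout pair (named e.g. ``P1-P2``) plus an
    ``Average`` row across transitions.  Transitions with no full 1-s window
    are omitted with a warning.  Rows sum to 100%.
    """
    if len(bouts) < 2:
        raise ValueError("need at least 2 bouts to have a transition")
    from chairkit.loadcell import repair_extreme_outliers  # local to avoid cycle at import time

    fs = stream.fs_loadcell
    chans = {c: repair_extreme_outliers(stream.channels[c], g.max_capacity_g) for c in ("F_g", "LB_g", "RB_g")}
    rows: dict[str, np.ndarray] = {}
    for (s0, e0, l0), (s1, e1, l1) in zip(bouts, bouts[1:]):
        name = f"{l0}-{l1}"
        if s1 - e0 < int(fs):
            logger.warning("transition %s has no full 1-s window; row omitted", name)
            continue
        means = {c: smooth_downsample(chans[c][e0:s1], fs) for c in chans}
        cmx, cmy, occ = compute_cm_series(means["F_g"], means["LB_g"], means["RB_g"], g)
        pts = np.column_stack([cmx[occ], cmy[occ]])
        if not len(pts):
            logger.warning("transition %s entirely unoccupied; row omitted", name)
            continue
        pred = np.asarray(classifier.predict(pts), dtype=object)
        freqs = np.array([100.0 * np.mean(pred == c) for c in class_set])
        rows[name] = freqs
    if not rows:
        raise ValueError("no transition produced any window")
    frame = pd.DataFrame(rows, index=list(class_set)).T
    frame.loc["Average"] = frame.mean(axis=0)
    return frame
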