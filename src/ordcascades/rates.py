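"""Pairwise base classifiers and the memorised FC/SC rate table.

For a label space of m classes, all (m-1)*m ordered-pair binary classifiers
c_{i,j} (trained on samples of classes y_i and y_j only, with y_i as "first"
class) are fitted once per cross-validation split and evaluated on the
held-out samples of *every* class. The resulting table of

* ``FC(i,j)``   — first-class sensitivity of c_{i,j} on held-out X_i, and
* ``SC(i,j,r)`` — rate at which held-out samples of class y_r are passed on
  (predicted as the second class y_j) by c_{i,j}, for every r including i, j

is what drives both the sensitivity bounds and the order screening: the
pairwise training sets do not depend on any assumed class order, so the same
(m-1)*m table serves all m! candidate orders. This replaces the (m-1)*m!
fits a de-novo training of every cascade would need.

Rates are unweighted means of per-split class-conditional rates over all
repeat x fold test sets of a shared fold assignment.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from sklearn.base import clone
from sklearn.svm import SVC

from .dataset import FoldAssignment, LabeledDataset

__all__ = [
    "BaseLearnerSpec",
    "linear_svm",
    "RateTable",
    "train_pairwise_table",
    "count_precalc_trainings",
    "count_denovo_trainings",
]


@dataclass
class BaseLearnerSpec:
    """Recipe for the binary base learner.

    ``factory`` returns a fresh sklearn-style estimator (fit/decision_function
    or fit/predict). The default is a linear soft-margin SVM with cost fixed
    to one, no feature scaling and no class weighting; its fit is
    deterministic given identical inputs.
    """

    name: str = "linear-svm"
    params: dict = field(default_factory=lambda: {"C": 1.0})
    factory: Callable[[], Any] = None

    def make(self):
        if self.factory is not None:
            return clone(self.factory())
        return SVC(kernel="linear", C=self.params.get("C", 1.0))

    def describe(self) -> dict:
        return {"name": self.name, "params": dict(self.params)}


def linear_svm(C: float = 1.0) -> BaseLearnerSpec:
    return BaseLearnerSpec(name="linear-svm", params={"C": C})


@dataclass
class _SplitCache:
    """Held-out predictions of one (repeat, fold) split.

    ``preds[(a, b)]`` (a < b, label indices) holds the predicted label index
    (a or b) of the pair's shared binary model for every test sample of the
    split. Cascade evaluation replays these instead of refitting, which is
    what makes screening over m! orders tractable and makes the empirical
    bound dominance exact rather than approximate.
    """

    repeat: int
    fold: int
    test_idx: np.ndarray
    test_class: np.ndarray
    preds: dict
    models: dict | None = None


@dataclass
class RateTable:
    """Cross-validated FC/SC rates for all ordered class pairs.

    ``fc[i, j]`` and ``sc[i, j, r]`` are indexed by position in ``labels``;
    diagonal entries (i == j) are NaN. ``splits`` optionally caches the
    per-split held-out predictions (and models) for cascade reuse.
    """

    labels: tuple
    fc: np.ndarray
    sc: np.ndarray
    provenance: dict = field(default_factory=dict)
    splits: list = None
    n_splits: int = 0

    def __post_init__(self):
        m = len(self.labels)
        if self.fc.shape != (m, m) or self.sc.shape != (m, m, m):
            raise ValueError("rate array shapes do not match label count")
        off = ~np.eye(m, dtype=bool)
        if np.nanmin(self.fc[off]) < 0 or np.nanmax(self.fc[off]) > 1:
            raise ValueError("FC rates outside [0, 1]")
        if np.nanmin(self.sc[off]) < 0 or np.nanmax(self.sc[off]) > 1:
            raise ValueError("SC rates outside [0, 1]")
        self._index = {l: i for i, l in enumerate(self.labels)}

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[str(label)]
        except KeyError:
            raise KeyError(f"unknown label {label!r}; known: {list(self.labels)}")

    def fc_rate(self, first, second) -> float:
        return float(self.fc[self.index(first), self.index(second)])

    def sc_rate(self, first, second, evaluated_on) -> float:
        return float(self.sc[self.index(first), self.index(second), self.index(evaluated_on)])

    @property
    def has_cache(self) -> bool:
        return bool(self.splits)

    def pair_model(self, split: int, first, second):
        """Fitted binary model of an ordered pair for one split (if cached)."""
        if not self.splits or self.splits[split].models is None:
            raise ValueError("rate table was built without model caching")
        a, b = sorted((self.index(first), self.index(second)))
        return self.splits[split].models[(a, b)]

    # -- serialisation (rates only; fold caches are in-memory) -------------
    def to_json(self, path=None) -> str:
        def cell(v):
            return None if np.isnan(v) else float(v)

        doc = {
            "format": "ordcascades.rate_table/1",
            "labels": list(self.labels),
            "fc": [[cell(v) for v in row] for row in self.fc],
            "sc": [[[cell(v) for v in row] for row in plane] for plane in self.sc],
            "n_splits": self.n_splits,
            "provenance": self.provenance,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RateTable":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)

        def arr(x):
            return np.array(
                [[np.nan if v is None else v for v in row] for row in x], dtype=float
            )

        fc = arr(doc["fc"])
        sc = np.array(
            [
                [[np.nan if v is None else v for v in row] for row in plane]
                for plane in doc["sc"]
            ],
            dtype=float,
        )
        return cls(
            labels=tuple(doc["labels"]),
            fc=fc,
            sc=sc,
            provenance=doc.get("provenance", {}),
            n_splits=doc.get("n_splits", 0),
        )


def _predict_pair(model, X, a: int, b: int) -> np.ndarray:
    """Predicted label index (a or b, with a < b) for each row of X.

    Uses the decision function where available; a decision value of exactly
    zero resolves to the later class b (for the orientation (a, b) this is the
    pass-on direction). Continuous data never hits the tie.
    """
    if hasattr(model, "decision_function"):
        d = np.asarray(model.decision_function(X)).ravel()
        hi = int(model.classes_[1])
        if hi == b:
            return np.where(d >= 0, b, a)
        return np.where(d > 0, a, b)
    pred = np.asarray(model.predict(X))
    return np.where(pred == b, b, a)


def train_pairwise_table(
    dataset: LabeledDataset,
    folds: FoldAssignment,
    learner: BaseLearnerSpec | None = None,
    *,
    cache_predictions: bool = True,
    cache_models: bool = False,
) -> RateTable:
    """Fit all pairwise base classifiers on the shared folds and tabulate rates.

    For each split, the learner is fitted on the training-portion samples of
    each class pair and evaluated on the test-portion samples of all classes.
    FC and SC are per-split rates averaged over all repeat x fold test sets.

    The ordered entries (i, j) and (j, i) of one unordered pair share a single
    fit: the training set and the deterministic learner are identical, only
    the first/second-class roles swap.
    """
    if folds.n_samples != dataset.n_samples:
        raise ValueError("fold assignment does not match dataset size")
    learner = learner or linear_svm()
    m = dataset.n_classes
    y = dataset.label_indices
    X = dataset.features

    fc_sum = np.zeros((m, m))
    sc_sum = np.zeros((m, m, m))
    n_splits = 0
    split_caches = [] if (cache_predictions or cache_models) else None

    for rep, fold, train_idx, test_idx in folds.splits():
        y_tr = y[train_idx]
        te_cls = y[test_idx]
        X_te = X[test_idx]
        class_masks = [te_cls == r for r in range(m)]
        if any(not mk.any() for mk in class_masks):
            missing = dataset.label_space[[mk.any() for mk in class_masks].index(False)]
            raise ValueError(
                f"test fold (repeat {rep}, fold {fold}) lacks class {missing!r}"
            )
        preds = {}
        models = {} if cache_models else None
        for a in range(m):
            for b in range(a + 1, m):
                pair_tr = train_idx[(y_tr == a) | (y_tr == b)]
                pair_y = y[pair_tr]
                if not ((pair_y == a).any() and (pair_y == b).any()):
                    raise ValueError(
                        f"training portion of (repeat {rep}, fold {fold}) lacks one of "
                        f"pair ({dataset.label_space[a]!r}, {dataset.label_space[b]!r})"
                    )
                try:
                    model = learner.make().fit(X[pair_tr], pair_y)
                    p = _predict_pair(model, X_te, a, b)
                except Exception as exc:  # learner failure with pair identity
                    raise RuntimeError(
                        f"base learner failed for pair "
                        f"({dataset.label_space[a]!r}, {dataset.label_space[b]!r}) "
                        f"in repeat {rep}, fold {fold}: {exc}"
                    ) from exc
                preds[(a, b)] = p.astype(np.int16)
                if cache_models:
                    models[(a, b)] = model
                # fraction of each held-out class predicted as b
                frac_b = np.array([np.mean(p[mk] == b) for mk in class_masks])
                # ordered entry (a, b): first class a, second b
                fc_sum[a, b] += 1.0 - frac_b[a]
                sc_sum[a, b] += frac_b
                # ordered entry (b, a): first class b, second a
                fc_sum[b, a] += frac_b[b]
                sc_sum[b, a] += 1.0 - frac_b
        if split_caches is not None:
            split_caches.append(
                _SplitCache(
                    repeat=rep,
                    fold=fold,
                    test_idx=test_idx,
                    test_class=te_cls,
                    preds=preds if cache_predictions else {},
                    models=models,
                )
            )
        n_splits += 1

    fc = fc_sum / n_splits
    sc = sc_sum / n_splits
    di = np.arange(m)
    fc[di, di] = np.nan
    sc[di, di, :] = np.nan

    h = hashlib.sha1()
    h.update(np.ascontiguousarray(dataset.features).tobytes())
    h.update("|".join(dataset.labels).encode())
    provenance = {
        "dataset_sha1": h.hexdigest(),
        "n_samples": dataset.n_samples,
        "n_features": dataset.n_features,
        "fold_seed": folds.seed,
        "repeats": folds.repeats,
        "folds": folds.folds_per_repeat,
        "learner": learner.describe(),
    }
    return RateTable(
        labels=dataset.label_space,
        fc=fc,
        sc=sc,
        provenance=provenance,
        splits=split_caches,
        n_splits=n_splits,
    )


def count_precalc_trainings(n_classes: int) -> int:
    """Base-classifier fits needed by the precalculation scheme: (n-1)*n."""
    if n_classes < 2:
        raise ValueError("need at least two classes")
    return (n_classes - 1) * n_classes


def count_denovo_trainings(n_classes: int) -> int:
    """Base-classifier fits a de-novo training of all n! cascades needs: (n-1)*n!."""
    if n_classes < 2:
        raise ValueError("need at least two classes")
    return (n_classes - 1) * math.factorial(n_classes)
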