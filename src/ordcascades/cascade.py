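"""Ordinal classifier cascades: fusion rule, sensitivities and upper bounds.

A cascade for an assumed class order y_(1) < ... < y_(m) evaluates the
adjacent-pair base classifiers sequentially: the first classifier c_(k) that
predicts its first class y_(k) determines the output; if every classifier
passes the sample on, the last label y_(m) is predicted.

The minimal class-wise sensitivity p* = min_i p_h(y_(i) | X_(i)) measures how
well the assumed order is reflected in feature space. Two structural upper
bounds hold per test set and carry over to fold-averaged rates:

* the cascade's sensitivity for y_(i) is at most the first-class sensitivity
  FC of its own base classifier, and
* at most the pass-on rate SC of every earlier classifier evaluated on
  samples of y_(i) (a sample claimed early can never reach position i).

Because cascade evaluation replays the *same* cached per-fold predictions the
rate table was built from, the dominance p* <= overall bound is exact here,
not just asymptotic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import FoldAssignment, LabeledDataset
from .rates import RateTable

__all__ = [
    "ClassOrder",
    "BoundReport",
    "SensitivityReport",
    "predict_cascade",
    "evaluate_cascade",
    "bound_for_order",
]

ORDER_SEP = "<"


@dataclass(frozen=True)
class ClassOrder:
    """A total order (y_(1), ..., y_(m)) over a subset of the label space."""

    labels: tuple

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if len(self.labels) < 2:
            raise ValueError("an order needs at least two classes")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"order repeats a label: {self.labels}")
        if any(ORDER_SEP in l for l in self.labels):
            raise ValueError(f"labels may not contain {ORDER_SEP!r}")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __str__(self) -> str:
        return ORDER_SEP.join(self.labels)

    @classmethod
    def from_string(cls, text: str) -> "ClassOrder":
        return cls(tuple(p.strip() for p in text.split(ORDER_SEP) if p.strip()))

    def reversed(self) -> "ClassOrder":
        return ClassOrder(self.labels[::-1])

    def is_full(self, label_space) -> bool:
        return set(self.labels) == set(label_space)

    def validate_against(self, label_space) -> None:
        unknown = [l for l in self.labels if l not in set(label_space)]
        if unknown:
            raise ValueError(f"order references unknown label(s) {unknown}")


@dataclass(frozen=True)
class BoundReport:
    """Per-position sensitivity bounds for one class order.

    ``fc_bounds[i]`` is the first-class sensitivity of the i-th base pair
    (undefined, ``None``, at the last position: no classifier has the last
    label as first class). ``chain_bounds[i]`` is the minimum pass-on rate of
    all earlier pairs evaluated on class (i) (undefined at position 0).
    ``class_bounds[i]`` is the minimum of the two and ``overall_bound`` the
    minimum over positions — an upper bound on the cascade's p*.
    """

    order: ClassOrder
    fc_bounds: tuple
    chain_bounds: tuple
    class_bounds: tuple
    overall_bound: float

    def to_dict(self) -> dict:
        return {
            "order": str(self.order),
            "fc_bounds": list(self.fc_bounds),
            "chain_bounds": list(self.chain_bounds),
            "class_bounds": list(self.class_bounds),
            "overall_bound": self.overall_bound,
        }


@dataclass(frozen=True)
class SensitivityReport:
    """Cross-validated class-wise sensitivities of one evaluated cascade."""

    order: ClassOrder
    class_sensitivities: tuple
    min_sensitivity: float
    bounds: BoundReport | None = None

    def sensitivity(self, label: str) -> float:
        return self.class_sensitivities[self.order.labels.index(str(label))]

    def to_dict(self) -> dict:
        doc = {
            "order": str(self.order),
            "class_sensitivities": {
                l: s for l, s in zip(self.order.labels, self.class_sensitivities)
            },
            "min_sensitivity": self.min_sensitivity,
        }
        if self.bounds is not None:
            doc["bounds"] = self.bounds.to_dict()
        return doc


def predict_cascade(sample, order: ClassOrder, pair_models) -> str:
    """Classify one sample by strictly sequential cascade evaluation.

    ``pair_models`` maps each adjacent ordered pair ``(first, second)`` of the
    order to a fitted binary model whose ``predict`` returns labels of that
    pair. Models after the first "first-class" decision are not consulted.
    """
    x = np.asarray(sample, dtype=float).reshape(1, -1)
    labels = order.labels
    for k in range(len(labels) - 1):
        pair = (labels[k], labels[k + 1])
        try:
            model = pair_models[pair]
        except KeyError:
            raise KeyError(f"missing base model for pair {pair!r}")
        pred = str(np.asarray(model.predict(x)).ravel()[0])
        if pred == labels[k]:
            return labels[k]
    return labels[-1]


def bound_for_order(table: RateTable, order: ClassOrder) -> BoundReport:
    """Structural upper bounds on the cascade sensitivities of an order, by pure table lookups."""
    order.validate_against(table.labels)
    idx = [table.index(l) for l in order.labels]
    m = len(idx)
    fc_bounds, chain_bounds, class_bounds = [], [], []
    for i in range(m):
        fc_i = float(table.fc[idx[i], idx[i + 1]]) if i < m - 1 else None
        if i == 0:
            ch_i = None
        else:
            ch_i = min(float(table.sc[idx[k], idx[k + 1], idx[i]]) for k in range(i))
        terms = [v for v in (fc_i, ch_i) if v is not None]
        fc_bounds.append(fc_i)
        chain_bounds.append(ch_i)
        class_bounds.append(min(terms))
    return BoundReport(
        order=order,
        fc_bounds=tuple(fc_bounds),
        chain_bounds=tuple(chain_bounds),
        class_bounds=tuple(class_bounds),
        overall_bound=min(class_bounds),
    )


def _cascade_labels(split, idx) -> np.ndarray:
    """Cascade prediction (as label index) for every test sample of a split.

    Vectorised replay of the fusion rule on the cached pairwise predictions:
    the output is the first position whose base pair predicts its first
    class, else the last label of the order.
    """
    m = len(idx)
    n = split.test_class.size
    stops = np.zeros((m - 1, n), dtype=bool)
    for k in range(m - 1):
        a, b = idx[k], idx[k + 1]
        key = (a, b) if a < b else (b, a)
        stops[k] = split.preds[key] == a
    any_stop = stops.any(axis=0)
    first = stops.argmax(axis=0)
    pos = np.where(any_stop, first, m - 1)
    return np.asarray(idx, dtype=np.int64)[pos]


def evaluate_cascade(
    dataset: LabeledDataset,
    order: ClassOrder,
    folds: FoldAssignment,
    table: RateTable,
) -> SensitivityReport:
    """Cross-validated class-wise sensitivities of the cascade for an order.

    Per (repeat, fold), test samples of the order's classes are classified by
    sequential cascade evaluation using that split's cached base-classifier
    predictions; per-class sensitivities are unweighted means over splits and
    p* their minimum. Samples of classes outside a partial order are ignored.
    """
    order.validate_against(dataset.label_space)
    if not table.has_cache:
        raise ValueError(
            "rate table carries no cached fold predictions; rebuild it with "
            "train_pairwise_table(..., cache_predictions=True)"
        )
    if len(table.splits) != folds.n_splits:
        raise ValueError("fold assignment does not match the table's cached splits")
    idx = [table.index(l) for l in order.labels]
    sens_sum = np.zeros(len(idx))
    n_used = np.zeros(len(idx))
    for split in table.splits:
        out = _cascade_labels(split, idx)
        for pos, cls in enumerate(idx):
            mask = split.test_class == cls
            if mask.any():
                sens_sum[pos] += np.mean(out[mask] == cls)
                n_used[pos] += 1
    if (n_used == 0).any():
        empty = order.labels[int(np.argmin(n_used))]
        raise ValueError(f"class {empty!r} never appears in a test fold")
    sens = tuple(float(s) for s in sens_sum / n_used)
    return SensitivityReport(
        order=order,
        class_sensitivities=sens,
        min_sensitivity=float(min(sens)),
        bounds=bound_for_order(table, order),
    )
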