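"""Exhaustive, bound-pruned screening of all class orders.

The screen enumerates the orders of a label set depth-first. The first
position is filled unconditionally (no base classifier exists yet); extending
a partial order ending in y_i by y_j requires the memorised rates to satisfy

    FC(i, j) >= t   and   SC(i, j, r) >= t  for every remaining label r

(including r = y_j itself: the pass-on rate of the pair for its own second
class bounds that class's sensitivity too). A failed check prunes the whole
subtree — (remaining-1)! full orders — so rejected orders are counted
analytically without being enumerated. Surviving complete orders are
candidates; because the checks are exactly the terms of the per-position
bounds, the candidate set equals {orders with overall bound >= t}, which the
pruning-free :func:`brute_force_screen` verifies on small label sets.

Passing the bound does not guarantee p* >= t, so candidates are cross-checked
by evaluating the full cascade (:func:`cross_check`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .cascade import ClassOrder, bound_for_order, evaluate_cascade
from .dataset import FoldAssignment, LabeledDataset
from .rates import RateTable

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "CandidateCheck",
    "cascades_screen",
    "brute_force_screen",
    "cross_check",
    "max_certified_bound",
    "worst_case_lookups",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Settings of one screening run.

    ``threshold`` is the minimal class-wise sensitivity t the bounds are
    checked against (pass on ties, i.e. ``>= t``). ``label_subset`` restricts
    the screen to orders of a subset of the label space (partial cascades).
    ``inclusive_sc`` controls whether the pass-on check at an extension also
    covers the label just being placed (the default; the exclusive variant
    only checks the labels still to be placed).
    """

    threshold: float
    label_subset: tuple = None
    inclusive_sc: bool = True
    trace: bool = False

    def __post_init__(self):
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must lie in [0, 1], got {self.threshold}")
        if self.label_subset is not None:
            object.__setattr__(
                self, "label_subset", tuple(str(l) for l in self.label_subset)
            )
            if len(self.label_subset) < 2:
                raise ValueError("label subset needs at least two classes")
            if len(set(self.label_subset)) != len(self.label_subset):
                raise ValueError("label subset repeats a label")


@dataclass(frozen=True)
class CandidateCheck:
    """Cross-check outcome of one surviving candidate order."""

    order: ClassOrder
    report: SensitivityReport
    passed: bool


@dataclass
class ScreenResult:
    """Candidates and accounting of one screening run.

    ``candidates + rejected_count`` always equals (subset size)!; pruned
    subtrees are counted analytically. ``lookups`` is the number of FC/SC
    table reads performed (short-circuited), an instrumentation of the
    early-stopping payoff.
    """

    config: ScreenConfig
    labels: tuple
    candidates: list
    bounds: list
    rejected_count: int
    lookups: int
    prune_events: list = field(default_factory=list)
    cross_checked: list = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_orders(self) -> int:
        return math.factorial(len(self.labels))

    @property
    def passing(self) -> list:
        """Candidates that also passed the cross-check (if performed)."""
        if self.cross_checked is None:
            return list(self.candidates)
        return [c.order for c in self.cross_checked if c.passed]

    def to_dict(self) -> dict:
        doc = {
            "threshold": self.config.threshold,
            "labels": list(self.labels),
            "n_orders": self.n_orders,
            "rejected_count": self.rejected_count,
            "lookups": self.lookups,
            "candidates": [
                {"order": str(o), "overall_bound": b}
                for o, b in zip(self.candidates, self.bounds)
            ],
            "provenance": self.provenance,
        }
        if self.cross_checked is not None:
            for entry, chk in zip(doc["candidates"], self.cross_checked):
                entry["min_sensitivity"] = chk.report.min_sensitivity
                entry["class_sensitivities"] = chk.report.to_dict()["class_sensitivities"]
                entry["passed"] = chk.passed
        return doc

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = []
        checks = self.cross_checked or [None] * len(self.candidates)
        for order, bound, chk in zip(self.candidates, self.bounds, checks):
            row = {"order": str(order), "overall_bound": bound}
            if chk is not None:
                row["min_sensitivity"] = chk.report.min_sensitivity
                row["passed"] = chk.passed
                for l, s in zip(order.labels, chk.report.class_sensitivities):
                    row[f"sens[{l}]"] = s
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)


def _subset_indices(table: RateTable, config: ScreenConfig) -> list:
    if config.label_subset is None:
        return list(range(table.n_classes))
    return [table.index(l) for l in config.label_subset]


def cascades_screen(table: RateTable, config: ScreenConfig) -> ScreenResult:
    """Depth-first enumeration of all orders with bound-based early stopping.

    Returns the surviving candidate orders (lexicographic by label-space
    index) with their overall bounds, plus analytic rejected-order counts and
    the number of table lookups actually performed.
    """
    idx = _subset_indices(table, config)
    t = config.threshold
    fc, sc = table.fc, table.sc
    labels = table.labels
    candidates: list = []
    bounds: list = []
    state = {"rejected": 0, "lookups": 0}
    prune_events: list = []

    def extend(prev: int | None, remaining: list, prefix: list) -> None:
        if not remaining:
            order = ClassOrder(tuple(labels[i] for i in prefix))
            candidates.append(order)
            bounds.append(bound_for_order(table, order).overall_bound)
            return
        for pos, j in enumerate(remaining):
            ok = True
            if prev is not None:
                state["lookups"] += 1
                if fc[prev, j] < t:
                    ok = False
                else:
                    for r in remaining:
                        if r == j and not config.inclusive_sc:
                            continue
                        state["lookups"] += 1
                        if sc[prev, j, r] < t:
                            ok = False
                            break
            if ok:
                rest = remaining[:pos] + remaining[pos + 1:]
                extend(j, rest, prefix + [j])
            else:
                state["rejected"] += math.factorial(len(remaining) - 1)
                if config.trace:
                    prune_events.append(
                        {
                            "prefix": [labels[i] for i in prefix],
                            "rejected_label": labels[j],
                            "subtree_orders": math.factorial(len(remaining) - 1),
                        }
                    )

    extend(None, idx, [])
    return ScreenResult(
        config=config,
        labels=tuple(labels[i] for i in idx),
        candidates=candidates,
        bounds=bounds,
        rejected_count=state["rejected"],
        lookups=state["lookups"],
        prune_events=prune_events,
        provenance=dict(table.provenance),
    )


def brute_force_screen(table: RateTable, config: ScreenConfig) -> list:
    """Pruning-free ground truth: every permutation, bound computed directly.

    Guarded to small label sets (<= 8 classes) — this is the test oracle for
    :func:`cascades_screen`, not a screening path.
    """
    idx = _subset_indices(table, config)
    if len(idx) > 8:
        raise ValueError("brute-force screen is limited to 8 classes")
    out = []
    for perm in permutations(idx):
        order = ClassOrder(tuple(table.labels[i] for i in perm))
        if bound_for_order(table, order).overall_bound >= config.threshold:
            out.append(order)
    return out


def cross_check(
    result: ScreenResult,
    dataset: LabeledDataset,
    folds: FoldAssignment,
    table: RateTable,
) -> ScreenResult:
    """Evaluate every surviving candidate as a full cascade.

    A candidate passes iff its measured minimal class-wise sensitivity p*
    reaches the screening threshold; both the certified bound and the actual
    p* are kept side by side in the completed result.
    """
    t = result.config.threshold
    checks = []
    for order in result.candidates:
        report = evaluate_cascade(dataset, order, folds, table)
        checks.append(
            CandidateCheck(order=order, report=report, passed=report.min_sensitivity >= t)
        )
    completed = replace_cross(result, checks)
    return completed


def replace_cross(result: ScreenResult, checks: list) -> ScreenResult:
    return ScreenResult(
        config=result.config,
        labels=result.labels,
        candidates=result.candidates,
        bounds=result.bounds,
        rejected_count=result.rejected_count,
        lookups=result.lookups,
        prune_events=result.prune_events,
        cross_checked=checks,
        provenance=result.provenance,
    )


def _exists_order(table: RateTable, idx: list, t: float, exclude: set) -> bool:
    """Is there any (non-excluded) order whose overall bound reaches t?

    Early-exit depth-first search with the same pruning checks as the screen.
    """
    fc, sc = table.fc, table.sc

    def extend(prev, remaining, prefix):
        if not remaining:
            return tuple(prefix) not in exclude
        for pos, j in enumerate(remaining):
            if prev is not None:
                if fc[prev, j] < t:
                    continue
                if any(sc[prev, j, r] < t for r in remaining):
                    continue
            if extend(j, remaining[:pos] + remaining[pos + 1:], prefix + [j]):
                return True
        return False

    return extend(None, idx, [])


def max_certified_bound(
    table: RateTable,
    *,
    label_subset=None,
    exclude=(),
    tol: float = 1e-6,
) -> float:
    """Maximum certified overall bound over all orders (optionally excluding some).

    Threshold bisection over the pruned screen: an early-exit existence query
    brackets the maximum, then one full screen just below it returns the
    exact maximal bound. ``exclude`` lists orders (ClassOrder or label
    sequences) to ignore, e.g. the returned candidates.
    """
    cfg = ScreenConfig(threshold=0.0, label_subset=label_subset)
    idx = _subset_indices(table, cfg)
    excl = set()
    for o in exclude:
        labels = tuple(o.labels) if isinstance(o, ClassOrder) else tuple(str(l) for l in o)
        excl.add(tuple(table.index(l) for l in labels))
    if not _exists_order(table, idx, 0.0, excl):
        raise ValueError("all orders are excluded")
    lo, hi = 0.0, 1.0
    if _exists_order(table, idx, 1.0, excl):
        lo = 1.0
    else:
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if _exists_order(table, idx, mid, excl):
                lo = mid
            else:
                hi = mid
    if lo == 0.0:
        # no order reaches even tol: with fold-averaged rates (multiples of
        # 1/n_splits per fold count) the maximum is exactly zero
        return 0.0
    # exact maximum among the (few) orders whose bound reaches the bracket
    result = cascades_screen(table, ScreenConfig(threshold=lo, label_subset=label_subset))
    best = -np.inf
    for order, bound in zip(result.candidates, result.bounds):
        key = tuple(table.index(l) for l in order.labels)
        if key not in excl and bound > best:
            best = bound
    return float(best)


def worst_case_lookups(n_classes: int) -> int:
    """Closed-form worst-case comparison count f(n) = sum_{k=2}^{n} k*C(n, k+1)."""
    if n_classes < 2:
        raise ValueError("need at least two classes")
    return sum(k * math.comb(n_classes, k + 1) for k in range(2, n_classes + 1))
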