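"""Shared fixtures: generated datasets, trained rate tables, random tables.

All fixtures are deterministic (fixed seeds chosen once); heavy tables are
built lazily and memoised for the whole session so the screening tests share
one 10x10 cross-validated table per (family, sd) condition.
"""

from __future__ import annotations

import functools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ordcascades as oc

settings.register_profile(
    "suite", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")

DATA_SEED = 1
FOLD_SEED = 2


@pytest.fixture(scope="session")
def trained():
    """Memoised builder for full-size benchmark conditions.

    ``trained(kind, sd)`` -> (dataset, folds, table) with 10 classes x 100
    samples and a shared 10x10 stratified CV, matching the benchmark
    protocol.
    """

    @functools.lru_cache(maxsize=None)
    def build(kind: str, sd: float):
        dataset = oc.generate(oc.SyntheticSpec(kind=kind, sd=sd, seed=DATA_SEED))
        folds = oc.make_folds(dataset, repeats=10, folds=10, seed=FOLD_SEED)
        table = oc.train_pairwise_table(dataset, folds)
        return dataset, folds, table

    return build


@pytest.fixture(scope="session")
def six_class():
    """Small overlapping 6-class ordinal dataset with a shared 3x5 CV."""
    dataset = oc.generate(
        oc.SyntheticSpec(kind="linear", n_classes=6, n_per_class=30, sd=0.8, seed=DATA_SEED)
    )
    folds = oc.make_folds(dataset, repeats=3, folds=5, seed=FOLD_SEED)
    table = oc.train_pairwise_table(dataset, folds)
    return dataset, folds, table


def random_rate_table(rng: np.random.Generator, m: int) -> oc.RateTable:
    """A synthetic rate table with uniform rates and the binary-output
    conservation FC(i,j) + SC(i,j,i) = 1 enforced."""
    labels = tuple(chr(ord("a") + i) for i in range(m))
    fc = rng.uniform(size=(m, m))
    sc = rng.uniform(size=(m, m, m))
    di = np.arange(m)
    for i in range(m):
        for j in range(m):
            if i != j:
                sc[i, j, i] = 1.0 - fc[i, j]
    fc[di, di] = np.nan
    sc[di, di, :] = np.nan
    return oc.RateTable(labels=labels, fc=fc, sc=sc)


@pytest.fixture
def make_random_table():
    return random_rate_table


def constant_rate_table(m: int, value: float) -> oc.RateTable:
    """All FC and SC rates equal to ``value`` (conservation not enforced:
    used for threshold tie and traversal-count checks)."""
    labels = tuple(chr(ord("a") + i) for i in range(m))
    fc = np.full((m, m), value)
    sc = np.full((m, m, m), value)
    di = np.arange(m)
    fc[di, di] = np.nan
    sc[di, di, :] = np.nan
    return oc.RateTable(labels=labels, fc=fc, sc=sc)
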