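"""Labeled datasets, delimited-text I/O and the shared cross-validation folds.

A :class:`LabeledDataset` holds a real-valued feature matrix (samples x
features, e.g. normalised expression profiles) together with one categorical
class label per sample and, optionally, a per-sample group id (subject id)
for grouped cross-validation.

A :class:`FoldAssignment` is a repeated, stratified partition of the samples.
One assignment is shared by *all* pairwise base classifiers and *all* cascade
evaluations of a run: the sensitivity bounds of the screening procedure hold
per test set, so evaluating every rate on identical held-out sets keeps the
bound-dominance guarantee exact for the fold-averaged rates as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "FoldAssignment",
    "load_dataset",
    "write_dataset",
    "make_folds",
    "conditional_prediction_rate",
]


@dataclass
class LabeledDataset:
    """Feature matrix plus per-sample class labels (and optional groups).

    Parameters
    ----------
    features:
        Real matrix of shape (n_samples, n_features); no missing values.
    labels:
        One class label per sample (strings).
    label_space:
        Distinct labels in a fixed order; defaults to order of first
        appearance in ``labels``. Must have at least two entries and every
        entry must occur in ``labels``.
    sample_ids:
        Optional unique sample identifiers; default ``s1..sN``.
    groups:
        Optional per-sample group id; samples of one group are kept in the
        same cross-validation fold.
    """

    features: np.ndarray
    labels: np.ndarray
    label_space: tuple = None
    sample_ids: tuple = None
    groups: np.ndarray = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix (samples x features)")
        if not np.isfinite(self.features).all():
            bad = np.argwhere(~np.isfinite(self.features))[0]
            raise ValueError(
                f"feature matrix contains missing/non-finite value at "
                f"row {bad[0]}, column {bad[1]}"
            )
        self.labels = np.asarray([str(l) for l in np.asarray(self.labels).ravel()], dtype=object)
        if len(self.labels) != self.features.shape[0]:
            raise ValueError(
                f"number of labels ({len(self.labels)}) does not match number "
                f"of feature rows ({self.features.shape[0]})"
            )
        if self.label_space is None:
            self.label_space = tuple(dict.fromkeys(self.labels))
        else:
            self.label_space = tuple(str(l) for l in self.label_space)
        if len(self.label_space) < 2:
            raise ValueError("label space must contain at least two classes")
        if len(set(self.label_space)) != len(self.label_space):
            raise ValueError("label_space contains duplicate labels")
        present = set(self.labels)
        missing = [l for l in present if l not in self.label_space]
        if missing:
            raise ValueError(f"labels {missing} not in label_space")
        unused = [l for l in self.label_space if l not in present]
        if unused:
            raise ValueError(f"label_space entries {unused} have no samples")
        if self.sample_ids is None:
            self.sample_ids = tuple(f"s{i + 1}" for i in range(self.n_samples))
        else:
            self.sample_ids = tuple(str(s) for s in self.sample_ids)
            if len(self.sample_ids) != self.n_samples:
                raise ValueError("sample_ids length does not match sample count")
            if len(set(self.sample_ids)) != self.n_samples:
                dup = pd.Index(self.sample_ids)
                dup = dup[dup.duplicated()][0]
                raise ValueError(f"duplicated sample id: {dup!r}")
        if self.groups is not None:
            self.groups = np.asarray([str(g) for g in np.asarray(self.groups).ravel()], dtype=object)
            if len(self.groups) != self.n_samples:
                raise ValueError("groups length does not match sample count")
        self._index = {l: i for i, l in enumerate(self.label_space)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.label_space)

    def label_index(self, label: str) -> int:
        try:
            return self._index[str(label)]
        except KeyError:
            raise KeyError(f"unknown label {label!r}; known: {list(self.label_space)}")

    @property
    def label_indices(self) -> np.ndarray:
        """Per-sample integer class index into ``label_space``."""
        return np.fromiter((self._index[l] for l in self.labels), dtype=np.int64, count=self.n_samples)

    def indices_of(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == str(label))

    def class_counts(self) -> dict:
        return {l: int((self.labels == l).sum()) for l in self.label_space}


@dataclass
class FoldAssignment:
    """Repeated stratified partition of a dataset's samples.

    ``assignment[r, s]`` is the fold index of sample ``s`` in repeat ``r``.
    Within each repeat the folds partition all samples and every fold's test
    set contains at least one sample of every class.
    """

    repeats: int
    folds_per_repeat: int
    assignment: np.ndarray
    seed: int

    @property
    def n_splits(self) -> int:
        return self.repeats * self.folds_per_repeat

    @property
    def n_samples(self) -> int:
        return self.assignment.shape[1]

    def splits(self) -> Iterator[tuple]:
        """Yield ``(repeat, fold, train_idx, test_idx)`` for every split."""
        for r in range(self.repeats):
            row = self.assignment[r]
            for f in range(self.folds_per_repeat):
                test = np.flatnonzero(row == f)
                train = np.flatnonzero(row != f)
                yield r, f, train, test


def make_folds(dataset: LabeledDataset, repeats: int, folds: int, seed: int) -> FoldAssignment:
    """Build a repeated stratified fold assignment (e.g. 10x10 CV).

    Stratification deals each class's samples round-robin onto the folds (with
    a random per-class starting fold), so each test fold holds an equal share
    of every class. If the dataset carries groups, whole groups are dealt
    instead of samples; groups must be label-pure and every class must span at
    least ``folds`` groups.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if folds < 2:
        raise ValueError("folds must be >= 2 (a single fold leaves no held-out split)")
    counts = dataset.class_counts()
    small = [l for l, c in counts.items() if c < folds]
    if small:
        raise ValueError(
            f"classes {small} have fewer samples than folds={folds}; "
            "stratified folds are impossible"
        )

    # units: per class, the index groups dealt onto folds
    if dataset.groups is not None:
        units_by_class = {l: [] for l in dataset.label_space}
        for g in dict.fromkeys(dataset.groups):
            idx = np.flatnonzero(dataset.groups == g)
            glabels = set(dataset.labels[idx])
            if len(glabels) != 1:
                raise ValueError(
                    f"group {g!r} mixes labels {sorted(glabels)}; grouped folds "
                    "require label-pure groups"
                )
            units_by_class[glabels.pop()].append(idx)
        few = [l for l, u in units_by_class.items() if len(u) < folds]
        if few:
            raise ValueError(
                f"classes {few} have fewer groups than folds={folds}; "
                "grouping is incompatible with stratification"
            )
    else:
        units_by_class = {
            l: [np.array([i]) for i in dataset.indices_of(l)] for l in dataset.label_space
        }

    children = np.random.SeedSequence(seed).spawn(repeats)
    assignment = np.empty((repeats, dataset.n_samples), dtype=np.int16)
    for r in range(repeats):
        rng = np.random.default_rng(children[r])
        for label in dataset.label_space:
            units = units_by_class[label]
            order = rng.permutation(len(units))
            start = int(rng.integers(folds))
            for k, u in enumerate(order):
                assignment[r, units[u]] = (start + k) % folds
    return FoldAssignment(repeats=repeats, folds_per_repeat=folds, assignment=assignment, seed=seed)


def conditional_prediction_rate(predicted_labels: Sequence, target_label) -> float:
    """Fraction of predictions equal to ``target_label``.

    The indicator-mean estimator of a conditional prediction rate
    p_c(y_j | X_i): evaluated on predictions for samples of one class, it is a
    sensitivity (same class), a confusion (another class of the classifier's
    label space) or an external rate (a class foreign to the classifier) —
    the distinction is the caller's context, the arithmetic is identical.
    """
    preds = np.asarray(list(predicted_labels), dtype=object)
    if preds.size == 0:
        raise ValueError("rate undefined for an empty prediction list")
    return float(np.mean(preds == str(target_label)))


# ---------------------------------------------------------------------------
# delimited-text I/O


def _sep_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def load_dataset(
    matrix_path,
    *,
    label_col: str = "label",
    labels_file=None,
    groups_col: str | None = None,
    samples_in_columns: bool = False,
    delimiter: str | None = None,
) -> LabeledDataset:
    """Read a delimited numeric matrix plus labels into a LabeledDataset.

    The matrix is TSV/CSV with a header row of feature ids and sample ids in
    the first column; ``samples_in_columns=True`` transposes a matrix written
    the series-matrix way (features in rows). Labels come either from a named
    column of the matrix (``label_col``) or from a separate two-column
    sample -> label file (``labels_file``).
    """
    sep = _sep_for(matrix_path, delimiter)
    df = pd.read_csv(matrix_path, sep=sep, index_col=0, float_precision="round_trip")
    if samples_in_columns:
        df = df.T
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicated sample id: {dup!r}")

    labels = None
    groups = None
    if labels_file is not None:
        lf = pd.read_csv(labels_file, sep=_sep_for(labels_file, delimiter), header=None, dtype=str)
        if lf.shape[1] < 2:
            raise ValueError("labels file must have two columns: sample id, label")
        lmap = dict(zip(lf.iloc[:, 0], lf.iloc[:, 1]))
        missing = [str(s) for s in df.index if str(s) not in lmap]
        if missing:
            raise ValueError(f"no label for sample(s): {missing[:5]}")
        labels = np.array([lmap[str(s)] for s in df.index], dtype=object)
    else:
        if label_col not in df.columns:
            raise ValueError(
                f"label column {label_col!r} not found; columns: {list(df.columns)[:10]}..."
            )
        lab = df[label_col]
        if lab.isna().any():
            missing = df.index[lab.isna()][0]
            raise ValueError(f"sample {missing!r} has no label")
        labels = lab.astype(str).to_numpy(dtype=object)
        df = df.drop(columns=[label_col])
    if groups_col is not None:
        if groups_col not in df.columns:
            raise ValueError(f"group column {groups_col!r} not found")
        groups = df[groups_col].astype(str).to_numpy(dtype=object)
        df = df.drop(columns=[groups_col])

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.any().any():
        col = bad.any(axis=0)
        col = col.index[col][0]
        row = bad[col]
        row = bad.index[row][0]
        raise ValueError(f"non-numeric cell at sample {row!r}, feature {col!r}")
    if numeric.isna().any().any():
        col = numeric.isna().any(axis=0)
        col = col.index[col][0]
        raise ValueError(f"missing values in feature column {col!r}")

    return LabeledDataset(
        features=numeric.to_numpy(dtype=float),
        labels=labels,
        sample_ids=tuple(str(s) for s in df.index),
        groups=groups,
    )


def write_dataset(
    dataset: LabeledDataset,
    matrix_path,
    *,
    label_col: str = "label",
    delimiter: str | None = None,
) -> None:
    """Write a dataset as a delimited matrix with a label column.

    Values are written with shortest round-trip float formatting so that
    :func:`load_dataset` reproduces the features bit-exactly.
    """
    sep = _sep_for(matrix_path, delimiter)
    # shortest round-trip representation per cell, so reload is bit-exact
    cells = [[repr(float(v)) for v in row] for row in dataset.features]
    df = pd.DataFrame(
        cells,
        index=pd.Index(dataset.sample_ids, name="sample"),
        columns=[f"f{i + 1}" for i in range(dataset.n_features)],
    )
    df[label_col] = dataset.labels
    df.to_csv(matrix_path, sep=sep)
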