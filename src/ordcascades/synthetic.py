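"""Generators for the artificial benchmark families.

Three two-dimensional Gaussian-cloud designs, each with 10 classes of 100
samples by default and a common isotropic standard deviation:

* ``linear``     — class i centred at (i, i): centroids on a line, a perfectly
  ordinal arrangement.
* ``curved``     — centroids follow a random monotone walk from (0, 0) with
  per-step increments drawn uniformly from (0.5, 2) in each coordinate: still
  ordinal, but curved.
* ``nonordinal`` — centroids on a fixed scrambled grid inside [1, 4]^2 that
  admits no total order which is monotone in both coordinates; a screen for
  orders should come back empty.

Samples are drawn i.i.d. from N(m_y, sd^2 I). Everything is deterministic
given the spec's seed; for the curved family the centroid walk is drawn from
the seed before any sample noise, so centroids and noise are independently
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import LabeledDataset

__all__ = [
    "SyntheticSpec",
    "DEFAULT_NONORDINAL_CENTROIDS",
    "centroids_for",
    "gen_linear",
    "gen_curved",
    "gen_nonordinal",
    "generate",
]

#: 10 grid points spanning [1, 4]^2, assigned to classes in a scrambled order
#: so that no permutation of the centroids is simultaneously non-decreasing
#: in both coordinates (no monotone chain of length 10 exists).
DEFAULT_NONORDINAL_CENTROIDS = (
    (2.5, 2.5),
    (1.0, 4.0),
    (4.0, 1.0),
    (1.0, 1.0),
    (4.0, 4.0),
    (2.5, 1.0),
    (1.0, 2.5),
    (4.0, 2.5),
    (2.5, 4.0),
    (1.75, 1.75),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one artificial dataset draw.

    ``sd`` is the common standard deviation of the isotropic Gaussian noise
    around each centroid (the benchmark sweep uses sd in {0.1, ..., 1.0};
    0.2 is the headline setting). ``increment_range`` only applies to the
    curved family, ``centroids`` only to the non-ordinal one.
    """

    kind: str
    n_classes: int = 10
    n_per_class: int = 100
    sd: float = 0.2
    seed: int = 0
    increment_range: tuple = (0.5, 2.0)
    centroids: tuple = None

    def __post_init__(self):
        if self.kind not in ("linear", "curved", "nonordinal"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.n_per_class < 1:
            raise ValueError("need at least one sample per class")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.kind == "nonordinal":
            cents = self.centroids if self.centroids is not None else DEFAULT_NONORDINAL_CENTROIDS
            cents = tuple((float(a), float(b)) for a, b in cents)
            if len(cents) != self.n_classes:
                raise ValueError(
                    f"centroid list length {len(cents)} != n_classes {self.n_classes}"
                )
            object.__setattr__(self, "centroids", cents)

    def to_dict(self) -> dict:
        doc = {
            "kind": self.kind,
            "n_classes": self.n_classes,
            "n_per_class": self.n_per_class,
            "sd": self.sd,
            "seed": self.seed,
        }
        if self.kind == "curved":
            doc["increment_range"] = list(self.increment_range)
        if self.kind == "nonordinal":
            doc["centroids"] = [list(c) for c in self.centroids]
        return doc


def _labels(n_classes: int) -> list:
    return [f"y{i + 1}" for i in range(n_classes)]


def centroids_for(spec: SyntheticSpec) -> np.ndarray:
    """Class centroids of a spec, one row per class.

    For the curved family the centroid walk consumes the first draws of the
    seed's stream, exactly as generation does, so the returned centroids match
    the generated dataset.
    """
    if spec.kind == "linear":
        return np.array([[i, i] for i in range(1, spec.n_classes + 1)], dtype=float)
    if spec.kind == "curved":
        rng = np.random.default_rng(spec.seed)
        lo, hi = spec.increment_range
        return np.cumsum(rng.uniform(lo, hi, size=(spec.n_classes, 2)), axis=0)
    return np.array(spec.centroids, dtype=float)


def _assemble(centroids: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator) -> LabeledDataset:
    labels = _labels(spec.n_classes)
    feats, labs, ids = [], [], []
    for i, label in enumerate(labels):
        noise = rng.normal(0.0, spec.sd, size=(spec.n_per_class, 2))
        feats.append(centroids[i] + noise)
        labs.extend([label] * spec.n_per_class)
        ids.extend(f"{label}_{k + 1:03d}" for k in range(spec.n_per_class))
    return LabeledDataset(
        features=np.vstack(feats),
        labels=np.array(labs, dtype=object),
        label_space=tuple(labels),
        sample_ids=tuple(ids),
    )


def gen_linear(spec: SyntheticSpec) -> LabeledDataset:
    """Ordinal clouds on a line: class i is N((i, i), sd^2 I)."""
    if spec.kind != "linear":
        raise ValueError("spec.kind must be 'linear'")
    rng = np.random.default_rng(spec.seed)
    return _assemble(centroids_for(spec), spec, rng)


def gen_curved(spec: SyntheticSpec) -> LabeledDataset:
    """Ordinal clouds on a random monotone walk from (0, 0).

    Each centroid adds a fresh uniform increment from ``increment_range`` to
    its predecessor in both coordinates, so centroid coordinates are strictly
    increasing in class index; the walk is drawn once per dataset from the
    seed, before any sample noise.
    """
    if spec.kind != "curved":
        raise ValueError("spec.kind must be 'curved'")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.increment_range
    steps = rng.uniform(lo, hi, size=(spec.n_classes, 2))  # consumed before noise
    return _assemble(np.cumsum(steps, axis=0), spec, rng)


def gen_nonordinal(spec: SyntheticSpec) -> LabeledDataset:
    """Non-ordinal clouds on a scrambled grid in [1, 4]^2."""
    if spec.kind != "nonordinal":
        raise ValueError("spec.kind must be 'nonordinal'")
    centroids = np.array(spec.centroids, dtype=float)
    if (centroids < 1.0).any() or (centroids > 4.0).any():
        warnings.warn("centroid(s) outside the [1, 4]^2 grid range", stacklevel=2)
    rng = np.random.default_rng(spec.seed)
    return _assemble(centroids, spec, rng)


_GENERATORS = {"linear": gen_linear, "curved": gen_curved, "nonordinal": gen_nonordinal}


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Dispatch to the family named by ``spec.kind``."""
    return _GENERATORS[spec.kind](spec)
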