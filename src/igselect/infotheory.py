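"""Entropy, divergence and information-gain computations on discretized features.

All quantities are in bits (base-2 logarithms). Probabilities are empirical
frequencies from counts, with the standard convention 0*log(0) = 0; no
smoothing or priors are applied.

The central score is the information gain of a categorical feature A with
respect to the sample label C,

    IG(C, A) = H(C) - H(C|A),

which equals the Kullback-Leibler divergence from the observed joint
distribution p(a, c) to the product of its margins p(a)p(c). Classification
effectiveness rescales IG to a percentage of the label entropy,
CE = IG / H(C) x 100, so 100% means the feature's cells separate the classes
perfectly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LabelVector",
    "CategoricalFeature",
    "ContingencyTable",
    "ScoredSubset",
    "shannon_entropy",
    "conditional_entropy",
    "information_gain",
    "information_gain_kl",
    "kl_divergence",
    "delta_information_gain",
    "classification_effectiveness",
    "join_features",
]


class DegenerateLabelsError(ValueError):
    """Raised when an operation needs label diversity the input lacks."""


class DivergenceUndefinedError(ValueError):
    """Raised when KL(p|q) is undefined because q(x) = 0 where p(x) > 0."""


@dataclass(frozen=True)
class LabelVector:
    """Categorical class label per sample (the classification target C)."""

    labels: tuple
    classes: tuple = field(init=False)

    def __init__(self, labels: Sequence):
        labels = tuple(labels)
        if len(labels) == 0:
            raise ValueError("label vector must be non-empty")
        object.__setattr__(self, "labels", labels)
        seen: dict = {}
        for lab in labels:
            if lab not in seen:
                seen[lab] = None
        object.__setattr__(self, "classes", tuple(seen))

    def __len__(self) -> int:
        return len(self.labels)

    def counts(self) -> np.ndarray:
        """Class counts in ``classes`` order."""
        idx = {c: i for i, c in enumerate(self.classes)}
        out = np.zeros(len(self.classes), dtype=np.int64)
        for lab in self.labels:
            out[idx[lab]] += 1
        return out

    def codes(self) -> np.ndarray:
        """Integer codes in ``classes`` order."""
        idx = {c: i for i, c in enumerate(self.classes)}
        return np.fromiter((idx[l] for l in self.labels), dtype=np.int64, count=len(self.labels))


@dataclass(frozen=True)
class CategoricalFeature:
    """Per-sample discrete code for a gene or gene subset (a discretized A)."""

    values: tuple

    def __init__(self, values: Sequence):
        values = tuple(values)
        if len(values) == 0:
            raise ValueError("feature must be non-empty")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def arity(self) -> int:
        return len(set(self.values))

    def codes(self) -> np.ndarray:
        order: dict = {}
        for v in self.values:
            if v not in order:
                order[v] = len(order)
        return np.fromiter((order[v] for v in self.values), dtype=np.int64, count=len(self.values))


@dataclass(frozen=True)
class ContingencyTable:
    """Feature x class count matrix holding the empirical joint distribution."""

    counts: np.ndarray  # (feature arity, n classes)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or (counts < 0).any():
            raise ValueError("counts must be a non-negative 2-D integer matrix")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_observations(cls, labels: LabelVector, feature: CategoricalFeature) -> "ContingencyTable":
        if len(labels) != len(feature):
            raise ValueError(
                f"length mismatch: {len(labels)} labels vs {len(feature)} feature values"
            )
        fi = feature.codes()
        ci = labels.codes()
        counts = np.zeros((fi.max() + 1, ci.max() + 1), dtype=np.int64)
        np.add.at(counts, (fi, ci), 1)
        return cls(counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def joint(self) -> np.ndarray:
        return self.counts / self.n


def _entropy_from_counts(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def shannon_entropy(labels: LabelVector) -> float:
    """H(C) = -sum_c p(c) log2 p(c) over observed classes, in bits."""
    return _entropy_from_counts(labels.counts())


def conditional_entropy(labels: LabelVector, feature: CategoricalFeature) -> float:
    """H(C|A) = sum_a |C_{A=a}|/|C| * H(C_{A=a}), in bits.

    Empty cells contribute 0; the result lies in [0, H(C)].
    """
    table = ContingencyTable.from_observations(labels, feature)
    n = table.n
    out = 0.0
    for row in table.counts:
        nr = row.sum()
        if nr > 0:
            out += (nr / n) * _entropy_from_counts(row)
    return out


def information_gain(labels: LabelVector, feature: CategoricalFeature) -> float:
    """IG(C, A) = H(C) - H(C|A), in bits (non-negative up to rounding)."""
    return shannon_entropy(labels) - conditional_entropy(labels, feature)


def information_gain_kl(table: ContingencyTable) -> float:
    """IG as KL from the joint to the product of margins, from a count table.

    Independent route used to cross-check :func:`information_gain`; both are
    equal analytically, differing only in float summation order.
    """
    n = table.n
    if n == 0:
        return 0.0
    joint = table.joint()
    pr = table.row_marginals / n
    pc = table.col_marginals / n
    out = 0.0
    for i in range(joint.shape[0]):
        for j in range(joint.shape[1]):
            pij = joint[i, j]
            if pij > 0:
                out -= pij * np.log2(pr[i] * pc[j] / pij)
    return float(out)


def kl_divergence(p: Sequence[float], q: Sequence[float], allow_infinite: bool = False) -> float:
    """KL(p|q) = -sum p(x) log2(q(x)/p(x)), in bits.

    Terms with p(x) = 0 contribute 0. If q(x) = 0 somewhere p(x) > 0 the
    divergence is undefined; by default this raises
    :class:`DivergenceUndefinedError` rather than silently returning infinity
    (pass ``allow_infinite=True`` to get ``inf``).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have equal length")
    for vec, name in ((p, "p"), (q, "q")):
        if (vec < 0).any():
            raise ValueError(f"{name} has negative entries")
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} does not sum to 1 (got {vec.sum()!r})")
    mask = p > 0
    if (q[mask] == 0).any():
        if allow_infinite:
            return float("inf")
        raise DivergenceUndefinedError("q(x) = 0 where p(x) > 0; KL(p|q) is undefined")
    return float(-(p[mask] * np.log2(q[mask] / p[mask])).sum())


def delta_information_gain(base_ig: float, extended_ig: float) -> float:
    """IG improvement from extending a subset: extended - base.

    May be negative: re-running fuzzy c-means on a larger gene block can lose
    information. Acceptance decisions belong to the search layer.
    """
    if not (np.isfinite(base_ig) and np.isfinite(extended_ig)):
        raise ValueError("information gains must be finite")
    return extended_ig - base_ig


def classification_effectiveness(ig: float, label_entropy: float) -> float:
    """CE = IG / H(C) x 100, in percent of the label entropy."""
    if label_entropy <= 0:
        raise DegenerateLabelsError("label entropy must be positive to define CE")
    if ig < -1e-9 or ig > label_entropy + 1e-9:
        raise ValueError(f"IG {ig} outside [0, H(C)={label_entropy}]")
    return min(max(ig, 0.0), label_entropy) / label_entropy * 100.0


def join_features(a: CategoricalFeature, b: CategoricalFeature) -> CategoricalFeature:
    """Exact categorical join (cross-tabulation) of two features.

    The join refines both inputs, so IG(C, join(a, b)) >= IG(C, a); this is a
    property of exact joins and does NOT hold for re-clustered blocks.
    """
    if len(a) != len(b):
        raise ValueError("features must have equal length")
    return CategoricalFeature(tuple(zip(a.values, b.values)))


@dataclass(frozen=True)
class ScoredSubset:
    """A gene-index set S with its information gain (bits) and CE (%)."""

    genes: tuple
    ig: float
    ce: float

    def __post_init__(self):
        genes = tuple(sorted(set(self.genes)))
        if len(genes) == 0:
            raise ValueError("gene subset must be non-empty")
        if len(genes) != len(tuple(self.genes)):
            raise ValueError("gene subset has duplicate indices")
        object.__setattr__(self, "genes", genes)
        if self.ig < -1e-9:
            raise ValueError("information gain must be non-negative")
        if not -1e-7 <= self.ce <= 100 + 1e-7:
            raise ValueError("classification effectiveness must lie in [0, 100]")

    @property
    def size(self) -> int:
        return len(self.genes)
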