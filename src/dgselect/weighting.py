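"""Gain-ratio attribute weighting.

Every attribute is ranked exactly once at the start of a run by the gain
ratio of its best single binary split (C4.5 style): the continuous values
are sorted, candidate thresholds sit at midpoints between consecutive
distinct values, the threshold maximizing information gain is chosen, and
the rank is information gain divided by the split's intrinsic (split)
information. Ranks are normalized into weights summing to 1; the weights
steer mutation and recombination toward informative attributes.

All entropies are in bits (log base 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["WeightTable", "gain_ratio", "compute_weights"]

logger = logging.getLogger(__name__)


def _entropy_rows(p: np.ndarray) -> np.ndarray:
    """Shannon entropy (bits) of each row of a matrix of probabilities."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=-1)


def gain_ratio(values, labels) -> float:
    """Gain ratio of the best single binary split of a continuous attribute.

    Returns 0.0 for a constant attribute (no split exists). The threshold
    with the highest information gain is used; on ties the lowest threshold
    wins, making the statistic deterministic.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.ndim != 1 or values.shape != labels.shape:
        raise ValueError(
            f"values and labels must be equal-length vectors, got shapes "
            f"{values.shape} and {labels.shape}"
        )
    n = values.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    classes, codes = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError("labels contain a single class; gain ratio undefined")

    order = np.argsort(values, kind="stable")
    v = values[order]
    y = codes[order]

    # candidate split after position i wherever the sorted value increases
    cut = np.nonzero(np.diff(v) > 0)[0]
    if cut.size == 0:
        return 0.0

    onehot = np.zeros((n, classes.size))
    onehot[np.arange(n), y] = 1.0
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]

    n_left = (cut + 1).astype(float)
    n_right = n - n_left
    left = cum[cut]
    right = total[None, :] - left

    h_parent = _entropy_rows(total / n)
    h_left = _entropy_rows(left / n_left[:, None])
    h_right = _entropy_rows(right / n_right[:, None])
    ig = h_parent - (n_left / n) * h_left - (n_right / n) * h_right

    best = int(np.argmax(ig))  # first maximum -> lowest threshold
    p = n_left[best] / n
    intrinsic = float(_entropy_rows(np.array([p, 1.0 - p])))
    if intrinsic <= 0.0:
        return 0.0
    return float(max(ig[best], 0.0) / intrinsic)


@dataclass(frozen=True)
class WeightTable:
    """Per-attribute gain-ratio ranks and normalized weights.

    ``attribute_ids`` are stored in descending-weight order (stable ties
    broken by attribute ID) so callers can iterate from strongest to
    weakest. Computed once per run and never mutated afterward.
    """

    attribute_ids: tuple[str, ...]
    ranks: np.ndarray
    weights: np.ndarray
    _index: dict = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.attribute_ids) != len(self.ranks) or len(self.ranks) != len(
            self.weights
        ):
            raise ValueError("attribute_ids, ranks and weights must align")
        object.__setattr__(
            self, "_index", {a: i for i, a in enumerate(self.attribute_ids)}
        )

    @classmethod
    def from_ranks(cls, attribute_ids, ranks) -> "WeightTable":
        """Normalize raw ranks into weights and order attributes by weight."""
        ids = tuple(attribute_ids)
        ranks = np.asarray(ranks, dtype=float)
        if ranks.ndim != 1 or len(ids) != ranks.shape[0]:
            raise ValueError("one rank per attribute required")
        if len(set(ids)) != len(ids):
            raise ValueError("attribute IDs must be unique")
        total = float(ranks.sum())
        if total <= 0.0:
            raise ValueError("all ranks are zero; use uniform weights instead")
        weights = ranks / total
        order = sorted(range(len(ids)), key=lambda i: (-weights[i], ids[i]))
        return cls(
            attribute_ids=tuple(ids[i] for i in order),
            ranks=ranks[order],
            weights=weights[order],
        )

    @classmethod
    def uniform(cls, attribute_ids) -> "WeightTable":
        ids = tuple(sorted(attribute_ids))
        m = len(ids)
        return cls(
            attribute_ids=ids,
            ranks=np.ones(m),
            weights=np.full(m, 1.0 / m),
        )

    @property
    def sum(self) -> float:
        """Total of the raw ranks (the normalizer)."""
        return float(self.ranks.sum())

    def weight(self, attribute_id: str) -> float:
        return float(self.weights[self._index[attribute_id]])

    def rank(self, attribute_id: str) -> float:
        return float(self.ranks[self._index[attribute_id]])

    def __contains__(self, attribute_id: object) -> bool:
        return attribute_id in self._index

    def __len__(self) -> int:
        return len(self.attribute_ids)


def compute_weights(matrix, labels, attribute_ids=None) -> WeightTable:
    """Rank every attribute (column of ``matrix``) by gain ratio and
    normalize into a :class:`WeightTable`.

    If every rank is zero (e.g. an all-constant matrix) the table falls back
    to uniform weights with a logged warning, so downstream operators still
    have a well-defined ordering.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"matrix must be 2-D (samples x attributes), got {X.ndim}-D")
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError(
            f"label count {labels.shape[0]} != sample count {X.shape[0]}"
        )
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to weight attributes")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    m = X.shape[1]
    if attribute_ids is None:
        attribute_ids = tuple(f"a{i}" for i in range(m))
    else:
        attribute_ids = tuple(attribute_ids)
        if len(attribute_ids) != m:
            raise ValueError("one attribute ID per column required")

    ranks = np.array([gain_ratio(X[:, j], labels) for j in range(m)])
    if ranks.sum() <= 0.0:
        logger.warning(
            "all gain-ratio ranks are zero; falling back to uniform weights"
        )
        return WeightTable.uniform(attribute_ids)
    return WeightTable.from_ranks(attribute_ids, ranks)
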