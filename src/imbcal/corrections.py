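"""Class-imbalance corrections: random under-/over-sampling and SMOTE.

Each correction takes a training :class:`~imbcal.datagen.Dataset` and
returns a new dataset with exactly balanced classes.  The minority class is
the less frequent outcome value in the input (ties mean the data are already
balanced and RUS/ROS return it unchanged up to resampling noise of size 0).

SMOTE synthesises minority rows by convex interpolation between a minority
row and one of its k nearest minority neighbours (Euclidean distance,
self excluded, ties broken by row index).  Synthetic points are allocated as
evenly as possible across minority rows: ``floor(needed / n_min)`` each plus
one extra for a random subset, giving exact balance.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial.distance import cdist

from .datagen import Dataset

__all__ = [
    "CorrectionError",
    "random_undersample",
    "random_oversample",
    "smote",
    "smote_round_ordinal",
]

logger = logging.getLogger(__name__)

DEFAULT_K = 5  # SMOTE nearest-neighbour count


class CorrectionError(ValueError):
    """The dataset cannot be corrected (e.g. only one class present)."""


def _split_classes(data: Dataset) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Row indices of (minority, majority) and their labels."""
    y = data.outcome
    n1 = int(y.sum())
    n0 = y.size - n1
    if n0 == 0 or n1 == 0:
        raise CorrectionError("both outcome classes must be present")
    min_label = 1 if n1 <= n0 else 0
    maj_label = 1 - min_label
    return (
        np.flatnonzero(y == min_label),
        np.flatnonzero(y == maj_label),
        min_label,
        maj_label,
    )


def _take(data: Dataset, idx: np.ndarray) -> Dataset:
    pi = None if data.true_probability is None else data.true_probability[idx]
    return Dataset(data.predictors[idx], data.outcome[idx], pi)


def random_undersample(data: Dataset, rng: np.random.Generator) -> Dataset:
    """Discard random majority rows until the classes have equal size.

    Minority rows are retained unchanged; every output row is a distinct row
    of the input.  The output has 2 * (minority count) rows.
    """
    min_idx, maj_idx, *_ = _split_classes(data)
    keep_maj = rng.choice(maj_idx, size=min_idx.size, replace=False)
    idx = np.sort(np.concatenate([min_idx, keep_maj]))
    return _take(data, idx)


def random_oversample(data: Dataset, rng: np.random.Generator) -> Dataset:
    """Resample minority rows with replacement until the classes balance.

    All original rows are retained; the extra minority rows are exact
    duplicates of original minority rows.  The output has
    2 * (majority count) rows.
    """
    min_idx, maj_idx, *_ = _split_classes(data)
    n_extra = maj_idx.size - min_idx.size
    extra = rng.choice(min_idx, size=n_extra, replace=True)
    idx = np.concatenate([np.arange(data.n), extra])
    return _take(data, idx)


def smote(
    data: Dataset, k: int = DEFAULT_K, rng: np.random.Generator | None = None
) -> Dataset:
    """Synthetic Minority Oversampling: interpolated minority rows.

    For each synthetic point, a minority row ``x_i`` and one of its ``k``
    nearest minority neighbours ``x_nn`` (Euclidean distance in predictor
    space, self excluded) are combined as ``x_i + u * (x_nn - x_i)`` with
    ``u ~ Uniform(0, 1)``.  Original rows are retained and the output is
    exactly balanced at the majority count.

    If ``k`` is at least the minority count, it is clamped to
    ``minority count - 1`` with a logged warning.
    """
    if rng is None:
        raise TypeError("smote requires an explicit rng")
    if k < 1:
        raise ValueError("k must be >= 1")
    min_idx, maj_idx, min_label, _ = _split_classes(data)
    n_min = min_idx.size
    if n_min < 2:
        raise CorrectionError("SMOTE needs at least 2 minority rows")
    if k >= n_min:
        logger.warning(
            "SMOTE k=%d >= minority count %d; clamping to %d", k, n_min, n_min - 1
        )
        k = n_min - 1

    n_needed = maj_idx.size - n_min
    if n_needed == 0:
        return _take(data, np.arange(data.n))

    Xmin = data.predictors[min_idx]
    # k nearest minority neighbours, self excluded, distance ties by row index
    d = cdist(Xmin, Xmin)
    np.fill_diagonal(d, np.inf)
    part = np.argpartition(d, k - 1, axis=1)[:, :k]
    pd_ = np.take_along_axis(d, part, axis=1)
    nn = np.take_along_axis(part, np.lexsort((part, pd_), axis=1), axis=1)

    # even allocation: floor(needed/n_min) per row, one extra for a subset
    base, rem = divmod(n_needed, n_min)
    counts = np.full(n_min, base, dtype=int)
    if rem:
        counts[rng.choice(n_min, size=rem, replace=False)] += 1
    donors = np.repeat(np.arange(n_min), counts)
    chosen_nn = nn[donors, rng.integers(0, k, size=n_needed)]
    u = rng.random((n_needed, 1))
    X_syn = Xmin[donors] + u * (Xmin[chosen_nn] - Xmin[donors])

    X_out = np.vstack([data.predictors, X_syn])
    y_out = np.concatenate(
        [data.outcome, np.full(n_needed, min_label, dtype=np.int64)]
    )
    return Dataset(X_out, y_out)


def smote_round_ordinal(
    data: Dataset,
    ordinal_columns: dict[int, tuple[int, int]],
    k: int = DEFAULT_K,
    rng: np.random.Generator | None = None,
) -> Dataset:
    """SMOTE followed by rounding of ordinal predictor columns.

    ``ordinal_columns`` maps a column index to its (low, high) integer range;
    interpolated values in those columns are rounded to the nearest integer
    and clipped to the range.  Used for fixtures with ordinal predictors
    (e.g. a papillation count), where plain interpolation would fabricate
    fractional category levels.
    """
    out = smote(data, k=k, rng=rng)
    X = out.predictors
    for col, (lo, hi) in ordinal_columns.items():
        X[:, col] = np.clip(np.rint(X[:, col]), lo, hi)
    return Dataset(X, out.outcome)
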