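"""Class-imbalance resampling: SMOTE oversampling and random undersampling.

SMOTE raises each minority class to a target count by interpolating between
a randomly chosen class member and one of its ``k_neighbors`` nearest
same-class neighbours (Euclidean distance):

    x_new = x_i + u * (x_j - x_i),   u ~ Uniform(0, 1)

The random undersampler then draws, independently per class and *with
replacement*, a balanced number of rows.  Both steps are fully determined
by their random states.

Degenerate cases are handled explicitly rather than erroring: a class
already at or above its SMOTE target passes through unchanged, and a class
too small for neighbour search (count <= k_neighbors) falls back to
resampling its own rows with replacement.  Both fallbacks are logged.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    targets: dict,
    k_neighbors: int = 3,
    random_state: int = 0,
):
    """Oversample each class up to ``targets[class]`` rows.

    Original rows are kept verbatim (in input order, grouped as-is) and
    synthetic rows are appended per class.  Classes absent from ``targets``
    pass through unchanged.

    Returns ``(X_out, y_out)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(random_state)
    xs = [X]
    ys = [y]
    for cls in sorted(targets, key=str):
        target = int(targets[cls])
        if target <= 0:
            raise ValueError(f"SMOTE target for {cls!r} must be positive")
        idx = np.flatnonzero(y == cls)
        n = idx.size
        if n == 0 or n >= target:
            if n > target:
                logger.info("class %r count %d above SMOTE target %d; passed through", cls, n, target)
            continue
        need = target - n
        Xc = X[idx]
        if n <= k_neighbors:
            logger.info(
                "class %r has %d rows (<= k_neighbors=%d); falling back to "
                "resampling with replacement", cls, n, k_neighbors,
            )
            pick = rng.integers(0, n, size=need)
            synth = Xc[pick]
        else:
            nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xc)
            # Column 0 is the point itself; keep the k true neighbours.
            neigh = nn.kneighbors(Xc, return_distance=False)[:, 1:]
            base = rng.integers(0, n, size=need)
            which = rng.integers(0, k_neighbors, size=need)
            partner = neigh[base, which]
            u = rng.random(need)[:, None]
            synth = Xc[base] + u * (Xc[partner] - Xc[base])
        xs.append(synth)
        ys.append(np.full(need, cls, dtype=y.dtype))
    return np.concatenate(xs), np.concatenate(ys)


def random_undersample(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    replacement: bool = True,
    target: int | None = None,
):
    """Draw a balanced subsample: ``target`` rows from every class.

    ``target`` defaults to the smallest class count.  Sampling is with
    replacement by default, seeded per call so an ensemble can vary only
    the seed between members.

    Returns ``(X_out, y_out)`` with classes in sorted order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if target is None:
        target = int(counts.min())
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        if replacement:
            pick = rng.choice(idx, size=target, replace=True)
        else:
            if idx.size < target:
                raise ValueError(
                    f"class {cls!r} has {idx.size} rows < target {target} "
                    "and replacement=False"
                )
            pick = rng.choice(idx, size=target, replace=False)
        xs.append(X[pick])
        ys.append(y[pick])
    return np.concatenate(xs), np.concatenate(ys)
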