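"""Heart-rate to R-R interval conversion and Lorenz (Poincaré) plot statistics.

A wrist-worn tracker reports heart rate in beats per minute on a coarse
cadence (nominally every 15 s).  Each sample is converted to an equivalent
R-R interval, RRI = 60000 / bpm milliseconds, and consecutive RRIs are
scattered as points (RRI(t), RRI(t+1)).  The cloud's spread along the
identity axis y = x (``delta_x``) and the anti-identity axis y = -x
(``delta_neg_x``) summarise heart-rate variability; the fitted ellipse area

    S = pi * delta_x * delta_neg_x

shrinks when the sympathetic branch dominates (high physical stress) and
grows under parasympathetic (relaxed) dominance.

Conventions
-----------
* Standard deviations use the population divisor ``n``; flip
  :data:`SD_DDOF` to 1 for the sample convention.
* Projections are centred about their own mean before taking the spread, so
  a constant series always yields area 0.
* Pairs are only formed between samples closer than ``max_gap`` seconds,
  so sensor dropouts and interval boundaries never bridge a pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError

#: Milliseconds in one minute; the numerator of the bpm -> RRI conversion.
MS_PER_MINUTE = 60_000.0

#: Divisor convention for all spreads in this module (0 = population).
SD_DDOF = 0

#: Pairs are dropped when consecutive samples are farther apart than this
#: (seconds).  Two nominal 15 s periods: a single missing sample breaks the
#: chain rather than producing a spurious 30 s "consecutive" pair.
DEFAULT_MAX_GAP_S = 30.0

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class LorenzStats:
    """Ellipse summary of a set of consecutive-RRI pairs.

    Attributes
    ----------
    n_pairs : number of (RRI(t), RRI(t+1)) points.
    m : mean signed distance from the origin along y = x, i.e. the mean of
        (a + b) / sqrt(2), in ms.  Stored for completeness; no downstream
        feature consumes it.
    delta_x : spread of the y = x projections (ms).
    delta_neg_x : spread of the y = -x projections (ms).
    area : pi * delta_x * delta_neg_x (ms^2).
    """

    n_pairs: int
    m: float
    delta_x: float
    delta_neg_x: float
    area: float


def hr_to_rri(bpm):
    """Convert heart rate (beats/min) to an R-R interval in milliseconds.

    Accepts a scalar or array; 60 bpm maps to 1000 ms, 120 bpm to 500 ms.

    Raises
    ------
    DomainError
        If any value is non-positive or non-finite.
    """
    arr = np.asarray(bpm, dtype=float)
    if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr <= 0)):
        raise DomainError("bpm must be finite and > 0")
    out = MS_PER_MINUTE / arr
    if np.isscalar(bpm) or np.ndim(bpm) == 0:
        return float(out)
    return out


def rri_to_hr(rri_ms):
    """Inverse of :func:`hr_to_rri` (bpm = 60000 / rri_ms)."""
    arr = np.asarray(rri_ms, dtype=float)
    if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr <= 0)):
        raise DomainError("rri_ms must be finite and > 0")
    out = MS_PER_MINUTE / arr
    if np.isscalar(rri_ms) or np.ndim(rri_ms) == 0:
        return float(out)
    return out


def series_to_rri(samples: pd.DataFrame) -> pd.DataFrame:
    """Convert a heart-rate series to an RRI series.

    Parameters
    ----------
    samples : DataFrame with columns ``timestamp`` (datetime64) and ``bpm``.
        Timestamps must be strictly increasing.

    Returns
    -------
    DataFrame with columns ``timestamp`` and ``rri_ms``, same row order.
    """
    if "timestamp" not in samples.columns or "bpm" not in samples.columns:
        raise ValidationError("heart-rate frame needs 'timestamp' and 'bpm' columns")
    ts = pd.to_datetime(samples["timestamp"])
    if len(ts) > 1:
        diffs = ts.to_numpy()
        bad = np.flatnonzero(diffs[1:] <= diffs[:-1])
        if bad.size:
            raise ValidationError(
                "timestamps not strictly increasing at indices "
                f"{(bad + 1).tolist()[:10]}"
            )
    return pd.DataFrame(
        {"timestamp": ts.to_numpy(), "rri_ms": hr_to_rri(samples["bpm"].to_numpy())}
    )


def build_pairs(
    rri: pd.DataFrame, max_gap_s: float = DEFAULT_MAX_GAP_S
) -> np.ndarray:
    """Form consecutive-RRI pairs, respecting the maximum-gap rule.

    Parameters
    ----------
    rri : DataFrame with ``timestamp`` and ``rri_ms``, sorted by time.
    max_gap_s : pairs are formed only between consecutive samples whose
        timestamps differ by at most this many seconds.

    Returns
    -------
    ndarray of shape (n_pairs, 2); empty (0, 2) array for < 2 samples.
    """
    values = np.asarray(rri["rri_ms"], dtype=float)
    if values.size < 2:
        return np.empty((0, 2), dtype=float)
    ts = pd.to_datetime(rri["timestamp"]).to_numpy().astype("datetime64[ns]")
    gaps_s = np.diff(ts).astype("timedelta64[ns]").astype(np.int64) / 1e9
    keep = gaps_s <= max_gap_s
    return np.column_stack([values[:-1][keep], values[1:][keep]])


def pairs_from_values(values: np.ndarray) -> np.ndarray:
    """All consecutive pairs of a gap-free RRI value array."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return np.empty((0, 2), dtype=float)
    return np.column_stack([values[:-1], values[1:]])


def lorenz_stats(pairs: np.ndarray) -> Optional[LorenzStats]:
    """Compute the Lorenz-plot ellipse summary of a pair set.

    Each point (a, b) is projected onto the identity axis, u = (a+b)/sqrt(2),
    and the anti-identity axis, v = (a-b)/sqrt(2).  ``delta_x``/``delta_neg_x``
    are the (population) standard deviations of u and v; the ellipse area is
    pi * delta_x * delta_neg_x.

    Returns ``None`` (insufficient data) for fewer than 2 pairs.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or (pairs.size and pairs.shape[1] != 2):
        raise ValidationError("pairs must be an (n, 2) array")
    n = pairs.shape[0]
    if n < 2:
        return None
    u = (pairs[:, 0] + pairs[:, 1]) / _SQRT2
    v = (pairs[:, 0] - pairs[:, 1]) / _SQRT2
    dx = float(np.std(u, ddof=SD_DDOF))
    dnx = float(np.std(v, ddof=SD_DDOF))
    return LorenzStats(
        n_pairs=n,
        m=float(np.mean(u)),
        delta_x=dx,
        delta_neg_x=dnx,
        area=float(np.pi * dx * dnx),
    )


def lorenz_area(pairs: np.ndarray) -> Optional[float]:
    """Ellipse area of a pair set, or ``None`` below 2 pairs."""
    stats = lorenz_stats(pairs)
    return None if stats is None else stats.area


def rri_variance(rri_ms) -> Optional[float]:
    """Population variance of RRI values (ms^2); ``None`` below 2 samples."""
    values = _values(rri_ms)
    if values.size < 2:
        return None
    return float(np.var(values, ddof=SD_DDOF))


def mean_rri(rri_ms) -> Optional[float]:
    """Arithmetic mean RRI (ms); ``None`` for an empty series."""
    values = _values(rri_ms)
    if values.size < 1:
        return None
    return float(np.mean(values))


def _values(rri_ms) -> np.ndarray:
    if isinstance(rri_ms, pd.DataFrame):
        return np.asarray(rri_ms["rri_ms"], dtype=float)
    return np.asarray(rri_ms, dtype=float)
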