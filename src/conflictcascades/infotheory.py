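"""Plug-in information measures on binary time series and shuffle tests.

Lag-1 self mutual information

    I[X_t; X_{t+1}] = sum_{x_t, x_{t+1}} q(x_t, x_{t+1})
                      log2[ q(x_t, x_{t+1}) / (q(x_t) q(x_{t+1})) ]

detects self-influence of a site, and transfer entropy

    T[X; Y] = sum_{x_t, x_{t+1}, y_t} q(x_t, x_{t+1}, y_t)
              log2[ q(x_{t+1} | x_t, y_t) / q(x_{t+1} | x_t) ]

measures how much the present of a neighboring site Y improves prediction
of X's future beyond X's own past; it is zero exactly when
q(x_{t+1}|x_t,y_t) = q(x_{t+1}|x_t) on all attained states. All
probabilities are plug-in (empirical) estimates from transition counts;
logs are base 2 (bits) and 0*log 0 := 0.

Because plug-in estimates on finite series are biased upward, a measured
value counts as signal only if it beats the distribution obtained by
permuting the series uniformly in time: significance at level ``p_cut``
requires at least a fraction 1 - p_cut of time-shuffled values to be
strictly smaller than the measured value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_LN2 = math.log(2.0)


def _as_binary(x) -> np.ndarray:
    x = np.asarray(x)
    if x.dtype != np.int8:
        x = x.astype(np.int8)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if x.size < 2:
        raise ValueError("series must have length >= 2")
    if ((x != 0) & (x != 1)).any():
        raise ValueError("series must be binary (0/1)")
    return x


def lag1_counts(x: np.ndarray) -> np.ndarray:
    """2x2 counts over (x_t, x_{t+1})."""
    idx = 2 * x[:-1] + x[1:]
    return np.bincount(idx, minlength=4).reshape(2, 2)


def te_counts(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """2x2x2 counts over (x_t, x_{t+1}, y_t)."""
    idx = 4 * x[:-1] + 2 * x[1:] + y[:-1]
    return np.bincount(idx, minlength=8).reshape(2, 2, 2)


def mi_from_counts(counts: np.ndarray) -> float:
    """Plug-in mutual information (bits) from a 2x2 joint count table."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        return 0.0
    q = counts / n
    qx = q.sum(axis=1, keepdims=True)
    qy = q.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.where(q > 0, np.log(q) - np.log(qx * qy), 0.0)
    return float(max(np.sum(q * log_ratio) / _LN2, 0.0))


def te_from_counts(counts: np.ndarray) -> float:
    """Plug-in transfer entropy (bits) from 2x2x2 (x_t, x_{t+1}, y_t) counts."""
    c = np.asarray(counts, dtype=float)  # axes: (x_t, x_{t+1}, y_t)
    n = c.sum()
    if n <= 0:
        return 0.0
    c_xy = c.sum(axis=1, keepdims=True)      # counts over (x_t, ., y_t)
    c_xx1 = c.sum(axis=2, keepdims=True)     # counts over (x_t, x_{t+1}, .)
    c_x = c.sum(axis=(1, 2), keepdims=True)  # counts over x_t
    with np.errstate(divide="ignore", invalid="ignore"):
        # log [ q(x1|x,y) / q(x1|x) ] = log[c/c_xy] - log[c_xx1/c_x]
        log_ratio = np.where(
            c > 0, np.log(c) - np.log(c_xy) - np.log(c_xx1) + np.log(c_x), 0.0)
    return float(max(np.sum((c / n) * log_ratio) / _LN2, 0.0))


def mutual_information(x) -> float:
    """Lag-1 self mutual information of a binary series, in bits.

    A constant series carries no information about itself and returns 0.
    """
    x = _as_binary(x)
    return mi_from_counts(lag1_counts(x))


def transfer_entropy(x, y) -> float:
    """Transfer entropy from source ``y`` to target ``x`` (bits), history 1."""
    x = _as_binary(x)
    y = _as_binary(y)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    return te_from_counts(te_counts(x, y))


def _shuffled_te(x: np.ndarray, y: np.ndarray, n_shuffles: int,
                 rng: np.random.Generator) -> np.ndarray:
    """TE values for n_shuffles uniform time permutations of the source y.

    Vectorized: for fixed x, the 8-state counts depend on y only through the
    sum of permuted y over the four (x_t, x_{t+1}) strata.
    """
    pair_idx = 2 * x[:-1] + x[1:]
    masks = [pair_idx == k for k in range(4)]
    n_pairs = x.size - 1
    # each row is y permuted over the full series, truncated to y_t positions
    Y = rng.permuted(np.tile(y, (n_shuffles, 1)), axis=1)[:, :n_pairs]
    out = np.empty(n_shuffles)
    counts = np.empty((n_shuffles, 2, 2, 2))
    for k in range(4):
        ones = Y[:, masks[k]].sum(axis=1)
        tot = masks[k].sum()
        counts[:, k // 2, k % 2, 1] = ones
        counts[:, k // 2, k % 2, 0] = tot - ones
    c = counts
    n = n_pairs
    c_xy = c.sum(axis=2, keepdims=True)
    c_xx1 = c.sum(axis=3, keepdims=True)
    c_x = c.sum(axis=(2, 3), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.where(c > 0,
                             np.log(np.where(c > 0, c, 1.0)) - np.log(np.where(c_xy > 0, c_xy, 1.0))
                             - np.log(np.where(c_xx1 > 0, c_xx1, 1.0)) + np.log(np.where(c_x > 0, c_x, 1.0)),
                             0.0)
    np.maximum((c * log_ratio).sum(axis=(1, 2, 3)) / (n * _LN2), 0.0, out=out)
    return out


def _shuffled_mi(x: np.ndarray, n_shuffles: int, rng: np.random.Generator) -> np.ndarray:
    """Lag-1 MI values for n_shuffles uniform time permutations of x."""
    X = rng.permuted(np.tile(x, (n_shuffles, 1)), axis=1)
    a = X[:, :-1].astype(np.int64)
    b = X[:, 1:].astype(np.int64)
    n = x.size - 1
    n11 = (a & b).sum(axis=1)
    n1_ = a.sum(axis=1)
    n_1 = b.sum(axis=1)
    c = np.empty((n_shuffles, 2, 2))
    c[:, 1, 1] = n11
    c[:, 1, 0] = n1_ - n11
    c[:, 0, 1] = n_1 - n11
    c[:, 0, 0] = n - n1_ - n_1 + n11
    q = c / n
    qx = q.sum(axis=2, keepdims=True)
    qy = q.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.where(q > 0,
                             np.log(np.where(q > 0, q, 1.0)) - np.log(np.where(qx * qy > 0, qx * qy, 1.0)),
                             0.0)
    return np.maximum((q * log_ratio).sum(axis=(1, 2)) / _LN2, 0.0)


@dataclass
class SignificanceResult:
    value: float
    exceedance: float
    significant: bool
    degenerate: bool = False


def shuffle_significance(statistic, x, y=None, n_shuffles: int = 100,
                         p_cut: float = 1 / 20,
                         rng: np.random.Generator | None = None) -> SignificanceResult:
    """Time-shuffle permutation test for an information statistic.

    Parameters
    ----------
    statistic : "te", "mi", or callable
        For ``"te"`` the source ``y`` is permuted uniformly in time with the
        target ``x`` untouched; for ``"mi"`` the single series ``x`` is
        permuted. A callable must accept ``(x, y)`` (or ``(x,)``) and is
        evaluated on the same permutation scheme (pluggable measure hook).
    n_shuffles : int
        Must be at least ceil(1/p_cut), otherwise the requested level is
        unattainable and a ValueError is raised.

    Returns the observed value, the exceedance fraction
    (#shuffled values >= observed)/n_shuffles, and the significance flag
    ``exceedance <= p_cut`` (ties count against significance). A constant
    input series short-circuits to an insignificant, degenerate result.
    """
    if not (0 < p_cut <= 1):
        raise ValueError("p_cut must lie in (0, 1]")
    if n_shuffles < math.ceil(1 / p_cut):
        raise ValueError(
            f"n_shuffles={n_shuffles} cannot attain p_cut={p_cut}; "
            f"need at least {math.ceil(1 / p_cut)}")
    rng = np.random.default_rng(rng)
    x = _as_binary(x)
    y = _as_binary(y) if y is not None else None

    if statistic == "te":
        if y is None:
            raise ValueError("transfer entropy needs a source series y")
        if len({int(v) for v in x}) < 2 or len({int(v) for v in y}) < 2:
            return SignificanceResult(0.0, 1.0, False, degenerate=True)
        observed = transfer_entropy(x, y)
        shuffled = _shuffled_te(x, y, n_shuffles, rng)
    elif statistic == "mi":
        if len({int(v) for v in x}) < 2:
            return SignificanceResult(0.0, 1.0, False, degenerate=True)
        observed = mutual_information(x)
        shuffled = _shuffled_mi(x, n_shuffles, rng)
    elif callable(statistic):
        args = (x,) if y is None else (x, y)
        observed = float(statistic(*args))
        shuffled = np.empty(n_shuffles)
        for i in range(n_shuffles):
            if y is None:
                shuffled[i] = statistic(rng.permutation(x))
            else:
                shuffled[i] = statistic(x, rng.permutation(y))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    exceedance = float(np.mean(shuffled >= observed))
    return SignificanceResult(value=float(observed), exceedance=exceedance,
                              significant=exceedance <= p_cut)
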