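"""Permutation-tested correlation between aging and expansion profiles.

With one value per parcel for each of two maps (e.g. |t| of age-related GM
decline and z-scored relative expansion), the parcels are the exchangeable
units: the null distribution of Pearson's r is built by permuting one
vector's parcel assignment.  The add-one estimator
p = (1 + #extreme) / (1 + n_perm) keeps the test valid at any permutation
count; for small vectors all permutations are enumerated exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

EXHAUSTIVE_MAX_N = 8  # 8! = 40320 permutations; enumerate below this size

Tail = Literal["two_sided", "greater", "less"]


@dataclass
class AssociationResult:
    r: float
    p_perm: float
    n_perm: int
    n_parcels: int
    tail: str
    seed: int | None
    exhaustive: bool
    null_r: np.ndarray | None = None


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("zero variance in one of the inputs")
    return float(xc @ yc / denom)


def _tail_count(null: np.ndarray, observed: float, tail: Tail) -> int:
    if tail == "two_sided":
        return int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    if tail == "greater":
        return int(np.sum(null >= observed - 1e-12))
    if tail == "less":
        return int(np.sum(null <= observed + 1e-12))
    raise ValueError(f"unknown tail: {tail!r}")


def _null_correlations(
    x: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Pearson r of x against row-wise permutations of y, vectorized."""
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    out = np.empty(n_perm)
    chunk = max(1, min(n_perm, 20000))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)
        out[done:done + b] = (yc[idx] @ xc) / denom
        done += b
    return out


def permutation_correlation(
    x,
    y,
    n_perm: int = 100000,
    tail: Tail = "two_sided",
    seed: int | None = None,
    keep_null: bool = False,
    method: Literal["auto", "exhaustive", "montecarlo"] = "auto",
) -> AssociationResult:
    """Pearson correlation across parcels with a permutation p-value.

    For up to 8 parcels every permutation of ``y`` is enumerated and the
    p-value is exact (the identity permutation contributes the observed
    statistic, so p >= 1/n!).  Otherwise ``n_perm`` random permutations are
    drawn and the add-one Monte-Carlo estimator is used, so p >= 1/(n_perm+1)
    and the test never reports zero.  ``method`` forces one of the two
    routes, e.g. to cross-check the Monte-Carlo estimate against the exact
    enumeration on a small vector.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must be aligned parcel vectors")
    if x.size < 3:
        raise ValueError("need at least 3 parcels")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    r_obs = _pearson(x, y)

    if method == "exhaustive" and x.size > EXHAUSTIVE_MAX_N:
        raise ValueError(f"exhaustive enumeration limited to n <= {EXHAUSTIVE_MAX_N}")
    use_exhaustive = (
        method == "exhaustive"
        or (method == "auto" and x.size <= EXHAUSTIVE_MAX_N)
    )
    if use_exhaustive:
        perms = np.array(list(itertools.permutations(range(x.size))))
        yc = y - y.mean()
        xc = x - x.mean()
        denom = np.sqrt((xc @ xc) * (yc @ yc))
        null = (yc[perms] @ xc) / denom
        p = _tail_count(null, r_obs, tail) / null.size
        return AssociationResult(
            r=r_obs, p_perm=float(p), n_perm=int(null.size), n_parcels=x.size,
            tail=tail, seed=None, exhaustive=True,
            null_r=null if keep_null else None,
        )

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    null = _null_correlations(x, y, n_perm, rng)
    p = (1 + _tail_count(null, r_obs, tail)) / (1 + n_perm)
    return AssociationResult(
        r=r_obs, p_perm=float(p), n_perm=n_perm, n_parcels=x.size,
        tail=tail, seed=seed, exhaustive=False,
        null_r=null if keep_null else None,
    )


def correlation_difference_test(
    x,
    y1,
    y2,
    n_perm: int = 100000,
    tail: Tail = "two_sided",
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation test for a difference of dependent correlations.

    The statistic is delta_r = r(x, y1) - r(x, y2).  Under the null that x
    relates equally to both maps, permuting x jointly against the (y1, y2)
    pairs leaves the dependence between y1 and y2 intact while destroying
    both correlations with x.  Returns (delta_r, p).
    """
    x = np.asarray(x, dtype=float).ravel()
    y1 = np.asarray(y1, dtype=float).ravel()
    y2 = np.asarray(y2, dtype=float).ravel()
    if not (x.size == y1.size == y2.size):
        raise ValueError("vectors must be aligned")
    if x.size < 3:
        raise ValueError("need at least 3 parcels")
    d_obs = _pearson(x, y1) - _pearson(x, y2)

    xc = x - x.mean()
    y1c = y1 - y1.mean()
    y2c = y2 - y2.mean()
    d1 = np.sqrt((xc @ xc) * (y1c @ y1c))
    d2 = np.sqrt((xc @ xc) * (y2c @ y2c))
    if d1 == 0 or d2 == 0:
        raise ValueError("zero variance in one of the inputs")

    if x.size <= EXHAUSTIVE_MAX_N:
        perms = np.array(list(itertools.permutations(range(x.size))))
        Xp = xc[perms]
        null = (Xp @ y1c) / d1 - (Xp @ y2c) / d2
        p = _tail_count(null, d_obs, tail) / null.size
        return float(d_obs), float(p)

    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(n_perm, 20000))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((b, x.size)), axis=1)
        null = (xc[idx] @ y1c) / d1 - (xc[idx] @ y2c) / d2
        count += _tail_count(null, d_obs, tail)
        done += b
    p = (1 + count) / (1 + n_perm)
    return float(d_obs), float(p)
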