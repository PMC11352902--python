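"""Granularity selection: bootstrapped error curves and cross-species ARI.

The number of OPNMF factors is a free parameter.  Two signals guide its
choice: (i) the change in mean reconstruction error (MRE) as factors are
added, bootstrapped over subjects — once the curve plateaus, further factors
model noise; and (ii) the cross-species similarity of the parcellations at
each granularity, quantified by the adjusted Rand index (ARI) after
transporting one species' labels into the other's template space.  The
comparative granularity is the ARI optimum inside the plateau window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score

from crossmorph.opnmf import fit_opnmf, winner_takes_all
from crossmorph.preprocess import GMStack


@dataclass
class GranularityCurve:
    """Bootstrapped MRE trajectory over a range of factor counts.

    ``delta_mre`` follows the convention delta_k = mre_{k-1} - mre_k (the
    improvement gained by the step *to* k); the first entry is NaN.
    """

    k_values: np.ndarray
    mre: np.ndarray          # n_boot x len(k_values)
    mre_mean: np.ndarray
    mre_sd: np.ndarray
    delta_mre_mean: np.ndarray
    delta_mre_sd: np.ndarray
    n_boot: int
    seed: int | None = None


@dataclass
class SimilarityTable:
    """Cross-species parcellation similarity per granularity."""

    k_values: np.ndarray
    mean_ari: np.ndarray
    per_parcel_ari: dict = field(default_factory=dict)  # k -> {parcel: ari}


@dataclass
class GranularitySelection:
    k: int
    plateau_window: np.ndarray
    used_fallback: bool
    diagnostics: dict


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two labelings of the same items.

    1 means identical partitions, values near 0 chance-level agreement, and
    negative values less-than-chance agreement.  Items labeled 0 in either
    vector (unassigned voxels) are excluded pairwise.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    keep = (a != 0) & (b != 0)
    if not keep.any():
        raise ValueError("no jointly assigned items to compare")
    return float(adjusted_rand_score(a[keep], b[keep]))


def bootstrap_mre_curve(
    X: GMStack | np.ndarray,
    k_range=range(2, 41),
    n_boot: int = 100,
    seed: int | None = None,
    max_iter: int = 10000,
    tol: float = 1e-5,
) -> GranularityCurve:
    """Bootstrap the MRE-versus-k curve by resampling subjects.

    Each bootstrap draws subjects (columns) with replacement — voxels stay
    fixed — fits OPNMF at every k and records the per-entry mean
    reconstruction error.  delta_mre is computed within bootstrap and then
    summarized, matching how change-in-error curves are usually reported.
    """
    M = X.data if isinstance(X, GMStack) else np.asarray(X, dtype=float)
    ks = np.asarray(list(k_range), dtype=int)
    if not np.all(np.diff(ks) > 0):
        raise ValueError("k_range must be strictly increasing")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    n = M.shape[1]

    mre = np.full((n_boot, ks.size), np.nan)
    for b in range(n_boot):
        cols = rng.integers(0, n, size=n)
        Xb = M[:, cols]
        for i, k in enumerate(ks):
            if k >= min(Xb.shape):
                warnings.warn(
                    f"bootstrap {b}: k={k} not fittable on resample; skipped",
                    RuntimeWarning,
                )
                continue
            model = fit_opnmf(Xb, k, max_iter=max_iter, tol=tol)
            mre[b, i] = model.mre

    delta = np.full_like(mre, np.nan)
    delta[:, 1:] = mre[:, :-1] - mre[:, 1:]

    def _summ(arr, fn):
        out = np.full(arr.shape[1], np.nan)
        for i in range(arr.shape[1]):
            col = arr[:, i]
            col = col[np.isfinite(col)]
            if col.size:
                out[i] = fn(col)
        return out

    return GranularityCurve(
        k_values=ks,
        mre=mre,
        mre_mean=_summ(mre, np.mean),
        mre_sd=_summ(mre, np.std),
        delta_mre_mean=_summ(delta, np.mean),
        delta_mre_sd=_summ(delta, np.std),
        n_boot=n_boot,
        seed=seed,
    )


def _per_parcel_ari(a: np.ndarray, b: np.ndarray) -> dict:
    """ARI of each source parcel's indicator vs its max-overlap target parcel."""
    out = {}
    for lab in np.unique(a):
        if lab == 0:
            continue
        ind_a = (a == lab).astype(int)
        overlap_labels, counts = np.unique(b[a == lab], return_counts=True)
        nz = overlap_labels != 0
        if not nz.any():
            out[int(lab)] = 0.0
            continue
        best = overlap_labels[nz][np.argmax(counts[nz])]
        ind_b = (b == best).astype(int)
        out[int(lab)] = float(adjusted_rand_score(ind_a, ind_b))
    return out


def cross_species_ari(
    labels_a_in_b_space: np.ndarray,
    labels_b: np.ndarray,
    joint_mask: np.ndarray,
) -> tuple[float, dict]:
    """Similarity of two species' parcellations on a common grid.

    ``labels_a_in_b_space`` is species A's label volume already transported
    to species B's grid; the comparison runs over ``joint_mask`` (the
    intersection of both species' brain masks).  Returns the overall ARI and
    per-parcel ARIs computed by binary max-overlap matching.
    """
    la = np.asarray(labels_a_in_b_space)
    lb = np.asarray(labels_b)
    jm = np.asarray(joint_mask, dtype=bool)
    if la.shape != lb.shape or la.shape != jm.shape:
        raise ValueError("label volumes and joint mask must share a grid")
    if not jm.any():
        raise ValueError("joint mask is empty (disjoint species masks)")
    a, b = la[jm], lb[jm]
    mean_ari = adjusted_rand_index(a, b)
    return mean_ari, _per_parcel_ari(a, b)


def select_granularity(
    curve: GranularityCurve,
    sim: SimilarityTable,
    plateau_fraction: float = 0.15,
) -> GranularitySelection:
    """Pick the comparative granularity: ARI argmax inside the MRE plateau.

    A granularity k belongs to the plateau when the improvement gained
    *beyond* it (delta at k+1) drops below ``plateau_fraction`` of the
    largest observed improvement — i.e. adding factors past k mostly models
    noise.  The final k in the range joins the window when its own incoming
    delta is sub-threshold.  Within the window the k with the highest mean
    cross-species ARI wins; ties break towards the smaller k (parsimony).
    Falls back to the global ARI argmax if the window is empty.
    """
    ks = np.asarray(curve.k_values)
    if not np.array_equal(ks, np.asarray(sim.k_values)):
        raise ValueError("curve and similarity table must cover the same k range")
    delta = np.asarray(curve.delta_mre_mean, dtype=float)
    finite = delta[np.isfinite(delta)]
    if finite.size == 0:
        raise ValueError("curve has no usable delta-MRE values")
    thresh = plateau_fraction * float(np.nanmax(finite))

    in_plateau = np.zeros(ks.size, dtype=bool)
    for i in range(ks.size):
        if i + 1 < ks.size:
            in_plateau[i] = np.isfinite(delta[i + 1]) and delta[i + 1] < thresh
        else:
            in_plateau[i] = np.isfinite(delta[i]) and delta[i] < thresh

    # keep only the maximal run: a single contiguous plateau window
    window = np.array([], dtype=int)
    if in_plateau.any():
        runs = []
        start = None
        for i, flag in enumerate(in_plateau):
            if flag and start is None:
                start = i
            if (not flag or i == ks.size - 1) and start is not None:
                end = i if flag else i - 1
                runs.append((start, end))
                start = None
        start, end = max(runs, key=lambda r: r[1] - r[0])
        window = np.arange(start, end + 1)

    used_fallback = window.size == 0
    if used_fallback:
        warnings.warn(
            "empty plateau window; falling back to global ARI argmax",
            RuntimeWarning,
        )
        candidates = np.arange(ks.size)
    else:
        candidates = window

    ari = np.asarray(sim.mean_ari, dtype=float)[candidates]
    best = candidates[int(np.argmax(ari))]  # argmax takes the first (smallest k) on ties
    return GranularitySelection(
        k=int(ks[best]),
        plateau_window=ks[window],
        used_fallback=used_fallback,
        diagnostics={
            "threshold": thresh,
            "delta_mre_mean": delta,
            "mean_ari": np.asarray(sim.mean_ari, dtype=float),
            "k_values": ks,
        },
    )


def parcellate_at_k(
    X: GMStack | np.ndarray,
    k: int,
    mask: np.ndarray | None = None,
    max_iter: int = 10000,
    tol: float = 1e-5,
):
    """Convenience: fit OPNMF at k and return (model, parcellation)."""
    model = fit_opnmf(X, k, max_iter=max_iter, tol=tol)
    if mask is None and isinstance(X, GMStack):
        mask = X.mask
    parc = winner_takes_all(model.W, mask=mask)
    return model, parc
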