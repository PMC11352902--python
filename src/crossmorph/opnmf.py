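"""Orthogonal projective non-negative matrix factorization (OPNMF).

OPNMF approximates a non-negative voxel-by-subject matrix ``X`` (m x n) by
``W W^T X`` with ``W >= 0`` and ``W^T W = I``, minimising the squared
Frobenius reconstruction error

    min_W || X - W W^T X ||_F^2   s.t.   W^T W = I,  W >= 0.

Because the subject weights are obtained by projection, ``H = W^T X``, every
factor participates in reconstructing every subject, which drives the
columns of ``W`` towards sparse, minimally overlapping spatial components.
A hard parcellation follows by assigning each voxel to its largest loading
(winner takes all).

The fit is fully deterministic: initialization uses non-negative double
singular value decomposition (NNDSVD) and the update is multiplicative, so
no random state is involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from crossmorph.preprocess import GMStack

EPS = 1e-16  # denominator floor in the multiplicative update


@dataclass
class FactorModel:
    """Fitted OPNMF factorization.

    ``W`` is m x k, non-negative with (approximately) orthonormal columns;
    ``H = W^T X`` holds the projected subject weights.  ``recon_error`` is the
    squared Frobenius norm of the residual and ``mre`` its per-entry mean.
    """

    W: np.ndarray
    H: np.ndarray
    k: int
    recon_error: float
    mre: float
    n_iter: int
    converged: bool
    orthogonality_residual: float
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_rescues: int = 0


@dataclass
class Parcellation:
    """Hard voxel labeling derived from a factor matrix.

    Labels run 1..k; 0 marks unassigned voxels (all-zero loading rows).
    ``dropped`` lists factors that won no voxel.
    """

    labels: np.ndarray
    k: int
    label_volume: np.ndarray | None = None
    dropped: tuple = ()

    def to_volume(self, mask: np.ndarray) -> np.ndarray:
        vol = np.zeros(mask.shape, dtype=np.int32)
        vol[mask] = self.labels
        return vol


def _as_matrix(X: GMStack | np.ndarray) -> np.ndarray:
    M = X.data if isinstance(X, GMStack) else np.asarray(X, dtype=float)
    if M.ndim != 2:
        raise ValueError("X must be a 2-D voxels-by-subjects matrix")
    if np.any(M < 0):
        raise ValueError("X must be non-negative")
    return M


def nndsvd_init(X: GMStack | np.ndarray, k: int) -> np.ndarray:
    """Non-negative double SVD initialization of the factor matrix.

    The leading k singular vector pairs are split into their positive and
    negative sections; for each pair the section with the larger energy
    product is kept and rescaled, yielding a sparse non-negative ``W0``
    (zeros are left at zero).  Deterministic given ``X`` and ``k``.
    """
    M = _as_matrix(X)
    m, n = M.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(m, n):
        raise ValueError(f"k={k} exceeds min(m, n)={min(m, n)}")

    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    rank = int(np.sum(S > S[0] * max(m, n) * np.finfo(float).eps)) if S.size else 0
    W0 = np.zeros((m, k))

    # leading pair: componentwise absolute value (Perron-Frobenius direction)
    W0[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])

    for j in range(1, min(k, rank)):
        u, v = U[:, j], Vt[j, :]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(v, 0, None), np.clip(-v, 0, None)
        n_up, n_un = np.linalg.norm(up), np.linalg.norm(un)
        n_vp, n_vn = np.linalg.norm(vp), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            sec, n_sec, n_other = up, n_up, n_vp
        else:
            sec, n_sec, n_other = un, n_un, n_vn
        if n_sec > 0:
            W0[:, j] = np.sqrt(S[j] * n_sec * n_other) * sec / n_sec

    if k > rank:
        warnings.warn(
            f"k={k} exceeds numerical rank {rank}; trailing columns zero-padded",
            RuntimeWarning,
        )
    return W0


def opnmf_step(W: np.ndarray, X: GMStack | np.ndarray) -> np.ndarray:
    """One multiplicative OPNMF update followed by renormalization.

    W'_ij = W_ij * (X X^T W)_ij / (W W^T X X^T W)_ij, with the denominator
    floored at 1e-16.  Products are evaluated as ``X (X^T W)`` so the m x m
    Gram matrix is never formed.  The updated matrix is rescaled by its
    spectral norm: the multiplicative rule only approaches the
    orthonormality constraint, and the global rescaling removes the scale
    indeterminacy without perturbing the descent (per-column rescaling, by
    contrast, empirically stalls the fit and breaks the monotone decrease
    of the reconstruction error).  At convergence ``W^T W ~ I``, so the
    spectral norm and the column norms agree.
    """
    M = _as_matrix(X)
    W = np.asarray(W, dtype=float)
    if W.shape[0] != M.shape[0]:
        raise ValueError("W rows must match X rows")
    num = M @ (M.T @ W)              # X X^T W
    den = W @ (W.T @ num)            # W W^T X X^T W
    Wn = W * num / np.maximum(den, EPS)

    norms = np.linalg.norm(Wn, axis=0)
    dead = np.flatnonzero(norms == 0)
    if dead.size:
        warnings.warn(
            f"{dead.size} factor column(s) collapsed to zero; re-seeding from residual",
            RuntimeWarning,
        )
        resid = np.clip(M - Wn @ (Wn.T @ M), 0, None)
        seed = np.linalg.norm(resid, axis=1)
        if seed.sum() == 0:
            seed = np.ones(M.shape[0])
        for j in dead:
            Wn[:, j] = seed
    return Wn / np.linalg.norm(Wn, 2)


def reconstruction_error(X: GMStack | np.ndarray, W: np.ndarray) -> float:
    """Squared Frobenius norm of ``X - W W^T X``."""
    M = _as_matrix(X)
    W = np.asarray(W, dtype=float)
    if W.shape[0] != M.shape[0]:
        raise ValueError("W rows must match X rows")
    R = M - W @ (W.T @ M)
    return float(np.sum(R * R))


def mean_reconstruction_error(X: GMStack | np.ndarray, W: np.ndarray) -> float:
    """Per-entry mean reconstruction error: ||X - W W^T X||_F^2 / (m n)."""
    M = _as_matrix(X)
    return reconstruction_error(M, W) / M.size


def fit_opnmf(
    X: GMStack | np.ndarray,
    k: int,
    max_iter: int = 10000,
    tol: float = 1e-5,
    W0: np.ndarray | None = None,
    rescue_dead_factors: int = 3,
) -> FactorModel:
    """Fit OPNMF by multiplicative updates from an NNDSVD start.

    Iterates :func:`opnmf_step` until the relative change of the
    reconstruction error falls below ``tol`` or ``max_iter`` is reached,
    then sets ``H = W^T X``.

    The multiplicative dynamics occasionally converge with a "dead" factor
    — a weak dense component that wins (almost) no voxels under
    winner-takes-all —
    while two covariance blocks share one factor.  Analogous to empty-
    cluster re-seeding in k-means, such factors are deterministically
    re-seeded on the worst-reconstructed voxels and the fit is continued;
    up to ``rescue_dead_factors`` rounds (0 disables the rescue).  The
    returned ``loss_history`` is that of the final run.

    Parameters
    ----------
    X:
        Non-negative voxels-by-subjects matrix (or :class:`GMStack`).
    k:
        Number of factors, 1 <= k <= min(m, n).
    max_iter:
        Iteration cap per run; the canonical setting for production runs
        is 10000.
    tol:
        Relative reconstruction-error change below which the fit stops.
    W0:
        Optional custom starting matrix (defaults to NNDSVD).
    """
    M = _as_matrix(X)
    model = _fit_single(M, k, max_iter, tol, W0)
    # "dead" = winning (almost) no voxels: under 5% of the fair share m/k
    dead_threshold = max(1, int(0.05 * M.shape[0] / k))
    for n_rescues in range(1, rescue_dead_factors + 1):
        winners = np.bincount(np.argmax(model.W, axis=1), minlength=k)
        dead = np.flatnonzero(winners < dead_threshold)
        if dead.size == 0:
            break
        W = model.W.copy()
        resid = M - W @ (W.T @ M)
        row_err = np.sum(resid * resid, axis=1)
        cutoff = np.quantile(row_err, 0.75)
        seed_col = np.where(row_err >= cutoff, np.sqrt(row_err), 0.0)
        nrm = np.linalg.norm(seed_col)
        if nrm == 0:
            break
        for j in dead:
            W[:, j] = seed_col / nrm
        candidate = _fit_single(M, k, max_iter, tol, W)
        if candidate.recon_error >= model.recon_error:
            break  # rescue did not help; keep the original fit
        candidate.n_rescues = n_rescues
        model = candidate
    return model


def _fit_single(
    X: np.ndarray,
    k: int,
    max_iter: int,
    tol: float,
    W0: np.ndarray | None,
) -> FactorModel:
    M = _as_matrix(X)
    W = nndsvd_init(M, k) if W0 is None else np.asarray(W0, dtype=float).copy()
    # unit columns at the start: if the initialization already spans the
    # data (disjoint blocks), the very first error is then the optimum
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    W = W / norms

    total_energy = float(np.sum(M * M))
    errors = [reconstruction_error(M, W)]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        W = opnmf_step(W, M)
        if not np.all(np.isfinite(W)):
            raise FloatingPointError(
                f"non-finite values in W at iteration {n_iter}"
            )
        err = reconstruction_error(M, W)
        errors.append(err)
        prev = errors[-2]
        # guard the denominator so fits that hit (near-)zero error register
        # as converged instead of dividing noise by noise
        denom = max(prev, 1e-12 * total_energy, np.finfo(float).tiny)
        rel = abs(prev - err) / denom
        if rel < tol:
            converged = True
            break

    H = W.T @ M
    err = errors[-1]
    # orthogonality is judged scale-free, on unit columns; W itself is
    # returned exactly as iterated so recon_error matches it
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    Wc = W / norms
    ortho = float(np.max(np.abs(Wc.T @ Wc - np.eye(k))))
    return FactorModel(
        W=W,
        H=H,
        k=k,
        recon_error=err,
        mre=err / M.size,
        n_iter=n_iter,
        converged=converged,
        orthogonality_residual=ortho,
        loss_history=np.asarray(errors),
    )


def winner_takes_all(
    W: np.ndarray, mask: np.ndarray | None = None
) -> Parcellation:
    """Hard-label voxels by their largest factor loading.

    Ties are broken towards the lowest factor index; all-zero rows receive
    label 0 (unassigned) with a warning; factors that win no voxel are
    reported in ``dropped``.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2:
        raise ValueError("W must be 2-D")
    if np.any(W < 0):
        raise ValueError("W must be non-negative")
    k = W.shape[1]
    labels = np.argmax(W, axis=1).astype(np.int32) + 1
    zero_rows = ~np.any(W > 0, axis=1)
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} voxel(s) have all-zero loadings; labeled 0",
            RuntimeWarning,
        )
        labels[zero_rows] = 0
    present = set(np.unique(labels)) - {0}
    dropped = tuple(sorted(set(range(1, k + 1)) - present))
    label_volume = None
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        label_volume = np.zeros(mask.shape, dtype=np.int32)
        label_volume[mask] = labels
    return Parcellation(labels=labels, k=k, label_volume=label_volume, dropped=dropped)
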