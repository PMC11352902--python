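"""Preprocessing of modulated gray-matter volumes.

Covers the standard steps applied to voxel-based-morphometry data before
factorization: Gaussian smoothing in millimetres, resampling to a coarser
grid, assembly of the masked voxel-by-subject matrix, and sample-homogeneity
quality control based on pairwise subject correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

# FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

REQUIRED_COVARIATES = ("age", "sex", "tiv", "field_strength")


@dataclass
class GMStack:
    """Masked voxel-by-subject gray-matter data matrix.

    Attributes
    ----------
    data:
        Non-negative array of shape ``(m, n)``: in-mask voxels by subjects.
        Row order is the ascending C-order linear index of the mask, so row
        semantics are stable across runs.
    mask:
        Boolean volume; ``mask.sum() == m``.
    affine:
        4x4 voxel-to-world transform in mm (NIfTI convention).
    covariates:
        One row per subject with at least columns
        ``age`` (years), ``sex`` (0/1), ``tiv`` (ml), ``field_strength`` (0/1).
    """

    data: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (voxels x subjects)")
        if self.data.shape[0] != int(self.mask.sum()):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but mask has "
                f"{int(self.mask.sum())} voxels"
            )
        if np.any(self.data < 0):
            raise ValueError("GM data must be non-negative")
        if len(self.covariates) and len(self.covariates) != self.data.shape[1]:
            raise ValueError("covariate rows must match number of subjects")
        if len(self.covariates):
            missing = [c for c in REQUIRED_COVARIATES if c not in self.covariates]
            if missing:
                raise ValueError(f"missing covariate columns: {missing}")
            if self.covariates[list(REQUIRED_COVARIATES)].isna().any().any():
                raise ValueError("covariates contain missing values")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.data.shape[1]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (|det affine[:3,:3]| / 1000)."""
        return abs(float(np.linalg.det(self.affine[:3, :3]))) / 1000.0

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter an ``(m,)`` vector back into a volume on the mask grid."""
        values = np.asarray(values)
        vol = np.full(self.mask.shape, fill, dtype=values.dtype)
        vol[self.mask] = values
        return vol


def _voxel_sizes(voxel_size_mm: float | Sequence[float]) -> np.ndarray:
    sizes = np.atleast_1d(np.asarray(voxel_size_mm, dtype=float))
    if sizes.size == 1:
        sizes = np.repeat(sizes, 3)
    if sizes.size != 3 or np.any(sizes <= 0):
        raise ValueError("voxel size must be a positive scalar or length-3")
    return sizes


def smooth_volume(
    volume: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float | Sequence[float] = 1.0,
) -> np.ndarray:
    """Gaussian-smooth a scalar volume with the kernel width given in mm FWHM.

    Sigma per axis is ``fwhm / (2*sqrt(2 ln 2)) / voxel_size``.  Zero padding
    is used at the boundary, so the total sum is conserved up to mass leaving
    the field of view (negligible on volumes padded by a background shell).
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    volume = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return volume.copy()
    sigmas = fwhm_mm * FWHM_TO_SIGMA / _voxel_sizes(voxel_size_mm)
    return ndimage.gaussian_filter(volume, sigma=sigmas, mode="constant", cval=0.0)


def resample_volume(
    volume: np.ndarray,
    voxel_size_mm: float | Sequence[float],
    target_voxel_mm: float | Sequence[float],
    method: Literal["linear", "nearest"] = "linear",
    affine: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Resample a volume to a new voxel size.

    ``linear`` (order-1 spline) is appropriate for scalar maps, ``nearest``
    for label maps.  Returns the resampled volume and, when an affine is
    supplied, the updated affine with rescaled voxel axes.
    """
    if method not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation method: {method!r}")
    src = _voxel_sizes(voxel_size_mm)
    dst = _voxel_sizes(target_voxel_mm)
    volume = np.asarray(volume, dtype=float)
    zoom = src / dst
    if np.allclose(zoom, 1.0):
        out = volume.copy()
    else:
        order = 1 if method == "linear" else 0
        out = ndimage.zoom(volume, zoom, order=order, mode="nearest", grid_mode=True)
    new_affine = None
    if affine is not None:
        new_affine = affine.copy().astype(float)
        new_affine[:3, :3] = affine[:3, :3] / zoom[np.newaxis, :]
    return out, new_affine


def apply_gm_mask(
    volumes: Sequence[np.ndarray] | np.ndarray,
    probability_map: np.ndarray,
    threshold: float,
    affine: np.ndarray | None = None,
    covariates: pd.DataFrame | None = None,
) -> GMStack:
    """Assemble a :class:`GMStack` from per-subject volumes and a GM mask.

    Voxels with tissue probability strictly above ``threshold`` become matrix
    rows, in ascending C-order linear index.  Typical thresholds are 0.3 for
    chimpanzee and 0.2 for human samples.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    probability_map = np.asarray(probability_map, dtype=float)
    mask = probability_map > threshold
    if not mask.any():
        raise ValueError(f"threshold {threshold} produces an empty mask")
    vols = [np.asarray(v, dtype=float) for v in volumes]
    for v in vols:
        if v.shape != probability_map.shape:
            raise ValueError("all volumes must share the mask grid")
    data = np.column_stack([v[mask] for v in vols])
    data = np.clip(data, 0.0, None)
    if affine is None:
        affine = np.eye(4)
    if covariates is None:
        covariates = pd.DataFrame()
    return GMStack(data=data, mask=mask, affine=affine, covariates=covariates)


@dataclass
class QCResult:
    """Outcome of iterative homogeneity screening."""

    flagged: list
    passed: list
    n_iterations: int
    iteration_stats: list  # per iteration: dict with mean, sd, flagged ids
    reasons: dict  # subject id -> reason string


def qc_homogeneity(
    stack: GMStack | np.ndarray,
    n_sd: float = 2.0,
    subject_ids: Sequence | None = None,
    max_iterations: int = 10,
) -> QCResult:
    """Flag subjects whose GM maps are unusually dissimilar to the sample.

    For every subject the mean Pearson correlation of its voxel vector with
    all other subjects is computed; subjects falling below
    ``mean - n_sd * SD`` of that distribution are flagged.  The screen is
    re-applied to the passing set (statistics recomputed on the survivors)
    until an iteration flags nobody.
    """
    data = stack.data if isinstance(stack, GMStack) else np.asarray(stack, float)
    n = data.shape[1]
    if n < 3:
        raise ValueError("homogeneity QC requires at least 3 subjects")
    if subject_ids is None:
        subject_ids = list(range(n))
    subject_ids = list(subject_ids)
    if len(subject_ids) != n:
        raise ValueError("subject_ids length must match subject count")

    reasons: dict = {}
    flagged_all: list = []
    current = list(range(n))

    # zero-variance maps cannot enter a correlation; flag them up front
    sds = data.std(axis=0)
    degenerate = [i for i in current if sds[i] == 0]
    for i in degenerate:
        reasons[subject_ids[i]] = "zero-variance voxel vector"
        flagged_all.append(subject_ids[i])
    current = [i for i in current if sds[i] > 0]

    iteration_stats = []
    n_iter = 0
    while len(current) >= 3 and n_iter < max_iterations:
        n_iter += 1
        sub = data[:, current]
        corr = np.corrcoef(sub.T)
        np.fill_diagonal(corr, np.nan)
        mean_corr = np.nanmean(corr, axis=1)
        mu, sd = float(mean_corr.mean()), float(mean_corr.std())
        cutoff = mu - n_sd * sd
        newly = [current[j] for j in range(len(current))
                 if sd > 0 and mean_corr[j] < cutoff]
        iteration_stats.append({
            "iteration": n_iter,
            "n_subjects": len(current),
            "mean": mu,
            "sd": sd,
            "cutoff": cutoff,
            "flagged": [subject_ids[i] for i in newly],
        })
        if not newly:
            break
        for i in newly:
            reasons[subject_ids[i]] = (
                f"mean correlation below mean - {n_sd} SD in iteration {n_iter}"
            )
            flagged_all.append(subject_ids[i])
        current = [i for i in current if i not in set(newly)]

    passed = [subject_ids[i] for i in current]
    return QCResult(
        flagged=flagged_all,
        passed=passed,
        n_iterations=n_iter,
        iteration_stats=iteration_stats,
        reasons=reasons,
    )
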