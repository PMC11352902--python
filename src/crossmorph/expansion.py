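"""Relative volumetric expansion maps from cross-species deformations.

The Jacobian determinant of a deformation field gives the local volume
change factor; dividing by the global brain-size ratio between the two
species yields the *relative* expansion: values of one mean a region grew
exactly in proportion to overall brain size, values above one mark regions
that expanded more than the brain as a whole.  Per-parcel means of the
relative expansion, z-scored across parcels, summarize the interregional
pattern for association with aging statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ExpansionMap:
    jacobian: np.ndarray
    global_ratio: float
    relative: np.ndarray
    source_mask: np.ndarray | None = None
    sources: list = field(default_factory=list)


def jacobian_determinant(
    displacement: np.ndarray,
    spacing_mm: float | tuple[float, float, float] = 1.0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Jacobian determinant of phi(x) = x + u(x) by finite differences.

    ``displacement`` has shape ``grid + (3,)``, in the same units as
    ``spacing_mm``.  np.gradient provides central differences in the
    interior and one-sided differences at the edges.  Non-positive
    determinants inside the mask (folding) are reported with a warning.
    """
    u = np.asarray(displacement, dtype=float)
    if u.ndim != 4 or u.shape[-1] != 3:
        raise ValueError("displacement must have shape (nx, ny, nz, 3)")
    if not np.all(np.isfinite(u)):
        raise ValueError("displacement field contains non-finite values")
    sp = np.atleast_1d(np.asarray(spacing_mm, dtype=float))
    if sp.size == 1:
        sp = np.repeat(sp, 3)

    # gradient of the mapping: identity + du/dx
    J = np.empty(u.shape[:3] + (3, 3))
    for comp in range(3):
        grads = np.gradient(u[..., comp], *sp, axis=(0, 1, 2))
        for ax in range(3):
            J[..., comp, ax] = grads[ax] + (1.0 if comp == ax else 0.0)
    det = np.linalg.det(J)

    check = det[np.asarray(mask, bool)] if mask is not None else det
    n_bad = int(np.sum(check <= 0))
    if n_bad:
        warnings.warn(
            f"{n_bad} voxel(s) with non-positive Jacobian determinant (folding)",
            RuntimeWarning,
        )
    return det


def relative_expansion(
    jacobian: np.ndarray,
    source_mask: np.ndarray,
    target_mask: np.ndarray,
    source_voxel_vol_ml: float = 1.0,
    target_voxel_vol_ml: float | None = None,
) -> ExpansionMap:
    """Normalize a Jacobian volume by the global brain-size ratio.

    global_ratio = target brain volume / source brain volume, measured from
    the binary template masks; relative = jacobian / global_ratio.  A
    deformation that scales the whole brain uniformly by the size ratio
    therefore maps to a relative expansion of exactly one everywhere.
    """
    jac = np.asarray(jacobian, dtype=float)
    smask = np.asarray(source_mask, dtype=bool)
    tmask = np.asarray(target_mask, dtype=bool)
    if jac.shape != smask.shape:
        raise ValueError("jacobian and source mask must share a grid")
    if target_voxel_vol_ml is None:
        target_voxel_vol_ml = source_voxel_vol_ml
    src_vol = smask.sum() * source_voxel_vol_ml
    tgt_vol = tmask.sum() * target_voxel_vol_ml
    if src_vol == 0:
        raise ValueError("source mask is empty")
    ratio = float(tgt_vol / src_vol)
    return ExpansionMap(
        jacobian=jac,
        global_ratio=ratio,
        relative=jac / ratio,
        source_mask=smask,
    )


def parcel_means(relative: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean relative expansion per parcel (labels 1..k; 0 ignored).

    Returns (parcel ids, means); empty parcels are simply absent.
    """
    rel = np.asarray(relative, dtype=float)
    lab = np.asarray(labels)
    if rel.shape != lab.shape:
        raise ValueError("expansion volume and label volume must share a grid")
    ids = np.unique(lab)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("label volume contains no parcels")
    means = np.array([rel[lab == i].mean() for i in ids])
    return ids, means


def parcel_expansion(
    expmap: ExpansionMap | np.ndarray, parcellation
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-parcel mean relative expansion and its z-score across parcels.

    z = (mean_j - mean of means) / population SD of means.  Raises when the
    parcel means are all equal (zero SD: z is undefined for a uniform
    expansion) or when fewer than two parcels exist.
    """
    rel = expmap.relative if isinstance(expmap, ExpansionMap) else np.asarray(expmap)
    labels = getattr(parcellation, "label_volume", parcellation)
    if labels is None:
        raise ValueError("parcellation has no label volume")
    ids, means = parcel_means(rel, np.asarray(labels))
    if ids.size < 2:
        raise ValueError("z-scoring requires at least two parcels")
    sd = means.std()  # population SD across parcels
    if sd == 0:
        raise ValueError(
            "parcel means are identical (uniform expansion); z-scores undefined"
        )
    z = (means - means.mean()) / sd
    return ids, means, z


def average_expansion_maps(maps: list[ExpansionMap]) -> ExpansionMap:
    """Voxel-wise arithmetic mean of several relative expansion maps.

    Used when several reference templates provide one expansion map each and
    a consensus map is wanted.  All maps must share the source grid.
    """
    if not maps:
        raise ValueError("need at least one expansion map")
    shape = maps[0].relative.shape
    for m in maps:
        if m.relative.shape != shape:
            raise ValueError("expansion maps are on different grids")
    rel = np.mean([m.relative for m in maps], axis=0)
    jac = np.mean([m.jacobian for m in maps], axis=0)
    ratio = float(np.mean([m.global_ratio for m in maps]))
    return ExpansionMap(
        jacobian=jac,
        global_ratio=ratio,
        relative=rel,
        source_mask=maps[0].source_mask,
        sources=[id(m) for m in maps],
    )
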