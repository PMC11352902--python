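"""Parcel-wise gray-matter aging statistics.

Each parcel's average GM volume is regressed on age with sex, total
intracranial volume (TIV) and scanner field strength as covariates; the age
t-statistic per parcel, family-wise-error corrected across parcels, is the
aging readout that downstream association analyses use.  A whole-brain
model regresses GM as a percentage of TIV on age.  Interspecies age-range
matching applies a fixed scaling between species' aging clocks (one human
year ~ 1.15 chimpanzee years).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from crossmorph.opnmf import Parcellation
from crossmorph.preprocess import GMStack

COVARIATE_COLUMNS = ("age", "sex", "tiv", "field_strength")


@dataclass
class GMFractionFit:
    """Simple regression of whole-brain GM%-of-TIV on age."""

    r_squared: float
    p_value: float
    slope: float
    intercept: float
    n: int


def match_age_range(
    ages, reference_max_age: float, factor: float = 1.15
) -> tuple[int, np.ndarray]:
    """Age-matched subject selection across species.

    The cutoff is ``ceil(reference_max_age * factor)``: e.g. with the oldest
    chimpanzee at 50 years and the 1.15x human-to-chimpanzee aging ratio,
    humans above 58 years are excluded.  Returns (cutoff, kept indices).
    """
    if factor <= 0:
        raise ValueError("scaling factor must be positive")
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < 0):
        raise ValueError("ages must be non-negative")
    cutoff = math.ceil(reference_max_age * factor)
    kept = np.flatnonzero(ages <= cutoff)
    if kept.size == 0:
        raise ValueError(f"no subjects at or below the cutoff of {cutoff} years")
    return cutoff, kept


def parcel_gm_volumes(
    stack: GMStack, parc: Parcellation | np.ndarray
) -> pd.DataFrame:
    """Average GM volume (ml) of each parcel for every subject.

    volume_{j,i} = mean GM value of parcel j in subject i, times the
    parcel's voxel count, times the voxel volume in ml — i.e. the summed
    modulated GM within the parcel expressed in millilitres.
    """
    labels = parc.labels if isinstance(parc, Parcellation) else np.asarray(parc)
    labels = np.asarray(labels).ravel()
    if labels.size != stack.n_voxels:
        raise ValueError("parcellation must label every stack voxel")
    voxvol = stack.voxel_volume_ml
    ids = np.unique(labels)
    ids = ids[ids > 0]
    rows = {}
    for j in ids:
        sel = labels == j
        rows[int(j)] = stack.data[sel, :].sum(axis=0) * voxvol
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "parcel_id"
    if len(stack.covariates):
        df.columns = stack.covariates["subject_id"].tolist()
    return df


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COVARIATE_COLUMNS if c not in covariates]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    X = covariates[list(COVARIATE_COLUMNS)].astype(float)
    X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = [
            c for c in X.columns
            if np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear: {bad}")
    return X


def fit_aging_model(
    volumes: pd.DataFrame | np.ndarray,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    signed: bool = False,
) -> pd.DataFrame:
    """Per-parcel OLS of GM volume on age + sex + TIV + field strength.

    Parameters
    ----------
    volumes:
        Parcels-by-subjects table of average GM volumes (the response).
    covariates:
        Per-subject table with age (years), sex (0/1), tiv (ml) and
        field_strength (0/1).
    alpha:
        FWE level for the significance flags.
    signed:
        If True the decline metric keeps the sign of the age t-statistic;
        by default its absolute value is used.

    Returns
    -------
    DataFrame indexed by parcel id with columns beta_age, t_age, p_age,
    p_fwe, significant, decline_metric.
    """
    if isinstance(volumes, np.ndarray):
        volumes = pd.DataFrame(volumes, index=np.arange(1, volumes.shape[0] + 1))
    n = volumes.shape[1]
    if len(covariates) != n:
        raise ValueError("covariate rows must match subject count")
    X = _design_matrix(covariates.reset_index(drop=True))
    if n <= X.shape[1]:
        raise ValueError("need more subjects than predictors")

    records = []
    for parcel_id, y in volumes.iterrows():
        fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
        records.append(
            {
                "parcel_id": parcel_id,
                "beta_age": fit.params["age"],
                "t_age": fit.tvalues["age"],
                "p_age": fit.pvalues["age"],
            }
        )
    table = pd.DataFrame.from_records(records).set_index("parcel_id")
    p_fwe, flags = fwe_correct(table["p_age"].to_numpy(), alpha=alpha)
    table["p_fwe"] = p_fwe
    table["significant"] = flags
    t = table["t_age"].to_numpy()
    table["decline_metric"] = t if signed else np.abs(t)
    return table


def fwe_correct(
    p_values, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down family-wise error correction.

    Returns (adjusted p-values, significance flags at ``alpha``).  Holm
    controls the FWE under arbitrary dependence and uniformly dominates
    Bonferroni.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any(np.isnan(p)):
        raise ValueError("p-values contain NaN")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    flags, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return p_adj, flags


def gm_fraction_regression(gm_total, tiv, age) -> GMFractionFit:
    """Whole-brain GM as a percentage of TIV regressed on age.

    Expressing GM relative to TIV removes head-size differences before the
    age fit.  Returns r-squared, two-sided p, slope (%/year) and intercept.
    """
    gm = np.asarray(gm_total, dtype=float)
    tiv_a = np.asarray(tiv, dtype=float)
    age_a = np.asarray(age, dtype=float)
    if np.any(tiv_a <= 0):
        raise ValueError("TIV must be positive")
    if np.ptp(age_a) == 0:
        raise ValueError("age has no variance")
    frac = 100.0 * gm / tiv_a
    res = stats.linregress(age_a, frac)
    return GMFractionFit(
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=int(age_a.size),
    )
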