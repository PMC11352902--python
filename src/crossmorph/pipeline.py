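"""End-to-end orchestration of the comparative workflow.

The pipeline ties the stages together in the order

    simulate -> preprocess -> fit -> select-k -> expansion -> aging -> correlate

working entirely from files under a single output directory so that every
stage can be re-run independently.  A manifest records configuration,
seeds, package version and SHA-256 checksums of all outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import crossmorph
from crossmorph import io as cio
from crossmorph.aging import fit_aging_model, gm_fraction_regression, match_age_range, parcel_gm_volumes
from crossmorph.association import permutation_correlation
from crossmorph.expansion import jacobian_determinant, parcel_expansion, relative_expansion
from crossmorph.granularity import (
    GranularityCurve,
    SimilarityTable,
    bootstrap_mre_curve,
    cross_species_ari,
    parcellate_at_k,
    select_granularity,
)
from crossmorph.preprocess import apply_gm_mask, qc_homogeneity, smooth_volume
from crossmorph.synthetic import SpeciesSpec, generate_deformation, generate_species

STAGES = ("simulate", "preprocess", "fit", "select-k", "expansion", "aging", "correlate")


class PipelineError(RuntimeError):
    """A stage failed; partial outputs remain on disk."""


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run (YAML-loadable)."""

    output_dir: str
    species_a: dict = dc_field(default_factory=dict)   # SpeciesSpec fields
    species_b: dict = dc_field(default_factory=dict)
    expansion_factors: list = dc_field(default_factory=list)
    k_range: tuple = (2, 8)
    n_boot: int = 5
    max_iter: int = 2000
    tol: float = 1e-5
    plateau_fraction: float = 0.15
    mask_threshold: float = 0.1
    smoothing_fwhm: float = 0.0
    qc_n_sd: float = 2.0
    alpha: float = 0.05
    age_match_factor: float = 1.15
    n_perm: int = 10000
    tail: str = "two_sided"
    seed: int = 0
    signed_decline: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "output_dir" not in raw:
            raise ValueError("config must be a mapping with an output_dir")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def spec(self, which: str) -> SpeciesSpec:
        overrides = dict(self.species_a if which == "a" else self.species_b)
        for key in ("grid_shape", "age_range_years", "parcel_age_slopes"):
            if key in overrides and overrides[key] is not None:
                overrides[key] = tuple(overrides[key])
        overrides.setdefault("seed", self.seed + (0 if which == "a" else 1))
        return SpeciesSpec(**overrides)

    @property
    def ks(self) -> list[int]:
        lo, hi = self.k_range
        return list(range(int(lo), int(hi) + 1))

    @property
    def root(self) -> Path:
        return Path(self.output_dir)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _record_outputs(cfg: PipelineConfig, manifest: dict, stage: str) -> None:
    files = sorted(p for p in cfg.root.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest.setdefault("outputs", {})
    manifest["outputs"][stage] = {
        str(p.relative_to(cfg.root)): _sha256(p) for p in files
    }


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> None:
    spec_a, spec_b = cfg.spec("a"), cfg.spec("b")
    stack_a, truth_a = generate_species(spec_a)
    stack_b, truth_b = generate_species(spec_b)
    factors = cfg.expansion_factors or [1.0] * spec_a.k_true
    deform = generate_deformation(spec_a, factors)
    truth_a.parcel_expansion_factors = np.asarray(factors, dtype=float)
    cio.write_species_dataset(cfg.root / "raw", stack_a, truth_a, name="species_a")
    cio.write_species_dataset(cfg.root / "raw", stack_b, truth_b, name="species_b")
    ddir = cfg.root / "deformation"
    ddir.mkdir(parents=True, exist_ok=True)
    cio.save_volume(ddir / "displacement.nii.gz", deform.displacement(), stack_a.affine)
    cio.save_volume(ddir / "jacobian_analytic.nii.gz", deform.jacobian_volume(), stack_a.affine)
    cio.write_json(ddir / "deformation.json", {
        "factors": factors,
        "slab_edges": deform.slab_edges,
        "ramp_halfwidth_mm": deform.ramp_halfwidth_mm,
    })


def _load_deformation(cfg: PipelineConfig):
    return generate_deformation(cfg.spec("a"), cfg.expansion_factors or [1.0] * cfg.spec("a").k_true)


def stage_preprocess(cfg: PipelineConfig) -> None:
    for name in ("species_a", "species_b"):
        stack, _ = cio.load_species_dataset(cfg.root / "raw" / name)
        vox = float(np.abs(np.diag(stack.affine)[:3]).mean())
        vols = []
        for i in range(stack.n_subjects):
            vol = stack.unmask(stack.data[:, i])
            if cfg.smoothing_fwhm > 0:
                vol = smooth_volume(vol, cfg.smoothing_fwhm, vox)
            vols.append(vol)
        prob = np.mean(vols, axis=0)
        prob = prob / max(prob.max(), 1e-12)
        new = apply_gm_mask(vols, prob, cfg.mask_threshold,
                            affine=stack.affine, covariates=stack.covariates)
        qc = qc_homogeneity(new, n_sd=cfg.qc_n_sd,
                            subject_ids=stack.covariates["subject_id"].tolist())
        keep = [i for i, sid in enumerate(stack.covariates["subject_id"]) if sid in set(qc.passed)]
        new.data = new.data[:, keep]
        new.covariates = stack.covariates.iloc[keep].reset_index(drop=True)
        cio.write_species_dataset(cfg.root / "preprocessed", new, name=name)
        cio.write_json(cfg.root / "preprocessed" / name / "qc.json", {
            "flagged": qc.flagged, "passed": qc.passed,
            "n_iterations": qc.n_iterations, "iteration_stats": qc.iteration_stats,
        })


def stage_fit(cfg: PipelineConfig) -> None:
    for name in ("species_a", "species_b"):
        stack, _ = cio.load_species_dataset(cfg.root / "preprocessed" / name)
        outdir = cfg.root / "fit" / name
        outdir.mkdir(parents=True, exist_ok=True)
        curve = bootstrap_mre_curve(
            stack, cfg.ks, n_boot=cfg.n_boot, seed=cfg.seed,
            max_iter=cfg.max_iter, tol=cfg.tol,
        )
        pd.DataFrame({
            "k": curve.k_values,
            "mre_mean": curve.mre_mean, "mre_sd": curve.mre_sd,
            "delta_mre_mean": curve.delta_mre_mean, "delta_mre_sd": curve.delta_mre_sd,
        }).to_csv(outdir / "mre_curve.tsv", sep="\t", index=False)
        for k in cfg.ks:
            model, parc = parcellate_at_k(stack, k, max_iter=cfg.max_iter, tol=cfg.tol)
            cio.save_labels(outdir / f"parcellation_k{k}.nii.gz",
                            parc.to_volume(stack.mask), stack.affine)
            w4d = np.stack([stack.unmask(model.W[:, j]) for j in range(k)], axis=-1)
            cio.save_volume(outdir / f"factors_k{k}.nii.gz", w4d, stack.affine)
            cio.write_json(outdir / f"fit_k{k}.json", {
                "k": k, "recon_error": model.recon_error, "mre": model.mre,
                "n_iter": model.n_iter, "converged": model.converged,
                "orthogonality_residual": model.orthogonality_residual,
            })


def stage_select_k(cfg: PipelineConfig) -> None:
    deform = _load_deformation(cfg)
    mask_a, _ = cio.load_volume(cfg.root / "preprocessed" / "species_a" / "mask.nii.gz")
    mask_b, _ = cio.load_volume(cfg.root / "preprocessed" / "species_b" / "mask.nii.gz")
    mask_a, mask_b = mask_a > 0, mask_b > 0
    aris = []
    per_parcel = {}
    for k in cfg.ks:
        la, _ = cio.load_volume(cfg.root / "fit" / "species_a" / f"parcellation_k{k}.nii.gz")
        lb, _ = cio.load_volume(cfg.root / "fit" / "species_b" / f"parcellation_k{k}.nii.gz")
        la_in_b = deform.transport_labels(la.astype(np.int32), mask_b.shape)
        joint = (la_in_b > 0) & mask_b
        mean_ari, pp = cross_species_ari(la_in_b, lb.astype(np.int32), joint)
        aris.append(mean_ari)
        per_parcel[k] = pp
    sim = SimilarityTable(k_values=np.asarray(cfg.ks), mean_ari=np.asarray(aris),
                          per_parcel_ari=per_parcel)
    curve_df = pd.read_csv(cfg.root / "fit" / "species_a" / "mre_curve.tsv", sep="\t")
    curve = GranularityCurve(
        k_values=curve_df["k"].to_numpy(),
        mre=np.empty((0, len(curve_df))),
        mre_mean=curve_df["mre_mean"].to_numpy(),
        mre_sd=curve_df["mre_sd"].to_numpy(),
        delta_mre_mean=curve_df["delta_mre_mean"].to_numpy(),
        delta_mre_sd=curve_df["delta_mre_sd"].to_numpy(),
        n_boot=cfg.n_boot, seed=cfg.seed,
    )
    sel = select_granularity(curve, sim, plateau_fraction=cfg.plateau_fraction)
    pd.DataFrame({"k": cfg.ks, "mean_ari": aris}).to_csv(
        cfg.root / "fit" / "similarity.tsv", sep="\t", index=False)
    cio.write_json(cfg.root / "fit" / "selection.json", {
        "selected_k": sel.k,
        "plateau_window": sel.plateau_window,
        "used_fallback": sel.used_fallback,
        "mean_ari": aris,
        "per_parcel_ari_selected": per_parcel.get(sel.k, {}),
    })


def _selected_k(cfg: PipelineConfig) -> int:
    import json
    return int(json.loads((cfg.root / "fit" / "selection.json").read_text())["selected_k"])


def stage_expansion(cfg: PipelineConfig) -> None:
    spec_a = cfg.spec("a")
    deform = _load_deformation(cfg)
    disp, affine = cio.load_volume(cfg.root / "deformation" / "displacement.nii.gz")
    mask_a, _ = cio.load_volume(cfg.root / "preprocessed" / "species_a" / "mask.nii.gz")
    mask_a = mask_a > 0
    jac = jacobian_determinant(disp, spec_a.voxel_size_mm, mask=mask_a)
    voxvol = spec_a.voxel_size_mm ** 3 / 1000.0
    target_vol = deform.target_mask_volume_ml(mask_a)
    source_vol = mask_a.sum() * voxvol
    # the deformed source mask plays the target template's brain mask
    ratio = target_vol / source_vol
    expmap = relative_expansion(jac, mask_a, mask_a, voxvol, voxvol * ratio)
    k = _selected_k(cfg)
    labels, _ = cio.load_volume(cfg.root / "fit" / "species_a" / f"parcellation_k{k}.nii.gz")
    ids, means, z = parcel_expansion(expmap, labels.astype(np.int32))
    outdir = cfg.root / "expansion"
    outdir.mkdir(parents=True, exist_ok=True)
    cio.save_volume(outdir / "jacobian.nii.gz", jac, affine)
    cio.save_volume(outdir / "relative_expansion.nii.gz", expmap.relative, affine)
    pd.DataFrame({"parcel_id": ids, "mean_expansion": means, "z": z}).to_csv(
        outdir / "parcel_expansion.tsv", sep="\t", index=False)
    cio.write_json(outdir / "expansion.json", {"global_ratio": expmap.global_ratio, "k": k})


def stage_aging(cfg: PipelineConfig) -> None:
    k = _selected_k(cfg)
    outdir = cfg.root / "aging"
    outdir.mkdir(parents=True, exist_ok=True)
    ref_max_age = None
    for name in ("species_a", "species_b"):
        stack, _ = cio.load_species_dataset(cfg.root / "preprocessed" / name)
        labels, _ = cio.load_volume(cfg.root / "fit" / name / f"parcellation_k{k}.nii.gz")
        lab_vec = labels.astype(np.int32)[stack.mask]
        cov = stack.covariates
        if name == "species_a":
            ref_max_age = float(cov["age"].max())
            cutoff, kept = None, np.arange(len(cov))
        else:
            cutoff, kept = match_age_range(cov["age"], ref_max_age, cfg.age_match_factor)
        sub = stack
        if len(kept) != len(cov):
            sub = type(stack)(
                data=stack.data[:, kept], mask=stack.mask, affine=stack.affine,
                covariates=cov.iloc[kept].reset_index(drop=True),
            )
        vols = parcel_gm_volumes(sub, lab_vec)
        table = fit_aging_model(vols, sub.covariates, alpha=cfg.alpha,
                                signed=cfg.signed_decline)
        table.to_csv(outdir / f"aging_{name}.tsv", sep="\t")
        frac = gm_fraction_regression(
            vols.sum(axis=0).to_numpy(), sub.covariates["tiv"], sub.covariates["age"])
        cio.write_json(outdir / f"gm_fraction_{name}.json", {
            "r_squared": frac.r_squared, "p_value": frac.p_value,
            "slope": frac.slope, "intercept": frac.intercept,
            "n": frac.n, "age_cutoff": cutoff,
        })


def stage_correlate(cfg: PipelineConfig) -> None:
    aging = pd.read_csv(cfg.root / "aging" / "aging_species_a.tsv", sep="\t",
                        index_col="parcel_id")
    expand = pd.read_csv(cfg.root / "expansion" / "parcel_expansion.tsv", sep="\t",
                         index_col="parcel_id")
    common = aging.index.intersection(expand.index)
    if len(common) < 3:
        raise PipelineError("fewer than 3 parcels shared between aging and expansion")
    res = permutation_correlation(
        aging.loc[common, "decline_metric"], expand.loc[common, "z"],
        n_perm=cfg.n_perm, tail=cfg.tail, seed=cfg.seed,
    )
    cio.write_json(cfg.root / "association.json", {
        "r": res.r, "p_perm": res.p_perm, "n_perm": res.n_perm,
        "n_parcels": res.n_parcels, "tail": res.tail,
        "seed": res.seed, "exhaustive": res.exhaustive,
    })


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "fit": stage_fit,
    "select-k": stage_select_k,
    "expansion": stage_expansion,
    "aging": stage_aging,
    "correlate": stage_correlate,
}


def run_pipeline(cfg: PipelineConfig, stages=None) -> dict:
    """Execute (a subset of) the workflow and write a manifest.

    Stage failures raise :class:`PipelineError` naming the stage; outputs of
    completed stages are preserved on disk so the run can resume from the
    failed stage.
    """
    stages = list(stages) if stages is not None else list(STAGES)
    for s in stages:
        if s not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {s!r}; valid: {STAGES}")
    cfg.root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": crossmorph.__version__,
        "seed": cfg.seed,
        "config": {k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
        "stages_run": [],
    }
    for s in stages:
        try:
            _STAGE_FUNCS[s](cfg)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage {s!r} failed: {exc}") from exc
        manifest["stages_run"].append(s)
        _record_outputs(cfg, manifest, s)
    cio.write_json(cfg.root / "manifest.json", manifest)
    return manifest
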