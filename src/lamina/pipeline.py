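"""End-to-end orchestration on synthetic data.

Stages are isolated: each consumes only files written by earlier stages
into the output directory, so any stage can be re-run in place.

    synth  ->  glm  ->  conncorr            (residual correlation analysis)
           \->  vaso -> laminar             (CBV depth profiles + depth BML)
           \->  roibin                      (eccentricity-bin BML)
            -> bml                          (ROI-level valence-index BML)

A single global seed fans out to per-(stage, subject, run) seeds through
``SeedSequence`` spawn keys, so stages draw from independent streams and
re-running with the same configuration reproduces all non-MCMC outputs
byte-for-byte (MCMC outputs are reproducible conditional on the sampler
version).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bml as bml_mod
from . import conncorr, glm, io, laminar, roibin, synth, vaso
from .design import FACE_CONDITIONS, make_block_design

log = logging.getLogger("lamina")

STAGES = ["synth", "glm", "conncorr", "vaso", "laminar", "roibin", "bml"]


@dataclass
class PipelineConfig:
    """Serializable configuration of a full synthetic-cohort analysis."""

    seed: int = 0
    protocol: str = "7T-BOLD"
    n_subjects: int = 15
    runs_per_subject: int = 3
    rois: tuple[str, ...] = synth.DEFAULT_ROIS
    noise_sd: float = 1.0
    ar1_coef: float = 0.3
    # VASO / laminar
    n_vaso_subjects: int = 10
    vaso_grid: tuple[int, int, int] = (24, 25, 5)
    ribbon_thickness: int = 21
    n_depth_bins: int = 21
    upsample_factor: int = 4
    # eccentricity
    n_ecc_subjects: int = 14
    ecc_grid: tuple[int, int, int] = (36, 3, 3)
    ecc_edges: tuple[float, ...] = roibin.DEFAULT_ECC_EDGES
    # analysis
    fir_window: float | None = None  # None: one design period (block + fixation)
    bml_chains: int = 4
    bml_iterations: int = 1000
    bonferroni: str = "cells"  # or "rois"

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("rois", "vaso_grid", "ecc_grid", "ecc_edges"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for k in ("rois", "vaso_grid", "ecc_grid", "ecc_edges"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def stage_seed(cfg_seed: int, stage: str, *indices: int) -> int:
    """Deterministic per-(stage, index...) integer seed below 2**31."""
    key = [cfg_seed, STAGES.index(stage)] + list(indices)
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31))


def _subdir(out: Path, name: str) -> Path:
    p = out / name
    p.mkdir(parents=True, exist_ok=True)
    return p


# --------------------------------------------------------------------------
# synth


def stage_synth(cfg: PipelineConfig, out: Path) -> None:
    """Generate designs, BOLD ROI runs, VASO pairs, ribbon, eccentricity data."""
    t0 = time.time()
    root = _subdir(out, "synth")
    io.write_yaml(root / "config.yaml", cfg.to_dict())
    designs = _subdir(root, "designs")
    bold = _subdir(root, "bold")
    for s in range(cfg.n_subjects):
        for r in range(cfg.runs_per_subject):
            d_seed = stage_seed(cfg.seed, "synth", 0, s, r)
            design = make_block_design(cfg.protocol, d_seed)
            io.write_events(designs / f"sub-{s:02d}_run-{r:02d}_events.tsv", design.events)
            scfg = synth.SyntheticConfig(
                seed=stage_seed(cfg.seed, "synth", 1, s, r),
                protocol=cfg.protocol,
                roi_names=tuple(cfg.rois),
                shared_latent_coupling=synth.default_couplings(cfg.rois),
                noise_sd=cfg.noise_sd,
                ar1_coef=cfg.ar1_coef,
            )
            runs = synth.simulate_bold_runs(design, scfg)
            df = pd.DataFrame({roi: runs[roi].data for roi in cfg.rois})
            df.to_csv(bold / f"sub-{s:02d}_run-{r:02d}_series.tsv", sep="\t", index=False)

    # VASO: one run per VASO subject on a shared ribbon grid
    vroot = _subdir(root, "vaso")
    ribbon, _ = synth.make_ribbon_and_eccentricity(
        cfg.vaso_grid, thickness=cfg.ribbon_thickness, n_bins=cfg.n_depth_bins
    )
    io.save_mask(vroot / "ribbon_wm.nii.gz", ribbon.wm_boundary)
    io.save_mask(vroot / "ribbon_csf.nii.gz", ribbon.csf_boundary)
    io.save_mask(vroot / "ribbon_gray.nii.gz", ribbon.gray_mask)
    for s in range(cfg.n_vaso_subjects):
        design = make_block_design("7T-VASO", stage_seed(cfg.seed, "synth", 2, s))
        io.write_events(vroot / f"sub-{s:02d}_events.tsv", design.events)
        scfg = synth.SyntheticConfig(
            seed=stage_seed(cfg.seed, "synth", 3, s),
            protocol="7T-VASO",
            roi_names=tuple(cfg.rois),
        )
        nulled, notnulled = synth.simulate_vaso_run(design, scfg, ribbon)
        io.save_volume(vroot / f"sub-{s:02d}_nulled.nii.gz", np.moveaxis(nulled.data, 0, -1))
        io.save_volume(vroot / f"sub-{s:02d}_notnulled.nii.gz", np.moveaxis(notnulled.data, 0, -1))

    # eccentricity-mapped voxel runs
    eroot = _subdir(root, "ecc")
    emap = synth.make_eccentricity_map(cfg.ecc_grid)
    io.save_volume(eroot / "eccentricity.nii.gz", emap.values)
    io.save_mask(eroot / "v1_mask.nii.gz", np.ones(cfg.ecc_grid, dtype=bool))
    for s in range(cfg.n_ecc_subjects):
        design = make_block_design(cfg.protocol, stage_seed(cfg.seed, "synth", 4, s))
        io.write_events(eroot / f"sub-{s:02d}_events.tsv", design.events)
        scfg = synth.SyntheticConfig(
            seed=stage_seed(cfg.seed, "synth", 5, s),
            protocol=cfg.protocol,
            roi_names=tuple(cfg.rois),
            noise_sd=cfg.noise_sd,
            ar1_coef=cfg.ar1_coef,
        )
        run = synth.simulate_retinotopic_run(design, scfg, emap)
        io.save_volume(eroot / f"sub-{s:02d}_series.nii.gz", np.moveaxis(run.data, 0, -1))
    log.info("stage synth done in %.1f s", time.time() - t0)


# --------------------------------------------------------------------------
# glm


def stage_glm(cfg: PipelineConfig, out: Path) -> None:
    """Canonical-HRF betas per (subject, ROI, condition) and FIR residuals."""
    t0 = time.time()
    root = _subdir(out, "glm")
    resid_dir = _subdir(root, "residuals")
    rows = []
    for s in range(cfg.n_subjects):
        per_run_betas = []
        for r in range(cfg.runs_per_subject):
            events = io.read_events(out / "synth" / "designs" / f"sub-{s:02d}_run-{r:02d}_events.tsv")
            design = _design_from_events(events, cfg.protocol)
            df = pd.read_csv(out / "synth" / "bold" / f"sub-{s:02d}_run-{r:02d}_series.tsv", sep="\t")
            y = df.to_numpy()
            X = glm.build_design_matrix(design, y.shape[0], design.tr, basis="canonical-hrf")
            fit = glm.fit_glm(y, X)
            per_run_betas.append(fit)
            _, fir_fit = glm.deconvolve_evoked(y, design, fir_window=cfg.fir_window)
            pd.DataFrame(fir_fit.residual, columns=df.columns).to_csv(
                resid_dir / f"sub-{s:02d}_run-{r:02d}.tsv", sep="\t", index=False
            )
        for ri, roi in enumerate(cfg.rois):
            for cond in FACE_CONDITIONS:
                beta = float(np.mean([f.beta(cond)[ri] for f in per_run_betas]))
                r2 = float(np.mean([np.atleast_1d(f.r2)[ri] for f in per_run_betas]))
                rows.append((f"sub-{s:02d}", roi, cond, beta, r2))
    pd.DataFrame(rows, columns=["subject", "roi", "condition", "beta", "r2"]).to_csv(
        root / "betas.tsv", sep="\t", index=False
    )
    log.info("stage glm done in %.1f s", time.time() - t0)


def _design_from_events(events, protocol):
    from .design import PROTOCOLS, BlockDesign

    face_dur, fix_dur, n_rep, tr = PROTOCOLS[protocol]
    end = max(o + d for _, o, d in events)
    n_tr = int(np.ceil(end / tr - 1e-9))
    return BlockDesign(events=events, run_duration=n_tr * tr, tr=tr, protocol=protocol)


# --------------------------------------------------------------------------
# conncorr


def stage_conncorr(cfg: PipelineConfig, out: Path) -> None:
    """Per-condition residual correlation matrices, contrasts and tests."""
    t0 = time.time()
    root = _subdir(out, "conncorr")
    rois = list(cfg.rois)
    per_subject: dict[str, list[pd.DataFrame]] = {c: [] for c in FACE_CONDITIONS}
    for s in range(cfg.n_subjects):
        runs = []
        for r in range(cfg.runs_per_subject):
            events = io.read_events(out / "synth" / "designs" / f"sub-{s:02d}_run-{r:02d}_events.tsv")
            design = _design_from_events(events, cfg.protocol)
            df = pd.read_csv(out / "glm" / "residuals" / f"sub-{s:02d}_run-{r:02d}.tsv", sep="\t")
            runs.append(({roi: df[roi].to_numpy() for roi in rois}, design))
        epochs = {c: conncorr.concatenate_runs(runs, c) for c in FACE_CONDITIONS}
        mats = conncorr.correlation_matrices(epochs, rois)
        for c in FACE_CONDITIONS:
            per_subject[c].append(mats.r[c])
            mats.r[c].to_csv(root / f"sub-{s:02d}_corr_{c}.tsv", sep="\t")
    m_cells = len(rois) if cfg.bonferroni == "rois" else None
    for c in FACE_CONDITIONS:
        avg = conncorr.average_sessions(per_subject[c])
        avg.to_csv(root / f"group_corr_{c}.tsv", sep="\t")
        conncorr.matrix_tests(per_subject[c], kind="baseline", correction_cells=m_cells).to_csv(
            root / f"tests_baseline_{c}.tsv", sep="\t", index=False
        )
    for c1 in ("fearful", "happy"):
        diffs = [f - n for f, n in zip(per_subject[c1], per_subject["neutral"])]
        conncorr.average_sessions(diffs).to_csv(
            root / f"group_contrast_{c1}-neutral.tsv", sep="\t"
        )
        conncorr.matrix_tests(diffs, kind="contrast", correction_cells=m_cells).to_csv(
            root / f"tests_contrast_{c1}-neutral.tsv", sep="\t", index=False
        )
    log.info("stage conncorr done in %.1f s", time.time() - t0)


# --------------------------------------------------------------------------
# vaso


def stage_vaso(cfg: PipelineConfig, out: Path) -> None:
    """Interleave, split, align and BOLD-correct the VASO runs."""
    t0 = time.time()
    root = _subdir(out, "vaso")
    src = out / "synth" / "vaso"
    for s in range(cfg.n_vaso_subjects):
        events = io.read_events(src / f"sub-{s:02d}_events.tsv")
        design = _design_from_events(events, "7T-VASO")
        nulled = np.moveaxis(io.load_volume(src / f"sub-{s:02d}_nulled.nii.gz"), -1, 0)
        notnulled = np.moveaxis(io.load_volume(src / f"sub-{s:02d}_notnulled.nii.gz"), -1, 0)
        pair = vaso.VasoPair(
            nulled=synth.RunSeries(nulled, tr=design.tr, modality="nulled", design=design,
                                   t0=vaso.TR_NULLED / 2.0),
            notnulled=synth.RunSeries(notnulled, tr=design.tr, modality="not-nulled", design=design,
                                      t0=vaso.TR_NULLED + vaso.TR_NOTNULLED / 2.0),
            effective_tr=design.tr,
        )
        # exercise the interleave round trip before alignment
        pair = vaso.split_interleaved(vaso.interleave(pair), nulled_first=True)
        pair.nulled.design = pair.notnulled.design = design
        aligned = vaso.align_and_trim(pair)
        corrected = vaso.bold_correct(aligned)
        io.save_volume(root / f"sub-{s:02d}_vaso_pct.nii.gz", np.moveaxis(corrected.data, 0, -1))
        anat, _ = vaso.vaso_anatomy(pair)
        io.save_volume(root / f"sub-{s:02d}_anatomy.nii.gz", np.nan_to_num(anat))
        io.write_yaml(
            root / f"sub-{s:02d}_timing.yaml",
            {"t0": float(corrected.t0), "tr": float(corrected.tr)},
        )
    log.info("stage vaso done in %.1f s", time.time() - t0)


# --------------------------------------------------------------------------
# laminar


def stage_laminar(cfg: PipelineConfig, out: Path) -> None:
    """Depth profiles per condition, smoothed pooled profile, per-depth BML."""
    t0 = time.time()
    root = _subdir(out, "laminar")
    src = out / "synth" / "vaso"
    ribbon = laminar.grow_depths(
        io.load_mask(src / "ribbon_wm.nii.gz"),
        io.load_mask(src / "ribbon_csf.nii.gz"),
        io.load_mask(src / "ribbon_gray.nii.gz"),
        n_bins=cfg.n_depth_bins,
    )
    fine_ribbon = laminar.upsample_ribbon(ribbon, cfg.upsample_factor)
    rows = []
    pooled = []
    for s in range(cfg.n_vaso_subjects):
        events = io.read_events(src / f"sub-{s:02d}_events.tsv")
        design = _design_from_events(events, "7T-VASO")
        data = np.moveaxis(io.load_volume(out / "vaso" / f"sub-{s:02d}_vaso_pct.nii.gz"), -1, 0)
        timing = io.read_yaml(out / "vaso" / f"sub-{s:02d}_timing.yaml")
        flat = data.reshape(data.shape[0], -1)
        X = glm.build_design_matrix(design, flat.shape[0], timing["tr"], t0=timing["t0"])
        fit = glm.fit_glm(flat, X)
        r2_vol = np.asarray(fit.r2).reshape(data.shape[1:])
        cond_profiles = {}
        for cond in FACE_CONDITIONS:
            beta_vol = fit.beta(cond).reshape(data.shape[1:])
            prof = laminar.extract_depth_profile(
                laminar.upsample_inplane(beta_vol, cfg.upsample_factor),
                laminar.upsample_inplane(r2_vol, cfg.upsample_factor),
                fine_ribbon,
                fine_ribbon.gray_mask,
            )
            cond_profiles[cond] = prof
            for b in range(prof.n_bins):
                rows.append((f"sub-{s:02d}", cond, b, prof.depth_centers[b], prof.mean[b], prof.se[b]))
        all_faces = laminar.DepthProfile(
            mean=np.mean([cond_profiles[c].mean for c in FACE_CONDITIONS], axis=0),
            se=np.mean([cond_profiles[c].se for c in FACE_CONDITIONS], axis=0),
            n_voxels=cond_profiles["fearful"].n_voxels,
            n_bins=cfg.n_depth_bins,
            slices_used=cond_profiles["fearful"].slices_used,
        )
        pooled.append(all_faces)
    prof_df = pd.DataFrame(rows, columns=["subject", "condition", "bin", "depth_fraction", "mean", "se"])
    prof_df.to_csv(root / "profiles.tsv", sep="\t", index=False)

    group = laminar.DepthProfile(
        mean=np.mean([p.mean for p in pooled], axis=0),
        se=np.std([p.mean for p in pooled], axis=0, ddof=1) / np.sqrt(len(pooled)),
        n_voxels=pooled[0].n_voxels,
        n_bins=cfg.n_depth_bins,
    )
    smoothed = laminar.smooth_profile(group)
    smoothed.to_frame().to_csv(root / "group_profile_allfaces.tsv", sep="\t", index=False)

    # per-depth BML on (condition, depth-bin, subject) means
    y = np.empty((len(FACE_CONDITIONS), cfg.n_depth_bins, cfg.n_vaso_subjects))
    for ic, cond in enumerate(FACE_CONDITIONS):
        sub = prof_df[prof_df.condition == cond]
        for s in range(cfg.n_vaso_subjects):
            y[ic, :, s] = sub[sub.subject == f"sub-{s:02d}"].sort_values("bin")["mean"].to_numpy()
    data = bml_mod.BmlData(
        y=y,
        conditions=list(FACE_CONDITIONS),
        regions=[f"depth{b:02d}" for b in range(cfg.n_depth_bins)],
        subjects=[f"sub-{s:02d}" for s in range(cfg.n_vaso_subjects)],
    )
    post = bml_mod.fit_bml(
        data,
        chains=cfg.bml_chains,
        iterations=cfg.bml_iterations,
        seed=stage_seed(cfg.seed, "laminar", 0),
    )
    _write_contrast_summary(post, root / "depth_bml_summary.tsv")
    bml_mod.diagnostics(post).to_csv(root / "depth_bml_diagnostics.tsv", sep="\t", index=False)
    log.info("stage laminar done in %.1f s", time.time() - t0)


def _write_contrast_summary(post: bml_mod.BmlPosterior, path: Path) -> None:
    rows = []
    for c1, c2 in (("fearful", "neutral"), ("happy", "neutral")):
        if c1 not in post.conditions or c2 not in post.conditions:
            continue
        for region in post.regions:
            d = post.region_contrast(c1, c2, region)
            idx = post.region_modulation_index(c1, c2, region)
            rows.append(
                (
                    f"{c1}-{c2}",
                    region,
                    float(d.mean()),
                    float(np.quantile(d, 0.025)),
                    float(np.quantile(d, 0.975)),
                    bml_mod.posterior_positive_prob(d),
                    float(idx.mean()),
                    float(np.quantile(idx, 0.025)),
                    float(np.quantile(idx, 0.975)),
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "contrast", "region", "mean", "q2.5", "q97.5", "p_plus",
            "index_mean", "index_q2.5", "index_q97.5",
        ],
    ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# roibin (eccentricity analysis)


def stage_roibin(cfg: PipelineConfig, out: Path) -> None:
    """Eccentricity binning and the per-bin valence-contrast BML."""
    t0 = time.time()
    root = _subdir(out, "roibin")
    src = out / "synth" / "ecc"
    emap = roibin.EccentricityMap(
        values=io.load_volume(src / "eccentricity.nii.gz"),
        valid=io.load_mask(src / "v1_mask.nii.gz"),
    )
    labelled, labels = roibin.bin_by_eccentricity(emap, cfg.ecc_edges)
    masks = roibin.bin_masks(labelled, len(labels))
    pd.DataFrame(
        {
            "bin": labels,
            "n_voxels": [int(m.sum()) for m in masks],
            "mean_ecc": [float(emap.values[m].mean()) if m.any() else np.nan for m in masks],
        }
    ).to_csv(root / "ecc_bins.tsv", sep="\t", index=False)
    central, peripheral = roibin.define_stimulus_and_peripheral_v1(emap, emap.valid)
    io.save_mask(root / "v1_central.nii.gz", central)
    io.save_mask(root / "v1_peripheral.nii.gz", peripheral)

    rows = []
    for s in range(cfg.n_ecc_subjects):
        events = io.read_events(src / f"sub-{s:02d}_events.tsv")
        design = _design_from_events(events, cfg.protocol)
        data = np.moveaxis(io.load_volume(src / f"sub-{s:02d}_series.nii.gz"), -1, 0)
        flat = data.reshape(data.shape[0], -1)
        X = glm.build_design_matrix(design, flat.shape[0], design.tr)
        fit = glm.fit_glm(flat, X)
        for cond in FACE_CONDITIONS:
            beta_vol = fit.beta(cond).reshape(data.shape[1:])
            for bi, m in enumerate(masks):
                if m.any():
                    rows.append((f"sub-{s:02d}", labels[bi], cond, float(beta_vol[m].mean())))
    beta_df = pd.DataFrame(rows, columns=["subject", "bin", "condition", "beta"])
    beta_df.to_csv(root / "ecc_betas.tsv", sep="\t", index=False)
    (
        beta_df.groupby("bin", sort=False)["beta"].mean().rename("mean_beta").reset_index()
    ).to_csv(root / "ecc_profile.tsv", sep="\t", index=False)

    # 2-condition BML over the eccentricity bins (fearful vs neutral)
    sub = beta_df[beta_df.condition.isin(["fearful", "neutral"])]
    bins_present = [b for b in labels if (sub.bin == b).any()]
    y = np.empty((2, len(bins_present), cfg.n_ecc_subjects))
    for ic, cond in enumerate(("fearful", "neutral")):
        for ib, b in enumerate(bins_present):
            for s in range(cfg.n_ecc_subjects):
                v = sub[(sub.condition == cond) & (sub.bin == b) & (sub.subject == f"sub-{s:02d}")]
                y[ic, ib, s] = float(v.beta.iloc[0])
    data = bml_mod.BmlData(
        y=y,
        conditions=["fearful", "neutral"],
        regions=bins_present,
        subjects=[f"sub-{s:02d}" for s in range(cfg.n_ecc_subjects)],
    )
    post = bml_mod.fit_bml(
        data,
        chains=cfg.bml_chains,
        iterations=cfg.bml_iterations,
        seed=stage_seed(cfg.seed, "roibin", 0),
    )
    _write_contrast_summary(post, root / "ecc_bml_summary.tsv")
    bml_mod.diagnostics(post).to_csv(root / "ecc_bml_diagnostics.tsv", sep="\t", index=False)
    log.info("stage roibin done in %.1f s", time.time() - t0)


# --------------------------------------------------------------------------
# bml (ROI-level valence indices)


def stage_bml(cfg: PipelineConfig, out: Path) -> None:
    """ROI-level Bayesian multilevel model of the three condition betas."""
    t0 = time.time()
    root = _subdir(out, "bml")
    betas = pd.read_csv(out / "glm" / "betas.tsv", sep="\t")
    rois = list(cfg.rois)
    subjects = sorted(betas.subject.unique())
    y = np.empty((len(FACE_CONDITIONS), len(rois), len(subjects)))
    for ic, cond in enumerate(FACE_CONDITIONS):
        for ir, roi in enumerate(rois):
            for isub, s in enumerate(subjects):
                v = betas[(betas.condition == cond) & (betas.roi == roi) & (betas.subject == s)]
                y[ic, ir, isub] = float(v.beta.iloc[0])
    data = bml_mod.BmlData(
        y=y, conditions=list(FACE_CONDITIONS), regions=rois, subjects=subjects
    )
    post = bml_mod.fit_bml(
        data,
        chains=cfg.bml_chains,
        iterations=cfg.bml_iterations,
        seed=stage_seed(cfg.seed, "bml", 0),
    )
    _write_contrast_summary(post, root / "roi_posterior.tsv")
    bml_mod.diagnostics(post).to_csv(root / "roi_diagnostics.tsv", sep="\t", index=False)
    # ridgeline-ready quantiles of the per-ROI modulation-index posteriors
    qs = np.arange(1, 100) / 100.0
    rows = []
    for c1 in ("fearful", "happy"):
        for roi in rois:
            idx = post.region_modulation_index(c1, "neutral", roi)
            rows.append([f"{c1}-neutral", roi] + list(np.quantile(idx, qs)))
    pd.DataFrame(rows, columns=["contrast", "region"] + [f"q{int(q*100):02d}" for q in qs]).to_csv(
        root / "roi_index_quantiles.tsv", sep="\t", index=False
    )
    log.info("stage bml done in %.1f s", time.time() - t0)


# --------------------------------------------------------------------------


STAGE_FUNCS = {
    "synth": stage_synth,
    "glm": stage_glm,
    "conncorr": stage_conncorr,
    "vaso": stage_vaso,
    "laminar": stage_laminar,
    "roibin": stage_roibin,
    "bml": stage_bml,
}


def run_end_to_end(cfg: PipelineConfig, out: str | Path) -> dict:
    """Run every stage in order and write a machine-readable report index."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("pipeline start, seed=%d, config=%s", cfg.seed, cfg.to_dict())
    try:
        for name in STAGES:
            try:
                STAGE_FUNCS[name](cfg, out)
            except Exception as err:
                raise RuntimeError(f"stage {name!r} failed: {err}") from err
        report = {
            "config": cfg.to_dict(),
            "outputs": {
                "roi_posterior": "bml/roi_posterior.tsv",
                "roi_index_quantiles": "bml/roi_index_quantiles.tsv",
                "correlation_contrast": "conncorr/group_contrast_fearful-neutral.tsv",
                "correlation_tests": "conncorr/tests_contrast_fearful-neutral.tsv",
                "depth_profiles": "laminar/profiles.tsv",
                "group_profile": "laminar/group_profile_allfaces.tsv",
                "depth_bml": "laminar/depth_bml_summary.tsv",
                "ecc_bml": "roibin/ecc_bml_summary.tsv",
            },
        }
        io.write_json(out / "report.json", report)
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
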