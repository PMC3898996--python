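"""End-to-end orchestration: simulate -> globals -> mask -> fit ->
ROI ranking -> LGM coupling -> cross-validation -> toy demo.

Every stage writes its artifacts under one output directory and records
them, with SHA-256 checksums and the child seed it received, in a JSON
run manifest.  A failure in one adjustment mode does not abort the
others.  Two runs from the same config and master seed produce
identical manifests (NIfTI outputs are written uncompressed so their
bytes are reproducible).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adjustments import ADJUSTMENT_MODES, fit_with_adjustment
from .crossval import CVConfig, full_data_r2, run_crossval, summarize_cv
from .glm import DesignMatrix, contrast_t, fit_ols, fwe_correct, global_trend_table
from .image_ops import GMVolumeSet, make_mask
from .lgm import slope_vs_lgm
from .roi import (
    AtlasLabels,
    kendall_concordance,
    ks_normality_table,
    rank_rois,
    roi_age_summary,
    roi_mean_effect,
    roi_mean_values,
)
from .synthetic import (
    CohortSpec,
    ImageGenSpec,
    child_seeds,
    default_region_specs,
    generate_cohort,
    generate_two_region_dataset,
    generate_gm_images,
    make_synthetic_atlas,
    update_cohort_globals,
)

__all__ = ["RunConfig", "run_pipeline", "two_region_demo"]

ALL_STAGES = ("simulate", "globals", "mask", "fit", "roi", "lgm", "crossval", "toy")
#: fixed order in which stage child seeds are drawn from the master seed
SEEDED_STAGES = ("cohort", "atlas", "regions", "images", "crossval", "fwe")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    outdir: str = "vbmglobals_run"
    seed: int = 0
    n_per_decade: int = 70
    age_range: tuple[float, float] = (18.0, 77.0)
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_regions: int = 116
    coupling: str = "heterogeneous"
    pv_profile: str = "radial"
    pv_floor: float = 0.3
    noise_sd: float = 0.04
    smoothing_fwhm: float = 8.0
    mask_threshold: float = 0.1
    modes: tuple = ADJUSTMENT_MODES
    fwe_method: str = "bonferroni"
    n_perm: int = 500
    cv_iterations: int = 200
    stratify: str = "none"
    ks_mc_draws: int = 500
    stages: tuple = ALL_STAGES
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("age_range", "grid_shape", "modes", "stages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, config: RunConfig):
        self.data = {"config": config.to_dict(), "stages": {}}
        self.outdir = Path(config.outdir)

    def record(self, stage: str, files: list[Path], seed=None, status="ok",
               elapsed=None, error=None, extra=None):
        entry = {
            "status": status,
            "seed": seed,
            "elapsed_s": None if elapsed is None else round(elapsed, 3),
            "files": {
                str(p.relative_to(self.outdir)): _sha256(p) for p in files
            },
        }
        if error:
            entry["error"] = error
        if extra:
            entry.update(extra)
        self.data["stages"][stage] = entry

    def save(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)
        return path


def _write_map(values, mask, grid_shape, voxel_size, path: Path) -> None:
    """Embed masked per-voxel values into the full grid and save NIfTI."""
    import nibabel as nib

    full = np.zeros(int(np.prod(grid_shape)))
    full[mask.mask] = values
    img = nib.Nifti1Image(
        full.reshape(grid_shape),
        np.diag([voxel_size, voxel_size, voxel_size, 1.0]),
    )
    nib.save(img, str(path))


def two_region_demo(params: dict | None = None) -> pd.DataFrame:
    """Fit the four adjustment modes to the two-region toy dataset.

    The toy models contain only a centered age term and a constant (no
    TIV, no sex terms).  Local Scaling divides the slope by the constant
    and carries the unadjusted statistics over unchanged.  Returns one
    row per (mode, region) with the slope, its one-tailed p-value (in
    the direction of the estimated slope) and the full-model R^2.
    """
    from scipy import stats as sps

    data = generate_two_region_dataset(params)
    age = data["age"].to_numpy()
    d = age - age.mean()
    X = np.column_stack([d, np.ones(len(d))])
    names = ["age_lin", "const"]
    tgm = data["tgm"].to_numpy()
    rows = []

    def one_fit(y):
        dm = DesignMatrix(matrix=X, names=names, centering={}, sex_counts={})
        fit = fit_ols(y[:, None], dm)
        con = contrast_t(fit, np.array([1.0, 0.0]), tail="two")
        slope = float(con.effect[0])
        p_one = float(sps.t.sf(abs(con.t[0]), fit.df))
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float(fit.rss[0]) / tss if tss > 0 else 0.0
        const = float(fit.beta[names.index("const"), 0])
        return slope, p_one, r2, const

    def lc_fit(y):
        Xt = np.column_stack([X, tgm - tgm.mean()])
        dm = DesignMatrix(
            matrix=Xt, names=names + ["tgm"], centering={}, sex_counts={}
        )
        fit = fit_ols(y[:, None], dm)
        con = contrast_t(fit, np.array([1.0, 0.0, 0.0]), tail="two")
        p_one = float(sps.t.sf(abs(con.t[0]), fit.df))
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float(fit.rss[0]) / tss if tss > 0 else 0.0
        return float(con.effect[0]), p_one, r2

    for region, col in (("region1", "region1_gm"), ("region2", "region2_gm")):
        y = data[col].to_numpy(dtype=np.float64)
        slope, p, r2, const = one_fit(y)
        rows.append(("none", region, slope, p, r2))
        s_gs, p_gs, r2_gs, _ = one_fit(y / tgm)
        rows.append(("global_scaling", region, s_gs, p_gs, r2_gs))
        s_lc, p_lc, r2_lc = lc_fit(y)
        rows.append(("local_covariation", region, s_lc, p_lc, r2_lc))
        rows.append(("local_scaling", region, slope / const, p, r2))
    return pd.DataFrame(
        rows, columns=["mode", "region", "slope", "p_one_tailed", "r2_model"]
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest dictionary (also written to
    ``<outdir>/manifest.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    seeds = dict(zip(SEEDED_STAGES, child_seeds(config.seed, len(SEEDED_STAGES))))
    stages = set(config.stages)

    ctx: dict = {}
    if "simulate" in stages:
        t0 = time.time()
        cohort = generate_cohort(
            CohortSpec(
                n_per_decade=config.n_per_decade,
                age_range=config.age_range,
                seed=seeds["cohort"],
            )
        )
        atlas = make_synthetic_atlas(
            config.grid_shape, config.n_regions, seed=seeds["atlas"]
        )
        regions = default_region_specs(
            atlas, seed=seeds["regions"], coupling=config.coupling
        )
        imgspec = ImageGenSpec(
            grid_shape=config.grid_shape,
            pv_profile=config.pv_profile,
            pv_floor=config.pv_floor,
            noise_sd=config.noise_sd,
            smoothing_fwhm=config.smoothing_fwhm,
            seed=seeds["images"],
        )
        unsm, sm, truth = generate_gm_images(cohort, regions, atlas, imgspec)
        cohort = update_cohort_globals(cohort, unsm)
        files = []
        cohort.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
        files.append(outdir / "cohort.tsv")
        atlas.save(outdir / "atlas.nii", outdir / "atlas_labels.tsv")
        files += [outdir / "atlas.nii", outdir / "atlas_labels.tsv"]
        unsm.save(outdir / "gm_unsmoothed.nii")
        sm.save(outdir / "gm_smoothed.nii")
        files += [outdir / "gm_unsmoothed.nii", outdir / "gm_smoothed.nii"]
        truth.to_json(outdir / "ground_truth.json")
        files.append(outdir / "ground_truth.json")
        manifest.record(
            "simulate", files, seed=config.seed, elapsed=time.time() - t0,
            extra={"n_subjects": len(cohort), "clip_rate": truth.clip_rate},
        )
        ctx.update(cohort=cohort, atlas=atlas, sm=sm, unsm=unsm, truth=truth)
    else:
        ctx["cohort"] = pd.read_csv(outdir / "cohort.tsv", sep="\t")
        ctx["atlas"] = AtlasLabels.load(
            outdir / "atlas.nii", outdir / "atlas_labels.tsv"
        )
        ctx["sm"] = GMVolumeSet.from_nifti(
            outdir / "gm_smoothed.nii", subject_ids=list(ctx["cohort"]["subject_id"])
        )

    if "globals" in stages:
        t0 = time.time()
        table = global_trend_table(ctx["cohort"])
        table.to_csv(outdir / "globals_trends.tsv", sep="\t", index=False)
        manifest.record(
            "globals", [outdir / "globals_trends.tsv"], elapsed=time.time() - t0
        )

    if "mask" in stages:
        t0 = time.time()
        mask = make_mask(ctx["sm"], threshold=config.mask_threshold)
        mask.save(outdir / "mask.nii")
        manifest.record(
            "mask", [outdir / "mask.nii"], elapsed=time.time() - t0,
            extra={"n_voxels": mask.n_voxels},
        )
        ctx["mask"] = mask

    results = {}
    if "fit" in stages:
        sm, mask, cohort = ctx["sm"], ctx["mask"], ctx["cohort"]
        Y = sm.data[:, mask.mask]
        for mode in config.modes:
            t0 = time.time()
            mdir = outdir / f"fit_{mode}"
            mdir.mkdir(exist_ok=True)
            try:
                res = fit_with_adjustment(Y, cohort, mode)
                con = res.contrast
                if config.fwe_method:
                    con = fwe_correct(
                        con,
                        config.fwe_method,
                        fit=res.glm,
                        Y=Y,
                        n_perm=config.n_perm,
                        seed=seeds["fwe"],
                    )
                files = []
                for nm, vals in (
                    ("slope", res.slope),
                    ("t", con.t),
                    ("p", con.p),
                    ("p_fwe", con.p_fwe),
                    ("lgm", res.lgm),
                ):
                    if vals is None:
                        continue
                    _write_map(
                        vals, mask, sm.shape, sm.voxel_size, mdir / f"{nm}.nii"
                    )
                    files.append(mdir / f"{nm}.nii")
                if res.scaled_slope is not None:
                    _write_map(
                        np.nan_to_num(res.scaled_slope), mask, sm.shape,
                        sm.voxel_size, mdir / "scaled_slope.nii",
                    )
                    files.append(mdir / "scaled_slope.nii")
                manifest.record(
                    f"fit_{mode}", files, seed=seeds["fwe"],
                    elapsed=time.time() - t0,
                    extra={
                        "n_sig_fwe": int((con.p_fwe < 0.05).sum())
                        if con.p_fwe is not None
                        else None
                    },
                )
                results[mode] = res
            except Exception as exc:  # isolate mode failures
                manifest.record(
                    f"fit_{mode}", [], status="failed",
                    elapsed=time.time() - t0, error=str(exc),
                )
        ctx["results"] = results

    if "roi" in stages and results:
        t0 = time.time()
        atlas, mask, sm, cohort = ctx["atlas"], ctx["mask"], ctx["sm"], ctx["cohort"]
        rdir = outdir / "roi"
        rdir.mkdir(exist_ok=True)
        files = []
        rankings = {}
        for mode, res in results.items():
            eff = res.scaled_slope if mode == "local_scaling" else res.slope
            effmap = np.where(np.isnan(eff), 0.0, eff)
            per_roi = roi_mean_effect(
                _embed(effmap, mask), atlas, mask
            )
            for hemi in ("L", "R"):
                rk = rank_rois(per_roi, atlas.table, hemisphere=hemi)
                rk.to_csv(rdir / f"ranking_{mode}_{hemi}.tsv", sep="\t", index=False)
                files.append(rdir / f"ranking_{mode}_{hemi}.tsv")
            rankings[mode] = rank_rois(per_roi, atlas.table)
        taus = [
            {"mode_a": a, "mode_b": b,
             "kendall_tau": kendall_concordance(rankings[a], rankings[b])}
            for a in rankings for b in rankings if a < b
        ]
        pd.DataFrame(taus).to_csv(rdir / "kendall.tsv", sep="\t", index=False)
        files.append(rdir / "kendall.tsv")
        Y_roi = roi_mean_values(sm, atlas, mask)
        Y_roi.to_csv(rdir / "roi_means.tsv", sep="\t")
        files.append(rdir / "roi_means.tsv")
        summary = roi_age_summary(Y_roi, cohort)
        summary.to_csv(rdir / "roi_summary.tsv", sep="\t", index=False)
        files.append(rdir / "roi_summary.tsv")
        if config.ks_mc_draws:
            ks = ks_normality_table(
                Y_roi, n_mc=config.ks_mc_draws, seed=seeds["regions"]
            )
            ks.to_csv(rdir / "ks_normality.tsv", sep="\t", index=False)
            files.append(rdir / "ks_normality.tsv")
        manifest.record("roi", files, elapsed=time.time() - t0)
        ctx["Y_roi"] = Y_roi

    if "lgm" in stages and "none" in results:
        t0 = time.time()
        ldir = outdir / "lgm"
        ldir.mkdir(exist_ok=True)
        res = slope_vs_lgm(results["none"].glm, keep_histograms=config.make_plots)
        pd.DataFrame(
            [
                {
                    "r_raw": res.r_raw,
                    "p_raw": res.p_raw,
                    "r_scaled": res.r_scaled,
                    "p_scaled": res.p_scaled,
                    "n_voxels": res.n_voxels,
                    "mean_rel_constant_error": res.mean_rel_constant_error,
                }
            ]
        ).to_csv(ldir / "slope_vs_lgm.tsv", sep="\t", index=False)
        files = [ldir / "slope_vs_lgm.tsv"]
        if config.make_plots:
            files.append(_plot_lgm(res, ldir))
        manifest.record("lgm", files, elapsed=time.time() - t0)

    if "crossval" in stages:
        t0 = time.time()
        cdir = outdir / "crossval"
        cdir.mkdir(exist_ok=True)
        Y_roi = ctx.get("Y_roi")
        if Y_roi is None:
            Y_roi = pd.read_csv(outdir / "roi" / "roi_means.tsv", sep="\t", index_col=0)
            Y_roi.columns = Y_roi.columns.astype(int)
        cohort = ctx["cohort"]
        cv = run_crossval(
            Y_roi,
            cohort,
            CVConfig(
                n_iterations=config.cv_iterations,
                stratify=config.stratify,
                seed=seeds["crossval"],
            ),
        )
        summ = summarize_cv(cv)
        fd = full_data_r2(Y_roi, cohort)
        files = []
        fd.to_csv(cdir / "full_data_r2.tsv", sep="\t")
        summ.roi_medians.to_csv(cdir / "roi_medians.tsv", sep="\t")
        summ.iteration_means.to_csv(cdir / "iteration_means.tsv", sep="\t", index=False)
        files += [
            cdir / "full_data_r2.tsv",
            cdir / "roi_medians.tsv",
            cdir / "iteration_means.tsv",
        ]
        if config.make_plots:
            files.append(_plot_cv(summ, cdir))
        manifest.record(
            "crossval", files, seed=seeds["crossval"], elapsed=time.time() - t0,
            extra={
                "wins": summ.wins,
                "full_data_gs_wins": int((fd["r2_gs"] > fd["r2_lc"]).sum()),
            },
        )

    if "toy" in stages:
        t0 = time.time()
        fdir = outdir / "toy"
        fdir.mkdir(exist_ok=True)
        table = two_region_demo()
        table.to_csv(fdir / "two_region_table.tsv", sep="\t", index=False)
        files = [fdir / "two_region_table.tsv"]
        if config.make_plots:
            files.append(_plot_toy(fdir))
        manifest.record("toy", files, elapsed=time.time() - t0)

    manifest.save()
    return manifest.data


def _embed(values, mask) -> np.ndarray:
    full = np.zeros(mask.mask.size)
    full[mask.mask] = values
    return full


def _plot_lgm(res, outdir: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, hist, title, r in (
        (axes[0], res.hist_raw, "raw slope vs LGM", res.r_raw),
        (axes[1], res.hist_scaled, "scaled slope vs LGM", res.r_scaled),
    ):
        counts, xe, ye = hist
        ax.pcolormesh(ye, xe, np.log1p(counts), cmap="viridis")
        ax.set_xlabel("LGM (constant term)")
        ax.set_ylabel("linear age slope")
        ax.set_title(f"{title} (r = {r:.2f})")
    fig.tight_layout()
    path = outdir / "slope_vs_lgm.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def _plot_cv(summ, outdir: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for col, label in (
        ("gs_test", "Global Scaling (test)"),
        ("lc_test", "Local Covariation (test)"),
    ):
        ax.hist(summ.iteration_means[col], bins=40, alpha=0.6, label=label)
    ax.set_xlabel("ROI-mean variance explained by age")
    ax.set_ylabel("iterations")
    ax.legend()
    fig.tight_layout()
    path = outdir / "cv_histograms.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def _plot_toy(outdir: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = generate_two_region_dataset()
    age = data["age"].to_numpy()
    tgm = data["tgm"].to_numpy()
    panels = {
        "unadjusted": (data["region1_gm"], data["region2_gm"]),
        "global scaling": (data["region1_gm"] / tgm, data["region2_gm"] / tgm),
    }
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, (title, (y1, y2)) in zip(axes, panels.items()):
        ax.scatter(age, y1, label="region 1")
        ax.scatter(age, y2, label="region 2")
        ax.set_title(title)
        ax.set_xlabel("age (years)")
        ax.set_ylabel("GMV (a.u.)")
        ax.legend()
    fig.tight_layout()
    path = outdir / "two_region_panels.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
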