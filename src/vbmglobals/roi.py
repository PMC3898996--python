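"""Atlas-based ROI aggregation, ranking, normality checks and summaries.

ROI aggregation comes in two distinct flavours, both provided and
labelled: averaging the voxelwise *parameter-estimate* map within each
region (used for ranking regions by rate of decline), and refitting the
GLMs on per-region mean data (used for per-ROI age-trajectory summaries
and TIV-residualized plots).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats

from .adjustments import ADJUSTMENT_MODES, apply_global_scaling
from .glm import age_decline_contrast, build_design, fit_ols, partial_r2
from .image_ops import GMVolumeSet, _default_affine

__all__ = [
    "AtlasLabels",
    "roi_mean_effect",
    "roi_mean_values",
    "rank_rois",
    "kendall_concordance",
    "ks_normality",
    "ks_normality_table",
    "roi_age_summary",
    "tiv_residualize",
]


@dataclass
class AtlasLabels:
    """Integer label image (0 = background) plus a label table.

    ``table`` has columns ``label``, ``name``, ``hemisphere`` (L/R).
    """

    labels: np.ndarray  # flat int array, n_voxels
    shape: tuple[int, int, int]
    voxel_size: float
    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).ravel().astype(np.int32)
        present = set(np.unique(self.labels)) - {0}
        known = set(self.table["label"].tolist())
        orphan = sorted(present - known)
        if orphan:
            raise ValueError(f"labels in image missing from table: {orphan[:10]}")

    @property
    def label_ids(self) -> np.ndarray:
        return self.table["label"].to_numpy()

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(
            self.labels.reshape(self.shape).astype(np.int16),
            _default_affine(self.voxel_size),
        )

    def save(self, image_path: str | Path, table_path: str | Path) -> None:
        nib.save(self.to_nifti(), str(image_path))
        self.table.to_csv(table_path, sep="\t", index=False)

    @classmethod
    def load(cls, image_path: str | Path, table_path: str | Path) -> "AtlasLabels":
        img = nib.load(str(image_path))
        arr = np.asarray(img.dataobj)
        return cls(
            labels=arr.ravel(),
            shape=arr.shape,
            voxel_size=float(np.abs(img.affine[0, 0])),
            table=pd.read_csv(table_path, sep="\t"),
        )


def _check_grid(n_values: int, atlas: AtlasLabels) -> None:
    if n_values != atlas.labels.size:
        raise ValueError(
            f"map has {n_values} voxels but atlas grid has {atlas.labels.size}"
        )


def roi_mean_effect(
    effect_map: np.ndarray, atlas: AtlasLabels, mask=None
) -> pd.Series:
    """Mean of an effect map over in-mask voxels, per atlas label.

    Labels with no in-mask voxels are reported as NaN (missing).
    """
    v = np.asarray(effect_map, dtype=np.float64).ravel()
    _check_grid(v.size, atlas)
    keep = np.ones(v.size, dtype=bool) if mask is None else _mask_array(mask, atlas)
    out = {}
    for lab in atlas.label_ids:
        sel = (atlas.labels == lab) & keep
        out[lab] = float(v[sel].mean()) if sel.any() else np.nan
    return pd.Series(out, name="mean_effect")


def _mask_array(mask, atlas: AtlasLabels) -> np.ndarray:
    m = getattr(mask, "mask", mask)
    m = np.asarray(m, dtype=bool).ravel()
    _check_grid(m.size, atlas)
    return m


def roi_mean_values(
    images: GMVolumeSet, atlas: AtlasLabels, mask=None
) -> pd.DataFrame:
    """Per-subject ROI means: subjects x regions DataFrame.

    Rows follow the image-set subject order; columns are atlas labels.
    """
    _check_grid(images.n_voxels, atlas)
    keep = (
        np.ones(images.n_voxels, dtype=bool) if mask is None else _mask_array(mask, atlas)
    )
    cols = {}
    for lab in atlas.label_ids:
        sel = (atlas.labels == lab) & keep
        cols[lab] = images.data[:, sel].mean(axis=1) if sel.any() else np.full(
            images.n_subjects, np.nan
        )
    return pd.DataFrame(cols, index=images.subject_ids)


def rank_rois(
    effects: pd.Series, atlas_table: pd.DataFrame, hemisphere: str | None = None
) -> pd.DataFrame:
    """Rank ROIs by mean linear age effect, most negative first.

    Ties are broken by atlas label order (recorded in ``tie_rule``).
    """
    tab = atlas_table.copy()
    if hemisphere is not None:
        tab = tab[tab["hemisphere"] == hemisphere]
    tab = tab.merge(
        effects.rename("effect"), left_on="label", right_index=True, how="left"
    )
    if tab["effect"].isna().any():
        missing = tab.loc[tab["effect"].isna(), "label"].tolist()
        raise ValueError(f"no effect value for labels: {missing[:10]}")
    tab = tab.sort_values(["effect", "label"], kind="mergesort").reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    tab.attrs["tie_rule"] = "ties broken by ascending atlas label"
    return tab


def kendall_concordance(ranking_a: pd.DataFrame, ranking_b: pd.DataFrame) -> float:
    """Kendall's tau between two ROI rankings (aligned by label)."""
    a = ranking_a.set_index("label")["effect"]
    b = ranking_b.set_index("label")["effect"]
    common = a.index.intersection(b.index)
    tau, _ = stats.kendalltau(a.loc[common], b.loc[common])
    return float(tau)


def ks_normality(
    x, n_mc: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Kolmogorov–Smirnov test of normality with estimated parameters.

    Lilliefors-style: the KS statistic is computed against a normal with
    the sample mean and SD, and its null distribution is obtained by a
    seeded Monte-Carlo (``n_mc`` draws of the same size, parameters
    re-estimated each time).  Returns ``(statistic, p)``; a constant
    input is reported as p = 0 with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("constant input; normality rejected by convention")
        return np.inf, 0.0
    stat = stats.kstest(x, "norm", args=(x.mean(), sd)).statistic
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_mc, n))
    mu = draws.mean(axis=1, keepdims=True)
    s = draws.std(axis=1, ddof=1, keepdims=True)
    z = np.sort((draws - mu) / s, axis=1)
    grid = np.arange(1, n + 1) / n
    cdf = stats.norm.cdf(z)
    null = np.maximum(np.abs(grid - cdf), np.abs(grid - 1.0 / n - cdf)).max(axis=1)
    p = (1.0 + (null >= stat).sum()) / (n_mc + 1.0)
    return float(stat), float(p)


def ks_normality_table(
    Y_roi: pd.DataFrame, residuals: np.ndarray | None = None,
    n_mc: int = 2000, seed: int = 0,
) -> pd.DataFrame:
    """Per-ROI KS normality p-values for the data and, optionally, the
    residuals of a fitted model (columns aligned with ``Y_roi``)."""
    rows = []
    for j, lab in enumerate(Y_roi.columns):
        _, p_data = ks_normality(Y_roi[lab].to_numpy(), n_mc=n_mc, seed=seed + 2 * j)
        row = {"label": lab, "p_data": p_data}
        if residuals is not None:
            _, p_res = ks_normality(residuals[:, j], n_mc=n_mc, seed=seed + 2 * j + 1)
            row["p_residuals"] = p_res
        rows.append(row)
    return pd.DataFrame(rows)


def tiv_residualize(Y_roi: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Remove the TIV fit (plus per-sex means) for plotting.

    Returns residuals after regressing each ROI's values on per-sex
    constants and mean-centered TIV, with the grand mean added back so
    the values stay on the GM-density scale.
    """
    design = build_design(cohort, include_age=False, include_tiv=True)
    Y = Y_roi.to_numpy(dtype=np.float64)
    fit = fit_ols(Y, design)
    resid = Y - design.matrix @ fit.beta
    out = resid + Y.mean(axis=0, keepdims=True)
    return pd.DataFrame(out, index=Y_roi.index, columns=Y_roi.columns)


def roi_age_summary(
    Y_roi: pd.DataFrame,
    cohort: pd.DataFrame,
    modes=("none", "global_scaling", "local_covariation"),
) -> pd.DataFrame:
    """Refit the voxelwise GLM suite on per-ROI mean data.

    For each ROI and adjustment mode, returns the sex-averaged linear
    age slope, its one-tailed (decline) p-value, and the partial R^2 of
    the linear age terms.
    """
    Y = Y_roi.to_numpy(dtype=np.float64)
    rows = []
    for mode in modes:
        if mode not in ADJUSTMENT_MODES:
            raise ValueError(f"unknown adjustment mode: {mode!r}")
        Ym = Y
        if mode == "global_scaling":
            Ym = apply_global_scaling(Y, cohort["tgm"].to_numpy(dtype=np.float64))
        design = build_design(cohort, include_tgm=(mode == "local_covariation"))
        fit = fit_ols(Ym, design)
        con = age_decline_contrast(fit)
        lin = [n for n in design.names if n.startswith("age_lin_")]
        reduced = design.subset([n for n in design.names if n not in lin])
        pr2 = partial_r2(fit, fit_ols(Ym, reduced))
        for j, lab in enumerate(Y_roi.columns):
            rows.append(
                {
                    "label": lab,
                    "mode": mode,
                    "slope": float(con.effect[j]),
                    "p_one_tailed": float(con.p[j]),
                    "partial_r2_linear": float(pr2[j]),
                }
            )
    return pd.DataFrame(rows)
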