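"""Voxelwise coupling between local mean GM and the linear age slope.

In partial-volume-affected data, voxels with higher mean GM (larger
constant term, "LGM") tend to show larger age-related decline, making
the raw slope map partly a map of tissue fraction.  This module
quantifies that coupling — the Pearson correlation across voxels
between the sex-averaged linear slope and the constant term — before
and after Local Scaling (dividing the slope by the LGM).  The error in
the constant-term estimate is ignored when treating LGM as an axis, but
its average relative magnitude is reported for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .adjustments import LGM_FLOOR, local_scale_slopes
from .glm import GLMFit, age_decline_contrast, lgm_map, lgm_weights

__all__ = ["SlopeLGMResult", "slope_vs_lgm"]


@dataclass
class SlopeLGMResult:
    r_raw: float
    p_raw: float
    r_scaled: float
    p_scaled: float
    n_voxels: int
    mean_rel_constant_error: float
    hist_raw: tuple | None = None  # (counts, slope_edges, lgm_edges)
    hist_scaled: tuple | None = None


def slope_vs_lgm(
    fit: GLMFit,
    mask=None,
    floor: float = LGM_FLOOR,
    bins: int = 200,
    keep_histograms: bool = True,
) -> SlopeLGMResult:
    """Correlate the linear-slope map with the constant (LGM) map.

    ``fit`` must come from an unadjusted (``none``-mode) voxelwise
    model.  The correlation is recomputed after Local Scaling (slope
    divided by LGM) with the same low-LGM exclusions applied to both.
    A 2-D histogram (``bins`` per axis) summarizes the voxel scatter.
    """
    con = age_decline_contrast(fit)
    slope = con.effect
    lgm = lgm_map(fit)
    keep = np.ones(slope.size, dtype=bool)
    if mask is not None:
        m = getattr(mask, "mask", mask)
        keep &= np.asarray(m, dtype=bool).ravel()
    scaled_all, excluded = local_scale_slopes(slope, lgm, floor=floor)
    keep &= ~excluded
    if keep.sum() < 10:
        raise ValueError("fewer than 10 usable voxels")
    s, c, sc = slope[keep], lgm[keep], scaled_all[keep]
    r_raw, p_raw = stats.pearsonr(s, c)
    r_scaled, p_scaled = stats.pearsonr(sc, c)
    # relative error of the constant-term estimate, averaged over voxels
    w = lgm_weights(fit.design)
    se_lgm = np.sqrt(fit.resid_var * float(w @ fit.xtx_inv @ w))
    rel_err = float(np.mean(se_lgm[keep] / np.abs(c)))
    hist_raw = hist_scaled = None
    if keep_histograms:
        hist_raw = np.histogram2d(s, c, bins=bins)
        hist_scaled = np.histogram2d(sc, c, bins=bins)
    return SlopeLGMResult(
        r_raw=float(r_raw),
        p_raw=float(p_raw),
        r_scaled=float(r_scaled),
        p_scaled=float(p_scaled),
        n_voxels=int(keep.sum()),
        mean_rel_constant_error=rel_err,
        hist_raw=hist_raw,
        hist_scaled=hist_scaled,
    )
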