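"""The four global-adjustment modes for regional gray-matter analyses.

Given modulated GM data ``y`` and each subject's total gray matter
``t`` (TGM):

* ``none``            — fit the age model to the raw data;
* ``global_scaling``  — divide each subject's data by their TGM first
  (proportional adjustment, uniform across voxels);
* ``local_covariation`` — add TGM as a per-unit covariate (additive
  adjustment, with a separate TGM coefficient at every unit);
* ``local_scaling``   — fit as ``none``, then divide the sex-averaged
  linear slope map by the constant-term (LGM) map.  This changes the
  effect-size map only; t and p statistics are those of the unadjusted
  fit.

TIV is always included as a covariate of no interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .glm import (
    ContrastResult,
    GLMFit,
    age_decline_contrast,
    build_design,
    contrast_t,
    fit_ols,
    lgm_map,
)

__all__ = [
    "ADJUSTMENT_MODES",
    "apply_global_scaling",
    "AdjustedAgeModel",
    "AdjustmentResult",
    "fit_with_adjustment",
    "local_scale_slopes",
]

ADJUSTMENT_MODES = ("none", "global_scaling", "local_covariation", "local_scaling")

#: below this |constant| (density units) a unit is excluded from scaled maps
LGM_FLOOR = 1e-3


def apply_global_scaling(
    Y: np.ndarray, tgm, rescale: bool = True, subject_ids=None
) -> np.ndarray:
    """Divide each subject's row by their TGM.

    With ``rescale`` the result is multiplied by the cohort-mean TGM so
    values remain interpretable GM densities; this affects beta
    magnitudes but not t or p statistics.
    """
    Y = np.asarray(Y, dtype=np.float64)
    t = np.asarray(tgm, dtype=np.float64)
    if t.shape[0] != Y.shape[0]:
        raise ValueError("tgm must have one value per subject (row of Y)")
    bad = np.where(t <= 0)[0]
    if bad.size:
        ids = (
            [subject_ids[i] for i in bad[:10]]
            if subject_ids is not None
            else bad[:10].tolist()
        )
        raise ValueError(f"nonpositive TGM for subjects: {ids}")
    out = Y / t[:, None]
    if rescale:
        out = out * t.mean()
    return out


def local_scale_slopes(
    slope: np.ndarray, lgm: np.ndarray, floor: float = LGM_FLOOR
) -> tuple[np.ndarray, np.ndarray]:
    """Scale a linear-slope map by the local mean GM map.

    Returns ``(scaled, excluded)`` where ``scaled = slope / lgm``
    (units: fraction of local mean GM per year) and ``excluded`` flags
    units with ``|lgm| < floor``, which are set to NaN to avoid division
    blow-up in low-GM voxels.
    """
    slope = np.asarray(slope, dtype=np.float64)
    lgm = np.asarray(lgm, dtype=np.float64)
    excluded = np.abs(lgm) < floor
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(excluded, np.nan, slope / np.where(excluded, 1.0, lgm))
    return scaled, excluded


@dataclass
class AdjustmentResult:
    """Everything one adjustment mode produces for a unit set."""

    mode: str
    glm: GLMFit
    contrast: ContrastResult  # sex-averaged linear decline, one-tailed
    slope: np.ndarray  # sex-averaged linear age slope per unit
    lgm: np.ndarray  # sex-weighted constant per unit
    scaled_slope: np.ndarray | None = None  # local_scaling only
    excluded: np.ndarray | None = None


class AdjustedAgeModel(BaseEstimator):
    """Age-polynomial GLM under one of the four TGM-adjustment modes.

    A scikit-learn style estimator: ``fit(cohort, Y)`` takes the cohort
    table as ``X`` (columns ``age``, ``sex``, ``tiv`` and — for Local
    Covariation — ``tgm``) and the ``(n_subjects, n_units)`` data as
    ``y``.  Fitted attributes: ``glm_``, ``contrast_``, ``slope_``,
    ``lgm_`` and, for ``local_scaling``, ``scaled_slope_``/``excluded_``.

    Parameters
    ----------
    adjustment : one of ``ADJUSTMENT_MODES``
    quadratic : include per-sex quadratic age columns
    include_tiv : include mean-centered TIV (on by default, as in every
        model of the main analysis)
    gs_rescale : re-multiply globally scaled data by the mean TGM
    lgm_floor : exclusion floor for Local Scaling
    """

    def __init__(
        self,
        adjustment: str = "none",
        quadratic: bool = True,
        include_tiv: bool = True,
        gs_rescale: bool = True,
        lgm_floor: float = LGM_FLOOR,
    ):
        self.adjustment = adjustment
        self.quadratic = quadratic
        self.include_tiv = include_tiv
        self.gs_rescale = gs_rescale
        self.lgm_floor = lgm_floor

    def fit(self, X: pd.DataFrame, y: np.ndarray):
        if self.adjustment not in ADJUSTMENT_MODES:
            raise ValueError(
                f"unknown adjustment {self.adjustment!r}; "
                f"expected one of {ADJUSTMENT_MODES}"
            )
        cohort = X
        Y = np.asarray(y, dtype=np.float64)
        if Y.ndim == 1:
            Y = Y[:, None]
        if self.adjustment == "global_scaling":
            Y = apply_global_scaling(
                Y,
                cohort["tgm"].to_numpy(dtype=np.float64),
                rescale=self.gs_rescale,
                subject_ids=list(cohort.index),
            )
        design = build_design(
            cohort,
            include_tgm=(self.adjustment == "local_covariation"),
            include_tiv=self.include_tiv,
            quadratic=self.quadratic,
        )
        glm = fit_ols(Y, design)
        self.design_ = design
        self.glm_ = glm
        self.contrast_ = age_decline_contrast(glm)
        self.slope_ = self.contrast_.effect
        self.lgm_ = lgm_map(glm)
        if self.adjustment == "local_scaling":
            self.scaled_slope_, self.excluded_ = local_scale_slopes(
                self.slope_, self.lgm_, floor=self.lgm_floor
            )
        else:
            self.scaled_slope_ = None
            self.excluded_ = None
        self.n_features_in_ = design.p
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Fitted GM values for a cohort table (training centering)."""
        design = build_design(
            X,
            include_tgm=(self.adjustment == "local_covariation"),
            include_tiv=self.include_tiv,
            quadratic=self.quadratic,
            centering=self.design_.centering,
        )
        return design.matrix @ self.glm_.beta

    def tgm_coefficients(self) -> np.ndarray:
        """Per-unit TGM coefficients (Local Covariation only)."""
        if self.adjustment != "local_covariation":
            raise ValueError("TGM coefficients exist only under local_covariation")
        return self.glm_.beta[self.design_.names.index("tgm")]


def fit_with_adjustment(
    Y: np.ndarray, cohort: pd.DataFrame, mode: str, **opts
) -> AdjustmentResult:
    """Fit one adjustment mode and package the comparable outputs."""
    model = AdjustedAgeModel(adjustment=mode, **opts).fit(cohort, Y)
    return AdjustmentResult(
        mode=mode,
        glm=model.glm_,
        contrast=model.contrast_,
        slope=model.slope_,
        lgm=model.lgm_,
        scaled_slope=model.scaled_slope_,
        excluded=model.excluded_,
    )


def compare_adjustments(
    Y: np.ndarray, cohort: pd.DataFrame, modes=ADJUSTMENT_MODES, **opts
) -> dict[str, AdjustmentResult]:
    """Run several adjustment modes on identical data and subject order."""
    return {m: fit_with_adjustment(Y, cohort, m, **opts) for m in modes}
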