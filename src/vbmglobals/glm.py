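"""Mass-univariate GLM engine for morphometry-style age analyses.

Design matrices follow the usual neuroimaging group-model convention for
"separately per sex": sex-partitioned linear and quadratic age columns
plus per-sex constants, with total-intracranial-volume (TIV) and,
optionally, total gray matter (TGM) as mean-centered nuisance covariates.

All age columns are centered so that every non-constant column has zero
grand mean.  Under that centering the sex-weighted constant term equals
the per-unit mean of the response — the "local gray matter" (LGM)
identity that the Local Scaling adjustment relies on.

The fitting core is ordinary least squares solved per unit (voxel or
ROI) on a shared design; :class:`MassUnivariateOLS` wraps it as a
scikit-learn estimator so it composes with sklearn pipelines, and the
module-level functions are thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "DesignMatrix",
    "GLMFit",
    "ContrastResult",
    "MassUnivariateOLS",
    "build_design",
    "fit_ols",
    "contrast_t",
    "age_decline_contrast",
    "lgm_weights",
    "lgm_map",
    "partial_r2",
    "fwe_correct",
    "GlobalTrendFit",
    "fit_global_trend",
    "global_trend_table",
]

SEX_ORDER = ("M", "F")


@dataclass
class DesignMatrix:
    """Subjects x regressors matrix with named column roles.

    ``centering`` records every mean used to build the columns so a test
    set can be projected onto exactly the same basis (needed by the
    split-half cross-validation).
    """

    matrix: np.ndarray
    names: list[str]
    centering: dict
    sex_counts: dict[str, int]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def indices(self, prefix: str) -> list[int]:
        return [i for i, n in enumerate(self.names) if n.startswith(prefix)]

    def subset(self, names: list[str]) -> "DesignMatrix":
        idx = [self.names.index(n) for n in names]
        return DesignMatrix(
            matrix=self.matrix[:, idx],
            names=list(names),
            centering=self.centering,
            sex_counts=dict(self.sex_counts),
        )


def _check_cohort(cohort: pd.DataFrame, need: list[str]) -> None:
    missing = [c for c in need if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")


def build_design(
    cohort: pd.DataFrame,
    include_tgm: bool = False,
    *,
    include_tiv: bool = True,
    include_age: bool = True,
    quadratic: bool = True,
    centering: dict | None = None,
) -> DesignMatrix:
    """Build the age-polynomial design matrix from a cohort table.

    Columns (when both sexes are present, quadratic on, TIV on, TGM on):
    ``age_lin_M, age_quad_M, age_lin_F, age_quad_F, const_M, const_F,
    tiv, tgm``.  Per-sex age columns are zero for the other sex and are
    demeaned within their own sex; TIV/TGM are demeaned over the whole
    cohort.  Passing a previous design's ``centering`` reuses its means
    and column layout (for projecting held-out subjects).
    """
    need = ["age", "sex"]
    if include_tiv:
        need.append("tiv")
    if include_tgm:
        need.append("tgm")
    _check_cohort(cohort, need)
    age = cohort["age"].to_numpy(dtype=np.float64)
    sex = cohort["sex"].astype(str).to_numpy()
    n = len(cohort)

    if centering is not None:
        age_mean = centering["age_mean"]
        sexes = centering["sexes"]
        offsets = centering["offsets"]
        tiv_mean = centering.get("tiv_mean")
        tgm_mean = centering.get("tgm_mean")
    else:
        age_mean = float(age.mean())
        sexes = [s for s in SEX_ORDER if s in set(sex)]
        unknown = sorted(set(sex) - set(SEX_ORDER))
        if unknown:
            raise ValueError(f"unknown sex codes: {unknown} (expected M/F)")
        if len(sexes) == 1:
            warnings.warn(
                f"single-sex cohort ({sexes[0]}): the other sex's columns "
                "are dropped",
                UserWarning,
                stacklevel=2,
            )
        offsets = {}
        tiv_mean = None
        tgm_mean = None

    delta = age - age_mean
    cols: list[np.ndarray] = []
    names: list[str] = []
    for s in sexes:
        ind = (sex == s).astype(np.float64)
        terms = [("age_lin_" + s, delta * ind)]
        if quadratic:
            terms.append(("age_quad_" + s, delta**2 * ind))
        for nm, col in terms:
            if not include_age:
                continue
            if centering is None:
                m = float(col[ind > 0].mean()) if ind.any() else 0.0
                offsets[nm] = m
            else:
                m = offsets[nm]
            cols.append((col - m) * ind)
            names.append(nm)
    for s in sexes:
        cols.append((sex == s).astype(np.float64))
        names.append("const_" + s)
    for flag, key in ((include_tiv, "tiv"), (include_tgm, "tgm")):
        if not flag:
            continue
        vals = cohort[key].to_numpy(dtype=np.float64)
        mean = tiv_mean if key == "tiv" else tgm_mean
        if mean is None:
            mean = float(vals.mean())
            if key == "tiv":
                tiv_mean = mean
            else:
                tgm_mean = mean
        col = vals - mean
        if centering is None and np.allclose(col, 0.0):
            warnings.warn(
                f"{key.upper()} is constant across subjects; column dropped",
                UserWarning,
                stacklevel=2,
            )
            continue
        cols.append(col)
        names.append(key)

    X = np.column_stack(cols) if cols else np.empty((n, 0))
    ctr = {
        "age_mean": age_mean,
        "sexes": list(sexes),
        "offsets": dict(offsets),
        "tiv_mean": tiv_mean,
        "tgm_mean": tgm_mean,
    }
    sex_counts = {s: int((sex == s).sum()) for s in sexes}
    dm = DesignMatrix(matrix=X, names=names, centering=ctr, sex_counts=sex_counts)
    if centering is None:
        _check_rank(dm)
    return dm


def _check_rank(design: DesignMatrix) -> None:
    X = design.matrix
    if X.shape[1] == 0:
        return
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns from the QR diagonal
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        scale = diag.max() if diag.max() > 0 else 1.0
        bad = [design.names[i] for i in np.where(diag / scale < 1e-10)[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


@dataclass
class GLMFit:
    """Per-unit OLS fit: betas, residual variance, degrees of freedom."""

    beta: np.ndarray  # (p, n_units)
    resid_var: np.ndarray  # (n_units,)
    rss: np.ndarray  # (n_units,)
    df: int
    design: DesignMatrix
    xtx_inv: np.ndarray  # (p, p)
    n: int
    unit_ids: np.ndarray | None = None

    def fitted(self, design: DesignMatrix | None = None) -> np.ndarray:
        X = (design or self.design).matrix
        return X @ self.beta


def fit_ols(Y: np.ndarray, design: DesignMatrix, unit_ids=None) -> GLMFit:
    """Ordinary least squares per unit on a shared design.

    ``Y`` is ``(n_subjects, n_units)`` with rows aligned to the design.
    """
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != design.n:
        raise ValueError(
            f"Y has {Y.shape[0]} rows but design has {design.n} subjects"
        )
    bad = np.where(~np.isfinite(Y).all(axis=0))[0]
    if bad.size:
        raise ValueError(f"non-finite values in units: {bad[:20].tolist()}")
    X = design.matrix
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _check_rank(design)  # raises with column names
        raise ValueError("design matrix is rank deficient")
    df = design.n - rank
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    resid_var = rss / df
    return GLMFit(
        beta=beta,
        resid_var=resid_var,
        rss=rss,
        df=df,
        design=design,
        xtx_inv=xtx_inv,
        n=design.n,
        unit_ids=None if unit_ids is None else np.asarray(unit_ids),
    )


class MassUnivariateOLS(RegressorMixin, BaseEstimator):
    """Scikit-learn estimator wrapper around the mass-univariate OLS core.

    ``X`` may be a :class:`DesignMatrix` or a plain ``(n, p)`` array;
    ``y`` is ``(n, n_units)``.  Fitted attributes follow the sklearn
    convention (``coef_`` is ``(p, n_units)``).
    """

    def fit(self, X, y):
        if isinstance(X, DesignMatrix):
            design = X
        else:
            X = np.asarray(X, dtype=np.float64)
            design = DesignMatrix(
                matrix=X,
                names=[f"x{i}" for i in range(X.shape[1])],
                centering={},
                sex_counts={},
            )
        fit = fit_ols(np.asarray(y, dtype=np.float64), design)
        self.fit_ = fit
        self.design_ = design
        self.coef_ = fit.beta
        self.resid_var_ = fit.resid_var
        self.df_ = fit.df
        self.n_features_in_ = design.p
        return self

    def predict(self, X):
        if isinstance(X, DesignMatrix):
            X = X.matrix
        return np.asarray(X, dtype=np.float64) @ self.coef_


@dataclass
class ContrastResult:
    """A linear contrast of the betas with t and one- or two-tailed p."""

    weights: np.ndarray
    effect: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    tail: str
    df: int
    p_fwe: np.ndarray | None = None
    fwe_method: str | None = None
    unit_ids: np.ndarray | None = None


def contrast_t(fit: GLMFit, weights, tail: str = "two") -> ContrastResult:
    """t test of ``w' beta`` per unit.

    ``tail='lower'`` gives ``P(T <= t)`` (the decline convention for a
    slope contrast), ``'upper'`` gives ``P(T >= t)``, ``'two'`` doubles
    the upper tail of ``|t|``.  A degenerate 0/0 statistic (zero effect
    with zero residual variance) is reported as t = 0.
    """
    if tail not in ("lower", "upper", "two"):
        raise ValueError(f"invalid tail: {tail!r}")
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (fit.design.p,):
        raise ValueError(f"weights must have length {fit.design.p}")
    effect = w @ fit.beta
    var_w = float(w @ fit.xtx_inv @ w)
    se = np.sqrt(fit.resid_var * var_w)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / np.where(se > 0, se, 1.0), 0.0)
    inf_mask = (se == 0) & (effect != 0)
    if inf_mask.any():
        t = t.copy()
        t[inf_mask] = np.sign(effect[inf_mask]) * np.inf
    if tail == "lower":
        p = stats.t.cdf(t, fit.df)
    elif tail == "upper":
        p = stats.t.sf(t, fit.df)
    else:
        p = 2.0 * stats.t.sf(np.abs(t), fit.df)
    return ContrastResult(
        weights=w,
        effect=effect,
        se=se,
        t=np.asarray(t),
        p=np.asarray(p),
        tail=tail,
        df=fit.df,
        unit_ids=fit.unit_ids,
    )


def _age_lin_weights(design: DesignMatrix) -> np.ndarray:
    idx = design.indices("age_lin_")
    if not idx:
        raise ValueError("design has no linear age columns")
    w = np.zeros(design.p)
    w[idx] = 1.0 / len(idx)
    return w


def age_decline_contrast(fit: GLMFit) -> ContrastResult:
    """Sex-averaged linear age slope, tested one-tailed for decline.

    The effect is the mean of the per-sex linear slopes; the p-value is
    the lower tail (negative slope = decline).
    """
    return contrast_t(fit, _age_lin_weights(fit.design), tail="lower")


def lgm_weights(design: DesignMatrix) -> np.ndarray:
    """Weights giving the sex-weighted constant (= mean GM, the LGM)."""
    idx = design.indices("const_")
    if not idx:
        raise ValueError("design has no constant columns")
    w = np.zeros(design.p)
    total = sum(design.sex_counts.values())
    for i in idx:
        s = design.names[i].removeprefix("const_")
        w[i] = design.sex_counts[s] / total
    return w


def lgm_map(fit: GLMFit) -> np.ndarray:
    """Per-unit local mean GM: the sex-weighted constant term."""
    return lgm_weights(fit.design) @ fit.beta


def partial_r2(fit_full: GLMFit, fit_reduced: GLMFit) -> np.ndarray:
    """Partial R^2 of the terms present in the full but not reduced model.

    ``(RSS_reduced - RSS_full) / RSS_reduced`` per unit, in [0, 1].
    """
    if not set(fit_reduced.design.names) <= set(fit_full.design.names):
        raise ValueError("reduced model is not nested in the full model")
    if fit_full.n != fit_reduced.n:
        raise ValueError("models were fit to different numbers of subjects")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            fit_reduced.rss > 0,
            (fit_reduced.rss - fit_full.rss) / np.where(fit_reduced.rss > 0, fit_reduced.rss, 1.0),
            0.0,
        )
    return np.clip(out, 0.0, 1.0)


def fwe_correct(
    result: ContrastResult,
    method: str = "bonferroni",
    *,
    fit: GLMFit | None = None,
    Y: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ContrastResult:
    """Familywise-error correction across units.

    ``bonferroni`` multiplies each p by the number of units.
    ``permutation_maxT`` runs Freedman–Lane residual permutation: the
    reduced (nuisance-only) model is fit, its residuals are permuted and
    added back to the nuisance fit, the full model is refit, and each
    unit's observed t is ranked against the permutation distribution of
    the most extreme statistic over units.
    """
    m = result.t.size
    if method == "bonferroni":
        p_fwe = np.minimum(1.0, m * result.p)
    elif method == "permutation_maxT":
        if fit is None or Y is None:
            raise ValueError("permutation correction needs fit= and Y=")
        if seed is None:
            raise ValueError("permutation correction needs a seed")
        if n_perm < 100:
            warnings.warn(
                f"n_perm={n_perm} is small; corrected p-values are coarse",
                UserWarning,
                stacklevel=2,
            )
        p_fwe = _maxt_permutation(result, fit, np.asarray(Y, float), n_perm, seed)
    else:
        raise ValueError(f"unknown FWE method: {method!r}")
    out = ContrastResult(**{**result.__dict__})
    out.p_fwe = p_fwe
    out.fwe_method = method
    return out


def _maxt_permutation(
    result: ContrastResult, fit: GLMFit, Y: np.ndarray, n_perm: int, seed: int
) -> np.ndarray:
    design = fit.design
    w = result.weights
    nuisance = [n for n, wi in zip(design.names, w) if wi == 0]
    Z = design.subset(nuisance) if nuisance else None
    if Z is not None and Z.p > 0:
        fitz = fit_ols(Y, Z)
        fitted = Z.matrix @ fitz.beta
        resid = Y - fitted
    else:
        fitted = np.zeros_like(Y)
        resid = Y
    rng = np.random.default_rng(seed)
    n = Y.shape[0]
    tail = result.tail
    extremes = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        Ystar = fitted + resid[perm]
        f = fit_ols(Ystar, design)
        tstar = contrast_t(f, w, tail=tail).t
        if tail == "lower":
            extremes[b] = tstar.min()
        elif tail == "upper":
            extremes[b] = tstar.max()
        else:
            extremes[b] = np.abs(tstar).max()
    t_obs = result.t
    if tail == "lower":
        counts = (extremes[None, :] <= t_obs[:, None]).sum(axis=1)
    elif tail == "upper":
        counts = (extremes[None, :] >= t_obs[:, None]).sum(axis=1)
    else:
        counts = (extremes[None, :] >= np.abs(t_obs)[:, None]).sum(axis=1)
    return (1.0 + counts) / (n_perm + 1.0)


@dataclass
class GlobalTrendFit:
    """Second-order polynomial age trend of a global tissue volume."""

    measure: str
    covary_tiv: bool
    beta_linear: float
    beta_quadratic: float
    t_linear: float
    t_quadratic: float
    p_linear: float  # one-tailed, in the direction of the estimate
    p_quadratic: float
    partial_r2_linear: float
    partial_r2_quadratic: float
    r2_age: float  # combined linear + quadratic
    percent_change: float  # fitted change over the age range, % of start
    age_range: tuple[float, float] = (0.0, 0.0)
    n: int = 0


def fit_global_trend(
    values,
    cohort: pd.DataFrame,
    covary_tiv: bool = False,
    measure: str = "value",
) -> GlobalTrendFit:
    """Fit ``value ~ age + age^2 (+ TIV)`` pooled across sexes.

    One value per subject (e.g. TIV, TGM, TWM or TCSF).  The reported
    statistics pool males and females; ``percent_change`` evaluates the
    fitted curve at the ends of the observed age range (covariates at
    their means).
    """
    v = np.asarray(values, dtype=np.float64)
    _check_cohort(cohort, ["age"])
    if len(v) != len(cohort):
        raise ValueError("values and cohort differ in length")
    if covary_tiv:
        _check_cohort(cohort, ["tiv"])
        tiv = cohort["tiv"].to_numpy(dtype=np.float64)
        if np.allclose(v, tiv):
            raise ValueError("cannot covary TIV out of TIV itself")
    age = cohort["age"].to_numpy(dtype=np.float64)
    d = age - age.mean()
    q = d**2 - (d**2).mean()
    cols = {"const": np.ones(len(v)), "lin": d, "quad": q}
    if covary_tiv:
        cols["tiv"] = tiv - tiv.mean()

    def _fit(names):
        X = np.column_stack([cols[c] for c in names])
        dm = DesignMatrix(matrix=X, names=list(names), centering={}, sex_counts={})
        return fit_ols(v[:, None], dm)

    full = _fit(list(cols))
    no_lin = _fit([c for c in cols if c != "lin"])
    no_quad = _fit([c for c in cols if c != "quad"])
    no_age = _fit([c for c in cols if c not in ("lin", "quad")])
    names = list(cols)
    b = full.beta[:, 0]
    tl = contrast_t(full, np.eye(len(names))[names.index("lin")], tail="two")
    tq = contrast_t(full, np.eye(len(names))[names.index("quad")], tail="two")
    a_lo, a_hi = float(age.min()), float(age.max())

    def f_at(a):
        dd = a - age.mean()
        return b[names.index("const")] + b[names.index("lin")] * dd + b[
            names.index("quad")
        ] * (dd**2 - (d**2).mean())

    f_lo, f_hi = f_at(a_lo), f_at(a_hi)
    pct = 100.0 * (f_hi - f_lo) / f_lo if f_lo != 0 else np.nan
    return GlobalTrendFit(
        measure=measure,
        covary_tiv=covary_tiv,
        beta_linear=float(b[names.index("lin")]),
        beta_quadratic=float(b[names.index("quad")]),
        t_linear=float(tl.t[0]),
        t_quadratic=float(tq.t[0]),
        p_linear=float(tl.p[0] / 2.0),
        p_quadratic=float(tq.p[0] / 2.0),
        partial_r2_linear=float(partial_r2(full, no_lin)[0]),
        partial_r2_quadratic=float(partial_r2(full, no_quad)[0]),
        r2_age=float(partial_r2(full, no_age)[0]),
        percent_change=float(pct),
        age_range=(a_lo, a_hi),
        n=len(v),
    )


def global_trend_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Age-trend fits for TIV, TGM, TWM, TCSF, raw and TIV-adjusted."""
    _check_cohort(cohort, ["age", "tiv", "tgm", "twm", "tcsf"])
    rows = []
    for measure in ("tiv", "tgm", "twm", "tcsf"):
        for covary in (False, True):
            if covary and measure == "tiv":
                continue
            ft = fit_global_trend(
                cohort[measure].to_numpy(), cohort, covary_tiv=covary, measure=measure
            )
            rows.append(
                {
                    "measure": measure,
                    "tiv_adjusted": covary,
                    "beta_linear": ft.beta_linear,
                    "beta_quadratic": ft.beta_quadratic,
                    "p_linear": ft.p_linear,
                    "p_quadratic": ft.p_quadratic,
                    "partial_r2_linear": ft.partial_r2_linear,
                    "partial_r2_quadratic": ft.partial_r2_quadratic,
                    "r2_age": ft.r2_age,
                    "percent_change": ft.percent_change,
                }
            )
    return pd.DataFrame(rows)
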