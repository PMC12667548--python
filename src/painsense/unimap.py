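"""Univariate brain-behavior mapping.

Voxelwise Pearson/Spearman correlation with Benjamini-Hochberg FDR
masking, partial correlation with dataset-wise standardization, ROI
summaries, mask overlap (Dice, conjunction), Steiger's z for dependent
correlations, and family-aware mixed-effects mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatMap",
    "RoiSet",
    "SteigerInputs",
    "voxelwise_correlation",
    "fdr_bh",
    "partial_correlation_map",
    "roi_mean_signal",
    "roi_correlation",
    "dice",
    "conjunction",
    "steiger_z",
    "mixed_effect_map",
]


@dataclass
class StatMap:
    """Per-voxel statistics with multiplicity-adjusted significance.

    Voxels with NaN statistic (untestable, e.g. constant) are excluded
    from the FDR family: their q is NaN and they are never significant.
    """

    statistic: np.ndarray
    p: np.ndarray
    q: np.ndarray
    sig_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        return int(self.sig_mask.sum())


@dataclass
class RoiSet:
    """Named binary regions over the analysis-mask voxels."""

    labels: list[str]
    masks: list[np.ndarray]  # boolean vectors over mask voxels
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.masks):
            raise ValueError("labels and masks must align")
        for label, m in zip(self.labels, self.masks):
            if not np.any(m):
                raise ValueError(f"ROI {label!r} is empty")


def _build_statmap(stat, p, q_level, meta) -> StatMap:
    stat = np.asarray(stat, dtype=float)
    p = np.asarray(p, dtype=float)
    testable = np.isfinite(stat)
    q = np.full_like(p, np.nan)
    sig = np.zeros(stat.shape, dtype=bool)
    if testable.any():
        sig_t, q_t = fdr_bh(p[testable], q_level)
        q[testable] = q_t
        sig[testable] = sig_t
    return StatMap(statistic=stat, p=p, q=q, sig_mask=sig, meta=meta)


def _pearson_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of every column of X against y; NaN for constant columns."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[sx == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def _pearson_p(r: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p from the t transform of r with ``df`` degrees of freedom."""
    r = np.asarray(r, dtype=float)
    p = np.ones_like(r)
    ok = np.isfinite(r) & (np.abs(r) < 1.0)
    t = np.abs(r[ok]) * np.sqrt(df / (1.0 - r[ok] ** 2))
    p[ok] = 2.0 * stats.t.sf(t, df)
    exact = np.isfinite(r) & (np.abs(r) >= 1.0)
    p[exact] = 0.0
    p[~np.isfinite(r)] = 1.0
    return p


def voxelwise_correlation(maps: np.ndarray, behavior: np.ndarray,
                          method: str = "pearson",
                          q_level: float = 0.05) -> StatMap:
    """Correlate every voxel column with the behavior vector.

    ``method`` is "pearson" or "spearman" (average ranks, asymptotic t
    p-values).  Two-sided p, BH-FDR adjusted q at ``q_level``.  Constant
    voxels get statistic NaN / p 1 and sit outside the FDR family.
    """
    maps = np.asarray(maps, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    if maps.ndim != 2 or maps.shape[0] != behavior.shape[0]:
        raise ValueError("maps rows must align with behavior length")
    n = behavior.shape[0]
    if n < 4:
        raise ValueError("need at least 4 participants")
    if np.ptp(behavior) == 0:
        raise ValueError("behavior vector is constant")
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 0, maps)
        y = stats.rankdata(behavior)
    elif method == "pearson":
        X, y = maps, behavior
    else:
        raise ValueError(f"unknown method {method!r}")
    r = _pearson_columns(X, y)
    p = _pearson_p(r, n - 2)
    meta = {"method": method, "n": n, "covariates": []}
    return _build_statmap(r, p, q_level, meta)


def fdr_bh(p_vector: np.ndarray, q_level: float = 0.05):
    """Benjamini-Hochberg step-up procedure.

    Returns ``(sig_mask, q_adjusted)`` where ``q_adjusted`` are the
    monotone BH-adjusted values and ``sig_mask`` marks q <= q_level.
    """
    p = np.asarray(p_vector, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q <= q_level, q


def _residualize(M: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, M, rcond=None)
    return M - design @ beta


def _covariate_design(covariate_table, n: int) -> np.ndarray:
    """Intercept + covariate columns, with median imputation of missing."""
    if covariate_table is None:
        return np.ones((n, 1))
    C = np.asarray(pd.DataFrame(covariate_table), dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("covariate rows must align with participants")
    for j in range(C.shape[1]):
        col = C[:, j]
        if np.isnan(col).any():
            col[np.isnan(col)] = np.nanmedian(col)
    keep = np.ptp(C, axis=0) > 0
    return np.column_stack([np.ones(n), C[:, keep]])


def partial_correlation_map(maps: np.ndarray, behavior: np.ndarray,
                            covariate_table=None,
                            dataset_labels=None,
                            q_level: float = 0.05) -> StatMap:
    """Partial correlation of voxels with behavior given covariates.

    When ``dataset_labels`` is supplied, maps (voxel-wise) and behavior
    are first standardized within each dataset, which absorbs both mean
    and range differences between datasets; covariates (e.g. the dataset
    dummy, sex, age) are then regressed out of both sides and the
    residuals correlated.  Missing covariate values are median-imputed.
    """
    maps = np.asarray(maps, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    n = behavior.shape[0]
    if maps.shape[0] != n:
        raise ValueError("maps rows must align with behavior length")

    if dataset_labels is not None:
        maps = maps.copy()
        behavior = behavior.copy()
        for lab in np.unique(dataset_labels):
            idx = np.asarray(dataset_labels) == lab
            sub = maps[idx]
            sd = sub.std(axis=0)
            sd[sd == 0] = 1.0
            maps[idx] = (sub - sub.mean(axis=0)) / sd
            bsd = behavior[idx].std()
            if bsd > 0:
                behavior[idx] = (behavior[idx] - behavior[idx].mean()) / bsd

    design = _covariate_design(covariate_table, n)
    k = design.shape[1] - 1
    y_res = _residualize(behavior[:, None], design)[:, 0]
    if y_res.std() < 1e-12 * max(behavior.std(), 1.0):
        raise ValueError("behavior explained by covariates")
    X_res = _residualize(maps, design)
    r = _pearson_columns(X_res, y_res)
    p = _pearson_p(r, n - 2 - k)
    meta = {"method": "partial", "n": n, "covariates": k}
    return _build_statmap(r, p, q_level, meta)


def roi_mean_signal(maps: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """Mean over ROI voxels per participant."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    return np.asarray(maps, dtype=float)[:, roi_mask].mean(axis=1)


def roi_correlation(maps: np.ndarray, behavior: np.ndarray,
                    roi_mask: np.ndarray, method: str = "pearson"):
    """Correlation of the ROI mean signal with behavior -> (r, p)."""
    signal = roi_mean_signal(maps, roi_mask)
    if method == "pearson":
        res = stats.pearsonr(signal, behavior)
    elif method == "spearman":
        res = stats.spearmanr(signal, behavior)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) between two binary masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        warnings.warn("both masks empty; Dice undefined", RuntimeWarning)
        return float("nan")
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def conjunction(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    return np.logical_and(a, b)


@dataclass
class SteigerInputs:
    """The two compared dependent correlations and their cross terms.

    ``r_jk`` and ``r_hm`` are the correlations under comparison; the four
    cross-correlations tie the two variable pairs together; ``n`` is the
    shared sample size.
    """

    r_jk: float
    r_hm: float
    r_jh: float
    r_jm: float
    r_kh: float
    r_km: float
    n: int

    def __post_init__(self) -> None:
        vals = [self.r_jk, self.r_hm, self.r_jh, self.r_jm,
                self.r_kh, self.r_km]
        if any(abs(v) > 1 for v in vals):
            raise ValueError("correlations must lie in [-1, 1]")
        if self.n < 4:
            raise ValueError("need n >= 4")
        R = self.correlation_matrix()
        if np.linalg.eigvalsh(R)[0] < -1e-8:
            warnings.warn("implied correlation matrix is not PSD",
                          RuntimeWarning)

    def correlation_matrix(self) -> np.ndarray:
        """4x4 matrix over variables (j, k, h, m)."""
        return np.array([
            [1.0, self.r_jk, self.r_jh, self.r_jm],
            [self.r_jk, 1.0, self.r_kh, self.r_km],
            [self.r_jh, self.r_kh, 1.0, self.r_hm],
            [self.r_jm, self.r_km, self.r_hm, 1.0],
        ])


def steiger_z(inputs: SteigerInputs) -> tuple[float, float]:
    """Steiger's z for two dependent correlations with no shared variable.

    Fisher-transforms both correlations and compares them using the
    pooled-estimate covariance term

        c = [ r̄²(r_jh² + r_jm² + r_kh² + r_km²)/2 + r_jh·r_km + r_jm·r_kh
              − r̄(r_jh·r_jm + r_kh·r_km + r_jh·r_kh + r_jm·r_km) ] / (1 − r̄²)²

    with r̄ = (r_jk + r_hm)/2, giving z = (Z_jk − Z_hm) /
    sqrt(2(1 − c)/(n − 3)).  Returns ``(z, two-sided p)``.
    """
    r_jk, r_hm = inputs.r_jk, inputs.r_hm
    if abs(r_jk) >= 1.0 or abs(r_hm) >= 1.0:
        raise ValueError("|r| = 1 has infinite Fisher transform")
    z_jk = np.arctanh(r_jk)
    z_hm = np.arctanh(r_hm)
    rbar = (r_jk + r_hm) / 2.0
    r_jh, r_jm = inputs.r_jh, inputs.r_jm
    r_kh, r_km = inputs.r_kh, inputs.r_km
    psi = (
        0.5 * rbar**2 * (r_jh**2 + r_jm**2 + r_kh**2 + r_km**2)
        + r_jh * r_km + r_jm * r_kh
        - rbar * (r_jh * r_jm + r_kh * r_km + r_jh * r_kh + r_jm * r_km)
    )
    c = psi / (1.0 - rbar**2) ** 2
    z = (z_jk - z_hm) / np.sqrt(2.0 * (1.0 - c) / (inputs.n - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def mixed_effect_map(maps: np.ndarray, behavior: np.ndarray,
                     family_ids: np.ndarray, covariates=None,
                     q_level: float = 0.05) -> StatMap:
    """Per-voxel standardized fixed-effect slope of behavior on BOLD with
    a family random intercept (REML), Wald two-sided p.

    When every family is a singleton (or there is a single family) the
    random intercept is unidentifiable and plain OLS is used instead,
    with a warning.
    """
    import statsmodels.api as sm

    maps = np.asarray(maps, dtype=float)
    y = _standardize(np.asarray(behavior, dtype=float))
    family_ids = np.asarray(family_ids)
    if maps.shape[0] != y.shape[0] or family_ids.shape[0] != y.shape[0]:
        raise ValueError("maps, behavior and family_ids must align")
    n_groups = np.unique(family_ids).size
    degenerate = n_groups <= 1 or n_groups == y.shape[0]
    if degenerate:
        warnings.warn("family structure degenerate; falling back to OLS",
                      RuntimeWarning)

    design_extra = None
    if covariates is not None:
        C = np.asarray(pd.DataFrame(covariates), dtype=float)
        design_extra = np.column_stack(
            [_standardize(C[:, j]) for j in range(C.shape[1])])

    n_voxels = maps.shape[1]
    beta = np.full(n_voxels, np.nan)
    pvals = np.ones(n_voxels)
    for v in range(n_voxels):
        x = maps[:, v]
        if x.std() == 0:
            continue
        cols = [np.ones_like(y), _standardize(x)]
        if design_extra is not None:
            cols.extend(design_extra.T)
        X = np.column_stack(cols)
        try:
            if degenerate:
                fit = sm.OLS(y, X).fit()
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.MixedLM(y, X, groups=family_ids).fit(reml=True)
            beta[v] = fit.params[1]
            pvals[v] = fit.pvalues[1]
        except Exception:  # nonconvergence at this voxel
            continue
    meta = {"method": "mixed" if not degenerate else "ols-fallback",
            "n": y.shape[0],
            "covariates": 0 if design_extra is None else design_extra.shape[1]}
    return _build_statmap(beta, pvals, q_level, meta)
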