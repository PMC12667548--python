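"""Model interpretation and transfer.

Virtual-lesion region importance, signature application to external /
trial / difference maps, spatial signature comparison, and
treatment-reduction prediction with optional family random intercepts
and baseline adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .signature import EvaluationReport, evaluate, fit_lasso_pcr

__all__ = [
    "Parcellation",
    "LesionReport",
    "virtual_lesion",
    "apply_signature",
    "compare_signatures",
    "predict_reduction",
    "baseline_adjusted_reduction",
    "single_trial_prediction",
]


@dataclass
class Parcellation:
    """Integer region labels over the analysis-mask voxels.

    ``labels`` assigns each mask voxel a region code (0 = background);
    ``lookup`` maps codes to region names.
    """

    labels: np.ndarray
    lookup: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        codes = set(np.unique(self.labels)) - {0}
        if not codes:
            raise ValueError("parcellation has no nonbackground regions")
        for code in codes:
            self.lookup.setdefault(int(code), f"region_{code}")

    @property
    def region_codes(self) -> list[int]:
        return sorted(set(np.unique(self.labels)) - {0})

    def region_mask(self, code: int) -> np.ndarray:
        return self.labels == code


@dataclass
class LesionReport:
    """Per-region change in CV R^2 under remove/keep refits.

    Deltas are on cross-validated R^2 (labeled as such in the table).
    """

    baseline_r2: float
    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows,
                          columns=["region", "mode", "r2_refit", "delta_r2"])
        df.attrs["baseline_r2"] = self.baseline_r2
        df.attrs["r2_kind"] = "cross-validated"
        return df


def virtual_lesion(maps: np.ndarray, y: np.ndarray,
                   parcellation: Parcellation, mode: str = "remove",
                   fit_settings: dict | None = None,
                   baseline_report: EvaluationReport | None = None,
                   ) -> LesionReport:
    """Refit the signature with each region deleted (``remove``) or as the
    only surviving region (``keep``).

    Columns are genuinely deleted and PCA re-run per refit; folds and
    seed are shared with the full model so deltas reflect the lesion, not
    fold noise.  Regions with no in-mask voxels are skipped with a log.
    """
    if mode not in ("remove", "keep"):
        raise ValueError("mode must be 'remove' or 'keep'")
    maps = np.asarray(maps, dtype=float)
    y = np.asarray(y, dtype=float)
    if parcellation.labels.size != maps.shape[1]:
        raise ValueError("parcellation not aligned with map columns")
    fit_settings = dict(fit_settings or {})

    if baseline_report is None:
        _, baseline_report = fit_lasso_pcr(maps, y, **fit_settings)
    full_r2 = baseline_report.r_squared

    report = LesionReport(baseline_r2=full_r2)
    for code in parcellation.region_codes:
        region = parcellation.region_mask(code)
        if not region.any():
            warnings.warn(f"region {code} empty; skipped", RuntimeWarning)
            continue
        cols = ~region if mode == "remove" else region
        if not cols.any():
            warnings.warn(f"region {code} leaves no features; skipped",
                          RuntimeWarning)
            continue
        _, refit = fit_lasso_pcr(maps[:, cols], y, **fit_settings)
        report.rows.append({
            "region": parcellation.lookup[code],
            "mode": mode,
            "r2_refit": refit.r_squared,
            "delta_r2": refit.r_squared - full_r2,
        })
    return report


def apply_signature(weights: np.ndarray, constant: float,
                    maps: np.ndarray) -> np.ndarray:
    """Signature expression: dot product of the weight vector with each
    map row, plus the additive constant."""
    weights = np.asarray(weights, dtype=float)
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 1:
        maps = maps[None, :]
    if maps.shape[-1] != weights.shape[0]:
        raise ValueError("weight length does not match map voxel count")
    out = maps @ weights + constant
    return out[0] if out.shape == (1,) else out


def compare_signatures(weight_a: np.ndarray, weight_b: np.ndarray,
                       shared_mask: np.ndarray | None = None) -> float:
    """Spatial Pearson correlation of two weight maps over their shared
    (finite) voxels; NaN if either is constant there."""
    a = np.asarray(weight_a, dtype=float)
    b = np.asarray(weight_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("weight maps must share a voxel space")
    ok = np.isfinite(a) & np.isfinite(b)
    if shared_mask is not None:
        ok &= np.asarray(shared_mask, dtype=bool)
    if ok.sum() < 2:
        raise ValueError("need >= 2 shared voxels")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def _family_beta(real: np.ndarray, predicted: np.ndarray,
                 family_ids: np.ndarray,
                 covariates: np.ndarray | None = None):
    """Standardized slope of real on predicted with a family random
    intercept; returns (beta, p)."""
    import statsmodels.api as sm

    def z(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    cols = [np.ones_like(real), z(predicted)]
    if covariates is not None:
        cols.extend(z(covariates[:, j]) for j in range(covariates.shape[1]))
    X = np.column_stack(cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MixedLM(z(real), X, groups=np.asarray(family_ids)).fit(
            reml=True)
    return float(fit.params[1]), float(fit.pvalues[1])


def predict_reduction(weights: np.ndarray, constant: float,
                      pre_maps: np.ndarray, post_maps: np.ndarray,
                      pre_ratings: np.ndarray, post_ratings: np.ndarray,
                      family_ids=None):
    """Correlate signature expression of (pre - post) difference maps with
    the real rating reduction.

    Returns an :class:`EvaluationReport`; when ``family_ids`` is given a
    ``(beta, p)`` tuple from the mixed model real ~ predicted +
    (1|family) is attached to the report as ``per_fold=[{"beta": ...}]``-
    style metadata via the returned second element.
    """
    pre_maps = np.asarray(pre_maps, dtype=float)
    post_maps = np.asarray(post_maps, dtype=float)
    real = np.asarray(pre_ratings, dtype=float) - np.asarray(post_ratings,
                                                             dtype=float)
    if pre_maps.shape != post_maps.shape or pre_maps.shape[0] != real.size:
        raise ValueError("pre/post inputs are not paired")
    predicted = apply_signature(weights, constant, pre_maps - post_maps)
    if np.ptp(real) == 0:
        warnings.warn("all rating reductions identical; correlation "
                      "undefined", RuntimeWarning)
        report = EvaluationReport(pearson_r=float("nan"),
                                  r_squared=float("nan"),
                                  n=int(real.size), p_value=float("nan"))
        return (report, None) if family_ids is not None else report
    res = stats.pearsonr(predicted, real)
    report = EvaluationReport(pearson_r=float(res.statistic),
                              r_squared=float("nan"),
                              n=int(real.size),
                              p_value=float(res.pvalue))
    if family_ids is not None:
        return report, _family_beta(real, predicted, family_ids)
    return report


def baseline_adjusted_reduction(weights: np.ndarray, constant: float,
                                pre_maps: np.ndarray, post_maps: np.ndarray,
                                pre_ratings: np.ndarray,
                                post_ratings: np.ndarray,
                                baseline_ratings: np.ndarray,
                                family_ids=None):
    """Reduction prediction after partialling out baseline ratings.

    Residualizes both the predicted and the real reductions on the
    baseline ratings and correlates the residuals (partial r with
    n - 3 df); with ``family_ids`` the mixed model adds baseline as a
    fixed covariate and the standardized beta is returned instead.
    """
    real = np.asarray(pre_ratings, dtype=float) - np.asarray(post_ratings,
                                                             dtype=float)
    predicted = apply_signature(
        weights, constant,
        np.asarray(pre_maps, dtype=float) - np.asarray(post_maps,
                                                       dtype=float))
    baseline = np.asarray(baseline_ratings, dtype=float)
    if family_ids is not None:
        return _family_beta(real, predicted, family_ids,
                            covariates=baseline[:, None])
    design = np.column_stack([np.ones_like(baseline), baseline])
    beta_r, *_ = np.linalg.lstsq(design, real, rcond=None)
    beta_p, *_ = np.linalg.lstsq(design, predicted, rcond=None)
    r_res = real - design @ beta_r
    p_res = predicted - design @ beta_p
    if r_res.std() == 0 or p_res.std() == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(r_res, p_res)[0, 1])
    df = real.size - 3
    t = abs(r) * np.sqrt(df / (1.0 - r**2)) if abs(r) < 1 else np.inf
    return r, float(2.0 * stats.t.sf(t, df))


def single_trial_prediction(weights: np.ndarray, constant: float,
                            trial_maps: np.ndarray,
                            trial_ratings: np.ndarray) -> dict:
    """Within-individual prediction of trial ratings from trial maps.

    Returns per-participant Pearson r between trial expressions and
    ratings, the group mean r with a one-sample t test against 0, and a
    pooled mixed-model slope (rating ~ expression + (1|participant)).
    Participants with constant trial ratings are NaN and excluded from
    the group test.
    """
    import statsmodels.api as sm

    trial_maps = np.asarray(trial_maps, dtype=float)
    trial_ratings = np.asarray(trial_ratings, dtype=float)
    n, n_trials = trial_ratings.shape
    if n_trials < 3:
        raise ValueError("need >= 3 trials per participant")
    per_r = np.full(n, np.nan)
    for i in range(n):
        expr = apply_signature(weights, constant, trial_maps[i])
        if np.ptp(trial_ratings[i]) == 0 or np.ptp(expr) == 0:
            warnings.warn(f"participant {i}: constant trial data; excluded",
                          RuntimeWarning)
            continue
        per_r[i] = np.corrcoef(expr, trial_ratings[i])[0, 1]
    ok = np.isfinite(per_r)
    if ok.sum() >= 2:
        t_res = stats.ttest_1samp(per_r[ok], 0.0)
        group_p = float(t_res.pvalue)
    else:
        group_p = float("nan")

    # pooled slope with participant random intercepts
    expr_all = np.stack([
        apply_signature(weights, constant, trial_maps[i]) for i in range(n)
    ]).ravel()
    ratings_all = trial_ratings.ravel()
    groups = np.repeat(np.arange(n), n_trials)

    def z(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(z(ratings_all),
                             np.column_stack([np.ones_like(expr_all),
                                              z(expr_all)]),
                             groups=groups).fit(reml=True)
        pooled_beta, pooled_p = float(fit.params[1]), float(fit.pvalues[1])
    except Exception:
        pooled_beta, pooled_p = float("nan"), float("nan")

    return {
        "per_participant_r": per_r,
        "mean_r": float(np.nanmean(per_r)) if ok.any() else float("nan"),
        "group_p": group_p,
        "n_included": int(ok.sum()),
        "pooled_beta": pooled_beta,
        "pooled_p": pooled_p,
    }
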