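"""LASSO principal-component regression signatures.

Voxel features are standardized, decomposed by PCA (all components up to
min(n_train - 1, p) retained) and the component scores enter an
L1-penalized regression

    Loss = sum_i (y_i - b0 - sum_j b_j x_ij)^2 + lambda * sum_j |b_j|

with lambda chosen from a log-uniform grid by cross-validated mean
squared error.  Nested five-fold cross-validation (outer folds for
performance, inner folds for lambda) yields out-of-fold predictions;
the deployable model is refit on all data with lambda selected by plain
k-fold CV.  Standardization and PCA are always fit inside training folds
only.  Component coefficients back-project to a raw-voxel-space weight
map whose dot product with a map (plus a constant) reproduces the model
prediction exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

__all__ = [
    "SignatureModel",
    "BehaviorModel",
    "StackedModel",
    "EvaluationReport",
    "LearningCurve",
    "default_lambda_grid",
    "split_discovery_holdout",
    "fit_lasso_pcr",
    "predict",
    "evaluate",
    "backproject_weights",
    "learning_curve",
    "covariate_adjusted_fit",
    "fit_behavior_lasso",
    "fit_stacking",
]


def default_lambda_grid(num: int = 100) -> np.ndarray:
    """``num`` lambda values log-uniform in [1e-2, 1e2]."""
    return np.logspace(-2.0, 2.0, num)


@dataclass
class EvaluationReport:
    """Pearson r and variance-explained R^2 of predictions.

    R^2 = 1 - SSE/SST; unlike r^2 it can be negative when the model is
    worse than predicting the mean.
    """

    pearson_r: float
    r_squared: float
    n: int
    p_value: float
    per_fold: list[dict] = field(default_factory=list)


@dataclass
class SignatureModel:
    """A fitted LASSO-PCR signature with its back-projected weight map."""

    voxel_means: np.ndarray  # over kept voxels
    voxel_sds: np.ndarray
    pca_mean: np.ndarray  # residual centering of scaled features
    component_basis: np.ndarray  # (n_kept_voxels, n_components), orthonormal
    component_coefs: np.ndarray
    intercept: float
    lam: float
    kept: np.ndarray  # boolean over the original voxel columns
    voxel_weights: np.ndarray  # full-length raw-space weights
    weight_constant: float
    training_meta: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return self.kept.size


@dataclass
class BehaviorModel:
    """Plain LASSO on standardized behavioral features (no PCA)."""

    feature_means: np.ndarray
    feature_sds: np.ndarray
    coefs: np.ndarray
    intercept: float
    lam: float
    feature_names: list[str] = field(default_factory=list)
    training_meta: dict = field(default_factory=dict)

    def predict(self, features) -> np.ndarray:
        X = _as_feature_matrix(features, self.feature_means)
        Z = (X - self.feature_means) / self.feature_sds
        return Z @ self.coefs + self.intercept


@dataclass
class StackedModel:
    """fMRI LASSO-PCR + behavior LASSO combined by a linear stacker."""

    fmri_model: SignatureModel
    behavior_model: BehaviorModel
    combiner_coefs: np.ndarray  # (intercept, w_fmri, w_behavior)
    lam_fmri: float
    lam_behavior: float

    def predict(self, maps, features) -> np.ndarray:
        f1 = predict(self.fmri_model, maps)
        f2 = self.behavior_model.predict(features)
        return (self.combiner_coefs[0]
                + self.combiner_coefs[1] * f1
                + self.combiner_coefs[2] * f2)


@dataclass
class LearningCurve:
    train_sizes: np.ndarray
    mean_r2: np.ndarray
    sd_r2: np.ndarray
    reps: int
    seed: int


def split_discovery_holdout(n: int, fraction: float = 0.5, seed: int = 0):
    """Random disjoint, exhaustive split of ``range(n)`` into discovery
    (floor(fraction * n)) and holdout index arrays."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if n < 8:
        raise ValueError("need n >= 8 to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_disc = int(np.floor(n * fraction))
    return np.sort(perm[:n_disc]), np.sort(perm[n_disc:])


# ---------------------------------------------------------------------------
# internals


def _as_feature_matrix(features, ref=None) -> np.ndarray:
    X = np.asarray(pd.DataFrame(features), dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    # median imputation of missing entries
    if np.isnan(X).any():
        med = np.nanmedian(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = med[idx[1]]
    return X


def _safe_sds(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return sd


class _PcrBasis:
    """Standardizer + PCA fit on a training block."""

    def __init__(self, X_train: np.ndarray, max_components: int | None = None):
        self.means = X_train.mean(axis=0)
        self.sds = _safe_sds(X_train)
        Z = (X_train - self.means) / self.sds
        n, p = Z.shape
        k = min(n - 1, p)
        if max_components is not None:
            k = min(k, max_components)
        self.pca = PCA(n_components=k, svd_solver="full" if k >= min(n, p)
                       else "auto", random_state=0)
        self.scores_train = self.pca.fit_transform(Z)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.pca.transform((X - self.means) / self.sds)


def _lasso_path_predictions(S_train, y_train, S_test, lambdas):
    """Lasso solutions over the whole lambda grid at once.

    ``S_train`` columns are centered (PCA scores), so the intercept is the
    training mean of y.  Returns (coefs (k, n_lambda), intercept,
    test predictions (n_test, n_lambda)) in the order of ``lambdas``.
    """
    n = S_train.shape[0]
    alphas = np.asarray(lambdas, dtype=float) / (2.0 * n)
    order = np.argsort(-alphas, kind="stable")  # lasso_path wants decreasing
    ybar = float(y_train.mean())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, coefs_desc, _ = lasso_path(S_train, y_train - ybar,
                                      alphas=alphas[order])
    coefs = np.empty_like(coefs_desc)
    coefs[:, order] = coefs_desc
    preds = S_test @ coefs + ybar
    return coefs, ybar, preds


def _cv_mse_per_lambda(X, y, lambdas, n_folds, seed) -> np.ndarray:
    """Mean squared CV error of LASSO-PCR for every lambda in the grid."""
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    sse = np.zeros(len(lambdas))
    for tr, va in kf.split(X):
        basis = _PcrBasis(X[tr])
        S_va = basis.transform(X[va])
        _, _, preds = _lasso_path_predictions(
            basis.scores_train, y[tr], S_va, lambdas)
        sse += ((preds - y[va][:, None]) ** 2).sum(axis=0)
    return sse / X.shape[0]


def _fit_final(X, y, lam) -> SignatureModel:
    basis = _PcrBasis(X)
    coefs, intercept, _ = _lasso_path_predictions(
        basis.scores_train, y, basis.scores_train[:0], [lam])
    coefs = coefs[:, 0]
    V = basis.pca.components_.T  # (p, k)
    u = V @ coefs
    w_kept = u / basis.sds
    constant = (intercept - float(basis.pca.mean_ @ u)
                - float(basis.means @ w_kept))
    model = SignatureModel(
        voxel_means=basis.means,
        voxel_sds=basis.sds,
        pca_mean=basis.pca.mean_,
        component_basis=V,
        component_coefs=coefs,
        intercept=intercept,
        lam=float(lam),
        kept=np.ones(X.shape[1], dtype=bool),  # caller overwrites
        voxel_weights=w_kept,  # caller expands to full length
        weight_constant=constant,
    )
    return model


def fit_lasso_pcr(maps: np.ndarray, y: np.ndarray, lambda_grid=None,
                  n_folds: int = 5, seed: int = 0):
    """Fit a LASSO-PCR signature with nested cross-validation.

    Returns ``(SignatureModel, EvaluationReport)``.  The report scores the
    outer-fold out-of-fold predictions (lambda re-selected by inner
    ``n_folds``-fold CV inside each outer training set); the returned
    model is refit on all rows with lambda selected by plain k-fold CV.
    """
    X_full = np.asarray(maps, dtype=float)
    y = np.asarray(y, dtype=float)
    if X_full.shape[0] != y.shape[0]:
        raise ValueError("maps rows must align with y")
    if X_full.shape[0] < 2 * n_folds:
        raise ValueError("need n >= 2 * n_folds")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if np.any(lambda_grid <= 0):
        raise ValueError("lambda grid must be positive")

    kept = X_full.std(axis=0) > 0
    n_dropped = int((~kept).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} zero-variance voxels",
                      RuntimeWarning)
    X = X_full[:, kept]

    outer = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.full(y.shape[0], np.nan)
    per_fold = []
    for fold_id, (tr, te) in enumerate(outer.split(X)):
        mse = _cv_mse_per_lambda(X[tr], y[tr], lambda_grid, n_folds,
                                 seed=seed + 1)
        lam_fold = float(lambda_grid[int(np.argmin(mse))])
        basis = _PcrBasis(X[tr])
        _, _, preds = _lasso_path_predictions(
            basis.scores_train, y[tr], basis.transform(X[te]), [lam_fold])
        oof[te] = preds[:, 0]
        fold_eval = evaluate(y[te], oof[te])
        per_fold.append({"fold": fold_id, "lambda": lam_fold,
                         "r": fold_eval.pearson_r,
                         "r_squared": fold_eval.r_squared})

    report = evaluate(y, oof)
    report.per_fold = per_fold

    mse_full = _cv_mse_per_lambda(X, y, lambda_grid, n_folds, seed=seed)
    lam = float(lambda_grid[int(np.argmin(mse_full))])
    model = _fit_final(X, y, lam)
    if np.all(model.component_coefs == 0):
        warnings.warn("null model: all coefficients zero at the selected "
                      "lambda", RuntimeWarning)
    # expand kept-voxel quantities to the original column space
    w_full = np.zeros(X_full.shape[1])
    w_full[kept] = model.voxel_weights
    model.kept = kept
    model.voxel_weights = w_full
    model.training_meta = {"n": int(y.shape[0]), "n_folds": n_folds,
                           "seed": seed, "lambda_grid_size": lambda_grid.size}
    return model, report


def predict(model: SignatureModel, maps: np.ndarray) -> np.ndarray:
    """Predict through the component path (identical to the voxel-weight
    dot product up to float round-off)."""
    X = np.asarray(maps, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    Z = (X[:, model.kept] - model.voxel_means) / model.voxel_sds
    scores = (Z - model.pca_mean) @ model.component_basis
    return scores @ model.component_coefs + model.intercept


def evaluate(y: np.ndarray, y_hat: np.ndarray) -> EvaluationReport:
    """Pearson r (with two-sided p) and R^2 = 1 - SSE/SST."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must align")
    sst = ((y - y.mean()) ** 2).sum()
    sse = ((y - y_hat) ** 2).sum()
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    if np.ptp(y_hat) == 0 or np.ptp(y) == 0 or y.size < 3:
        r, p = float("nan"), float("nan")
    else:
        res = stats.pearsonr(y, y_hat)
        r, p = float(res.statistic), float(res.pvalue)
    return EvaluationReport(pearson_r=r, r_squared=float(r2),
                            n=int(y.size), p_value=p)


def backproject_weights(model: SignatureModel):
    """Raw-voxel-space weights and additive constant of a fitted model.

    ``maps @ weights + constant`` equals :func:`predict` exactly.
    """
    return model.voxel_weights, model.weight_constant


def learning_curve(maps: np.ndarray, y: np.ndarray, sizes=None,
                   reps: int = 100, seed: int = 0, lambda_grid=None,
                   n_folds: int = 5) -> LearningCurve:
    """Cross-validated R^2 as a function of training-set size.

    For training size ``s`` a subsample of round(s * k/(k-1)) rows is
    drawn (fresh shuffle per repetition) and scored by k-fold CV with
    lambda selected by inner CV inside each training fold.  Sizes below
    10 are skipped.
    """
    X = np.asarray(maps, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if sizes is None:
        sizes = np.arange(20, 301, 5)
    sizes = np.asarray([s for s in np.atleast_1d(sizes)], dtype=int)
    usable = sizes[sizes >= 10]
    factor = n_folds / (n_folds - 1)
    if round(usable.max() * factor) > n:
        raise ValueError("largest size exceeds the k-fold CV geometry "
                         f"(need n >= {round(usable.max() * factor)})")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(25)

    r2 = np.full((usable.size, reps), np.nan)
    for rep in range(reps):
        rng = np.random.default_rng(np.random.SeedSequence((seed, rep)))
        perm = rng.permutation(n)
        for si, s in enumerate(usable):
            m = int(round(s * factor))
            idx = perm[:m]
            _, rep_eval = fit_lasso_pcr(
                X[idx], y[idx], lambda_grid=lambda_grid,
                n_folds=n_folds, seed=int(rng.integers(2**31)))
            r2[si, rep] = rep_eval.r_squared
    return LearningCurve(train_sizes=usable,
                         mean_r2=r2.mean(axis=1),
                         sd_r2=r2.std(axis=1, ddof=1) if reps > 1
                         else np.zeros(usable.size),
                         reps=reps, seed=seed)


def covariate_adjusted_fit(maps: np.ndarray, y: np.ndarray, covariates,
                           **fit_kwargs):
    """Regress covariates out of maps and behavior, then fit LASSO-PCR
    on the residuals.  Covariates are median-imputed; a rank-deficient
    covariate design raises."""
    X = np.asarray(maps, dtype=float)
    y = np.asarray(y, dtype=float)
    C = _as_feature_matrix(covariates)
    design = np.column_stack([np.ones(y.shape[0]), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    beta_X, *_ = np.linalg.lstsq(design, X, rcond=None)
    return fit_lasso_pcr(X - design @ beta_X, y - design @ beta_y,
                         **fit_kwargs)


def _behavior_cv_mse(Z, y, lambdas, n_folds, seed):
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    sse = np.zeros(len(lambdas))
    for tr, va in kf.split(Z):
        mu = Z[tr].mean(axis=0)
        sd = _safe_sds(Z[tr])
        _, _, preds = _lasso_path_predictions(
            (Z[tr] - mu) / sd, y[tr], (Z[va] - mu) / sd, lambdas)
        sse += ((preds - y[va][:, None]) ** 2).sum(axis=0)
    return sse / Z.shape[0]


def fit_behavior_lasso(behavior_features, y: np.ndarray, lambda_grid=None,
                       n_folds: int = 5, seed: int = 0):
    """Plain LASSO on standardized behavioral features (PCA omitted).

    Returns ``(BehaviorModel, EvaluationReport)`` with the report computed
    on out-of-fold predictions at the per-fold inner-CV-selected lambda.
    """
    names = (list(behavior_features.columns)
             if isinstance(behavior_features, pd.DataFrame) else [])
    X = _as_feature_matrix(behavior_features)
    if X.shape[1] == 0:
        raise ValueError("no behavioral features supplied")
    y = np.asarray(y, dtype=float)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    outer = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.full(y.shape[0], np.nan)
    for tr, te in outer.split(X):
        mse = _behavior_cv_mse(X[tr], y[tr], lambda_grid, n_folds, seed + 1)
        lam_fold = lambda_grid[int(np.argmin(mse))]
        mu, sd = X[tr].mean(axis=0), _safe_sds(X[tr])
        _, _, preds = _lasso_path_predictions(
            (X[tr] - mu) / sd, y[tr], (X[te] - mu) / sd, [lam_fold])
        oof[te] = preds[:, 0]
    report = evaluate(y, oof)

    mse = _behavior_cv_mse(X, y, lambda_grid, n_folds, seed)
    lam = float(lambda_grid[int(np.argmin(mse))])
    mu, sd = X.mean(axis=0), _safe_sds(X)
    coefs, intercept, _ = _lasso_path_predictions(
        (X - mu) / sd, y, ((X - mu) / sd)[:0], [lam])
    model = BehaviorModel(feature_means=mu, feature_sds=sd,
                          coefs=coefs[:, 0], intercept=intercept, lam=lam,
                          feature_names=names,
                          training_meta={"n": int(y.size), "seed": seed})
    return model, report


def _oof_matrix_pcr(X, y, lambdas, n_folds, seed):
    """Out-of-fold LASSO-PCR predictions for every lambda (n, n_lambda)."""
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.empty((y.shape[0], len(lambdas)))
    for tr, te in kf.split(X):
        basis = _PcrBasis(X[tr])
        _, _, preds = _lasso_path_predictions(
            basis.scores_train, y[tr], basis.transform(X[te]), lambdas)
        oof[te] = preds
    return oof


def _oof_matrix_lasso(X, y, lambdas, n_folds, seed):
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.empty((y.shape[0], len(lambdas)))
    for tr, te in kf.split(X):
        mu, sd = X[tr].mean(axis=0), _safe_sds(X[tr])
        _, _, preds = _lasso_path_predictions(
            (X[tr] - mu) / sd, y[tr], (X[te] - mu) / sd, lambdas)
        oof[te] = preds
    return oof


def _fit_combiner(F: np.ndarray, y: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(y.shape[0]), F])
    coefs, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coefs


def fit_stacking(maps, behavior_features, y, grid_1=None, grid_2=None,
                 n_folds: int = 5, seed: int = 0):
    """Stacked fMRI + behavior model.

    Out-of-fold predictions of the LASSO-PCR (lambda_1) and behavior
    LASSO (lambda_2) base models feed a two-predictor least-squares
    combiner; the (lambda_1, lambda_2) pair is selected jointly by the
    cross-validated MSE of the combined prediction.

    Returns ``(StackedModel, EvaluationReport)``.
    """
    X = np.asarray(maps, dtype=float)
    B = _as_feature_matrix(behavior_features)
    y = np.asarray(y, dtype=float)
    if grid_1 is None:
        grid_1 = default_lambda_grid(10)
    if grid_2 is None:
        grid_2 = default_lambda_grid(10)
    grid_1 = np.asarray(grid_1, dtype=float)
    grid_2 = np.asarray(grid_2, dtype=float)

    kept = X.std(axis=0) > 0
    oof1 = _oof_matrix_pcr(X[:, kept], y, grid_1, n_folds, seed)
    oof2 = _oof_matrix_lasso(B, y, grid_2, n_folds, seed)
    for name, oof in (("fMRI", oof1), ("behavior", oof2)):
        if np.allclose(oof.std(axis=0), 0):
            warnings.warn(f"{name} base model degenerate (constant "
                          "predictions at every lambda)", RuntimeWarning)

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed + 7)
    splits = list(kf.split(y))
    best = (np.inf, 0, 0)
    for i1 in range(grid_1.size):
        for i2 in range(grid_2.size):
            F = np.column_stack([oof1[:, i1], oof2[:, i2]])
            sse = 0.0
            for tr, te in splits:
                coefs = _fit_combiner(F[tr], y[tr])
                pred = coefs[0] + F[te] @ coefs[1:]
                sse += ((pred - y[te]) ** 2).sum()
            if sse < best[0]:
                best = (sse, i1, i2)
    _, i1, i2 = best
    lam1, lam2 = float(grid_1[i1]), float(grid_2[i2])

    # CV report: out-of-fold combined predictions at the selected pair
    F = np.column_stack([oof1[:, i1], oof2[:, i2]])
    oof_combined = np.full(y.shape[0], np.nan)
    for tr, te in splits:
        coefs = _fit_combiner(F[tr], y[tr])
        oof_combined[te] = coefs[0] + F[te] @ coefs[1:]
    report = evaluate(y, oof_combined)

    fmri_model = _fit_final(X[:, kept], y, lam1)
    w_full = np.zeros(X.shape[1])
    w_full[kept] = fmri_model.voxel_weights
    fmri_model.kept = kept
    fmri_model.voxel_weights = w_full
    fmri_model.training_meta = {"n": int(y.size), "seed": seed}

    mu, sd = B.mean(axis=0), _safe_sds(B)
    coefs_b, intercept_b, _ = _lasso_path_predictions(
        (B - mu) / sd, y, ((B - mu) / sd)[:0], [lam2])
    behavior_model = BehaviorModel(
        feature_means=mu, feature_sds=sd, coefs=coefs_b[:, 0],
        intercept=intercept_b, lam=lam2)

    combiner = _fit_combiner(F, y)
    model = StackedModel(fmri_model=fmri_model, behavior_model=behavior_model,
                         combiner_coefs=combiner, lam_fmri=lam1,
                         lam_behavior=lam2)
    return model, report


# ---------------------------------------------------------------------------
# serialization: NIfTI weight image + JSON sidecar


def save_signature(model: SignatureModel, mask: np.ndarray,
                   affine: np.ndarray, path_prefix) -> tuple:
    """Write ``<prefix>.nii`` (back-projected weights) and ``<prefix>.json``
    (constant, lambda, standardization vectors, metadata)."""
    import json
    from pathlib import Path

    from .shell.io import unvectorize, write_volume

    path_prefix = Path(path_prefix)
    nii_path = path_prefix.with_suffix(".nii")
    json_path = path_prefix.with_suffix(".json")
    write_volume(unvectorize(model.voxel_weights, mask).astype(np.float64),
                 affine, nii_path)
    sidecar = {
        "format_version": 1,
        "weight_constant": model.weight_constant,
        "lambda": model.lam,
        "intercept": model.intercept,
        "voxel_means": model.voxel_means.tolist(),
        "voxel_sds": model.voxel_sds.tolist(),
        "kept": model.kept.astype(int).tolist(),
        "training_meta": model.training_meta,
    }
    json_path.write_text(json.dumps(sidecar))
    return nii_path, json_path


def load_signature_weights(path_prefix):
    """Reload the weight vector and constant written by
    :func:`save_signature` -> (weights, constant, mask, affine)."""
    import json
    from pathlib import Path

    from .shell.io import read_volume, vectorize

    path_prefix = Path(path_prefix)
    vol, affine = read_volume(path_prefix.with_suffix(".nii"))
    sidecar = json.loads(path_prefix.with_suffix(".json").read_text())
    mask = np.isfinite(vol)
    weights = vectorize(vol, mask)
    return weights, float(sidecar["weight_constant"]), mask, affine
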