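"""Synthetic cohort simulation with known ground truth.

Generates participant-level voxel "contrast maps" coupled to a latent
pain-sensitivity trait through a sparse, spatially smooth weight pattern,
together with trial-level ratings, demographic confounds, twin-family
structure, optional nonpain modalities, optional trial-level maps and a
treatment arm.  Every stochastic quantity flows from a single integer seed,
so identical configurations reproduce bit-identical cohorts.

Generative model (per modality ``m`` with coupling ``kappa_m``)::

    trait_i   = sigma_s * (sqrt(R2) * g_i + sqrt(1 - R2) * e_i)
    s_i       = mu + confounds_i + trait_i
    rating_it = clip(s_i + eps_it, scale bounds)
    map_iv    = kappa_m * a_v * g_i + sigma_n * eta_iv

where ``g_i`` and ``e_i`` are unit-variance latents sharing the family
intraclass correlation, ``a_v`` is the sparse weight pattern (RMS 1 over
its support), ``eta`` is spatially smoothed unit-variance Gaussian noise
and ``R2`` is the fraction of trait variance encoded in the maps (the
ceiling for any map-based predictor of the trait).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CohortBundle",
    "generate_weight_pattern",
    "simulate_cohort",
    "simulate_treatment",
    "write_fixture",
    "read_fixture",
    "LMS_BARELY_DETECTABLE",
]

#: "barely detectable" anchor on the 0-1 labeled magnitude scale.
LMS_BARELY_DETECTABLE = 0.014

_SCALE_BOUNDS = {
    "zero_to_ten": (0.0, 10.0),
    "zero_to_one_lms": (0.0, 1.0),
}

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort generator."""

    n_participants: int = 100
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_trials: int = 10
    #: condition label -> coupling strength in [0, 1]; 1.0 = full coupling.
    modalities: dict[str, float] = field(default_factory=lambda: {"pain": 1.0})
    sensitivity_mean: float = 5.0
    sensitivity_sd: float = 1.5
    rating_scale: str = "zero_to_ten"
    pattern_density: float = 0.08
    smoothness_fwhm: float = 2.0
    #: fraction of trait variance encoded in the maps (multivariate ceiling).
    explainable_r2: float = 0.25
    #: per-voxel signal fraction at the RMS signal voxel; defaults to
    #: ``explainable_r2`` when None.
    signal_voxel_r2: float | None = None
    dataset_shift: float = 0.0
    sex_effect: float = 0.0
    age_slope: float = 0.0
    n_families: int | None = None
    family_icc: float = 0.0
    treatment_coupling: float = 0.0
    trial_noise_sd: float = 1.0
    make_trial_maps: bool = False
    #: coupling of within-participant trial rating deviations to trial maps.
    state_coupling: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rating_scale not in _SCALE_BOUNDS:
            raise ValueError(f"unknown rating_scale {self.rating_scale!r}")
        if not 0.0 <= self.explainable_r2 < 1.0:
            raise ValueError("explainable_r2 must lie in [0, 1)")
        if self.signal_voxel_r2 is not None and not 0.0 < self.signal_voxel_r2 < 1.0:
            raise ValueError("signal_voxel_r2 must lie in (0, 1)")
        if not 0.0 <= self.family_icc < 1.0:
            raise ValueError("family_icc must lie in [0, 1)")
        if not 0.0 < self.pattern_density <= 1.0:
            raise ValueError("pattern_density must lie in (0, 1]")
        if abs(self.treatment_coupling) > 1.0:
            raise ValueError("treatment_coupling must lie in [-1, 1]")
        if self.sensitivity_sd <= 0 or self.trial_noise_sd < 0:
            raise ValueError("scale parameters must be positive")
        if self.n_participants < 2:
            raise ValueError("need at least two participants")

    @property
    def scale_bounds(self) -> tuple[float, float]:
        return _SCALE_BOUNDS[self.rating_scale]


@dataclass
class GroundTruth:
    """Generative parameters stored alongside a simulated cohort."""

    true_weights: np.ndarray  # a_v over mask voxels, RMS 1 on support
    true_voxel_correlation: np.ndarray  # rho_v = corr(map_v, latent trait)
    true_explainable_r2: float
    family_variance: float
    treatment_coupling_true: float
    noise_sd: float  # sigma_n of the map noise


@dataclass
class CohortBundle:
    """A simulated cohort: maps, behavior table, mask and ground truth."""

    maps: dict[str, np.ndarray]  # condition -> (n_participants, n_voxels)
    behavior: pd.DataFrame  # trial-level long table
    mask: np.ndarray  # boolean 3-D volume
    affine: np.ndarray  # 4x4 voxel-to-world transform
    ground_truth: GroundTruth
    sensitivity_latent: np.ndarray  # noiseless s_i for the first condition
    trial_maps: dict[str, np.ndarray] | None = None  # (n, n_trials, n_voxels)
    pre_ratings: np.ndarray | None = None
    post_ratings: np.ndarray | None = None
    post_maps: np.ndarray | None = None
    treatment_condition: str | None = None

    @property
    def conditions(self) -> list[str]:
        return list(self.maps)

    @property
    def n_participants(self) -> int:
        return next(iter(self.maps.values())).shape[0]

    @property
    def participants(self) -> pd.DataFrame:
        """One row per participant with demographic columns."""
        cols = ["participant_id", "dataset", "sex", "age", "family_id"]
        return (
            self.behavior[cols]
            .drop_duplicates("participant_id")
            .sort_values("participant_id")
            .reset_index(drop=True)
        )

    def mean_ratings(self, condition: str) -> np.ndarray:
        """Per-participant mean trial rating ("pain sensitivity"), aligned
        with the row order of ``maps[condition]``."""
        sub = self.behavior[self.behavior["condition"] == condition]
        means = sub.groupby("participant_id")["rating"].mean()
        return means.sort_index().to_numpy()

    @property
    def pre_maps(self) -> np.ndarray:
        if self.treatment_condition is None:
            raise ValueError("no treatment arm simulated")
        return self.maps[self.treatment_condition]

    @property
    def difference_maps(self) -> np.ndarray:
        if self.post_maps is None:
            raise ValueError("no treatment arm simulated")
        return self.pre_maps - self.post_maps


def _default_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoid inscribed in the grid; keeps 40-60% of voxels."""
    idx = np.indices(grid_shape).astype(float)
    center = (np.asarray(grid_shape, float) - 1.0) / 2.0
    radii = np.asarray(grid_shape, float) / 2.0
    dist = sum(((idx[d] - center[d]) / radii[d]) ** 2 for d in range(3))
    return dist <= 1.0


def _smooth_unit_noise(rng, shape, fwhm: float) -> np.ndarray:
    """White noise, optionally Gaussian-smoothed, rescaled to unit variance."""
    noise = rng.standard_normal(shape)
    if fwhm > 0:
        sigma = fwhm * _FWHM_TO_SIGMA
        # smooth only over the trailing three (spatial) axes
        sigmas = (0,) * (noise.ndim - 3) + (sigma,) * 3
        noise = ndimage.gaussian_filter(noise, sigma=sigmas)
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
    return noise


def generate_weight_pattern(
    grid_shape: tuple[int, int, int],
    pattern_density: float,
    smoothness_fwhm: float,
    seed: int,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Sparse, spatially smooth weight vector over the mask voxels.

    Smoothed Gaussian noise is thresholded at the top ``density`` fraction
    of absolute values; surviving values are rescaled to RMS 1.  Returns a
    vector of length ``mask.sum()`` with exactly
    ``round(density * n_voxels)`` nonzero entries.
    """
    if not 0.0 < pattern_density <= 1.0:
        raise ValueError("pattern_density must lie in (0, 1]")
    if smoothness_fwhm < 0:
        raise ValueError("smoothness_fwhm must be >= 0")
    if mask is None:
        mask = _default_mask(grid_shape)
    n_voxels = int(mask.sum())
    k = int(round(pattern_density * n_voxels))
    if k < 1:
        raise ValueError("empty pattern: density * n_voxels < 1")
    rng = np.random.default_rng(seed)
    vol = _smooth_unit_noise(rng, grid_shape, smoothness_fwhm)
    vals = _vectorize(vol, mask)
    weights = np.zeros(n_voxels)
    order = np.argsort(-np.abs(vals), kind="stable")
    support = order[:k]
    weights[support] = vals[support]
    rms = np.sqrt(np.mean(weights[support] ** 2))
    weights[support] /= rms
    return weights


def _vectorize(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Masked voxels in Fortran order (first axis fastest-varying)."""
    return volume.ravel(order="F")[mask.ravel(order="F")]


def _family_structured_latent(rng, family_ids: np.ndarray, icc: float) -> np.ndarray:
    """Unit-variance latent with intraclass correlation ``icc`` by family."""
    uniq, inverse = np.unique(family_ids, return_inverse=True)
    fam_part = rng.standard_normal(uniq.size)[inverse]
    ind_part = rng.standard_normal(family_ids.size)
    return np.sqrt(icc) * fam_part + np.sqrt(1.0 - icc) * ind_part


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Draw a full cohort from the generative model in the module docstring."""
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    mask = _default_mask(config.grid_shape)
    n_voxels = int(mask.sum())
    lo, hi = config.scale_bounds

    weights = generate_weight_pattern(
        config.grid_shape,
        config.pattern_density,
        config.smoothness_fwhm,
        seed=int(rng.integers(2**31)),
        mask=mask,
    )
    if n_voxels < 2 * int((weights != 0).sum()):
        raise ValueError("grid too small: need >= 2x the signal voxel count")

    # demographics and confounds
    n_families = config.n_families or (n + 1) // 2
    family_ids = np.arange(n) % n_families
    dataset = (np.arange(n) % 2).astype(int)
    sex = rng.integers(0, 2, size=n)
    age = rng.uniform(18.0, 40.0, size=n)
    confound_part = (
        config.dataset_shift * (dataset - dataset.mean())
        + config.sex_effect * (sex - sex.mean())
        + config.age_slope * (age - age.mean())
    )

    r2 = config.explainable_r2
    svr = config.signal_voxel_r2 if config.signal_voxel_r2 is not None else r2
    if svr <= 0:  # fully null maps
        sigma_n = 1.0
    else:
        sigma_n = np.sqrt((1.0 - svr) / svr)

    sens_sd = config.sensitivity_sd
    icc = config.family_icc

    maps: dict[str, np.ndarray] = {}
    trial_maps: dict[str, np.ndarray] = {}
    behavior_rows = []
    first_latent = None
    first_g = None
    for condition, kappa in config.modalities.items():
        if not 0.0 <= kappa <= 1.0:
            raise ValueError("modality coupling must lie in [0, 1]")
        g = _family_structured_latent(rng, family_ids, icc)
        e = _family_structured_latent(rng, family_ids, icc)
        trait = sens_sd * (np.sqrt(r2) * g + np.sqrt(1.0 - r2) * e)
        s = config.sensitivity_mean + confound_part + trait

        eps = rng.normal(0.0, config.trial_noise_sd, size=(n, config.n_trials))
        ratings = np.clip(s[:, None] + eps, lo, hi)

        noise = _smooth_unit_noise(
            rng, (n,) + tuple(config.grid_shape), config.smoothness_fwhm
        )
        noise = np.stack([_vectorize(noise[i], mask) for i in range(n)])
        cond_maps = kappa * np.outer(g, weights) + sigma_n * noise
        maps[condition] = cond_maps

        if config.make_trial_maps:
            dev = ratings - ratings.mean(axis=1, keepdims=True)
            dev_scale = config.trial_noise_sd if config.trial_noise_sd > 0 else 1.0
            tnoise = rng.standard_normal((n, config.n_trials, n_voxels))
            per_trial = (
                kappa * g[:, None] + config.state_coupling * dev / dev_scale
            )
            trial_maps[condition] = (
                per_trial[:, :, None] * weights[None, None, :] + sigma_n * tnoise
            )

        for i in range(n):
            for t in range(config.n_trials):
                behavior_rows.append(
                    (i, int(dataset[i]), int(sex[i]), float(age[i]),
                     int(family_ids[i]), condition, t, float(ratings[i, t]))
                )
        if first_latent is None:
            first_latent = s
            first_g = g
            first_kappa = kappa

    behavior = pd.DataFrame(
        behavior_rows,
        columns=["participant_id", "dataset", "sex", "age", "family_id",
                 "condition", "trial_index", "rating"],
    )

    # closed-form corr(map_v, noiseless sensitivity) for the first condition
    var_conf = float(np.var(confound_part))
    sd_s = np.sqrt(sens_sd**2 + var_conf)
    map_sd = np.sqrt((first_kappa * weights) ** 2 + sigma_n**2)
    rho = (first_kappa * weights / map_sd) * np.sqrt(r2) * sens_sd / sd_s

    gt = GroundTruth(
        true_weights=weights,
        true_voxel_correlation=rho,
        true_explainable_r2=r2 * sens_sd**2 / sd_s**2,
        family_variance=icc * sens_sd**2,
        treatment_coupling_true=0.0,
        noise_sd=sigma_n,
    )
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    bundle = CohortBundle(
        maps=maps,
        behavior=behavior,
        mask=mask,
        affine=affine,
        ground_truth=gt,
        sensitivity_latent=first_latent,
        trial_maps=trial_maps or None,
    )
    if config.treatment_coupling != 0.0:
        bundle = simulate_treatment(
            bundle, config.treatment_coupling, seed=int(rng.integers(2**31))
        )
    return bundle


def simulate_treatment(
    bundle: CohortBundle,
    treatment_coupling: float,
    seed: int,
    condition: str | None = None,
    mean_reduction: float = 1.0,
    reduction_sd: float = 0.5,
) -> CohortBundle:
    """Attach a pre/post treatment arm to a simulated cohort.

    Post-treatment maps are the pre maps minus a change pattern whose
    true-weight expression correlates with the pre-minus-post rating
    reduction at ``treatment_coupling`` (exactly, in expectation over
    participants).
    """
    if abs(treatment_coupling) > 1.0:
        raise ValueError("treatment_coupling must lie in [-1, 1]")
    condition = condition or bundle.conditions[0]
    rng = np.random.default_rng(seed)
    n = bundle.n_participants
    gt = bundle.ground_truth
    weights = gt.true_weights
    n_voxels = weights.size

    t_latent = rng.standard_normal(n)
    grid = bundle.mask.shape
    noise = _smooth_unit_noise(rng, (n,) + grid, fwhm=0.0)
    noise = np.stack([_vectorize(noise[i], bundle.mask) for i in range(n)])
    diff_maps = np.outer(t_latent, weights) + gt.noise_sd * noise

    # couple the reduction to the realized pattern expression
    expression = diff_maps @ weights
    z_expr = (expression - expression.mean()) / expression.std()
    c = treatment_coupling
    reduction = mean_reduction + reduction_sd * (
        c * z_expr + np.sqrt(1.0 - c**2) * rng.standard_normal(n)
    )

    pre = bundle.mean_ratings(condition)
    post = pre - reduction

    new_gt = dataclasses.replace(gt, treatment_coupling_true=float(c))
    return dataclasses.replace(
        bundle,
        ground_truth=new_gt,
        pre_ratings=pre,
        post_ratings=post,
        post_maps=bundle.maps[condition] - diff_maps,
        treatment_condition=condition,
    )


# ---------------------------------------------------------------------------
# fixture serialization


def write_fixture(bundle: CohortBundle, directory, overwrite: bool = False) -> Path:
    """Write a cohort to disk: one NIfTI per participant per condition, a
    mask image, the behavior CSV and a ground-truth sidecar."""
    from .shell.io import unvectorize, write_volume

    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} is not empty; pass overwrite=True")
    directory.mkdir(parents=True, exist_ok=True)

    write_volume(bundle.mask.astype(np.uint8), bundle.affine,
                 directory / "mask.nii")
    for condition, mat in bundle.maps.items():
        cond_dir = directory / "maps" / condition
        cond_dir.mkdir(parents=True, exist_ok=True)
        for i in range(mat.shape[0]):
            vol = unvectorize(mat[i], bundle.mask)
            write_volume(vol.astype(np.float32), bundle.affine,
                         cond_dir / f"sub-{i:04d}.nii")

    behavior = bundle.behavior.copy()
    behavior.to_csv(directory / "behavior.csv", index=False, na_rep="NA")

    gt_dir = directory / "ground_truth"
    gt_dir.mkdir(exist_ok=True)
    gt = bundle.ground_truth
    write_volume(unvectorize(gt.true_weights, bundle.mask).astype(np.float64),
                 bundle.affine, gt_dir / "true_weights.nii")
    write_volume(
        unvectorize(gt.true_voxel_correlation, bundle.mask).astype(np.float64),
        bundle.affine, gt_dir / "true_voxel_correlation.nii")
    scalars = {
        "true_explainable_r2": gt.true_explainable_r2,
        "family_variance": gt.family_variance,
        "treatment_coupling_true": gt.treatment_coupling_true,
        "noise_sd": gt.noise_sd,
    }
    (gt_dir / "scalars.json").write_text(json.dumps(scalars, indent=2))
    return directory


def read_fixture(directory) -> CohortBundle:
    """Reload a cohort written by :func:`write_fixture`."""
    from .shell.io import read_volume

    directory = Path(directory)
    mask_vol, affine = read_volume(directory / "mask.nii")
    mask = mask_vol.astype(bool)

    maps: dict[str, np.ndarray] = {}
    for cond_dir in sorted((directory / "maps").iterdir()):
        rows = []
        for path in sorted(cond_dir.glob("sub-*.nii")):
            vol, _ = read_volume(path)
            rows.append(_vectorize(vol, mask))
        maps[cond_dir.name] = np.stack(rows)

    behavior = pd.read_csv(directory / "behavior.csv", na_values=["NA"])

    gt_dir = directory / "ground_truth"
    w_vol, _ = read_volume(gt_dir / "true_weights.nii")
    r_vol, _ = read_volume(gt_dir / "true_voxel_correlation.nii")
    scalars = json.loads((gt_dir / "scalars.json").read_text())
    gt = GroundTruth(
        true_weights=_vectorize(w_vol, mask),
        true_voxel_correlation=_vectorize(r_vol, mask),
        true_explainable_r2=scalars["true_explainable_r2"],
        family_variance=scalars["family_variance"],
        treatment_coupling_true=scalars["treatment_coupling_true"],
        noise_sd=scalars["noise_sd"],
    )
    first = list(maps)[0]
    sens = (
        behavior[behavior["condition"] == first]
        .groupby("participant_id")["rating"].mean().sort_index().to_numpy()
    )
    return CohortBundle(
        maps=maps, behavior=behavior, mask=mask, affine=affine,
        ground_truth=gt, sensitivity_latent=sens,
    )
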