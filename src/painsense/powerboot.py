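"""Bootstrap detection-probability surfaces and minimal sample sizes.

For a grid of subsample sizes, participants are drawn with replacement
from the parent cohort; in each draw the voxelwise (or ROI) correlation
is thresholded — BH-FDR within the subsample for whole-brain mode, raw
alpha for ROI mode — and the per-unit detection probability is the
fraction of draws reaching significance.  The minimal sample size is the
first grid point whose detection probability reaches the target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .unimap import fdr_bh, roi_mean_signal, _pearson_columns, _pearson_p

__all__ = [
    "PowerSurface",
    "MinSampleMap",
    "bootstrap_detection",
    "min_sample_size",
    "analytic_power",
    "analytic_min_n",
    "roi_power_curves",
]


@dataclass
class PowerSurface:
    """Detection probability over units (voxels or ROIs) x sizes."""

    sizes: np.ndarray
    reps: int
    detect_prob: np.ndarray  # (n_units, n_sizes)
    threshold_rule: str  # "fdr:<q>" or "alpha:<a>"
    seed: int


@dataclass
class MinSampleMap:
    """Smallest tested size reaching the target detection probability."""

    min_n: np.ndarray  # float; NaN = censored (never reached)
    target: float
    sizes: np.ndarray

    @property
    def censored(self) -> np.ndarray:
        return ~np.isfinite(self.min_n)

    def summary(self, detected_only: bool = True) -> dict:
        """Median/SD/quartiles of min_n; censored voxels excluded by
        default (flagged in the output)."""
        vals = self.min_n[np.isfinite(self.min_n)]
        if vals.size == 0:
            return {"n_detected": 0, "n_censored": int(self.censored.sum())}
        return {
            "median": float(np.median(vals)),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "q1": float(np.percentile(vals, 25)),
            "q2": float(np.percentile(vals, 50)),
            "q3": float(np.percentile(vals, 75)),
            "n_detected": int(vals.size),
            "n_censored": int(self.censored.sum()),
            "censored_excluded": detected_only,
        }


def _parse_rule(rule: str) -> tuple[str, float]:
    try:
        kind, value = rule.split(":")
        return kind, float(value)
    except ValueError as err:
        raise ValueError(
            f"rule must be 'fdr:<q>' or 'alpha:<a>', got {rule!r}") from err


def bootstrap_detection(maps: np.ndarray, behavior: np.ndarray,
                        sizes, reps: int, rule: str = "fdr:0.05",
                        seed: int = 0) -> PowerSurface:
    """Per-voxel detection probability across bootstrap subsample sizes.

    ``rule`` is ``"fdr:q"`` (BH within each subsample, whole-brain mode)
    or ``"alpha:a"`` (raw threshold, ROI mode).  Duplicated participants
    in a subsample are kept as drawn.  Each (size, rep) cell uses an
    independent RNG substream derived from ``seed``.
    """
    maps = np.asarray(maps, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    sizes = np.asarray(sorted(int(s) for s in np.atleast_1d(sizes)))
    if reps < 1:
        raise ValueError("reps must be >= 1")
    kind, level = _parse_rule(rule)
    if kind not in ("fdr", "alpha"):
        raise ValueError(f"unknown rule kind {kind!r}")
    n_parent = behavior.shape[0]
    if sizes.max() > n_parent:
        warnings.warn("subsample size exceeds parent n (with-replacement "
                      "sampling permits it)", RuntimeWarning)

    counts = np.zeros((maps.shape[1], sizes.size))
    for si, size in enumerate(sizes):
        for rep in range(reps):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=(seed, si, rep)))
            idx = rng.integers(0, n_parent, size=size)
            y = behavior[idx]
            if size < 4 or np.ptp(y) == 0:
                continue  # unusable draw; logged as a skipped rep
            r = _pearson_columns(maps[idx], y)
            p = _pearson_p(r, size - 2)
            testable = np.isfinite(r)
            sig = np.zeros(r.size, dtype=bool)
            if kind == "fdr":
                sig[testable], _ = fdr_bh(p[testable], level)
            else:
                sig[testable] = p[testable] <= level
            counts[:, si] += sig
    return PowerSurface(sizes=sizes, reps=reps,
                        detect_prob=counts / reps,
                        threshold_rule=rule, seed=seed)


def min_sample_size(surface: PowerSurface, target: float = 0.8) -> MinSampleMap:
    """First size at which detection probability reaches ``target``."""
    if not 0.0 < target < 1.0:
        raise ValueError("target must lie in (0, 1)")
    prob = surface.detect_prob
    reached = prob >= target
    min_n = np.full(prob.shape[0], np.nan)
    any_hit = reached.any(axis=1)
    first = reached.argmax(axis=1)
    min_n[any_hit] = surface.sizes[first[any_hit]]
    return MinSampleMap(min_n=min_n, target=target, sizes=surface.sizes)


def analytic_power(rho: float, n: int, alpha: float) -> float:
    """Closed-form two-sided power of the Fisher-z correlation test."""
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if n <= 3:
        raise ValueError("need n > 3")
    zcrit = stats.norm.isf(alpha / 2.0)
    shift = abs(np.arctanh(rho)) * np.sqrt(n - 3)
    return float(stats.norm.cdf(shift - zcrit) + stats.norm.cdf(-shift - zcrit))


def analytic_min_n(rho: float, alpha: float, target: float = 0.8) -> float:
    """Smallest real n with analytic_power >= target (Fisher-z formula)."""
    zcrit = stats.norm.isf(alpha / 2.0)
    zpow = stats.norm.isf(1.0 - target)
    return ((zcrit + zpow) / abs(np.arctanh(rho))) ** 2 + 3.0


def roi_power_curves(maps: np.ndarray, behavior: np.ndarray, roi_set,
                     sizes, reps: int, alphas=(0.01, 0.001),
                     seed: int = 0) -> dict[tuple[str, float], PowerSurface]:
    """Detection-probability curves per ROI per alpha level.

    ROI mean signals are extracted once; each (roi, alpha) pair gets a
    single-unit PowerSurface suitable for line charts.
    """
    signals = np.column_stack(
        [roi_mean_signal(maps, m) for m in roi_set.masks])
    out: dict[tuple[str, float], PowerSurface] = {}
    for alpha in alphas:
        surface = bootstrap_detection(signals, behavior, sizes, reps,
                                      rule=f"alpha:{alpha}", seed=seed)
        for li, label in enumerate(roi_set.labels):
            out[(label, alpha)] = PowerSurface(
                sizes=surface.sizes, reps=reps,
                detect_prob=surface.detect_prob[li:li + 1],
                threshold_rule=surface.threshold_rule, seed=seed)
    return out
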