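"""Stage orchestration and reproducibility manifests.

A pipeline run is described by a plain config mapping (YAML/JSON on
disk).  Every stage draws its randomness from a substream derived from
the single master seed, so rerunning the same config + seed reproduces
all outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("painsense")

STAGES = ("simulate", "map", "power", "fit", "lesion")


@dataclass
class RunManifest:
    config: dict
    master_seed: int
    stage_seeds: dict = field(default_factory=dict)
    software_version: str = ""
    outputs: list = field(default_factory=list)
    digests: dict = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0
    error: str | None = None

    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   default=str))
        return path


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed."""
    ss = np.random.SeedSequence((master_seed, STAGES.index(stage)))
    return int(ss.generate_state(1)[0])


def load_config(path) -> dict:
    import yaml

    text = Path(path).read_text()
    return yaml.safe_load(text)


def run_pipeline(config: dict, out_dir, master_seed: int = 0) -> RunManifest:
    """Execute the requested stages on a simulated cohort.

    Recognized stage keys (in fixed order): ``simulate`` (required; its
    mapping feeds :class:`~painsense.simcohort.SimulationConfig`),
    ``map``, ``power``, ``fit``, ``lesion``.  Unknown stage keys raise.
    Any stage error aborts the run after flushing a partial manifest.
    """
    from .. import __version__, probe, powerboot, signature, simcohort, unimap
    from . import io as shio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    known = set(STAGES)
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    if "simulate" not in config:
        raise ValueError("config must contain a 'simulate' stage")

    manifest = RunManifest(config=config, master_seed=master_seed,
                           software_version=__version__,
                           started=time.time())
    manifest_path = out_dir / "manifest.json"

    def emit(path: Path):
        manifest.outputs.append(str(path))
        manifest.digests[str(path)] = _digest(path)

    try:
        sim_cfg = dict(config["simulate"])
        sim_cfg["seed"] = stage_seed(master_seed, "simulate")
        manifest.stage_seeds["simulate"] = sim_cfg["seed"]
        bundle = simcohort.simulate_cohort(
            simcohort.SimulationConfig(**sim_cfg))
        condition = bundle.conditions[0]
        maps = bundle.maps[condition]
        y = bundle.mean_ratings(condition)
        shio.write_behavior_table(bundle.behavior, out_dir / "behavior.csv")
        emit(out_dir / "behavior.csv")
        logger.info("simulate: n=%d, voxels=%d", maps.shape[0], maps.shape[1])

        if "map" in config:
            opts = dict(config["map"])
            method = opts.get("method", "pearson")
            q = float(opts.get("q", 0.05))
            if method == "partial":
                parts = bundle.participants
                cov = parts[["dataset", "sex", "age"]]
                stat = unimap.partial_correlation_map(
                    maps, y, cov, dataset_labels=parts["dataset"].to_numpy(),
                    q_level=q)
            elif method == "mixed":
                stat = unimap.mixed_effect_map(
                    maps, y, bundle.participants["family_id"].to_numpy(),
                    q_level=q)
            else:
                stat = unimap.voxelwise_correlation(maps, y, method=method,
                                                    q_level=q)
            for name, vec in (("stat", stat.statistic), ("p", stat.p),
                              ("q", stat.q),
                              ("sig", stat.sig_mask.astype(float))):
                p = shio.write_stat_map(vec, bundle.mask, bundle.affine,
                                        out_dir / f"map_{name}.nii")
                emit(p)
            logger.info("map: %d significant voxels", stat.n_significant)

        if "power" in config:
            opts = dict(config["power"])
            seed = stage_seed(master_seed, "power")
            manifest.stage_seeds["power"] = seed
            sizes = opts.get("sizes", [50, 100])
            if isinstance(sizes, str):
                a, b, s = (int(v) for v in sizes.split(":"))
                sizes = list(range(a, b + 1, s))
            surface = powerboot.bootstrap_detection(
                maps, y, sizes, reps=int(opts.get("reps", 20)),
                rule=opts.get("rule", "fdr:0.05"), seed=seed)
            msm = powerboot.min_sample_size(
                surface, target=float(opts.get("target", 0.8)))
            p = shio.write_stat_map(msm.min_n, bundle.mask, bundle.affine,
                                    out_dir / "min_sample_size.nii")
            emit(p)
            (out_dir / "power_summary.json").write_text(
                json.dumps(msm.summary(), indent=2))
            emit(out_dir / "power_summary.json")

        model = None
        if "fit" in config:
            opts = dict(config["fit"])
            seed = stage_seed(master_seed, "fit")
            manifest.stage_seeds["fit"] = seed
            grid = signature.default_lambda_grid(
                int(opts.get("lambda_grid_size", 100)))
            model, report = signature.fit_lasso_pcr(
                maps, y, lambda_grid=grid,
                n_folds=int(opts.get("folds", 5)), seed=seed)
            nii, js = signature.save_signature(model, bundle.mask,
                                               bundle.affine,
                                               out_dir / "signature")
            emit(nii)
            emit(js)
            (out_dir / "fit_report.json").write_text(json.dumps({
                "pearson_r": report.pearson_r,
                "r_squared": report.r_squared,
                "n": report.n, "lambda": model.lam,
            }, indent=2))
            emit(out_dir / "fit_report.json")
            logger.info("fit: CV r=%.3f R2=%.3f lambda=%.3g",
                        report.pearson_r, report.r_squared, model.lam)

        if "lesion" in config:
            opts = dict(config["lesion"])
            seed = stage_seed(master_seed, "lesion")
            manifest.stage_seeds["lesion"] = seed
            n_regions = int(opts.get("n_regions", 4))
            labels = (np.arange(maps.shape[1]) * n_regions
                      // maps.shape[1]) + 1
            parc = probe.Parcellation(labels=labels, lookup={})
            fit_settings = {
                "lambda_grid": signature.default_lambda_grid(
                    int(opts.get("lambda_grid_size", 25))),
                "seed": seed,
            }
            report = probe.virtual_lesion(
                maps, y, parc, mode=opts.get("mode", "remove"),
                fit_settings=fit_settings)
            df = report.to_frame()
            df.to_csv(out_dir / "lesion_report.tsv", sep="\t", index=False)
            emit(out_dir / "lesion_report.tsv")
    except Exception as err:
        manifest.error = f"{type(err).__name__}: {err}"
        manifest.finished = time.time()
        manifest.save(manifest_path)
        raise
    manifest.finished = time.time()
    manifest.save(manifest_path)
    return manifest
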