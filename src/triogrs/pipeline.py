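"""End-to-end orchestration: simulate/score/contrast/screen/describe.

A single validated :class:`RunConfig` (YAML on disk, pydantic in memory)
drives the whole analysis; every stochastic stage receives a seed derived
from the run seed, so re-running the same config reproduces byte-identical
result tables.  A JSON manifest records the seed, a hash of the canonical
config, and each stage's outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__, descriptives, grs_engine, io_formats, screen as screen_mod
from .contrast import SubgroupSpec, run_contrast_suite
from .errors import ValidationError
from .simulate import SimConfig, panel_to_weight_table, simulate_trios

logger = logging.getLogger(__name__)


class ContrastOptions(BaseModel):
    quantile_levels: list[float] = [0.95, 0.90, 0.75]
    cohort: str = "all"
    exclude_overt_phenotype: bool = False
    ctd_subtype: Optional[str] = None
    normality_alpha: float = 0.05


class RunConfig(BaseModel):
    """Validated pipeline configuration.

    Exactly one input source is allowed: either a ``sim`` block (synthetic
    cohort) or the three real-input paths (``pedigree``, ``dosages``,
    ``weights``).
    """

    seed: int
    outdir: Path
    sim: Optional[SimConfig] = None
    pedigree: Optional[Path] = None
    dosages: Optional[Path] = None
    dosage_format: Optional[Literal["vcf", "tabular"]] = None
    weights: Optional[Path] = None
    associations: Optional[Path] = None
    missing_policy: str = "impute_role_mean"
    contrast: ContrastOptions = Field(default_factory=ContrastOptions)

    @model_validator(mode="before")
    @classmethod
    def _inject_sim_seed(cls, values):
        if isinstance(values, dict):
            sim = values.get("sim")
            if isinstance(sim, dict) and "seed" not in sim and "seed" in values:
                sim = dict(sim)
                sim["seed"] = values["seed"]
                values = dict(values)
                values["sim"] = sim
        return values

    @model_validator(mode="after")
    def _exactly_one_source(self):
        real = [self.pedigree, self.dosages, self.weights]
        if self.sim is not None and any(p is not None for p in real):
            raise ValueError("supply either a sim block or real-input paths, not both")
        if self.sim is None and not all(p is not None for p in real):
            raise ValueError("real-input runs need pedigree, dosages and weights paths")
        return self


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "package_version": __version__,
        "config_sha256": _config_hash(config),
        "stages": {},
    }

    def record(stage: str, *paths: Path):
        manifest["stages"][stage] = {"outputs": [str(p) for p in paths]}

    try:
        # -- stage 1: inputs ------------------------------------------------
        if config.sim is not None:
            trios, dm, truth = simulate_trios(config.sim)
            from .simulate import generate_panel
            weights = panel_to_weight_table(generate_panel(config.sim))
            ped_path, dos_path, w_path = out / "pedigree.tsv", out / "dosages.tsv", out / "weights.tsv"
            truth_path = out / "truth.json"
            io_formats.write_trios(trios, ped_path)
            io_formats.write_dosages(dm, dos_path)
            io_formats.write_weight_table(weights, w_path)
            truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
            record("simulate", ped_path, dos_path, w_path, truth_path)
            # re-read from disk so the scored data is exactly what was written
            trios = io_formats.read_trios(ped_path)
            weights = io_formats.read_weight_table(w_path)
            dm = io_formats.read_dosages(dos_path, weights, format="tabular")
        else:
            trios = io_formats.read_trios(config.pedigree)
            weights = io_formats.read_weight_table(config.weights)
            dm = io_formats.read_dosages(config.dosages, weights, format=config.dosage_format)

        # -- stage 2: score -------------------------------------------------
        dm = grs_engine.align_alleles(dm, weights)
        grs = grs_engine.compute_grs(dm, weights, io_formats.parent_roles(trios),
                                     missing_policy=config.missing_policy)
        grs_path = out / "grs.tsv"
        grs_engine.write_grs(grs, grs_path)
        record("score", grs_path)

        # -- stage 3: contrast ----------------------------------------------
        panel_sizes = weights["condition"].value_counts().to_dict()
        panel_sizes["combined"] = int(sum(panel_sizes.values()))
        suite = run_contrast_suite(
            grs, trios,
            SubgroupSpec(
                cohort=config.contrast.cohort,
                exclude_overt_phenotype=config.contrast.exclude_overt_phenotype,
                ctd_subtype=config.contrast.ctd_subtype,
            ),
            quantile_levels=config.contrast.quantile_levels,
            normality_alpha=config.contrast.normality_alpha,
            panel_sizes=panel_sizes,
        )
        means_path = out / "contrast_means.tsv"
        thr_path = out / "contrast_thresholds.tsv"
        suite.means.to_csv(means_path, sep="\t", index=False, float_format="%.6g")
        suite.thresholds.to_csv(thr_path, sep="\t", index=False, float_format="%.6g")
        record("contrast", means_path, thr_path)

        # -- stage 4: screen (optional) ---------------------------------
        if config.associations is not None:
            assoc = io_formats.read_associations(config.associations)
            sizes = {c: int(n) for c, n in weights["condition"].value_counts().items()}
            scr = screen_mod.classify(assoc, sizes)
            scr_path = out / "screen.tsv"
            screen_mod.write_screen(scr, scr_path)
            record("screen", scr_path)

        # -- stage 5: describe -----------------------------------------
        table1 = descriptives.cohort_table(trios, seed=config.seed)
        t1_path = out / "table1.tsv"
        table1.to_csv(t1_path, sep="\t", index=False, float_format="%.6g")
        record("describe", t1_path)
    except Exception as exc:
        stage = len(manifest["stages"]) + 1
        raise ValidationError(f"pipeline failed at stage {stage}: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _config_hash(config: RunConfig) -> str:
    canon = json.dumps(json.loads(config.model_dump_json()), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()
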