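"""End-to-end pipeline: coding -> quadratic fit -> ANOVA -> RSM optimum ->
ANN training -> GA optimum -> comparison report.

Every stage's artifact is written under the output directory and stamped
with the run's seed and config hash; a manifest lists them all.  All
randomness derives from the single pipeline seed, split into named
per-stage substreams, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .ann import AnnConfig, fit_surrogate, save_model
from .compare import build_report
from .design import DesignTable, FactorSpec
from .ga import GaConfig, optimize_ann_ga
from .io import config_hash, fixture_design, fixture_factors, load_design_csv, write_design_csv
from .optimize import maximize_in_box
from .rsm import anova, fit_quadratic

logger = logging.getLogger("extraopt.pipeline")


@dataclass
class PipelineConfig:
    """Configuration of one full run.

    With ``design_path`` (and ``factors``) unset, the packaged reference
    experiment is analyzed.  ``verification_yields`` are wet-lab
    measurements at each model's optimum; without them the comparison is
    emitted with blank error cells.
    """

    outdir: Path
    design_path: str | None = None
    factors: list[FactorSpec] | None = None
    ann: AnnConfig = field(default_factory=AnnConfig)
    ga: GaConfig = field(default_factory=GaConfig)
    seed: int = 0
    verification_yields: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "design_path": self.design_path,
            "factors": None if self.factors is None
            else [f.to_dict() for f in self.factors],
            "ann": self.ann.to_dict(),
            "ga": self.ga.to_dict(),
            "seed": self.seed,
            "verification_yields": self.verification_yields,
        }


def _stage_seed(seed: int, stage: int) -> int:
    """Named substream: child seed below 2^31, stable across stage order."""
    return int(np.random.SeedSequence(seed, spawn_key=(stage,)).generate_state(1)[0]
               % (2 ** 31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the result objects and artifact paths.

    A failure in any stage propagates with the stage name prefixed;
    artifacts written before the failure are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # hash the scientific configuration only: where artifacts land must not
    # change their contents
    chash = config_hash({k: v for k, v in config.to_dict().items()
                         if k != "outdir"})
    stamp = f"config_hash={chash} seed={config.seed}"
    artifacts: list[str] = []
    results: dict = {}

    def emit_json(name: str, payload: dict) -> None:
        path = outdir / name
        path.write_text(json.dumps(
            {"config_hash": chash, "seed": config.seed, **payload}, indent=1))
        artifacts.append(name)

    def emit_csv(name: str, frame) -> None:
        path = outdir / name
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# {stamp}\n")
            frame.to_csv(fh, index=False)
        artifacts.append(name)

    stage = "load"
    try:
        factors = config.factors or fixture_factors()
        design = fixture_design() if config.design_path is None \
            else load_design_csv(config.design_path, factors)
        if config.design_path is None:
            factors = design.factors
        results["design"] = design
        write_design_csv(design, outdir / "design_coded.csv", header_comment=stamp)
        artifacts.append("design_coded.csv")

        stage = "fit"
        fit = fit_quadratic(design)
        results["fit"] = fit
        emit_json("fit.json", {"coefficients": fit.coefficients(),
                               "ms_residual": fit.ms_residual, "n_obs": fit.n_obs})

        stage = "anova"
        tab = anova(design, fit)
        results["anova"] = tab
        emit_csv("anova.csv", tab.to_frame())
        (outdir / "anova.txt").write_text(f"# {stamp}\n" + tab.to_text() + "\n")
        artifacts.append("anova.txt")

        stage = "optimize-rsm"
        rsm_opt = maximize_in_box(fit)
        results["rsm_optimum"] = rsm_opt
        emit_json("rsm_optimum.json", rsm_opt.to_dict())

        stage = "train-ann"
        ann_cfg = dataclasses.replace(config.ann, seed=_stage_seed(config.seed, 1))
        model = fit_surrogate(design, ann_cfg)
        results["ann_model"] = model
        save_model(model, outdir / "ann_model.json")
        artifacts.append("ann_model.json")
        emit_csv("ann_training_log.csv", model.history)

        stage = "optimize-ga"
        ga_cfg = dataclasses.replace(config.ga, seed=_stage_seed(config.seed, 2))
        ann_opt = optimize_ann_ga(model, factors, config=ga_cfg)
        results["ann_optimum"] = ann_opt
        emit_json("ann_optimum.json", ann_opt.to_dict())
        emit_csv("ga_trajectory.csv", ann_opt.trajectory)

        stage = "compare"
        report = build_report(rsm_opt, ann_opt, design, fit, model,
                              config.verification_yields)
        results["report"] = report
        emit_csv("comparison.csv", report.to_frame())
        (outdir / "comparison.txt").write_text(f"# {stamp}\n" + report.to_text() + "\n")
        artifacts.append("comparison.txt")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "extraopt",
        "version": __version__,
        "seed": config.seed,
        "config_hash": chash,
        "config": config.to_dict(),
        "versions": {m.__name__: m.__version__
                     for m in map(__import__, ("numpy", "scipy", "pandas"))},
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    results["outdir"] = outdir
    return results
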