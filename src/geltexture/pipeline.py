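"""End-to-end experiment orchestration.

Reproduces the four-phase study design on synthetic data: simulate gels,
extract texture features, standardize, train and evaluate every model on a
shared stratified 10-fold split, and run the statistical model-selection
workflow. A run is fully determined by ``(config, seed)``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import baselines, evaluation, gelsim, statcompare
from .dataset import build_table, feature_columns, standardize, write_table
from .fsmkl import FSMKLClassifier
from .textures import TextureConfig, default_inventory

log = logging.getLogger("geltexture")

ALL_MODELS = ("nb", "svm", "mkl", "fsmkl", "svm-rfe", "ga-svm", "pso-svm")


@dataclass
class ExperimentConfig:
    """Everything that determines a run, serializable to/from YAML.

    The default simulation is a scaled version of the full study design
    (10 images at 512 x 512 with 15 + 15 ROIs each, 300 samples) so a whole
    8-model comparison completes in minutes; the gelsim module default keeps
    the full 10 x (50 + 50) = 1000-ROI design.
    """

    sim: gelsim.GelSimConfig = field(
        default_factory=lambda: gelsim.GelSimConfig(
            height=512, width=512, spots_per_image=15, noise_per_image=15
        )
    )
    textures: TextureConfig = field(default_factory=TextureConfig)
    models: tuple[str, ...] = ALL_MODELS
    folds: int = 10
    alpha: float = 0.05
    seed: int = 0
    standardize_mode: str = "global"
    fsmkl_C: float = 10.0
    wrapper: baselines.WrapperConfig = field(
        default_factory=lambda: baselines.WrapperConfig(population=24, iterations=20)
    )
    outdir: str = "geltexture-run"

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def model_factories(config: ExperimentConfig, groups: dict[str, str]) -> dict:
    """Factories for every requested model, sharing the experiment seed."""
    seed = config.seed
    factories = {
        "nb": lambda: baselines.NaiveBayesModel(),
        "svm": lambda: baselines.SVMModel(random_state=seed),
        "mkl": lambda: baselines.GroupMKLModel(groups, C=config.fsmkl_C,
                                               random_state=seed),
        "fsmkl": lambda: FSMKLClassifier(groups, C=config.fsmkl_C,
                                         random_state=seed),
        "svm-rfe": lambda: baselines.SVMRFEModel(random_state=seed),
        "ga-svm": lambda: baselines.WrapperModel("GA", config.wrapper,
                                                 random_state=seed),
        "pso-svm": lambda: baselines.WrapperModel("PSO", config.wrapper,
                                                  random_state=seed),
    }
    unknown = [m for m in config.models if m not in factories]
    if unknown:
        raise ValueError(f"unknown model(s) {unknown}")
    return {m: factories[m] for m in config.models}


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    table: pd.DataFrame
    metrics: pd.DataFrame
    report: statcompare.WorkflowReport
    timings: dict[str, float]


def run_experiment(config: ExperimentConfig, write: bool = True) -> ExperimentResult:
    """Simulate, extract, standardize, evaluate and compare; write artifacts."""
    outdir = Path(config.outdir)
    timings: dict[str, float] = {}

    def _stage(name: str):
        log.info("stage: %s", name)
        timings[name] = time.perf_counter()

    def _done(name: str):
        timings[name] = time.perf_counter() - timings[name]
        log.info("stage %s done in %.1fs", name, timings[name])

    _stage("simulate")
    _, rois = gelsim.generate_dataset(config.sim, seed=config.seed)
    _done("simulate")

    _stage("extract")
    inventory = default_inventory(config.textures)
    table = build_table(rois, inventory, config.textures)
    _done("extract")

    _stage("standardize")
    ztable, _stats = standardize(table, mode=config.standardize_mode)
    feats = feature_columns(ztable)
    X = ztable[feats]
    y = ztable["label"].to_numpy()
    _done("standardize")

    _stage("evaluate")
    folds = evaluation.make_folds(len(y), y, k=config.folds, seed=config.seed)
    groups = inventory.groups
    metrics, fold_results = evaluation.run_comparison(
        X, y, model_factories(config, groups), folds
    )
    _done("evaluate")

    _stage("compare")
    report = statcompare.decision_workflow(
        metrics, feature_counts=metrics[["model", "fold", "n_features"]],
        alpha=config.alpha,
    )
    _done("compare")

    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(table, outdir / "features.csv", inventory, config.textures)
        metrics.to_csv(outdir / "metrics.csv", index=False)
        report.posthoc.table.to_csv(outdir / "posthoc.csv", index=False)
        (outdir / "summary.txt").write_text(report.summary() + "\n")
        curves = []
        for r in fold_results:
            fpr, tpr = r.roc_points
            curves.append(pd.DataFrame(
                {"model": r.model, "fold": r.fold, "fpr": fpr, "tpr": tpr}
            ))
        pd.concat(curves).to_csv(outdir / "roc_curves.csv", index=False)
        import sklearn
        provenance = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "sklearn": sklearn.__version__,
            },
            "timings_s": timings,
        }
        (outdir / "provenance.json").write_text(
            json.dumps(provenance, indent=1, default=str)
        )
    return ExperimentResult(config, table, metrics, report, timings)
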