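"""End-to-end orchestration: screen -> scan -> full-model estimation.

`TwoStepQtsMapper` composes the three stage estimators behind one
scikit-learn ``fit``; :func:`run_pipeline` is the file-based entry point that
reads the inputs, runs the mapper and writes candidates.tsv, scan.tsv,
effects.tsv plus a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from sklearn.base import BaseEstimator

from ._data import as_genotype_matrix, as_phenotype_table
from .gmdr import GmdrScreen
from .mlm import MixedModelScan
from .mcmc import FullModelMcmc, summarize_architecture

logger = logging.getLogger(__name__)

__all__ = ["TwoStepQtsMapper", "PipelineConfig", "run_pipeline"]


class TwoStepQtsMapper(BaseEstimator):
    """The full two-step mapping strategy as one composite estimator.

    Stage 1 screens the marker panel by exhaustive GMDR; stage 2a tests every
    screened marker and marker pair in a mixed model against permutation
    thresholds; stage 2b assembles the significant terms into a full model
    and estimates every effect's posterior by Gibbs sampling.

    Attributes (after ``fit``)
    --------------------------
    screen_ : fitted :class:`~qtsmap.gmdr.GmdrScreen`
    scan_ : fitted :class:`~qtsmap.mlm.MixedModelScan`
    mcmc_ : fitted :class:`~qtsmap.mcmc.FullModelMcmc`
    candidates_, results_, summary_ : stage outputs
    """

    def __init__(
        self,
        max_order: int = 2,
        retain_m: int = 10,
        k_folds: int = 10,
        n_permutations: int = 200,
        alpha: float = 0.05,
        cofactor_window_cm: float | None = 30.0,
        iterations: int = 12000,
        burnin: int = 2000,
        thin: int = 2,
        prune_window_cm: float = 30.0,
        random_state: int = 0,
    ):
        self.max_order = max_order
        self.retain_m = retain_m
        self.k_folds = k_folds
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.cofactor_window_cm = cofactor_window_cm
        self.iterations = iterations
        self.burnin = burnin
        self.thin = thin
        self.prune_window_cm = prune_window_cm
        self.random_state = random_state

    def fit(self, X, y):
        G = as_genotype_matrix(X)
        y = as_phenotype_table(y, G)
        self.screen_ = GmdrScreen(
            max_order=self.max_order,
            retain_m=self.retain_m,
            k_folds=self.k_folds,
            random_state=self.random_state,
        ).fit(G, y)
        self.candidates_ = self.screen_.candidates_
        self.scan_ = MixedModelScan(
            n_permutations=self.n_permutations,
            alpha=self.alpha,
            cofactor_window_cm=self.cofactor_window_cm,
            random_state=self.random_state,
        ).fit(G, y, candidates=self.candidates_)
        self.results_ = self.scan_.results_
        self.mcmc_ = FullModelMcmc(
            iterations=self.iterations,
            burnin=self.burnin,
            thin=self.thin,
            prune_window_cm=self.prune_window_cm,
            random_state=self.random_state,
        ).fit(G, y, model=self.results_)
        self.summary_ = self.mcmc_.summary_
        self.n_features_in_ = G.n_markers
        return self


@dataclass
class PipelineConfig:
    """File paths and stage parameters for one pipeline run."""

    genotypes: str
    phenotypes: str
    out_dir: str
    genotype_format: str = "auto"
    map_path: str | None = None
    trait: str = "trait"
    seed: int = 0
    verbose: bool = False
    screen: dict = field(default_factory=lambda: {"max_order": 2, "retain_m": 10, "k_folds": 10})
    scan: dict = field(
        default_factory=lambda: {"n_permutations": 200, "alpha": 0.05, "cofactor_window_cm": 30.0}
    )
    mcmc: dict = field(
        default_factory=lambda: {"iterations": 12000, "burnin": 2000, "thin": 2, "prune_window_cm": 30.0}
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        for label, p in (("genotypes", self.genotypes), ("phenotypes", self.phenotypes)):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} path does not exist: {p}")
        if self.map_path and not Path(self.map_path).exists():
            raise FileNotFoundError(f"map path does not exist: {self.map_path}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run screen -> scan -> estimate from files and write all artifacts.

    Writes ``candidates.tsv``, ``scan.tsv``, ``effects.tsv``,
    ``architecture.tsv`` and ``manifest.json`` under ``config.out_dir``. On a
    stage failure the partial artifacts are kept and the manifest records the
    failure point before the exception is re-raised.
    """
    from . import __version__
    from .io import read_genotypes, read_phenotypes

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root_logger = logging.getLogger("qtsmap")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.DEBUG if config.verbose else logging.INFO)
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "inputs": {
            "genotypes_sha256": _sha256(config.genotypes),
            "phenotypes_sha256": _sha256(config.phenotypes),
        },
        "status": "started",
        "failed_stage": None,
    }

    def flush():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")

    stage = "read"
    try:
        G = read_genotypes(config.genotypes, config.genotype_format, config.map_path)
        y = read_phenotypes(config.phenotypes, G)

        stage = "screen"
        mapper = TwoStepQtsMapper(
            **config.screen,
            **config.scan,
            **config.mcmc,
            random_state=config.seed,
        )
        screener = GmdrScreen(
            max_order=mapper.max_order,
            retain_m=mapper.retain_m,
            k_folds=mapper.k_folds,
            random_state=config.seed,
        ).fit(G, y)
        cand = screener.candidates_
        cand_rows = [
            {
                "order": m.order,
                "markers": ",".join(m.combo),
                "mean_accuracy": m.mean_accuracy,
                "consistency": m.consistency,
            }
            for m in cand.models
        ]
        import pandas as pd

        pd.DataFrame(cand_rows).to_csv(out / "candidates.tsv", sep="\t", index=False)

        stage = "scan"
        scanner = MixedModelScan(
            n_permutations=mapper.n_permutations,
            alpha=mapper.alpha,
            cofactor_window_cm=mapper.cofactor_window_cm,
            random_state=config.seed,
        ).fit(G, y, candidates=cand)
        scanner.results_.write(out / "scan.tsv")

        stage = "estimate"
        estimator = FullModelMcmc(
            iterations=mapper.iterations,
            burnin=mapper.burnin,
            thin=mapper.thin,
            prune_window_cm=mapper.prune_window_cm,
            random_state=config.seed,
        ).fit(G, y, model=scanner.results_)
        estimator.summary_.write(out / "effects.tsv")
        summarize_architecture(estimator.summary_, G, trait=config.trait).to_csv(
            out / "architecture.tsv", sep="\t", index=False, float_format="%.6g"
        )

        manifest["status"] = "ok"
        manifest["thresholds"] = scanner.thresholds_
        manifest["total_h2_pct"] = estimator.summary_.total_h2_pct
        flush()
        logger.info("pipeline complete: artifacts in %s", out)
        root_logger.removeHandler(handler)
        handler.close()
        return {
            "candidates": cand,
            "scan": scanner.results_,
            "summary": estimator.summary_,
            "out_dir": str(out),
        }
    except Exception:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        flush()
        logger.error("pipeline failed at stage %r", stage)
        root_logger.removeHandler(handler)
        handler.close()
        raise
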