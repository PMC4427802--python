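"""End-to-end orchestration: normalize -> folds -> DE selection -> views.

A run consumes a matrix TSV and a design CSV (or generates both
synthetically), executes every stage, and writes all result tables plus a
manifest (config hash, seed, library versions, per-stage row-count funnel)
to the output directory.  Reruns with identical config and inputs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import sklearn
import yaml

import serodiff
from serodiff.cohort import compare_cohorts, read_design, write_design
from serodiff.config import ConfigError, SimulationConfig
from serodiff.de import partition_up_down, select_de
from serodiff.folds import build_folds
from serodiff.matrix import IntensityMatrix, read_matrix, write_matrix
from serodiff.multivariate import (
    cluster_heatmap,
    pca_scores,
    top_protein_boxes,
    volcano,
)
from serodiff.normalization import normalize_chain
from serodiff.synthetic import simulate_cohort, simulate_matrix

logger = logging.getLogger("serodiff.pipeline")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on.

    Either ``matrix``/``design`` point at input files, or ``simulate`` holds
    a :class:`SimulationConfig` and the inputs are generated into the output
    directory first.
    """

    out_dir: str = "serodiff_run"
    matrix: str | None = None
    design: str | None = None
    simulate: SimulationConfig | None = None
    # normalization
    log2: bool = False  # inputs are typically already log2 ratios
    median: bool = True
    rank: bool = True
    rank_method: str = "quantile"
    # fold plan / selection
    k: int = 6
    fold_mode: str = "partition"
    seed: int = 0
    alpha: float = 0.01
    min_obs_per_group: int = 2
    test_scope: str = "train"
    # multivariate
    cluster_metric: str = "euclidean"
    cluster_linkage: str = "average"
    pca_components: int = 3
    n_top: int = 5
    # clinical comparison
    clinical_alpha: float = 0.05
    test_map: dict | None = None

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.k < 2:
            raise ConfigError(f"k must be >= 2, got {self.k}")
        if self.simulate is None and (self.matrix is None or self.design is None):
            raise ConfigError("either matrix+design paths or a simulate block is required")
        if self.simulate is not None:
            self.simulate.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            d["simulate"] = SimulationConfig.from_dict(d["simulate"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def analysis_dict(self) -> dict:
        """Config without the output path: what determines the results."""
        d = self.to_dict()
        d.pop("out_dir")
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.analysis_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _stage(manifest: dict, name: str, **counts) -> None:
    logger.info("stage %s: %s", name, counts)
    manifest["stages"].append({"name": name, **counts})


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the output directory.

    Outputs written: ``normalized_matrix.tsv`` (+ stage sidecar),
    ``fold_plan.json``, ``de_table.tsv``, ``de_up.txt``/``de_down.txt``,
    ``cluster_display.tsv``, ``cluster_assignments.tsv``,
    ``pca_scores.tsv``, ``volcano.tsv``, ``top_boxes.tsv``,
    ``cohort_comparison.tsv``, and ``manifest.json``.  Any stage failure
    aborts with the stage name; the manifest marks the run incomplete.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.analysis_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "serodiff": serodiff.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
        },
        "stages": [],
        "complete": False,
    }
    stage_name = "setup"
    try:
        if config.simulate is not None:
            stage_name = "simulate"
            design = simulate_cohort(config.simulate)
            matrix, truth = simulate_matrix(config.simulate, design)
            write_design(design, out / "design.csv")
            write_matrix(matrix, out / "matrix.tsv", sidecar=True)
            truth.to_csv(out / "truth.tsv", sep="\t", index=False)
            _stage(manifest, "simulate", proteins=matrix.n_proteins,
                   samples=matrix.n_samples, true_de=int(truth["is_de"].sum()))
        else:
            stage_name = "read_inputs"
            matrix = read_matrix(config.matrix)
            design = read_design(config.design)
            _stage(manifest, "read_inputs", proteins=matrix.n_proteins,
                   samples=matrix.n_samples)

        stage_name = "normalize"
        norm = normalize_chain(
            matrix,
            log2=config.log2,
            median=config.median,
            rank=config.rank,
            rank_method=config.rank_method,
        )
        write_matrix(norm, out / "normalized_matrix.tsv", sidecar=True)
        _stage(manifest, "normalize", proteins=norm.n_proteins,
               stages=list(norm.stages))

        stage_name = "build_folds"
        plan = build_folds(design, k=config.k, mode=config.fold_mode,
                           seed=config.seed)
        plan.to_json(out / "fold_plan.json")
        _stage(manifest, "build_folds", k=plan.k, mode=plan.mode)

        stage_name = "select_de"
        table = select_de(
            norm, design, plan,
            alpha=config.alpha,
            min_obs_per_group=config.min_obs_per_group,
            test_scope=config.test_scope,
        )
        table.to_csv(out / "de_table.tsv", sep="\t")
        up, down = partition_up_down(table)
        (out / "de_up.txt").write_text("\n".join(up) + ("\n" if up else ""))
        (out / "de_down.txt").write_text("\n".join(down) + ("\n" if down else ""))
        _stage(manifest, "select_de",
               quantifiable=int(table["quantifiable"].sum()),
               selected=int(table["is_de"].sum()),
               up=len(up), down=len(down))

        stage_name = "multivariate"
        vol = volcano(table, cutoff=config.alpha)
        vol.to_csv(out / "volcano.tsv", sep="\t")
        de_ids = table.index[table["is_de"]].tolist()
        if len(de_ids) >= 2:
            sub = norm.restrict(de_ids)
            clu = cluster_heatmap(sub, design, metric=config.cluster_metric,
                                  method=config.cluster_linkage)
            clu.display.to_csv(out / "cluster_display.tsv", sep="\t")
            assign = pd.DataFrame(
                {
                    "cluster": clu.sample_clusters,
                    "group": design.set_index("sample_id")["group"].reindex(
                        clu.sample_clusters.index
                    ),
                }
            )
            assign.index.name = "sample_id"
            assign.to_csv(out / "cluster_assignments.tsv", sep="\t")
            pca = pca_scores(sub, design, n_components=config.pca_components)
            scores = pca.scores.copy()
            scores.index.name = "sample_id"
            scores.to_csv(out / "pca_scores.tsv", sep="\t")
            boxes = top_protein_boxes(norm, design, detable=table,
                                      n_top=config.n_top)
            boxes.to_csv(out / "top_boxes.tsv", sep="\t", index=False)
            _stage(manifest, "multivariate", de_proteins=len(de_ids),
                   cluster_misassigned=clu.n_misassigned,
                   pca_separation=round(pca.separation, 6))
        else:
            logger.warning("fewer than 2 DE proteins; skipping cluster/PCA views")
            _stage(manifest, "multivariate", de_proteins=len(de_ids),
                   skipped=True)

        stage_name = "compare_cohorts"
        comp = compare_cohorts(design, alpha=config.clinical_alpha,
                               test_map=config.test_map)
        comp.to_csv(out / "cohort_comparison.tsv", sep="\t", index=False)
        _stage(manifest, "compare_cohorts", variables=len(comp))

        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_stage"] = stage_name
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
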