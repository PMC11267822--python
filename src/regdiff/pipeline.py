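"""End-to-end pipeline: simulate -> diffexp -> gsea -> mr -> network -> stats.

A single :class:`PipelineConfig` carries every stage's parameters;
defaults are the canonical permutation depths of the analysis the
package implements (10,000 label permutations for the differential
null, 1,000 for the LMR cutoff, 100,000 resampling draws for the MR
test, 1,000 gene-set permutations for GSEA).  One master seed spawns
deterministic per-stage sub-seeds so re-running with an identical
config reproduces every output bit-identically except timestamps.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexp, gsea, mra, network
from .errors import ConfigError
from .io import (
    ExpressionMatrix,
    FLOAT_FORMAT,
    GeneSetCollection,
    SampleAnnotation,
    TFTargetMap,
    read_annotations,
    read_expression,
    read_gmt,
    read_tf_targets,
    write_annotations,
    write_expression,
    write_tf_targets,
)
from .simulate import SimulationConfig, generate_cohort
from .stats import stratified_activity_comparison

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run.

    Any of the input paths may be None when ``simulate`` is set, in
    which case a synthetic cohort is generated first.
    """

    out_dir: str = "regdiff_out"
    expr_path: str | None = None
    annotations_path: str | None = None
    tf_targets_path: str | None = None
    gmt_path: str | None = None
    group_col: str = "group"
    simulate: bool = False
    sim_config: SimulationConfig = field(default_factory=SimulationConfig)
    n_perm_de: int = 10_000
    n_perm_cutoff: int = 1000
    n_perm_mr: int = 100_000
    n_perm_gsea: int = 1000
    fdr_de: float = 0.05
    fdr_mr: float = 0.01
    min_targets: int = 5
    top_k: int = 10
    gsea_weight: int = 1
    lmr_cut: float | None = None
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        for name in ("n_perm_de", "n_perm_cutoff", "n_perm_mr", "n_perm_gsea"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("fdr_de", "fdr_mr"):
            if not 0 < getattr(self, name) < 1:
                raise ConfigError(f"{name} must be in (0, 1)")
        if not self.simulate and (self.expr_path is None or self.annotations_path is None):
            raise ConfigError("expression and annotation paths required unless simulating")
        return self


def stage_seeds(master_seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage sub-seeds below 2^31."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write outputs plus a manifest.

    Returns the manifest dictionary.  Stage failures propagate with
    the stage name in the message; the manifest marks the run
    incomplete in that case (written on a best-effort basis).
    """
    cfg = config.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    manifest: dict = {
        "config": {k: (asdict(v) if isinstance(v, SimulationConfig) else v)
                   for k, v in asdict(cfg).items()},
        "stage_seeds": seeds,
        "stages": {},
        "complete": False,
    }
    stage_start = time.perf_counter()

    def _finish(stage: str, **extra) -> None:
        nonlocal stage_start
        manifest["stages"][stage] = {
            "runtime_s": round(time.perf_counter() - stage_start, 3), **extra
        }
        stage_start = time.perf_counter()

    try:
        # --- inputs ---------------------------------------------------
        if cfg.simulate:
            sim_cfg = SimulationConfig(**{**asdict(cfg.sim_config), "seed": seeds[0]})
            expr, ann, tf_map, truth = generate_cohort(sim_cfg)
            write_expression(expr, out / "expression.tsv")
            write_annotations(ann, out / "annotations.tsv")
            write_tf_targets(tf_map, out / "tf_targets.tsv")
            with open(out / "truth.json", "w") as fh:
                json.dump(
                    {"de_genes": truth.de_genes,
                     "active_tfs": truth.active_tfs,
                     "effect_sizes": truth.effect_sizes},
                    fh, indent=2,
                )
            _finish("simulate", n_genes=expr.shape[0], n_samples=expr.shape[1])
        else:
            expr = read_expression(cfg.expr_path)
            ann = read_annotations(cfg.annotations_path, group_col=cfg.group_col)
            tf_map = read_tf_targets(cfg.tf_targets_path) if cfg.tf_targets_path else None
            _finish("load", n_genes=expr.shape[0], n_samples=expr.shape[1])
        collection = read_gmt(cfg.gmt_path) if cfg.gmt_path else None

        # --- differential expression ----------------------------------
        table = diffexp.run_diffexp(
            expr, ann, n_perm=cfg.n_perm_de, n_perm_cutoff=cfg.n_perm_cutoff,
            fdr_cut=cfg.fdr_de, lmr_cut=cfg.lmr_cut, seed=seeds[1],
        )
        table.to_csv(out / "gene_stats.tsv", sep="\t", float_format=FLOAT_FORMAT)
        up_a = sorted(table.index[table["direction"] == "up_in_A"])
        up_b = sorted(table.index[table["direction"] == "up_in_B"])
        (out / "degs_up_A.txt").write_text("\n".join(up_a) + ("\n" if up_a else ""))
        (out / "degs_up_B.txt").write_text("\n".join(up_b) + ("\n" if up_b else ""))
        _finish("diffexp", n_deg_up_A=len(up_a), n_deg_up_B=len(up_b),
                lmr_cut=table.attrs["lmr_cut"])

        # --- GSEA ------------------------------------------------------
        if collection is not None:
            enr = gsea.run_gsea(
                table, collection, weight_exponent=cfg.gsea_weight,
                n_perm=cfg.n_perm_gsea, seed=seeds[2],
            )
            enr.to_csv(out / "enrichment.tsv", sep="\t", float_format=FLOAT_FORMAT)
            _finish("gsea", n_sets=len(enr))

        # --- master regulators & network -------------------------------
        if tf_map is not None:
            universe = frozenset(expr.gene_ids)
            deg_union = frozenset(up_a) | frozenset(up_b)
            mr_table = mra.mr_permutation_test(
                tf_map, deg_union, universe, n_perm=cfg.n_perm_mr, seed=seeds[3],
            )
            mr_table.to_csv(out / "mr_table.tsv", sep="\t", float_format=FLOAT_FORMAT)
            top = mra.select_mrs(
                mr_table, fdr_cut=cfg.fdr_mr, min_targets=cfg.min_targets,
                top_k=cfg.top_k,
            )
            (out / "top_tfs.txt").write_text("\n".join(top) + ("\n" if top else ""))
            _finish("master_regulator", n_selected=len(top))

            if top and deg_union:
                model = network.build_network_model(tf_map, top, deg_union, expr, ann)
                network.export_network(model, out / "network.graphml", fmt="graphml")
                network.export_network(model, out / "network.json", fmt="json")
                act = network.network_activity(expr, tf_map, top)
                act.to_frame().to_csv(out / "network_activity.tsv", sep="\t",
                                      index_label="sample_id",
                                      float_format=FLOAT_FORMAT)
                strat_frames = []
                for col in ann.strata_cols:
                    df = stratified_activity_comparison(act, ann, col)
                    df.insert(0, "stratum_col", col)
                    strat_frames.append(df)
                if strat_frames:
                    pd.concat(strat_frames).to_csv(
                        out / "stratified_activity.tsv", sep="\t",
                        float_format=FLOAT_FORMAT,
                    )
                _finish("network", n_nodes=len(model.nodes), n_edges=len(model.edges))

        manifest["complete"] = True
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest
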