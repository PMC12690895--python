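"""End-to-end pipeline runner, configuration and reproducibility plumbing.

Stages (each independently re-runnable from its TSV/JSON artifacts):

1. residualize M values on covariates, select HVPs (top variance decile);
2. group HVPs into VMRs/sVMPs, summarize regional methylation (median);
3. map each locus to its cis SNPs (1 Mb window);
4. lasso-screen SNPs and exposures per locus (three scenarios);
5. fit G/E/G+E/GxE models, pick the AIC winner, LMG-decompose it;
6. build the joint-shuffle permutation null and demote weak winners to B.

All stage parameters default to the framework's reference values (HVP
quantile 0.90, max gap 1 kb, correlation threshold 0.15, cis window 1 Mb,
10-fold CV lasso with the MSE-minimizing penalty, 10 permutations, 95th
percentile cutoff).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import AlignedDataset, load_dataset
from .hvp_detection import find_hvps
from .vml_identification import find_vml, summarize_all, vml_table, vml_to_bed
from .cis_mapping import build_cis_map, cis_map_table
from .null_filter import apply_filter, build_null, evaluate_ge

logger = logging.getLogger("methylgxe")


def setup_logging(level=logging.INFO) -> None:
    """Structured logging to stderr (idempotent)."""
    root = logging.getLogger("methylgxe")
    if not root.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
        root.addHandler(h)
    root.setLevel(level)


@dataclass
class RunConfig:
    """All inputs and stage parameters of one pipeline run."""

    methylation: str = ""
    probe_manifest: str = ""
    genotypes: str = ""
    snp_manifest: str | None = None
    exposome: str = ""
    covariates: str = ""
    output_dir: str = "results"

    hvp_quantile: float = 0.90
    hvp_inclusive: bool = False
    max_gap: int = 1000
    min_r: float = 0.15
    svmp_mode: str = "array"
    cis_window: int = 1_000_000
    lasso_folds: int = 10
    lambda_rule: str = "1se"
    n_alphas: int = 50
    n_permutations: int = 10
    percentile: float = 95.0
    autosomes_only: bool = True
    seed: int = 0
    threads: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def param_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    hvp_table: pd.DataFrame
    vmls: list
    summarized: pd.DataFrame
    cis_map: dict[str, list[str]]
    observed: pd.DataFrame
    null: object
    final: pd.DataFrame
    summary: pd.DataFrame = field(default=None)


def class_summary(final: pd.DataFrame) -> pd.DataFrame:
    """Model-class proportions overall and by VML kind."""
    rows = []
    groups = [("all", final)] + [
        (k, g) for k, g in final.groupby("kind") if k
    ]
    for name, g in groups:
        counts = g["winner_class"].value_counts()
        n = len(g)
        row = {"vml_kind": name, "n_vml": n}
        for cls in ("B", "G", "E", "GE_ADD", "GXE"):
            row[cls] = counts.get(cls, 0) / n if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline_on(dataset: AlignedDataset, config: RunConfig) -> PipelineResult:
    """Run all stages on an in-memory dataset."""
    lasso_kw = dict(
        n_folds=config.lasso_folds,
        lambda_rule=config.lambda_rule,
        n_alphas=config.n_alphas,
    )
    t0 = time.time()
    hvps = find_hvps(
        dataset.methylation, dataset.covariates,
        config.hvp_quantile, config.hvp_inclusive,
    )
    hvp_ids = list(hvps.loc[hvps["is_hvp"], "probe_id"])
    logger.info("stage hvp: %d/%d probes (%.1fs)", len(hvp_ids), len(hvps), time.time() - t0)

    vmls = find_vml(
        hvp_ids, dataset.probe_manifest, dataset.methylation,
        max_gap=config.max_gap, min_r=config.min_r, svmp_mode=config.svmp_mode,
    )
    summarized = summarize_all(dataset.methylation, vmls)
    kinds = {v.vml_id: v.kind for v in vmls}
    logger.info("stage vml: %d loci (%d VMR, %d sVMP)",
                len(vmls), sum(v.kind == "VMR" for v in vmls),
                sum(v.kind == "sVMP" for v in vmls))

    cis_map = build_cis_map(vmls, dataset.snp_manifest, config.cis_window)

    t1 = time.time()
    observed = evaluate_ge(
        dataset, summarized, cis_map, config.seed,
        vml_kinds=kinds, n_jobs=config.threads, **lasso_kw,
    )
    logger.info("stage model: observed run done (%.1fs)", time.time() - t1)

    t2 = time.time()
    null = build_null(
        dataset, summarized, cis_map, config.seed,
        n_permutations=config.n_permutations, percentile=config.percentile,
        vml_kinds=kinds, n_jobs=config.threads, **lasso_kw,
    )
    logger.info(
        "stage null: cutoffs marginal=%.4f joint=%.4f (%.1fs)",
        null.cutoff_marginal, null.cutoff_joint, time.time() - t2,
    )
    final = apply_filter(observed, null)
    return PipelineResult(
        hvps, vmls, summarized, cis_map, observed, null, final, class_summary(final)
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load inputs, run all stages, write per-stage artifacts and a
    run-manifest JSON to ``config.output_dir``."""
    setup_logging()
    dataset = load_dataset(
        config.methylation, config.probe_manifest, config.genotypes,
        config.snp_manifest, config.exposome, config.covariates,
        autosomes_only=config.autosomes_only,
    )
    result = run_pipeline_on(dataset, config)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.hvp_table.to_csv(out / "hvps.tsv", sep="\t", index=False)
    vt = vml_table(result.vmls)
    # final table carries coordinates so downstream agreement runs need no join
    vt.to_csv(out / "vml.tsv", sep="\t", index=False)
    vml_to_bed(result.vmls).to_csv(out / "vml.bed", sep="\t", index=False, header=False)
    result.summarized.to_csv(out / "summarized_dname.tsv", sep="\t")
    cis_map_table(result.cis_map).to_csv(out / "cis_map.tsv", sep="\t", index=False)
    result.observed.to_csv(out / "models_observed.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "stratum": ["marginal"] * len(result.null.delta_r2_marginal)
            + ["joint"] * len(result.null.delta_r2_joint),
            "delta_r2": np.concatenate(
                [result.null.delta_r2_marginal, result.null.delta_r2_joint]
            ),
        }
    ).to_csv(out / "null_delta_r2.tsv", sep="\t", index=False)
    with open(out / "null_cutoffs.json", "w") as fh:
        json.dump(
            {
                "cutoff_marginal": result.null.cutoff_marginal,
                "cutoff_joint": result.null.cutoff_joint,
                "percentile": result.null.percentile,
                "n_permutations": result.null.n_permutations,
            },
            fh, indent=1,
        )
    final = result.final.merge(
        vt[["vml_id", "chrom", "start", "end", "n_probes"]], on="vml_id"
    )
    final.to_csv(out / "results.tsv", sep="\t", index=False)
    result.summary.to_csv(out / "class_summary.tsv", sep="\t", index=False)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(
            {
                "version": __version__,
                "config": asdict(config),
                "param_hash": config.param_hash(),
                "n_samples": dataset.n_samples,
                "n_vml": len(result.vmls),
            },
            fh, indent=1,
        )
    return result
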