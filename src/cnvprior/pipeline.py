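"""End-to-end orchestration: preprocess → features → pretrain → finetune
→ score → stats → enrichment, with a run manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrich import fold_enrichment, make_gene_set, phenotype_ratios, ratios_to_frame
from .features import (
    FeatureKey,
    FeatureMatrix,
    build_feature_matrix,
    overlap_counts,
    prefilter_features,
)
from .io import (
    Cohort,
    filter_cnvs,
    read_cnv_table,
    read_gene_annotation,
    read_gene_set,
    summarize_cohort,
)
from .prioritize import (
    finetune,
    gene_scores,
    pretrain,
    rank_genes,
    results_to_frame,
)
from .stats import bh_fdr, fisher_exact_counts, permutation_test_matrix, sex_segregation
from .vae import TrainConfig, save_checkpoint

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration for a full pipeline run (YAML-loadable)."""

    # inputs
    cnv_tables: dict[str, str] = field(default_factory=dict)  # tag -> path
    target: str = ""  # tag of the disorder to fine-tune on
    gene_annotation: str = ""
    annotation_format: str = "bed"
    gene_sets: dict[str, str] = field(default_factory=dict)  # name -> path
    phenotype_table: Optional[str] = None
    # preprocessing / features
    min_len_bp: int = 1000
    drop_chrY: bool = True
    scaling: str = "unit_interval"
    feature_values: str = "length"
    min_overlap_bp: int = 1
    # training
    train: TrainConfig = field(default_factory=TrainConfig)
    pretrain_epochs: int = 200
    finetune_epochs: int = 200
    finetune_mode: str = "joint"
    # stats
    alternative: str = "greater"
    n_perm: int = 0  # 0 disables permutation p-values
    # enrichment / reporting
    n_top: int = 40
    ranking: str = "score"
    # misc
    out_dir: str = "cnvprior_out"
    seed: int = 0
    stats_only: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        train_raw = raw.pop("train", {}) or {}
        cfg = cls(**raw)
        cfg.train = TrainConfig(**train_raw)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: (v.__dict__ if isinstance(v, TrainConfig) else v) for k, v in self.__dict__.items()},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _tsv_header_comment(config: RunConfig) -> str:
    return f"# cnvprior {__version__} config_hash={config.config_hash()} seed={config.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_tsv_header_comment(config))
        df.to_csv(fh, sep="\t", index=False)


def feature_stats(
    cohort: Cohort,
    genes,
    config: RunConfig,
    seed: Optional[int] = None,
) -> tuple[FeatureMatrix, pd.DataFrame, np.ndarray, Optional[np.ndarray], np.ndarray]:
    """Features, counts, Fisher p, optional permutation p, q-values."""
    fm = build_feature_matrix(
        cohort,
        genes,
        scaling=config.scaling,
        values=config.feature_values,
        min_overlap_bp=config.min_overlap_bp,
    )
    counts = overlap_counts(cohort, genes, min_overlap_bp=config.min_overlap_bp)
    fm = prefilter_features(fm, counts)
    kept = {k: i for i, k in enumerate(fm.feature_keys)}
    counts = counts[
        [
            FeatureKey(g, d) in kept
            for g, d in zip(counts["gene_id"], counts["dosage"])
        ]
    ].reset_index(drop=True)
    fisher_p = fisher_exact_counts(
        counts["case_ov"].to_numpy(),
        counts["control_ov"].to_numpy(),
        cohort.n_cases,
        cohort.n_controls,
        alternative=config.alternative,
    )
    perm_p = None
    if config.n_perm > 0:
        carrier = (fm.X > 0).astype(float)
        labels = fm.y
        perm_p = permutation_test_matrix(
            carrier, labels, n_perm=config.n_perm, seed=config.seed if seed is None else seed
        )
    q = bh_fdr(fisher_p)
    return fm, counts, fisher_p, perm_p, q


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest (also written).

    Stages: read + filter each disorder cohort; build the pooled feature
    matrix; pretrain the VAE on pooled unlabeled data; fine-tune on the
    target cohort with labels; score genes by the weight product; burden
    statistics; ranked table; optional gene-set enrichment and phenotype
    ratios.  ``stats_only`` skips all model stages.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "cnvprior",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    if not config.cnv_tables:
        raise ValueError("config error: no cnv_tables given")
    target = config.target or next(iter(config.cnv_tables))
    if target not in config.cnv_tables:
        raise ValueError(f"config error: target {target!r} not among cnv_tables")

    genes = read_gene_annotation(config.gene_annotation, format=config.annotation_format)
    cohorts: dict[str, Cohort] = {}
    for tag, path in config.cnv_tables.items():
        raw = read_cnv_table(path, disease_tag=tag)
        cohort = filter_cnvs(raw, min_len_bp=config.min_len_bp, drop_chrY=config.drop_chrY)
        cohorts[tag] = cohort
        s = summarize_cohort(cohort)
        manifest["stages"][f"preprocess:{tag}"] = {
            "rows_in": len(raw.records) + raw.n_dropped_rows,
            "rows_dropped_parse": raw.n_dropped_rows,
            "rows_after_filter": len(cohort.records),
            "n_case_cnvs": s.n_case_cnvs,
            "n_control_cnvs": s.n_control_cnvs,
            "n_patients": s.n_patients,
            "n_healthy": s.n_healthy,
        }

    tc = cohorts[target]
    fm, counts, fisher_p, perm_p, q = feature_stats(tc, genes, config)
    manifest["stages"]["features"] = {
        "n_samples": fm.n_samples,
        "n_features": fm.n_features,
        "n_ranking_excluded": int(fm.ranking_excluded.sum()),
    }

    stats_df = pd.DataFrame(
        {
            "gene": counts["gene_id"],
            "status": counts["dosage"],
            "caseOV": counts["case_ov"],
            "controlOV": counts["control_ov"],
            "n_case": tc.n_cases,
            "n_control": tc.n_controls,
            "fisher_p": fisher_p,
            "perm_p": perm_p if perm_p is not None else np.nan,
            "q_value": q,
        }
    )
    _write_tsv(stats_df, out / "stats.tsv", config)
    manifest["stages"]["stats"] = {"n_features": len(stats_df)}

    if not config.stats_only:
        kept_keys = set(fm.feature_keys)
        pooled_parts = []
        for tag, cohort in cohorts.items():
            part = build_feature_matrix(
                cohort,
                genes,
                scaling=config.scaling,
                values=config.feature_values,
                min_overlap_bp=config.min_overlap_bp,
            )
            sel = [k in kept_keys for k in part.feature_keys]
            pooled_parts.append(part.X[:, np.array(sel)])
        pooled_X = np.vstack(pooled_parts)
        pre_cfg = TrainConfig(
            **{
                **config.train.__dict__,
                "seed": config.seed,
                "max_epochs": config.pretrain_epochs,
            }
        )
        params, pre_trace = pretrain(pooled_X, pre_cfg)
        manifest["stages"]["pretrain"] = {
            "n_pooled_samples": int(pooled_X.shape[0]),
            "epochs_run": len(pre_trace["val"]),
            "final_val_loss": pre_trace["val"][-1],
        }
        ft_cfg = TrainConfig(
            **{
                **config.train.__dict__,
                "seed": config.seed + 1,
                "max_epochs": config.finetune_epochs,
            }
        )
        params, head, metrics = finetune(params, fm, ft_cfg, mode=config.finetune_mode)
        manifest["stages"]["finetune"] = {
            "mode": config.finetune_mode,
            "epochs_run": len(metrics["val_loss"]),
            "heldout_accuracy": metrics["accuracy"],
            "heldout_auc": metrics["auc"],
        }
        save_checkpoint(
            out / "model.ckpt",
            params,
            config=ft_cfg,
            head={"head_w": head.weights, "head_b": np.array([head.bias])},
        )
        scores = gene_scores(params, head)
    else:
        # statistics-only mode ranks by Fisher p
        scores = -np.log10(np.maximum(fisher_p, 1e-300))

    results = rank_genes(
        scores,
        counts,
        fisher_p,
        perm_p=perm_p,
        q_values=q,
        by=("fisher" if config.stats_only else config.ranking),
    )
    ranked_df = results_to_frame(results)
    _write_tsv(ranked_df, out / "ranked.tsv", config)
    manifest["stages"]["rank"] = {
        "n_ranked": int((~ranked_df["excluded"]).sum()),
        "n_excluded": int(ranked_df["excluded"].sum()),
    }

    if config.gene_sets:
        universe = [g.gene_id for g in genes]
        top = [
            r.key.gene_id
            for r in results
            if not r.excluded and r.rank is not None and r.rank <= config.n_top
        ]
        top = list(dict.fromkeys(top))
        rows = []
        for name, path in config.gene_sets.items():
            gs = make_gene_set(name, sorted(read_gene_set(path)), universe)
            res = fold_enrichment(top, gs)
            rows.append(
                {
                    "set": name,
                    "n_top": res.n_top,
                    "k_in_set": res.k_in_set,
                    "set_size": res.set_size,
                    "universe_size": res.universe_size,
                    "top_fraction": res.top_fraction,
                    "background_fraction": res.background_fraction,
                    "fold": res.fold,
                    "hypergeom_p": res.hypergeom_p,
                }
            )
        _write_tsv(pd.DataFrame(rows), out / "enrichment.tsv", config)
        manifest["stages"]["enrich"] = {"n_sets": len(rows)}

    if config.phenotype_table:
        phen = pd.read_csv(config.phenotype_table, sep="\t", dtype=str)
        frames = []
        for r in results:
            if r.excluded or r.rank is None or r.rank > config.n_top:
                continue
            rows = phenotype_ratios(tc, genes, r.key, phen, min_overlap_bp=config.min_overlap_bp)
            if rows:
                frames.append(ratios_to_frame(rows, dosage=r.key.dosage))
        if frames:
            _write_tsv(pd.concat(frames, ignore_index=True), out / "phenotype_ratios.tsv", config)
        manifest["stages"]["phenotypes"] = {"n_genes": len(frames)}

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
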