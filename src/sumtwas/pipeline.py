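"""Orchestration of the train -> assoc -> simulate stages.

Each stage reads/writes tab-delimited artifacts under the configured output
directory and records a manifest with input checksums, the resolved
configuration and the seed, so reruns with identical inputs are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .assoc import transcriptome_scan
from .config import RunConfig
from .datatypes import GeneAnnotation
from .ld import interpolate_cm, sample_ld, shrink_ld
from .sim import run_accuracy_experiment, run_power_experiment, run_type1_experiment
from .train import PenaltySpec, TrainingConfig, WeightModel, fit_gene, validate_models

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "train_stage", "assoc_stage", "simulate_stage",
           "write_weight_db", "read_weight_db", "load_expression"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_expression(path) -> pd.DataFrame:
    """Expression TSV: first column sample_id, remaining columns gene ids."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])


def _load_panel(path: str):
    p = Path(path)
    if p.suffix in {".vcf", ".gz"} or p.name.endswith(".vcf.gz"):
        return sio.read_vcf(p)
    return sio.read_plink(p if p.suffix == "" else p.with_suffix(""))


def write_weight_db(out_dir: Path, models: list[WeightModel]) -> None:
    weight_rows, meta_rows = [], []
    for m in models:
        snp_by_id = dict(zip(m.snp_ids, m.w_hat))
        for sid, w in snp_by_id.items():
            if w != 0.0:
                weight_rows.append(
                    {"gene_id": m.gene_id, "snp_id": sid,
                     "penalty_family": m.penalty.family, "weight": w}
                )
        meta_rows.append(
            {
                "gene_id": m.gene_id,
                "family": m.penalty.family,
                "lambda": m.penalty.lam,
                "theta": m.penalty.theta,
                "gamma": m.penalty.gamma,
                "alpha": m.penalty.alpha,
                "r2_tuning": m.r2_tuning,
                "r2_testing": m.r2_testing,
                "n_nonzero": m.n_nonzero,
                "snp_ids": ",".join(m.snp_ids),
            }
        )
    pd.DataFrame(weight_rows).to_csv(out_dir / "weights.tsv", sep="\t", index=False)
    pd.DataFrame(meta_rows).to_csv(out_dir / "weight_meta.tsv", sep="\t", index=False)


def read_weight_db(out_dir: Path) -> dict[str, list[WeightModel]]:
    weights = pd.read_csv(out_dir / "weights.tsv", sep="\t")
    meta = pd.read_csv(out_dir / "weight_meta.tsv", sep="\t")
    by_gene: dict[str, list[WeightModel]] = {}
    for _, row in meta.iterrows():
        snp_ids = str(row["snp_ids"]).split(",")
        w = np.zeros(len(snp_ids))
        sub = weights[(weights["gene_id"] == row["gene_id"]) & (weights["penalty_family"] == row["family"])]
        pos = {s: i for i, s in enumerate(snp_ids)}
        for wr in sub.itertuples():
            w[pos[wr.snp_id]] = wr.weight
        spec = PenaltySpec(
            family=row["family"], lam=float(row["lambda"]), gamma=float(row["gamma"]),
            alpha=float(row["alpha"]), theta=float(row["theta"]),
        )
        m = WeightModel(
            gene_id=row["gene_id"], snp_ids=snp_ids, w_hat=w, penalty=spec,
            r2_tuning=float(row["r2_tuning"]),
            r2_testing=None if pd.isna(row["r2_testing"]) else float(row["r2_testing"]),
        )
        by_gene.setdefault(row["gene_id"], []).append(m)
    return by_gene


def _prepare_gene(cfg: RunConfig, gene: GeneAnnotation, panel, gmap):
    """Window, filter, harmonize one gene's eQTL table against the panel."""
    table = sio.load_eqtl_summary(cfg.paths.eqtl, gene)
    table = sio.restrict_to_cis_window(table, gene, cfg.filters.window_bp)
    hm3: frozenset = frozenset()
    if cfg.filters.hapmap3:
        hm3 = frozenset(Path(cfg.filters.hapmap3).read_text().split())
    table = sio.filter_snps(table, panel, hm3, cfg.filters.maf_min, cfg.filters.hwe_min)
    table = sio.harmonize_alleles(table, panel)
    if len(table) == 0:
        return None, None
    gpanel = sio.align_panel(panel, table.snp_ids)
    cm = interpolate_cm(gpanel.records, gmap)
    ld = sample_ld(gpanel)
    ld_shrunk = shrink_ld(ld, cm, cfg.ld.n_e, cfg.ld.m, cfg.ld.c)
    return table, (gpanel, ld, ld_shrunk)


def train_stage(cfg: RunConfig, out_dir: Path) -> list[str]:
    genes = sio.load_gene_annotations(cfg.paths.annotation)
    panel = _load_panel(cfg.paths.panel)
    gmap = sio.read_genetic_map(cfg.paths.map)
    tune = load_expression(cfg.paths.tuning_expr)
    test = load_expression(cfg.paths.testing_expr)
    tune_ids = [s for s in panel.sample_ids if s in tune.index]
    test_ids = [s for s in panel.sample_ids if s in test.index]
    sample_pos = {s: i for i, s in enumerate(panel.sample_ids)}
    all_models = []
    for gene in genes:
        if gene.gene_id not in tune.columns:
            logger.warning("gene %s has no tuning expression; skipped", gene.gene_id)
            continue
        table, prep = _prepare_gene(cfg, gene, panel, gmap)
        if table is None:
            logger.warning("gene %s: no usable SNPs after filtering", gene.gene_id)
            continue
        gpanel, _ld_raw, ld_shrunk = prep
        g = gpanel.imputed()
        x_tune = g[[sample_pos[s] for s in tune_ids]]
        e_tune = tune.loc[tune_ids, gene.gene_id].to_numpy(dtype=float)
        models = fit_gene(table, ld_shrunk, (x_tune, e_tune), cfg.training)
        x_test = g[[sample_pos[s] for s in test_ids]]
        e_test = test.loc[test_ids, gene.gene_id].to_numpy(dtype=float)
        admitted = validate_models(models, (x_test, e_test), cfg.training.r2_min)
        all_models.extend(admitted)
    write_weight_db(out_dir, all_models)
    return ["weights.tsv", "weight_meta.tsv"]


def assoc_stage(cfg: RunConfig, out_dir: Path) -> list[str]:
    weights_dir = Path(cfg.paths.weights) if cfg.paths.weights else out_dir
    if not (weights_dir / "weights.tsv").exists():
        raise FileNotFoundError(
            f"assoc stage requires a weight database; none found at {weights_dir}"
        )
    models_by_gene = read_weight_db(weights_dir)
    panel = _load_panel(cfg.paths.panel)
    gmap = sio.read_genetic_map(cfg.paths.map)
    gwas = sio.load_gwas_summary(cfg.paths.gwas)
    gwas = sio.harmonize_alleles(gwas, panel)
    z_by_id = dict(zip(gwas.snp_ids, gwas.z))
    gwas_by_gene, v_by_gene = {}, {}
    for gene_id, models in models_by_gene.items():
        snp_ids = [s for s in models[0].snp_ids if s in z_by_id]
        if not snp_ids:
            gwas_by_gene[gene_id] = np.array([])
            continue
        # restrict every model to the SNPs present in the GWAS
        keep = [i for i, s in enumerate(models[0].snp_ids) if s in z_by_id]
        for m in models:
            m.w_hat = m.w_hat[keep]
            m.snp_ids = snp_ids
        gwas_by_gene[gene_id] = np.array([z_by_id[s] for s in snp_ids])
        gpanel = sio.align_panel(panel, snp_ids)
        ld = sample_ld(gpanel)
        if cfg.association.v_mode == "shrunk":
            cm = interpolate_cm(gpanel.records, gmap)
            ld = shrink_ld(ld, cm, cfg.ld.n_e, cfg.ld.m, cfg.ld.c)
        v_by_gene[gene_id] = ld
    models_by_gene = {g: [m for m in ms if m.n_nonzero > 0] for g, ms in models_by_gene.items()}
    df = transcriptome_scan(models_by_gene, gwas_by_gene, v_by_gene, cfg.association.alpha)
    df.to_csv(out_dir / "associations.tsv", sep="\t", index=False)
    return ["associations.tsv"]


def simulate_stage(cfg: RunConfig, out_dir: Path) -> list[str]:
    sim_cfg = dataclasses.replace(cfg.simulation, seed=cfg.seed)
    if cfg.scenario == "accuracy":
        df = run_accuracy_experiment(sim_cfg)
        summary = {"mean_test_r2": float(df["test_r2"].mean()),
                   "n_replicates": int(len(df))}
    elif cfg.scenario == "power":
        res = run_power_experiment(sim_cfg)
        df = res.pop("per_replicate")
        summary = {k: v for k, v in res.items()}
    elif cfg.scenario == "type1":
        res = run_type1_experiment(sim_cfg)
        df = pd.DataFrame({"null_p": res["null_p"]})
        summary = {"rates": {str(k): v for k, v in res["rates"].items()}, "n_null": res["n_null"]}
    else:
        raise ValueError(f"unknown scenario {cfg.scenario!r}")
    df.to_csv(out_dir / "simulation_replicates.tsv", sep="\t", index=False)
    (out_dir / "simulation_summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return ["simulation_replicates.tsv", "simulation_summary.json"]


_STAGES = {"train": train_stage, "assoc": assoc_stage, "simulate": simulate_stage}


def run_pipeline(cfg: RunConfig, stages: list[str]) -> dict:
    """Run the requested stages and write a manifest; returns the manifest."""
    unknown = set(stages) - set(_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {', '.join(sorted(unknown))}")
    out_dir = Path(cfg.paths.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = {}
    for f in dataclasses.fields(cfg.paths):
        val = getattr(cfg.paths, f.name)
        if f.name != "out" and val and Path(val).is_file():
            inputs[f.name] = _sha256(Path(val))
    manifest = {
        "seed": cfg.seed,
        "inputs_sha256": inputs,
        "config": dataclasses.asdict(cfg),
        "stages": {},
    }
    for stage in ("train", "assoc", "simulate"):
        if stage not in stages:
            continue
        try:
            artifacts = _STAGES[stage](cfg, out_dir)
            manifest["stages"][stage] = {
                "status": "ok",
                "artifacts": {a: _sha256(out_dir / a) for a in artifacts},
            }
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
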