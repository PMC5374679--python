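"""End-to-end orchestration: simulate or load inputs, then run the
enabled stages in dependency order and write per-stage TSV outputs plus
a machine-readable summary JSON.

Stage outputs are pure functions of (inputs, parameters, seed); the
master seed fans out to per-stage seeds by stable hashing of stage
names.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differentiation as diff
from . import envassoc as ea
from . import enrichment as enr
from . import structure as st
from .diversity import DiversityParams, window_diversity
from .io import (
    ConfigurationError,
    apply_region_mask,
    load_annotation,
    parse_bed,
    parse_sync,
    read_env_table,
)
from .simulate import SimulationConfig, simulate_gradient_experiment

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "diversity", "fst", "classify", "fixeddiff", "structure", "fstats",
    "envassoc", "goenrich",
)


@dataclass
class PipelineConfig:
    simulate: SimulationConfig | None = None
    sync: str | None = None
    n_pools: int | None = None
    gff: str | None = None
    obo: str | None = None
    gene2go: str | None = None
    env: str | None = None
    mask: str | None = None
    reads: str | None = None
    stages: tuple = ALL_STAGES
    outdir: str = "poolcline_run"
    seed: int = 0
    diversity_params: DiversityParams = field(default_factory=DiversityParams)
    fst_params: diff.FstParams = field(default_factory=diff.FstParams)
    block_size: int = 500
    n_cov_snps: int = 10_000
    top_fraction: float = 0.01
    enrich_alpha: float = 0.05
    enrich_min_genes: int = 4

    def __post_init__(self) -> None:
        if self.simulate is None and self.sync is None:
            raise ConfigurationError("either a simulate block or a sync path")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        need = {
            "fixeddiff": "fst", "structure": "fst", "fstats": "fst",
            "envassoc": "fst", "goenrich": "envassoc",
        }
        for stage, dep in need.items():
            if stage in self.stages and dep not in self.stages:
                raise ConfigurationError(f"stage '{stage}' requires '{dep}'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimulationConfig(**raw["simulate"])
        if "diversity_params" in raw:
            raw["diversity_params"] = DiversityParams(**raw["diversity_params"])
        if "fst_params" in raw:
            raw["fst_params"] = diff.FstParams(**raw["fst_params"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _param_hash(config: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__") or hasattr(o, "__dataclass_fields__"):
            return asdict(o) if hasattr(o, "__dataclass_fields__") else vars(o)
        return str(o)

    fields = asdict(config)
    fields.pop("outdir", None)  # hash the science, not the location
    blob = json.dumps(fields, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the summary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "seed": config.seed,
        "parameter_hash": _param_hash(config),
        "stages": list(config.stages),
    }
    models = ontology = env_table = None
    if config.simulate is not None:
        ds = simulate_gradient_experiment(config.simulate)
        table, models, ontology, env_table = (
            ds.table, ds.gene_models, ds.ontology, ds.env,
        )
        ds.write(out / "inputs")
    else:
        if config.n_pools is None:
            raise ConfigurationError("n_pools required with a sync input")
        table = parse_sync(config.sync, config.n_pools)
        if config.gff and config.obo and config.gene2go:
            models, ontology = load_annotation(config.gff, config.obo,
                                               config.gene2go)
        if config.env:
            env_table = read_env_table(config.env)
    if config.mask:
        table = apply_region_mask(table, parse_bed(config.mask))
    summary["n_sites"] = len(table)
    manifest = []

    if "diversity" in config.stages:
        wd = window_diversity(table, config.diversity_params,
                              seed=stage_seed(config.seed, "diversity"))
        wd.to_csv(out / "diversity.tsv", sep="\t", index=False)
        manifest.append("diversity.tsv")
        okw = wd[wd.ok]
        summary["diversity"] = {
            "n_windows": int(len(wd)),
            "mean_pi": float(okw.pi.mean()) if len(okw) else None,
            "mean_theta_w": float(okw.theta_w.mean()) if len(okw) else None,
            "mean_tajima_d": float(okw.tajima_d.mean()) if len(okw) else None,
        }

    fst = None
    if "fst" in config.stages:
        fst = diff.pairwise_fst_table(table, config.fst_params)
        fst.to_csv(out / "fst.tsv", sep="\t", index=False)
        manifest.append("fst.tsv")
        cols = diff.fst_columns(fst)
        pooled = fst[cols].to_numpy().ravel()
        thresh, _ = diff.empirical_outliers(pooled, config.fst_params.snp_quantile)
        summary["fst"] = {
            "n_snps": int(len(fst)),
            "mean_pairwise_fst": float(np.nanmean(fst[cols].to_numpy())),
            "pairwise_means": {c: float(fst[c].mean()) for c in cols},
            "outlier_threshold": float(thresh),
            "bonferroni_p": diff.bonferroni_threshold(
                config.fst_params.family_alpha, len(cols)
            ),
        }

    if "classify" in config.stages and models is not None:
        src = fst if fst is not None else None
        scaf = (src["scaffold"].to_numpy() if src is not None else table.scaffold)
        pos = (src["position"].to_numpy() if src is not None else table.position)
        classes = diff.classify_snps(scaf, pos, models,
                                     config.fst_params.promoter_length)
        classes.to_csv(out / "classification.tsv", sep="\t", index=False)
        manifest.append("classification.tsv")
        summary["classification"] = diff.classification_summary(classes)

    if "fixeddiff" in config.stages and config.simulate is not None:
        sim = config.simulate
        idx = diff.fixed_between_clusters(
            table, sim.cluster_a, sim.cluster_c, config.fst_params.min_minor_count
        )
        summary["fixed_between_clusters"] = int(len(idx))

    freqs = depths = snp_idx = None
    if fst is not None and ("structure" in config.stages
                            or "fstats" in config.stages
                            or "envassoc" in config.stages):
        freqs, depths, snp_idx = st.pool_frequencies(
            table, config.fst_params.min_minor_count
        )

    if "structure" in config.stages and fst is not None:
        cols = diff.fst_columns(fst)
        pair_index = [tuple(int(x) for x in c.split("_")[1:]) for c in cols]
        vals = fst[cols].to_numpy()
        dset = st.quantile_distance_matrices(vals, pair_index, table.n_pools)
        space = st.distatis(dset, n_boot=200,
                            seed=stage_seed(config.seed, "structure"),
                            fst_values=vals, pair_index=pair_index)
        labels = [f"pop{i + 1}" for i in range(table.n_pools)]
        med = dset[list(st.DEFAULT_QUANTILES).index(0.5)]
        newick = st.nj_tree(med, labels)
        (out / "nj_fst_median.nwk").write_text(newick + "\n")
        manifest.append("nj_fst_median.nwk")
        coords = {
            labels[p]: [float(space.scores[p, 0]), float(space.scores[p, 1])]
            for p in range(table.n_pools)
        }
        (out / "distatis.json").write_text(json.dumps(
            {"alphas": space.alphas.tolist(),
             "eigenvalues": space.eigenvalues.tolist(),
             "coordinates": coords}, indent=2))
        manifest.append("distatis.json")
        summary["structure"] = {"compromise_axis1": coords}

    if "fstats" in config.stages and freqs is not None:
        ft = st.f_statistics_table(freqs, config.block_size, depths)
        ft.to_csv(out / "fstats.tsv", sep="\t", index=False)
        manifest.append("fstats.tsv")
        f3 = ft[ft.statistic == "f3"]
        f4 = ft[ft.statistic == "f4"]
        summary["fstats"] = {
            "n_f3": int(len(f3)),
            "n_f4": int(len(f4)),
            "n_f3_significant_negative": int(((f3.z < -3)).sum()),
            "n_f4_rejecting_treeness": int((f4.z.abs() > 3).sum()),
        }

    env_scores_df = None
    if "envassoc" in config.stages and freqs is not None and env_table is not None:
        comp = ea.env_pca(env_table)
        model = ea.estimate_covariance(
            freqs, config.n_cov_snps, seed=stage_seed(config.seed, "envassoc")
        )
        env_scores_df = ea.env_score(freqs, depths, model, comp)
        env_scores_df.insert(0, "position", pd.array(table.position[snp_idx]))
        env_scores_df.insert(0, "scaffold", table.scaffold[snp_idx])
        env_scores_df.to_csv(out / "env_scores.tsv", sep="\t", index=False)
        manifest.append("env_scores.tsv")
        n_top = max(1, int(round(config.top_fraction * len(env_scores_df))))
        top_rows = env_scores_df.nsmallest(n_top, "rank")
        top_env = set(zip(top_rows.scaffold, top_rows.position))
        summary["envassoc"] = {
            "env1_variance_pct": round(100 * comp.variance_fraction, 1),
            "omega_convergence": model.convergence,
            "n_top": n_top,
        }
        if fst is not None:
            cols = diff.fst_columns(fst)
            pooled_max = fst[cols].to_numpy().max(axis=1)
            _, fst_out = diff.empirical_outliers(pooled_max,
                                                 config.fst_params.snp_quantile)
            out_rows = fst.iloc[fst_out]
            rep = ea.overlap_report(
                top_env, set(zip(out_rows.scaffold, out_rows.position))
            )
            rep.pop("overlap")
            summary["envassoc"]["overlap_with_fst"] = rep

    if "goenrich" in config.stages and ontology is not None and models is not None \
            and env_scores_df is not None:
        n_top = max(1, int(round(config.top_fraction * len(env_scores_df))))
        top = env_scores_df.nsmallest(n_top, "rank")
        classes = diff.classify_snps(top["scaffold"].to_numpy(),
                                     top["position"].to_numpy(), models)
        snp_map = diff._snp_gene_map(top["scaffold"].to_numpy(),
                                     top["position"].to_numpy(), models)
        study = {
            models.genes.iloc[gi].gene_id
            for gi, hits in enumerate(snp_map) if hits
        }
        study &= set(ontology.annotations)
        if study:
            res = enr.elim_enrichment(ontology, study, config.enrich_alpha,
                                      config.enrich_min_genes)
            tab = enr.enrichment_table(res)
            tab.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            manifest.append("enrichment.tsv")
            summary["goenrich"] = {
                "n_study_genes": len(study),
                "n_terms_tested": int(len(tab)),
                "n_significant": int((tab.p_classic.notna()
                                      & (tab.log10_p < np.log10(
                                          config.enrich_alpha))).sum()),
            }
        else:
            summary["goenrich"] = {"n_study_genes": 0}

    summary["manifest"] = manifest
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    (out / "MANIFEST").write_text("\n".join(manifest + ["summary.json"]) + "\n")
    return summary
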