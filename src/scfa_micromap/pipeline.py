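"""End-to-end orchestration of the microbe-SCFA analysis.

One :class:`PipelineConfig` drives the full sequence: load (or simulate) a
cohort -> high-abundance filter -> ALR transform -> PERMANOVA on Bray-
Curtis distances -> transit-conditioned pCCA with the model permutation
test -> per-SCFA projection rankings (overall and per group) -> bootstrap
Bayesian-network consensus -> trait and per-taxon group statistics.  Every
stage logs sample/feature counts and writes flat TSVs plus a resolved
config and a JSON manifest; a failure in an optional late stage (the
network) does not discard earlier outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compositional, diversity, ordination, projection
from .associations import adjusted_feature_model, gmm_associate, kruskal_dunn
from .errors import ConfigError, ScfaMicromapError
from .network import bootstrap_consensus, scfa_neighborhood
from .simulate import GeneratorConfig, generate_cohort
from .tables import (
    AbundanceTable,
    CohortMetadata,
    align_samples,
    read_abundance_table,
    read_gmm_definitions,
    read_metadata,
    write_result_tables,
)

logger = logging.getLogger(__name__)

DEFAULT_CONSTRAINTS = ("acetate", "butyrate", "propionate", "acetate_butyrate_ratio")


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run.

    Defaults follow the published analysis parameters: 0.1% abundance in
    >= 2 specimens of >= 1 group, transit as the conditioning variable,
    999 permutations, a 60-degree cone with a 0.5 projection cutoff, and a
    500-bootstrap consensus retaining edges at 50% frequency.
    """

    abundance_path: str | None = None
    metadata_path: str | None = None
    ko_path: str | None = None
    gmm_path: str | None = None
    generator: GeneratorConfig | None = None
    abundance_kind: str = "relative"
    alr_reference: str | None = None
    abundance_min: float = 0.001
    min_prevalent_samples: int = 2
    constraints: tuple[str, ...] = DEFAULT_CONSTRAINTS
    conditions: tuple[str, ...] = ("transit",)
    covariates: tuple[str, ...] = ("age", "sex", "bmi")
    n_perm: int = 999
    cone_deg: float = 60.0
    score_min: float = 0.5
    n_boot: int = 500
    retention: float = 0.5
    bn_max_taxa: int | None = 30
    bn_max_parents: int | None = 5
    fold_min: float = 3.0
    traits: tuple[str, ...] = (
        "total_scfa",
        "acetate",
        "butyrate",
        "propionate",
        "acetate_butyrate_ratio",
        "transit",
    )
    run_network: bool = True
    seed: int = 0
    out_dir: str = "scfa_micromap_out"

    def validate(self) -> None:
        has_files = self.abundance_path is not None and self.metadata_path is not None
        if has_files == (self.generator is not None):
            raise ConfigError("give either input paths or a generator config")
        if self.n_perm < 1 or self.n_boot < 1:
            raise ConfigError("n_perm and n_boot must be >= 1")
        if not self.constraints:
            raise ConfigError("at least one constraint is required")

    # Stage seeds fan out from the global seed by fixed offsets so that a
    # stage keeps its stream when other stages are toggled.
    def stage_seed(self, stage: str) -> int:
        offsets = {"generator": 0, "permanova": 11, "pcca": 23, "network": 37}
        return (self.seed + offsets[stage]) % (2**31 - 1)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    gen = raw.pop("generator", None)
    cfg = PipelineConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
    if gen is not None:
        from .simulate import Driver

        drivers = tuple(
            Driver(int(d[0]), str(d[1]), float(d[2])) for d in gen.pop("drivers", [])
        )
        gen = {k: tuple(map(tuple, v)) if k in ("n_per_group", "gamma") else v for k, v in gen.items()}
        cfg = dataclasses.replace(
            cfg, generator=GeneratorConfig(drivers=drivers, **gen) if drivers else GeneratorConfig(**gen)
        )
    return cfg


def _log(stage: str, **kv) -> None:
    pairs = " ".join(f"{k}={v}" for k, v in kv.items())
    logger.info("ts=%.3f stage=%s %s", time.time(), stage, pairs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(_config_dict(config), fh, sort_keys=False)

    if config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=config.stage_seed("generator"))
        table, meta, truth = generate_cohort(gen)
        truth_path = out / "ground_truth.json"
        with open(truth_path, "w") as fh:
            json.dump(
                {
                    "drivers": [
                        {"taxon": truth.taxon_ids[d.taxon_index], "scfa": d.scfa, "beta": d.beta}
                        for d in truth.drivers
                    ],
                    "gamma": truth.gamma,
                },
                fh,
                indent=2,
            )
    else:
        table = read_abundance_table(config.abundance_path, kind=config.abundance_kind)
        meta = read_metadata(config.metadata_path)
    table, meta, align_log = align_samples(table, meta)
    _log("load", n_samples=table.n_samples, n_features=table.n_features, **align_log)

    rel = table.to_relative()
    results: dict[str, pd.DataFrame] = {}

    filtered, report = compositional.filter_high_abundant(
        rel, meta, config.abundance_min, config.min_prevalent_samples
    )
    results["filter_report"] = report.to_frame()
    _log("filter", kept=len(report.kept_features), dropped=len(report.dropped_features))

    closed = filtered.to_relative()
    alr = compositional.alr_transform(closed, config.alr_reference)
    results["alr"] = alr.data.reset_index(names="sample_id")
    _log("alr", reference=alr.reference_id, pseudocount=alr.pseudocount)

    results["fold_changes"] = compositional.fold_change_screen(
        rel, meta, config.fold_min
    )

    dist = diversity.bray_curtis(rel)
    perm_unadj = diversity.permanova(
        dist, meta, n_perm=config.n_perm, seed=config.stage_seed("permanova")
    )
    complete = meta.complete_for(config.covariates)
    perm_adj = diversity.permanova(
        diversity.bray_curtis(rel.select_samples(complete).to_relative()),
        meta.select_samples(complete),
        covariates=list(config.covariates),
        n_perm=config.n_perm,
        seed=config.stage_seed("permanova"),
    )
    results["permanova"] = pd.DataFrame(
        [
            ("unadjusted", perm_unadj.pseudo_F, perm_unadj.R2, perm_unadj.p_value),
            ("adjusted", perm_adj.pseudo_F, perm_adj.R2, perm_adj.p_value),
        ],
        columns=["model", "pseudo_F", "R2", "p_value"],
    )
    _log("permanova", p_unadjusted=perm_unadj.p_value, p_adjusted=perm_adj.p_value)

    constraints = [c for c in config.constraints if c in meta.data.columns]
    complete = meta.complete_for(list(constraints) + list(config.conditions))
    pc_table = closed.select_samples(complete).to_relative()
    pc_meta = meta.select_samples(complete)
    ordn = ordination.pcca(
        pc_table,
        pc_meta.data[list(constraints)].astype(float),
        pc_meta.data[list(config.conditions)].astype(float) if config.conditions else None,
    )
    test = ordination.pcca_permutation_test(
        pc_table,
        pc_meta.data[list(constraints)].astype(float),
        pc_meta.data[list(config.conditions)].astype(float) if config.conditions else None,
        n_perm=config.n_perm,
        seed=config.stage_seed("pcca"),
    )
    results["pcca_inertia"] = ordn.inertia_frame()
    results["pcca_species_scores"] = ordn.species_scores.reset_index(names="feature_id")
    results["pcca_biplot_scores"] = ordn.biplot_scores.reset_index(names="constraint")
    results["pcca_test"] = pd.DataFrame(
        [(test.pseudo_F, ordn.R2, test.p_value, test.n_perm)],
        columns=["pseudo_F", "R2", "p_value", "n_perm"],
    )
    _log("pcca", features_in=pc_table.n_features, p=test.p_value, R2=round(ordn.R2, 4))

    rankings = projection.rank_by_group(
        rel,
        meta,
        list(constraints),
        list(config.conditions),
        config.cone_deg,
        config.score_min,
        abundance_min=config.abundance_min,
        min_prevalent_samples=config.min_prevalent_samples,
    )
    rank_rows = []
    for unit, per_scfa in rankings.items():
        for ranking in per_scfa:
            frame = ranking.entries.assign(group=unit, scfa=ranking.scfa_id)
            rank_rows.append(frame)
    results["projection_rankings"] = (
        pd.concat(rank_rows, ignore_index=True)
        if rank_rows
        else pd.DataFrame(columns=["feature_id", "projection_score", "angle_deg", "group", "scfa"])
    )
    counts = {
        unit: sum(r.n_retained for r in per_scfa) for unit, per_scfa in rankings.items()
    }
    _log("rank", **{f"retained_{k}": v for k, v in counts.items()})

    manifest_extra = {}
    if config.run_network:
        try:
            scfa_cols = [c for c in constraints if c in pc_meta.data.columns]
            taxa = alr.data.columns
            if config.bn_max_taxa is not None and len(taxa) > config.bn_max_taxa:
                # Bound the node set to the taxa most implicated in the
                # constrained ordination (largest species-score norm).
                relevance = (
                    np.sqrt((ordn.species_scores**2).sum(axis=1))
                    .reindex(taxa)
                    .fillna(0.0)
                )
                taxa = relevance.nlargest(config.bn_max_taxa).index
            net_data = pd.concat(
                [
                    alr.data.loc[pc_meta.sample_ids, taxa],
                    pc_meta.data[scfa_cols + list(config.conditions)].astype(float),
                ],
                axis=1,
            )
            net = bootstrap_consensus(
                net_data,
                n_boot=config.n_boot,
                retention=config.retention,
                seed=config.stage_seed("network"),
                max_parents=config.bn_max_parents,
            )
            results["consensus_edges"] = net.to_frame()
            results["scfa_neighborhood"] = scfa_neighborhood(net, scfa_cols)
            _log("network", retained_edges=net.retained_edges.shape[0])
        except ScfaMicromapError as exc:  # optional stage: keep earlier outputs
            logger.warning("network stage failed: %s", exc)
            manifest_extra["network_error"] = str(exc)

    trait_rows = []
    for trait in config.traits:
        if trait not in meta.data.columns:
            continue
        cmp_res = kruskal_dunn(meta, trait)
        for _, pr in cmp_res.pairwise.iterrows():
            trait_rows.append(
                (trait, cmp_res.kw_H, cmp_res.kw_p, pr["group_a"], pr["group_b"],
                 pr["dunn_z"], pr["p_raw"], pr["p_bonferroni"])
            )
    results["trait_comparisons"] = pd.DataFrame(
        trait_rows,
        columns=["trait", "kw_H", "kw_p", "group_a", "group_b", "dunn_z", "p_raw", "p_bonferroni"],
    )

    assoc_rows = []
    groups = meta.groups_present()
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            for a in adjusted_feature_model(alr, meta, list(config.covariates), (ga, gb)):
                assoc_rows.append((a.feature_id, a.term, a.estimate, a.se, a.p))
    results["adjusted_taxa"] = pd.DataFrame(
        assoc_rows, columns=["feature_id", "term", "estimate", "se", "p"]
    )

    if config.ko_path and config.gmm_path:
        ko = read_abundance_table(config.ko_path, kind="counts")
        gmm = read_gmm_definitions(config.gmm_path)
        ko_aligned, meta_aligned, _ = align_samples(ko, meta)
        frames = []
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                frames.append(
                    gmm_associate(
                        ko_aligned, gmm, meta_aligned, list(config.covariates),
                        contrast=(ga, gb),
                    )
                )
        results["gmm_associations"] = pd.concat(frames, ignore_index=True)
    elif config.gmm_path and not config.ko_path:
        logger.warning("gmm stage skipped: no KO table supplied")
        manifest_extra["gmm_skipped"] = "no KO table supplied"

    manifest = write_result_tables(results, out)
    manifest.update(manifest_extra)
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("generator") is not None:
        d["generator"] = dataclasses.asdict(config.generator)
    return d
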