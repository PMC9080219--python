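"""Pipeline orchestration: preprocessing -> season/niche annotation ->
local similarity analysis -> environmentally-driven edge removal -> core
network, with a YAML-backed configuration, per-stage child seeds, and a
reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from planktonet import io as pio
from planktonet.ended import EndedConfig, remove_indirect
from planktonet.lsa import LsaConfig, build_association_table
from planktonet.network import (
    classify_central,
    filter_core,
    mcode_modules,
    network_stats,
    node_metrics,
    seasonal_subnetwork,
)
from planktonet.prep import CountTable, PrepConfig, PrepResult, prepare
from planktonet.seasons import indval, label_months, niche_table
from planktonet.synth import SynthConfig, SynthTruth, evaluate_recovery, simulate_dataset

log = logging.getLogger("planktonet")


@dataclass
class SeasonConfig:
    indval_n_perm: int = 999
    niche_n_perm: int = 1000
    niche_variables: tuple[str, ...] = ("temperature", "daylength")
    indval_alpha: float = 0.05
    tie_break: str | None = "closed-lower"


@dataclass
class CoreConfig:
    ls_min: float = 0.7
    rho_min: float = 0.7
    q_max: float = 0.001
    network_p_max: float = 0.05  # unadjusted mixed-p cut for edges entering EnDED
    mcode_vwp: float = 0.2
    mcode_score_min: float = 4.0
    compute_modularity: bool = True
    # edge-betweenness modularity is quadratic in edges; larger graphs get NaN
    modularity_max_edges: int = 600


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str | None = None
    synthetic: SynthConfig = field(default_factory=SynthConfig)
    prep: PrepConfig = field(default_factory=PrepConfig)
    season: SeasonConfig = field(default_factory=SeasonConfig)
    lsa: LsaConfig = field(default_factory=LsaConfig)
    ended: EndedConfig = field(default_factory=EndedConfig)
    corenet: CoreConfig = field(default_factory=CoreConfig)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload or {})
        kwargs = {}
        sections = {
            "synthetic": SynthConfig,
            "prep": PrepConfig,
            "season": SeasonConfig,
            "lsa": LsaConfig,
            "ended": EndedConfig,
            "corenet": CoreConfig,
        }
        for key in ("seed", "out_dir"):
            if key in payload:
                kwargs[key] = payload.pop(key)
        for key, klass in sections.items():
            if key in payload:
                section = payload.pop(key) or {}
                known = {f.name for f in dataclasses.fields(klass)}
                unknown = set(section) - known
                if unknown:
                    raise ValueError(f"unknown keys in section {key!r}: {sorted(unknown)}")
                kwargs[key] = klass(**section)
        if payload:
            raise ValueError(f"unknown configuration keys: {sorted(payload)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineResult:
    config: PipelineConfig
    tables: list[CountTable]
    env: pd.DataFrame
    truth: SynthTruth | None
    prep: PrepResult
    season_labels: pd.Series
    indval_table: pd.DataFrame
    niche: pd.DataFrame
    associations: pd.DataFrame
    network_edges: pd.DataFrame
    ended_report: pd.DataFrame
    core: nx.Graph
    core_stats: dict
    metrics: pd.DataFrame
    central: pd.Series
    modules: list
    seasonal_stats: dict[str, dict]
    summary: pd.DataFrame
    recovery: dict[str, float] | None
    manifest: dict


def run_pipeline(
    config: PipelineConfig,
    tables: list[CountTable] | None = None,
    env: pd.DataFrame | None = None,
    truth: SynthTruth | None = None,
) -> PipelineResult:
    """Run the full pipeline; without explicit tables, a seeded synthetic
    dataset is generated from ``config.synthetic``."""
    cfg = config
    if tables is None:
        synth_cfg = dataclasses.replace(cfg.synthetic, seed=_stage_seed(cfg.seed, 0))
        tables, env, truth = simulate_dataset(synth_cfg)
        log.info("simulated %d tables, %d months", len(tables), synth_cfg.n_months)
    if env is None:
        raise ValueError("environmental table required when count tables are supplied")

    prep_cfg = dataclasses.replace(cfg.prep, seed=_stage_seed(cfg.seed, 1))
    prep_res = prepare(tables, env, prep_cfg)
    for line in prep_res.log:
        log.info("prep: %s", line)

    labels = label_months(env, tie_break=cfg.season.tie_break)
    iv = indval(
        prep_res.abundance,
        labels,
        n_perm=cfg.season.indval_n_perm,
        seed=_stage_seed(cfg.seed, 2),
    )
    niche = niche_table(
        prep_res.abundance,
        env,
        variables=cfg.season.niche_variables,
        n_perm=cfg.season.niche_n_perm,
        seed=_stage_seed(cfg.seed, 3),
    )

    lsa_cfg = dataclasses.replace(cfg.lsa, seed=_stage_seed(cfg.seed, 4))
    associations = build_association_table(prep_res.abundance, prep_res.env, lsa_cfg)
    log.info("lsa: %d pairs evaluated", associations.attrs.get("n_tests", len(associations)))

    network_edges = associations[associations["p"] < cfg.corenet.network_p_max].reset_index(
        drop=True
    )
    network_edges.attrs.update(associations.attrs)
    log.info("network: %d edges enter the indirect-edge stage", len(network_edges))

    ended_cfg = dataclasses.replace(cfg.ended, seed=_stage_seed(cfg.seed, 5))
    surviving, report = remove_indirect(network_edges, prep_res.abundance, prep_res.env, ended_cfg)
    log.info("ended: %s", report.attrs.get("summary", ""))

    core = filter_core(
        surviving, cfg.corenet.ls_min, cfg.corenet.rho_min, cfg.corenet.q_max
    )
    otu_info = {}
    for t in tables:
        for otu in t.otu_ids:
            otu_info[otu] = (t.domain, t.size_fraction)
    season_of = {}
    for otu in prep_res.abundance.index:
        if otu in iv.index and iv.at[otu, "p"] == iv.at[otu, "p"] and iv.at[otu, "p"] < cfg.season.indval_alpha:
            season_of[otu] = str(iv.at[otu, "best_season"])
        else:
            season_of[otu] = "none"
    for node, data in core.nodes(data=True):
        if data.get("kind") == "otu":
            domain, fraction = otu_info.get(node, ("unknown", "unknown"))
            core.nodes[node]["domain"] = domain
            core.nodes[node]["size_fraction"] = fraction
            core.nodes[node]["season"] = season_of.get(node, "none")

    def _with_modularity(g: nx.Graph) -> bool:
        return (
            cfg.corenet.compute_modularity
            and g.number_of_edges() <= cfg.corenet.modularity_max_edges
        )

    if core.number_of_nodes() >= 2:
        stats = network_stats(core, compute_modularity=_with_modularity(core)).as_dict()
        metrics = node_metrics(core)
        central = classify_central(metrics)
        modules = mcode_modules(core, vwp=cfg.corenet.mcode_vwp)
        for mod in modules:
            seasons = [season_of.get(n, "none") for n in mod.nodes]
            mod.season_majority = max(set(seasons), key=seasons.count)
        seasonal_stats = {}
        for season in ("winter", "spring", "summer", "autumn"):
            sub = seasonal_subnetwork(core, season_of, season)
            if sub.number_of_nodes() >= 2 and sub.number_of_edges() >= 1:
                seasonal_stats[season] = network_stats(
                    sub, compute_modularity=_with_modularity(sub)
                ).as_dict()
    else:
        stats = {}
        metrics = pd.DataFrame(columns=["degree", "betweenness", "closeness", "clustering"])
        central = pd.Series(dtype=object)
        modules = []
        seasonal_stats = {}

    summary = _summary_table(tables, prep_res, core)

    recovery = None
    if truth is not None and (truth.direct_pairs or truth.env_driven_pairs):
        core_otu_edges = [
            (u, v)
            for u, v in core.edges
            if core.nodes[u].get("kind") == "otu" and core.nodes[v].get("kind") == "otu"
        ]
        removed = report[report["removed"]][["node_a", "node_b"]].itertuples(index=False)
        recovery = evaluate_recovery(core_otu_edges, truth, removed_edges=list(removed))

    manifest = {
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "networkx": nx.__version__,
        "n_tests": int(associations.attrs.get("n_tests", len(associations))),
    }

    result = PipelineResult(
        config=cfg,
        tables=tables,
        env=env,
        truth=truth,
        prep=prep_res,
        season_labels=labels,
        indval_table=iv,
        niche=niche,
        associations=associations,
        network_edges=network_edges,
        ended_report=report,
        core=core,
        core_stats=stats,
        metrics=metrics,
        central=central,
        modules=modules,
        seasonal_stats=seasonal_stats,
        summary=summary,
        recovery=recovery,
        manifest=manifest,
    )
    if cfg.out_dir:
        write_bundle(result, cfg.out_dir)
    return result


def _summary_table(tables, prep_res: PrepResult, core: nx.Graph) -> pd.DataFrame:
    """Counts of all / resident / core OTUs by domain and size fraction."""
    rows = []
    core_otus = {n for n, d in core.nodes(data=True) if d.get("kind") == "otu"}
    residents = set(prep_res.residents)
    for t in tables:
        otus = set(t.otu_ids)
        rows.append(
            {
                "domain": t.domain,
                "size_fraction": t.size_fraction,
                "all_otus": len(otus),
                "resident_otus": len(otus & residents),
                "core_otus": len(otus & core_otus),
            }
        )
    total = {
        "domain": "all",
        "size_fraction": "all",
        "all_otus": sum(r["all_otus"] for r in rows),
        "resident_otus": len(residents),
        "core_otus": len(core_otus),
    }
    return pd.DataFrame(rows + [total])


def write_bundle(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t in result.tables:
        pio.write_count_table(t, out / f"counts_{t.domain}_{t.size_fraction}.tsv")
    pio.write_env(result.env, out / "environment.csv")
    if result.truth is not None:
        pio.write_truth(result.truth, out / "truth.json")
    pio.write_associations(result.associations, out / "associations.tsv")
    pio.write_associations(result.ended_report, out / "ended_report.tsv")
    pio.write_network(result.core, out / "core_network", fmt="tsv")
    pio.write_network(result.core, out / "core_network", fmt="graphml")
    result.indval_table.to_csv(out / "indval.tsv", sep="\t")
    result.niche.to_csv(out / "niche.tsv", sep="\t", index=False)
    result.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    stats_payload = {
        "core": result.core_stats,
        "seasonal": result.seasonal_stats,
        "recovery": result.recovery,
    }
    (out / "stats.json").write_text(json.dumps(stats_payload, indent=1, default=float))
    stat_rows = []
    if result.core_stats:
        stat_rows.append({"network": "core", **result.core_stats})
    for season, s in result.seasonal_stats.items():
        stat_rows.append({"network": season, **s})
    if stat_rows:
        pd.DataFrame(stat_rows).to_csv(out / "network_stats.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
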