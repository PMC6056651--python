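"""End-to-end orchestration: regions -> mapping -> Bayes -> downstream.

``run_all`` executes every stage in dependency order on either synthetic or
user-supplied tables, writes each stage's TSV outputs under an output
directory, and records a run manifest (config snapshot, seeds, row counts,
warnings) that is written in both success and failure modes.  Rerunning
with the same config and seed reproduces identical tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import PriorSpec, analyze_counts, call_drivers
from .domains import bootstrap_test, domain_disorder_rates, domain_hypergeom
from .mutations import count_all, deduplicate, parse_mutations
from .network import build_network, rwr, top_targets
from .regions import build_partitions
from .simulate import SimulationConfig, simulate_all
from .sitestats import (
    compare_conservation,
    compare_deleteriousness,
    deleterious_score,
    score_distribution,
)
from .survival import assign_groups, compare_groups

STAGES = [
    "simulate",
    "build_regions",
    "map_mutations",
    "call_drivers",
    "domain_test",
    "site_stats",
    "survival",
    "network_rwr",
]


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 42
    # stage parameters
    priors: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    n_iter: int = 5200
    burn_in: int = 200
    fdr: float = 0.05
    bootstrap_reps: int = 1000
    restart_prob: float = 0.7
    rwr_tol: float = 1e-10
    top_k: int = 10
    bayes_method: str = "gibbs"
    cancer_types: tuple[str, ...] | None = None  # restrict strata; None = all present
    # input tables; None means "generate synthetically"
    mutations_path: str | None = None
    sites_path: str | None = None
    sequences_path: str | None = None
    network_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        for p in (self.mutations_path, self.sites_path, self.network_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        cfg = cls(simulation=sim, **raw)
        return cfg


def _write(df: pd.DataFrame, path: Path, params: dict | None = None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if params:
            fh.write("# " + json.dumps(params, sort_keys=True) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }
    sim_cfg = config.simulation
    try:
        # -- simulate (or load) ------------------------------------------
        if config.mutations_path is None:
            sim_cfg.seed = config.seed
            data = simulate_all(sim_cfg)
            proteins, sites = data["proteins"], data["sites"]
            mutations = data["mutations"]
            domains, predictors = data["domains"], data["predictors"]
            survival_tbl, edges = data["survival"], data["edges"]
            _write(data["truth"].rates, out / "ground_truth.tsv")
            _write(mutations, out / "mutations.tsv")
        else:
            mutations, n_malformed = parse_mutations(config.mutations_path)
            sites = pd.read_csv(config.sites_path, sep="\t")
            proteins = pd.read_csv(config.sequences_path, sep="\t")
            domains = predictors = survival_tbl = edges = None
            manifest["warnings"].append(f"{n_malformed} malformed mutation rows skipped")
        if config.cancer_types is not None:
            unknown = set(config.cancer_types) - set(mutations["cancer_type"])
            if unknown:
                raise ValueError(f"unknown cancer type label(s): {sorted(unknown)}")
            mutations = mutations[mutations["cancer_type"].isin(config.cancer_types)]
        manifest["stages"]["simulate"] = {"n_mutations": len(mutations), "n_sites": len(sites)}

        # -- regions ------------------------------------------------------
        sequences = dict(zip(proteins["protein_id"], proteins["sequence"]))
        partitions = {}
        for mod_type, grp in sites.groupby("mod_type"):
            parts = build_partitions(grp, sequences, seed=config.seed)
            for pid, part in parts.items():
                prev = partitions.get(pid)
                if prev is None:
                    partitions[pid] = part
                else:
                    merged = np.union1d(prev.mod_positions, part.mod_positions)
                    prev.mod_positions = merged
        intervals = pd.concat(
            [p.intervals() for p in partitions.values()], ignore_index=True
        ) if partitions else pd.DataFrame()
        _write(intervals, out / "partitions.tsv")
        manifest["stages"]["build_regions"] = {"n_proteins": len(partitions)}

        # -- mapping ------------------------------------------------------
        records = deduplicate(mutations)
        counts_list, skipped = count_all(records, partitions)
        from .mutations import counts_to_frame

        _write(counts_to_frame(counts_list), out / "position_counts.tsv")
        manifest["stages"]["map_mutations"] = {
            "n_records": len(records),
            "n_skipped_unknown_protein": skipped,
        }

        # -- Bayes --------------------------------------------------------
        priors = PriorSpec(*config.priors)
        results = analyze_counts(
            counts_list,
            priors,
            method=config.bayes_method,
            n_iter=config.n_iter,
            burn_in=config.burn_in,
            seed=config.seed,
        )
        calls = call_drivers(results, fdr=config.fdr)
        _write(calls.results, out / "driver_results.tsv", asdict(priors))
        _write(calls.recurrent, out / "recurrent_drivers.tsv")
        driver_ids = set(calls.results.loc[calls.results["driver"].fillna(False), "protein_id"])
        manifest["stages"]["call_drivers"] = {
            "n_tested": int(calls.results["p_value"].notna().sum()),
            "n_drivers": len(driver_ids),
        }

        # -- downstream on synthetic annotations --------------------------
        if domains is not None:
            mod_mut = records.merge(
                mutations[["mutation_id", "mutation_class"]], how="left"
            ) if "mutation_class" not in records.columns else records
            mod_only = mod_mut[mod_mut["mutation_class"] == "modification-related"]
            mutated_positions = {
                pid: grp["position"].to_numpy() for pid, grp in mod_only.groupby("protein_id")
            }
            lengths = {
                pid: partitions[pid].n for pid in partitions
            }
            rates = domain_disorder_rates(domains, mutated_positions, lengths)
            if len(rates) >= 2:
                boot = bootstrap_test(
                    rates["domain_rate"],
                    rates["disorder_rate"],
                    B=config.bootstrap_reps,
                    seed=config.seed,
                )
                _write(
                    rates,
                    out / "domain_rates.tsv",
                    dict(t_obs=boot.t_obs, p_value=boot.p_value, B=boot.B, seed=boot.seed),
                )
                manifest["stages"]["domain_test"] = {
                    "t_obs": boot.t_obs,
                    "p_value": boot.p_value,
                }
            hyper = domain_hypergeom(domains, mutated_positions, lengths)
            _write(hyper, out / "domain_enrichment.tsv")

            scores = deleterious_score(predictors)
            is_mod = predictors["mutation_class"] == "modification-related"
            prop = compare_deleteriousness(scores[is_mod], scores[~is_mod])
            _write(prop, out / "deleteriousness.tsv")
            _write(score_distribution(scores[is_mod], scores[~is_mod]), out / "score_distribution.tsv")
            cons = compare_conservation(
                predictors.loc[is_mod, "conservation"],
                predictors.loc[~is_mod, "conservation"],
            )
            _write(cons.cdf, out / "conservation_cdf.tsv",
                   dict(D=cons.statistic, p_value=cons.p_value))
            manifest["stages"]["site_stats"] = {
                "ks_D": cons.statistic,
                "ks_p": cons.p_value,
            }

            # group patients by mutations in the identified drivers' regions
            surv_parts = {
                pid: p for pid, p in partitions.items() if pid in driver_ids
            } or partitions
            labelled = assign_groups(
                survival_tbl.drop(columns=["group"], errors="ignore"), records, surv_parts
            )
            try:
                curves, lr = compare_groups(labelled)
                for name, curve in curves.items():
                    _write(curve, out / f"km_{name.replace('-', '_')}.tsv")
                manifest["stages"]["survival"] = {
                    "logrank_stat": lr.statistic,
                    "logrank_p": lr.p_value,
                }
            except ValueError as exc:
                manifest["warnings"].append(f"survival stage skipped: {exc}")

            net = build_network(edges)
            prot_nodes = [n for n, k in net.kinds().items() if k == "protein"]
            # synthetic protein ids are not network node ids; seed the walk at
            # as many network proteins as there are driver calls (proxy seeds)
            seeds = sorted(prot_nodes)[: max(1, min(len(driver_ids), len(prot_nodes)))]
            res = rwr(net, seeds, r=config.restart_prob, tol=config.rwr_tol)
            targets, drugs = top_targets(res, net, k=config.top_k)
            _write(targets, out / "rwr_targets.tsv", dict(restart=res.restart, seeds=len(seeds)))
            _write(drugs, out / "rwr_drugs.tsv")
            manifest["stages"]["network_rwr"] = {
                "n_targets": len(targets),
                "n_drugs": len(drugs),
                "iterations": res.iterations,
            }
        manifest["status"] = "success"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
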