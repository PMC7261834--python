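"""End-to-end orchestration: diversity -> differentiation -> admixture ->
bottleneck -> ABC -> core collection from a single config.

The config fixes every stage's seed, so a rerun with an identical config
reproduces every output byte-for-byte.  Consensus cluster labels from the
admixture stage (at the K maximizing delta-K among interior K, unless the
config pins K) feed the per-cluster statistics, the bottleneck tests and the
ABC stage; "admixed" individuals are excluded from per-cluster statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abc_demography, admixture, bottleneck, core_collection, differentiation, diversity
from .io_formats import GenotypeMatrix, Partition, frame_to_tsv, read_genotype_table
from .synthetic import worldwide_preset

log = logging.getLogger("ssrdem")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Pipeline settings; every stochastic stage carries an explicit seed."""

    genotypes: str | None = None          # input path; None -> synthetic preset
    dialect: str = "csv"
    preset_seed: int | None = 0           # used when genotypes is None
    out_dir: str = "ssrdem_out"
    k_min: int = 1
    k_max: int = 6
    k_fixed: int | None = None
    n_runs: int = 3
    mcmc: tuple[int, int, int] = (300, 1500, 10)
    n_perm: int = 200
    n_boot: int = 200
    bottleneck_models: tuple[str, ...] = ("iam", "smm", "tpm")
    tpm_single: float = 0.95
    tpm_var: float = 12.0
    heq_iters: int = 1000
    abc_enabled: bool = False
    abc_sims: int = 500
    abc_loci: int = 8
    abc_accept: float = 0.05
    seeds: dict = field(default_factory=dict)

    REQUIRED_SEEDS = ("diversity", "differentiation", "admixture", "bottleneck", "abc", "core")

    def validate(self):
        missing = [s for s in self.REQUIRED_SEEDS if s not in self.seeds]
        if missing:
            raise ValueError(f"config missing stage seeds: {missing}")
        if self.genotypes is not None and not Path(self.genotypes).exists():
            raise ValueError(f"genotype file not found: {self.genotypes}")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("bad K range")

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("mcmc", "bottleneck_models"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def _write(df: pd.DataFrame, path: Path, cfg_hash: str):
    with open(path, "w") as fh:
        fh.write(f"# ssrdem config={cfg_hash}\n")
        fh.write(df.to_csv(sep="\t", float_format="%.6g"))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns a dict of the in-memory stage results."""
    cfg.validate()
    cfg_hash = cfg.content_hash()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config_hash": cfg_hash}
    stage = "load"
    try:
        if cfg.genotypes is None:
            g, geo, _true_q, _true_part = worldwide_preset(cfg.preset_seed)
        else:
            with open(cfg.genotypes) as fh:
                g, geo = read_genotype_table(fh, cfg.dialect)
        if geo is None:
            geo = Partition({ind: "all" for ind in g.individuals})

        stage = "diversity"
        per_locus, multi = diversity.locus_summary(
            g, n_perm=cfg.n_perm, seed=cfg.seeds["diversity"]
        )
        groups = diversity.group_summary(g, geo)
        _write(per_locus, out / "diversity_loci.tsv", cfg_hash)
        _write(groups, out / "diversity_groups.tsv", cfg_hash)
        results["diversity"] = (per_locus, multi, groups)

        stage = "differentiation"
        fst, fst_p, theta_global = differentiation.pairwise_fst(
            g, geo, n_perm=0, seed=cfg.seeds["differentiation"]
        )
        nei = differentiation.nei_distance(g, geo)
        am = differentiation.amova(g, geo, n_perm=cfg.n_perm,
                                   seed=cfg.seeds["differentiation"])
        _write(fst.to_frame(), out / "fst_groups.tsv", cfg_hash)
        _write(nei.to_frame(), out / "nei_groups.tsv", cfg_hash)
        _write(am.table, out / "amova_groups.tsv", cfg_hash)
        tree = differentiation.nj_tree(
            nei,
            bootstrap=dict(
                distance_fn=lambda gb: differentiation.nei_distance(gb, geo),
                genotypes=g, replicates=cfg.n_boot,
                seed=cfg.seeds["differentiation"],
            ),
        )
        (out / "nei_groups.nwk").write_text(tree.newick + "\n")
        results["differentiation"] = dict(fst=fst, nei=nei, amova=am,
                                          theta_global=theta_global, tree=tree)

        stage = "admixture"
        ks = [cfg.k_fixed] if cfg.k_fixed else list(range(cfg.k_min, cfg.k_max + 1))
        ens = admixture.run_ensemble(
            g, ks, n_runs=cfg.n_runs, mcmc=cfg.mcmc, seed=cfg.seeds["admixture"]
        )
        _write(ens.summary(), out / "structure_summary.tsv", cfg_hash)
        if cfg.k_fixed:
            k_star = cfg.k_fixed
        elif ens.delta_k:
            k_star = max(ens.delta_k, key=ens.delta_k.get)
        else:
            k_star = ks[-1]
        qbar = ens.consensus[k_star]
        labels, tallies = admixture.assign_clusters(
            qbar, individuals=g.individuals, partition=geo
        )
        qdf = pd.DataFrame(qbar, index=list(g.individuals),
                           columns=[f"cluster{k + 1}" for k in range(k_star)])
        qdf["label"] = labels
        _write(qdf, out / f"structure_Q_K{k_star}.tsv", cfg_hash)
        _write(tallies, out / "assignment_tallies.tsv", cfg_hash)
        results["admixture"] = dict(ensemble=ens, k_star=k_star,
                                    labels=labels, tallies=tallies)
        assigned = {
            ind: lab for ind, lab in zip(g.individuals, labels) if lab != "admixed"
        }
        clusters = Partition(assigned) if len(set(assigned.values())) >= 1 else None

        stage = "bottleneck"
        sim = bottleneck.HeqSimulator(n_iter=cfg.heq_iters,
                                      seed=cfg.seeds["bottleneck"])
        tpm = bottleneck.TpmParams(cfg.tpm_single, cfg.tpm_var)
        bn_rows = []
        if clusters is not None:
            usable = [grp for grp, rows in clusters.group_indices(g).items()
                      if rows.size >= 10]
            for grp in usable:
                hist, verdict = bottleneck.mode_shift(g, clusters, grp)
                for model in cfg.bottleneck_models:
                    rep = bottleneck.heterozygosity_excess_test(
                        g, clusters, grp, model=model, tpm=tpm, simulator=sim
                    )
                    bn_rows.append(dict(group=grp, model=model,
                                        wilcoxon_p=rep.wilcoxon_p,
                                        n_loci=rep.n_loci_used,
                                        mode_shift=verdict))
        bn = pd.DataFrame(bn_rows)
        if not bn.empty:
            _write(bn.set_index(["group", "model"]), out / "bottleneck.tsv", cfg_hash)
        results["bottleneck"] = bn

        stage = "abc"
        if cfg.abc_enabled and clusters is not None and len(clusters.groups) == 5:
            scen = abc_demography.default_scenario()
            remap = {grp: f"C{i+1}" for i, grp in enumerate(sorted(clusters.groups))}
            part5 = Partition({ind: remap[lab] for ind, lab in assigned.items()},
                              tuple(f"C{i+1}" for i in range(5)))
            obs = abc_demography.summary_statistics(g, part5)
            res = abc_demography.abc_fit(
                obs, scen, n_sims=cfg.abc_sims, n_loci=cfg.abc_loci,
                accept_rate=cfg.abc_accept, seed=cfg.seeds["abc"],
            )
            report = abc_demography.posterior_r_report(res)
            _write(report, out / "abc_report.tsv", cfg_hash)
            results["abc"] = dict(result=res, report=report)

        stage = "core"
        core = core_collection.build_core(g, seed=cfg.seeds["core"])
        parts = {"geographic": geo}
        if clusters is not None:
            parts["cluster"] = clusters
        cov = core_collection.coverage_report(g, core, parts)
        core_df = pd.DataFrame({"selected": list(core.selected)})
        _write(core_df.set_index("selected"), out / "core_members.tsv", cfg_hash)
        summary = pd.DataFrame(
            {"value": [cov["coverage"], cov["size_fraction_pct"],
                       cov["n_core"], cov["n_panel"]]},
            index=["allele_coverage", "size_fraction_pct", "n_core", "n_panel"],
        )
        _write(summary, out / "core_summary.tsv", cfg_hash)
        results["core"] = cov
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (out / "summary.md").write_text(_summary_doc(cfg, cfg_hash, results))
    return results


def _summary_doc(cfg, cfg_hash, results) -> str:
    lines = [
        "# ssrdem pipeline summary",
        f"config hash: {cfg_hash}",
        f"seeds: {json.dumps(cfg.seeds, sort_keys=True)}",
        "",
    ]
    if "admixture" in results:
        lines.append(f"selected K: {results['admixture']['k_star']}")
    if "differentiation" in results:
        lines.append(
            f"global theta (groups): {results['differentiation']['theta_global']:.4f}"
        )
    if "core" in results:
        cov = results["core"]
        lines.append(
            f"core: {cov['n_core']}/{cov['n_panel']} accessions "
            f"({cov['size_fraction_pct']:.2f}%), allele coverage {cov['coverage']:.3f}"
        )
    return "\n".join(lines) + "\n"
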