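"""End-to-end orchestration: simulate/load -> alpha -> beta -> networks ->
cross-network comparison, with a machine-readable provenance report.

A run is fully determined by its configuration (including the seed): the
same RunConfig reproduces byte-identical outputs.  Each stage's outputs and
status land in ``report.json``; a failing stage is recorded with its error
and dependent stages are skipped, leaving completed outputs in place.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .tables_io import (OtuTable, SampleMetadata, TaxonomyRecord,
                        filter_low_abundance, aggregate_by_rank,
                        read_otu_table, read_sample_metadata, read_taxonomy,
                        to_relative_abundance, write_otu_table,
                        write_sample_metadata, write_taxonomy)
from .synthetic import SyntheticDesign, default_design, generate_table
from .diversity import alpha_table, group_abundance_summary
from .beta import (bray_curtis, nmds, pairwise_permanova, permanova, upgma)
from .cooccurrence import (build_network, edge_list_frame, node_frame,
                           nonrandomness_test, spearman_all_pairs, topology,
                           write_graphml)
from .netcompare import (classify_profiles, heatmap_matrix, profile_frame,
                         shared_nodes)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "alpha", "beta", "network", "compare")


class ConfigError(ValueError):
    """Invalid run configuration; raised before any computation."""


@dataclass
class RunConfig:
    outdir: str = "run_out"
    seed: int = 0
    # either a synthetic design (None -> default design with default guilds)
    # or paths to the three input tables
    design: SyntheticDesign | None = None
    otu_table_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    filter_threshold: float = 0.001  # mean relative abundance, per host
    rho_min: float = 0.6
    p_max: float = 0.01
    permutations: int = 9999
    nmds_restarts: int = 20
    nonrandom_reps: int = 999
    run_pairwise: bool = True
    run_nonrandomness: bool = True
    profile_params: dict = field(default_factory=lambda: {
        "enrichment_factor": 10.0, "similarity_factor": 3.0,
        "location_cv_threshold": 1.0})

    def __post_init__(self) -> None:
        if not 0 < self.filter_threshold < 1:
            raise ConfigError(f"filter_threshold must be in (0,1): {self.filter_threshold}")
        if not 0 < self.rho_min <= 1:
            raise ConfigError(f"rho_min must be in (0,1]: {self.rho_min}")
        if not 0 < self.p_max <= 1:
            raise ConfigError(f"p_max must be in (0,1]: {self.p_max}")
        if self.permutations < 99:
            raise ConfigError("permutations must be >= 99")
        if self.nonrandom_reps < 99:
            raise ConfigError("nonrandom_reps must be >= 99")
        if self.nmds_restarts < 1:
            raise ConfigError("nmds_restarts must be >= 1")
        have_paths = [self.otu_table_path, self.metadata_path, self.taxonomy_path]
        if any(have_paths) and not all(have_paths):
            raise ConfigError("provide all three input paths or none")

    @property
    def synthetic(self) -> bool:
        return self.otu_table_path is None

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        # normalize to JSON/YAML-representable types (tuples -> lists)
        return json.loads(json.dumps(out))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        design = raw.pop("design", None)
        cfg = cls(**raw)
        if design is not None:
            from .synthetic import GroupSpec, GuildSpec
            groups = [GroupSpec(**g) for g in design.pop("groups", [])]
            guilds = [GuildSpec(**g) for g in design.pop("guilds", [])]
            kwargs = dict(design)
            if groups:
                kwargs["groups"] = groups
            kwargs["guilds"] = guilds
            cfg.design = SyntheticDesign(**kwargs)
        return cfg


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("permanova", "pairwise", "nmds", "community", "nonrandom")
    state = np.random.SeedSequence(seed).generate_state(len(names)) % (2 ** 31)
    return {name: int(s) for name, s in zip(names, state)}


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in dependency order; returns the report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "stages": {},
    }
    state: dict = {}
    order = [s for s in STAGES if s in stages or s == "simulate"]

    failed = False
    for stage in order:
        if failed:
            report["stages"][stage] = {"status": "skipped",
                                       "reason": "upstream failure"}
            continue
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FUNCS[stage](config, state, outdir, seeds)
            report["stages"][stage] = {"status": "ok", "outputs": outputs}
        except Exception as exc:  # recorded, downstream skipped
            logger.exception("stage %s failed", stage)
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
            failed = True
        logger.info("stage %s finished in %.2fs", stage,
                    time.perf_counter() - t0)
    _write_json(report, outdir / "report.json")
    return report


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, state: dict, outdir: Path,
                    seeds: dict) -> list[str]:
    if config.synthetic:
        design = config.design
        if design is None:
            design = default_design(seed=config.seed)
        table, meta, tax, truth = generate_table(design)
        _write_json(truth, outdir / "truth.json")
        outputs = ["otu_table.tsv", "metadata.tsv", "taxonomy.tsv", "truth.json"]
    else:
        table = read_otu_table(config.otu_table_path)
        meta = read_sample_metadata(config.metadata_path)
        tax = read_taxonomy(config.taxonomy_path)
        truth = None
        outputs = ["otu_table.tsv", "metadata.tsv", "taxonomy.tsv"]
    meta.check_covers(table.sample_ids)
    write_otu_table(table, outdir / "otu_table.tsv")
    write_sample_metadata(meta, outdir / "metadata.tsv")
    write_taxonomy(tax, outdir / "taxonomy.tsv")
    state.update(table=table, meta=meta, tax=tax, truth=truth,
                 rel=to_relative_abundance(table))
    return outputs


def _stage_alpha(config: RunConfig, state: dict, outdir: Path,
                 seeds: dict) -> list[str]:
    alpha = alpha_table(state["table"])
    alpha.to_csv(outdir / "alpha.tsv", sep="\t", index=False)
    agg = aggregate_by_rank(state["rel"], state["tax"], "phylum",
                            special_rules=True)
    summary = group_abundance_summary(agg, state["meta"])
    summary.to_csv(outdir / "group_summary.tsv", sep="\t", index=False)
    return ["alpha.tsv", "group_summary.tsv"]


def _stage_beta(config: RunConfig, state: dict, outdir: Path,
                seeds: dict) -> list[str]:
    rel, meta = state["rel"], state["meta"]
    dm = bray_curtis(rel)
    dm.write(outdir / "distance.tsv")
    state["dm"] = dm
    groups = meta.group_labels(dm.sample_ids)
    rows = []

    res_host = permanova(dm, [meta.host_of(s) for s in dm.sample_ids],
                         m=config.permutations, seed=seeds["permanova"],
                         factor="host")
    rows.append(res_host)
    # per-host, across locations (the paper's one-way tests)
    for host in ("Galaxea", "Montipora"):
        keep = [s for s in dm.sample_ids
                if meta.host_of(s) == host]
        if len(set(meta.group_labels(keep))) >= 2:
            sub = dm.submatrix(keep)
            rows.append(permanova(
                sub, [g.split("-")[0] for g in meta.group_labels(keep)],
                m=config.permutations, seed=seeds["permanova"],
                factor=f"location|{host}"))
    if config.run_pairwise:
        rows.extend(pairwise_permanova(dm, groups, m=config.permutations,
                                       seed=seeds["pairwise"]))
    import pandas as pd
    perm_frame = pd.DataFrame([{
        "factor": r.factor, "pseudo_F": r.pseudo_F, "p_value": r.p_value,
        "n_permutations": r.n_permutations,
        "groups": ";".join(f"{g}:{n}" for g, n in r.groups.items()),
    } for r in rows])
    perm_frame.to_csv(outdir / "permanova.tsv", sep="\t", index=False)
    state["permanova"] = rows

    ord_res = nmds(dm, dims=2, n_restarts=config.nmds_restarts,
                   seed=seeds["nmds"])
    coords = ord_res.to_frame()
    coords.insert(0, "group", groups)
    coords.to_csv(outdir / "nmds.tsv", sep="\t")
    _write_json({"stress": ord_res.stress, "converged": ord_res.converged,
                 "n_restarts": ord_res.n_restarts, "seed": ord_res.seed},
                outdir / "nmds_stats.json")
    state["nmds"] = ord_res

    tree = upgma(dm)
    (outdir / "dendrogram.nwk").write_text(tree.newick + "\n")
    return ["distance.tsv", "permanova.tsv", "nmds.tsv", "nmds_stats.json",
            "dendrogram.nwk"]


def _stage_network(config: RunConfig, state: dict, outdir: Path,
                   seeds: dict) -> list[str]:
    rel, meta, tax = state["rel"], state["meta"], state["tax"]
    outputs: list[str] = []
    state["networks"] = {}
    state["topologies"] = {}
    state["retained"] = {}
    for host in ("Galaxea", "Montipora"):
        scope = [s for s in rel.sample_ids if meta.host_of(s) == host]
        if not scope:
            continue
        retained = filter_low_abundance(rel, config.filter_threshold, scope)
        state["retained"][host] = retained
        sub = rel.select_otus(retained).loc[:, scope]
        corr = spearman_all_pairs(sub)
        net = build_network(corr, rho_min=config.rho_min, p_max=config.p_max,
                            host=host, tax=tax)
        topo = topology(net, community_seed=seeds["community"])
        state["networks"][host] = net
        state["topologies"][host] = topo

        tag = host.lower()
        edge_list_frame(net).to_csv(outdir / f"edges_{tag}.tsv", sep="\t",
                                    index=False)
        node_frame(net, topo.communities).to_csv(outdir / f"nodes_{tag}.tsv",
                                                 sep="\t", index=False)
        write_graphml(net, outdir / f"network_{tag}.graphml")
        topo_dict = topo.to_dict()
        topo_dict["n_retained_otus"] = len(retained)
        if config.run_nonrandomness:
            null = nonrandomness_test(sub, rho_min=config.rho_min,
                                      p_max=config.p_max,
                                      n_reps=config.nonrandom_reps,
                                      seed=seeds["nonrandom"])
            topo_dict["nonrandomness"] = dataclasses.asdict(null)
        _write_json(topo_dict, outdir / f"topology_{tag}.json")
        outputs += [f"edges_{tag}.tsv", f"nodes_{tag}.tsv",
                    f"network_{tag}.graphml", f"topology_{tag}.json"]
    return outputs


def _stage_compare(config: RunConfig, state: dict, outdir: Path,
                   seeds: dict) -> list[str]:
    nets = state.get("networks", {})
    if len(nets) < 2:
        raise ValueError("network comparison needs both host networks")
    rel, meta, tax = state["rel"], state["meta"], state["tax"]
    a, b = nets["Galaxea"], nets["Montipora"]
    report = shared_nodes(a, b, tax)
    _write_json(report.to_dict(), outdir / "shared_report.json")

    import pandas as pd
    rows = []
    for name, breakdown in (("Galaxea", report.breakdown_a),
                            ("Montipora", report.breakdown_b),
                            ("shared", report.breakdown_shared)):
        for taxon, count in breakdown.items():
            rows.append({"set": name, "taxon": taxon, "count": count})
    pd.DataFrame(rows).to_csv(outdir / "breakdown.tsv", sep="\t", index=False)

    union = sorted(set(a.nodes) | set(b.nodes))
    profiles = classify_profiles(rel, meta, union, **config.profile_params)
    profile_frame(profiles).to_csv(outdir / "profiles.tsv", sep="\t",
                                   index=False)
    heatmap_matrix(rel, union).to_csv(outdir / "heatmap_matrix.tsv", sep="\t",
                                      na_rep="ND")
    state["shared_report"] = report
    state["profiles"] = profiles
    return ["shared_report.json", "breakdown.tsv", "profiles.tsv",
            "heatmap_matrix.tsv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "alpha": _stage_alpha,
    "beta": _stage_beta,
    "network": _stage_network,
    "compare": _stage_compare,
}
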