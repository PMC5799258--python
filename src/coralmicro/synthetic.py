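"""Synthetic OTU-table generator with planted structure.

Emulates a two-genus coral microbiome survey: hosts Galaxea and Montipora
sampled at up to four locations each with ~6 biological replicate colonies,
plus replicated seawater references, at roughly 10,000 reads per sample.
Log-abundances follow an additive latent model

    log a_is = baseline_i + host_i(h(s)) + loc_i(l(s)) + sum_g lambda_g f_gs + eps_is,

relative abundances are the softmax over OTUs, and counts are drawn
multinomially at a Poisson read depth.  "Guilds" are sets of OTUs loading on
a shared latent factor f_gs, which plants positive pairwise rank
correlations — the ground truth against which co-occurrence network recovery
is scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import (OtuTable, RelAbundanceTable, SampleMetadata,
                        TaxonomyRecord, to_relative_abundance)

HOST_ABBR = {"Galaxea": "Ga", "Montipora": "Mo", "Seawater": "SW"}

# Loading inflation compensating rank-correlation attenuation from the
# location-block and counting layers; fixed by Monte-Carlo calibration over
# 200 replicate simulations at 40 samples (see docs/methods.md).  The
# generator caps the factor contribution at the residual budget, so the
# inflated loading never increases a member's marginal variance.
LOADING_INFLATION = 1.1

_SPECIES = {
    ("Montipora", "LI"): "M. venosa",
    ("Montipora", "CB"): "M. peltiformis",
    ("Montipora", "LHT"): "M. monasteriata",
    ("Montipora", "SB"): "M. monasteriata",
}

# (domain, phylum, class, [genera]) pool with sampling weights roughly
# matching a coral 16S survey: Proteobacteria dominate, Archaea are rare.
_TAXON_POOL = [
    (0.26, ("Bacteria", "Proteobacteria", "Alphaproteobacteria",
            ["Ruegeria", "Roseibium", "Pelagibius", "Brevundimonas", "Hoeflea",
             "Loktanella", "Phaeobacter", "Roseovarius", "Filomicrobium",
             "Methyloceanibacter"])),
    (0.23, ("Bacteria", "Proteobacteria", "Gammaproteobacteria",
            ["Endozoicomonas", "Acinetobacter", "Thalassomonas", "Vibrio",
             "Shewanella", "Thioalkalivibrio", "Thioprofundum", "Escherichia"])),
    (0.06, ("Bacteria", "Proteobacteria", "Deltaproteobacteria",
            ["Desulfovibrio", "Bdellovibrio"])),
    (0.04, ("Bacteria", "Proteobacteria", "Betaproteobacteria",
            ["Methylophilus", "Burkholderia"])),
    (0.12, ("Bacteria", "Bacteroidetes", "Flavobacteriia",
            ["Tenacibaculum", "Winogradskyella"])),
    (0.08, ("Bacteria", "Cyanobacteria", "Cyanophyceae",
            ["Synechococcus", "Prochlorococcus"])),
    (0.06, ("Bacteria", "Firmicutes", "Bacilli", ["Bacillus", "Staphylococcus"])),
    (0.06, ("Bacteria", "Actinobacteria", "Actinobacteria",
            ["Propionibacterium", "Mycobacterium"])),
    (0.04, ("Archaea", "Thaumarchaeota", "Nitrososphaeria", ["Nitrosopumilus"])),
    (0.02, ("Archaea", "Euryarchaeota", "Thermoplasmata", ["Marine_group_II"])),
    (0.02, ("Bacteria", "Nitrospirae", "Nitrospira", ["Nitrospira"])),
    (0.02, ("Bacteria", "Chloroflexi", "Anaerolineae", ["Anaerolinea"])),
    (0.02, ("Bacteria", "Fusobacteria", "Fusobacteriia", ["Fusobacterium"])),
    (0.07, ("Bacteria", "Planctomycetes", "Planctomycetia", ["Rhodopirellula"])),
]


@dataclass
class GuildSpec:
    """A set of OTUs sharing one latent factor (a planted co-occurring guild)."""

    member_otu_ids: list[str]
    loading: float  # lambda, factor loading on the log scale
    factor_sd: float = 1.0
    target_hosts: tuple[str, ...] = ("Galaxea", "Montipora")
    baseline_shift: float = 3.0  # planted among the abundant fraction

    def __post_init__(self) -> None:
        if len(self.member_otu_ids) < 3:
            raise ValueError("a guild needs at least 3 member OTUs")
        if not (math.isfinite(self.loading) and self.loading >= 0):
            raise ValueError(f"invalid loading: {self.loading}")
        if not (math.isfinite(self.factor_sd) and self.factor_sd >= 0):
            raise ValueError(f"invalid factor_sd: {self.factor_sd}")


@dataclass
class GroupSpec:
    """One host-by-location sampling group.

    ``n_technical`` extra technical replicates re-observe the last
    biological replicate's latent state (re-drawn sequencing depth and
    multinomial only).
    """

    host: str
    location: str
    n_biological: int
    n_technical: int = 0

    def __post_init__(self) -> None:
        if self.host not in HOST_ABBR:
            raise ValueError(f"unknown host: {self.host!r}")
        if self.n_biological < 1:
            raise ValueError("each group needs at least one biological sample")
        if self.n_technical < 0:
            raise ValueError("n_technical must be >= 0")


def default_groups() -> list[GroupSpec]:
    """The survey design emulated by default: 24 Galaxea + 22 Montipora
    (incl. 2 technical replicates) + 13 seawater samples = 59."""
    return [
        GroupSpec("Galaxea", "CB", 6), GroupSpec("Galaxea", "LHT", 6),
        GroupSpec("Galaxea", "SB", 6), GroupSpec("Galaxea", "DI", 6),
        GroupSpec("Montipora", "LI", 6), GroupSpec("Montipora", "CB", 5),
        GroupSpec("Montipora", "LHT", 4, n_technical=2),
        GroupSpec("Montipora", "SB", 5),
        GroupSpec("Seawater", "LI", 1, n_technical=1),
        GroupSpec("Seawater", "CB", 1, n_technical=1),
        GroupSpec("Seawater", "LHT", 1, n_technical=2),
        GroupSpec("Seawater", "SB", 1, n_technical=2),
        GroupSpec("Seawater", "DI", 1, n_technical=2),
    ]


def guild_loading_for_spearman(target_rho: float, noise_sd: float = 1.0,
                               factor_sd: float = 1.0,
                               inflation: float = LOADING_INFLATION) -> float:
    """Loading lambda so two guild members reach roughly the target pairwise
    Spearman correlation.

    The generator is variance-preserving: a member's residual noise is
    scaled down so that factor plus residual carry the same marginal
    variance noise_sd^2 as a non-member (the factor replaces variance, it
    does not add on top — planting correlation must not inflate the
    composition).  The latent Pearson correlation between two members is
    then r = lambda^2 fsd^2 / noise_sd^2, and for a bivariate normal the
    Spearman is rho_s = (6/pi) asin(r/2).  Location-block noise and
    multinomial counting attenuate the realized rank correlation,
    compensated by a fixed Monte-Carlo-calibrated inflation factor; the
    generator caps lambda*fsd at noise_sd.
    """
    if not 0 < target_rho < 1:
        raise ValueError("target_rho must be in (0, 1)")
    r = 2.0 * math.sin(math.pi * target_rho / 6.0)
    lam = (noise_sd / factor_sd) * math.sqrt(r)
    return lam * inflation


def otu_name(i: int) -> str:
    return f"OTU_{i + 1:04d}"


def default_guilds(n_otus: int, n_per_host: int = 2, size: int = 8,
                   target_rho: float = 0.8, noise_sd: float = 1.0) -> list[GuildSpec]:
    """Disjoint guilds of ``size`` OTUs per coral host, loading calibrated
    for the target within-guild Spearman correlation."""
    lam = guild_loading_for_spearman(target_rho, noise_sd=noise_sd)
    guilds: list[GuildSpec] = []
    nxt = 0
    for host in ("Galaxea", "Montipora"):
        for _ in range(n_per_host):
            members = [otu_name(i) for i in range(nxt, nxt + size)]
            if nxt + size > n_otus:
                raise ValueError("not enough OTUs for the requested guilds")
            guilds.append(GuildSpec(members, loading=lam, target_hosts=(host,)))
            nxt += size
    return guilds


@dataclass
class SyntheticDesign:
    n_otus: int = 300
    groups: list[GroupSpec] = field(default_factory=default_groups)
    depth_mean: float = 10_000.0
    guilds: list[GuildSpec] = field(default_factory=list)
    host_effect_sd: float = 1.5
    location_effect_sd: float = 0.3
    noise_sd: float = 1.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus < 1:
            raise ValueError("n_otus must be positive")
        for sd in (self.host_effect_sd, self.location_effect_sd,
                   self.noise_sd, self.baseline_sd):
            if sd < 0 or not math.isfinite(sd):
                raise ValueError(f"standard deviations must be finite and >= 0: {sd}")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        valid = {otu_name(i) for i in range(self.n_otus)}
        seen: set[str] = set()
        for g in self.guilds:
            for m in g.member_otu_ids:
                if m not in valid:
                    raise ValueError(f"guild member not in design: {m!r}")
                if m in seen:
                    raise ValueError(f"OTU in two guilds: {m!r}")
                seen.add(m)

    @property
    def otu_ids(self) -> list[str]:
        return [otu_name(i) for i in range(self.n_otus)]

    @property
    def hosts(self) -> list[str]:
        return sorted({g.host for g in self.groups})

    @property
    def locations(self) -> list[str]:
        out: list[str] = []
        for g in self.groups:
            if g.location not in out:
                out.append(g.location)
        return out


def default_design(seed: int = 0) -> SyntheticDesign:
    """The default study: the full two-host, five-location design with two
    calibrated guilds planted per coral host."""
    base = SyntheticDesign(seed=seed)
    return SyntheticDesign(
        seed=seed,
        guilds=default_guilds(base.n_otus, noise_sd=base.noise_sd))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def generate_table(design: SyntheticDesign
                   ) -> tuple[OtuTable, SampleMetadata, dict[str, TaxonomyRecord], dict]:
    """Draw one synthetic study: counts, metadata, taxonomy, and ground truth.

    Identical designs (including seed) give identical outputs.  The truth
    record stores the seed, guild memberships, host/location effect values,
    and the per-sample latent guild factors.
    """
    ss = np.random.SeedSequence(design.seed)
    rng_struct, rng_tax, rng_sample = [np.random.default_rng(c) for c in ss.spawn(3)]

    otu_ids = design.otu_ids
    hosts = design.hosts
    locations = design.locations
    n = design.n_otus

    baseline = rng_struct.normal(0.0, design.baseline_sd, size=n)
    member_idx_by_guild: dict[str, np.ndarray] = {}
    for gi, guild in enumerate(design.guilds):
        idx = np.array([otu_ids.index(m) for m in guild.member_otu_ids])
        member_idx_by_guild[f"guild_{gi + 1}"] = idx
        baseline[idx] += guild.baseline_shift
    host_eff = {h: rng_struct.normal(0.0, design.host_effect_sd, size=n) for h in hosts}
    loc_eff = {l: rng_struct.normal(0.0, design.location_effect_sd, size=n)
               for l in locations}

    taxonomy = _synthesize_taxonomy(otu_ids, rng_tax)

    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    factor_log: dict[str, dict[str, float]] = {}

    # factor-variance budget: for samples where a guild is active, its
    # members' residual noise is scaled down so factor + residual carry the
    # same marginal variance as any other OTU (the loading is capped at the
    # residual budget)
    lam_eff: dict[str, float] = {}
    for gi, gid in enumerate(member_idx_by_guild):
        guild = design.guilds[gi]
        lam = guild.loading
        if guild.factor_sd > 0 and design.noise_sd > 0:
            lam = min(lam, design.noise_sd / guild.factor_sd)
        lam_eff[gid] = lam

    for group in design.groups:
        abbr = HOST_ABBR[group.host]
        resid_sd = np.full(n, design.noise_sd)
        for gi, (gid, idx) in enumerate(member_idx_by_guild.items()):
            guild = design.guilds[gi]
            if group.host in guild.target_hosts:
                contrib = lam_eff[gid] * guild.factor_sd
                resid_sd[idx] = math.sqrt(max(design.noise_sd ** 2
                                              - contrib ** 2, 0.0))
        for b in range(1, group.n_biological + 1):
            base_id = f"{group.location}-{abbr}{b}"
            factors = {gid: rng_sample.normal(0.0, design.guilds[gi].factor_sd)
                       for gi, gid in enumerate(member_idx_by_guild)}
            logit = (baseline + host_eff[group.host] + loc_eff[group.location]
                     + rng_sample.normal(0.0, 1.0, size=n) * resid_sd)
            for gi, (gid, idx) in enumerate(member_idx_by_guild.items()):
                guild = design.guilds[gi]
                if group.host in guild.target_hosts:
                    logit[idx] += lam_eff[gid] * factors[gid]
            p = _softmax(logit)
            replicate_ids = [base_id]
            if b == group.n_biological:  # technical reps re-observe the last colony
                replicate_ids += [f"{base_id}-TR{k}" for k in range(2, group.n_technical + 2)]
            for rep_i, sid in enumerate(replicate_ids):
                depth = max(1, rng_sample.poisson(design.depth_mean))
                counts = rng_sample.multinomial(depth, p)
                columns.append(counts)
                sample_ids.append(sid)
                meta_rows.append({
                    "sample_id": sid,
                    "host": group.host,
                    "species_label": _SPECIES.get((group.host, group.location),
                                                  "G. fascicularis"
                                                  if group.host == "Galaxea"
                                                  else "seawater"),
                    "location": group.location,
                    "replicate_role": "biological" if rep_i == 0 else "technical",
                })
            factor_log[base_id] = factors

    table = OtuTable(otu_ids, sample_ids, np.column_stack(columns))
    meta = SampleMetadata(pd.DataFrame(meta_rows))
    truth = {
        "seed": design.seed,
        "guilds": {gid: [otu_ids[i] for i in idx]
                   for gid, idx in member_idx_by_guild.items()},
        "guild_target_hosts": {f"guild_{gi + 1}": list(g.target_hosts)
                               for gi, g in enumerate(design.guilds)},
        "host_effect": {h: host_eff[h].tolist() for h in hosts},
        "location_effect": {l: loc_eff[l].tolist() for l in locations},
        "baseline": baseline.tolist(),
        "guild_factors": factor_log,
    }
    return table, meta, taxonomy, truth


def truth_guild_partition(truth: dict) -> dict[str, str | None]:
    """Planted OTU -> guild-id mapping (None for OTUs outside every guild)."""
    assignment: dict[str, str | None] = {}
    for gid, members in truth["guilds"].items():
        for m in members:
            if assignment.get(m) is not None:
                raise ValueError(f"OTU {m!r} planted in two guilds")
            assignment[m] = gid
    n = len(truth["baseline"])
    for i in range(n):
        assignment.setdefault(otu_name(i), None)
    return assignment


def generate_relative(design: SyntheticDesign
                      ) -> tuple[RelAbundanceTable, SampleMetadata,
                                 dict[str, TaxonomyRecord], dict]:
    """Convenience wrapper: generated counts converted to relative abundances."""
    table, meta, tax, truth = generate_table(design)
    return to_relative_abundance(table), meta, tax, truth


def _synthesize_taxonomy(otu_ids: list[str],
                         rng: np.random.Generator) -> dict[str, TaxonomyRecord]:
    weights = np.array([w for w, _ in _TAXON_POOL])
    weights = weights / weights.sum()
    records: dict[str, TaxonomyRecord] = {}
    for otu_id in otu_ids:
        k = rng.choice(len(_TAXON_POOL), p=weights)
        domain, phylum, klass, genera = _TAXON_POOL[k][1]
        genus = genera[rng.integers(len(genera))]
        similarity = float(rng.uniform(88.0, 100.0))
        ambiguous = bool(rng.random() < 0.15)
        records[otu_id] = TaxonomyRecord(
            otu_id=otu_id,
            lineage={"domain": domain, "phylum": phylum, "class": klass,
                     "genus": genus},
            best_hit_similarity=similarity,
            genus_match_ambiguous=ambiguous)
    return records
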