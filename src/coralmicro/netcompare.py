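"""Cross-host network comparison: shared co-occurring species, taxon
breakdowns, and abundance-profile classification against seawater."""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .tables_io import RelAbundanceTable, SampleMetadata, TaxonomyRecord

PROFILE_GROUPS = ("seawater_similar", "coral_enriched", "location_variable")


def taxon_breakdown(nodes, tax: dict[str, TaxonomyRecord]) -> OrderedDict:
    """Node counts per display taxon, ordered by decreasing count then name.

    Display convention: Proteobacteria are reported at class level
    (Alpha/Beta/Gamma/Delta...), everything else — including archaeal
    phyla — at phylum level.
    """
    counts: dict[str, int] = {}
    for node in nodes:
        rec = tax.get(node)
        if rec is None:
            label = "Unclassified"
        elif rec.rank_label("phylum") == "Proteobacteria":
            label = rec.rank_label("class")
        else:
            label = rec.rank_label("phylum")
        counts[label] = counts.get(label, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return OrderedDict(ordered)


@dataclass
class SharedNodeReport:
    shared_ids: list[str]
    only_a_ids: list[str]
    only_b_ids: list[str]
    n_a: int
    n_b: int
    n_shared: int
    n_union: int
    breakdown_a: OrderedDict = field(default_factory=OrderedDict)
    breakdown_b: OrderedDict = field(default_factory=OrderedDict)
    breakdown_shared: OrderedDict = field(default_factory=OrderedDict)

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a, "n_b": self.n_b, "n_shared": self.n_shared,
            "n_union": self.n_union,
            "shared_ids": self.shared_ids,
            "only_a_ids": self.only_a_ids, "only_b_ids": self.only_b_ids,
            "breakdown_a": dict(self.breakdown_a),
            "breakdown_b": dict(self.breakdown_b),
            "breakdown_shared": dict(self.breakdown_shared),
        }


def shared_nodes(a: nx.Graph, b: nx.Graph,
                 tax: dict[str, TaxonomyRecord] | None = None) -> SharedNodeReport:
    """Set algebra over two networks' node sets (identity = OTU id), with a
    per-taxon breakdown of each set; |union| = |A| + |B| - |shared|."""
    set_a, set_b = set(a.nodes), set(b.nodes)
    if not set_a or not set_b:
        raise ValueError("both networks must be non-empty")
    shared = sorted(set_a & set_b)
    only_a = sorted(set_a - set_b)
    only_b = sorted(set_b - set_a)
    tax = tax or {}
    return SharedNodeReport(
        shared_ids=shared, only_a_ids=only_a, only_b_ids=only_b,
        n_a=len(set_a), n_b=len(set_b), n_shared=len(shared),
        n_union=len(set_a | set_b),
        breakdown_a=taxon_breakdown(sorted(set_a), tax),
        breakdown_b=taxon_breakdown(sorted(set_b), tax),
        breakdown_shared=taxon_breakdown(shared, tax))


# ---------------------------------------------------------------------------
# Abundance-profile classification
# ---------------------------------------------------------------------------

@dataclass
class ProfileClass:
    otu_id: str
    group: str  # one of PROFILE_GROUPS
    coral_mean: float
    seawater_mean: float
    location_means: dict[str, float]
    location_cv: float
    fallback: bool = False  # no rule matched cleanly; nearest rule assigned


def classify_profiles(r: RelAbundanceTable, meta: SampleMetadata,
                      nodes, enrichment_factor: float = 10.0,
                      similarity_factor: float = 3.0,
                      location_cv_threshold: float = 1.0) -> list[ProfileClass]:
    """Classify each network OTU's abundance profile into one of three
    groups, by precedence:

    1. ``location_variable`` — coefficient of variation of per-location
       coral means exceeds ``location_cv_threshold``;
    2. ``coral_enriched`` — mean coral abundance at least
       ``enrichment_factor`` times the mean seawater abundance;
    3. ``seawater_similar`` — coral and seawater means within a factor of
       ``similarity_factor`` of each other.

    OTUs matching no rule are assigned to the nearest rule's group with a
    fallback flag.  The split an actual survey produces depends on these
    thresholds; they are configuration, not biology.
    """
    meta.check_covers(r.sample_ids)
    sw_samples = [s for s in meta.samples_where(host="Seawater")
                  if s in r.sample_ids]
    if not sw_samples:
        raise ValueError("no seawater samples: profile classification undefined")
    coral_samples = [s for s in r.sample_ids if s not in set(sw_samples)]
    frame = r.to_frame()
    locations = sorted({meta.frame.loc[meta.frame.sample_id == s, "location"].iloc[0]
                        for s in coral_samples})
    loc_cols = {loc: [s for s in coral_samples
                      if s in set(meta.samples_where(location=loc))]
                for loc in locations}

    out: list[ProfileClass] = []
    for otu in nodes:
        row = frame.loc[otu]
        coral_mean = float(row[coral_samples].mean())
        sw_mean = float(row[sw_samples].mean())
        loc_means = {loc: float(row[cols].mean())
                     for loc, cols in loc_cols.items() if cols}
        lm = np.array(list(loc_means.values()))
        if lm.size >= 2 and lm.mean() > 0:
            cv = float(lm.std(ddof=1) / lm.mean())
        else:
            cv = 0.0

        fallback = False
        if cv > location_cv_threshold:
            group = "location_variable"
        elif sw_mean > 0 and coral_mean >= enrichment_factor * sw_mean:
            group = "coral_enriched"
        elif sw_mean == 0 and coral_mean > 0:
            group = "coral_enriched"
        elif coral_mean == 0 and sw_mean == 0:
            group = "seawater_similar"
        elif max(coral_mean, sw_mean) / max(min(coral_mean, sw_mean),
                                            np.finfo(float).tiny) \
                <= similarity_factor:
            group = "seawater_similar"
        else:
            # intermediate ratio, or seawater-dominated: nearest rule
            group = "coral_enriched" if coral_mean > sw_mean else "seawater_similar"
            fallback = True
        out.append(ProfileClass(otu_id=otu, group=group, coral_mean=coral_mean,
                                seawater_mean=sw_mean, location_means=loc_means,
                                location_cv=cv, fallback=fallback))
    return out


def profile_frame(profiles: list[ProfileClass]) -> pd.DataFrame:
    return pd.DataFrame([{
        "otu_id": p.otu_id, "group": p.group, "coral_mean": p.coral_mean,
        "seawater_mean": p.seawater_mean, "location_cv": p.location_cv,
        "fallback": p.fallback,
    } for p in profiles])


def heatmap_matrix(r: RelAbundanceTable, nodes) -> pd.DataFrame:
    """log10 percent relative abundance of the given OTUs for heat-map
    rendering: value -2 is 0.01%, -1 is 0.1%, 0 is 1%, 1 is 10%;
    non-detections (zero counts) are NaN and rendered as 'ND'."""
    sub = r.select_otus(list(nodes)).to_numpy()
    with np.errstate(divide="ignore"):
        logged = np.where(sub > 0, np.log10(sub * 100.0), np.nan)
    return pd.DataFrame(logged, index=list(nodes), columns=r.sample_ids)
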