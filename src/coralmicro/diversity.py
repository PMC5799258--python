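"""Alpha diversity (observed species, Shannon) and group abundance summaries."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .tables_io import OtuTable, RelAbundanceTable, SampleMetadata


def observed_species(counts: np.ndarray) -> int:
    """Number of OTUs with a strictly positive count in one sample."""
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    return int((counts > 0).sum())


def shannon(counts: np.ndarray, base: float = math.e) -> float:
    """Shannon index H = -sum p_i log_base p_i over OTUs present in the sample.

    The log base is configurable (natural log by default, base 2 common in
    QIIME-era outputs); outputs should always be labelled with the base used.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero count vector has no Shannon index")
    p = counts[counts > 0] / total
    return float(-(p * (np.log(p) / math.log(base))).sum())


def alpha_table(t: OtuTable, base: float = math.e) -> pd.DataFrame:
    """Per-sample alpha-diversity summary: clean-tag count, observed
    species, Shannon index."""
    rows = []
    for j, sid in enumerate(t.sample_ids):
        col = t.counts[:, j]
        rows.append({
            "sample_id": sid,
            "n_tags": int(col.sum()),
            "observed_species": observed_species(col),
            "shannon": shannon(col, base=base),
        })
    frame = pd.DataFrame(rows)
    frame.attrs["shannon_log_base"] = base
    return frame


def group_abundance_summary(agg: RelAbundanceTable,
                            meta: SampleMetadata) -> pd.DataFrame:
    """Five-number summary (min/Q1/median/Q3/max) of each taxon's relative
    abundance within each host-by-location group.

    Quartiles use linear interpolation between order statistics.
    """
    meta.check_covers(agg.sample_ids)
    labels = meta.group_labels(agg.sample_ids)
    frame = agg.to_frame()
    rows = []
    for group in sorted(set(labels)):
        cols = [s for s, lab in zip(agg.sample_ids, labels) if lab == group]
        if not cols:
            raise ValueError(f"group {group!r} has no samples")
        sub = frame.loc[:, cols].to_numpy()
        q = np.percentile(sub, [0, 25, 50, 75, 100], axis=1, method="linear")
        for i, taxon in enumerate(agg.otu_ids):
            rows.append({"taxon": taxon, "group": group, "n": len(cols),
                         "min": q[0, i], "q1": q[1, i], "median": q[2, i],
                         "q3": q[3, i], "max": q[4, i]})
    return pd.DataFrame(rows)
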