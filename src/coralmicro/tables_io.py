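"""OTU tables, sample metadata, and taxonomy annotations.

The root objects of the pipeline: an integer OTU-by-sample count table
(QIIME-classic tab-separated layout), a per-sample metadata table (host,
species, location, replicate role), and per-OTU taxonomy records with a
best-hit similarity / ambiguity annotation rule.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

# QIIME-style single-letter rank prefixes ("k__" is the domain/kingdom slot)
_PREFIX_TO_RANK = {"k": "domain", "d": "domain", "p": "phylum", "c": "class",
                   "o": "order", "f": "family", "g": "genus"}

UNCLASSIFIED = "Unclassified"

HOSTS = ("Galaxea", "Montipora", "Seawater")
REPLICATE_ROLES = ("biological", "technical")

METADATA_COLUMNS = ("sample_id", "host", "species_label", "location", "replicate_role")


class TableValidationError(ValueError):
    """Raised when an OTU table or companion table violates its invariants."""


# ---------------------------------------------------------------------------
# OTU count table
# ---------------------------------------------------------------------------

@dataclass
class OtuTable:
    """Integer count matrix, rows = OTUs, columns = samples."""

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_otus, n_samples), dtype int64

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.otu_ids = [str(i) for i in self.otu_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        validate_otu_table(self)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: list[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(list(self.otu_ids), list(sample_ids), self.counts[:, idx].copy())


@dataclass
class RelAbundanceTable:
    """Per-sample relative abundances on the same axes as an OtuTable."""

    otu_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # fractions in [0, 1]; columns sum to 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        sums = self.values.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise TableValidationError("relative-abundance columns must sum to 1")
        if (self.values < 0).any() or (self.values > 1).any():
            raise TableValidationError("relative abundances must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.otu_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: list[str]) -> "RelAbundanceTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return RelAbundanceTable(list(self.otu_ids), list(sample_ids),
                                 self.values[:, idx].copy())

    def select_otus(self, otu_ids: list[str]) -> pd.DataFrame:
        """Sub-matrix for the given OTUs (rows), keeping column sums as-is.

        Returns a plain DataFrame because a row subset is no longer a
        composition (columns do not sum to 1).
        """
        frame = self.to_frame()
        return frame.loc[list(otu_ids)]


def validate_otu_table(t: OtuTable) -> None:
    for name, ids in (("OTU", t.otu_ids), ("sample", t.sample_ids)):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise TableValidationError(f"duplicate {name} id: {i!r}")
            seen.add(i)
    if t.counts.ndim != 2 or t.counts.shape != (len(t.otu_ids), len(t.sample_ids)):
        raise TableValidationError(
            f"counts shape {t.counts.shape} does not match ids "
            f"({len(t.otu_ids)} OTUs x {len(t.sample_ids)} samples)")
    if not np.issubdtype(t.counts.dtype, np.integer):
        if np.issubdtype(t.counts.dtype, np.floating) and np.all(t.counts == np.floor(t.counts)):
            t.counts = t.counts.astype(np.int64)
        else:
            raise TableValidationError("counts must be integers")
    if (t.counts < 0).any():
        r, c = np.argwhere(t.counts < 0)[0]
        raise TableValidationError(
            f"negative count at OTU {t.otu_ids[r]!r}, sample {t.sample_ids[c]!r}")
    col_sums = t.counts.sum(axis=0)
    if (col_sums == 0).any():
        empty = [s for s, tot in zip(t.sample_ids, col_sums) if tot == 0]
        raise TableValidationError(f"empty sample column(s): {', '.join(empty)}")


def read_otu_table(path: str | Path, format: str = "qiime-classic") -> OtuTable:
    """Read a tab-separated OTU table.

    The header row holds sample ids; the first column holds OTU ids.  A
    leading ``#OTU ID`` header cell and a trailing ``taxonomy``/``Taxonomy``
    column are tolerated (the taxonomy column is split off and ignored here;
    use :func:`read_taxonomy` for lineage data).
    """
    if format not in ("qiime-classic", "tsv"):
        raise ValueError(f"unknown OTU-table dialect: {format!r}")
    path = Path(path)
    text = path.read_text()
    # QIIME classic sometimes carries a "# Constructed from biom file" banner
    lines = [ln for ln in text.splitlines() if not ln.startswith("# ")]
    frame = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", header=0,
                        index_col=0, dtype=str)
    if frame.columns.size and frame.columns[-1].strip().lower() == "taxonomy":
        frame = frame.iloc[:, :-1]
    otu_ids = [str(i) for i in frame.index]
    sample_ids = [str(c) for c in frame.columns]
    counts = np.empty(frame.shape, dtype=np.int64)
    for j, col in enumerate(frame.columns):
        for i, raw in enumerate(frame[col].to_numpy()):
            try:
                val = float(raw)
            except (TypeError, ValueError):
                raise TableValidationError(
                    f"non-numeric cell at OTU {otu_ids[i]!r}, sample {sample_ids[j]!r}: {raw!r}")
            if val < 0 or val != int(val):
                raise TableValidationError(
                    f"invalid count at OTU {otu_ids[i]!r}, sample {sample_ids[j]!r}: {raw!r}")
            counts[i, j] = int(val)
    return OtuTable(otu_ids, sample_ids, counts)


def write_otu_table(t: OtuTable, path: str | Path) -> None:
    """Write in QIIME-classic layout; round-trips losslessly with read_otu_table."""
    frame = t.to_frame()
    frame.index.name = "#OTU ID"
    frame.to_csv(path, sep="\t")


def to_relative_abundance(t: OtuTable) -> RelAbundanceTable:
    totals = t.counts.sum(axis=0)
    if (totals == 0).any():
        empty = [s for s, tot in zip(t.sample_ids, totals) if tot == 0]
        raise TableValidationError(f"zero-total sample(s): {', '.join(empty)}")
    values = t.counts / totals[np.newaxis, :]
    return RelAbundanceTable(list(t.otu_ids), list(t.sample_ids), values)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleMetadata:
    """One row per sample: host, species label, location, replicate role."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.frame.columns]
        if missing:
            raise TableValidationError(f"metadata missing column(s): {', '.join(missing)}")
        self.frame = self.frame.loc[:, list(METADATA_COLUMNS)].astype(str)
        if self.frame["sample_id"].duplicated().any():
            dup = self.frame["sample_id"][self.frame["sample_id"].duplicated()].iloc[0]
            raise TableValidationError(f"duplicate sample_id in metadata: {dup!r}")
        bad_host = set(self.frame["host"]) - set(HOSTS)
        if bad_host:
            raise TableValidationError(f"unknown host value(s): {sorted(bad_host)}")
        bad_role = set(self.frame["replicate_role"]) - set(REPLICATE_ROLES)
        if bad_role:
            raise TableValidationError(f"unknown replicate_role value(s): {sorted(bad_role)}")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def check_covers(self, sample_ids: list[str]) -> None:
        missing = set(sample_ids) - set(self.sample_ids)
        if missing:
            raise TableValidationError(f"samples without metadata: {sorted(missing)}")

    def host_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["host"].iloc[0]

    def group_labels(self, sample_ids: list[str]) -> list[str]:
        """Deterministic host-by-location group label per sample, e.g. 'CB-Ga'."""
        abbr = {"Galaxea": "Ga", "Montipora": "Mo", "Seawater": "SW"}
        lookup = {r.sample_id: f"{r.location}-{abbr[r.host]}"
                  for r in self.frame.itertuples()}
        return [lookup[s] for s in sample_ids]

    def samples_where(self, host: str | None = None, location: str | None = None,
                      replicate_role: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.frame.index)
        if host is not None:
            mask &= self.frame["host"] == host
        if location is not None:
            mask &= self.frame["location"] == location
        if replicate_role is not None:
            mask &= self.frame["replicate_role"] == replicate_role
        return list(self.frame.loc[mask, "sample_id"])


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t", dtype=str))


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

@dataclass
class TaxonomyRecord:
    otu_id: str
    lineage: dict[str, str] = field(default_factory=dict)  # rank -> label
    best_hit_similarity: float | None = None  # percent identity of best hit
    genus_match_ambiguous: bool | None = None
    status: str = "unassessed"  # annotated | unknown | unassessed

    def __post_init__(self) -> None:
        for rank in RANKS:
            self.lineage.setdefault(rank, UNCLASSIFIED)
        if self.best_hit_similarity is not None and self.genus_match_ambiguous is not None:
            self.status = classify_annotation(self.best_hit_similarity,
                                              self.genus_match_ambiguous)

    def rank_label(self, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank: {rank!r}")
        return self.lineage.get(rank, UNCLASSIFIED) or UNCLASSIFIED


def classify_annotation(similarity: float, ambiguous: bool) -> str:
    """Annotation status: 'unknown' below 94% best-hit identity or on any
    ambiguous genus match, else 'annotated'."""
    if not 0 <= similarity <= 100:
        raise ValueError(f"similarity out of [0, 100]: {similarity}")
    return "unknown" if (similarity < 94 or ambiguous) else "annotated"


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse 'k__Bacteria;p__Proteobacteria;...' or plain 'Bacteria;Proteobacteria;...'.

    Missing or empty ranks map to 'Unclassified'.
    """
    out = {rank: UNCLASSIFIED for rank in RANKS}
    if not lineage or not lineage.strip():
        return out
    parts = [p.strip() for p in lineage.split(";")]
    prefixed = any(len(p) > 2 and p[1] == "_" and p[2] == "_" for p in parts if p)
    if prefixed:
        for part in parts:
            if len(part) >= 3 and part[1:3] == "__":
                rank = _PREFIX_TO_RANK.get(part[0].lower())
                label = part[3:].strip()
                if rank and label:
                    out[rank] = label
    else:
        for rank, label in zip(RANKS, parts):
            if label:
                out[rank] = label
    return out


def format_lineage(lineage: dict[str, str]) -> str:
    prefixes = {"domain": "k", "phylum": "p", "class": "c", "order": "o",
                "family": "f", "genus": "g"}
    parts = []
    for rank in RANKS:
        label = lineage.get(rank, UNCLASSIFIED)
        parts.append(f"{prefixes[rank]}__{'' if label == UNCLASSIFIED else label}")
    return ";".join(parts)


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"otu_id", "lineage"}
    if not required <= set(frame.columns):
        raise TableValidationError("taxonomy table needs columns otu_id, lineage")
    records: dict[str, TaxonomyRecord] = {}
    for row in frame.itertuples():
        sim = getattr(row, "best_hit_similarity", None)
        sim = float(sim) if sim not in (None, "", "nan") and not pd.isna(sim) else None
        amb = getattr(row, "genus_match_ambiguous", None)
        if amb is not None and not pd.isna(amb):
            amb = str(amb).strip().lower() in ("true", "1", "yes")
        else:
            amb = None
        if row.otu_id in records:
            raise TableValidationError(f"duplicate otu_id in taxonomy: {row.otu_id!r}")
        records[row.otu_id] = TaxonomyRecord(
            otu_id=row.otu_id, lineage=parse_lineage(row.lineage),
            best_hit_similarity=sim, genus_match_ambiguous=amb)
    return records


def write_taxonomy(tax: dict[str, TaxonomyRecord], path: str | Path) -> None:
    rows = []
    for otu_id, rec in tax.items():
        rows.append({
            "otu_id": otu_id,
            "lineage": format_lineage(rec.lineage),
            "best_hit_similarity": ("" if rec.best_hit_similarity is None
                                    else f"{rec.best_hit_similarity:.1f}"),
            "genus_match_ambiguous": ("" if rec.genus_match_ambiguous is None
                                      else str(rec.genus_match_ambiguous).lower()),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Aggregation and filtering
# ---------------------------------------------------------------------------

def aggregate_by_rank(r: RelAbundanceTable, tax: dict[str, TaxonomyRecord],
                      rank: str, special_rules: bool = False) -> RelAbundanceTable:
    """Sum OTU abundances into taxa at the given rank.

    With ``special_rules`` on, the conventional amplicon-survey reporting is
    applied: Proteobacteria are broken out at class level and all Archaea are
    pooled at domain level; everything else stays at the requested rank.
    Per-sample total mass is conserved (columns still sum to 1).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank: {rank!r}")
    labels = []
    for otu_id in r.otu_ids:
        rec = tax.get(otu_id)
        if rec is None:
            labels.append(UNCLASSIFIED)
            continue
        if special_rules:
            if rec.rank_label("domain") == "Archaea":
                labels.append("Archaea")
                continue
            if rec.rank_label("phylum") == "Proteobacteria":
                labels.append(rec.rank_label("class"))
                continue
        labels.append(rec.rank_label(rank))
    frame = r.to_frame()
    frame.index = pd.Index(labels, name=rank)
    agg = frame.groupby(level=0, sort=True).sum()
    return RelAbundanceTable(list(agg.index), list(r.sample_ids), agg.to_numpy())


def filter_low_abundance(r: RelAbundanceTable, threshold: float,
                         scope: list[str]) -> list[str]:
    """OTU ids whose mean relative abundance over ``scope`` samples is at
    least ``threshold`` (boundary retained); order follows the input table.

    ``scope`` is normally one host's coral samples only — the abundance
    filter is applied per host dataset before network construction.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1): {threshold}")
    if not scope:
        raise ValueError("empty sample scope")
    missing = set(scope) - set(r.sample_ids)
    if missing:
        raise ValueError(f"scope samples not in table: {sorted(missing)}")
    sub = r.to_frame().loc[:, list(scope)]
    means = sub.mean(axis=1)
    return [otu for otu in r.otu_ids if means[otu] >= threshold]
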