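"""OTU-cluster taxonomy handling: cluster filtering, identity-based rank
truncation, and aggregation of clusters to a chosen taxonomic rank.

An OTU cluster carries the lineage of its best database hit together with the
percent identity of that hit.  The identity caps how deep the lineage can be
trusted: a hit at 90% identity, for instance, supports the assignment only
down to family.  The default caps are the rank-specific identity minima of
94.5% (genus), 86.5% (family), 82.0% (order), 78.5% (class) and 75.0%
(phylum); comparisons are inclusive, so an identity exactly at a threshold
earns that rank.  Species is never assigned: genus is the deepest reported
rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .containers import CommunityTable, ValidationError

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

__all__ = [
    "RANKS",
    "TaxonomyRecord",
    "RankThresholds",
    "filter_clusters",
    "truncate_lineage",
    "aggregate_to_rank",
    "read_taxonomy_tsv",
    "write_taxonomy_tsv",
]


@dataclass(frozen=True)
class RankThresholds:
    """Minimum percent identity required to assign each rank.

    Must decrease strictly from genus up to phylum; domain is always assigned.
    """

    genus: float = 94.5
    family: float = 86.5
    order: float = 82.0
    class_: float = 78.5
    phylum: float = 75.0

    def __post_init__(self) -> None:
        seq = (self.genus, self.family, self.order, self.class_, self.phylum)
        if any(a <= b for a, b in zip(seq, seq[1:])):
            raise ValidationError(
                "rank thresholds must be strictly decreasing genus -> phylum"
            )

    def deepest_rank(self, identity: float) -> str:
        """Deepest rank whose threshold is <= identity (inclusive)."""
        if not 0.0 <= identity <= 100.0:
            raise ValidationError(f"identity {identity} outside [0, 100]")
        for rank, thr in (
            ("genus", self.genus),
            ("family", self.family),
            ("order", self.order),
            ("class", self.class_),
            ("phylum", self.phylum),
        ):
            if identity >= thr:
                return rank
        return "domain"


@dataclass
class TaxonomyRecord:
    """Best-hit lineage and percent identity for one OTU cluster."""

    cluster_id: str
    lineage: tuple = field(default_factory=tuple)  # up to 7 ranks, "" for empty
    identity: float = 100.0

    def __post_init__(self) -> None:
        lineage = tuple(self.lineage) + ("",) * (len(RANKS) - len(self.lineage))
        if len(lineage) > len(RANKS):
            raise ValidationError(
                f"{self.cluster_id}: lineage has more than {len(RANKS)} ranks"
            )
        object.__setattr__(self, "lineage", lineage)
        if not 0.0 <= self.identity <= 100.0:
            raise ValidationError(
                f"{self.cluster_id}: identity {self.identity} outside [0, 100]"
            )
        # non-empty ranks must be a prefix: empty tails only
        seen_empty = False
        for name in self.lineage:
            if name == "":
                seen_empty = True
            elif seen_empty:
                raise ValidationError(
                    f"{self.cluster_id}: lineage has a gap (empty rank followed "
                    f"by a named rank)"
                )

    def label_at(self, rank: str) -> str:
        return self.lineage[RANKS.index(rank)]

    def deepest_assigned(self) -> str:
        """Name of the deepest non-empty rank (falls back to 'unknown')."""
        for name in reversed(self.lineage):
            if name:
                return name
        return "unknown"


def truncate_lineage(
    record: TaxonomyRecord, thresholds: RankThresholds | None = None
) -> TaxonomyRecord:
    """Blank the lineage below the rank supported by the hit identity.

    Idempotent, and monotone in identity: a higher identity never yields a
    shallower truncation.  Species is always blanked (genus is the deepest
    assignable rank).
    """
    thresholds = thresholds or RankThresholds()
    deepest = thresholds.deepest_rank(record.identity)
    keep = RANKS.index(deepest) + 1
    keep = min(keep, RANKS.index("genus") + 1)  # species never assigned
    lineage = record.lineage[:keep] + ("",) * (len(RANKS) - keep)
    return TaxonomyRecord(record.cluster_id, lineage, record.identity)


def filter_clusters(table: CommunityTable, min_mean: float = 5.0) -> CommunityTable:
    """Discard clusters with a mean count per sample strictly below ``min_mean``.

    The mean is taken over all samples in the table, zeros included; clusters
    whose mean equals the threshold are retained.  The sample set is unchanged.
    """
    if table.n_taxa == 0 or table.n_samples == 0:
        logger.warning("filter_clusters called on an empty table")
        return table.copy()
    means = table.values.mean(axis=0)
    kept = means.index[means >= min_mean]
    return CommunityTable(table.values[list(kept)].copy(), table.meta.copy())


def aggregate_to_rank(
    table: CommunityTable,
    records: dict | list,
    rank: str = "genus",
    thresholds: RankThresholds | None = None,
    truncate: bool = True,
) -> CommunityTable:
    """Sum OTU clusters into taxa at ``rank``, conserving per-sample totals.

    Clusters whose (identity-truncated) lineage is unassigned at ``rank`` are
    pooled under ``"uncl_<deepest assigned label>"``.  Every cluster column in
    the table must have a taxonomy record.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}")
    if not isinstance(records, dict):
        records = {r.cluster_id: r for r in records}
    labels = {}
    for cluster in table.taxa:
        rec = records.get(cluster)
        if rec is None:
            raise ValidationError(f"no taxonomy record for cluster {cluster!r}")
        if truncate:
            rec = truncate_lineage(rec, thresholds)
        name = rec.label_at(rank)
        labels[cluster] = name if name else f"uncl_{rec.deepest_assigned()}"
    grouped = table.values.T.groupby(
        table.values.columns.map(labels), sort=True
    ).sum().T
    return CommunityTable(grouped, table.meta.copy())


def read_taxonomy_tsv(path) -> dict:
    """Read a taxonomy TSV: cluster_id, ';'-separated 7-rank lineage, identity."""
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    frame.columns = [c.strip().lower() for c in frame.columns]
    required = {"cluster_id", "lineage", "identity"}
    if not required.issubset(frame.columns):
        raise ValidationError(
            f"taxonomy table needs columns {sorted(required)}, got "
            f"{list(frame.columns)}"
        )
    records = {}
    for row in frame.itertuples(index=False):
        lineage = tuple(part.strip() for part in str(row.lineage).split(";"))
        if lineage == ("nan",):
            lineage = ()
        records[row.cluster_id] = TaxonomyRecord(
            row.cluster_id, lineage, float(row.identity)
        )
    return records


def write_taxonomy_tsv(records: dict, path) -> None:
    rows = [
        {
            "cluster_id": rec.cluster_id,
            "lineage": ";".join(rec.lineage).rstrip(";"),
            "identity": rec.identity,
        }
        for rec in records.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
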