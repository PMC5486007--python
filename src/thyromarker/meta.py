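"""Cross-study vote-counting meta-analysis of differential gene lists.

Published FTC-vs-FTA expression studies report their differential gene
lists under heterogeneous identifiers (symbols, GenBank/RefSeq accessions,
array probe ids...).  This module harmonizes those records to canonical
Entrez-style gene ids through a user-supplied mapping snapshot, collapses
within-study duplicates, tallies how many studies report each gene, and
classifies direction concordance (direction is binary relative to FTC:
``up`` = higher in carcinoma).  Genes reported in several studies with a
consistent direction are the meta-analysis candidates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .datatypes import ValidationError

logger = logging.getLogger(__name__)

DIRECTIONS = ("up", "down")


@dataclass(frozen=True)
class StudyRecord:
    """One gene reported by one study.

    ``gene_id``/``symbol`` are filled by :func:`harmonize_ids`; before
    harmonization only ``raw_id`` within ``namespace`` identifies the gene.
    """

    study_id: str
    raw_id: str
    namespace: str
    direction: str
    gene_id: str | None = None
    symbol: str | None = None

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")


@dataclass
class StudyGeneListCollection:
    """Per-study differential gene lists.

    ``canonical`` is True once every record carries a canonical ``gene_id``
    (after :func:`harmonize_ids`, or by construction for simulated lists).
    """

    records: list[StudyRecord]
    canonical: bool = False

    def __post_init__(self):
        if self.canonical and any(r.gene_id is None for r in self.records):
            raise ValidationError("canonical collection contains records without gene_id")

    @property
    def study_ids(self) -> list[str]:
        return sorted({r.study_id for r in self.records})

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class IdMap:
    """Snapshot mapping (raw_id, namespace) -> canonical gene id + symbol.

    A static table (never a live lookup) so runs are reproducible.  The
    mapping must be many-to-one: within a namespace a raw id maps to exactly
    one canonical id.
    """

    table: pd.DataFrame  # columns: raw_id, namespace, gene_id, symbol

    def __post_init__(self):
        required = {"raw_id", "namespace", "gene_id", "symbol"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"id map missing columns: {sorted(missing)}")
        t = self.table.astype(str)
        dup = t.groupby(["raw_id", "namespace"])["gene_id"].nunique()
        conflicts = dup[dup > 1]
        if not conflicts.empty:
            raise ValidationError(
                f"raw ids mapping to multiple canonical ids: {list(conflicts.index[:5])}")
        self._lookup = {(r, ns): (g, s) for r, ns, g, s in
                        zip(t["raw_id"], t["namespace"], t["gene_id"], t["symbol"])}
        self.namespaces = set(t["namespace"])

    def get(self, raw_id: str, namespace: str):
        return self._lookup.get((str(raw_id), namespace))


@dataclass
class HarmonizeLog:
    """Bookkeeping from identifier harmonization."""

    n_unmapped: int = 0
    n_duplicates_collapsed: int = 0
    n_direction_conflicts: int = 0
    unmapped: list = field(default_factory=list)


def harmonize_ids(collection: StudyGeneListCollection, idmap: IdMap
                  ) -> tuple[StudyGeneListCollection, HarmonizeLog]:
    """Map records to canonical gene ids and collapse within-study duplicates.

    Unmapped records are dropped and counted; within one study, several
    aliases of the same gene collapse to a single record; a within-study
    direction conflict (same gene up and down) makes the gene unusable for
    that study and the records are dropped with a log line.
    """
    unknown = {r.namespace for r in collection.records} - idmap.namespaces
    if unknown:
        raise ValidationError(f"id map does not cover namespace(s): {sorted(unknown)}")

    log = HarmonizeLog()
    mapped: dict[tuple[str, str], list[StudyRecord]] = {}
    order: list[tuple[str, str]] = []
    for rec in collection.records:
        hit = idmap.get(rec.raw_id, rec.namespace)
        if hit is None:
            log.n_unmapped += 1
            log.unmapped.append((rec.study_id, rec.raw_id, rec.namespace))
            continue
        gene_id, symbol = hit
        key = (rec.study_id, gene_id)
        if key not in mapped:
            mapped[key] = []
            order.append(key)
        mapped[key].append(replace(rec, gene_id=gene_id, symbol=symbol))

    records: list[StudyRecord] = []
    for key in order:
        group = mapped[key]
        directions = {r.direction for r in group}
        if len(directions) > 1:
            log.n_direction_conflicts += 1
            logger.warning("study %s: gene %s reported both up and down; dropped",
                           key[0], key[1])
            continue
        if len(group) > 1:
            log.n_duplicates_collapsed += len(group) - 1
        records.append(group[0])

    if log.n_unmapped:
        logger.info("harmonize_ids: dropped %d unmapped record(s)", log.n_unmapped)
    return StudyGeneListCollection(records=records, canonical=True), log


@dataclass
class VoteTable:
    """Per-gene vote counts across studies.

    ``table`` is indexed by canonical gene id, ordered by count descending
    then gene id ascending, with columns ``symbol``, ``count``,
    ``directions`` (per supporting study, in study order), ``concordant``,
    ``consensus_direction`` (None when discordant) and ``studies``.
    """

    table: pd.DataFrame

    def genes_with_count(self, count: int) -> list[str]:
        return list(self.table.index[self.table["count"] == count])


def _gene_sort_key(gene_id: str):
    try:
        return (0, int(gene_id), "")
    except (TypeError, ValueError):
        return (1, 0, str(gene_id))


def tally_votes(collection: StudyGeneListCollection) -> VoteTable:
    """Tally, per canonical gene, the studies reporting it and their directions."""
    if not collection.canonical:
        raise ValidationError("tally_votes requires a harmonized (canonical) collection")
    per_gene: dict[str, dict] = {}
    for rec in collection.records:
        entry = per_gene.setdefault(rec.gene_id, {"symbol": rec.symbol, "votes": []})
        entry["votes"].append((rec.study_id, rec.direction))

    rows = []
    for gene_id, entry in per_gene.items():
        votes = sorted(entry["votes"])
        directions = tuple(d for _s, d in votes)
        studies = tuple(s for s, _d in votes)
        concordant = len(set(directions)) == 1
        rows.append({
            "gene_id": gene_id,
            "symbol": entry["symbol"] if entry["symbol"] is not None else gene_id,
            "count": len(votes),
            "directions": directions,
            "concordant": concordant,
            "consensus_direction": directions[0] if concordant else None,
            "studies": studies,
        })
    if not rows:
        table = pd.DataFrame(columns=["symbol", "count", "directions", "concordant",
                                      "consensus_direction", "studies"])
        table.index.name = "gene_id"
        return VoteTable(table)
    table = pd.DataFrame(rows).set_index("gene_id")
    order = sorted(table.index, key=lambda g: (-table.at[g, "count"],) + _gene_sort_key(g))
    return VoteTable(table.loc[order])


def select_candidates(table: VoteTable, min_count: int = 2,
                      concordant_only: bool = True) -> pd.DataFrame:
    """Genes supported by at least ``min_count`` studies, optionally
    restricted to those with a consistent direction of change."""
    if min_count < 1:
        raise ValidationError("min_count must be >= 1")
    t = table.table
    keep = t["count"] >= min_count
    if concordant_only:
        keep &= t["concordant"]
    return t[keep].copy()
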