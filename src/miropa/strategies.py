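"""The three enrichment strategies for miRNA signatures.

All three test the same question — is the overlap between a query set and
each pathway larger than expected under hypergeometric sampling — and differ
only in how the query, the reference sets and the universe are built:

* **Strategy 1** (indirect, native pathways): the query is the union of
  target genes of the signature miRNAs; references are the pathways' full
  gene memberships.  This is the approach dominating the literature, and the
  one contaminated by knowledge bias in the target database.
* **Strategy 2** (indirect, tailored pathways): as strategy 1, but pathways
  are first restricted to genes targeted by at least one miRNA anywhere in
  the database, and the universe is that targeted-gene set.
* **Strategy 3** (direct, converted pathways): each pathway is re-expressed
  as the set of miRNAs targeting at least one of its genes (each miRNA
  counted once no matter how many member genes it hits), and the miRNA
  signature itself is the query.  The universe is the database's miRNAs.

Because the universe definition changes every p-value and is nowhere
standardized, it is an explicit, reported parameter: every result table
carries a metadata string recording the universe used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import pandas as pd

from .core_stats import ContingencyCounts, bh_adjust, hypergeom_upper_tail
from .knowledge_io import PathwayCollection, PathwayEntry, Signature, TargetMap

__all__ = [
    "EnrichmentTable",
    "map_signature_to_targets",
    "match_signature",
    "strategy1",
    "tailor_pathways",
    "strategy2",
    "convert_pathways",
    "strategy3",
    "write_enrichment_tsv",
]

logger = logging.getLogger(__name__)

ROW_COLUMNS = [
    "pathway_id", "pathway_name", "N", "R", "n", "r",
    "overlap_members", "p_value", "fdr",
]


@dataclass
class EnrichmentTable:
    """Per-pathway contingency counts, p-values and BH FDRs.

    ``rows`` is a DataFrame with columns pathway_id, pathway_name, N, R, n,
    r, overlap_members (sorted tuple), p_value, fdr; the BH family is exactly
    the rows present.  ``metadata`` records the strategy tag, the universe
    definition and input sizes so any table can be audited.
    """

    rows: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def selected(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.rows[self.rows["fdr"] < alpha].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)


def match_signature(signature: Signature, tmap: TargetMap) -> tuple:
    """Signature miRNAs present in the target map, plus the unmatched ids.

    Unmatched identifiers are dropped with a logged count, mirroring the
    usual reduction of published signatures against a given database.
    """
    matched = tuple(m for m in signature.mirnas if m in tmap.targets_of)
    unmatched = tuple(m for m in signature.mirnas if m not in tmap.targets_of)
    if unmatched:
        logger.warning(
            "signature %r: %d of %d miRNAs not in target map %r",
            signature.label, len(unmatched), len(signature), tmap.source_name,
        )
    return matched, unmatched


def map_signature_to_targets(signature: Signature, tmap: TargetMap) -> frozenset:
    """Union of target genes of the signature miRNAs found in the map."""
    matched, _ = match_signature(signature, tmap)
    if not matched:
        raise ValueError(
            f"no miRNA of signature {signature.label!r} matches target map "
            f"{tmap.source_name!r}"
        )
    out: set = set()
    for m in matched:
        out |= tmap.targets_of[m]
    return frozenset(out)


def _gene_universe(tmap: TargetMap, pathways: PathwayCollection, mode: str) -> frozenset:
    if mode == "annotation":
        return frozenset(pathways.all_members() | set(tmap.targeters_of))
    if mode == "pathways":
        return pathways.all_members()
    if mode == "targeted":
        return frozenset(tmap.targeters_of)
    raise ValueError(
        f"unknown universe_mode {mode!r} (expected annotation|pathways|targeted)"
    )


def _enrich(
    query: frozenset,
    pathways: PathwayCollection,
    universe: frozenset,
    metadata: dict,
    min_pathway_size: int = 1,
    min_overlap: int = 0,
) -> EnrichmentTable:
    """Shared test loop: one hypergeometric test per retained pathway, BH over
    the retained family.  Pathways whose reference set (after intersection
    with the universe) is empty or below ``min_pathway_size`` are dropped
    before correction so the BH family size stays auditable."""
    N = len(universe)
    R = len(query)
    records = []
    n_dropped = 0
    for entry in pathways:
        ref = entry.members & universe
        if len(ref) == 0 or len(ref) < min_pathway_size:
            n_dropped += 1
            continue
        overlap = query & ref
        if len(overlap) < min_overlap:
            n_dropped += 1
            continue
        counts = ContingencyCounts(N=N, R=R, n=len(ref), r=len(overlap))
        records.append(
            (
                entry.pathway_id, entry.name, N, R, counts.n, counts.r,
                tuple(sorted(overlap)), hypergeom_upper_tail(counts),
            )
        )
    if n_dropped:
        logger.info("dropped %d untestable pathways before BH", n_dropped)
    rows = pd.DataFrame(records, columns=ROW_COLUMNS[:-1])
    rows["fdr"] = bh_adjust(rows["p_value"].to_numpy()) if len(rows) else []
    metadata = dict(metadata)
    metadata.update(n_pathways_tested=len(rows), n_pathways_dropped=n_dropped)
    return EnrichmentTable(rows=rows, metadata=metadata)


def strategy1(
    signature: Signature,
    tmap: TargetMap,
    pathways: PathwayCollection,
    universe_mode: str = "annotation",
    min_pathway_size: int = 1,
    min_overlap: int = 0,
) -> EnrichmentTable:
    """Indirect enrichment of the signature's target genes in native pathways."""
    if pathways.member_kind != "genes":
        raise ValueError("strategy1 requires a gene-level pathway collection")
    universe = _gene_universe(tmap, pathways, universe_mode)
    query = map_signature_to_targets(signature, tmap) & universe
    if not query:
        raise ValueError("query is empty after intersection with the universe")
    meta = {
        "strategy": "strategy1",
        "universe": f"mode={universe_mode}; {len(universe)} genes",
        "signature": signature.label,
        "signature_size": len(signature),
        "query_size": len(query),
    }
    return _enrich(query, pathways, universe, meta, min_pathway_size, min_overlap)


def tailor_pathways(pathways: PathwayCollection, tmap: TargetMap) -> PathwayCollection:
    """Restrict each pathway to genes targeted by at least one miRNA."""
    if pathways.member_kind != "genes":
        raise ValueError("tailor_pathways requires a gene-level collection")
    targeted = frozenset(tmap.targeters_of)
    entries = []
    n_dropped = 0
    for e in pathways:
        kept = e.members & targeted
        if kept:
            entries.append(PathwayEntry(e.pathway_id, e.name, kept))
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("tailoring dropped %d pathways with no targeted gene", n_dropped)
    if not entries:
        raise ValueError("tailoring emptied every pathway")
    return PathwayCollection(entries=entries, member_kind="genes")


def strategy2(
    signature: Signature,
    tmap: TargetMap,
    pathways: PathwayCollection,
    min_pathway_size: int = 1,
    min_overlap: int = 0,
) -> EnrichmentTable:
    """As strategy 1 but on tailored pathways over the targeted-gene universe."""
    tailored = tailor_pathways(pathways, tmap)
    universe = _gene_universe(tmap, pathways, "targeted")
    query = map_signature_to_targets(signature, tmap) & universe
    if not query:
        raise ValueError("query is empty after intersection with the universe")
    meta = {
        "strategy": "strategy2",
        "universe": f"mode=targeted; {len(universe)} genes",
        "signature": signature.label,
        "signature_size": len(signature),
        "query_size": len(query),
    }
    return _enrich(query, tailored, universe, meta, min_pathway_size, min_overlap)


def convert_pathways(pathways: PathwayCollection, tmap: TargetMap) -> PathwayCollection:
    """Convert gene pathways to miRNA sets: every miRNA targeting >=1 member.

    A miRNA appears at most once per converted pathway regardless of how many
    member genes it targets; pathways with no targeted gene are dropped.
    """
    if pathways.member_kind != "genes":
        raise ValueError("convert_pathways requires a gene-level collection")
    entries = []
    n_dropped = 0
    for e in pathways:
        mirnas: set = set()
        for g in e.members:
            mirnas |= tmap.targeters_of.get(g, frozenset())
        if mirnas:
            entries.append(PathwayEntry(e.pathway_id, e.name, frozenset(mirnas)))
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("conversion dropped %d pathways with no targeted gene", n_dropped)
    if not entries:
        raise ValueError("conversion emptied every pathway")
    return PathwayCollection(entries=entries, member_kind="mirnas")


def strategy3(
    signature: Signature,
    converted: PathwayCollection,
    tmap: TargetMap,
    min_pathway_size: int = 1,
    min_overlap: int = 0,
) -> EnrichmentTable:
    """Direct enrichment of the miRNA signature in converted pathways."""
    if converted.member_kind != "mirnas":
        raise ValueError("strategy3 requires a miRNA-level (converted) collection")
    universe = frozenset(tmap.targets_of)
    matched, _ = match_signature(signature, tmap)
    query = frozenset(matched) & universe
    if not query:
        raise ValueError(
            f"no miRNA of signature {signature.label!r} matches target map "
            f"{tmap.source_name!r}"
        )
    meta = {
        "strategy": "strategy3",
        "universe": f"mode=tmap-mirnas; {len(universe)} miRNAs",
        "signature": signature.label,
        "signature_size": len(signature),
        "query_size": len(query),
    }
    return _enrich(query, converted, universe, meta, min_pathway_size, min_overlap)


def write_enrichment_tsv(table: EnrichmentTable, path, extra_metadata: Optional[dict] = None) -> None:
    """Write an EnrichmentTable as TSV with ``#`` metadata header lines."""
    path = Path(path)
    meta = {**table.metadata, **(extra_metadata or {})}
    rows = table.rows.copy()
    rows["overlap_members"] = rows["overlap_members"].map(lambda t: ",".join(t))
    with path.open("w") as fh:
        for k in sorted(meta):
            fh.write(f"#{k}={meta[k]}\n")
        rows.to_csv(fh, sep="\t", index=False)
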