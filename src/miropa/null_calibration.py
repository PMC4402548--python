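"""Negative controls: random-signature calibration and database bias scans.

An enrichment strategy is only informative if a *random* signature of the
same size rarely selects any pathway.  This module measures that directly:

* :func:`calibrate` runs a strategy on B random signatures of size k drawn
  uniformly without replacement from the database's miRNAs and reports, per
  pathway, the fraction of draws in which the pathway was called enriched at
  FDR < alpha (the non-specificity frequency).  Summary lists at the 10% and
  90% frequency thresholds are produced by default.
* :func:`global_bias_scan` runs the indirect strategy with the *whole* list
  of targeted genes as query: any pathway it selects reflects bias of the
  target database itself, not of any signature.
* :func:`top_targeted_scan` tests the most-commonly-targeted genes (the ones
  an indirect strategy is most likely to pick up for any signature) against
  tailored pathways, exposing why tailoring alone does not fix the bias.

Per-draw seeds are derived from a master seed by counter, so reports are
bit-reproducible and two calibrations with the same master seed see the
same signatures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .knowledge_io import PathwayCollection, Signature, TargetMap
from .strategies import EnrichmentTable, _enrich, _gene_universe, tailor_pathways

__all__ = [
    "CalibrationReport",
    "BiasScanResult",
    "draw_random_signature",
    "calibrate",
    "flag_nonspecific",
    "global_bias_scan",
    "top_targeted_scan",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.1, 0.9)


@dataclass
class CalibrationReport:
    """Per-pathway selection frequencies over random signatures."""

    strategy: str
    signature_size: int
    n_draws: int
    alpha: float
    seed: int
    table: pd.DataFrame  # pathway_id, selection_count, selection_frequency
    thresholds: dict = field(default_factory=dict)  # threshold -> list of ids
    n_failed_draws: int = 0

    def frequency_of(self, pathway_id: str) -> float:
        sub = self.table[self.table["pathway_id"] == pathway_id]
        if sub.empty:
            raise KeyError(pathway_id)
        return float(sub["selection_frequency"].iloc[0])

    def write(self, tsv_path, json_path=None) -> None:
        """TSV of per-pathway counts plus a JSON sidecar of run parameters."""
        tsv_path = Path(tsv_path)
        self.table.to_csv(tsv_path, sep="\t", index=False)
        sidecar = {
            "strategy": self.strategy,
            "k": self.signature_size,
            "B": self.n_draws,
            "alpha": self.alpha,
            "seed": self.seed,
            "n_failed_draws": self.n_failed_draws,
            "thresholds": {str(t): ids for t, ids in self.thresholds.items()},
        }
        json_path = Path(json_path) if json_path else tsv_path.with_suffix(".json")
        json_path.write_text(json.dumps(sidecar, indent=2) + "\n")


@dataclass
class BiasScanResult:
    """EnrichmentTable produced from a degenerate (signature-free) query."""

    table: EnrichmentTable
    query_definition: str


def draw_random_signature(tmap: TargetMap, k: int, rng) -> Signature:
    """k distinct miRNAs sampled uniformly from the target map's miRNAs."""
    universe = tmap.mirnas  # sorted, deterministic
    if k > len(universe):
        raise ValueError(f"k={k} exceeds miRNA universe size {len(universe)}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    picked = rng.choice(len(universe), size=k, replace=False)
    return Signature(label=f"rand-{k}", mirnas=tuple(universe[i] for i in sorted(picked)))


def _run_strategy(strategy_fn: Callable, signature, tmap, pathways, **kw) -> EnrichmentTable:
    # strategy3 takes (signature, converted, tmap); strategy1/2 take
    # (signature, tmap, pathways).  Dispatch on the collection's member kind.
    if pathways.member_kind == "mirnas":
        return strategy_fn(signature, pathways, tmap, **kw)
    return strategy_fn(signature, tmap, pathways, **kw)


def calibrate(
    strategy_fn: Callable,
    tmap: TargetMap,
    pathways: PathwayCollection,
    k: int,
    B: int,
    alpha: float = 0.05,
    seed: int = 0,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    **strategy_kwargs,
) -> CalibrationReport:
    """Selection frequency of every pathway over B random size-k signatures.

    ``strategy_fn`` is one of the strategy functions; when ``pathways`` is a
    converted (miRNA-level) collection it is passed in strategy 3's argument
    order.  Failed draws (a strategy error on a degenerate signature) are
    counted and logged, and B keeps counting attempted draws so frequency
    denominators stay honest; all draws failing is an error.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    counts = {pid: 0 for pid in pathways.ids}
    n_failed = 0
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(b,)))
        sig = draw_random_signature(tmap, k, rng)
        try:
            table = _run_strategy(strategy_fn, sig, tmap, pathways, **strategy_kwargs)
        except ValueError as exc:
            n_failed += 1
            logger.warning("draw %d failed: %s", b, exc)
            continue
        for pid in table.selected(alpha)["pathway_id"]:
            counts[pid] += 1
    if n_failed == B:
        raise RuntimeError(f"all {B} calibration draws failed")
    table = pd.DataFrame(
        {
            "pathway_id": list(counts),
            "selection_count": list(counts.values()),
            "selection_frequency": [c / B for c in counts.values()],
        }
    )
    thr = {
        float(t): sorted(
            table.loc[table["selection_frequency"] >= t, "pathway_id"]
        )
        for t in thresholds
    }
    strategy_name = getattr(strategy_fn, "__name__", str(strategy_fn))
    return CalibrationReport(
        strategy=strategy_name,
        signature_size=k,
        n_draws=B,
        alpha=alpha,
        seed=seed,
        table=table,
        thresholds=thr,
        n_failed_draws=n_failed,
    )


def flag_nonspecific(
    results: EnrichmentTable,
    report: CalibrationReport,
    threshold: float = 0.1,
) -> EnrichmentTable:
    """Annotate enrichment rows whose null selection frequency >= threshold.

    Adds a boolean ``nonspecific`` column and records, in the metadata, the
    fraction of *selected* pathways (fdr < the report's alpha) that are
    non-specific — the overlap-with-null statistic.
    """
    freqs = dict(
        zip(report.table["pathway_id"], report.table["selection_frequency"])
    )
    missing = [pid for pid in results.rows["pathway_id"] if pid not in freqs]
    if missing:
        raise ValueError(f"pathways absent from calibration report: {missing}")
    rows = results.rows.copy()
    rows["nonspecific"] = [
        freqs[pid] >= threshold for pid in rows["pathway_id"]
    ]
    selected = rows[rows["fdr"] < report.alpha]
    frac = float(selected["nonspecific"].mean()) if len(selected) else 0.0
    meta = dict(results.metadata)
    meta.update(
        nonspecific_threshold=threshold,
        nonspecific_fraction_of_selected=frac,
    )
    return EnrichmentTable(rows=rows, metadata=meta)


def global_bias_scan(
    tmap: TargetMap,
    pathways: PathwayCollection,
    universe_mode: str = "annotation",
) -> BiasScanResult:
    """Strategy-1 enrichment with query = all genes targeted by >=1 miRNA.

    Pathways selected here are enriched for *any* signature's targets: the
    knowledge-bias pathway list of the target database.
    """
    if pathways.member_kind != "genes":
        raise ValueError("global_bias_scan requires a gene-level collection")
    universe = _gene_universe(tmap, pathways, universe_mode)
    query = frozenset(tmap.targeters_of) & universe
    if not query:
        raise ValueError("no targeted gene lies in the universe")
    meta = {
        "strategy": "global_bias_scan",
        "universe": f"mode={universe_mode}; {len(universe)} genes",
        "query_size": len(query),
    }
    table = _enrich(query, pathways, universe, meta)
    return BiasScanResult(
        table=table,
        query_definition=f"all {len(query)} genes targeted by >=1 miRNA",
    )


def rank_genes_by_targeting(tmap: TargetMap) -> list:
    """Genes ordered by number of distinct targeting miRNAs (descending),
    ties broken by lexicographic gene id for determinism."""
    return sorted(tmap.targeters_of, key=lambda g: (-len(tmap.targeters_of[g]), g))


def top_targeted_scan(
    tmap: TargetMap,
    pathways: PathwayCollection,
    k_list: Iterable[int],
) -> list:
    """Strategy-2-style enrichment of the top-k most-targeted genes.

    For each k, the query is the k genes with the most distinct targeting
    miRNAs, tested against tailored pathways over the targeted-gene universe.
    With k equal to the whole targeted-gene list the query equals the
    universe and no pathway can be enriched — by design.
    """
    ranked = rank_genes_by_targeting(tmap)
    universe = frozenset(tmap.targeters_of)
    tailored = tailor_pathways(pathways, tmap)
    results = []
    for k in k_list:
        if k > len(ranked):
            raise ValueError(f"k={k} exceeds {len(ranked)} targeted genes")
        if k < len(ranked) and len(tmap.targeters_of[ranked[k - 1]]) == len(
            tmap.targeters_of[ranked[k]]
        ):
            logger.info("top_targeted_scan: tie at rank %d cut lexicographically", k)
        query = frozenset(ranked[:k])
        meta = {
            "strategy": "top_targeted_scan",
            "universe": f"mode=targeted; {len(universe)} genes",
            "query_size": k,
        }
        table = _enrich(query, tailored, universe, meta)
        results.append(
            BiasScanResult(table=table, query_definition=f"top {k} most-targeted genes")
        )
    return results
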