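"""Synthetic target maps and pathway collections with known ground truth.

Real target databases cannot be bundled, and — more importantly — they carry
an unknown amount of knowledge bias.  This generator builds a world where
the bias is *known*: pathways are uniform random gene subsets, each
(miRNA, gene) interaction occurs independently with a base probability, and
genes belonging to designated "biased" pathways are targeted at a multiplied
rate — the mechanism by which a curated database over-represents
heavily-studied pathways.  Optionally a "signal" pathway is planted together
with a signature drawn from the miRNAs targeting its genes, so recovery of a
genuine regulatory signal can be measured against the generator's truth.

Everything is driven by a single master seed through independent derived
streams (pathway construction, interaction sampling, signature sampling), so
a fixture is fully determined by its spec.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .knowledge_io import (
    PathwayCollection,
    PathwayEntry,
    Signature,
    TargetMap,
)
from .strategies import EnrichmentTable

__all__ = ["FixtureSpec", "Fixture", "FixtureTruth", "generate", "truth_recovery_check", "RecoverySummary"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic world.

    Defaults describe a desk-scale analogue of a curated human target
    database against a KEGG-sized pathway collection: 2,000 genes, 300
    miRNAs, 100 pathways of 20-80 genes, a 1% per-pair interaction rate
    (so a miRNA targets ~20 genes, like validated-interaction databases),
    and, when bias is requested, a 5x targeting rate for genes of the
    designated pathways.
    """

    n_genes: int = 2000
    n_mirnas: int = 300
    n_pathways: int = 100
    pathway_size_range: Tuple[int, int] = (20, 80)
    base_target_prob: float = 0.01
    biased_pathway_ids: Tuple[str, ...] = ()
    bias_multiplier: float = 1.0
    signal_pathway_id: Optional[str] = None
    signal_signature_size: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_mirnas", "n_pathways"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid pathway_size_range {self.pathway_size_range}")
        if hi > self.n_genes:
            raise ValueError(
                f"max pathway size {hi} exceeds n_genes={self.n_genes}"
            )
        if not 0 <= self.base_target_prob <= 1:
            raise ValueError("base_target_prob must be in [0, 1]")
        if self.bias_multiplier < 1:
            raise ValueError("bias_multiplier must be >= 1")
        if self.signal_signature_size < 1:
            raise ValueError("signal_signature_size must be positive")

    def pathway_ids(self) -> Tuple[str, ...]:
        return tuple(f"PW{i:03d}" for i in range(1, self.n_pathways + 1))


@dataclass(frozen=True)
class FixtureTruth:
    biased_pathway_ids: Tuple[str, ...]
    signal_pathway_id: Optional[str]
    signal_signature: Optional[Signature]


@dataclass(frozen=True)
class Fixture:
    spec: FixtureSpec
    tmap: TargetMap
    pathways: PathwayCollection
    truth: FixtureTruth

    def write(self, out_dir) -> None:
        """Emit target-map TSV, pathway GMT, signature file and truth JSON."""
        from .knowledge_io import write_gmt, write_signature, write_target_map

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_target_map(self.tmap, out / "target_map.tsv")
        write_gmt(self.pathways, out / "pathways.gmt")
        truth = {
            "biased_pathway_ids": list(self.truth.biased_pathway_ids),
            "signal_pathway_id": self.truth.signal_pathway_id,
            "spec": asdict(self.spec),
        }
        if self.truth.signal_signature is not None:
            write_signature(self.truth.signal_signature, out / "signature.txt")
            truth["signal_signature"] = list(self.truth.signal_signature.mirnas)
        (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")


def generate(spec: FixtureSpec) -> Fixture:
    """Build a fixture fully determined by ``spec`` (including its seed)."""
    ids = spec.pathway_ids()
    unknown = [p for p in spec.biased_pathway_ids if p not in ids]
    if unknown:
        raise ValueError(f"biased_pathway_ids not generated by this spec: {unknown}")
    if spec.signal_pathway_id is not None and spec.signal_pathway_id not in ids:
        raise ValueError(f"signal pathway {spec.signal_pathway_id!r} not generated by this spec")

    ss = np.random.SeedSequence(spec.seed)
    rng_path, rng_int, rng_sig = (np.random.default_rng(s) for s in ss.spawn(3))

    genes = np.array([f"G{i:04d}" for i in range(1, spec.n_genes + 1)])
    mirnas = np.array([f"mir-{i}" for i in range(1, spec.n_mirnas + 1)])

    lo, hi = spec.pathway_size_range
    entries = []
    member_idx = {}
    for pid in ids:
        size = int(rng_path.integers(lo, hi + 1))
        idx = rng_path.choice(spec.n_genes, size=size, replace=False)
        member_idx[pid] = idx
        entries.append(PathwayEntry(pid, f"synthetic pathway {pid}", frozenset(genes[idx])))
    pathways = PathwayCollection(entries=entries, member_kind="genes")

    # per-gene targeting probability: multiplied (once) for biased-pathway genes
    prob = np.full(spec.n_genes, spec.base_target_prob)
    if spec.biased_pathway_ids and spec.bias_multiplier > 1:
        biased = np.unique(np.concatenate([member_idx[p] for p in spec.biased_pathway_ids]))
        prob[biased] = np.minimum(1.0, prob[biased] * spec.bias_multiplier)

    hits = rng_int.random((spec.n_mirnas, spec.n_genes)) < prob[None, :]
    mi, gi = np.nonzero(hits)
    if mi.size == 0:
        raise ValueError("generated zero interaction pairs (base_target_prob too low?)")
    tmap = TargetMap.from_pairs(
        zip(mirnas[mi], genes[gi]), source_name=f"synthetic(seed={spec.seed})"
    )

    signal_signature = None
    if spec.signal_pathway_id is not None:
        targeters: set = set()
        for g in pathways.get(spec.signal_pathway_id).members:
            targeters |= tmap.targeters_of.get(g, frozenset())
        pool = sorted(targeters)
        if len(pool) < spec.signal_signature_size:
            raise ValueError(
                f"signal pathway {spec.signal_pathway_id!r} has only "
                f"{len(pool)} targeters < signal_signature_size="
                f"{spec.signal_signature_size}"
            )
        picked = rng_sig.choice(len(pool), size=spec.signal_signature_size, replace=False)
        signal_signature = Signature(
            label=f"signal-{spec.signal_pathway_id}",
            mirnas=tuple(pool[i] for i in sorted(picked)),
        )

    logger.info(
        "generated fixture: %d interactions, %d miRNAs with targets, %d targeted genes",
        len(tmap), len(tmap.targets_of), len(tmap.targeters_of),
    )
    return Fixture(
        spec=spec,
        tmap=tmap,
        pathways=pathways,
        truth=FixtureTruth(
            biased_pathway_ids=tuple(spec.biased_pathway_ids),
            signal_pathway_id=spec.signal_pathway_id,
            signal_signature=signal_signature,
        ),
    )


@dataclass
class RecoverySummary:
    """Did an enrichment run find the planted signal, and how cleanly?"""

    signal_selected: Optional[bool]
    signal_rank: Optional[int]  # 1-based rank by ascending p-value
    n_false_selected: int
    n_selected: int


def truth_recovery_check(
    fixture: Fixture, enrichment: EnrichmentTable, alpha: float = 0.05
) -> RecoverySummary:
    """Compare an enrichment table on this fixture with the generator truth.

    Rank is by ascending p-value with ties broken by pathway id.  Pathways
    selected at ``fdr < alpha`` that are neither the signal pathway nor a
    designated biased pathway count as false selections.
    """
    rows = enrichment.rows
    selected = rows[rows["fdr"] < alpha]
    truth_ids = set(fixture.truth.biased_pathway_ids)
    signal = fixture.truth.signal_pathway_id
    if signal is not None:
        truth_ids.add(signal)
    n_false = int((~selected["pathway_id"].isin(truth_ids)).sum())
    signal_selected = signal_rank = None
    if signal is not None:
        if signal not in set(rows["pathway_id"]):
            raise ValueError(
                f"signal pathway {signal!r} absent from the enrichment table"
            )
        signal_selected = bool(signal in set(selected["pathway_id"]))
        ordered = rows.sort_values(["p_value", "pathway_id"], kind="stable").reset_index(drop=True)
        signal_rank = int(ordered.index[ordered["pathway_id"] == signal][0]) + 1
    return RecoverySummary(
        signal_selected=signal_selected,
        signal_rank=signal_rank,
        n_false_selected=n_false,
        n_selected=int(len(selected)),
    )
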