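"""Readers, writers and identifier normalization for the three knowledge inputs.

The package consumes three artifacts:

* a miRNA→target-gene map (tab-separated, mirTarBase/TargetScan-style exports
  with a configurable column mapping),
* a pathway collection in the MSigDB GMT dialect (one set per line:
  id, free-text description, members...),
* a miRNA signature as a plain-text list, one identifier per line.

miRNA identifiers are normalized to a lowercase ``mir``/``let`` stem so that
signatures and databases written with different capitalisation ("MIR-146A",
"miR-146a") compare equal.  Arm suffixes (-5p/-3p) are distinct identifiers:
the two arms of a hairpin have different target sets.  An optional flag strips
species prefixes such as ``hsa-``.  Gene identifiers are opaque strings
(Entrez ids and symbols both pass through unchanged apart from whitespace).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "TargetMap",
    "PathwayCollection",
    "PathwayEntry",
    "Signature",
    "read_gmt",
    "write_gmt",
    "read_target_map",
    "write_target_map",
    "read_signature",
    "normalize_mirna_id",
]

logger = logging.getLogger(__name__)

_SPECIES_PREFIX = re.compile(r"^[a-z]{3,4}-(?=(?:mir|let)[-0-9])")


def normalize_mirna_id(raw: str, collapse_species_prefix: bool = False) -> str:
    """Trim and case-fold a miRNA identifier; optionally strip ``hsa-`` etc.

    Idempotent: applying twice gives the same result.  Arm suffixes are kept.
    """
    norm = raw.strip().lower()
    if not norm:
        raise ValueError(f"empty miRNA identifier after trimming: {raw!r}")
    if collapse_species_prefix:
        norm = _SPECIES_PREFIX.sub("", norm)
    return norm


def _normalize_gene_id(raw: str) -> str:
    return raw.strip()


@dataclass(frozen=True)
class TargetMap:
    """Bipartite miRNA→gene mapping with both directional indexes.

    ``targets_of`` maps each miRNA to its gene set, ``targeters_of`` each gene
    to the miRNAs hitting it; the two views are built from the same pair set
    and are mutually consistent by construction.
    """

    source_name: str
    interactions: frozenset
    targets_of: dict
    targeters_of: dict

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple], source_name: str = ""
    ) -> "TargetMap":
        clean = set()
        for mirna, gene in pairs:
            if not mirna or not gene:
                raise ValueError(f"empty identifier in pair ({mirna!r}, {gene!r})")
            clean.add((mirna, gene))
        targets: dict = {}
        targeters: dict = {}
        for mirna, gene in clean:
            targets.setdefault(mirna, set()).add(gene)
            targeters.setdefault(gene, set()).add(mirna)
        return cls(
            source_name=source_name,
            interactions=frozenset(clean),
            targets_of={m: frozenset(g) for m, g in targets.items()},
            targeters_of={g: frozenset(m) for g, m in targeters.items()},
        )

    @property
    def mirnas(self) -> tuple:
        """All miRNAs with at least one target, sorted."""
        return tuple(sorted(self.targets_of))

    @property
    def genes(self) -> tuple:
        """All genes targeted by at least one miRNA, sorted."""
        return tuple(sorted(self.targeters_of))

    def __len__(self) -> int:
        return len(self.interactions)


@dataclass(frozen=True)
class PathwayEntry:
    pathway_id: str
    name: str
    members: frozenset


@dataclass
class PathwayCollection:
    """Ordered collection of named sets; members are genes or miRNAs."""

    entries: list
    member_kind: str = "genes"

    def __post_init__(self) -> None:
        if self.member_kind not in ("genes", "mirnas"):
            raise ValueError(f"member_kind must be 'genes' or 'mirnas', got {self.member_kind!r}")
        ids = [e.pathway_id for e in self.entries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate pathway ids: {sorted(dupes)}")

    @property
    def ids(self) -> tuple:
        return tuple(e.pathway_id for e in self.entries)

    def get(self, pathway_id: str) -> PathwayEntry:
        for e in self.entries:
            if e.pathway_id == pathway_id:
                return e
        raise KeyError(pathway_id)

    def all_members(self) -> frozenset:
        out: set = set()
        for e in self.entries:
            out |= e.members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[PathwayEntry]:
        return iter(self.entries)


@dataclass
class Signature:
    """An ordered, duplicate-free list of normalized miRNA identifiers."""

    label: str
    mirnas: tuple

    @classmethod
    def from_ids(
        cls,
        ids: Sequence[str],
        label: str = "",
        collapse_species_prefix: bool = False,
    ) -> "Signature":
        seen: dict = {}
        n_dup = 0
        for raw in ids:
            norm = normalize_mirna_id(raw, collapse_species_prefix)
            if norm in seen:
                n_dup += 1
            else:
                seen[norm] = None
        if n_dup:
            logger.warning("signature %r: dropped %d duplicate ids", label, n_dup)
        return cls(label=label, mirnas=tuple(seen))

    def __len__(self) -> int:
        return len(self.mirnas)


# ---------------------------------------------------------------------------
# GMT

_MEMBER_KIND_HEADER = re.compile(r"^#\s*member_kind\s*=\s*(\w+)\s*$")


def read_gmt(path, member_kind: str = "genes") -> PathwayCollection:
    """Read a GMT file: one set per line, tab-separated id, description, members.

    A comment line ``#member_kind=mirna`` (written by :func:`write_gmt`)
    overrides the ``member_kind`` argument.  Members are deduplicated and
    normalized according to the member kind; entries whose member set
    normalizes to empty are dropped with a warning.
    """
    path = Path(path)
    entries = []
    seen_ids = set()
    kind = member_kind
    n_lines = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            m = _MEMBER_KIND_HEADER.match(line)
            if m:
                kind = "mirnas" if m.group(1).lower().startswith("mirna") else "genes"
                continue
            if line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: fewer than 3 fields (got {len(fields)})"
                )
            pid, desc = fields[0].strip(), fields[1].strip()
            if not pid:
                raise ValueError(f"{path}:{lineno}: empty pathway id")
            if pid in seen_ids:
                raise ValueError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            seen_ids.add(pid)
            raw_members = [f for f in fields[2:] if f.strip()]
            if kind == "mirnas":
                members = frozenset(normalize_mirna_id(m) for m in raw_members)
            else:
                members = frozenset(_normalize_gene_id(m) for m in raw_members)
            if not members:
                logger.warning("%s:%d: dropping %r (empty member set)", path, lineno, pid)
                continue
            entries.append(PathwayEntry(pid, desc, members))
    if n_lines == 0:
        raise ValueError(f"{path}: empty GMT file")
    return PathwayCollection(entries=entries, member_kind=kind)


def write_gmt(collection: PathwayCollection, path) -> None:
    """Write a collection as GMT; members sorted for a stable byte layout."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#member_kind={'mirna' if collection.member_kind == 'mirnas' else 'genes'}\n")
        for e in collection.entries:
            fh.write("\t".join([e.pathway_id, e.name, *sorted(e.members)]) + "\n")


# ---------------------------------------------------------------------------
# Target map TSV


def read_target_map(
    path,
    mirna_col: int | str = 0,
    gene_col: int | str = 1,
    has_header: bool = False,
    collapse_species_prefix: bool = False,
    source_name: Optional[str] = None,
) -> TargetMap:
    """Read a tab-separated miRNA→gene interaction table.

    ``mirna_col``/``gene_col`` are 0-based column indexes, or column names
    when ``has_header`` is true.  Pairs are deduplicated after identifier
    normalization; an empty result is an error.
    """
    path = Path(path)
    pairs = []
    with path.open() as fh:
        header: Optional[list] = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if has_header and header is None:
                header = [f.strip() for f in fields]
                continue
            mi = _resolve_col(mirna_col, header, "mirna_col")
            gi = _resolve_col(gene_col, header, "gene_col")
            if max(mi, gi) >= len(fields):
                raise ValueError(
                    f"{path}:{lineno}: column index {max(mi, gi)} exceeds "
                    f"field count {len(fields)}"
                )
            mirna = normalize_mirna_id(fields[mi], collapse_species_prefix)
            gene = _normalize_gene_id(fields[gi])
            if not gene:
                raise ValueError(f"{path}:{lineno}: empty gene identifier")
            pairs.append((mirna, gene))
    if not pairs:
        raise ValueError(f"{path}: zero interaction pairs")
    tmap = TargetMap.from_pairs(pairs, source_name=source_name or path.name)
    logger.info(
        "%s: %d interactions, %d miRNAs, %d genes",
        path, len(tmap), len(tmap.targets_of), len(tmap.targeters_of),
    )
    return tmap


def _resolve_col(col: int | str, header: Optional[list], what: str) -> int:
    if isinstance(col, int):
        return col
    if header is None:
        raise ValueError(f"{what}={col!r} is a name but the file has no header")
    if col not in header:
        raise ValueError(f"{what}: column {col!r} not found in header {header}")
    return header.index(col)


def write_target_map(tmap: TargetMap, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("mirna\tgene\n")
        for mirna, gene in sorted(tmap.interactions):
            fh.write(f"{mirna}\t{gene}\n")


# ---------------------------------------------------------------------------
# Signatures


def read_signature(
    path,
    label: Optional[str] = None,
    collapse_species_prefix: bool = False,
) -> Signature:
    """Read a signature file: one miRNA id per line, ``#`` comments ignored."""
    path = Path(path)
    ids = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ids.append(line)
    if not ids:
        raise ValueError(f"{path}: empty signature")
    return Signature.from_ids(
        ids, label=label or path.stem, collapse_species_prefix=collapse_species_prefix
    )


def write_signature(signature: Signature, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# signature: {signature.label}\n")
        for m in signature.mirnas:
            fh.write(m + "\n")
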