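"""Pathway redundancy: per-element pathway counts and Jaccard clustering.

Converting pathways to miRNA sets inflates their mutual overlap: a miRNA
targeting genes in many pathways belongs to every one of their converted
sets, so pathway information is far more redundant at the miRNA level than
at the gene level.  This module quantifies that redundancy — how many
pathways each element belongs to, the pairwise Jaccard index
J(A, B) = |A∩B| / |A∪B|, and clusters of pathways sharing on average at
least a given fraction of their members (average-linkage agglomerative
clustering on distance 1−J, tree cut at 1−threshold).  Redundant converted
pathways can then be aggregated into merged sets before enrichment, which
also shrinks the multiple-testing family.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .knowledge_io import PathwayCollection, PathwayEntry

__all__ = [
    "JaccardMatrix",
    "ClusterAssignment",
    "pathways_per_element",
    "jaccard_matrix",
    "cluster_by_average_jaccard",
    "cluster_size_distribution",
    "aggregate_clusters",
]

logger = logging.getLogger(__name__)


@dataclass
class JaccardMatrix:
    """Symmetric pairwise Jaccard indexes with unit diagonal."""

    pathway_ids: tuple
    values: np.ndarray

    def write(self, path) -> None:
        pd.DataFrame(
            self.values, index=list(self.pathway_ids), columns=list(self.pathway_ids)
        ).to_csv(Path(path), sep="\t")


@dataclass
class ClusterAssignment:
    """Partition of pathway ids into clusters at a given linkage threshold."""

    labels: Dict[str, str]  # pathway_id -> cluster label
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def members(self, label: str) -> tuple:
        return tuple(sorted(p for p, l in self.labels.items() if l == label))

    def sizes(self) -> Dict[str, int]:
        return dict(Counter(self.labels.values()))

    def write(self, path) -> None:
        with Path(path).open("w") as fh:
            fh.write("pathway_id\tcluster\n")
            for pid in sorted(self.labels):
                fh.write(f"{pid}\t{self.labels[pid]}\n")


def pathways_per_element(collection: PathwayCollection) -> Dict[str, int]:
    """For every member id, the number of pathways containing it."""
    if not len(collection):
        raise ValueError("empty pathway collection")
    counts: Counter = Counter()
    for entry in collection:
        counts.update(entry.members)
    hist = Counter(counts.values())
    logger.info(
        "pathways per element over %d elements: %s",
        len(counts), dict(sorted(hist.items())),
    )
    return dict(counts)


def jaccard_matrix(collection: PathwayCollection) -> JaccardMatrix:
    """J(A,B) = |A∩B| / |A∪B| for every pathway pair; exact integer ratio."""
    if len(collection) < 2:
        raise ValueError("need at least 2 pathways")
    for entry in collection:
        if not entry.members:
            raise ValueError(f"pathway {entry.pathway_id!r} has an empty member set")
    # lexicographic id order makes downstream linkage tie-breaking deterministic
    entries = sorted(collection.entries, key=lambda e: e.pathway_id)
    m = len(entries)
    values = np.ones((m, m), dtype=float)
    for i in range(m):
        for j in range(i + 1, m):
            inter = len(entries[i].members & entries[j].members)
            union = len(entries[i].members | entries[j].members)
            values[i, j] = values[j, i] = inter / union
    return JaccardMatrix(
        pathway_ids=tuple(e.pathway_id for e in entries), values=values
    )


def cluster_by_average_jaccard(
    matrix: JaccardMatrix, threshold: float = 0.2
) -> ClusterAssignment:
    """Average-linkage clusters of pathways sharing >= threshold on average.

    Agglomerative clustering on distance 1−J with average linkage; the tree
    is cut at height 1−threshold, so members of a cluster share on average
    at least ``threshold`` of their elements.  Singletons are allowed.
    Cluster labels are C1, C2, ... ordered by each cluster's smallest
    pathway id.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ids = matrix.pathway_ids
    if len(ids) == 1:
        return ClusterAssignment(labels={ids[0]: "C1"}, threshold=threshold)
    dist = 1.0 - matrix.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")
    flat = fcluster(tree, t=1.0 - threshold, criterion="distance")
    groups: Dict[int, list] = {}
    for pid, c in zip(ids, flat):
        groups.setdefault(int(c), []).append(pid)
    ordered = sorted(groups.values(), key=lambda g: min(g))
    labels = {pid: f"C{k}" for k, group in enumerate(ordered, start=1) for pid in group}
    return ClusterAssignment(labels=labels, threshold=threshold)


def cluster_size_distribution(assignment: ClusterAssignment) -> Dict[int, int]:
    """Histogram of cluster sizes: size -> number of clusters of that size."""
    return dict(Counter(assignment.sizes().values()))


def aggregate_clusters(
    converted: PathwayCollection, assignment: ClusterAssignment
) -> PathwayCollection:
    """Merge each multi-pathway cluster into one union set.

    Singleton clusters pass through unchanged; a merged entry takes its
    cluster label as id and the semicolon-joined constituent names as name.
    Done before enrichment this shrinks the BH family to the cluster count.
    """
    missing = [e.pathway_id for e in converted if e.pathway_id not in assignment.labels]
    if missing:
        raise ValueError(f"assignment does not cover pathways: {missing}")
    by_label: Dict[str, list] = {}
    label_order = []
    for e in converted:
        label = assignment.labels[e.pathway_id]
        if label not in by_label:
            label_order.append(label)
        by_label.setdefault(label, []).append(e)
    existing_ids = set(converted.ids)
    entries = []
    for label in label_order:
        group = by_label[label]
        if len(group) == 1:
            entries.append(group[0])
            continue
        if label in existing_ids:
            raise ValueError(f"cluster label {label!r} collides with a pathway id")
        members: set = set()
        for e in group:
            members |= e.members
        name = ";".join(e.name for e in sorted(group, key=lambda e: e.pathway_id))
        entries.append(PathwayEntry(label, name, frozenset(members)))
    return PathwayCollection(entries=entries, member_kind=converted.member_kind)
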