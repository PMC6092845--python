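"""Objective clustering of barcodes into MOTUs, and threshold stability.

Objective clustering at a distance cutoff groups specimens into the
connected components of the graph with an edge wherever the pairwise
uncorrected distance is at or below the threshold (single linkage at
cutoff).  The comparison is inclusive (``d <= t``), so a pair exactly at
the threshold is clustered together.  Components are order-independent,
which removes tie-breaking ambiguity entirely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix

DEFAULT_THRESHOLDS = (0.03, 0.04, 0.05)


@dataclass
class MotuPartition:
    """A partition of specimens into MOTUs at one clustering threshold.

    Each MOTU is labelled by its lexicographically smallest member ID,
    which is deterministic and stable under subsetting.
    """

    threshold: float
    clusters: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        members = [m for c in self.clusters.values() for m in c]
        if len(members) != len(set(members)):
            raise ValueError("clusters are not disjoint")
        for label, cluster in self.clusters.items():
            if not cluster:
                raise ValueError("empty cluster")
            if label != min(cluster):
                raise ValueError(f"label {label!r} is not the smallest member")

    @property
    def n_motus(self) -> int:
        return len(self.clusters)

    @property
    def specimens(self) -> frozenset[str]:
        return frozenset(m for c in self.clusters.values() for m in c)

    def motu_of(self) -> dict[str, str]:
        """Map each specimen ID to its MOTU label."""
        return {m: label for label, c in self.clusters.items() for m in c}

    def member_sets(self) -> frozenset[frozenset[str]]:
        return frozenset(self.clusters.values())

    def sizes(self) -> dict[str, int]:
        return {label: len(c) for label, c in self.clusters.items()}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("specimen_id\tmotu_label\tthreshold\n")
            for label in sorted(self.clusters):
                for sid in sorted(self.clusters[label]):
                    fh.write(f"{sid}\t{label}\t{self.threshold}\n")


@dataclass
class StabilityReport:
    """How MOTUs change across clustering thresholds.

    A MOTU is congruent when the same member set appears in every
    partition; a specimen is sensitive when it belongs to no congruent
    MOTU (it lumps or splits somewhere in the threshold range).
    """

    thresholds: list[float]
    n_motus_per_threshold: list[int]
    n_congruent: int
    n_sensitive_specimens: int
    pct_sensitive: float
    congruent_labels: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds,
            "n_motus_per_threshold": self.n_motus_per_threshold,
            "n_congruent": self.n_congruent,
            "n_sensitive_specimens": self.n_sensitive_specimens,
            "pct_sensitive": self.pct_sensitive,
            "congruent_labels": self.congruent_labels,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def summary(self) -> str:
        counts = ", ".join(
            f"{n} ({t:.0%})"
            for t, n in zip(self.thresholds, self.n_motus_per_threshold)
        )
        return (
            f"MOTUs per threshold: {counts}; congruent MOTUs: {self.n_congruent}; "
            f"sensitive specimens: {self.n_sensitive_specimens} "
            f"({self.pct_sensitive:.1f}%)"
        )


def objective_cluster(matrix: DistanceMatrix, threshold: float) -> MotuPartition:
    """Single-linkage-at-cutoff clustering of a fully defined matrix."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    if not matrix.is_fully_defined():
        raise ValueError(
            f"matrix has undefined distances for pairs {matrix.undefined_pairs()}; "
            "resolve upstream (raise min_overlap handling or drop specimens)"
        )
    adj = csr_matrix(matrix.d <= threshold)
    _, comp = connected_components(adj, directed=False)
    clusters: dict[int, list[str]] = {}
    for sid, c in zip(matrix.ids, comp):
        clusters.setdefault(int(c), []).append(sid)
    labelled = {min(members): frozenset(members) for members in clusters.values()}
    return MotuPartition(threshold=threshold, clusters=labelled)


def cluster_at_thresholds(
    matrix: DistanceMatrix, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> list[MotuPartition]:
    """Cluster at each threshold (strictly increasing order required)."""
    if list(thresholds) != sorted(set(thresholds)):
        raise ValueError("thresholds must be strictly increasing")
    return [objective_cluster(matrix, t) for t in thresholds]


def stability_report(partitions: Sequence[MotuPartition]) -> StabilityReport:
    """Count congruent MOTUs and threshold-sensitive specimens.

    Congruence is exact member-set identity across every partition —
    the strictest reading, so the sensitive-specimen count is an upper
    bound on softer definitions.
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    specimen_sets = {p.specimens for p in partitions}
    if len(specimen_sets) != 1:
        raise ValueError("partitions cover different specimen sets")

    common = frozenset.intersection(*(p.member_sets() for p in partitions))
    congruent_specimens = frozenset(m for c in common for m in c)
    all_specimens = partitions[0].specimens
    n_sensitive = len(all_specimens) - len(congruent_specimens)
    return StabilityReport(
        thresholds=[p.threshold for p in partitions],
        n_motus_per_threshold=[p.n_motus for p in partitions],
        n_congruent=len(common),
        n_sensitive_specimens=n_sensitive,
        pct_sensitive=round(100.0 * n_sensitive / len(all_specimens), 1),
        congruent_labels=sorted(min(c) for c in common),
    )
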