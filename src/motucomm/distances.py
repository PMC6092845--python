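"""Specimen I/O and uncorrected pairwise distances.

Barcodes are treated as a pre-aligned, primer-defined amplicon region:
all sequences must have equal length and the uncorrected p-distance is
the proportion of mismatches among compared sites.  A site is compared
only when both sequences carry an unambiguous base (A/C/G/T); gaps, N
and IUPAC ambiguity codes are removed pairwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Characters counted as comparable sites.
UNAMBIGUOUS = b"ACGT"

#: Default minimum number of jointly unambiguous sites for a defined distance.
DEFAULT_MIN_OVERLAP = 100

LIFE_STAGES = ("larva", "adult", "unknown")


@dataclass(frozen=True)
class SpecimenRecord:
    """One barcoded specimen with its collection metadata."""

    specimen_id: str
    sequence: str
    site: str = "unknown"
    habitat: str = "unknown"
    life_stage: str = "unknown"

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValueError("specimen_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"empty sequence for specimen {self.specimen_id!r}")


@dataclass
class DistanceMatrix:
    """Symmetric uncorrected p-distance matrix over specimens.

    ``condensed == np.nan`` marks pairs whose site overlap fell below the
    configured minimum; such pairs must be resolved before clustering.
    """

    ids: list[str]
    d: np.ndarray
    overlap: np.ndarray
    min_overlap: int = DEFAULT_MIN_OVERLAP

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.overlap.shape != (n, n):
            raise ValueError("matrix shapes do not match id count")

    @property
    def n(self) -> int:
        return len(self.ids)

    def undefined_pairs(self) -> list[tuple[str, str]]:
        """Pairs whose distance is undefined (insufficient site overlap)."""
        i, j = np.where(np.isnan(np.triu(self.d, k=1)))
        mask = i < j
        return [(self.ids[a], self.ids[b]) for a, b in zip(i[mask], j[mask])]

    def is_fully_defined(self) -> bool:
        return not np.isnan(self.d).any()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write_square(self, path: str | Path) -> None:
        """Square labelled matrix as tab-separated text."""
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f")

    def write_lower_triangular(self, path: str | Path) -> None:
        """Lower-triangular rows ``id<TAB>d(i,0)..d(i,i-1)``."""
        with open(path, "w") as fh:
            for i, name in enumerate(self.ids):
                vals = "\t".join(f"{self.d[i, j]:.6f}" for j in range(i))
                fh.write(f"{name}\t{vals}\n" if vals else f"{name}\n")


def read_specimens(
    fasta_path: str | Path,
    metadata_path: str | Path,
    *,
    strict: bool = True,
) -> list[SpecimenRecord]:
    """Join FASTA barcodes to a tab-separated metadata table.

    The first whitespace-delimited token of each FASTA header is the
    specimen ID and must match a ``specimen_id`` row in the metadata.
    In strict mode any unmatched or duplicate ID aborts; in lenient mode
    unmatched FASTA records are dropped with a warning.
    """
    seqs: dict[str, str] = {}
    dupes: list[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            dupes.append(rec.id)
        seqs[rec.id] = str(rec.seq).upper()
    if dupes:
        raise ValueError(f"duplicate FASTA specimen IDs: {sorted(set(dupes))}")

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("unknown")
    if "specimen_id" not in meta.columns:
        raise ValueError("metadata must have a 'specimen_id' column")
    if meta["specimen_id"].duplicated().any():
        raise ValueError(
            "duplicate metadata specimen IDs: "
            f"{sorted(meta.loc[meta['specimen_id'].duplicated(), 'specimen_id'])}"
        )
    meta = meta.set_index("specimen_id")

    unmatched_fasta = sorted(set(seqs) - set(meta.index))
    unmatched_meta = sorted(set(meta.index) - set(seqs))
    if strict and (unmatched_fasta or unmatched_meta):
        raise ValueError(
            f"unmatched IDs: fasta-only={unmatched_fasta}, metadata-only={unmatched_meta}"
        )
    for sid in unmatched_fasta:
        logger.warning("dropping FASTA record with no metadata: %s", sid)
    for sid in unmatched_meta:
        logger.warning("metadata row with no sequence: %s", sid)

    records = []
    for sid in seqs:
        if sid not in meta.index:
            continue
        row = meta.loc[sid]
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                sequence=seqs[sid],
                site=row.get("site", "unknown"),
                habitat=row.get("habitat", "unknown"),
                life_stage=row.get("life_stage", "unknown"),
            )
        )
    return records


def _encode(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Byte-encode a sequence and mask its unambiguous (A/C/G/T) sites."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    valid = np.isin(arr, np.frombuffer(UNAMBIGUOUS, dtype=np.uint8))
    return arr, valid


def p_distance(
    seq_a: str, seq_b: str, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> float:
    """Uncorrected p-distance with pairwise deletion.

    Returns ``nan`` when fewer than ``min_overlap`` sites are jointly
    unambiguous.  Raises on unequal lengths: trim or align upstream —
    the pipeline assumes a fixed amplicon region.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"unequal sequence lengths ({len(seq_a)} vs {len(seq_b)}); "
            "trim/align to a common region upstream"
        )
    a, va = _encode(seq_a)
    b, vb = _encode(seq_b)
    both = va & vb
    n_comp = int(both.sum())
    if n_comp < min_overlap:
        return float("nan")
    if n_comp == 0:
        return float("nan")
    return float(((a != b) & both).sum() / n_comp)


def pairwise_matrix(
    records: Sequence[SpecimenRecord],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    *,
    strict: bool = False,
) -> DistanceMatrix:
    """All-pairs uncorrected p-distance matrix (vectorised).

    Pairs with overlap below ``min_overlap`` are set to ``nan`` and
    reported; in strict mode any such pair raises.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    lengths = {len(r.sequence) for r in records}
    if len(lengths) > 1:
        raise ValueError(
            f"sequences have unequal lengths {sorted(lengths)}; "
            "trim/align to a common region upstream"
        )
    ids = [r.specimen_id for r in records]
    if len(set(ids)) != len(ids):
        seen, dup = set(), set()
        for s in ids:
            (dup if s in seen else seen).add(s)
        raise ValueError(f"duplicate specimen IDs: {sorted(dup)}")

    n = len(records)
    L = lengths.pop()
    arr = np.empty((n, L), dtype=np.uint8)
    valid = np.empty((n, L), dtype=bool)
    for i, r in enumerate(records):
        arr[i], valid[i] = _encode(r.sequence)

    d = np.zeros((n, n), dtype=float)
    overlap = np.empty((n, n), dtype=np.int64)
    np.fill_diagonal(overlap, valid.sum(axis=1))
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        n_comp = both.sum(axis=1)
        mism = ((arr[i] != arr[i + 1 :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(n_comp >= max(min_overlap, 1), mism / n_comp, np.nan)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
        overlap[i, i + 1 :] = n_comp
        overlap[i + 1 :, i] = n_comp

    mat = DistanceMatrix(ids=ids, d=d, overlap=overlap, min_overlap=min_overlap)
    bad = mat.undefined_pairs()
    if bad:
        if strict:
            raise ValueError(f"pairs below min_overlap={min_overlap}: {bad}")
        logger.warning("%d pairs below min_overlap=%d", len(bad), min_overlap)
    return mat
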