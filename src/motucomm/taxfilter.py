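"""Rule-based taxonomic contamination filter for MOTUs.

After clustering, each MOTU is kept or discarded based on the top-10
taxonomic hits of its specimens (BLAST-tabular-like rows augmented with
a taxon label).  A MOTU is kept when it satisfies any of six ordered
criteria; the first criterion satisfied is recorded, so kept MOTUs are
partitioned by criterion:

1. any hit to the target family above the identity threshold (> 96%);
2. all 10 of the top-10 hits are the target family;
3. 7–9 of the top-10 hits are the target family;
4. fewer than 7 target hits, but every non-target hit is to a "very
   different" taxon that cannot be confused with the target's larvae;
5. a large MOTU (> 10 specimens) whose top hits are all Schizophora —
   large enough to rule out a pre-sorting error;
6. some top hits are to other aquatic Diptera, but the best target-hit
   identity is strictly higher than the best aquatic-Diptera identity.

MOTU-level summaries use the hit profile of a representative specimen
(longest sequence, ties broken by smallest ID), except the best target
identity, which is taken over all member specimens.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HitRecord:
    """One ranked taxonomic hit for one specimen."""

    query_id: str
    subject_taxon: str
    percent_identity: float
    rank: int


@dataclass
class FilterConfig:
    """Thresholds and taxon sets behind the six keep-criteria."""

    target_taxon: str = "Chironomidae"
    identity_threshold: float = 96.0
    large_motu_min: int = 11  # "> 10 specimens"
    schizophora_label: str = "Schizophora"
    aquatic_diptera_taxa: frozenset[str] = frozenset(
        {"Ceratopogonidae", "Culicidae", "Simuliidae", "Chaoboridae", "Dixidae"}
    )
    very_different_taxa: frozenset[str] = frozenset(
        {"Tachinidae", "Drosophilidae", "Syrphidae", "Muscidae", "Lepidoptera"}
    )

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 100:
            raise ValueError("identity_threshold must be in (0, 100]")
        for name in ("aquatic_diptera_taxa", "very_different_taxa"):
            taxa = getattr(self, name)
            if self.target_taxon in taxa:
                raise ValueError(f"{name} must not contain the target taxon")
            setattr(self, name, frozenset(taxa))


@dataclass
class FilterDecision:
    """Keep/discard verdict for one MOTU with the criterion that fired."""

    motu_label: str
    kept: bool
    criterion: int | None  # 1..6, or None when no criterion fired
    n_specimens: int
    evidence: dict = field(default_factory=dict)


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a tab-separated hit table (query_id, subject_taxon, percent_identity, rank)."""
    df = pd.read_csv(path, sep="\t")
    return [
        HitRecord(
            query_id=str(r.query_id),
            subject_taxon=str(r.subject_taxon),
            percent_identity=float(r.percent_identity),
            rank=int(r.rank),
        )
        for r in df.itertuples()
    ]


def group_hits_by_query(rows: Iterable[HitRecord]) -> dict[str, list[HitRecord]]:
    by_query: dict[str, list[HitRecord]] = {}
    for row in rows:
        by_query.setdefault(row.query_id, []).append(row)
    for q, hits in by_query.items():
        hits.sort(key=lambda h: h.rank)
        if len({h.rank for h in hits}) != len(hits):
            raise ValueError(f"duplicate hit ranks for query {q}")
        if len(hits) > 10:
            raise ValueError(f"more than 10 hits for query {q}")
    return by_query


def choose_representative(
    specimen_ids: Iterable[str], seq_lengths: Mapping[str, int] | None = None
) -> str:
    """Representative = longest sequence, tie (or no lengths) -> smallest ID."""
    ids = sorted(specimen_ids)
    if seq_lengths:
        return min(ids, key=lambda s: (-seq_lengths.get(s, 0), s))
    return ids[0]


def evaluate_motu(
    motu_label: str,
    motu_hits: Mapping[str, Sequence[HitRecord]],
    n_specimens: int,
    config: FilterConfig | None = None,
    representative: str | None = None,
) -> FilterDecision:
    """Apply the six ordered keep-criteria to one MOTU's hit profiles.

    ``motu_hits`` maps each member specimen to its ranked hits (<= 10).
    An empty hit table yields a discard with ``criterion=None`` and a
    warning — distinct from "evaluated but no criterion satisfied".
    """
    config = config or FilterConfig()
    all_rows = [h for hits in motu_hits.values() for h in hits]
    if not all_rows:
        logger.warning("MOTU %s has no hit data; discarded unevaluated", motu_label)
        return FilterDecision(
            motu_label=motu_label,
            kept=False,
            criterion=None,
            n_specimens=n_specimens,
            evidence={"note": "empty hit table"},
        )

    rep = representative or choose_representative(motu_hits.keys())
    rep_hits = sorted(motu_hits.get(rep, []), key=lambda h: h.rank)

    target_rows = [h for h in all_rows if h.subject_taxon == config.target_taxon]
    best_target = max((h.percent_identity for h in target_rows), default=None)

    top_target = [h for h in rep_hits if h.subject_taxon == config.target_taxon]
    top_nontarget = [h for h in rep_hits if h.subject_taxon != config.target_taxon]
    aquatic = [h for h in rep_hits if h.subject_taxon in config.aquatic_diptera_taxa]
    best_aquatic = max((h.percent_identity for h in aquatic), default=None)

    evidence = {
        "n_top10": len(rep_hits),
        "n_target_top10": len(top_target),
        "best_target_identity": best_target,
        "best_aquatic_identity": best_aquatic,
        "representative": rep,
    }

    criterion: int | None = None
    if best_target is not None and best_target > config.identity_threshold:
        criterion = 1
    elif len(rep_hits) == 10 and len(top_target) == 10:
        criterion = 2
    elif 7 <= len(top_target) <= 9:
        criterion = 3
    elif (
        len(top_target) < 7
        and top_nontarget
        and all(h.subject_taxon in config.very_different_taxa for h in top_nontarget)
    ):
        criterion = 4
    elif n_specimens >= config.large_motu_min and rep_hits and all(
        h.subject_taxon == config.schizophora_label for h in rep_hits
    ):
        criterion = 5
    elif (
        aquatic
        and best_target is not None
        and best_aquatic is not None
        and best_target > best_aquatic
    ):
        criterion = 6

    return FilterDecision(
        motu_label=motu_label,
        kept=criterion is not None,
        criterion=criterion,
        n_specimens=n_specimens,
        evidence=evidence,
    )


@dataclass
class FilterSummary:
    """Dataset-level outcome of the contamination filter."""

    retained_specimens: frozenset[str]
    decisions: list[FilterDecision]
    n_specimens_total: int
    n_specimens_removed: int
    motus_per_criterion: dict[str, int]
    retention_pct: float

    def to_dict(self) -> dict:
        return {
            "n_specimens_total": self.n_specimens_total,
            "n_specimens_retained": len(self.retained_specimens),
            "n_specimens_removed": self.n_specimens_removed,
            "retention_pct": self.retention_pct,
            "motus_per_criterion": self.motus_per_criterion,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_decisions_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("motu_label\tkept\tcriterion\tn_specimens\n")
            for d in self.decisions:
                crit = d.criterion if d.criterion is not None else "none"
                fh.write(f"{d.motu_label}\t{d.kept}\t{crit}\t{d.n_specimens}\n")


def filter_dataset(
    partition,
    hit_rows: Iterable[HitRecord],
    config: FilterConfig | None = None,
    seq_lengths: Mapping[str, int] | None = None,
    *,
    strict: bool = True,
) -> FilterSummary:
    """Evaluate every MOTU of a partition and pool the retained specimens.

    ``partition`` is a :class:`~motucomm.clustering.MotuPartition`.  In
    strict mode a specimen without hit data aborts; otherwise it simply
    contributes an empty table.
    """
    config = config or FilterConfig()
    by_query = group_hits_by_query(hit_rows)
    all_specimens = partition.specimens
    missing = sorted(all_specimens - set(by_query))
    if missing and strict:
        raise ValueError(f"specimens with no hit data: {missing[:10]}" +
                         (f" (+{len(missing) - 10} more)" if len(missing) > 10 else ""))

    decisions = []
    retained: set[str] = set()
    per_criterion: dict[str, int] = {str(k): 0 for k in (1, 2, 3, 4, 5, 6)}
    per_criterion["none"] = 0
    for label in sorted(partition.clusters):
        members = partition.clusters[label]
        motu_hits = {sid: by_query.get(sid, []) for sid in members}
        rep = choose_representative(members, seq_lengths)
        decision = evaluate_motu(
            label, motu_hits, n_specimens=len(members), config=config,
            representative=rep,
        )
        decisions.append(decision)
        if decision.kept:
            retained |= set(members)
            per_criterion[str(decision.criterion)] += 1
        else:
            per_criterion["none"] += 1

    n_total = len(all_specimens)
    n_removed = n_total - len(retained)
    return FilterSummary(
        retained_specimens=frozenset(retained),
        decisions=decisions,
        n_specimens_total=n_total,
        n_specimens_removed=n_removed,
        motus_per_criterion=per_criterion,
        retention_pct=round(100.0 * len(retained) / n_total, 1) if n_total else 0.0,
    )


def retention_summary(n_sorted: int, n_barcoded: int, n_removed: int) -> dict:
    """Survey-level retention bookkeeping.

    Retained = barcoded − removed; the retention percentage is reported
    against the sorted specimens that were not flagged as contaminants
    (sorted − removed), to one decimal.
    """
    n_retained = n_barcoded - n_removed
    denominator = n_sorted - n_removed
    return {
        "n_sorted": n_sorted,
        "n_barcoded": n_barcoded,
        "n_removed": n_removed,
        "n_retained": n_retained,
        "denominator": denominator,
        "retention_pct": round(100.0 * n_retained / denominator, 1),
    }
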