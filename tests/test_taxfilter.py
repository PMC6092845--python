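"""Rule-based contamination filter: criterion order and dataset summaries."""

import pytest

from motucomm import (
    FilterConfig,
    HitRecord,
    evaluate_motu,
    filter_dataset,
    pairwise_matrix,
    retention_summary,
    simulate_hit_table,
)
from motucomm.clustering import MotuPartition, objective_cluster


def hits(query, rows):
    """rows = [(taxon, identity), ...] sorted by identity descending."""
    rows = sorted(rows, key=lambda r: -r[1])
    return [
        HitRecord(query_id=query, subject_taxon=t, percent_identity=i, rank=r + 1)
        for r, (t, i) in enumerate(rows)
    ]


CHIRO = "Chironomidae"


@pytest.mark.parametrize(
    "rows, n_specimens, kept, criterion",
    [
        # criterion 1: any match to the target family above 96%
        ([(CHIRO, 97.2)] + [("Ceratopogonidae", 90.0)] * 9, 3, True, 1),
        # criterion 2: all 10 top hits are the target family (identities <= 96)
        ([(CHIRO, 94.0 - 0.3 * i) for i in range(10)], 3, True, 2),
        # criterion 3: 7-9 of top 10
        ([(CHIRO, 95.0 - 0.2 * i) for i in range(8)]
         + [("Tachinidae", 91.0), ("Muscidae", 90.0)], 3, True, 3),
        # criterion 4: < 7 target hits but all others very different taxa
        ([(CHIRO, 93.0)] * 3
         + [("Tachinidae", 92.0), ("Drosophilidae", 91.0), ("Syrphidae", 90.5),
            ("Muscidae", 90.0), ("Lepidoptera", 89.0), ("Tachinidae", 88.0),
            ("Syrphidae", 87.0)], 3, True, 4),
        # criterion 5: > 10 specimens, all hits Schizophora
        ([("Schizophora", 95.0 - 0.1 * i) for i in range(10)], 12, True, 5),
        # same profile but small MOTU: not kept
        ([("Schizophora", 95.0 - 0.1 * i) for i in range(10)], 10, False, None),
        # criterion 6: aquatic Diptera present but target identity wins
        ([(CHIRO, 95.0)] * 4 + [("Ceratopogonidae", 94.0)] * 6, 3, True, 6),
        # criterion 6 fails when target identity is not strictly higher
        ([(CHIRO, 93.0)] * 4 + [("Ceratopogonidae", 95.0)] * 6, 3, False, None),
        # designed negative: confidently another family
        ([("Ceratopogonidae", 98.0 - 0.1 * i) for i in range(10)], 3, False, None),
    ],
)
def test_criteria_fire_in_order(rows, n_specimens, kept, criterion):
    decision = evaluate_motu("m1", {"q1": hits("q1", rows)}, n_specimens)
    assert decision.kept is kept
    assert decision.criterion == criterion


def test_first_match_wins_over_later_criteria():
    # satisfies both 1 (97.0 > 96) and 2 (all ten target): criterion 1 reported
    rows = [(CHIRO, 97.0)] + [(CHIRO, 94.0 - 0.1 * i) for i in range(9)]
    decision = evaluate_motu("m1", {"q1": hits("q1", rows)}, 3)
    assert decision.criterion == 1


def test_best_target_identity_taken_over_all_members():
    # representative (smallest ID) has weak hits, another member exceeds 96
    motu_hits = {
        "a1": hits("a1", [("Ceratopogonidae", 95.0)] * 10),
        "a2": hits("a2", [(CHIRO, 97.1)] + [("Ceratopogonidae", 94.0)] * 9),
    }
    decision = evaluate_motu("m1", motu_hits, 2)
    assert decision.criterion == 1
    assert decision.evidence["representative"] == "a1"


def test_empty_hit_table_distinct_from_unsatisfied(caplog):
    with caplog.at_level("WARNING"):
        decision = evaluate_motu("m1", {"q1": []}, 2)
    assert decision.kept is False and decision.criterion is None
    assert "no hit data" in " ".join(caplog.messages)


def test_raising_identity_threshold_never_rescues_a_discard():
    rows = {"q1": hits("q1", [(CHIRO, 95.0)] + [("Culicidae", 96.5)] * 9)}
    base = evaluate_motu("m1", rows, 3, FilterConfig(identity_threshold=94.0))
    stricter = evaluate_motu("m1", rows, 3, FilterConfig(identity_threshold=96.0))
    assert base.criterion == 1
    assert stricter.criterion != 1


def test_filter_dataset_on_archetypes_matches_ground_truth(small_dataset):
    mat = pairwise_matrix(small_dataset.specimens, min_overlap=50)
    partition = objective_cluster(mat, 0.04)
    rows = simulate_hit_table(small_dataset)
    lengths = {r.specimen_id: len(r.sequence) for r in small_dataset.specimens}
    summary = filter_dataset(partition, rows, seq_lengths=lengths)

    arch_of_specimen = {
        rec.specimen_id: small_dataset.archetypes[
            small_dataset.specimen_to_species[rec.specimen_id]
        ]
        for rec in small_dataset.specimens
    }
    expected_fired = {"discard": None}
    for d in summary.decisions:
        member = next(iter(partition.clusters[d.motu_label]))
        arch = arch_of_specimen[member]
        want = None if arch == "discard" else int(arch[-1])
        assert d.criterion == want, (d.motu_label, arch, d.criterion)
    # retained specimens = exactly the target-species specimens
    target_ids = {
        rec.specimen_id
        for rec in small_dataset.specimens
        if arch_of_specimen[rec.specimen_id] != "discard"
    }
    assert summary.retained_specimens == frozenset(target_ids)


def test_filter_dataset_all_kept_means_full_retention(small_dataset):
    mat = pairwise_matrix(small_dataset.specimens, min_overlap=50)
    partition = objective_cluster(mat, 0.04)
    scenario = {sp.species_id: "criterion2" for sp in small_dataset.species}
    rows = simulate_hit_table(small_dataset, scenario)
    summary = filter_dataset(partition, rows)
    assert summary.retention_pct == 100.0
    assert summary.n_specimens_removed == 0


def test_missing_hit_data_strict_vs_lenient():
    partition = MotuPartition(
        threshold=0.04, clusters={"a": frozenset({"a", "b"})}
    )
    with pytest.raises(ValueError, match="no hit data"):
        filter_dataset(partition, [])
    summary = filter_dataset(partition, [], strict=False)
    assert summary.retained_specimens == frozenset()


def test_retention_summary_reports_one_decimal_percent():
    larvae = retention_summary(n_sorted=6620, n_barcoded=4027, n_removed=417)
    assert larvae["n_retained"] == 3610
    assert larvae["denominator"] == 6203
    assert larvae["retention_pct"] == 58.2
    adults = retention_summary(n_sorted=1551, n_barcoded=1278, n_removed=137)
    assert adults["n_retained"] == 1141
    assert adults["denominator"] == 1414
    assert adults["retention_pct"] == pytest.approx(100 * 1141 / 1414, abs=0.05)
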