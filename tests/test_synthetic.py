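"""Synthetic community generator: ground truth, determinism, structure."""

import numpy as np
import pytest

from motucomm import (
    SimulationConfig,
    cluster_at_thresholds,
    pairwise_matrix,
    simulate_community,
    simulate_hit_table,
    simulate_species,
    simulate_specimens,
)
from motucomm.distances import p_distance
from motucomm.synthetic import assign_archetypes


def test_single_species_has_no_pairwise_constraint():
    sp = simulate_species(SimulationConfig(n_species=1, seed=0))
    assert len(sp) == 1 and len(sp[0].centroid_sequence) == 313


def test_centroids_respect_d_inter():
    cfg = SimulationConfig(n_species=25, L=100, d_inter=0.06, seed=1)
    sp = simulate_species(cfg)
    for i in range(len(sp)):
        for j in range(i + 1, len(sp)):
            d = p_distance(sp[i].centroid_sequence, sp[j].centroid_sequence, 1)
            assert d >= 0.06
            assert round(d * 100) >= 6  # >= 6 mismatching sites of 100


def test_simulation_is_deterministic_under_seed():
    cfg = SimulationConfig(n_species=15, seed=7)
    a, b = simulate_community(cfg), simulate_community(cfg)
    assert [s.centroid_sequence for s in a.species] == [
        s.centroid_sequence for s in b.species
    ]
    assert [(r.specimen_id, r.sequence, r.site) for r in a.specimens] == [
        (r.specimen_id, r.sequence, r.site) for r in b.specimens
    ]
    assert simulate_hit_table(a) == simulate_hit_table(b)


def test_infeasible_config_raises_naming_constraint():
    cfg = SimulationConfig(n_species=30, L=4, d_inter=0.9, seed=0, max_retries=20)
    with pytest.raises(RuntimeError, match="d_inter"):
        simulate_species(cfg)


def test_abundance_vector_is_respected():
    cfg = SimulationConfig(
        n_species=2, L=300, d_intra=0.01, abundances=[3, 1], seed=2,
        n_sites=1, n_habitats=1, contaminant_fraction=0.0,
    )
    ds = simulate_specimens(simulate_species(cfg), cfg)
    assert len(ds.specimens) == 4
    counts = sorted(ds.abundances.values())
    assert counts == [1, 3]


def test_zero_intraspecific_noise_gives_identical_sequences():
    cfg = SimulationConfig(
        n_species=3, d_intra=0.0, abundances=[2, 2, 2], seed=3,
        contaminant_fraction=0.0,
    )
    ds = simulate_specimens(simulate_species(cfg), cfg)
    cents = {s.species_id: s.centroid_sequence for s in ds.species}
    for rec in ds.specimens:
        assert rec.sequence == cents[ds.specimen_to_species[rec.specimen_id]]


def test_logseries_singleton_proportion_in_range():
    cfg = SimulationConfig(n_species=300, seed=4)
    ds = simulate_specimens(simulate_species(cfg), cfg)
    assert 0.2 <= ds.singleton_proportion() <= 0.5


def test_site_overlap_zero_gives_endemic_species(small_dataset):
    # every species occurs at exactly one site when overlap = 0
    sites_of = {}
    for rec in small_dataset.specimens:
        sites_of.setdefault(
            small_dataset.specimen_to_species[rec.specimen_id], set()
        ).add(rec.site)
    assert all(len(s) == 1 for s in sites_of.values())


def test_end_to_end_ground_truth_recovery(small_dataset):
    mat = pairwise_matrix(small_dataset.specimens, min_overlap=50)
    truth = frozenset(small_dataset.true_partition().values())
    for p in cluster_at_thresholds(mat, [0.03, 0.04, 0.05]):
        assert p.n_motus == small_dataset.config.n_species
        assert p.member_sets() == truth


def test_unknown_archetype_rejected(small_dataset):
    scenario = {sp.species_id: "criterion9" for sp in small_dataset.species}
    with pytest.raises(ValueError, match="criterion9"):
        simulate_hit_table(small_dataset, scenario)


def test_criterion5_needs_large_motu():
    cfg = SimulationConfig(
        n_species=2, abundances=[3, 12], seed=5, contaminant_fraction=0.0,
        n_sites=1, n_habitats=1,
    )
    ds = simulate_specimens(simulate_species(cfg), cfg)
    ids = [s.species_id for s in ds.species]
    small, big = sorted(ids, key=lambda s: ds.abundances[s])
    with pytest.raises(ValueError, match="> 10 specimens"):
        simulate_hit_table(ds, {small: "criterion5", big: "criterion2"})
    rows = simulate_hit_table(ds, {small: "criterion2", big: "criterion5"})
    assert {r.query_id for r in rows} == {r.specimen_id for r in ds.specimens}


def test_hit_rows_ranked_and_capped(small_dataset):
    rows = simulate_hit_table(small_dataset)
    by_query = {}
    for r in rows:
        by_query.setdefault(r.query_id, []).append(r)
    for hits in by_query.values():
        hits.sort(key=lambda h: h.rank)
        assert len(hits) <= 10
        idents = [h.percent_identity for h in hits]
        assert idents == sorted(idents, reverse=True)


def test_contaminants_get_discard_archetype(small_dataset):
    arch = assign_archetypes(small_dataset)
    for sp in small_dataset.species:
        if not sp.is_target:
            assert arch[sp.species_id] == "discard"
        else:
            assert arch[sp.species_id].startswith("criterion")


def test_written_files_round_trip(tmp_path, small_dataset):
    small_dataset.write_fasta(tmp_path / "s.fasta")
    small_dataset.write_metadata(tmp_path / "m.tsv")
    from motucomm import read_specimens

    recs = read_specimens(tmp_path / "s.fasta", tmp_path / "m.tsv")
    assert len(recs) == len(small_dataset.specimens)
    by_id = {r.specimen_id: r for r in recs}
    for rec in small_dataset.specimens:
        assert by_id[rec.specimen_id].sequence == rec.sequence
        assert by_id[rec.specimen_id].habitat == rec.habitat
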