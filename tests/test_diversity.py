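"""Richness/diversity estimators, rarefaction and coverage standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio.diversity.alpha import chao1 as skbio_chao1

from motucomm import (
    CommunityMatrix,
    build_matrix,
    chao1,
    chao2,
    hill_number,
    pairwise_matrix,
    rarefy_extrapolate,
    sample_coverage,
    singleton_stats,
    standardize_to_coverage,
)
from motucomm.clustering import objective_cluster
from motucomm.diversity import rarefied_coverage, rarefied_richness

ABUND = st.lists(st.integers(1, 20), min_size=1, max_size=40)


@pytest.mark.parametrize(
    "x, expected",
    [
        ([2, 2, 2], 3.0),                      # no singletons: estimate = observed
        ([1, 1, 2, 3, 5], 5 + (11 / 12) * 2),  # f1=2, f2=1, n=12
        ([1], 1.0),                            # bias-corrected, f1(f1-1)=0
    ],
)
def test_chao1_point_examples(x, expected):
    assert chao1(x).point == pytest.approx(expected)


def test_chao1_agrees_with_skbio_up_to_small_sample_factor(rng):
    # classic (uncorrected) Chao1 lacks the (n-1)/n factor; undo it exactly
    for _ in range(10):
        x = rng.integers(1, 9, size=25)
        est = chao1(x)
        n, s = est.inputs["n"], est.inputs["S_obs"]
        if est.inputs["f2"] == 0:
            continue
        classic = s + (est.point - s) * n / (n - 1)
        assert classic == pytest.approx(skbio_chao1(x, bias_corrected=False))


def test_chao2_point_examples():
    # occupancy [4,3,2,1,1] over 4 units: q1=2, q2=1 -> 5 + 0.75*2 = 6.5
    inc = np.zeros((4, 5))
    for s, occ in enumerate([4, 3, 2, 1, 1]):
        inc[:occ, s] = 1
    assert chao2(inc).point == pytest.approx(6.5)
    # no uniques -> point = S_obs
    assert chao2(np.ones((3, 4)) * 2).point == pytest.approx(4.0)
    with pytest.raises(ValueError, match="2 sampling units"):
        chao2(np.ones((1, 4)))


@given(x=ABUND)
@settings(deadline=None)
def test_chao_estimators_never_below_observed(x):
    est = chao1(x)
    assert est.point >= est.inputs["S_obs"] - 1e-9
    lo, hi = est.ci95
    assert lo - 1e-9 <= est.point <= hi + 1e-9
    if est.inputs["f1"] == 0:
        assert est.point == pytest.approx(est.inputs["S_obs"])


@pytest.mark.parametrize(
    "x, q, expected",
    [
        ([10, 10, 10], 0, 3.0),
        ([10, 10, 10], 1, 3.0),
        ([10, 10, 10], 2, 3.0),
        ([9, 1], 1, 1.3841),
        ([9, 1], 2, 1.2195),
    ],
)
def test_hill_number_examples(x, q, expected):
    assert hill_number(x, q) == pytest.approx(expected, abs=1e-3)


@given(x=ABUND)
@settings(deadline=None)
def test_hill_numbers_nonincreasing_in_q(x):
    values = [hill_number(x, q) for q in (0, 0.5, 1, 2, 3)]
    assert values[0] == len(x)
    for a, b in zip(values, values[1:]):
        assert a >= b - 1e-9


def test_hill_rejects_negative_q():
    with pytest.raises(ValueError):
        hill_number([1, 2], -1)


@pytest.mark.parametrize(
    "x, expected",
    [
        ([2, 2, 3], 1.0),             # f1 = 0
        ([1, 1, 2, 3, 3], 0.82),      # n=10, f1=2, f2=1
        ([1], 0.0),                   # single specimen
    ],
)
def test_sample_coverage_examples(x, expected):
    assert sample_coverage(x) == pytest.approx(expected)


def test_rarefaction_boundary_values(rng):
    x = rng.integers(1, 10, size=15)
    n = int(x.sum())
    assert rarefied_richness(x, 1) == pytest.approx(1.0)
    assert rarefied_richness(x, n) == pytest.approx(len(x))
    assert rarefied_richness([2, 2], 2) == pytest.approx(2 - 2 / 6)


def test_interpolated_curve_matches_monte_carlo(rng):
    x = np.array([1, 1, 1, 2, 3, 5, 8, 13, 2, 1])
    pool = np.repeat(np.arange(len(x)), x)
    for k in (2, 5, 10, 20, 30):
        draws = np.array(
            [
                len(np.unique(rng.choice(pool, size=k, replace=False)))
                for _ in range(10_000)
            ]
        )
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(rarefied_richness(x, k) - draws.mean()) <= 3 * max(se, 1e-9)


def test_curve_shape_and_bootstrap_band(rng):
    x = rng.integers(1, 6, size=30)
    n = int(x.sum())
    curve = rarefy_extrapolate(x, n_boot=100, seed=0)
    r = np.array(curve.expected_richness)
    assert (np.diff(r) >= -1e-9).all()
    at_n = curve.sizes.index(n)
    assert r[at_n] == pytest.approx(len(x))
    # interpolated part is concave: divided differences non-increasing
    interp = r[: at_n + 1]
    ks = np.array(curve.sizes[: at_n + 1], dtype=float)
    if len(interp) > 2:
        slopes = np.diff(interp) / np.diff(ks)
        assert (np.diff(slopes) <= 1e-9).all()
    # singleton-bearing sample: positive band width at the reference size
    if (x == 1).any():
        assert curve.ci_high[at_n] - curve.ci_low[at_n] > 0
    assert curve.n_boot == 100


def test_extrapolation_cap_enforced(rng):
    x = rng.integers(1, 6, size=10)
    n = int(x.sum())
    with pytest.raises(ValueError, match="cap"):
        rarefy_extrapolate(x, sizes=[5 * n], extrapolation_factor=2.0)


def test_rarefaction_deterministic_under_seed():
    x = [1, 1, 2, 3, 5, 8]
    a = rarefy_extrapolate(x, n_boot=50, seed=9)
    b = rarefy_extrapolate(x, n_boot=50, seed=9)
    assert a.ci_low == b.ci_low and a.ci_high == b.ci_high


def test_chao1_recovers_deeply_sampled_richness(rng):
    # every species with abundance >= 3: no singletons/doubletons
    x = rng.integers(3, 20, size=50)
    assert chao1(x).point == pytest.approx(50)


def test_chao1_ci_covers_truth_under_shallow_sampling():
    K, n, covered = 100, 200, 0
    for rep in range(100):
        r = np.random.default_rng(1000 + rep)
        counts = np.bincount(r.integers(0, K, size=n), minlength=K)
        lo, hi = chao1(counts[counts > 0]).ci95
        covered += lo <= K <= hi
    assert covered >= 90


def test_build_matrix_counts_and_aggregation(small_dataset):
    mat = pairwise_matrix(small_dataset.specimens, min_overlap=50)
    partition = objective_cluster(mat, 0.04)
    site_matrix = build_matrix(small_dataset.specimens, partition, by="site")
    assert int(site_matrix.counts.values.sum()) == len(small_dataset.specimens)
    # per-site totals match the metadata
    per_site = {}
    for rec in small_dataset.specimens:
        per_site[rec.site] = per_site.get(rec.site, 0) + 1
    assert site_matrix.site_totals().to_dict() == per_site
    # habitat aggregation conserves column sums
    hab = site_matrix.aggregate_by_habitat()
    assert (hab.motu_totals() == site_matrix.motu_totals()).all()
    # matrix equals the simulator's ground-truth allocation
    truth_totals = dict(small_dataset.abundances)
    label_of = {
        min(m): small_dataset.specimen_to_species[min(m)]
        for m in partition.clusters.values()
    }
    for label, species_id in label_of.items():
        assert int(site_matrix.counts[label].sum()) == truth_totals[species_id]


def test_ground_truth_singletons_match_downstream(small_dataset):
    mat = pairwise_matrix(small_dataset.specimens, min_overlap=50)
    partition = objective_cluster(mat, 0.04)
    site_matrix = build_matrix(small_dataset.specimens, partition, by="site")
    f1, _ = singleton_stats(site_matrix.pooled())
    truth = np.array(list(small_dataset.abundances.values()))
    assert f1 == int((truth == 1).sum())


def test_singleton_stats_reporting():
    x = [1] * 54 + [2] * 104
    f1, pct = singleton_stats(x)
    assert (f1, pct) == (54, 34.2)
    assert singleton_stats([2, 3])[1] == 0.0
    assert singleton_stats([1, 1])[1] == 100.0


def test_coverage_standardization_drops_hopeless_sites():
    counts = pd.DataFrame(
        {
            "m1": [20, 1, 1],
            "m2": [15, 1, 0],
            "m3": [10, 1, 1],
            "m4": [5, 1, 0],
        },
        index=["deep", "all_singletons", "sparse"],
    )
    matrix = CommunityMatrix(counts)
    std, report, dropped = standardize_to_coverage(matrix, 0.70, seed=0)
    assert "all_singletons" in dropped
    assert "deep" in std.sites
    for site in std.sites:
        assert report[site]["coverage"] >= 0.70
        assert report[site]["subsample_size"] <= report[site]["n"]
    # determinism
    std2, _, _ = standardize_to_coverage(matrix, 0.70, seed=0)
    assert std.counts.equals(std2.counts)


def test_rarefied_coverage_monotone(rng):
    x = rng.integers(1, 6, size=12)
    n = int(x.sum())
    cov = [rarefied_coverage(x, k) for k in range(1, n + 1)]
    assert all(b >= a - 1e-9 for a, b in zip(cov, cov[1:]))
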