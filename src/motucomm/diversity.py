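"""Community matrices and nonparametric diversity estimation.

Implements the abundance- and incidence-based Chao richness estimators
with their classic variance formulas and log-normal confidence
intervals, Hill numbers of order q, the sample-coverage estimator,
hypergeometric rarefaction with Chao-based extrapolation (bootstrap
confidence bands), and coverage-standardized subsampling of site-by-MOTU
matrices.

Notation: for abundance data, ``n`` specimens, ``S_obs`` observed
species, ``f1``/``f2`` singletons and doubletons; for incidence data
over ``m`` sampling units, ``q1``/``q2`` uniques and duplicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .clustering import MotuPartition
from .distances import SpecimenRecord

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class CommunityMatrix:
    """Site (or habitat) × MOTU abundance matrix."""

    counts: pd.DataFrame  # rows = sites/units, columns = MOTUs, int
    grouping: dict[str, str] | None = None  # site -> habitat

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative abundances")
        self.counts = self.counts.astype(int)

    @property
    def sites(self) -> list[str]:
        return list(self.counts.index)

    @property
    def motus(self) -> list[str]:
        return list(self.counts.columns)

    def site_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def motu_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def pooled(self) -> np.ndarray:
        """Pooled abundance vector across all rows (zero MOTUs dropped)."""
        tot = self.motu_totals().to_numpy()
        return tot[tot > 0]

    def drop_empty_motus(self) -> "CommunityMatrix":
        keep = self.counts.columns[self.counts.sum(axis=0) > 0]
        return CommunityMatrix(self.counts[keep].copy(), self.grouping)

    def aggregate_by_habitat(self) -> "CommunityMatrix":
        if not self.grouping:
            raise ValueError("no site->habitat grouping set")
        grouped = self.counts.groupby(
            self.counts.index.map(self.grouping)
        ).sum()
        grouped.index.name = "habitat"
        return CommunityMatrix(grouped)

    def write_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CommunityMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def build_matrix(
    specimens: Sequence[SpecimenRecord],
    partition: MotuPartition,
    by: str = "site",
) -> CommunityMatrix:
    """Tabulate retained specimens into a unit × MOTU count matrix.

    ``by`` selects the row unit ("site" or "habitat").  Every specimen
    must appear in the partition and carry a non-empty unit label.
    """
    if by not in ("site", "habitat"):
        raise ValueError("by must be 'site' or 'habitat'")
    motu_of = partition.motu_of()
    rows: dict[str, dict[str, int]] = {}
    grouping: dict[str, str] = {}
    for rec in specimens:
        unit = getattr(rec, by)
        if not unit:
            raise ValueError(f"specimen {rec.specimen_id} has no {by} label")
        if rec.specimen_id not in motu_of:
            raise ValueError(f"specimen {rec.specimen_id} missing from partition")
        motu = motu_of[rec.specimen_id]
        rows.setdefault(unit, {}).setdefault(motu, 0)
        rows[unit][motu] += 1
        if by == "site":
            grouping[rec.site] = rec.habitat
    df = pd.DataFrame(rows).T.fillna(0).astype(int)
    df = df.sort_index().reindex(sorted(df.columns), axis=1)
    df.index.name = by
    return CommunityMatrix(df, grouping=grouping if by == "site" else None)


@dataclass
class DiversityEstimate:
    """A point estimate of richness/diversity with its uncertainty."""

    estimator: str
    point: float
    se: float | None
    ci95: tuple[float, float] | None
    inputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "point": self.point,
            "se": self.se,
            "ci95": list(self.ci95) if self.ci95 else None,
            "inputs": self.inputs,
        }


def _chao_lognormal_ci(s_obs: float, point: float, var: float) -> tuple[float, float]:
    """Standard log-normal CI for Chao-type lower-bound estimators."""
    t = point - s_obs
    if t <= 0 or var <= 0:
        return (point, point)
    k = np.exp(Z95 * np.sqrt(np.log1p(var / t**2)))
    return (s_obs + t / k, s_obs + t * k)


def _abundance_counts(x) -> np.ndarray:
    x = np.asarray(x)
    if x.size == 0 or (x < 0).any():
        raise ValueError("need a non-empty vector of non-negative abundances")
    if not np.allclose(x, np.round(x)):
        raise ValueError("abundances must be integers")
    x = x.astype(int)
    if x.sum() == 0:
        raise ValueError("all-zero abundance vector")
    return x[x > 0]


def chao1(abundances) -> DiversityEstimate:
    """Chao1 abundance-based richness with classic variance.

    point = S_obs + ((n−1)/n)·f1²/(2·f2); when f2 = 0 the bias-corrected
    form S_obs + ((n−1)/n)·f1(f1−1)/2 is used.
    """
    x = _abundance_counts(abundances)
    n = int(x.sum())
    s_obs = len(x)
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    a = (n - 1) / n if n > 1 else 0.0
    if f2 > 0:
        point = s_obs + a * f1**2 / (2 * f2)
        r = f1 / f2
        var = f2 * (a / 2 * r**2 + a**2 * r**3 + a**2 / 4 * r**4)
    else:
        point = s_obs + a * f1 * (f1 - 1) / 2
        var = (
            a * f1 * (f1 - 1) / 2
            + a**2 * f1 * (2 * f1 - 1) ** 2 / 4
            - (a**2 * f1**4 / (4 * point) if point > 0 else 0.0)
        )
    var = max(var, 0.0)
    return DiversityEstimate(
        estimator="Chao1",
        point=float(point),
        se=float(np.sqrt(var)),
        ci95=_chao_lognormal_ci(s_obs, point, var),
        inputs={"S_obs": s_obs, "f1": f1, "f2": f2, "n": n},
    )


def chao2(incidence) -> DiversityEstimate:
    """Chao2 incidence-based richness over m sampling units.

    ``incidence`` is a units × species matrix (counts are binarized).
    point = S_obs + ((m−1)/m)·q1²/(2·q2), bias-corrected when q2 = 0.
    """
    inc = np.asarray(getattr(incidence, "values", incidence))
    if inc.ndim != 2:
        raise ValueError("incidence must be a 2-D units × species matrix")
    m = inc.shape[0]
    if m < 2:
        raise ValueError(f"need at least 2 sampling units, got {m}")
    y = (inc > 0).sum(axis=0)
    y = y[y > 0]
    s_obs = len(y)
    if s_obs == 0:
        raise ValueError("no species present in any unit")
    q1 = int((y == 1).sum())
    q2 = int((y == 2).sum())
    a = (m - 1) / m
    if q2 > 0:
        point = s_obs + a * q1**2 / (2 * q2)
        r = q1 / q2
        var = q2 * (a / 2 * r**2 + a**2 * r**3 + a**2 / 4 * r**4)
    else:
        point = s_obs + a * q1 * (q1 - 1) / 2
        var = (
            a * q1 * (q1 - 1) / 2
            + a**2 * q1 * (2 * q1 - 1) ** 2 / 4
            - (a**2 * q1**4 / (4 * point) if point > 0 else 0.0)
        )
    var = max(var, 0.0)
    return DiversityEstimate(
        estimator="Chao2",
        point=float(point),
        se=float(np.sqrt(var)),
        ci95=_chao_lognormal_ci(s_obs, point, var),
        inputs={"S_obs": s_obs, "q1": q1, "q2": q2, "m": m},
    )


def hill_number(abundances, q: float) -> float:
    """Hill number of order q: effective number of equally common species.

    q = 0 is richness, q = 1 exponential Shannon (continuous limit),
    q = 2 inverse Simpson.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    x = _abundance_counts(abundances).astype(float)
    p = x / x.sum()
    if abs(q - 1) < 1e-9:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1 / (1 - q)))


def sample_coverage(abundances) -> float:
    """Estimated sample coverage Ĉ = 1 − (f1/n)·(n−1)f1/((n−1)f1 + 2f2)."""
    x = _abundance_counts(abundances)
    n = int(x.sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f1 == 0:
        return 1.0
    denom = (n - 1) * f1 + 2 * f2
    bracket = (n - 1) * f1 / denom if denom > 0 else 1.0
    return float(1 - (f1 / n) * bracket)


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness(abundances, k: int) -> float:
    """Expected richness of a hypergeometric subsample of size k ≤ n."""
    x = _abundance_counts(abundances)
    n = int(x.sum())
    if not 1 <= k <= n:
        raise ValueError(f"subsample size {k} outside [1, n={n}]")
    keep = (n - x) >= k
    terms = np.exp(_log_comb(n - x[keep], k) - _log_comb(n, k)) if keep.any() else 0.0
    return float(len(x) - np.sum(terms))


def rarefied_coverage(abundances, k: int) -> float:
    """Expected coverage of a subsample of size k ≤ n (Ĉ at k = n)."""
    x = _abundance_counts(abundances)
    n = int(x.sum())
    if not 1 <= k <= n:
        raise ValueError(f"subsample size {k} outside [1, n={n}]")
    if k == n:
        return sample_coverage(x)
    keep = (n - x) >= k
    terms = (
        np.sum(x[keep] / n * np.exp(_log_comb(n - x[keep], k) - _log_comb(n - 1, k)))
        if keep.any()
        else 0.0
    )
    return float(1 - terms)


def _extrapolated_richness(x: np.ndarray, k: int) -> float:
    n = int(x.sum())
    s_obs = len(x)
    f1 = int((x == 1).sum())
    f0 = chao1(x).point - s_obs
    if f0 <= 0 or f1 == 0:
        return float(s_obs)
    return float(s_obs + f0 * (1 - (1 - f1 / (n * f0 + f1)) ** (k - n)))


def _extrapolated_coverage(x: np.ndarray, k: int) -> float:
    n = int(x.sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f1 == 0:
        return 1.0
    denom = (n - 1) * f1 + 2 * f2
    a = (n - 1) * f1 / denom if denom > 0 else 1.0
    return float(1 - f1 / n * a ** (k - n + 1))


def _richness_at(x: np.ndarray, k: int) -> float:
    n = int(x.sum())
    return rarefied_richness(x, k) if k <= n else _extrapolated_richness(x, k)


@dataclass
class RarefactionCurve:
    """Rarefaction/extrapolation curve with bootstrap confidence band."""

    sizes: list[int]
    expected_richness: list[float]
    ci_low: list[float]
    ci_high: list[float]
    coverage: list[float]
    n_boot: int
    reference_n: int
    s_obs: int

    def to_dict(self) -> dict:
        return {
            "sizes": self.sizes,
            "expected_richness": self.expected_richness,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "coverage": self.coverage,
            "n_boot": self.n_boot,
            "reference_n": self.reference_n,
            "s_obs": self.s_obs,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("size\texpected_richness\tci_low\tci_high\tcoverage\n")
            for row in zip(
                self.sizes, self.expected_richness, self.ci_low,
                self.ci_high, self.coverage,
            ):
                fh.write("{}\t{:.4f}\t{:.4f}\t{:.4f}\t{:.6f}\n".format(*row))


def _bootstrap_probabilities(x: np.ndarray) -> np.ndarray:
    """Coverage-adjusted community for the rarefaction bootstrap.

    Seen species get shrunk probabilities that sum to Ĉ; the Chao1
    estimate of the number of unseen species shares the remaining
    1 − Ĉ equally.
    """
    n = int(x.sum())
    cov = sample_coverage(x)
    p = x / n
    f0 = int(np.ceil(chao1(x).point - len(x)))
    if cov >= 1.0 or f0 <= 0:
        return p
    w = p * (1 - p) ** n
    lam = (1 - cov) / w.sum() if w.sum() > 0 else 0.0
    p_seen = p * (1 - lam * (1 - p) ** n)
    p_unseen = np.full(f0, (1 - cov) / f0)
    return np.concatenate([p_seen, p_unseen])


def rarefy_extrapolate(
    abundances,
    sizes: Sequence[int] | None = None,
    n_boot: int = 200,
    seed: int | None = None,
    extrapolation_factor: float = 2.0,
) -> RarefactionCurve:
    """Rarefaction/extrapolation curve with a 200-replicate bootstrap band.

    Interpolation is exact hypergeometric; extrapolation uses the
    Chao1-based unseen-species estimate and is capped at
    ``extrapolation_factor`` × the reference sample size.  Confidence
    bands are point ± 1.96 × bootstrap SE.
    """
    x = _abundance_counts(abundances)
    n = int(x.sum())
    cap = int(np.floor(extrapolation_factor * n))
    if sizes is None:
        sizes = sorted(set(np.unique(np.linspace(1, cap, 40).astype(int))) | {n})
    sizes = [int(k) for k in sizes]
    if any(k < 1 for k in sizes):
        raise ValueError("sizes must be >= 1")
    too_big = [k for k in sizes if k > cap]
    if too_big:
        raise ValueError(
            f"sizes {too_big} exceed the extrapolation cap "
            f"{extrapolation_factor}×n = {cap}"
        )

    expected = [_richness_at(x, k) for k in sizes]
    coverage = [
        rarefied_coverage(x, k) if k <= n else _extrapolated_coverage(x, k)
        for k in sizes
    ]

    rng = np.random.default_rng(seed)
    probs = _bootstrap_probabilities(x)
    boot = np.empty((n_boot, len(sizes)))
    for b in range(n_boot):
        sample = rng.multinomial(n, probs)
        sample = sample[sample > 0]
        boot[b] = [_richness_at(sample, k) for k in sizes]
    se = boot.std(axis=0, ddof=1)
    return RarefactionCurve(
        sizes=sizes,
        expected_richness=[float(v) for v in expected],
        ci_low=[float(v - Z95 * s) for v, s in zip(expected, se)],
        ci_high=[float(v + Z95 * s) for v, s in zip(expected, se)],
        coverage=[float(c) for c in coverage],
        n_boot=n_boot,
        reference_n=n,
        s_obs=len(x),
    )


def standardize_to_coverage(
    matrix: CommunityMatrix,
    target_coverage: float = 0.70,
    seed: int | None = None,
) -> tuple[CommunityMatrix, dict[str, dict], list[str]]:
    """Subsample every site to the smallest size reaching the coverage target.

    Sites whose estimated coverage never reaches the target (even at
    full size) are dropped and listed.  Subsampling is without
    replacement at a fixed seed, so results are reproducible.

    Returns (standardized matrix, per-site report, dropped sites).
    """
    if not 0 < target_coverage < 1:
        raise ValueError("target_coverage must be in (0,1)")
    rng = np.random.default_rng(seed)
    report: dict[str, dict] = {}
    dropped: list[str] = []
    new_rows = {}
    for site in matrix.sites:
        row = matrix.counts.loc[site].to_numpy()
        x = row[row > 0]
        if x.size == 0:
            dropped.append(site)
            report[site] = {"n": 0, "subsample_size": None, "coverage": 0.0}
            continue
        n = int(x.sum())
        full_cov = sample_coverage(x)
        if full_cov < target_coverage:
            dropped.append(site)
            report[site] = {"n": n, "subsample_size": None, "coverage": full_cov}
            continue
        lo, hi = 1, n  # coverage is non-decreasing in subsample size
        while lo < hi:
            mid = (lo + hi) // 2
            if rarefied_coverage(x, mid) >= target_coverage:
                hi = mid
            else:
                lo = mid + 1
        k = lo
        pool = np.repeat(np.arange(len(row)), row)
        chosen = rng.choice(pool, size=k, replace=False)
        sub = np.bincount(chosen, minlength=len(row))
        new_rows[site] = sub
        report[site] = {
            "n": n,
            "subsample_size": k,
            "coverage": float(rarefied_coverage(x, k)),
        }
    if not new_rows:
        raise ValueError("no site reaches the target coverage")
    df = pd.DataFrame.from_dict(new_rows, orient="index")
    df.columns = matrix.counts.columns
    df.index.name = matrix.counts.index.name
    sub_matrix = CommunityMatrix(df, matrix.grouping).drop_empty_motus()
    return sub_matrix, report, dropped


def singleton_stats(abundances) -> tuple[int, float]:
    """Number of singleton species and their share of observed species (1-dp %)."""
    x = _abundance_counts(abundances)
    f1 = int((x == 1).sum())
    return f1, round(100.0 * f1 / len(x), 1)
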