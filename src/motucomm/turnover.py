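"""Between-site and between-habitat community turnover.

Bray-Curtis dissimilarity on raw abundances (optionally square-root
transformed), one-tailed Mantel permutation tests with Pearson's r, and
shared-species inventories with per-species directionality (which
habitat holds the larger abundance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_braycurtis

from .diversity import CommunityMatrix

DEFAULT_N_PERM = 999


def bray_curtis(x, y, sqrt_transform: bool = False) -> float:
    """Bray-Curtis dissimilarity 1 − 2·Σmin(x,y)/(Σx + Σy)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors have different lengths")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two empty assemblages")
    if sqrt_transform:
        x, y = np.sqrt(x), np.sqrt(y)
    return float(_scipy_braycurtis(x, y))


@dataclass
class DissimilarityMatrix:
    """Symmetric dissimilarity matrix over sites/habitats."""

    units: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.units)
        if self.values.shape != (n, n):
            raise ValueError("shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix not symmetric")
        if np.diag(self.values).any():
            raise ValueError("diagonal must be zero")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("values must lie in [0,1]")

    @property
    def n(self) -> int:
        return len(self.units)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.units, columns=self.units)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f")


def dissimilarity_matrix(
    matrix: CommunityMatrix, sqrt_transform: bool = False
) -> DissimilarityMatrix:
    """All-pairs Bray-Curtis over the rows of a community matrix."""
    units = matrix.sites
    n = len(units)
    vals = np.zeros((n, n))
    rows = matrix.counts.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = bray_curtis(
                rows[i], rows[j], sqrt_transform=sqrt_transform
            )
    return DissimilarityMatrix(units=units, values=vals)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    n_units: int

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n_perm": self.n_perm, "n_units": self.n_units}


def mantel(
    d1: DissimilarityMatrix,
    d2: DissimilarityMatrix,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> MantelResult:
    """One-tailed Mantel test (Pearson r, positive association).

    The observed statistic is the Pearson correlation of the two upper
    triangles; the null distribution permutes the rows and columns of
    the second matrix simultaneously.  p = (1 + #{r_perm ≥ r_obs}) /
    (n_perm + 1), so fixed seed gives an identical p across runs.
    """
    if d1.units != d2.units:
        raise ValueError("matrices are over different (or differently ordered) units")
    n = d1.n
    if n < 3:
        raise ValueError("need at least 3 units")
    iu = np.triu_indices(n, k=1)
    v1 = d1.values[iu]
    v2 = d2.values[iu]
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")

    z1 = (v1 - v1.mean()) / v1.std()
    z2 = (v2 - v2.mean()) / v2.std()
    r_obs = float((z1 * z2).mean())

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = d2.values[np.ix_(perm, perm)][iu]
        zp = (vp - vp.mean()) / vp.std()
        if (z1 * zp).mean() >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, n_units=n)


@dataclass
class SharedSpeciesReport:
    """Species sharing between two habitats with directionality."""

    shared: list[dict]  # motu, abundance_a, abundance_b, direction
    n_shared: int
    n_union: int
    n_unique_a: int
    n_unique_b: int
    s_a: int
    s_b: int
    pct_specimens_shared: float
    habitat_a: str = "a"
    habitat_b: str = "b"

    def to_dict(self) -> dict:
        return {
            "habitat_a": self.habitat_a,
            "habitat_b": self.habitat_b,
            "n_shared": self.n_shared,
            "n_union": self.n_union,
            "n_unique_a": self.n_unique_a,
            "n_unique_b": self.n_unique_b,
            "s_a": self.s_a,
            "s_b": self.s_b,
            "pct_specimens_shared": self.pct_specimens_shared,
            "shared": self.shared,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def shared_species_report(
    matrix_a: CommunityMatrix,
    matrix_b: CommunityMatrix,
    equal_tolerance: int = 0,
    habitat_a: str = "a",
    habitat_b: str = "b",
) -> SharedSpeciesReport:
    """Inventory species shared between two habitats.

    Both matrices must come from the same clustering run (a common MOTU
    label space); species present in both habitats are listed with their
    abundances and the habitat holding the larger one.
    """
    tot_a = matrix_a.motu_totals()
    tot_b = matrix_b.motu_totals()
    overlap_labels = set(tot_a.index) & set(tot_b.index)
    if not overlap_labels and len(tot_a) and len(tot_b):
        raise ValueError(
            "disjoint MOTU label spaces: matrices come from different clustering runs"
        )
    present_a = set(tot_a.index[tot_a > 0])
    present_b = set(tot_b.index[tot_b > 0])
    shared_ids = sorted(present_a & present_b)

    shared = []
    for motu in shared_ids:
        a, b = int(tot_a.get(motu, 0)), int(tot_b.get(motu, 0))
        if a > b + equal_tolerance:
            direction = "a"
        elif b > a + equal_tolerance:
            direction = "b"
        else:
            direction = "equal"
        shared.append(
            {"motu": motu, "abundance_a": a, "abundance_b": b, "direction": direction}
        )

    s_a, s_b = len(present_a), len(present_b)
    n_shared = len(shared_ids)
    n_union = s_a + s_b - n_shared
    n_total = int(tot_a.sum() + tot_b.sum())
    n_in_shared = int(sum(d["abundance_a"] + d["abundance_b"] for d in shared))
    return SharedSpeciesReport(
        shared=shared,
        n_shared=n_shared,
        n_union=n_union,
        n_unique_a=s_a - n_shared,
        n_unique_b=s_b - n_shared,
        s_a=s_a,
        s_b=s_b,
        pct_specimens_shared=round(100.0 * n_in_shared / n_total, 1) if n_total else 0.0,
        habitat_a=habitat_a,
        habitat_b=habitat_b,
    )


def cross_habitat_mantel(
    matrix_a: CommunityMatrix,
    matrix_b: CommunityMatrix,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    min_shared: int = 5,
) -> MantelResult | None:
    """Mantel correlation of two habitats' MOTU co-distribution structure.

    When habitats have different site sets, no common unit space exists
    for a site-level Mantel test.  Instead the shared MOTUs become the
    units: within each habitat, pairwise Bray-Curtis between MOTU
    across-site abundance profiles gives a MOTU-space dissimilarity
    matrix, and the two matrices are compared with a standard Mantel
    test.  Returns None when fewer than ``min_shared`` (default 5) MOTUs are
    shared — with so few units the permutation test is degenerate; this construction is an
    interpretation, not a canonical definition.
    """
    tot_a = matrix_a.motu_totals()
    tot_b = matrix_b.motu_totals()
    shared = sorted(set(tot_a.index[tot_a > 0]) & set(tot_b.index[tot_b > 0]))
    if len(shared) < min_shared:
        return None

    def motu_space(matrix: CommunityMatrix) -> DissimilarityMatrix:
        profiles = matrix.counts[shared].T  # MOTU × site
        n = len(shared)
        vals = np.zeros((n, n))
        arr = profiles.to_numpy(dtype=float)
        for i in range(n):
            for j in range(i + 1, n):
                vals[i, j] = vals[j, i] = bray_curtis(arr[i], arr[j])
        return DissimilarityMatrix(units=list(shared), values=vals)

    return mantel(motu_space(matrix_a), motu_space(matrix_b), n_perm=n_perm, seed=seed)
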