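"""Synthetic barcode communities with known ground truth.

Generates specimen-level COI-like barcode datasets that mimic the
statistical structure of a tropical midge survey: a few hundred species,
a singleton-heavy (log-series) abundance distribution, intraspecific
divergence well below the clustering thresholds, interspecific
divergence above them, several sites split across habitats with
configurable species-pool overlap, and a minority of non-target
(contaminant) taxa.

Species centroids are built by divergence from previously accepted
centroids, so the *minimum* interspecific distance actually sits near
``d_inter`` rather than at the ~0.75 expected for independent random
sequences.  That is what makes threshold-sensitivity experiments
(overlapping intra/inter divergence) meaningful.

Mutations are substitutions only (uniform over sites and over the three
alternative bases); all sequences stay equal-length, so downstream
p-distances need no alignment step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .distances import SpecimenRecord
from .taxfilter import HitRecord

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Non-target taxa used for contaminant species, cycled in order.
CONTAMINANT_TAXA = (
    "Ceratopogonidae",
    "Culicidae",
    "Simuliidae",
    "Tachinidae",
    "Drosophilidae",
)

ARCHETYPES = (
    "criterion1",
    "criterion2",
    "criterion3",
    "criterion4",
    "criterion5",
    "criterion6",
    "discard",
)


@dataclass(frozen=True)
class SpeciesTemplate:
    """A simulated species: centroid barcode plus taxonomic identity."""

    species_id: str
    centroid_sequence: str
    is_target: bool
    taxon_label: str


@dataclass
class SimulationConfig:
    """Knobs for one synthetic community.

    Defaults emulate the structure of a specimen-based midge survey:
    ~250 species, 313 bp mini-barcodes, intraspecific divergence <= 1%,
    interspecific divergence >= 8%, a log-series abundance distribution
    whose expected singleton share is ~32% of species, 8 sites in two
    habitats with disjoint species pools (near-complete turnover), and
    ~5% of species flagged as non-target contaminants.
    """

    n_species: int = 250
    L: int = 313
    d_inter: float = 0.08
    d_intra: float = 0.01
    abundances: Sequence[int] | None = None
    logseries_p: float = 0.95
    n_sites: int = 8
    n_habitats: int = 2
    site_overlap: float = 0.0
    contaminant_fraction: float = 0.05
    adult_fraction: float = 0.0
    seed: int = 0
    max_retries: int = 1000
    target_taxon: str = "Chironomidae"

    def __post_init__(self) -> None:
        if not 0 <= self.d_intra < self.d_inter <= 1:
            raise ValueError("need 0 <= d_intra < d_inter <= 1")
        if not 0 <= self.contaminant_fraction < 1:
            raise ValueError("contaminant_fraction must be in [0,1)")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 1 <= self.n_habitats <= self.n_sites:
            raise ValueError("need 1 <= n_habitats <= n_sites")
        if self.abundances is not None and len(self.abundances) != self.n_species:
            raise ValueError("abundance vector length != n_species")


@dataclass
class SimulatedDataset:
    """Specimens plus full ground truth for one simulated community."""

    config: SimulationConfig
    species: list[SpeciesTemplate]
    specimens: list[SpecimenRecord]
    abundances: dict[str, int]
    specimen_to_species: dict[str, str]
    site_of_habitat: dict[str, str]
    archetypes: dict[str, str] = field(default_factory=dict)

    def true_partition(self) -> dict[str, frozenset[str]]:
        """Ground-truth clustering keyed like a MOTU partition."""
        groups: dict[str, set[str]] = {}
        for sid, sp in self.specimen_to_species.items():
            groups.setdefault(sp, set()).add(sid)
        return {min(m): frozenset(m) for m in groups.values()}

    def singleton_proportion(self) -> float:
        counts = np.array(list(self.abundances.values()))
        return float((counts == 1).sum() / (counts > 0).sum())

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.specimens:
                fh.write(f">{rec.specimen_id}\n{rec.sequence}\n")

    def write_metadata(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("specimen_id\tsite\thabitat\tlife_stage\n")
            for rec in self.specimens:
                fh.write(
                    f"{rec.specimen_id}\t{rec.site}\t{rec.habitat}\t{rec.life_stage}\n"
                )

    def write_ground_truth(self, path: str | Path) -> None:
        truth = {
            "specimen_to_species": self.specimen_to_species,
            "abundances": self.abundances,
            "archetypes": self.archetypes,
            "species": [
                {
                    "species_id": s.species_id,
                    "is_target": s.is_target,
                    "taxon_label": s.taxon_label,
                }
                for s in self.species
            ],
        }
        Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def _p_dist(a: np.ndarray, b: np.ndarray) -> float:
    return float((a != b).mean())


def _mutate(seq: np.ndarray, n_sub: int, rng: np.random.Generator) -> np.ndarray:
    """Substitute exactly ``n_sub`` distinct sites to a different base."""
    out = seq.copy()
    if n_sub == 0:
        return out
    sites = rng.choice(len(seq), size=n_sub, replace=False)
    # shift by 1..3 positions in the base alphabet => always a different base
    idx = np.searchsorted(BASES, out[sites])
    out[sites] = BASES[(idx + rng.integers(1, 4, size=n_sub)) % 4]
    return out


def simulate_species(config: SimulationConfig) -> list[SpeciesTemplate]:
    """Draw species centroids with all pairwise p-distances >= d_inter.

    The first centroid is uniform random; each later one diverges from a
    randomly chosen accepted centroid by d_inter–1.5×d_inter substitutions
    and is kept only if it clears ``d_inter`` against every accepted
    centroid (rejection sampling, capped at ``max_retries`` per species).
    """
    rng = np.random.default_rng(config.seed)
    L, d_inter = config.L, config.d_inter
    centroids: list[np.ndarray] = [rng.choice(BASES, size=L)]
    for k in range(1, config.n_species):
        accepted = False
        for _ in range(config.max_retries):
            parent = centroids[rng.integers(len(centroids))]
            # uniform over the achievable range, starting at the boundary
            # ceil(d_inter*L): exact-threshold species pairs stay possible
            min_sub = int(np.ceil(d_inter * L))
            max_sub = max(min_sub, int(np.ceil(1.5 * d_inter * L)))
            n_sub = int(rng.integers(min_sub, max_sub + 1))
            cand = _mutate(parent, min(n_sub, L), rng)
            if all(_p_dist(cand, c) >= d_inter for c in centroids):
                centroids.append(cand)
                accepted = True
                break
        if not accepted:
            raise RuntimeError(
                f"could not place species {k + 1}/{config.n_species} with "
                f"min interspecific distance d_inter={d_inter} at L={L} "
                f"after {config.max_retries} retries"
            )

    n_contam = int(round(config.contaminant_fraction * config.n_species))
    contam_idx = set(
        rng.choice(config.n_species, size=n_contam, replace=False).tolist()
    )
    width = len(str(config.n_species))
    species = []
    for k, cent in enumerate(centroids):
        is_target = k not in contam_idx
        species.append(
            SpeciesTemplate(
                species_id=f"sp{k + 1:0{width}d}",
                centroid_sequence=cent.tobytes().decode("ascii"),
                is_target=is_target,
                taxon_label=config.target_taxon
                if is_target
                else CONTAMINANT_TAXA[k % len(CONTAMINANT_TAXA)],
            )
        )
    return species


def _draw_abundances(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.abundances is not None:
        ab = np.asarray(config.abundances, dtype=int)
        if (ab < 1).any():
            raise ValueError("all abundances must be >= 1")
        return ab
    # i.i.d. log-series via inverse transform on the generator stream
    p = config.logseries_p
    k = np.arange(1, 10001)
    pmf = -(p**k) / (k * np.log1p(-p))
    cdf = np.cumsum(pmf / pmf.sum())
    u = rng.random(config.n_species)
    return np.searchsorted(cdf, u) + 1


def simulate_specimens(
    species: Sequence[SpeciesTemplate], config: SimulationConfig
) -> SimulatedDataset:
    """Instantiate specimens around each centroid and place them at sites.

    Every specimen is its species centroid with at most
    ``floor(d_intra/2 * L)`` substitutions, so conspecific pairwise
    distances never exceed ``d_intra``.  A ``site_overlap`` fraction of
    species occurs at every site; the rest are endemic to one site.
    Each species' abundance is split multinomially across its sites.
    """
    if not species:
        raise ValueError("empty species list")
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31) + 1)
    L = config.L
    max_m = int(np.floor(config.d_intra / 2 * L))
    abund = _draw_abundances(config, rng)

    sites = [f"site{j + 1:02d}" for j in range(config.n_sites)]
    # contiguous blocks of sites per habitat
    bounds = np.linspace(0, config.n_sites, config.n_habitats + 1).astype(int)
    site_of_habitat = {}
    for h in range(config.n_habitats):
        for j in range(bounds[h], bounds[h + 1]):
            site_of_habitat[sites[j]] = f"habitat{chr(ord('A') + h)}"

    n_shared = int(round(config.site_overlap * len(species)))
    shared = set(rng.choice(len(species), size=n_shared, replace=False).tolist())
    species_sites: list[list[str]] = []
    for k in range(len(species)):
        if k in shared:
            species_sites.append(sites)
        else:
            species_sites.append([sites[rng.integers(config.n_sites)]])

    total = int(abund.sum())
    width = len(str(total))
    specimens: list[SpecimenRecord] = []
    specimen_to_species: dict[str, str] = {}
    counter = 0
    for k, sp in enumerate(species):
        cent = np.frombuffer(sp.centroid_sequence.encode("ascii"), dtype=np.uint8)
        pool = species_sites[k]
        alloc = rng.multinomial(int(abund[k]), np.full(len(pool), 1 / len(pool)))
        for site, n_here in zip(pool, alloc):
            for _ in range(int(n_here)):
                counter += 1
                sid = f"SP{counter:0{width}d}"
                m = int(rng.integers(0, max_m + 1)) if max_m > 0 else 0
                seq = _mutate(cent, m, rng)
                stage = "adult" if rng.random() < config.adult_fraction else "larva"
                specimens.append(
                    SpecimenRecord(
                        specimen_id=sid,
                        sequence=seq.tobytes().decode("ascii"),
                        site=site,
                        habitat=site_of_habitat[site],
                        life_stage=stage,
                    )
                )
                specimen_to_species[sid] = sp.species_id

    return SimulatedDataset(
        config=config,
        species=list(species),
        specimens=specimens,
        abundances={sp.species_id: int(a) for sp, a in zip(species, abund)},
        specimen_to_species=specimen_to_species,
        site_of_habitat=site_of_habitat,
    )


def assign_archetypes(
    dataset: SimulatedDataset, rng: np.random.Generator | None = None
) -> dict[str, str]:
    """Assign each species a filter-criterion archetype.

    Contaminant species get the designed-negative "discard" archetype.
    Target species are spread over criteria 1, 2, 3, 4 and 6, with
    criterion 5 reserved for species large enough (> 10 specimens) to
    qualify.  The assignment is stored on the dataset and returned.
    """
    rng = rng or np.random.default_rng(dataset.config.seed + 2)
    rotation = ["criterion1", "criterion2", "criterion2", "criterion3",
                "criterion4", "criterion2", "criterion6"]
    out: dict[str, str] = {}
    i = 0
    for sp in dataset.species:
        if not sp.is_target:
            out[sp.species_id] = "discard"
        elif dataset.abundances[sp.species_id] > 10 and rng.random() < 0.2:
            out[sp.species_id] = "criterion5"
        else:
            out[sp.species_id] = rotation[i % len(rotation)]
            i += 1
    dataset.archetypes = out
    return out


def _archetype_rows(archetype: str, query_id: str, target: str) -> list[HitRecord]:
    """Top-10 hit rows engineered to fire exactly one filter criterion."""
    rows: list[tuple[str, float]]
    if archetype == "criterion1":
        rows = [(target, 97.5)] + [("Ceratopogonidae", 94.0 - 0.2 * i) for i in range(9)]
    elif archetype == "criterion2":
        rows = [(target, 94.0 - 0.3 * i) for i in range(10)]
    elif archetype == "criterion3":
        rows = [(target, 95.5 - 0.2 * i) for i in range(8)] + [
            ("Tachinidae", 92.0),
            ("Drosophilidae", 91.5),
        ]
    elif archetype == "criterion4":
        vd = ["Tachinidae", "Drosophilidae", "Syrphidae", "Muscidae",
              "Lepidoptera", "Tachinidae", "Syrphidae"]
        rows = [(target, 93.5 - 0.2 * i) for i in range(3)] + [
            (t, 92.5 - 0.2 * i) for i, t in enumerate(vd)
        ]
    elif archetype == "criterion5":
        rows = [("Schizophora", 95.0 - 0.2 * i) for i in range(10)]
    elif archetype == "criterion6":
        rows = [(target, 95.0 - 0.2 * i) for i in range(4)] + [
            ("Ceratopogonidae", 94.0 - 0.2 * i) for i in range(6)
        ]
    elif archetype == "discard":
        rows = [("Ceratopogonidae", 98.0 - 0.2 * i) for i in range(10)]
    else:
        raise ValueError(f"unknown archetype {archetype!r}")
    rows.sort(key=lambda r: -r[1])
    return [
        HitRecord(query_id=query_id, subject_taxon=t, percent_identity=pid, rank=r + 1)
        for r, (t, pid) in enumerate(rows)
    ]


def simulate_hit_table(
    dataset: SimulatedDataset,
    scenario: Mapping[str, str] | None = None,
) -> list[HitRecord]:
    """Build per-specimen top-10 hit rows realising each species' archetype.

    Every specimen of a species gets the same engineered profile, so the
    MOTU-level decision is independent of the representative choice.
    A "criterion5" archetype on a species with <= 10 specimens cannot
    fire and is rejected.
    """
    if scenario is None:
        scenario = dataset.archetypes or assign_archetypes(dataset)
    unknown = set(scenario.values()) - set(ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetype name(s): {sorted(unknown)}")
    for sp_id, arch in scenario.items():
        if arch == "criterion5" and dataset.abundances.get(sp_id, 0) <= 10:
            raise ValueError(
                f"archetype criterion5 requires > 10 specimens; {sp_id} has "
                f"{dataset.abundances.get(sp_id, 0)}"
            )
    dataset.archetypes = dict(scenario)
    target = dataset.config.target_taxon
    rows: list[HitRecord] = []
    for rec in dataset.specimens:
        arch = scenario[dataset.specimen_to_species[rec.specimen_id]]
        rows.extend(_archetype_rows(arch, rec.specimen_id, target))
    return rows


def write_hit_table(rows: Sequence[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tsubject_taxon\tpercent_identity\trank\n")
        for r in rows:
            fh.write(f"{r.query_id}\t{r.subject_taxon}\t{r.percent_identity:.1f}\t{r.rank}\n")


def simulate_community(config: SimulationConfig) -> SimulatedDataset:
    """One-call convenience: species, specimens, archetypes and hit rows."""
    species = simulate_species(config)
    dataset = simulate_specimens(species, config)
    assign_archetypes(dataset)
    return dataset
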