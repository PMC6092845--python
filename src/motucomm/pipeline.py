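"""End-to-end orchestration: simulate/read → distances → cluster →
stability → contamination filter → community matrices → diversity →
turnover, with a machine-readable run report.

A run is configured either from input files (FASTA + metadata + hit
table) or from a simulation block, executes each stage in order, writes
every stage's artifacts under the output directory, and is byte-stable
under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import __version__
from .clustering import (
    DEFAULT_THRESHOLDS,
    cluster_at_thresholds,
    stability_report,
)
from .distances import SpecimenRecord, pairwise_matrix, read_specimens
from .diversity import (
    build_matrix,
    chao1,
    chao2,
    hill_number,
    rarefy_extrapolate,
    sample_coverage,
    singleton_stats,
    standardize_to_coverage,
)
from .synthetic import (
    SimulationConfig,
    simulate_community,
    simulate_hit_table,
    write_hit_table,
)
from .taxfilter import FilterConfig, filter_dataset, read_hit_table
from .turnover import (
    cross_habitat_mantel,
    dissimilarity_matrix,
    shared_species_report,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    fasta: str | None = None
    metadata: str | None = None
    hit_table: str | None = None
    simulation: SimulationConfig | None = None
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    primary_threshold: float = 0.04
    filter: FilterConfig = field(default_factory=FilterConfig)
    n_boot: int = 200
    target_coverage: float = 0.70
    extrapolation_factor: float = 2.0
    n_perm: int = 999
    min_overlap: int = 100
    seed: int = 0
    output_dir: str = "motucomm_out"

    def validate(self) -> None:
        if self.primary_threshold not in self.thresholds:
            raise ValueError(
                f"primary_threshold {self.primary_threshold} not in thresholds "
                f"{list(self.thresholds)}"
            )
        if self.simulation is None:
            for name in ("fasta", "metadata", "hit_table"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"no simulation block and no {name} path")
                if not Path(path).exists():
                    raise ValueError(f"{name} path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        filt = raw.pop("filter", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        if filt is not None:
            for key in ("aquatic_diptera_taxa", "very_different_taxa"):
                if key in filt:
                    filt[key] = frozenset(filt[key])
            cfg.filter = FilterConfig(**filt)
        cfg.thresholds = tuple(cfg.thresholds)
        return cfg


@dataclass
class RunReport:
    """Per-stage record of one pipeline run; round-trips through JSON."""

    version: str
    seed: int
    parameters: dict
    counts: dict
    stability: dict
    filter_summary: dict
    diversity: dict
    turnover: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunReport":
        return cls(**json.loads(Path(path).read_text()))

    def validate_counts(self) -> None:
        c = self.counts
        if not (c["specimens_retained"] <= c["specimens_barcoded"]):
            raise ValueError("retained > barcoded")


def _habitat_diversity(pooled: np.ndarray, per_site, n_boot: int, seed: int,
                       extrapolation_factor: float) -> dict:
    c1 = chao1(pooled)
    out = {
        "s_obs": int(c1.inputs["S_obs"]),
        "n": int(c1.inputs["n"]),
        "chao1": c1.to_dict(),
        "hill": {str(q): hill_number(pooled, q) for q in (0, 1, 2)},
        "coverage": sample_coverage(pooled),
        "singletons": dict(zip(("n_singletons", "pct_singletons"),
                               singleton_stats(pooled))),
    }
    if per_site is not None and per_site.shape[0] >= 2:
        out["chao2"] = chao2(per_site).to_dict()
    curve = rarefy_extrapolate(
        pooled, n_boot=n_boot, seed=seed, extrapolation_factor=extrapolation_factor
    )
    out["rarefaction"] = curve.to_dict()
    return out


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write all artifacts to the output dir.

    On a stage failure, partial outputs are kept and a ``FAILED`` marker
    naming the stage is written next to them.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        report = _run_stages(config, out)
    except PipelineError as pe:
        (out / "FAILED").write_text(f"{pe.stage}: {pe.cause}\n")
        raise
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()
    return report


def _run_stages(config: RunConfig, out: Path) -> RunReport:

    # --- input stage -----------------------------------------------------
    stage = "input"
    try:
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            dataset = simulate_community(sim)
            specimens = dataset.specimens
            hit_rows = simulate_hit_table(dataset)
            dataset.write_fasta(out / "specimens.fasta")
            dataset.write_metadata(out / "metadata.tsv")
            dataset.write_ground_truth(out / "ground_truth.json")
            write_hit_table(hit_rows, out / "hits.tsv")
        else:
            specimens = read_specimens(config.fasta, config.metadata)
            hit_rows = read_hit_table(config.hit_table)
    except Exception as e:  # noqa: BLE001 - stage naming contract
        raise PipelineError(stage, e) from e

    # --- distances -------------------------------------------------------
    stage = "distances"
    try:
        matrix = pairwise_matrix(specimens, min_overlap=config.min_overlap)
        matrix.write_square(out / "distances.tsv")
    except Exception as e:
        raise PipelineError(stage, e) from e

    # --- clustering + stability ------------------------------------------
    stage = "clustering"
    try:
        partitions = cluster_at_thresholds(matrix, config.thresholds)
        for p in partitions:
            p.write_tsv(out / f"motus_{p.threshold:g}.tsv")
        stability = stability_report(partitions)
        stability.write_json(out / "stability.json")
        primary = partitions[list(config.thresholds).index(config.primary_threshold)]
    except Exception as e:
        raise PipelineError(stage, e) from e

    # --- contamination filter --------------------------------------------
    stage = "filter"
    try:
        seq_lengths = {r.specimen_id: len(r.sequence) for r in specimens}
        summary = filter_dataset(primary, hit_rows, config.filter, seq_lengths)
        summary.write_json(out / "filter_summary.json")
        summary.write_decisions_tsv(out / "filter_decisions.tsv")
        retained = [r for r in specimens if r.specimen_id in summary.retained_specimens]
        if not retained:
            raise ValueError("no specimens retained by the contamination filter")
        kept_ids = frozenset(r.specimen_id for r in retained)
        kept_partition_clusters = {}
        for label, members in primary.clusters.items():
            kept = members & kept_ids
            if kept:
                kept_partition_clusters[min(kept)] = kept
        primary_kept = dataclasses.replace(
            primary, clusters=kept_partition_clusters
        )
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, e) from e

    # --- community matrices + diversity ----------------------------------
    stage = "diversity"
    try:
        site_matrix = build_matrix(retained, primary_kept, by="site")
        site_matrix.write_tsv(out / "community_sites.tsv")
        habitat_matrix = build_matrix(retained, primary_kept, by="habitat")
        habitat_matrix.write_tsv(out / "community_habitats.tsv")

        diversity: dict[str, Any] = {"per_habitat": {}}
        habitats = sorted(habitat_matrix.sites)
        grouping = site_matrix.grouping or {}
        for hab in habitats:
            pooled_row = habitat_matrix.counts.loc[hab].to_numpy()
            pooled = pooled_row[pooled_row > 0]
            hab_sites = [s for s in site_matrix.sites if grouping.get(s) == hab]
            per_site = (
                site_matrix.counts.loc[hab_sites].to_numpy()
                if len(hab_sites) >= 2
                else None
            )
            diversity["per_habitat"][hab] = _habitat_diversity(
                pooled, per_site, config.n_boot, config.seed,
                config.extrapolation_factor,
            )
        std_matrix, cov_report, dropped = standardize_to_coverage(
            site_matrix, config.target_coverage, seed=config.seed
        )
        std_matrix.write_tsv(out / "community_sites_cov_standardized.tsv")
        diversity["coverage_standardization"] = {
            "target": config.target_coverage,
            "sites_retained": std_matrix.sites,
            "sites_dropped": dropped,
            "per_site": cov_report,
        }
    except Exception as e:
        raise PipelineError(stage, e) from e

    # --- turnover ---------------------------------------------------------
    stage = "turnover"
    try:
        turnover_out: dict[str, Any] = {}
        if len(site_matrix.sites) >= 2:
            bc = dissimilarity_matrix(site_matrix)
            bc.write_tsv(out / "bray_curtis_sites.tsv")
            turnover_out["mean_bray_curtis_sites"] = float(bc.condensed().mean())
        if len(habitats) >= 2:
            pairs = {}
            for ha, hb in combinations(habitats, 2):
                sub_a = CommunitySlice(habitat_matrix, ha)
                sub_b = CommunitySlice(habitat_matrix, hb)
                rep = shared_species_report(
                    sub_a.matrix, sub_b.matrix, habitat_a=ha, habitat_b=hb
                )
                entry: dict[str, Any] = {"shared_species": rep.to_dict()}
                grouping = site_matrix.grouping or {}
                ma = _habitat_site_matrix(site_matrix, ha)
                mb = _habitat_site_matrix(site_matrix, hb)
                mres = cross_habitat_mantel(
                    ma, mb, n_perm=config.n_perm, seed=config.seed
                )
                entry["mantel"] = mres.to_dict() if mres else None
                pairs[f"{ha}|{hb}"] = entry
            turnover_out["habitat_pairs"] = pairs
        (out / "turnover.json").write_text(
            json.dumps(turnover_out, indent=2, sort_keys=True) + "\n"
        )
    except Exception as e:
        raise PipelineError(stage, e) from e

    report = RunReport(
        version=__version__,
        seed=config.seed,
        parameters={
            "thresholds": list(config.thresholds),
            "primary_threshold": config.primary_threshold,
            "n_boot": config.n_boot,
            "target_coverage": config.target_coverage,
            "n_perm": config.n_perm,
            "min_overlap": config.min_overlap,
        },
        counts={
            "specimens_barcoded": len(specimens),
            "specimens_retained": len(retained),
            "motus_per_threshold": {
                f"{p.threshold:g}": p.n_motus for p in partitions
            },
            "motus_retained": primary_kept.n_motus,
        },
        stability=stability.to_dict(),
        filter_summary=summary.to_dict(),
        diversity=diversity,
        turnover=turnover_out,
    )
    report.validate_counts()
    report.write_json(out / "run_report.json")
    return report


class CommunitySlice:
    """One habitat row of a habitat-level matrix, as a 1-row matrix."""

    def __init__(self, habitat_matrix, habitat: str):
        from .diversity import CommunityMatrix

        self.matrix = CommunityMatrix(
            habitat_matrix.counts.loc[[habitat]].copy()
        )


def _habitat_site_matrix(site_matrix, habitat: str):
    from .diversity import CommunityMatrix

    grouping = site_matrix.grouping or {}
    sites = [s for s in site_matrix.sites if grouping.get(s) == habitat]
    return CommunityMatrix(site_matrix.counts.loc[sites].copy(), grouping=None)


def summarize(report: RunReport) -> str:
    """One-screen human-readable summary of a run report."""
    c = report.counts
    lines = [
        f"motucomm v{report.version} (seed {report.seed})",
        f"specimens: {c['specimens_barcoded']} barcoded, "
        f"{c['specimens_retained']} retained "
        f"({report.filter_summary['retention_pct']}%)",
        "MOTUs@" + "/".join(
            f"{float(t) * 100:g}%" for t in c["motus_per_threshold"]
        ) + ": " + "/".join(str(v) for v in c["motus_per_threshold"].values()),
        f"congruent MOTUs: {report.stability['n_congruent']}; "
        f"sensitive specimens: {report.stability['n_sensitive_specimens']} "
        f"({report.stability['pct_sensitive']}%)",
    ]
    for hab, d in sorted(report.diversity.get("per_habitat", {}).items()):
        chao = d["chao1"]
        lines.append(
            f"{hab}: S_obs={d['s_obs']}, Chao1={chao['point']:.1f}±"
            f"{chao['se']:.1f}, coverage={d['coverage']:.3f}, "
            f"singletons={d['singletons']['pct_singletons']}%"
        )
    std = report.diversity.get("coverage_standardization")
    if std and std["sites_dropped"]:
        lines.append(
            f"coverage standardization dropped sites: "
            f"{', '.join(std['sites_dropped'])}"
        )
    pairs = report.turnover.get("habitat_pairs")
    if pairs:
        for name, entry in sorted(pairs.items()):
            sp = entry["shared_species"]
            m = entry["mantel"]
            mantel_txt = (
                f"Mantel R={m['r']:.2f} p={m['p']:.3f}" if m else "Mantel n/a"
            )
            lines.append(
                f"{name}: union {sp['n_union']} species, shared {sp['n_shared']}, "
                f"{sp['pct_specimens_shared']}% of specimens in shared species; "
                + mantel_txt
            )
    else:
        lines.append("turnover: single habitat, between-habitat section omitted")
    return "\n".join(lines)
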