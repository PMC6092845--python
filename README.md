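# motucomm

Species-level community analysis of specimen-based DNA-barcode surveys.

`motucomm` is for ecologists who barcode *every specimen* in a bulk
sample (one COI sequence per specimen, e.g. NGS-barcoded chironomid
midges) and want to go from a FASTA of barcodes plus a metadata table to
species-proxy units, contamination-checked inventories, diversity
estimates and between-habitat turnover — with every step reproducible
under a fixed seed and validated against ground-truth synthetic
communities.

## What it computes

* **Uncorrected p-distances** between equal-length barcodes, with
  pairwise deletion of gaps/ambiguities and a minimum-overlap guard.
* **MOTU delimitation** by objective clustering: MOTUs are the
  connected components of the graph linking specimen pairs with
  `d ≤ t` (single linkage at cutoff), at one or several thresholds
  (default 3/4/5%), plus a **stability report** (MOTU counts per
  threshold, congruent MOTUs, threshold-sensitive specimens).
* **Contamination filtering** of MOTUs from BLAST-tabular-like top-10
  hit tables via six ordered keep-criteria (identity > 96% to the
  target family; 10/10, 7–9/10 target hits; "very different taxa"
  escapes; large all-Schizophora MOTUs; aquatic-Diptera identity
  comparisons).
* **Diversity**: Chao1 (abundance) and Chao2 (incidence) with SE and
  log-normal 95% CI — point estimate S_obs + ((n−1)/n)·f1²/(2f2) and
  its bias-corrected form; Hill numbers ^qD = (Σ p_i^q)^(1/(1−q)) for
  q ∈ {0, 1, 2}; sample coverage; hypergeometric rarefaction with
  Chao-based extrapolation and a 200-replicate bootstrap band; and
  coverage-standardized subsampling of site × MOTU matrices (default
  70% target).
* **Turnover**: Bray-Curtis dissimilarity, one-tailed Mantel
  permutation tests (Pearson r, 999 permutations), and shared-species
  reports with per-species directionality between habitats.
* **Synthetic communities** with known ground truth (species centroids
  with controlled intra/interspecific divergence, log-series
  abundances, site/habitat structure, contaminants, engineered hit
  tables) so the whole pipeline is testable without any download.

## Worked example

Run the bundled simulator end to end (120 species, two habitats with a
small shared species pool, 5% contaminant species):

```python
import motucomm as mc

cfg = mc.RunConfig(
    simulation=mc.SimulationConfig(n_species=120, seed=7, site_overlap=0.08),
    seed=7, output_dir="demo_out", n_boot=200, n_perm=999,
)
report = mc.run(cfg)
print(mc.summarize(report))
```

prints

```
motucomm v0.1.0 (seed 7)
specimens: 618 barcoded, 532 retained (86.1%)
MOTUs@3%/4%/5%: 120/120/120
congruent MOTUs: 120; sensitive specimens: 0 (0.0%)
habitatA: S_obs=65, Chao1=78.8±8.3, coverage=0.946, singletons=29.2%
habitatB: S_obs=57, Chao1=165.3±62.3, coverage=0.817, singletons=57.9%
coverage standardization dropped sites: site07
habitatA|habitatB: union 114 species, shared 8, 10.7% of specimens in shared species; Mantel R=-0.02 p=0.511
```

Reading this: all 120 simulated species are recovered as MOTUs at every
threshold (intraspecific divergence 1% is far below the 3–5% cutoffs,
interspecific 8% far above), and no specimen is threshold-sensitive.
The contamination filter removed the simulated non-target specimens
(86.1% retained). Habitat B is less completely sampled (coverage 0.817,
58% singleton species), so its Chao1 estimate is both higher and much
more uncertain; one all-singleton-ish site cannot reach 70% coverage
and is dropped from the standardized matrix. The two habitats share 8
of 114 species — near-complete turnover — and their MOTU co-distribution
structure is uncorrelated (Mantel R ≈ 0, p > 0.05).

The same pipeline runs from the shell on real files:

```bash
motucomm simulate --n-species 120 --seed 7 --out-dir sim
motucomm cluster sim/specimens.fasta sim/metadata.tsv --out-dir clusters
motucomm run config.yaml       # FASTA/metadata/hits paths or a simulation block
motucomm summarize out/run_report.json
```

## Layout

```
src/motucomm/
  synthetic.py    ground-truth community simulator
  distances.py    specimen I/O, uncorrected p-distance matrix
  clustering.py   objective clustering, threshold stability
  taxfilter.py    six-criterion contamination filter
  diversity.py    Chao1/Chao2, Hill numbers, coverage, rarefaction
  turnover.py     Bray-Curtis, Mantel, shared species
  pipeline.py     end-to-end orchestration and run reports
  cli.py          click command-line interface
docs/methods.md   models, formulas, numerical choices, limitations
```
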