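# Methods

This note documents the models, algorithms and numerical choices behind
`motucomm`, and what the synthetic validation does and does not show.

## Problem setting

The package analyses specimen-level DNA-barcode surveys of aquatic
insect communities (the motivating system is tropical chironomid
midges): every specimen carries one COI barcode from a fixed,
primer-defined amplicon region, plus collection metadata (site, habitat,
life stage). The questions are (i) how many species-like units (MOTUs)
are present, (ii) how robust that count is to the clustering threshold,
(iii) which units are contaminants rather than the target family, and
(iv) how much diversity each habitat holds and how strongly habitats
turn over.

## Distances

Barcodes are treated as pre-aligned equal-length sequences; the package
refuses unequal lengths rather than aligning. The uncorrected p-distance
between two sequences is mismatches over compared sites, where a site is
compared only when both sequences carry A, C, G or T (pairwise deletion
of gaps, N and IUPAC ambiguity codes). A pair with fewer than
`min_overlap` (default 100) jointly unambiguous sites has an undefined
distance and must be resolved before clustering. Pairwise deletion and
the 100-site floor are defaults of this package — survey papers rarely
state their handling — and both are configurable.

## MOTU delimitation and stability

Objective clustering at threshold *t* returns the connected components
of the graph with an edge wherever `d(i,j) <= t` (single linkage at
cutoff). The comparison is inclusive, so a pair exactly at the threshold
is clustered together; this choice is documented because it decides
boundary cases. Components are computed with scipy's sparse graph
machinery and are order-independent; each MOTU is labelled by its
lexicographically smallest member, which is stable under subsetting.

Stability across thresholds (default 3/4/5%) is summarised by: the MOTU
count per threshold (non-increasing, and partitions are nested because
the edge sets are nested); the number of *congruent* MOTUs, defined as
member sets identical in every partition; and the number of *sensitive*
specimens, those belonging to no congruent MOTU. Exact member-set
congruence is the strictest reading of "same MOTU at all thresholds", so
the sensitive-specimen count upper-bounds looser definitions.

## Contamination filter

Six ordered keep-criteria are applied to each MOTU's top-10 taxonomic
hit rows (BLAST-tabular-like input with a taxon-label column); the first
criterion satisfied is recorded, so kept MOTUs are partitioned by
criterion. The MOTU-level profile is the hit table of a representative
specimen (longest sequence, ties to smallest ID), except the best
target-family identity, which is taken over all members — hits are
per-specimen but the decision is per-MOTU, and a deterministic
representative rule makes the procedure reproducible. The "very
different taxa" exclusion set (criterion 4) and the aquatic-Diptera set
(criterion 6) are configurable label sets seeded with the families that
plausibly co-occur in such samples (Tachinidae, Drosophilidae,
Syrphidae, Muscidae, Lepidoptera; Ceratopogonidae, Culicidae,
Simuliidae, Chaoboridae, Dixidae). An empty hit table is a discard with
criterion "none", distinct from "evaluated and unsatisfied".

## Diversity estimation

* **Chao1 / Chao2.** Lower-bound richness estimators from singletons and
  doubletons (abundance) or uniques and duplicates over sampling units
  (incidence), with the small-sample factor (n−1)/n (resp. (m−1)/m), the
  bias-corrected fallback when f2 (q2) = 0, the classic variance
  formulas, and the standard log-normal 95% CI on the estimated number
  of unseen species (which always contains the point estimate). Both SE
  and CI are reported because "± x" in survey reports is often ambiguous
  between the two.
* **Hill numbers.** (Σ p_i^q)^(1/(1−q)), with the exponential-Shannon
  continuous limit at q = 1; q ∈ {0, 1, 2} covers richness, Shannon and
  Simpson diversity.
* **Sample coverage.** Ĉ = 1 − (f1/n)·(n−1)f1/((n−1)f1 + 2f2); the
  degenerate denominator (n = 1) resolves to coverage 0.
* **Rarefaction/extrapolation.** Interpolation is the exact
  hypergeometric expectation, computed in log-gamma space;
  extrapolation uses the Chao1 unseen-species estimate and is capped at
  2× the reference size (configurable), the conventional reliability
  limit. Confidence bands are point ± 1.96·SE from a 200-replicate
  bootstrap that resamples a coverage-adjusted community: seen species'
  probabilities are shrunk to sum to Ĉ and the estimated unseen species
  share 1 − Ĉ equally.
* **Coverage standardization.** Each site is subsampled without
  replacement (fixed seed) to the smallest size whose interpolated
  coverage reaches the target (default 70%); the size is found by
  bisection, valid because interpolated coverage is non-decreasing in
  subsample size. Sites that cannot reach the target at full size —
  e.g. all-singleton sites, whose estimated coverage is 0 — are dropped
  and listed. Random subsampling was preferred over analytic
  coverage-matching for reproducibility and simplicity at matrix level.
* Chao2's incidence units are sites (configurable by passing any
  units × species matrix); the unit choice is the caller's.

## Turnover

Bray-Curtis dissimilarity is computed on raw abundances (a flag enables
square-root transformation). The Mantel test uses Pearson correlation of
the upper triangles, a one-tailed (positive association) permutation
test with simultaneous row/column permutation of the second matrix, and
p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1) with n_perm = 999 by default;
fixed seed gives an identical p. Shared-species reports list every MOTU
present in both habitats with its abundances and direction (which
habitat dominates), plus union/unique counts and the share of specimens
belonging to shared species.

Comparing *habitats* with different site sets has no canonical Mantel
construction. The package's cross-habitat Mantel treats the shared MOTUs
as units and correlates the two habitats' MOTU-space Bray-Curtis
matrices (each MOTU represented by its across-site abundance profile
within one habitat); when fewer than 3 MOTUs are shared the statistic is
meaningless and `None` is returned. This is an explicit interpretation,
not a standard method.

## Synthetic communities

The generator emulates the statistical structure such surveys assume:

* **Species centroids.** The first centroid is uniform random over
  {A,C,G,T}^L (default L = 313, a typical mini-barcode length); each
  subsequent centroid diverges from a randomly chosen accepted centroid
  by a uniform number of substitutions in [⌈d_inter·L⌉, ⌈1.5·d_inter·L⌉]
  and is accepted only if it clears `d_inter` against every accepted
  centroid (rejection sampling, capped retries, explicit failure naming
  the constraint). Starting the divergence range at the constraint
  boundary matters: it keeps exact-threshold species pairs possible, so
  threshold-sensitivity experiments exercise real boundary behaviour.
  For such experiments L should make d_inter·L an integer (e.g. L = 300
  with d_inter = 0.05); otherwise the inclusive boundary is unoccupied
  and sensitivity is structurally suppressed.
* **Specimens.** Substitutions only (no indels), uniform over sites and
  the three alternative bases, at most ⌊d_intra/2·L⌋ per specimen, so
  conspecific pairwise distances never exceed d_intra and no alignment
  is needed downstream.
* **Abundances.** A supplied vector, or i.i.d. log-series draws
  (default parameter 0.95, whose expected singleton share ≈ 32% of
  species, matching the singleton-heavy structure of real chironomid
  surveys, 23–34%). The log-series family is a modelling convenience,
  not a claim about any particular fauna.
* **Sites and habitats.** Default 8 sites in 2 habitats (contiguous
  blocks). A `site_overlap` fraction of species occurs at every site;
  the rest are endemic to one random site, and abundances are split
  multinomially across a species' sites. Overlap ≈ 0 reproduces
  near-complete habitat turnover.
* **Contaminants.** round(contaminant_fraction × n_species) random
  species are flagged non-target (default 5%); the realized specimen
  share therefore fluctuates around the nominal fraction.
* **Hit tables.** Each species is assigned a filter-criterion archetype
  (contaminants get the designed-negative "discard"); every specimen of
  a species receives the same engineered top-10 profile, constructed to
  fail all earlier criteria and satisfy exactly the intended one.

What the generator does **not** emulate: sequencing error and chimeras,
indels and length variation, geographic structure within species,
phylogenetic signal beyond the centroid divergence tree, abundance–site
covariance, and realistic BLAST identity noise. Passing tests therefore
validate the algorithms under their stated assumptions; they do not show
that real data satisfy those assumptions.

## Validation design and problem sizes

The test suite checks every estimator against closed-form hand values,
clustering against exhaustive graph components (networkx), rarefaction
against a 10⁴-draw Monte-Carlo subsampling oracle (within 3 SEs),
Chao1/Mantel against scikit-bio as an independent implementation, and
Mantel type-I error against its binomial band (200 independent pairs of
15-unit matrices, rejection rate in [0.02, 0.08] at α = 0.05).

Chao1 CI coverage is validated on a homogeneous community of K = 100
species sampled shallowly (n = 200, mean two specimens per species),
where the estimator is approximately unbiased; measured true coverage of
the log-normal CI there is ≈ 94%, so the ≥ 90%-of-replicates check is a
property of the estimator, not of a lucky draw. Deeper designs
(n ≳ 3K) push the log-normal CI's true coverage down to ≈ 80–90% — a
known behaviour of Chao-type intervals — and are deliberately not used
as the validation condition.

End-to-end recovery uses clean communities (d_intra = 0.01,
d_inter = 0.08, K ∈ {10, 50, 100}): clustering at 3–5% must return
exactly the ground-truth partition. The sensitivity scenario uses
overlapping divergences (d_intra = 0.03, d_inter = 0.05, K = 150,
L = 300) and requires a positive sensitive-specimen count. The
reproduction script runs a survey-scale community of 250 species
(~1,500 specimens) — large enough for stable community statistics while
keeping the full run in seconds.

## Known limitations

* Objective clustering is single linkage: one boundary pair chains two
  otherwise distinct clusters. That is the published algorithm's
  behaviour, reported via the stability machinery rather than patched.
* Chao estimators are lower bounds; under strongly heterogeneous
  detection their CIs undercover.
* The filter criteria encode one family's contamination logic; other
  target taxa need their own label sets.
* Cross-habitat Mantel (above) is an interpretation; compare habitats
  sharing a site design with a site-level Mantel where possible.
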