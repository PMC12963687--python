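# Methods

This note documents the statistical procedures implemented in `tlspatial`,
the defaults they ship with, and the reasoning behind the genuinely open
design choices. Nothing here reports an empirical claim that the test suite
or `scripts/acceptance.py` does not itself compute.

## Data model and preprocessing

A `SpatialDataset` is a gene × spot matrix with centroid coordinates in μm
(origin top-left, y downward, Euclidean distances) and a units tag
(`counts | tpm | log2_tpm1 | zscore`). Bundles use the Visium dialect —
Matrix Market triplets, TSV features/barcodes, a CSV tissue-positions table
(headered or header-less) — with pixel→μm conversion taken from a
scale-factors file when present, else calibrated so the smallest inter-spot
pixel distance equals the configured spot pitch (default 100 μm,
center-to-center spacing of Visium spots).

Preprocessing follows strict boundary semantics: a gene is dropped iff its
TPM is **below** 1 in **more than** 90 % of samples; log-normalization is
log2(TPM + 1); cell QC keeps cells with detected-gene counts in [200, 2500]
and mitochondrial fraction ≤ 10 % ("fewer than", "more than" and "over" are
strict exclusions, so the stated bounds themselves survive). The
low-abundance filter is applied once, on the full table, before any cohort
subsetting.

## Signature scoring

`ssgsea_scores` ranks genes per unit by descending expression (ties broken
deterministically by gene-symbol lexicographic order — scoring contains no
randomness) and accumulates

ES = Σ_j [ P_in(j) − P_out(j) ],

where P_in is the cumulative fraction of in-set genes weighted by
(rank magnitude)^α, α = 0.25 by default, and P_out the unweighted cumulative
fraction of out-of-set genes; α = 0 reduces to the unweighted
Kolmogorov-style sum. When normalization is on, scores are divided by their
range across units. Because the score depends only on ranks it is invariant
under any strictly increasing transform of expression — the property the
test suite asserts.

`mean_z_scores` (mean of per-gene z-scores, population SD) is the default
spot-level method in the pipeline: for compact signatures its ordering tracks
the enrichment score closely at a fraction of the cost, and every downstream
use — median splits, quantile binarization, region ranking — consumes only
score order. Kernel-density-smoothed scoring variants are deliberately not
implemented for the same reason. `stratify_median` puts scores strictly above
the median in High, ties in Low, so High is strictly above the median.

## Co-occurrence and permutation inference

Spots are binarized per marker (+ iff strictly above the median or a chosen
quantile) and crossed into the joint classes `A+B+ / A+B- / A-B+ / A-B-`.
For condition class C and target class T, over cumulative radii r_1 < … < r_m
(default 30 bins over 0–6000 μm):

ratio(r_j) = [#{ordered pairs (i, k): i ∈ C, k ≠ i, d(i,k) ≤ r_j, k ∈ T}
              / #{ordered pairs (i, k): i ∈ C, k ≠ i, d(i,k) ≤ r_j}]
             / (|T| / n).

Cumulative (not annular) bins are used because they are monotone in
information and match the conditional-probability reading; an annulus
analysis can be had by differencing the counts. The denominator is the
global target fraction over all spots, self included; excluding the
conditioning spot changes the ratio by O(1/n). Bins with no conditioning
pair are undefined (NaN) and skipped.

Inference permutes the joint four-class label vector as a unit across spot
positions — conserving the per-spot marker contingency exactly so the test
isolates spatial arrangement — and reduces each curve to a scalar, by
default the mean of (ratio − 1) over defined bins up to the evaluation
radius (default 6000 μm); a max-deviation statistic is available. The
empirical p uses the add-one formula (p ≥ 1/(n_perm + 1)); with the default
one-sided "greater" alternative the test asks whether co-occurrence exceeds
random expectation. The reported interval is the 2.5th–97.5th percentile of
the null sample (a bootstrap interval for the observed statistic would answer
a different question; the null band is what the permutation test actually
thresholds against). The permutation count defaults to 1000.

Implementation note: pair distances are binned once into an n × n index
matrix; each permutation only re-aggregates counts, so 1000 shuffles of a
2500-spot section run in seconds.

`centroid_proximity` implements the 50 μm rule for segmented-cell centroids:
an A-point is co-localized iff some B-point lies at distance ≤ 50 μm
("within" is inclusive).

## Hotspots

Published hotspot tools model feature autocorrelation on a latent-space
KNN graph; that machinery is out of scope here. `tlspatial` instead uses
the classical **Getis–Ord Gi\*** local statistic on the *spatial* KNN graph
(k = 6, matching hex-lattice adjacency), binary weights including self:

z_i = (S_i − x̄ W_i) / (s √((n W_i − W_i²)/(n − 1))), W_i = k + 1,

with x̄, s the global mean and population SD. This is fully specified,
exactly testable against a hand-coded oracle, and serves the one downstream
need — flagging high-expression spatial clusters for TLS/metabolism overlap
analysis. One-sided upper p-values from the normal reference are
BH-corrected across spots; flags require q ≤ α (default 0.05). A
zero-variance field is degenerate: all z are defined as 0 and nothing is
flagged. z is location/scale-free, so flags are invariant under affine
transforms of the input.

## TLS regions and maturity

A spot is a TLS-region member iff its TLS signature score is strictly above
the 0.75 quantile **and** it is a hotspot; members connected through the
(symmetrized) KNN graph merge into numbered regions. No segmentation method
is prescribed by the underlying biology, so graph connectivity — the same
graph the hotspot statistic uses — is the simplest consistent choice.

A region is **mature** iff every evaluated criterion holds:

1. *molecular*: mean expression of the cytokine panel (CXCL9, CXCL13,
   TNFSF13, RORA) **and** of the germinal-center panel (AICDA, CD38, IGHG1 —
   IgG operationalized as IGHG1, the plasma-cell marker) both strictly above
   the cohort medians of region-level panel means. "Elevated" has no
   canonical definition; the cohort median is the least parametric reference
   and is exposed as a configurable quantile. The two panels are combined by
   AND; a weighted combination would need weights with no principled source.
2. *cellular*: GC-like B cells / plasmablasts present (a flag or proportion
   > 0, supplied externally, e.g. from deconvolution or scRNA-seq).
3. *histological* (optional): organized T/B zones; evaluated only when a
   histology flag is provided, so purely transcriptomic runs classify on
   criteria 1–2.

The IHC composite score is proportion bin × intensity: 0 = none,
(0,25]→1, (25,50]→2, (50,75]→3, (75,100]→4 (half-open bins cover
non-integer percentages), intensity negative/weak/moderate/strong → 0–3;
attainable finals are {0,1,2,3,4,6,8,9,12}.

## Cohort analysis

`loo_influence` removes each sample in turn and recomputes the cohort
statistic. Two statistics are exposed because the natural reading of
"influence on the group contrast" differs from "influence on the mean":
`group_difference` (High mean − Low mean; the default) and `mean`. In mean
mode the average of the n leave-one-out means equals the full mean exactly —
an algebraic identity the tests assert to machine precision. Ranking is by
absolute deviation, ties broken by sample id.

`compare_two_groups` reports which engine it selected: two-sample t-test when
both groups pass Shapiro–Wilk normality and Levene's (mean-centred) variance
test at α = 0.05, else Mann–Whitney U; groups smaller than 3 cannot support
the normality check and fall back to the rank test with a warning; two
all-tied groups report p = 1 on the rank path. Multi-group comparisons use
Kruskal–Wallis with BH-adjusted pairwise rank tests. Fisher's exact test
returns the two-sided hypergeometric p and the conditional-MLE odds ratio.
The underlying test engines are scipy's; the package's contribution is the
selection logic and reporting contract, which the tests validate against
enumeration oracles (Fisher against full margin enumeration, BH against the
step-up formula).

## Synthetic data: what it emulates, and what it does not

The generator plants known structure in data with Visium-like geometry and
noise so every pipeline stage can be validated against ground truth:

- **Lattice**: hex (default) or square, 50 × 50 spots at 100 μm pitch
  (2500 spots). Square lattices are kept for oracle simplicity in tests.
- **Counts**: negative binomial per gene × spot, mean μ = 5, dispersion
  θ = 2 (variance μ + μ²/θ ≈ 17.5) — spot-level transcript counts are
  overdispersed, so Poisson noise would understate the error a real analysis
  faces. 200 genes: the 8 TLS signature genes (CXCL9, CXCL13, TNFSF13, RORA,
  AICDA, CD38, IGHG1, MS4A1), the 4 kynurenine-pathway genes (TDO2, IDO1,
  KMO, KYNU), and background genes.
- **Niches**: 3 TLS + 3 metabolic disks of radius 180 μm (≈ a dozen spots
  each, ~1.5 % coverage per system — compact lymphoid-aggregate scale).
  Signature genes are elevated 4-fold inside their niches. The niche size
  was chosen so that, under the pipeline's top-decile binarization, chance
  crossings of the *other* marker's threshold inside a niche stay below one
  spot per niche: with larger niches those crossings make the double-positive
  class itself weakly clustered, which is not the avoidance structure the
  generator is meant to produce (its double-positives should be
  noise-dominated and spatially unstructured).
- **ρ (overlap)**: +1 places metabolic centers exactly on TLS centers; 0
  places them independently and uniformly; ρ < 0 rejection-samples centers
  with a minimum cross-type distance of |ρ| · 2 · radius, so ρ = −1 yields
  disjoint niche systems. A distance constraint was preferred over a copula
  because it is interpretable and directly testable geometry. Same-type
  centers always keep ≥ 2 · radius separation (disjoint niches); infeasible
  configurations fail with a placement error after a bounded number of
  rejections.
- **Cohorts**: Beta-distributed GC-like B cell frequencies, Low-group mean
  0.18, concentration 30, High-group mean shifted by `effect_delta`
  (default −0.08 — high metabolic activity depresses GC-like frequencies);
  26 samples, 13 per group.
- **Null labels**: i.i.d. four-class draws independent of coordinates, for
  calibration of the permutation test.

Not emulated: library-size variation between spots, gene–gene correlation,
segmentation, spatial deconvolution mixtures, cell-cycle structure, graded
niche boundaries, or batch effects. Passing tests therefore demonstrate that
the statistics recover planted structure under realistic counting noise and
geometry — not that any particular biological dataset contains such
structure.

## Pipeline defaults and problem sizes

The report pipeline defaults to: mean-z spot scoring, binarization at the
0.90 score quantile (marker positivity as the top decile; the niche systems
cover a few percent of the section, so positives are dominated by genuinely
elevated spots), 30 cumulative bins to 6000 μm, 1000 permutations, k = 6,
α = 0.05 for hotspots, 0.75 quantile for region calling. All randomness
flows from one root seed split per stage; identical config + seed reproduces
every JSON artifact byte for byte, and the provenance record (config, seeds,
version) suffices to regenerate the report.

Validation protocols: planted-pattern recovery uses 20 sections per
condition at 2500 spots with 499 permutations; null calibration uses 200
replicates of 400 spots at 199 permutations plus a 3000-spot section for
curve calibration, with tolerances derived from the binomial standard error
of the conditional fraction (accounting for pairs sharing a target spot);
hotspot recovery plants a 3-SD Gaussian bump of width 300 μm and scores
recovery against its full-width-half-maximum extent. `scripts/acceptance.py`
re-runs these protocols (calibration scaled to 100 replicates) in about a
minute on one CPU.

## Known limitations

- The co-occurrence permutation test is powerful on 2500-spot sections: any
  genuine spatial structure in a class, however biologically trivial, will
  reject given enough members. Interpretation should lean on the curve and
  effect size, not the p-value alone.
- The normal reference for Gi\* p-values is asymptotic; for very small
  sections a permutation mode is the safer choice.
- Maturity criterion 1 ranks regions against their own cohort; on cohorts of
  few, statistically identical regions the median reference classifies
  roughly half (or all) as immature by construction.
- The generator's independence assumptions (between genes, between spots)
  make its null sharper than real Visium data; calibration results bound the
  test's behavior under exchangeability, not under arbitrary spatial
  covariance.
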