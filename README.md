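# tlspatial

Spatial co-occurrence, hotspot and maturity analysis of **tertiary lymphoid
structures (TLS)** versus **tryptophan metabolism** in spatial
transcriptomics.

Tumors catabolize tryptophan through the kynurenine pathway (TDO2, IDO1, KMO,
KYNU), an immunosuppressive program suspected of excluding the immune niches —
TLS — where B cells mature and class-switch. Testing that hypothesis on a
Visium-style section comes down to a handful of reusable statistical
operations, which this package implements as a library for computational
immunologists:

- **Signature scoring** per spot or bulk sample: a single-sample enrichment
  score (ssGSEA-style running sum) and a mean z-score variant, plus median
  stratification into High/Low activity groups.
- **Marker-pair spot classification** (`A+B+ / A+B- / A-B+ / A-B-`) from two
  binarized scores, e.g. CXCL9 vs TDO2.
- **Distance-conditional co-occurrence**: for a condition class C and target
  class T, the curve reports at each radius r

  ```
  ratio(r) = P(spot in T | within r of a spot in C) / P(spot in T)
  ```

  over cumulative radii 0–6000 μm — 1 under spatial independence — with a
  joint-label **permutation test** (default n = 1000 shuffles) giving an
  empirical p-value and null percentile bounds.
- **Hotspot detection** with the Getis–Ord Gi\* local statistic on the spatial
  k-nearest-neighbour graph, BH-corrected across spots.
- **TLS region calling** (high score ∧ hotspot, merged by graph connectivity)
  and **maturity classification** from the cytokine panel (CXCL9, CXCL13,
  TNFSF13, RORA), the germinal-center panel (AICDA, CD38, IGHG1) and the
  presence of GC-like B cells / plasmablasts.
- **IHC composite scoring** (proportion bin 0–4 × intensity 0–3) and the
  50 μm centroid co-localization rule for segmented cells.
- **Cohort analysis**: leave-one-out influence of each sample on the
  High–Low difference in GC-like B cell frequency, and standard test
  selection (Shapiro–Wilk + Levene → t-test or Mann–Whitney; Kruskal–Wallis;
  Fisher exact).
- A **synthetic Visium-like generator**: hex lattice at 100 μm pitch,
  negative-binomial counts, planted disk-shaped TLS and metabolic niches, and
  a co-localization/avoidance parameter ρ ∈ [−1, 1] with full ground truth —
  so every operation can be validated against known structure.

## Worked example

```python
from tlspatial import (
    METABOLIC_SIGNATURE, TLS_SIGNATURE, SyntheticSpatialConfig,
    binarize_scores, cooccurrence_permutation_test, mean_z_scores,
    pair_classes, simulate_spatial,
)

dataset, truth = simulate_spatial(SyntheticSpatialConfig(overlap=-1.0, seed=1))
a = binarize_scores(mean_z_scores(dataset, TLS_SIGNATURE), rule="quantile", q=0.90)
b = binarize_scores(mean_z_scores(dataset, METABOLIC_SIGNATURE), rule="quantile", q=0.90)
labels = pair_classes(a, b, spot_ids=dataset.spot_ids)
for cls in ("A-B+", "A+B+"):
    res = cooccurrence_permutation_test(dataset.coords, labels, cls, cls,
                                        n_perm=999, seed=2)
    print(cls, round(res.observed, 3), round(res.pvalue, 4))
```

prints

```
A-B+ 0.06 0.001
A+B+ 0.036 0.104
```

On a section where metabolic regions avoid TLS niches (ρ = −1), the
metabolic-only class `A-B+` co-occurs with itself far beyond its permutation
null (p = 0.001): tryptophan-metabolism signal concentrates away from TLS
zones. The double-positive class `A+B+` — spots crossing both thresholds by
chance — stays compatible with spatial randomness (p = 0.104). On a
co-localized section (ρ = +1) the pattern reverses.

The `examples/` directory holds one short script per capability
(simulation/scoring, co-occurrence, hotspots + TLS regions, LOO influence,
full report pipeline); each prints the numbers it computes with a note on
what they mean. A thin CLI mirrors the library
(`tlspatial simulate|score|classify|cooccur|permtest|hotspot|tls|ihc-score|loo|compare|report`).

## Documentation

`docs/methods.md` describes the model and every default in detail: the
co-occurrence ratio and its permutation null, the Gi\* substitution for
latent-space hotspot methods, the synthetic generator's geometry and what it
does and does not emulate, and the package's numerical conventions.
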