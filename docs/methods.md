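# Methods

`hypogeo` implements a desk pipeline for flagging potential conservation
concern in hypogeous (truffle-forming) fungi from soil eDNA metabarcoding,
together with a genus-level analysis of host and environmental preference.
This note records the models, the defaults and why they were chosen, and
what the simulation-based tests do and do not demonstrate.

## Occurrence currency

All occurrence arithmetic runs on **distinct ASV types per phylotype per
sample**, not read counts. Read counts in eDNA surveys are dominated by PCR
and sequencing depth; the number of distinct sequence variants of a
phylotype recovered from a sample is a more conservative signal of local
presence and intraspecific diversity. An optional read matrix is carried
only for relative-abundance summaries (taxon reads / total reads × 100).

## Population size

For one phylotype,

    N = Σᵢ ASVᵢ × 10 × 12/7

where ASVᵢ is the phylotype's ASV-type count in sample *i*, 10 converts a
genet detection into mature individuals (the fungal mature-individual
multiplier used in fruit-body red-listing), and 12/7 corrects for the
average number of distinct host trees represented in a 9-subsample pooled
sample. The factor 12/7 is held as an exact `Fraction`, so e.g. a total of
7 ASV types yields N = 120 with no floating-point residue. Phylotypes with
N **strictly greater than 500** are eligible for Criterion-B scoring;
N ≤ 500 is Data Deficient regardless of geometry (the source phrasing
covers "exceeding 500" and "below 500" but not equality; strict-greater is
this package's documented choice). The 500-individual gate itself is a
convention inherited from fruit-body surveys and should be read with the
same caution there — the mapping from ASV counts to genets is unvalidated.

## Range geometry

* **Projection.** Occurrence points (WGS84) are projected with a spherical
  Lambert azimuthal equal-area projection (R = 6371.0088 km) centred on the
  occurrence centroid. Equal-area is the correct property for IUCN area
  thresholds; centring per phylotype keeps distortion negligible at
  national scale. No ellipsoidal geodesy is attempted — planar equal-area
  areas are the contract.
* **AOO.** Occupied 2 km × 2 km half-open cells `[i·c,(i+1)·c) ×
  [j·c,(j+1)·c)` anchored at the projection origin;
  `AOO = n_cells × c² × correction_factor`. Anchoring at the origin is
  deterministic and documented; IUCN permits any fixed grid placement.
  `correction_factor` defaults to 1 (raw cells). For point-sampling designs
  that visit only a few localities per sampling grid, the helper
  `grid_standardization_factor` = grid area / (sites per grid × cell area)
  (≈ 19.22 for the default design) rescales cell occupancy to the grain of
  the sampling grid; the factor is always an explicit parameter, never
  applied silently.
* **EOO.** The alpha-shape area of the deduplicated points; `alpha = 0`
  (the default) is the convex hull. Automatic alpha optimisation is
  unstable and irreproducible, so alpha is explicit; for `alpha > 0` the
  shape is the union of Delaunay triangles with circumradius < 1/alpha,
  summed over components. Coordinates are deduplicated at 1 m resolution
  (rounding used only as the duplicate key, so retained coordinates are
  exact). Fewer than three distinct points → EOO `UNDEFINED`; three or
  more exactly-collinear points → area 0 with a `DEGENERATE_COLLINEAR`
  flag, because the hull exists but its zero area is a sampling artifact.

## Criterion-B categorisation

B1 (EOO, km²): CR < 100, EN < 5 000, VU < 20 000; B2 (AOO, km²): CR < 10,
EN < 500, VU < 2 000; all bounds strict "<" ("less than"), boundary values
fall to the less-threatened side. NT has no numeric Criterion-B bound and
is reachable only through a user-supplied threshold table. When B1 and B2
disagree, the **more threatened** category is assigned (a join on the
severity lattice — commutative, associative, idempotent). Undefined EOO
defers to B2 alone unless `require_eoo` is set; degenerate EOO defaults to
"drop B1" rather than CR-by-zero-area (policy `as_zero` is available). The
B subcriteria (fragmentation, decline, fluctuation) cannot be assessed
from a single-timepoint survey, so outputs are provisional flags, not IUCN
listings.

## Preference statistics

* **rclr.** Per sample, nonzero genus counts x → ln x − mean(ln of that
  sample's nonzero counts); zeros stay missing. This avoids
  pseudo-counting zeros that in eDNA data mean "not detected", not
  "absent at known zero abundance". All-zero samples are dropped and
  recorded.
* **Host test.** Two-sided Wilcoxon rank-sum on non-missing rclr values,
  Pinus vs Quercus (hosts outside the two focal genera are excluded).
  Exact null when both groups are ≤ 20 and tie-free, normal approximation
  with tie correction otherwise. A genus detected under a single host is
  flagged (`SINGLE_HOST_ONLY`) with its direction reported but no p-value.
* **Correlations.** Two-sided Spearman with average ranks against the 11
  numerical variables (MAT, MAP, longitude, latitude, altitude, pH, TOC,
  TN, NH4+, NO3−, TP), pairwise deletion of missing values, ≥ 3 complete
  pairs required.
* **FDR.** Benjamini–Hochberg step-up, by default one family per variable
  across genera (matching a column-wise display of the genus × variable
  matrix); a single global family is available. Stars at 0.05/0.01/0.001
  on adjusted p.
* **Clustering.** Genera are clustered on their Spearman-ρ profiles
  (missing → 0, i.e. no evidence of association), complete linkage on
  squared Euclidean distance; rows are pre-sorted lexicographically so tie
  handling is deterministic. The choice of ρ profiles as the feature
  matrix is this package's decision; significance-weighted alternatives
  would change the dendrogram but not the per-cell tests.
* Genera detected in fewer than `min_grids` (default 2) distinct sampling
  grids are excluded from the whole preference analysis and reported as
  such.

## Synthetic survey generator

`DesignConfig` defaults encode the emulated design: 162 grids of
11.062 km × 13.902 km on a near-square lattice, 2 sites per grid placed
uniformly with ≥ 10 km separation (rejection sampling, bounded retries),
one pooled sample per host (Pinus, Quercus) per site → 648 samples.
Covariates follow simple plausible models — MAT ≈ 16.5 − 0.75·(lat − 33) −
6.5·altitude[km] + N(0, 0.4) °C, altitude and the soil-chemistry variables
log-normal (medians ~200 m, MAP 1300 mm, pH N(5.5, 0.5), TOC 30 g/kg,
TN 2.5, NH4+ 10 mg/kg, NO3− 8, TP 500) — chosen to sit in the realistic
range for temperate-peninsula forest soils; they are stand-ins for real
covariate structure, not a climate model.

Phylotype truth: a disc range (centre, radius in planar km) or widespread;
detection per in-range sample via
`logit p = logit(p₀) + host_bias·h + Σ effect_v·z_v`; detected samples draw
counts `1 + Poisson(λ·exp(Σ abundance_effect_v·z_v))`. The abundance-side
effects exist because an effect confined to detection is structurally
invisible to rclr-based correlation — zeros become missing values, so only
detected samples are tested; a generator meant to exercise the Spearman
stage must move the conditional intensity too. The shifted Poisson keeps
counts integer and ≥ 1 as the population formula expects.

What the generator does **not** emulate: spatial autocorrelation of
covariates beyond the latitude gradient, non-disc (fragmented or
climatically bounded) ranges, inter-phylotype dependence, PCR/sequencing
error, or the taxonomic identification pipeline. Passing recovery tests
therefore show the *pipeline arithmetic* is faithful under the stated
design, not that real surveys achieve these error rates.

## Category-recovery testing

`expected_category` computes the analytically implied category of a truth
record under complete detection (hull and cells of all reachable samples,
expected N = n_reachable × (1 + λ) × 10 × 12/7) with the same decision
table used on realized data. The recovery suite targets all five outcomes
DD/CR/EN/VU/LC. Under the 2-sites-per-grid point design, raw 2-km cell
occupancy caps AOO at ~1 296 km², so B2 can never reach LC with
`correction_factor = 1`; conversely, with the grid-standardised factor one
cell already exceeds the 10 km² CR bound. The recovery suite therefore
assesses local-range targets (DD/CR/EN/VU) with raw cells and widespread
targets (LC) with the grid-standardised factor — always using the same
factor for the expected and the realized side of a comparison. EN and VU
disc centres are restricted to sites with enough neighbours (≥ 12 within
18 km, ≥ 100 within 60 km) so the expected population size sits far above
the eligibility gate; this encodes "eligibility ensured" in the truth
itself rather than leaving it to Poisson fluctuation at the 500 boundary.

## Problem sizes and numerical choices

The shipped test suite and the acceptance script run geometry oracles on
200 random point sets (≤ 50 points), the population-formula property on
1 000 random vectors, category recovery on 300 phylotypes under the full
648-sample design, rclr properties on 200 random matrices, null
calibration on 20 genera × 11 variables over 500 replicates (200 in the
script), and planted-effect power (true Spearman ρ = 0.5 via a Gaussian
copula, n = 100, BH family of 20) over 100 replicates — sizes at which the
binomial error bands in the assertions are meaningful while a full run
stays in the minutes range on one CPU. Tolerances: rclr centring and EOO
oracle agreement at 1e-9 (relative for areas), exact equality for AOO cell
sets and the decision table; ties in ranks use average ranks throughout.

## Known limitations

* AOO/EOO from presence points under-sample true ranges; the correction
  factor is a blunt instrument and its appropriate value depends on the
  sampling design, which is why it is exposed rather than fixed.
* The mature-individual multiplier and pooling factor are conventions; N
  is best read as a relative eligibility score, not a census.
* The rank tests treat samples as independent; spatial pseudo-replication
  (two sites per grid) is not modelled.
* The alpha-shape EOO with `alpha > 0` is not monotone in points and is
  reported without a degenerate-case guarantee beyond the hull case.
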