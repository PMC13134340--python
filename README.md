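# hypogeo

Provisional red-listing and environmental-preference analysis of hypogeous
(truffle-forming) fungi from soil eDNA metabarcoding.

Hypogeous fungi fruit underground, so conventional fruit-body surveys miss
most of their diversity, and the majority of molecularly detected lineages
("dark taxa") have never been assessed for conservation status. `hypogeo`
starts where a metabarcoding identification pipeline ends — a phylotype ×
sample table of **distinct ASV-type counts** joined to georeferenced soil
samples — and computes, per phylotype:

* **population size** `N = Σᵢ ASVᵢ × 10 × 12/7` (ASVᵢ = ASV types in
  sample *i*; 10 = mature-individual multiplier for fungi; 12/7 = pooled
  host-tree correction), with N ≤ 500 gated to Data Deficient;
* **EOO** (IUCN Criterion B1): area of the alpha shape of the occurrence
  points (convex hull at the default `alpha = 0`) after equal-area
  projection, undefined below three distinct localities;
* **AOO** (Criterion B2): occupied 2 km × 2 km cells × 4 km² × an explicit
  scale-correction factor;
* a **provisional category** (CR/EN/VU/LC/DD) from the Criterion-B area
  thresholds, taking the higher-threat of B1 and B2.

At genus level it computes host-preference (Wilcoxon rank-sum, Pinus vs
Quercus soil) and Spearman correlations against 11 environmental variables
on robust-clr (rclr) transformed counts, with Benjamini–Hochberg FDR and
complete-linkage clustering of the correlation profiles.

A seeded simulator of the nationwide survey design (162 grids of
11.062 km × 13.902 km, 2 sites ≥ 10 km apart per grid, one pooled sample
per host per site → 648 samples) provides ground-truth data, so every
stage is testable by parameter recovery. See `docs/methods.md` for the
models and their assumptions.

## Worked example

Simulate a small survey (24 grids → 96 samples, 12 phylotypes spanning the
category spectrum), assess it, and run the preference analysis:

```sh
hypogeo simulate --out-dir demo --seed 42 --n-grids 24 --n-phylotypes 12
hypogeo assess demo/samples.tsv demo/incidence.tsv --out demo/assessment.tsv
hypogeo envpref demo/samples.tsv demo/incidence.tsv \
    --out demo/preference.tsv --newick-out demo/dendro.nwk
```

`assessment.tsv` (selected columns):

```
phylotype_id  n_samples  n_estimated  aoo_km2  eoo_km2  category_b1    category_b2  category_final
sim-DD-0001   2          68.5714      4                 NOT_EVALUATED  CR           DD
sim-CR-0004   2          994.286      4                 NOT_EVALUATED  CR           CR
sim-EN-0007   25         1165.71      52       576.129  EN             EN           EN
```

Reading the rows: `sim-DD-0001` was detected in 2 samples with 4 ASV types
in total, so N = 4 × 10 × 12/7 ≈ 68.6 ≤ 500 → Data Deficient, whatever its
geometry. `sim-CR-0004` occurs at a single locality (EOO undefined, AOO one
cell = 4 km² < 10) but with many ASV types (N ≈ 994 > 500), so it is
assessable and lands in CR via B2. `sim-EN-0007` spans 25 samples; its hull
area 576 km² sits in the EN band of B1 (100–5 000) and its 13 occupied
cells (52 km²) in the EN band of B2 (10–500), giving EN.

`preference.tsv` holds one row per genus × variable:

```
genus    variable  statistic   p_raw     p_adjusted  stars  direction  flag    n_pairs
Genus00  host      1117.5      0.921666  0.921666           PINUS      TESTED  94
Genus00  MAT       -0.111666   0.283939  0.378586           NEGATIVE   TESTED  94
```

— here Genus00 shows no significant host preference (rank-sum p ≈ 0.92)
and a weak, non-significant negative MAT correlation (ρ ≈ −0.11, BH-adjusted
p ≈ 0.38). The dendrogram (`demo/dendro.nwk`) is Newick with
complete-linkage merge heights:

```
(Genus03:0.80171,(Genus01:0.502119,(Genus00:0.223387,Genus02:0.223387):0.278732):0.299592):0;
```

The same machinery is available as a library
(`hypogeo.assess_table`, `hypogeo.preference_report`,
`hypogeo.generate_design`, ...).

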