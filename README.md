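# varscape

Variant **composition** (the proportions of variant types) and variant
**distribution** (variant density) across a genome, analysed under a
two-mechanism mutation model with optional background selection — built for
*C. elegans*-style polymorphism data (many wild isolates, arm-high /
center-low recombination landscapes) and fully exercisable on synthetic data.

## The model

The recombination rate of a genomic interval is r = g/n, with g its genetic
length (cM) and n its physical length (Mb). All mutation processes are split
into two classes:

- **Morgan mechanism** — output proportional to *genetic* distance
  (anchored to programmed meiotic double-strand breaks), coefficient M:
  `#variants = M·g`;
- **Sanger mechanism** — output proportional to *physical* distance
  (e.g. replication errors), coefficient S: `#variants = S·n`.

With R = S/M (units cM/Mb) and d generations of divergence, an interval
accumulates

```
v_o = (r + R) · n · M·d
```

variants, and a variant type generated with probability F_M by the Morgan
mechanism and F_S by the Sanger mechanism has expected proportion

```
f_o = (r·F_M + R·F_S) / (r + R)
```

— monotone in r, between F_M and F_S, with the sign of its correlation with
the recombination rate given by sign(F_M − F_S). Coupling with background
selection (deleterious rate U, selection coefficient s_d, inbreeding
F = (1−c)/(1+c) for outcrossing rate c) gives the post-selection count

```
v_b = (r + R) · d · n · M · exp(−U / (s_d + r·(1−F))) / (1 + F)
```

The reduction factor is type-independent: background selection reshapes the
distribution but never the composition. (R, F_M, F_S) and (R, M·d) are
estimated by Levenberg–Marquardt least squares over intervals; only the
product M·d is identifiable.

## What's in the package

| module | role |
| --- | --- |
| `varscape.synthetic_data` | genomes, genetic maps, annotations, tracks, and variant sets drawn from the model; selection thinning; curation-artifact injection |
| `varscape.variant_io` | polymorphism GFF3 parsing/writing, SNP/indel size-class classification, adjacent-record merging, overlap/overshadow resolution, feature annotation, population selection |
| `varscape.genome_intervals` | the four interval boundary schemes (1-Mb and 5-cM, forward/reverse, 0.2-Mb terminal merge), feature densities, GC/expression/chromatin summaries |
| `varscape.composition_stats` | per-interval counting, proportion definitions, Pearson/Spearman/Kendall screens, OLS, Welch t |
| `varscape.mutation_model` | forward predictions, composition/distribution fits, the acceptable-R scan, Morgan fraction, fold difference, fit aggregation with Benjamini–Hochberg |
| `varscape.selection_model` | background-selection factor, combined-model fits of s_d, the closed-form apparent-R distortion under type-biased removal |

## Worked example

`examples/04_fit_mutation_model.py` builds a three-chromosome synthetic
genome (high-recombination arms at 8 cM/Mb, centers at 0.5), simulates
variants with truth R = 10, M·d = 1500, pools interval rows from all four
boundary schemes, and re-estimates the coefficients:

```
composition fit on SNP/variants (truth R=10, F_M=0.67, F_S=0.72):
  R    =   5.802 +/- 2.966   t =    2.0   p = 0.055
  F_M  =   0.679 +/- 0.009   t =   75.7   p = 1.4e-63
  F_S  =   0.724 +/- 0.002   t =  359.8   p = 4.3e-106
distribution fit on all-variant counts (truth R=10, M*d=1500):
  R    =    10.1 +/- 0.044
  M_d  =  1494.7 +/- 5.3
acceptable presumed R (all fitted F in [0,1]): [0.73, 242]
R =  5.80: Morgan share 42.3%, arm/center density fold 2.19
R = 10.00: Morgan share 29.8%, arm/center density fold 1.71
```

The distribution fit pins (R, M·d) tightly because counts are Poisson-rich;
the composition fit's R is honest but noisy (the SNP proportion moves only a
few points across the landscape), exactly the asymmetry the analysis
predicts. The Morgan share Σg/(Σg + R·Σn) is the fraction of all variants
attributed to the genetic-distance mechanism; the fold (r_hi+R)/(r_lo+R) is
the arm/center density contrast mutation alone would produce.

The other examples cover dataset generation (`01`), curation round trips
(`02`), the composition/correlation screen (`03`), and the combined
mutation + background-selection model with the s_d grid fit (`05`).

A thin CLI mirrors the main steps:

```sh
varscape fixtures --out data/ --seed 1 --scale 0.05
varscape clean --in data/variants.gff3 --combine-adjacent --resolve-conflicts --out clean.gff3
varscape intervals --map data/genetic_map.tsv --scheme pf,pr,gf,gr --out intervals.csv
varscape fit-composition --in data/variants.gff3 --map data/genetic_map.tsv
varscape fit-distribution --in data/variants.gff3 --map data/genetic_map.tsv
```

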