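# Methods

## The model and its assumptions

The package analyses two per-interval observables over a genome tiled into
windows: the variant **count** (distribution) and the per-type variant
**proportions** (composition). The generative model assumes that every
mutation process belongs to one of two classes — one whose output per
generation scales with the genetic distance g of an interval (Morgan
mechanism, coefficient M), one whose output scales with the physical
distance n (Sanger mechanism, coefficient S) — and that each mechanism
generates each variant type with a fixed probability (F_M, F_S per type,
each table summing to 1). Both class contributions are constant in time, so
after d generations of divergence an interval at recombination rate
r = g/n holds

    v_o = (r + R) · n · M·d,        R = S/M  (cM/Mb),

variants in expectation, and the expected proportion of a type is the
mixture

    f_o(r) = (r·F_M + R·F_S) / (r + R).

Consequences used throughout: f_o is monotone in r, bounded by F_M and F_S,
tends to F_S as r→0 and to F_M as r→∞; its correlation with r has the sign
of F_M − F_S; and equal F values give a flat proportion regardless of R.
For denominators other than "all variants" (proportions out of SNPs or out
of non-SNPs) the same functional form holds exactly after renormalizing the
F tables over the denominator set and rescaling R to R·F_S(D)/F_M(D); the
fitted "R" of such a definition is that effective value, which equals R when
the mechanisms allocate similar mass to the denominator set.

Background selection multiplies the expected count by the classical
reduction factor

    exp(−U / (s_d + r·(1−F))) / (1 + F),      F = (1−c)/(1+c),

with U the deleterious mutation rate per generation, s_d the average
selection coefficient, and c the outcrossing rate of a selfing species. The
factor is type-independent by construction, so it alters distribution but
not composition — which is why composition-based estimates of R isolate
mutation, while distribution-based estimates confound mutation with linked
selection. The numeric value of r is used in the exponent as-is (cM/Mb); a
`r_scale` knob on `SelectionParams` exposes the unit ambiguity explicitly.

Direct, type-biased selection does distort composition. Removing a fraction
q of the complement of a focal class (e.g. half of all indels, no SNPs)
transforms the proportion curve into the *same* functional form with

    R'   = R·(1 − q(1−F_S)) / (1 − q(1−F_M)),
    F_M' = F_M / (1 − q(1−F_M)),    F_S' = F_S / (1 − q(1−F_S)),

so a least-squares analysis of the distorted data recovers (R', F'), not
(R, F). `distortion_apparent_R` returns this closed form and verifies it by
re-fitting noiseless transformed proportions (agreement ≤ 1e-6). For
(R = 10, F_M = 0.8, F_S = 0.7, q = 0.5 on non-SNPs) the closed form gives
R' = 10·0.85/0.9 = 9.444…: removal biased against the class the *Sanger*
mechanism under-produces pulls the apparent R toward the Morgan side. A
frequently quoted value of 10.6 for this scenario equals 10·0.9/0.85, i.e.
the same ratio inverted; the algebra above, confirmed by the independent
refit, is what the package reports.

## Estimation

All fits are unweighted least squares over interval rows (an optional
denominator-count weighting exists), minimized by Levenberg–Marquardt
(`scipy.optimize.least_squares`, method `lm`), with standard errors from the
Jacobian at the optimum (covariance = (JᵀJ)⁻¹·SSE/df), t = estimate/SE, and
two-sided p from the t distribution with df = N − #parameters.

- **Composition fit** (R, F_M, F_S): the three-parameter rational curve is
  identifiable from ≥3 distinct r values; the optimizer is multi-started
  over R₀ ∈ {0.1, 1, 10, 100} with (F_M, F_S) seeded by the closed-form
  linear solve at each R₀, and the best-SSE solution kept. F estimates are
  reported unclamped: an F̂ outside [0, 1] is evidence against the
  parameterization, and `scan_R_range` turns that into an acceptable-R
  interval by scanning presumed R over a log grid (default 0.01–9900) and
  accepting values whose fitted F_M and F_S all stay inside [0, 1].
- **Distribution fit** (R, M·d): linear in r on the density scale, seeded by
  OLS of count/n on r (slope = M·d, intercept/slope = R) and polished by LM
  for uniform SE machinery. A non-positive slope, or an implied R beyond 1e6,
  is flagged unidentifiable instead of fitted.
- **s_d estimation**: for each presumed M·d on a grid, a one-parameter LS
  fit of the combined model; the row with the smallest p is flagged best.
  The (s_d, M·d) pair is deliberately not fitted jointly — the two trade off
  along a ridge, which the grid output makes visible. Estimates outside
  (0, 1] are reported with an `in_range` flag, not clamped. With U = 0 the
  factor is constant in s_d and the SE correctly diverges.
- **Fit aggregation**: `summarize_fits` filters by |t| or p cutoffs, applies
  Benjamini–Hochberg (statsmodels `fdr_bh`) at a chosen FDR, and reports the
  median/quartiles of surviving R̂. Pooled multi-scheme fits carry an
  `aggregated` flag, propagated as a caveat: their interval rows are not
  independent, so their p values should not be read at face value.

## Intervals and curation

Four tiling schemes: 1-Mb windows from the left (`pf`) or right (`pr`)
telomere, 5-cM windows from the left (`gf`) or right (`gr`) on the genetic
map; any fragment shorter than 0.2 Mb of physical length is merged into its
neighbour (the threshold is physical in all four schemes). Genetic positions
interpolate linearly between map anchors and are clamped beyond the terminal
anchors; zero-recombination windows are retained with r = 0. Applied to the
reference *C. elegans* chromosome lengths, the 1-Mb rule yields 102 windows
genome-wide. When a feature class (exons, CDS) is excluded from a variant
subset, `adjust_lengths` shrinks n by the merged feature space and leaves r
unchanged (assuming the excluded space is evenly spread, genetic and
physical distance shrink proportionately), so g′ = r·n′.

Variants are counted in a window only if both endpoints lie inside it;
boundary-straddling records are counted nowhere. Feature densities
union-merge spans before summing (duplicates, containments and overlaps all
collapse); intron space is counted net of exon space inside introns.

Curation follows three rules. (1) Maximal runs of immediately adjacent
records carried by identical isolate sets merge into one record, alleles
concatenated in genomic order; runs are keyed by carrier set so records of
other isolates interleaved in coordinate order cannot break them. (2) Within
each isolate's record set, a record strictly inside a deletion's span is
censored (overshadowed); the enveloping record must be a deletion.
(3) Remaining overlapping records merge into one record spanning their
union; since the joint allele of conflicting calls is unknowable, the merged
record carries placeholder IUPAC alleles whose lengths preserve the summed
net change. Both passes are idempotent and never increase the record count.
"Affects a feature" means ≥1 bp of the feature changes (insertions at a
feature's edge change no base of it); "inside" means no DNA outside the
feature is affected; "affects exons" is the union over CDS, UTRs,
pseudogenes and ncRNA. Aggregate counting weights each variant by its
number of retained carrier isolates (double-counting shared variants), the
convention behind multi-isolate pooling.

## The synthetic-data generator

The generator emulates the inputs of a wild-isolate polymorphism analysis:
chromosome sequences (GC 0.36), a piecewise-linear genetic map from
(span, rate) domains, gene/exon/CDS/ncRNA/repeat annotations with
essential-gene flags, expression coverage segments, a 10-bp-step chromatin
track, and the variant set itself. Defaults, chosen once: six chromosomes of
14–21 Mb with two 25%-length arms at 4–7.5 cM/Mb flanking a low-rate center
(0.4–1.2 cM/Mb), 40 isolates, and F tables anchored at the published point
probabilities for SNPs (F_M = 0.67, F_S = 0.72) and the 40–699-bp indel
class (0.022 / 0.005), the remaining mass spread over the small-indel
classes in decreasing size order.

Variant draws follow the model exactly: per chromosome, Poisson(M·d × map
length) Morgan variants placed by inverse transform on the map (density ∝
local rate) and Poisson(M·d × R × Mb) Sanger variants uniform in bp; types
drawn from F_M or F_S by origin; ref/alt alleles read off the generated
sequence so classification is exact. Each variant is carried by a geometric
random number of isolates (mean 3, truncated at the panel size) — a
stand-in: no coalescent genealogy, linkage structure, demographic history,
or realistic site-frequency spectrum is modelled, so passing tests validate
the counting, curation and estimation machinery, not population-genetic
realism. Background thinning retains each variant with probability
proportional to the reduction factor at its local rate, normalized so the
maximum retention is 1 (this normalization rescales the recoverable M·d
upward, visible in the s_d grid example); direct thinning removes by
per-type probability, optionally restricted to exon-affecting records.
Artifact injection reproduces three curation defects with known ground
truth: splitting equal-length multi-base substitutions into adjacent
per-base SNPs, duplicating span records with a 1-bp shift, and planting
ghost records strictly inside deletions of a carrier. Splits and
overshadows are exactly undone by the curation pipeline; overlap-duplicates
are resolved into union spans, which by design need not restore the original
span. Everything is reproducible bit-for-bit from the seeds.

## Numerical choices and problem sizes

Tolerances: noiseless identifiability is asserted at 1e-6; tiling
conservation at 1e-9 relative; the distortion refit at 1e-6. Kendall is
tau-b (tie-corrected, scipy); the Welch t-test is used for group contrasts;
correlations refuse constant inputs and n < 3. Calibration checks run 100
seeded replicates on a 320-row landscape (the pooled four-scheme size) with
Poisson denominators at M·d = 1500 — per-interval counts of 5,000–25,000 —
asserting ≥90/100 coverage of the ±2 SE interval for R; the composition
replicates use the large-indel proportion, whose wide F_M/F_S contrast makes
R well-identified (the SNP proportion's small contrast leaves R weakly
identified at these counts, visible in its larger SE). Examples and test
fixtures use 6-Mb chromosomes with 1.5/3/1.5-Mb rate domains so 1-Mb windows
resolve the arm/center contrast cleanly.

## Known limitations

- The isolate-sharing model is a placeholder; aggregate-mode results scale
  with mean sharing (an aggregate fit of M·d recovers ≈ sharing-mean ×
  truth).
- Merged overlap records carry placeholder alleles; sequence-level truth is
  not reconstructed.
- The acceptable-R scan reports grid extremes; bounds are only as fine as
  the grid.
- Real-data coefficient values require the original polymorphism download
  and are treated as reference points only; nothing in the package asserts
  them.
- The unit of r inside the background-selection exponent is a convention
  (cM/Mb), exposed as a knob rather than resolved.
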