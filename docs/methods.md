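# Methods

`durumpanel` characterises panels of inbred (selfing) crop lines genotyped
with biallelic SNP arrays: marker curation, within/between-group diversity,
linkage-disequilibrium (LD) decay, putative-selection-sweep (PSW) scanning,
and stratified core-collection selection. This note records the models,
estimators, defaults and numerical choices, and what the synthetic test
substrate does and does not establish.

## Genotype model and ploidy conventions

Genotypes are dosages of the alternate allele, 0/1/2, with `-1` for
missing. Durum wheat and similar selfers are near-fully homozygous, so all
diversity and differentiation statistics use a **haploid coding**: each
accession contributes one gene copy, homozygotes map to 0/1 and the rare
heterozygous calls are treated as missing. Curation-level filters (carrier
counts, MAF) instead use the conventional array accounting of two gene
copies per accession over observed calls. The two conventions live in
`diversity.haploid_freqs` and `curation.allele_counts` respectively; no
statistic mixes them.

Coordinates are 1-based bp on input (HapMap/VCF convention); every internal
interval — sweep peaks, PSW clusters, feature annotation, truth files — is
half-open `[start, end)` after subtracting 1 from the start. This is fixed
in one place (`core_io`) so overlap tests are unambiguous.

## Curation

* **Carrier filter**: a marker is kept when its minor allele is carried by
  at least 3 accessions (a heterozygote counts once). The boundary is
  inclusive: exactly 3 carriers pass.
* **MAF filter**: strictly greater than 0.05 over observed calls;
  optionally per group (kept if it clears the threshold in any group).
* **LD pruning** (`r2` = squared Pearson correlation of dosage columns over
  pairwise-complete accessions): greedy left-to-right scan within each
  chromosome with a 250-marker window. A marker joins the first retained
  representative within the window at `r2 >= cut`; in merge mode the
  representative (leftmost by position, ties by id) absorbs the group and
  its missing cells are filled by the consensus of sign-aligned members, so
  complementarily coded duplicates (dosage `2 - x`) merge as they should.
  Full-chromosome all-pairs pruning is quadratic in markers; the windowed
  scan is the tractable standard and the window is configurable.
* **Multi-hit placement**: a marker with several candidate map positions is
  placed at the candidate whose 10 nearest mapped neighbours (within 5 Mbp)
  give the highest mean `r2`, required to exceed 0.3; otherwise unplaced.
* **IBS and duplicates**: IBS(a,b) = mean over shared markers of
  `(2 - |da - db|)/2`. Duplicate groups are single-linkage components over
  IBS strictly above 0.95; the first-listed member is retained.
* **Imputation harness**: the package does not ship a production imputer.
  `imputation_accuracy` masks 1% of called genotypes per replicate
  (independent re-draws each replicate), runs any pluggable imputer, and
  scores exact recovery; the bundled per-marker mode imputer exists to
  exercise the harness and as a floor baseline.

## Diversity and differentiation

Per-locus statistics from haploid frequencies `p` estimated on `n` gene
copies:

* Nei unbiased gene diversity `He = n/(n-1) (1 - p^2 - q^2)`;
* Botstein `PIC = 1 - (p^2 + q^2) - 2 p^2 q^2` (maximum 0.375);
* Shannon–Wiener `H = -sum p_i ln p_i` and Hill evenness
  `E5 = (1/lambda - 1)/(e^H - 1)`, `lambda = sum p_i^2`, undefined at
  fixation and exactly 1 at equal frequencies;
* minor-allele SFS binned at 0.05 over `(0, 0.5]`, last bin closed.

Group summaries average He/PIC over loci polymorphic **within the group**
and report that count alongside (the table layout used for germplasm
panels). Mean pairwise differences (pi) average, over accession pairs, the
count of differing haploid loci among pairwise-complete loci rescaled by
`total/complete` — the raw count when nothing is missing.

**AMOVA** is one-level: squared inter-accession distance = the rescaled
differing-locus count; `SS_total` and within-group SS from the usual
`sum d^2 / n` bookkeeping; `sigma2_within = MS_within`,
`sigma2_among = (MS_among - MS_within)/n_c` with the unequal-size
coefficient `n_c = (N - sum n_g^2/N)/(G-1)`; `Fst` is the among share.
Significance is the fraction of label permutations with `Fst >=` observed,
reported with the `(b+1)/(m+1)` correction so p is never 0. Pairwise
group `Fst` applies the same machinery to each pair. Nei (1972) standard
distance uses locus-averaged identity terms,
`D = -ln(Jxy / sqrt(Jx Jy))`.

**Unique alleles** are assessed on the MAF-unfiltered set: the panel-wide
minor allele of a marker is private to a group when its copy count is
positive there and zero elsewhere; it is *rare-unique* when its owner-group
frequency is below 0.05 (the complementary summary column counts
frequencies above 0.05).

**Per-locus Fst** (for scans) is the single-locus Weir–Cockerham
variance-components estimator for haploid samples
(`MSP`, `MSG`, `theta = (MSP - MSG)/(MSP + (n_c - 1) MSG)`). For
genome-wide summaries the package exposes `wc_fst_multilocus`, which sums
the per-locus components before taking the ratio. The distinction matters:
under strong drift the arithmetic mean of per-locus ratio estimates is not
a consistent estimate of the divergence parameter (it under-reads F = 0.30
by ~0.09 on calibrated panels), while the component-sum estimator recovers
the simulated F within ±0.01 across F in {0.05, 0.13, 0.30}.

## LD decay

Pairwise `r2` within chromosomes (distance-capped at 50 Mbp by default;
decay is flat beyond background) is fitted by least squares to the
drift–recombination expectation for a sample of `n` gene copies

    E[r2] = (10+C)/((2+C)(11+C)) * [1 + ((3+C)(12+12C+C^2))/(n(2+C)(11+C))]

with `C = a d`; only the scale `a` is fitted (log-parameterised,
multi-start across decades, Levenberg–Marquardt). Critical distances invert
the fitted curve by bracketing + Brent root finding; the curve is strictly
decreasing so the inversion is unique. Note the curve family caps at
`(10/22)(1 + 36/(22 n))` as `d -> 0` — about 0.459 for n = 150 — so a
critical distance at `r2 = 0.5` exists only for small samples (n ≲ 14);
`critical_distance` raises a no-crossing error otherwise. Background LD is
the 95th quantile (linear interpolation between order statistics,
deterministic given the documented convention) of `r2` over a seeded random
subsample of inter-chromosomal pairs. Local LD per marker is the mean `r2`
with its 50 bp-nearest neighbours, then smoothed like the scan tracks.

## Sweep scanning

Two per-marker indices between a reference (ancestral-like) and target
(derived-like) group:

* **Fst**: single-locus Weir–Cockerham as above; monomorphic-in-both
  markers are 0, markers absent from one group are missing and excluded
  from smoothing denominators.
* **DRI**: `(He_ref + eps)/(He_target + eps)` with `eps = 0.01`; values
  above 1 mark diversity loss in the target. The epsilon regularises
  fixed loci and sets `DRI = 1` when both groups are monomorphic. A log2
  output is available for symmetric display.

Raw tracks are smoothed per chromosome with a centred 15-marker moving
average, one-marker step, truncated windows at chromosome ends, missing
values dropped from numerator and denominator.

Significance is the two-step rule, with both "distributions" taken as
empirical distributions of smoothed values: (1) contiguous runs at or above
the genome-wide 90th percentile are candidate peaks; apexes on a chromosome
closer than the merge distance (an explicit bp value, or the group pair's
fitted critical distance at `r2 = 0.5` where that exists) collapse to the
highest; (2) the distribution is re-formed with each merged peak region
contributing its apex once, and apexes at or above its 95th percentile are
significant. A peak's interval is the contiguous run around its apex above
the step-1 level. Because every value above the step-1 percentile lies
inside some candidate run, the re-formed 95th percentile usually falls
just below the step-1 level and the second cut bites only when candidate
regions occupy a large share of the genome; the procedure is deliberately
an outlier screen, not an error-rate-controlled test, and the whole
thresholding logic is isolated in `detect_significant` so alternative
readings can be swapped in. A perfectly flat track is defined to carry no
peaks.

PSW clusters are connected components of significant peaks (all
comparisons and both indices) under half-open overlap, with an optional gap
allowance; a component qualifies with two member signals, or one region
supported by both indices (which necessarily contributes two peaks). They
are named `Cls-chr<label>.<n>` ordered by position. Feature annotation
(BED/GFF3 via pyranges, both normalised to half-open bp) lists overlapping
features longest-overlap first; a feature abutting a cluster boundary does
not overlap.

## Core-collection selection

Accession distance is `1 - IBS`. Ward agglomerative linkage (scipy) builds
the dendrogram; memberships are read at any `k`. Stratified sampling per
group: duplicates above 0.95 IBS collapse first; a configurable share
(default 10%) of the quota is reserved for rare haplotypes (lowest mean IBS
to the whole panel); the rest is allocated across the group's Ward
sub-clusters — the finest cut `k <= 10` whose smallest sub-cluster keeps at
least 3 members — proportionally to size (largest-remainder, minimum one
per sub-cluster), picking the sub-cluster medoid and then the most central
members. "Representative" is defined as the medoid because it is
deterministic and defensible; all ties break on accession id, so the
procedure is seed-independent and input-order invariant. Quotas are plan
inputs, not constants: real campaigns set them from the collection's
structure.

The retention report correlates per-locus MAF, He, Shannon H and E5
between the full panel and the subset over loci polymorphic in at least
one of the two, and contrasts the two SFS histograms; the headline
"diversity loss" is the range of `1 - correlation`.

## Synthetic panels

The generator is the package's test substrate and defines its study
conditions:

* **Divergence** follows Balding–Nichols: ancestral frequency
  `p ~ U(0.05, 0.95)` (an array-like ascertainment floor), population
  frequency `Beta(p(1-F)/F, (1-p)(1-F)/F)`. The default F = 0.13 matches
  the landrace-vs-modern differentiation regime of real durum panels;
  calibration is checked at F in {0.05, 0.13, 0.30}.
* **Block LD** uses a nested-prefix founder construction: per (population,
  block) each line draws one of K = 24 founder ranks; a site's allele
  occupies the first `round(K p_i)` ranks (stochastic rounding keeps the
  realised frequency unbiased at granularity cost ~1/(4K^2)). Sites within
  a block therefore carry nested allele sets — strong positive `r2` —
  while blocks are independent. This was chosen over small random founder
  pools because those add uncontrolled founder drift that would break the
  Fst calibration; the price is that within-block allele associations are
  all positive, which is irrelevant to `r2`-based analyses.
* **Scales**: 14 chromosomes ("1A".."7B") of 600 Mbp, 360 markers each
  (~5,000 genome-wide); exponential block lengths with means 4 Mbp
  (landrace-like, short LD) and 18 Mbp (modern-like, long LD). Real
  high-density panels resolve LD at 0.4–1.8 Mbp; at this synthetic marker
  density (~1.7 Mbp spacing) those scales are invisible, so the block
  lengths are density-scaled to keep the qualitative short-vs-long contrast
  measurable. The `ldcontrast` profile uses 12-line groups because the
  decay-curve family only crosses `r2 = 0.5` for small samples (above).
* **Selfing**: lines are doubled haploids with residual heterozygosity
  1 - 0.98 per cell; missing calls at 2% (the realistic 1–5% band).
* **Sweeps**: inside the interval the target population's major allele is
  pushed to a final frequency of 0.98 by i.i.d. redraws, collapsing He and
  inflating Fst locally; haplotype structure *inside* a swept interval is
  not emulated, so haplotype-based sweep statistics could not be validated
  on these panels (none are implemented). The default profile injects one
  60 Mbp sweep (~36 markers, spanning at least two smoothing windows) on
  chromosome 3B of the modern-like group.

Everything is deterministic given the config seed; fixture writing is
byte-reproducible.

### What the synthetic substrate does not show

The generator has no mutation/recombination genealogy, no ascertainment
beyond the uniform frequency floor, no genotyping error model, no
population admixture, and independent blocks rather than decaying
haplotype sharing. Passing tests therefore establish estimator
correctness, calibration against the generating model, and qualitative
behaviours (LD contrast, sweep recovery, retention), not performance on
real array data with structure, admixture and call-error artefacts.

## Numerical and degenerate-input choices

* Percentiles/quantiles everywhere: linear interpolation between order
  statistics (numpy default), documented once and shared by LD background
  and scan thresholds.
* Permutation p-values: `(b+1)/(m+1)`.
* `r2` needs at least 3 complete pairs and positive variance on both sides;
  otherwise the pair is skipped (scans/pruning) or NaN (tracks).
* Decay fits flag `poor_fit` when the scale collapses to the positive
  lower bound (no decay in the data).
* AMOVA excludes single-member groups with a warning; accession pairs with
  no shared complete locus are excluded from pi and contribute zero to
  AMOVA sums, with a warning.
* Ties in duplicate retention, merge representatives, medoid picks and
  sub-cluster allocation all break on id sort order — no hidden RNG.

## Problem sizes used by tests and the acceptance script

Simulated panels are 2 x 150 lines x ~5,000 markers for calibration and
sweep work (10–20 seeds), 2 x 12 lines for the LD-contrast profile
(10 seeds), 200 small null panels (40 x 200) for permutation-test size, and
a 500-line panel for retention — sizes at which every Monte-Carlo check has
comfortable resolution while the whole suite stays fast on one CPU.
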