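# Methods

## The divergence model

`jsdscan` treats every cytosine position *i* of a reference genome as a
small contingency table over a sample of *s* methylomes: methylome *j*
contributes `n_ij1` methylated and `n_ij2` unmethylated read counts,
with per-methylome coverage `n_ij = n_ij1 + n_ij2` and total site
coverage `n_i = Σ_j n_ij`.  Each methylome defines an empirical
methylation distribution `P̂_ij = (n_ij1, n_ij2) / n_ij`, and the
population divergence at the site is the Jensen-Shannon divergence of
these distributions,

    D̂_i = H(Σ_j π̂_ij P̂_ij) − Σ_j π̂_ij H(P̂_ij) = H⟨P̂_i⟩ − ⟨Ĥ_i⟩,

with Shannon entropy H in base 2 (bits) and coverage weights
`π̂_ij = n_ij / n_i`.  This is the plug-in (empirical) estimator: it
replaces probabilities by observed frequencies.  With coverage weights
it equals the mutual information between the "methylome" and
"methylation state" margins of the pooled table, a fact the test suite
exploits as an independent brute-force oracle.  The companion statistic
is the weighted methylation level

    MET_i = μ̂_i = Σ_j n_ij1 / n_i,

the pooled fraction of methylated reads.  For a binary state space,
0 ≤ D̂_i ≤ H(MET_i) ≤ 1 bit, so every site lives under the
binary-entropy envelope of the (MET, JSD) phase plane.

Assumptions worth keeping in mind: reads are treated as independent
draws from each methylome's per-site methylation state; cytosines on
opposite strands of a CpG are independent sites (no strand merging);
and no minimum read depth is imposed beyond the user-chosen filters.
The estimator is biased towards small JSD when coverage is very uneven
across methylomes (one dominant weight π̂ → 1 forces the mixture onto a
single distribution); `jsdscan` exposes `weighting="equal"` as an
alternative that weights every covered methylome uniformly.

## Phase-plane classification

Sites are partitioned into four C types:

| label | rule | interpretation |
|---|---|---|
| LMC | MET < 0.2 | low-methylated |
| HMC | MET > 0.8 | high-methylated |
| MMC | 0.2 ≤ MET ≤ 0.8, JSD ≤ 0.7 bit | medium-methylated, population-stable |
| MSC | 0.2 ≤ MET ≤ 0.8, JSD > 0.7 bit | metastable: the population segregates |

Boundary MET values (exactly 0.2 or 0.8) fall in the middle band; the
LMC/HMC rules are strict inequalities.  All three thresholds are
parameters (`PhasePlaneThresholds`) with the defaults above.  The
0.7-bit threshold is meaningful because an idealized metastable site —
half the population near MET 1, half near 0 — approaches
H(0.5) − H(θ_high) ≈ 0.71–0.8 bit, whereas LMC/HMC sites are capped at
H(0.2) ≈ 0.72 bit and typically sit far below it.

## Genome scan

`scan_population` merges the per-sample tables position-synchronously
(a k-way union on (chromosome, position) with a consistency check on
chromosome ordering).  A sample with no row at a position has zero
coverage there and receives weight zero — no imputation.  Sites are
filtered by `min_samples` (default 2: a single covered methylome always
gives JSD 0) and `min_coverage` (default 1, i.e. off).  No per-sample
minimum depth is applied by default because callers differ on this;
both filters are exposed.

Downstream summaries: `ctype_proportions` (percent of each C type per
context, rows sum to 100), `bin_signal` (means or C-type fractions over
non-overlapping, genome-tiling, half-open bins; empty bins are NaN,
never 0; the terminal bin is truncated to the chromosome length), and
`correlate_signals` (pairwise Spearman ρ with pairwise-complete bins,
hierarchical clustering on distance 1 − ρ with average linkage — the
distance and linkage are choices, configurable via the linkage method
argument).  Typical bin widths are 10–50 kb; binned-track functions
take the width as an explicit argument with 50 kb as the conventional
figure-scale choice.

## Feature statistics

*Metagene profiles* use literal 50-bp bins over fixed 2-kb flanks and a
length-scaled body divided into a fixed number of bins (default 60).
Fixed-width bins cannot apply verbatim to variable-length bodies, so
body scaling is the deliberate compromise; features shorter than the
bin count are mapped proportionally (with a warning).  Minus-strand
features are orientation-flipped before binning; each bin reports the
arithmetic mean over all (feature, site) pairs.

*Metastable genes (MSGs)* are selected by ranking genes on the
proportion of MSC sites among their classified gene-body sites (genes
with fewer than `min_sites` classified sites, default 5, are excluded)
and keeping genes strictly above the 0.95 quantile of that
distribution.  The strict-above rule makes degenerate cases behave
sensibly: if all proportions are equal the selection is empty, and any
gene tied with a selected gene is automatically selected too.  The MSG
fraction track normalizes the per-bin MSG count by the per-bin total
gene count, assigning each gene to the bin containing its start.

*Relative distance* measures spatial association: for each query
midpoint, the distance to the nearest reference midpoint divided by the
spacing of the two flanking reference midpoints, a value in [0, 0.5]
that is uniform under spatial independence regardless of the reference
layout.  Queries outside the reference span and chromosomes with fewer
than two references are skipped and counted.

## Randomization tests

Both tests report the observed statistic, the null sample, the raw
empirical p-value `p_raw = #(null ≥ observed) / n` — which can be
exactly 0 and reproduces the convention of reporting zero for extreme
enrichments — and the add-one estimate `(b + 1)/(n + 1)`, which cannot
be 0 and is the better point estimate.  All draws come from a seedable
`numpy` Generator recorded in the result metadata.

* **CSD/LSD test** (`csd_lsd_test`): given a binned signal and a Hi-C
  eigenvalue-sign segmentation on the same bins, the statistic is
  ⟨S | e<0⟩ − ⟨S | e>0⟩.  The null permutes the sign labels over bins,
  preserving the count of each sign (default 1000 permutations).  The
  primary p-value is one-sided for "null difference at least as large
  as observed"; the alternative convention P(null difference > 0) is
  also reported in `meta["p_positive"]` because the two disagree only
  in degenerate situations and both appear in practice.
* **MSG-near-TE test** (`msg_te_proximity_test`): the statistic g is
  the fraction of MSGs whose span, extended by `near_dist` (default
  2 kb on each side, matching the conventional flank width; "near" has
  no canonical definition), overlaps any TE.  The null draws gene sets
  of the same size uniformly without replacement from the background
  (default 10,000 draws); p = P(g_null ≥ g_observed).

Calibration note: the proximity statistic is discrete (a fraction of a
finite gene set), so its valid p-values are slightly conservative and
lumpy when the MSG set is small.  Uniformity checks of the null
therefore use large gene and MSG sets, chosen so the null statistic's
probability atoms are below the resolution of a Kolmogorov-Smirnov
comparison; with small sets the p-values remain valid but discretely
conservative.  Planted-effect checks are designed to be well powered
(effect-to-noise z ≳ 7), so a failure would indicate a defect rather
than an unlucky seed.

## The synthetic-data generator

`simulate_population` emulates a population of bisulfite methylation
tables with known per-site truth:

* **Site models** — `conserved_low` (θ = 0.03), `conserved_high`
  (θ = 0.97), `intermediate` (θ = 0.5), `metastable` (each sample
  independently methylated, θ = 0.97, with probability 0.5, else
  θ = 0.03).  The default mixture is 70/20/8/2 percent, reflecting a
  mostly unmethylated genome with a small metastable fraction.
  θ bounds fold in bisulfite non-conversion and sequencing error, which
  is why they are not 0 and 1.
* **Coverage** — per site and sample, negative binomial with mean 30
  and size 10 (variance 120); the overdispersion mimics the very uneven
  depths of public BS-seq runs pooled across studies.  Size = ∞ gives
  the Poisson limit.  Zero-coverage rows are omitted from the tables,
  exercising the scan's missing-sample path.
* **Genome** — cytosines are planted at regular spacing on an A/T
  filler using 3-bp motifs (CG / CAG / CAT), so each planted site's
  context is exact by construction.  Default context mixture
  15/15/70 percent CG/CHG/CHH, approximating the strong CHH excess
  among plant genomic cytosines.

What the generator does *not* emulate: linkage between neighboring
sites (real methylation is regionally correlated), strand-paired CpGs,
context-dependent methylation levels, mapping artifacts, or realistic
GC content.  Passing recovery tests therefore demonstrates the
correctness of the estimator and classification machinery under the
stated sampling model, not performance on real methylomes.

`simulate_annotations` places non-overlapping genes, attaches TEs
preferentially downstream of designated "metastable" genes, and tiles
the genome with an alternating-sign 50-kb segmentation;
`simulate_binned_signal` adds an optional planted shift in
negative-sign bins.  `simulate_msg_study` plants metastable-rich sites
inside a known 5% of genes for end-to-end MSG recovery.  All outputs
are deterministic given the seed (byte-identical files).

### Sample size matters for MSC recovery

A structural property of the metastable model worth documenting: with
*s* samples and a balanced mix, the high/low split at a site is
k ~ Binomial(s, 0.5), and the asymptotic JSD is H(mixture) − H(θ_high),
which for unbalanced splits falls below the 0.7-bit MSC threshold
(e.g. k = 2 of 10 gives ≈ 0.56 bit while its MET ≈ 0.22 is still inside
the middle band).  In-band MSC recovery is therefore capped near ~84%
at s = 10 regardless of coverage, and exceeds 95% only from roughly 30
samples upwards (99.7% at s = 50, measured in the test suite).  This is
a property of the statistic, not an implementation artifact: detecting
metastability reliably needs population-scale sample counts, which is
exactly the regime real methylome compendia provide.

## Numerical choices

* 0·log 0 := 0 throughout; entropies are computed in natural logs and
  rescaled, and −0.0 is normalized to 0.0.
* JSD is clipped at 0 against floating-point cancellation; a site with
  a single covered methylome is set to exactly 0.
* Zero-coverage rows receive weight 0 and are excluded from the average
  entropy; `samples_covered` records the contributing rows.
* Probability validation uses an absolute tolerance of 1e-9 on the
  simplex constraint.
* All computation is done in full double precision; rounding (e.g. the
  6-decimal TSV output) happens only at presentation.
* Generalized K-state tables (e.g. three-state epigenotype
  distributions) use the same `plugin_jsd` path; the vectorized scan is
  specialized to K = 2.

## Problem sizes in the default test run

The shipped tests run at desk scale: 50,000-site populations of 10–50
samples for recovery checks, 500-replicate calibration studies with
100–1000 permutations or draws per test, and 10,000-query uniformity
checks.  These sizes were chosen so the whole suite completes in well
under a minute on one CPU while keeping every statistical check
adequately powered.

## Known limitations

* The plug-in estimator is biased; no small-sample or k-nearest-neighbor
  correction and no bootstrap uncertainty is provided.
* Per-region divergence is summarized as the average of per-site JSD,
  which ignores within-region variation; it is not a regional JSD.
* Chromosome name matching is exact text; no "chr" aliasing.
* bgzip + tabix random access is delegated to `pysam` when a `.gz` path
  is given; plain-text region queries scan and filter and require
  sorted input.
* The CLI holds each scan in memory; it is sized for desk-scale and
  single-chromosome workflows rather than whole-compendium scans.
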