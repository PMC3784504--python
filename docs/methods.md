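# Methods

## Scope and model

`chiptile` implements the analysis chain for factor-binding ChIP-chip on
short-probe genomic tiling arrays: probe-level scoring, permutation-FDR
selection of binding loci, co-localization statistics between factors, and
the χ²/qPCR summaries used for phenotype quantification. The ingestion
boundary is a tab-delimited probe table (chrom, start, end, one intensity
column per hybridised sample); raw scanner formats are out of scope. All
coordinates are 0-based half-open everywhere, in memory and on disk, and
chromosome names are matched by exact string equality.

## Scoring

For each factor the pipeline computes, per biological replicate *r*,
log₂((ChIP_r + c)/(Input_r + c)) and log₂((Mock_r + c)/(Input_r + c)) with
pseudocount *c* (default 1.0 raw-intensity unit, guarding zeros). All ratio
columns of the factor — ChIP and Mock replicates together — are
quantile-normalized as one matrix: each column's ranks are mapped onto the
reference distribution (the row-wise mean of the per-column sorted
vectors), and tied values within a column receive the mean of the reference
values over the tied span, so the map is well defined and deterministic.
Replicates are then averaged with equal weights, each averaged ratio is
median-scaled (its genome-wide median is subtracted, pinning the null level
at 0 in log space — scores are log-ratios, so centering rather than
division is the scale-appropriate operation), and the Mock component is
subtracted from the ChIP component to give the per-probe score.

Two properties of this construction are worth stating explicitly:

* **Scale invariance.** Multiplying every raw intensity by a constant (a
  constant shift in log₂ space) leaves the score unchanged when *c* = 0;
  with *c* > 0 the invariance is approximate for intensities ≫ *c*.
* **Tail attenuation by joint quantile normalization.** Normalizing
  signal-bearing (ChIP) and signal-free (Mock) columns to a common
  distribution averages their upper tails. When bound probes are rare
  (≈0.6% of the genome in the default simulations) this compresses the
  in-site score by roughly 5–7% of the planted effect. This is an inherent
  bias of quantile normalization across heterogeneous channels, not an
  implementation artifact; the recovery tests allow for it (they require
  the in-site mean within 10% of the planted effect after the full
  pipeline, and within 3 standard errors at the raw-ratio stage, where no
  such bias exists). Per-factor (per-antibody) normalization is the
  default; nothing pools across factors.

## Peak calling

A peak at threshold *t* is a maximal run of probes with score ≥ *t*
containing at least `min_probes` supra-threshold probes and at most
`max_gap` consecutive sub-threshold probes internally, never crossing a
chromosome boundary; the locus spans the first to the last supra-threshold
probe, extended to probe boundaries. Defaults `min_probes = 4` (~140 bp at
35 bp spacing, well inside a ~500 bp sonication footprint) and
`max_gap = 1` tolerate single failed probes.

The threshold is selected by Monte-Carlo FDR. Candidate thresholds are
score quantiles (default 0.90–0.99 in steps of 0.01, plus 0.995 and 0.999).
Scores are shuffled uniformly within each chromosome (preserving each
chromosome's score distribution while destroying the spatial clustering
that makes peaks; a genome-wide shuffle is available by flag), peaks are
re-counted on `n_permutations` shuffled tracks (default 100; permutation
*r* is seeded with `seed + r`), and

    FDR(t) = min(1, mean null peak count / max(1, observed peak count)).

The raw curve need not be monotone — raising the threshold can split one
gap-tolerated run into two qualifying runs, so observed (and null) peak
counts can locally increase with *t* — which is exactly why the estimate is
finalized by a running minimum over increasing *t*. Loci are reported at
the smallest grid threshold whose adjusted FDR is strictly below α
(default 0.01); if none qualifies the locus set is empty. The denominator
floor of 1 keeps the estimate defined when nothing is observed. Called
peaks are the binding loci directly; there is no secondary merging step.

## Co-localization

Locus sets are merged interval unions per factor (true ≥1 bp overlaps are
merged on construction; bookended intervals stay separate). Overlap between
sets is counted in loci: a locus of A overlaps B when it intersects any
locus of B by at least 1 bp. The enrichment null re-places each locus of A
uniformly at random on its own chromosome with its length preserved, B held
fixed (1000 shuffles by default). Shuffled placements may overlap one
another — the placement is unbiased and is deliberately not merged, so the
null counts loci on the same footing as the observation; rejection sampling
to disjoint placements is available by flag. Fold enrichment is
observed / null mean (reported as infinity when the null mean is 0), and
the empirical p-value is (1 + #{null ≥ observed})/(1 + n_shuffles), whose
floor 1/(n_shuffles + 1) equals 0.001 at 999 shuffles — the granularity at
which "p < 0.001" is reportable. "Cohesin loci" for a chaperone-vs-cohesin
comparison are the intersection regions of the SMC1 and SA locus sets.

Venn classification assigns each locus of each set the exact subset of
other sets it touches; because one locus of A can touch several loci of B,
the per-set accountings are reported per set rather than forced into a
single mutual table. Profile agreement is the genome-wide Pearson
correlation of two score tracks on the identical probe grid (no binning);
zero-variance tracks are rejected explicitly rather than returning NaN.

## Phenotype statistics

Frequency tables of mitotic phenotypes (e.g. resolved/unresolved sister
chromatids across knockdowns) are tested with Pearson's χ² of independence
(scipy's `chi2_contingency`, no continuity correction by default, Yates
available for 2×2); zero marginals are rejected because expected counts
are undefined. ChIP-qPCR enrichments are expressed relative to the mean
mock-treated signal per region, summarised as the mean ratio with its
standard error (sample SD/√n; undefined at n = 1) across biological
replicates.

## The synthetic generator

The generator emulates the *structure* the analysis assumes: a tiled genome
(default four 1 Mb chromosomes with 25 bp probes every 35 bp, a desk-scale
stand-in for fly chromosome arms tiled at ~35 bp resolution), ChIP/Mock/
Input channels for two biological replicates per factor, binding sites of
normal width (mean 500 bp, sd 100 bp, truncated at 200 bp — sonication
fragments set the achievable resolution), and controllable cross-factor
sharing (a chosen fraction of sites copied position-identical between
factors, the rest placed uniformly without intra-factor overlap).

Intensities are lognormal: Input = 2^(b + ε), ChIP = 2^(b + e·1[site] + ε +
s_r), Mock the same with the effect scaled by `mock_effect_fraction`, where
b is the baseline log₂ intensity (default 10 ≈ intensity 1024), ε per-probe
per-sample N(0, 0.5²) noise, and s_r a per-(channel, replicate) level shift
N(0, 0.1²). A probe carries a site's effect exactly when its midpoint falls
inside the site, avoiding boundary double-membership. The default
`mock_effect_fraction` of 0.1 keeps the mock-subtraction step non-trivial.
Everything is reproducible bit-for-bit from (configuration, seed); the draw
order is fixed and documented in the code.

What the generator does **not** model: probe sequence affinity and GC bias,
cross-hybridization, amplification/labeling noise, spatially autocorrelated
background, and copy-number structure. Real arrays have broadly
autocorrelated signal, which is why genome-wide replicate and cross-factor
correlations on sparse synthetic data (r ≈ 0.2 at ~2% site coverage) are
much lower than on dense real profiles, even when every planted site is
recovered: with sparse sites the genome-wide correlation is bounded near
cov/(cov + noise) regardless of how clean the site signal is. Passing tests
therefore demonstrate correctness of the computations and calibration of
the FDR under the stated noise model, not performance on hybridization
artifacts the model omits.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale by design:
calibration batches use 20 simulated genomes of 4 × 1 Mb (≈114k probes)
with 50 planted sites of effect 3.0, 100 permutations at α = 0.01; the
acceptance pipeline uses three factors of 150 sites each with sharing
fractions 0.8 (SA vs SMC1) and 0.6 (NAP1 vs SMC1) and 999 placement
shuffles. Seeds are fixed everywhere; derived seeds stay below 2³¹.
Quantile normalization uses stable sorting so ties are handled identically
across platforms. Median scaling uses the standard linear-interpolation
median. Empty locus sets, single-probe chromosomes, and zero-observed
thresholds are all defined, tested degenerate cases.

## Known limitations

* The run-rule parameters (`min_probes`, `max_gap`) and the permutation
  unit are analysis choices, not recoverable facts; both are configurable
  and the defaults are stated above.
* Fold enrichment depends on locus density and length distributions, so its
  magnitude is comparable only between analyses on the same genome and
  locus geometry.
* The Mock channel is modelled as attenuated signal plus independent noise;
  real pre-immune IPs can carry structured background the subtraction step
  would then remove less cleanly.
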