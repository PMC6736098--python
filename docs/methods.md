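# Methods

This note records the models, rules and numerical choices implemented in
`ploidyhic`, including the places where the underlying procedure admits more
than one reasonable reading and a concrete choice had to be made.

## Coordinate system and genome model

All coordinates are 0-based half-open (BED convention); 1-based inputs must be
converted at the reader boundary.  A `GenomeLayout` holds ordered chromosome
sizes, a fixed-width bin grid (default 50 kb; the last bin of a chromosome may
be short), per-chromosome pericentromere intervals supplied as BED (the tool is
genome-agnostic; nothing is hard-coded), and a telomere fraction (default 5% of
each chromosome end).  A bin is *pericentromeric* when more than half of its
length overlaps the pericentromere interval — a symmetric, testable rule; the
remaining bins are left/right arm by position relative to the pericentromere
midpoint.  Bin tiling is asserted to partition each chromosome on every build.

## Balancing

`kr_balance` finds a positive diagonal scaling `D` such that every unmasked row
of `D·M·D` sums to 1, using the Knight–Ruiz inner–outer Newton iteration with
conjugate-gradient inner solves; a damped symmetric Sinkhorn iteration is the
automatic fallback (at these matrix sizes the two agree to well below 1e-6).
Bins with zero raw marginal (threshold configurable) are masked before
balancing, stay zero, and are excluded from all downstream statistics.  The
row-sum target is 1 rather than the mean count: any global scale cancels in the
median-normalized difference matrix, and scale-equivariance
(`kr_balance(cM) = kr_balance(M)`) is a tested invariant.  Replicate
reproducibility is Pearson correlation over upper-triangle entries including
the diagonal; it is computed on balanced matrices by default (a flag switches
to raw), with entries masked in both inputs excluded.

## Difference matrix and differential bins

For balanced maps A and B with a shared mask, zeros in each map are replaced by
that map's 1st-percentile non-zero value (the only reading of "1% quantile
patching" that yields a small positive fill), the elementwise ratio is log2
transformed, and the median over unmasked entries is subtracted.  Median
*subtraction* in log space (equivalently division of ratios by their median)
was chosen for numerical symmetry.  `Z(A,A) = 0` and invariance of Z to scaling
either input are tested invariants.

The criterion for a *differential-interaction bin* is not a settled convention,
so the rule is explicit, configurable and recorded in output metadata.  The
default score is the **mean of |Z| over the bin's unmasked row after
per-distance median centring**: each cis diagonal of Z, and the trans field,
is centred on its own median first, because a genome-wide change of decay
exponent or trans level shifts entire diagonals and would otherwise dominate
every bin's score, hiding bin-specific changes.  The mean (not the median) of
|Z| is used because a compartment flip only alters the cis third of a bin's
row and leaves the whole-row median nearly unchanged.  Bins are flagged either
above an absolute score or, by default, as the top 25% of unmasked bins by
score.  On the default synthetic cohort this rule recovers ≥90% of planted
differential bins at a false-flag rate below 10%.

Interaction statistics: trans/cis ratios include the diagonal in cis sums
(self-bin contacts are cis signal); region classes (intra-arm, inter-arm,
inter-chromosome, intra/inter-pericentromere, intra/inter-telomere) return the
full multiset of balanced values for rank-sum comparison.  The rank-sum test
wraps the Mann–Whitney U statistic: exact enumeration for tie-free samples
with n1+n2 ≤ 12, tie-corrected normal approximation otherwise; two identical
constant samples return p = 1 with a warning.  The observed/expected
inter-chromosome map uses expected(c1,c2) ∝ the product of the two
chromosomes' trans-marginal shares, normalized so total expected trans equals
total observed trans — a perfectly uniform trans field gives log-ratio 0.

## Decay exponents

The decay curve is the mean balanced value over all unmasked pairs at each
genomic distance within a region; multi-part regions (all chromosomes, pooled
telomeric ends) contribute pairs within each part only.  The IDE is the OLS
slope of log10(mean frequency) on log10(distance in bp), restricted to a
reported fit range.  The default range is 100 kb–10 Mb: the first diagonal is
excluded because self-ligation artifacts dominate it, and the upper bound
keeps the fit inside the well-populated distance regime.  Log base does not
affect the slope.  Slope invariance to global scaling is a tested invariant.
Note that row-sum balancing slightly flattens the apparent decay of small
single-chromosome matrices (edge bins receive larger scale factors); parameter
recovery against a generative exponent is therefore assessed on the raw
simulated map, whose coverage is uniform by construction.

## Structure domains

Per chromosome: restrict to unmasked arm bins (pericentromeres excluded),
divide each diagonal of the cis map by its mean (observed/expected), take the
Pearson correlation matrix of its columns, and use the leading eigenvector of
that correlation matrix as PC1 — the Hi-C community standard, not PCA of raw
contacts.  The eigenvector sign is intrinsically arbitrary, so it is oriented
so its correlation with an activity track (gene density by default, an
H3K4me3 track alternatively) is positive; then PC1 > 0 = LSD, PC1 < 0 = CSD,
PC1 = 0 = masked.  Chromosomes with fewer than 10 usable bins are masked with
a warning.  Computation is per chromosome (arms concatenated); a per-arm mode
is a flag.  Bins are the atomic unit; domains are reported as maximal
same-label runs with no smoothing by default.  Transition maps are four-way
per-bin categories over bins called in both conditions; percentage symmetry
under condition swap and bin-count conservation are tested invariants.

## Histone marks

Bin signal is the length-weighted mean of bedGraph coverage (RPKM-like after
optional library-size scaling); mass conservation is a tested invariant.  Peak
BEDs are projected to bins the same way.  The K-means noise-removal step is
under-specified in common usage, so the concrete rule here is: 1-D K-means
(k = 10, seeded, 20 restarts) on bin values within each domain label
separately; bins in the lowest-centroid cluster are set to 0.  If a label has
fewer distinct values than k, k is reduced with a warning; all-equal values
skip the rule.  The rule is switchable off and recorded in metadata.
Between-condition mark ratios use a pseudocount of 1e-6.  Interval-set
similarity is the Jaccard index on merged intervals (intersection bp over
union bp).

## Expression links

Genes map to the bin containing their TSS (whole-gene overlap is a flag;
TSS-mapping avoids double counting in overlap fractions).  The DE table is an
input; a helper applies p ≤ 0.05, BH-FDR ≤ 0.05 and |log2FC| ≥ 1 when statuses
must be derived.  The bootstrap null draws 1000 equal-size groups of
non-regulated genes *without replacement within each group* (a group is a
set), independently across groups; the pool is all non-DE genes in the table.
The verdict is confident iff the observed DE fraction is *strictly* above the
null's 95th percentile.  Promoters are the 2-kb window upstream of the TSS,
strand-aware, half-open; promoter- and enhancer-enriched bins hold strictly
more elements (assigned by midpoint) than the median over all unmasked bins —
ties at the median are excluded, and a fully degenerate median rule raises.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes, for a
"diploid" and a "tetraploid" condition sharing one layout (ploidy is
represented by parameter changes, not duplicated chromosomes, matching
analyses that map doubled genomes onto a single reference):

* cis expectation `N·s^(−α)·(1 ± δ)` (same/opposite compartment sign), diagonal
  `N·(1+δ)`, uniform trans level `t0`; Poisson sampling (ratios, decays and
  ranks downstream need no overdispersion; a negative-binomial knob would be a
  straightforward extension); an expectation mode returns the noise-free map.
* Defaults: 3 chromosomes × 6 Mb at 50-kb bins (360 bins), central
  pericentromere of one sixth of each chromosome, plaid blocks of 10 bins,
  δ = 0.4, depth N = 200, α = 0.8 (diploid) vs 1.0 (tetraploid) — the doubled
  condition loses contacts faster with distance — and trans level 0.8 vs 1.2 —
  relatively more inter-chromosome contact.  These sizes keep a full cohort
  under a second to generate while leaving every distance regime populated.
* 10% of arm bins flip compartment sign in the tetraploid (whole plaid blocks,
  trimmed to the exact count); a further set of "relocated" bins shifts
  contact weight from cis to trans by a factor of 2 — a shape effect chosen
  deliberately because any pure per-bin scaling is removed by balancing and
  would be unrecoverable by construction.  Flips plus relocated bins (25% of
  all bins) form the recorded intended-differential ground truth; the
  observational design this emulates has no ground truth, so the simulator
  must carry its own.
* LSD–LSD contacts in the tetraploid get a mild 1.2× pairwise boost (elevated
  regulatory-element contacts); H3K4me3/H3K27me3 means are 8 vs 2 RPKM-like
  units between their preferred and disfavored domains with Gaussian noise
  (sd 1), each condition following its own domain profile; peaks are
  threshold-called at the midpoint (5) and merged.
* 7430 genes (placed 3:1 in favor of LSD bins, sparse in pericentromeres) of
  which 743 are DE with a 436:307 up:down split; 72.5% of DE genes are planted
  in intended-differential bins (placement becomes uniform when the planting
  fraction is unset, giving the type-I control); up-regulation is preferred in
  CSD→LSD flip bins and down in LSD→CSD; expression is log-normal with a 4×
  higher LSD mean.  600 enhancers of 500 bp are placed with the same LSD
  preference.
* Every stochastic stage derives its stream from one recorded seed; the full
  manifest (config, seed, flips, relocated bins, profiles) is written beside
  the outputs and regeneration is bit-identical.

What the generator does *not* emulate: restriction-fragment structure and
ligation artifacts, copy-number or mappability bias (so balancing has little
real work to do), distance-dependent overdispersion, TAD-like or loop-level
features, and correlated replicate structure.  Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
generative model, not robustness to every artifact of real Hi-C libraries.

## Pipeline sizes and determinism

The default end-to-end run (360 bins, 7430 genes, 1000 bootstrap draws)
completes in a few seconds on one CPU.  All stages are pure functions of
(inputs, config, seed); manifests record version, seeds, input digests and the
decision parameters (patch quantile, differential rule, fit range, k,
orientation mode), and deterministic artifacts reproduce bit-identically from
a manifest.

## Known limitations

* The differential-bin rule, while explicit and recorded, is one of several
  defensible choices; overlap counts depend on it and on the top-fraction
  threshold.
* PC1 calling assumes two dominant states; sub-compartment structure is out of
  scope, as are TAD and loop calling.
* Balancing small matrices biases decay-curve edges (see above); IDE values
  from different matrix sizes should not be compared without a common fit
  range.
* The exact rank-sum mode is limited to tie-free samples with n1+n2 ≤ 12;
  beyond that the tie-corrected normal approximation is used.
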