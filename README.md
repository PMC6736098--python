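# ploidyhic

Comparative 3D-genome analysis for diploid versus genome-doubled (autotetraploid)
plant samples, built around binned Hi-C contact maps at 50-kb resolution.  The
package covers the full comparison workflow:

* **Matrix balancing** — Knight–Ruiz diagonal scaling of the symmetric contact
  map so every usable row sums to 1 (Sinkhorn fallback), plus replicate
  reproducibility by Pearson correlation.
* **Difference matrices** — the standardized log2 ratio
  `Z = log2(A/B) − median(log2(A/B))` of two balanced maps, with zeros patched
  per matrix by the 1st-percentile non-zero value, and per-bin
  differential-interaction calls from row scores of |Z|.
* **Interaction decay exponents (IDE)** — the slope of an OLS fit of
  log10 mean contact frequency on log10 genomic distance, for whole-genome cis,
  single chromosomes, pericentromeres and telomeric ends.
* **Structure domains** — loose (LSD) and compacted (CSD) domains, the plant
  analogue of A/B compartments, from the sign of the first principal component
  of the distance-normalized contact correlation matrix per chromosome
  (PC1 > 0 = LSD), with four-way transition maps between conditions.
* **Epigenome association** — H3K4me3/H3K27me3 bin signal, K-means noise
  removal, mark/domain Jaccard indices and mark-ratio comparisons across
  domain transitions.
* **Expression association** — overlap of differentially expressed (DE) genes
  with differential-interaction bins against a bootstrap null of random
  non-regulated gene groups (confident iff the observed fraction exceeds the
  null's 95th percentile), expression by domain and transition, and
  promoter-/enhancer-enriched-bin contact statistics.
* **Synthetic cohort** — a seeded generator producing both conditions (contact
  maps with power-law decay and plaid compartments, mark tracks, peaks, gene/DE
  tables, enhancers) with recorded ground truth, so every stage is testable
  without external data.

Interaction statistics (trans/cis ratios, region-class contact distributions,
observed/expected inter-chromosome log ratios) use Wilcoxon rank-sum tests,
exact for small tie-free samples.

## Worked example

Run the one-shot demo pipeline (simulation → balancing → difference matrix →
IDE → domains → marks → expression) on the default synthetic cohort:

```bash
ploidyhic run-all --seed 3 --out demo/
```

The printed summary includes (abridged, seed 3):

```
"ide": [
 {"condition": "diploid",    "slope": -0.7347, "r_squared": 0.954},
 {"condition": "tetraploid", "slope": -0.9447, "r_squared": 0.929}],
"transition_percentages": {
 "LSD->LSD": 56.67, "CSD->CSD": 33.33, "CSD->LSD": 6.67, "LSD->CSD": 3.33},
"h3k4me3_jaccard_lsd": 0.994,
"bootstrap": {"observed_fraction": 0.704, "null_95th": 0.299, "confident": true}
```

Reading: the genome-doubled condition loses short-range contacts faster with
distance (more negative IDE slope); 10% of arm bins switch domain between
conditions (6.67% CSD→LSD + 3.33% LSD→CSD); H3K4me3 peaks coincide almost
exactly with LSD; and DE genes fall in differential-interaction bins far above
the bootstrap null's 95th percentile, so the association is called confident.

Individual stages are available as `ploidyhic simulate | balance | diff |
decay | domains | epigenome | expression`; every output directory contains a
`run_manifest.json` with the tool version, seeds, input digests and the
decision parameters in force.

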