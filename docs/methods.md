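# Methods

## Gene models and analysis regions

Genes are collapsed to a single transcription start site (TSS) and a
single termination site (TTS), held as 0-based base positions. The TSS
is the strand-aware 5′-most isoform start unless a per-gene override
table (emulating CAGE-based TSS assignment) supplies one; the TTS is the
most distal isoform end. Three regions are derived per gene:

* **promoter** — `[TSS−300, TSS+300]` inclusive, 601 bases. The source
  definition ("±300 around the TSS") does not state inclusivity; we
  include both boundary bases and expose the flank as a parameter.
* **gene body** — from 1 kb downstream of the TSS to the TTS
  (strand-aware). Genes of length ≤ 1 kb have no body and are excluded
  from body-dependent metrics while remaining available to topology.
* **TTS-downstream** — the 2 kb window past the TTS.

Intervals are clipped to chromosome bounds and never have negative
length. Genes shorter than 2 kb are dropped by the default annotation
filter (`min_length=2000`, boundary kept by ≥).

## Neighbor topology

For each focal gene the **tandem upstream** neighbor is the
same-chromosome, same-strand gene whose TSS lies strictly upstream of
the focal TSS (in the focal transcription direction) and whose TTS comes
closest to it; the distance is focal TSS minus upstream TTS. Design
choices where the underlying analysis is not fully specified:

* upstream genes whose TTS passes the focal TSS (overlap, negative
  distance) disqualify the focal gene rather than being clamped to 0
  (clamping available via `include_overlaps`);
* nested genes never qualify;
* ties in TTS position break lexicographically by gene id, making the
  assignment deterministic and order-independent.

The **divergent partner** is the nearest opposite-strand gene whose TSS
lies upstream of the focal TSS and which transcribes away from the focal
gene; distance is the absolute 5′–5′ separation, capped at 50 kb by
default (no cap is stated in the source analysis).

Both assignments are verified against an exhaustive all-pairs oracle in
the test suite, including layouts with overlapping and nested genes.

## Interference statistics

The signature is quantified on the join of a differential-expression
table and the neighbor table:

* Spearman rank correlation (midrank ties) between log₂ fold change and
  tandem distance over genes with distance < 10 kb. P values use the
  large-sample t approximation, replaced by exact permutation
  enumeration for n ≤ 9.
* Distance bins `[0,2 kb), [2,6), [6,20), [20 kb,∞)`. The named
  thresholds (2 kb, ~6 kb) come from the underlying analysis; the exact
  outer edges are our choice and configurable. The shortest bin is split
  at the median upstream expression (configurable quantile). Each bin is
  compared with the most distal bin by a two-sided Wilcoxon rank-sum
  test. No multiple-testing correction is applied across bins (raw P
  values are reported, as in the source figures).
* The divergent control repeats the binning on 5′–5′ distances without
  the expression split.
* Medians are computed on log₂ fold changes throughout.
* The promoter-accessibility association forms three disjoint groups —
  genes with reduced-accessibility promoter peaks, their tandem upstream
  neighbors, and all other promoter-peak genes (peak-bearing genes are
  the universe) — and reports per-group medians with pairwise rank-sum
  P values. A one-sample two-sided Wilcoxon signed-rank test evaluates
  grouped promoter accessibility shifts against zero.

## Coverage metrics

Tracks are per-base unstranded depths with a library size (total mapped
reads) and a read length converting depth sums to read counts. Totals
are scaled to a library of 10⁷ mapped reads ("normalized reads"); this
linear normalization stands in for tag-directory-based normalization,
since every downstream statistic depends only on a consistent scale.

* **Pausing index**: `((promoter_total + 0.5)/promoter_len) /
  ((body_total + 0.5)/body_len)`. The 0.5 pseudocount is added to region
  totals before dividing by lengths (the source wording is ambiguous
  between totals and averages; pseudocount-on-totals is the default).
  Genes need ≥ 5 normalized reads per kb of gene body to be eligible. A
  pausing change is called at >25% in either direction (linear ratio
  ≥ 1.25 or ≤ 0.8).
* **TTS-downstream enrichment**: log₂ of pseudocounted normalized totals
  (signal vs control) with a two-sided exact binomial test of the raw
  signal count against the library-share expectation of the pooled
  count, Benjamini–Hochberg adjusted across genes. The exact binomial
  replaces a count-model fit; recovery is validated by simulation rather
  than by reproducing any particular gene list.
* **Metagene profiles**: gene spans rescaled to `n_bins` fractional
  slices (reversal-symmetric interpolation on cumulative sums), flanked
  by fixed-width windows binned at `n_bins//2` each, oriented 5′→3′,
  averaged within expression quartiles.
* **Exon/intron fractions** assign depth to exonic (any exon), intronic
  (within a gene span, outside exons), or intergenic.

Jointly scaling a track's depths and library size leaves totals,
densities, pausing indices and log₂ enrichments unchanged to 1e-9. The
exact-test P value is deliberately outside this invariance: it reflects
raw read evidence, which grows with sequencing depth.

## Mendelian tests

Pearson chi-squared goodness of fit, `Σ(obs−exp)²/exp`, df = k−1,
uncorrected by default (the published P = 0.2 for litter counts
(41, 58, 38) vs 1:2:1 matches the uncorrected statistic). A Yates
continuity correction (two categories) and an exact multinomial test
(probability-ordering convention) are available for small litters;
expected cells below 5 trigger a warning.

## Synthetic data: what it emulates and what it does not

The generator produces the statistical structure the analysis assumes,
at desk scale:

* **Layout** — genes in tandem runs (default 80% of genes, runs of 8),
  divergent pairs (10%) and isolated placements (10%), with log-uniform
  intergenic gaps between 200 b and 50 kb and 35% of tandem gaps below
  2 kb. The tandem-dominated defaults make the distance-correlation
  sample (~950 genes under 10 kb out of 2,000) resemble a genome-scale
  analysis; blocks are separated by 60–100 kb spacers so block types do
  not interact. Quotas are met deterministically, so arrangement
  fractions are realized within ±2% for n ≥ 1000.
* **Expression** — log-normal (ln-scale μ = 1, σ = 1.5), a heavy-tailed
  FPKM-like distribution.
* **Effect law** — `log2FC = −β·h(E_up)·exp(−d/λ) + N(0, noise_sd)` with
  β = 0.8, λ = 2 kb, noise 0.2. `h` is normalized to [0, 1] and defaults
  to a step at the median upstream expression, mirroring stratified
  analyses in which repression is essentially confined to the
  high-expression half; a log-linear weighting (`h_mode="linear-in-log"`)
  is available. The exponential decay is a modeling choice — only
  monotone trends and the ~2 kb / ~6 kb thresholds are externally given —
  and a step alternative exists through the same switch.
* **Counts** — negative binomial with dispersion α = 0.02 (clean bulk
  fibroblast RNA-seq scale; variance μ + αμ²), 5 replicates per
  condition, mean control counts ≈ 25 per expression unit. α = 0 falls
  back to Poisson. A single shared library size per condition is the
  default; per-sample jitter is optional.
* **Coverage** — per-base Poisson around piecewise-constant expectations:
  flat input; Pol II body plateau proportional to expression with the
  promoter window raised to the target pausing index; CHD2-like tracks
  carry an input-level background, a small body plateau (coefficient
  0.02 per expression unit, keeping the plateau a minor library share)
  and a TTS-downstream bump of `tts_bump_fold` times the input level.
  The compact coverage preset (200 genes, 40–60 kb spacers) keeps the
  intergenic background the dominant library component, as in a real
  genome; without this, enriched regions distort the library-size
  normalization — the same composition bias real ChIP input
  normalization faces.
* **Litters** — multinomial genotype draws followed by per-genotype
  binomial survival.

Everything is reproducible bit for bit from `(config, seed)`; seeds are
combined with fixed stream ids so each sub-generator is independent.

Not emulated: read-level artifacts (mappability, GC bias, duplicates),
isoform structure, dispersion trends with expression, peak shapes
beyond piecewise plateaus, and inter-replicate batch effects. Passing
tests therefore demonstrate correctness of the estimators and statistics
under the assumed generative structure, not robustness to every artifact
of real sequencing data.

## Problem sizes and numerical choices

Simulation-based checks use 2,000-gene genomes for expression analyses,
200-gene compact genomes for coverage analyses, and 200 replicates for
null calibration — sizes at which Monte-Carlo error is small relative to
the tested margins. Degenerate inputs (constant ranks, all-zero shifts,
empty bins, zero-count regions) return `None`/warnings rather than
NaNs, and are covered by tests. The distance-correlation null check uses
a dense tandem layout (~2,300 informative genes) so the |ρ| < 0.05 bound
sits ~2.3 standard errors from zero.

## Known limitations

* Adjusted P values are accepted from external DE tools; the built-in
  fold-change estimator provides point estimates only (no shrinkage, no
  inference), so classification on synthetic data uses supplied or
  placeholder adjusted P values.
* The median-of-ratios normalization produces a small apparent up-shift
  of unaffected genes when many genes are repressed (composition
  effect); this is inherent to the normalization, visible in the
  synthetic recovery runs, and shared with standard DE workflows.
* The exact binomial enrichment test treats read counts as independent
  Bernoulli draws; overdispersion between replicates is not modeled
  (single-track comparisons only).
* Chromosome-scale arrays hold per-base coverage in memory; tracks
  beyond ~10⁸ bases per chromosome are better processed in windows.
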