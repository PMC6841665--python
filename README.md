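# tic — transcriptional interference context analysis

`tic` quantifies **transcriptional interference between tandem genes**:
the repression of a promoter that sits closely downstream of the
transcription termination site (TTS) of a highly expressed gene on the
same strand. This genomic configuration — exemplified by the
*Chaserr*–*Chd2* lncRNA/chromatin-remodeller pair in mouse — produces a
characteristic signature when the interfering activity is increased:

* expression changes of downstream genes **correlate positively with the
  distance** to the upstream gene's TTS (Spearman ρ on log₂ fold changes,
  repression fading beyond a few kb);
* within the shortest distance stratum, repression **deepens with the
  upstream gene's expression**;
* **divergent** neighbors (opposite strands, compared by 5′–5′ distance)
  show no comparable effect, serving as the orientation control.

The package is aimed at regulatory genomicists who have differential
expression tables, gene annotations and coverage tracks and want to test
whether a perturbation produces this signature.

## What it computes

| Component | Core quantity |
| --- | --- |
| `genome_model` | single-TSS/most-distal-TTS gene models; promoter (TSS ± 300 b), gene body (TSS+1 kb → TTS), TTS-downstream (TTS + 2 kb) regions |
| `neighbor_topology` | per-gene closest tandem-upstream gene (TSS−TTS distance) and closest divergent partner (5′–5′ distance) |
| `expression_tables` | median-of-ratios size factors, point log₂ fold changes, up/down/unchanged classes (±25% fold, adjusted *P* < 0.05) |
| `interference_stats` | distance–ΔE Spearman ρ, distance bins [0,2 kb)/[2,6)/[6,20)/[20 kb,∞) with an upstream-expression split of the shortest bin, rank-sum tests vs the distal bin, divergent control, promoter-accessibility association |
| `coverage_metrics` | Pol II pausing index `PI = ((promoter+0.5)/len) / ((body+0.5)/len)` with a ≥5 reads/kb body filter, TTS-downstream enrichment vs input (exact binomial + Benjamini–Hochberg), metagene profiles by expression quartile, exon/intron read fractions |
| `mendelian_stats` | chi-squared goodness of fit of litter genotype counts to Mendelian ratios |
| `synthetic_data` | generator with ground-truth interference: `log2FC = −β·h(E_up)·exp(−d/λ) + noise`, NB counts, Poisson coverage with pausing peaks and TTS bumps, litter draws |
| `pipeline_cli` | `tic` command line: `run`, `neighbors`, `interference`, `pausing`, `ttsenrich`, `metagene`, `ripfrac`, `mendelian`, `simulate` |

All coverage quantities are normalized to reads per 10⁷ mapped, making
every derived statistic invariant to sequencing depth.

## Worked example

Simulate a study with an interference effect and analyze it:

```sh
tic simulate --preset interference --seed 1 --out sim/
tic neighbors sim/genes.gtf --expression sim/expression.tsv --out sim/neighbors.tsv
tic interference --de-table sim/de_table.tsv --neighbors sim/neighbors.tsv \
    --out sim/interference.json
```

The last command prints:

```
spearman_rho=0.3079 p=7.93e-23 n=974
```

meaning: among the 974 genes whose tandem upstream neighbor terminates
within 10 kb, log₂ fold changes rise with distance (ρ = 0.31) — genes
closest to an active upstream TTS are the most repressed, exactly the
interference signature the generator planted (β = 0.8, λ = 2 kb). The
JSON report adds the distance bins: the < 2 kb, high-upstream-expression
stratum has a median log₂ fold change of −0.46 (rank-sum *P* ≈ 5×10⁻⁷⁰
against the ≥ 20 kb bin), while divergent neighbors show no effect.

Mendelian litter arithmetic works on plain TSV tables:

```sh
$ tic mendelian litters.tsv
          genotypes ratio   n     chi2  df        p
wt=41,het=58,hom=38 1:2:1 137 3.350365   2 0.187274
```

a litter that does not deviate from the expected 1:2:1 (P ≈ 0.2).

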