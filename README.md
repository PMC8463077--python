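# cobind

Summit-centred analysis of transcriptional co-activator target sites:
multi-factor ChIP-seq co-occupancy, motif-class assignment against
accessibility-matched controls, paralog-specific site calling, and
motif-class gene-signature survival stratification.

## The problem

Co-activators such as YAP and TAZ do not bind DNA themselves — they are
recruited to chromatin by sequence-specific transcription factors (TEAD,
AP-1 family proteins such as JUNB, and STAT3).  Given called peak sets and
signal tracks for several factors, the questions this package answers are:

- Do the factors co-occupy the same sites?  Measured by the median distance
  between peak summits of factor pairs over overlapping peaks, compared to
  the replicate-to-replicate baseline.
- Which recruiting motif does each co-activator site carry?  Each peak is
  reduced to its summit ±150 bp window and scanned with AP-1, TEAD
  (monomer or dimer), and STAT3 position weight matrices at an exact
  per-window p-value threshold of 10⁻⁴; peaks are classed as `AP1_only`,
  `TEAD_only`, `STAT3_only`, composite (`AP1_TEAD`, …) or `none`.
- Are those motifs enriched relative to comparably accessible chromatin?
  Control regions are DNase hypersensitive sites sampled to match the
  accessibility Z-score distribution of the bound sites exactly per 0.1
  Z-score bin, and enrichment is a Pearson chi-square on the 2×2 table.
- Which sites are specific to one paralog (YAP vs TAZ)?  A per-peak
  negative-binomial Wald test on replicate read counts (median-of-ratios
  normalization, BH adjustment, |log₂FC| > 0 at padj < 0.05), confirmed by
  requiring signal loss only in the matching knockout line.
- Is the complex monolithic or motif-dependent?  The per-peak
  log₂(JUNB/TEAD) crosslinking ratio is correlated (Pearson r) with AP-1
  and TEAD motif scores; a motif-dependent complex shows r > 0 against the
  AP-1 score and r < 0 against the TEAD score.
- Do motif-class target genes stratify patient survival?  Genes with a
  class-specific peak within 2 kb of a TSS form a signature; each patient's
  gene signature score is GSS = Σᵢ (xᵢ − μᵢ)/σᵢ over signature genes
  (cohort mean μᵢ and SD σᵢ, after removing genes with CV < 5% or > 85%);
  patients with GSS ≥ 0 (high-risk) are compared to GSS < 0 by
  Kaplan–Meier curves and a two-group log-rank test.

Real inputs are standard text formats (narrowPeak/BED, bedGraph, FASTA,
TSV).  A first-class synthetic-data generator (`cobind.simulate`) emulates
the full data structure with known ground truth — planted motif classes,
planted factor-specific sites, a planted crosslink-ratio correlation, and a
planted hazard effect on the high-GSS group — so every stage can be
validated end to end.

## Worked example

Simulate a 600-peak dataset and run every stage:

```bash
cobind simulate --seed 7 --out example_data --n-peaks 600
cobind run-all --data example_data --out example_out --seed 7
```

`example_out/motif_enrichment.tsv` — motif frequency in peak windows vs the
Z-score-matched control DHSs:

```
motif         frac_target  frac_control  fold     chisq    pvalue
AP1           0.416667     0.125         3.33333  129.231  6.03746e-30
TEAD_monomer  0.281667     0.118333      2.38028  50.0208  1.52122e-12
TEAD_dimer    0.1          0.00666667    15       51.7606  6.26986e-13
STAT3         0.203333     0.12          1.69444  15.3717  8.83015e-05
```

All planted motif families are significantly enriched over matched
controls.  `example_out/summit_distances.tsv` shows the co-occupancy
signature — median summit distances of 14–15 bp between factor pairs
(the generator jitters each factor's summit by N(0, 15 bp), so the median
pair distance is the half-normal value 0.674·15·√2 ≈ 14.3 bp), with every
peak pair overlapping:

```
factor_a  factor_b  n_pairs  median_summit_distance_bp  overlap_fraction
YAP       TAZ       600      15                         1
YAP       JUNB      600      14                         1
```

`example_out/crosslink_correlation.json` recovers the planted
motif-dependent complex: the JUNB:TEAD log-ratio correlates positively with
AP-1 motif quality and negatively with TEAD motif quality:

```json
{"pearson_r_AP1": 0.104962, "pearson_r_TEAD_monomer": -0.154059}
```

`example_out/specific_sites.tsv` confirms 75 of the 75 planted YAP-specific
and 267 of the 270 planted TAZ-specific sites through the knockout rule,
and `example_out/survival_results.tsv` shows the planted hazard effect on
the AP-1 class signature (high-GSS patients fare worse; the other
signatures carry no planted effect):

```
signature     n_genes  n_low  n_high  logrank_chisq  logrank_p    surv_high_at_median_t  surv_low_at_median_t
AP1_only      116      225    175     35.3512        2.75292e-09  0.494035               0.661312
TEAD_only     107      197    203     0.340374       0.559613     0.577039               0.598599
AP1_and_TEAD  58       201    199     0.601671       0.437941     0.562514               0.612376
```

96.7% of peaks receive their planted motif class
(`peak_classes.tsv` vs `example_data/truth_peaks.tsv`), and
`manifest.json` records a SHA-256 checksum for every output so a rerun with
the same seed is verifiably byte-identical.

Every stage is also available as its own subcommand (`summits`, `motifs`,
`classify`, `controls`, `enrich`, `cooccupancy`, `specific`, `ratios`,
`targets`, `signature`, `survive`), and the whole library can be used
directly from Python (`import cobind`).

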