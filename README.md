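# poolcomp

Evaluate pooled sequencing (pool-seq) against individual sequencing
(ind-seq) for population-genomic study design. The package estimates
per-accession allele frequencies from genotype score reports and pooled
read-count reports, quantifies their agreement — shared SNPs,
Representativity (%), Lin's concordance correlation coefficient — across
a factor grid of sample size, missing-data threshold, sequencing depth
and minor-allele-frequency cutoff, and computes the downstream diversity
and structure statistics (H_O, H_E, F_IS, allelic richness, effective
alleles, ΔH_E, Nei/Rogers distances, Weir–Cockerham F_ST, AMOVA, metric
MDS, Mantel test, ANOVA/Tukey/Levene).

A first-class synthetic-data generator emulates the nested-pool design
the analysis assumes (divergent inbred accessions; nested pools of
20/30/40/50/60 individuals; two tissue replicates, each sequenced as a
0.9 Mr and a 1.5 Mr library, merged to 1.8/3.0/4.8 Mr analysis depths;
unequal DNA contributions; marker-quality-coupled missingness and
coverage), so the entire pipeline runs end to end with no external data.

## Layout

| module | contents |
| --- | --- |
| `poolcomp.synthetic` | simulation of score/count reports under a Balding–Nichols metapopulation |
| `poolcomp.dart_io` | CSV readers/writers for score, count, design-map and sample-map files |
| `poolcomp.frequencies` | allele-frequency estimation, replicate/depth merging, MD/MAF filtering |
| `poolcomp.concordance` | shared SNPs, Representativity, Lin's CCC, the full factor sweep |
| `poolcomp.diversity` | H_O, H_E, F_IS, rarefaction richness, effective alleles, ΔH_E |
| `poolcomp.structure` | Nei/Rogers distances, Weir–Cockerham F_ST, AMOVA, MDS, Mantel |
| `poolcomp.experiment` | ANOVA / Tukey HSD / Levene, full-experiment orchestration |

## CLI

All commands operate on plain-CSV artifacts (`score_report.csv`,
`count_report.csv`, `design_map.csv`, `sample_map.csv`):

```bash
# simulate a dataset (key = value config file; every default overridable)
poolcomp simulate --seed 7 --out run/

# filtered allele frequencies
poolcomp freqs-ind  --in run/ --accession A1 --size 50 --md-max 0.10 --maf-min 0.05 --out fi.csv
poolcomp freqs-pool --in run/ --accession A1 --size 50 --depth 4.8 --maf-min 0.01 --out fp.csv

# the full accession x size x MD x depth x MAF concordance sweep
poolcomp sweep --in run/ --out sweep.csv

# diversity per accession and the pool-vs-ind expected-heterozygosity gap
poolcomp diversity --in run/ --out diversity.csv
poolcomp delta-he --diversity-table diversity.csv --out delta.csv

# structure: nei | fst | amova | mds | mantel
poolcomp structure --in run/ --what amova --size 50 --out amova.json

# group statistics on a sweep table
poolcomp stats --sweep-table sweep.csv --response ccc --factor depth --out stats.json

# everything at once, with a JSON run manifest
poolcomp run-all --seed 7 --out full_run/
```

## Conventions

* Genotype codes: `0` hom-major, `1` het, `2` hom-minor, `-` missing;
  polarity fixed per marker and shared between score and count reports.
* Filters: a marker is retained iff missing fraction < `md_max`
  (strict) and MAF > `maf_min` (strict; MAF equal to the threshold is
  discarded). Filtering is per accession-dataset.
* CCC uses population (N-denominator) moments.
* F_IS defaults to the ratio-of-means convention `1 − H̄_O / H̄_E`; a
  per-locus variant is exposed.
* "Ae" for ind-seq is rarefaction allelic richness; for pool-seq it is
  the effective number of alleles `1/(p²+q²)`. The two are computed
  differently by construction and labelled distinctly.
* AMOVA uses individuals as units for ind-seq and pool-library samples
  as units for pool-seq, with squared Rogers distances.
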