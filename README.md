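# ripseed

Genome-wide microRNA target profiling from paired RISC-immunoprecipitation
(RIP) and gene-expression experiments, built around the miR-191 targetome
design: transfect a mature miRNA duplex (or a control), profile both total
RNA and AGO2-immunoprecipitated RNA, and combine the two signals into a
per-gene target score. The package also implements the sequence-side
validation analyses — seed-match location in 5′UTR/CDS/3′UTR, relative
seed frequency across ranked gene bins, and a 6-mer tiling scan across the
guide — plus a synthetic-study generator with planted targets so every
stage can be verified by parameter recovery.

Intended users: computational biologists analyzing RIP-seq / RIP-ChIP +
expression experiments for miRNA target identification, and anyone needing
a transparent, testable reference implementation of ratio-based target
scoring.

## The model

With replicate-mean, floored (FPKM < 1 → 1) abundances per gene:

```
repression   R = expr_control / expr_treatment
enrichment   E = (rip_treatment / expr_treatment) / (rip_control / expr_control)
score        S = (E + R) / 2
```

R > 1 means the transcript is lower after miRNA transfection; E > 1 means
miRNA-dependent RISC association beyond what expression alone explains.
Genes with S ≥ 1.5 form the target set.

The transcript-side seed match is the DNA reverse complement of guide
positions 2–8 (7mer-m8 by default; window start and length are
configurable). For miR-191 (guide 5′-CAACGGAAUCCCAAAAGCAGCUG-3′) the
7-mer match is `TTCCGTT`. Validation analyses ask whether this k-mer
concentrates where the scores say the targets are: in top-ranked bins of
250 genes, in particular transcript regions, and — tiling every 6-mer
window of the guide — specifically at the seed windows rather than
elsewhere along the miRNA.

## Worked example

Simulate a 2,000-gene study with 100 planted 3′UTR targets
(RIP-enrichment fold 3, repression fold 2, log-normal replicate noise
σ = 0.25, 3 replicates per library class), then run the full report:

```
ripseed simulate --out-dir demo --n-genes 2000 --n-targets 100 --rng-seed 42
ripseed report --fasta demo/transcripts.fasta --regions demo/regions.tsv \
               --abundance demo/abundance.tsv --design demo/design.tsv \
               --out-dir demo_report
# report complete: 175 targets called from 2000 genes
```

`demo_report/scores.tsv` ranks genes by score (top rows):

```
gene_id  repression          enrichment          score               is_target
G0984    3.566258918581534   6.234100922817929   4.900179920699731   True
G1507    2.481853993692223   5.060302319926711   3.771078156809467   True
```

`demo_report/bins.tsv` shows the ranked-bin seed-frequency gradient — the
top 250 genes by score carry 99 of the 100 3′UTR seed matches, a 7.9-fold
excess over the all-genes background, which collapses immediately in
lower bins:

```
bin_index  bin_size  n_match  relative_frequency  partial
1          250       99       7.92                False
2          250       1        0.08                False
3          250       0        0.0                 False
```

`demo_report/tiling.tsv` shows seed specificity: of all 18 6-mer windows
of the guide, the two lying inside guide positions 2–8 (`TCCGTT`,
`TTCCGT`) have the highest target-set 3′UTR frequency relative to
background (3.4× and 4.0× here), while windows pairing to other parts of
the miRNA stay near 1×.

The `scan`, `score`, `bins`, `regions` and `tiling` subcommands run the
individual stages; every output is a plot-ready TSV, and
`run_summary.json` records the configuration and gene accounting for the
run. The same functionality is available as a library
(`ripseed.score_pipeline`, `ripseed.run_report`, ...).

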