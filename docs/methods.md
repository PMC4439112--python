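# Methods

## Scoring model

The experiment contrasts four library classes per gene: expression and
RISC-immunoprecipitation (RIP), each under a miRNA transfection
("treatment") and a control transfection, with biological replicates.
Abundances are FPKM-like and processed as follows.

1. **Replicate combination.** Arithmetic mean of per-replicate abundances
   within each (assay, condition) class. This is a deliberate, simple
   deterministic choice; it weighs replicates equally and keeps the
   pipeline free of dispersion modeling.
2. **Flooring.** After averaging, every value below the floor constant
   (default 1.0) is set to the floor. The floor prevents denominator
   inflation in the ratio statistics; applying it after averaging
   preserves information from replicates above the floor. Flooring before
   averaging is available by flooring the matrix explicitly first.
3. **Ratios.** Repression R = expr_control / expr_treatment, so R > 1
   means the gene is knocked down by the miRNA. Enrichment
   E = (rip_trt / expr_trt) / (rip_ctl / expr_ctl): RIP abundances are
   normalized to expression within each condition first, so E isolates
   treatment-dependent RISC association from expression change. The
   repression direction (control in the numerator) is chosen so that
   repressed genes score above 1 and the two ratios combine on the same
   scale.
4. **Target score.** S = (E + R) / 2; genes with S ≥ threshold (default
   1.5, inclusive) are the target set. The output table is ordered by
   descending score with ties broken by gene id, making every run
   deterministic.

Genes missing any of the four classes are dropped and logged. The floor,
threshold, and seed parameters are all exposed in `RunConfig` / CLI flags
with the defaults above.

## Seed matching

Guides are stored as RNA (T accepted on input), transcripts as DNA; N is
permitted in transcripts and never matches. The seed match k-mer is the
DNA reverse complement of a guide window, default positions 2–8
(7mer-m8): pure complementarity to the canonical seed region, with no
assumption about an A1 anchor. 6-mer (positions 2–7) and 8-mer variants
are available through the window parameters. Matches are reported at
every (possibly overlapping) occurrence; a gene's transcript is
partitioned into 5′UTR / CDS / 3′UTR by 1-based inclusive CDS
coordinates, a match is assigned to the region containing its start
position, and matches whose span crosses a region boundary carry a
`spans_boundary` flag. The start-position rule is a deterministic
convention for the rare boundary-spanning site.

## Profile analyses

- **Ranked bins.** Genes are ranked (descending, ties by gene id) by
  score, enrichment, or repression and cut into consecutive bins of 250.
  A bin's relative seed frequency is its fraction of genes with a
  (region-restricted, default 3′UTR) seed match divided by the background
  fraction over all profiled genes. The final partial bin is retained and
  flagged so that the size-weighted mean of bin fractions reproduces the
  overall fraction exactly.
- **Region proportions.** Inclusive mode counts a gene in every region
  where it has a match; exclusive mode counts only single-region genes,
  with `multiple` and `none` categories completing a partition of the
  universe. Distribution comparisons between region groups default to
  exclusive groups, because a gene with both CDS and 3′UTR sites
  confounds region attribution; inclusive grouping is a flag away.
- **Transformation.** Ratio statistics are log2-transformed before ECDFs
  and t-tests; ratios are multiplicative, and the log makes
  enrichment/repression symmetric about 0.
- **Tiling.** For every k-mer window of the guide (default k = 6, giving
  18 windows on the 23-nt miR-191 guide), the fraction of target-set
  genes whose 3′UTR contains the window's reverse-complement k-mer is
  divided by the same fraction over all profiled genes. Specific seed
  pairing shows up as a peak confined to the windows inside guide
  positions 2–8. A window absent from every background 3′UTR yields NaN
  for that window rather than aborting.

## Statistical kernel

Welch's unequal-variance t-test is computed from closed forms
(t = (m_a − m_b)/√(s²_a/n_a + s²_b/n_b), Welch–Satterthwaite df), with
p-values from scipy's t-distribution; one-sided directions are named
explicitly (`a_greater` / `b_greater`). Zero pooled variance is handled
deterministically (t = 0 or ±∞, flagged degenerate, p at the
corresponding limit) so that property tests on tiny degenerate groups are
stable. Pearson correlation is computed from centered sums; Spearman is
Pearson on average ranks (scipy's tie-aware ranking). A paired t-test is
included for completeness but not wired into any pipeline stage. All
three are cross-checked against scipy's implementations in the test
suite; scipy is never the implementation path.

## Synthetic studies

The generator emulates the statistical structure of the profiled
abundance tables, not their biology:

- **Transcripts.** Per gene, region lengths are drawn uniformly within
  ±30% of the mean lengths (defaults 150 / 1000 / 700 nt for
  5′UTR / CDS / 3′UTR — compact but realistically proportioned mRNAs)
  with i.i.d. bases at the configured GC content (default 0.5).
  Non-target transcripts are rejection-sampled to be entirely free of the
  seed match k-mer, giving the bin and tiling analyses a clean expected
  gradient; `background_site_rate` can re-introduce chance sites. Each
  true target carries exactly one planted site, spliced in at a uniform
  position within the configured region (default 3′UTR; `mixed` with
  weights available), re-drawn if the junction would create a second
  occurrence.
- **Abundances.** Per-gene baseline b is log-normal (median 30 FPKM,
  log-sd 1.0 — a heavy-tailed distribution with most genes well above the
  floor and a realistic low-expression tail). Class expectations are b
  except for true targets: expression/treatment = b / repression_fold and
  RIP/treatment = (b / repression_fold) × enrichment_fold. The enrichment
  fold acts on the RIP:expression ratio (RISC loading per transcript), so
  the expression-normalized E recovers `enrichment_fold` exactly in the
  noise-free limit rather than compounding with the knockdown.
  RIP/control for targets is baseline by default
  (`rip_background_fold` adds treatment-independent loading). Every
  replicate multiplies its expectation by exp(N(0, σ²)), independently
  per library replicate (default σ = 0.25, 3 replicates/class).
- **Defaults as study conditions.** The default configuration — 10,000
  genes, 500 planted 3′UTR targets, enrichment fold 3, repression fold 2 —
  is the study the recovery checks and `scripts/acceptance.py` run on; it
  executes in seconds on one CPU.

What the generator does **not** model: read-level sampling noise,
fragment/length biases, between-gene correlation, multiple sites per
target, site-context effects (position in UTR, AU content, supplementary
3′ pairing), or non-seed-mediated RISC association. Passing recovery
tests therefore demonstrates that the pipeline's inference is correct
under its own assumptions — multiplicative effects, log-normal noise,
seed-driven targeting — not that those assumptions hold in any real
dataset.

### Expected operating characteristics under noise

Under the default noise model the per-gene log-ratios have standard
deviations of about σ√(2/3) ≈ 0.20 (R) and σ√(4/3) ≈ 0.29 (E) on the
natural-log scale, and R and E are positively correlated through the
shared expression classes. At σ = 0.25 this puts a non-trivial mass of
null genes above S = 1.5 (≈ 4% of non-targets), so the called set
recovers planted targets with near-perfect recall but only moderate
precision (≈ 0.55 at the defaults). Precision rises quickly as σ falls,
replicates increase, or the threshold is raised; the defaults are kept as
stated study conditions rather than tuned for a cleaner-looking
confusion matrix. One acceptance-level check asserts a ≥ 0.9 precision
bound that these conditions cannot meet; it is knowingly left failing
with this analysis as the explanation.

## Numerical and format choices

- All tables are TSV (header row, UTF-8, '.' decimal); floats are written
  at full precision, which makes writer→reader round-trips lossless and
  repeated runs byte-identical (the two properties the formats are tested
  for).
- Coordinates are 1-based inclusive everywhere a user sees them.
- All pipeline outputs are deterministic functions of (inputs, config);
  the only randomness lives behind the simulator's `rng_seed`.
- Degenerate inputs have defined behavior rather than errors where a
  convention suffices (empty UTRs, k-mer longer than sequence → no
  matches, zero-variance groups → flagged ±∞ t); they raise typed errors
  where silence would corrupt results (zero background frequency, empty
  target set, missing sample classes, negative abundances).

## Known limitations

- One platform at a time: RNA-seq-like and array-like tables are scored
  separately, not jointly.
- The scorer consumes abundance tables; it does not estimate FPKMs from
  reads or model differential-expression dispersion (the upstream
  procedure it mirrors has none).
- Seed matching is exact complementarity: no wobble pairing, no
  thermodynamics, no conservation filtering, and transcript-space only.
- Whether the original 7-mer seed definition was m8- or A1-anchored is
  not recoverable from the analysis description; 7mer-m8 is this
  package's documented default and the alternative is one parameter away.
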