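# Methods

## The pair-barcode model

A pooled library codes each sample by an ordered pair (F, R) of 6-nt
barcodes: the F-barcode sits at the 5' end of the main read, immediately
followed by the small-RNA insert and, when the insert is shorter than the
read, a prefix of the 3' adaptor; the R-barcode is read separately, either by
a second sequencing primer (a short "tag" read, the default layout) or at a
fixed offset of a single read. Decoding is sequential: the F window is
matched first, and only F-decoded reads proceed to R matching, so the
run-level fractions compose exactly as

    both/total = (F/total) × (R-of-F/F).

All spans are 0-based half-open internally; the CLI reports 1-based
inclusive coordinates.

### Barcode matching and the distance floors

A window is assigned to the unique barcode within Hamming distance ≤ 1; two
or more barcodes tying at the minimal qualifying distance leave the read
unassigned ("ambiguous"), never arbitrarily resolved. For this rule to be
unambiguous by construction the set must have minimum pairwise distance
≥ 3 (= 2·1 + 1). Because SOLiD-style platforms compare reads in dibase
color space, sets are additionally required to differ at ≥ 2 color
positions; both floors are enforced conjunctively by default and each can be
disabled. The color floor is computed under a shared anchor base (default T,
configurable), modelling the constant adaptor base 5' of the barcode; the
junction color is included in the comparison.

The dibase matrix is the standard SOLiD scheme — with bases indexed A=0,
C=1, G=2, T=3, color(x, y) = index(x) XOR index(y) — which is the unique
scheme with same-base = 0 and bijective rows. Two consequences the tests
verify exhaustively: a color string plus anchor decodes to a unique
nucleotide sequence, and a single substitution flips exactly two adjacent
colors (one at the terminal position).

### Set design and the multiplex planner

`design_set` scans candidate k-mers in a seeded-random order and accepts a
candidate iff it respects both distance floors against all accepted
barcodes. Greedy search is ample at k = 6 (it saturates near 90 words for
the nucleotide-distance-3 code, far above the 4–12 barcodes a pooled run
needs) and is deterministic per seed. An optional composition filter
(no homopolymer run > 3) is off by default. Infeasible requests fail
explicitly, naming the achieved set size.

`plan_oligos(N)` minimises n_F + n_R subject to n_F · n_R ≥ N by scanning
n_R ≤ ⌈√N⌉, breaking ties toward the most balanced split with n_F ≥ n_R
(10 → 4 + 3 = 7; 100 → 10 + 10; 10000 → 100 + 100). For 1000 samples the
optimum is 32 + 32 = 64; published comparisons of this design sometimes
quote 34 + 33 = 67 for that row, which is not optimal under this
minimisation — the planner always emits the optimum. The pair design beats
one-oligo-per-sample for every N ≥ 6 (and ties at N = 4, 5 is equal-cost at
3 + 2).

### Insert extraction and adaptor trimming

The insert is the main read minus the F window, cut at the leftmost position
where a prefix of the 3' adaptor aligns with mismatch rate ≤ 0.2 over ≥ 5
symbols; with no detectable adaptor the cut is the read end. In color mode
the adaptor's internal colors are used and the junction color (which depends
on the unknown final insert base) is wildcarded.

## miRNA quantification

Inserts are full-length small RNAs read from the mature 5' terminus, so
matching is ungapped and 5'-anchored over the common prefix of insert and
reference (no indels; genome mapping is out of scope). The mismatch budget
is positional: ≤ 2 mismatches among insert positions 1–18 and ≤ 3 in the
remainder. The two budgets are read as independent caps (total ≤ 5); an
optional `total_mm` collapses them into one overall cap for the stricter
reading — the field phrasing is ambiguous and both are one flag apart.
Inserts shorter than 15 nt are not matched. The unique best hit (fewest
total mismatches) is counted; equal-best ties are discarded as
multi-mapping; inserts matching the contaminant (other ncRNA) set under the
same policy are removed first. Per-sample classification bins (miRNA /
contaminant / unmatched / multi / too-short) conserve reads exactly.

## Normalization and differential expression

**Quantile-quantile scaling.** For each dataset d and reference r (default
M1), rows with counts > 5 in *both* are selected; both selections are sorted
independently and paired by quantile rank, and

    factor_d = median(log2 q_d − log2 q_r),

after which every value of d is multiplied by 2^(−factor_d) — one linear
transformation per dataset. When the two selections differ in size (only
possible with asymmetric selection rules) the larger side is linearly
interpolated at the smaller side's plotting positions; with the default
both-over-threshold rule the sizes are equal and the pairing is exact. The
procedure is idempotent (re-normalizing yields factors of 0) whenever
rescaling does not move rows across the count-5 threshold; threshold
crossings can change the qualifying set and leave residual factors of a few
hundredths.

**Filtering and testing.** Differential expression between two dataset
groups (e.g. 19 tumour vs 6 normal of 25 analysed; inclusion is always an
explicit mask, never implicit) considers miRNAs with > 5 raw counts in ≥ 20
analysed datasets. The test is a two-sided Welch t-test on
log2(normalized + 1); pooled-variance and linear-scale variants are flags.
Log scale is the default because the counts are log-normal-like over orders
of magnitude; Welch because the group sizes are unequal and variance
homogeneity is not defensible. Zero variance in both groups with equal
means gives t = 0, p = 1 by convention and is flagged. Records sort by raw
p; the significance flag is raw p < 0.05, with Benjamini–Hochberg adjusted
p-values always reported alongside (reported, not used for the cut — the
headline DE count in this field's practice is a raw-p cut). Group ratios
are log2(mean_A / mean_B) with zero means replaced by a pseudocount of 1,
rounded to 2 decimals in tabular output.

**Replicate concordance** is the Pearson correlation over miRNAs with counts
> 5 in both datasets (≥ 3 qualifying rows required).

## The simulator

`simulate_run` emulates a pooled pair-barcoded run and is the ground-truth
source for every pipeline test:

- **Design**: 32 samples (26 "BC" + 6 "BO"; 19 + 6 analysed) on a 4 F × 8 R
  grid, row-major pair assignment — the pooled-run design this toolkit
  targets.
- **Depths**: per-sample expected read counts are log-normal
  (σ = 1.0) around `mean_reads`, reproducing the tens-fold spread seen
  across barcode pairs in real pools; depth is independent of barcode
  identity (the spread comes from library dilution, not barcode bias).
- **Abundances**: per-miRNA baselines are log-normal (σ = 1.5); each sample
  multiplies them by independent log-normal biological noise (CV 0.3); reads
  are multinomial given the depth.
- **Planted effects**: `n_de` miRNAs get a ±`effect_log2` multiplier in the
  BC group (alternating sign), drawn from the upper half of baseline
  abundance — differential calls are only defined for detectably expressed
  miRNAs, and planting in the undetectable tail would only measure the
  expression filter.
- **Reads**: F-barcode + insert + adaptor prefix padded to 35 nt (6 + 29) on
  the main read; R-barcode on a 6-nt tag read. Junk reads (the configured
  fraction of the run) carry random sequence in both barcode regions; a
  random 6-mer still lands within distance 1 of a barcode occasionally, so
  junk contributes a ~10⁻³-scale excess to the decoded fraction — far inside
  the binomial noise at the tested scales. Errors are i.i.d. per-base
  substitutions (per-color flips in color mode); no indels, no quality
  modelling, no PCR duplicates or chimeras.
- **Determinism**: one `numpy` generator seeded from `SimConfig.seed` drives
  every draw; identical seeds give byte-identical runs.

What the simulator does *not* emulate — sequence-composition bias, ligation
bias, quality-correlated errors, isomiRs, cross-mapping paralog families —
bounds what green tests mean: they validate the decoding, counting and
statistical machinery under the stated noise model, not performance on any
particular wet-lab library.

### Problem sizes used by the test suite

The suite runs the pipeline at desk scale as this package's own test
conditions: run-level demultiplexing checks use ~10⁵-read pools
(`mean_reads = 2000` across 32 samples), the type-I calibration uses 100
count-level replicates of the 200-miRNA × 25-dataset design, planted-effect
recovery uses 20 count-level replicates at the default depth
(`mean_reads = 20000`) plus one full read-level run (60 miRNAs,
`mean_reads = 8000`, 0.5% per-base error). Run-level percentages from any
specific sequencing experiment (total read counts in the hundreds of
millions, exact decode percentages, specific correlation coefficients)
depend on that experiment's libraries and are not reproduced; the suite
checks the structural and statistical properties that generate them.

## Numerical and policy choices

- Ambiguity in barcode or insert matching is always resolved to
  "unassigned"/"multi", never arbitrarily.
- The decode comparison space follows the read space: nucleotide reads are
  compared as nucleotides, color-space reads natively as colors (avoiding
  error-propagating color→nucleotide conversion). Either can be forced.
- Unexpected-but-valid (F,R) pairs are a separate diagnostic class from
  undecodable reads.
- `qq_normalize` requires ≥ 2 qualifying shared rows per dataset and fails
  explicitly otherwise; `replicate_correlation` requires ≥ 3.
- Scaling factors are exact medians (`numpy.median`); no tolerance is
  applied anywhere in normalization.
- The greedy barcode search enumerates all 4^k candidates for k ≤ 9 and
  falls back to capped random sampling for longer barcodes.

## Known limitations

- Substitution-only error model: barcodes with indels shift the frame and
  decode as failures (correct but conservative); Levenshtein codes are a
  non-goal.
- Quantification ignores isomiR 5'/3' heterogeneity beyond the prefix rule
  and cannot distinguish identical-prefix family members (they become
  "multi").
- The t-test stack assumes approximate log-normality of normalized counts;
  count-model alternatives (negative-binomial GLMs) are out of scope.
- Color-space quality values are passed through, never used to weight
  decoding.
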