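# Methods

## Coordinates and genome model

All coordinates are 1-based with inclusive ends (GFF convention). The genome
is a single replicon, circular by default; window profiles and motif scans
wrap across the origin junction by virtually appending the first
`window − 1` (resp. `motif length − 1`) bases. `rotate_to_origin` places the
first forward-strand occurrence of the DnaA box `TGTTTCACG` at position 1;
reverse-strand occurrences are ignored because no orientation convention
exists for the box, and the rotation is a pure cyclic permutation (the
circular k-mer multiset is invariant, which the tests assert).

Genomic regions expose two lengths: `length_bp = end − start + 1` (the
inclusive count) and `span_bp = end − start` (the coordinate difference).
Published round-number region sizes are coordinate spans — the symbiosis
island at 1,000,419–1,681,419 is "681 kb" only under the span convention —
so reported island arithmetic uses `span_bp` while compartment per-kb
normalisation uses true inclusive lengths. The island's share of the genome
is reported as computed (7.48 % of 9,106,064 bp), not rounded to match any
particular precision.

Ambiguity bases are retained on load but can never host a motif site: the
motif letter `N` matches only A/C/G/T. This prevents phantom sites on
low-quality reference stretches.

### Upstream regions

The regulatory compartment of a gene is the intergenic interval 5′ of its
start on its own strand, truncated at `upstream_max_len` (default 500 bp)
and at the nearest neighbouring gene boundary; abutting or overlapping
neighbours give an empty region. 500 bp is a typical bacterial
promoter/UTR window and exceeds the default intergenic gap of the
simulator, so truncation paths are exercised. A site in the shared gap
between divergent genes belongs to both genes' upstream regions — the
grouping is by region membership with no exclusivity rule.

## Motif scanning

A motif is a degenerate IUPAC word with a 1-based `modified_offset` marking
the methylatable base and a modification type (m6A/m4C); bipartite spacers
are written `GAGA(N)6RTG` and expanded to `N` runs. Scanning reports every
overlapping occurrence on both strands: forward matches give `+` sites at
`match_start + offset − 1`; forward matches of the reverse complement are
`−`-strand occurrences whose methylated base sits `offset` positions from
the occurrence's 3′ end, i.e. at `match_start + length − offset`. Site
identity is the (position, strand) pair, because single-molecule calls are
strand-specific and the two strands of the bipartite duplex motif carry
different methylated adenines (`CAY(N)6TCTC` offset 2 / `GAGA(N)6RTG`
offset 4 — the two words are exact reverse complements, which the tests
assert base by base). Both per-strand and per-duplex counting are
available; the pipeline counts per strand, matching the calls.

The default motif set carries six specs: the five m6A motifs plus the
weakly-supported m4C at CRAGGAT offset 1. m4C sites are scanned and
summarised but excluded from differential analysis by default
(`include_m4c` re-enables them), since cytosine calls below the QC floor
carry no usable signal.

## Modification calls and QC

Input is the PacBio-style modifications GFF dialect: one record per called
base, score column = Phred-like modQV, `coverage=`/`IPDRatio=` attributes.
The QC filter keeps records with coverage ≥ 25 **and** modQV ≥ 30, both
boundaries inclusive (the operative protocol wording; a strict `>` variant
circulates but the inclusive form is used and both thresholds are
configurable). A site is methylated iff a passing record of the right type
sits exactly at its (position, strand); absence of a call is unmethylated —
no explicit unmethylated records are expected. Sites whose only call failed
QC are *undecidable* rather than demonstrably unmethylated; the default
folds them into unmethylated and logs their count separately. Off-motif
records are counted and logged, duplicate records at one
(position, strand, type) are rejected as ambiguous input.

## Differential methylation

A methylation change is a per-site state flip (gain = unmethylated in
condition A, methylated in B); magnitudes and QV deltas are not used, so
gains + losses + unchanged partition the site set exactly. Summaries report
percent methylated half-up-rounded to 2 decimals and QC-metric means over
methylated sites only. Changed sites are attributed to every gene whose
coding or upstream compartment contains them (double attribution across
genes is intentional; coding events of non-overlapping genes are attributed
exactly once). Regional tallies cover genome × island × remainder crossed
with coding/upstream/all compartments per motif; per-kb values divide by
the merged (union) compartment length inside the region. Because the
published analysis reports raw counts, no test is attached to per-site
changes; a two-sided binomial test of gain/loss symmetry is available as an
optional extra, off by default.

## Differential expression

The matrix is log2 intensities, rows = (gene, spot), columns = arrays, each
array assigned to one of two conditions (≥ 2 arrays per condition).
Processing order: per-array median-centering (the under-specified
within-array step is approximated this way and can be switched off),
quantile normalisation (rank-average ties, every column distribution equal
afterwards), spot averaging, then per-gene testing.

The test statistic is a two-sample t with pooled variance, with each gene's
variance shrunk toward the genome-wide mean residual variance using a fixed
prior weight of d0 = 4 pseudo-degrees of freedom:

    s²_g,mod = (d0·s̄² + df·s²_g) / (d0 + df),   df_mod = d0 + df.

This is a deliberate simplification of empirical-Bayes moderation: the
prior scale is the plug-in mean rather than a fitted hyperparameter, which
is conservative in the far tail. It is the default because at 2–3 arrays
per condition the raw pooled t (df = 4) is dominated by variance-estimate
noise — even 3-log2-unit effects are then missed a substantial fraction of
the time at the stringent significance convention — while the moderated
form is both stabler and closer to standard microarray practice. `d0 = 0`
restores the plain pooled t. p-values are BH step-up adjusted
(statsmodels), significance at adjusted p < 0.001, and
log2FC = mean(A) − mean(B) with A = free-living, so positive values mean
higher expression in culture.

## Integration

One summary row per annotated gene joins change counts, changed motifs,
log2FC, adjusted p and flags; genes missing from either input default to
zero changes / non-significant and are counted in the log. A gene is a
candidate iff it has ≥ 1 change and is DE-significant — asserted
set-algebraically on every run. Genes straddling the island boundary count
as in-island iff their start lies inside (a single unambiguous rule; none
is stated in the source analyses). Headline percentages round half-up to
1 decimal. Sliding windows (default 1 kb, step 100 bp — "overlapping"
requires step < window; the step itself is a free choice) report the
methylated fraction per motif and condition; windows with no sites are
missing, not 0 %, because a 0/0 proportion is undefined. Tracks are
exported as bedGraph with wrapped windows clipped at the sequence end.

## Synthetic data

The generator emulates the study conditions end to end; its defaults *are*
those conditions, chosen once:

* genome: 100 kb circular, i.i.d. bases at GC 0.64 with a 15-kb island at
  GC 0.59 (the real contrast is ~0.64 vs ~0.59; the island is 15 % of the
  synthetic genome vs 7.5 % of the real one to keep island gene counts
  usable at desk scale);
* motif sites: the 7–13-mer motifs are rare under the i.i.d. model
  (~10–20 expected), so occurrences are planted at random well-spaced loci
  until each motif has ≥ 400 strand-specific sites — enough for binomial
  standard errors of ~2 percentage points at p ≈ 0.8. After planting, the
  genome is point-mutated until no two motifs share a methylatable base:
  a single base carries a single state, so per-motif rates are only well
  defined on disjoint site sets (chance overlaps such as `CCTTGAGTC`, which
  embeds a GANTC on the same adenine, are resolved in favour of the rarer
  motif). The duplex loci of the bipartite pair still coincide, as they
  must.
* methylation: each site is methylated independently with its motif's
  per-condition rate; defaults are the published percent-methylated values
  (free-living: GANTC 0.9977, CRAGGAT 0.9995, GAGA(N)6RTG 1.0,
  CAY(N)6TCTC 0.9995, CCTTGAG 0.0; bacteroid: 0.9746 / 0.8749 / 0.8260 /
  0.8606 / 0.8006). Methylated sites emit one GFF record with coverage
  ~ N(130, 26) in culture and N(64, 12.8) in the bacteroid (the published
  mean coverages; SD fixed at 20 % of the mean), modQV ~ N(136, 15) /
  N(85, 15), IPD ratio ~ N(4.5, 0.5). Unmethylated sites emit nothing
  (absence model). A configurable fraction of methylated sites is written
  with sub-threshold QV/coverage to exercise the QC filter; the default is
  0 because no sub-threshold rate is published and a nonzero default would
  bias percent-methylated recovery away from the configured rates.
* genes: 900-bp bodies with 300-bp gaps (83 genes at 100 kb), strands
  random, for analytic tractability of per-kb tallies; ~30 % of island
  genes are flagged with a symbiosis role.
* expression: per-gene baselines ~ N(8, 1.5) log2 units, 3 arrays per
  condition, 2 spots per gene, per-measurement noise σ = 0.25. A
  `de_fraction` (default 0.3) of genes receives additive effects recycled
  from the nine published candidate-gene log2FC values
  (3.06, 5.49, 4.60, 5.06, 4.55, 1.23, 0.89, 5.73, 0.78), split
  symmetrically between conditions with alternating signs so that array
  distributions stay exchangeable under quantile normalisation.

Ground truth records every site state, the sub-threshold set, planted gene
effects, and two candidate sets: `candidates_all` (every gene with a
realised methylation change and any planted effect) and
`expected_candidates`, the subset whose planted |log2FC| ≥ 2.0
(`truth_min_lfc`). The threshold is a power screen fixed in advance from
the design arithmetic: at σ = 0.25 and n = 3 the standard error of a log2FC
is ≈ 0.20, so effects ≥ 2 are detected with essentially full power at
adjusted p < 0.001 while the 0.78–1.23 planted effects are intrinsically
borderline there. Recovery is therefore scored as sensitivity against
`expected_candidates` (what the design can detect) and FDR against
`candidates_all` (a weak-effect gene that does reach significance is a true
discovery, not a false one).

Everything derives from a single `numpy` Generator seeded by the config:
identical (seed, config) pairs give byte-identical output files. The run
log is excluded from byte-identity comparisons across *different* input
directories since it echoes input paths.

## What passing tests do and do not show

The generator draws site states independently per site and noise
independently per measurement. Real SMRT data violate this in ways the
suite does not probe: methylation is spatially and mechanistically
correlated (one methyltransferase serves all sites of a motif), coverage
varies systematically around the origin, modQV depends on coverage and
sequence context, bacteroid samples carry host-read contamination upstream
of calling, and expression arrays have dye and batch structure that
median-centering + quantile normalisation only partly models. Passing
recovery tests therefore demonstrate correctness of the bookkeeping —
scanning, QC, state calling, differencing, attribution, testing,
intersection — under a faithful but idealised noise model, not robustness
to every artefact of the platforms.

## Numerical conventions

Reported percentages use half-up rounding (2 decimals in motif tables,
1 decimal for headline fractions). Zero-site summaries report missing
percentages rather than 0. Degenerate t statistics (zero standard error)
map to p = 0 for a nonzero mean difference and p = 1 otherwise; with the
default shrinkage this arises only when the whole matrix is constant.
Tables are written with `%.6g` floats to make reruns byte-comparable.
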