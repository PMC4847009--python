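# Methods

`mirprof` re-implements, as a tested and reusable pipeline, a developmental
small RNA-seq analysis: from barcoded reads through isomiR-aware miRNA
quantification, count normalization, replicate-homogeneity screening and
nonparametric differential expression, together with a synthetic-data
generator that stands in for the original sequencing libraries so every
stage is testable offline. This note records the models, the parameters
that matter, and the design decisions taken where the design was genuinely
open.

## The synthetic-data generator

The generator emulates a time-course design: five postnatal stages
(P4/P8/P14/P21/P28 by default) with 4–7 biological replicates each, one
barcoded library per replicate.

**Reference.** A toy miRBase-like reference of `n_hairpins` stem-loop
precursors, each carrying an annotated 5p mature arm (20–24 nt) and, with
probability `two_arm_probability`, a 3p arm. Declared families share the
seed region (bases 2–8) of their 5p arm and differ at at least one
downstream base. All mature sequences are unique across the reference and
occur nowhere else in any hairpin, so exact alignment is unambiguous by
construction. Hairpin loops and flanks are random sequence; no attempt is
made to produce thermodynamically foldable stems, because nothing
downstream consumes secondary structure.

**Expression model.** Per-miRNA baseline abundance is lognormal with
natural-log parameters (log 500, 1.5), reproducing the heavy-tailed
abundance spectrum of small-RNA libraries in which a handful of miRNAs
absorb most reads. Planted differential expression is multiplicative: for
a planted stage pair, a chosen fraction of miRNAs is multiplied by the
fold (or its reciprocal — direction is drawn per miRNA) from the later
stage onward, so adjacent-pair effects compose along the time course.
Between-replicate biological variability is a per-library lognormal factor
with `replicate_noise_sd = 0.30`; this value makes the global CV of a
homogeneous synthetic stage land near 0.30, the regime observed for
reproducible stages in real ARC/ME data (0.28–0.33). Each miRNA carries a
lognormal ligation-bias factor (`ligation_bias_sd = 1.0`) identical in
every library: adaptor-ligation bias is a property of the RNA sequence and
is reproducible between libraries, which is why it cancels from
between-library comparisons yet can distort within-library abundance by
an order of magnitude.

**Counts.** Each library is one multinomial draw of `reads_per_library`
reads over the bias-weighted expected abundances, so column sums are exact
and sampling noise scales correctly with depth. The default depth is
5×10⁴ reads per library — a desk-scale choice; real libraries run to ~10⁶
mapped reads, and depth is an explicit scale knob, not a claim.

**Reads.** Each read is the mature sequence — optionally end-shifted —
followed by the library's 3′ adaptor, truncated to 36 nt. The first eleven
adaptor bases are the library barcode; a constant tail follows. IsomiR
end-heterogeneity uses category probabilities (canonical, 3′-shift,
5′-shift) = (0.60, 0.25, 0.15) with shift magnitudes of 1 nt (p = 0.7) or
2 nt (p = 0.3), either direction. Substitution errors are i.i.d. at
`per_base_error_rate = 0.002` (a typical short-read machine error rate);
qualities are a constant 'I' because no downstream stage consumes quality.
Barcodes are generated with pairwise Hamming distance ≥ 5.

**Heterogeneous-stage scenario.** A flag mixes two regimes among one
stage's replicates: the last `n_outliers` (default 2) replicates shift a
fraction (default 30%) of miRNAs by `heterogeneous_fold` up or down. The
default fold is 4.0, calibrated so the synthetic heterogeneous stage
reproduces the CV contrast observed in real heterogeneous stages (full-set
global CV ≈ 0.45 against ≈ 0.30 for the homogeneous core — matching the
observed 0.48–0.55 vs 0.27–0.33 regimes); the replicates of such a stage
straddle a developmental transition in which a fifth of miRNAs change
more than 3-fold, so shifts well above 2-fold are the faithful analogue.

**qPCR.** Ct values follow `Ct = intercept − log_E(expression) + ε`,
with per-assay amplification efficiency `E ∈ (1, 2]` and Gaussian noise ε.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: genomic background reads and other small-RNA
classes (tRNA/rRNA fragments), adapter dimers, RNA editing, quality decay
along the read, lane effects, and any correlation between miRNA abundance
and ligation bias. Conclusions about demultiplexing specificity and
alignment accuracy transfer only to the extent that real contaminant
reads are rejected rather than misassigned.

## Read processing

Demultiplexing searches each read for `barcode + constant tail`
occurrences. A candidate position must show the barcode within
`max_mismatch` (default 1) mismatches — the full 11-mer where it fits,
or at least 8 terminal bases where the read end truncates it — and the
visible tail bases within a 10% mismatch rate. Among candidates the fewest
total mismatches win, ties breaking to the leftmost (adaptor-proximal)
position; two barcodes tied at the same position send the read to the
unassigned stream. Scoring by mismatches before position matters: with a
10% allowance, a leftmost-qualifying rule misfires on chance 11-mer
matches inside inserts at realistic read counts, whereas the best-match
rule keeps the error-free round trip exact. Trimming removes the best
(fewest-mismatch, then leftmost) occurrence of the library's adaptor
prefix at ≥ 8 nt overlap, terminal partial overlaps included — the
behaviour of cutadapt-style trimmers. Inserts shorter than 16 nt are
discarded; 16-nt inserts are retained (the discard rule is "< 16").
N bases never match anything, including other Ns.

## Quantification

Alignment is ungapped Hamming search of each insert against every offset
of every hairpin, keeping all hits in the best stratum up to 2 mismatches
(the tolerance used for the original genome mapping, applied here at
miRNA assignment). Alignment to the hairpin set replaces the original
whole-genome mapping through an external (discontinued) service; the
hairpin space is exactly what the downstream miRNA profiles consume.
Naming follows the isomiR convention: 3′-end variants share the canonical
arm name (a 3′ shift leaves the seed intact), while any 5′-shifted variant
is reported as the separate entity `<arm>-hairp`, since a shifted seed
retargets the miRNA. Counts tied between several reporting names are
split equally — deterministic and conservation-preserving. Hits covering
less than half the insert with annotated arm sequence are "unknown arm"
and excluded from profiles but tallied in the run report.

Optional per-miRNA efficiency factors correct a protocol variant against
a reference protocol using a control library pair built from the same
RNA: `f = variant/reference` where both counts ≥ 20 (below that the ratio
is dominated by sampling noise), `f = 1` elsewhere; corrected counts are
`raw/f`. Off by default for synthetic runs.

The expression filter retains miRNAs exceeding 10 normalized reads in at
least one stage mean (strictly greater); low-expression profiles in a
multi-cell-type tissue are uninterpretable abundance-wise and dominate CV
noise.

## Normalization

Median-of-ratios size factors: `s_j = median_i k_ij / (∏_v k_iv)^(1/m)`
over miRNAs positive in every library, computed on the unfiltered profile
(the estimator wants the full composition, and the filter itself needs
normalized means). The median is taken on the log scale, so an even count
of miRNAs averages the two central ratios geometrically — the convention
of the reference DESeq implementation, against which `size_factors` is
verified to machine precision. Note the estimator is anchored by the
geometric mean across the observed libraries: rescaling one raw column
changes the normalized matrix by one global constant (all relative
comparisons are preserved exactly); the factors themselves are not
per-column equivariant.

## Homogeneity screening

Per-miRNA CV = sample SD (n−1 denominator; the denominator is a
convention choice at n = 4–7) over mean, computed across a stage's
replicates on normalized, filter-passing values. The global CV is the
mean ± SEM of per-miRNA CVs (matching how stage-level CVs are reported
as mean ± SEM); sliding CVs are means over 50-miRNA windows stepped by 1
through miRNAs ranked by decreasing mean abundance, exposing the
noise–abundance relationship.

Sub-stage discovery formalizes what was originally a visual judgement:
every proper replicate subset of size ≥ 4 is scored by its global CV
(per-miRNA CVs recomputed within the subset; ≤ 2⁷ subsets, so the search
is exact by enumeration), and the lowest-CV subset is accepted when its
global CV is ≤ 0.35 (between the observed homogeneous 0.27–0.33 and
heterogeneous 0.48–0.55 regimes) *and* ≤ 0.75 × the full-set CV (a
subset must be materially, not marginally, tighter). Both thresholds are
config knobs. A returned subset whose members share one litter is flagged
litter-confounded rather than suppressed.

## Differential expression

Per-miRNA two-group comparison by the Mann-Whitney U test on normalized
expression values: exact two-sided p by full enumeration when the pooled
sample is tie-free and ≤ 14 (scipy's exact path, cross-checked in the
suite against a literal enumeration oracle for all group sizes ≤ 7),
otherwise the normal approximation with tie and continuity correction.
Adjustment is Benjamini-Yekutieli — valid under arbitrary dependence,
which matters because miRNA counts within a library are compositionally
coupled — applied within each comparison as its own family, across the
filter-passing miRNAs actually tested (rows with both group means zero
are excluded from the family). Significant miRNAs (adjusted p < 0.05) are
classified by fold change: beyond threshold (fold > 3 strictly, or
< 1/3 strictly — the reciprocal, not the printed rounding 0.33) or
within. When only the denominator group mean is zero, 0.5 is added to
both means to keep the ratio defined.

Small-sample discreteness is a property of this design, documented and
tested rather than patched: with 6 vs 6 replicates the smallest exact
two-sided p is 2/924 ≈ 0.00216, so among ~500 tests an isolated perfectly
separated miRNA cannot survive BY adjustment; only a sufficiently large
block of co-changing miRNAs is rescued by the step-up rank. Developmental
transitions move hundreds of miRNAs at once, which is exactly the regime
in which the procedure has power.

## qPCR validation

Relative expression uses the efficiency-corrected ratio form of ΔΔCt:
`E_T^(ΔCt_T) / E_R^(ΔCt_R)` with ΔCt = Ct(calibrator) − Ct(sample); at
E = 2 this reduces to 2^(−ΔΔCt). The reference assay for miRNA
quantification defaults to miR-124-3p (U6 is size-excluded from small-RNA
fractions and a stably expressed miRNA serves instead). Sample QC
computes POMC relative to GAPDH against the mean of POMC-non-expressing
PVN control punches and discards samples below 3-fold over the controls,
plus samples below 0.2 × their stage median (both cutoffs formalize
qualitative discard decisions and are config knobs). Concordance between
sequencing and qPCR compares ratio-of-ratio tables (miRNA over reference
miRNA, stage over calibrator stage) cell by cell: log₂ difference and a
direction-agreement flag.

## Benchmarks and problem sizes

`mirprof.evaluate` drives the standard benchmark: 500 single-arm miRNAs,
two conditions with 6 replicates each, 10⁵ reads per library, 200 miRNAs
planted at 4-fold (random direction), 300 null. Over 50 such datasets the
pipeline's mean empirical false-discovery proportion among declared
miRNAs is ~0.005–0.01 (bounded by the nominal 0.05; BY under discreteness
is conservative), sensitivity for the planted effects among
filter-passing miRNAs is ~0.90, and the median |log(estimated/planted)|
fold error for miRNAs above 50 normalized reads is ~0.13 (within ±25%).
Sensitivity is reported over planted miRNAs passing the expression filter
— the set the pipeline tests at all; ~15% of planted miRNAs fall below
the filter at this depth, a depth effect, not a test effect. Fold-change
accuracy is a typical-case (median) statement: with lognormal replicate
noise of sd 0.30, a 6-replicate group-mean ratio carries ~17% sampling
spread, so individual estimates beyond ±25% are expected and correct.
The read-level round trip (demultiplex → trim → align → count equals the
simulated matrix exactly) is checked at 5×10⁴ reads × 10 libraries with
errors off and canonical-only isomiRs; the sub-stage benchmark runs 20
heterogeneous-stage datasets (4 + 2 replicates) and recovers the exact
homogeneous quadruple in 20/20 at the default regime shift.

## Numerical choices and degenerate inputs

- All randomness flows from one master seed; per-library streams are
  derived deterministically, so any stage is reproducible in isolation.
- Median of an even-length ratio vector: geometric mean of the central
  pair (log-scale median).
- CV of a single value: undefined; SEM of a single CV: 0 by convention.
- Fewer miRNAs than one sliding window: a single window over all of them.
- `mann_whitney` on two all-identical groups returns p = 1 directly (the
  normal approximation would divide by a zero tie-corrected variance).
- Zero-count rows never enter size-factor estimation; a matrix with no
  all-positive row raises an estimation error rather than guessing.
- Ambiguous demultiplex candidates (two barcodes, same score, same
  position) are unassigned, never arbitrarily broken.

## Known limitations

- Hairpin-space alignment cannot rescue reads whose true origin is
  elsewhere in the genome; with real data, contaminants that happen to be
  within 2 mismatches of a mature arm would be counted.
- The exhaustive sub-stage search is exponential in replicate count —
  exact and fast for n ≤ 10, inappropriate beyond that.
- Efficiency-factor correction assumes the control pair shares the true
  composition; disagreement below 20 reads is ignored by design.
- The generator's isomiR model shifts ends independently of abundance;
  real 3′ heterogeneity is miRNA-specific.
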