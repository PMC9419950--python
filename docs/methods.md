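# Methods

## The measurement

A Cas9 ribonucleoprotein directed by a 20-nt spacer cleaves its genomic
target 3 bp from the PAM-proximal protospacer boundary (blunt cut
between protospacer positions 17 and 18). Repair by non-homologous end
joining leaves insertions and deletions at the cut. The pipeline
estimates, per sample and per amplicon locus, the percentage of
sequenced molecules carrying such an indel, and from the per-locus
percentages an on-target specificity score. All downstream statistics
(dose–response tables, replicate ANOVA/Tukey chains) operate on these
percentages.

Every stage is exactly conservative: input read pairs are partitioned
into merge failures, structure rejects (by failing component), and
demultiplexed reads, and the pipeline refuses to finish if the
partition does not add up.

## Pipeline stages and their parameters

**Pair merging.** Amplicons (240 nt by default) are shorter than the
300 nt covered by a 2×150 pair, so every pair overlaps. For each pair
the merger scores all overlap lengths between `min_overlap` (default
20 nt) and the full read length between read 1's 3′ end and the reverse
complement of read 2, picking the overlap with the smallest mismatch
fraction, ties broken toward the longer overlap; pairs whose best
overlap exceeds `max_mismatch_frac` (default 0.1) fail merging.
Consensus bases in the overlap come from the higher-quality read
(read 1 on ties). The search is exhaustive, so the implementation is
testable against a brute-force oracle; a zero-mismatch overlap found
while scanning longest-first is accepted immediately, since nothing can
beat it under this objective.

**Structure filter.** A merged read must start with a known 5-nt
barcode, matched exactly — a barcode matched loosely could silently
move reads between samples — immediately followed by that sample's
forward-primer annealing part and ending with the reverse complement of
its reverse primer, each tolerating `max_primer_mismatch` substitutions
(default 1, absorbing ordinary sequencing error in primer regions).
Accepted reads are trimmed of barcode and primer parts before
alignment, so primer-region errors can never appear as locus indels;
`trim=False` retains the full sequence for inspection.

**Locus assignment and alignment.** Each insert is fit-aligned (read
global, reference local: free reference end gaps) against every
candidate amplicon under affine gap scoring — match +2, mismatch −3,
gap open −8, gap extend −1, where a length-L gap costs
`open + (L−1)·extend`. The penalties are deliberately gap-averse so
that isolated substitution errors at Q30-level rates are absorbed as
mismatches instead of opening false gaps. The best-scoring locus wins;
a read is left unassigned (never double-counted) when its best score
falls below `min_score_frac` (default 0.5) of the perfect-match score
or when the top two loci tie exactly. Alignment is performed by
Biopython's `PairwiseAligner`; its optimal scores are verified in the
test suite against an independent three-state (Gotoh) dynamic program.
Aligning to the known amplicon references replaces genome-wide mapping:
with user-supplied loci a whole-genome search adds nothing but an
external dependency. This is the pipeline's one deliberate
methodological substitution, and alignments can be exported as SAM for
inspection with standard tools.

**Indel calling.** Insertions and deletions are read directly off the
alignment's operation list (CIGAR semantics): one event per I/D
operation with reference-coordinate position (between-base index for
insertions, leftmost deleted base for deletions) and length. By
default a read counts as edited if it carries any indel anywhere in the
insert — the whole-read CIGAR criterion. An optional cut-site window
(`window_halfwidth`, suggested ±25 bp) restricts counting to events
near the cut, which suppresses residual gap artifacts at higher error
rates; it is off by default since whole-read counting is the plainer
rule and the two agree on clean data. Position spectra are keyed
relative to the cut site, length spectra by signed length (+insertion,
−deletion). Identical inserts are aligned once and cached — amplicon
pools are dominated by exact duplicate reads, which makes the batch
caller roughly an order of magnitude faster at deep coverage.

**Summaries and specificity.** `pct_indels = 100·n_indel/n_pass`
counts only structure-passing, locus-assigned reads in the denominator
(the choice is explicit because mapped-versus-passing denominators
differ in principle; passing assigned reads is the defensible, fully
observable choice here). A zero denominator raises an error rather
than reporting 0%. Specificity is
`100·on_pct/(on_pct + Σ off_pcts)` — scale-invariant, monotone
increasing in the on-target percentage and decreasing in each
off-target percentage, and undefined (explicit error) when every term
is zero, which is why no-nuclease conditions are excluded from
specificity panels. The implementation accepts any number of
off-target loci; two is the canonical, tested configuration.

**Replicate statistics.** `compare_groups` runs Shapiro–Wilk normality
per group, Levene's variance-homogeneity test, one-way ANOVA, and
Tukey's range post hoc test over all pairwise comparisons within one
panel, reporting adjusted p-values with 0.05/0.01/0.001 significance
tiers. The Tukey family is the panel's own pairs only; no cross-panel
correction is applied, matching how per-panel comparisons are normally
displayed.

## The synthetic-data generator

The generator emulates the structure of a pooled amplicon sequencing
run and nothing more. Templates are `barcode + amplicon`; with
probability `true_indel_rate` a template carries exactly one indel —
deletion with probability `deletion_fraction` (default 0.6), length
geometric with `p_len = 0.3` capped at 30 nt, positioned at the cut
site ±2 bp of uniform jitter. Reads are the first 150 nt of the
template and of its reverse complement, with independent per-base
substitution errors (default 10⁻³) and constant Q30 qualities (the
pipeline only consults qualities at merge consensus, so a richer
quality model would be unobservable). Amplicons default to 240 nt so
pairs always overlap by ≥60 nt. Off-target loci carry protospacers at
an exact, configurable Hamming distance (default 2) from the on-target
protospacer, embedded in otherwise unrelated random amplicons with
valid NGG PAMs on either strand.

What this does *not* model: PCR amplification bias and chimeras,
multiple indels per molecule, homology-directed or substitution-only
editing outcomes, quality-dependent error profiles, or realistic indel
length/position spectra beyond the parametric family above. Passing
the recovery tests therefore shows that the pipeline correctly counts
what the truth table says it planted — it does not validate behaviour
on artifacts the generator never produces.

Determinism: each sample draws from a generator seeded by
`(master_seed, crc32(sample_id))`, so runs are reproducible per sample
and independent across samples; FASTQ gzip members are written with a
pinned mtime so reruns are byte-identical.

## The inhibitor designer

Designs are DNA oligos, 5′→3′. The core of a length-*n* design is the
reverse complement of the *n* PAM-proximal (3′-most) spacer bases —
equivalently, the target-strand sequence adjacent to the PAM. PAM-loop
variants prepend `PAM + loop + revcomp(PAM)`, so the first three bases
fold back onto the three preceding the core to present a 3-bp
double-stranded PAM; `hairpin_check` verifies that duplex and scans
exhaustively for unintended self-complementary runs (≥6 nt by default).
The loop linker is not dictated by any published sequence available
here; the default `TTTT` is a conventional short, non-structured
linker and is configurable. Scrambled controls are seeded uniform
permutations of a parent design, re-drawn until they differ from the
parent and retain no complementary run of ≥8 nt against the spacer —
the rejection guarantees the control cannot act through the same
seed-pairing logic as a real inhibitor; the threshold is configurable.
No thermodynamic folding is computed; all checks are exact
complementarity.

## Gel quantification

Band intensities arrive as a tidy TSV from any densitometry tool. Each
(assay, condition) series is normalised to its time-zero lane
(`I_rel(t0) = 1`); `% digestion = (1 − I_rel)·100`. Noise can push a
lane above its t0 reference; the raw (negative) value is retained and a
clamped [0, 100] display column reported beside it. Time-lapse
summaries aggregate replicate assays per (condition, delay in seconds)
as mean ± SD (SD left empty for single replicates). Fragment
prediction for a single blunt cut is `(cut, length − cut)` and
conserves total length.

## Problem sizes and numerical choices

The recovery tests and the acceptance script use three loci × three
replicates × 2000 read pairs (18,000 pairs, ~10 s on one CPU) — deep
enough that a 99% binomial interval on a 40% rate spans under ±3
percentage points, small enough to run casually. Percentages are
carried at full precision and rounded only at report time. Coordinates
are 0-based half-open internally; only human-readable reports use
1-based positions. Alignment ties and sub-threshold scores yield
`unassigned`, counted and reported, never guessed. Where alignment
placement of an indel is ambiguous (repeats around the cut), the
aligner's leftmost-equivalent placement is accepted; spectra are
therefore reported relative to the cut site rather than asserted at
exact coordinates.

## Known limitations

* Indel quantification only: substitution editing, HDR outcomes and
  UMI-based deduplication are out of scope.
* Off-target loci are user-supplied; the package does not discover
  them.
* The specificity score inherits the usual caveat that it is
  uninformative when overall activity is near zero; the pipeline
  surfaces this as an explicit undefined-statistic error.
* Inhibitor design checks exact base-pairing only — no ΔG, no chemical
  modifications.
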