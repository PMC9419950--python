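# crispramp

Quantification of CRISPR–Cas9 genome editing from amplicon deep
sequencing, and design of guide-complementary DNA oligo inhibitors of
Cas9.

When Cas9 cuts a genomic target, error-prone repair by non-homologous
end joining leaves insertions and deletions (indels) at the cut site.
Deep sequencing of PCR amplicons spanning the target is the standard
readout: the fraction of reads carrying an indel estimates the editing
rate. Short single-stranded DNA oligos complementary to the
PAM-proximal, spacer-derived part of the guide RNA can base-pair with
the guide and inhibit Cas9; a 5′ fold-back extension presenting a
double-stranded PAM ("PAM-loop") makes that inhibition effective even
against preformed ribonucleoprotein. `crispramp` packages both sides of
such an experiment for computational use: the sequencing-analysis
pipeline (with a synthetic-read generator providing exact ground truth)
and the inhibitor oligo designer, plus quantification of in vitro
cleavage from gel densitometry.

## Core quantities

For each sample and amplicon locus, with `n_pass` structure-passing
reads assigned to the locus and `n_indel` of them carrying at least one
insertion or deletion in their gapped alignment (CIGAR operations I/D):

```
pct_indels      = 100 · n_indel / n_pass
```

On-target specificity over one on-target locus and its off-target loci
(canonically two), computed on percentages so that per-locus read depth
cancels:

```
pct_specificity = 100 · on_pct / (on_pct + Σ off_pct_i)
```

i.e. the percentage of observed indels that occur on-target. It is
undefined (an explicit error, not 0) when no locus shows indels.

In vitro cleavage from gel band intensities, normalised per series to
the time-zero lane:

```
I_rel = intensity / intensity(t0);    % digestion = (1 − I_rel) · 100
```

Replicate comparisons run Shapiro–Wilk, Levene, one-way ANOVA and
Tukey's range post hoc test, in that order.

## Worked example

Simulate a pool (one on-target locus, two off-target loci whose
protospacers differ at two positions), then run the full pipeline:

```
crispramp simulate --seed 6 --out-dir sim --n-reads 2000 --replicates 3
crispramp run --r1 sim/reads_R1.fastq.gz --r2 sim/reads_R2.fastq.gz \
    --reference-fasta sim/reference.fasta --loci-tsv sim/loci.tsv \
    --samples-tsv sim/samples.tsv --out-dir out --seed 6
```

The run log prints the stage counts and the conservation check:

```
pairs=18000 merge_failures=0 rejects=77 assigned=17923 conserved=True
```

`out/summaries.tsv` then holds per-sample `pct_indels`,
`out/specificity.tsv` per-condition `pct_specificity`. (The CLI
simulator applies one indel rate to every locus; per-locus rates are
set through the Python API's `SimulationConfig`.) On a pool simulated
at truth indel rates 0.40 / 0.05 / 0.02 (on, off1, off2) — the
conditions `scripts/acceptance.py` uses — the pipeline reports mean
percentages 39.6 / 4.8 / 2.0 and mean specificity 85.4, against a
closed-form value on the truth rates of 100·40/(40+5+2) = 85.1.

Designing inhibitors for a guide (8- and 20-nt cores, PAM-loop
variants, one scrambled control each):

```
$ crispramp design --spacer GGGCACTAGCTTACGGATCC --pam TGG \
      --core-lengths 8,20 --scramble-seeds 1
>L8 kind=L8 core=8
GGATCCGT
>L8_PAM kind=L8_PAM core=8 loop=TTTT
TGGTTTTCCAGGATCCGT
>SCRAMBLED_L8_seed1 kind=SCRAMBLED core=8 seed=1
CGGCAGTT
>L20 kind=L20 core=20
GGATCCGTAAGCTAGTGCCC
>L20_PAM kind=L20_PAM core=20 loop=TTTT
TGGTTTTCCAGGATCCGTAAGCTAGTGCCC
>SCRAMBLED_L20_seed1 kind=SCRAMBLED core=20 seed=1
GGCGTCTCTATCCAGAGAGC
```

The `L8` core `GGATCCGT` is the reverse complement of the spacer's
eight 3′-most (PAM-proximal) bases; `L8_PAM` prepends
`PAM + TTTT + revcomp(PAM)` so the 5′ arm folds back into a 3-bp PAM
duplex. Gel quantification takes a lane-intensity TSV
(`crispramp gelquant bands.tsv --out-dir gel/`) and writes per-lane
`% digestion` plus per-condition mean ± SD summaries.

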