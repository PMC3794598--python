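# Methods

## The analysis

RdDM-pathway genomics rests on two measurements and one statistic.

**Methylation levels.** Bisulfite treatment converts unmethylated cytosine
to uracil (read as T) while methylated cytosine stays C, so the methylation
level of a site, and by pooling of a region, is

    m = ΣC / (ΣC + ΣT)

over reads covering cytosine positions. A site contributes only with at
least `min_coverage = 5` informative (C or T) reads; below that the level
is undefined and propagates as missing, never as zero. Contexts are
assigned 5'→3' on the cytosine's own strand: CG (next base G), CHG
(next-next G), CHH otherwise, H ∈ {A,C,T}; positions too close to a
chromosome end to establish a G fall to CHH. Region levels pool counts
(coverage-weighted) rather than averaging site levels; a feature-averaged
metagene mode exists behind a flag for comparison.

**Differential methylation.** For each annotated region (gene body, TE
body, 1-kb strand-aware promoter) the pooled (C, T) counts of two
genotypes form a 2×2 table tested with a two-sided Fisher exact test under
the point-mass definition: p is the total probability of all tables with
the observed margins whose hypergeometric probability does not exceed the
observed table's (relative tie slack 1e-7, the customary convention). The
implementation evaluates the hypergeometric pmf over the support once per
margin triple (vectorized, sort + cumulative sum), which makes exhaustive
scans over hundreds of thousands of tables cheap; it is checked against an
exact integer-arithmetic enumeration. Regions enter testing only with
> 10% pooled-context methylation in at least one genotype, and calls use
raw *P* < 0.01 with direction set by the level comparison. No
multiple-testing correction is applied by default, matching the raw-P
selection convention of this analysis; `call_dmrs(..., fdr=True)` applies
Benjamini–Hochberg for users who want it. Tests default to counts pooled
across contexts (one hypo/hyper verdict per region); a per-context mode
exists.

**siRNA dependence classification.** 18–30-nt reads are mapped exactly
(0 mismatches, both strands); multimappers are spread fractionally (1/n)
by default, with a discard mode for stricter behaviour. 24-nt reads are
counted in non-overlapping 500-bp windows by 5' end and normalized to
reads per million, with the denominator the library's total mapped
18–30-nt reads (configurable to 24-nt-only). A window is Pol IV-dependent
when the baseline RPM drops ≥ 5-fold in nrpd1, and Pol V-/STA1-dependent
(evaluated only inside the Pol IV-dependent set) at ≥ 2-fold in
nrpe1/sta1. Two numerical choices matter here and are configuration, not
biology: a zero mutant count passes any fold threshold (no pseudocount by
default; an option exists), and a raw-count floor on the baseline library
(default 10 reads) keeps fold changes off near-zero noise — without a
floor, a 1-read window dropping to 0 would count as infinitely reduced.
Reported percentages are rounded to one decimal, half away from zero;
cell-count ratios use nearest-integer rendering.

## Bisulfite alignment

Conversion makes matching asymmetric: read T over reference C is
consistent with conversion (no mismatch) while read C over reference T is
a mismatch. Candidate loci are found in a fully reduced alphabet — C→T on
both read and reference for plus-strand candidacy, G→A (against the
reverse-complemented read) for minus-strand candidacy — where every
asymmetric match is also a reduced match. A read is split into
`max_mismatches + 1` non-overlapping seeds, so by pigeonhole any alignment
within the mismatch budget (default 2) has at least one exact seed hit;
the asymmetric mismatch count over candidates then selects hits. Only
single best-scoring alignments are used for methylation calling; tied best
hits are reported with `unique=False` and excluded downstream
(conservative uniqueness — the standard when the original choice is
unknowable). Reads are never wrapped around chromosome ends; candidate
starts are limited to `[0, L − read_length]`. Coordinates are 0-based
half-open internally and 1-based in all emitted text formats (GFF3, SAM,
CX tables); bedGraph output is 0-based half-open as that format requires.
A brute-force scan over every position and strand
(`bisulfite_align_bruteforce`) implements the identical scoring rule with
no index and serves as the reference the indexed aligner is verified
against. Base qualities are ignored throughout (the simulator emits flat
qualities and no quality-dependent step exists in the analysis).

## The synthetic-study generator

The generator emulates the *structure* the analysis depends on, not any
particular genome:

* **Genome.** Default 2 × 100 kb chromosomes of uniform random sequence;
  TEs (default 30, 600–1200 bp) are placed without overlap, 80% of them
  inside the central 20% of each chromosome around the centromere
  midpoint, genes (default 20, 1–2 kb) on the arms. The pericentromeric
  enrichment is what makes chromosome-scale methylation and siRNA
  profiles structured at toy scale; at a 100-kb chromosome the 500-kb
  profile superwindow of a real genome scales down to 10 kb.
* **RdDM design.** All TEs are RdDM loci by default (`rddm_fraction`
  allows genotype-invariant null TEs, used in the DMR recovery study);
  50% of RdDM loci are Pol V-dependent and 30% STA1-dependent, with 95%
  of the STA1 set drawn from inside the Pol V set, emulating the strong
  observed nesting of downstream dependencies.
* **Methylomes.** Probabilities are deterministic per (region class,
  context, genotype): TE bodies CG/CHG/CHH = 0.8/0.5/0.3 at RdDM loci,
  gene bodies CG-only 0.3, background 0.05/0.01/0.01. Genotype multipliers
  act on the genotype's locus set — nrpd1: ×0.1 on CHG/CHH (CG ×0.9,
  "nearly unchanged") at all RdDM loci; nrpe1/sta1: ×0.4 on CHG/CHH at
  their subsets. Symmetric CpG sites get identical probabilities on both
  strands by resolving region membership at the plus-strand C of the pair.
* **Bisulfite reads.** Single-end 50-nt reads, uniform over both strands,
  per-chromosome counts Poisson at the requested depth. Per read, each
  cytosine of the originating strand is methylated with its methylome
  probability; unmethylated cytosines convert C→T with probability
  `conversion_rate` (default 0.995 — a 0.5% failure rate leaves residual
  C), methylated cytosines always stay C; independent substitution errors
  at `error_rate` (default 0.001). These defaults are typical library
  values and are exposed in configuration. Ground truth (origin, per-base
  methylation state) always accompanies the FASTQ.
* **Small-RNA libraries.** 24-nt reads Poisson-sampled per cluster (all
  RdDM TEs by default, 60% of the library) with genotype multipliers 0.1
  (nrpd1, all clusters) and 0.3 (nrpe1/sta1 at their subsets) — safely
  past the 5-fold and 2-fold classification thresholds; 21-nt miRNA-like
  reads from fixed gene positions with genotype-independent expectation
  (5% of the library); the remainder uniform 18–30-nt background. Every
  read is an exact genome substring and carries its source locus.

The genotypes are modelled on the double-mutant design in which all
contrasts are taken against a *ros1* background: the baseline is "wild
type for RdDM-locus methylation" and ROS1 demethylation dynamics are not
modelled. Library depth per genotype is a free parameter (the original
study reports only total read counts).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: non-uniform base composition and repeats (beyond
the single duplicated-segment cases in tests, multimapping is essentially
absent from random sequence), PCR duplicates and coverage biases,
quality-score structure, paired ends, indels, chloroplast-based
conversion-rate estimation, miRNA hairpin biogenesis, and any biological
variation between replicates (there are none). Recovery results quantify
the correctness of the pipeline's computations under the stated model,
not its robustness to real-library artefacts.

## Validation experiments (`rddmkit.validation`)

Each experiment regenerates its inputs from a seed and runs the regular
pipeline code:

* **Fisher oracle** — the batched p-value path is compared with an exact
  `math.comb` enumeration for every 2×2 table with total ≤ 60 (628,055
  tables); agreement is at machine precision (~6e-16).
* **Mapping oracle** — ~1000 simulated reads on a 10-kb genome; the
  indexed aligner must reproduce the brute-force scan exactly.
* **Methylation recovery** — depth 50 on a 60-kb genome; for each ≥ 5×
  site the unconverted count is scored against the central 99% binomial
  interval at the site's *expected C-report probability*
  `π = (m(1−e) + (1−m)e/3) / (...)` with `m = p + (1−p)(1−c)`. The raw
  methylome probability p is not the parameter the counts are binomial
  in once conversion failure and error are nonzero (a p = 0 site retains
  C in ~0.5% of reads by chemistry alone), so truth is defined under the
  simulated chemistry. Typical in-interval fractions are ≥ 99.5%.
* **DMR recovery** — 40 TEs of which 30 are designed RdDM loci (CHH
  0.30 → 0.03 in nrpd1), depth 50; sensitivity and false-discovery
  proportion of hypo TE calls at *P* < 0.01 after the > 10% prefilter.
  The 10 null TEs, gene bodies and promoters provide the null tests.
* **siRNA recovery** — four 200k-read libraries over 40 designed
  clusters. Designed windows are derived from the generator's bookkeeping:
  a window's baseline 24-nt reads are split into cluster-derived and other
  reads, the genotype multiplier gives its expected mutant abundance, and
  the window is designed-dependent when the expected fold change crosses
  the classification threshold (windows at a cluster's edge whose signal
  is dominated by background never truly cross 5-fold and are not
  designed positives). Sensitivities run ~0.93–1.0 with no false flags
  among cluster-free windows.

Problem sizes (60-kb / 2×100-kb genomes, depth 50, 200k-read libraries)
were chosen as the smallest scales at which the designed contrasts are
measured with comfortable statistical margin; all are configuration.

## Known limitations

* The aligner holds the genome and all indexes in memory and is exhaustive
  only through the pigeonhole guarantee; it is built for ≤ megabase toy
  genomes, not real plant chromosomes.
* No indels, no paired-end reads, no quality trimming, no duplicate
  marking; regions are annotation-defined (no de novo DMR discovery).
* Fisher tests on pooled counts treat reads as independent observations;
  overlapping reads from the same fragment would violate this on real
  data.
* The ros1 baseline stands in for "wild type"; whether the original
  classification used the true wild type or the ros1 single mutant is
  ambiguous, and the package documents (and uses) the ros1-like baseline.
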