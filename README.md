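# rddmkit

A desk-scale toolkit for the genomics of RNA-directed DNA methylation
(RdDM) — the plant pathway in which Pol IV-derived 24-nt siRNAs guide de
novo cytosine methylation to transposable elements, and Pol V scaffold
transcripts tether the effector complex to chromatin. The package
reimplements, as a tested and reusable library, the analysis used to place
a factor (such as the splicing protein STA1) in this pathway:

* **Bisulfite methylation calling** — reduced-alphabet read alignment
  (≤ 2 mismatches), per-cytosine C/T pileup, and CG/CHG/CHH methylation
  levels `m = ΣC / (ΣC + ΣT)` under a ≥ 5× site-coverage rule, with
  metagene and chromosome-scale profiles.
* **Differential methylation (DMRs)** — two-sided Fisher exact tests on
  pooled region counts over gene bodies, TE bodies and 1-kb strand-aware
  promoters, keeping regions with > 10% methylation in at least one
  genotype and calling hypo/hyper at *P* < 0.01, plus overlap (Venn)
  summaries between mutants.
* **24-nt siRNA window classification** — exact mapping of 18–30-nt
  reads, RPM-normalized 24-nt counts in non-overlapping 500-bp windows,
  and dependence flags: Pol IV-dependent when WT/nrpd1 RPM ≥ 5, Pol V- or
  STA1-dependent (within the Pol IV set) when the respective fold ≥ 2.
* **A synthetic-study generator** — annotated toy genomes with
  pericentromeric TE enrichment, genotype-conditioned methylomes (ros1-like
  baseline; nrpd1/nrpe1/sta1-like losses at designed locus subsets),
  bisulfite reads with configurable conversion-failure and error rates, and
  small-RNA libraries with designed cluster collapses — so the whole
  pipeline is testable against known ground truth without external data.

The intended user is someone studying methylation/siRNA pipelines or
prototyping RdDM analyses who wants every stage transparent, seeded and
verifiable, rather than a production aligner for full-size genomes.

## Worked example

`examples/` holds one short script per capability. Classifying siRNA
windows across the four genotypes (`python examples/sirna_classification.py`):

```
68 Pol IV-dependent windows (>=5-fold loss in nrpd1)
  34 Pol V-dependent (50.0%)
  20 STA1-dependent (29.4%)
  20 depend on both (100.0% of STA1 set)
```

68 of the 500-bp windows lose ≥ 5-fold of their 24-nt siRNA RPM in the
Pol IV mutant; half of those also drop ≥ 2-fold in the Pol V mutant and
about a quarter in *sta1*, with the STA1-dependent set nested inside the
Pol V-dependent one — the dependence structure the generator designed.
Calling DMRs between the baseline and the Pol IV mutant
(`python examples/dmr_calling.py`):

```
20 regions defined, 8 pass the >10% prefilter
  TE_body: 8 tested, 8 hypo, 0 hyper
example call te0001: level 0.44 -> 0.17, P = 7.77e-122
```

Every RdDM-targeted TE body is called hypomethylated while CG-only gene
bodies stay non-significant. The `rddmkit` console script exposes the same
stages as subcommands (`simulate`, `align`, `methylome`, `dmr`, `sirna`,
`report`, `all`); `rddmkit all --outdir out --seed 1` runs the full
synthetic study and writes FASTA/GFF3/FASTQ inputs, CX methylation tables,
DMR BED files, siRNA window TSVs and a JSON summary.

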