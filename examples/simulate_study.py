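"""Generate a miniature RdDM study: genome, methylomes, read libraries.

Builds a 2 x 100 kb genome with pericentromeric TEs, designates which TEs
are RdDM targets (and which of those depend on Pol V / STA1), and prints
the design plus a few simulated reads. The same objects feed every other
example.
"""
import rddmkit as rk

genome = rk.generate_genome(n_chromosomes=2, chrom_length=100_000,
                            te_pericentromeric_fraction=0.8,
                            n_genes=20, n_tes=30, seed=1)
design = rk.designate_rddm_loci(genome, seed=1)

print(f"genome: {len(genome.chromosomes)} chromosomes, "
      f"{len(genome.features)} features")
print(f"RdDM loci: {len(design.rddm_loci)} TEs "
      f"({len(design.polv_subset)} Pol V-dependent, "
      f"{len(design.sta1_subset)} STA1-dependent)")

methylome = rk.build_methylome(genome, "ros1", design=design, seed=1)
reads = rk.simulate_bisulfite_reads(genome, methylome, depth=2.0, seed=1)
print(f"\nbisulfite library (depth 2x): {len(reads)} single-end 50-nt reads")
read = reads.reads[0]
print(f"first read {read.read_id} from {read.chrom}:{read.start + 1}({read.strand})")
print(f"  sequence     {read.sequence}")
print(f"  methylation  {read.meth_states}   (M methylated C, U unmethylated, . other)")

smallrna = rk.simulate_smallrna_reads(genome, "ros1", design=design,
                                      total_reads=20_000, seed=1)
n24 = sum(1 for r in smallrna if len(r.sequence) == 24)
print(f"\nsmall-RNA library: {len(smallrna)} reads, {n24} of 24 nt")
print("Most 24-nt reads come from designated siRNA clusters; their abundance")
print("collapses in the mutant genotypes, which the sirna example classifies.")
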