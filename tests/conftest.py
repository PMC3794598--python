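"""Shared fixtures: a small synthetic study reused across test modules.

The session-scoped study keeps the suite fast: one 50-kb genome with
simulated bisulfite and small-RNA libraries for the genotypes, aligned and
piled up once. Tests that need special inputs build their own tiny genomes
locally.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import rddmkit as rk


def make_genome(length: int = 10_000, seed: int = 0,
                features: list[rk.Feature] | None = None) -> rk.AnnotatedGenome:
    """Random genome of arbitrary length with manually placed features."""
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    return rk.AnnotatedGenome(
        chromosomes={"chr1": seq},
        features=features or [],
        centromere_midpoints={"chr1": length // 2},
    )


@dataclass
class Study:
    genome: rk.AnnotatedGenome
    design: rk.RdDMDesign
    methylomes: dict
    bs_reads: dict
    pileups: dict
    sirna_flags: object  # classified window table (DataFrame)
    sirna_aligned: dict  # genotype -> alignment DataFrame
    sirna_reads: dict


@pytest.fixture(scope="session")
def study() -> Study:
    genome = rk.generate_genome(n_chromosomes=1, chrom_length=50_000,
                                n_genes=6, n_tes=8, seed=11)
    design = rk.designate_rddm_loci(genome, seed=11)
    methylomes, bs_reads, pileups = {}, {}, {}
    aligner = rk.BisulfiteAligner(genome)
    for i, genotype in enumerate(("ros1", "nrpd1", "sta1")):
        methylome = rk.build_methylome(genome, genotype, design=design, seed=11)
        reads = rk.simulate_bisulfite_reads(genome, methylome, depth=20.0,
                                            seed=100 + i)
        alignments = rk.bisulfite_align(reads, genome, aligner=aligner)
        methylomes[genotype] = methylome
        bs_reads[genotype] = reads
        pileups[genotype] = rk.pileup_cytosines(alignments, reads, genome)

    matcher = rk.ExactMatcher(genome)
    counts, totals, sr_aligned, sr_reads = {}, {}, {}, {}
    for i, genotype in enumerate(rk.GENOTYPES):
        reads = rk.simulate_smallrna_reads(genome, genotype, design=design,
                                           total_reads=40_000, seed=200 + i)
        aligned = rk.length_filter_and_map(reads, genome, matcher=matcher)
        totals[genotype] = float(aligned["weight"].sum())
        counts[genotype] = rk.window_counts(aligned, genome)
        sr_aligned[genotype] = aligned
        sr_reads[genotype] = reads
    table = rk.build_window_table(counts, totals, genome)
    flags = rk.classify_dependence(table)
    return Study(genome=genome, design=design, methylomes=methylomes,
                 bs_reads=bs_reads, pileups=pileups, sirna_flags=flags,
                 sirna_aligned=sr_aligned, sirna_reads=sr_reads)
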