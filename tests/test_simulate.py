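"""Generator behaviour: placement, genotype arithmetic, read chemistry."""
from __future__ import annotations

import numpy as np
import pytest

import rddmkit as rk
from rddmkit.simulate import DEFAULT_BASE_RATES


class TestGenerateGenome:
    def test_placement_and_pericentromeric_enrichment(self):
        genome = rk.generate_genome(n_chromosomes=2, chrom_length=100_000,
                                    te_pericentromeric_fraction=0.8,
                                    n_genes=20, n_tes=30, seed=1)
        assert len(genome.features) == 50
        # no overlap within a chromosome
        for chrom in genome.chromosomes:
            ivs = sorted((f.start, f.end) for f in genome.features
                         if f.chrom == chrom)
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))
        # >= 24 of the 30 TEs inside the central 20% around the centromere
        n_peri = 0
        for feat in genome.features_of_kind("TE"):
            mid = genome.centromere_midpoints[feat.chrom]
            half = len(genome.chromosomes[feat.chrom]) // 10
            if feat.start >= mid - half and feat.end <= mid + half:
                n_peri += 1
        assert n_peri >= 24

    def test_deterministic_for_fixed_seed(self):
        a = rk.generate_genome(seed=5)
        b = rk.generate_genome(seed=5)
        assert a.chromosomes == b.chromosomes
        assert a.features == b.features

    def test_impossible_placement_raises(self):
        with pytest.raises(rk.PlacementError):
            rk.generate_genome(chrom_length=100_000, n_tes=10 ** 6, seed=0)

    def test_short_chromosome_rejected(self):
        with pytest.raises(ValueError):
            rk.generate_genome(chrom_length=10_000)

    def test_fasta_gff3_roundtrip(self, tmp_path):
        genome = rk.generate_genome(n_chromosomes=1, chrom_length=50_000,
                                    n_genes=4, n_tes=6, seed=2)
        genome.write_fasta(tmp_path / "g.fa")
        genome.write_gff3(tmp_path / "g.gff3")
        back = rk.AnnotatedGenome.from_files(tmp_path / "g.fa", tmp_path / "g.gff3")
        assert back.chromosomes == genome.chromosomes
        assert back.features == genome.features
        assert back.centromere_midpoints == genome.centromere_midpoints


class TestDesignateRddmLoci:
    def test_subset_structure(self, study):
        design = study.design
        assert design.sta1_subset <= design.rddm_loci
        assert design.polv_subset <= design.rddm_loci

    def test_fractional_designation_leaves_null_tes(self):
        genome = rk.generate_genome(seed=1)
        design = rk.designate_rddm_loci(genome, seed=1, rddm_fraction=0.5)
        te_ids = {f.feature_id for f in genome.features_of_kind("TE")}
        assert len(design.rddm_loci) == 15
        assert design.rddm_loci < te_ids


@pytest.fixture(scope="module")
def genome_and_design():
    genome = rk.generate_genome(n_chromosomes=1, chrom_length=50_000,
                                n_genes=4, n_tes=6, seed=3)
    return genome, rk.designate_rddm_loci(genome, seed=3)


@pytest.fixture(scope="module")
def bs_genome():
    return rk.generate_genome(n_chromosomes=1, chrom_length=50_000,
                              n_genes=4, n_tes=6, seed=4)


class TestBuildMethylome:
    def _chh_prob_at(self, genome, methylome, feature):
        """First plus-strand CHH probability inside the feature."""
        from rddmkit.methylation import context_arrays
        ctx_plus, _ = context_arrays(genome)[feature.chrom]
        arr = methylome.prob[feature.chrom]["+"]
        sites = np.flatnonzero(ctx_plus[feature.start:feature.end] == 3)
        return arr[feature.start + sites[0]]

    def test_baseline_carries_full_te_rates(self, genome_and_design):
        genome, design = genome_and_design
        m = rk.build_methylome(genome, "ros1", design=design)
        te = genome.feature_map[sorted(design.rddm_loci)[0]]
        assert self._chh_prob_at(genome, m, te) == pytest.approx(0.30)

    def test_nrpd1_multiplies_non_cg_down(self, genome_and_design):
        genome, design = genome_and_design
        m = rk.build_methylome(genome, "nrpd1", design=design)
        te = genome.feature_map[sorted(design.rddm_loci)[0]]
        assert self._chh_prob_at(genome, m, te) == pytest.approx(0.03)

    def test_sta1_spares_loci_outside_its_subset(self, genome_and_design):
        genome, design = genome_and_design
        ros1 = rk.build_methylome(genome, "ros1", design=design)
        sta1 = rk.build_methylome(genome, "sta1", design=design)
        spared = sorted(design.rddm_loci - design.sta1_subset)[0]
        feat = genome.feature_map[spared]
        np.testing.assert_array_equal(
            ros1.prob[feat.chrom]["+"][feat.start:feat.end],
            sta1.prob[feat.chrom]["+"][feat.start:feat.end])
        if design.sta1_subset:
            hit = genome.feature_map[sorted(design.sta1_subset)[0]]
            assert self._chh_prob_at(genome, sta1, hit) == pytest.approx(0.30 * 0.4)

    def test_gene_bodies_cg_only(self, genome_and_design):
        genome, design = genome_and_design
        from rddmkit.methylation import context_arrays
        m = rk.build_methylome(genome, "ros1", design=design)
        gene = genome.features_of_kind("gene")[0]
        ctx_plus, _ = context_arrays(genome)[gene.chrom]
        arr = m.prob[gene.chrom]["+"][gene.start:gene.end]
        carr = ctx_plus[gene.start:gene.end]
        assert np.all(arr[carr == 1] == DEFAULT_BASE_RATES["gene"]["CG"])
        assert np.all(arr[(carr == 2) | (carr == 3)] == 0.0)

    def test_cg_strand_symmetry(self, genome_and_design):
        genome, design = genome_and_design
        m = rk.build_methylome(genome, "nrpd1", design=design)
        seq = genome.chromosomes["chr1"]
        cpg = [i for i in range(len(seq) - 1) if seq[i:i + 2] == "CG"]
        plus = m.prob["chr1"]["+"]
        minus = m.prob["chr1"]["-"]
        assert all(plus[i] == minus[i + 1] for i in cpg)

    def test_unknown_genotype_raises(self, genome_and_design):
        genome, design = genome_and_design
        with pytest.raises(ValueError, match="genotype"):
            rk.build_methylome(genome, "ddm1", design=design)


class TestSimulateBisulfiteReads:
    def _flat_methylome(self, genome, rate):
        rates = {cls: {c: rate for c in rk.CONTEXTS}
                 for cls in ("TE", "gene", "background")}
        return rk.build_methylome(genome, "ros1", base_rates=rates)

    def test_all_unmethylated_full_conversion_leaves_no_c(self, bs_genome):
        methylome = self._flat_methylome(bs_genome, 0.0)
        reads = rk.simulate_bisulfite_reads(bs_genome, methylome, depth=0.5,
                                            conversion_rate=1.0, error_rate=0.0,
                                            seed=1)
        for read in reads:
            assert "C" not in read.sequence

    def test_all_methylated_reads_match_reference(self, bs_genome):
        from rddmkit._seq import revcomp
        methylome = self._flat_methylome(bs_genome, 1.0)
        reads = rk.simulate_bisulfite_reads(bs_genome, methylome, depth=0.5,
                                            error_rate=0.0, seed=1)
        for read in reads:
            ref = bs_genome.chromosomes[read.chrom][read.start:read.start + 50]
            expected = ref if read.strand == "+" else revcomp(ref)
            assert read.sequence == expected

    def test_read_count_poisson(self, bs_genome):
        methylome = self._flat_methylome(bs_genome, 0.0)
        reads = rk.simulate_bisulfite_reads(bs_genome, methylome, depth=10.0,
                                            read_length=50, seed=2)
        expectation = 10.0 * 50_000 / 50
        assert abs(len(reads) - expectation) <= 3 * np.sqrt(expectation)

    def test_truth_bookkeeping_matches_sequences(self, bs_genome):
        methylome = self._flat_methylome(bs_genome, 0.5)
        reads = rk.simulate_bisulfite_reads(bs_genome, methylome, depth=0.3,
                                            error_rate=0.0, seed=3)
        for read in list(reads)[:50]:
            for base, state in zip(read.sequence, read.meth_states):
                if state == "M":
                    assert base == "C"
                # unmethylated: C (conversion failure) or T

    def test_parameter_validation(self, bs_genome):
        methylome = self._flat_methylome(bs_genome, 0.0)
        with pytest.raises(ValueError):
            rk.simulate_bisulfite_reads(bs_genome, methylome, conversion_rate=0.8)
        with pytest.raises(ValueError):
            rk.simulate_bisulfite_reads(bs_genome, methylome, depth=0)
        with pytest.raises(ValueError):
            rk.simulate_bisulfite_reads(bs_genome, methylome, read_length=60_000)

    def test_deterministic(self, bs_genome):
        methylome = self._flat_methylome(bs_genome, 0.3)
        a = rk.simulate_bisulfite_reads(bs_genome, methylome, depth=1.0, seed=9)
        b = rk.simulate_bisulfite_reads(bs_genome, methylome, depth=1.0, seed=9)
        assert [r.sequence for r in a] == [r.sequence for r in b]


class TestSimulateSmallRNA:
    def test_cluster_poisson_scaling(self, study):
        cluster = sorted(study.design.rddm_loci)[0]
        reads = rk.simulate_smallrna_reads(
            study.genome, "nrpd1", design=study.design,
            cluster_abundance={cluster: 1000.0}, total_reads=5000, seed=7)
        observed = sum(1 for r in reads if r.source == cluster)
        assert abs(observed - 100) <= 3 * np.sqrt(100)

    def test_mirna_counts_genotype_independent(self, study):
        per_genotype = {}
        for genotype in ("ros1", "nrpd1"):
            reads = study.sirna_reads[genotype]
            per_genotype[genotype] = sum(
                1 for r in reads if r.source and r.source.startswith("miRNA"))
        expectation = 0.05 * 40_000
        for count in per_genotype.values():
            assert abs(count - expectation) <= 4 * np.sqrt(expectation)

    def test_reads_are_exact_genome_substrings(self, study):
        from rddmkit._seq import revcomp
        for read in list(study.sirna_reads["ros1"])[:200]:
            ref = study.genome.chromosomes[read.chrom][
                read.start:read.start + len(read.sequence)]
            expected = ref if read.strand == "+" else revcomp(ref)
            assert read.sequence == expected
            assert 18 <= len(read.sequence) <= 30

    def test_designed_class_separation(self, study):
        """Generator bookkeeping: >=5-fold collapse in nrpd1, >=2-fold in sta1."""
        def cluster_counts(genotype):
            counts = {}
            for read in study.sirna_reads[genotype]:
                if read.source in study.design.rddm_loci:
                    counts[read.source] = counts.get(read.source, 0) + 1
            return counts

        ros1 = cluster_counts("ros1")
        nrpd1 = cluster_counts("nrpd1")
        sta1 = cluster_counts("sta1")
        for cid, n_ros1 in ros1.items():
            assert n_ros1 / max(nrpd1.get(cid, 0), 1) >= 5
        for cid in study.design.sta1_subset:
            assert ros1[cid] / max(sta1.get(cid, 0), 1) >= 2

    def test_error_cases(self, study):
        with pytest.raises(ValueError):
            rk.simulate_smallrna_reads(study.genome, "ros1",
                                       design=study.design, total_reads=0)
        with pytest.raises(ValueError):
            rk.simulate_smallrna_reads(
                study.genome, "ros1", design=study.design,
                cluster_abundance={"no_such_te": 10.0}, total_reads=100)
        with pytest.raises(ValueError):
            rk.simulate_smallrna_reads(study.genome, "bogus",
                                       design=study.design, total_reads=100)
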