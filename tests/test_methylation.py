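"""Context assignment, coverage rule, region pooling, profiles."""
from __future__ import annotations

import numpy as np
import pytest

import rddmkit as rk
from rddmkit import _seq
from rddmkit.methylation import (CytosinePileup, CytosineRecord, assign_context,
                                 chromosome_methylation_profile,
                                 clone_bisulfite_summary, context_arrays,
                                 metagene_profile, region_methylation,
                                 site_methylation)

from conftest import make_genome


def genome_from(seq: str, features=None) -> rk.AnnotatedGenome:
    return rk.AnnotatedGenome(chromosomes={"chr1": seq}, features=features or [],
                              centromere_midpoints={"chr1": len(seq) // 2})


def _oracle_context(seq: str, pos: int, strand: str) -> str:
    """Independent context call via explicit reverse complement."""
    if strand == "-":
        rc = _seq.revcomp(seq)
        pos = len(seq) - 1 - pos
        seq = rc
    window = seq[pos + 1:pos + 3]
    if window[:1] == "G":
        return "CG"
    if window[1:2] == "G":
        return "CHG"
    return "CHH"


class TestAssignContext:
    def test_plus_strand_definitions(self):
        genome = genome_from("TTCGTTCAGTTCTTT")
        assert assign_context(genome, "chr1", 2, "+") == "CG"
        assert assign_context(genome, "chr1", 6, "+") == "CHG"
        assert assign_context(genome, "chr1", 11, "+") == "CHH"

    def test_minus_strand_ctg_is_chg(self):
        # reference CTG: the G at index 2 is a minus-strand cytosine whose
        # own strand reads CAG -> CHG
        genome = genome_from("ACTGAA")
        assert assign_context(genome, "chr1", 3, "-") == "CHG"

    def test_chromosome_end_truncation_falls_to_chh(self):
        genome = genome_from("AAAC")  # C at the last position
        assert assign_context(genome, "chr1", 3, "+") == "CHH"
        genome2 = genome_from("AAACG")  # next base visible: CG
        assert assign_context(genome2, "chr1", 3, "+") == "CG"

    def test_non_cytosine_raises(self):
        genome = genome_from("ACGT")
        with pytest.raises(ValueError):
            assign_context(genome, "chr1", 0, "+")
        with pytest.raises(ValueError):
            assign_context(genome, "chr1", 1, "-")

    def test_matches_reverse_complement_oracle_everywhere(self):
        genome = make_genome(2000, seed=9)
        seq = genome.chromosomes["chr1"]
        for pos, base in enumerate(seq):
            if base == "C":
                assert assign_context(genome, "chr1", pos, "+") == \
                    _oracle_context(seq, pos, "+")
            if base == "G":
                assert assign_context(genome, "chr1", pos, "-") == \
                    _oracle_context(seq, pos, "-")

    def test_context_arrays_agree_with_pointwise(self):
        genome = make_genome(2000, seed=10)
        ctx_plus, ctx_minus = context_arrays(genome)["chr1"]
        seq = genome.chromosomes["chr1"]
        for pos, base in enumerate(seq):
            if base == "C":
                assert rk.CONTEXTS[ctx_plus[pos] - 1] == \
                    assign_context(genome, "chr1", pos, "+")
            else:
                assert ctx_plus[pos] == 0
            if base == "G":
                assert rk.CONTEXTS[ctx_minus[pos] - 1] == \
                    assign_context(genome, "chr1", pos, "-")
            else:
                assert ctx_minus[pos] == 0

    def test_context_partition_counts(self):
        """CG + CHG + CHH site counts equal total cytosines on both strands."""
        genome = make_genome(5000, seed=11)
        ctx_plus, ctx_minus = context_arrays(genome)["chr1"]
        seq = genome.chromosomes["chr1"]
        assert (ctx_plus > 0).sum() == seq.count("C")
        assert (ctx_minus > 0).sum() == seq.count("G")


class TestSiteMethylation:
    @pytest.mark.parametrize("counts,expected", [
        ((5, 5), 0.5),
        ((2, 2), None),   # below the 5x coverage rule
        ((0, 7), 0.0),
        ((4, 0), None),
        ((5, 0), 1.0),
    ])
    def test_coverage_rule(self, counts, expected):
        assert site_methylation(counts) == expected

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            site_methylation((-1, 3))

    def test_accepts_record(self):
        rec = CytosineRecord("chr1", 0, "+", "CG", 6, 2)
        assert site_methylation(rec) == pytest.approx(0.75)


class TestRegionMethylation:
    def _pileup_with(self, genome, sites):
        records = [CytosineRecord("chr1", pos, strand,
                                  assign_context(genome, "chr1", pos, strand),
                                  unc, conv)
                   for pos, strand, unc, conv in sites]
        return CytosinePileup.from_records(records, genome)

    def test_pooled_counts(self):
        genome = make_genome(1000, seed=1)
        seq = genome.chromosomes["chr1"]
        c_pos = [i for i, b in enumerate(seq) if b == "C"][:2]
        pileup = self._pileup_with(genome, [(c_pos[0], "+", 5, 5),
                                            (c_pos[1], "+", 10, 0)])
        rm = region_methylation(pileup, ("chr1", 0, 1000))
        assert rm.level(None) == pytest.approx(15 / 20)

    def test_all_below_coverage_is_undefined(self):
        genome = make_genome(1000, seed=1)
        c_pos = [i for i, b in enumerate(genome.chromosomes["chr1"]) if b == "C"]
        pileup = self._pileup_with(genome, [(c_pos[0], "+", 2, 1)])
        rm = region_methylation(pileup, ("chr1", 0, 1000))
        assert rm.level(None) is None
        assert sum(rm.n_sites_covered.values()) == 0

    def test_pooling_equals_weighted_mean_of_site_levels(self, study):
        """Region level == coverage-weighted mean of covered site levels."""
        pileup = study.pileups["ros1"]
        rm = region_methylation(pileup, ("chr1", 0, 10_000))
        ctx_plus, ctx_minus = context_arrays(study.genome)["chr1"]
        num = den = 0.0
        for strand, carr in (("+", ctx_plus), ("-", ctx_minus)):
            unc, conv = pileup.counts["chr1"][strand]
            for pos in np.flatnonzero(carr[:10_000] > 0):
                cov = unc[pos] + conv[pos]
                if cov >= 5:
                    num += (unc[pos] / cov) * cov
                    den += cov
        assert rm.level(None) == pytest.approx(num / den, abs=1e-12)

    def test_malformed_interval_raises(self, study):
        with pytest.raises(ValueError):
            region_methylation(study.pileups["ros1"], ("chr1", 500, 100))


class TestMetagene:
    def _uniform_pileup(self, genome, level_c=4, level_t=1):
        ctx_plus, ctx_minus = context_arrays(genome)["chr1"]
        records = []
        for strand, carr in (("+", ctx_plus), ("-", ctx_minus)):
            for pos in np.flatnonzero(carr > 0):
                records.append(CytosineRecord("chr1", int(pos), strand,
                                              rk.CONTEXTS[carr[pos] - 1],
                                              level_c, level_t))
        return CytosinePileup.from_records(records, genome)

    def test_uniform_sites_give_flat_body(self):
        feat = rk.Feature("f1", "chr1", 2000, 3000, "+", "gene")
        genome = make_genome(6000, seed=3, features=[feat])
        pileup = self._uniform_pileup(genome)  # every site 4/5 = 0.8
        profile = metagene_profile(pileup, [feat])
        body = profile.levels[:, 10:30]
        assert np.allclose(body[~np.isnan(body)], 0.8)

    def test_strand_reversal_mirrors_bins(self, study):
        pileup = study.pileups["ros1"]
        feat = study.genome.features_of_kind("TE")[0]
        flipped = rk.Feature(feat.feature_id, feat.chrom, feat.start, feat.end,
                             "-" if feat.strand == "+" else "+", feat.kind)
        fwd = metagene_profile(pileup, [feat]).levels
        rev = metagene_profile(pileup, [flipped]).levels
        np.testing.assert_array_almost_equal(fwd, rev[:, ::-1])

    def test_te_chh_exceeds_gene_chh_in_baseline(self, study):
        """The designed TE/gene contrast shows up in the metagene bodies."""
        pileup = study.pileups["ros1"]
        tes = study.genome.features_of_kind("TE")
        genes = study.genome.features_of_kind("gene")
        te_prof = metagene_profile(pileup, tes)
        gene_prof = metagene_profile(pileup, genes)
        chh = rk.CONTEXTS.index("CHH")
        te_body = np.nanmean(te_prof.levels[chh, 10:30])
        gene_body = np.nanmean(gene_prof.levels[chh, 10:30])
        assert te_body > gene_body + 0.1

    def test_requires_single_kind(self, study):
        feats = [study.genome.features_of_kind("TE")[0],
                 study.genome.features_of_kind("gene")[0]]
        with pytest.raises(ValueError, match="kind"):
            metagene_profile(study.pileups["ros1"], feats)
        with pytest.raises(ValueError):
            metagene_profile(study.pileups["ros1"], [])


class TestCloneSummary:
    def test_fully_methylated_clones(self):
        ref = "ACGTCAGTCTTA"  # CG, CHG and CHH sites present
        clones = [ref] * 15
        result = clone_bisulfite_summary(clones, ref)
        assert set(result) == {"CG", "CHG", "CHH"}
        assert all(v == 100.0 for v in result.values())

    def test_few_clones_warn_but_compute(self):
        ref = "ACGT"
        with pytest.warns(UserWarning, match="clones"):
            result = clone_bisulfite_summary([ref] * 10, ref)
        assert result["CG"] == 100.0

    def test_half_methylated_cg(self):
        ref = "ACGAACGAACGAACGA"  # 4 CG sites
        meth = ref
        unmeth = ref.replace("C", "T")
        result = clone_bisulfite_summary([meth] * 15 + [unmeth] * 15, ref,
                                         min_clones=15)
        assert result["CG"] == pytest.approx(50.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            clone_bisulfite_summary(["ACG"], "ACGT", min_clones=1)


class TestChromosomeProfile:
    def test_window_without_coverage_is_nan(self, study):
        pileup = CytosinePileup(study.genome)  # empty
        df = chromosome_methylation_profile(pileup, 10_000)
        assert df["CHH"].isna().all()

    def test_trailing_partial_window_kept(self, study):
        df = chromosome_methylation_profile(study.pileups["ros1"], 15_000)
        assert df.iloc[-1]["end"] == 50_000
        assert df.iloc[-1]["end"] - df.iloc[-1]["start"] == 5_000

    def test_pericentromeric_chh_exceeds_arms(self, study):
        """TE-dense centre of the toy chromosome is CHH-hot in the baseline."""
        df = chromosome_methylation_profile(study.pileups["ros1"], 5_000)
        mid = study.genome.centromere_midpoints["chr1"]
        centre = df[(df["start"] >= mid - 10_000) & (df["end"] <= mid + 10_000)]
        arms = df[(df["end"] <= 10_000) | (df["start"] >= 40_000)]
        assert centre["CHH"].mean() > arms["CHH"].mean()

    def test_bad_window_raises(self, study):
        with pytest.raises(ValueError):
            chromosome_methylation_profile(study.pileups["ros1"], 0)


class TestIO:
    def test_cx_tsv_roundtrip(self, tmp_path, study):
        pileup = study.pileups["ros1"]
        path = tmp_path / "m.cx.tsv"
        pileup.write_cx_tsv(path, covered_only=True)
        back = CytosinePileup.read_cx_tsv(path, study.genome)
        for strand in ("+", "-"):
            np.testing.assert_array_equal(pileup.counts["chr1"][strand][0],
                                          back.counts["chr1"][strand][0])
            np.testing.assert_array_equal(pileup.counts["chr1"][strand][1],
                                          back.counts["chr1"][strand][1])

    def test_bedgraph_levels(self, tmp_path, study):
        path = tmp_path / "chh.bedGraph"
        study.pileups["ros1"].write_bedgraph(path, "CHH")
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert lines
        chrom, start, end, value = lines[0].split("\t")
        assert int(end) == int(start) + 1
        assert 0.0 <= float(value) <= 1.0
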