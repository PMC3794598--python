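"""Self-validation experiments: oracle comparisons and parameter recovery.

Each experiment builds its inputs from scratch with the supplied seed,
runs the regular pipeline code on them, and measures how well known ground
truth is recovered. The reference computations are deliberately
independent of the implementation they check: the Fisher oracle
enumerates hypergeometric tables with exact integer binomials, and the
mapping oracle is the brute-force full-positional scan.
"""
from __future__ import annotations

from math import comb

import numpy as np
from scipy.stats import binom

from . import dmr as dmr_mod
from . import mapping, methylation, simulate, sirna


# --------------------------------------------------------------------------
# Fisher exact test vs exact enumeration
# --------------------------------------------------------------------------

def fisher_enumeration_oracle(total: int, row1: int, col1: int) -> np.ndarray:
    """Two-sided p for every table with the given margins, by brute force.

    Probabilities come from exact integer binomial coefficients; the
    point-mass sum uses the same 1e-7 relative tie slack as the
    implementation under test.
    """
    lo, hi = max(0, row1 + col1 - total), min(row1, col1)
    denom = comb(total, col1)
    pmf = [comb(row1, a) * comb(total - row1, col1 - a) / denom
           for a in range(lo, hi + 1)]
    pvals = [sum(p for p in pmf if p <= p_obs * (1 + 1e-7)) for p_obs in pmf]
    return np.minimum(np.array(pvals), 1.0)


def fisher_oracle_experiment(max_total: int = 60) -> dict:
    """Compare the pipeline Fisher p with enumeration over every 2x2 table
    whose grand total is at most ``max_total``. Degenerate margins admit a
    single table, where both sides give p = 1 by definition."""
    max_dev = 0.0
    n_tables = 0
    for total in range(1, max_total + 1):
        for row1 in range(1, total):
            for col1 in range(1, total):
                ks, impl = dmr_mod._two_sided_pvalues(total, row1, col1)
                oracle = fisher_enumeration_oracle(total, row1, col1)
                max_dev = max(max_dev, float(np.max(np.abs(impl - oracle))))
                n_tables += len(ks)
    # spot-join the scalar API onto the batched path it uses
    for (a, b, c, d) in ((20, 80, 5, 95), (3, 7, 9, 1), (0, 12, 12, 0)):
        ks, batch = dmr_mod._two_sided_pvalues(a + b + c + d, a + b, a + c)
        scalar = dmr_mod.fisher_exact_2x2(a, b, c, d)
        max_dev = max(max_dev, abs(scalar - float(batch[a - ks[0]])))
    return {"max_abs_dev": max_dev, "n_tables": n_tables}


# --------------------------------------------------------------------------
# mapping oracle
# --------------------------------------------------------------------------

def _small_genome(length: int, seed: int) -> simulate.AnnotatedGenome:
    """Random genome below the generator's minimum size, with fixed features."""
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    third = length // 5
    features = [
        simulate.Feature("te0001", "chr1", third, third + 800, "+", "TE"),
        simulate.Feature("te0002", "chr1", 3 * third, 3 * third + 800, "-", "TE"),
        simulate.Feature("gene0001", "chr1", 2 * third, 2 * third + 1000, "+", "gene"),
    ]
    return simulate.AnnotatedGenome(chromosomes={"chr1": seq}, features=features,
                                    centromere_midpoints={"chr1": length // 2})


def mapping_oracle_experiment(seed: int, genome_length: int = 10_000,
                              n_reads: int = 1000) -> dict:
    """Indexed aligner vs brute-force scan on simulated bisulfite reads.

    Agreement is the fraction of alignment records (read, locus, strand,
    mismatches, uniqueness) shared between the two outputs.
    """
    genome = _small_genome(genome_length, seed)
    methylome = simulate.build_methylome(genome, "ros1", seed=seed)
    depth = n_reads * 50 / genome_length
    reads = simulate.simulate_bisulfite_reads(genome, methylome, depth=depth,
                                              error_rate=0.001, seed=seed)
    fast = mapping.bisulfite_align(reads, genome)
    slow = mapping.bisulfite_align_bruteforce(reads, genome)
    key = lambda a: (a.read_index, a.chrom, a.start, a.strand,
                     a.mismatch_count, a.unique)
    fast_set, slow_set = set(map(key, fast)), set(map(key, slow))
    agreement = len(fast_set & slow_set) / max(len(fast_set | slow_set), 1)
    return {"agreement": agreement, "n_reads": len(reads),
            "n_alignments": len(slow)}


# --------------------------------------------------------------------------
# methylation level recovery
# --------------------------------------------------------------------------

def expected_c_report_probability(p: np.ndarray, conversion_rate: float,
                                  error_rate: float) -> np.ndarray:
    """P(a covering read reports C | it reports C or T) for true level p.

    The pre-error probability of retaining C is m = p + (1-p)(1-c); a
    substitution error then moves a base to each other base with
    probability e/3.
    """
    m = p + (1.0 - p) * (1.0 - conversion_rate)
    p_c = m * (1.0 - error_rate) + (1.0 - m) * (error_rate / 3.0)
    p_t = m * (error_rate / 3.0) + (1.0 - m) * (1.0 - error_rate)
    return p_c / (p_c + p_t)


def methylation_recovery_experiment(seed: int, depth: float = 50.0,
                                    conversion_rate: float = 0.995,
                                    error_rate: float = 0.001,
                                    chrom_length: int = 60_000) -> dict:
    """Simulate, map and call methylation; score sites against binomial CIs.

    For every cytosine with >= 5x coverage the unconverted count is checked
    against the central 99% binomial interval at the site's expected
    C-report probability under the simulated chemistry. Reported is the
    fraction of sites inside their interval.
    """
    genome = simulate.generate_genome(n_chromosomes=1, chrom_length=chrom_length,
                                      n_genes=6, n_tes=8, seed=seed)
    design = simulate.designate_rddm_loci(genome, seed=seed)
    methylome = simulate.build_methylome(genome, "ros1", design=design, seed=seed)
    reads = simulate.simulate_bisulfite_reads(
        genome, methylome, depth=depth, conversion_rate=conversion_rate,
        error_rate=error_rate, seed=seed)
    alignments = mapping.bisulfite_align(reads, genome)
    pileup = mapping.pileup_cytosines(alignments, reads, genome)

    n_sites = n_inside = 0
    for chrom in genome.chromosomes:
        for strand in ("+", "-"):
            unc, conv = pileup.counts[chrom][strand]
            cov = unc + conv
            sites = np.flatnonzero(cov >= 5)
            truth = methylome.prob[chrom][strand][sites]
            pi = expected_c_report_probability(truth, conversion_rate, error_rate)
            lo, hi = binom.interval(0.99, cov[sites], pi)
            inside = (unc[sites] >= lo) & (unc[sites] <= hi)
            n_sites += len(sites)
            n_inside += int(inside.sum())
    return {"fraction_in_ci": n_inside / max(n_sites, 1), "n_sites": n_sites}


# --------------------------------------------------------------------------
# DMR recovery
# --------------------------------------------------------------------------

def dmr_recovery_experiment(seed: int, depth: float = 50.0, n_tes: int = 40,
                            rddm_fraction: float = 0.75,
                            alpha: float = 0.01) -> dict:
    """Designed hypo-TEs (CHH 0.30 -> 0.03 in nrpd1) vs DMR calls.

    Sensitivity is the fraction of designed RdDM TEs called hypomethylated;
    the false-discovery proportion is measured over hypo TE-body calls,
    with non-designed TEs (and all other regions) serving as nulls.
    """
    genome = simulate.generate_genome(n_tes=n_tes, seed=seed)
    design = simulate.designate_rddm_loci(genome, seed=seed,
                                          rddm_fraction=rddm_fraction)
    aligner = mapping.BisulfiteAligner(genome)
    regions = dmr_mod.define_regions(genome)
    region_meth = {}
    for gi, genotype in enumerate(("ros1", "nrpd1")):
        methylome = simulate.build_methylome(genome, genotype, design=design,
                                             seed=seed)
        reads = simulate.simulate_bisulfite_reads(genome, methylome,
                                                  depth=depth,
                                                  seed=seed * 2 + gi + 1)
        alignments = mapping.bisulfite_align(reads, genome, aligner=aligner)
        pileup = mapping.pileup_cytosines(alignments, reads, genome)
        region_meth[genotype] = {
            r.region_id: methylation.region_methylation(
                pileup, r.interval, region_id=r.region_id)
            for r in regions
        }
    retained = dmr_mod.prefilter_regions(regions, region_meth)
    calls = dmr_mod.call_dmrs(retained, region_meth, "ros1", "nrpd1", alpha=alpha)
    hypo_tes = {c.region_id for c in calls
                if c.region_class == "TE_body" and c.direction == "hypo"}
    designed = design.rddm_loci
    sensitivity = len(hypo_tes & designed) / len(designed)
    fdp = len(hypo_tes - designed) / max(len(hypo_tes), 1)
    return {"sensitivity": sensitivity, "fdp": fdp,
            "n_designed": len(designed), "n_hypo_calls": len(hypo_tes),
            "n_tested": len(retained)}


# --------------------------------------------------------------------------
# siRNA classification recovery
# --------------------------------------------------------------------------

def _five_prime_window(read: simulate.SimRead, window_bp: int) -> str:
    five = read.start if read.strand == "+" else read.start + len(read.sequence) - 1
    return f"{read.chrom}:{(five // window_bp) * window_bp}"


def sirna_recovery_experiment(seed: int, total_reads: int = 200_000,
                              n_tes: int = 40, window_bp: int = 500,
                              min_wt_raw: float = 10.0,
                              polIV_fold: float = 5.0,
                              downstream_fold: float = 2.0) -> dict:
    """Designed siRNA clusters vs window dependence flags.

    The designed window sets come from the generator's own bookkeeping:
    for each window the baseline library's 24-nt reads are split into
    cluster-derived and other reads, and the genotype multipliers give the
    window's expected mutant abundance. A window is designed Pol IV-
    (STA1-) dependent when its expected fold change crosses the
    classification threshold and it clears the expression floor. False
    flags are counted over windows with no cluster-derived read at all.
    """
    genome = simulate.generate_genome(n_tes=n_tes, seed=seed)
    design = simulate.designate_rddm_loci(genome, seed=seed)
    loss = simulate.DEFAULT_SIRNA_FOLD_LOSS
    matcher = sirna.ExactMatcher(genome)
    counts, totals = {}, {}
    # per-window 24-nt composition of the baseline library by source class
    comp: dict[str, dict[str, float]] = {}
    for gi, genotype in enumerate(simulate.GENOTYPES):
        reads = simulate.simulate_smallrna_reads(genome, genotype, design=design,
                                                 total_reads=total_reads,
                                                 seed=seed * 4 + gi + 1)
        if genotype == "ros1":
            for read in reads:
                if len(read.sequence) != 24:
                    continue
                win = _five_prime_window(read, window_bp)
                entry = comp.setdefault(win, {"cluster": 0, "sta1": 0,
                                              "polv": 0, "other": 0})
                if read.source in design.rddm_loci:
                    entry["cluster"] += 1
                    if read.source in design.sta1_subset:
                        entry["sta1"] += 1
                    if read.source in design.polv_subset:
                        entry["polv"] += 1
                else:
                    entry["other"] += 1
        aligned = sirna.length_filter_and_map(reads, genome, matcher=matcher)
        totals[genotype] = float(aligned["weight"].sum())
        counts[genotype] = sirna.window_counts(aligned, genome, window_bp)
    table = sirna.build_window_table(counts, totals, genome, window_bp)
    flags = sirna.classify_dependence(table, polIV_fold=polIV_fold,
                                      downstream_fold=downstream_fold,
                                      min_wt_raw=min_wt_raw)
    flags = flags.set_index("window_id")

    designed_poliv, designed_sta1 = set(), set()
    nrpd1_mult = loss["nrpd1"]["rddm"]
    sta1_mult = loss["sta1"]["sta1"]
    for win, entry in comp.items():
        wt = entry["cluster"] + entry["other"]
        if wt < min_wt_raw or entry["cluster"] == 0:
            continue
        expected_nrpd1 = nrpd1_mult * entry["cluster"] + entry["other"]
        if wt / max(expected_nrpd1, 1e-12) >= polIV_fold:
            designed_poliv.add(win)
            expected_sta1 = (sta1_mult * entry["sta1"]
                             + (entry["cluster"] - entry["sta1"])
                             + entry["other"])
            if wt / max(expected_sta1, 1e-12) >= downstream_fold:
                designed_sta1.add(win)
    poliv_flagged = set(flags.index[flags["polIV_dependent"]])
    sta1_flagged = set(flags.index[flags["sta1_dependent"]])
    with_cluster_reads = {w for w, e in comp.items() if e["cluster"] > 0}
    unaffected = set(flags.index) - with_cluster_reads
    false_flags = len(poliv_flagged & unaffected)
    return {
        "poliv_sensitivity": len(poliv_flagged & designed_poliv)
        / max(len(designed_poliv), 1),
        "sta1_sensitivity": len(sta1_flagged & designed_sta1)
        / max(len(designed_sta1), 1),
        "false_flag_rate": false_flags / max(len(unaffected), 1),
        "sta1_subset_of_poliv": bool((~flags["sta1_dependent"]
                                      | flags["polIV_dependent"]).all()),
        "n_designed_poliv": len(designed_poliv),
        "n_designed_sta1": len(designed_sta1),
        "n_windows": len(flags),
    }


# --------------------------------------------------------------------------
# coverage rule
# --------------------------------------------------------------------------

def coverage_rule_check(min_coverage: int = 5) -> dict:
    """Exhaustive check of the coverage rule boundary.

    Every (C, T) split with C + T = min_coverage - 1 must be undefined and
    every split with C + T = min_coverage must yield a level.
    """
    violations = 0
    n_checked = 0
    for c in range(min_coverage):
        t = (min_coverage - 1) - c
        if methylation.site_methylation((c, t), min_coverage) is not None:
            violations += 1
        n_checked += 1
    for c in range(min_coverage + 1):
        t = min_coverage - c
        level = methylation.site_methylation((c, t), min_coverage)
        if level is None or not np.isclose(level, c / min_coverage):
            violations += 1
        n_checked += 1
    return {"violations": violations, "n_checked": n_checked}
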