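"""End-to-end pipeline: simulate -> align -> call -> classify -> report.

``run_pipeline`` drives every stage on a synthetic study and writes
machine-readable artifacts (FASTA/GFF3/FASTQ inputs, CX methylation
tables, DMR BED, siRNA window TSVs, a JSON summary). Every output file
states its coordinate convention in a header comment; re-running with the
same config reproduces identical files.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

from . import dmr as dmr_mod
from . import mapping, methylation, simulate, sirna

logger = logging.getLogger(__name__)


def ratio_report(numerator: int, denominator: int, mode: str = "one_decimal") -> str:
    """Render a count ratio as the percentage string a report would print.

    ``one_decimal`` (region ratios): 2443/5283 -> "46.2%".
    ``integer`` (cell-count ratios): 101/111 -> "91%".
    Rounding is half away from zero in both modes.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    if mode == "one_decimal":
        return f"{pct.quantize(Decimal('0.1'), rounding=ROUND_HALF_UP)}%"
    if mode == "integer":
        return f"{pct.quantize(Decimal('1'), rounding=ROUND_HALF_UP)}%"
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class PipelineConfig:
    """All knobs of the synthetic end-to-end run.

    Threshold defaults are the analysis constants: 5x site coverage, two
    alignment mismatches, Fisher P < 0.01 with a >10% prefilter, 500-bp
    siRNA windows with 5-fold (Pol IV) and 2-fold (downstream) cuts, 1-kb
    promoters and flanks.
    """

    # genome simulation
    n_chromosomes: int = 2
    chrom_length: int = 100_000
    n_genes: int = 20
    n_tes: int = 30
    te_pericentromeric_fraction: float = 0.8
    genotypes: tuple[str, ...] = ("ros1", "nrpd1", "nrpe1", "sta1")
    # bisulfite simulation
    depth: float = 20.0
    read_length: int = 50
    conversion_rate: float = 0.995
    error_rate: float = 0.001
    # small RNA simulation
    sirna_total_reads: int = 100_000
    # thresholds
    min_coverage: int = 5
    max_mismatches: int = 2
    dmr_alpha: float = 0.01
    prefilter_level: float = 0.10
    window_bp: int = 500
    superwindow_bp: int = 10_000
    polIV_fold: float = 5.0
    downstream_fold: float = 2.0
    min_wt_raw: float = 10.0
    promoter_bp: int = 1000
    flank_bp: int = 1000
    # run control
    seed: int = 0
    outdir: str = "rddmkit_out"
    write_fastq: bool = True

    def validate(self) -> None:
        positive = ["chrom_length", "depth", "read_length", "min_coverage",
                    "window_bp", "superwindow_bp", "polIV_fold",
                    "downstream_fold", "promoter_bp", "flank_bp",
                    "sirna_total_reads"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.dmr_alpha < 1:
            raise ValueError("dmr_alpha must be in (0, 1)")
        if not 0 <= self.prefilter_level < 1:
            raise ValueError("prefilter_level must be in [0, 1)")
        if "ros1" not in self.genotypes:
            raise ValueError("the ros1 baseline genotype is required")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        payload["genotypes"] = list(self.genotypes)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        payload["genotypes"] = tuple(payload.get("genotypes", cls.genotypes))
        config = cls(**payload)
        config.validate()
        return config


def _child_seed(seed: int, *path: int) -> int:
    """Stable derived seed below 2**31 for one pipeline stage."""
    return int(np.random.SeedSequence([seed, *path]).generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic study; returns the summary report dict.

    Stages: genome + RdDM locus design; per-genotype methylome, bisulfite
    library, alignment and cytosine pileup; region methylation, prefilter
    and DMR calls per mutant against ros1 with the hypo-overlap Venn;
    per-genotype small-RNA library, 24-nt window table, dependence
    classification, overlap percentages and chromosome profile; box-plot
    summaries of window methylation split by STA1 dependence.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.json")
    report: dict = {"seed": config.seed}

    genome = simulate.generate_genome(
        n_chromosomes=config.n_chromosomes, chrom_length=config.chrom_length,
        te_pericentromeric_fraction=config.te_pericentromeric_fraction,
        n_genes=config.n_genes, n_tes=config.n_tes, seed=config.seed)
    design = simulate.designate_rddm_loci(genome, seed=config.seed)
    genome.write_fasta(outdir / "genome.fa")
    genome.write_gff3(outdir / "features.gff3")
    logger.info("genome: %d chromosomes x %d bp, %d features",
                config.n_chromosomes, config.chrom_length, len(genome.features))

    aligner = mapping.BisulfiteAligner(genome, config.max_mismatches)
    regions = dmr_mod.define_regions(genome, config.promoter_bp)
    region_meth: dict[str, dict[str, methylation.RegionMethylation]] = {}
    pileups: dict[str, methylation.CytosinePileup] = {}

    for gi, genotype in enumerate(config.genotypes):
        methylome = simulate.build_methylome(genome, genotype, design=design,
                                             seed=config.seed)
        bs_reads = simulate.simulate_bisulfite_reads(
            genome, methylome, depth=config.depth,
            read_length=config.read_length,
            conversion_rate=config.conversion_rate,
            error_rate=config.error_rate,
            seed=_child_seed(config.seed, 1, gi))
        if config.write_fastq:
            bs_reads.write_fastq(outdir / f"bisulfite_{genotype}.fastq")
            bs_reads.write_truth_tsv(outdir / f"bisulfite_{genotype}.truth.tsv")
        alignments = mapping.bisulfite_align(bs_reads, genome,
                                             config.max_mismatches, aligner=aligner)
        n_unique = sum(1 for a in alignments if a.unique)
        logger.info("%s: %d bisulfite reads, %d alignments (%d unique)",
                    genotype, len(bs_reads), len(alignments), n_unique)
        pileup = mapping.pileup_cytosines(alignments, bs_reads, genome)
        pileup.write_cx_tsv(outdir / f"methylation_{genotype}.cx.tsv",
                            covered_only=True)
        pileups[genotype] = pileup
        region_meth[genotype] = {
            r.region_id: methylation.region_methylation(
                pileup, r.interval, min_coverage=config.min_coverage,
                region_id=r.region_id)
            for r in regions
        }

    # ---------------------------------------------------------------- DMRs
    mutants = [g for g in config.genotypes if g != "ros1"]
    hypo_sets: dict[str, dict[str, set[str]]] = {}
    dmr_counts: dict[str, dict] = {}
    for genotype in mutants:
        retained = dmr_mod.prefilter_regions(regions, {
            "ros1": region_meth["ros1"], genotype: region_meth[genotype]},
            min_level=config.prefilter_level)
        calls = dmr_mod.call_dmrs(retained, region_meth, "ros1", genotype,
                                  alpha=config.dmr_alpha)
        dmr_mod.write_dmr_bed(calls, outdir / f"dmr_ros1_vs_{genotype}.bed")
        counts: dict = {}
        for cls in dmr_mod.REGION_CLASSES:
            sub = [c for c in calls if c.region_class == cls]
            counts[cls] = {
                "tested": len(sub),
                "hypo": sum(1 for c in sub if c.direction == "hypo"),
                "hyper": sum(1 for c in sub if c.direction == "hyper"),
            }
        dmr_counts[genotype] = counts
        hypo_sets[genotype] = {
            cls: {c.region_id for c in calls
                  if c.region_class == cls and c.direction == "hypo"}
            for cls in dmr_mod.REGION_CLASSES
        }
        logger.info("DMRs ros1 vs %s: %s", genotype, counts)
    report["dmr_counts"] = dmr_counts

    venn_rows = []
    if "sta1" in hypo_sets and "nrpd1" in hypo_sets:
        venn: dict[str, dict] = {}
        for cls in dmr_mod.REGION_CLASSES:
            summary = dmr_mod.venn_overlap({
                "sta1": hypo_sets["sta1"][cls],
                "nrpd1": hypo_sets["nrpd1"][cls]})
            venn[cls] = {
                "sta1": len(summary.sets["sta1"]),
                "nrpd1": len(summary.sets["nrpd1"]),
                "overlap": summary.pairwise[("sta1", "nrpd1")],
            }
            venn_rows.append({"class": cls, **venn[cls]})
        report["hypo_venn"] = venn
        pd.DataFrame(venn_rows).to_csv(outdir / "dmr_hypo_venn.tsv",
                                       sep="\t", index=False)

    # --------------------------------------------------------------- siRNA
    matcher = sirna.ExactMatcher(genome)
    counts_by_genotype: dict[str, pd.Series] = {}
    totals: dict[str, float] = {}
    for gi, genotype in enumerate(config.genotypes):
        sr_reads = simulate.simulate_smallrna_reads(
            genome, genotype, design=design,
            total_reads=config.sirna_total_reads,
            seed=_child_seed(config.seed, 2, gi))
        if config.write_fastq:
            sr_reads.write_fastq(outdir / f"smallrna_{genotype}.fastq")
        aligned = sirna.length_filter_and_map(sr_reads, genome, matcher=matcher)
        totals[genotype] = float(aligned["weight"].sum())
        counts_by_genotype[genotype] = sirna.window_counts(
            aligned, genome, window_bp=config.window_bp)
        logger.info("%s: %d small-RNA reads, %.0f mapped (18-30 nt)",
                    genotype, len(sr_reads), totals[genotype])
    table = sirna.build_window_table(counts_by_genotype, totals, genome,
                                     window_bp=config.window_bp)
    flags = sirna.classify_dependence(table, polIV_fold=config.polIV_fold,
                                      downstream_fold=config.downstream_fold,
                                      min_wt_raw=config.min_wt_raw)
    with open(outdir / "sirna_windows.tsv", "w") as fh:
        fh.write("# 0-based half-open window coordinates\n")
        flags.to_csv(fh, sep="\t", index=False)
    overlap = sirna.dependence_overlap(flags)
    report["sirna_overlap"] = overlap
    report["sirna_percent_strings"] = {
        "polV": ratio_report(overlap["n_polV"], overlap["n_polIV"])
        if overlap["n_polIV"] else "0.0%",
        "sta1": ratio_report(overlap["n_sta1"], overlap["n_polIV"])
        if overlap["n_polIV"] else "0.0%",
    }
    profile = sirna.chromosome_sirna_profile(flags, config.superwindow_bp)
    with open(outdir / "sirna_profile.tsv", "w") as fh:
        fh.write("# 0-based half-open superwindow start coordinates\n")
        profile.to_csv(fh, sep="\t", index=False)

    # ------------------------- methylation at Pol IV-dependent siRNA windows
    poliv = flags[flags["polIV_dependent"]]
    level_rows = []
    for _, row in poliv.iterrows():
        for genotype in config.genotypes:
            rm = methylation.region_methylation(
                pileups[genotype], (row["chrom"], int(row["start"]), int(row["end"])),
                min_coverage=config.min_coverage, region_id=row["window_id"])
            for context in methylation.CONTEXTS:
                level = rm.level(context)
                level_rows.append({"window_id": row["window_id"],
                                   "genotype": genotype, "context": context,
                                   "level": np.nan if level is None else level})
    window_levels = pd.DataFrame(level_rows, columns=["window_id", "genotype",
                                                      "context", "level"])
    partitions = {
        "STA1_dependent": set(poliv[poliv["sta1_dependent"]]["window_id"]),
        "STA1_independent": set(poliv[~poliv["sta1_dependent"]]["window_id"]),
    }
    boxes = dmr_mod.methylation_by_sirna_dependence(partitions, window_levels)
    boxes.to_csv(outdir / "sirna_window_methylation.tsv", sep="\t", index=False)
    report["sirna_methylation_groups"] = int(len(boxes))

    with open(outdir / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
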