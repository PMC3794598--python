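"""Differential methylation over annotated regions.

Regions are annotation-defined — gene bodies, TE bodies and the 1-kb
strand-aware promoter upstream of each gene — not discovered de novo.
For each region the pooled (C, T) counts of the two genotypes form a 2x2
table tested with a two-sided Fisher exact test; regions must first show
>10% pooled-context methylation in at least one genotype, and calls use
raw P < 0.01 with no multiple-testing correction by default (a
Benjamini-Hochberg option exists for users who want it).

The two-sided p-value uses the point-mass definition: the sum of all
hypergeometric outcomes (margins fixed) whose probability does not exceed
the observed table's probability, with the customary 1e-7 relative slack
for numerical ties.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .methylation import CONTEXTS, RegionMethylation
from .simulate import AnnotatedGenome

REGION_CLASSES = ("gene_body", "TE_body", "promoter_1kb")
_TIE_EPS = 1 + 1e-7


@dataclass(frozen=True)
class Region:
    region_id: str
    region_class: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str = "+"
    truncated: bool = False

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def define_regions(genome: AnnotatedGenome, promoter_bp: int = 1000) -> list[Region]:
    """Gene bodies, TE bodies and strand-aware 1-kb gene promoters.

    The promoter is the window immediately 5' of the gene start (upstream
    on the gene's strand), truncated at chromosome ends and flagged when
    truncation occurred.
    """
    regions: list[Region] = []
    for feat in genome.features:
        cls = "TE_body" if feat.kind == "TE" else "gene_body"
        regions.append(Region(feat.feature_id, cls, feat.chrom,
                              feat.start, feat.end, feat.strand))
        if feat.kind == "gene":
            chrom_len = len(genome.chromosomes[feat.chrom])
            if feat.strand == "+":
                start, end = feat.start - promoter_bp, feat.start
            else:
                start, end = feat.end, feat.end + promoter_bp
            t_start, t_end = max(start, 0), min(end, chrom_len)
            if t_end > t_start:
                regions.append(Region(f"{feat.feature_id}:promoter", "promoter_1kb",
                                      feat.chrom, t_start, t_end, feat.strand,
                                      truncated=(t_start != start or t_end != end)))
    return regions


def prefilter_regions(
    regions: Sequence[Region],
    methylation_by_genotype: Mapping[str, Mapping[str, RegionMethylation]],
    min_level: float = 0.10,
) -> list[Region]:
    """Keep regions with pooled-context methylation above ``min_level``
    in at least one genotype; regions undefined everywhere are dropped."""
    kept = []
    for region in regions:
        for meth in methylation_by_genotype.values():
            rm = meth.get(region.region_id)
            if rm is None:
                continue
            level = rm.level(None)
            if level is not None and level > min_level:
                kept.append(region)
                break
    return kept


# --------------------------------------------------------------------------
# Fisher exact test (two-sided, point-mass definition)
# --------------------------------------------------------------------------

def _two_sided_pvalues(total: int, row1: int, col1: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided p for every table with the given margins.

    Returns ``(ks, pvals)`` over the support of a (first-cell count) for a
    2x2 table with first-row margin ``row1``, first-column margin ``col1``
    and grand total ``total``.
    """
    lo = max(0, row1 + col1 - total)
    hi = min(row1, col1)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, total, row1, col1)
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    csum = np.cumsum(sorted_pmf)
    # for each observed table, sum all pmf <= pmf_obs * (1 + eps)
    idx = np.searchsorted(sorted_pmf, pmf * _TIE_EPS, side="right")
    pvals = np.where(idx > 0, csum[np.maximum(idx - 1, 0)], 0.0)
    return ks, np.minimum(pvals, 1.0)


def fisher_exact_2x2(c_ref: int, t_ref: int, c_test: int, t_test: int) -> float:
    """Two-sided Fisher exact p for the table [[c_ref, t_ref], [c_test, t_test]].

    Exact point-mass definition: the probabilities of all tables with the
    observed margins that are no more likely than the observed one are
    summed. Raises on negative counts or an all-zero table.
    """
    cells = (c_ref, t_ref, c_test, t_test)
    if any(x < 0 for x in cells):
        raise ValueError("counts must be non-negative")
    total = sum(cells)
    if total == 0:
        raise ValueError("all-zero table")
    row1 = c_ref + t_ref
    col1 = c_ref + c_test
    if row1 in (0, total) or col1 in (0, total):
        return 1.0  # degenerate margin: only one table possible
    ks, pvals = _two_sided_pvalues(total, row1, col1)
    return float(pvals[c_ref - ks[0]])


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-FDR adjusted p-values (optional; region calls default to raw P)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# --------------------------------------------------------------------------
# DMR calling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DMRCall:
    region_id: str
    region_class: str
    chrom: str
    start: int
    end: int
    ref_label: str
    test_label: str
    c_ref: int
    t_ref: int
    c_test: int
    t_test: int
    level_ref: float | None
    level_test: float | None
    p_value: float
    direction: str  # "hypo" | "hyper" | "ns"

    @property
    def significant(self) -> bool:
        return self.direction != "ns"


def call_dmrs(
    regions: Sequence[Region],
    methylation_by_genotype: Mapping[str, Mapping[str, RegionMethylation]],
    ref_label: str,
    test_label: str,
    alpha: float = 0.01,
    context: str | None = None,
    fdr: bool = False,
) -> list[DMRCall]:
    """One Fisher test per region on pooled (C, T) counts.

    Counts pool across all contexts by default (``context`` selects a
    single-context mode). Direction is hypo when significant and the test
    level is below the reference, hyper when above, ns otherwise. Regions
    without counts in either genotype are reported ns with p = NaN.
    ``fdr=True`` applies Benjamini-Hochberg to the p-values before the
    alpha cut (off by default, matching raw-P selection).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    ref_meth = methylation_by_genotype[ref_label]
    test_meth = methylation_by_genotype[test_label]
    raw: list[tuple[Region, tuple[int, int], tuple[int, int], float]] = []
    for region in regions:
        rm_ref = ref_meth.get(region.region_id)
        rm_test = test_meth.get(region.region_id)
        cr, tr = rm_ref.counts(context) if rm_ref else (0, 0)
        ct, tt = rm_test.counts(context) if rm_test else (0, 0)
        if cr + tr == 0 or ct + tt == 0:
            p = float("nan")
        else:
            p = fisher_exact_2x2(cr, tr, ct, tt)
        raw.append((region, (cr, tr), (ct, tt), p))

    pvals = np.array([p for *_, p in raw])
    if fdr:
        finite = ~np.isnan(pvals)
        adj = pvals.copy()
        adj[finite] = benjamini_hochberg(pvals[finite])
        effective = adj
    else:
        effective = pvals

    calls: list[DMRCall] = []
    for (region, (cr, tr), (ct, tt), p), p_eff in zip(raw, effective):
        level_ref = cr / (cr + tr) if cr + tr else None
        level_test = ct / (ct + tt) if ct + tt else None
        direction = "ns"
        if (not math.isnan(p_eff) and p_eff < alpha
                and level_ref is not None and level_test is not None):
            if level_test < level_ref:
                direction = "hypo"
            elif level_test > level_ref:
                direction = "hyper"
        calls.append(DMRCall(region.region_id, region.region_class,
                             region.chrom, region.start, region.end,
                             ref_label, test_label, cr, tr, ct, tt,
                             level_ref, level_test, p, direction))
    return calls


def write_dmr_bed(calls: Sequence[DMRCall], path) -> None:
    """BED6+ output: score = -log10 p (capped at 1000), extra columns with
    class, direction, levels and counts. 0-based half-open coordinates."""
    with open(path, "w") as fh:
        fh.write("# BED6+: 0-based half-open; score=-log10(p) capped at 1000\n")
        fh.write("# chrom\tstart\tend\tname\tscore\tstrand\tclass\tdirection\t"
                 "level_ref\tlevel_test\tc_ref\tt_ref\tc_test\tt_test\tp_value\n")
        for call in calls:
            if math.isnan(call.p_value) or call.p_value <= 0:
                score = 1000.0
            else:
                score = min(-math.log10(call.p_value), 1000.0)
            lr = "NA" if call.level_ref is None else f"{call.level_ref:.4f}"
            lt = "NA" if call.level_test is None else f"{call.level_test:.4f}"
            fh.write(f"{call.chrom}\t{call.start}\t{call.end}\t{call.region_id}\t"
                     f"{score:.2f}\t.\t{call.region_class}\t{call.direction}\t"
                     f"{lr}\t{lt}\t{call.c_ref}\t{call.t_ref}\t{call.c_test}\t"
                     f"{call.t_test}\t{call.p_value:.3e}\n")


# --------------------------------------------------------------------------
# overlap summaries
# --------------------------------------------------------------------------

@dataclass
class VennSummary:
    labels: list[str]
    sets: dict[str, frozenset[str]]
    pairwise: dict[tuple[str, str], int]
    total_intersection: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"labels": label, "count": len(s)} for label, s in self.sets.items()]
        rows += [{"labels": f"{a} & {b}", "count": n}
                 for (a, b), n in self.pairwise.items()]
        if len(self.labels) > 2:
            rows.append({"labels": " & ".join(self.labels),
                         "count": self.total_intersection})
        return pd.DataFrame(rows)


def venn_overlap(call_sets: Mapping[str, Iterable[str]]) -> VennSummary:
    """Exact set intersections of hypo region ids across >= 2 labelled sets."""
    sets = {label: frozenset(ids) for label, ids in call_sets.items()}
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    labels = list(sets)
    pairwise = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            pairwise[(a, b)] = len(sets[a] & sets[b])
    total = len(frozenset.intersection(*sets.values()))
    return VennSummary(labels, sets, pairwise, total)


# --------------------------------------------------------------------------
# methylation grouped by siRNA dependence
# --------------------------------------------------------------------------

def methylation_by_sirna_dependence(
    partitions: Mapping[str, Iterable[str]],
    window_levels: pd.DataFrame,
) -> pd.DataFrame:
    """Box-plot summaries of window methylation per dependence partition.

    ``partitions`` maps a partition label (e.g. STA1-dependent /
    STA1-independent) to window ids; ``window_levels`` has columns
    window_id, genotype, context, level. Returns one row per (partition,
    genotype, context) with median, quartiles and 1.5*IQR whiskers clipped
    to the data range. Empty partitions contribute no rows.
    """
    required = {"window_id", "genotype", "context", "level"}
    if not required <= set(window_levels.columns):
        raise ValueError(f"window_levels must have columns {sorted(required)}")
    rows = []
    for label, ids in partitions.items():
        ids = set(ids)
        sub = window_levels[window_levels["window_id"].isin(ids)]
        for (genotype, context), grp in sub.groupby(["genotype", "context"]):
            values = grp["level"].dropna().to_numpy()
            if values.size == 0:
                continue
            q1, med, q3 = np.percentile(values, [25, 50, 75])
            iqr = q3 - q1
            lo = values[values >= q1 - 1.5 * iqr].min()
            hi = values[values <= q3 + 1.5 * iqr].max()
            rows.append({"partition": label, "genotype": genotype,
                         "context": context, "n": int(values.size),
                         "median": med, "q1": q1, "q3": q3,
                         "whisker_lo": lo, "whisker_hi": hi})
    return pd.DataFrame(rows, columns=["partition", "genotype", "context", "n",
                                       "median", "q1", "q3",
                                       "whisker_lo", "whisker_hi"])
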