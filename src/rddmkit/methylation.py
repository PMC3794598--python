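"""Cytosine contexts and methylation levels.

Methylation of a cytosine is observed through bisulfite sequencing as the
fraction of reads retaining C (unconverted) among reads reporting C or T.
A site contributes to any summary only when it reaches ``min_coverage``
(default 5) informative reads; levels of uncovered sites are undefined and
propagate as missing values, never as zero.

Contexts follow the plant convention, reading 5'->3' on the cytosine's own
strand: CG (next base G), CHG (next-next base G), CHH otherwise, with
H in {A, C, T}. Positions too close to a chromosome end to establish a G
fall back to CHH.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _seq

CONTEXTS = ("CG", "CHG", "CHH")
_CTX_CODE = {"CG": 1, "CHG": 2, "CHH": 3}


# --------------------------------------------------------------------------
# context assignment
# --------------------------------------------------------------------------

def context_arrays(genome) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome context code arrays (0=not a cytosine, 1=CG, 2=CHG, 3=CHH).

    Returns ``{chrom: (ctx_plus, ctx_minus)}`` where minus-strand cytosines
    (reference G) are indexed at their plus-strand coordinate. Cached on the
    genome object.
    """
    cache = getattr(genome, "_ctx_cache", None)
    if cache is not None:
        return cache
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in genome.chromosomes:
        codes = genome.codes(chrom)
        n = len(codes)
        # pad with A: A is never C or G, so truncated contexts fall to CHH
        nxt1 = np.concatenate([codes[1:], [0]])
        nxt2 = np.concatenate([codes[2:], [0, 0]])
        prv1 = np.concatenate([[0], codes[:-1]])
        prv2 = np.concatenate([[0, 0], codes[:-2]])

        ctx_plus = np.zeros(n, dtype=np.uint8)
        is_c = codes == _seq.C
        ctx_plus[is_c] = 3
        ctx_plus[is_c & (nxt2 == _seq.G)] = 2
        ctx_plus[is_c & (nxt1 == _seq.G)] = 1

        ctx_minus = np.zeros(n, dtype=np.uint8)
        is_g = codes == _seq.G
        ctx_minus[is_g] = 3
        ctx_minus[is_g & (prv2 == _seq.C)] = 2
        ctx_minus[is_g & (prv1 == _seq.C)] = 1
        out[chrom] = (ctx_plus, ctx_minus)
    try:
        genome._ctx_cache = out
    except AttributeError:
        pass
    return out


def assign_context(genome, chrom: str, position: int, strand: str) -> str:
    """Context of one cytosine, reading 5'->3' on its own strand.

    The addressed base must be C on the given strand (a reference G when
    ``strand == '-'``); otherwise a ``ValueError`` is raised.
    """
    codes = genome.codes(chrom)
    n = len(codes)
    if not 0 <= position < n:
        raise ValueError(f"position {position} outside {chrom}")
    if strand == "+":
        if codes[position] != _seq.C:
            raise ValueError(f"{chrom}:{position}+ is not a cytosine")
        nxt = [int(codes[position + i]) for i in (1, 2) if position + i < n]
        downstream_is_g = [b == _seq.G for b in nxt]
    elif strand == "-":
        if codes[position] != _seq.G:
            raise ValueError(f"{chrom}:{position}- is not a cytosine")
        # next base on the minus strand is the complement of the base at
        # position-1 on the plus strand; complement(C)=G
        nxt = [int(codes[position - i]) for i in (1, 2) if position - i >= 0]
        downstream_is_g = [b == _seq.C for b in nxt]
    else:
        raise ValueError(f"bad strand {strand!r}")
    if len(downstream_is_g) >= 1 and downstream_is_g[0]:
        return "CG"
    if len(downstream_is_g) >= 2 and downstream_is_g[1]:
        return "CHG"
    return "CHH"


# --------------------------------------------------------------------------
# pileup container
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine site with converted/unconverted read counts."""

    chrom: str
    position: int  # 0-based
    strand: str
    context: str
    count_unconverted: int  # reads reporting C
    count_converted: int  # reads reporting T

    @property
    def coverage(self) -> int:
        return self.count_unconverted + self.count_converted


class CytosinePileup:
    """Dense per-site C/T counts over a genome, split by strand.

    ``counts[chrom][strand]`` is a pair of int32 arrays (unconverted,
    converted) indexed by plus-strand coordinate. This is the working
    container for all region/profile aggregation; :meth:`records` and
    :meth:`to_dataframe` expose the per-site view.
    """

    def __init__(self, genome) -> None:
        self.genome = genome
        self.counts: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        for chrom, seq in genome.chromosomes.items():
            n = len(seq)
            self.counts[chrom] = {
                "+": (np.zeros(n, dtype=np.int32), np.zeros(n, dtype=np.int32)),
                "-": (np.zeros(n, dtype=np.int32), np.zeros(n, dtype=np.int32)),
            }

    # ------------------------------------------------------------- access
    def site_counts(self, chrom: str, position: int, strand: str) -> tuple[int, int]:
        unc, conv = self.counts[chrom][strand]
        return int(unc[position]), int(conv[position])

    def records(self, covered_only: bool = True) -> Iterable[CytosineRecord]:
        ctx = context_arrays(self.genome)
        for chrom in self.counts:
            ctx_plus, ctx_minus = ctx[chrom]
            for strand, carr in (("+", ctx_plus), ("-", ctx_minus)):
                unc, conv = self.counts[chrom][strand]
                sites = np.flatnonzero(carr > 0)
                if covered_only:
                    sites = sites[(unc[sites] + conv[sites]) > 0]
                for pos in sites:
                    yield CytosineRecord(
                        chrom, int(pos), strand, CONTEXTS[carr[pos] - 1],
                        int(unc[pos]), int(conv[pos]),
                    )

    def to_dataframe(self, covered_only: bool = True) -> pd.DataFrame:
        rows = [(r.chrom, r.position, r.strand, r.context,
                 r.count_unconverted, r.count_converted)
                for r in self.records(covered_only=covered_only)]
        return pd.DataFrame(rows, columns=[
            "chrom", "position", "strand", "context",
            "count_unconverted", "count_converted"])

    @classmethod
    def from_records(cls, records: Iterable[CytosineRecord], genome) -> "CytosinePileup":
        pileup = cls(genome)
        for rec in records:
            unc, conv = pileup.counts[rec.chrom][rec.strand]
            unc[rec.position] += rec.count_unconverted
            conv[rec.position] += rec.count_converted
        return pileup

    # ---------------------------------------------------------------- I/O
    def write_cx_tsv(self, path: str | Path, covered_only: bool = False) -> None:
        """CX-style TSV: chrom, 1-based position, strand, context, C count, T count."""
        ctx = context_arrays(self.genome)
        with open(path, "w") as fh:
            fh.write("# coordinates: 1-based positions\n")
            fh.write("chrom\tposition\tstrand\tcontext\t"
                     "count_unconverted\tcount_converted\n")
            for chrom in self.counts:
                ctx_plus, ctx_minus = ctx[chrom]
                for strand, carr in (("+", ctx_plus), ("-", ctx_minus)):
                    unc, conv = self.counts[chrom][strand]
                    sites = np.flatnonzero(carr > 0)
                    if covered_only:
                        sites = sites[(unc[sites] + conv[sites]) > 0]
                    for pos in sites:
                        fh.write(f"{chrom}\t{pos + 1}\t{strand}\t"
                                 f"{CONTEXTS[carr[pos] - 1]}\t{unc[pos]}\t{conv[pos]}\n")

    @classmethod
    def read_cx_tsv(cls, path: str | Path, genome) -> "CytosinePileup":
        pileup = cls(genome)
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or line.startswith("chrom\t"):
                    continue
                chrom, pos, strand, _ctx, unc, conv = line.rstrip("\n").split("\t")
                arr_u, arr_c = pileup.counts[chrom][strand]
                arr_u[int(pos) - 1] += int(unc)
                arr_c[int(pos) - 1] += int(conv)
        return pileup

    def write_bedgraph(self, path: str | Path, context: str,
                       min_coverage: int = 5) -> None:
        """Per-site levels of one context as bedGraph (0-based half-open).

        Both strands are written as separate single-base intervals.
        """
        code = _CTX_CODE[context]
        ctx = context_arrays(self.genome)
        with open(path, "w") as fh:
            fh.write(f"# {context} methylation levels; bedGraph 0-based "
                     "half-open; strands written separately\n")
            for chrom in self.counts:
                arrs = ctx[chrom]
                for strand, carr in (("+", arrs[0]), ("-", arrs[1])):
                    unc, conv = self.counts[chrom][strand]
                    cov = unc + conv
                    sites = np.flatnonzero((carr == code) & (cov >= min_coverage))
                    for pos in sites:
                        level = unc[pos] / cov[pos]
                        fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{level:.6g}\n")


# --------------------------------------------------------------------------
# levels
# --------------------------------------------------------------------------

def site_methylation(record, min_coverage: int = 5) -> float | None:
    """Methylation level of one site, or None below the coverage rule.

    Accepts a :class:`CytosineRecord` or a ``(count_unconverted,
    count_converted)`` pair. The level is C/(C+T); it is undefined (None)
    when C+T < ``min_coverage``.
    """
    if isinstance(record, CytosineRecord):
        unc, conv = record.count_unconverted, record.count_converted
    else:
        unc, conv = record
    if unc < 0 or conv < 0:
        raise ValueError("negative counts")
    if unc + conv < min_coverage:
        return None
    return unc / (unc + conv)


@dataclass
class RegionMethylation:
    """Pooled C/T counts and level per context for one interval.

    Only sites passing the coverage rule contribute. ``level(None)`` pools
    counts across all three contexts.
    """

    region_id: str
    chrom: str
    start: int
    end: int
    context_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    n_sites_covered: dict[str, int] = field(default_factory=dict)

    def counts(self, context: str | None = None) -> tuple[int, int]:
        if context is not None:
            return self.context_counts.get(context, (0, 0))
        total_u = sum(u for u, _ in self.context_counts.values())
        total_c = sum(c for _, c in self.context_counts.values())
        return total_u, total_c

    def level(self, context: str | None = None) -> float | None:
        unc, conv = self.counts(context)
        if unc + conv == 0:
            return None
        return unc / (unc + conv)


def _normalize_pileup(records, genome=None) -> CytosinePileup:
    if isinstance(records, CytosinePileup):
        return records
    if genome is None:
        raise ValueError("genome required when passing raw records")
    return CytosinePileup.from_records(records, genome)


def region_methylation(
    pileup: CytosinePileup,
    interval: tuple[str, int, int],
    context_filter: str | None = None,
    min_coverage: int = 5,
    region_id: str | None = None,
) -> RegionMethylation:
    """Pooled methylation of a half-open interval, per context.

    Pools counts over both strands across all qualifying sites of each
    context inside the interval; the coverage rule applies per site before
    pooling. ``context_filter`` restricts the result to one context.
    """
    chrom, start, end = interval
    n = len(pileup.genome.chromosomes[chrom])
    if not (0 <= start < end <= n):
        raise ValueError(f"malformed interval {interval}")
    ctx_plus, ctx_minus = context_arrays(pileup.genome)[chrom]
    wanted = [context_filter] if context_filter else list(CONTEXTS)
    result = RegionMethylation(region_id or f"{chrom}:{start}-{end}",
                               chrom, start, end)
    for context in wanted:
        code = _CTX_CODE[context]
        total_u = total_c = n_sites = 0
        for strand, carr in (("+", ctx_plus), ("-", ctx_minus)):
            unc, conv = pileup.counts[chrom][strand]
            u = unc[start:end]
            c = conv[start:end]
            mask = (carr[start:end] == code) & (u + c >= min_coverage)
            total_u += int(u[mask].sum())
            total_c += int(c[mask].sum())
            n_sites += int(mask.sum())
        result.context_counts[context] = (total_u, total_c)
        result.n_sites_covered[context] = n_sites
    return result


# --------------------------------------------------------------------------
# metagene profiles
# --------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    """Average methylation over length-normalized feature bodies plus flanks.

    ``levels`` has shape (3 contexts, flank_bins + body_bins + flank_bins);
    NaN marks bins with no covered site. Orientation is strand-aware:
    index 0 is the far upstream (5') flank bin.
    """

    kind: str
    levels: np.ndarray
    n_features: int
    body_bins: int
    flank_bins: int
    flank_bp: int
    mode: str = "pooled"

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.levels.T, columns=list(CONTEXTS))
        df.insert(0, "bin", np.arange(self.n_bins))
        return df


def _feature_bins(feature, chrom_len: int, flank_bp: int,
                  body_bins: int, flank_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Positions and global bin indices for one feature, strand-oriented.

    Bins are laid out left-to-right in plus orientation and the indices are
    flipped for minus-strand features, so reversing a feature's strand
    mirrors its bin vector exactly.
    """
    length = feature.end - feature.start
    n_bins = 2 * flank_bins + body_bins
    body_pos = np.arange(feature.start, feature.end)
    off = body_pos - feature.start
    body_bin = flank_bins + np.minimum(off * body_bins // length, body_bins - 1)

    flank_width = flank_bp / flank_bins
    left = np.arange(feature.start - flank_bp, feature.start)
    left_bin = np.minimum(((left - (feature.start - flank_bp)) / flank_width)
                          .astype(int), flank_bins - 1)
    right = np.arange(feature.end, feature.end + flank_bp)
    right_bin = np.minimum(((right - feature.end) / flank_width).astype(int),
                           flank_bins - 1) + flank_bins + body_bins

    pos = np.concatenate([left, body_pos, right])
    bins = np.concatenate([left_bin, body_bin, right_bin])
    if feature.strand == "-":
        bins = (n_bins - 1) - bins  # index 0 = far upstream (5') flank
    keep = (pos >= 0) & (pos < chrom_len)  # flanks truncated at chromosome ends
    return pos[keep], bins[keep]


def metagene_profile(
    pileup: CytosinePileup,
    features: Sequence,
    flank_bp: int = 1000,
    body_bins: int = 20,
    flank_bins: int = 10,
    min_coverage: int = 5,
    feature_averaged: bool = False,
) -> MetageneProfile:
    """Metagene methylation profile over features of one kind.

    Bodies are length-normalized into ``body_bins``; each flank is
    ``flank_bins`` fixed-width bins over ``flank_bp``. In the default
    pooled mode, C/T counts are pooled across features per bin and then
    converted to a level; ``feature_averaged`` instead averages per-feature
    bin levels, weighting each feature equally.
    """
    features = list(features)
    if not features:
        raise ValueError("at least one feature required")
    kinds = {f.kind for f in features}
    if len(kinds) != 1:
        raise ValueError(f"features must share one kind, got {kinds}")
    n_bins = 2 * flank_bins + body_bins
    ctx = context_arrays(pileup.genome)

    pooled_u = np.zeros((3, n_bins))
    pooled_c = np.zeros((3, n_bins))
    avg_sum = np.zeros((3, n_bins))
    avg_n = np.zeros((3, n_bins))

    for feat in features:
        chrom_len = len(pileup.genome.chromosomes[feat.chrom])
        pos, bins = _feature_bins(feat, chrom_len, flank_bp, body_bins, flank_bins)
        ctx_plus, ctx_minus = ctx[feat.chrom]
        feat_u = np.zeros((3, n_bins))
        feat_c = np.zeros((3, n_bins))
        for strand, carr in (("+", ctx_plus), ("-", ctx_minus)):
            unc, conv = pileup.counts[feat.chrom][strand]
            cov = unc[pos] + conv[pos]
            ok = cov >= min_coverage
            codes = carr[pos]
            for ci in range(3):
                sel = ok & (codes == ci + 1)
                np.add.at(feat_u[ci], bins[sel], unc[pos][sel])
                np.add.at(feat_c[ci], bins[sel], conv[pos][sel])
        pooled_u += feat_u
        pooled_c += feat_c
        feat_cov = feat_u + feat_c
        with np.errstate(invalid="ignore"):
            feat_level = np.where(feat_cov > 0, feat_u / np.maximum(feat_cov, 1), np.nan)
        has = feat_cov > 0
        avg_sum[has] += feat_level[has]
        avg_n += has

    if feature_averaged:
        with np.errstate(invalid="ignore"):
            levels = np.where(avg_n > 0, avg_sum / np.maximum(avg_n, 1), np.nan)
        mode = "feature_averaged"
    else:
        cov = pooled_u + pooled_c
        with np.errstate(invalid="ignore"):
            levels = np.where(cov > 0, pooled_u / np.maximum(cov, 1), np.nan)
        mode = "pooled"
    return MetageneProfile(kind=features[0].kind, levels=levels,
                           n_features=len(features), body_bins=body_bins,
                           flank_bins=flank_bins, flank_bp=flank_bp, mode=mode)


# --------------------------------------------------------------------------
# clone (Sanger-style) bisulfite summaries
# --------------------------------------------------------------------------

def clone_bisulfite_summary(
    clone_sequences: Sequence[str],
    reference: str,
    min_clones: int = 15,
) -> dict[str, float]:
    """Per-context methylation percentages from end-to-end locus clones.

    Clones represent the bisulfite-converted plus strand of the locus and
    must match the reference length. For each reference cytosine, a clone C
    is a methylated call and a clone T an unmethylated call; other bases are
    ignored. Returns ``{context: percentage}`` for the contexts present.
    Fewer than ``min_clones`` clones triggers a warning, not a failure.
    """
    if len(clone_sequences) < min_clones:
        warnings.warn(
            f"only {len(clone_sequences)} clones (< {min_clones}); "
            "percentages may be unstable", stacklevel=2)
    ref = _seq.encode(reference)
    n = len(ref)
    meth = {c: 0 for c in CONTEXTS}
    total = {c: 0 for c in CONTEXTS}
    c_positions = np.flatnonzero(ref == _seq.C)
    ctx_of: dict[int, str] = {}
    for pos in c_positions:
        nxt1 = ref[pos + 1] if pos + 1 < n else None
        nxt2 = ref[pos + 2] if pos + 2 < n else None
        if nxt1 == _seq.G:
            ctx_of[int(pos)] = "CG"
        elif nxt2 == _seq.G:
            ctx_of[int(pos)] = "CHG"
        else:
            ctx_of[int(pos)] = "CHH"
    for clone in clone_sequences:
        if len(clone) != n:
            raise ValueError("clone length does not match reference locus")
        codes = _seq.encode(clone)
        for pos, context in ctx_of.items():
            base = codes[pos]
            if base == _seq.C:
                meth[context] += 1
                total[context] += 1
            elif base == _seq.T:
                total[context] += 1
    return {c: 100.0 * meth[c] / total[c] for c in CONTEXTS if total[c] > 0}


# --------------------------------------------------------------------------
# chromosome-scale profiles
# --------------------------------------------------------------------------

def chromosome_methylation_profile(
    pileup: CytosinePileup,
    window_bp: int,
    min_coverage: int = 5,
) -> pd.DataFrame:
    """Pooled-count methylation levels in non-overlapping windows.

    Windows tile from coordinate 0; the trailing partial window is kept.
    Returns a DataFrame with chrom, start, end and one level column per
    context (NaN when the window has no covered site of that context).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rows = []
    for chrom, seq in pileup.genome.chromosomes.items():
        n = len(seq)
        for start in range(0, n, window_bp):
            end = min(start + window_bp, n)
            rm = region_methylation(pileup, (chrom, start, end),
                                    min_coverage=min_coverage)
            row: dict = {"chrom": chrom, "start": start, "end": end}
            for context in CONTEXTS:
                level = rm.level(context)
                row[context] = np.nan if level is None else level
            rows.append(row)
    return pd.DataFrame(rows)
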