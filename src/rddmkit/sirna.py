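"""24-nt siRNA quantification in 500-bp windows and dependence classification.

Small-RNA reads of 18-30 nt are mapped exactly (0 mismatches, both
strands); 24-nt read counts are tallied in non-overlapping 500-bp windows
by 5' end, normalized to reads per million (RPM, denominator = all mapped
18-30-nt reads of the library), and classified:

* Pol IV-dependent — wild-type-background RPM drops >= 5-fold in nrpd1
  (a zero mutant count passes any fold threshold);
* Pol V-dependent / STA1-dependent — evaluated only inside Pol IV-dependent
  windows, with a >= 2-fold drop in nrpe1 / sta1 respectively.

A raw-count floor on the reference library (default 10 reads) keeps fold
changes off near-zero noise; the floor and the RPM denominator are both
configuration, not biology.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _seq
from .simulate import AnnotatedGenome, ReadSet


# --------------------------------------------------------------------------
# exact mapping
# --------------------------------------------------------------------------

class ExactMatcher:
    """Exact-substring search over both genome strands via a k-mer prefix index."""

    def __init__(self, genome: AnnotatedGenome, k: int = 15) -> None:
        self.genome = genome
        self.k = k
        self.chroms = list(genome.chromosomes)
        self._ref = {c: genome.codes(c) for c in self.chroms}
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ref in self._ref.items():
            n = len(ref) - k + 1
            h = np.zeros(max(n, 0), dtype=np.int64)
            for j in range(k):
                h = h * 4 + ref[j:j + n]
            order = np.argsort(h, kind="stable").astype(np.int64)
            self._index[chrom] = (h[order], order)

    def _find_forward(self, q: np.ndarray) -> list[tuple[str, int]]:
        hits = []
        h = 0
        for v in q[:self.k]:
            h = h * 4 + int(v)
        for chrom in self.chroms:
            sorted_hashes, order = self._index[chrom]
            ref = self._ref[chrom]
            lo = np.searchsorted(sorted_hashes, h, side="left")
            hi = np.searchsorted(sorted_hashes, h, side="right")
            for pos in order[lo:hi]:
                start = int(pos)
                if start + len(q) <= len(ref) and np.array_equal(ref[start:start + len(q)], q):
                    hits.append((chrom, start))
        return hits

    def find(self, sequence: str) -> list[tuple[str, int, str]]:
        """All exact occurrences as (chrom, plus-strand start, strand)."""
        q = _seq.encode(sequence)
        if len(q) < self.k:
            raise ValueError(f"read shorter than index k={self.k}")
        out = [(c, s, "+") for c, s in self._find_forward(q)]
        out += [(c, s, "-") for c, s in self._find_forward(_seq.revcomp_codes(q))]
        return sorted(out)


def length_filter_and_map(
    reads: ReadSet,
    genome: AnnotatedGenome,
    min_len: int = 18,
    max_len: int = 30,
    multimap: str = "fractional",
    matcher: ExactMatcher | None = None,
) -> pd.DataFrame:
    """Filter reads to [min_len, max_len] nt and map them exactly.

    Multimapping reads are either spread over all loci with weight 1/n
    (``fractional``, the default) or dropped (``discard``). Returns a
    DataFrame with read_index, read_id, length, chrom, start, strand,
    weight, n_hits; unmapped reads are absent.
    """
    if reads.protocol != "smallRNA":
        raise ValueError("read set protocol must be 'smallRNA'")
    if multimap not in ("fractional", "discard"):
        raise ValueError("multimap must be 'fractional' or 'discard'")
    if matcher is None:
        matcher = ExactMatcher(genome)
    rows = []
    for idx, read in enumerate(reads):
        length = len(read.sequence)
        if not min_len <= length <= max_len:
            continue
        hits = matcher.find(read.sequence)
        if not hits:
            continue
        if multimap == "discard" and len(hits) > 1:
            continue
        weight = 1.0 / len(hits)
        for chrom, start, strand in hits:
            rows.append((idx, read.read_id, length, chrom, start, strand,
                         weight, len(hits)))
    return pd.DataFrame(rows, columns=["read_index", "read_id", "length",
                                       "chrom", "start", "strand",
                                       "weight", "n_hits"])


# --------------------------------------------------------------------------
# windows
# --------------------------------------------------------------------------

def window_grid(genome: AnnotatedGenome, window_bp: int = 500) -> pd.DataFrame:
    """Non-overlapping tiling from coordinate 0, trailing partial kept."""
    rows = []
    for chrom, seq in genome.chromosomes.items():
        n = len(seq)
        for start in range(0, n, window_bp):
            rows.append((f"{chrom}:{start}", chrom, start, min(start + window_bp, n)))
    return pd.DataFrame(rows, columns=["window_id", "chrom", "start", "end"])


def window_counts(
    alignments: pd.DataFrame,
    genome: AnnotatedGenome,
    window_bp: int = 500,
    read_length_select: int | None = 24,
) -> pd.Series:
    """Weighted read counts per window, assigned by 5' end position.

    Only reads of ``read_length_select`` nt are counted (None keeps all).
    Returns a Series indexed by window_id covering the whole genome grid
    (zero-filled).
    """
    grid = window_grid(genome, window_bp)
    sub = alignments
    if read_length_select is not None:
        sub = sub[sub["length"] == read_length_select]
    if len(sub):
        five_prime = np.where(sub["strand"] == "+", sub["start"],
                              sub["start"] + sub["length"] - 1)
        win_id = sub["chrom"].astype(str) + ":" + pd.Series(
            (five_prime // window_bp) * window_bp, index=sub.index).astype(str)
        counted = pd.Series(sub["weight"].to_numpy(), index=win_id).groupby(level=0).sum()
    else:
        counted = pd.Series(dtype=float)
    out = counted.reindex(grid["window_id"], fill_value=0.0)
    out.name = "count"
    return out


def rpm_normalize(raw, library_total: float):
    """Reads per million: raw * 1e6 / library_total."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    return raw * 1e6 / library_total


def build_window_table(
    counts_by_genotype: Mapping[str, pd.Series],
    library_totals: Mapping[str, float],
    genome: AnnotatedGenome,
    window_bp: int = 500,
) -> pd.DataFrame:
    """Merge per-genotype window counts into one table with raw and RPM columns."""
    table = window_grid(genome, window_bp).set_index("window_id")
    for genotype, counts in counts_by_genotype.items():
        table[f"raw_{genotype}"] = counts.reindex(table.index, fill_value=0.0)
        table[f"rpm_{genotype}"] = rpm_normalize(table[f"raw_{genotype}"],
                                                 library_totals[genotype])
    return table.reset_index()


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def classify_dependence(
    window_table: pd.DataFrame,
    polIV_fold: float = 5.0,
    downstream_fold: float = 2.0,
    min_wt_raw: float = 10.0,
    wt: str = "ros1",
) -> pd.DataFrame:
    """Flag Pol IV-, Pol V- and STA1-dependent windows.

    A window is Pol IV-dependent iff the reference library has at least
    ``min_wt_raw`` raw 24-nt reads and its RPM drops >= ``polIV_fold``
    in nrpd1 (zero mutant RPM counts as an infinite drop). Pol V and STA1
    dependence are evaluated only within Pol IV-dependent windows at
    ``downstream_fold`` against nrpe1 / sta1.
    """
    out = window_table.copy()
    wt_rpm = _require(out, f"rpm_{wt}")
    wt_raw = _require(out, f"raw_{wt}")
    expressed = wt_raw >= min_wt_raw

    def ratio(mutant: str) -> pd.Series:
        mut = _require(out, f"rpm_{mutant}")
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(mut > 0, wt_rpm / mut.replace(0, np.nan), np.inf)
        return pd.Series(np.where(wt_rpm > 0, r, 0.0), index=out.index)

    out["polIV_dependent"] = expressed & (ratio("nrpd1") >= polIV_fold)
    if "rpm_nrpe1" in out.columns:
        out["polV_dependent"] = out["polIV_dependent"] & (ratio("nrpe1") >= downstream_fold)
    out["sta1_dependent"] = out["polIV_dependent"] & (ratio("sta1") >= downstream_fold)
    return out


def _require(df: pd.DataFrame, column: str) -> pd.Series:
    if column not in df.columns:
        raise ValueError(f"missing genotype column {column!r}")
    return df[column]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (so 46.25 -> 46.3), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def dependence_overlap(flags: pd.DataFrame) -> dict[str, float]:
    """Counts and percentages of the dependence classes.

    Reports |Pol IV|, |Pol V ∩ Pol IV|, |STA1 ∩ Pol IV|, the triple
    intersection, and percentages relative to |Pol IV| rounded to one
    decimal (half away from zero). All-zero input yields zeros.
    """
    poliv = flags["polIV_dependent"].astype(bool)
    polv = flags.get("polV_dependent", pd.Series(False, index=flags.index)).astype(bool)
    sta1 = flags["sta1_dependent"].astype(bool)
    n_poliv = int(poliv.sum())
    n_polv = int((polv & poliv).sum())
    n_sta1 = int((sta1 & poliv).sum())
    n_triple = int((sta1 & polv & poliv).sum())

    def pct(n: int) -> float:
        return round_half_away(100.0 * n / n_poliv, 1) if n_poliv else 0.0

    return {
        "n_polIV": n_poliv,
        "n_polV": n_polv,
        "n_sta1": n_sta1,
        "n_sta1_and_polV": n_triple,
        "pct_polV": pct(n_polv),
        "pct_sta1": pct(n_sta1),
        "pct_sta1_and_polV": pct(n_triple),
    }


# --------------------------------------------------------------------------
# chromosome-scale profile
# --------------------------------------------------------------------------

def chromosome_sirna_profile(
    window_table: pd.DataFrame,
    superwindow_bp: int,
    rpm_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Sum window RPM into non-overlapping superwindows along each chromosome.

    ``superwindow_bp`` defaults in the synthetic pipeline to a size scaled
    to the toy genome (e.g. 10 kb on a 100-kb chromosome); 500 kb is the
    real-genome convention.
    """
    if superwindow_bp <= 0:
        raise ValueError("superwindow_bp must be positive")
    if rpm_columns is None:
        rpm_columns = [c for c in window_table.columns if c.startswith("rpm_")]
    df = window_table.copy()
    df["super_start"] = (df["start"] // superwindow_bp) * superwindow_bp
    grouped = (df.groupby(["chrom", "super_start"], as_index=False)[list(rpm_columns)]
               .sum())
    return grouped.rename(columns={"super_start": "start"})
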