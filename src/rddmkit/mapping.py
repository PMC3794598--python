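"""Bisulfite read mapping on a reduced alphabet, and per-cytosine pileup.

Bisulfite conversion turns unmethylated C into T, so a converted read can
differ from its locus at any unmethylated cytosine. Matching is therefore
asymmetric: a read T over a reference C is *not* a mismatch (it may be a
converted cytosine), while a read C over a reference T is. Candidate
locations are found in a fully reduced alphabet (C->T for plus-strand
candidacy, G->A for minus-strand candidacy, applied to both read and
reference), where every asymmetric match is also a reduced-alphabet match;
the asymmetric mismatch count then decides acceptance.

The indexed aligner is exact within its contract: a read is split into
``max_mismatches + 1`` non-overlapping seeds, so any alignment with at
most ``max_mismatches`` mismatches has at least one exact seed hit
(pigeonhole). :func:`bisulfite_align_bruteforce` scans every position and
strand directly and serves as an independent reference implementation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _seq
from .methylation import CytosinePileup
from .simulate import AnnotatedGenome, ReadSet

logger = logging.getLogger(__name__)

DEFAULT_MAX_MISMATCHES = 2


@dataclass(frozen=True)
class Alignment:
    read_index: int
    read_id: str
    chrom: str
    start: int  # 0-based
    strand: str
    mismatch_count: int
    unique: bool


def _reduce_ct(codes: np.ndarray) -> np.ndarray:
    out = codes.copy()
    out[out == _seq.C] = _seq.T
    return out


def _reduce_ga(codes: np.ndarray) -> np.ndarray:
    out = codes.copy()
    out[out == _seq.G] = _seq.A
    return out


def _mismatches_plus(q: np.ndarray, ref: np.ndarray) -> int:
    """Asymmetric count for a plus-strand alignment: ref C matches read C or T."""
    match = (q == ref) | ((ref == _seq.C) & (q == _seq.T))
    return int(len(q) - np.count_nonzero(match))


def _mismatches_minus(rq: np.ndarray, ref: np.ndarray) -> int:
    """Asymmetric count for a minus-strand alignment.

    ``rq`` is the reverse complement of the read laid on plus coordinates;
    a minus-strand converted C appears as A over a reference G.
    """
    match = (rq == ref) | ((ref == _seq.G) & (rq == _seq.A))
    return int(len(rq) - np.count_nonzero(match))


def _hash_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer of every k-mer (Horner scheme, int64)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    h = np.zeros(n, dtype=np.int64)
    for j in range(k):
        h = h * 4 + codes[j:j + n]
    return h


class BisulfiteAligner:
    """Seed-and-extend bisulfite aligner over an in-memory genome."""

    def __init__(self, genome: AnnotatedGenome,
                 max_mismatches: int = DEFAULT_MAX_MISMATCHES) -> None:
        if not genome.chromosomes or all(len(s) == 0 for s in genome.chromosomes.values()):
            raise ValueError("empty genome")
        self.genome = genome
        self.max_mismatches = max_mismatches
        self.chrom_names = list(genome.chromosomes)
        self._ref = {c: genome.codes(c) for c in self.chrom_names}
        self._red_ct = {c: _reduce_ct(r) for c, r in self._ref.items()}
        self._red_ga = {c: _reduce_ga(r) for c, r in self._ref.items()}
        # seed indexes built lazily per seed length: {(k, mode): {chrom: (sorted_hashes, order)}}
        self._index: dict[tuple[int, str], dict[str, tuple[np.ndarray, np.ndarray]]] = {}

    def _get_index(self, k: int, mode: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        key = (k, mode)
        if key not in self._index:
            source = self._red_ct if mode == "ct" else self._red_ga
            built = {}
            for chrom, red in source.items():
                hashes = _hash_kmers(red, k)
                order = np.argsort(hashes, kind="stable").astype(np.int64)
                built[chrom] = (hashes[order], order)
            self._index[key] = built
        return self._index[key]

    def _candidates(self, qred: np.ndarray, k: int, mode: str,
                    read_len: int) -> dict[str, set[int]]:
        index = self._get_index(k, mode)
        n_seeds = self.max_mismatches + 1
        offsets = [i * k for i in range(n_seeds)]
        out: dict[str, set[int]] = {}
        for chrom, (sorted_hashes, order) in index.items():
            max_start = len(self._ref[chrom]) - read_len
            if max_start < 0:
                continue
            starts: set[int] = set()
            for off in offsets:
                h = 0
                for v in qred[off:off + k]:
                    h = h * 4 + int(v)
                lo = np.searchsorted(sorted_hashes, h, side="left")
                hi = np.searchsorted(sorted_hashes, h, side="right")
                for pos in order[lo:hi]:
                    start = int(pos) - off
                    if 0 <= start <= max_start:
                        starts.add(start)
            if starts:
                out[chrom] = starts
        return out

    def align_codes(self, qcodes: np.ndarray) -> list[tuple[str, int, str, int]]:
        """All best-scoring hits of one read: (chrom, start, strand, mismatches)."""
        read_len = len(qcodes)
        k = read_len // (self.max_mismatches + 1)
        if k < 4:
            raise ValueError(f"read of length {read_len} too short to seed")
        rq = _seq.revcomp_codes(qcodes)
        hits: list[tuple[str, int, str, int]] = []
        best = self.max_mismatches
        for strand, query, qred, mode, scorer in (
            ("+", qcodes, _reduce_ct(qcodes), "ct", _mismatches_plus),
            ("-", rq, _reduce_ga(rq), "ga", _mismatches_minus),
        ):
            for chrom, starts in self._candidates(qred, k, mode, read_len).items():
                ref = self._ref[chrom]
                for start in starts:
                    mm = scorer(query, ref[start:start + read_len])
                    if mm <= best:
                        hits.append((chrom, start, strand, mm))
        if not hits:
            return []
        best_mm = min(h[3] for h in hits)
        return sorted(h for h in hits if h[3] == best_mm)


def bisulfite_align(
    reads: ReadSet,
    genome: AnnotatedGenome,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    aligner: BisulfiteAligner | None = None,
) -> list[Alignment]:
    """Align a bisulfite read set; ambiguous best hits are flagged non-unique.

    Reads longer than every chromosome are skipped with a warning. Only
    hits at the best mismatch count (<= ``max_mismatches``) are reported;
    a read with several tied best hits contributes them all with
    ``unique=False`` and is excluded from methylation calling downstream.
    """
    if reads.protocol != "bisulfite":
        raise ValueError("read set protocol must be 'bisulfite'")
    if aligner is None:
        aligner = BisulfiteAligner(genome, max_mismatches)
    max_chrom = max(len(s) for s in genome.chromosomes.values())
    alignments: list[Alignment] = []
    for idx, read in enumerate(reads):
        if len(read.sequence) > max_chrom:
            logger.warning("read %s longer than every chromosome; skipped", read.read_id)
            continue
        hits = aligner.align_codes(_seq.encode(read.sequence))
        unique = len(hits) == 1
        for chrom, start, strand, mm in hits:
            alignments.append(Alignment(idx, read.read_id, chrom, start,
                                        strand, mm, unique))
    return alignments


def bisulfite_align_bruteforce(
    reads: ReadSet,
    genome: AnnotatedGenome,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> list[Alignment]:
    """Full scan over every position and strand; reference implementation.

    Applies the identical asymmetric mismatch rule and best-hit selection
    as the indexed aligner, without any seeding, so the two must agree
    exactly.
    """
    if not genome.chromosomes or all(len(s) == 0 for s in genome.chromosomes.values()):
        raise ValueError("empty genome")
    refs = {c: genome.codes(c) for c in genome.chromosomes}
    max_chrom = max(len(r) for r in refs.values())
    alignments: list[Alignment] = []
    for idx, read in enumerate(reads):
        read_len = len(read.sequence)
        if read_len > max_chrom:
            logger.warning("read %s longer than every chromosome; skipped", read.read_id)
            continue
        q = _seq.encode(read.sequence)
        rq = _seq.revcomp_codes(q)
        hits: list[tuple[str, int, str, int]] = []
        for chrom, ref in refs.items():
            if len(ref) < read_len:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(ref, read_len)
            match_p = (windows == q) | ((windows == _seq.C) & (q == _seq.T))
            mm_p = read_len - match_p.sum(axis=1)
            match_m = (windows == rq) | ((windows == _seq.G) & (rq == _seq.A))
            mm_m = read_len - match_m.sum(axis=1)
            for start in np.flatnonzero(mm_p <= max_mismatches):
                hits.append((chrom, int(start), "+", int(mm_p[start])))
            for start in np.flatnonzero(mm_m <= max_mismatches):
                hits.append((chrom, int(start), "-", int(mm_m[start])))
        if not hits:
            continue
        best_mm = min(h[3] for h in hits)
        best = sorted(h for h in hits if h[3] == best_mm)
        unique = len(best) == 1
        for chrom, start, strand, mm in best:
            alignments.append(Alignment(idx, read.read_id, chrom, start,
                                        strand, mm, unique))
    return alignments


def pileup_cytosines(
    alignments: list[Alignment],
    reads: ReadSet,
    genome: AnnotatedGenome,
) -> CytosinePileup:
    """Tally converted/unconverted read counts at every reference cytosine.

    Only unique alignments contribute. Plus-strand cytosines (reference C)
    take evidence only from plus-strand alignments; minus-strand cytosines
    (reference G, read laid as its reverse complement) only from
    minus-strand alignments. Read bases other than C/T over a cytosine are
    ignored (sequencing errors).
    """
    pileup = CytosinePileup(genome)
    by_group: dict[tuple[str, str, int], list[Alignment]] = {}
    for aln in alignments:
        if not aln.unique:
            continue
        read_len = len(reads.reads[aln.read_index].sequence)
        if aln.start + read_len > len(genome.chromosomes[aln.chrom]):
            raise ValueError(f"alignment of {aln.read_id} beyond chromosome end")
        by_group.setdefault((aln.chrom, aln.strand, read_len), []).append(aln)

    for (chrom, strand, read_len), group in by_group.items():
        ref = genome.codes(chrom)
        starts = np.array([a.start for a in group])
        qmat = np.empty((len(group), read_len), dtype=np.uint8)
        for i, aln in enumerate(group):
            codes = _seq.encode(reads.reads[aln.read_index].sequence)
            qmat[i] = codes if strand == "+" else _seq.revcomp_codes(codes)
        pos = starts[:, None] + np.arange(read_len)[None, :]
        unc_arr, conv_arr = pileup.counts[chrom][strand]
        if strand == "+":
            site = ref[pos] == _seq.C
            np.add.at(unc_arr, pos[site & (qmat == _seq.C)], 1)
            np.add.at(conv_arr, pos[site & (qmat == _seq.T)], 1)
        else:
            site = ref[pos] == _seq.G
            np.add.at(unc_arr, pos[site & (qmat == _seq.G)], 1)
            np.add.at(conv_arr, pos[site & (qmat == _seq.A)], 1)
    return pileup


def write_sam(
    alignments: list[Alignment],
    reads: ReadSet,
    genome: AnnotatedGenome,
    path,
    unique_only: bool = False,
) -> None:
    """Minimal SAM output (1-based positions, NM mismatch tag, XU uniqueness)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, seq in genome.chromosomes.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(seq)}\n")
        fh.write("@PG\tID:rddmkit\tPN:rddmkit\n")
        for aln in alignments:
            if unique_only and not aln.unique:
                continue
            read = reads.reads[aln.read_index]
            flag = 0 if aln.strand == "+" else 16
            seq = read.sequence if aln.strand == "+" else _seq.revcomp(read.sequence)
            fh.write(
                f"{aln.read_id}\t{flag}\t{aln.chrom}\t{aln.start + 1}\t255\t"
                f"{len(seq)}M\t*\t0\t0\t{seq}\t*\tNM:i:{aln.mismatch_count}\t"
                f"XU:i:{int(aln.unique)}\n"
            )
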