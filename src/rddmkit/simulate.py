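"""Synthetic study generator: annotated toy genome, genotype methylomes, reads.

This module fabricates a complete miniature RdDM study so that every
downstream stage (bisulfite mapping, methylation calling, DMR detection,
siRNA window classification) can be exercised and validated against known
ground truth. The design mirrors the structure of an Arabidopsis-style
genome at desk scale: a few short chromosomes whose pericentromeric cores
are enriched for transposable elements (the targets of RNA-directed DNA
methylation), with protein-coding genes on the arms.

Genotypes model the classical RdDM mutant contrasts, all in a common
"ros1-like" baseline:

* ``ros1``  — baseline; RdDM loci carry full TE methylation and full
  24-nt siRNA output.
* ``nrpd1`` — Pol IV dead: CHG/CHH methylation collapses at every RdDM
  locus and 24-nt siRNA output drops genome-wide.
* ``nrpe1`` — Pol V dead: a subset of RdDM loci (the Pol V-dependent
  ones) lose part of their non-CG methylation and siRNAs.
* ``sta1``  — splicing-factor mutant: like ``nrpe1`` but acting on a
  smaller subset, mostly contained in the Pol V-dependent set.

All randomness flows through :func:`numpy.random.default_rng` seeded from
the caller's ``seed``, so identical parameters reproduce byte-identical
output.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from . import _seq
from ._seq import encode, decode, decode_rows

GENOTYPES = ("ros1", "nrpd1", "nrpe1", "sta1")
CONTEXTS = ("CG", "CHG", "CHH")

#: Per-context methylation probabilities by region class. TE values apply at
#: RdDM loci; gene bodies are CG-only (body methylation), everything else is
#: near-unmethylated background.
DEFAULT_BASE_RATES: dict[str, dict[str, float]] = {
    "TE": {"CG": 0.80, "CHG": 0.50, "CHH": 0.30},
    "gene": {"CG": 0.30, "CHG": 0.0, "CHH": 0.0},
    "background": {"CG": 0.05, "CHG": 0.01, "CHH": 0.01},
}

#: Per-genotype multipliers applied at that genotype's affected loci.
#: nrpd1 hits every RdDM locus hard in non-CG contexts with CG nearly
#: unchanged; nrpe1/sta1 act partially on their own subsets.
DEFAULT_RDDM_LOSS: dict[str, dict[str, float]] = {
    "ros1": {"CG": 1.0, "CHG": 1.0, "CHH": 1.0},
    "nrpd1": {"CG": 0.9, "CHG": 0.1, "CHH": 0.1},
    "nrpe1": {"CG": 1.0, "CHG": 0.4, "CHH": 0.4},
    "sta1": {"CG": 1.0, "CHG": 0.4, "CHH": 0.4},
}

#: Which designed locus class each genotype's siRNA loss applies to, and the
#: abundance multiplier. nrpd1 collapses all clusters >=5-fold; nrpe1/sta1
#: reduce their dependent clusters >=2-fold, per the classification thresholds
#: the analysis applies downstream.
DEFAULT_SIRNA_FOLD_LOSS: dict[str, dict[str, float]] = {
    "ros1": {},
    "nrpd1": {"rddm": 0.1},
    "nrpe1": {"polV": 0.3},
    "sta1": {"sta1": 0.3},
}


class PlacementError(RuntimeError):
    """Raised when non-overlapping feature placement cannot be satisfied."""


@dataclass(frozen=True)
class Feature:
    feature_id: str
    chrom: str
    start: int  # 0-based, half-open
    end: int
    strand: str
    kind: str  # "gene" | "TE"


@dataclass
class AnnotatedGenome:
    """Chromosome sequences plus gene/TE annotation.

    Coordinates are 0-based half-open internally; all text output is
    1-based closed (GFF3 convention).
    """

    chromosomes: dict[str, str]
    features: list[Feature]
    centromere_midpoints: dict[str, int]
    _codes: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for feat in self.features:
            if feat.feature_id in seen:
                raise ValueError(f"duplicate feature id {feat.feature_id!r}")
            seen.add(feat.feature_id)
            if feat.kind not in ("gene", "TE"):
                raise ValueError(f"bad feature kind {feat.kind!r}")
            if feat.chrom not in self.chromosomes:
                raise ValueError(f"feature {feat.feature_id} on unknown chromosome")
            length = len(self.chromosomes[feat.chrom])
            if not (0 <= feat.start < feat.end <= length):
                raise ValueError(f"feature {feat.feature_id} out of bounds")
        for name, seq in self.chromosomes.items():
            if set(seq) - set("ACGT"):
                raise ValueError(f"chromosome {name} contains non-ACGT bases")

    def codes(self, chrom: str) -> np.ndarray:
        """Encoded (A=0,C=1,G=2,T=3) sequence, cached per chromosome."""
        if chrom not in self._codes:
            self._codes[chrom] = encode(self.chromosomes[chrom])
        return self._codes[chrom]

    @property
    def feature_map(self) -> dict[str, Feature]:
        return {f.feature_id: f for f in self.features}

    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    # ---------------------------------------------------------- file I/O
    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self.chromosomes:
                fh.write(f">{name}\n")
                seq = self.chromosomes[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        """Write features as GFF3 (1-based, closed; kind in column 3)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, mid in self.centromere_midpoints.items():
                fh.write(f"##centromere {name} {mid + 1}\n")
            for feat in self.features:
                fh.write(
                    f"{feat.chrom}\trddmkit\t{feat.kind}\t{feat.start + 1}\t"
                    f"{feat.end}\t.\t{feat.strand}\t.\tID={feat.feature_id}\n"
                )

    @classmethod
    def from_files(cls, fasta_path: str | Path, gff3_path: str | Path) -> "AnnotatedGenome":
        import pyfaidx

        fasta = pyfaidx.Fasta(str(fasta_path))
        chromosomes = {name: str(fasta[name][:]).upper() for name in fasta.keys()}
        features: list[Feature] = []
        centromeres: dict[str, int] = {}
        with open(gff3_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("##centromere"):
                    _, name, pos = line.split()
                    centromeres[name] = int(pos) - 1
                    continue
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
                features.append(Feature(
                    feature_id=attrs.get("ID", f"feat{len(features)}"),
                    chrom=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                    kind=cols[2],
                ))
        if not centromeres:
            centromeres = {n: len(s) // 2 for n, s in chromosomes.items()}
        return cls(chromosomes=chromosomes, features=features,
                   centromere_midpoints=centromeres)


@dataclass(frozen=True)
class RdDMDesign:
    """Ground-truth designation of RdDM target loci and their dependencies.

    ``sta1_subset`` and ``polv_subset`` are subsets of ``rddm_loci``; most of
    the STA1-dependent loci also sit in the Pol V-dependent set, emulating
    the strong overlap between downstream-pathway dependencies.
    """

    rddm_loci: frozenset[str]
    polv_subset: frozenset[str]
    sta1_subset: frozenset[str]

    def __post_init__(self) -> None:
        if not self.sta1_subset <= self.rddm_loci:
            raise ValueError("sta1_subset must be a subset of rddm_loci")
        if not self.polv_subset <= self.rddm_loci:
            raise ValueError("polv_subset must be a subset of rddm_loci")

    def multiplier_class(self, feature_id: str) -> set[str]:
        classes: set[str] = set()
        if feature_id in self.rddm_loci:
            classes.add("rddm")
        if feature_id in self.polv_subset:
            classes.add("polV")
        if feature_id in self.sta1_subset:
            classes.add("sta1")
        return classes


def designate_rddm_loci(
    genome: AnnotatedGenome,
    seed: int = 0,
    rddm_fraction: float = 1.0,
    polv_fraction: float = 0.5,
    sta1_fraction: float = 0.3,
    sta1_in_polv: float = 0.95,
) -> RdDMDesign:
    """Pick which TEs are RdDM targets and their Pol V / STA1 dependence.

    ``rddm_fraction`` of the TEs are RdDM loci (all of them by default;
    a smaller fraction leaves genotype-invariant null TEs in the genome).
    ``polv_fraction`` of the RdDM loci are Pol V-dependent and
    ``sta1_fraction`` are STA1-dependent, with ``sta1_in_polv`` of the
    STA1 set drawn from inside the Pol V set (dependence on the downstream
    factors co-occurs at most loci).
    """
    rng = np.random.default_rng([seed, 101])
    all_tes = sorted(f.feature_id for f in genome.features_of_kind("TE"))
    if not all_tes:
        raise ValueError("genome has no TEs to designate as RdDM loci")
    n_rddm = int(round(rddm_fraction * len(all_tes)))
    if n_rddm == 0:
        raise ValueError("rddm_fraction leaves no RdDM loci")
    te_ids = sorted(rng.choice(all_tes, size=n_rddm, replace=False))
    n = len(te_ids)
    n_polv = int(round(polv_fraction * n))
    polv = set(rng.choice(te_ids, size=n_polv, replace=False)) if n_polv else set()
    n_sta1 = int(round(sta1_fraction * n))
    n_inside = min(int(round(sta1_in_polv * n_sta1)), len(polv))
    outside_pool = sorted(set(te_ids) - polv)
    n_outside = min(n_sta1 - n_inside, len(outside_pool))
    sta1: set[str] = set()
    if n_inside:
        sta1 |= set(rng.choice(sorted(polv), size=n_inside, replace=False))
    if n_outside:
        sta1 |= set(rng.choice(outside_pool, size=n_outside, replace=False))
    return RdDMDesign(rddm_loci=frozenset(te_ids),
                      polv_subset=frozenset(polv),
                      sta1_subset=frozenset(sta1))


# --------------------------------------------------------------------------
# genome generation
# --------------------------------------------------------------------------

def generate_genome(
    n_chromosomes: int = 2,
    chrom_length: int = 100_000,
    te_pericentromeric_fraction: float = 0.8,
    n_genes: int = 20,
    n_tes: int = 30,
    seed: int = 0,
    gene_length_range: tuple[int, int] = (1000, 2000),
    te_length_range: tuple[int, int] = (600, 1200),
    max_tries: int = 2000,
) -> AnnotatedGenome:
    """Generate a random annotated genome with pericentromeric TE enrichment.

    ``te_pericentromeric_fraction`` of the TEs land inside the central 20%
    of a chromosome (around the centromere midpoint); the remaining TEs and
    all genes land on the arms. Features never overlap. Deterministic for a
    fixed seed; raises :class:`PlacementError` if the requested features
    cannot be placed without overlap within a bounded number of tries.
    """
    if chrom_length < 50_000:
        raise ValueError("chrom_length must be at least 50,000 bp")
    if not 0.0 <= te_pericentromeric_fraction <= 1.0:
        raise ValueError("te_pericentromeric_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)

    chrom_names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    chromosomes = {
        name: decode(rng.integers(0, 4, size=chrom_length).astype(np.uint8))
        for name in chrom_names
    }
    centromeres = {name: chrom_length // 2 for name in chrom_names}
    peri_half = chrom_length // 10  # central 20% of the chromosome

    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in chrom_names}

    def overlaps(chrom: str, start: int, end: int) -> bool:
        return any(start < e and s < end for s, e in occupied[chrom])

    def place(kind: str, index: int, pericentromeric: bool) -> Feature:
        length_range = te_length_range if kind == "TE" else gene_length_range
        chrom = chrom_names[index % n_chromosomes]
        mid = centromeres[chrom]
        for _ in range(max_tries):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            if pericentromeric:
                lo, hi = mid - peri_half, mid + peri_half - length
            else:
                lo, hi = 0, chrom_length - length
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + length
            in_peri = start >= mid - peri_half and end <= mid + peri_half
            if pericentromeric != in_peri:
                continue
            if overlaps(chrom, start, end):
                continue
            occupied[chrom].append((start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            prefix = "te" if kind == "TE" else "gene"
            return Feature(f"{prefix}{index + 1:04d}", chrom, start, end, strand, kind)
        raise PlacementError(
            f"could not place {kind} #{index + 1} without overlap "
            f"(pericentromeric={pericentromeric}) after {max_tries} tries"
        )

    features: list[Feature] = []
    n_peri = int(round(te_pericentromeric_fraction * n_tes))
    for i in range(n_tes):
        features.append(place("TE", i, pericentromeric=i < n_peri))
    for i in range(n_genes):
        features.append(place("gene", i, pericentromeric=False))

    return AnnotatedGenome(chromosomes=chromosomes, features=features,
                           centromere_midpoints=centromeres)


# --------------------------------------------------------------------------
# methylome models
# --------------------------------------------------------------------------

@dataclass
class MethylomeModel:
    """Per-site methylation probabilities for one genotype.

    ``prob[chrom][strand]`` is a float array over plus-strand coordinates;
    entries at non-cytosine positions (for that strand) are 0. Minus-strand
    cytosines are indexed by the plus-strand coordinate of the reference G.
    """

    genotype: str
    prob: dict[str, dict[str, np.ndarray]]
    rddm_loci: frozenset[str]
    polv_subset: frozenset[str]
    sta1_subset: frozenset[str]

    def probability(self, chrom: str, position: int, strand: str) -> float:
        return float(self.prob[chrom][strand][position])


def build_methylome(
    genome: AnnotatedGenome,
    genotype: str,
    base_rates: Mapping[str, Mapping[str, float]] | None = None,
    rddm_loss: Mapping[str, float] | None = None,
    design: RdDMDesign | None = None,
    seed: int = 0,
) -> MethylomeModel:
    """Build the genotype-conditioned methylome for a genome.

    Probabilities are deterministic per (region class, context, genotype):
    RdDM loci (TEs) carry the TE base rates, gene bodies the gene rates
    (CG-only by default), everything else background. The genotype's
    ``rddm_loss`` multipliers act on its affected locus set: all RdDM loci
    for ``nrpd1``, the Pol V subset for ``nrpe1``, the STA1 subset for
    ``sta1``, nothing for ``ros1``.

    Symmetric CpG sites receive identical probabilities on both strands
    (membership is resolved at the plus-strand C of the pair).
    """
    from .methylation import context_arrays

    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    rates = {k: dict(v) for k, v in (base_rates or DEFAULT_BASE_RATES).items()}
    loss = dict(rddm_loss or DEFAULT_RDDM_LOSS[genotype])
    if design is None:
        if genome.features_of_kind("TE"):
            design = designate_rddm_loci(genome, seed=seed)
        else:
            design = RdDMDesign(frozenset(), frozenset(), frozenset())

    affected: frozenset[str]
    if genotype == "nrpd1":
        affected = design.rddm_loci
    elif genotype == "nrpe1":
        affected = design.polv_subset
    elif genotype == "sta1":
        affected = design.sta1_subset
    else:
        affected = frozenset()

    ctx = context_arrays(genome)
    feature_list = genome.features
    # rate matrix indexed [class, context-1]; classes 0=background 1=gene 2=TE
    rate_matrix = np.array([
        [rates["background"][c] for c in CONTEXTS],
        [rates["gene"][c] for c in CONTEXTS],
        [rates["TE"][c] for c in CONTEXTS],
    ])
    loss_vec = np.array([loss[c] for c in CONTEXTS])

    prob: dict[str, dict[str, np.ndarray]] = {}
    for chrom, seq in genome.chromosomes.items():
        length = len(seq)
        cls = np.zeros(length, dtype=np.int8)
        hit = np.zeros(length, dtype=bool)  # position inside an affected locus
        for feat in feature_list:
            if feat.chrom != chrom:
                continue
            cls[feat.start:feat.end] = 2 if feat.kind == "TE" else 1
            if feat.feature_id in affected:
                hit[feat.start:feat.end] = True
        ctx_plus, ctx_minus = ctx[chrom]
        out: dict[str, np.ndarray] = {}
        for strand, carr in (("+", ctx_plus), ("-", ctx_minus)):
            is_c = carr > 0
            # membership position: for minus-strand CG cytosines use the
            # plus-strand C of the CpG pair so symmetric sites agree exactly
            pos = np.arange(length)
            if strand == "-":
                pos = np.where(carr == 1, np.maximum(pos - 1, 0), pos)
            cidx = np.where(is_c, carr - 1, 0)
            p = rate_matrix[cls[pos], cidx]
            mult = np.where(hit[pos], loss_vec[cidx], 1.0)
            out[strand] = np.where(is_c, p * mult, 0.0)
        prob[chrom] = out

    return MethylomeModel(genotype=genotype, prob=prob,
                          rddm_loci=design.rddm_loci,
                          polv_subset=design.polv_subset,
                          sta1_subset=design.sta1_subset)


# --------------------------------------------------------------------------
# read sets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    chrom: str
    start: int  # 0-based plus-strand coordinate of the leftmost base
    strand: str
    meth_states: str | None = None  # per read base: '.'=non-C, 'M'/'U'
    source: str | None = None  # smallRNA: cluster id / miRNA locus / background


@dataclass
class ReadSet:
    reads: list[SimRead]
    protocol: str  # "bisulfite" | "smallRNA"
    conversion_failure_rate: float = 0.0
    error_rate: float = 0.0

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for read in self.reads:
                fh.write(f"@{read.read_id}\n{read.sequence}\n+\n"
                         f"{'I' * len(read.sequence)}\n")

    def write_truth_tsv(self, path: str | Path) -> None:
        """Ground-truth bookkeeping (1-based start in text, like all output)."""
        with open(path, "w") as fh:
            fh.write("# coordinates: 1-based start of leftmost base\n")
            fh.write("read_id\tchrom\tstart\tstrand\tmeth_states\tsource\n")
            for read in self.reads:
                fh.write(f"{read.read_id}\t{read.chrom}\t{read.start + 1}\t"
                         f"{read.strand}\t{read.meth_states or '.'}\t"
                         f"{read.source or '.'}\n")


def simulate_bisulfite_reads(
    genome: AnnotatedGenome,
    methylome: MethylomeModel,
    depth: float = 50.0,
    read_length: int = 50,
    conversion_rate: float = 0.995,
    error_rate: float = 0.001,
    seed: int = 0,
) -> ReadSet:
    """Simulate single-end bisulfite reads with known ground truth.

    Each read is drawn uniformly from both strands of each chromosome; the
    per-chromosome read count is Poisson with mean depth*L/read_length.
    Cytosines on the originating strand are methylated with the methylome
    probability; unmethylated cytosines are converted C->T with probability
    ``conversion_rate`` (a conversion failure leaves an unmethylated C);
    methylated cytosines always stay C. Sequencing errors substitute each
    base independently with probability ``error_rate``.
    """
    if not 0.9 < conversion_rate <= 1.0:
        raise ValueError("conversion_rate must be in (0.9, 1.0]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if any(read_length > len(s) for s in genome.chromosomes.values()):
        raise ValueError("read_length exceeds a chromosome length")
    rng = np.random.default_rng(seed)

    reads: list[SimRead] = []
    counter = 0
    for chrom, seq in genome.chromosomes.items():
        length = len(seq)
        ref = genome.codes(chrom)
        n_reads = int(rng.poisson(depth * length / read_length))
        starts = rng.integers(0, length - read_length + 1, size=n_reads)
        strands = rng.random(n_reads) < 0.5  # True = plus
        for is_plus in (True, False):
            sel = np.flatnonzero(strands == is_plus)
            if sel.size == 0:
                continue
            sub_starts = starts[sel]
            offs = np.arange(read_length)
            if is_plus:
                pos = sub_starts[:, None] + offs[None, :]
                codes = ref[pos].copy()
                prob = methylome.prob[chrom]["+"][pos]
            else:
                pos = sub_starts[:, None] + (read_length - 1 - offs)[None, :]
                codes = (3 - ref[pos])
                prob = methylome.prob[chrom]["-"][pos]
            is_c = codes == _seq.C
            meth = (rng.random(codes.shape) < prob) & is_c
            unmeth = is_c & ~meth
            converted = unmeth & (rng.random(codes.shape) < conversion_rate)
            codes[converted] = _seq.T
            states = np.full(codes.shape, ord("."), dtype=np.uint8)
            states[meth] = ord("M")
            states[unmeth] = ord("U")
            if error_rate > 0:
                err = rng.random(codes.shape) < error_rate
                shift = rng.integers(1, 4, size=codes.shape)
                codes = np.where(err, (codes + shift) % 4, codes).astype(np.uint8)
            seqs = decode_rows(codes)
            n_rows, width = states.shape
            state_bytes = states.tobytes()
            strand_char = "+" if is_plus else "-"
            for i in range(len(sel)):
                reads.append(SimRead(
                    read_id=f"bs_{chrom}_{counter + i}",
                    sequence=seqs[i],
                    chrom=chrom,
                    start=int(sub_starts[i]),
                    strand=strand_char,
                    meth_states=state_bytes[i * width:(i + 1) * width].decode(),
                ))
            counter += len(sel)

    return ReadSet(reads=reads, protocol="bisulfite",
                   conversion_failure_rate=1.0 - conversion_rate,
                   error_rate=error_rate)


def simulate_smallrna_reads(
    genome: AnnotatedGenome,
    genotype: str,
    design: RdDMDesign | None = None,
    cluster_abundance: Mapping[str, float] | None = None,
    fold_loss: Mapping[str, Mapping[str, float]] | None = None,
    total_reads: int = 200_000,
    mirna_fraction: float = 0.05,
    n_mirna_loci: int = 3,
    cluster_fraction: float = 0.6,
    seed: int = 0,
) -> ReadSet:
    """Simulate a small-RNA library for one genotype.

    24-nt siRNA reads are Poisson-sampled from RdDM clusters (TEs) with
    genotype-scaled expectations; 21-nt miRNA-like reads come from fixed
    positions in a few gene loci with genotype-independent expectation;
    the remainder of the library is uniform 18-30-nt background. Every read
    is an exact genome substring and carries its source in the bookkeeping.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    rng = np.random.default_rng(seed)
    if design is None:
        design = designate_rddm_loci(genome, seed=seed)
    fmap = genome.feature_map

    if cluster_abundance is None:
        te_ids = sorted(design.rddm_loci)
        per = cluster_fraction * total_reads / max(len(te_ids), 1)
        cluster_abundance = {t: per for t in te_ids}
    unknown = set(cluster_abundance) - set(fmap)
    if unknown:
        raise ValueError(f"cluster_abundance references unknown features: {sorted(unknown)}")
    loss_map = (fold_loss or DEFAULT_SIRNA_FOLD_LOSS)[genotype]

    reads: list[SimRead] = []
    counter = 0

    def emit(chrom: str, start: int, length: int, strand: str, source: str) -> None:
        nonlocal counter
        ref = genome.codes(chrom)
        codes = ref[start:start + length]
        if strand == "-":
            codes = _seq.revcomp_codes(codes)
        reads.append(SimRead(
            read_id=f"sr_{genotype}_{counter}", sequence=decode(codes),
            chrom=chrom, start=start, strand=strand, source=source,
        ))
        counter += 1

    # siRNA clusters (24 nt)
    for fid in sorted(cluster_abundance):
        feat = fmap[fid]
        mult = 1.0
        for cls in design.multiplier_class(fid):
            if cls in loss_map:
                mult = min(mult, loss_map[cls])
        n = int(rng.poisson(cluster_abundance[fid] * mult))
        span = feat.end - feat.start - 24
        if span <= 0:
            raise ValueError(f"cluster {fid} shorter than 24 nt")
        starts = rng.integers(feat.start, feat.start + span + 1, size=n)
        strands = rng.random(n) < 0.5
        for s, plus in zip(starts, strands):
            emit(feat.chrom, int(s), 24, "+" if plus else "-", fid)

    # miRNA-like species (21 nt, fixed loci, genotype-independent)
    gene_ids = sorted(f.feature_id for f in genome.features_of_kind("gene"))
    mirna_loci = gene_ids[:n_mirna_loci]
    if mirna_loci:
        per_locus = mirna_fraction * total_reads / len(mirna_loci)
        for gid in mirna_loci:
            feat = fmap[gid]
            n = int(rng.poisson(per_locus))
            start = feat.start + 10
            for _ in range(n):
                emit(feat.chrom, start, 21, "+", f"miRNA:{gid}")

    # uniform background filling up to the library total
    n_background = max(total_reads - len(reads), 0)
    chrom_names = sorted(genome.chromosomes)
    lengths = np.array([len(genome.chromosomes[c]) for c in chrom_names], dtype=float)
    chrom_pick = rng.choice(len(chrom_names), size=n_background, p=lengths / lengths.sum())
    read_lens = rng.integers(18, 31, size=n_background)
    strand_pick = rng.random(n_background) < 0.5
    for ci, rl, plus in zip(chrom_pick, read_lens, strand_pick):
        chrom = chrom_names[ci]
        start = int(rng.integers(0, len(genome.chromosomes[chrom]) - int(rl) + 1))
        emit(chrom, start, int(rl), "+" if plus else "-", "background")

    return ReadSet(reads=reads, protocol="smallRNA", error_rate=0.0)
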