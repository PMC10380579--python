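"""Synthetic circular mitogenomes with truth-annotated sequencing reads.

The generator emulates the data structure the analysis modules assume, at
toy scale: a small circular genome with a two-strand gene layout in the
style of published mitogenome organisation tables, perfect inverted repeats
planted inside coding genes, a DNA-seq library with hairpin-length-
dependent read dropout, and an RNA-seq library derived from polycistronic
per-strand precursors that are cleaved at planted sites, polyadenylated
(with optional non-templated CCA at tRNA 3' ends), sampled with a 3'
coverage bias, and likewise thinned over hairpins (reverse-transcription
dropout).  Reads are emitted pre-aligned as truth SAM, so the pipeline is
testable without an external mapper; every planted feature is recorded in a
:class:`TruthSet` sufficient to score the detectors exactly.

All randomness flows from one integer-seeded generator; the same seed
yields byte-identical FASTA/SAM/JSON outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pysam

from .coverage import AlignmentRecord
from .genome import CircularSequence, GeneRecord, GeneTable, revcomp

_NONPAIRING = {"A": "A", "T": "T", "G": "G", "C": "C"}  # x never pairs with x


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSpec:
    """One gene in the synthetic layout: name, strand, length in bp."""

    name: str
    strand: str
    length: int
    gene_class: str = ""


@dataclass(frozen=True)
class CleavageSpec:
    """A planted precursor cleavage/polyadenylation point.

    The site is the 3'-terminal base (transcript sense) of ``after_gene``;
    ``usage`` is the per-molecule probability that the precursor is cut
    there.  Sites at tRNA 3' ends additionally receive non-templated CCA
    before the tail with the configured probability.
    """

    after_gene: str
    usage: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.usage <= 1.0:
            raise ValueError("usage must be in [0, 1]")


#: Default layout: a miniature of the nematomorph arrangement -- a long (+)
#: block of PCGs interleaved with tRNAs, a (-) block with a tRNA and an
#: rRNA, small intergenic gaps.
DEFAULT_LAYOUT: tuple[GeneSpec, ...] = (
    GeneSpec("cox1", "+", 900),
    GeneSpec("cox2", "+", 600),
    GeneSpec("trnK", "+", 60),
    GeneSpec("trnD", "+", 60),
    GeneSpec("atp8", "+", 120),
    GeneSpec("atp6", "+", 480),
    GeneSpec("nad3", "+", 300),
    GeneSpec("trnA", "+", 60),
    GeneSpec("trnR", "+", 60),
    GeneSpec("nad6", "+", 400),
    GeneSpec("cytb", "+", 500),
    GeneSpec("nad2", "-", 600),
    GeneSpec("trnV", "-", 60),
    GeneSpec("rrnS", "-", 500),
)

#: Default planted cleavage points: 12 sites.  Every PCG boundary is cut
#: somewhere except nad6|cytb (their mRNA stays bicistronic); cox2 and nad3
#: illustrate tRNA-punctuated 3' UTRs (sites after trnK/trnD and trnR),
#: with a partial-usage site directly after the nad3 ORF as well.
DEFAULT_CLEAVAGE: tuple[CleavageSpec, ...] = (
    CleavageSpec("cox1", 1.0),
    CleavageSpec("trnK", 1.0),
    CleavageSpec("trnD", 1.0),
    CleavageSpec("atp8", 1.0),
    CleavageSpec("atp6", 1.0),
    CleavageSpec("nad3", 0.5),
    CleavageSpec("trnR", 1.0),
    CleavageSpec("cytb", 1.0),
    CleavageSpec("nad2", 1.0),
    CleavageSpec("trnV", 1.0),
    CleavageSpec("rrnS", 1.0),
    CleavageSpec("cox2", 0.5),
)

#: Default planted repeats: (gene, stem_len, loop_len).  Stems of 30+ bp are
#: the 'long' class associated with DNA dropout; the short one is below it.
DEFAULT_REPEATS: tuple[tuple[str, int, int], ...] = (
    ("atp6", 30, 8),
    ("nad6", 40, 6),
    ("nad2", 35, 10),
    ("cytb", 12, 5),
)


def _step_dropout(threshold: int, p: float) -> Callable[[int], float]:
    return lambda stem: p if stem >= threshold else 0.0


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the standard toy study.

    ``dna_dropout``/``rna_dropout`` map a hairpin stem length to the
    probability that a read overlapping the hairpin is lost (sequencing
    dropout for DNA, reverse-transcription dropout for RNA).
    """

    seed: int = 0
    genome_length: int = 6000
    layout: Sequence[GeneSpec] = DEFAULT_LAYOUT
    planted_repeats: Sequence[tuple[str, int, int]] = DEFAULT_REPEATS
    cleavage: Sequence[CleavageSpec] = DEFAULT_CLEAVAGE
    dna_depth: float = 100.0
    rna_depth: float = 50.0
    read_len: int = 150
    min_gap: int = 4
    max_gap: int = 20
    dna_dropout: Callable[[int], float] = field(default=_step_dropout(30, 0.8))
    rna_dropout: Callable[[int], float] = field(default=_step_dropout(20, 0.8))
    tail_mean: float = 30.0          # geometric poly(A) tail length
    cca_prob: float = 0.8            # CCA before tail at tRNA 3' ends
    three_prime_bias: float = 2.0    # exponent of within-transcript 3' weighting
    min_anchor: int = 20             # min templated bases for an RNA read
    wrap_policy: str = "truncate"    # "truncate" or "reject" at the origin
    substitution_rate: float = 0.0   # optional sequencing-error rate

    def __post_init__(self) -> None:
        for p in (self.cca_prob, self.substitution_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.wrap_policy not in ("truncate", "reject"):
            raise ValueError(f"unknown wrap_policy {self.wrap_policy!r}")


@dataclass
class PlantedRepeat:
    gene: str
    left_start: int  # 1-based
    stem_len: int
    loop_len: int


@dataclass
class PlantedSite:
    site: int        # 1-based genomic position of the last templated base
    strand: str
    usage: float
    is_trna_end: bool
    after_gene: str


@dataclass
class TruthSet:
    """Ground truth of one simulation, sufficient to score every detector."""

    planted_repeats: list[PlantedRepeat] = field(default_factory=list)
    cleavage_sites: list[PlantedSite] = field(default_factory=list)
    cca_sites: list[int] = field(default_factory=list)
    n_dna_reads: int = 0
    n_rna_reads: int = 0
    n_tail_reads_per_site: dict[int, int] = field(default_factory=dict)
    read_provenance: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_repeats": [asdict(r) for r in self.planted_repeats],
            "cleavage_sites": [asdict(s) for s in self.cleavage_sites],
            "cca_sites": self.cca_sites,
            "n_dna_reads": self.n_dna_reads,
            "n_rna_reads": self.n_rna_reads,
            "n_tail_reads_per_site": {str(k): v for k, v in
                                      sorted(self.n_tail_reads_per_site.items())},
            "read_provenance": self.read_provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def simulate_genome(
    config: SimulationConfig,
) -> tuple[CircularSequence, GeneTable, TruthSet]:
    """Random circular genome with a gene layout and planted hairpins.

    Genes are laid out in order with small random intergenic gaps; each
    planted repeat is written inside its gene (right stem as the exact
    reverse complement of the left) and is made exactly maximal by forcing
    the flanking and innermost-loop bases to be non-pairing, so detectors
    must recover the planted (position, stem, loop) verbatim.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    seq = list("".join(rng.choice(list("ACGT"), size=L)))

    # lay out genes
    records: list[GeneRecord] = []
    pos0 = 0
    for spec in config.layout:
        gap = int(rng.integers(config.min_gap, config.max_gap + 1))
        start0 = pos0 + gap
        stop0 = start0 + spec.length  # half-open
        if stop0 > L:
            raise ValueError(
                f"layout does not fit in genome_length={L} (at gene {spec.name})"
            )
        records.append(
            GeneRecord(spec.name, spec.strand, start0 + 1, stop0, spec.gene_class)
        )
        pos0 = stop0
    table = GeneTable("synthetic_mito", L, records)

    truth = TruthSet()

    # plant repeats inside genes, exactly maximal
    occupied: list[tuple[int, int]] = []
    for gene_name, stem, loop in config.planted_repeats:
        g = table.get(gene_name)
        g0, g1 = g.interval(L)
        footprint = 2 * stem + loop
        # keep the repeat clear of the gene's transcript 3' end by one read
        # length, so hairpin dropout cannot erase the tail reads that anchor
        # the cleavage site there: the planted signals stay separable
        margin = min(config.read_len, max(0, (g1 - g0) - footprint - 3))
        lo = g0 + 1 if g.strand == "+" else g0 + 1 + margin
        hi = (g1 - footprint - 1 - margin) if g.strand == "+" else g1 - footprint - 1
        if footprint + 2 > g1 - g0 or hi <= lo:
            raise ValueError(
                f"planted repeat ({stem},{loop}) does not fit inside {gene_name}"
            )
        for _ in range(200):
            left0 = int(rng.integers(lo, hi))
            span = (left0 - 1, left0 + footprint + 1)
            if all(span[1] <= a or span[0] >= b for a, b in occupied):
                break
        else:
            raise ValueError(f"cannot place planted repeat in {gene_name}")
        occupied.append(span)
        stem_seq = "".join(rng.choice(list("ACGT"), size=stem))
        loop_seq = "".join(rng.choice(list("ACGT"), size=loop))
        seq[left0 : left0 + stem] = stem_seq
        seq[left0 + stem : left0 + stem + loop] = loop_seq
        seq[left0 + stem + loop : left0 + footprint] = revcomp(stem_seq)
        # block outward extension: flank bases equal => never complementary
        seq[left0 - 1] = "A"
        seq[left0 + footprint] = "A"
        # block inward extension: innermost loop bases equal
        if loop >= 2:
            seq[left0 + stem] = "G"
            seq[left0 + stem + loop - 1] = "G"
        truth.planted_repeats.append(PlantedRepeat(gene_name, left0 + 1, stem, loop))

    # plant cleavage sites at gene 3' ends; guarantee the tails are
    # recognisably non-templated by forcing the next transcript-sense base
    for spec in config.cleavage:
        g = table.get(spec.after_gene)
        site = g.three_prime(L)
        is_trna = g.gene_class == "tRNA"
        nxt0 = site % L if g.strand == "+" else (site - 2) % L
        # next base must differ from the tail start (A, or C for CCA sites)
        want_not = {"A", "C"} if is_trna else {"A"}
        if (seq[nxt0] if g.strand == "+" else revcomp(seq[nxt0])) in want_not:
            repl = "T" if g.strand == "+" else "A"  # reads as T on gene strand
            if not any(a <= nxt0 < b for a, b in occupied):
                seq[nxt0] = repl
        truth.cleavage_sites.append(
            PlantedSite(site, g.strand, spec.usage, is_trna, g.name)
        )
        if is_trna:
            # the forced first base also guarantees the genome is CCA-free
            # at the clip positions, so observed CCA is truly non-templated
            truth.cca_sites.append(site)

    genome = CircularSequence("synthetic_mito", "".join(seq))
    return genome, table, truth


# ---------------------------------------------------------------------------
# SAM plumbing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimRead:
    """A simulated aligned read, ready for SAM serialisation."""

    read_id: str
    ref_start: int          # 1-based
    cigar: str
    seq: str                # reference-forward orientation, clips included
    strand: str


def sim_reads_to_sam(
    reads: Sequence[SimRead], genome_id: str, L: int, path: str | Path
) -> None:
    """Write truth alignments as a headered SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": genome_id, "LN": L}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.reference_id = 0
            a.reference_start = r.ref_start - 1
            a.cigarstring = r.cigar
            a.query_sequence = r.seq
            a.mapping_quality = 60
            a.flag = 16 if r.strand == "-" else 0
            out.write(a)


def to_alignment_records(reads: Sequence[SimRead]) -> list[AlignmentRecord]:
    """In-memory equivalent of writing SAM and re-reading it."""
    out = []
    for r in reads:
        ops = []
        n = ""
        for ch in r.cigar:
            if ch.isdigit():
                n += ch
            else:
                ops.append((ch, int(n)))
                n = ""
        aligned_len = sum(k for op, k in ops if op in "M=XD")
        left = ops[0][1] if ops[0][0] == "S" else 0
        right = ops[-1][1] if ops[-1][0] == "S" else 0
        out.append(
            AlignmentRecord(
                read_id=r.read_id,
                ref_start=r.ref_start,
                aligned_len=aligned_len,
                strand=r.strand,
                left_clip_seq=r.seq[:left],
                right_clip_seq=r.seq[len(r.seq) - right:] if right else "",
            )
        )
    return out


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = "ACGT"[int(rng.integers(0, 4))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# DNA library
# ---------------------------------------------------------------------------

def _repeat_footprints(truth: TruthSet) -> list[tuple[int, int, int]]:
    """(start0, stop0_halfopen, stem_len) for each planted repeat."""
    return [
        (r.left_start - 1, r.left_start - 1 + 2 * r.stem_len + r.loop_len, r.stem_len)
        for r in truth.planted_repeats
    ]


def _max_dropout(
    start0: int, stop0: int, footprints, dropout: Callable[[int], float]
) -> float:
    p = 0.0
    for a, b, stem in footprints:
        if start0 < b and a < stop0:
            p = max(p, dropout(stem))
    return p


def simulate_dna_reads(
    genome: CircularSequence,
    truth: TruthSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[SimRead], TruthSet]:
    """Uniform genomic reads with hairpin-length-dependent dropout.

    Read starts are uniform on the circle; a read overlapping a planted
    hairpin is retained with probability ``1 - dna_dropout(stem_len)`` (the
    largest overlapped stem governs).  Reads crossing the origin are
    truncated at the cut with the overhang soft-clipped -- the behaviour of
    a linear mapper on a circular molecule -- or rejected, per
    ``wrap_policy``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    L = len(genome)
    n_target = int(round(config.dna_depth * L / config.read_len))
    footprints = _repeat_footprints(truth)
    reads: list[SimRead] = []
    i = 0
    attempts = 0
    while len(reads) < n_target and attempts < 50 * n_target + 100:
        attempts += 1
        start0 = int(rng.integers(0, L))
        strand = "+" if rng.random() < 0.5 else "-"
        end0 = start0 + config.read_len  # half-open, may pass L
        if end0 > L and config.wrap_policy == "reject":
            continue
        p_drop = _max_dropout(start0, min(end0, L), footprints, config.dna_dropout)
        if end0 > L:
            p_drop = max(p_drop, _max_dropout(0, end0 - L, footprints, config.dna_dropout))
        i += 1
        rid = f"dna_{i:07d}"
        if rng.random() < p_drop:
            continue  # read lost to the hairpin
        if end0 <= L:
            cigar = f"{config.read_len}M"
            seq = genome.fetch(start0, config.read_len)
            ref_start = start0 + 1
        else:
            len1 = L - start0
            len2 = end0 - L
            full = genome.fetch(start0, config.read_len)
            if len1 >= len2:  # keep the left piece, clip the overhang
                cigar = f"{len1}M{len2}S"
                ref_start = start0 + 1
            else:  # the mapper places the wrapped piece at the origin
                cigar = f"{len1}S{len2}M"
                ref_start = 1
            seq = full
        seq = _apply_errors(seq, config.substitution_rate, rng)
        reads.append(SimRead(rid, ref_start, cigar, seq, strand))
        truth.read_provenance[rid] = {"library": "DNA", "start": start0 + 1,
                                      "strand": strand}
    truth.n_dna_reads = len(reads)
    return reads, truth


# ---------------------------------------------------------------------------
# RNA library
# ---------------------------------------------------------------------------

def _fragments_for_pattern(
    active_sites: list[PlantedSite], strand: str, L: int
) -> list[tuple[int, int, int]]:
    """Mature fragments (g5, g3, length) for one cleavage pattern.

    The per-strand precursor is the whole circle; cutting after each active
    site (transcript sense) yields arcs whose 3' terminal base is a site.
    """
    if not active_sites:
        return []
    if strand == "+":
        cuts = sorted(s.site for s in active_sites)
        frags = []
        for i, s in enumerate(cuts):
            prev = cuts[i - 1]
            g5 = prev % L + 1
            length = (s - prev) % L or L
            frags.append((g5, s, length))
        return frags
    cuts = sorted((s.site for s in active_sites), reverse=True)
    frags = []
    for i, s in enumerate(cuts):
        prev = cuts[i - 1]
        g5 = (prev - 2) % L + 1
        length = (prev - s) % L or L
        frags.append((g5, s, length))
    return frags


def simulate_rna_reads(
    genome: CircularSequence,
    table: GeneTable,
    truth: TruthSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[SimRead], TruthSet]:
    """Reads from cleaved, polyadenylated per-strand precursors.

    Per read: a cleavage pattern is drawn (each planted site cuts with its
    usage probability), a mature fragment is chosen in proportion to its
    length, a poly(A) tail (geometric, plus CCA at tRNA ends) is appended,
    and the read's 3' end is placed with the configured 3' bias.  Tail
    bases beyond the last templated base become soft clips in the SAM;
    reads overlapping planted hairpins are dropped with the RNA dropout
    probability (reverse-transcription failure).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    L = len(genome)
    n_target = int(round(config.rna_depth * L / config.read_len))
    footprints = _repeat_footprints(truth)
    sites_by_strand = {
        st: [s for s in truth.cleavage_sites if s.strand == st] for st in "+-"
    }
    strands = [st for st in "+-" if sites_by_strand[st]]
    if not strands:
        truth.n_rna_reads = 0
        return [], truth
    reads: list[SimRead] = []
    i = 0
    attempts = 0
    p_geom = min(1.0, 1.0 / max(config.tail_mean, 1.0))
    while len(reads) < n_target and attempts < 100 * n_target + 100:
        attempts += 1
        strand = strands[int(rng.integers(0, len(strands)))]
        pattern = [s for s in sites_by_strand[strand] if rng.random() < s.usage]
        frags = _fragments_for_pattern(pattern, strand, L)
        if not frags:
            continue
        lengths = np.array([f[2] for f in frags], dtype=float)
        fi = int(rng.choice(len(frags), p=lengths / lengths.sum()))
        g5, g3, n = frags[fi]
        end_site = next(s for s in pattern if s.site == g3)
        tail_len = int(rng.geometric(p_geom))
        cca = end_site.is_trna_end and rng.random() < config.cca_prob
        extra = ("CCA" if cca else "") + "A" * tail_len
        nm = n + len(extra)
        # read 3' end position (1-based in molecule), 3'-biased
        if config.three_prime_bias > 0:
            u = rng.random()
            q = int(np.ceil(nm * u ** (1.0 / (config.three_prime_bias + 1))))
        else:
            q = int(rng.integers(1, nm + 1))
        q = max(1, min(q, nm))
        a = max(1, q - config.read_len + 1)
        templ_hi = min(q, n)   # last templated molecule position covered
        if templ_hi < a or templ_hi - a + 1 < config.min_anchor:
            continue  # read (almost) entirely in the tail: unmappable
        clip = extra[: q - n] if q > n else ""
        # genomic coordinates of templated part [a .. templ_hi]
        if strand == "+":
            gstart0 = (g5 - 1 + (a - 1)) % L
            gspan = templ_hi - a + 1
            gend0 = gstart0 + gspan  # half-open, may wrap
        else:
            # molecule position 1 is g5, moving downward
            ghi0 = (g5 - 1 - (a - 1)) % L          # genomic of molecule pos a
            glo0 = (g5 - 1 - (templ_hi - 1)) % L   # genomic of molecule pos templ_hi
            gstart0 = glo0
            gspan = templ_hi - a + 1
            gend0 = gstart0 + gspan
        # origin handling: fragments never wrap an active cut, but may wrap
        # the sequence origin; a linear mapper truncates there.
        i += 1
        rid = f"rna_{i:07d}"
        if gend0 > L:
            if config.wrap_policy == "reject":
                continue
            # keep the piece carrying the 3' end (and the tail clip)
            if strand == "+":
                keep_lo = 0 if (gend0 - L) > (L - gstart0) else gstart0
                if keep_lo == 0:
                    gspan = gend0 - L
                    gstart0 = 0
                else:
                    # 3' end wraps away: drop the tail part, clip at L
                    gspan = L - gstart0
                    clip = ""
            else:
                if (gend0 - L) >= (L - gstart0):
                    gspan = gend0 - L
                    gstart0 = 0
                    clip = ""  # 5' piece lost, 3' (left, genomic) kept? see below
                else:
                    gspan = L - gstart0
            if gspan < config.min_anchor:
                continue
        p_drop = _max_dropout(gstart0, gstart0 + gspan, footprints, config.rna_dropout)
        if rng.random() < p_drop:
            continue
        templated = genome.fetch(gstart0, gspan)
        if strand == "+":
            cigar = f"{gspan}M{len(clip)}S" if clip else f"{gspan}M"
            seq = templated + clip
        else:
            cigar = f"{len(clip)}S{gspan}M" if clip else f"{gspan}M"
            seq = (revcomp(clip) if clip else "") + templated
        seq = _apply_errors(seq, config.substitution_rate, rng)
        reads.append(SimRead(rid, gstart0 + 1, cigar, seq, strand))
        prov = {"library": "RNA", "strand": strand, "fragment_3p": g3,
                "has_tail": bool(clip), "cca": bool(cca and clip)}
        truth.read_provenance[rid] = prov
        if clip:
            truth.n_tail_reads_per_site[g3] = truth.n_tail_reads_per_site.get(g3, 0) + 1
    truth.n_rna_reads = len(reads)
    return reads, truth


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimulationConfig, out_dir: str | Path | None = None):
    """Genome + annotation + DNA and RNA truth reads (+ files if out_dir).

    Returns ``(genome, table, dna_reads, rna_reads, truth)``; with
    ``out_dir`` also writes genome.fasta, genes.tsv, dna.sam, rna.sam and
    truth.json.
    """
    genome, table, truth = simulate_genome(config)
    dna, truth = simulate_dna_reads(genome, truth, config)
    rna, truth = simulate_rna_reads(genome, table, truth, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        genome.to_fasta(out / "genome.fasta")
        table.to_tsv(out / "genes.tsv")
        sim_reads_to_sam(dna, genome.id, len(genome), out / "dna.sam")
        sim_reads_to_sam(rna, genome.id, len(genome), out / "rna.sam")
        truth.to_json(out / "truth.json")
    return genome, table, dna, rna, truth
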