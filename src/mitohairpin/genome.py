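"""Circular mitochondrial genome and annotation model.

Small metazoan mitogenomes are single circular DNA molecules of ~14 kb
carrying a canonical set of 37 genes (13 protein-coding genes, 22 tRNAs,
2 rRNAs) with almost no intergenic space.  This module holds the genome as a
circular string, the annotation as an ordered table of 1-based inclusive
gene intervals (the convention of published organisation tables), and
implements the composition statistics (base percentages, AT/GC skew), the
circular intergenic complement, annotation validation, and origin rotation.

Coordinate conventions
----------------------
External I/O is 1-based inclusive; origin-spanning genes are written with
``stop < start``.  Internally every interval is converted to 0-based
half-open through :func:`to_internal` / :func:`to_external`, and circular
arithmetic is done modulo the genome length.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Strand = str  # "+" or "-"


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# coordinate conversion (centralised; everything else goes through these)
# ---------------------------------------------------------------------------

def to_internal(start: int, stop: int, length: int) -> tuple[int, int]:
    """1-based inclusive (possibly origin-spanning) -> 0-based half-open.

    Returns ``(start0, stop0)`` with ``stop0 > start0``; an origin-spanning
    interval is unwrapped so that ``stop0`` may exceed ``length`` (positions
    are taken modulo ``length`` when materialised).
    """
    if not (1 <= start <= length and 1 <= stop <= length):
        raise ValueError(
            f"coordinates ({start}, {stop}) outside genome of length {length}"
        )
    start0 = start - 1
    stop0 = stop if stop >= start else stop + length
    return start0, stop0


def to_external(start0: int, stop0: int, length: int) -> tuple[int, int]:
    """0-based half-open (possibly unwrapped) -> 1-based inclusive."""
    return start0 % length + 1, (stop0 - 1) % length + 1


def interval_positions(start0: int, stop0: int, length: int) -> np.ndarray:
    """0-based positions of an (unwrapped) half-open circular interval."""
    return np.arange(start0, stop0) % length


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircularSequence:
    """A circular DNA sequence over {A,C,G,T,N}.

    Indexing with an integer is modulo the length; :meth:`fetch` extracts a
    (possibly origin-wrapping) subsequence.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains unsupported characters {sorted(bad)}; "
                "only A,C,G,T,N are accepted"
            )
        if not self.seq:
            raise ValueError("empty sequence")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    def __getitem__(self, i: int) -> str:
        return self.seq[i % len(self.seq)]

    def fetch(self, start0: int, length: int) -> str:
        """Subsequence of ``length`` bases starting at 0-based ``start0``, wrapping."""
        L = len(self.seq)
        start0 %= L
        if start0 + length <= L:
            return self.seq[start0 : start0 + length]
        doubled = self.seq + self.seq
        return doubled[start0 : start0 + length] if length <= L else ""

    def reverse_complement(self) -> "CircularSequence":
        return CircularSequence(self.id, revcomp(self.seq))

    def rotated(self, new_origin: int) -> "CircularSequence":
        """Sequence cut so that 1-based ``new_origin`` becomes position 1."""
        L = len(self.seq)
        if not 1 <= new_origin <= L:
            raise ValueError(f"rotation origin {new_origin} outside 1..{L}")
        k = new_origin - 1
        return CircularSequence(self.id, self.seq[k:] + self.seq[:k])

    @classmethod
    def from_fasta(cls, path: str | Path) -> "CircularSequence":
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(
                f"{path}: expected a single-record FASTA, found {len(records)} records"
            )
        rec = records[0]
        return cls(rec.id, str(rec.seq))

    def to_fasta(self, path: str | Path) -> None:
        rec = SeqRecord(Seq(self.seq), id=self.id, description="")
        with open(path, "w") as fh:
            SeqIO.write([rec], fh, "fasta")


GENE_CLASSES = ("PCG", "tRNA", "rRNA")


def infer_gene_class(name: str) -> str:
    if name.startswith("trn"):
        return "tRNA"
    if name.startswith("rrn"):
        return "rRNA"
    return "PCG"


@dataclass
class GeneRecord:
    """One annotated gene with 1-based inclusive circular coordinates."""

    name: str
    strand: Strand
    start: int
    stop: int
    gene_class: str = ""
    start_codon: str = ""
    stop_codon: str = ""
    has_repeat: bool | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.name}: strand must be '+' or '-', got {self.strand!r}")
        if not self.gene_class:
            self.gene_class = infer_gene_class(self.name)
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"{self.name}: unknown gene class {self.gene_class!r}")

    def length(self, genome_length: int) -> int:
        start0, stop0 = to_internal(self.start, self.stop, genome_length)
        return stop0 - start0

    def interval(self, genome_length: int) -> tuple[int, int]:
        """0-based half-open (possibly unwrapped past L) interval."""
        return to_internal(self.start, self.stop, genome_length)

    def three_prime(self, genome_length: int) -> int:
        """1-based genomic position of the gene's 3' terminal base."""
        return self.stop if self.strand == "+" else self.start

    def five_prime(self, genome_length: int) -> int:
        return self.start if self.strand == "+" else self.stop


@dataclass
class GeneTable:
    """Ordered annotation of a circular genome (organisation-table layout)."""

    genome_id: str
    genome_length: int
    records: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate gene names: {sorted(dupes)}")
        for r in self.records:
            to_internal(r.start, r.stop, self.genome_length)  # validates range

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    def get(self, name: str) -> GeneRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def by_class(self, gene_class: str) -> list[GeneRecord]:
        return [r for r in self.records if r.gene_class == gene_class]

    def class_counts(self) -> dict[str, int]:
        return {c: len(self.by_class(c)) for c in GENE_CLASSES}

    # -- I/O ---------------------------------------------------------------

    TSV_HEADER = ["gene", "strand", "start", "stop", "class", "start_codon", "stop_codon"]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(self.TSV_HEADER) + "\n")
            for r in self.records:
                fh.write(
                    "\t".join(
                        [r.name, r.strand, str(r.start), str(r.stop), r.gene_class,
                         r.start_codon, r.stop_codon]
                    )
                    + "\n"
                )

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {self.genome_id} 1 {self.genome_length}\n")
            for r in self.records:
                attrs = f"Name={r.name};gene_class={r.gene_class}"
                fh.write(
                    "\t".join(
                        [self.genome_id, "mitohairpin", "gene", str(r.start),
                         str(r.stop), ".", r.strand, ".", attrs]
                    )
                    + "\n"
                )


def read_gene_table(
    path: str | Path,
    dialect: str = "tsv",
    genome_id: str = "",
    genome_length: int = 0,
) -> GeneTable:
    """Read an annotation table (TSV with the standard header, or GFF3).

    The TSV layout mirrors published mitogenome organisation tables: columns
    ``gene  strand  start  stop  class  start_codon  stop_codon`` with
    1-based inclusive coordinates; ``class`` may be empty (inferred from the
    gene-name prefix).  GFF3 input uses ``type=gene`` lines with ``Name``
    and optional ``gene_class`` attributes.
    """
    path = Path(path)
    if dialect not in ("tsv", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[GeneRecord] = []
    lines = path.read_text().splitlines()
    if dialect == "tsv":
        body = [ln for ln in lines if ln.strip()]
        if not body:
            logger.warning("%s: empty annotation file", path)
            return GeneTable(genome_id or path.stem, genome_length or 1, [])
        header = body[0].rstrip("\n").split("\t")
        if [h.strip().lower() for h in header[:4]] != ["gene", "strand", "start", "stop"]:
            raise ValueError(
                f"{path}: line 1: expected header starting 'gene\\tstrand\\tstart\\tstop'"
            )
        for lineno, ln in enumerate(body[1:], start=2):
            fields = ln.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected >=4 tab-separated fields")
            try:
                rec = GeneRecord(
                    name=fields[0].strip(),
                    strand=fields[1].strip(),
                    start=int(fields[2].replace(",", "")),
                    stop=int(fields[3].replace(",", "")),
                    gene_class=fields[4].strip() if len(fields) > 4 else "",
                    start_codon=fields[5].strip() if len(fields) > 5 else "",
                    stop_codon=fields[6].strip() if len(fields) > 6 else "",
                )
            except ValueError as e:
                raise ValueError(f"{path}: line {lineno}: {e}") from e
            records.append(rec)
    else:  # gff3
        seqid = genome_id
        for lineno, ln in enumerate(lines, start=1):
            if ln.startswith("##sequence-region"):
                parts = ln.split()
                if len(parts) >= 4:
                    seqid, genome_length = parts[1], int(parts[3])
                continue
            if not ln.strip() or ln.startswith("#"):
                continue
            fields = ln.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            if fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID")
            if not name:
                raise ValueError(f"{path}: line {lineno}: gene feature without Name/ID")
            records.append(
                GeneRecord(
                    name=name,
                    strand=fields[6],
                    start=int(fields[3]),
                    stop=int(fields[4]),
                    gene_class=attrs.get("gene_class", ""),
                )
            )
        genome_id = seqid or path.stem
    if not genome_length:
        # fall back to the furthest coordinate; good enough for toy tables
        genome_length = max((max(r.start, r.stop) for r in records), default=1)
    return GeneTable(genome_id or path.stem, genome_length, records)


# ---------------------------------------------------------------------------
# composition and skews
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositionStats:
    """Base percentages and strand-asymmetry skews on the (+) strand.

    ``at_skew = (A - T) / (A + T)`` and ``gc_skew = (G - C) / (G + C)``,
    computed from absolute base counts; N bases are excluded from the
    denominators.
    """

    n_bases: int
    pct_A: float
    pct_T: float
    pct_G: float
    pct_C: float

    @property
    def pct_GC(self) -> float:
        return self.pct_G + self.pct_C

    @property
    def at_skew(self) -> float:
        return at_skew(self.pct_A, self.pct_T)

    @property
    def gc_skew(self) -> float:
        return gc_skew(self.pct_G, self.pct_C)

    def rounded(self, digits: int = 0) -> dict[str, float]:
        """Report at table precision (integer percentages by default)."""
        r = lambda x: round(x, digits) if digits else int(round(x))
        return {
            "GC%": r(self.pct_GC), "A%": r(self.pct_A), "T%": r(self.pct_T),
            "G%": r(self.pct_G), "C%": r(self.pct_C),
            "AT-skew": round(self.at_skew, 3), "GC-skew": round(self.gc_skew, 2),
        }


def at_skew(a: float, t: float) -> float:
    """(A - T)/(A + T); accepts absolute counts or percentages."""
    if a + t == 0:
        return 0.0
    return (a - t) / (a + t)


def gc_skew(g: float, c: float) -> float:
    """(G - C)/(G + C); accepts absolute counts or percentages."""
    if g + c == 0:
        return 0.0
    return (g - c) / (g + c)


def composition(
    seq: CircularSequence, subset: Sequence[GeneRecord] | None = None
) -> CompositionStats:
    """Base composition of the whole genome or of a subset of gene intervals.

    Percentages are always taken on the (+) strand, whatever the genes'
    strands (the convention of mitogenome composition tables).
    """
    L = len(seq)
    if subset is None:
        bases = seq.seq
    else:
        mask = np.zeros(L, dtype=bool)
        for r in subset:
            mask[interval_positions(*r.interval(L), L)] = True
        if not mask.any():
            raise ValueError("subset covers zero bases")
        arr = np.frombuffer(seq.seq.encode(), dtype="S1")
        bases = b"".join(arr[mask]).decode()
    counts = {b: bases.count(b) for b in "ACGT"}
    denom = sum(counts.values())  # N excluded
    if denom == 0:
        raise ValueError("no unambiguous bases in selection")
    pct = {b: 100.0 * counts[b] / denom for b in "ACGT"}
    return CompositionStats(
        n_bases=denom, pct_A=pct["A"], pct_T=pct["T"], pct_G=pct["G"], pct_C=pct["C"]
    )


# ---------------------------------------------------------------------------
# intergenic complement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntergenicSegment:
    """A maximal run of positions covered by no gene (1-based inclusive)."""

    start: int
    stop: int
    length: int
    left_gene: str
    right_gene: str


def _coverage_mask(table: GeneTable) -> np.ndarray:
    mask = np.zeros(table.genome_length, dtype=bool)
    for r in table.records:
        mask[interval_positions(*r.interval(table.genome_length), table.genome_length)] = True
    return mask


def intergenic_complement(table: GeneTable) -> list[IntergenicSegment]:
    """Circular complement of the union of all gene intervals.

    Overlapping genes are merged before complementing; a segment spanning
    the origin is reported once, in circular coordinates (stop < start).
    Segments are sorted by start and annotated with the flanking genes.
    """
    L = table.genome_length
    mask = _coverage_mask(table)
    if mask.all():
        return []
    if not mask.any():
        return [IntergenicSegment(1, L, L, "", "")]
    # maximal runs of uncovered positions on the circle: rotate so position 0
    # is covered, find linear runs, map back.
    anchor = int(np.flatnonzero(mask)[0])
    rot = np.roll(~mask, -anchor)
    padded = np.concatenate([[False], rot, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)  # half-open
    segments = []
    for s, e in zip(starts, stops):
        start0 = (s + anchor) % L
        stop0_incl = (e - 1 + anchor) % L
        length = e - s
        segments.append((int(start0) + 1, int(stop0_incl) + 1, int(length)))
    segments.sort()
    out = []
    for start1, stop1, length in segments:
        left = _gene_ending_at(table, (start1 - 2) % L + 1)
        right = _gene_starting_at(table, stop1 % L + 1)
        out.append(IntergenicSegment(start1, stop1, length, left, right))
    return out


def _gene_ending_at(table: GeneTable, pos1: int) -> str:
    """Name of a gene whose interval covers pos1, preferring one that ends there."""
    L = table.genome_length
    covering = [
        r for r in table.records
        if ((pos1 - 1 - r.interval(L)[0]) % L) < r.length(L)
    ]
    for r in covering:
        if r.stop == pos1:
            return r.name
    return covering[0].name if covering else ""


def _gene_starting_at(table: GeneTable, pos1: int) -> str:
    L = table.genome_length
    covering = [
        r for r in table.records
        if ((pos1 - 1 - r.interval(L)[0]) % L) < r.length(L)
    ]
    for r in covering:
        if r.start == pos1:
            return r.name
    return covering[0].name if covering else ""


# ---------------------------------------------------------------------------
# annotation validation
# ---------------------------------------------------------------------------

@dataclass
class AdjacencyReport:
    """Relation between two genes adjacent in genomic order."""

    left: str
    right: str
    relation: str  # "overlap", "abut", "gap"
    n_bases: int   # overlap or gap size; 0 for abut


@dataclass
class ValidationReport:
    adjacencies: list[AdjacencyReport]
    n_overlaps: int
    n_gaps: int
    total_gene_union: int
    total_intergenic: int
    n_intergenic_segments: int
    frame_flags: dict[str, int]  # PCG name -> length mod 3 (nonzero = remainder)

    def summary(self) -> str:
        lines = [
            f"gene union: {self.total_gene_union} bp; "
            f"intergenic: {self.total_intergenic} bp in "
            f"{self.n_intergenic_segments} segments",
            f"{self.n_overlaps} overlapping pairs, {self.n_gaps} gapped pairs",
        ]
        for a in self.adjacencies:
            tag = a.relation if a.relation == "abut" else f"{a.relation}({a.n_bases})"
            lines.append(f"  {a.left} | {a.right}: {tag}")
        for name, rem in self.frame_flags.items():
            lines.append(
                f"  frame: {name} length % 3 == {rem} "
                "(incomplete stop codon or coordinate inconsistency)"
            )
        return "\n".join(lines)


def validate_annotation(table: GeneTable) -> ValidationReport:
    """Pairwise adjacency relations, coverage totals, and PCG frame checks.

    The totals are computed from the printed coordinates; if they disagree
    with a genome's published companion figures the discrepancy is surfaced
    here rather than reconciled.
    """
    L = table.genome_length
    ordered = sorted(table.records, key=lambda r: r.start)
    adjacencies = []
    for a, b in zip(ordered, ordered[1:] + ordered[:1]):
        a0, a1 = a.interval(L)
        b0, b1 = b.interval(L)
        if b is ordered[0]:
            b0, b1 = b0 + L, b1 + L
        gap = b0 - a1
        if gap > 0:
            adjacencies.append(AdjacencyReport(a.name, b.name, "gap", gap))
        elif gap == 0:
            adjacencies.append(AdjacencyReport(a.name, b.name, "abut", 0))
        else:
            adjacencies.append(AdjacencyReport(a.name, b.name, "overlap", -gap))
    segments = intergenic_complement(table)
    union = int(_coverage_mask(table).sum())
    frame_flags = {
        r.name: r.length(L) % 3
        for r in table.by_class("PCG")
        if r.length(L) % 3 != 0
    }
    return ValidationReport(
        adjacencies=adjacencies,
        n_overlaps=sum(1 for a in adjacencies if a.relation == "overlap"),
        n_gaps=sum(1 for a in adjacencies if a.relation == "gap"),
        total_gene_union=union,
        total_intergenic=sum(s.length for s in segments),
        n_intergenic_segments=len(segments),
        frame_flags=frame_flags,
    )


# ---------------------------------------------------------------------------
# strand partition and rotation
# ---------------------------------------------------------------------------

def strand_partition(table: GeneTable) -> tuple[list[GeneRecord], list[GeneRecord]]:
    """Split records into (+)-strand and (-)-strand lists, order preserved."""
    plus = [r for r in table.records if r.strand == "+"]
    minus = [r for r in table.records if r.strand == "-"]
    return plus, minus


def rotate(
    seq: CircularSequence, table: GeneTable, new_origin: int
) -> tuple[CircularSequence, GeneTable]:
    """Cut the circle so 1-based ``new_origin`` becomes position 1.

    Sequence and all annotation coordinates move consistently; rotating by
    ``new_origin`` and then by ``L - new_origin + 2`` restores the input.
    """
    L = len(seq)
    if table.genome_length != L:
        raise ValueError("sequence and table lengths disagree")
    new_seq = seq.rotated(new_origin)
    k = new_origin - 1
    shift = lambda p: (p - 1 - k) % L + 1
    new_records = [
        replace(r, start=shift(r.start), stop=shift(r.stop)) for r in table.records
    ]
    return new_seq, GeneTable(table.genome_id, L, new_records)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def intergenic_to_bed(segments: Iterable[IntergenicSegment], genome_id: str,
                      genome_length: int, path: str | Path) -> None:
    """BED (0-based half-open) export; origin-spanning segments split in two."""
    with open(path, "w") as fh:
        for i, s in enumerate(segments):
            name = f"intergenic_{i+1}_{s.left_gene}_{s.right_gene}"
            if s.stop >= s.start:
                fh.write(f"{genome_id}\t{s.start-1}\t{s.stop}\t{name}\n")
            else:
                fh.write(f"{genome_id}\t{s.start-1}\t{genome_length}\t{name}\n")
                fh.write(f"{genome_id}\t0\t{s.stop}\t{name}\n")


def composition_report(seq: CircularSequence, table: GeneTable) -> dict:
    """Whole-genome and per-class composition, table-style rounding."""
    report = {"whole_genome": composition(seq).rounded()}
    for cls in GENE_CLASSES:
        recs = table.by_class(cls)
        if recs:
            report[cls] = composition(seq, recs).rounded()
    return report


def write_composition_json(seq: CircularSequence, table: GeneTable,
                           path: str | Path) -> None:
    Path(path).write_text(json.dumps(composition_report(seq, table), indent=2) + "\n")
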