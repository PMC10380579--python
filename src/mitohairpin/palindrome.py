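"""Perfect inverted-repeat (hairpin) detection.

A perfect inverted repeat is a pair of nearby segments on the same strand
where the right segment is the exact reverse complement of the left: in
single-stranded form the region folds into a stem-loop (hairpin), with the
two segments as the paired stem and the spacer between them as the loop.
Nematomorph mitochondrial genomes are unusually enriched in such repeats,
embedded inside coding genes, and the folded stems interfere with
amplification, reverse transcription and short-read sequencing.

The scanner reports *maximal* perfect repeats under stem/loop constraints:
a reported stem can be extended neither outward (the flanking bases do not
pair) nor inward (the loop cannot be shrunk by pairing its outermost bases).
Sub-repeats sharing a centre with a reported repeat are suppressed; repeats
with distinct centres are reported even when nested.  ``N`` pairs with
nothing, so repeats never cross masked bases.

Default constraints (stem 10..300 bp, loop <= 100 bp, zero mismatches,
overlaps allowed) are the classic palindrome-scan parameter set for these
genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .genome import CircularSequence, GeneRecord, GeneTable, revcomp

_PAIR = {"AT", "TA", "GC", "CG"}


def _pairs(a: str, b: str) -> bool:
    return a + b in _PAIR


@dataclass(frozen=True)
class ScanParams:
    """Stem/loop constraints for the repeat scan."""

    min_stem: int = 10
    max_stem: int = 300
    max_loop: int = 100
    mismatches: int = 0  # only 0 supported: repeats are perfect
    allow_overlap: bool = True
    circular: bool = False

    def __post_init__(self) -> None:
        if self.min_stem < 2:
            raise ValueError("min_stem must be >= 2")
        if self.max_stem < self.min_stem:
            raise ValueError("max_stem must be >= min_stem")
        if self.max_loop < 0:
            raise ValueError("max_loop must be >= 0")
        if self.mismatches != 0:
            raise ValueError("only perfect repeats (mismatches=0) are supported")


@dataclass(frozen=True, order=True)
class InvertedRepeat:
    """One perfect inverted repeat; 1-based coordinates.

    The left stem occupies ``left_start .. left_start+stem_len-1``, the loop
    the next ``loop_len`` bases, and the right stem (reverse complement of
    the left) the ``stem_len`` bases after that.
    """

    left_start: int
    stem_len: int
    loop_len: int

    @property
    def right_start(self) -> int:
        return self.left_start + self.stem_len + self.loop_len

    @property
    def footprint(self) -> tuple[int, int]:
        """1-based inclusive span of the whole repeat."""
        return self.left_start, self.left_start + 2 * self.stem_len + self.loop_len - 1

    @property
    def footprint_len(self) -> int:
        return 2 * self.stem_len + self.loop_len

    def sort_key(self) -> tuple[int, int, int]:
        return (self.left_start, -self.stem_len, self.loop_len)


def find_inverted_repeats(
    seq: CircularSequence | str, params: ScanParams = ScanParams()
) -> list[InvertedRepeat]:
    """All maximal perfect inverted repeats satisfying ``params``.

    Scans every hairpin centre (each position/gap combination), extends the
    stem outward as far as complementarity and ``max_stem`` allow, and keeps
    the result if the stem reaches ``min_stem`` and the loop cannot pair
    further inward.  Output is sorted by (left_start, -stem_len, loop_len).

    In circular mode the doubled sequence is scanned and repeats are
    deduplicated by their canonical start, so hairpins spanning the origin
    are reported in circular coordinates.
    """
    s = seq.seq if isinstance(seq, CircularSequence) else str(seq).upper()
    L = len(s)
    if params.circular:
        doubled = s + s
        found = {}
        for rep in _scan_linear(doubled, params):
            if rep.left_start > L or rep.footprint_len > L:
                continue
            canonical = InvertedRepeat(
                (rep.left_start - 1) % L + 1, rep.stem_len, rep.loop_len
            )
            found[canonical] = None
        out = list(found)
    else:
        out = _scan_linear(s, params)
    return sorted(out, key=InvertedRepeat.sort_key)


def _scan_linear(s: str, params: ScanParams) -> list[InvertedRepeat]:
    L = len(s)
    out = []
    # A stem with innermost pair (i, j), j = i + gap + 1, extends outward to
    # pairs (i-t, j+t).  Iterate over innermost positions and gaps.
    for i in range(L - 1):
        jmax = min(i + params.max_loop + 1, L - 1)
        for j in range(i + 1, jmax + 1):
            if not _pairs(s[i], s[j]):
                continue
            stem = 1
            while (
                stem < params.max_stem
                and i - stem >= 0
                and j + stem < L
                and _pairs(s[i - stem], s[j + stem])
            ):
                stem += 1
            if stem < params.min_stem:
                continue
            # inward-maximality: if the bases just inside the loop pair, this
            # centre's repeat starts deeper in and this one is a sub-repeat --
            # unless the deeper stem would exceed max_stem, in which case both
            # are maximal under the constraints.
            if stem < params.max_stem and j - i >= 3 and _pairs(s[i + 1], s[j - 1]):
                continue
            out.append(InvertedRepeat(i - stem + 2, stem, j - i - 1))
    return out


def brute_force_repeats(
    seq: CircularSequence | str, params: ScanParams = ScanParams()
) -> list[InvertedRepeat]:
    """Exhaustive reference enumeration (test oracle; sequences <= 2,000 bp).

    Enumerates every (left_start, stem_len, loop_len) triple, keeps those
    whose right stem equals the reverse complement of the left, then filters
    to maximal repeats by direct character checks.  Independent of the
    scanning implementation.
    """
    s = seq.seq if isinstance(seq, CircularSequence) else str(seq).upper()
    L = len(s)
    if L > 2000:
        raise ValueError("brute_force_repeats guards at 2,000 bp; use find_inverted_repeats")
    out = []
    for left0 in range(L):
        for stem in range(params.min_stem, params.max_stem + 1):
            inner_left = left0 + stem - 1
            if inner_left >= L:
                break
            for loop in range(params.max_loop + 1):
                r0 = left0 + stem + loop
                if r0 + stem > L:
                    break
                # cheap innermost/outermost pair screens before the full
                # reverse-complement comparison
                if not _pairs(s[inner_left], s[r0]):
                    continue
                if not _pairs(s[left0], s[r0 + stem - 1]):
                    continue
                if s[left0 : left0 + stem] != revcomp(s[r0 : r0 + stem]):
                    continue
                # outward-extendable?
                if (
                    stem < params.max_stem
                    and left0 - 1 >= 0
                    and r0 + stem < L
                    and _pairs(s[left0 - 1], s[r0 + stem])
                ):
                    continue
                # inward-extendable (loop shrinkable by one pair)?
                if (
                    stem < params.max_stem
                    and loop >= 2
                    and _pairs(s[left0 + stem], s[r0 - 1])
                ):
                    continue
                out.append(InvertedRepeat(left0 + 1, stem, loop))
    return sorted(set(out), key=InvertedRepeat.sort_key)


@dataclass(frozen=True)
class HairpinRegion:
    """Union footprint of transitively overlapping repeats (1-based inclusive)."""

    start: int
    stop: int
    members: tuple[InvertedRepeat, ...]

    @property
    def max_stem(self) -> int:
        return max(m.stem_len for m in self.members)

    @property
    def length(self) -> int:
        return self.stop - self.start + 1


def merge_hairpin_regions(repeats: Sequence[InvertedRepeat]) -> list[HairpinRegion]:
    """Merge overlapping repeat footprints into disjoint hairpin regions."""
    if not repeats:
        return []
    reps = sorted(repeats, key=lambda r: r.footprint)
    regions = []
    cur_start, cur_stop = reps[0].footprint
    cur_members = [reps[0]]
    for rep in reps[1:]:
        a, b = rep.footprint
        if a <= cur_stop:  # >= 1 bp overlap
            cur_stop = max(cur_stop, b)
            cur_members.append(rep)
        else:
            regions.append(HairpinRegion(cur_start, cur_stop, tuple(cur_members)))
            cur_start, cur_stop, cur_members = a, b, [rep]
    regions.append(HairpinRegion(cur_start, cur_stop, tuple(cur_members)))
    return regions


def annotate_genes_with_repeats(
    table: GeneTable, regions: Sequence[HairpinRegion]
) -> GeneTable:
    """Set each gene's ``has_repeat`` flag: any region overlap of >= 1 bp."""
    L = table.genome_length
    new_records = []
    for r in table.records:
        g0, g1 = r.interval(L)  # half-open, possibly unwrapped past L
        hit = False
        for reg in regions:
            a0, b0 = reg.start - 1, reg.stop  # half-open
            # compare on the circle: shift region by 0 or L to catch wrapped genes
            for off in (0, L):
                if a0 + off < g1 and g0 < b0 + off:
                    hit = True
                    break
            if hit:
                break
        rec = GeneRecord(
            r.name, r.strand, r.start, r.stop, r.gene_class,
            r.start_codon, r.stop_codon, has_repeat=hit,
        )
        new_records.append(rec)
    return GeneTable(table.genome_id, L, new_records)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def repeats_to_tsv(repeats: Iterable[InvertedRepeat], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("left_start\tstem_len\tloop_len\tright_start\tfootprint_start\tfootprint_stop\n")
        for r in repeats:
            a, b = r.footprint
            fh.write(f"{r.left_start}\t{r.stem_len}\t{r.loop_len}\t{r.right_start}\t{a}\t{b}\n")


def regions_to_bed(regions: Iterable[HairpinRegion], genome_id: str,
                   path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, reg in enumerate(regions):
            fh.write(
                f"{genome_id}\t{reg.start-1}\t{reg.stop}\t"
                f"hairpin_region_{i+1}\t{reg.max_stem}\t.\n"
            )
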