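"""Per-site coverage and read-end statistics on a circular reference.

From read alignments this module computes per-site depth, counts of read 5'
and 3' ends (in read orientation, so a minus-strand read's 5' end is its
rightmost aligned base), and the end-ratio statistic

    ratio(i) = (ends5(i) + ends3(i)) / depth(i)

whose local maxima mark transcript boundaries (cleavage / polyadenylation
pile-ups).  It also implements masking/capping of dominant coverage peaks
for plotting, the circular-permutation check for the linearisation artifact
at the reference cut point, and the hairpin-associated coverage-drop
statistic (median depth inside a hairpin region over median depth in its
flanks).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .palindrome import HairpinRegion

logger = logging.getLogger(__name__)

_SUPPORTED_OPS = set("M=XIDS")
# CIGAR ops consuming the reference
_REF_OPS = set("M=XD")


@dataclass(frozen=True)
class AlignmentRecord:
    """A simplified alignment: reference span plus soft-clipped sequence."""

    read_id: str
    ref_start: int        # 1-based leftmost aligned reference position
    aligned_len: int      # reference bases consumed (may wrap past L)
    strand: str           # "+" or "-"
    left_clip_seq: str = ""
    right_clip_seq: str = ""

    def __post_init__(self) -> None:
        if self.aligned_len < 1:
            raise ValueError(f"{self.read_id}: aligned_len must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.read_id}: bad strand {self.strand!r}")

    @property
    def ref_end(self) -> int:
        """1-based rightmost aligned position (unwrapped; may exceed L)."""
        return self.ref_start + self.aligned_len - 1

    def five_prime_site(self, L: int) -> int:
        """1-based site of the read's 5' end on the reference."""
        p = self.ref_start if self.strand == "+" else self.ref_end
        return (p - 1) % L + 1

    def three_prime_site(self, L: int) -> int:
        p = self.ref_end if self.strand == "+" else self.ref_start
        return (p - 1) % L + 1


def read_alignments(path: str | Path, ref_id: str | None = None) -> list[AlignmentRecord]:
    """Load primary mapped records from a SAM file.

    Only CIGAR ops M/=/X/I/D/S are accepted; unmapped, secondary and
    supplementary records are skipped (counts logged).  Soft clips are
    captured as literal read sequence in reference orientation.
    """
    out: list[AlignmentRecord] = []
    skipped = {"unmapped": 0, "secondary": 0, "supplementary": 0, "other_ref": 0}
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as sam:
        if not sam.header.get("SQ"):
            raise ValueError(f"{path}: SAM header lacks @SQ reference lines")
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                skipped["unmapped"] += 1
                continue
            if aln.is_secondary:
                skipped["secondary"] += 1
                continue
            if aln.is_supplementary:
                skipped["supplementary"] += 1
                continue
            if ref_id is not None and aln.reference_name != ref_id:
                skipped["other_ref"] += 1
                continue
            cigar = aln.cigartuples or []
            ops = [("MIDNSHP=XB"[op]) for op, _ in cigar]
            bad = set(ops) - _SUPPORTED_OPS
            if bad:
                raise ValueError(
                    f"{path}: read {aln.query_name}: unsupported CIGAR op(s) {sorted(bad)}"
                )
            aligned_len = sum(n for (op, n), o in zip(cigar, ops) if o in _REF_OPS)
            seq = aln.query_sequence or ""
            left_clip = right_clip = ""
            if ops and ops[0] == "S":
                left_clip = seq[: cigar[0][1]]
            if ops and ops[-1] == "S":
                right_clip = seq[len(seq) - cigar[-1][1]:]
            out.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    ref_start=aln.reference_start + 1,
                    aligned_len=aligned_len,
                    strand="-" if aln.is_reverse else "+",
                    left_clip_seq=left_clip,
                    right_clip_seq=right_clip,
                )
            )
    if any(skipped.values()):
        logger.info("skipped records: %s", {k: v for k, v in skipped.items() if v})
    return out


@dataclass
class CoverageTrack:
    """Per-site depth and read-end counts over positions 1..L."""

    depth: np.ndarray
    ends5: np.ndarray
    ends3: np.ndarray
    library: str = "DNA"           # "DNA" or "RNA"
    strand_mode: str = "combined"  # "combined", "plus", "minus"
    masked_intervals: tuple[tuple[int, int], ...] = ()
    raw_depth: np.ndarray | None = None  # pre-mask depth, kept internally

    @property
    def L(self) -> int:
        return len(self.depth)

    def rotated(self, new_origin: int) -> "CoverageTrack":
        k = new_origin - 1
        return CoverageTrack(
            np.roll(self.depth, -k), np.roll(self.ends5, -k),
            np.roll(self.ends3, -k), self.library, self.strand_mode,
        )


def coverage_tracks(
    reads: Sequence[AlignmentRecord],
    L: int,
    strand_mode: str = "combined",
    library: str = "DNA",
) -> CoverageTrack:
    """Accumulate depth/ends5/ends3 from alignments on a circular reference.

    A read whose aligned span runs past position L wraps onto the origin for
    depth, but still contributes exactly one 5' and one 3' end.
    """
    if strand_mode not in ("combined", "plus", "minus"):
        raise ValueError(f"bad strand_mode {strand_mode!r}")
    depth = np.zeros(L, dtype=np.int64)
    ends5 = np.zeros(L, dtype=np.int64)
    ends3 = np.zeros(L, dtype=np.int64)
    want = {"combined": ("+", "-"), "plus": ("+",), "minus": ("-",)}[strand_mode]
    for r in reads:
        if r.strand not in want:
            continue
        start0 = r.ref_start - 1
        positions = np.arange(start0, start0 + r.aligned_len) % L
        np.add.at(depth, positions, 1)
        ends5[r.five_prime_site(L) - 1] += 1
        ends3[r.three_prime_site(L) - 1] += 1
    return CoverageTrack(depth, ends5, ends3, library=library, strand_mode=strand_mode)


@dataclass
class EndRatioTrack:
    """(ends5+ends3)/depth per covered site; NaN where depth is zero."""

    ratio: np.ndarray
    undefined_sites: np.ndarray  # 1-based positions with depth 0

    @property
    def L(self) -> int:
        return len(self.ratio)


def end_ratio(track: CoverageTrack) -> EndRatioTrack:
    depth = track.depth.astype(float)
    ends = (track.ends5 + track.ends3).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(depth > 0, ends / np.where(depth > 0, depth, 1), np.nan)
    undefined = np.flatnonzero(track.depth == 0) + 1
    return EndRatioTrack(ratio=ratio, undefined_sites=undefined)


def mask_and_cap(
    track: CoverageTrack,
    intervals: Sequence[tuple[int, int]],
    cap: int,
) -> CoverageTrack:
    """Cap the *reported* depth inside the given 1-based inclusive intervals.

    Dominant peaks (e.g. the rRNA locus in RNA-seq) otherwise flatten every
    other feature in a plot; the paper-style remedy is to cap them at a
    stated maximum.  The original depth is retained in ``raw_depth`` and the
    capped intervals are annotated on the returned track.
    """
    merged = _merge_intervals(intervals)
    if len(merged) < len(list(intervals)):
        warnings.warn("overlapping mask intervals merged", stacklevel=2)
    new_depth = track.depth.copy()
    for a, b in merged:
        idx = np.arange(a - 1, b) % track.L
        new_depth[idx] = np.minimum(new_depth[idx], cap)
    return CoverageTrack(
        new_depth, track.ends5.copy(), track.ends3.copy(),
        track.library, track.strand_mode,
        masked_intervals=tuple(merged),
        raw_depth=track.depth.copy(),
    )


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for a, b in ivs:
        if out and a <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


@dataclass
class OriginArtifactReport:
    """End-ratio at the linearisation cut before/after circular permutation."""

    boundary_ratio_before: float   # mean end-ratio at positions 1 and L
    boundary_ratio_after: float    # same genomic sites after rotation
    new_boundary_ratio: float      # ratio at the new cut point (pos 1/L after)
    interior_ratio_median: float   # background level away from either cut


def origin_artifact_check(
    reads: Sequence[AlignmentRecord], L: int, rotation_origin: int
) -> OriginArtifactReport:
    """Quantify the linear-reference artifact at the sequence cut point.

    Reads from a circular molecule mapped to a linearised reference cannot
    cross the cut, so positions 1 and L accumulate an excess of read ends.
    Rotating the coordinate system moves the reads but not their truncation,
    so the artifact travels with the original cut; this report compares the
    end-ratio at the boundary sites before and after rotation.
    """
    track = coverage_tracks(reads, L)
    ratio = end_ratio(track).ratio
    k = rotation_origin - 1
    rotated = [
        replace(r, ref_start=(r.ref_start - 1 - k) % L + 1) for r in reads
    ]
    track_rot = coverage_tracks(rotated, L)
    ratio_rot = end_ratio(track_rot).ratio

    def _at(arr: np.ndarray, sites0: Iterable[int]) -> float:
        vals = [arr[i] for i in sites0 if not np.isnan(arr[i])]
        return float(np.mean(vals)) if vals else float("nan")

    before = _at(ratio, [0, L - 1])
    # the old boundary sites, in rotated coordinates
    old_in_new = [(0 - k) % L, (L - 1 - k) % L]
    after = _at(ratio_rot, old_in_new)
    new_boundary = _at(ratio_rot, [0, L - 1])
    interior = float(np.nanmedian(ratio[2 : L - 2])) if L > 4 else float("nan")
    return OriginArtifactReport(before, after, new_boundary, interior)


@dataclass
class DropCall:
    """Depth drop inside a region relative to its flanks."""

    region: HairpinRegion | tuple[int, int]
    inside_stat: float
    flank_stat: float
    drop_ratio: float
    flagged: bool
    indeterminate: bool = False

    @property
    def span(self) -> tuple[int, int]:
        if isinstance(self.region, HairpinRegion):
            return self.region.start, self.region.stop
        return self.region


def hairpin_drop_calls(
    track: CoverageTrack,
    regions: Sequence[HairpinRegion],
    flank: int = 200,
    threshold: float = 0.5,
) -> list[DropCall]:
    """One DropCall per hairpin region: median depth inside vs. in flanks.

    Flanks of ``flank`` bp on each side exclude positions lying inside any
    other region; a region is flagged when inside/flank < ``threshold``.
    Regions with zero-depth (or empty) flanks are marked indeterminate.
    """
    L = track.L
    in_any = np.zeros(L, dtype=bool)
    for reg in regions:
        in_any[np.arange(reg.start - 1, reg.stop) % L] = True
    out = []
    for reg in regions:
        inside_idx = np.arange(reg.start - 1, reg.stop) % L
        left_idx = np.arange(reg.start - 1 - flank, reg.start - 1) % L
        right_idx = np.arange(reg.stop, reg.stop + flank) % L
        flank_idx = np.concatenate([left_idx, right_idx])
        flank_idx = flank_idx[~in_any[flank_idx]]
        inside = float(np.median(track.depth[inside_idx]))
        if flank_idx.size == 0:
            out.append(DropCall(reg, inside, float("nan"), float("nan"),
                                flagged=False, indeterminate=True))
            continue
        flank_med = float(np.median(track.depth[flank_idx]))
        if flank_med == 0:
            out.append(DropCall(reg, inside, 0.0, float("nan"),
                                flagged=False, indeterminate=True))
            continue
        ratio = inside / flank_med
        out.append(DropCall(reg, inside, flank_med, ratio, flagged=ratio < threshold))
    return out


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_bedgraph(values: np.ndarray, genome_id: str, path: str | Path) -> None:
    """bedGraph (0-based half-open) with runs of equal value collapsed."""
    with open(path, "w") as fh:
        L = len(values)
        i = 0
        while i < L:
            j = i + 1
            v = values[i]
            while j < L and (
                (np.isnan(values[j]) and np.isnan(v)) or values[j] == v
            ):
                j += 1
            if not (isinstance(v, float) and np.isnan(v)):
                val = int(v) if float(v).is_integer() else float(v)
                fh.write(f"{genome_id}\t{i}\t{j}\t{val}\n")
            i = j


def drop_calls_to_tsv(calls: Sequence[DropCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tstop\tmax_stem\tinside_median\tflank_median\tdrop_ratio\tflagged\tindeterminate\n")
        for c in calls:
            a, b = c.span
            stem = c.region.max_stem if isinstance(c.region, HairpinRegion) else ""
            fh.write(
                f"{a}\t{b}\t{stem}\t{c.inside_stat}\t{c.flank_stat}\t"
                f"{c.drop_ratio:.4f}\t{int(c.flagged)}\t{int(c.indeterminate)}\n"
                if not np.isnan(c.drop_ratio) else
                f"{a}\t{b}\t{stem}\t{c.inside_stat}\t{c.flank_stat}\tNA\t0\t1\n"
            )
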