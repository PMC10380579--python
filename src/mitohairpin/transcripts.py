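"""Poly(A)/CCA calling and tRNA-punctuation transcript classification.

Mitochondrial genes are transcribed as long polycistronic precursors that
are cleaved into mature RNAs; in the tRNA-punctuation model the tRNAs
interleaved between protein-coding genes mark the cleavage points.  Mature
mRNAs receive a non-templated poly(A) tail at the cleavage site (which can
also complete an incomplete T/TA stop codon to TAA), and tRNAs receive the
non-templated 3' CCA.  In short-read RNA-seq both events are visible as
soft-clipped read tails that disagree with the reference downstream of the
last templated base.

This module turns soft-clipped alignments into tail observations, clusters
them into supported polyadenylation sites, completes stop codons, assembles
mature transcript models (mono/bi/multicistronic, with any 3'-UTR tRNAs),
and classifies each protein-gene boundary (tRNA-punctuated vs. cleavage
without a tRNA vs. no cleavage), including the coverage-gradient signature
of forward/reverse processing through tRNA blocks.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .coverage import AlignmentRecord, CoverageTrack, EndRatioTrack
from .genome import CircularSequence, GeneRecord, GeneTable, revcomp

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# tail detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TailObservation:
    """One read whose transcript-3' soft clip is a (CCA-prefixed) poly(A) tail."""

    read_id: str
    site: int            # 1-based genomic position of last templated base
    strand: str
    tail_seq: str        # clip in transcript orientation
    has_cca_prefix: bool
    tail_a_len: int


def _tail_match(clip: str, min_tail: int, max_mismatch: int = 0
                ) -> tuple[bool, bool, int]:
    """Classify a transcript-orientation clip as (CCA)?A{min_tail,}.

    ``max_mismatch`` non-A bases are tolerated in the post-CCA residue
    (default 0: the tail must be pure A).
    """
    rest = clip
    cca = False
    if rest.startswith("CCA") and len(rest) > 3:
        cca = True
        rest = rest[3:]
    a_len = rest.count("A")
    non_a = len(rest) - a_len
    if a_len >= min_tail and non_a <= max_mismatch:
        return True, cca, a_len
    return False, cca, a_len


def detect_tails(
    reads: Sequence[AlignmentRecord],
    genome: CircularSequence,
    min_tail: int = 4,
    max_mismatch_in_tail: int = 0,
) -> list[TailObservation]:
    """Find reads carrying non-templated poly(A) (optionally CCA+poly(A)) tails.

    A read qualifies when its transcript-3' soft clip is ``(CCA)?A{min_tail,}``
    *and* the clip disagrees with the reference continuation past the last
    aligned base -- a clip that matches the genome is templated sequence
    (e.g. a genomic A-run), not a tail.  ``max_mismatch_in_tail`` is the
    number of non-A bases tolerated in the post-CCA tail residue (default
    0: pure-A tails only).
    """
    L = len(genome)
    out = []
    for r in reads:
        if r.strand == "+":
            clip = r.right_clip_seq
            site = (r.ref_end - 1) % L + 1
            ref_next = genome.fetch(site, len(clip)) if clip else ""
        else:
            clip = revcomp(r.left_clip_seq)
            site = r.ref_start
            # continuation in transcript sense: upstream on the (+) strand,
            # read off the (-) strand
            ref_next = revcomp(genome.fetch(site - 1 - len(clip), len(clip))) if clip else ""
        if not clip:
            continue
        ok, cca, a_len = _tail_match(clip, min_tail, max_mismatch_in_tail)
        if not ok:
            continue
        if clip == ref_next:
            continue  # templated: the clip matches the reference continuation
        out.append(
            TailObservation(
                read_id=r.read_id, site=site, strand=r.strand,
                tail_seq=clip, has_cca_prefix=cca, tail_a_len=a_len,
            )
        )
    return out


# ---------------------------------------------------------------------------
# site calling
# ---------------------------------------------------------------------------

UTR_CLASSES = ("immediate", "short_utr", "one_trna", "two_trna", "other")


@dataclass
class PolyASite:
    """A supported polyadenylation (precursor cleavage) site."""

    site: int
    strand: str
    n_reads: int
    cca_fraction: float
    context_gene: str = ""
    utr_class: str = "other"


def call_polya_sites(
    tails: Sequence[TailObservation],
    min_support: int = 2,
    cluster_window: int = 3,
) -> list[PolyASite]:
    """Cluster tail observations into supported sites.

    Observations on the same strand within ``cluster_window`` bp of each
    other merge into one site placed at the modal observed position (ties
    broken toward the smaller coordinate); clusters with fewer than
    ``min_support`` reads are dropped.
    """
    out = []
    by_strand: dict[str, list[TailObservation]] = defaultdict(list)
    for t in tails:
        by_strand[t.strand].append(t)
    for strand, obs in sorted(by_strand.items()):
        obs.sort(key=lambda t: t.site)
        cluster: list[TailObservation] = []
        clusters = []
        for t in obs:
            if cluster and t.site - cluster[-1].site > cluster_window:
                clusters.append(cluster)
                cluster = []
            cluster.append(t)
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            if len(cl) < min_support:
                continue
            counts = Counter(t.site for t in cl)
            best = max(counts.values())
            site = min(p for p, c in counts.items() if c == best)
            cca = sum(t.has_cca_prefix for t in cl) / len(cl)
            out.append(PolyASite(site=site, strand=strand, n_reads=len(cl),
                                 cca_fraction=cca))
    out.sort(key=lambda s: (s.site, s.strand))
    return out


def annotate_sites(
    sites: Sequence[PolyASite], table: GeneTable, short_utr_max: int = 10
) -> list[PolyASite]:
    """Attach the nearest upstream gene and a 3'-UTR class to each site.

    ``immediate``: the site is the gene's own 3' terminal base;
    ``short_utr``: <= ``short_utr_max`` bp downstream of the ORF end;
    ``one_trna``/``two_trna``: that many same-strand tRNAs lie between the
    ORF end and the site; ``other`` otherwise.
    """
    L = table.genome_length
    for s in sites:
        best = None
        best_dist = None
        for g in table.records:
            if g.strand != s.strand or g.gene_class == "tRNA":
                continue
            end3 = g.three_prime(L)
            dist = (s.site - end3) % L if s.strand == "+" else (end3 - s.site) % L
            if best_dist is None or dist < best_dist:
                best, best_dist = g, dist
        if best is None:
            continue
        s.context_gene = best.name
        end3 = best.three_prime(L)
        trna_dists = []
        for g in table.records:
            if g.strand != s.strand or g.gene_class != "tRNA":
                continue
            g3 = g.three_prime(L)
            d = (g3 - end3) % L if s.strand == "+" else (end3 - g3) % L
            if 0 < d <= best_dist:
                trna_dists.append(d)
        # the site must lie at (or just past) the last tRNA's 3' end for the
        # UTR to count as tRNA-terminated
        at_trna_end = bool(trna_dists) and best_dist - max(trna_dists) <= short_utr_max
        if best_dist == 0:
            s.utr_class = "immediate"
        elif at_trna_end and len(trna_dists) == 1:
            s.utr_class = "one_trna"
        elif at_trna_end and len(trna_dists) == 2:
            s.utr_class = "two_trna"
        elif not trna_dists and best_dist <= short_utr_max:
            s.utr_class = "short_utr"
        else:
            s.utr_class = "other"
    return list(sites)


# ---------------------------------------------------------------------------
# stop-codon completion
# ---------------------------------------------------------------------------

def complete_stop_codon(
    gene: GeneRecord, site: PolyASite, genome: CircularSequence
) -> str:
    """Classify a PCG's stop codon given polyadenylation at/near its 3' end.

    Mitochondrial ORFs may end on an incomplete stop codon -- a bare T (frame
    remainder 1) or TA (remainder 2) at the DNA level -- completed to TAA by
    the poly(A) tail of the mature mRNA.  Returns one of ``complete``,
    ``completed_T``, ``completed_TA``, ``inconsistent``.
    """
    if gene.gene_class != "PCG":
        raise ValueError(f"{gene.name} is not a protein-coding gene")
    L = len(genome)
    n = gene.length(L)
    rem = n % 3
    start0, stop0 = gene.interval(L)
    coding = genome.fetch(start0, n)
    if gene.strand == "-":
        coding = revcomp(coding)
    tail3 = coding[-3:]
    if rem == 0 and tail3 in ("TAA", "TAG"):
        return "complete"
    if rem == 1 and coding[-1] == "T":
        return "completed_T"
    if rem == 2 and coding[-2:] == "TA":
        return "completed_TA"
    return "inconsistent"


# ---------------------------------------------------------------------------
# transcript models
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """A mature mRNA model: its PCGs, terminal site, and 3'-UTR tRNAs."""

    cistrons: list[str]
    strand: str
    three_end: PolyASite | None
    terminal_trnas: list[str] = field(default_factory=list)
    five_end: int | None = None  # not called from short reads

    @property
    def cistronic_class(self) -> str:
        n = len(self.cistrons)
        return "mono" if n == 1 else ("bi" if n == 2 else "multi")


def build_transcript_models(
    table: GeneTable,
    sites: Sequence[PolyASite],
    max_span: int | None = None,
) -> list[TranscriptModel]:
    """Walk each strand in transcript order, cutting at called sites.

    For every PCG the model extends downstream, collecting interleaved
    same-strand genes, until the first called polyadenylation site; PCGs
    that share that terminal site fuse into one bi-/multicistronic model.
    A PCG with no site within ``max_span`` bp (default: half the genome)
    gets an open 3' end and a warning.
    """
    L = table.genome_length
    if max_span is None:
        max_span = L // 2
    models: dict[int, TranscriptModel] = {}  # keyed by terminal site position
    open_models = []
    for strand in ("+", "-"):
        strand_sites = sorted(
            (s for s in sites if s.strand == strand), key=lambda s: s.site
        )
        genes = [g for g in table.records if g.strand == strand]
        for g in genes:
            if g.gene_class != "PCG":
                continue
            end3 = g.three_prime(L)
            # first site downstream (transcript sense) of the ORF end
            best_site, best_dist = None, None
            for s in strand_sites:
                d = (s.site - end3) % L if strand == "+" else (end3 - s.site) % L
                if best_dist is None or d < best_dist:
                    best_site, best_dist = s, d
            if best_site is None or best_dist > max_span:
                logger.warning("%s: no polyadenylation site within %d bp", g.name, max_span)
                open_models.append(TranscriptModel([g.name], strand, None))
                continue
            trnas = []
            for t in genes:
                if t.gene_class != "tRNA":
                    continue
                t3 = t.three_prime(L)
                d = (t3 - end3) % L if strand == "+" else (end3 - t3) % L
                if 0 < d <= best_dist:
                    trnas.append((d, t.name))
            key = (best_site.site, strand)
            if key in models:
                m = models[key]
                m.cistrons.append(g.name)
                # keep the tRNA list of the innermost (closest) PCG
                if len(trnas) < len(m.terminal_trnas):
                    m.terminal_trnas = [n for _, n in sorted(trnas)]
            else:
                models[key] = TranscriptModel(
                    [g.name], strand, best_site, [n for _, n in sorted(trnas)]
                )
    out = list(models.values()) + open_models
    # order cistrons in transcript sense within each model
    for m in out:
        order = {g.name: i for i, g in enumerate(table.records)}
        m.cistrons.sort(key=lambda n: order[n], reverse=(m.strand == "-"))
    return out


# ---------------------------------------------------------------------------
# boundary classification
# ---------------------------------------------------------------------------

@dataclass
class BoundaryClass:
    """Processing class of one adjacent same-strand PCG/PCG boundary."""

    upstream: str
    downstream: str
    boundary_class: str  # "trna_punctuated", "non_trna_cleavage", "no_cleavage"
    gradient: str        # "forward", "reverse", "none"
    slope: float = 0.0
    noise_threshold: float = 0.0


def _block_gradient(
    depth: np.ndarray,
    block0: np.ndarray,
    flank0: np.ndarray,
    strand: str,
    rng: np.random.Generator,
    n_boot: int = 100,
) -> tuple[str, float, float]:
    """Sign of the least-squares depth slope across a block, vs. flank noise.

    The noise threshold is twice the standard deviation of slopes fitted to
    ``n_boot`` bootstrap-resampled windows of the flanking depth; a block
    slope below it is called 'none'.  'reverse' means depth increases toward
    the upstream PCG's 3' end (against the transcription direction).
    """
    if block0.size < 3:
        return "none", 0.0, 0.0
    y = depth[block0].astype(float)
    x = np.arange(y.size, dtype=float)
    slope = float(np.polyfit(x, y, 1)[0])
    w = y.size
    boot_slopes = []
    if flank0.size >= w:
        fl = depth[flank0].astype(float)
        for _ in range(n_boot):
            start = rng.integers(0, fl.size - w + 1)
            yy = fl[start : start + w]
            boot_slopes.append(np.polyfit(x, yy, 1)[0])
    thresh = 2.0 * float(np.std(boot_slopes)) if boot_slopes else 0.0
    if abs(slope) <= max(thresh, 1e-9):
        return "none", slope, thresh
    # genomic slope > 0 = depth increasing with coordinate.  On the (+)
    # strand transcription runs with the coordinate, so increasing depth
    # toward the upstream gene's 3' end (block left edge) = negative slope.
    increasing_downstream = slope > 0 if strand == "+" else slope < 0
    return ("forward" if increasing_downstream else "reverse"), slope, thresh


def classify_boundaries(
    table: GeneTable,
    sites: Sequence[PolyASite],
    ratio_track: EndRatioTrack | None,
    depth_track: CoverageTrack,
    flank: int = 200,
    seed: int = 0,
) -> list[BoundaryClass]:
    """Classify each adjacent same-strand PCG pair against tRNA punctuation.

    ``trna_punctuated``: at least one same-strand tRNA lies between the two
    ORFs and a site is called in the interval; ``non_trna_cleavage``: a site
    with no intervening tRNA; ``no_cleavage``: no called site (mRNA runs on,
    e.g. a bicistron).  The depth gradient across the inter-ORF block is
    reported alongside.
    """
    L = table.genome_length
    rng = np.random.default_rng(seed)
    out = []
    for strand in ("+", "-"):
        genes = [g for g in table.records if g.strand == strand]
        pcgs = [g for g in genes if g.gene_class == "PCG"]
        if len(pcgs) < 2:
            continue
        if strand == "-":
            pcgs = list(reversed(pcgs))  # transcript order
        for up, down in zip(pcgs, pcgs[1:]):
            up3 = up.three_prime(L)
            down5 = down.five_prime(L)
            span = (down5 - up3) % L if strand == "+" else (up3 - down5) % L
            in_between = lambda p: (
                0 <= ((p - up3) % L) <= span if strand == "+"
                else 0 <= ((up3 - p) % L) <= span
            )
            trnas = [
                t.name for t in genes
                if t.gene_class == "tRNA" and in_between(t.three_prime(L))
            ]
            cut_sites = [s for s in sites if s.strand == strand and in_between(s.site)]
            if cut_sites and trnas:
                cls = "trna_punctuated"
            elif cut_sites:
                cls = "non_trna_cleavage"
            else:
                cls = "no_cleavage"
            if strand == "+":
                block0 = np.arange(up3, up3 + span + 1) % L
                flank0 = np.arange(up3 - flank, up3) % L
            else:
                block0 = np.arange(up3 - span - 1, up3) % L
                flank0 = np.arange(up3, up3 + flank) % L
            grad, slope, thresh = _block_gradient(
                depth_track.depth, block0, flank0, strand, rng
            )
            out.append(BoundaryClass(up.name, down.name, cls, grad, slope, thresh))
    return out


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def sites_to_tsv(sites: Sequence[PolyASite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("site\tstrand\tn_reads\tcca_fraction\tcontext_gene\tutr_class\n")
        for s in sites:
            fh.write(
                f"{s.site}\t{s.strand}\t{s.n_reads}\t{s.cca_fraction:.3f}\t"
                f"{s.context_gene}\t{s.utr_class}\n"
            )


def tails_to_tsv(tails: Sequence[TailObservation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsite\tstrand\ttail_seq\thas_cca_prefix\ttail_a_len\n")
        for t in tails:
            fh.write(
                f"{t.read_id}\t{t.site}\t{t.strand}\t{t.tail_seq}\t"
                f"{int(t.has_cca_prefix)}\t{t.tail_a_len}\n"
            )


def models_to_tsv(models: Sequence[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cistrons\tstrand\tcistronic_class\tthree_end\tterminal_trnas\n")
        for m in models:
            end = m.three_end.site if m.three_end else "NA"
            fh.write(
                f"{','.join(m.cistrons)}\t{m.strand}\t{m.cistronic_class}\t"
                f"{end}\t{','.join(m.terminal_trnas)}\n"
            )


def boundaries_to_tsv(bounds: Sequence[BoundaryClass], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("upstream\tdownstream\tclass\tgradient\tslope\tnoise_threshold\n")
        for b in bounds:
            fh.write(
                f"{b.upstream}\t{b.downstream}\t{b.boundary_class}\t{b.gradient}\t"
                f"{b.slope:.4f}\t{b.noise_threshold:.4f}\n"
            )
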