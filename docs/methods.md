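# Methods

This note records the models implemented by `mitohairpin`, the parameter
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing its outputs.

## Coordinates and circularity

External I/O is 1-based inclusive, the convention of published mitogenome
organisation tables; a gene with `stop < start` spans the origin.
Internally every interval is converted once (``to_internal``/``to_external``)
to 0-based half-open coordinates, unwrapped past the origin where needed,
and all position arithmetic is modulo the genome length. The circular
intergenic complement merges overlapping genes before complementing and
reports an origin-spanning gap as a single segment, so segment lengths plus
the merged gene union always sum to the genome length (property-tested).

Sequences are restricted to {A,C,G,T,N}. Other IUPAC ambiguity codes are
rejected at load: the masking procedure used for dominant coverage peaks
introduces N runs, and a well-defined composition/skew denominator requires
unambiguous bases (N is excluded from denominators; N pairs with nothing in
the repeat scanner).

## Composition and skews

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C), computed from
absolute counts on the (+) strand of the selected region. Because the
formulas are ratios of linear combinations, percentages can be substituted
for counts unchanged; report helpers round to table precision (integer
percentages, 3 d.p. AT-skew, 2 d.p. GC-skew) while full precision is kept
internally.

## Maximal perfect inverted repeats

A repeat is a pair (left stem, right stem) with the right stem the exact
reverse complement of the left, separated by a loop. The scanner walks
every hairpin centre (an innermost base pair plus a gap) and extends the
stem outward while bases pair, reporting the repeat when

* the stem reaches `min_stem` (default 10),
* it can be extended neither outward (flanks do not pair, or `max_stem`
  is reached, or the sequence ends) nor inward (the loop's outermost bases
  do not pair, or pairing them would exceed `max_stem`).

Sub-repeats sharing a centre with a reported repeat are therefore
suppressed; nested repeats with distinct centres are all reported. The
defaults (stem 10–300, loop ≤ 100, zero mismatches, overlaps allowed) are
the classic palindrome-scan parameter set for hairpin-dense mitogenomes.
One consequence worth noting: a spacer whose ends happen to pair is
absorbed into the stem, so e.g. `A₁₀CGCGT₁₀` is one stem-12/loop-0 repeat,
not stem-10/loop-2+2.

`brute_force_repeats` is an independent exhaustive enumeration of all
(left start, stem, loop) triples with direct maximality checks, guarded to
≤ 2 kb; scanner ≡ oracle is asserted on random sequences in the test suite
and re-measured by the acceptance script. The linear scan is the default
(matching analyses of deposited linear representations); circular mode
scans the doubled sequence and de-duplicates by canonical start.

Overlapping repeat *footprints* (≥ 1 bp; abutting does not count) merge
transitively into disjoint hairpin regions; a gene is flagged as
repeat-containing when any region overlaps it by ≥ 1 bp.

## Coverage tracks and the end-ratio

Depth counts reference bases consumed (CIGAR M/=/X/D; insertions and soft
clips do not consume reference). Read ends are defined in read orientation:
a (−)-strand read's 5′ end is its rightmost aligned base. Tracks are
combined-strand by default (per-strand available). A read wrapping the
origin contributes depth on both arcs but exactly one 5′ and one 3′ end,
so `sum(depth) = Σ aligned_len` and `sum(ends5) = sum(ends3) = #reads`
hold exactly and tracks rotate equivariantly with the genome (tested).

The end-ratio (ends5+ends3)/depth is *undefined* (NaN), not zero, at
zero-depth sites. On uniformly tiled data it settles at ≈ 2/read-length;
cleavage sites appear as local maxima.

Linearising a circular molecule forces every alignment to stop at the cut,
piling read ends at positions 1 and L. `origin_artifact_check` quantifies
this: because the truncation is attached to the reads, rotating the
coordinate system moves the artifact with the old cut rather than removing
it — the behaviour the permutation control is designed to reveal.

Dominant peaks (e.g. an rRNA locus in RNA-seq) can be capped for reporting
(`mask_and_cap`); the raw depth is retained alongside and capped intervals
are annotated.

## Hairpin-associated coverage drops

For each hairpin region the drop statistic is median depth inside the
region divided by median depth in flanks of `flank` bp per side, excluding
flank positions that fall inside any other region; the region is flagged
when the ratio falls below `threshold` (defaults 200 bp / 0.5, both
reported). Regions with empty or zero-depth flanks are marked
indeterminate rather than flagged.

Two measurement caveats, both consequences of *read-level* dropout: (i)
flank positions within one read length of the region edge are partially
depressed (reads overlapping the region also cover them), so when the goal
is to *estimate* the retention probability rather than flag a drop, flanks
longer than ~4× the read length should be used — the acceptance
measurement uses 600 bp with 150 bp reads; (ii) a single ~70 bp region's
median ratio fluctuates with sd ≈ 0.04 at 100×, so retention is estimated
as the mean over regions.

## Tail detection and polyadenylation sites

A tail observation is a read whose transcript-3′ soft clip matches
`(CCA)?A{min_tail,}` *and* disagrees with the reference continuation past
the last aligned base (a clip identical to the reference is templated
sequence, e.g. a genomic A-run, and is never a tail). Defaults:
`min_tail = 4` non-templated A's; the post-CCA residue must be pure A
(`max_mismatch_in_tail = 0`). On (−)-strand reads the clip is taken from
the genomic-left end and reverse-complemented into transcript orientation.

Observations on one strand within `cluster_window = 3` bp merge into a
site placed at the modal observed position, ties broken toward the smaller
coordinate; sites with fewer than `min_support = 2` reads are dropped.
These two thresholds exist to make reproducible what is often done by eye
in an alignment viewer. Each site records its CCA fraction and a 3′-UTR
class relative to the nearest upstream ORF: `immediate` (at the stop),
`short_utr` (≤ 10 bp, no tRNA), `one_trna`/`two_trna` (the site lies at
the last of 1–2 intervening tRNA 3′ ends), else `other`.

Stop-codon completion classifies an ORF by frame remainder and terminal
bases: remainder 1 ending …T → `completed_T` (TAA after polyadenylation),
remainder 2 ending …TA → `completed_TA`, remainder 0 with TAA/TAG →
`complete`, anything else `inconsistent`.

## Transcript models and boundary classes

For each protein gene the model walks downstream on its strand to the
first called site (search capped at half the genome by default; genes with
no site get an open 3′ end and a warning). Genes sharing a terminal site
fuse into one bi-/multicistronic model; tRNAs between the innermost ORF
end and the site are recorded as the 3′-UTR tRNAs. Every protein gene
lands in exactly one model (tested). Mature 5′ ends are *not* called:
short-read pile-ups do not separate genuine 5′ termini from degradation
and library edge effects, so `five_end` stays unknown unless supplied.

Each adjacent same-strand protein-gene pair is classified from the called
sites and annotation: `trna_punctuated` (intervening same-strand tRNA and
a called site), `non_trna_cleavage` (site, no tRNA), `no_cleavage`
(bicistron candidate). The depth gradient across the inter-ORF block is
the sign of the least-squares slope; it is called only when |slope|
exceeds twice the standard deviation of slopes fitted to 100 bootstrap
windows drawn from the upstream flank (seeded; a 1e-9 floor keeps exactly
flat tracks at "none"). `reverse` means depth rises toward the upstream
ORF's 3′ end — the signature of 3′→5′ processing through a tRNA block;
`forward` the opposite.

## Gene orders

Orders are signed circular permutations; rotation and
reflection-with-sign-flip are equivalences, and oriented adjacencies are
stored in a canonical orientation so all comparisons inherit those
invariances (tested). tRNAs are excluded by default (block reasoning is at
the PCG+rRNA level); `include_trna=True` restores them. Conserved blocks
Block-1 (nad2-cox1-cox2-atp8-atp6-cox3-nad3), Block-2 (nad4l-nad4-nad5),
Block-3 (nad1-rrnL-rrnS), Block-4 (nad6-cytb) are built in; a block is
`intact` when its genes are consecutive and co-oriented (forward or
reversed). `diff_single_transposition` returns every gene whose removal
makes the orders equivalent — for a swap of neighbours both partners
qualify, and both are reported. The bundled ancestral gordioid order is a
reconstruction from the conserved-block logic, labelled synthetic; the two
observed order fixtures are exact.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
toy scale (6 kb, 14 genes on both strands), with every planted feature
recorded in a truth set:

* **Genome**: i.i.d. uniform background; planted repeats written with the
  right stem as the exact reverse complement of the left, made *exactly*
  maximal by forcing non-pairing flanking and innermost-loop bases, so
  detectors must reproduce (position, stem, loop) verbatim. Repeats are
  placed ≥ one read length away from their gene's transcript 3′ end so
  hairpin dropout cannot erase the tail reads anchoring a cleavage site —
  planted signals must stay separable for the truth set to score
  detectors exactly.
* **DNA library** (default 100×, 150 bp): uniform starts on the circle;
  a read overlapping a planted hairpin is retained with probability
  1 − dropout(stem) (default: 0.8 dropout for stems ≥ 30 bp, the "long
  hairpin" regime). Origin-crossing reads are soft-clipped at the cut like
  a linear mapper's output (default), reproducing the linearisation
  artifact, or rejected.
* **RNA library** (default 50×): per read, a per-strand precursor
  (the whole circle) is cleaved independently at each planted site with
  its usage probability; a mature fragment is chosen ∝ length; a geometric
  poly(A) tail (mean 30 nt — typical short-read-visible tail scale) is
  appended, preceded by CCA with probability 0.8 at tRNA 3′ ends; the read
  3′ end is placed with density ∝ position^bias (default exponent 2,
  emulating poly(A)-primed library chemistry); reads need ≥ 20 templated
  bases to be "mappable"; hairpin-overlapping reads are dropped with the
  RNA dropout (reverse-transcription failure, default 0.8 for stems
  ≥ 20 bp). Tail bases become soft clips in the emitted SAM.
* **Defaults**: 12 planted cleavage sites — one at almost every gene-group
  3′ end, two at partial usage 0.5, none between nad6 and cytb (so their
  mRNA is the planted bicistron), four at tRNA 3′ ends (CCA-eligible).
  Reads are error-free by default (the signals under study are structural);
  an optional substitution rate exists.

All randomness flows from one integer seed; identical seeds give
byte-identical FASTA/SAM/JSON. What the generator does **not** emulate:
sequencing errors and quality profiles, PCR duplicates, paired-end
fragment-size structure, expression differences between transcripts,
partial/degraded molecules, and real secondary-structure thermodynamics
(dropout is a step function of stem length). Passing recovery tests
therefore demonstrates correctness of the detectors' logic on structurally
faithful data, not robustness to every artefact of real libraries.

## Problem sizes and determinism

The bundled published annotation (37 genes, 14,013 bp) drives the
desk-scale statistics in seconds. Synthetic validation uses a 6 kb genome
at 100× DNA / 50× RNA (4,000 + 2,000 reads); scanner/oracle agreement is
measured on 100 random sequences of 50–500 bp. Pipeline outputs are
sorted and seeded, so re-running a configuration reproduces byte-identical
TSV/JSON.

## Known limitations

* Only perfect (mismatch-free, ungapped-stem) repeats are detected;
  imperfect repeats and free-energy-based hairpin prediction are out of
  scope.
* The drop statistic is a descriptive ratio, not a significance test; at
  low depth its flanking baseline is noisy (see the flank guidance above).
* Site calling depends on soft clips being present in the input
  alignments; mappers that trim rather than clip will hide tails.
* Boundary gradients from short-read cDNA conflate processing order with
  library 3′ bias; they corroborate, not prove, a cleavage direction.
* CCA assignment is per site; abutting tRNAs sharing one position are
  counted once.
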