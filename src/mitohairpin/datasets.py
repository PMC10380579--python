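"""Bundled reference data.

The package ships the published organisation table of the *Parachordodes
pustulosus* mitochondrial genome (GenBank OR003915, 14,013 bp; 37 genes) and
its whole-genome base composition, plus the gordioid mitochondrial gene
orders used for block/rearrangement comparison.  The raw sequence itself is
not bundled; accession-level analyses require the user to supply the FASTA.
"""

from __future__ import annotations

from importlib import resources

from .genome import GeneTable, read_gene_table
from .order import SignedCircularOrder

P_PUSTULOSUS_GENOME_ID = "OR003915"
P_PUSTULOSUS_GENOME_LENGTH = 14_013

#: Published whole-genome base percentages of P. pustulosus mtDNA, (+) strand.
P_PUSTULOSUS_COMPOSITION = {"A": 33.0, "T": 40.0, "G": 12.0, "C": 15.0}

#: Per-class GC percentages as published (whole genome, PCGs, tRNA, rRNA).
P_PUSTULOSUS_GC_BY_CLASS = {"whole_genome": 27, "PCG": 29, "tRNA": 23, "rRNA": 21}


def p_pustulosus_gene_table() -> GeneTable:
    """The published 37-gene annotation, 1-based inclusive coordinates."""
    with resources.as_file(
        resources.files("mitohairpin.data") / "parachordodes_pustulosus_genes.tsv"
    ) as path:
        return read_gene_table(
            path,
            dialect="tsv",
            genome_id=P_PUSTULOSUS_GENOME_ID,
            genome_length=P_PUSTULOSUS_GENOME_LENGTH,
        )


# ---------------------------------------------------------------------------
# Gordioid mitochondrial gene orders (PCG + rRNA level, genomic order).
# ---------------------------------------------------------------------------

#: Order shared by P. pustulosus, Gordionus alpestris, G. wolterstorffii and
#: Gordius sp. (derived from the organisation table above).
GORDIOID_COMMON_ORDER = SignedCircularOrder(
    "gordioid_common",
    [
        ("cox1", "+"), ("cox2", "+"), ("atp8", "+"), ("atp6", "+"),
        ("cox3", "+"), ("nad3", "+"), ("nad4l", "+"), ("nad4", "+"),
        ("nad5", "+"), ("nad2", "-"), ("nad6", "+"), ("cytb", "+"),
        ("rrnL", "-"), ("rrnS", "-"), ("nad1", "-"),
    ],
)

#: Chordodes sp. order: one transposition between nad6 and nad2, splitting
#: the nad6-cytb block.
CHORDODES_ORDER = SignedCircularOrder(
    "chordodes_sp",
    [
        ("cox1", "+"), ("cox2", "+"), ("atp8", "+"), ("atp6", "+"),
        ("cox3", "+"), ("nad3", "+"), ("nad4l", "+"), ("nad4", "+"),
        ("nad5", "+"), ("nad6", "+"), ("nad2", "-"), ("cytb", "+"),
        ("rrnL", "-"), ("rrnS", "-"), ("nad1", "-"),
    ],
)

#: Putative ancestral gordioid order.  Synthetic reconstruction from the
#: conserved bilaterian blocks (Block-1 with nad2 restored upstream of cox1
#: on the coding strand, Block-2, Block-3 in the gordioid rrnL-rrnS-nad1
#: arrangement, Block-4); not an observed genome.
ANCESTRAL_GORDIOID_ORDER = SignedCircularOrder(
    "ancestral_gordioida_synthetic",
    [
        ("nad2", "+"), ("cox1", "+"), ("cox2", "+"), ("atp8", "+"),
        ("atp6", "+"), ("cox3", "+"), ("nad3", "+"), ("nad4l", "+"),
        ("nad4", "+"), ("nad5", "+"), ("nad6", "+"), ("cytb", "+"),
        ("rrnL", "-"), ("rrnS", "-"), ("nad1", "-"),
    ],
)
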