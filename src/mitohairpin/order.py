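"""Signed circular gene orders and conserved-block comparison.

Mitochondrial gene arrangements are compared as signed circular permutations:
a genome is the cyclic sequence of its genes with strand signs, and two
orders are the same arrangement if they differ only by rotation or by
reading the circle in the opposite direction with all strands flipped.
Conservation is assessed against the classic bilaterian gene blocks and by
counting shared oriented adjacencies; a single-gene transposition between
two orders can be identified exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

SignedGene = tuple[str, str]  # (gene name, "+" or "-")


def _flip(g: SignedGene) -> SignedGene:
    return (g[0], "-" if g[1] == "+" else "+")


@dataclass(frozen=True)
class SignedCircularOrder:
    """A circular sequence of (gene, strand) pairs in genomic order."""

    genome_id: str
    order: tuple[SignedGene, ...]

    def __init__(self, genome_id: str, order: Iterable[SignedGene]):
        object.__setattr__(self, "genome_id", genome_id)
        object.__setattr__(self, "order", tuple((str(n), s) for n, s in order))
        names = [n for n, _ in self.order]
        if len(set(names)) != len(names):
            raise ValueError(f"{genome_id}: duplicate gene names in order")
        for _, s in self.order:
            if s not in ("+", "-"):
                raise ValueError(f"{genome_id}: strand must be '+'/'-'")

    def __len__(self) -> int:
        return len(self.order)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(n for n, _ in self.order)

    def restricted(self, keep: Iterable[str]) -> "SignedCircularOrder":
        keep = set(keep)
        return SignedCircularOrder(
            self.genome_id, [g for g in self.order if g[0] in keep]
        )

    def reflected(self) -> "SignedCircularOrder":
        """Read the circle the other way round, flipping every strand."""
        return SignedCircularOrder(
            self.genome_id, [_flip(g) for g in reversed(self.order)]
        )

    def rotated(self, k: int) -> "SignedCircularOrder":
        n = len(self.order)
        k %= n
        return SignedCircularOrder(self.genome_id, self.order[k:] + self.order[:k])

    def canonical(self) -> tuple[SignedGene, ...]:
        """Lexicographically minimal representative over rotations and reflection."""
        candidates = []
        for variant in (self.order, self.reflected().order):
            for k in range(len(variant)):
                candidates.append(variant[k:] + variant[:k])
        return min(candidates) if candidates else ()

    def equivalent(self, other: "SignedCircularOrder") -> bool:
        return self.canonical() == other.canonical()

    def adjacencies(self) -> frozenset[tuple[SignedGene, SignedGene]]:
        """Oriented adjacency set, symmetric under reading direction.

        The adjacency a->b equals the adjacency -b->-a seen from the other
        strand; each pair is stored in a canonical orientation.
        """
        n = len(self.order)
        out = set()
        for i in range(n):
            a, b = self.order[i], self.order[(i + 1) % n]
            out.add(min((a, b), (_flip(b), _flip(a))))
        return frozenset(out)

    @classmethod
    def from_tsv(cls, path: str | Path, genome_id: str = "") -> "SignedCircularOrder":
        """One gene per line: ``gene<TAB>strand``; '#' comments allowed."""
        path = Path(path)
        order = []
        for ln in path.read_text().splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            fields = ln.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: expected 'gene<TAB>strand', got {ln!r}")
            order.append((fields[0], fields[1]))
        return cls(genome_id or path.stem, order)

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{n}\t{s}\n" for n, s in self.order)
        )


@dataclass(frozen=True)
class ConservedBlock:
    """A bilaterian conserved gene cluster (ordered, co-oriented)."""

    name: str
    genes: tuple[str, ...]


#: The classic bilaterian conserved blocks used in gene-order comparisons.
CONSERVED_BLOCKS = {
    "Block-1": ConservedBlock(
        "Block-1", ("nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3")
    ),
    "Block-2": ConservedBlock("Block-2", ("nad4l", "nad4", "nad5")),
    "Block-3": ConservedBlock("Block-3", ("nad1", "rrnL", "rrnS")),
    "Block-4": ConservedBlock("Block-4", ("nad6", "cytb")),
}


def _is_trna(name: str) -> bool:
    return name.startswith("trn")


def _maybe_drop_trna(order: SignedCircularOrder, include_trna: bool) -> SignedCircularOrder:
    if include_trna:
        return order
    return order.restricted([n for n in order.genes if not _is_trna(n)])


def shared_adjacencies(
    a: SignedCircularOrder,
    b: SignedCircularOrder,
    include_trna: bool = False,
) -> tuple[int, list[tuple[SignedGene, SignedGene]]]:
    """Count oriented adjacencies present in both circular orders.

    tRNAs are dropped before comparison unless ``include_trna``; if the two
    gene universes differ, the comparison is restricted to the intersection
    (with a warning), and disjoint universes are an error.
    """
    a = _maybe_drop_trna(a, include_trna)
    b = _maybe_drop_trna(b, include_trna)
    common = a.genes & b.genes
    if not common:
        raise ValueError("orders share no genes")
    if common != a.genes or common != b.genes:
        warnings.warn(
            f"gene universes differ; comparing on {len(common)} shared genes",
            stacklevel=2,
        )
        a, b = a.restricted(common), b.restricted(common)
    shared = sorted(a.adjacencies() & b.adjacencies())
    return len(shared), shared


@dataclass(frozen=True)
class BlockStatus:
    status: str  # "intact", "partial", "absent"
    breaks: tuple[str, ...] = ()  # genes out of place / interrupting


def block_intact(
    order: SignedCircularOrder,
    block: ConservedBlock,
    include_trna: bool = False,
) -> BlockStatus:
    """Is a conserved block retained as a consecutive, co-oriented run?

    ``intact``: the block's genes appear consecutively (ignoring interleaved
    tRNAs unless ``include_trna``), in block order or fully reversed, all on
    one relative orientation.  ``partial`` lists the genes that break the
    run; ``absent`` if none of the block's genes are present.
    """
    present = [g for g in block.genes if g in order.genes]
    if not present:
        return BlockStatus("absent")
    if len(present) < len(block.genes):
        missing = tuple(g for g in block.genes if g not in order.genes)
        if len(present) == 1:
            return BlockStatus("partial", missing)
    ord_r = _maybe_drop_trna(order, include_trna)
    seq = list(ord_r.order)
    n = len(seq)
    target = [g for g in block.genes if g in ord_r.genes]
    m = len(target)
    if m >= 2:
        for variant in (target, target[::-1]):
            for k in range(n):
                window = [seq[(k + j) % n] for j in range(m)]
                if [g[0] for g in window] != variant:
                    continue
                signs = {g[1] for g in window} if variant == target else \
                        {("-" if g[1] == "+" else "+") for g in window}
                if len(signs) == 1:
                    return BlockStatus("intact")
    elif m == 1:
        return BlockStatus("intact")
    # find the offenders: genes of the block whose neighbours within the
    # block-restricted order are not their block neighbours
    block_only = ord_r.restricted(target)
    breaks = []
    bseq = [g[0] for g in block_only.order]
    nb = len(bseq)
    idx = {g: i for i, g in enumerate(target)}
    for i, g in enumerate(bseq):
        nxt = bseq[(i + 1) % nb]
        if abs(idx[g] - idx[nxt]) != 1 and nb > 1:
            breaks.extend([g, nxt])
    # genes whose strand disagrees with the majority also break co-orientation
    strands = [s for _, s in block_only.order]
    if len(set(strands)) > 1:
        majority = max(set(strands), key=strands.count)
        breaks.extend(g for (g, s) in block_only.order if s != majority)
    return BlockStatus("partial", tuple(dict.fromkeys(breaks)))


def block_report(order: SignedCircularOrder, include_trna: bool = False
                 ) -> dict[str, BlockStatus]:
    return {
        name: block_intact(order, blk, include_trna)
        for name, blk in CONSERVED_BLOCKS.items()
    }


def diff_single_transposition(
    a: SignedCircularOrder, b: SignedCircularOrder, include_trna: bool = False
) -> list[str]:
    """Genes whose removal alone makes the two circular orders equivalent.

    If the orders differ by the transposition of one gene, both the moved
    gene and (for an adjacent swap) its exchange partner satisfy the test;
    all candidates are returned.  Empty list: identical orders or orders
    differing by more than one move.
    """
    a = _maybe_drop_trna(a, include_trna)
    b = _maybe_drop_trna(b, include_trna)
    if a.genes != b.genes:
        raise ValueError("orders must share a gene universe")
    if a.equivalent(b):
        return []
    candidates = []
    for g in sorted(a.genes):
        keep = a.genes - {g}
        if a.restricted(keep).equivalent(b.restricted(keep)):
            candidates.append(g)
    return candidates
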