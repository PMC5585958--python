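"""Gene-universe indexing and bitset set algebra.

Every gene in the universe owns one bit position; the target set of a miRNA
(or of a miRNA group) is a fixed-width bit vector over that universe. Group
target sets are built by folding member bitsets with bitwise-or, and the
overlap between a group and an annotation category is counted by
*bit-probing*: for each gene of the (small) category, the corresponding bit
of the (large) group bitset is tested and a counter incremented when it is
set. ``popcount_overlap`` (popcount of the bitwise-and) is the cross-check
used by the test suite.

Union and probe operations are tallied in :class:`OpCounters` so a run can
report exactly how many primitive set operations it performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import LogicError
from .io import AnnotationTable, InteractionTable

logger = logging.getLogger(__name__)

_ONE = np.uint64(1)


@dataclass
class OpCounters:
    """Run-level tallies of primitive set operations."""

    union_ops: int = 0   # one per member bitset folded into a group union
    probe_ops: int = 0   # one per category gene probed against a group bitset

    def merge(self, other: "OpCounters") -> None:
        self.union_ops += other.union_ops
        self.probe_ops += other.probe_ops


@dataclass
class UniverseConfig:
    """Controls which genes receive a bit position.

    Genes that appear only in the annotation table can never be targeted, so
    by default they are excluded: they cannot contribute to any overlap
    count. Including them widens the bitsets and makes the reported
    ``category_size`` count all annotated genes.
    """

    include_annotation_only_genes: bool = False


class GeneUniverse:
    """Bijection between gene identifiers and bit positions 0..U-1.

    Bit positions follow the sorted order of gene identifiers, so the
    universe is independent of input row order.
    """

    def __init__(self, gene_ids: Iterable[str]):
        self.gene_at: list[str] = sorted(set(gene_ids))
        self.index_of: dict[str, int] = {g: i for i, g in enumerate(self.gene_at)}

    @property
    def size(self) -> int:
        return len(self.gene_at)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.index_of

    def __len__(self) -> int:
        return self.size


class TargetBitset:
    """Fixed-width bit vector over a gene universe.

    Backed by a numpy uint64 word array; bits at positions >= n_bits are
    never set.
    """

    __slots__ = ("n_bits", "words")

    def __init__(self, n_bits: int, words: np.ndarray | None = None):
        self.n_bits = int(n_bits)
        n_words = (self.n_bits + 63) >> 6
        if words is None:
            self.words = np.zeros(n_words, dtype=np.uint64)
        else:
            if words.shape != (n_words,):
                raise LogicError(f"word array of shape {words.shape} does not fit {n_bits} bits")
            self.words = words

    @classmethod
    def from_positions(cls, positions: Sequence[int], n_bits: int) -> "TargetBitset":
        bs = cls(n_bits)
        pos = np.asarray(positions, dtype=np.int64)
        if pos.size:
            if pos.min() < 0 or pos.max() >= n_bits:
                raise LogicError("bit position outside universe")
            np.bitwise_or.at(bs.words, pos >> 6, _ONE << (pos & 63).astype(np.uint64))
        return bs

    def cardinality(self) -> int:
        return int(np.bitwise_count(self.words).sum())

    def test(self, position: int) -> bool:
        return bool((self.words[position >> 6] >> np.uint64(position & 63)) & _ONE)

    def positions(self) -> np.ndarray:
        """Sorted array of set bit positions (used by the naive oracle and tests)."""
        out = np.flatnonzero(
            np.unpackbits(self.words.view(np.uint8), bitorder="little")
        )
        return out[out < self.n_bits]

    def copy(self) -> "TargetBitset":
        return TargetBitset(self.n_bits, self.words.copy())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TargetBitset)
            and self.n_bits == other.n_bits
            and bool(np.array_equal(self.words, other.words))
        )

    def __hash__(self):  # mutable; identity hashing only
        return id(self)

    def __repr__(self) -> str:
        return f"TargetBitset(n_bits={self.n_bits}, cardinality={self.cardinality()})"


@dataclass
class CategoryIndex:
    """An annotation category as sorted bit positions over the universe."""

    category_id: str
    name: str
    gene_bits: np.ndarray  # strictly increasing int64 positions, all < U

    @property
    def size(self) -> int:
        return int(self.gene_bits.size)


def build_universe(
    interactions: InteractionTable,
    annotations: AnnotationTable | None = None,
    config: UniverseConfig | None = None,
) -> GeneUniverse:
    """Index every targetable gene; optionally also annotation-only genes."""
    config = config or UniverseConfig()
    if not interactions.entries:
        raise LogicError("cannot build a gene universe from an empty interaction table")
    genes = {g for _, g in interactions.entries}
    if config.include_annotation_only_genes and annotations is not None:
        genes |= {g for g, _, _ in annotations.entries}
    return GeneUniverse(genes)


def category_indexes(
    annotations: AnnotationTable, universe: GeneUniverse
) -> list[CategoryIndex]:
    """Project annotation categories onto the universe.

    Genes without a bit position are dropped from the category; categories
    left empty are dropped entirely (logged). Output is sorted by category id.
    """
    by_cat: dict[str, tuple[str, list[int]]] = {}
    for gene_id, cat_id, cat_name in annotations.entries:
        name, bits = by_cat.setdefault(cat_id, (cat_name, []))
        idx = universe.index_of.get(gene_id)
        if idx is not None:
            bits.append(idx)
    out: list[CategoryIndex] = []
    for cat_id in sorted(by_cat):
        name, bits = by_cat[cat_id]
        if not bits:
            logger.warning("category %s has no gene in the universe; dropped", cat_id)
            continue
        out.append(
            CategoryIndex(cat_id, name, np.unique(np.asarray(bits, dtype=np.int64)))
        )
    return out


def mirna_bitsets(
    interactions: InteractionTable, universe: GeneUniverse
) -> dict[str, TargetBitset]:
    """One target bitset per miRNA; cardinality = distinct target count."""
    targets: dict[str, list[int]] = {}
    for mirna_id, gene_id in interactions.entries:
        targets.setdefault(mirna_id, []).append(universe.index_of[gene_id])
    return {
        m: TargetBitset.from_positions(pos, universe.size)
        for m, pos in targets.items()
    }


def group_union(
    members: Sequence[TargetBitset], counters: OpCounters | None = None
) -> TargetBitset:
    """Fold member bitsets with bitwise-or into an initially empty accumulator.

    Increments the union counter by one per member folded.
    """
    if not members:
        logger.warning("group_union called with an empty member list")
        raise LogicError("group_union needs the universe width; empty member list")
    width = members[0].n_bits
    for m in members[1:]:
        if m.n_bits != width:
            raise LogicError("group_union members have mismatched widths")
    acc = np.zeros_like(members[0].words)
    for m in members:
        np.bitwise_or(acc, m.words, out=acc)
    if counters is not None:
        counters.union_ops += len(members)
    return TargetBitset(width, acc)


def probe_overlap(
    group: TargetBitset, category: CategoryIndex, counters: OpCounters | None = None
) -> int:
    """|group ∩ category| by probing one group bit per category gene."""
    pos = category.gene_bits
    if pos.size and int(pos[-1]) >= group.n_bits:
        raise LogicError("category position outside the group's universe")
    hits = (group.words[pos >> 6] >> (pos & 63).astype(np.uint64)) & _ONE
    if counters is not None:
        counters.probe_ops += category.size
    return int(hits.sum())


def popcount_overlap(group: TargetBitset, category_bitset: TargetBitset) -> int:
    """popcount(group AND category); the intersection-size cross-check."""
    if group.n_bits != category_bitset.n_bits:
        raise LogicError("popcount_overlap requires equal widths")
    return int(np.bitwise_count(group.words & category_bitset.words).sum())


def stack_bitsets(
    bitsets: Mapping[str, TargetBitset], order: Sequence[str]
) -> np.ndarray:
    """Matrix of bitset words, one row per miRNA in `order` (pool fast path)."""
    return np.stack([bitsets[m].words for m in order])
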