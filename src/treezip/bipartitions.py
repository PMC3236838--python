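"""Clade bitstrings, universal hashing and the bipartition table.

Every edge of a rooted tree defines a clade: the set of taxa below it,
encoded as an n-bit bitstring over the lexicographic taxon order (bit
``b_0`` is the first taxon).  A rooted binary tree on n taxa has exactly
``2(n-1)`` such clades, one per non-root node, leaves included.

Bitstrings are held as Python ints with taxon ``i`` at bit position
``n-1-i``, so the integer order of two same-length masks equals the
lexicographic order of their bitstring texts.

Two universal hash functions address the table: ``h1`` places a clade in
a bucket, ``h2`` gives it a short bipartition identifier (BID).  Both
are modular dot products of the bitstring with a seeded random vector.
Record identity is always decided on the full bitstring, so hash
collisions cannot corrupt output; the hashes only organise storage.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Optional, Sequence

import sympy

from .trees import Node, Phylotree, TaxaIndex, quantize_length

__all__ = [
    "mask_to_text",
    "text_to_mask",
    "canonical_sort_key",
    "extract_clades",
    "HashParams",
    "default_hash_params",
    "h1",
    "h2",
    "BipartitionRecord",
    "BipartitionTable",
    "tree_signature",
    "deduplicate",
]


def mask_to_text(mask: int, n: int) -> str:
    """Bitstring text, ``b_0`` leftmost (e.g. taxa A,B of six -> '110000')."""
    if mask < 0 or mask >= (1 << n):
        raise ValueError(f"mask {mask} does not fit in {n} bits")
    return format(mask, f"0{n}b")


def text_to_mask(text: str) -> int:
    if not text or set(text) - {"0", "1"}:
        raise ValueError(f"not a bitstring: {text!r}")
    return int(text, 2)


def canonical_sort_key(mask: int) -> tuple[int, int]:
    """Sort key for the canonical TRZ line order.

    Decreasing count of set bits, ties broken by decreasing bitstring
    text (equivalently decreasing mask value at fixed width).
    """
    return (-mask.bit_count(), -mask)


def extract_clades(
    tree: Phylotree, taxa: TaxaIndex
) -> list[tuple[int, Optional[Decimal]]]:
    """All clades of *tree* as ``(mask, branch length)`` pairs.

    One entry per non-root node (leaves included), produced by a
    post-order traversal in which each internal mask is the OR of its
    children's masks.  The root clade (all bits set) is excluded.
    Emission order is traversal order; callers must not rely on it.
    """
    n = len(taxa)
    out: list[tuple[int, Optional[Decimal]]] = []
    seen: set[str] = set()

    def walk(node: Node, is_root: bool) -> int:
        if node.is_leaf:
            label = node.label or ""
            if label in seen:
                raise ValueError(f"duplicate leaf {label!r}")
            seen.add(label)
            mask = 1 << (n - 1 - taxa.position(label))
        else:
            mask = 0
            for child in node.children:
                mask |= walk(child, False)
        if not is_root:
            out.append((mask, node.length))
        return mask

    full = walk(tree.root, True)
    if full != (1 << n) - 1:
        missing = [name for i, name in enumerate(taxa) if not full >> (n - 1 - i) & 1]
        raise ValueError(f"tree is missing taxa: {missing}")
    return out


# ---------------------------------------------------------------------------
# universal hashing


@dataclass(frozen=True)
class HashParams:
    """Parameters of the two universal hash functions.

    ``r`` and ``s`` are length-n vectors of random integers drawn in
    ``[0, m1)`` and ``[0, m2)``; ``m1`` is the (prime) table size and
    ``m2`` the (prime) BID space size.
    """

    r: tuple[int, ...]
    s: tuple[int, ...]
    m1: int
    m2: int
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.r) != len(self.s):
            raise ValueError("R and S must have equal length")
        if self.m1 < 2 or self.m2 < 2:
            raise ValueError("m1 and m2 must be at least 2")
        # entries are drawn in [0, m1) / [0, m2) by generate(), but larger
        # values are harmless under the modular dot product, so only
        # negativity is rejected here
        if any(x < 0 for x in self.r) or any(x < 0 for x in self.s):
            raise ValueError("hash vector entries must be non-negative")

    @property
    def n(self) -> int:
        return len(self.r)

    @classmethod
    def generate(cls, n: int, m1: int, m2: int, seed: int = 1) -> "HashParams":
        rng = random.Random(seed)
        r = tuple(rng.randrange(m1) for _ in range(n))
        s = tuple(rng.randrange(m2) for _ in range(n))
        return cls(r=r, s=s, m1=m1, m2=m2, seed=seed)


def default_hash_params(n: int, t: int, seed: int = 1) -> HashParams:
    """Seeded default parameters for a collection of *t* trees on *n* taxa.

    ``m1`` is the smallest prime >= max(37, 4*n*ceil(sqrt(t))); ``m2``
    the smallest prime >= 10^8.  These affect only internal bucket
    layout: the TRZ output is canonical (sorted) and independent of them.
    """
    ceil_sqrt = math.isqrt(max(t, 1))
    if ceil_sqrt * ceil_sqrt < max(t, 1):
        ceil_sqrt += 1
    bound = max(37, 4 * n * ceil_sqrt)
    m1 = int(sympy.nextprime(bound - 1))
    m2 = int(sympy.nextprime(10**8 - 1))
    return HashParams.generate(n, m1, m2, seed)


def _dot_mod(mask: int, vec: Sequence[int], modulus: int) -> int:
    n = len(vec)
    if mask < 0 or mask >= (1 << n):
        raise ValueError(f"bitstring does not fit the {n}-entry hash vector")
    total = 0
    m = mask
    i = n - 1
    while m:
        if m & 1:
            total += vec[i]
        m >>= 1
        i -= 1
    return total % modulus


def h1(mask: int, params: HashParams) -> int:
    """Bucket index: ``(sum_i b_i * r_i) mod m1``."""
    return _dot_mod(mask, params.r, params.m1)


def h2(mask: int, params: HashParams) -> int:
    """Bipartition identifier (BID): ``(sum_i b_i * s_i) mod m2``."""
    return _dot_mod(mask, params.s, params.m2)


# ---------------------------------------------------------------------------
# the table


@dataclass
class BipartitionRecord:
    mask: int
    bid: int
    members: list[int] = field(default_factory=list)
    weights: Optional[list[Decimal]] = None


class BipartitionTable:
    """Hash table mapping clade bitstrings to the trees containing them.

    Buckets are addressed by ``h1``; records in a bucket are told apart
    by full-bitstring comparison (the BID from ``h2`` is stored but never
    trusted for identity).  Trees are inserted in id order, so member
    lists come out strictly increasing.
    """

    def __init__(self, params: HashParams, n: int, weighted: bool) -> None:
        if params.n != n:
            raise ValueError("hash vectors must have one entry per taxon")
        self.params = params
        self.n = n
        self.weighted = weighted
        self.buckets: dict[int, list[BipartitionRecord]] = {}
        self._count = 0

    def __len__(self) -> int:
        """Number of distinct bipartitions stored (B)."""
        return self._count

    def lookup(self, mask: int) -> Optional[BipartitionRecord]:
        for rec in self.buckets.get(h1(mask, self.params), ()):
            if rec.mask == mask:
                return rec
        return None

    def insert(self, mask: int, uid: int, weight: Optional[Decimal] = None) -> None:
        if mask <= 0 or mask >= (1 << self.n) - 1:
            raise ValueError("clade must be a proper non-empty subset of the taxa")
        if self.weighted and weight is None:
            raise ValueError("weighted table requires a branch length")
        if not self.weighted and weight is not None:
            raise ValueError("unweighted table does not accept branch lengths")
        idx = h1(mask, self.params)
        bucket = self.buckets.setdefault(idx, [])
        for rec in bucket:
            if rec.mask == mask:
                if rec.members and uid < rec.members[-1]:
                    raise ValueError("tree ids must be inserted in increasing order")
                if rec.members and uid == rec.members[-1]:
                    raise ValueError(
                        f"clade {mask_to_text(mask, self.n)} inserted twice for tree {uid}"
                    )
                rec.members.append(uid)
                if self.weighted:
                    assert rec.weights is not None
                    rec.weights.append(weight)  # type: ignore[arg-type]
                return
        rec = BipartitionRecord(
            mask=mask,
            bid=h2(mask, self.params),
            members=[uid],
            weights=[weight] if self.weighted else None,  # type: ignore[list-item]
        )
        bucket.append(rec)
        self._count += 1

    def records(self) -> list[BipartitionRecord]:
        out: list[BipartitionRecord] = []
        for bucket in self.buckets.values():
            out.extend(bucket)
        return out

    def sorted_records(self) -> list[BipartitionRecord]:
        """Records in canonical TRZ order (decreasing set bits, then
        decreasing bitstring text)."""
        return sorted(self.records(), key=lambda rec: canonical_sort_key(rec.mask))


def tree_signature(
    table: BipartitionTable,
    clades: Sequence[tuple[int, Optional[Decimal]]],
    mantissa_digits: int = 6,
) -> tuple:
    """A tree's signature over the finished table's bipartition universe.

    A k-bit membership vector over the B bipartitions in canonical order;
    in weighted mode it is augmented with the tree's branch lengths
    (quantized), aligned to the set positions, so identity requires equal
    weights as well as equal topology.
    """
    order = {rec.mask: j for j, rec in enumerate(table.sorted_records())}
    bits = ["0"] * len(order)
    weights: list[tuple[int, Decimal]] = []
    for mask, length in clades:
        if mask not in order:
            raise KeyError(f"clade {mask_to_text(mask, table.n)} absent from table")
        j = order[mask]
        bits[j] = "1"
        if table.weighted:
            if length is None:
                raise ValueError("weighted table but clade carries no length")
            weights.append((j, quantize_length(length, mantissa_digits)))
    if table.weighted:
        weights.sort()
        return ("".join(bits), tuple(w for _, w in weights))
    return ("".join(bits),)


def deduplicate(
    clade_rows: Sequence[Sequence[tuple[int, Optional[Decimal]]]],
    weighted: bool,
    mantissa_digits: int = 6,
) -> tuple[list[int], dict[int, tuple[int, ...]]]:
    """Assign unique-tree ids by first appearance.

    *clade_rows* holds the clade set of each original tree in file order.
    Two trees are the same iff their clade sets match — including branch
    lengths at mantissa precision in weighted mode.  Returns the unique
    id of every original position and a duplicates map listing, for each
    unique id appearing more than once, all its original positions.
    """
    assignment: list[int] = []
    first_seen: dict[frozenset, int] = {}
    positions: dict[int, list[int]] = {}
    for pos, row in enumerate(clade_rows):
        if weighted:
            sig = frozenset(
                (mask, quantize_length(w, mantissa_digits))  # type: ignore[arg-type]
                for mask, w in row
            )
        else:
            sig = frozenset(mask for mask, _ in row)
        uid = first_seen.setdefault(sig, len(first_seen))
        assignment.append(uid)
        positions.setdefault(uid, []).append(pos)
    duplicates = {
        uid: tuple(poss) for uid, poss in positions.items() if len(poss) > 1
    }
    return assignment, duplicates
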