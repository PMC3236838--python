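"""End-to-end compression, decompression and consensus.

Compression walks every tree, collects its clades into the bipartition
hash table keyed by unique-tree id, and emits one canonical TRZ line per
distinct bipartition.  Because the lines are sorted canonically and tree
identity is semantic, two collections with one-to-one identical trees
produce byte-identical TRZ files no matter how their Newick strings were
written.

Decompression rebuilds each tree from its clades by refining a star
tree: clades arrive in decreasing size, so each new internal node simply
adopts the already-placed subtrees it contains.  The same refinement
builds strict and majority-rule consensus trees directly from the
bipartition occurrence counts, without reconstructing the collection.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from typing import Optional, Sequence

from .bipartitions import (
    BipartitionTable,
    default_hash_params,
    deduplicate,
    extract_clades,
    mask_to_text,
)
from .trees import Node, Phylotree, TaxaIndex, quantize_length
from .trz_codec import TRZDocument, TRZHeader, TRZLine

__all__ = [
    "DecodeMatrices",
    "compress",
    "rebuild_matrices",
    "build_tree_from_clades",
    "decompress_all",
    "decompress_unique",
    "consensus",
]


@dataclass
class DecodeMatrices:
    """Per-unique-tree clade lists used to rebuild trees.

    Row ``i`` of ``M`` holds the clade bitstrings of unique tree ``i`` in
    decreasing set-bit order (the stored TRZ order); row ``i`` of ``N``
    holds the aligned branch lengths (weighted documents only).
    """

    M: list[list[int]]
    N: Optional[list[list[Decimal]]]


def compress(
    trees: Sequence[Phylotree],
    taxa: TaxaIndex,
    mantissa_digits: int = 6,
    hash_seed: int = 1,
) -> TRZDocument:
    """Compress a uniform collection of trees over *taxa* into a TRZ document."""
    if not trees:
        raise ValueError("cannot compress an empty collection")
    weighted = trees[0].weighted
    if any(tr.weighted != weighted for tr in trees):
        raise ValueError("collection mixes weighted and unweighted trees")
    rows = [extract_clades(tr, taxa) for tr in trees]
    assignment, duplicates = deduplicate(rows, weighted, mantissa_digits)
    u = max(assignment) + 1
    first_row: dict[int, Sequence] = {}
    for pos, uid in enumerate(assignment):
        first_row.setdefault(uid, rows[pos])
    params = default_hash_params(len(taxa), len(trees), hash_seed)
    table = BipartitionTable(params, len(taxa), weighted)
    for uid in range(u):
        for mask, length in first_row[uid]:
            table.insert(
                mask,
                uid,
                quantize_length(length, mantissa_digits) if weighted else None,
            )
    lines = [
        TRZLine(
            mask=rec.mask,
            members=tuple(rec.members),
            weights=tuple(rec.weights) if weighted else None,  # type: ignore[arg-type]
        )
        for rec in table.sorted_records()
    ]
    header = TRZHeader(
        taxa=taxa,
        t=len(trees),
        u=u,
        n_bipartitions=len(table),
        weighted=weighted,
        mantissa_digits=mantissa_digits,
    )
    return TRZDocument(header=header, lines=lines, duplicates=duplicates)


def rebuild_matrices(doc: TRZDocument) -> DecodeMatrices:
    """Distribute the document's lines into per-unique-tree clade rows.

    Lines are processed in stored (canonical) order and appended to every
    member's row, so each row comes out in decreasing set-bit order with
    its branch lengths aligned.
    """
    u = doc.header.u
    M: list[list[int]] = [[] for _ in range(u)]
    N: Optional[list[list[Decimal]]] = (
        [[] for _ in range(u)] if doc.header.weighted else None
    )
    for line in doc.lines:
        for k, uid in enumerate(line.members):
            if uid >= u:
                raise ValueError(f"member id {uid} >= u={u}")
            M[uid].append(line.mask)
            if N is not None:
                assert line.weights is not None
                N[uid].append(line.weights[k])
    return DecodeMatrices(M=M, N=N)


def build_tree_from_clades(
    masks: Sequence[int],
    weights: Optional[Sequence[Decimal]],
    taxa: TaxaIndex,
) -> Phylotree:
    """Rebuild one tree from its clades by star-tree refinement.

    Starting from the star tree on n taxa, each multi-taxon clade (in
    decreasing set-bit order) becomes a new internal node adopting the
    current siblings it fully contains; single-taxon clades attach leaf
    branch lengths.  The result's clade set equals the input set.
    """
    n = len(taxa)
    if weights is not None and len(weights) != len(masks):
        raise ValueError("weights must align with clades")
    prev_bits = n + 1
    leaves: list[Node] = [Node(label=name) for name in taxa]
    root = Node(children=list(leaves))
    node_mask: dict[int, int] = {id(root): (1 << n) - 1}
    for i, leaf in enumerate(leaves):
        node_mask[id(leaf)] = 1 << (n - 1 - i)

    for j, mask in enumerate(masks):
        bits = mask.bit_count()
        if bits > prev_bits:
            raise ValueError("clades must be presented in decreasing set-bit order")
        prev_bits = bits
        length = weights[j] if weights is not None else None
        if bits == 0 or mask >= (1 << n) - 1:
            raise ValueError("clade must be a proper non-empty taxon subset")
        if bits == 1:
            leaf = leaves[n - mask.bit_length()]
            leaf.length = length
            continue
        # descend to the deepest node whose clade contains the new one
        parent = root
        while True:
            for child in parent.children:
                cmask = node_mask[id(child)]
                if cmask & mask == mask and cmask != mask:
                    parent = child
                    break
            else:
                break
        contained: list[Node] = []
        union = 0
        for child in parent.children:
            cmask = node_mask[id(child)]
            overlap = cmask & mask
            if overlap == cmask:
                contained.append(child)
                union |= cmask
            elif overlap:
                raise ValueError(
                    f"incompatible clade {mask_to_text(mask, n)}: overlaps an "
                    "existing group without containing it"
                )
        if union != mask:
            raise ValueError(
                f"clade {mask_to_text(mask, n)} is not a union of current siblings"
            )
        if len(contained) == len(parent.children):
            raise ValueError(
                f"clade {mask_to_text(mask, n)} duplicates an existing group"
            )
        new = Node(children=contained, length=length)
        node_mask[id(new)] = mask
        insert_at = parent.children.index(contained[0])
        parent.children = [
            c for c in parent.children if c not in contained
        ]
        parent.children.insert(insert_at, new)
    return Phylotree(root)


def _build_unique_trees(doc: TRZDocument) -> list[Phylotree]:
    matrices = rebuild_matrices(doc)
    taxa = doc.header.taxa
    out = []
    for uid in range(doc.header.u):
        weights = matrices.N[uid] if matrices.N is not None else None
        out.append(build_tree_from_clades(matrices.M[uid], weights, taxa))
    return out


def decompress_unique(doc: TRZDocument) -> list[Phylotree]:
    """The u unique trees of the collection, in unique-id order."""
    return _build_unique_trees(doc)


def decompress_all(doc: TRZDocument) -> list[Phylotree]:
    """All t trees, in their original file order (duplicates expanded)."""
    unique = _build_unique_trees(doc)
    return [unique[uid].copy() for uid in doc.position_map()]


def consensus(doc: TRZDocument, mode: str) -> Phylotree:
    """Strict or majority-rule consensus of the collection.

    Occurrence counts are taken over all t original trees (duplicates
    expanded).  ``strict`` keeps the clades present in every tree;
    ``majority`` those present in strictly more than half.  The result is
    emitted without branch lengths.
    """
    if mode not in ("strict", "majority"):
        raise ValueError(f"unknown consensus mode: {mode!r}")
    t = doc.header.t
    if t == 0:
        raise ValueError("cannot take the consensus of an empty collection")
    multiplicity = [1] * doc.header.u
    for uid, positions in doc.duplicates.items():
        multiplicity[uid] = len(positions)
    kept: list[int] = []
    for line in doc.lines:
        count = sum(multiplicity[uid] for uid in line.members)
        if (mode == "strict" and count == t) or (mode == "majority" and 2 * count > t):
            kept.append(line.mask)
    # lines are already in decreasing set-bit order
    return build_tree_from_clades(kept, None, doc.header.taxa)
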