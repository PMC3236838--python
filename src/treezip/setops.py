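"""Union, intersection and set difference on TRZ documents.

The operations work on whole trees: two trees are the same iff they
share their clade set — including branch lengths at the documents'
mantissa precision in weighted mode (a topology-only comparison is
available behind a flag).  Identity is decided on clade signatures read
straight out of the two documents, so no tree structure is ever rebuilt
and the result is itself a TRZ document with no loss of space savings.
"""

from __future__ import annotations

from decimal import Decimal
from typing import Optional, Sequence

from .engine import rebuild_matrices
from .trz_codec import TRZDocument, TRZHeader, TRZLine

__all__ = ["SET_OPERATIONS", "apply_setop", "chain_setops"]

SET_OPERATIONS = ("union", "intersection", "difference")


def _signatures(doc: TRZDocument, topology_only: bool) -> list[frozenset]:
    matrices = rebuild_matrices(doc)
    out: list[frozenset] = []
    for uid in range(doc.header.u):
        if matrices.N is not None and not topology_only:
            out.append(frozenset(zip(matrices.M[uid], matrices.N[uid])))
        else:
            out.append(frozenset(matrices.M[uid]))
    return out


def _rows(doc: TRZDocument) -> list[tuple[tuple[int, ...], Optional[tuple[Decimal, ...]]]]:
    matrices = rebuild_matrices(doc)
    return [
        (
            tuple(matrices.M[uid]),
            tuple(matrices.N[uid]) if matrices.N is not None else None,
        )
        for uid in range(doc.header.u)
    ]


def _document_from_rows(
    rows: Sequence[tuple[tuple[int, ...], Optional[tuple[Decimal, ...]]]],
    template: TRZHeader,
) -> TRZDocument:
    weighted = template.weighted
    members: dict[int, list[int]] = {}
    weights: dict[int, list[Decimal]] = {}
    for uid, (masks, lens) in enumerate(rows):
        for k, mask in enumerate(masks):
            members.setdefault(mask, []).append(uid)
            if weighted:
                assert lens is not None
                weights.setdefault(mask, []).append(lens[k])
    lines = [
        TRZLine(
            mask=mask,
            members=tuple(ids),
            weights=tuple(weights[mask]) if weighted else None,
        )
        for mask, ids in members.items()
    ]
    header = TRZHeader(
        taxa=template.taxa,
        t=len(rows),
        u=len(rows),
        n_bipartitions=len(lines),
        weighted=weighted,
        mantissa_digits=template.mantissa_digits,
    )
    return TRZDocument(header=header, lines=lines, duplicates={})


def apply_setop(
    a: TRZDocument,
    b: TRZDocument,
    op: str,
    topology_only: bool = False,
) -> TRZDocument:
    """Apply *op* (``union``/``intersection``/``difference``) to two
    compatible documents.

    The result contains unique trees only (t = u, no duplicates
    section), ordered by first appearance scanning a's unique trees then
    b's.  An empty result is a valid document with t = u = B = 0.
    """
    if op not in SET_OPERATIONS:
        raise ValueError(f"unknown set operation: {op!r}")
    if a.header.taxa != b.header.taxa:
        only_a = set(a.header.taxa) - set(b.header.taxa)
        only_b = set(b.header.taxa) - set(a.header.taxa)
        raise ValueError(
            f"taxa mismatch between operands (only in first: {sorted(only_a)}, "
            f"only in second: {sorted(only_b)})"
        )
    if a.header.weighted != b.header.weighted:
        raise ValueError("cannot combine a weighted and an unweighted document")
    if a.header.mantissa_digits != b.header.mantissa_digits:
        raise ValueError("operands disagree on branch-length precision")
    sig_a = _signatures(a, topology_only)
    sig_b = _signatures(b, topology_only)
    rows_a = _rows(a)
    rows_b = _rows(b)
    kept: list = []
    seen: set[frozenset] = set()
    if op == "union":
        for sig, row in zip(sig_a + sig_b, rows_a + rows_b):
            if sig not in seen:
                seen.add(sig)
                kept.append(row)
    elif op == "intersection":
        b_set = set(sig_b)
        for sig, row in zip(sig_a, rows_a):
            if sig in b_set and sig not in seen:
                seen.add(sig)
                kept.append(row)
    else:  # difference
        b_set = set(sig_b)
        for sig, row in zip(sig_a, rows_a):
            if sig not in b_set and sig not in seen:
                seen.add(sig)
                kept.append(row)
    return _document_from_rows(kept, a.header)


def chain_setops(
    documents: Sequence[TRZDocument],
    ops: Sequence[str],
    topology_only: bool = False,
) -> TRZDocument:
    """Left-fold a sequence of set operations over documents.

    ``chain((d0, d1, d2), (op0, op1))`` computes ``op1(op0(d0, d1), d2)``;
    every intermediate result is itself a valid TRZ document.
    """
    if len(ops) != len(documents) - 1:
        raise ValueError("need exactly one operation between consecutive documents")
    result = documents[0]
    for doc, op in zip(documents[1:], ops):
        result = apply_setop(result, doc, op, topology_only=topology_only)
    return result
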