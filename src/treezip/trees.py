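"""Rooted phylogenetic trees and the Newick text format.

Trees are kept exactly as written: rooted, with the child order of the
input string preserved.  A tree on ``n`` taxa has ``O(2^(n-1))`` equivalent
Newick strings that differ only in the order of children at internal
nodes; :func:`canonical_newick` picks one deterministic representative and
:func:`commute` draws a random equivalent one, which together are the
basis for testing that downstream compression depends only on the tree,
never on the string.

Branch lengths are carried as :class:`decimal.Decimal` so that fixed
mantissa-precision round trips are exact.
"""

from __future__ import annotations

import copy
import math
import random
from dataclasses import dataclass
from decimal import Decimal, InvalidOperation, ROUND_HALF_UP
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "NewickError",
    "TaxaIndex",
    "Node",
    "Phylotree",
    "parse_newick",
    "read_newick_file",
    "write_newick",
    "canonical_newick",
    "canonical_topology_key",
    "commute",
    "quantize_length",
]

#: characters that may not appear in taxon names (the TRZ header is
#: whitespace-delimited and Newick reserves the punctuation)
_FORBIDDEN_NAME_CHARS = set(" \t\r\n\f\v:,;()")

_NUMBER_CHARS = set("0123456789.eE+-")


class NewickError(ValueError):
    """Malformed Newick text or an invalid tree/collection."""


def quantize_length(value: Decimal, mantissa_digits: int = 6) -> Decimal:
    """Round *value* to a fixed number of fractional digits.

    Rounding is half away from zero.  This is the precision at which
    branch lengths are stored, compared and printed canonically.
    """
    return value.quantize(Decimal(1).scaleb(-mantissa_digits), rounding=ROUND_HALF_UP)


@dataclass(frozen=True)
class TaxaIndex:
    """Lexicographically ordered taxon names.

    Position ``i`` of a name defines bit ``b_i`` of every clade bitstring
    built over this index.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("taxa index must contain at least one name")
        for name in self.names:
            if not name or any(c in _FORBIDDEN_NAME_CHARS for c in name):
                raise ValueError(f"invalid taxon name: {name!r}")
        if list(self.names) != sorted(set(self.names)):
            raise ValueError("taxon names must be unique and sorted lexicographically")

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "TaxaIndex":
        return cls(tuple(sorted(set(names))))

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def position(self, name: str) -> int:
        # names are sorted, but collections are small; bisect is overkill
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(name) from None


class Node:
    """A tree node: ordered children, a leaf label, an edge length above it."""

    __slots__ = ("children", "label", "length")

    def __init__(
        self,
        children: Optional[list["Node"]] = None,
        label: Optional[str] = None,
        length: Optional[Decimal] = None,
    ) -> None:
        self.children: list[Node] = children if children is not None else []
        self.label = label
        self.length = length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = f"leaf {self.label!r}" if self.is_leaf else f"{len(self.children)} children"
        return f"<Node {kind} length={self.length}>"


class Phylotree:
    """A rooted tree with ordered children and optional branch lengths.

    The root carries no branch length; every other node either has one
    (weighted tree) or none (unweighted tree), never mixed.
    """

    __slots__ = ("root",)

    def __init__(self, root: Node) -> None:
        self.root = root
        self._validate()

    def _validate(self) -> None:
        if self.root.is_leaf:
            raise NewickError("a tree must have at least two leaves")
        if self.root.length is not None:
            raise NewickError("the root may not carry a branch length")
        labels: list[str] = []
        has_len = 0
        non_root = 0
        stack = [(self.root, True)]
        while stack:
            node, is_root = stack.pop()
            if not is_root:
                non_root += 1
                if node.length is not None:
                    has_len += 1
            if node.is_leaf:
                if node.label is None:
                    raise NewickError("leaf without a label")
                labels.append(node.label)
            else:
                if node.label is not None:
                    raise NewickError("internal node labels are not supported")
                if len(node.children) < 2:
                    raise NewickError("internal nodes must have at least two children")
                stack.extend((c, False) for c in node.children)
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise NewickError(f"duplicate leaf label(s): {', '.join(dupes)}")
        if has_len not in (0, non_root):
            raise NewickError("tree mixes weighted and unweighted branches")

    @property
    def weighted(self) -> bool:
        return self.root.children[0].length is not None

    def leaf_labels(self) -> list[str]:
        """Leaf labels in tree (left-to-right) order."""
        out: list[str] = []

        def walk(node: Node) -> None:
            if node.is_leaf:
                out.append(node.label)  # type: ignore[arg-type]
            else:
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    def taxa(self) -> "TaxaIndex":
        return TaxaIndex.from_names(self.leaf_labels())

    def copy(self) -> "Phylotree":
        return Phylotree(copy.deepcopy(self.root))


# ---------------------------------------------------------------------------
# parsing


def parse_newick(text: str) -> Phylotree:
    """Parse one ``;``-terminated Newick string into a :class:`Phylotree`.

    Child order is preserved exactly as written.  Labels are allowed on
    leaves only; branch lengths are decimal (scientific notation is
    accepted and converted); whitespace around punctuation is skipped.
    """
    s = text
    i = 0

    def skip_ws(j: int) -> int:
        while j < len(s) and s[j].isspace():
            j += 1
        return j

    def parse_node(j: int) -> tuple[Node, int]:
        j = skip_ws(j)
        if j >= len(s):
            raise NewickError("unexpected end of input (unbalanced parentheses?)")
        if s[j] == "(":
            j += 1
            children: list[Node] = []
            while True:
                child, j = parse_node(j)
                children.append(child)
                j = skip_ws(j)
                if j >= len(s):
                    raise NewickError("unbalanced parentheses")
                if s[j] == ",":
                    j += 1
                    continue
                if s[j] == ")":
                    j += 1
                    break
                raise NewickError(f"unexpected character {s[j]!r} at position {j}")
            node = Node(children=children)
            j = skip_ws(j)
            if j < len(s) and s[j] not in ":,();":
                raise NewickError("internal node labels are not supported")
        else:
            start = j
            while j < len(s) and not s[j].isspace() and s[j] not in ":,();":
                j += 1
            label = s[start:j]
            if not label:
                raise NewickError(f"expected a taxon label at position {start}")
            node = Node(label=label)
        j = skip_ws(j)
        if j < len(s) and s[j] == ":":
            j = skip_ws(j + 1)
            start = j
            while j < len(s) and s[j] in _NUMBER_CHARS:
                j += 1
            token = s[start:j]
            try:
                node.length = Decimal(token)
            except InvalidOperation:
                raise NewickError(f"branch length {token!r} is not a decimal number") from None
        return node, j

    root, i = parse_node(0)
    i = skip_ws(i)
    if i >= len(s) or s[i] != ";":
        raise NewickError("tree must be terminated by ';' (unbalanced parentheses?)")
    i = skip_ws(i + 1)
    if i != len(s):
        raise NewickError(f"unexpected trailing characters: {s[i:]!r}")
    return Phylotree(root)


def read_newick_file(source) -> tuple[list[Phylotree], TaxaIndex]:
    """Read a Newick collection, one tree per line.

    *source* is a text file object, an iterable of lines, or a whole-file
    string.  All trees must share one taxon set and be uniformly weighted
    or uniformly unweighted; the returned :class:`TaxaIndex` is the sorted
    taxon set.
    """
    if isinstance(source, str):
        lines: Iterable[str] = source.splitlines()
    else:
        lines = source
    trees: list[Phylotree] = []
    taxa_set: Optional[frozenset[str]] = None
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        try:
            tree = parse_newick(line)
        except NewickError as exc:
            raise NewickError(f"line {lineno}: {exc}") from None
        labels = frozenset(tree.leaf_labels())
        if taxa_set is None:
            taxa_set = labels
        elif labels != taxa_set:
            raise NewickError(
                f"line {lineno}: taxon set differs from the first tree "
                f"(extra: {sorted(labels - taxa_set)}, missing: {sorted(taxa_set - labels)})"
            )
        if trees and tree.weighted != trees[0].weighted:
            raise NewickError(f"line {lineno}: mixes weighted and unweighted trees")
        trees.append(tree)
    if not trees:
        raise NewickError("no trees found in input")
    return trees, TaxaIndex(tuple(sorted(taxa_set)))  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# writing


def _format_length(value: Decimal, mantissa_digits: Optional[int]) -> str:
    if mantissa_digits is not None:
        value = quantize_length(value, mantissa_digits)
    return format(value, "f")


def write_newick(
    tree: Phylotree,
    canonical: bool = False,
    include_lengths: bool = True,
    mantissa_digits: Optional[int] = None,
) -> str:
    """Serialize a tree to Newick.

    When *canonical* is true, children at every node are ordered by their
    lexicographically smallest descendant taxon, yielding one fixed
    representative of all equivalent strings; pass *mantissa_digits* to
    also fix the printed branch-length precision.
    """
    weighted = tree.weighted and include_lengths

    def render(node: Node) -> tuple[str, str]:
        # returns (newick fragment, smallest descendant taxon)
        if node.is_leaf:
            frag = node.label or ""
            key = node.label or ""
        else:
            parts = [render(c) for c in node.children]
            if canonical:
                parts.sort(key=lambda p: p[1])
            frag = "(" + ",".join(p[0] for p in parts) + ")"
            key = min(p[1] for p in parts)
        if weighted and node.length is not None:
            frag += ":" + _format_length(node.length, mantissa_digits)
        return frag, key

    return render(tree.root)[0] + ";"


def canonical_newick(tree: Phylotree, mantissa_digits: int = 6) -> str:
    """The canonical Newick representative (fixed-precision lengths)."""
    return write_newick(tree, canonical=True, mantissa_digits=mantissa_digits)


def canonical_topology_key(
    tree: Phylotree, with_weights: bool = True, mantissa_digits: int = 6
) -> str:
    """A string under which two trees compare equal iff they are the same
    tree (topology, plus branch lengths at mantissa precision when
    *with_weights* and the tree is weighted).

    Invariant under :func:`commute`; used for deduplication and as the
    oracle for set operations.
    """
    return write_newick(
        tree,
        canonical=True,
        include_lengths=with_weights,
        mantissa_digits=mantissa_digits,
    )


# ---------------------------------------------------------------------------
# commuting


def commute(tree: Phylotree, seed: int) -> Phylotree:
    """Return an equivalent tree with uniformly re-ordered children.

    Every internal node's child list receives an independent uniform
    random permutation drawn from a generator seeded with *seed*; the
    clade set and all branch lengths are unchanged.  Writing the result
    non-canonically yields a different-but-equivalent Newick string.
    """
    rng = random.Random(seed)
    out = tree.copy()

    def shuffle(node: Node) -> None:
        if not node.is_leaf:
            rng.shuffle(node.children)
            for c in node.children:
                shuffle(c)

    shuffle(out.root)
    return out
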