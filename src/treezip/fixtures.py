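"""Deterministic synthetic tree collections for tests and benchmarks.

Phylogenetic searches (Bayesian MCMC samples, parsimony result sets)
return thousands of trees that share most of their bipartitions and
often repeat whole topologies.  The generator emulates that regime:
tree 0 is random, each later tree is either an exact repeat of an
earlier tree or a copy perturbed by a small number of subtree-regraft
moves, so clade sharing stays high.  Everything is driven by one seed
and reproduces byte for byte.
"""

from __future__ import annotations

import copy
import math
import random
from dataclasses import dataclass
from decimal import Decimal

from .trees import Node, Phylotree, commute, parse_newick, write_newick

__all__ = ["CollectionSpec", "random_tree", "random_collection", "commuted_copy"]

_SEED_SPACE = 2**31


@dataclass(frozen=True)
class CollectionSpec:
    """Parameters of a synthetic collection.

    ``perturbation_rate`` is the expected number of subtree-regraft moves
    applied to a derived tree (Poisson-distributed); ``dup_rate`` the
    probability that a tree is an exact repeat of an earlier one;
    ``integral_rate`` the probability that a branch length exceeds 1.
    """

    n: int
    t: int
    perturbation_rate: float = 0.2
    dup_rate: float = 0.1
    weighted: bool = True
    integral_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need at least 3 taxa")
        if self.t < 1:
            raise ValueError("need at least one tree")
        for name in ("perturbation_rate", "dup_rate", "integral_rate"):
            value = getattr(self, name)
            if name == "perturbation_rate":
                if value < 0:
                    raise ValueError(f"{name} must be >= 0")
            elif not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def _taxon_names(n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"T{i:0{width}d}" for i in range(n)]


def random_tree(n: int, seed: int) -> Phylotree:
    """A rooted binary tree on taxa ``T000..`` by random sequential leaf
    attachment; deterministic per seed."""
    if n < 3:
        raise ValueError("need at least 3 taxa")
    rng = random.Random(seed)
    names = _taxon_names(n)
    order = list(range(n))
    rng.shuffle(order)
    root = Node(children=[Node(label=names[order[0]]), Node(label=names[order[1]])])
    for idx in order[2:]:
        # split the edge above a random non-root node
        candidates = _non_root_nodes_with_parents(root)
        target, parent = rng.choice(candidates)
        leaf = Node(label=names[idx])
        pair = [target, leaf]
        rng.shuffle(pair)
        joint = Node(children=pair)
        parent.children[parent.children.index(target)] = joint
    return Phylotree(root)


def _non_root_nodes_with_parents(root: Node) -> list[tuple[Node, Node]]:
    out: list[tuple[Node, Node]] = []
    stack = [root]
    while stack:
        node = stack.pop()
        for child in node.children:
            out.append((child, node))
            stack.append(child)
    return out


def _poisson(rng: random.Random, lam: float) -> int:
    if lam <= 0:
        return 0
    threshold = math.exp(-lam)
    count = 0
    p = 1.0
    while True:
        p *= rng.random()
        if p <= threshold:
            return count
        count += 1


def _regraft(root: Node, rng: random.Random) -> Node:
    """One subtree-prune-and-regraft move preserving rootedness.

    Detaches a random non-root subtree (collapsing the emptied parent)
    and re-attaches it by splitting a random remaining edge; the root is
    a valid attachment point, in which case a fresh root is created.
    """
    for _ in range(50):
        nodes = _non_root_nodes_with_parents(root)
        prune, parent = rng.choice(nodes)
        siblings = [c for c in parent.children if c is not prune]
        if parent is root and len(siblings) == 1 and siblings[0].is_leaf:
            continue  # would leave a bare-leaf root
        # detach
        if len(siblings) >= 2:
            parent.children = siblings
            new_root = root
        elif parent is root:
            new_root = siblings[0]
        else:
            grand = next(
                p for c, p in _non_root_nodes_with_parents(root) if c is parent
            )
            grand.children[grand.children.index(parent)] = siblings[0]
            new_root = root
        # regraft above a random node of the remaining tree (or the root)
        attach_points: list[tuple[Node, Node | None]] = [(new_root, None)]
        attach_points += _non_root_nodes_with_parents(new_root)
        target, tparent = rng.choice(attach_points)
        pair = [target, prune]
        rng.shuffle(pair)
        joint = Node(children=pair)
        if tparent is None:
            return joint
        tparent.children[tparent.children.index(target)] = joint
        return new_root
    return root


def _assign_weights(root: Node, rng: random.Random, integral_rate: float) -> None:
    stack = [(root, True)]
    while stack:
        node, is_root = stack.pop()
        if not is_root:
            mantissa = Decimal(rng.randrange(1, 10**6)).scaleb(-6)
            if integral_rate and rng.random() < integral_rate:
                mantissa += rng.randint(1, 3)
            node.length = mantissa
        stack.extend((c, False) for c in node.children)


def random_collection(spec: CollectionSpec) -> str:
    """Generate a Newick collection (one tree per line) from *spec*.

    Exact repeats reuse the earlier tree verbatim — weights included —
    so they deduplicate under compression even in weighted mode.
    """
    rng = random.Random(spec.seed)
    trees: list[Phylotree] = []
    first = random_tree(spec.n, rng.randrange(_SEED_SPACE))
    if spec.weighted:
        _assign_weights(first.root, rng, spec.integral_rate)
    trees.append(first)
    for _ in range(1, spec.t):
        source = trees[rng.randrange(len(trees))]
        if rng.random() < spec.dup_rate:
            trees.append(source.copy())
            continue
        root = copy.deepcopy(source.root)
        for _ in range(_poisson(rng, spec.perturbation_rate)):
            root = _regraft(root, rng)
        root.length = None  # a regraft can promote an edge to the root
        if spec.weighted:
            _assign_weights(root, rng, spec.integral_rate)
        trees.append(Phylotree(root))
    return "".join(write_newick(tr) + "\n" for tr in trees)


def commuted_copy(newick_text: str, p: float, seed: int) -> str:
    """Rewrite ``ceil(p * t / 100)`` randomly chosen trees of a Newick
    file with random equivalent child orderings.

    Every line's tree is unchanged semantically (identical canonical
    key); only the string representation of the chosen trees moves.
    """
    if not 0 <= p <= 100:
        raise ValueError("p must be a percentage in [0, 100]")
    rng = random.Random(seed)
    lines = [ln for ln in newick_text.splitlines() if ln.strip()]
    trees = [parse_newick(ln) for ln in lines]
    count = math.ceil(p * len(trees) / 100)
    chosen = set(rng.sample(range(len(trees)), count))
    out: list[str] = []
    for i, tree in enumerate(trees):
        if i in chosen:
            tree = commute(tree, rng.randrange(_SEED_SPACE))
        out.append(write_newick(tree))
    return "".join(ln + "\n" for ln in out)
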